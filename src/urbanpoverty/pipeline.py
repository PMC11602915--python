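"""End-to-end pipeline: scenario (or loaded surveys) -> poverty labels ->
measure selection -> city summaries, performance classes, context
correlations -> tidy output files plus a run manifest.

Every configurable decision (cut-offs, modes, thresholds) is captured in
``RunSettings`` and echoed into ``run_manifest.json``, so a run is fully
reproducible: the same manifest produces byte-identical output tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .absolute import DeprivationIndex, SlumClassifier, classify_below_poverty_line
from .dictionary import default_dictionary
from .errors import DegenerateDataError
from .evaluation import (
    agreement_by_city,
    agreement_medians,
    median_gap,
    poorest_group_sizes,
    select_preferred_measure,
    SelectionResult,
)
from .outcomes import outcome_table
from .performance import (
    PerformanceRule,
    context_correlations,
    export_tidy_outputs,
    group_prevalences,
    performance_table,
)
from .survey import CityContext, SurveyDataset, weighted_quantile_rank
from .synthetic import ScenarioConfig, generate_scenario
from .wealth import WealthSpec, compute_wealth_score, validate_against_provided

logger = logging.getLogger(__name__)

__all__ = ["RunSettings", "PipelineResult", "label_city", "run_pipeline", "run_from_manifest"]


@dataclass
class RunSettings:
    """Every switch of the analysis, with its default."""

    cutoffs: tuple[int, ...] = (30, 40, 50, 60)
    poverty_line_per_day: float = 1.9
    income_division: str = "household"          # or "percapita"
    consumption_correction: str = "share_ratio"  # or "hh_share_of_gdp"
    sds_threshold: float = 1.0 / 3.0
    low_education_mode: str = "household"
    school_age: tuple[int, int] = (6, 14)
    water_time_threshold_min: float = 30.0
    max_persons_per_room: float = 3.0
    min_poorest_n: float = 100.0
    agreement_threshold: float = 0.60
    agreement_weighted: bool = False
    provided_score_threshold: float = 0.95
    use_provided_score: bool = True
    prevalence_basis: str = "overall"
    rule: PerformanceRule = field(default_factory=PerformanceRule)

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["cutoffs"] = list(self.cutoffs)
        d["school_age"] = list(self.school_age)
        return d


@dataclass
class PipelineResult:
    labels_by_city: dict
    size_summary: pd.DataFrame
    agreements: pd.DataFrame
    group_prev_all_measures: pd.DataFrame
    gaps: pd.DataFrame
    selection: SelectionResult
    city_summaries: pd.DataFrame
    performance: pd.DataFrame
    correlations: pd.DataFrame
    wealth_validation: pd.DataFrame


def label_city(dataset: SurveyDataset, context: CityContext, settings: RunSettings,
               dictionary=None) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Compute the seven poverty labels and the five outcomes for one city.

    Returns ``(labels, outcomes, info)`` where labels columns are
    ``pline/sds/slum/w30..w60`` as 1/0/NaN floats and ``info`` records the
    wealth-score validation against the survey-provided score.
    """
    d = dictionary or default_dictionary()
    hh = dataset.households
    w = hh["weight"].to_numpy(float)

    computed = compute_wealth_score(dataset, WealthSpec(), d)
    info = {"city_id": dataset.city_id, "provided_score_used": False, "validation_r": np.nan}
    score = computed
    if settings.use_provided_score and "survey_wealth_score" in hh.columns:
        provided = pd.to_numeric(hh["survey_wealth_score"], errors="coerce")
        try:
            r = validate_against_provided(computed, provided)
        except DegenerateDataError:
            r = np.nan
        if not np.isnan(r) and r < 0:
            # opposite orientation: flip before comparing magnitude
            r = -r
            provided = -provided
        info["validation_r"] = r
        if not np.isnan(r) and r >= settings.provided_score_threshold:
            score = provided
            info["provided_score_used"] = True

    ranks = weighted_quantile_rank(score, w)

    missing_rank = np.isnan(ranks)
    labels = pd.DataFrame(index=hh.index)
    for c in settings.cutoffs:
        lab = (ranks <= c / 100.0).astype(float)
        lab[missing_rank] = np.nan
        labels[f"w{c}"] = lab

    poor_line = np.asarray(classify_below_poverty_line(
        ranks, hh["n_members"].to_numpy(float), context,
        settings.poverty_line_per_day, settings.income_division,
        settings.consumption_correction), dtype=float)
    poor_line[missing_rank] = np.nan
    labels["pline"] = poor_line

    sds = DeprivationIndex(threshold=settings.sds_threshold,
                           school_age=settings.school_age).score(hh, dataset.persons, d)
    labels["sds"] = sds["sds_deprived"]

    labels["slum"] = SlumClassifier(settings.max_persons_per_room,
                                    settings.water_time_threshold_min).predict(hh, d)

    outcomes = outcome_table(hh, dataset.persons, d, settings.school_age,
                             settings.low_education_mode, settings.water_time_threshold_min)
    return labels, outcomes, info


def run_pipeline(pairs: list[tuple[SurveyDataset, CityContext]],
                 settings: RunSettings | None = None,
                 outdir=None) -> PipelineResult:
    """Run the full analysis over ``(dataset, context)`` pairs.

    When ``outdir`` is given, writes the evaluation tables, decision record,
    city summaries, performance matrix, correlation table, tidy plot data
    and the run manifest there (all deterministic CSV/JSON bytes).
    """
    settings = settings or RunSettings()
    d = default_dictionary()

    labels_by_city, outcomes_by_city, weights_by_city = {}, {}, {}
    validations = []
    for dataset, context in pairs:
        labels, outcomes, info = label_city(dataset, context, settings, d)
        labels_by_city[dataset.city_id] = labels
        outcomes_by_city[dataset.city_id] = outcomes
        weights_by_city[dataset.city_id] = dataset.households["weight"].to_numpy(float)
        validations.append(info)
    validations = pd.DataFrame(validations)

    # criterion summaries over every measure
    size_summary = poorest_group_sizes(labels_by_city)
    agreements = agreement_by_city(labels_by_city, settings.agreement_weighted, weights_by_city)

    gp_rows = []
    for dataset, context in pairs:
        labels = labels_by_city[dataset.city_id]
        outcomes = outcomes_by_city[dataset.city_id]
        for m in labels.columns:
            gp = group_prevalences(dataset.households, labels[m], outcomes, dataset.city_id)
            gp.insert(1, "measure", m)
            gp_rows.append(gp)
    group_prev_all = pd.concat(gp_rows, ignore_index=True)
    gaps = median_gap(group_prev_all)

    selection = select_preferred_measure(
        size_summary, gaps, agreement_medians(agreements),
        settings.min_poorest_n, settings.agreement_threshold)

    chosen = selection.selected
    if chosen is None:
        logger.warning("no measure selected: %s", selection.reason)
        city_summaries = pd.DataFrame(columns=["city_id", "outcome"])
        perf = pd.DataFrame()
        corr = pd.DataFrame()
    else:
        city_summaries = group_prev_all[group_prev_all["measure"] == chosen].drop(columns="measure").reset_index(drop=True)
        perf = performance_table(city_summaries, settings.rule, settings.prevalence_basis)
        contexts_df = pd.DataFrame([c.to_dict() for _, c in pairs])
        corr = context_correlations(city_summaries, contexts_df)

    result = PipelineResult(labels_by_city, size_summary, agreements, group_prev_all,
                            gaps, selection, city_summaries, perf, corr, validations)
    if outdir is not None:
        _write_outputs(result, settings, Path(outdir))
    return result


def _write_outputs(result: PipelineResult, settings: RunSettings, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.size_summary.to_csv(outdir / "poorest_group_sizes.csv")
    result.agreements.sort_values(["relative", "absolute", "city_id"], kind="stable").to_csv(
        outdir / "agreement_by_city.csv", index=False)
    agreement_medians(result.agreements).to_csv(outdir / "agreement_medians.csv", index=False)
    result.gaps.to_csv(outdir / "median_gaps.csv", index=False)
    result.wealth_validation.to_csv(outdir / "wealth_validation.csv", index=False)

    rec = result.selection.decision_record.reset_index()
    record = {
        "selected": result.selection.selected,
        "reason": result.selection.reason,
        "parameters": result.selection.parameters,
        "criteria": json.loads(rec.to_json(orient="records")),
    }
    (outdir / "decision_record.json").write_text(json.dumps(record, indent=2, sort_keys=True))

    if result.selection.selected is not None:
        result.city_summaries.to_csv(outdir / "city_summaries.csv", index=False)
        export_tidy_outputs(result.city_summaries, result.correlations,
                            result.performance, outdir, rule=settings.rule)

    manifest = {"settings": settings.to_jsonable(), "selected_measure": result.selection.selected}
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def run_from_manifest(manifest_path, outdir=None) -> PipelineResult:
    """Re-run a scenario + analysis from a manifest produced by
    :func:`urbanpoverty.synthetic.write_scenario` (``config`` key) optionally
    merged with ``settings``."""
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    cfg_raw = manifest["config"]
    cfg_raw = dict(cfg_raw)
    cfg_raw["households_per_city"] = tuple(cfg_raw["households_per_city"])
    cfg_raw["asset_loadings"] = {k: tuple(v) for k, v in cfg_raw["asset_loadings"].items()}
    cfg_raw["roster_size_dist"] = {int(k): v for k, v in cfg_raw["roster_size_dist"].items()}
    cfg_raw["school_age"] = tuple(cfg_raw.get("school_age", (6, 14)))
    config = ScenarioConfig(**cfg_raw)
    settings_raw = manifest.get("settings") or {}
    settings = _settings_from_dict(settings_raw)
    pairs = generate_scenario(config)
    return run_pipeline(pairs, settings, outdir)


def _settings_from_dict(raw: dict) -> RunSettings:
    raw = dict(raw)
    rule_raw = raw.pop("rule", None)
    s = RunSettings(**{k: v for k, v in raw.items() if k in RunSettings.__dataclass_fields__})
    if isinstance(s.cutoffs, list):
        s.cutoffs = tuple(s.cutoffs)
    if isinstance(s.school_age, list):
        s.school_age = tuple(s.school_age)
    if rule_raw:
        s.rule = PerformanceRule(**rule_raw)
    return s
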