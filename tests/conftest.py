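import numpy as np
import pandas as pd
import pytest

from urbanpoverty import ScenarioConfig, generate_city, generate_context, generate_scenario


@pytest.fixture(scope="session")
def small_config():
    return ScenarioConfig(n_cities=4, households_per_city=(250, 500), seed=7)


@pytest.fixture(scope="session")
def small_scenario(small_config):
    return generate_scenario(small_config)


@pytest.fixture(scope="session")
def one_city(small_config):
    ds = generate_city(small_config, 0)
    ctx = generate_context(small_config, ds, 0)
    return ds, ctx


# ---------------------------------------------------------------------------
# independent brute-force oracles (plain loops, no package code)
# ---------------------------------------------------------------------------


def loop_weighted_prevalence(x, w, subset=None):
    num = den = 0.0
    for i in range(len(x)):
        if subset is not None and not subset[i]:
            continue
        if x[i] != x[i]:  # NaN
            continue
        num += w[i] * x[i]
        den += w[i]
    return num / den


def loop_midpoint_ranks(scores, weights):
    n = len(scores)
    total = sum(weights)
    ranks = []
    for i in range(n):
        below = sum(weights[j] for j in range(n) if scores[j] < scores[i])
        tied = sum(weights[j] for j in range(n) if scores[j] == scores[i])
        ranks.append((below + 0.5 * tied) / total)
    return ranks


def loop_agreement(a, b):
    num = den = 0
    for x, y in zip(a, b):
        if x != x or y != y:
            continue
        den += 1
        num += int(bool(x) == bool(y))
    return num / den
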