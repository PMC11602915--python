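# Versioned variable dictionary: canonical category codes and their
# improved/durable/clean groupings (WHO/UNICEF JMP-aligned ladders).
version: 1

assets:
  - radio
  - tv
  - fridge
  - phone
  - computer
  - bicycle
  - motorcycle
  - car

water_sources:
  improved:
    - piped_dwelling
    - piped_yard
    - public_tap
    - tubewell_borehole
    - protected_well
    - protected_spring
    - rainwater
  unimproved:
    - unprotected_well
    - unprotected_spring
    - surface_water
    - tanker_truck

# water sources assumed on premises (round-trip collection time zero)
water_on_premises:
  - piped_dwelling
  - piped_yard

sanitation:
  improved:
    - flush_to_sewer
    - flush_to_septic
    - flush_to_pit
    - vip_latrine
    - pit_latrine_with_slab
    - composting_toilet
  unimproved:
    - flush_elsewhere
    - pit_latrine_no_slab
    - bucket
    - hanging_toilet
  none:
    - no_facility

floor_materials:
  durable:
    - cement
    - tiles
    - vinyl
    - carpet
    - polished_wood
  non_durable:
    - earth_sand
    - dung
    - wood_planks
    - palm_bamboo

wall_materials:
  durable:
    - cement
    - bricks
    - stone_with_cement
    - covered_adobe
  non_durable:
    - mud
    - cane_palm
    - uncovered_adobe
    - plywood
    - cardboard
    - reused_wood

roof_materials:
  durable:
    - metal_sheet
    - cement
    - tiles
    - shingles
  non_durable:
    - thatch_palm
    - mud
    - plastic_sheet
    - cardboard
    - wood_planks

cooking_fuels:
  clean:
    - electricity
    - lpg
    - natural_gas
    - biogas
  unclean:
    - kerosene
    - charcoal
    - wood
    - dung
    - crop_residue
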