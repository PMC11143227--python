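"""Canonical names, orders and documented synthetic ranges.

Everything downstream (grids, models, attribution) relies on the fixed factor
order defined here; reordering it is an interface break.
"""

from __future__ import annotations

# The ten environmental factors, canonical order. Attribution tie-breaks and
# model feature order follow this tuple.
FACTORS: tuple[str, ...] = (
    "temperature",
    "salinity",
    "pco2",
    "mixed_layer_depth",
    "oxygen",
    "nitrate",
    "phosphate",
    "silicate",
    "carbonate",
    "iron",
)

FACTOR_UNITS: dict[str, str] = {
    "temperature": "degC",
    "salinity": "PSU",
    "pco2": "uatm",
    "mixed_layer_depth": "m",
    "oxygen": "umol kg-1",
    "nitrate": "umol kg-1",
    "phosphate": "umol kg-1",
    "silicate": "umol kg-1",
    "carbonate": "umol kg-1",
    "iron": "nmol kg-1",
}

# Documented synthetic ranges per factor (lo, hi). Synthetic fields live inside
# these; only relative structure matters for the recovery experiments, not
# oceanographic realism.
FACTOR_RANGES: dict[str, tuple[float, float]] = {
    "temperature": (-2.0, 30.0),
    "salinity": (30.0, 38.0),
    "pco2": (300.0, 1000.0),
    "mixed_layer_depth": (10.0, 300.0),
    "oxygen": (150.0, 400.0),
    "nitrate": (0.0, 35.0),
    "phosphate": (0.0, 2.5),
    "silicate": (0.0, 100.0),
    "carbonate": (50.0, 250.0),
    "iron": (0.0, 2.0),
}

# Nutrient grouping used for grouped driver-attribution shares.
NUTRIENT_FACTORS: tuple[str, ...] = (
    "nitrate",
    "phosphate",
    "silicate",
    "carbonate",
    "iron",
)

# Five dominant taxa of the surface-ocean community (>80% of reads).
DOMINANT_TAXA: tuple[str, ...] = (
    "Cyanobacteria",
    "Proteobacteria",
    "Bacteroidetes",
    "Ascomycota",
    "Firmicutes",
)

# 19 biogeochemical pathways across the four core element cycles.
# The default list is overridable through PipelineConfig.
PATHWAYS: tuple[str, ...] = (
    # photosynthesis
    "photosystem_I",
    "photosystem_II",
    "cytochrome_b6f",
    "ATP_synthase",
    "ferredoxin_NADP_reductase",
    # carbon fixation
    "calvin_cycle",
    "reductive_TCA",
    "wood_ljungdahl",
    "3HP_4HB",
    "pta_ack",
    # nitrogen metabolism
    "nitrogen_fixation",
    "nitrification",
    "assimilatory_nitrate_reduction",
    "dissimilatory_nitrate_reduction",
    "anammox",
    # sulfur metabolism
    "sulfur_oxidation",
    "assimilatory_sulfate_reduction",
    "dissimilatory_sulfate_reduction",
    "thiosulfate_oxidation_SOX",
)

ELEMENT_CYCLES: tuple[str, ...] = (
    "photosynthesis",
    "carbon fixation",
    "nitrogen metabolism",
    "sulfur metabolism",
)

PATHWAY_CYCLE: dict[str, str] = {
    p: ELEMENT_CYCLES[i // 5 if i < 15 else 3] for i, p in enumerate(PATHWAYS)
}

# The 26 microbial indices: 5 dominant taxa + richness + Shannon + 19 pathways.
INDEX_NAMES: tuple[str, ...] = DOMINANT_TAXA + ("richness", "shannon") + PATHWAYS

# The 25 status features exclude richness (no usable regression model for it).
STATUS_FEATURES: tuple[str, ...] = tuple(n for n in INDEX_NAMES if n != "richness")

assert len(INDEX_NAMES) == 26
assert len(STATUS_FEATURES) == 25
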