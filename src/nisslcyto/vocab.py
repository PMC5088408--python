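"""Controlled vocabulary for Nissl cytology.

Every feature a rater assesses on a Nissl-stained cell profile is a closed
categorical vocabulary.  Tokens are lowercase snake_case; free-text synonyms
encountered in data files are mapped through :data:`ALIASES` before
validation, so file I/O is bit-exact against these canonical spellings.

The heterochromatin terms follow the standard nuclear nomenclature:
*peripheral* heterochromatin sits under the nuclear envelope, the
*heterochromatin net* extends from the periphery into the nuclear interior,
and *perinucleolar* heterochromatin surrounds the nucleolus.
"""

from __future__ import annotations

NUCLEUS_STAIN = ("dark", "light")

NUCLEAR_SHAPE = (
    "round",
    "ovoid",
    "potato",  # ovoid with shallow concavities (typical astrocyte)
    "elongated",
    "comma",
    "polylobular",
    "molded_to_vessel",
)

CYTOPLASM_RIM = ("continuous_thick", "continuous_thin", "crescent", "not_visible")

HET_PERIPHERAL = (
    "not_visible",
    "few_granules",
    "rim_with_granules",
    "many_small_granules",
)

HET_NET = (
    "not_visible",
    "few_granules_variable_size",      # 1-2 granules of variable size
    "rounded_granules_one_larger",     # 2-4 rounded granules, one stands out
    "several_granules_same_size",
    "grid_many_small",                 # many small granules forming a grid
)

HET_PERINUCLEOLAR = (
    "none",
    "thin_granules",        # 0-4 small/thin granules
    "thick_clumps",         # 1-4 thick clumps, partially/totally around nucleolus
    "single_thick_granule",
)

NUCLEOLUS = ("prominent_large", "medium", "faint", "not_visible")

EUCHROMATIN = (
    "empty_unstained",
    "light_homogeneous",
    "light_watery",
    "dark_obscured",
)
EUCHROMATIN_LIGHT = ("empty_unstained", "light_homogeneous", "light_watery")

INCLUSIONS = ("none", "yellow", "greenish")

ACCESSORY_FLAGS = (
    "perinuclear_halo",
    "pinkish_crescent",
    "neuropil_threads",
    "molded_to_vessel",
    "satellite_to_neuron",
    "satellite_to_vessel",
)

SPECIES = ("monkey", "human")

FINE_LABELS = (
    "large_neuron",
    "small_neuron",
    "astrocyte",
    "oligodendrocyte",
    "microglia",
    "endothelial",
)

#: Canonical order of the five-way rating categories used in the rating tests
#: and throughout the reliability analysis.
RATING_LABELS = ("neuron", "astrocyte", "oligodendrocyte", "microglia", "endothelial")

#: Deterministic collapse of the six-way fine label onto the five rating
#: categories (large and small neurons are both rated "neuron").
RATING_OF_FINE = {
    "large_neuron": "neuron",
    "small_neuron": "neuron",
    "astrocyte": "astrocyte",
    "oligodendrocyte": "oligodendrocyte",
    "microglia": "microglia",
    "endothelial": "endothelial",
}

#: Vocabulary per profile field (excluding booleans, counts and flag sets).
FIELD_VOCAB = {
    "nucleus_stain": NUCLEUS_STAIN,
    "nuclear_shape": NUCLEAR_SHAPE,
    "cytoplasm_rim": CYTOPLASM_RIM,
    "het_peripheral": HET_PERIPHERAL,
    "het_net": HET_NET,
    "het_perinucleolar": HET_PERINUCLEOLAR,
    "nucleolus": NUCLEOLUS,
    "euchromatin_texture": EUCHROMATIN,
    "inclusions": INCLUSIONS,
    "species": SPECIES,
}

#: Free-text synonym table, applied per field after lowercasing and replacing
#: spaces/hyphens with underscores.  Closed: anything not canonical and not
#: listed here is a validation error.
ALIASES: dict[str, dict[str, str]] = {
    "nuclear_shape": {
        "ovoid_with_shallow_concavities": "potato",
        "potato_shaped": "potato",
        "comma_shaped": "comma",
        "oval": "ovoid",
    },
    "cytoplasm_rim": {
        "thick_rim": "continuous_thick",
        "thin_rim": "continuous_thin",
        "invisible": "not_visible",
    },
    "euchromatin_texture": {
        "empty": "empty_unstained",
        "not_stained": "empty_unstained",
        "homogeneous": "light_homogeneous",
        "light_blue": "light_homogeneous",
        "watery": "light_watery",
        "dark": "dark_obscured",
        "dark_blue": "dark_obscured",
        "obscured": "dark_obscured",
    },
    "het_peripheral": {
        "thin_rim": "rim_with_granules",
        "thick_rim": "rim_with_granules",
    },
    "het_perinucleolar": {
        "not_visible": "none",
    },
    "nucleolus": {
        "prominent": "prominent_large",
        "large": "prominent_large",
        "sometimes_visible": "faint",
        "invisible": "not_visible",
    },
    "inclusions": {
        "lipofuscin": "yellow",
        "yellowish": "yellow",
    },
}
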