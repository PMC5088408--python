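"""Synthetic cytological profiles and simulated rating experiments.

The generator draws labeled profiles feature-wise from per-type categorical
distributions whose modal values are the thick-section feature table's
typical entries; the residual probability mass covers the documented
variants (round microglia, light oligodendrocytes, small neurons with an
indiscernible rim, ...).  This models *biological* variability: every rater
sees the same, possibly atypical, ground-truth profile.

*Observer* noise is modeled per rater: each feature of the profile a rater
inspects is independently mis-seen with probability ``theta``, substituting
a value from a confusable-value map (e.g. homogeneous vs watery
euchromatin, a thin rim vs no rim, the one-larger-granule net vs the
small-granule grid).  Perturbed profiles are repaired so cross-field
invariants keep holding.  Section-level staining noise (typically dark
cells appearing light and vice versa) is shared by all raters and is part
of the generator's per-type outlier rates rather than the rater model.

The default experiment mirrors the published rating study: two tests of
236 and 114 cells, eight raters (three experienced at theta = 0.04, five
inexperienced at theta = 0.10), with one inexperienced rater missing from
the second test.  Each simulated rating is the five-way rating collapse of
the rule classifier applied to that rater's perturbed view of the cell.

Seeding: one master seed expands deterministically into per-stage and per
(unit, rater) child streams, so runs are exactly reproducible and the
observer-noise draws are shared across runs that differ only in ``theta``
(common random numbers).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import vocab
from .profiles import CytologicalProfile, PROTOTYPES
from .reliability import RatingsTable
from .rules import classify


class ConfigError(ValueError):
    """Invalid generator configuration (e.g. a distribution not summing to 1)."""


# -- per-type feature distributions ---------------------------------------

#: Default per-type distributions.  The key "euchromatin_light" is the
#: texture drawn when the sampled stain is light; a dark stain forces
#: dark_obscured.  "flags" draws one accessory-flag set.  Modal values carry
#: probability 0.8 (the microglia shape row spells out the documented
#: variant mix instead, and hard anatomical facts keep probability 1).
DEFAULT_DISTRIBUTIONS: dict[str, dict[str, dict]] = {
    "large_neuron": {
        "nucleus_stain": {"light": 1.0},
        "nuclear_shape": {"round": 0.8, "ovoid": 0.2},
        "cytoplasm_rim": {"continuous_thick": 0.8, "continuous_thin": 0.2},
        "envelope_folding": {False: 0.7, True: 0.3},
        "het_peripheral": {"not_visible": 0.8, "few_granules": 0.2},
        "het_net": {"not_visible": 0.8, "few_granules_variable_size": 0.2},
        "het_perinucleolar": {"thin_granules": 0.8, "none": 0.2},
        "nucleolus": {"prominent_large": 1.0},
        "nucleolus_count": {1: 0.9, 2: 0.1},
        "euchromatin_light": {"empty_unstained": 1.0},
        "inclusions": {"yellow": 0.8, "none": 0.2},
        "flags": {(): 0.9, ("satellite_to_neuron",): 0.1},
    },
    "small_neuron": {
        "nucleus_stain": {"light": 1.0},
        "nuclear_shape": {"round": 0.8, "ovoid": 0.2},
        # The rim of some small neurons is hard to discern (outlier rate).
        "cytoplasm_rim": {
            "continuous_thin": 0.8,
            "continuous_thick": 0.1,
            "not_visible": 0.1,
        },
        "envelope_folding": {False: 0.6, True: 0.4},
        "het_peripheral": {"few_granules": 0.8, "not_visible": 0.2},
        "het_net": {"few_granules_variable_size": 0.8, "not_visible": 0.2},
        "het_perinucleolar": {
            "thick_clumps": 0.8,
            "single_thick_granule": 0.1,
            "thin_granules": 0.1,
        },
        "nucleolus": {"medium": 0.8, "faint": 0.2},
        "nucleolus_count": {1: 1.0},
        "euchromatin_light": {"light_homogeneous": 0.95, "empty_unstained": 0.05},
        "inclusions": {"yellow": 0.6, "none": 0.4},
        "flags": {(): 1.0},
    },
    "astrocyte": {
        "nucleus_stain": {"light": 1.0},
        "nuclear_shape": {"potato": 0.8, "ovoid": 0.2},
        "cytoplasm_rim": {"not_visible": 0.9, "crescent": 0.1},
        "envelope_folding": {False: 1.0},
        "het_peripheral": {"rim_with_granules": 0.8, "few_granules": 0.2},
        "het_net": {
            "several_granules_same_size": 0.8,
            "few_granules_variable_size": 0.2,
        },
        "het_perinucleolar": {"thin_granules": 0.8, "none": 0.2},
        "nucleolus": {"faint": 0.8, "not_visible": 0.2},
        "nucleolus_count": {1: 1.0},
        "euchromatin_light": {"light_homogeneous": 0.9, "light_watery": 0.1},
        "inclusions": {"yellow": 0.7, "none": 0.3},
        "flags": {
            (): 0.6,
            ("satellite_to_neuron",): 0.2,
            ("neuropil_threads",): 0.2,
        },
    },
    "oligodendrocyte": {
        # Some oligodendrocytes (notably human) are lightly stained.
        "nucleus_stain": {"dark": 0.92, "light": 0.08},
        "nuclear_shape": {"round": 0.9, "ovoid": 0.1},
        "cytoplasm_rim": {"not_visible": 0.8, "crescent": 0.2},
        "envelope_folding": {False: 1.0},
        "het_peripheral": {"few_granules": 0.8, "not_visible": 0.2},
        "het_net": {
            "rounded_granules_one_larger": 0.8,
            "several_granules_same_size": 0.1,
            "few_granules_variable_size": 0.1,
        },
        "het_perinucleolar": {"single_thick_granule": 0.8, "thin_granules": 0.2},
        "nucleolus": {"faint": 0.5, "not_visible": 0.5},
        "nucleolus_count": {1: 1.0},
        "euchromatin_light": {"light_homogeneous": 1.0},
        "inclusions": {"none": 1.0},
        "flags": {
            ("perinuclear_halo",): 0.4,
            (): 0.3,
            ("pinkish_crescent",): 0.2,
            ("satellite_to_neuron",): 0.1,
        },
    },
    "microglia": {
        "nucleus_stain": {"dark": 0.92, "light": 0.08},
        # Documented variant mix: most irregular, some round/ovoid.
        "nuclear_shape": {
            "elongated": 0.35,
            "comma": 0.15,
            "polylobular": 0.15,
            "round": 0.2,
            "ovoid": 0.15,
        },
        "cytoplasm_rim": {"not_visible": 1.0},
        "envelope_folding": {False: 0.9, True: 0.1},
        "het_peripheral": {"many_small_granules": 0.85, "rim_with_granules": 0.15},
        "het_net": {"grid_many_small": 0.85, "several_granules_same_size": 0.15},
        "het_perinucleolar": {"thin_granules": 0.6, "none": 0.4},
        "nucleolus": {"not_visible": 0.8, "faint": 0.2},
        "nucleolus_count": {1: 1.0},
        "euchromatin_light": {"light_homogeneous": 1.0},
        "inclusions": {"greenish": 0.4, "none": 0.6},
        "flags": {(): 0.8, ("satellite_to_vessel",): 0.1, ("satellite_to_neuron",): 0.1},
    },
    "endothelial": {
        "nucleus_stain": {"light": 1.0},
        "nuclear_shape": {"molded_to_vessel": 0.8, "elongated": 0.1, "ovoid": 0.1},
        "cytoplasm_rim": {"not_visible": 1.0},
        "envelope_folding": {False: 1.0},
        "het_peripheral": {"rim_with_granules": 0.8, "few_granules": 0.2},
        "het_net": {
            "several_granules_same_size": 0.8,
            "rounded_granules_one_larger": 0.2,
        },
        "het_perinucleolar": {"none": 0.8, "thin_granules": 0.2},
        "nucleolus": {"faint": 0.5, "not_visible": 0.5},
        "nucleolus_count": {1: 1.0},
        "euchromatin_light": {"light_watery": 0.85, "light_homogeneous": 0.15},
        "inclusions": {"none": 1.0},
        "flags": {(): 1.0},
    },
}

_SAMPLED_FIELDS = (
    "nucleus_stain",
    "nuclear_shape",
    "cytoplasm_rim",
    "envelope_folding",
    "het_peripheral",
    "het_net",
    "het_perinucleolar",
    "nucleolus",
    "nucleolus_count",
    "euchromatin_light",
    "inclusions",
    "flags",
)


def _prototype_distributions() -> dict:
    """All probability mass on the per-type modal (prototype) value."""
    dists: dict[str, dict[str, dict]] = {}
    for fine, proto in PROTOTYPES.items():
        dists[fine] = {
            "nucleus_stain": {proto.nucleus_stain: 1.0},
            "nuclear_shape": {proto.nuclear_shape: 1.0},
            "cytoplasm_rim": {proto.cytoplasm_rim: 1.0},
            "envelope_folding": {proto.envelope_folding: 1.0},
            "het_peripheral": {proto.het_peripheral: 1.0},
            "het_net": {proto.het_net: 1.0},
            "het_perinucleolar": {proto.het_perinucleolar: 1.0},
            "nucleolus": {proto.nucleolus: 1.0},
            "nucleolus_count": {max(proto.nucleolus_count, 1): 1.0},
            "euchromatin_light": {
                (
                    proto.euchromatin_texture
                    if proto.euchromatin_texture != "dark_obscured"
                    else "light_homogeneous"
                ): 1.0
            },
            "inclusions": {proto.inclusions: 1.0},
            "flags": {tuple(sorted(proto.accessory_flags)): 1.0},
        }
    return dists


@dataclass
class ProfileGeneratorConfig:
    """Per-type feature distributions plus species metadata and seed policy."""

    distributions: dict = field(default_factory=lambda: DEFAULT_DISTRIBUTIONS)
    species: str = "monkey"

    def __post_init__(self) -> None:
        for fine, per_field in self.distributions.items():
            if fine not in vocab.FINE_LABELS:
                raise ConfigError(f"unknown cell type {fine!r}")
            for fname in _SAMPLED_FIELDS:
                if fname not in per_field:
                    raise ConfigError(f"{fine}: missing distribution for {fname!r}")
                dist = per_field[fname]
                total = float(sum(dist.values()))
                if abs(total - 1.0) > 1e-9:
                    raise ConfigError(
                        f"{fine}.{fname}: probabilities sum to {total}, not 1"
                    )
                if any(p < 0 for p in dist.values()):
                    raise ConfigError(f"{fine}.{fname}: negative probability")

    @classmethod
    def prototype_mode(cls, species: str = "monkey") -> "ProfileGeneratorConfig":
        """Degenerate config reproducing the six prototypes exactly."""
        return cls(distributions=_prototype_distributions(), species=species)


def _draw(dist: dict, rng: np.random.Generator):
    values = list(dist.keys())
    probs = np.fromiter(dist.values(), dtype=float)
    return values[int(rng.choice(len(values), p=probs / probs.sum()))]


def _repair(p: CytologicalProfile) -> CytologicalProfile:
    """Restore cross-field invariants after sampling or perturbation."""
    if p.nucleus_stain == "dark":
        p.euchromatin_texture = "dark_obscured"
    elif p.euchromatin_texture == "dark_obscured":
        # A light stain reveals euchromatin darker than an astrocyte's but
        # still homogeneous (the light-oligodendrocyte reading).
        p.euchromatin_texture = "light_homogeneous"
    if p.nucleolus == "not_visible":
        p.nucleolus_count = 0
    elif p.nucleolus_count == 0:
        p.nucleolus_count = 1
    if p.nuclear_shape == "molded_to_vessel":
        p.accessory_flags = p.accessory_flags | {"molded_to_vessel"}
    return p


def sample_profile(
    fine_label: str, config: ProfileGeneratorConfig, rng: np.random.Generator
) -> CytologicalProfile:
    per_field = config.distributions[fine_label]
    stain = _draw(per_field["nucleus_stain"], rng)
    eu_light = _draw(per_field["euchromatin_light"], rng)
    profile = CytologicalProfile(
        nucleus_stain=stain,
        nuclear_shape=_draw(per_field["nuclear_shape"], rng),
        cytoplasm_rim=_draw(per_field["cytoplasm_rim"], rng),
        envelope_folding=bool(_draw(per_field["envelope_folding"], rng)),
        het_peripheral=_draw(per_field["het_peripheral"], rng),
        het_net=_draw(per_field["het_net"], rng),
        het_perinucleolar=_draw(per_field["het_perinucleolar"], rng),
        nucleolus=_draw(per_field["nucleolus"], rng),
        nucleolus_count=int(_draw(per_field["nucleolus_count"], rng)),
        euchromatin_texture="dark_obscured" if stain == "dark" else eu_light,
        inclusions=_draw(per_field["inclusions"], rng),
        accessory_flags=frozenset(_draw(per_field["flags"], rng)),
        species=config.species,
    )
    return _repair(profile).validate()


def generate_profiles(
    config: ProfileGeneratorConfig,
    counts: dict[str, int],
    seed=None,
) -> list[tuple[str, CytologicalProfile]]:
    """Draw ``counts[fine_label]`` labeled profiles per type.

    Returns ``(fine_label, profile)`` pairs in a deterministic order under a
    fixed seed.
    """
    rng = np.random.default_rng(seed)
    out = []
    for fine in vocab.FINE_LABELS:
        k = int(counts.get(fine, 0))
        if k < 0:
            raise ConfigError(f"negative count for {fine!r}")
        for _ in range(k):
            out.append((fine, sample_profile(fine, config, rng)))
    return out


# -- rater model -----------------------------------------------------------

#: For each feature value, the values a rater may mis-see it as.  Pairs are
#: chosen from the documented ambiguities: thin rim vs no rim (small neuron
#: vs astrocyte), homogeneous vs watery euchromatin (astrocyte vs
#: endothelial), and the one-larger-granule net vs the small-granule grid
#: (oligodendrocyte vs microglia).  The overall dark/light stain level is
#: deliberately not in the per-rater map: abnormal staining is a property of
#: the section that every rater sees identically, so it lives in the
#: generator's outlier rates (light oligodendrocytes, light microglia), not
#: in observer noise.
DEFAULT_CONFUSABLE: dict[str, dict] = {
    "nucleus_stain": {"dark": (), "light": ()},
    "nuclear_shape": {
        "round": ("ovoid",),
        "ovoid": ("round", "potato"),
        "potato": ("ovoid",),
        "elongated": ("comma",),
        "comma": ("elongated",),
        "polylobular": ("elongated",),
        "molded_to_vessel": ("elongated",),
    },
    "cytoplasm_rim": {
        "continuous_thick": ("continuous_thin",),
        "continuous_thin": ("not_visible", "continuous_thick"),
        "crescent": ("not_visible",),
        "not_visible": ("continuous_thin", "crescent"),
    },
    "envelope_folding": {True: (False,), False: (True,)},
    "het_peripheral": {
        "not_visible": ("few_granules",),
        "few_granules": ("not_visible", "rim_with_granules"),
        "rim_with_granules": ("few_granules",),
        "many_small_granules": ("rim_with_granules",),
    },
    "het_net": {
        "not_visible": ("few_granules_variable_size",),
        "few_granules_variable_size": (
            "rounded_granules_one_larger",
            "several_granules_same_size",
        ),
        "rounded_granules_one_larger": (
            "grid_many_small",
            "few_granules_variable_size",
        ),
        "several_granules_same_size": (
            "few_granules_variable_size",
            "grid_many_small",
        ),
        "grid_many_small": (
            "rounded_granules_one_larger",
            "several_granules_same_size",
        ),
    },
    "het_perinucleolar": {
        "none": ("thin_granules",),
        "thin_granules": ("none", "thick_clumps"),
        "thick_clumps": ("thin_granules", "single_thick_granule"),
        "single_thick_granule": ("thick_clumps",),
    },
    "nucleolus": {
        "prominent_large": ("medium",),
        "medium": ("prominent_large", "faint"),
        "faint": ("medium", "not_visible"),
        "not_visible": ("faint",),
    },
    "euchromatin_texture": {
        "empty_unstained": ("light_homogeneous",),
        "light_homogeneous": ("empty_unstained", "light_watery"),
        "light_watery": ("light_homogeneous",),
        "dark_obscured": (),  # changes only through a stain flip + repair
    },
    "inclusions": {"none": (), "yellow": ("none",), "greenish": ("none",)},
}

_PERTURBED_FIELDS = (
    "nucleus_stain",
    "nuclear_shape",
    "cytoplasm_rim",
    "envelope_folding",
    "het_peripheral",
    "het_net",
    "het_perinucleolar",
    "nucleolus",
    "euchromatin_texture",
    "inclusions",
)


@dataclass
class RaterModel:
    """One simulated observer: id, experience tag and mis-seeing rate."""

    rater_id: str
    theta: float
    experience: str = "experienced"
    confusable: dict = field(default_factory=lambda: DEFAULT_CONFUSABLE)

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta < 1.0):
            raise ConfigError(f"theta must be in [0, 1), got {self.theta}")
        if self.experience not in ("experienced", "inexperienced"):
            raise ConfigError(f"unknown experience tag {self.experience!r}")


def perturb_profile(
    profile: CytologicalProfile, rater: RaterModel, rng: np.random.Generator
) -> CytologicalProfile:
    """One rater's noisy view of a profile.

    Every feature is independently mis-seen with probability ``theta``,
    substituting uniformly within its confusable set; cross-field invariants
    are then repaired.  The uniform decision and substitution draws are
    consumed for every feature regardless of ``theta``, so two runs that
    differ only in ``theta`` share their randomness (the flip sets are
    nested, which makes downstream agreement effectively monotone in theta).
    """
    perturbed = replace(profile)
    u = rng.random(len(_PERTURBED_FIELDS))
    r = rng.random(len(_PERTURBED_FIELDS))
    for i, fname in enumerate(_PERTURBED_FIELDS):
        if u[i] >= rater.theta:
            continue
        current = getattr(perturbed, fname)
        options = rater.confusable.get(fname, {}).get(current, ())
        if not options:
            continue
        setattr(perturbed, fname, options[int(r[i] * len(options)) % len(options)])
    return _repair(perturbed)


def default_raters(
    theta_experienced: float = 0.04, theta_inexperienced: float = 0.10
) -> list[RaterModel]:
    """The study panel: three experienced and five inexperienced raters."""
    raters = [
        RaterModel(f"E{i}", theta_experienced, "experienced") for i in (1, 2, 3)
    ]
    raters += [
        RaterModel(f"I{i}", theta_inexperienced, "inexperienced")
        for i in (1, 2, 3, 4, 5)
    ]
    return raters


# -- rating experiment design ---------------------------------------------


@dataclass(frozen=True)
class RatingDesign:
    """Which raters rate which test, and how many cells each test has."""

    tests: tuple  # of (test_id, n_units, tuple of rater ids)

    def __post_init__(self) -> None:
        if not self.tests:
            raise ConfigError("empty design")
        for _, n_units, rater_ids in self.tests:
            if n_units <= 0:
                raise ConfigError("each test needs at least one unit")
            if len(rater_ids) < 2:
                raise ConfigError("each test needs at least two raters")


def default_design(
    raters: list[RaterModel], n_test1: int = 236, n_test2: int = 114
) -> RatingDesign:
    """Two tests; the last inexperienced rater misses the second test."""
    all_ids = tuple(r.rater_id for r in raters)
    inexperienced = [r.rater_id for r in raters if r.experience == "inexperienced"]
    if inexperienced:
        absent = inexperienced[-1]
        second = tuple(rid for rid in all_ids if rid != absent)
    else:
        second = all_ids
    return RatingDesign(
        tests=(("test1", n_test1, all_ids), ("test2", n_test2, second))
    )


def _composition(n_units: int) -> dict[str, int]:
    """Uniform five-category composition; neurons split large/small."""
    base, rem = divmod(n_units, len(vocab.RATING_LABELS))
    per_rating = {
        cat: base + (1 if i < rem else 0)
        for i, cat in enumerate(vocab.RATING_LABELS)
    }
    counts = {}
    n_neuron = per_rating["neuron"]
    counts["large_neuron"] = n_neuron // 2
    counts["small_neuron"] = n_neuron - n_neuron // 2
    for cat in ("astrocyte", "oligodendrocyte", "microglia", "endothelial"):
        counts[cat] = per_rating[cat]
    return counts


@dataclass
class SimulationResult:
    profiles: list  # of (unit_id, fine_label, CytologicalProfile)
    truth: pd.Series  # unit_id -> true rating label
    ratings: RatingsTable


def simulate_ratings(
    profiles: list[tuple[str, str, CytologicalProfile]],
    raters: list[RaterModel],
    design: RatingDesign,
    unit_test: dict[str, str],
    seed: int = 0,
    tiebreak: bool = True,
) -> RatingsTable:
    """Apply every assigned rater to every unit of each test.

    ``profiles`` holds ``(unit_id, fine_label, profile)`` triples;
    ``unit_test`` assigns each unit to a test.  Each rating is the rating
    collapse of ``classify(perturb_profile(...))``.  Units a rater did not
    see are missing.
    """
    if len(raters) < 2:
        raise ConfigError("need at least two raters")
    rater_by_id = {r.rater_id: r for r in raters}
    raters_per_test = {tid: set(rids) for tid, _, rids in design.tests}
    columns = [r.rater_id for r in raters]
    rows = {}
    rater_index = {rid: j for j, rid in enumerate(columns)}
    for i, (unit_id, _, profile) in enumerate(profiles):
        test_id = unit_test[unit_id]
        row = {}
        for rid in columns:
            if rid not in raters_per_test.get(test_id, ()):  # absent rater
                continue
            rng = np.random.default_rng([seed, 7, i, rater_index[rid]])
            seen = perturb_profile(profile, rater_by_id[rid], rng)
            row[rid] = classify(seen, tiebreak=tiebreak).label.rating
        rows[unit_id] = row
    values = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    values = values.reindex(columns=columns)
    return RatingsTable(
        values=values,
        rater_experience={r.rater_id: r.experience for r in raters},
        unit_test=dict(unit_test),
    )


def simulate_study(
    seed: int,
    config: ProfileGeneratorConfig | None = None,
    raters: list[RaterModel] | None = None,
    design: RatingDesign | None = None,
    tiebreak: bool = True,
) -> SimulationResult:
    """Generate cells for the two-test design and simulate all ratings."""
    config = config or ProfileGeneratorConfig()
    raters = raters if raters is not None else default_raters()
    design = design or default_design(raters)

    profiles: list[tuple[str, str, CytologicalProfile]] = []
    unit_test: dict[str, str] = {}
    for t_idx, (test_id, n_units, _) in enumerate(design.tests):
        labeled = generate_profiles(
            config, _composition(n_units), seed=[seed, 5, t_idx]
        )
        rng_order = np.random.default_rng([seed, 6, t_idx])
        order = rng_order.permutation(len(labeled))
        for j, idx in enumerate(order):
            fine, prof = labeled[int(idx)]
            unit_id = f"T{t_idx + 1}-{j + 1:03d}"
            profiles.append((unit_id, fine, prof))
            unit_test[unit_id] = test_id

    ratings = simulate_ratings(
        profiles, raters, design, unit_test, seed=seed, tiebreak=tiebreak
    )
    truth = pd.Series(
        {uid: vocab.RATING_OF_FINE[fine] for uid, fine, _ in profiles},
        name="true_rating",
    )
    return SimulationResult(profiles=profiles, truth=truth, ratings=ratings)
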