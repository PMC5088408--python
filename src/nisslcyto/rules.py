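"""The four-question decision algorithm for cortical cell types.

The classifier walks a fixed question sequence over a cell's cytological
profile:

Q1  Is the nucleus darkly stained?  Dark nuclei belong to the
    oligodendrocyte/microglia group; an elongated, comma-shaped or
    polylobular dark nucleus is microglial outright.
Q2  (light nuclei) Is the nucleus surrounded by a continuous rim of
    cytoplasm?  If yes, the cell is a neuron.
Q3  What is the distribution of heterochromatin?  Separates microglia from
    oligodendrocytes in the dark group, large from small neurons in the
    neuron group, and routes rimless light nuclei toward
    astrocyte/endothelial (or rescues a small neuron whose rim was
    indiscernible but whose heterochromatin is central).
Q4  What is the staining status of the euchromatin?  Homogeneous means
    astrocyte, watery means endothelial.

The published question flow uses hedged language ("very likely ...");
here every branch is a hard rule and the residual ambiguous profiles are
routed through :func:`disambiguate`, which applies the documented pitfall
rules for the three confusable pairs and, when evidence stays balanced, a
deterministic accessory-evidence tie-break.  The result is a *total,
deterministic* function over valid profiles.

One rule extends the literal question list: a lightly stained nucleus with
no cytoplasmic rim whose heterochromatin forms the many-small-granule grid
is classified as microglia.  Human microglia are often lighter than monkey
microglia yet keep the grid, and the grid is exactly the feature that
separates microglia from endothelial cells; without this rule such cells
would fall into the astrocyte/endothelial branch.
"""

from __future__ import annotations

from dataclasses import dataclass

from .profiles import CytologicalProfile
from .vocab import FINE_LABELS, RATING_OF_FINE


class DisambiguationError(ValueError):
    """Raised for a candidate pair outside the supported pitfall pairs."""


@dataclass(frozen=True, slots=True)
class CellTypeLabel:
    """Six-way fine label together with its five-way rating collapse."""

    fine: str
    rating: str

    @classmethod
    def from_fine(cls, fine: str) -> "CellTypeLabel":
        return cls(fine=fine, rating=RATING_OF_FINE[fine])


@dataclass(frozen=True, slots=True)
class ClassificationResult:
    label: CellTypeLabel
    question_path: tuple[str, ...]
    supporting_features: tuple[str, ...]
    ambiguity: str  # "unambiguous" | "resolved_by_tiebreak" | "flagged"
    candidates: frozenset[str] = frozenset()


_CONTINUOUS_RIM = ("continuous_thick", "continuous_thin")
_IRREGULAR_DARK_SHAPES = ("elongated", "comma", "polylobular")
_OLIGO_NETS = ("rounded_granules_one_larger", "few_granules_variable_size")
_SPARSE_PERIPHERAL = ("not_visible", "few_granules")

#: Fixed fallback preference when accessory evidence stays balanced.  Encodes
#: astrocyte > small_neuron, oligodendrocyte > microglia and
#: astrocyte > endothelial for the three documented confusion pairs.
FALLBACK_ORDER = (
    "astrocyte",
    "oligodendrocyte",
    "small_neuron",
    "endothelial",
    "microglia",
    "large_neuron",
)


def _supporting_cues(profile: CytologicalProfile, label: str) -> tuple[str, ...]:
    """Accessory evidence present in the profile that favours ``label``."""
    flags = profile.accessory_flags
    cues: list[str] = []
    if label == "microglia":
        if profile.inclusions == "greenish":
            cues.append("greenish_inclusions")
    elif label == "oligodendrocyte":
        if "perinuclear_halo" in flags:
            cues.append("perinuclear_halo")
        if "pinkish_crescent" in flags:
            cues.append("pinkish_crescent")
    elif label == "astrocyte":
        if profile.inclusions == "yellow":
            cues.append("yellow_inclusions")
        if "neuropil_threads" in flags:
            cues.append("neuropil_threads")
    elif label == "endothelial":
        if "molded_to_vessel" in flags or profile.nuclear_shape == "molded_to_vessel":
            cues.append("molded_to_vessel")
    elif label == "small_neuron":
        if profile.envelope_folding:
            cues.append("envelope_folding")
    elif label == "large_neuron":
        if profile.nucleolus == "prominent_large":
            cues.append("prominent_nucleolus")
    return tuple(cues)


def _pitfall_decide(
    profile: CytologicalProfile, candidates: frozenset[str]
) -> str | None:
    """Apply the documented pitfall rule for a confusable pair.

    Returns the decided fine label, or ``None`` when the pitfall features do
    not settle the pair (balanced evidence).
    """
    if candidates == frozenset({"microglia", "oligodendrocyte"}):
        # Microglia: many small grains across the nucleus forming a grid.
        # Oligodendrocyte: one or two thicker grains stand out.
        if profile.het_net == "grid_many_small":
            return "microglia"
        if profile.het_net in _OLIGO_NETS:
            return "oligodendrocyte"
        if profile.het_peripheral == "many_small_granules":
            return "microglia"
        if profile.het_perinucleolar == "single_thick_granule":
            return "oligodendrocyte"
        return None
    if candidates == frozenset({"small_neuron", "astrocyte"}):
        # Heterochromatin in astrocytes is mostly peripheral (attached to the
        # rim); in small neurons it is mostly central (thick perinucleolar
        # clumps).  Nuclear envelope folding favours the neuron.
        central = profile.het_perinucleolar == "thick_clumps"
        peripheral = profile.het_peripheral == "rim_with_granules"
        if central and not peripheral:
            return "small_neuron"
        if peripheral and not central:
            return "astrocyte"
        if profile.envelope_folding:
            return "small_neuron"
        return None
    if candidates == frozenset({"astrocyte", "endothelial"}):
        # Q4: euchromatin texture.
        if profile.euchromatin_texture == "light_homogeneous":
            return "astrocyte"
        if profile.euchromatin_texture == "light_watery":
            return "endothelial"
        return None
    if candidates == frozenset({"large_neuron", "small_neuron"}):
        # Empty-looking euchromatin is the large-neuron hallmark.
        if profile.euchromatin_texture == "empty_unstained":
            return "large_neuron"
        return "small_neuron"
    raise DisambiguationError(f"unsupported candidate set: {sorted(candidates)}")


def _fallback(profile: CytologicalProfile, candidates: frozenset[str]) -> str:
    """Accessory-evidence count, then the fixed preference order."""
    scored = sorted(
        candidates,
        key=lambda lab: (-len(_supporting_cues(profile, lab)), FALLBACK_ORDER.index(lab)),
    )
    return scored[0]


SUPPORTED_PAIRS = (
    frozenset({"small_neuron", "astrocyte"}),
    frozenset({"microglia", "oligodendrocyte"}),
    frozenset({"astrocyte", "endothelial"}),
)


def disambiguate(profile: CytologicalProfile, candidates) -> CellTypeLabel:
    """Resolve one of the documented confusable pairs for a profile.

    ``candidates`` must be one of {small_neuron, astrocyte},
    {microglia, oligodendrocyte} or {astrocyte, endothelial}; anything else
    raises :class:`DisambiguationError`.
    """
    candidates = frozenset(candidates)
    if candidates not in SUPPORTED_PAIRS:
        raise DisambiguationError(
            f"unsupported candidate pair: {sorted(candidates)}"
        )
    label = _pitfall_decide(profile, candidates)
    if label is None:
        label = _fallback(profile, candidates)
    return CellTypeLabel.from_fine(label)


def _result(
    profile: CytologicalProfile,
    fine: str,
    path: list[str],
    ambiguity: str,
    candidates: frozenset[str] = frozenset(),
) -> ClassificationResult:
    return ClassificationResult(
        label=CellTypeLabel.from_fine(fine),
        question_path=tuple(path),
        supporting_features=_supporting_cues(profile, fine),
        ambiguity=ambiguity,
        candidates=candidates,
    )


def _resolve(
    profile: CytologicalProfile,
    candidates: frozenset[str],
    path: list[str],
    tiebreak: bool,
) -> ClassificationResult:
    decided = _pitfall_decide(profile, candidates)
    if decided is not None:
        return _result(profile, decided, path, "resolved_by_tiebreak", candidates)
    fine = _fallback(profile, candidates)
    ambiguity = "resolved_by_tiebreak" if tiebreak else "flagged"
    return _result(profile, fine, path, ambiguity, candidates)


def classify(
    profile: CytologicalProfile, tiebreak: bool = True
) -> ClassificationResult:
    """Classify a valid profile; total and deterministic.

    With ``tiebreak=False`` (interactive use) profiles whose evidence stays
    balanced after the pitfall rules are returned with ``ambiguity ==
    "flagged"`` (the label is still the deterministic fallback, so the
    mapping stays total); with ``tiebreak=True`` (simulation default) they
    are marked ``resolved_by_tiebreak``.
    """
    p = profile
    path = ["Q1"]

    if p.nucleus_stain == "dark":
        if p.nuclear_shape in _IRREGULAR_DARK_SHAPES:
            return _result(p, "microglia", path, "unambiguous")
        path.append("Q3")
        micro_ev = (
            p.het_net == "grid_many_small"
            or p.het_peripheral == "many_small_granules"
        )
        oligo_ev = (
            p.het_net in _OLIGO_NETS and p.het_peripheral in _SPARSE_PERIPHERAL
        )
        if micro_ev:
            return _result(p, "microglia", path, "unambiguous")
        if oligo_ev:
            return _result(p, "oligodendrocyte", path, "unambiguous")
        return _resolve(
            p, frozenset({"microglia", "oligodendrocyte"}), path, tiebreak
        )

    path.append("Q2")
    if p.cytoplasm_rim in _CONTINUOUS_RIM:
        path.append("Q3")
        large_ev = (
            p.euchromatin_texture == "empty_unstained"
            and p.het_perinucleolar in ("none", "thin_granules")
            and p.nucleolus == "prominent_large"
        )
        if large_ev:
            return _result(p, "large_neuron", path, "unambiguous")
        if p.het_perinucleolar == "thick_clumps":
            return _result(p, "small_neuron", path, "unambiguous")
        return _resolve(
            p, frozenset({"large_neuron", "small_neuron"}), path, tiebreak
        )

    path.append("Q3")
    if (
        p.het_net == "grid_many_small"
        or p.het_peripheral == "many_small_granules"
    ):
        # Light microglia: the heterochromatin grid persists even when the
        # overall stain is light (common in human tissue).
        return _result(p, "microglia", path, "unambiguous")

    astro_endo_ev = p.het_peripheral == "rim_with_granules"
    central_ev = p.het_perinucleolar == "thick_clumps" or p.envelope_folding

    if astro_endo_ev and not central_ev:
        path.append("Q4")
        if p.euchromatin_texture == "light_homogeneous":
            return _result(p, "astrocyte", path, "unambiguous")
        if p.euchromatin_texture == "light_watery":
            return _result(p, "endothelial", path, "unambiguous")
        return _resolve(
            p, frozenset({"astrocyte", "endothelial"}), path, tiebreak
        )

    if central_ev and not astro_endo_ev:
        # Indiscernible rim but central heterochromatin (or folding): the
        # pitfall rule for small neuron vs astrocyte points to the neuron.
        return _result(
            p,
            "small_neuron",
            path,
            "resolved_by_tiebreak",
            frozenset({"small_neuron", "astrocyte"}),
        )

    if central_ev and astro_endo_ev:
        return _resolve(
            p, frozenset({"small_neuron", "astrocyte"}), path, tiebreak
        )

    # Neither central heterochromatin nor a peripheral rim with granules:
    # fall through to the euchromatin question.
    path.append("Q4")
    if p.euchromatin_texture == "light_homogeneous":
        return _result(
            p,
            "astrocyte",
            path,
            "resolved_by_tiebreak",
            frozenset({"astrocyte", "endothelial"}),
        )
    if p.euchromatin_texture == "light_watery":
        return _result(
            p,
            "endothelial",
            path,
            "resolved_by_tiebreak",
            frozenset({"astrocyte", "endothelial"}),
        )
    return _resolve(p, frozenset({"astrocyte", "endothelial"}), path, tiebreak)
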