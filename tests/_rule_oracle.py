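"""Independent brute-force re-implementation of the decision rules.

Written as literal nested conditionals straight from the four-question
description and the pitfall rules, on purpose without any import from
``nisslcyto.rules``, so it can serve as a second opinion in
profile-by-profile equivalence tests.  It returns only the fine label (the
label is independent of the tie-break flag; only the ambiguity annotation
depends on it).
"""

OLIGO_NET_PATTERNS = ("rounded_granules_one_larger", "few_granules_variable_size")


def _astro_vs_endo_cues(p) -> str:
    astro = 0
    if p.inclusions == "yellow":
        astro += 1
    if "neuropil_threads" in p.accessory_flags:
        astro += 1
    endo = 0
    if "molded_to_vessel" in p.accessory_flags or p.nuclear_shape == "molded_to_vessel":
        endo += 1
    return "endothelial" if endo > astro else "astrocyte"


def oracle_fine_label(p) -> str:
    # ---- Question 1: darkly stained nucleus? ----
    if p.nucleus_stain == "dark":
        if p.nuclear_shape == "elongated":
            return "microglia"
        if p.nuclear_shape == "comma":
            return "microglia"
        if p.nuclear_shape == "polylobular":
            return "microglia"
        # round/ovoid dark nucleus: Question 3, heterochromatin distribution
        if p.het_net == "grid_many_small":
            return "microglia"
        if p.het_peripheral == "many_small_granules":
            return "microglia"
        if p.het_net in OLIGO_NET_PATTERNS and p.het_peripheral in (
            "not_visible",
            "few_granules",
        ):
            return "oligodendrocyte"
        # ambiguous: microglia-vs-oligodendrocyte pitfall
        if p.het_net in OLIGO_NET_PATTERNS:
            return "oligodendrocyte"
        if p.het_perinucleolar == "single_thick_granule":
            return "oligodendrocyte"
        micro_cues = 1 if p.inclusions == "greenish" else 0
        oligo_cues = 0
        if "perinuclear_halo" in p.accessory_flags:
            oligo_cues += 1
        if "pinkish_crescent" in p.accessory_flags:
            oligo_cues += 1
        if micro_cues > oligo_cues:
            return "microglia"
        return "oligodendrocyte"

    # ---- Question 2: continuous rim of cytoplasm? ----
    if p.cytoplasm_rim in ("continuous_thick", "continuous_thin"):
        # neuron; Question 3 separates large from small
        if (
            p.euchromatin_texture == "empty_unstained"
            and p.het_perinucleolar in ("none", "thin_granules")
            and p.nucleolus == "prominent_large"
        ):
            return "large_neuron"
        if p.het_perinucleolar == "thick_clumps":
            return "small_neuron"
        if p.euchromatin_texture == "empty_unstained":
            return "large_neuron"
        return "small_neuron"

    # ---- light nucleus, no continuous rim ----
    # light microglia keep the many-small-granule grid
    if p.het_net == "grid_many_small":
        return "microglia"
    if p.het_peripheral == "many_small_granules":
        return "microglia"

    peripheral_rim = p.het_peripheral == "rim_with_granules"
    central = p.het_perinucleolar == "thick_clumps" or p.envelope_folding

    if peripheral_rim and not central:
        # Question 4: euchromatin staining status
        if p.euchromatin_texture == "light_homogeneous":
            return "astrocyte"
        if p.euchromatin_texture == "light_watery":
            return "endothelial"
        return _astro_vs_endo_cues(p)

    if central and not peripheral_rim:
        return "small_neuron"

    if central and peripheral_rim:
        # small-neuron-vs-astrocyte pitfall with conflicting evidence
        if p.het_perinucleolar == "thick_clumps":
            if p.envelope_folding:
                return "small_neuron"
            return "astrocyte"  # balanced; fixed preference favours astrocyte
        # central only through folding while the peripheral rim carries
        # granules: the heterochromatin rule outranks the folding cue
        return "astrocyte"

    # neither central clumps nor a peripheral rim with granules
    if p.euchromatin_texture == "light_homogeneous":
        return "astrocyte"
    if p.euchromatin_texture == "light_watery":
        return "endothelial"
    return _astro_vs_endo_cues(p)
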