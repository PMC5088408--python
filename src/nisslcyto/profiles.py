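"""Cytological feature profiles: the symbolic record of one cell.

A :class:`CytologicalProfile` is what a rater can assess on a Nissl-stained
cell body under the optical microscope: overall nuclear staining intensity,
nuclear shape, the cytoplasmic rim, the three heterochromatin compartments
(peripheral, net, perinucleolar), the nucleolus, euchromatin texture, and a
handful of accessory cues (perinuclear halo, pinkish crescent, satellite
position, ...).  Profiles are purely symbolic; no pixel-level information is
represented.

Cross-field invariants
----------------------
* a darkly stained nucleus obscures the euchromatin
  (``nucleus_stain == "dark"  <=>  euchromatin_texture == "dark_obscured"``);
* an invisible nucleolus has count 0, a visible one counts 1 or 2;
* a nucleus molded to a vessel implies the ``molded_to_vessel`` accessory flag.

Pericytes sit inside the endothelial basal membrane and cannot be told apart
from endothelial cells in thick Nissl sections, so records carrying a
``context: within_basal_membrane`` marker are rejected at validation rather
than classified.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

from . import vocab


class ProfileError(ValueError):
    """Base class for profile validation failures."""


class UnknownTokenError(ProfileError):
    """A field carries a token outside its closed vocabulary."""

    def __init__(self, field_name: str, token: object) -> None:
        self.field_name = field_name
        self.token = token
        super().__init__(f"unknown token {token!r} for field {field_name!r}")


class ConsistencyError(ProfileError):
    """A cross-field invariant is violated."""


@dataclass(slots=True)
class CytologicalProfile:
    nucleus_stain: str
    nuclear_shape: str
    cytoplasm_rim: str
    envelope_folding: bool
    het_peripheral: str
    het_net: str
    het_perinucleolar: str
    nucleolus: str
    nucleolus_count: int
    euchromatin_texture: str
    inclusions: str = "none"
    accessory_flags: frozenset[str] = frozenset()
    species: str = "monkey"

    def validate(self) -> "CytologicalProfile":
        """Check vocabulary membership and all cross-field invariants.

        Returns ``self`` so it can be chained; raises
        :class:`UnknownTokenError` or :class:`ConsistencyError` otherwise.
        """
        for name, vocab_values in vocab.FIELD_VOCAB.items():
            value = getattr(self, name)
            if value not in vocab_values:
                raise UnknownTokenError(name, value)
        if not isinstance(self.envelope_folding, bool):
            raise UnknownTokenError("envelope_folding", self.envelope_folding)
        for flag in self.accessory_flags:
            if flag not in vocab.ACCESSORY_FLAGS:
                raise UnknownTokenError("accessory_flags", flag)

        if self.nucleus_stain == "dark":
            if self.euchromatin_texture != "dark_obscured":
                raise ConsistencyError(
                    "a darkly stained nucleus obscures the euchromatin; got "
                    f"euchromatin_texture={self.euchromatin_texture!r}"
                )
        elif self.euchromatin_texture == "dark_obscured":
            raise ConsistencyError(
                "a lightly stained nucleus cannot have dark_obscured euchromatin"
            )

        if self.nucleolus == "not_visible":
            if self.nucleolus_count != 0:
                raise ConsistencyError(
                    "nucleolus not_visible requires nucleolus_count = 0, got "
                    f"{self.nucleolus_count}"
                )
        elif self.nucleolus_count not in (1, 2):
            raise ConsistencyError(
                "a visible nucleolus requires nucleolus_count in {1, 2}, got "
                f"{self.nucleolus_count}"
            )

        if (
            self.nuclear_shape == "molded_to_vessel"
            and "molded_to_vessel" not in self.accessory_flags
        ):
            raise ConsistencyError(
                "nuclear_shape molded_to_vessel requires the molded_to_vessel "
                "accessory flag"
            )
        return self

    # -- record I/O --------------------------------------------------------

    def to_record(self) -> dict:
        """Flat record with accessory flags as a sorted ';'-joined string."""
        return {
            "nucleus_stain": self.nucleus_stain,
            "nuclear_shape": self.nuclear_shape,
            "cytoplasm_rim": self.cytoplasm_rim,
            "envelope_folding": self.envelope_folding,
            "het_peripheral": self.het_peripheral,
            "het_net": self.het_net,
            "het_perinucleolar": self.het_perinucleolar,
            "nucleolus": self.nucleolus,
            "nucleolus_count": self.nucleolus_count,
            "euchromatin_texture": self.euchromatin_texture,
            "inclusions": self.inclusions,
            "accessory_flags": ";".join(sorted(self.accessory_flags)),
            "species": self.species,
        }


REQUIRED_FIELDS = (
    "nucleus_stain",
    "nuclear_shape",
    "cytoplasm_rim",
    "envelope_folding",
    "het_peripheral",
    "het_net",
    "het_perinucleolar",
    "nucleolus",
    "nucleolus_count",
    "euchromatin_texture",
)

_TRUE_TOKENS = {"true", "1", "yes", "y", "t"}
_FALSE_TOKENS = {"false", "0", "no", "n", "f", ""}


def _canonical_token(field_name: str, raw: object) -> str:
    token = str(raw).strip().lower().replace(" ", "_").replace("-", "_")
    token = vocab.ALIASES.get(field_name, {}).get(token, token)
    allowed = vocab.FIELD_VOCAB.get(field_name)
    if allowed is not None and token not in allowed:
        raise UnknownTokenError(field_name, raw)
    return token


def _parse_bool(field_name: str, raw: object) -> bool:
    if isinstance(raw, bool):
        return raw
    token = str(raw).strip().lower()
    if token in _TRUE_TOKENS:
        return True
    if token in _FALSE_TOKENS:
        return False
    raise UnknownTokenError(field_name, raw)


def _parse_flags(raw: object) -> frozenset[str]:
    if raw is None:
        return frozenset()
    if isinstance(raw, (set, frozenset, list, tuple)):
        tokens = [str(t) for t in raw]
    else:
        tokens = [t for t in str(raw).replace(",", ";").split(";")]
    out = set()
    for t in tokens:
        t = t.strip().lower().replace(" ", "_").replace("-", "_")
        if not t:
            continue
        if t not in vocab.ACCESSORY_FLAGS:
            raise UnknownTokenError("accessory_flags", t)
        out.add(t)
    return frozenset(out)


def validate_profile(record: dict) -> CytologicalProfile:
    """Canonicalize a raw key/value record into a validated profile.

    Token spelling and case are normalized through the alias table; missing
    ``accessory_flags`` means the empty set.  Raises :class:`UnknownTokenError`
    naming the offending field and token, or :class:`ConsistencyError` for a
    violated cross-field invariant.
    """
    if str(record.get("context", "")).strip().lower().replace(" ", "_") == (
        "within_basal_membrane"
    ):
        raise ConsistencyError(
            "cell lies within the endothelial basal membrane (pericyte); "
            "pericytes cannot be distinguished in thick Nissl sections and "
            "are not a classifier output"
        )
    missing = [f for f in REQUIRED_FIELDS if f not in record or record[f] is None]
    if missing:
        raise ProfileError(f"record is missing required fields: {missing}")

    profile = CytologicalProfile(
        nucleus_stain=_canonical_token("nucleus_stain", record["nucleus_stain"]),
        nuclear_shape=_canonical_token("nuclear_shape", record["nuclear_shape"]),
        cytoplasm_rim=_canonical_token("cytoplasm_rim", record["cytoplasm_rim"]),
        envelope_folding=_parse_bool("envelope_folding", record["envelope_folding"]),
        het_peripheral=_canonical_token("het_peripheral", record["het_peripheral"]),
        het_net=_canonical_token("het_net", record["het_net"]),
        het_perinucleolar=_canonical_token(
            "het_perinucleolar", record["het_perinucleolar"]
        ),
        nucleolus=_canonical_token("nucleolus", record["nucleolus"]),
        nucleolus_count=int(record["nucleolus_count"]),
        euchromatin_texture=_canonical_token(
            "euchromatin_texture", record["euchromatin_texture"]
        ),
        inclusions=_canonical_token("inclusions", record.get("inclusions", "none")),
        accessory_flags=_parse_flags(record.get("accessory_flags")),
        species=_canonical_token("species", record.get("species", "monkey")),
    )
    return profile.validate()


# -- prototypes ------------------------------------------------------------

#: Modal per-type profiles transcribed from the thick-section feature table
#: (monkey/human thionin): one noise-free exemplar per fine cell type.
PROTOTYPES: dict[str, CytologicalProfile] = {
    "large_neuron": CytologicalProfile(
        nucleus_stain="light",
        nuclear_shape="round",
        cytoplasm_rim="continuous_thick",
        envelope_folding=False,
        het_peripheral="not_visible",
        het_net="not_visible",
        het_perinucleolar="thin_granules",
        nucleolus="prominent_large",
        nucleolus_count=1,
        euchromatin_texture="empty_unstained",
        inclusions="yellow",
    ),
    "small_neuron": CytologicalProfile(
        nucleus_stain="light",
        nuclear_shape="round",
        cytoplasm_rim="continuous_thin",
        envelope_folding=False,
        het_peripheral="few_granules",
        het_net="few_granules_variable_size",
        het_perinucleolar="thick_clumps",
        nucleolus="medium",
        nucleolus_count=1,
        euchromatin_texture="light_homogeneous",
        inclusions="yellow",
    ),
    "astrocyte": CytologicalProfile(
        nucleus_stain="light",
        nuclear_shape="potato",
        cytoplasm_rim="not_visible",
        envelope_folding=False,
        het_peripheral="rim_with_granules",
        het_net="several_granules_same_size",
        het_perinucleolar="thin_granules",
        nucleolus="faint",
        nucleolus_count=1,
        euchromatin_texture="light_homogeneous",
        inclusions="yellow",
    ),
    "oligodendrocyte": CytologicalProfile(
        nucleus_stain="dark",
        nuclear_shape="round",
        cytoplasm_rim="not_visible",
        envelope_folding=False,
        het_peripheral="few_granules",
        het_net="rounded_granules_one_larger",
        het_perinucleolar="single_thick_granule",
        nucleolus="faint",
        nucleolus_count=1,
        euchromatin_texture="dark_obscured",
        inclusions="none",
        accessory_flags=frozenset({"perinuclear_halo"}),
    ),
    "microglia": CytologicalProfile(
        nucleus_stain="dark",
        nuclear_shape="elongated",
        cytoplasm_rim="not_visible",
        envelope_folding=False,
        het_peripheral="many_small_granules",
        het_net="grid_many_small",
        het_perinucleolar="thin_granules",
        nucleolus="not_visible",
        nucleolus_count=0,
        euchromatin_texture="dark_obscured",
        inclusions="greenish",
    ),
    "endothelial": CytologicalProfile(
        nucleus_stain="light",
        nuclear_shape="molded_to_vessel",
        cytoplasm_rim="not_visible",
        envelope_folding=False,
        het_peripheral="rim_with_granules",
        het_net="several_granules_same_size",
        het_perinucleolar="none",
        nucleolus="faint",
        nucleolus_count=1,
        euchromatin_texture="light_watery",
        inclusions="none",
        accessory_flags=frozenset({"molded_to_vessel"}),
    ),
}


def prototype(fine_label: str) -> CytologicalProfile:
    """Return a fresh copy of the modal profile for a fine cell type."""
    return replace(PROTOTYPES[fine_label])


# -- exhaustive enumeration ------------------------------------------------

#: Accessory-flag sets spanning every flag the decision rules consult.
DEFAULT_ENUM_FLAGSETS = (
    frozenset(),
    frozenset({"perinuclear_halo"}),
    frozenset({"molded_to_vessel"}),
    frozenset({"satellite_to_neuron"}),
)


def enumerate_profiles(
    flag_sets=DEFAULT_ENUM_FLAGSETS,
    inclusions=vocab.INCLUSIONS,
    species=("monkey",),
):
    """Yield every valid profile of the decision-relevant feature space.

    The space is finite by construction.  Fields that provably never change
    the classification are held fixed or thinned: ``species`` is metadata,
    ``nucleolus_count`` is pinned to the value forced by nucleolus visibility,
    and accessory-flag sets range over the decision-relevant singletons.
    Every yielded profile satisfies all cross-field invariants.
    """
    stain_eu = [("dark", "dark_obscured")] + [
        ("light", eu) for eu in vocab.EUCHROMATIN_LIGHT
    ]
    for (stain, eu), shape, rim, folding, hp, hn, hpn, ncl, incl, flags, sp in (
        itertools.product(
            stain_eu,
            vocab.NUCLEAR_SHAPE,
            vocab.CYTOPLASM_RIM,
            (False, True),
            vocab.HET_PERIPHERAL,
            vocab.HET_NET,
            vocab.HET_PERINUCLEOLAR,
            vocab.NUCLEOLUS,
            inclusions,
            flag_sets,
            species,
        )
    ):
        if shape == "molded_to_vessel" and "molded_to_vessel" not in flags:
            continue
        yield CytologicalProfile(
            nucleus_stain=stain,
            nuclear_shape=shape,
            cytoplasm_rim=rim,
            envelope_folding=folding,
            het_peripheral=hp,
            het_net=hn,
            het_perinucleolar=hpn,
            nucleolus=ncl,
            nucleolus_count=0 if ncl == "not_visible" else 1,
            euchromatin_texture=eu,
            inclusions=incl,
            accessory_flags=flags,
            species=sp,
        )
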