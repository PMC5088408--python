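import numpy as np
import pandas as pd
import pytest
from hypothesis import strategies as st

from nisslcyto import vocab
from nisslcyto.profiles import CytologicalProfile
from nisslcyto.reliability import RatingsTable


@pytest.fixture
def two_rater_agree():
    """One unit, two raters, both 'neuron'."""
    return RatingsTable(
        pd.DataFrame({"A": ["neuron"], "B": ["neuron"]}, index=["c1"])
    )


@pytest.fixture
def two_rater_split():
    """One unit, rater A 'neuron', rater B 'astrocyte'."""
    return RatingsTable(
        pd.DataFrame({"A": ["neuron"], "B": ["astrocyte"]}, index=["c1"])
    )


def random_ratings_table(rng: np.random.Generator, with_missing: bool = True):
    """Small random ratings table, guaranteed >= 1 pairable unit and
    at least two categories in use (so alpha is defined)."""
    cats = list(vocab.RATING_LABELS)
    while True:
        n_units = int(rng.integers(4, 13))
        n_raters = int(rng.integers(2, 6))
        codes = rng.integers(0, len(cats), size=(n_units, n_raters))
        values = np.array(cats, dtype=object)[codes]
        if with_missing:
            mask = rng.random((n_units, n_raters)) < 0.25
            values = values.astype(object)
            values[mask] = np.nan
        df = pd.DataFrame(
            values,
            index=[f"u{i}" for i in range(n_units)],
            columns=[f"r{j}" for j in range(n_raters)],
        )
        counts = df.stack().value_counts()
        pairable = (df.notna().sum(axis=1) >= 2).sum()
        if pairable >= 2 and len(counts) >= 2:
            return df


@st.composite
def profiles(draw) -> CytologicalProfile:
    """Hypothesis strategy over valid cytological profiles."""
    stain = draw(st.sampled_from(vocab.NUCLEUS_STAIN))
    if stain == "dark":
        eu = "dark_obscured"
    else:
        eu = draw(st.sampled_from(vocab.EUCHROMATIN_LIGHT))
    nucleolus = draw(st.sampled_from(vocab.NUCLEOLUS))
    count = 0 if nucleolus == "not_visible" else draw(st.sampled_from([1, 2]))
    shape = draw(st.sampled_from(vocab.NUCLEAR_SHAPE))
    flags = draw(
        st.sets(st.sampled_from(vocab.ACCESSORY_FLAGS), max_size=3).map(frozenset)
    )
    if shape == "molded_to_vessel":
        flags = flags | {"molded_to_vessel"}
    return CytologicalProfile(
        nucleus_stain=stain,
        nuclear_shape=shape,
        cytoplasm_rim=draw(st.sampled_from(vocab.CYTOPLASM_RIM)),
        envelope_folding=draw(st.booleans()),
        het_peripheral=draw(st.sampled_from(vocab.HET_PERIPHERAL)),
        het_net=draw(st.sampled_from(vocab.HET_NET)),
        het_perinucleolar=draw(st.sampled_from(vocab.HET_PERINUCLEOLAR)),
        nucleolus=nucleolus,
        nucleolus_count=count,
        euchromatin_texture=eu,
        inclusions=draw(st.sampled_from(vocab.INCLUSIONS)),
        accessory_flags=flags,
        species=draw(st.sampled_from(vocab.SPECIES)),
    )
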