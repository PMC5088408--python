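# Methods

This note documents the models implemented in `nisslcyto`, the choices
made where the underlying procedure left the design open, and what the
test suite does and does not establish.

## 1. The feature model

A cell is represented symbolically by the features a rater can assess on
a Nissl-stained soma at the optical microscope: overall nuclear staining
intensity (dark/light), nuclear shape (round, ovoid, potato-shaped,
elongated, comma, polylobular, molded to a vessel), the cytoplasmic rim
(continuous thick/thin, crescent, not visible), envelope folding, the
three heterochromatin compartments — peripheral (under the envelope), net
(extending into the interior), perinucleolar — the nucleolus (prominent,
medium, faint, not visible; count 0–2), euchromatin texture (empty,
homogeneous, watery, dark-obscured), cytoplasmic inclusions
(yellow/greenish) and accessory context flags (perinuclear halo, pinkish
crescent, neuropil threads, molded to vessel, satellite positions).
Vocabularies are closed; free-text synonyms go through an explicit alias
table so file I/O is bit-exact.

Three cross-field invariants make the space coherent: a dark nucleus
obscures the euchromatin; nucleolus visibility fixes the admissible count;
a molded nuclear shape implies the molded accessory flag.  Records marked
as lying within the endothelial basal membrane (pericytes) are rejected at
validation: they cannot be told from endothelial cells in thick sections
and are deliberately not a classifier output.

## 2. The classifier

The four-question flow (stain → rim → heterochromatin → euchromatin) is
implemented as hard rules.  The source procedure hedges ("very likely
..."); determinism and totality are required for reproducible counts and
for simulation, so every profile not settled by a direct rule is routed
through the documented pitfall rules for the three confusable pairs, and,
if evidence remains balanced, through a deterministic tie-break:

1. prefer the candidate supported by more accessory cues (greenish
   inclusions → microglia; halo/pinkish crescent → oligodendrocyte;
   yellow inclusions/neuropil threads → astrocyte; molded shape or flag →
   endothelial; envelope folding → small neuron);
2. otherwise a fixed preference order (astrocyte > small neuron,
   oligodendrocyte > microglia, astrocyte > endothelial), mirroring which
   member of each confusable pair is the more numerous in cortex.

With `tiebreak=False` (interactive use) step 2 outcomes are labeled
`flagged` with their candidate set instead of silently resolved; the
label itself is unchanged, keeping the mapping total either way.

Two rules deserve explicit justification:

* **Dark + ovoid routes to the round/ovoid branch** — some microglia have
  round or ovoid nuclei, so shape alone cannot separate the dark group;
  the heterochromatin question does.
* **Light nucleus, no rim, grid heterochromatin → microglia.**  Human
  microglia are often less darkly stained than monkey microglia yet keep
  the many-small-granule grid, and the grid is exactly the feature that
  separates microglia from endothelial cells.  Without this rule, lightly
  stained microglia would be forced into the astrocyte/endothelial
  branch, which contradicts the description of both cell types.

The six-way fine label collapses deterministically onto the five rating
categories (large/small neuron → neuron).

Verification: the classifier is compared profile-by-profile against a
second, independently written nested-conditional implementation over an
exhaustively enumerated decision space of 768,000 valid profiles.  The
enumerated space holds decision-irrelevant dimensions fixed (species and
nucleolus count never enter any rule; accessory-flag sets range over the
decision-relevant singletons) — this is the package's operational
definition of "the enumerable profile space".  The six modal per-type
profiles transcribed from the thick-section feature table are classified
exactly and unambiguously.

## 3. Agreement statistics

The coincidence matrix counts *ordered* pairs of ratings per unit
(`Σ_u m_u(m_u−1)` pairs in total), so an agreeing pair contributes 2 to a
diagonal cell and a split contributes 1 to each symmetric off-diagonal
cell.  Missing ratings are handled by the pairable-values rule: a unit
enters with however many ratings it has, provided at least two; units
with fewer are excluded (and counted in a log line).  Nominal alpha is
computed from the raw pair counts,

    α = 1 − (n − 1)·Σ_{c≠k} o_ck / (n² − Σ_c n_c²),

equivalently `1 − D_o/D_e`.  Note this uses unnormalized pair counts
throughout, matching the pairwise-permutation description the statistics
are defined by here; treatments that divide each unit's pair counts by
`(m_u − 1)` differ for unbalanced designs in finite samples.  The nominal
difference function (0 if equal, 1 otherwise) is fixed: cell types are
unordered categories.  When all ratings fall in one category the expected
disagreement is zero and alpha is reported as undefined (an exception),
not as a number.

Percent agreement is computed per unordered rater pair over co-rated
units; the mean and the SEM *across rater pairs* are reported (the SEM of
a single pair is 0).  The disagreement ranking reports each unordered
off-diagonal pair with count `o_ck + o_kc`; `half_counts=True` divides by
two for the convention that quotes each unordered disagreement once.
Alpha is printed to two decimals in the CLI and at full precision in the
JSON report.

Verification: alpha is checked against an independently coded brute-force
pair-enumeration oracle (naive loops over ordered pairs; each rating
enters the chance pool with multiplicity `m_u − 1`) to 1e−10 on over one
hundred random tables with and without missing entries, plus closed-form
fixtures (a 2×2 coincidence matrix with α = 7/18) and invariance/
monotonicity properties (category relabeling; off-diagonal mass strictly
lowers alpha at fixed marginals).

## 4. The synthetic-data generator

`generate_profiles` draws each feature independently from per-type
categorical distributions and then repairs cross-field invariants.  The
defaults put probability 0.8 on the modal (prototype) value and spread
the rest over the documented variants; the qualitative frequency words of
the source tables ("most", "some", "rarely") are the only guidance
available, so the masses were fixed once at conventional readings (e.g.
"some" ≈ 0.1–0.2) and are fully config-exposed rather than hard-coded.
Three variant rates matter most downstream: microglia drawing round/ovoid
shapes (0.35 combined, via the documented shape mix elongated 0.35 /
comma 0.15 / polylobular 0.15 / round 0.20 / ovoid 0.15), lightly stained
oligodendrocytes and microglia (0.08 each), and small neurons whose rim
draws `not_visible` (0.10).  `prototype_mode` collapses every
distribution onto the modal value and reproduces the six prototypes
exactly.  The `species` field is metadata: it never changes decision
rules, only tags generated profiles (one algorithm serves both species).

### Noise model

Two noise sources are modeled in different places, deliberately:

* **Biological/section-level variability** lives in the generator: an
  atypical or abnormally stained cell looks atypical to *every* rater
  (light oligodendrocytes, round microglia, indiscernible rims).  This is
  why dark↔light stain flips are generator outlier rates rather than
  per-rater noise — staining level is a property of the section, seen
  identically by all observers.
* **Observer noise** lives in the rater model: with probability `theta`
  per feature, a rater independently mis-sees a value as one of its
  confusable alternatives (homogeneous↔watery euchromatin; thin
  rim↔no rim; the one-larger-granule net↔the small-granule grid; adjacent
  heterochromatin/nucleolus grades; shape neighbors).  Substitution is
  uniform within the confusable set and the perturbed profile is
  invariant-repaired (a stain change re-strata the euchromatin; a
  dark→light reveal maps to homogeneous texture, the light-oligodendrocyte
  reading, never to the endothelial watery signature).

Defaults: `theta = 0.04` for experienced raters, `0.10` for
inexperienced.  Under these defaults the simulated two-test experiment
yields group alphas of about 0.82 (all raters), 0.91 (experienced) and
0.78 (inexperienced) — a calibration into the reported 0.7–0.95 band of
group-level agreement, *not* a reproduction of any specific published
value, which would require the undeposited raw ratings.  Observer errors
are independent across features, raters and units; correlated
section-level noise is representable by moving mass in the generator
config instead.

### Experiment design and seeding

The default design mirrors the two-test structure: 236 cells rated by all
8 raters (3 experienced, 5 inexperienced), then 114 cells with one
inexperienced rater absent (recorded as missing ratings).  The true
cell-type composition of the tests is unknown, so the default composition
is uniform over the five rating categories, neurons split evenly between
large and small; it is configurable.  Each simulated rating is the rating
collapse of `classify(perturb_profile(cell, rater))` with tie-breaking
enabled.

One master seed expands into fixed-role child streams
(`[seed, 5, test]` for generation, `[seed, 6, test]` for shuffling,
`[seed, 7, unit, rater]` for observation).  Per-feature flip and
substitution draws are consumed whether or not a flip occurs, so runs
differing only in `theta` share randomness and their flip sets are
nested — this is why simulated alpha decreases essentially monotonically
in `theta` seed-by-seed, which the tests check on a grid
(0, 0.05, 0.1, 0.2, 0.4) at fixed seed.

### What the simulation does and does not show

Passing tests establish internal consistency: the statistics match their
definitions, the classifier matches its specification, noise degrades
agreement monotonically, and the confusion structure concentrates on the
documented ambiguous pairs (astrocyte–endothelial and neuron–astrocyte
rank at the top across seeds).  They do *not* establish that real raters
have feature-level error rates of 0.04/0.10, that real test sets were
uniformly composed, or that rater errors are independent — none of which
is knowable from the published summary statistics.  Simulated profiles
are feature-independent draws within type; real morphology is correlated
across features and continuous, so edge cases in tissue are harder than
their symbolic counterparts here.

## 5. Numerical and degenerate-input conventions

* Alpha with `n < 2` pairable pairs or no pairable unit: empty-data
  error; single-category data: undefined-alpha error.
* Ranking ties break by canonical category order (neuron, astrocyte,
  oligodendrocyte, microglia, endothelial); zero-count pairs are omitted.
* All file formats are plain text (CSV/JSON/YAML, UTF-8, LF); reports
  carry a `schema_version` field and serialize with sorted keys so
  equal-seed runs are byte-identical.
* Problem sizes in the test suite (exhaustive space of 768k profiles,
  100+ random tables for the oracle equivalence, 20 seeds × 350 cells for
  the confusion-structure check, 10,000 units for the chance-level alpha
  endpoint) were chosen to make the checks sharp at desk scale.

## 6. Known limitations

* The headline reliability values of the motivating study are not
  recomputable from public information (no deposited ratings; the
  published coincidence matrix omits six off-diagonal cells); the package
  therefore validates the *method* by construction and calibrates the
  simulator only to the reported band.
* The classifier follows the thick-section feature table where it and the
  semithin table disagree in detail (e.g. microglial nucleolus
  visibility); the semithin variant is representable through generator
  priors only.
* Pericytes are excluded by design; "uncertain rim" handling (routing
  through the pitfall rules) is this package's reading of the procedure,
  not an explicit instruction of the source.
* No bootstrap confidence intervals for alpha and no ordinal/interval
  difference functions: the rating categories are nominal and the
  reference analysis reports point estimates only.
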