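# Methods

This note records the models, conventions, defaults and numerical choices
behind `gcannotate`, and what the synthetic validation does and does not
demonstrate.

## Formula algebra

Element masses and isotope abundances are embedded as static IUPAC/NIST
values for eleven elements (C, H, N, O, S, P, F, Cl, Br, I, Si), chosen to
cover the analyte classes common in environmental GC work (PAHs, PCBs,
organophosphate esters, halogenated flame retardants, siloxanes). The
alphabet is configurable per call. Monoisotopic masses use the lightest
isotope; fragment cations are modeled as subformula mass minus one electron
mass (5.486 × 10⁻⁴ Da).

Subformula enumeration is a depth-first search over the parent's
Hill-sorted element counts with mass-bound pruning; the order is
lexicographic and therefore deterministic. Mass decomposition brute-forces
this enumeration inside the ppm window and sorts by absolute mass error
(ties by Hill string). No ring-double-bond-equivalent or valence filtering
is applied; callers can post-filter.

Isotope patterns are built by iterative convolution of per-element isotope
distributions, dropping intermediate terms below 10⁻¹² (probability mass
conservation holds to better than 10⁻⁶), aggregating peaks within a
10⁻⁴ Da merge window, then pruning below the requested fraction of the base
peak. Kendrick mass uses round-to-nearest nominal masses by default; the
floor convention, also common in the literature, is selectable.

## Spectral matching

Similarity is 1000 × cosine of weighted intensity vectors `mz^a · I^b`
(defaults a = 0, b = 0.5 — square-root intensity weighting, the common
convention for EI library search on the 0–1000 scale on which the 600/500
cutoffs are defined). Peak pairing is greedy nearest-m/z, one-to-one, ties
broken toward the higher summed intensity and then the lower m/z, so
results are fully deterministic. Unit-resolution mode bins m/z to the
nearest integer (bin width configurable); accurate mode pairs within a ppm
tolerance (default 10 ppm). Plain cosine, not the squared NIST match
factor, is used; the exponent convention is configurable through the
weighting object.

The reverse score recomputes the cosine after discarding query peaks
unmatched to the library, so `reverse ≥ forward` holds for every input
pair. With no matched peaks the reverse score is 0; a spectrum whose
weighted vector is all-zero raises an error rather than returning 0.

## HRMF / RHRMF

The high-resolution mass filter is the percentage of peaks whose accurate
m/z lies within tolerance (default 10 ppm) of any subformula cation mass of
the candidate formula. A hydrogen-transfer allowance (default ±1 H, to
admit the rearrangements common in EI) keeps the fragment's hydrogen count
within the parent's bounds; note that with exhaustive subformula
enumeration any such H-shifted composition is itself a subformula, so the
allowance changes nothing here — it is implemented literally so the
contract survives any future restriction of the enumerated set. The
reverse variant scores only the query peaks matched to library peaks and
reports "unavailable" (not 0) when nothing matches. Both scores are
monotone non-decreasing in the tolerance.

## Retention indices

Retention indices use van den Dool & Kratz linear interpolation between
bracketing n-alkane anchors (100 units per carbon). Extrapolation beyond
the calibration span is disabled by default and flagged when enabled,
because non-linear temperature programs make extrapolated indices
unreliable. RI agreement is strict: experimental library RIs must satisfy
|ΔRI| < 50 *and* |ΔRI| < 1.5 % of the library RI; predicted RIs must
satisfy |ΔRI| < 100.

## Blank feature filtering

`threshold = c · (blank mean + 3 · blank SD)` with c = 3 by default (the
midpoint of common practice, 2–10). The SD is the sample standard
deviation (ddof = 1; 0 for a single blank). Missing blank measurements are
treated as 0 — conservative toward retaining features. The sample
statistic is the mean by default; a percentile is available but no default
percentile is claimed. Fewer than four blanks triggers a warning, not an
error. The comparison is strictly greater-than, so a feature exactly at
the threshold fails. Note that the threshold is not monotone in a *single*
blank abundance (raising one low blank can shrink the SD); it is monotone
under uniform changes to the blank set, which is what the property tests
assert.

## Level assignment

Levels 2 and 3 are assigned per candidate from the evidence layers; the
soft-ionization path (PCI/ECNI/APCI with ≥ 5 library-matched fragments)
substitutes for the EI dot-product conditions. Whether the exact-mass
condition also binds on the soft-ionization path is genuinely ambiguous in
the framework's bullet lists; it is required by default and relaxable via
`ScoringConfig.ci_requires_exact_mass`. The "both spectral thresholds"
reading (RSI > 600 **and** SI > 500) is applied on the main path of levels
2 and 3. Requiring the molecular ion is off by default — it removes the
most candidates but at a steep false-negative cost — and can be switched
on per run for stable classes such as PAHs.

Level 1 is evaluated only when in-house standards are provided. Reference
ion ratios are taken relative to the most intense reference peak (the
ratio base is not otherwise pinned down; this choice is documented
behavior). Levels 4A–C are computed as flags alongside 2/3 and never
suppress them, since the sublevels are not ordered by confidence. Level 4A
requires a designated precursor peak; candidates must match the predicted
isotopologue envelope (peaks ≥ 5 % of base, absolute relative-abundance
tolerance 0.10) and explain all dominant fragments (≥ 10 % of base) as
subformula cations, and exactly one formula must survive. Level 4B groups
features by Kendrick mass defect (tolerance 0.002 Da), integer repeat
spacing (0.005 Da) and RI-vs-repeat linearity (R² ≥ 0.99, at least three
members).

Ranking within a level is by descending RSI (a weighted-sum scorer is
pluggable); the top hit is *preferred* only when a dominance margin over
the runner-up holds (evidence count ≥ 10×, |ΔRI| better by ≥ 30, RSI by
≥ 50, RHRMF by ≥ 10), otherwise the feature is flagged multi-hit.
Deduplication keeps the best assignment per identifier, falling back to
case/whitespace-normalized names; name collisions across distinct
identifiers are kept but logged for review. Equality of close isomers
cannot be derived from names, so validation uses explicit equivalence
groups from the truth sheet.

## Validation metrics

A false positive at level L is a truth-sheet feature whose top-ranked
candidate at L is wrong; the denominator is all features assigned L
(features absent from the truth sheet cannot be judged and enter the
denominator only). A false negative is a detected truth compound that does
not receive level L. Equivalence mode treats a candidate within the truth
compound's isomer group as correct and can only lower the FP rate.

Percent-filtered summaries average per-compound percentages with equal
weights and report the sample SD; pooled aggregation over summed counts is
available because published tables round inconsistently between the two
conventions. Display rounding is half-up to integer percent; raw values
are retained.

## Synthetic data: what it shows and what it does not

The generator emulates a spike-recovery study. Compound formulas are drawn
over {C, H, N, O, Cl}; every spectrum's fragment m/z values are exact
subformula cation masses, so a library entry self-matches at 1000 with
HRMF 100, and retention follows a monotone affine mass→RI model mapped
onto a C8–C32 alkane calibration (1 min per carbon). Defaults: 120 library
compounds, 50 spikes, 50 decoys, 10 contaminants, 6 samples, 4 blanks,
1 % multiplicative intensity noise, 0.005 min RT jitter, one seeded random
stream per run with the seed recorded in every output header. Decoys are
built by perturbing real entries (30 % peak dropout, intensity jitter) and
placing them 300 RI units away from their source compound, mimicking the
structurally-similar-isomer failure mode; contaminants carry comparable
sample and blank abundances so they must fail the blank gate.

Passing these tests shows the pipeline's logic is correct under its own
assumptions — it does not show field performance. Real EI fragmentation,
chromatographic peak shape, co-elution, deconvolution errors, library
incompleteness and matrix effects are all absent, so real-data FP/FN rates
will be substantially worse than the synthetic 0 %. The bundled
19-standard air-monitoring candidate-count table provides a real-data
anchor for the metrics arithmetic only.

## Problem sizes and determinism

The test suite and the acceptance script use the 110-feature synthetic
study (50 + 50 + 10) and the 19-row validation table; both complete in
seconds on one core. Identical inputs and configuration produce
byte-identical result tables; all randomness flows from a single
`numpy.random.default_rng` seed.

## Known limitations

- No in-silico EI spectrum prediction; predicted spectra are accepted only
  as library input.
- No mzML/vendor-raw parsing or deconvolution — features enter
  post-deconvolution via CSV.
- No QC-pool variability or calibration-curve linearity filtering; blank
  feature filtering is the only background gate.
- Trap-instrument gas-phase reaction products can defeat RHRMF; no model
  for this edge case.
- Metadata evidence counts are consumed as numbers; no external database
  retrieval is performed.
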