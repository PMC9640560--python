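# Methods

## Harmonization

Predictor outputs are mapped onto a four-value canonical scale
(`NEUTRAL < DELETERIOUS < STRONGLY_DELETERIOUS`, plus `UNKNOWN` outside the
order). Verbal labels are matched case- and whitespace-insensitively against
a shared vocabulary: damaging-family labels (Deleterious, Disease, Effect,
Probably/Possibly damaging, Mutation Assessor's High *and* Medium,
Destabilising/Destabilizing, Decrease, and the single-letter code D) map to
`DELETERIOUS`; benign-family labels (Neutral, Probably benign, Tolerated,
Low, Increase/Stabilizing, N) to `NEUTRAL`; "Strongly Decrease" (SD) to
`STRONGLY_DELETERIOUS`. Anything else becomes `UNKNOWN` with a logged
warning — an exotic label must not abort a screen. Mapping "Possibly
damaging" and "Medium" into the damaging family is required for the bundled
reference tables to be internally consistent (several tabulated survivors
carry only those grades from PolyPhen-2/Mutation Assessor).

Numeric rules mirror the verbal tiers for the tools that publish thresholds:

| tool | deleterious | strongly deleterious | unit |
|---|---|---|---|
| PoPMuSiC | score > 0 | score ≥ 4.0 | ΔΔG, kcal/mol |
| HoTMuSiC | score < 0 | score ≤ −10.0 | ΔTm, °C |
| SNPMuSiC | score > 0 | score ≥ 1.0 | — |
| CScape, CScape-somatic | score > 0.5 | — | p-score in [0,1] |

The published phrasing "close to or greater/lesser than" is implemented as an
inclusive comparison at exactly the stated cutoff: a fuzzy tolerance would be
an undocumented free parameter, whereas the cutoffs themselves are exposed in
the YAML config for anyone who wants a different reading. Deleterious cutoffs
are exclusive (0.5 itself is not oncogenic), strong cutoffs inclusive, which
guarantees the severity order: any score that qualifies as strong also
crosses the deleterious cutoff. Non-finite scores map to `UNKNOWN`.

## The two-stage screen

Stage 1 counts calls at `DELETERIOUS` or stronger over the 12-tool sequence
panel and passes a variant at ≥ 9 votes; stage 2 counts over the 8-tool
structure panel with threshold 6. `UNKNOWN` counts as a vote against (the
denominator stays the panel size): a tool that could not be run provides no
evidence of harm. The single exception is a structure panel that is entirely
`UNKNOWN` — for TPMT this is the initiator variant M1V, whose residue is
absent from the crystal structure (residues 1–16 unresolved) — which marks
the variant *non-evaluable* so benchmark denominators can exclude it rather
than score it as a miss.

The MuSiC-family tools are the only panel members with a strong-call tier, and
the screen uses it asymmetrically by design. Discovery mode (STRICT) demands
"Strongly Decrease" from them, because discovery hunts the *most* deleterious
variants among hundreds; benchmark mode (LENIENT) accepts plain "Decrease",
because re-detection asks only whether known-deleterious variants are flagged
at all. STRICT pass sets are provably subsets of LENIENT pass sets (tested as
a property). Sub-method outputs (I-Mutant/MUpro SVM vs NN, mCSM/SDM/DUET
components) are collapsed to one call per tool — the panel is defined as
eight tools, not eleven columns — and the extra components ride along as
non-voting `aux_*` columns.

The novelty filter subtracts variants already experimentally established
(default: Y240S) from the stage-2 pass set. Matching ignores dbSNP
identifiers — two records of the same substitution are the same variant.

The screen is evaluated lazily in discovery mode (structure tools consulted
only for stage-1 survivors, which is also how the bundled tables are shaped:
structural calls exist only for the six variants that ultimately passed) and
exhaustively in benchmark mode, where cumulative 20-tool tallies per variant
are wanted.

## Benchmarking

Gold-standard entries carry per-study severity reports (VD = very dangerous,
D = dangerous). `very_dangerous` means ≥ 1 VD report. The
`extremely_deleterious` subset is the high-confidence tier — VD in several
studies, or VD with corroborating further reports; because part of that
corroboration lives outside the evidence table itself (Y240S's additional
literature), membership ships as an explicit boolean column in the fixture
rather than being derived at runtime. A derivation rule (≥ 2 VD, or ≥ 1 VD
plus ≥ 2 further reports) is applied only when the column is absent, and
recovers 11 of the 12 flagged members. Percentages are rounded half-up to two
decimals; denominators exclude non-evaluable variants, and an empty class
yields an explicitly undefined percentage instead of a division error.

Three published cumulative-count entries in the benchmark table (A167G,
Y240C, Y240S) disagree with their own published per-tool calls by one; the
fixture transcribes the calls verbatim and keeps the published totals as
`printed_total` metadata, and the tests compare recomputed tallies against
the printed column only where the source is internally consistent.

## Relative scoring

Eight categories feed the final ranking: SQBT and SRBT (sequence/structure
vote counts, strict MuSiC counting for SRBT), CONSERVATION (ConSurf colour
score 1–9 + species conserving the residue in a 10-sequence alignment + count
among the 13 most dissimilar homologues, summed unweighted), ONCOGENIC
(CScape + CScape-somatic p-scores, summed), BPI (absolute binding-pocket
volume change, Å³, summed over affected pockets), AFR_DIST and PTM_DIST
(residue distances to the nearest amyloid-forming region / PTM site), and MDS
(change in MM-PBSA binding free energy, kJ/mol).

`HIGHER_WORSE` categories score `100·x/max(x)`; proximity categories invert:
`100 − 100·d/max(d)`, since closeness to a functional feature is what makes a
substitution dangerous. Consequences worth knowing: ties at the maximum all
score 100; a proximity category only contains an exact 100 when some mutation
sits at distance 0; scores are scale-invariant within a category; and raw
values must be non-negative — which the raw MM-PBSA binding energies are not,
so the MDS category consumes `ΔG_mutant − ΔG_wild-type` (re-baselined so that
weaker binding scores worse) rather than the raw negative energies, for which
normalize-by-max is ill-defined. `Total` sums the per-category relative
scores and is normalized the same way; distances are computed on inclusive
residue intervals with 0 inside a region.

Feature provenance: vote counts, oncogenic sums, binding-energy deltas and
amyloid distances are recomputed at run time from the bundled call/score
tables; conservation components, pocket-volume changes and PTM distances are
fixture inputs, and the entries not fixed by published text (CDD counts,
pocket volumes, two of the five PTM distances) are clearly labelled synthetic
stand-ins chosen once to satisfy every published qualitative constraint
(file `supplementary_synthetic_features.tsv`). The resulting ranking
W33G > W150G > V89E > L182P > W78R is therefore exact for the recomputed
categories and conditional on those stand-ins for the rest.

## Synthetic panels and vote analytics

The generator draws, per variant, a latent truth label
`Bernoulli(prevalence)`; label tools then emit a deleterious call with
probability `se_t` (truth = 1) or `1 − sp_t` (truth = 0), and score tools
draw from a truth-conditional Gaussian that is fed through the real
harmonization thresholds. Defaults: 12 + 5 label tools at `se = sp = 0.9`,
prevalence 0.3, and MuSiC Gaussians placed so a truly deleterious variant is
usually destabilizing but only sometimes *strongly* so
(PoPMuSiC N(3, 1.5²) vs N(−0.5, 1²); HoTMuSiC N(−8, 3²) vs N(0.5, 1²);
SNPMuSiC N(0.8, 0.5²) vs N(−0.3, 0.4²)) — mirroring the strong tier's role
as a high-specificity filter. Missing cells are injected uniformly at a
configured rate; a missing cell never votes, so analytic call probabilities
are scaled by the observation rate. A one-factor Gaussian-copula knob
(`correlation`) induces positive dependence between tools for robustness
studies; all closed-form operating points assume `correlation = 0`.
Reproducibility is defined by the config seed: same seed, byte-identical
tables.

The exact pass probability of a stage is the Poisson-binomial tail over the
per-tool call probabilities (strong-call probabilities substituted for the
MuSiC tools in strict mode), computed by an O(n²) dynamic program over the
count distribution — scipy ships no Poisson-binomial distribution, and at
panel sizes of 8–12 the DP is exact and instant. It is validated against
exhaustive 2ⁿ enumeration as a property test. Under conditional independence
the two stages are independent given the truth label, so the full screen's
sensitivity is the product of the stage operating points; the test suite and
the acceptance script check a 20,000-variant simulation against this value at
a 3-standard-error tolerance (at the defaults the analytic sensitivity is
≈ 0.43, dominated by the strict MuSiC stage).

What the simulation does *not* emulate: real predictor correlations (tools
share training data and features, so real panels are more dependent than the
copula default), per-variant difficulty structure, and any specific tool's
score distribution beyond two Gaussian components. Passing synthetic tests
therefore demonstrates the pipeline's correctness under its own model
assumptions, not the real-world accuracy of the published panel — that is
what the gold-standard re-detection benchmark is for.

## Numerical and I/O choices

Percentages round half-up (76.470…% → 76.47) via decimal arithmetic, not
banker's rounding. Table cells equal to `NA`, `-` or empty (configurable) are
missing; a trailing `*` on an NA token is tolerated (footnote markers in
transcribed tables). Typographic minus signs (U+2212, en-dash) are normalized
before numeric parsing. Wide vs long table layout is auto-detected from the
header; unknown tool columns are reported and skipped; conflicting duplicate
(variant, tool) cells are an error, identical duplicates are de-duplicated.
Reports are TSV/CSV with a JSON summary sidecar, floats at two decimals by
default.

## Problem sizes

The bundled analysis is small (53 + 6 + 25 variants across ≤ 20 tools) and
runs in well under a second. The Monte-Carlo check of the vote analytics uses
20,000 variants × 20 tools, the size at which a 3-SE band is tight enough
(≈ ±0.02 in sensitivity) to catch real calibration errors; it completes in a
few seconds.

## Known limitations

* External predictors are never executed; all raw calls/scores are trusted
  transcribed inputs, including their (three) internal inconsistencies.
* The extremely-deleterious class is fixture-defined; the fallback derivation
  rule is a documented approximation.
* Five feature values in the relative-scoring fixture are synthetic
  stand-ins (see above); rankings driven primarily by those categories should
  not be over-interpreted.
* The analytic two-stage factorization requires conditional independence;
  with the correlation knob engaged, only simulation gives the operating
  point.
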