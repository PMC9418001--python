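# Methods

This note documents the models, conventions and numerical choices behind
`pyrodom`, what the synthetic generator does and does not emulate, and the
known limitations.

## Scope and shape

The package is organized as a transformation pipeline (peak processing →
formula assignment → descriptors → Kendrick analysis) with a model-style
statistical layer on top: `SeverityComparison` is constructed from a presence
matrix and a per-formula metrics table, and `fit()` returns a
`SeverityComparisonResults` object carrying estimates, tests and a
`summary()` view. The transformation stages are deterministic functions, so
they are not forced into a fit/results mold; the comparison layer, which does
estimate and test quantities, is.

## Ion convention and constants

Only singly charged, deprotonated ions ([M−H]⁻, negative electrospray) are
supported: neutral mass = m/z + 1.00727646 Da. Monoisotopic element masses
are CODATA/IUPAC values (C 12 exactly, H 1.00782503, N 14.00307401,
O 15.99491462, P 30.97376163, S 31.97207117). The first isotopologue spacing
is ¹³C−¹²C = 1.0033548 Da. Electron mass is ignored; at 0.5 ppm on a
200–900 Da window this convention is self-consistent because the generator
and the assigner share it.

## Peak processing

- **m/z window**: closed interval [200, 900]. The boundary semantics are a
  package convention (the window is usually quoted without them).
- **Isotopologue removal**: peak P is dropped iff some peak Q exists with
  |mz_P − 1.0033548 − mz_Q| ≤ tol·mz_P (tol default 1 ppm) and
  intensity_Q > intensity_P. Decisions are evaluated simultaneously against
  the input list, which makes the operation idempotent: a surviving peak can
  only lose potential parents on a re-run, never gain one.
- **Internal recalibration**: the ppm error is modelled as a + b·m/z, fitted
  by least squares over anchor peaks and inverted
  (mz/(1 + ppm(mz)·10⁻⁶)). Anchors are auto-detected as peaks with a
  *unique* candidate formula at 1 ppm that belong to CH₂ homologous ladders
  (same O/N/S/P, constant H − 2C, ≥ 3 distinct carbon numbers) among the 400
  most intense peaks; fewer than 5 anchors yields an identity model with a
  warning. A linear model captures constant plus mass-proportional
  miscalibration — the two components a direct-infusion FTICR drift
  typically shows — and its recovery is testable: injected (a, b) drift is
  recovered to < 0.05 ppm residual RMS at zero random error.
- **Alignment**: peaks from all samples are pooled, sorted by (m/z,
  sample id), and clustered greedily — a new cluster starts when the next
  peak deviates more than 0.5 ppm from the running cluster mean. Greedy
  consensus was chosen over single-linkage because it is O(n log n) and
  order-deterministic; on inputs whose clusters are separated by more than
  the tolerance the two coincide (tested against a brute-force
  transitive-closure oracle), and on pathological drifting chains greedy
  *splits* once the chain leaves the consensus window rather than chaining
  indefinitely, which is the behaviour we want at 0.5 ppm. One peak per
  sample per cluster; displaced duplicates are logged as unresolved.
  Consensus m/z is the unweighted mean of member m/z.

Every input peak ends in exactly one bucket — kept, window-filtered,
isotopologue-removed, or alignment-unresolved — and the pipeline manifest
checks this identity on every run.

## Formula assignment

Candidates are enumerated exhaustively inside element bounds (defaults
C 1–100, H 1–200, O 0–60, N 0–5, S 0–2, P 0–2 — conventional DOM windows)
by looping over the (N, S, P, O) grid and solving for (C, H) by
residual-mass bounding: at a sub-ppm tolerance at most one hydrogen count
can match for a given carbon count, so no hydrogen loop is needed. The
enumeration is verified against an unpruned full-grid oracle in the test
suite. Validity rules: H/C ∈ [0.2, 3.0], O/C ∈ [0, 1.5], RDBE =
C − H/2 + N/2 + P/2 + 1 ≥ 0 and integer (the even-electron condition for
neutral molecules). The tolerance is strict (|error| < 0.5 ppm).

Ranking is deterministic: smallest |ppm error|, then fewest heteroatoms
(N+S+P), then Hill string. Strict mode refuses clusters whose top two
candidates differ by < 0.05 ppm (`ambiguous_if_strict`); otherwise the top
candidate is taken. Unassigned clusters carry a reason code. Ambiguity
(n_candidates > 1) grows steeply with mass; `ambiguity_by_mass_bin` reports
it per mass bin, and assignment accuracy claims in the tests are therefore
restricted to clusters whose oracle candidate is unique.

## Descriptors

- **NOSC**: default is the standard form
  4 − (4C + H − 3N − 2O + 5P − 2S − z)/C with z = 0 for neutral formulas.
  An `as_printed` variant, 4 − (5C + H − 3N − 2O − 2S)/C, reproduces a
  typeset corruption that circulates in the literature; for P = 0, z = 0 it
  equals standard − 1 exactly, which the tests assert as an identity so the
  two readings can never be silently conflated.
- **AI**: default is the standard Koch–Dittmar index; `modified` discounts
  oxygen by half in numerator and denominator; `as_printed` is 4 − standard
  (same typographic issue). Non-positive numerator or denominator floors the
  index at 0 rather than returning an undefined value — the floor is the
  common convention and keeps per-sample means well defined.
- **Van Krevelen classes** are half-open H/C × O/C rectangles loaded from
  `data/vk_classes.yaml` (lipid, protein, amino sugar, carbohydrate,
  unsaturated hydrocarbon, lignin, tannin, condensed aromatic, fallback
  `other`). Boundaries differ between studies, so they are configuration
  data; the shipped table uses widely used DOM rectangles, must be
  non-overlapping (tested), and tiles the plane together with the fallback.

## Kendrick analysis

KM = M × 50/base_exact with the C₄H₂ base unit. `base_exact` defaults to
the chemical monoisotopic mass 50.01565 Da; the 50.0587 value printed in
parts of the pyrogenic-DOM literature is available as
`C4H2_MASS_PRINTED`, but it does not keep KMD constant along true C₄H₂
series (the defect drifts ~0.027 per unit), so it is not the default.
The transform runs on ion m/z by default (the measured quantity), with a
neutral-mass mode for chemistry-clean tests.

Two NKM conventions exist because they trade faithfulness against
exactness: `"mass"` (default) rounds the original mass to the nearest
integer; `"kendrick"` rounds KM instead. Only the latter makes KMD exactly
invariant under adding k C₄H₂ units — rounding M can cross a half-integer
boundary since the exact unit mass exceeds 50 by 0.0157 Da — so the exact
invariance property is stated and tested in `"kendrick"` mode.

Series detection groups records by KMD within a tolerance (default 0.001;
measured masses never give exactly equal defects) using a greedy pass over
sorted KMDs with recursive splitting at the largest gap, then splits each
group by NKM residue class modulo 50 and keeps groups of ≥ 2. On
well-separated instances this equals the brute-force transitive closure
(tested). A series is "present" in a condition when *any* member formula
was detected there (union semantics; an every-member mode exists), and
retained when its presence covers the required condition set — by default
all four severities.

## Severity comparison

Downstream comparisons are presence-based (a formula is detected in a
sample or not); intensities are carried through the pipeline but only used
optionally as weights. Per-sample aromaticity is summarized as the
unweighted mean AI over that sample's detected formulas. Pairwise tests
are one-sided Welch t-tests oriented by the severity order (control < low
< moderate < high; H1: more severe ⇒ higher AI), Holm-adjusted across
pairs; a pooled-variance mode is available. Unique formulas of a group are
those detected in ≥ 1 of its samples and in no sample of any other group —
the sets are disjoint by construction. NOSC of unique formulas is
summarized by medians and kernel-free histogram densities, with the same
Welch/Holm machinery. Welch was preferred because per-condition sample
sizes and variances are small and unequal; the choice of adjustment (Holm)
is the standard default of pairwise-test routines.

## Synthetic generator

The generator emulates what the analysis assumes about negative-mode DOM
spectra, with every draw a pure function of (design, seed) via
`SeedSequence([seed, stream])` per stage:

- **Formula pools.** Each condition's pool is a shared core plus a
  condition-unique stratum; all formulas pass the assignment validity rules
  with neutral masses in [205, 895] Da (a strict subset of the window so
  that deprotonated ions never straddle the 200 Da edge). Formulas are
  sampled as homologous families — CH₂ ladders in the aliphatic stratum,
  C₄H₂ ladders in the aromatic (AI ≥ 0.5) stratum — because natural DOM is
  series-rich and the recalibration and Kendrick stages key on those
  series. The aromatic fraction of the unique stratum is the planted
  severity effect (defaults 0.05/0.15/0.25/0.40 for
  control/low/moderate/high); the realized pool-level aromatic fraction is
  (min_f·n_core + f_c·n_unique)/(n_core + n_unique), strictly increasing
  in f_c.
- **Replication** defaults to 4/6/5/6 samples for control/low/moderate/high,
  the replication of the surface-soil severity gradient this design
  emulates.
- **Peaks.** Each pool formula appears per replicate with probability 0.9;
  observed m/z = (M − 1.00727646)·(1 + ε·10⁻⁶) with ε ~ Normal(drift, sd),
  sd default 0.1 ppm (sub-ppm single-peak accuracy with most consensus
  masses well inside 0.5 ppm after averaging) and drift either constant or
  linear in m/z; intensities are log-normal (μ = 13, σ = 1, arbitrary
  units). When enabled, each peak gets a single-¹³C satellite at
  +1.0033548 Da with intensity 0.011·C·parent — the leading binomial term
  of natural ¹³C abundance, sufficient to exercise the isotopologue filter.
- **Ground truth** maps every emitted peak to its formula with an
  isotopologue flag, enabling accuracy measurement downstream.
- Pool sizes default to 2000 core + 150 unique formulas per condition —
  conventional for DOM spectra; integration tests and the acceptance script
  use 120–400-formula pools so the full pipeline runs in seconds while
  leaving hundreds of clusters per run.

Not emulated: peak shape/resolution, transient co-addition, scan averaging,
multiply charged ions, adducts other than [M−H]⁻, fine isotope structure,
intensity-dependent mass error, and chemical noise. Passing tests therefore
demonstrate the correctness of the analysis logic under the stated
statistical model of the data, not instrument-level robustness.

## Null calibration

Under an identical-pool design (no planted effect, detection noise only)
the one-sided AI test's rejection rate at α = 0.05 is measured over 500
simulated datasets and required to sit at the nominal rate (±2 points);
this guards against miscalibration introduced anywhere between the
generator and the test.

## Limitations

- Alignment precedes assignment; formulas are assigned to cluster consensus
  m/z, not per-sample peaks.
- Third-party assignment tools use unpublished validity filters, so formula
  counts from this package are not expected to replicate any particular
  tool's output; the rules here are explicit and configurable instead.
- Near-degenerate candidate pairs (< 0.05 ppm apart) are intrinsically
  unresolvable at 12 T-like accuracy; strict mode surfaces them rather than
  guessing.
- KMD series membership uses presence of any member per condition; studies
  that required every member per condition would retain fewer series.
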