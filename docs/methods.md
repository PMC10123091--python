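# Methods

This note documents the models implemented in `guideselect`, the parameter
choices that matter, and the limits of what the synthetic-data generators
establish.

## The construct and its coordinates

The selection substrate is a single DNA-represented amplicon,
`flank_5 | target | loop | guide | flank_3`, whose guide region is the
antisense of the target region. The target has odd length (21 or 31 nt)
with the edited adenosine at its centre. Positions are labelled
target-relatively: label 0 is the guide base opposite the edited A, labels
run −(L−1)/2 … +(L−1)/2 and increase 5'→3' along the *target* (and
therefore 3'→5' along the guide). `CoordinateMap` keeps the guide-index ↔
label bijection explicit so either display order can be rendered. The
internal alphabet is DNA (T, not U) throughout; reads and references arrive
as DNA and RNA rendering is a formatting concern.

The bundled demo construct is **synthetic**: the real target, loop and
primer sequences live in the source assay's supplementary material, so the
demo uses stand-ins with the correct geometry — a central TAG premature
stop codon giving the edited A its preferred 5'-T/3'-G neighbours, no other
A in the target (mirroring the design choice of removing editable off-target
A's), a 25 nt connector loop and 20 nt constant flanks.

## Library design statistics

Doped synthesis places the complementary base with weight 0.91 and each
alternative with 0.03 at every guide position except label 0, which is an
equimolar C:T mix (the internal selection control: ADAR prefers an A/C
mismatch at the edited site). Consequences, all closed-form:

* sequence space = 4^n over the n doped positions, computed in exact
  integer arithmetic (n = 20 → ≈1.10 × 10^12, n = 30 → ≈1.15 × 10^18);
* per-molecule mismatch counts are Binomial(n, 0.09) — the fixed C/T
  position is excluded from mismatch accounting since both halves are
  designed; ≥99% of molecules carry ≤5 mismatches at n = 20 and ≤7 at
  n = 30;
* molecules per reaction = concentration × volume × N_A (2.25 nM in 50 µl
  → 6.77 × 10^10).

The scientific-notation formatter supports truncation (default, matching
6.77 → "6.7") and half-up rounding (matching 1.0995 → "1.10"); published
figures mix the two conventions, so tests and reports choose the mode per
value.

## The selection simulator

One round is edit → select → regenerate:

1. every molecule is edited independently with probability
   p(g, E) = p_max · s(g) · E/(E + K), where E is the enzyme level and
   s(g) ∈ [0, 1] a guide score;
2. selection keeps edited molecules, plus unedited ones with probability
   `arms_leak` (default 0 — allele-specific PCR is modelled as perfectly
   selective, since the bench conditions for exclusive amplification of
   edited product were established empirically; the leak is exposed for
   robustness studies). An empty survivor set raises an explicit
   extinction error rather than crashing;
3. regeneration multinomially resamples survivors back to the configured
   pool size (PCR amplification without cycle-level modelling), with an
   optional per-base substitution rate for polymerase error.

Campaigns also record, per round, the expected pool-level edited fraction
at a ladder of enzyme levels — the analog of the non-selective PCR /
serial-dilution monitoring readout.

### The default fitness surface

No editing-probability model is specified by the assay itself; the default
here is an explicitly invented, pluggable per-position multiplicative
factor table chosen to encode three well-motivated rules:

* label 0: C scores 1.0, T scores 0.02, A/G score 0 — editing requires the
  canonical A/C mismatch;
* core labels −1, +1, +2, +3: any mismatch multiplies the score by 0.1 —
  duplex formation flanking the edited site is required;
* one distal preferred-mismatch position (default label +10): T scores
  1.0, anything else 0.3 — a stand-in for the beneficial distal mismatches
  the screen discovered; all other mismatches carry a mild 0.95 factor.

Under this surface the campaign reproduces the assay's two qualitative
signatures: the position-0 C frequency sweeps towards fixation within a few
rounds, and the perfectly complementary control guide is displaced by
higher-fitness mismatch variants. One dynamic is worth spelling out: any
fitness that *requires* C at label 0 necessarily *raises* the control's
frequency from round 0 to round 1, because the T half of the position-0 mix
is purged and the control is the fittest single genotype in the mismatch-
laden input pool. Its monotone decline begins once the pool's mean fitness
exceeds the control's score (round 1 onwards with the default parameters).
Claims about selection behaviour are therefore asserted over post-selection
rounds, plus final-below-initial. All quantitative claims in the tests are
properties of the selection operator (e.g. uniform fitness preserves
expected frequencies), not of this invented surface.

## Read simulation

Pool reads are full constructs with i.i.d. per-base substitution errors
(default 0.1%, the error rate assumed by the mismatch filter) and an
optional per-read single-base indel for exercising the indel filter.
Editing-sample reads carry a leading UMI and an A→G conversion at the
target site with the configured probability. Qualities are a constant
Phred+33 score (default Q30); the pipeline ignores them. Not emulated:
paired-end insert-size structure (merged reads are emitted directly), PCR
chimeras, quality-dependent error profiles, and position-dependent error
rates. A green end-to-end test therefore establishes correctness of the
bookkeeping under a homogeneous error model, not robustness to real MiSeq
artefacts.

### UMIs and saturation

A single random hexamer has only 4096 states, so at realistic molecule
counts tags collide, and directional clustering (below) merges singleton
neighbours — both bias molecule counts and, through consensus voting, pull
the editing estimate towards the majority class. The source workflow
extracted a hexamer from *each* read of a pair (~12 nt combined tag); the
analysis drivers and acceptance script therefore simulate and quantify with
`umi_length=12`, while the module default stays 6 for single-tag use.
`ReadSimConfig.umi_collision_free=True` samples tags without replacement —
an idealization used by the exactness tests so that "error-free reads
recover the simulated editing fraction exactly" is well-defined.

## Pool analytics

Because the amplicon has fixed structure, reads are anchored by locating
both constant flanks (≤1 mismatch each by default). Zero placements →
unanchored (this category also absorbs what a paired-end workflow would
drop as unpaired); more than one valid flank pair → the multi-mapping drop;
wrong inter-anchor length → indel; otherwise coordinates follow by offset
arithmetic and mismatches against the reference are counted everywhere
outside the guide window (anchor mismatches included). Reads with more
than 6 outside mismatches are dropped; `chance_mismatch_threshold` computes
the bound from first principles (smallest m with expected reads exceeding m
errors < 1 under Binomial(sites, error)) so the default can be justified or
overridden per dataset.

Profiling reports: a 4 × L base-frequency matrix by target-relative label
(N bases excluded, columns renormalized) suitable for logo rendering; a
mismatch histogram against the perfectly complementary guide with label 0
excluded (its designed C/T split is tallied separately, matching the
convention of marking the A/C mismatch apart); two operationalizations of
diversity — distinct sequences per read and singleton reads per read —
because "fraction of reads representing unique sequences" is ambiguous
between them; and a count-ranked guide table (ties broken
lexicographically, top-10 by default) with per-round frequency
trajectories for enrichment tracking.

## Editing quantification

Reads are collapsed to molecules by directional UMI clustering: visiting
tags in decreasing count order, a tag u merges into an already-kept
neighbour v when Hamming(u, v) ≤ 1 and count(v) ≥ 2·count(u) − 1. Each
cluster votes a per-position consensus; ties become N. Editing is
G/(G + A) at the target adenosine over consensus molecules — C, T and N at
the site are excluded from the ratio, and zero A+G coverage is an explicit
error.

The empirical p-value treats the per-position non-reference frequencies at
all covered non-target positions as a background error sample (an
A-sites-only / A→G-channel mode is available), fits a Gaussian KDE with
Scott's bandwidth, and reports the KDE's mass above the observed editing
fraction renormalized over [0, 1], floored at 1/(n_background + 1). The
kernel, bandwidth, support renormalization and floor are implementation
decisions (recorded in each call's metadata); a rank alternative
(1 + #background ≥ observed)/(n + 1) is provided, and a zero-spread
background (e.g. error-free data, where the KDE is singular) automatically
falls back to it. At least 20 covered background positions are required.

Calibration, verified by simulation at coverage 1000 and 0.1% error: with
no true editing the p-value exceeds 0.05 in ≥95% of replicates (the
observed A→G error rate is about a third of the total background error
rate, which makes the upper-tail test conservative); with ≥5% true editing
the p-value sits at its floor in ≥95% of replicates.

## Curve fitting

* One-phase association E(t) = Emax(1 − e^(−kt)): trust-region least
  squares with Emax ∈ (0, 1.2], k bounded by 10³/median positive time;
  initialization Emax₀ = max(E), k₀ = ln2 / first half-rise time with
  1/median(t) fallback — robust on both fast and slow series. Replicates
  are fitted independently and reported as mean ± SD by default (pooled
  fitting available). Flat series raise a degenerate-fit error;
  non-convergence raises a fit error with diagnostics. The fitter is
  unit-agnostic: k is returned in the reciprocal of the input time unit.
  (Published rate constants for this assay are printed in s⁻¹ against a
  0–120 minute sampling grid, which is internally inconsistent; printed
  values are treated as opaque numbers for ratio computations and no unit
  correction is invented.)
* Four-parameter logistic R(d) = bottom + (top − bottom)/(1 + (EC50/d)^h):
  bounded least squares, hill ∈ [0.1, 10], EC50 within (min dose/100, max
  dose×100), initialized at the data extremes and the geometric mean dose.
  Descending fits are reported in the ascending convention (swap
  bottom/top, negate hill — an exact reparameterization).
* Fold changes are Decimal ratios rendered at fixed precision with half-up
  rounding by default and a truncation mode, since published ratios mix
  conventions.
* The editing-vs-fluorescence relation is ordinary least squares with r².

Default simulated-measurement grids are the assay's: nine time points
(0–120 min) and doses spanning 0.07–300 nM.

## Known limitations

* The default fitness surface is a caricature; nothing quantitative about
  real guide efficacy follows from it, and real round-by-round numbers
  (diversity percentages, specific winner sequences) are not reproducible
  without the assay's raw sequencing data.
* The anchor matcher assumes the fixed amplicon layout; it is not a
  substitute for an aligner on structurally variable data, and mapping-
  quality filtering has no analog here.
* Synthesis bias away from the nominal 91:3:3:3 (observed in the real
  initial pool) is available only as an explicit per-position override in
  the pool sampler; the design math stays the theoretical scheme.
* KDE-based p-values at very low background spread depend on the singular-
  matrix fallback; with fewer than ~20 informative background positions the
  statistic is not reported at all.
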