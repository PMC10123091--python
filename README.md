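# guideselect

A tested re-implementation of the computational machinery behind an
iterative *in vitro* selection assay for ADAR-recruiting guide RNAs, aimed
at people building or analysing SELEX-style screens for site-directed RNA
editing (SDRE).

The bench assay links a partially randomized antisense guide to its editing
target in one hairpin molecule (`flank5 | target | 25 nt loop | guide |
flank3`), edits the pool with ADAR2, amplifies only the edited molecules by
allele-specific (ARMS) PCR, and regenerates the pool for the next round —
so guides that drive efficient A-to-I editing enrich round by round and can
be read out by amplicon sequencing. This package provides everything around
that loop that is computation:

* **library design statistics** — the doped 91:3:3:3 synthesis scheme
  (91% complementary base, 3% each alternative, an equimolar C:T mix
  opposite the edited A), exact sequence-space counts
  (4^n), Binomial(n, 0.09) mismatch spectra, and molecules-per-reaction
  arithmetic (c·V·N_A);
* **a selection-campaign simulator** — per-molecule editing under a
  pluggable fitness model, ARMS selection with optional leak, multinomial
  PCR regeneration, plus FASTQ read simulation with substitution errors,
  indels and UMIs, and kinetic / dose-response series generators;
* **guide-pool analytics** — anchor-based amplicon matching (the amplicon
  has fixed structure, so flank anchoring plus offset arithmetic replaces a
  general aligner), QC filters (ambiguous anchoring, indels, >6 mismatches
  outside the guide region), per-position base-frequency matrices (logo
  input), mismatch histograms, diversity metrics and round-by-round
  enrichment trajectories;
* **editing quantification** — directional UMI deduplication with
  per-position consensus, editing as G/(G+A) at the target adenosine over
  deduplicated molecules, and an empirical p-value from a Gaussian KDE over
  the per-position error frequencies across the rest of the amplicon;
* **curve fitting** — one-phase association kinetics E(t) = Emax(1 −
  e^(−kt)), four-parameter logistic dose-response with EC50, ordinary least
  squares for editing-vs-fluorescence, and fixed-precision fold-change
  ratios.

## Worked example

```python
from guideselect import demo_library_spec, format_scientific, sequence_space_size
from guideselect.simulate import SelectionConfig, default_editing_model, run_campaign

spec = demo_library_spec(21)           # synthetic 21 nt construct, edited A at centre
print(format_scientific(sequence_space_size(20), 3, "round"))   # 1.10e+12

cfg = SelectionConfig(spec=spec, n_rounds=4, pool_size=50_000,
                      selection_enzyme_level=0.5, seed=20230901)
result = run_campaign(cfg, default_editing_model(spec))
for rnd, pool in enumerate(result.pools()):
    print(rnd, round(pool.frequency(spec.control_guide), 4))
```

prints the perfectly complementary control guide's frequency by round:

```
0 0.0764
1 0.1924
2 0.1746
3 0.1114
4 0.0519
```

After round 1 purges the T half of the position-0 C:T mix (which briefly
concentrates the control), the control declines steadily while mismatched
variants favoured by the fitness surface take over — the qualitative
signature of the bench assay, where the control went from most represented
to undetectable.

The numbered drivers under `analysis/` run the full story and write small
tables to `results/` (large FASTQ intermediates go to `scratch/`):

```bash
python analysis/01_design_arithmetic.py   # sequence space, molecule counts, mismatch spectrum
python analysis/02_simulate_campaign.py   # 4-round selection campaign + per-round FASTQ
python analysis/03_pool_profiles.py       # read-level profiling, logos, enrichment trajectories
python analysis/04_editing_quant.py       # UMI dedup + G/(G+A) + empirical p across editing levels
python analysis/05_fits.py                # kinetics, EC50, regression, fold changes
```

A thin CLI wraps the same library for shell use: `guideselect simulate`,
`guideselect analyze-pool`, `guideselect quantify-editing`,
`guideselect fit` (see `--help`).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's headline quantities from scratch by running the
library itself: the design arithmetic and its printed renderings, a
scaled-down four-round selection campaign with its position-0 and
control-guide trajectories, read-level pool profiling, UMI-based editing
quantification at 0.1% sequencing error, and the kinetic/dose-response
fits, then writes its JSON report to `--out`. The `--seed` argument drives
every source of randomness.

See `docs/methods.md` for the models, parameter choices, and what the
synthetic-data generators do and do not emulate.
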