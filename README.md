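# rockisc

Analysis toolkit for a question that matters to epidermal-sheet cell and
gene therapy: when cultured primary human keratinocytes are given a
short (six-day) course of the Rho-associated kinase inhibitor (ROCKi)
Y-27632 to boost their initial expansion, are the keratinocyte stem cells
(holoclone-forming cells) and the population's differentiation behaviour
permanently altered — or does everything revert once the inhibitor is
withdrawn?

The package implements the full computational workflow for the four-arm
design (Control-6D⁻, ROCKi-6D⁺, and the post-withdrawal arms
Control-6D⁻6D⁻, ROCKi-6D⁺6D⁻):

* **`syndata`** — a synthetic single-cell study generator with known ground
  truth (three keratinocyte stages along one differentiation axis, marker
  structure, donors, cell-cycle programs, contaminants, and a treatment
  pseudotime shift that reverts on withdrawal), plus synthetic stained
  plate scans;
* **`qc`** — 10x-style MTX I/O, per-cell metrics, detection filters,
  per-sample threshold filters, and marker-based exclusion of melanocytes
  and mesenchymal-like cells (≥2 counts of MLANA, PMEL, MITF, ACTG2, DLK1,
  MTRNR2L6/7/10/1, PRKAR2B or NR2F1);
* **`preprocess`** — analytic Pearson-residual normalization
  (r = (x−μ)/√(μ+μ²/θ), μ the depth-offset mean, clipped at ±√n), binned
  cell-cycle module scores with S−G2M regression, HVG selection, PCA, and
  soft-cluster donor integration;
* **`celltype`** — semi-supervised EM over published marker signatures to
  label cells holoclone-forming / clonogenic / terminally differentiated,
  and per-sample proportion vectors π;
* **`dabundance`** — multiscale kNN differential-abundance scores with a
  permutation null, yielding the fraction of treated cells occupying
  neighborhoods shared with control ("overlap");
* **`trajectory`** — one principal-curve lineage (holoclone → clonogenic →
  differentiated) fitted on each combined pair, giving comparable per-cell
  pseudotimes;
* **`revstats`** — the comparison statistics with bootstrap CIs:
  T = Σ_t |π_A(t) − π_B(t)|,
  D = mean_p |q_A(p) − q_B(p)| over the percentile grid 0.1…100.0,
  the treatment/withdrawal ratio R = D_treat/D_withdraw with a paired-draw
  CI, and Wilcoxon rank-sum differential expression with BH correction and
  a |log₂FC| > 1 call rule;
* **`colony`** — colony segmentation from plate scans (median filter,
  IsoData threshold, hole filling, watershed), mm-calibrated area and
  Crofton-perimeter circularity 4πA/P², the ≥1 mm² / ≥0.5 circularity
  counting rule, colony-forming efficiency, and the growth rate
  ln(harvested/seeded)/days;
* **`pipeline`** — one config, one seed, byte-reproducible JSON study
  report over both compared pairs.

See `docs/methods.md` for the models, parameter defaults and numerical
choices.

## Worked example

```python
import rockisc as rk
from rockisc import pipeline

sim = rk.SimulationConfig(n_cells_per_sample=1000, n_genes=600, seed=3)
cfg = pipeline.StudyConfig(sim=sim, seed=3, n_boot=200, n_perm=30)
report = pipeline.run_study(cfg)
t = report.pairs[pipeline.TREATMENT_PAIR]
w = report.pairs[pipeline.WITHDRAWAL_PAIR]
print(f"D treatment  {t.D.statistic:.3f}  CI {t.D.ci}")
print(f"D withdrawal {w.D.statistic:.3f}  CI {w.D.ci}")
print(f"ratio {report.ratio_D.ratio:.1f}  CI lower {report.ratio_D.ci[0]:.1f}")
print(f"overlap treatment {t.overlap.overlap_fraction:.2f} "
      f"withdrawal {w.overlap.overlap_fraction:.2f}")
```

prints (exactly reproducible for this seed):

```
D treatment  0.158  CI (0.1373786184150742, 0.18050984381100854)
D withdrawal 0.015  CI (0.01084191505235444, 0.035714071052704646)
ratio 10.3  CI lower 4.4
overlap treatment 0.33 withdrawal 0.89
```

Read: during treatment the pseudotime distributions of treated and control
cells differ by D ≈ 0.16 of the trajectory (the generator's built-in shift
of 0.2 minus clamping loss) and only a third of treated cells sit in
neighborhoods shared with control; after withdrawal D collapses to noise
level, the overlap rises to ~0.9, and the bootstrap ratio says the
treatment-phase difference is, with 95% confidence, at least ~4-fold the
post-withdrawal one — the reversibility signature the workflow is built to
detect.

A thin CLI wraps the same calls:

```sh
rockisc simulate --out study/ --cells 2000 --seed 0
rockisc run-study --out results/ --cells 2000 --seed 0
rockisc colony --image plate.png --dpi 600
rockisc growth-rate --seeded 1e6 --harvested 4e6 --days 6
```

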