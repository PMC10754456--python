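# clonalclock

Time-resolved analysis of clonally evolving genomes from variant-allele-
frequency (VAF) spectra — for researchers studying tumour evolution or
clonally reproducing organisms who have somatic/germline variant calls with
read depths and want to turn them into a chronology of the expansion.

## The method

A growing clone accumulates mutations at a rate proportional to its
evolutionary parameters: in an increment of time, dM ∝ μ·π·ω·γ·N dt, with
mutation rate μ (per genome per division), ploidy π, division rate ω,
offspring/cell survival probability γ and population size N. Because the
allele frequency f of a mutation reflects the population size at its
origin (1/f ∝ π·N), the cumulative mutation count M plotted against
u = 1/f is linear under neutral exponential growth, and changes of slope
mark phases of the expansion. On top of this curve the package provides:

* **Phase segmentation** — continuous piecewise-linear regression with
  Muggeo-style breakpoint optimisation, selected as the smallest number of
  segments reaching a target adjusted R² (≤ 20 breakpoints), with Davies'
  test for the significance of slope changes and 10-fold cross-validation
  against overfitting. Mutations outside [first, last] breakpoint (clonal
  ancestry and the detection limit) are excluded downstream.
* **Longitudinal dN/dS** — the nonsynonymous/synonymous count ratio in
  sliding windows on u, normalised by the genome's codon-opportunity
  baseline (Σ possible nonsynonymous / Σ possible synonymous single-base
  changes, weighted by codon usage), with bootstrap CIs.
* **Signature exposures** — 96-channel trinucleotide spectra per u-bin,
  decomposed by non-negative least squares onto a signature catalog;
  exposures θ are in mutation-count units.
* **Clock-time reconstruction** — with clock-like signatures (SBS1/SBS5)
  as a proxy for elapsed time, t_a.u.(u) = ∫ θ·f d(1/f); the arrow of time
  is the direction of increasing 1/f. A known time-to-recurrence T
  calibrates the recurrence timeline (t = t_a.u.·T/max T_a.u.); boundary
  mutation fluxes (dM/dt over the last/first 5% of time points) propagate
  time from the recurrence back into the primary tumour, and the
  tumour-cell survival ratio is γ_R/γ_P = [(1/f)_P/(1/f)_R]·(dM/dt)_R/(dM/dt)_P.
* **Expansion profiles** — ωγN(t) = d(1/f)/dt, known up to a constant,
  clustered (k-means on standardised 1000-point curves, Calinski–Harabasz
  model selection) into the shape classes Convex, Peak, Increase and
  Paused Start.
* **Trio mutation rates** — parent–offspring mutation rates per nucleotide
  per year with a three-component uncertainty model (genotyping, birth
  date, biological variability, combined in quadrature).
* **A clonal-expansion simulator** — a Galton–Watson-style generative
  model with a ground-truth ledger (per-mutation origin, carrier counts,
  true frequencies), including paired primary/recurrent designs with a
  prescribed γ_R/γ_P, so every estimator above has a recoverable target.

## Worked example

```python
import numpy as np
from clonalclock import sim, variantio, accumulation, signatures, chronology

# simulate a clonal expansion and sequence it at 250x
cfg = sim.SimulationConfig(mu=2.0, ploidy_pi=2, omega=0.3, gamma=0.95,
                           n0=20, n_generations=14, depth=250.0, seed=1)
table, truth = sim.simulate_clonal_expansion(cfg)
table = sim.attach_sequencing_noise(table, cfg.depth, cfg.ploidy_pi, seed=2)
print(f"simulated {len(table)} variants segregating in {truth.n_per_generation[-1]} cells")

# quality filter (QUAL >= 30, depth >= 10, alt depth >= 3) and M(1/f)
kept, report = variantio.apply_filters(table, variantio.FilterSpec())
print(f"kept {report['kept']}/{report['input']} variants after filtering")
curve = accumulation.build_maf_curve(kept)
fit = accumulation.fit_segmented(curve, target_adj_r2=0.995, seed=0)
p = accumulation.davies_test_curve(curve, fit)
print(f"segmentation: {fit.k} breakpoint(s), adj R^2 = {fit.adj_r2:.4f}, "
      f"Davies p = {p:.3g}")

# per-u-bin signature exposures -> clock time, calibrated to 14 months
catalog = signatures.synthetic_catalog()[["SBS1", "SBS5"]]
spectra = signatures.bin_spectra(kept, halfwidth=0.5)
series = signatures.fit_exposure_series(spectra, catalog)
theta = series.clock_exposure(("SBS1", "SBS5"))
edges = np.concatenate([series.centers - 0.5, [series.centers[-1] + 0.5]])
tc = chronology.time_arbitrary(edges, theta, counts=series.totals)
tc = chronology.calibrate_recurrence(tc, T_months=14.0)
print(f"clock time spans {tc.t_au[-1]:.3f} a.u. over u in "
      f"[{edges[0]:.1f}, {edges[-1]:.1f}]; calibrated so t_max = {tc.t_real[-1]:.0f} months")
```

prints

```
simulated 1694 variants segregating in 424 cells
kept 152/1694 variants after filtering
segmentation: 2 breakpoint(s), adj R^2 = 0.9965, Davies p = 1.13e-75
clock time spans 4.343 a.u. over u in [10.5, 95.5]; calibrated so t_max = 14 months
```

Only 152 of 1694 simulated variants are detectable at 250× — the rest sit
below the alt-read threshold, which is exactly the sequencing-depth limit
the segmentation's outer-phase trimming accounts for. The curve splits
into phases (the Davies p-value confirms real slope changes), and the
summed clock-like exposure integrates into a monotone timeline that the
known time-to-recurrence anchors in months.

The same pipeline is scriptable from the shell:

```
clonalclock --seed 1 --outdir out run-all --mode synthetic
clonalclock filter variants.tsv --min-qual 35 --min-depth 50 --max-depth 200
clonalclock rate counts.tsv --denominator genome --genome-nt 1.05e10
```

`run-all` writes one TSV per stage plus `manifest.json` with parameters,
seed and content hashes of every output.

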