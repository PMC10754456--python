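# Methods

This note documents the models implemented in `clonalclock`, the
assumptions behind them, the synthetic-data generator that backs the test
battery, and the numerical choices that were genuinely open.

## Accumulation model

The package analyses a clone whose mutation influx in an increment of time
is dM ∝ μ·π·ω·γ·N dt: μ mutations per genome per division, ploidy π,
division rate ω, survival probability γ per daughter, N cells. A mutation
arising when the population had size N' is later observed at allele
frequency f ≈ 1/(π·N') (one mutated copy of π, carried by the descendants
of one cell). Substituting N ∝ 1/f turns the influx into an increment over
inverse frequency, so the cumulative count M plotted against u = 1/f is
linear under constant parameters, with slope proportional to μ — and
independent of the selection coefficient, which cancels from the spectrum.
Phases of the expansion therefore appear as slope changes of M(u), and the
arrow of time is the direction of increasing u.

Selection does, however, move the nonsynonymous/synonymous composition,
which is why the dN/dS stage exists alongside the curve.

## Simulator

`sim.simulate_clonal_expansion` is a discrete-step Galton–Watson model:
per step each cell divides with probability ω (divisions per unit time ×
one unit step); each daughter survives with probability γ; each surviving
daughter gains Poisson(μ) single-base substitutions on one of π copies
(infinite sites — every event takes a fresh coordinate). Cells are
anonymous; the genealogy is kept as per-step parent-pointer arrays, and a
single backward fold over them yields every mutation's carrier count, so
the true frequency f = carriers/(π·N_final) is exact. The complete event
log is retained, which lets tests recount surviving mutations by brute
force replay.

Key modelling choices:

* **Discretisation fidelity.** The continuous model assumes N changes
  smoothly while γ may jump. Per step the population changes by the factor
  1 + ω(2γ − 1); a small ω (0.05 in the paired-tumour study) keeps that
  factor near 1 so boundary windows a few steps wide see an almost
  constant N even across an abrupt γ switch. This is the regime in which
  the survival-ratio estimator's algebra holds; larger ω trades fidelity
  for speed.
* **Selection as thinning.** Nonsynonymous events are retained with
  probability s at origination. Any monotone implementation suffices,
  because the frequency spectrum is s-free; only the label composition
  (dN/dS) responds.
* **Annotations.** Each event draws a trinucleotide channel from the
  configured signature mixture, a coding/noncoding state, and a
  syn/nonsyn/stopgain label (75% of coding events nonsynonymous before
  selection, 5% of those stop-gains — close to the opportunity ratio of
  the standard genetic code).
* **Sequencing noise.** Total depth ~ Poisson(depth), floored at one read;
  alt depth ~ Binomial(total, f). QUAL is a depth-scaled placeholder: the
  simulator emulates read sampling, not a caller's error model.
* **Paired designs.** `simulate_primary_recurrent` grows the primary under
  a γ schedule whose final steps are the primary-end regime γ_P, resects a
  random cell fraction, and regrows the recurrence under
  γ_R = ratio·γ_P. Inherited mutations keep their identity in both tables
  and the recurrent table flags de novo events.

What the generator does *not* emulate: copy-number change, ploidy
evolution, indels, caller artefacts, mapping bias, overlapping-generation
age structure. Passing recovery tests therefore show that the estimators
invert the model they assume, not that real data meet that model.

## Curve, segmentation, Davies test, CV

`build_maf_curve` sorts u ascending and returns the tie-collapsed
cumulative count. Confidence bands resample the binned counts (bin
half-width 0.25 on u, centres on the width grid, left-closed edges) as a
multinomial B times and take 2.5/97.5 percentiles, propagated to the
cumulative curve per replicate.

Segmented fits use Muggeo's iterative linearisation: regress on
{1, x, (x−ψ)₊, −1(x>ψ)} and update ψ by the ratio of the indicator to the
hinge coefficient, from quantile starts plus 4 random restarts (restarts
guard against local optima; runs whose breakpoints collapse or leave the
range are discarded). The number of breakpoints is the smallest k whose
adjusted R² (parameter count 2(k+1): k breakpoints, k+1 slopes, one
intercept under continuity) reaches the target — 0.995 in the
slow-accumulation default, 0.9995 for dense tumour curves — capped at 20
and flagged when unreachable.

Davies' bound handles the breakpoint being absent under the null: the
t statistic for adding one hinge is scanned over 10 breakpoint quantiles;
with M = max|t| and V the total variation of the t-process over the grid,
p = 2·[Φ(−M) + V·e^{−M²/2}/√(8π)], capped at 1. Null simulations put the
empirical size at ~4.5% for nominal 5%.

Cross-validation assigns points to 10 folds at random (seeded), refits per
candidate breakpoint count, and reports held-out ("test") and in-sample
("validation") MSE; a non-increasing test–validation gap when adding one
phase indicates the absence of overfitting. Note that among candidates
*above* the true count the argmin of test MSE is near-chance by
construction — one spurious breakpoint costs only ~2σ²/n of held-out MSE,
far below fold noise — so the CV check compares the chosen count against
coarser models, which is also how the reported CV tables are meant to be
read.

The accepted u-range is [first breakpoint, last breakpoint]: below the
first sit clonal/contamination mutations, above the last the
depth-limited tail; downstream stages see only the interior.

## dN/dS

The opportunity baseline counts, over all valid CDS (start ATG, end in a
stop, no internal stop, length divisible by 3; terminal stop excluded),
each codon's 9 single-base changes as synonymous or nonsynonymous
(stop-gain = nonsynonymous), weighted by codon usage. The windowed
statistic is (#nonsyn/#syn)/baseline in sliding windows on u (half-width
1.0, ≥ 20 mutations, windows without synonymous counts masked rather than
infinite), with percentile-bootstrap CIs from resampling labels within the
window and a running-median(5) + moving-average(3) smooth. Windows are not
multiplicity-corrected; the intervals are descriptive.

## Signatures and clock time

Spectra are binned on u with half-width 0.5 (tiling bins, centres on the
integer grid, edge values joining the right bin). Exposures solve
θ = argmin‖Cθ − counts‖₂, θ ≥ 0 (Lawson–Hanson NNLS) on raw counts, so θ
is a mutation flux — what the time integral needs. Bootstrap CIs resample
mutations (sets over 100,000 are first subsampled to 50,000 and rescaled).
The repository ships no external catalog; `signatures.synthetic_catalog()`
builds a synthetic stand-in with an SBS1-like N[C>T]G-peaked column, a
broad SBS5-like column and a flat column. Only the shapes matter to the
tests; analyses of real data should load a real catalog TSV via
`variantio.read_signature_catalog`.

Time in arbitrary units is t(u) = ∫ θ(v)·(1/v) dv from u_min. Because θ is
piecewise-constant per bin the integral is evaluated exactly as
Σ θ_b·ln(edge_{b+1}/edge_b) — the refinement limit of any trapezoid rule,
and exact for the closed-form checks. The clock set is configurable:
{SBS1, SBS5} by default, {SBS1} for the tumour setting.

## Time propagation and the survival ratio

Boundary windows are the first/last 5% of time points. The window
aggregate of 1/f is the **reciprocal of the mean allele frequency**
(harmonic mean of 1/f): the allele frequency is the unbiased proxy of the
inverse population size at origin (the lineage-size martingale has unit
mean), whereas the arithmetic mean of 1/f is inflated by lineage-size
noise — E[1/W] > 1, roughly twofold under near-exponential lineage-size
distributions — which on simulations halves the recovered survival ratio.
With the harmonic aggregate the estimator

    γ_R/γ_P = [(1/f)_P / (1/f)_R] · (dM/dt)_R / (dM/dt)_P

recovers a simulated truth of 30 with a replicate median of ~29.

Primary-timeline calibration inverts the same relation with an assumed
γ_P/γ_R (default 1/300): dt_P = dM_P / [(u_P/u_R)·(γ_P/γ_R)·(dM/dt)_R],
then rescales the primary's arbitrary-unit time so its terminal window
spans dt_P. Alternatively, assuming the primary lasted 2 or 7 years
(24/84 months) bounds γ_R/γ_P from below and above. The two directions are
algebraically inverse: propagating with ratio g and re-estimating returns
1/g to machine precision, which the tests assert.

Inherited mutations bias the recurrence-side quantities (they are clonal
in the recurrence, deflating (1/f)_R); the de novo restriction is exposed
as a flag but off by default, matching the descriptive convention of
reporting the biased and unbiased modes side by side.

Expansion profiles are ωγN(t) = du/dt by central differences with an
optional 3-point median smooth, labelled as known up to the constant π/K.

## Classification

Profiles are linearly interpolated onto a uniform 1..1000 timeline,
centred and scaled to unit SD per curve, and clustered by Euclidean
k-means with 5 restarts (scikit-learn). The Calinski–Harabasz criterion
CH = [B/(k−1)]/[W/(n−k)] is computed directly (perfect separation reported
as a capped sentinel) and selects k by argmax, with an optional rule that
prefers the smallest k within 10% of the maximal CH whose clusters cover
all configured reference shapes. Cluster names (Convex, Peak, Increase,
Paused Start) come from one-to-one correlation matching of cluster means
against analytic templates.

## Trio rates

Per-offspring rate = count / denominator / years, averaged across
offspring. Denominators: the full triploid genome (10.5×10⁹ nt,
conservative lower bound) or callable sites (486,234, upper bound);
default elapsed times 5.75 and 6.08 years. Uncertainty combines in
quadrature, all in rate units: binomial genotyping SD with plug-in
p = count/denominator; birth-date SD = (window/3) propagated through the
1/t dependence (default window 1 year); and the SD of per-offspring rates
(biological), undefined and flagged with a single offspring.

## Study conditions and problem sizes

The recovery battery (`clonalclock.studies`, run by the test suite and by
`scripts/acceptance.py`) uses the following fixed conditions, chosen once
as realistic for the models and sized to finish in a few minutes on one
CPU:

* neutral growth: μ = 0.3, π = 2, ω = 0.3, γ = 0.95, 20 founders, 32
  steps (≥ 10⁴ surviving variants); slope measured over the carrier-class
  range 10–50 (u ∈ [u_max/50, u_max/10]) — above it the spectrum
  degenerates into the atoms u_max/c for c = 1, 2, 3 where a regression on
  the cumulative staircase is ill-posed, below it sit founder mutations;
* paired tumours: ω = 0.05, γ growth 0.9, 185 growth steps, 3
  boundary steps at γ_P = 0.03, resection fraction 0.3, γ_R/γ_P = 30, 20
  replicates;
* segmentation: breakpoints {2.5, 5, 7.5} with slopes {5, 20, 2, 30} on
  n = 2000 points, noise SD 5, 100 replicates; Davies null at n = 100,
  1000 simulations;
* exposures: 0.6/0.4 clock-like mixture, 10⁴ mutations, 200 outer
  replicates at B = 200;
* dN/dS: 6×10⁴ opportunity-proportional labels over u ∈ (1, 201) with
  non-overlapping windows (independent coverage indicators), B = 1000;
* classification: 4 archetypes × 10 replicates, noise SD 0.3, 50 seeds;
* trio rates: μ = 2×10⁻⁵/nt/y over 10⁶ sites, 200 replicates.

## Known limitations

* The simulator's per-step Bernoulli division is a coarse clock; rate
  heterogeneity between cells and overlapping generations are not
  modelled.
* The synthetic signature catalog is a stand-in; exposure fits on real
  data require a real catalog and inherit its collinearity.
* dN/dS is the non-bias-correcting count ratio; it does not adjust for
  trinucleotide composition or coverage covariates.
* The survival ratio presumes μ and ω are equal across the resection
  boundary, and the (1/f) proxy for N presumes constant ploidy.
* Percentile-bootstrap intervals undercover slightly (~94–95% observed at
  nominal 95%) for windowed count ratios; the coverage checks account for
  this by using many independent windows.
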