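"""Canonical simulation studies exercising every stage of the pipeline.

Each function runs one recovery study under fixed, documented conditions
and returns the measured quantities; the test suite asserts on them and
``scripts/acceptance.py`` reports them. Problem sizes are chosen so the
whole battery completes in a few minutes on one CPU (see docs/methods.md).
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import accumulation, chronology, classify, rate, selection, signatures, sim
from .cli import synthetic_archetype_profiles


def time_integral_closed_forms() -> dict[str, float]:
    """Unit clock exposure: t_au spans must equal ln(u_max/u_min) exactly."""
    tc1 = chronology.time_arbitrary(np.array([1.0, np.e]), np.array([1.0]))
    tc2 = chronology.time_arbitrary(np.linspace(2.0, 8.0, 25), np.ones(24))
    return {"unit_exposure_1_to_e": float(tc1.t_au[-1]),
            "unit_exposure_2_to_8": float(tc2.t_au[-1]),
            "expected_2_to_8": float(np.log(4.0))}


def neutral_slope_study(seed: int, n_replicates: int = 20,
                        carrier_range: tuple[int, int] = (10, 50)
                        ) -> dict[str, object]:
    """Neutral growth: the regression slope of M on u over the mid-frequency
    range against the exact frequency-class count from the truth ledger.

    The mid-frequency range is u in [u_max/50, u_max/10] (carrier classes
    10..50): below it lie the near-clonal founder mutations; above it the
    spectrum degenerates into the discrete atoms u_max/c for c = 1, 2, 3,
    where a regression on the cumulative staircase is ill-posed.
    """
    ratios = []
    for i in range(n_replicates):
        table, truth = sim.neutral_growth_study(seed=seed * 1000 + i)
        curve = accumulation.build_maf_curve(table)
        u_max = truth.config.ploidy_pi * truth.n_per_generation[-1]
        lo, hi = u_max / carrier_range[1], u_max / carrier_range[0]
        mask = (curve.u >= lo) & (curve.u <= hi)
        slope = float(np.polyfit(curve.u[mask], curve.m[mask], 1)[0])
        carriers = truth.events["carriers"].to_numpy()
        u_oracle = u_max / carriers
        oracle = float(((u_oracle >= lo) & (u_oracle <= hi)).sum() / (hi - lo))
        ratios.append(slope / oracle)
    ratios = np.asarray(ratios)
    return {"ratios": ratios,
            "max_abs_error": float(np.max(np.abs(ratios - 1.0))),
            "mean_ratio": float(ratios.mean())}


def survival_ratio_study(seed: int, n_replicates: int = 20,
                         gamma_ratio: float = 30.0) -> dict[str, object]:
    """Paired primary/recurrent simulations; Eq-8 estimator vs truth."""
    estimates = []
    for i in range(n_replicates):
        p, r, truth, w = sim.primary_recurrent_study(seed=seed * 1000 + i,
                                                     gamma_ratio=gamma_ratio)
        estimates.append(chronology.survival_ratio_from_pair(
            p, r, truth.resection_generation, w))
    estimates = np.asarray(estimates)
    return {"estimates": estimates,
            "median": float(np.median(estimates)),
            "truth": gamma_ratio,
            "all_above_one": bool(np.all(estimates > 1.0))}


def round_trip_identity(seed: int) -> dict[str, float]:
    """propagate_primary then survival_ratio returns the assumed ratio."""
    rng = np.random.default_rng(seed)
    g = rng.uniform(1e-3, 0.9)
    dm_p = rng.uniform(20, 300)
    u_p, u_r = rng.uniform(1, 40, 2)
    dmdt_r = rng.uniform(0.5, 60)
    t_au = np.concatenate([[0.0], np.cumsum(rng.uniform(0.01, 1.0, 80))])
    _, t_real = chronology.propagate_primary(dm_p, u_p, u_r, dmdt_r, t_au,
                                             gamma_pr=g)
    w = max(2, int(np.ceil(chronology.WINDOW_FRACTION * len(t_real))))
    dmdt_p = dm_p / (t_real[-1] - t_real[-w])
    est = chronology.survival_ratio(dmdt_r, u_r, u_p, dmdt_p)
    return {"assumed": 1.0 / g, "recovered": est,
            "relative_error": abs(est * g - 1.0)}


def _piecewise(x, breaks, slopes):
    y = slopes[0] * x
    for b, (s0, s1) in zip(breaks, zip(slopes, slopes[1:])):
        y = y + (s1 - s0) * np.maximum(x - b, 0.0)
    return y


SEG_BREAKS = np.array([2.5, 5.0, 7.5])
SEG_SLOPES = [5.0, 20.0, 2.0, 30.0]


def segmentation_study(seed: int, n_replicates: int = 100, n: int = 2000,
                       noise_sd: float = 5.0) -> dict[str, object]:
    """Breakpoint recovery (within 10% of truth) and cross-validated
    preference for the true phase count over coarser models."""
    rng = np.random.default_rng(seed)
    x = np.linspace(0.0, 10.0, n)
    recovered = 0
    cv_true_best = 0
    for i in range(n_replicates):
        y = _piecewise(x, SEG_BREAKS, SEG_SLOPES) + rng.normal(0, noise_sd, n)
        psi, _, _ = accumulation._fit_k_breaks(x, y, 3, seed=seed + i)
        recovered += bool(np.all(np.abs(psi - SEG_BREAKS) <= 0.1 * SEG_BREAKS))
        cv = accumulation.kfold_cv_segmentation((x, y), candidate_ks=[0, 1, 2, 3],
                                                k_folds=10, seed=seed + i,
                                                restarts=2)
        cv_true_best += int(cv.loc[cv["test_mse"].idxmin(), "k"]) == 3
    return {"breakpoint_recovery_rate": recovered / n_replicates,
            "cv_true_k_rate": cv_true_best / n_replicates}


def davies_null_study(seed: int, n_sims: int = 1000, n: int = 100,
                      alpha: float = 0.05) -> dict[str, float]:
    """Type-I error of the Davies bound on straight-line data."""
    rng = np.random.default_rng(seed)
    x = np.linspace(0.0, 10.0, n)
    rejections = 0
    for _ in range(n_sims):
        y = 1.0 + 2.0 * x + rng.normal(0, 1.0, n)
        rejections += accumulation.davies_test(x, y) < alpha
    return {"rejection_rate": rejections / n_sims, "alpha": alpha}


def exposure_recovery_study(seed: int, n_mutations: int = 10_000,
                            n_replicates: int = 200, B: int = 200,
                            mixture: tuple[float, float] = (0.6, 0.4)
                            ) -> dict[str, object]:
    """NNLS recovery of a clock-like mixture and bootstrap CI coverage."""
    catalog = signatures.synthetic_catalog()[["SBS1", "SBS5"]]
    probs = (mixture[0] * catalog["SBS1"].to_numpy()
             + mixture[1] * catalog["SBS5"].to_numpy())
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_mutations, probs).astype(float)
    point = signatures.fit_exposures(counts, catalog)
    props = point.theta / point.theta.sum()
    covered = 0
    for i in range(n_replicates):
        c = rng.multinomial(n_mutations, probs).astype(float)
        _, lo, hi = signatures.bootstrap_exposures_spectrum(catalog=catalog,
                                                            counts=c, B=B,
                                                            seed=seed + i)
        truth = np.array(mixture) * n_mutations
        covered += bool(np.all((lo <= truth) & (truth <= hi)))
    return {"fitted_proportions": props,
            "max_proportion_error": float(np.max(np.abs(props - mixture))),
            "ci_coverage": covered / n_replicates}


def dnds_study(seed: int, n_mutations: int = 60_000,
               selection_s: float = 0.5) -> dict[str, object]:
    """Windowed dN/dS: neutrality coverage and purifying-selection direction.

    The neutrality check uses non-overlapping windows (step = window width)
    over a wide u range so that the per-window coverage indicators are
    independent and their fraction concentrates at the CI's true coverage.
    """
    opp = selection.codon_opportunities(selection.synthetic_cds(50, 200, seed=1))
    u_range = (1.0, 201.0)
    neutral = selection.opportunity_proportional_labels(n_mutations, opp,
                                                        seed=seed, u_range=u_range)
    s_neu = selection.dnds_longitudinal(neutral, opp.baseline, B=1000, seed=seed,
                                        step=2.0)
    t = s_neu.table.dropna(subset=["dnds"])
    coverage = float(((t["ci_lo"] <= 1.0) & (t["ci_hi"] >= 1.0)).mean())
    selected = selection.opportunity_proportional_labels(
        n_mutations, opp, seed=seed + 1, selection_s=selection_s,
        u_range=u_range)
    s_sel = selection.dnds_longitudinal(selected, opp.baseline, B=1000,
                                        seed=seed + 1, step=2.0)
    t2 = s_sel.table.dropna(subset=["dnds"])
    return {"neutral_ci_coverage_of_unity": coverage,
            "selected_fraction_below_one": float((t2["dnds"] < 1.0).mean()),
            "selected_fraction_ci_excludes_one": float((t2["ci_hi"] < 1.0).mean()),
            "baseline": opp.baseline}


def opportunity_oracle_study(seed: int, n_cds: int = 50) -> dict[str, object]:
    """Exact agreement of codon-opportunity totals with per-position
    enumeration, and the canonical TTT split."""
    from Bio.Seq import Seq

    cds = selection.synthetic_cds(n_cds, 30, seed=seed)
    table = selection.codon_opportunities(cds)
    syn = nonsyn = 0
    for s in cds:
        body = s[:-3]
        for i in range(len(body)):
            for b in "ACGT":
                if b == body[i]:
                    continue
                ci = 3 * (i // 3)
                new = body[:i] + b + body[i + 1:]
                if str(Seq(new[ci:ci + 3]).translate()) == \
                        str(Seq(body[ci:ci + 3]).translate()):
                    syn += 1
                else:
                    nonsyn += 1
    ttt = selection.codon_changes("TTT")
    return {"table_syn": table.total_syn, "oracle_syn": syn,
            "table_nonsyn": table.total_nonsyn, "oracle_nonsyn": nonsyn,
            "exact_match": bool(table.total_syn == syn
                                and table.total_nonsyn == nonsyn),
            "ttt_syn": ttt[0], "ttt_nonsyn": ttt[1]}


def classification_study(seed: int, n_seeds: int = 50,
                         ari_threshold: float = 0.8) -> dict[str, object]:
    """Archetype recovery by k-means and brute-force CH verification."""
    hits = 0
    for i in range(n_seeds):
        prof = synthetic_archetype_profiles(n_per_shape=10, seed=seed + i)
        truth = [k.rsplit("-", 1)[0] for k in prof]
        curves = classify.standardize_profiles(prof)
        part = classify.kmeans_curves(curves, k_candidates=[4], seed=seed + i)[4]
        hits += adjusted_rand_score(truth, part.labels) >= ari_threshold
    # exhaustive CH check on a four-point toy set
    X = np.array([[0.0], [1.0], [10.0], [11.0]])
    best_ch = -np.inf
    for assignment in itertools.product([0, 1], repeat=4):
        if len(set(assignment)) < 2:
            continue
        best_ch = max(best_ch, classify.calinski_harabasz(X, np.array(assignment)))
    direct = classify.calinski_harabasz(X, np.array([0, 0, 1, 1]))
    return {"ari_recovery_rate": hits / n_seeds,
            "ch_direct": float(direct), "ch_bruteforce_max": float(best_ch),
            "ch_matches_bruteforce": bool(np.isclose(direct, best_ch))}


def trio_rate_study(seed: int, n_replicates: int = 200,
                    mu: float = 2.0e-5) -> dict[str, object]:
    """Poisson round trip of the trio rate and the quadratic-sum identity."""
    rng = np.random.default_rng(seed)
    denom, years = 1e6, np.array(rate.DEFAULT_YEARS)
    hits = 0
    for _ in range(n_replicates):
        counts = rng.poisson(mu * denom * years)
        est = rate.rate_uncertainty(counts, denom, years)
        hits += abs(est.rate - mu) <= 2 * est.sd_total
    c = 0.37
    return {"coverage_2sd": hits / n_replicates,
            "quadratic_sum_identity": float(rate.combine_sd([c, c, c]) / (c * np.sqrt(3.0)))}
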