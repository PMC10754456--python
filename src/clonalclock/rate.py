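"""Parent–offspring (trio) mutation-rate estimation with a three-component
uncertainty model.

The per-offspring rate is the count of de novo biallelic mutated
nucleotides divided by the callable denominator (whole triploid genome for
the conservative lower bound, callable sites for the upper bound) and by
the elapsed years between parental and offspring birth dates. Uncertainty
combines, in rate units and in quadrature:

* genotyping — binomial variance of the observed mutation count;
* birth date — the birth-window uncertainty (SD = window/3) propagated
  through the 1/t dependence of the rate;
* biological — the SD of the per-offspring rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

#: Triploid marbled-crayfish genome size in nt (strict denominator).
GENOME_NT_TRIPLOID = 10.5e9
#: Callable sites of the relaxed-filter estimate (upper-bound denominator).
CALLABLE_SITES = 486_234
#: Elapsed years between parental and each offspring's birth.
DEFAULT_YEARS = (5.75, 6.08)


@dataclass
class RateEstimate:
    """Mutation rate per nucleotide per year with uncertainty components."""

    rate: float
    per_offspring_rates: np.ndarray
    counts: np.ndarray
    denominator_nt: float
    years: np.ndarray
    sd_genotyping: float | None = None
    sd_birthdate: float | None = None
    sd_biological: float | None = None
    sd_total: float | None = None


def trio_rate(counts, denominator_nt: float, years) -> RateEstimate:
    """Point estimate: mean of per-offspring rates count/(denominator*years)."""
    counts = np.asarray(counts, dtype=float)
    years = np.asarray(years, dtype=float)
    if denominator_nt <= 0:
        raise ValueError("denominator must be > 0")
    if np.any(counts < 0):
        raise ValueError("counts must be >= 0")
    if np.any(years <= 0):
        raise ValueError("years must be > 0")
    per = counts / denominator_nt / years
    return RateEstimate(rate=float(per.mean()), per_offspring_rates=per,
                        counts=counts, denominator_nt=float(denominator_nt),
                        years=years)


def rate_uncertainty(counts, denominator_nt: float, years,
                     birth_window_years: float = 1.0) -> RateEstimate:
    """Three-component standard deviation of the trio rate.

    Genotyping: per offspring, SD(count) = sqrt(n*p*(1-p)) with the plug-in
    p = count/denominator, converted to rate units and combined as the SD of
    the mean. Birth date: SD(t) = birth_window/3, propagated via
    |d rate/d t| = rate/t. Biological: SD across per-offspring rates
    (undefined, flagged None, with a single offspring). Total: quadratic sum.
    """
    est = trio_rate(counts, denominator_nt, years)
    counts, years = est.counts, est.years
    n_off = len(counts)
    p = counts / denominator_nt
    sd_count = np.sqrt(counts * (1.0 - p))
    sd_rate_geno = sd_count / denominator_nt / years
    est.sd_genotyping = float(np.sqrt(np.sum(sd_rate_geno ** 2)) / n_off)
    sd_t = birth_window_years / 3.0
    sd_rate_birth = est.per_offspring_rates * sd_t / years
    est.sd_birthdate = float(np.sqrt(np.sum(sd_rate_birth ** 2)) / n_off)
    if n_off >= 2:
        est.sd_biological = float(np.std(est.per_offspring_rates, ddof=1))
    else:
        warnings.warn("single offspring: biological variability undefined")
        est.sd_biological = None
    components = [est.sd_genotyping, est.sd_birthdate]
    if est.sd_biological is not None:
        components.append(est.sd_biological)
    est.sd_total = float(np.sqrt(sum(c * c for c in components)))
    return est


def combine_sd(components) -> float:
    """Quadratic sum of independent normal SD components."""
    components = np.asarray(components, dtype=float)
    return float(np.sqrt(np.sum(components ** 2)))
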