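"""Mutational-signature spectra along the inverse-allele-frequency axis.

Mutations are binned on u = 1/f, each bin is summarised as a 96-channel
single-base-substitution (SBS) spectrum in the pyrimidine-centred
trinucleotide convention, and signature exposures are obtained by
non-negative least squares against a catalog of signature profiles.
Exposures are fitted on raw counts (not proportions) so that the exposure
of a clock-like signature is directly a mutation flux, which is what the
downstream time reconstruction integrates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

# ---------------------------------------------------------------------------
# 96-channel convention

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = ("A", "C", "G", "T")

#: Canonical channel order: substitution-major (C>A, C>G, C>T, T>A, T>C, T>G),
#: then 5' flank, then 3' flank, both alphabetical — the COSMIC ordering.
CHANNELS_96 = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in _BASES
    for three in _BASES
)

_CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS_96)}

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def channel_of(ref: str, alt: str, context: str) -> str:
    """Map a substitution with its trinucleotide context to one of the 96
    pyrimidine-centred channels.

    ``context`` is the reference trinucleotide centred on the mutated base.
    Purine-centred changes are reverse-complemented (strand collapsing).
    """
    ref, alt, context = ref.upper(), alt.upper(), context.upper()
    if len(context) != 3 or context[1] != ref:
        raise ValueError(f"context {context!r} does not centre on ref {ref!r}")
    if ref == alt:
        raise ValueError("ref and alt are identical")
    if ref in ("A", "G"):
        context = revcomp(context)
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    channel = f"{context[0]}[{ref}>{alt}]{context[2]}"
    if channel not in _CHANNEL_INDEX:
        raise ValueError(f"invalid channel {channel!r}")
    return channel


def channel_parts(channel: str) -> tuple[str, str, str]:
    """Return (ref, alt, context) for a pyrimidine-centred channel label."""
    five, rest = channel[0], channel[2:]
    ref, alt, three = rest[0], rest[2], rest[4]
    return ref, alt, f"{five}{ref}{three}"


# ---------------------------------------------------------------------------
# Catalogs

def synthetic_catalog() -> pd.DataFrame:
    """A small synthetic signature catalog for simulations and tests.

    Three columns, 96 canonical rows, each summing to one:

    * ``SBS1``  — synthetic clock-like stand-in: mass concentrated on
      N[C>T]G channels (CpG deamination pattern);
    * ``SBS5``  — synthetic clock-like stand-in: broad, mildly T>C-tilted;
    * ``SBSflat`` — uniform over the 96 channels.

    These are constructed profiles, not COSMIC data; only their qualitative
    shapes (peaked vs flat) matter for the analyses in this package.
    """
    idx = pd.Index(CHANNELS_96, name="channel")
    sbs1 = np.full(96, 0.04 / 80)
    for i, ch in enumerate(CHANNELS_96):
        if "[C>T]" in ch and ch.endswith("G"):
            sbs1[i] = 0.96 / 16
    sbs5 = np.ones(96)
    for i, ch in enumerate(CHANNELS_96):
        if "[T>C]" in ch:
            sbs5[i] = 3.0
        elif "[C>T]" in ch:
            sbs5[i] = 1.8
    sbs5 /= sbs5.sum()
    flat = np.full(96, 1.0 / 96)
    return pd.DataFrame({"SBS1": sbs1 / sbs1.sum(), "SBS5": sbs5, "SBSflat": flat},
                        index=idx)


def mixture_channel_probs(catalog: pd.DataFrame, weights: dict[str, float]) -> np.ndarray:
    """Channel probabilities of a weighted signature mixture."""
    w = pd.Series(weights, dtype=float)
    if (w < 0).any():
        raise ValueError("signature weights must be nonnegative")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError(f"signature weights sum to {w.sum()}, expected 1")
    probs = np.zeros(96)
    for name, weight in w.items():
        if name not in catalog.columns:
            raise KeyError(f"signature {name!r} not in catalog")
        probs += weight * catalog[name].to_numpy()
    return probs / probs.sum()


# ---------------------------------------------------------------------------
# Binning on u = 1/f

@dataclass
class BinnedSpectrum:
    """96-channel mutation counts in one u-bin (centre ± half-width)."""

    center: float
    edges: tuple[float, float]          # [lo, hi), left-closed right-open
    counts: np.ndarray                  # length 96, canonical order
    total: int

    def __post_init__(self) -> None:
        assert self.counts.shape == (96,)
        assert int(self.counts.sum()) == self.total


def bin_spectra(records: pd.DataFrame, halfwidth: float = 0.5,
                u_range: tuple[float, float] | None = None) -> list[BinnedSpectrum]:
    """Tile the u axis into contiguous bins of width ``2*halfwidth`` and count
    mutations per 96-channel within each bin.

    Bin centres sit at integer multiples of the bin width (for the default
    half-width 0.5: centres 1, 2, 3, …; edges [c-0.5, c+0.5), left-closed).
    Records lacking a trinucleotide context are excluded with a warning count.
    Returns only non-empty bins unless ``u_range`` forces coverage.
    """
    width = 2.0 * halfwidth
    df = records
    has_ctx = df["context"].notna() if "context" in df.columns else pd.Series(False, index=df.index)
    n_missing = int((~has_ctx).sum())
    if n_missing:
        import warnings

        warnings.warn(f"{n_missing} records lack trinucleotide context; excluded")
    df = df[has_ctx]
    u = 1.0 / df["f"].to_numpy(dtype=float)
    if u_range is None:
        if len(u) == 0:
            return []
        u_range = (float(u.min()), float(u.max()))
    # centre index of u is floor(u/width + 1/2): edges [c-hw, c+hw) are
    # left-closed, so a value exactly on an edge joins the right bin
    lo_i = int(np.floor(u_range[0] / width + 0.5))
    hi_i = int(np.floor(u_range[1] / width + 0.5))
    centers = np.arange(lo_i, hi_i + 1) * width
    chan_idx = df["context"].map(_CHANNEL_INDEX).to_numpy()
    if np.isnan(chan_idx.astype(float)).any():
        raise ValueError("records carry context labels outside the 96-channel set")
    bin_of = np.floor(u / width + 0.5).astype(int) - lo_i
    out: list[BinnedSpectrum] = []
    for b, c in enumerate(centers):
        mask = bin_of == b
        if not mask.any():
            continue
        counts = np.bincount(chan_idx[mask].astype(int), minlength=96).astype(float)
        out.append(BinnedSpectrum(center=float(c),
                                  edges=(float(c - halfwidth), float(c + halfwidth)),
                                  counts=counts, total=int(counts.sum())))
    return out


# ---------------------------------------------------------------------------
# NNLS exposures

@dataclass
class ExposureFit:
    """Non-negative signature exposures for one spectrum, in mutation counts."""

    signatures: tuple[str, ...]
    theta: np.ndarray
    residual: float
    flagged_zero: bool = False


@dataclass
class ExposureSeries:
    """Per-bin exposures with bootstrap confidence intervals."""

    centers: np.ndarray
    signatures: tuple[str, ...]
    theta: np.ndarray                   # (n_bins, n_signatures)
    residual: np.ndarray                # (n_bins,)
    ci_lo: np.ndarray | None = None     # (n_bins, n_signatures)
    ci_hi: np.ndarray | None = None
    low_confidence: np.ndarray | None = None   # bins with <10 mutations
    totals: np.ndarray | None = None

    def clock_exposure(self, clock: tuple[str, ...] = ("SBS1", "SBS5")) -> np.ndarray:
        """Summed exposure of the configured clock-like set, per bin."""
        cols = [self.signatures.index(s) for s in clock if s in self.signatures]
        if not cols:
            raise ValueError(f"none of {clock} present in fitted signatures")
        return self.theta[:, cols].sum(axis=1)


def fit_exposures(counts: np.ndarray, catalog: pd.DataFrame) -> ExposureFit:
    """Lawson–Hanson NNLS of a 96-channel count vector on catalog columns.

    theta = argmin ||catalog @ theta - counts||_2 s.t. theta >= 0, in
    mutation-count units. A zero spectrum returns all-zero exposures, flagged.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (96,):
        raise ValueError("expected a 96-channel count vector")
    if counts.sum() == 0:
        return ExposureFit(tuple(catalog.columns), np.zeros(catalog.shape[1]),
                           0.0, flagged_zero=True)
    theta, rnorm = nnls(catalog.to_numpy(), counts)
    return ExposureFit(tuple(catalog.columns), theta, float(rnorm))


def fit_exposure_series(spectra: list[BinnedSpectrum], catalog: pd.DataFrame,
                        min_count: int = 10) -> ExposureSeries:
    """Fit NNLS exposures independently in every u-bin."""
    centers = np.array([s.center for s in spectra])
    theta = np.zeros((len(spectra), catalog.shape[1]))
    resid = np.zeros(len(spectra))
    totals = np.array([s.total for s in spectra], dtype=float)
    for i, s in enumerate(spectra):
        f = fit_exposures(s.counts, catalog)
        theta[i] = f.theta
        resid[i] = f.residual
    return ExposureSeries(centers=centers, signatures=tuple(catalog.columns),
                          theta=theta, residual=resid,
                          low_confidence=totals < min_count, totals=totals)


def bootstrap_exposures_spectrum(counts: np.ndarray, catalog: pd.DataFrame,
                                 B: int = 1000, seed: int = 0
                                 ) -> tuple[ExposureFit, np.ndarray, np.ndarray]:
    """Bootstrap 95% CI of the exposures of a single 96-channel spectrum.

    Mutation-level resampling with replacement is equivalent to redrawing
    the channel counts from a multinomial at the observed proportions, which
    is what this does. Returns (point fit, ci_lo, ci_hi) per signature.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    counts = np.asarray(counts, dtype=float)
    point = fit_exposures(counts, catalog)
    n = int(counts.sum())
    if n == 0:
        z = np.zeros(catalog.shape[1])
        return point, z, z
    rng = np.random.default_rng(seed)
    reps = rng.multinomial(n, counts / n, size=B)
    thetas = np.array([fit_exposures(r.astype(float), catalog).theta for r in reps])
    return point, np.percentile(thetas, 2.5, axis=0), np.percentile(thetas, 97.5, axis=0)


def bootstrap_exposures(records: pd.DataFrame, catalog: pd.DataFrame,
                        B: int = 1000, seed: int = 0,
                        halfwidth: float = 0.5,
                        subsample_threshold: int = 100_000,
                        subsample_to: int = 50_000) -> ExposureSeries:
    """Bootstrap 95% CIs on per-bin exposures by resampling mutations.

    Mutations are resampled with replacement ``B`` times; each replicate is
    re-binned and re-fitted. Sets larger than ``subsample_threshold`` are
    first subsampled without replacement to ``subsample_to`` mutations, and
    exposures rescaled back to the full-count scale.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    rng = np.random.default_rng(seed)
    df = records[records.get("context").notna()] if "context" in records.columns else records.iloc[0:0]
    scale = 1.0
    if len(df) > subsample_threshold:
        keep = rng.choice(len(df), size=subsample_to, replace=False)
        scale = len(df) / subsample_to
        df = df.iloc[np.sort(keep)]
    spectra = bin_spectra(df, halfwidth=halfwidth)
    point = fit_exposure_series(spectra, catalog)
    centers = point.centers
    u_range = (float(centers.min()), float(centers.max())) if len(centers) else None
    n = len(df)
    boot = np.full((B, len(centers), catalog.shape[1]), np.nan)
    center_pos = {c: i for i, c in enumerate(centers)}
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        rep = df.iloc[idx]
        for s in bin_spectra(rep, halfwidth=halfwidth, u_range=u_range):
            if s.center not in center_pos:
                continue
            boot[b, center_pos[s.center]] = fit_exposures(s.counts, catalog).theta
    boot = np.where(np.isnan(boot), 0.0, boot) * scale
    ci_lo = np.percentile(boot, 2.5, axis=0)
    ci_hi = np.percentile(boot, 97.5, axis=0)
    point.theta *= scale
    point.ci_lo, point.ci_hi = ci_lo, ci_hi
    return point
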