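"""Frequency-resolved dN/dS with a codon-opportunity baseline.

The raw nonsynonymous/synonymous count ratio in a window is normalised by
the genome-wide opportunity ratio — the number of possible nonsynonymous
single-base changes divided by the number of possible synonymous ones,
weighted by codon usage of the coding sequences. A normalised ratio of 1
indicates neutrality, < 1 purifying and > 1 positive selection. Stop-gain
changes count as nonsynonymous; mutations out of stop codons contribute no
opportunities (stops are excluded from the opportunity sums).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .variantio import CODON_TO_AA, STOP_CODONS

logger = logging.getLogger(__name__)

_BASES = ("A", "C", "G", "T")

NONSYN_EFFECTS = frozenset({"nonsyn", "stopgain"})


def codon_changes(codon: str) -> tuple[int, int]:
    """(synonymous, nonsynonymous) counts among the 9 single-base changes of
    a codon; stop-gain counts as nonsynonymous. Always sums to 9."""
    aa = CODON_TO_AA[codon]
    syn = nonsyn = 0
    for i in range(3):
        for b in _BASES:
            if b == codon[i]:
                continue
            new = codon[:i] + b + codon[i + 1:]
            if CODON_TO_AA[new] == aa:
                syn += 1
            else:
                nonsyn += 1
    return syn, nonsyn


@dataclass
class OpportunityTable:
    """Codon-usage-weighted counts of possible syn/nonsyn changes."""

    codon_counts: pd.Series            # codon -> occurrences in the CDS set
    per_codon: pd.DataFrame            # codon -> syn, nonsyn (out of 9)
    total_syn: float
    total_nonsyn: float
    n_cds_kept: int
    n_cds_dropped: int

    @property
    def baseline(self) -> float:
        """Genome-wide nonsynonymous/synonymous opportunity ratio."""
        if self.total_syn == 0:
            raise ValueError("no synonymous opportunities; baseline undefined")
        return self.total_nonsyn / self.total_syn


def _cds_valid(seq: str) -> bool:
    if len(seq) % 3 != 0 or len(seq) < 6:
        return False
    if not seq.startswith("ATG"):
        return False
    codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
    if codons[-1] not in STOP_CODONS:
        return False
    if any(c in STOP_CODONS for c in codons[:-1]):
        return False
    return all(set(c) <= set(_BASES) for c in codons)


def codon_opportunities(cds_fasta: str | Path | list[str]) -> OpportunityTable:
    """Count codons of valid CDS and enumerate their possible changes.

    CDS are dropped (and logged) when they do not start with ATG, do not end
    in a stop codon, contain internal stops, or have a length not divisible
    by 3. The terminal stop codon is excluded from the opportunity sums.
    """
    if isinstance(cds_fasta, (str, Path)):
        seqs = [str(rec.seq).upper() for rec in SeqIO.parse(str(cds_fasta), "fasta")]
    else:
        seqs = [s.upper() for s in cds_fasta]
    kept = [s for s in seqs if _cds_valid(s)]
    dropped = len(seqs) - len(kept)
    if dropped:
        logger.info("codon_opportunities: dropped %d invalid CDS", dropped)
    if not kept:
        raise ValueError("no valid coding sequences survive filtering")
    counts: dict[str, int] = {}
    for s in kept:
        for i in range(0, len(s) - 3, 3):      # terminal stop excluded
            c = s[i:i + 3]
            counts[c] = counts.get(c, 0) + 1
    codon_counts = pd.Series(counts).sort_index()
    per = {c: codon_changes(c) for c in codon_counts.index}
    per_codon = pd.DataFrame(per, index=["syn", "nonsyn"]).T
    total_syn = float((codon_counts * per_codon["syn"]).sum())
    total_nonsyn = float((codon_counts * per_codon["nonsyn"]).sum())
    return OpportunityTable(codon_counts=codon_counts, per_codon=per_codon,
                            total_syn=total_syn, total_nonsyn=total_nonsyn,
                            n_cds_kept=len(kept), n_cds_dropped=dropped)


# ---------------------------------------------------------------------------
# Longitudinal dN/dS

@dataclass
class DndsSeries:
    """Windowed, baseline-normalised dN/dS along u = 1/f."""

    table: pd.DataFrame    # u_center, n_nonsyn, n_syn, dnds, ci_lo, ci_hi, dnds_smooth
    baseline: float
    window_halfwidth: float


def _smooth(values: np.ndarray) -> np.ndarray:
    """Running median (window 5) then moving average (window 3), NaN-aware."""
    s = pd.Series(values)
    med = s.rolling(5, center=True, min_periods=1).median()
    return med.rolling(3, center=True, min_periods=1).mean().to_numpy()


def dnds_ratio(n_nonsyn: int, n_syn: int, baseline: float) -> float:
    """(nonsyn/syn)/baseline; undefined (NaN) when no synonymous counts."""
    if n_syn == 0:
        return float("nan")
    return (n_nonsyn / n_syn) / baseline


def dnds_longitudinal(records: pd.DataFrame, baseline: float,
                      window_halfwidth: float = 1.0,
                      step: float | None = None,
                      min_mutations: int = 20,
                      B: int = 1000, seed: int = 0) -> DndsSeries:
    """Sliding-window dN/dS over u with bootstrap 95% CIs.

    Per window the ratio is (#nonsyn / #syn) / baseline, with stop-gain in
    the numerator; windows lacking synonymous mutations or holding fewer
    than ``min_mutations`` coding mutations are masked (NaN), not infinite.
    CIs come from resampling the mutations within each window; smoothing is
    a running median then a moving average.
    """
    eff = records["effect"].astype(str)
    coding = records[eff.isin(NONSYN_EFFECTS | {"syn"})]
    if (coding["effect"] == "syn").sum() == 0:
        raise ValueError("no synonymous mutations anywhere; baseline ratio undefined")
    u = 1.0 / coding["f"].to_numpy(dtype=float)
    is_nonsyn = coding["effect"].astype(str).isin(NONSYN_EFFECTS).to_numpy()
    if step is None:
        step = window_halfwidth / 2.0
    centers = np.arange(np.floor(u.min()), np.ceil(u.max()) + step / 2, step)
    rng = np.random.default_rng(seed)
    rows = []
    for c in centers:
        mask = (u >= c - window_halfwidth) & (u < c + window_halfwidth)
        nn = int(is_nonsyn[mask].sum())
        ns = int(mask.sum() - nn)
        point = dnds_ratio(nn, ns, baseline)
        if mask.sum() < min_mutations or ns == 0:
            rows.append({"u_center": c, "n_nonsyn": nn, "n_syn": ns,
                         "dnds": np.nan, "ci_lo": np.nan, "ci_hi": np.nan})
            continue
        labels = is_nonsyn[mask]
        n_w = len(labels)
        boot = np.empty(B)
        draws = rng.integers(0, n_w, size=(B, n_w))
        nn_b = labels[draws].sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            boot = (nn_b / (n_w - nn_b)) / baseline
        boot = boot[np.isfinite(boot)]
        if len(boot) == 0:
            lo = hi = np.nan
        else:
            lo, hi = np.percentile(boot, [2.5, 97.5])
        rows.append({"u_center": c, "n_nonsyn": nn, "n_syn": ns,
                     "dnds": point, "ci_lo": lo, "ci_hi": hi})
    table = pd.DataFrame(rows)
    table["dnds_smooth"] = _smooth(table["dnds"].to_numpy())
    return DndsSeries(table=table, baseline=baseline,
                      window_halfwidth=window_halfwidth)


def synthetic_cds(n_cds: int, n_codons: int, seed: int = 0) -> list[str]:
    """Random valid coding sequences (ATG + non-stop codons + stop) for
    opportunity-baseline fixtures; synthetic, not drawn from any genome."""
    rng = np.random.default_rng(seed)
    sense = [a + b + c for a in _BASES for b in _BASES for c in _BASES
             if (a + b + c) not in STOP_CODONS]
    stops = sorted(STOP_CODONS)
    out = []
    for _ in range(n_cds):
        body = rng.choice(sense, size=n_codons)
        out.append("ATG" + "".join(body) + stops[rng.integers(len(stops))])
    return out


def neutral_label_probability(opportunities: OpportunityTable) -> float:
    """Probability that a random coding mutation is nonsynonymous when labels
    are drawn proportionally to opportunities."""
    return opportunities.total_nonsyn / (opportunities.total_nonsyn
                                         + opportunities.total_syn)


def opportunity_proportional_labels(n: int, opportunities: OpportunityTable,
                                    seed: int = 0, selection_s: float = 1.0,
                                    u_range: tuple[float, float] = (1.0, 20.0)
                                    ) -> pd.DataFrame:
    """Synthetic coding-mutation table with labels drawn proportionally to
    the codon opportunities (neutral when ``selection_s`` = 1; values < 1
    thin the nonsynonymous class by that factor). u is uniform over
    ``u_range``; the default study size for coverage checks is n = 1e4.
    """
    rng = np.random.default_rng(seed)
    q = neutral_label_probability(opportunities)
    q_sel = q * selection_s / (q * selection_s + (1.0 - q))
    u = rng.uniform(*u_range, size=n)
    eff = np.where(rng.random(n) < q_sel, "nonsyn", "syn")
    return pd.DataFrame({"f": 1.0 / u, "effect": eff})
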