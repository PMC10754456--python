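"""Synthetic clonal-expansion simulator with a ground-truth ledger.

The generative model is the discrete-step counterpart of the continuous
accumulation law dM = mu * pi * omega * gamma * N dt: cells live in
non-overlapping steps; at each step a cell divides with probability
``omega`` (divisions per unit time, one step = one time unit), each daughter
survives independently with probability ``gamma``, and every surviving
daughter acquires Poisson(``mu``) new single-base substitutions on one of
``ploidy_pi`` genome copies (infinite-sites: every event hits a fresh
coordinate). The true allele frequency of a mutation at observation time is

    f = carriers / (ploidy_pi * N_final),

where ``carriers`` is the number of surviving cells descending from the cell
in which the event occurred.

A small ``omega`` is the fidelity knob of the discretisation: the population
changes by the factor 1 + omega*(2*gamma - 1) per step, so with omega ~ 0.05
the population size is nearly constant across any short window even when
gamma switches abruptly — the regime the continuous model assumes. Both
``omega`` and ``gamma`` may be step functions of time (arrays over steps).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .signatures import CHANNELS_96, channel_parts, mixture_channel_probs, synthetic_catalog

# Share of coding mutations that would be nonsynonymous absent selection,
# close to the genome-wide opportunity ratio of the standard genetic code.
P_NONSYN_CODING = 0.75
# Share of nonsynonymous events that create a stop codon.
P_STOPGAIN_OF_NONSYN = 0.05


@dataclass
class SimulationConfig:
    """Evolutionary parameters of a simulated clonal expansion.

    mu : mutations per genome per division (per surviving daughter).
    genome_size : haploid genome length in nt (coordinate space).
    ploidy_pi : genome copies per cell.
    omega : division probability per cell per step; scalar or per-step array.
    gamma : daughter survival probability in [0, 1]; scalar or per-step array.
    n0 : founding cells.
    n_generations : number of steps.
    signature_weights : mixture over catalog signature columns, summing to 1.
    selection_s : multiplicative retention of nonsynonymous events
        (1 = neutral, 0.5 = half of the nonsynonymous events purged at origin).
    coding_fraction : fraction of mutations falling in coding sequence.
    depth : mean sequencing depth for read-level noise.
    seed : RNG seed; all substreams derive from it.
    """

    mu: float = 0.3
    genome_size: int = 100_000_000
    ploidy_pi: int = 2
    omega: float | np.ndarray = 0.3
    gamma: float | np.ndarray = 0.95
    n0: int = 1
    n_generations: int = 40
    signature_weights: dict[str, float] = field(
        default_factory=lambda: {"SBS1": 0.6, "SBS5": 0.4})
    selection_s: float = 1.0
    coding_fraction: float = 0.02
    depth: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.array(list(self.signature_weights.values()), dtype=float)
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("signature weights must be nonnegative and sum to 1")
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        for g in np.atleast_1d(np.asarray(self.gamma, dtype=float)):
            if not 0.0 <= g <= 1.0:
                raise ValueError("gamma must lie in [0, 1] at all times")
        for o in np.atleast_1d(np.asarray(self.omega, dtype=float)):
            if o < 0:
                raise ValueError("omega must be >= 0")
        if self.n0 < 1 or self.ploidy_pi < 1:
            raise ValueError("n0 and ploidy_pi must be >= 1")

    def per_step(self, name: str) -> np.ndarray:
        val = np.asarray(getattr(self, name), dtype=float)
        if val.ndim == 0:
            return np.full(self.n_generations, float(val))
        if len(val) != self.n_generations:
            raise ValueError(f"{name} array must have length n_generations")
        return val


@dataclass
class SimulationTruth:
    """Ground-truth ledger of one simulated expansion.

    ``events`` describes emitted (surviving, selection-retained) mutations,
    row-aligned with the variant table. ``raw_events`` is the complete event
    log (origin step, origin cell) including lineages that later died and
    events purged by selection; ``retained`` marks the selection survivors.
    ``parents`` holds the per-step parent-pointer arrays for replay oracles.
    """

    config: SimulationConfig
    n_per_generation: np.ndarray
    events: pd.DataFrame
    extinct: bool = False
    parents: list[np.ndarray] | None = None
    raw_events: np.ndarray | None = None       # (n_events, 2): origin step, cell
    retained: np.ndarray | None = None         # selection retention mask
    gamma_ratio_realized: float | None = None
    resection_generation: int | None = None
    primary_events: pd.DataFrame | None = None


class _Lineage:
    """Forward population of anonymous cells tracked by parent pointers."""

    def __init__(self, n0: int):
        self.n0 = n0
        self.n = n0
        self.parents: list[np.ndarray] = []      # parents[g-1][i] = index at step g-1
        self.event_gens: list[int] = []
        self.event_cells: list[int] = []

    def step(self, omega: float, gamma: float, mu: float,
             rng: np.random.Generator) -> None:
        g = len(self.parents) + 1
        n = self.n
        divides = rng.random(n) < omega
        div_idx = np.flatnonzero(divides)
        d_survive = rng.random((len(div_idx), 2)) < gamma
        keep_idx = np.flatnonzero(~divides)
        parent = np.concatenate([
            keep_idx,
            np.repeat(div_idx, d_survive.sum(axis=1)),
        ]).astype(np.int64)
        self.parents.append(parent)
        self.n = len(parent)
        n_new = int(d_survive.sum())
        if mu > 0 and n_new > 0:
            k = rng.poisson(mu, size=n_new)
            hit = np.repeat(np.arange(len(keep_idx), len(parent)), k)
            self.event_gens.extend([g] * len(hit))
            self.event_cells.extend(int(c) for c in hit)

    def subsample(self, frac: float, rng: np.random.Generator) -> None:
        """Resection: keep each cell independently with probability frac."""
        keep = np.flatnonzero(rng.random(self.n) < frac)
        self.parents.append(keep.astype(np.int64))
        self.n = len(keep)

    def pass_through(self) -> None:
        self.parents.append(np.arange(self.n, dtype=np.int64))

    def descendant_counts(self, upto: int | None = None) -> list[np.ndarray]:
        """counts[g][i] = surviving descendants (at step ``upto``, default
        final) of cell i in the population after step g."""
        last = len(self.parents) if upto is None else upto
        counts: list[np.ndarray] = [np.array([])] * (last + 1)
        counts[last] = np.ones(len(self.parents[last - 1]) if last > 0 else self.n0,
                               dtype=np.int64)
        for g in range(last, 0, -1):
            n_prev = len(self.parents[g - 2]) if g >= 2 else self.n0
            counts[g - 1] = np.bincount(self.parents[g - 1],
                                        weights=counts[g],
                                        minlength=n_prev).astype(np.int64)
        return counts


def _assign_annotations(n_events: int, config: SimulationConfig,
                        rng: np.random.Generator, catalog: pd.DataFrame):
    """Draw channel, effect label and selection retention per raw event."""
    probs = mixture_channel_probs(catalog, config.signature_weights)
    chan = rng.choice(96, size=n_events, p=probs)
    coding = rng.random(n_events) < config.coding_fraction
    nonsyn = coding & (rng.random(n_events) < P_NONSYN_CODING)
    stop = nonsyn & (rng.random(n_events) < P_STOPGAIN_OF_NONSYN)
    effect = np.where(~coding, "noncoding",
                      np.where(~nonsyn, "syn",
                               np.where(stop, "stopgain", "nonsyn")))
    retain = np.ones(n_events, dtype=bool)
    if config.selection_s < 1.0:
        purged = nonsyn & (rng.random(n_events) >= config.selection_s)
        retain = ~purged
    return chan, effect, retain


def _unique_positions(n: int, genome_size: int, rng: np.random.Generator) -> np.ndarray:
    """Fresh coordinate per event (infinite-sites)."""
    pos = rng.integers(1, genome_size + 1, size=n)
    seen: set[int] = set()
    for i in range(n):
        while int(pos[i]) in seen:
            pos[i] = rng.integers(1, genome_size + 1)
        seen.add(int(pos[i]))
    return pos


@dataclass
class _Annotations:
    gens: np.ndarray
    cells: np.ndarray
    chan: np.ndarray
    effect: np.ndarray
    retain: np.ndarray
    pos: np.ndarray


def _annotate_events(lin: _Lineage, config: SimulationConfig,
                     rng: np.random.Generator, catalog: pd.DataFrame) -> _Annotations:
    n_events = len(lin.event_gens)
    chan, effect, retain = _assign_annotations(n_events, config, rng, catalog)
    pos = _unique_positions(n_events, config.genome_size, rng)
    return _Annotations(gens=np.asarray(lin.event_gens, dtype=np.int64),
                        cells=np.asarray(lin.event_cells, dtype=np.int64),
                        chan=chan, effect=effect, retain=retain, pos=pos)


def _emit(ann: _Annotations, config: SimulationConfig,
          counts_by_step: list[np.ndarray], n_final: int,
          max_gen: int | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the variant table and the row-aligned truth-event table from
    annotated events, keeping selection-retained events with >= 1 carrier."""
    mask = ann.retain.copy()
    if max_gen is not None:
        mask &= ann.gens <= max_gen
    idx = np.flatnonzero(mask)
    gens, cells = ann.gens[idx], ann.cells[idx]
    carriers = np.array([counts_by_step[g][c] for g, c in zip(gens, cells)],
                        dtype=np.int64)
    alive = carriers > 0
    idx, gens, cells, carriers = idx[alive], gens[alive], cells[alive], carriers[alive]
    order = np.lexsort((ann.pos[idx], gens))
    idx, gens, cells, carriers = idx[order], gens[order], cells[order], carriers[order]
    true_f = carriers / (config.ploidy_pi * n_final)
    channels = [CHANNELS_96[i] for i in ann.chan[idx]]
    parts = [channel_parts(c) for c in channels]
    table = pd.DataFrame({
        "chrom": "sim1",
        "pos": ann.pos[idx],
        "ref": [p[0] for p in parts],
        "alt": [p[1] for p in parts],
        "context": channels,
        "effect": ann.effect[idx],
        "true_f": true_f,
        "origin_gen": gens,
        "f": true_f,
    })
    events = pd.DataFrame({
        "origin_gen": gens,
        "subclone": cells,
        "carriers": carriers,
        "cell_fraction": carriers / n_final,
        "true_f": true_f,
        "effect": ann.effect[idx],
        "channel": channels,
    })
    return table, events


_EMPTY_COLUMNS = ["chrom", "pos", "ref", "alt", "context", "effect",
                  "true_f", "origin_gen", "f"]


def simulate_clonal_expansion(config: SimulationConfig) -> tuple[pd.DataFrame, SimulationTruth]:
    """Grow a clone under the configured parameters and return all mutations
    present in at least one surviving cell, with their true frequencies.

    Population extinction is reported via ``truth.extinct`` (with an empty
    variant table), not an exception.
    """
    rng = np.random.default_rng(config.seed)
    catalog = synthetic_catalog()
    omega = config.per_step("omega")
    gamma = config.per_step("gamma")
    lin = _Lineage(config.n0)
    n_t = [config.n0]
    for g in range(config.n_generations):
        lin.step(omega[g], gamma[g], config.mu, rng)
        n_t.append(lin.n)
        if lin.n == 0:
            truth = SimulationTruth(config=config, n_per_generation=np.array(n_t),
                                    events=pd.DataFrame(), extinct=True,
                                    parents=lin.parents,
                                    raw_events=np.column_stack(
                                        [lin.event_gens, lin.event_cells]))
            return pd.DataFrame(columns=_EMPTY_COLUMNS), truth
    ann = _annotate_events(lin, config, rng, catalog)
    counts = lin.descendant_counts()
    table, events = _emit(ann, config, counts, lin.n)
    truth = SimulationTruth(config=config, n_per_generation=np.array(n_t),
                            events=events, parents=lin.parents,
                            raw_events=np.column_stack([ann.gens, ann.cells]),
                            retained=ann.retain)
    return table, truth


def simulate_primary_recurrent(config: SimulationConfig, gamma_ratio: float,
                               resection_fraction: float,
                               n_generations_recurrent: int | None = None
                               ) -> tuple[pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """Grow a primary tumour, resect, and regrow a recurrence.

    The primary runs under ``config`` (its gamma schedule ends in the
    primary-end survival regime gamma_P); at resection a random fraction
    ``resection_fraction`` of cells seeds the recurrence, grown under the
    constant survival gamma_R = gamma_ratio * gamma_P, where gamma_P is the
    last per-step gamma of the primary. Inherited mutations keep their
    identity (position, context, effect) across the two tables. Returns
    (primary table, recurrent table, truth); recurrent rows carry a
    ``de_novo`` flag.
    """
    if gamma_ratio <= 0:
        raise ValueError("gamma_ratio must be > 0")
    if not 0.0 < resection_fraction <= 1.0:
        raise ValueError("resection_fraction must lie in (0, 1]")
    gamma = config.per_step("gamma")
    gamma_p = float(gamma[-1])
    gamma_r = gamma_ratio * gamma_p
    if gamma_r > 1.0 + 1e-12:
        raise ValueError(
            f"gamma_R = gamma_ratio*gamma_P = {gamma_r:.3f} exceeds 1; "
            "survival probability cannot exceed 1")
    n_rec = (n_generations_recurrent if n_generations_recurrent is not None
             else config.n_generations)
    rng = np.random.default_rng(config.seed)
    catalog = synthetic_catalog()
    omega = config.per_step("omega")

    lin = _Lineage(config.n0)
    n_t = [config.n0]
    for g in range(config.n_generations):
        lin.step(omega[g], gamma[g], config.mu, rng)
        n_t.append(lin.n)
        if lin.n == 0:
            break
    resection_step = len(lin.parents)
    if lin.n == 0:
        truth = SimulationTruth(config=config, n_per_generation=np.array(n_t),
                                events=pd.DataFrame(), extinct=True,
                                parents=lin.parents)
        empty = pd.DataFrame(columns=_EMPTY_COLUMNS)
        return empty, empty.copy(), truth
    n_primary_final = lin.n
    if resection_fraction < 1.0:
        lin.subsample(resection_fraction, rng)
    else:
        lin.pass_through()
    omega_r = float(np.atleast_1d(np.asarray(config.omega, dtype=float))[-1])
    extinct_rec = lin.n == 0
    if not extinct_rec:
        for _ in range(n_rec):
            lin.step(omega_r, gamma_r, config.mu, rng)
            n_t.append(lin.n)
            if lin.n == 0:
                extinct_rec = True
                break
    ann = _annotate_events(lin, config, rng, catalog)
    counts_primary = lin.descendant_counts(upto=resection_step)
    primary_table, primary_events = _emit(ann, config, counts_primary,
                                          n_primary_final, max_gen=resection_step)
    if extinct_rec:
        truth = SimulationTruth(config=config, n_per_generation=np.array(n_t),
                                events=pd.DataFrame(), extinct=True,
                                parents=lin.parents, primary_events=primary_events,
                                resection_generation=resection_step,
                                gamma_ratio_realized=gamma_r / gamma_p)
        return primary_table, pd.DataFrame(columns=_EMPTY_COLUMNS), truth
    counts_full = lin.descendant_counts()
    recurrent_table, recurrent_events = _emit(ann, config, counts_full, lin.n)
    recurrent_table["de_novo"] = recurrent_table["origin_gen"].to_numpy() > resection_step
    recurrent_events["de_novo"] = recurrent_events["origin_gen"].to_numpy() > resection_step
    truth = SimulationTruth(config=config, n_per_generation=np.array(n_t),
                            events=recurrent_events, parents=lin.parents,
                            raw_events=np.column_stack([ann.gens, ann.cells]),
                            retained=ann.retain,
                            gamma_ratio_realized=gamma_r / gamma_p,
                            resection_generation=resection_step,
                            primary_events=primary_events)
    return primary_table, recurrent_table, truth


def attach_sequencing_noise(variants: pd.DataFrame, depth: float,
                            ploidy_pi: int, seed: int) -> pd.DataFrame:
    """Overlay read-sampling noise on true allele frequencies.

    Total depth ~ Poisson(depth) (floored at 1 read so every variant stays
    observable); alt depth ~ Binomial(total, true_f); observed f =
    alt/total. QUAL is populated with a depth-scaled placeholder score.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    rng = np.random.default_rng(seed)
    out = variants.copy()
    n = len(out)
    total = np.maximum(rng.poisson(depth, size=n), 1)
    alt = rng.binomial(total, out["true_f"].to_numpy(dtype=float))
    out["depth"] = total
    out["alt_depth"] = alt
    out["f"] = alt / total
    out["qual"] = np.round(30.0 + 10.0 * np.log10(1.0 + alt), 2)
    return out


# ---------------------------------------------------------------------------
# Study designs: canonical simulation conditions used by recovery analyses

def neutral_growth_study(seed: int, mu: float = 0.3, ploidy_pi: int = 2,
                         n_generations: int = 32) -> tuple[pd.DataFrame, SimulationTruth]:
    """Neutral exponential growth sized to yield >= 1e4 surviving variants.

    Conditions: mu = 0.3 mutations/genome/division, diploid, omega = 0.3,
    gamma = 0.95, 20 founding cells (several founders suppress the
    early-lag variance of single-lineage branching, so every realisation
    reaches the target variant count). Realisations that nevertheless fall
    short are redrawn from a seed-derived substream.
    """
    for attempt in range(20):
        config = SimulationConfig(mu=mu, ploidy_pi=ploidy_pi, omega=0.3, gamma=0.95,
                                  n0=20, n_generations=n_generations,
                                  selection_s=1.0, seed=seed * 100 + attempt)
        table, truth = simulate_clonal_expansion(config)
        if not truth.extinct and len(table) >= 10_000:
            return table, truth
    raise RuntimeError("no realisation reached 1e4 variants in 20 attempts")


def primary_recurrent_study(seed: int, gamma_ratio: float = 30.0,
                            boundary_steps: int = 3,
                            n_growth_steps: int = 185,
                            n_recurrent_steps: int = 40,
                            omega: float = 0.05,
                            gamma_grow: float = 0.9,
                            resection_fraction: float = 0.3,
                            mu: float = 0.3,
                            n0: int = 30):
    """Paired primary/recurrent simulation for survival-ratio recovery.

    The primary grows under gamma_grow, then spends ``boundary_steps`` steps
    in the primary-end regime gamma_P = gamma_grow / gamma_ratio before
    resection; the recurrence runs at gamma_R = gamma_grow. The small omega
    keeps N nearly constant across the boundary windows (see module
    docstring). Returns (primary, recurrent, truth, boundary_steps).
    """
    gamma_p = gamma_grow / gamma_ratio
    gamma = np.concatenate([np.full(n_growth_steps, gamma_grow),
                            np.full(boundary_steps, gamma_p)])
    config = SimulationConfig(mu=mu, ploidy_pi=2, omega=omega, gamma=gamma,
                              n0=n0, n_generations=len(gamma), seed=seed)
    primary, recurrent, truth = simulate_primary_recurrent(
        config, gamma_ratio=gamma_ratio, resection_fraction=resection_fraction,
        n_generations_recurrent=n_recurrent_steps)
    return primary, recurrent, truth, boundary_steps


def replay_event_log(truth: SimulationTruth) -> int:
    """Independent oracle: recount surviving, selection-retained mutation
    events by forward replay of the parent arrays, one event at a time.

    O(events * steps * N) — meant for small simulations only.
    """
    if truth.parents is None or truth.raw_events is None:
        raise ValueError("truth does not retain parent arrays / raw events")
    retained = (truth.retained if truth.retained is not None
                else np.ones(len(truth.raw_events), dtype=bool))
    survived = 0
    for (g, cell), keep in zip(truth.raw_events, retained):
        if not keep:
            continue
        alive = {int(cell)}
        for step in range(int(g), len(truth.parents)):
            par = truth.parents[step]
            alive = {i for i, p in enumerate(par) if int(p) in alive}
            if not alive:
                break
        if alive:
            survived += 1
    return survived
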