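"""Random mitotic segregation of individual mtDNA molecules.

Simulates vegetative segregation of a heteroplasmic point mutation
(m.3243A>G) through cell-culture passaging: a founder cell with a given
fraction of mutant molecules grows to confluence, is bottlenecked to a
fraction of the population (1/10 split), and regrown, for many passages.
Replication is neutral — templates are copied with no preference for
either genotype — and at division each molecule is independently assigned
to one of the two daughter cells.

Two replication modes are supported:

``strict_doubling``
    every molecule is copied exactly once per cycle, so drift arises from
    partitioning alone;
``relaxed_urn``
    molecules are added one at a time, each copying a template drawn
    uniformly from the current pool (a Pólya urn), which both restores the
    cell's copy-number set point and roughly doubles the per-generation
    drift rate.

An analytic variance oracle (exact finite-N heterozygosity-decay factors)
backs fast copy-number threshold scans, cross-checked against simulation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from numpy.random import Generator, default_rng
from scipy import stats

from .errors import ExtinctLineageError

logger = logging.getLogger(__name__)

STRICT_DOUBLING = "strict_doubling"
RELAXED_URN = "relaxed_urn"
REPLICATION_MODES = (STRICT_DOUBLING, RELAXED_URN)

#: effective population doublings per passage for a 10% split
DOUBLINGS_PER_TENFOLD = math.log2(10.0)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MoleculeCell:
    """A cell summarized by its mutant and wild-type mtDNA molecule counts."""

    mutant: int
    wildtype: int

    def __post_init__(self):
        if self.mutant < 0 or self.wildtype < 0:
            raise ValueError("molecule counts must be non-negative")

    @property
    def total(self) -> int:
        return self.mutant + self.wildtype

    @property
    def is_dead(self) -> bool:
        return self.total == 0

    @property
    def is_homoplasmic(self) -> bool:
        return self.mutant == 0 or self.wildtype == 0

    @property
    def heteroplasmy(self) -> float:
        if self.total == 0:
            raise ExtinctLineageError("heteroplasmy undefined for a dead cell")
        return self.mutant / self.total


@dataclass(frozen=True)
class DriftConfig:
    """Parameters of a passaging simulation.

    ``population_cap`` defaults to 10^4 cells, a scaled-down stand-in for the
    ~10^6-cell confluent dish; between-cell drift is dominated by within-cell
    sampling, so the cap has little effect on heteroplasmy variance (this is
    covered by a test).
    """

    founder_heteroplasmy: float
    copy_number: int
    n_passages: int
    population_cap: int = 10_000
    bottleneck_fraction: float = 0.1
    replication_mode: str = RELAXED_URN
    turnover_events_per_cycle: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if not 0.0 <= self.founder_heteroplasmy <= 1.0:
            raise ValueError("founder_heteroplasmy must be in [0, 1]")
        if self.copy_number < 1:
            raise ValueError("copy_number must be >= 1")
        if self.n_passages < 0:
            raise ValueError("n_passages must be >= 0")
        if not 0.0 < self.bottleneck_fraction < 1.0:
            raise ValueError("bottleneck_fraction must be in (0, 1)")
        if self.population_cap * self.bottleneck_fraction < 1:
            raise ValueError("bottleneck of population_cap must keep >= 1 cell")
        if self.replication_mode not in REPLICATION_MODES:
            raise ValueError(f"unknown replication mode {self.replication_mode!r}")
        if self.turnover_events_per_cycle < 0:
            raise ValueError("turnover_events_per_cycle must be >= 0")

    @property
    def founder_mutant_count(self) -> int:
        """Founder mutant molecules, rounding half away from zero."""
        return int(math.floor(self.founder_heteroplasmy * self.copy_number + 0.5))

    @property
    def doublings_per_passage(self) -> float:
        return math.log2(1.0 / self.bottleneck_fraction)

    def founder_cell(self) -> MoleculeCell:
        m = self.founder_mutant_count
        return MoleculeCell(m, self.copy_number - m)


@dataclass(frozen=True)
class PopulationSnapshot:
    """Per-cell heteroplasmies and copy numbers at one passage."""

    passage_index: int
    heteroplasmies: np.ndarray
    copy_numbers: np.ndarray

    def __post_init__(self):
        if len(self.heteroplasmies) != len(self.copy_numbers):
            raise ValueError("heteroplasmies and copy_numbers must align")

    @property
    def n_cells(self) -> int:
        return len(self.heteroplasmies)

    @property
    def mean(self) -> float:
        return float(np.mean(self.heteroplasmies))

    @property
    def sd(self) -> float:
        return float(np.std(self.heteroplasmies, ddof=1))

    @property
    def fraction_homoplasmic(self) -> float:
        h = self.heteroplasmies
        return float(np.mean((h == 0.0) | (h == 1.0)))


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def replicate_molecules(
    cell: MoleculeCell, target_total: int, mode: str, rng: Generator
) -> MoleculeCell:
    """Copy molecules with no genotype preference up to ``target_total``.

    ``strict_doubling`` requires ``target_total == 2 * cell.total`` and doubles
    each count exactly. ``relaxed_urn`` adds molecules one at a time, each a
    copy of a template drawn uniformly from the current pool; the number of
    mutant copies among the additions therefore follows the Pólya-urn
    (beta-binomial) law and expected heteroplasmy is unchanged.
    """
    if cell.is_dead:
        raise ExtinctLineageError("cannot replicate a dead cell")
    if target_total < cell.total:
        raise ValueError("target_total below current molecule count")
    if mode == STRICT_DOUBLING:
        if target_total != 2 * cell.total:
            raise ValueError("strict_doubling requires target_total == 2 * total")
        return MoleculeCell(2 * cell.mutant, 2 * cell.wildtype)
    if mode != RELAXED_URN:
        raise ValueError(f"unknown replication mode {mode!r}")
    j = target_total - cell.total
    if j == 0:
        return cell
    if cell.mutant == 0:
        return MoleculeCell(0, cell.wildtype + j)
    if cell.wildtype == 0:
        return MoleculeCell(cell.mutant + j, 0)
    # Pólya urn: additions ~ BetaBinomial(j; mutant, wildtype)
    added_mutant = int(rng.binomial(j, rng.beta(cell.mutant, cell.wildtype)))
    return MoleculeCell(cell.mutant + added_mutant, cell.wildtype + (j - added_mutant))


def divide_cell(cell: MoleculeCell, rng: Generator) -> tuple[MoleculeCell, MoleculeCell]:
    """Partition molecules individually and at random between two daughters.

    Each molecule goes to daughter 1 with probability 1/2, independently, so
    daughter totals are unequal in general but sum exactly to the parent's.
    A daughter may receive zero molecules; callers treat it as dead.
    """
    if cell.total < 2:
        raise ValueError("division requires at least 2 molecules")
    m1 = int(rng.binomial(cell.mutant, 0.5))
    w1 = int(rng.binomial(cell.wildtype, 0.5))
    d1 = MoleculeCell(m1, w1)
    d2 = MoleculeCell(cell.mutant - m1, cell.wildtype - w1)
    return d1, d2


def _apply_turnover_scalar(mutant: int, wildtype: int, rate: float, rng: Generator) -> tuple[int, int]:
    """One cell cycle of paired degradation+replication (Moran) events.

    ``rate`` is the expected number of turnover pairs per molecule per cycle.
    Each pair removes one uniformly chosen molecule and copies one uniformly
    chosen survivor; only events that change the mutant count are simulated
    (a change occurs with probability 2mw/(T(T-1)) and is ±1 with equal odds).
    """
    total = mutant + wildtype
    if rate <= 0 or total < 2 or mutant == 0 or wildtype == 0:
        return mutant, wildtype
    n_events = int(round(rate * total))
    while n_events > 0 and 0 < mutant < total:
        q = 2.0 * mutant * (total - mutant) / (total * (total - 1))
        # geometric skip to the next composition-changing event
        g = int(rng.geometric(q))
        if g > n_events:
            break
        n_events -= g
        mutant += 1 if rng.random() < 0.5 else -1
    return mutant, total - mutant


# ---------------------------------------------------------------------------
# population-level operations
# ---------------------------------------------------------------------------

def grow_population(
    cells: list[MoleculeCell],
    capacity: int,
    config: DriftConfig,
    rng: Generator,
) -> list[MoleculeCell]:
    """Grow a population to ``capacity`` by asynchronous random cell division.

    Repeatedly selects a random live cell, applies optional intra-cycle
    turnover, replicates its molecules (to twice the target copy number under
    ``relaxed_urn``, or exact doubling under ``strict_doubling``) and divides
    it. Zero-molecule daughters are removed and counted.
    """
    if not 1 <= len(cells) <= capacity:
        raise ValueError("need 1 <= len(cells) <= capacity")
    mutant = np.empty(capacity, dtype=np.int64)
    wild = np.empty(capacity, dtype=np.int64)
    for i, c in enumerate(cells):
        if c.is_dead:
            raise ExtinctLineageError("dead cell in input population")
        mutant[i], wild[i] = c.mutant, c.wildtype
    size = len(cells)
    n_dead = 0
    relaxed = config.replication_mode == RELAXED_URN
    target = 2 * config.copy_number
    rate = config.turnover_events_per_cycle
    while size < capacity:
        idx = int(rng.integers(size))
        m, w = int(mutant[idx]), int(wild[idx])
        if rate > 0:
            m, w = _apply_turnover_scalar(m, w, rate, rng)
        tot = m + w
        if relaxed:
            j = target - tot
            if j > 0:
                if m == 0:
                    w += j
                elif w == 0:
                    m += j
                else:
                    add = int(rng.binomial(j, rng.beta(m, w)))
                    m += add
                    w += j - add
        else:
            m, w = 2 * m, 2 * w
        m1 = int(rng.binomial(m, 0.5))
        w1 = int(rng.binomial(w, 0.5))
        m2, w2 = m - m1, w - w1
        if m1 + w1 == 0:
            mutant[idx], wild[idx] = m2, w2
            n_dead += 1
        elif m2 + w2 == 0:
            mutant[idx], wild[idx] = m1, w1
            n_dead += 1
        else:
            mutant[idx], wild[idx] = m1, w1
            mutant[size], wild[size] = m2, w2
            size += 1
    if n_dead:
        logger.debug("grow_population: removed %d zero-molecule daughters", n_dead)
    return [MoleculeCell(int(m), int(w)) for m, w in zip(mutant[:size], wild[:size])]


def passage_population(
    cells: list[MoleculeCell], fraction: float, rng: Generator
) -> list[MoleculeCell]:
    """Uniform random sample without replacement of ``floor(fraction * n)`` cells."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    k = int(math.floor(fraction * len(cells)))
    if k < 1:
        raise ValueError("bottleneck would leave an empty population")
    idx = rng.choice(len(cells), size=k, replace=False)
    return [cells[i] for i in idx]


def simulate_drift(config: DriftConfig, rng: Generator | None = None) -> list[PopulationSnapshot]:
    """Full passaging simulation from a single founder cell.

    The founder is first grown to ``population_cap`` (the initial outgrowth to
    confluence); the resulting state is recorded as passage 0. Each subsequent
    passage applies the bottleneck and regrows to the cap.
    """
    if rng is None:
        rng = default_rng(config.seed)
    founder = config.founder_cell()
    if founder.is_dead:
        raise ExtinctLineageError("founder cell has no molecules")
    cells = grow_population([founder], config.population_cap, config, rng)
    snapshots = [_snapshot(0, cells)]
    for p in range(1, config.n_passages + 1):
        cells = passage_population(cells, config.bottleneck_fraction, rng)
        cells = grow_population(cells, config.population_cap, config, rng)
        if not cells:
            raise ExtinctLineageError(f"population extinct at passage {p}")
        snapshots.append(_snapshot(p, cells))
    return snapshots


def _snapshot(index: int, cells: list[MoleculeCell]) -> PopulationSnapshot:
    het = np.array([c.heteroplasmy for c in cells])
    tot = np.array([c.total for c in cells])
    return PopulationSnapshot(index, het, tot)


# ---------------------------------------------------------------------------
# vectorized single-lineage simulation
# ---------------------------------------------------------------------------

def simulate_lineages(
    p0: float,
    copy_number: int,
    generations: int,
    reps: int,
    mode: str = RELAXED_URN,
    turnover_events_per_cycle: float = 0.0,
    rng: Generator | None = None,
) -> np.ndarray:
    """Follow ``reps`` independent single-cell lineages for ``generations``.

    Each generation: optional turnover, replication (mode-dependent), then a
    Bernoulli(1/2) partition of which one daughter is kept. Because a random
    cell of a growing population is statistically a random lineage, the spread
    of lineage heteroplasmies is the intrinsic single-cell drift variance.
    Returns the final heteroplasmies of surviving lineages (extinct lineages,
    possible only at very low copy number, are dropped).
    """
    if rng is None:
        rng = default_rng()
    if mode not in REPLICATION_MODES:
        raise ValueError(f"unknown replication mode {mode!r}")
    n = int(copy_number)
    m = np.full(reps, int(math.floor(p0 * n + 0.5)), dtype=np.int64)
    w = n - m
    alive = np.ones(reps, dtype=bool)
    rate = turnover_events_per_cycle
    for _ in range(int(generations)):
        if rate > 0:
            m, w = _turnover_vectorized(m, w, rate, rng)
        tot = m + w
        if mode == RELAXED_URN:
            j = np.maximum(2 * n - tot, 0)
            het = alive & (m > 0) & (w > 0)
            p_add = np.where(tot > 0, m / np.maximum(tot, 1), 0.0)
            if het.any():
                p_add[het] = rng.beta(m[het], w[het])
            add = rng.binomial(j, p_add)
            m = m + add
            w = w + (j - add)
        else:
            m = 2 * m
            w = 2 * w
        m = rng.binomial(m, 0.5)
        w = rng.binomial(w, 0.5)
        alive &= (m + w) > 0
    tot = m + w
    return (m[alive] / tot[alive]).astype(float)


def _turnover_vectorized(m: np.ndarray, w: np.ndarray, rate: float, rng: Generator):
    """Net effect of one cycle of Moran turnover events, vectorized.

    The number of composition-changing events in a cycle is binomial with the
    per-event change probability evaluated at the cycle's starting state (an
    excellent approximation when changes per cycle are few relative to the
    copy number); each change is ±1 with equal probability.
    """
    tot = m + w
    seg = (m > 0) & (w > 0) & (tot >= 2)
    events = np.round(rate * tot).astype(np.int64)
    q = np.zeros(len(m))
    q[seg] = 2.0 * m[seg] * w[seg] / (tot[seg] * (tot[seg] - 1.0))
    n_changes = rng.binomial(events, q)
    up = rng.binomial(n_changes, 0.5)
    m2 = np.clip(m + 2 * up - n_changes, 0, tot)
    return m2, tot - m2


# ---------------------------------------------------------------------------
# analytic variance oracle
# ---------------------------------------------------------------------------

def _stationary_total_pmf(copy_number: int):
    """Distribution of the post-partition total T ~ Binomial(2N, 1/2) | T > 0."""
    n2 = 2 * copy_number
    t = np.arange(1, n2 + 1)
    pmf = stats.binom.pmf(t, n2, 0.5)
    pmf /= pmf.sum()
    return t, pmf


def _turnover_factor(totals: np.ndarray, rate: float) -> np.ndarray:
    """Per-cycle heterozygosity retention from turnover at the given totals."""
    if rate <= 0:
        return np.ones_like(totals, dtype=float)
    tt = totals.astype(float)
    events = np.round(rate * tt)
    with np.errstate(divide="ignore", invalid="ignore"):
        per_event = np.where(tt >= 2, 1.0 - 2.0 / (tt * (tt - 1.0)), 1.0)
    return per_event ** events


def drift_variance_oracle(
    p0: float,
    copy_number: int,
    generations: float,
    mode: str = RELAXED_URN,
    turnover_events_per_cycle: float = 0.0,
) -> float:
    """Expected between-lineage heteroplasmy variance after ``generations``.

    Uses exact finite-N heterozygosity-decay factors rather than the large-N
    c·p(1−p)/N approximation, so it agrees with simulation (and with exact
    enumeration) down to copy numbers of a few molecules:

    * partition of ``M`` molecules into a daughter of size ``T`` multiplies
      expected heterozygosity p(1−p) by ``1 − (M−T)/(T(M−1))``
      (hypergeometric sampling identity);
    * a Pólya-urn refill from ``T`` to ``M`` molecules multiplies it by
      ``1 − (M−T)/(M(T+1))`` (beta-binomial identity);
    * ``e`` Moran turnover events at total ``T`` multiply it by
      ``(1 − 2/(T(T−1)))^e``.

    Under ``relaxed_urn`` the copy number is re-regulated to ``2N`` before
    every division, so the post-partition total is Binomial(2N, 1/2)
    (conditioned positive) each generation and the per-generation factor is a
    simple expectation over it. Under ``strict_doubling`` the total itself
    performs a critical branching walk; the factor is computed by dynamic
    programming over the totals path. In the large-N limit both reduce to the
    classic 1 − c/N per-generation decay with c ≈ 1 (relaxed) or 1/2 (strict).
    """
    if copy_number < 2:
        raise ValueError("copy_number must be >= 2")
    if generations < 0:
        raise ValueError("generations must be >= 0")
    pq = p0 * (1.0 - p0)
    if generations == 0 or pq == 0.0:
        return 0.0
    if mode == RELAXED_URN:
        ratio = _relaxed_h_ratio(copy_number, generations, turnover_events_per_cycle)
    elif mode == STRICT_DOUBLING:
        ratio = _strict_h_ratio(copy_number, int(round(generations)), turnover_events_per_cycle)
    else:
        raise ValueError(f"unknown replication mode {mode!r}")
    return pq * (1.0 - ratio)


def _relaxed_h_ratio(n: int, generations: float, rate: float) -> float:
    n2 = 2 * n
    t, pmf = _stationary_total_pmf(n)
    c_part = (n2 - t) / (t * (n2 - 1.0))          # partition from 2N to T
    b_refill = (n2 - t) / (n2 * (t + 1.0))        # urn refill from T to 2N
    tf = _turnover_factor(t, rate)
    # founder starts at exactly N molecules
    first = _turnover_factor(np.array([n]), rate)[0] * (1.0 - (n2 - n) / (n2 * (n + 1.0)))
    per_gen = float(np.sum(pmf * (1.0 - c_part) * tf * (1.0 - b_refill)))
    last = float(np.sum(pmf * (1.0 - c_part)))
    g = float(generations)
    if g <= 1.0:
        # interpolate fractional first generation on the log scale
        return (first * last) ** g
    return first * per_gen ** (g - 1.0) * last


def _strict_h_ratio(n: int, generations: int, rate: float) -> float:
    """Expected heterozygosity retention under strict doubling, by DP.

    Totals evolve autonomously (T' ~ Binomial(2T, 1/2)); conditional on the
    totals path the heterozygosity multiplier per generation is exactly
    ``turnover(T) * (1 − (2T−T')/(T'(2T−1)))``. The DP computes the path
    expectation of the product, conditioned on lineage survival. Totals above
    a generous cap are lumped into the cap state.
    """
    tmax = int(n + 12 * math.sqrt(n * max(generations, 1) / 2.0)) + 32
    v = np.ones(tmax + 1)       # E[product | survive] contribution
    s = np.ones(tmax + 1)       # survival probability
    v[0] = 0.0
    s[0] = 0.0
    totals = np.arange(tmax + 1)
    tf = _turnover_factor(totals, rate)
    for _ in range(generations):
        v_new = np.zeros(tmax + 1)
        s_new = np.zeros(tmax + 1)
        for t_cur in range(1, tmax + 1):
            m2 = 2 * t_cur
            tp = np.arange(0, m2 + 1)
            pmf = stats.binom.pmf(tp, m2, 0.5)
            if m2 > tmax:  # lump overflow into the cap state
                pmf[tmax] += pmf[tmax + 1:].sum()
                pmf = pmf[: tmax + 1]
                tp = tp[: tmax + 1]
            mult = np.zeros_like(pmf)
            nz = tp >= 1
            mult[nz] = 1.0 - (m2 - tp[nz]) / (tp[nz] * (m2 - 1.0))
            v_new[t_cur] = tf[t_cur] * float(np.sum(pmf[nz] * mult[nz] * v[tp[nz]]))
            s_new[t_cur] = float(np.sum(pmf[nz] * s[tp[nz]]))
        v, s = v_new, s_new
    if s[n] == 0.0:
        return 0.0
    return float(v[n] / s[n])


# ---------------------------------------------------------------------------
# copy-number threshold scan
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThresholdScanResult:
    """Outcome of a copy-number threshold scan."""

    threshold: int | None
    reached: bool
    generations: float
    criterion_sd: float
    table: tuple[tuple[int, float], ...]
    confirmation_sd: float | None = None
    confirmation_reps: int = 0


def default_copy_number_grid(lo: int = 350, hi: int = 24_000, points: int = 21) -> np.ndarray:
    """Logarithmic grid of candidate cellular mtDNA copy numbers."""
    return np.unique(np.rint(np.geomspace(lo, hi, points)).astype(int))


def copy_number_threshold_scan(
    p0: float,
    n_passages: int,
    criterion_sd: float,
    grid: np.ndarray | list[int],
    *,
    mode: str = RELAXED_URN,
    turnover_events_per_cycle: float = 0.0,
    bottleneck_fraction: float = 0.1,
    method: str = "oracle",
    sim_reps: int = 1000,
    confirm_reps: int = 0,
    rng: Generator | None = None,
) -> ThresholdScanResult:
    """Smallest copy number whose final-passage heteroplasmy SD meets a criterion.

    ``generations`` is ``n_passages * log2(1 / bottleneck_fraction)`` — the
    effective number of cell divisions a lineage experiences across the
    passaging schedule (~3.32 per 1/10 split). The per-N SD comes from the
    variance oracle (``method="oracle"``) or from ``sim_reps`` simulated
    lineages (``method="simulate"``); ``confirm_reps > 0`` additionally
    simulates lineages at the selected threshold.
    """
    if not 0.0 < criterion_sd < 0.5:
        raise ValueError("criterion_sd must be in (0, 0.5)")
    grid = sorted(int(n) for n in np.asarray(grid).ravel())
    if not grid:
        raise ValueError("grid must be non-empty")
    if rng is None:
        rng = default_rng()
    generations = n_passages * math.log2(1.0 / bottleneck_fraction)
    table = []
    threshold = None
    for n in grid:
        if method == "oracle":
            sd = math.sqrt(
                drift_variance_oracle(p0, n, generations, mode, turnover_events_per_cycle)
            )
        elif method == "simulate":
            h = simulate_lineages(
                p0, n, int(round(generations)), sim_reps, mode,
                turnover_events_per_cycle, rng,
            )
            sd = float(np.std(h, ddof=1))
        else:
            raise ValueError(f"unknown method {method!r}")
        table.append((n, sd))
        if threshold is None and sd <= criterion_sd:
            threshold = n
    confirmation_sd = None
    if threshold is not None and confirm_reps > 0:
        h = simulate_lineages(
            p0, threshold, int(round(generations)), confirm_reps, mode,
            turnover_events_per_cycle, rng,
        )
        confirmation_sd = float(np.std(h, ddof=1))
        logger.info(
            "threshold %d confirmed by %d lineages: simulated SD %.4f (criterion %.4f)",
            threshold, confirm_reps, confirmation_sd, criterion_sd,
        )
    return ThresholdScanResult(
        threshold=threshold,
        reached=threshold is not None,
        generations=generations,
        criterion_sd=criterion_sd,
        table=tuple(table),
        confirmation_sd=confirmation_sd,
        confirmation_reps=confirm_reps if threshold is not None else 0,
    )
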