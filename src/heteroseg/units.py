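"""The metastable heteroplasmic segregation-unit model.

A cell's mtDNA is organized into multi-copy segregation units, each with a
fixed mutant/wild-type composition (k mutant of n copies). Units replicate
faithfully — both daughters of a unit inherit its exact composition — and
are randomly partitioned at mitosis, so a cell homogeneous for one unit
genotype transmits its heteroplasmy unchanged forever. Heteroplasmy shifts
require a metastable event: a single unit changing composition, or a full
redistribution of the cell's molecule pool into new units. Under neutral
random segregation the probability that a lineage fixes a given unit
genotype equals that genotype's initial frequency among the cell's units.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
from numpy.random import Generator, default_rng

logger = logging.getLogger(__name__)

#: genotype of a segregation unit: (mutant copies, total copies)
Genotype = tuple[int, int]

BERNOULLI_PARTITION = "bernoulli"
BALANCED_PARTITION = "balanced"


@dataclass(frozen=True)
class SegregationUnit:
    """One segregation unit: ``mutant_copies`` of ``total_copies`` mtDNAs."""

    mutant_copies: int
    total_copies: int

    def __post_init__(self):
        if self.total_copies < 1:
            raise ValueError("a unit holds at least one mtDNA copy")
        if not 0 <= self.mutant_copies <= self.total_copies:
            raise ValueError("mutant copies must be within [0, total]")

    @property
    def load(self) -> float:
        return self.mutant_copies / self.total_copies

    @property
    def genotype(self) -> Genotype:
        return (self.mutant_copies, self.total_copies)


@dataclass(frozen=True)
class UnitCell:
    """A cell as a collection of segregation units."""

    units: tuple[SegregationUnit, ...]

    def __post_init__(self):
        if len(self.units) < 1:
            raise ValueError("a live cell has at least one unit")

    @classmethod
    def uniform(cls, n_units: int, mutant_copies: int, total_copies: int) -> "UnitCell":
        return cls(tuple(SegregationUnit(mutant_copies, total_copies) for _ in range(n_units)))

    @classmethod
    def from_genotypes(cls, genotypes: list[Genotype]) -> "UnitCell":
        return cls(tuple(SegregationUnit(k, n) for k, n in genotypes))

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def total_molecules(self) -> int:
        return sum(u.total_copies for u in self.units)

    @property
    def total_mutant(self) -> int:
        return sum(u.mutant_copies for u in self.units)

    @property
    def heteroplasmy(self) -> float:
        return self.total_mutant / self.total_molecules

    @property
    def is_homogeneous(self) -> bool:
        return len({u.genotype for u in self.units}) == 1

    def genotype_counts(self) -> Counter:
        return Counter(u.genotype for u in self.units)


def cell_heteroplasmy(cell: UnitCell) -> float:
    """Cell mutation load: summed mutant copies over summed total copies."""
    return cell.heteroplasmy


def replicate_and_partition_units(
    cell: UnitCell,
    rng: Generator,
    partition: str = BERNOULLI_PARTITION,
) -> tuple[tuple[SegregationUnit, ...], tuple[SegregationUnit, ...]]:
    """Faithfully duplicate every unit, then randomly partition the copies.

    ``bernoulli``: each of the 2U unit copies goes to daughter 1 with
    probability 1/2 independently (daughter unit counts differ in general).
    ``balanced``: daughter 1 receives exactly U of the 2U copies, drawn
    without replacement. Either way the union of the daughters' units equals
    the duplicated multiset. A daughter may end up with zero units under the
    Bernoulli rule; callers treat it as dead.
    """
    duplicated = cell.units + cell.units
    n2 = len(duplicated)
    if partition == BERNOULLI_PARTITION:
        mask = rng.random(n2) < 0.5
    elif partition == BALANCED_PARTITION:
        mask = np.zeros(n2, dtype=bool)
        mask[rng.choice(n2, size=n2 // 2, replace=False)] = True
    else:
        raise ValueError(f"unknown partition rule {partition!r}")
    d1 = tuple(u for u, take in zip(duplicated, mask) if take)
    d2 = tuple(u for u, take in zip(duplicated, mask) if not take)
    return d1, d2


def fixation_probabilities(cell: UnitCell) -> dict[Genotype, float]:
    """Neutral fixation probability of each distinct unit genotype.

    Under random mitotic segregation of faithfully replicating units, the
    fraction of units with a given genotype is a bounded martingale, so the
    probability that a descendant lineage ends up homogeneous for a genotype
    equals that genotype's initial frequency among the cell's units. A cell
    fixed for genotype (k, n) has heteroplasmy k/n.
    """
    counts = cell.genotype_counts()
    u = cell.n_units
    return {g: c / u for g, c in counts.items()}


@dataclass(frozen=True)
class FixationResult:
    """Empirical outcome of simulated unit-segregation lineages."""

    fixed_counts: dict[Genotype, int]
    n_dead: int
    n_unfixed: int
    reps: int

    def frequencies(self) -> dict[Genotype, float]:
        return {g: c / self.reps for g, c in self.fixed_counts.items()}


def simulate_unit_lineages(
    cell: UnitCell,
    reps: int,
    rng: Generator,
    max_generations: int | None = None,
    partition: str = BERNOULLI_PARTITION,
) -> FixationResult:
    """Monte-Carlo fixation frequencies along random daughter lineages.

    Each replicate follows one uniformly chosen daughter per division until
    the cell is homogeneous for a single unit genotype (fixation), the
    lineage receives zero units (death), or ``max_generations`` (default
    50 × U) is reached; unfixed lineages are reported, not dropped.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if max_generations is None:
        max_generations = 50 * cell.n_units
    start = dict(cell.genotype_counts())
    fixed: Counter = Counter()
    n_dead = 0
    n_unfixed = 0
    for _ in range(reps):
        state = dict(start)
        outcome = None
        for _ in range(max_generations):
            if len(state) == 1:
                (genotype,) = state
                outcome = genotype
                break
            state = _daughter_counts(state, rng, partition)
            if not state:
                outcome = "dead"
                break
        else:
            if len(state) == 1:
                (outcome,) = state
        if outcome is None:
            n_unfixed += 1
        elif outcome == "dead":
            n_dead += 1
        else:
            fixed[outcome] += 1
    return FixationResult(dict(fixed), n_dead, n_unfixed, reps)


def _daughter_counts(state: dict, rng: Generator, partition: str) -> dict:
    """Unit-genotype counts of one daughter after faithful duplication.

    Daughters are exchangeable, so following daughter 1 every division is the
    same as following a uniformly chosen daughter.
    """
    if partition == BERNOULLI_PARTITION:
        return {
            g: take
            for g, c in state.items()
            if (take := int(rng.binomial(2 * c, 0.5)))
        }
    if partition == BALANCED_PARTITION:
        genotypes = list(state)
        colors = [2 * state[g] for g in genotypes]
        taken = rng.multivariate_hypergeometric(colors, sum(colors) // 2)
        return {g: int(t) for g, t in zip(genotypes, taken) if t}
    raise ValueError(f"unknown partition rule {partition!r}")


def simulate_unit_lineage_loads(
    cell: UnitCell,
    generations: int,
    reps: int,
    rng: Generator,
    partition: str = BERNOULLI_PARTITION,
) -> np.ndarray:
    """Heteroplasmies of random daughter lineages after a fixed generation count.

    The segregation-unit counterpart of molecule-level lineage simulation;
    with single-copy units (n = 1, U = N) it reproduces molecule-level drift
    under strict doubling exactly. Dead lineages are dropped.
    """
    loads = []
    start = dict(cell.genotype_counts())
    for _ in range(reps):
        state = dict(start)
        for _ in range(generations):
            nxt = _daughter_counts(state, rng, partition)
            if not nxt:
                state = {}
                break
            state = nxt
        if state:
            mut = sum(k * c for (k, _), c in state.items())
            tot = sum(n * c for (_, n), c in state.items())
            loads.append(mut / tot)
    return np.array(loads)


def reorganize_single_unit(cell: UnitCell, unit_index: int, new_mutant_copies: int) -> UnitCell:
    """A metastable event altering the composition of one unit in place."""
    if not 0 <= unit_index < cell.n_units:
        raise IndexError("unit index out of range")
    target = cell.units[unit_index]
    if not 0 <= new_mutant_copies <= target.total_copies:
        raise ValueError("new mutant copies outside [0, unit total]")
    units = list(cell.units)
    units[unit_index] = SegregationUnit(new_mutant_copies, target.total_copies)
    return UnitCell(tuple(units))


def redistribute_all(cell: UnitCell, rng: Generator, method: str = "exact") -> UnitCell:
    """Randomly redistribute the cell's pooled molecules into fresh units.

    ``exact`` deals the pooled mutant molecules into U units of n slots by
    sampling without replacement (multivariate hypergeometric; requires a
    uniform unit size). ``binomial`` draws each unit's mutant count
    independently as Binomial(n, pooled load) and then repairs the total by
    incrementing/decrementing uniformly chosen units, so the cell's molecule
    pool is conserved either way.
    """
    sizes = {u.total_copies for u in cell.units}
    total_mutant = cell.total_mutant
    pooled_load = cell.heteroplasmy
    u_count = cell.n_units
    if method == "exact":
        if len(sizes) != 1:
            raise ValueError("exact redistribution requires a uniform unit size")
        n = sizes.pop()
        pool = np.zeros(u_count * n, dtype=np.int8)
        pool[:total_mutant] = 1
        rng.shuffle(pool)
        ks = pool.reshape(u_count, n).sum(axis=1)
        return UnitCell.from_genotypes([(int(k), n) for k in ks])
    if method != "binomial":
        raise ValueError(f"unknown redistribution method {method!r}")
    ns = np.array([u.total_copies for u in cell.units])
    ks = rng.binomial(ns, pooled_load)
    diff = int(ks.sum() - total_mutant)
    while diff > 0:
        candidates = np.flatnonzero(ks > 0)
        ks[rng.choice(candidates)] -= 1
        diff -= 1
    while diff < 0:
        candidates = np.flatnonzero(ks < ns)
        ks[rng.choice(candidates)] += 1
        diff += 1
    return UnitCell.from_genotypes([(int(k), int(n)) for k, n in zip(ks, ns)])


def hitchhike_bulk_fraction(
    units_per_cell: int,
    special_unit_load: float,
    background_load: float,
) -> tuple[float, float]:
    """Worked arithmetic for a single odd unit sweeping to fixation.

    A cell carrying one unit whose load differs from the (uniform) background
    founds a subpopulation that fixes the odd unit with probability 1/U, so
    the deviant subpopulation maximally reaches a fraction 1/U of the clone.
    The clone's bulk minor-allele fraction is that subpopulation fraction
    times the unit-load offset. Returns
    ``(max_subpopulation_fraction, bulk_minor_allele_fraction)``.
    """
    if units_per_cell < 1:
        raise ValueError("units_per_cell must be >= 1")
    sub = 1.0 / units_per_cell
    bulk = sub * abs(special_unit_load - background_load)
    return sub, bulk


def min_unit_size_from_spacing(spacing: float) -> int:
    """Smallest unit copy number whose load granularity 1/n resolves ``spacing``.

    A unit of n copies can only shift cellular heteroplasmy in steps of 1/n,
    so observed peak spacings of s imply at least ceil(1/s) copies per unit.
    """
    if not 0.0 < spacing <= 1.0:
        raise ValueError("spacing must be in (0, 1]")
    return math.ceil(1.0 / spacing - 1e-12)
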