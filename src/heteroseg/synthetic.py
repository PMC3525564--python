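"""Synthetic single-cell genotyping experiments with known ground truth.

Composes the molecule-drift or segregation-unit simulators with the
Padlock/RCA observation model to produce per-passage, per-cell dot-count
tables plus an event log of every reorganization and growth-advantage
assignment, so every analysis stage can be tested against planted truth.

The study-condition presets mirror the cybrid clones the method was built
around: V_3.2 (founder load 67%, ~1,800 mtDNA/cell, 81 passages, stable),
G_55.2 (55%, ~350 copies, 32 passages, fast drift with turnover), the
72-molecule / 9-unit toy cell, and a V_50-like near-homoplasmic clone with
a single odd segregation unit that can sweep.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.random import Generator, default_rng

from . import drift as _drift
from . import units as _units
from .drift import DriftConfig, MoleculeCell, RELAXED_URN
from .errors import DatasetFormatError, InfeasibleParameterError
from .observe import (
    DetectionConfig,
    INDEPENDENT_MOLECULES,
    UNIT_CLUSTERED,
    apply_rfmt_noise,
    simulate_cell_readout,
)
from .units import UnitCell

logger = logging.getLogger(__name__)

MOLECULE_DRIFT = "molecule_drift"
UNIT_FAITHFUL = "unit_faithful"

SINGLE_UNIT = "single_unit"
FULL_REDISTRIBUTION = "full_redistribution"

CELL_COLUMNS = ("passage", "cell_id", "true_load", "red_dots", "green_dots", "yellow_dots")


@dataclass(frozen=True)
class CloneScenario:
    """Complete specification of one synthetic clone experiment.

    ``reorganization_rate`` is the per-division probability of a metastable
    event in a daughter cell; ``advantage_multiplier`` (>= 1) is the relative
    division propensity granted to the lineage founded by the first cell that
    fixes a reorganization-derived unit genotype — a nuclear "hitchhiking"
    growth advantage, deliberately not tied to the mtDNA genotype itself.
    ``forced_initial_event`` applies a single-unit reorganization
    (unit_index, new_mutant_copies) to the founder before any growth.
    """

    model: str
    founder_load: float
    copy_number: int
    n_passages: int
    units_per_cell: int = 0
    unit_size: int = 0
    reorganization_rate: float = 0.0
    reorganization_kind: str = SINGLE_UNIT
    advantage_multiplier: float = 1.0
    turnover_events_per_cycle: float = 0.0
    detection: DetectionConfig = field(
        default_factory=lambda: DetectionConfig(efficiency=1.0 / 30.0)
    )
    founder_units: tuple[tuple[int, int], ...] | None = None
    forced_initial_event: tuple[int, int] | None = None
    population_cap: int = 10_000
    bottleneck_fraction: float = 0.1
    sample_cells: int = 300
    seed: int = 0

    def __post_init__(self):
        if self.model not in (MOLECULE_DRIFT, UNIT_FAITHFUL):
            raise ValueError(f"unknown model {self.model!r}")
        if self.model == UNIT_FAITHFUL:
            if self.units_per_cell < 1 or self.unit_size < 1:
                raise InfeasibleParameterError(
                    "unit_faithful requires units_per_cell >= 1 and unit_size >= 1"
                )
            if self.units_per_cell * self.unit_size != self.copy_number:
                raise InfeasibleParameterError(
                    "units_per_cell * unit_size must equal copy_number"
                )
        if self.reorganization_rate < 0:
            raise ValueError("reorganization_rate must be >= 0")
        if self.advantage_multiplier < 1.0:
            raise ValueError("advantage_multiplier must be >= 1")
        if self.reorganization_kind not in (SINGLE_UNIT, FULL_REDISTRIBUTION):
            raise ValueError(f"unknown reorganization kind {self.reorganization_kind!r}")

    def founder_unit_cell(self) -> UnitCell:
        if self.founder_units is not None:
            cell = UnitCell.from_genotypes(list(self.founder_units))
            if cell.total_molecules != self.copy_number:
                raise InfeasibleParameterError("founder_units do not sum to copy_number")
        else:
            k = int(math.floor(self.founder_load * self.unit_size + 0.5))
            cell = UnitCell.uniform(self.units_per_cell, k, self.unit_size)
        if self.forced_initial_event is not None:
            idx, new_k = self.forced_initial_event
            cell = _units.reorganize_single_unit(cell, idx, new_k)
        return cell


@dataclass
class SyntheticDataset:
    """Per-cell readout table, ground-truth event log and scenario echo."""

    cells: pd.DataFrame
    events: list[dict]
    scenario: dict

    def __post_init__(self):
        missing = [c for c in CELL_COLUMNS if c not in self.cells.columns]
        if missing:
            raise DatasetFormatError(f"missing column(s): {', '.join(missing)}")

    def passage_table(self, passage: int) -> pd.DataFrame:
        return self.cells[self.cells["passage"] == passage]


# ---------------------------------------------------------------------------
# scenario presets (the study conditions)
# ---------------------------------------------------------------------------

def paper_fixtures() -> dict[str, CloneScenario]:
    """Named scenarios mirroring the clones and toy example of the study.

    Detection efficiencies are anchored to the printed dot statistics:
    ~60 dots/cell at ~1,800 copies gives an apparent per-molecule efficiency
    of ~3.3% for V_3.2; G_55.2 (~350 copies) was well-detected (>= 40 dots in
    80% of cells), so its per-molecule efficiency is set to 0.15 to give
    ~50 dots/cell.
    """
    return {
        "V_3.2": CloneScenario(
            model=MOLECULE_DRIFT,
            founder_load=0.67,
            copy_number=1800,
            n_passages=81,
            detection=DetectionConfig(efficiency=60.0 / 1800.0, mode=INDEPENDENT_MOLECULES),
        ),
        "G_55.2": CloneScenario(
            model=MOLECULE_DRIFT,
            founder_load=0.55,
            copy_number=350,
            n_passages=32,
            turnover_events_per_cycle=2.0,
            detection=DetectionConfig(efficiency=0.15, mode=INDEPENDENT_MOLECULES),
        ),
        "Fig1_toy": CloneScenario(
            model=UNIT_FAITHFUL,
            founder_load=0.5,
            copy_number=72,
            units_per_cell=9,
            unit_size=8,
            n_passages=6,
            population_cap=2000,
            detection=DetectionConfig(efficiency=0.05, mode=UNIT_CLUSTERED),
        ),
        "V_50_like": CloneScenario(
            model=UNIT_FAITHFUL,
            founder_load=0.99,
            copy_number=1000,
            units_per_cell=100,
            unit_size=10,
            n_passages=20,
            population_cap=5000,
            founder_units=tuple([(10, 10)] * 99 + [(9, 10)]),
            reorganization_rate=1e-4,
            advantage_multiplier=1.5,
            detection=DetectionConfig(efficiency=0.06, mode=UNIT_CLUSTERED),
        ),
    }


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_scenario(scenario: CloneScenario) -> SyntheticDataset:
    """Run a scenario end to end; deterministic given its seed."""
    rng = default_rng(scenario.seed)
    if scenario.model == MOLECULE_DRIFT:
        rows, events = _generate_molecule(scenario, rng)
    else:
        rows, events = _generate_units(scenario, rng)
    cells = pd.DataFrame(rows, columns=list(CELL_COLUMNS))
    echo = asdict(scenario)
    echo["detection"] = asdict(scenario.detection)
    return SyntheticDataset(cells=cells, events=events, scenario=echo)


def _observe_rows(
    rows: list, passage: int, sampled, scenario: CloneScenario, rng: Generator
) -> None:
    noise_sd = scenario.detection.rfmt_noise_sd
    for cid, cell in enumerate(sampled):
        readout = simulate_cell_readout(cell, scenario.detection, rng)
        true_load = cell.heteroplasmy
        if noise_sd:
            true_load = apply_rfmt_noise(true_load, noise_sd, rng)
        rows.append(
            (passage, cid, true_load, readout.red_dots, readout.green_dots, readout.yellow_dots)
        )


def _generate_molecule(scenario: CloneScenario, rng: Generator):
    config = DriftConfig(
        founder_heteroplasmy=scenario.founder_load,
        copy_number=scenario.copy_number,
        n_passages=scenario.n_passages,
        population_cap=scenario.population_cap,
        bottleneck_fraction=scenario.bottleneck_fraction,
        replication_mode=RELAXED_URN,
        turnover_events_per_cycle=scenario.turnover_events_per_cycle,
    )
    founder = config.founder_cell()
    cells = _drift.grow_population([founder], config.population_cap, config, rng)
    rows: list = []
    for passage in range(scenario.n_passages + 1):
        if passage > 0:
            cells = _drift.passage_population(cells, scenario.bottleneck_fraction, rng)
            cells = _drift.grow_population(cells, config.population_cap, config, rng)
        sampled = _sample(cells, scenario.sample_cells, rng)
        _observe_rows(rows, passage, sampled, scenario, rng)
    return rows, []


class _UnitPopulation:
    """Growing population of unit-model cells with events and advantage."""

    def __init__(self, scenario: CloneScenario, rng: Generator):
        self.scenario = scenario
        self.rng = rng
        founder = scenario.founder_unit_cell()
        self.states: list[dict] = [dict(founder.genotype_counts())]
        self.advantaged: list[bool] = [False]
        self.events: list[dict] = []
        self.novel_genotypes: set = set()
        self.advantage_assigned = False
        self.passage = 0
        if scenario.forced_initial_event is not None:
            idx, new_k = scenario.forced_initial_event
            base = UnitCell.from_genotypes(
                list(scenario.founder_units)
                if scenario.founder_units is not None
                else [(int(math.floor(scenario.founder_load * scenario.unit_size + 0.5)),
                       scenario.unit_size)] * scenario.units_per_cell
            )
            novel = (new_k, base.units[idx].total_copies)
            self.novel_genotypes.add(novel)
            self.events.append(
                {"passage": 0, "kind": SINGLE_UNIT, "forced": True,
                 "unit_index": idx, "new_mutant_copies": new_k}
            )

    def _pick_divider(self) -> int:
        adv_idx = [i for i, a in enumerate(self.advantaged) if a]
        if adv_idx and self.scenario.advantage_multiplier > 1.0:
            n_adv = len(adv_idx)
            n_norm = len(self.states) - n_adv
            w_adv = self.scenario.advantage_multiplier * n_adv
            if self.rng.random() < w_adv / (w_adv + n_norm):
                return adv_idx[int(self.rng.integers(n_adv))]
            norm_idx = [i for i, a in enumerate(self.advantaged) if not a]
            return norm_idx[int(self.rng.integers(n_norm))]
        return int(self.rng.integers(len(self.states)))

    def _maybe_reorganize(self, state: dict) -> dict:
        if self.rng.random() >= self.scenario.reorganization_rate:
            return state
        cell = _state_to_cell(state)
        if self.scenario.reorganization_kind == SINGLE_UNIT:
            idx = int(self.rng.integers(cell.n_units))
            n = cell.units[idx].total_copies
            new_k = int(self.rng.integers(n + 1))
            cell = _units.reorganize_single_unit(cell, idx, new_k)
            detail = {"unit_index": idx, "new_mutant_copies": new_k}
        else:
            cell = _units.redistribute_all(cell, self.rng, method="exact")
            detail = {}
        new_state = dict(cell.genotype_counts())
        for g in new_state:
            self.novel_genotypes.add(g)
        self.events.append(
            {"passage": self.passage, "kind": self.scenario.reorganization_kind,
             "forced": False, **detail}
        )
        return new_state

    def _check_advantage(self, state: dict) -> bool:
        if self.advantage_assigned or self.scenario.advantage_multiplier <= 1.0:
            return False
        if len(state) == 1:
            (g,) = state
            if g in self.novel_genotypes:
                self.advantage_assigned = True
                self.events.append(
                    {"passage": self.passage, "kind": "advantage_assigned",
                     "genotype": list(g)}
                )
                return True
        return False

    def grow(self, capacity: int) -> None:
        rng = self.rng
        while len(self.states) < capacity:
            i = self._pick_divider()
            state = self.states[i]
            adv = self.advantaged[i]
            d1 = {g: t for g, c in state.items() if (t := int(rng.binomial(2 * c, 0.5)))}
            d2 = {g: 2 * c - d1.get(g, 0) for g, c in state.items()}
            d2 = {g: c for g, c in d2.items() if c}
            if self.scenario.reorganization_rate > 0:
                d1 = self._maybe_reorganize(d1) if d1 else d1
            if not d1 and not d2:
                continue  # both daughters empty cannot happen (2U copies); guard anyway
            if not d1 or not d2:
                survivor = d1 or d2
                self.states[i] = survivor
                self.advantaged[i] = adv or self._check_advantage(survivor)
                continue
            a1 = adv or self._check_advantage(d1)
            a2 = adv or self._check_advantage(d2)
            self.states[i] = d1
            self.advantaged[i] = a1
            self.states.append(d2)
            self.advantaged.append(a2)

    def bottleneck(self, fraction: float) -> None:
        k = max(1, int(math.floor(fraction * len(self.states))))
        idx = self.rng.choice(len(self.states), size=k, replace=False)
        self.states = [self.states[i] for i in idx]
        self.advantaged = [self.advantaged[i] for i in idx]

    def sample_cells(self, k: int) -> list[UnitCell]:
        idx = self.rng.choice(len(self.states), size=min(k, len(self.states)), replace=False)
        return [_state_to_cell(self.states[i]) for i in idx]

    def advantaged_fraction(self) -> float:
        return sum(self.advantaged) / len(self.advantaged)


def _state_to_cell(state: dict) -> UnitCell:
    genotypes: list = []
    for g, c in sorted(state.items()):
        genotypes.extend([g] * c)
    return UnitCell.from_genotypes(genotypes)


def _generate_units(scenario: CloneScenario, rng: Generator):
    pop = _UnitPopulation(scenario, rng)
    pop.grow(scenario.population_cap)
    rows: list = []
    for passage in range(scenario.n_passages + 1):
        pop.passage = passage
        if passage > 0:
            pop.bottleneck(scenario.bottleneck_fraction)
            pop.grow(scenario.population_cap)
        sampled = pop.sample_cells(scenario.sample_cells)
        _observe_rows(rows, passage, sampled, scenario, rng)
        pop.events.append(
            {"passage": passage, "kind": "advantaged_fraction",
             "value": pop.advantaged_fraction()}
        )
    return rows, pop.events


def generate_mixture_readouts(
    modes: list[tuple[float, float]],
    n_cells: int,
    rng: Generator,
    detection: DetectionConfig | None = None,
    copy_number: int = 1800,
) -> pd.DataFrame:
    """Planted mixture of load subpopulations passed through the dot readout.

    ``modes`` is a list of (true_load, weight) pairs (weights normalized).
    Returns a table in the standard cell-readout layout with passage 0 and
    ground-truth loads — the planted truth for histogram-recovery tests.
    """
    if detection is None:
        detection = DetectionConfig(efficiency=60.0 / copy_number)
    weights = np.array([w for _, w in modes], dtype=float)
    weights /= weights.sum()
    assignments = rng.choice(len(modes), size=n_cells, p=weights)
    rows = []
    for cid, a in enumerate(assignments):
        load = modes[a][0]
        mutant = int(math.floor(load * copy_number + 0.5))
        cell = MoleculeCell(mutant, copy_number - mutant)
        readout = simulate_cell_readout(cell, detection, rng)
        rows.append(
            (0, cid, cell.heteroplasmy, readout.red_dots, readout.green_dots,
             readout.yellow_dots)
        )
    return pd.DataFrame(rows, columns=list(CELL_COLUMNS))


def _sample(cells: list[MoleculeCell], k: int, rng: Generator) -> list[MoleculeCell]:
    idx = rng.choice(len(cells), size=min(k, len(cells)), replace=False)
    return [cells[i] for i in idx]


# ---------------------------------------------------------------------------
# persistence (plain TSV + JSON)
# ---------------------------------------------------------------------------

def write_dataset(dataset: SyntheticDataset, path: str | Path) -> Path:
    """Write a dataset to a directory as cells.tsv + events.json + scenario.json."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    dataset.cells.to_csv(
        path / "cells.tsv", sep="\t", index=False, float_format="%.17g"
    )
    with open(path / "events.json", "w") as fh:
        json.dump(dataset.events, fh, indent=1, sort_keys=True)
        fh.write("\n")
    with open(path / "scenario.json", "w") as fh:
        json.dump(dataset.scenario, fh, indent=1, sort_keys=True, default=list)
        fh.write("\n")
    return path


def read_dataset(path: str | Path) -> SyntheticDataset:
    """Read a dataset directory back; raises DatasetFormatError on bad files."""
    path = Path(path)
    cells_file = path / "cells.tsv"
    if not cells_file.exists():
        raise DatasetFormatError(f"missing {cells_file}")
    try:
        cells = pd.read_csv(cells_file, sep="\t", float_precision="round_trip")
    except pd.errors.ParserError as exc:  # pragma: no cover - pandas formats vary
        line = getattr(exc, "lineno", None)
        raise DatasetFormatError(f"malformed TSV: {exc}", line=line) from exc
    missing = [c for c in CELL_COLUMNS if c not in cells.columns]
    if missing:
        raise DatasetFormatError(
            f"missing column(s): {', '.join(missing)}", line=1
        )
    with open(path / "events.json") as fh:
        events = json.load(fh)
    with open(path / "scenario.json") as fh:
        scenario = json.load(fh)
    return SyntheticDataset(cells=cells, events=events, scenario=scenario)
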