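"""Single-cell mutation-load histograms and subpopulation analysis.

Cells pass a dots/cell stringency filter, their load estimates are binned
into 5% or 10% bins over [0, 100]%, and subpopulations are read off as
local maxima of the binned frequencies. Peak spacings bound the segregation
unit size from below (a unit of n copies shifts cellular load in steps of
1/n), and simulated drift distributions are compared against observed
histograms by mean, SD, homoplasmic fraction and a chi-square distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .drift import PopulationSnapshot
from .errors import EmptyHistogramError
from .observe import CellReadout
from .units import min_unit_size_from_spacing

logger = logging.getLogger(__name__)

ALLOWED_BIN_WIDTHS = (5, 10)


@dataclass(frozen=True)
class LoadHistogram:
    """Binned single-cell mutation-load frequencies with filtering metadata.

    Bins are left-closed, right-open, except the top bin which is closed
    ([95, 100] for 5% bins); ``retained_fraction`` is the share of all cells
    that passed the ``min_dots`` stringency.
    """

    bin_width: int
    counts: np.ndarray
    n_cells: int
    min_dots: int
    retained_fraction: float

    def __post_init__(self):
        if self.bin_width not in ALLOWED_BIN_WIDTHS:
            raise ValueError("bin_width must be 5 or 10 (percent)")
        if int(self.counts.sum()) != self.n_cells:
            raise ValueError("histogram counts must sum to n_cells")
        if not 0.0 <= self.retained_fraction <= 1.0:
            raise ValueError("retained_fraction must be in [0, 1]")

    @property
    def n_bins(self) -> int:
        return 100 // self.bin_width

    @property
    def edges(self) -> np.ndarray:
        return np.arange(0, 101, self.bin_width, dtype=float)

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / max(self.n_cells, 1)

    @property
    def mean(self) -> float:
        """Mean load in percent, from bin midpoints."""
        mids = self.edges[:-1] + self.bin_width / 2.0
        return float(np.sum(self.frequencies * mids))

    @property
    def sd(self) -> float:
        """SD of load in percent, from bin midpoints."""
        mids = self.edges[:-1] + self.bin_width / 2.0
        mu = self.mean
        return float(np.sqrt(np.sum(self.frequencies * (mids - mu) ** 2)))


@dataclass(frozen=True)
class PeakSet:
    """Subpopulation peaks of a load histogram.

    ``peak_loads`` are the left edges of the flagged bins, in percent, sorted
    ascending; ``spacings`` are the consecutive differences. ``shoulders``
    are above-threshold non-maximum bins adjacent to a peak.
    """

    peak_bins: tuple[int, ...]
    peak_loads: tuple[float, ...]
    spacings: tuple[float, ...]
    shoulder_bins: tuple[int, ...] = ()

    @classmethod
    def from_loads(cls, peak_loads: list[float]) -> "PeakSet":
        loads = tuple(sorted(peak_loads))
        spac = tuple(np.diff(loads).tolist())
        return cls(peak_bins=(), peak_loads=loads, spacings=spac)


def build_histogram(
    loads: list[float] | np.ndarray,
    readouts: list[CellReadout] | None = None,
    bin_width: int = 5,
    min_dots: int = 0,
) -> LoadHistogram:
    """Bin per-cell loads (fractions in [0, 1]) under a dots/cell stringency.

    When ``readouts`` are supplied they must align with ``loads``; cells with
    fewer than ``min_dots`` informative (red+green) dots are excluded before
    binning.
    """
    if bin_width not in ALLOWED_BIN_WIDTHS:
        raise ValueError("bin_width must be 5 or 10 (percent)")
    loads = np.asarray(loads, dtype=float)
    n_total = len(loads)
    if readouts is not None:
        if len(readouts) != n_total:
            raise ValueError("loads and readouts must align")
        keep = np.array([r.informative_dots >= min_dots for r in readouts])
        loads = loads[keep]
    if len(loads) == 0:
        raise EmptyHistogramError(
            f"no cell passed the >= {min_dots} dots/cell stringency"
        )
    if loads.min() < 0.0 or loads.max() > 1.0:
        raise ValueError("loads must be fractions in [0, 1]")
    edges = np.arange(0, 101, bin_width, dtype=float)
    counts, _ = np.histogram(loads * 100.0, bins=edges)
    return LoadHistogram(
        bin_width=bin_width,
        counts=counts,
        n_cells=len(loads),
        min_dots=min_dots,
        retained_fraction=len(loads) / n_total if n_total else 0.0,
    )


@dataclass(frozen=True)
class StringencySelection:
    """Chosen dots/cell threshold and bin width, or an under-detection flag."""

    min_dots: int
    bin_width: int
    under_detected: bool = False


def select_stringency(readouts: list[CellReadout]) -> StringencySelection:
    """Pick the stringency/bin-width combination the sample can support.

    Requires that more than 30% of all cells contribute to the histogram:
    prefer >= 40 dots/cell with 5% bins; fall back to >= 20 dots/cell with
    10% bins; otherwise flag the sample as under-detected (returned, never
    raised).
    """
    if not readouts:
        raise ValueError("need at least one readout")
    dots = np.array([r.informative_dots for r in readouts])
    if np.mean(dots >= 40) > 0.30:
        return StringencySelection(min_dots=40, bin_width=5)
    if np.mean(dots >= 20) > 0.30:
        return StringencySelection(min_dots=20, bin_width=10)
    logger.warning("fewer than 30%% of cells reach 20 dots; sample under-detected")
    return StringencySelection(min_dots=20, bin_width=10, under_detected=True)


def detect_subpopulations(hist: LoadHistogram, min_fraction: float = 0.10) -> PeakSet:
    """Flag histogram bins that mark cell subpopulations.

    A peak is a bin strictly greater than both neighbours (missing neighbours
    at the range ends count as empty; plateaus are resolved to their leftmost
    bin) with frequency >= ``min_fraction``. Above-threshold non-maximum bins
    adjacent to a peak are reported separately as shoulders.
    """
    if not 0.0 < min_fraction < 1.0:
        raise ValueError("min_fraction must be in (0, 1)")
    freq = hist.frequencies
    padded = np.concatenate([[-np.inf], freq, [-np.inf]])
    peaks = []
    for i in range(len(freq)):
        left, here = padded[i], padded[i + 1]
        # plateau rule: walk right past ties; peak iff the next differing
        # neighbour is lower and the left neighbour is lower (leftmost of run)
        if here <= left or here < min_fraction:
            continue
        j = i + 1
        while j < len(freq) and freq[j] == here:
            j += 1
        right = freq[j] if j < len(freq) else -np.inf
        if here > right:
            peaks.append(i)
    shoulders = tuple(
        i
        for i in range(len(freq))
        if i not in peaks
        and freq[i] >= min_fraction
        and any(abs(i - p) == 1 for p in peaks)
    )
    loads = tuple(float(hist.edges[i]) for i in peaks)
    spacings = tuple(np.diff(loads).tolist())
    return PeakSet(tuple(peaks), loads, spacings, shoulders)


def peak_spacing_to_unit_size(peaks: PeakSet) -> tuple[float, int]:
    """Minimum peak spacing (percent) and the implied minimum unit copy number."""
    if len(peaks.peak_loads) < 2:
        raise ValueError("need at least two peaks to measure a spacing")
    min_spacing = float(min(np.diff(sorted(peaks.peak_loads))))
    return min_spacing, min_unit_size_from_spacing(min_spacing / 100.0)


@dataclass(frozen=True)
class DistributionComparison:
    """Summary statistics of simulation vs observation."""

    simulated_mean: float
    simulated_sd: float
    simulated_fraction_homoplasmic: float
    observed_mean: float
    observed_sd: float
    chi_square_distance: float
    greater_variation: bool


def compare_distributions(
    simulated: PopulationSnapshot, observed: LoadHistogram
) -> DistributionComparison:
    """Compare a simulated passage against an observed load histogram.

    Simulated loads are binned at the observed bin width and the two
    frequency vectors are scored with the symmetric chi-square distance
    sum((p-q)^2 / (p+q)) over non-empty bins. ``greater_variation`` is true
    when the simulated SD exceeds the observed SD — homoplasmic in the
    simulation means literally 0 or 100% of molecules, while the observed
    histogram can only show "apparently homoplasmic" single-color cells, so
    the two SDs, not homoplasmic fractions, carry the verdict.
    """
    if simulated.n_cells == 0 or observed.n_cells == 0:
        raise ValueError("both distributions must be non-empty")
    sim_hist = build_histogram(simulated.heteroplasmies, bin_width=observed.bin_width)
    p = sim_hist.frequencies
    q = observed.frequencies
    denom = p + q
    mask = denom > 0
    chi2 = float(np.sum((p[mask] - q[mask]) ** 2 / denom[mask]))
    sim_sd_pct = 100.0 * float(np.std(simulated.heteroplasmies, ddof=1))
    return DistributionComparison(
        simulated_mean=100.0 * simulated.mean,
        simulated_sd=sim_sd_pct,
        simulated_fraction_homoplasmic=simulated.fraction_homoplasmic,
        observed_mean=observed.mean,
        observed_sd=observed.sd,
        chi_square_distance=chi2,
        greater_variation=sim_sd_pct > observed.sd,
    )
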