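"""Molecule-level segregation: elementary operations, lineages and the oracle."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest

import heteroseg as hs
from heteroseg.errors import ExtinctLineageError


# ---------------------------------------------------------------------------
# independent enumeration oracles
# ---------------------------------------------------------------------------

def polya_urn_law(mutant, wildtype, additions):
    """Exact distribution of the final mutant count of a Pólya urn, by recursion."""
    dist = {(mutant, wildtype): Fraction(1)}
    for _ in range(additions):
        nxt = {}
        for (m, w), p in dist.items():
            t = m + w
            nxt[(m + 1, w)] = nxt.get((m + 1, w), Fraction(0)) + p * Fraction(m, t)
            nxt[(m, w + 1)] = nxt.get((m, w + 1), Fraction(0)) + p * Fraction(w, t)
        dist = nxt
    out = {}
    for (m, _), p in dist.items():
        out[m] = out.get(m, Fraction(0)) + p
    return out


def enumerate_division(mutant, wildtype):
    """Exact daughter-1 (m, w) distribution by enumerating all 2^total splits."""
    dist = {}
    for bits in itertools.product([0, 1], repeat=mutant + wildtype):
        m1 = sum(bits[:mutant])
        w1 = sum(bits[mutant:])
        dist[(m1, w1)] = dist.get((m1, w1), 0) + 1
    total = 2 ** (mutant + wildtype)
    return {k: v / total for k, v in dist.items()}


def enumerate_strict_generation_variance(copy_number):
    """Exact daughter heteroplasmy variance of one doubling + random partition.

    A (N/2, N/2) parent doubles to 2N molecules and splits them individually;
    daughter-1's heteroplasmy variance is computed by summing the binomial law
    of its total against the hypergeometric law of its mutant count,
    conditioned on the daughter being alive.
    """
    from scipy import stats

    m2 = 2 * copy_number
    het_vals, weights = [], []
    for t in range(1, m2 + 1):
        pt = stats.binom.pmf(t, m2, 0.5)
        for x in range(max(0, t - copy_number), min(copy_number, t) + 1):
            px = stats.hypergeom.pmf(x, m2, copy_number, t)
            het_vals.append(x / t)
            weights.append(pt * px)
    het_vals = np.array(het_vals)
    weights = np.array(weights)
    weights /= weights.sum()
    mu = float(np.sum(weights * het_vals))
    return float(np.sum(weights * (het_vals - mu) ** 2))


def variance_3se(sample):
    """3x the standard error of a sample variance, from the fourth moment."""
    d = sample - sample.mean()
    v = np.var(sample, ddof=1)
    return 3.0 * math.sqrt(max(np.mean(d ** 4) - v ** 2, 0.0) / len(sample))


# ---------------------------------------------------------------------------
# replication
# ---------------------------------------------------------------------------

class TestReplicateMolecules:
    def test_strict_doubling_doubles_each_genotype(self, rng):
        cell = hs.replicate_molecules(hs.MoleculeCell(3, 1), 8, hs.STRICT_DOUBLING, rng)
        assert (cell.mutant, cell.wildtype) == (6, 2)

    def test_homoplasmy_is_absorbing_under_urn_replication(self, rng):
        cell = hs.replicate_molecules(hs.MoleculeCell(4, 0), 8, hs.RELAXED_URN, rng)
        assert (cell.mutant, cell.wildtype) == (8, 0)

    def test_urn_additions_follow_exact_polya_law(self, rng):
        """(1 mutant, 1 wild type) grown to 4 molecules: final count uniform on {1,2,3}."""
        law = polya_urn_law(1, 1, 2)
        assert law == {1: Fraction(1, 3), 2: Fraction(1, 3), 3: Fraction(1, 3)}
        reps = 30_000
        counts = np.bincount(
            [hs.replicate_molecules(hs.MoleculeCell(1, 1), 4, hs.RELAXED_URN, rng).mutant
             for _ in range(reps)],
            minlength=4,
        )
        for m, expected in law.items():
            p = float(expected)
            se = math.sqrt(p * (1 - p) / reps)
            assert abs(counts[m] / reps - p) <= 3 * se

    def test_error_cases(self, rng):
        with pytest.raises(ExtinctLineageError):
            hs.replicate_molecules(hs.MoleculeCell(0, 0), 4, hs.RELAXED_URN, rng)
        with pytest.raises(ValueError):
            hs.replicate_molecules(hs.MoleculeCell(2, 2), 2, hs.RELAXED_URN, rng)
        with pytest.raises(ValueError):
            hs.replicate_molecules(hs.MoleculeCell(2, 2), 6, hs.STRICT_DOUBLING, rng)


class TestDivideCell:
    def test_homoplasmic_parent_gives_homoplasmic_daughters(self, rng):
        for _ in range(20):
            d1, d2 = hs.divide_cell(hs.MoleculeCell(8, 0), rng)
            assert d1.wildtype == 0 and d2.wildtype == 0
            assert d1.mutant + d2.mutant == 8

    def test_molecule_conservation_on_every_division(self, rng):
        for _ in range(50):
            m, w = rng.integers(0, 30, size=2)
            if m + w < 2:
                continue
            parent = hs.MoleculeCell(int(m), int(w))
            d1, d2 = hs.divide_cell(parent, rng)
            assert d1.mutant + d2.mutant == parent.mutant
            assert d1.wildtype + d2.wildtype == parent.wildtype

    def test_partition_matches_exhaustive_enumeration(self, rng):
        """(2, 2) parent: daughter-1 law over all 16 assignments vs Monte Carlo."""
        exact = enumerate_division(2, 2)
        reps = 100_000
        m1 = rng.binomial(2, 0.5, size=reps)
        w1 = rng.binomial(2, 0.5, size=reps)
        for (em, ew), p in exact.items():
            phat = float(np.mean((m1 == em) & (w1 == ew)))
            se = math.sqrt(p * (1 - p) / reps)
            assert abs(phat - p) <= 3 * se


# ---------------------------------------------------------------------------
# population growth and passaging
# ---------------------------------------------------------------------------

class TestGrowPopulation:
    def config(self, n=8, mode=hs.RELAXED_URN):
        return hs.DriftConfig(founder_heteroplasmy=0.5, copy_number=n,
                              n_passages=1, population_cap=100,
                              replication_mode=mode)

    def test_single_founder_to_capacity_two_is_one_division(self, rng):
        out = hs.grow_population([hs.MoleculeCell(4, 4)], 2, self.config(), rng)
        assert len(out) == 2
        assert sum(c.total for c in out) == 16  # replicated to 2N then split

    def test_homoplasmic_population_stays_homoplasmic(self, rng):
        cells = [hs.MoleculeCell(8, 0)] * 4
        out = hs.grow_population(cells, 64, self.config(), rng)
        assert all(c.heteroplasmy == 1.0 for c in out)

    def test_neutral_drift_preserves_mean_heteroplasmy(self, rng):
        """Martingale property: mean over replicate growths equals founder load."""
        means = []
        for _ in range(200):
            out = hs.grow_population([hs.MoleculeCell(50, 50)], 64,
                                     self.config(n=100), rng)
            means.append(np.mean([c.heteroplasmy for c in out]))
        means = np.asarray(means)
        se = means.std(ddof=1) / math.sqrt(len(means))
        assert abs(means.mean() - 0.50) <= 3 * se

    def test_capacity_below_size_is_an_error(self, rng):
        with pytest.raises(ValueError):
            hs.grow_population([hs.MoleculeCell(1, 1)] * 4, 2, self.config(), rng)


class TestPassagePopulation:
    def test_tenth_of_ten_identical_cells(self, rng):
        cells = [hs.MoleculeCell(3, 1)] * 10
        out = hs.passage_population(cells, 0.1, rng)
        assert len(out) == 1 and out[0] == cells[0]

    def test_each_cell_sampled_with_fraction_probability(self, rng):
        """Sampling-without-replacement law: inclusion probability = fraction."""
        cells = [hs.MoleculeCell(i, 1000 - i) for i in range(1000)]
        reps = 3000
        hits = 0
        for _ in range(reps):
            out = hs.passage_population(cells, 0.1, rng)
            hits += any(c.mutant == 0 for c in out)
        se = math.sqrt(0.1 * 0.9 / reps)
        assert abs(hits / reps - 0.1) <= 3 * se

    def test_bottleneck_sampling_is_unbiased(self, rng):
        cells = [hs.MoleculeCell(int(m), 100 - int(m))
                 for m in rng.binomial(100, 0.67, size=500)]
        mean_pop = np.mean([c.heteroplasmy for c in cells])
        means = [np.mean([c.heteroplasmy for c in hs.passage_population(cells, 0.1, rng)])
                 for _ in range(400)]
        se = np.std(means, ddof=1) / math.sqrt(len(means))
        assert abs(np.mean(means) - mean_pop) <= 3 * se

    def test_empty_result_is_an_error(self, rng):
        with pytest.raises(ValueError):
            hs.passage_population([hs.MoleculeCell(1, 1)] * 5, 0.1, rng)


class TestSimulateDrift:
    def test_homoplasmic_founder_stays_fixed_at_every_passage(self):
        cfg = hs.DriftConfig(founder_heteroplasmy=1.0, copy_number=50,
                             n_passages=3, population_cap=200, seed=1)
        for snap in hs.simulate_drift(cfg):
            assert np.all(snap.heteroplasmies == 1.0)

    def test_heteroplasmy_variance_grows_across_passages(self):
        cfg = hs.DriftConfig(founder_heteroplasmy=0.67, copy_number=180,
                             n_passages=8, population_cap=1000, seed=3)
        snaps = hs.simulate_drift(cfg)
        assert snaps[-1].sd > snaps[0].sd

    def test_low_copy_turnover_clone_fixes_by_late_passage(self, rng):
        """With ~350 copies/cell and turnover, most lineages are homoplasmic
        after 32 passages (~106 generations) — drift is fast at low copy number."""
        g = int(round(32 * hs.DOUBLINGS_PER_TENFOLD))
        h = hs.simulate_lineages(0.55, 350, g, 1500, hs.RELAXED_URN,
                                 turnover_events_per_cycle=2.0, rng=rng)
        assert np.mean((h == 0.0) | (h == 1.0)) > 0.5

    def test_population_cap_does_not_drive_heteroplasmy_spread(self):
        """Drift is dominated by within-cell sampling, so a 10x larger dish
        leaves the final single-cell SD unchanged within Monte Carlo error."""
        sds = {}
        for cap in (1000, 10_000):
            reps = []
            for seed in range(6):
                cfg = hs.DriftConfig(founder_heteroplasmy=0.5, copy_number=100,
                                     n_passages=4, population_cap=cap, seed=seed)
                reps.append(hs.simulate_drift(cfg)[-1].sd)
            sds[cap] = (np.mean(reps), np.std(reps, ddof=1) / math.sqrt(len(reps)))
        diff = abs(sds[1000][0] - sds[10_000][0])
        se = math.hypot(sds[1000][1], sds[10_000][1])
        assert diff <= 3 * se


# ---------------------------------------------------------------------------
# lineages, martingale and absorption
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("mode", [hs.STRICT_DOUBLING, hs.RELAXED_URN])
def test_lineage_mean_heteroplasmy_is_a_martingale(mode, rng):
    h = hs.simulate_lineages(0.67, 64, 20, 10_000, mode, rng=rng)
    se = h.std(ddof=1) / math.sqrt(len(h))
    assert abs(h.mean() - 0.67) <= 3 * se


@pytest.mark.parametrize("p0", [0.0, 1.0])
def test_homoplasmy_is_absorbing_in_lineages(p0, rng):
    h = hs.simulate_lineages(p0, 32, 15, 500, hs.RELAXED_URN, rng=rng)
    assert np.all(h == p0)


# ---------------------------------------------------------------------------
# variance oracle
# ---------------------------------------------------------------------------

class TestDriftVarianceOracle:
    def test_zero_generations_and_fixed_founder_have_zero_variance(self):
        assert hs.drift_variance_oracle(0.3, 100, 0) == 0.0
        assert hs.drift_variance_oracle(1.0, 100, 50) == 0.0

    def test_one_strict_generation_matches_exact_enumeration(self):
        """Doubling 4 molecules to 8 and splitting them at random: the oracle
        reproduces the fully enumerated daughter heteroplasmy variance."""
        exact = enumerate_strict_generation_variance(4)
        oracle = hs.drift_variance_oracle(0.5, 4, 1, hs.STRICT_DOUBLING)
        assert oracle == pytest.approx(exact, rel=1e-9)

    @pytest.mark.parametrize("mode", [hs.STRICT_DOUBLING, hs.RELAXED_URN])
    @pytest.mark.parametrize("copy_number,generations",
                             [(4, 1), (4, 20), (16, 5), (64, 20)])
    def test_oracle_matches_simulated_lineages(self, mode, copy_number, generations, rng):
        h = hs.simulate_lineages(0.5, copy_number, generations, 12_000, mode, rng=rng)
        v = float(np.var(h, ddof=1))
        oracle = hs.drift_variance_oracle(0.5, copy_number, generations, mode)
        assert abs(v - oracle) <= variance_3se(h)

    def test_oracle_with_turnover_matches_simulation(self, rng):
        h = hs.simulate_lineages(0.55, 100, 30, 8_000, hs.RELAXED_URN,
                                 turnover_events_per_cycle=1.0, rng=rng)
        oracle = hs.drift_variance_oracle(0.55, 100, 30, hs.RELAXED_URN,
                                          turnover_events_per_cycle=1.0)
        assert abs(np.var(h, ddof=1) - oracle) <= variance_3se(h)

    def test_variance_monotone_in_copy_number_and_generations(self):
        variances = [hs.drift_variance_oracle(0.67, n, 100) for n in (350, 1000, 5000)]
        assert variances == sorted(variances, reverse=True)
        by_g = [hs.drift_variance_oracle(0.67, 1000, g) for g in (10, 50, 200)]
        assert by_g == sorted(by_g)


# ---------------------------------------------------------------------------
# threshold scan
# ---------------------------------------------------------------------------

class TestThresholdScan:
    def test_loose_criterion_selects_smallest_grid_member(self, rng):
        res = hs.copy_number_threshold_scan(0.67, 81, 0.49, [350, 1000], rng=rng)
        assert res.threshold == 350

    def test_unreachable_criterion_is_reported_not_raised(self, rng):
        res = hs.copy_number_threshold_scan(0.5, 81, 0.01, [4, 8], rng=rng)
        assert not res.reached and res.threshold is None

    def test_more_passages_never_lower_the_threshold(self, rng):
        grid = hs.default_copy_number_grid(350, 100_000, 25)
        t81 = hs.copy_number_threshold_scan(0.67, 81, 0.07, grid, rng=rng).threshold
        t162 = hs.copy_number_threshold_scan(0.67, 162, 0.07, grid, rng=rng).threshold
        assert t162 >= t81

    def test_simulated_scan_agrees_with_oracle_scan(self, rng):
        grid = [64, 256, 1024]
        oracle = hs.copy_number_threshold_scan(0.5, 3, 0.10, grid, rng=rng)
        sim = hs.copy_number_threshold_scan(0.5, 3, 0.10, grid, method="simulate",
                                            sim_reps=4000, rng=rng)
        assert sim.threshold == oracle.threshold
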