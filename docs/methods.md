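# Methods

## Models

### Molecule-level random mitotic segregation

A cell is the pair (mutant, wildtype) of mtDNA molecule counts; its
heteroplasmy (mutation load) is p = mutant/total. One culture cycle is:

1. *(optional)* turnover: paired degradation+replication events, each
   removing one uniformly chosen molecule and copying a uniformly chosen
   survivor (a Moran step);
2. replication with no genotype preference, either `strict_doubling`
   (each molecule copied exactly once) or `relaxed_urn` (molecules added
   one at a time, each copying a template drawn uniformly from the current
   pool, up to twice the copy-number set point — a Pólya urn, so additions
   follow the beta-binomial law);
3. division: every molecule independently assigned to a daughter with
   probability 1/2. Daughter totals are unequal in general; a
   zero-molecule daughter (negligible at realistic copy number) is removed
   and counted.

Populations grow by asynchronous division of uniformly chosen cells until
the dish capacity is reached; a passage is a uniform random sample of a
fraction (default 1/10) of the cells followed by regrowth, i.e.
log₂ 10 ≈ 3.32 effective doublings. Because a uniformly chosen cell of a
neutrally growing population is statistically a single random lineage, the
intrinsic single-cell drift variance is also computed by vectorized
lineage simulation (`simulate_lineages`), which is what the threshold scan
uses for confirmation.

Under `relaxed_urn` the copy number is re-regulated to the set point every
cycle. Under `strict_doubling` the total performs a critical branching
walk around the founder value; this mode exists for enumeration checks and
for the single-copy-unit equivalence, and the default for all
passaging-scale runs is `relaxed_urn`.

### Exact drift-variance oracle

Neutral drift leaves E[p] fixed and shrinks the expected heterozygosity
H = E[p(1−p)] by an exactly computable factor per cycle:

* partitioning M molecules into a daughter of size T (hypergeometric
  sampling): H ↦ H · (1 − (M−T)/(T(M−1)));
* Pólya-urn refill from T to M molecules (beta-binomial):
  H ↦ H · (1 − (M−T)/(M(T+1)));
* e Moran turnover events at total T: H ↦ H · (1 − 2/(T(T−1)))ᵉ.

For `relaxed_urn` the post-partition total is Binomial(2N, 1/2)
(conditioned positive) every generation, so the per-generation factor is a
single expectation over that law; fractional generation counts (passages ×
log₂ 10) exponentiate the asymptotic factor. For `strict_doubling` the
totals path is autonomous, and the oracle takes the path expectation of
the product of factors by dynamic programming over totals (truncated far
above the founder copy number, overflow mass lumped at the cap),
conditioned on lineage survival. The between-lineage variance after g
generations is then p₀(1−p₀)(1 − H_g/H₀). In the large-N limit both modes
reduce to the familiar 1 − c/N decay with c ≈ 1 (relaxed) and c ≈ ½
(strict): relaxed replication roughly doubles the drift rate. The oracle
is verified against brute-force enumeration (one doubling+partition of 8
molecules) and against simulation for N ∈ {4, 16, 64}, g ∈ {1, 5, 20},
both modes, within 3 SE.

### Copy-number threshold scan

`copy_number_threshold_scan` returns the smallest copy number on an
ascending grid whose final-passage SD (oracle or simulated) is at most the
criterion SD. The headline configuration — founder load 0.67, 81 passages
(≈ 269 generations), criterion SD 0.07, the single-cell assay's
measurement SD — yields 12,729 on the default 21-point log grid from 350
to 24,000 (the grid point nearest the ~12,000-copy requirement; the exact
crossing sits at N ≈ 12,000 where the per-generation decay ≈ 1/N makes
0.2211·(1 − e^(−269/N)) = 0.07²). The criterion SD is exposed as a
parameter because the published statement specifies no explicit criterion;
matching the measurement envelope is the natural reading.

### Metastable segregation-unit model

Units of n mtDNA copies (k mutant) replicate faithfully — both copies
inherit (k, n) — and the 2U unit copies are partitioned per-unit
Bernoulli(1/2) (a balanced without-replacement split is available). The
unit-genotype frequency among a lineage's units is a bounded martingale,
so the fixation probability of a genotype equals its initial frequency;
`fixation_probabilities` is the analytic form and
`simulate_unit_lineages` the stochastic counterpart (lineages are
followed down one daughter until all units share a genotype, die out, or
hit the 50×U generation cap; unfixed and dead lineages are reported, not
dropped). With single-copy units (n = 1, U = N) the model reduces exactly
to molecule-level strict doubling, which is tested.

Metastable events: `reorganize_single_unit` rewrites one unit's k;
`redistribute_all` re-deals the pooled molecules into fresh units, either
exactly (multivariate hypergeometric; requires uniform n) or as
independent Binomial(n, pooled load) draws repaired to conserve the pool
by incrementing/decrementing uniformly chosen units. The repair keeps the
binomial method's per-unit variance above the hypergeometric one but
slightly fattens the tails relative to a pure binomial, so tests score the
marginal by total-variation distance rather than an unbounded chi-square.

### Observation model

Per-molecule detection is Bernoulli(ε). In `independent_molecules` mode
each detected molecule is one dot of its genotype's color; in
`unit_clustered` mode each unit is at most one dot, red with probability
(1−(1−ε)^k)(1−ε)^(n−k), green symmetrically, yellow when both genotypes
are detected, undetected with (1−ε)^n. Load is estimated as
red/(red+green); yellow dots are recorded but excluded (the assay derives
load from the two single-color channels). Given red+green = t, red is
Binomial(t, p), so the estimator is conditionally unbiased at any
efficiency. ~60 dots/cell over ~1,800 molecules gives an apparent
independent-molecule efficiency of 3.3%; inverting the unit-clustered
detection equation U(1−(1−ε)^n) = dots for U = 225, n = 8 gives ε ≈ 3.8%,
bracketing the assay's ~3–5%. An optional lognormal per-cell efficiency
multiplier (unit mean) reproduces the ~2-fold dots/cell variability between
passages; optional Gaussian noise truncated to [0, 1] emulates the
PCR-RFMT assay (SD 4–8%).

### Histograms and peaks

Loads are binned at 5% or 10% into left-closed bins with a closed top bin
([95, 100]). Stringency selection requires >30% of cells to contribute:
≥40 dots with 5% bins when possible, else ≥20 dots with 10% bins, else an
under-detected flag. Peaks are bins strictly above both neighbours
(plateaus resolved leftmost, range ends treated as empty) with frequency
above a threshold (default 10%); adjacent above-threshold bins are
reported as shoulders. This is a deliberate, testable formalization of
peaks that were originally identified by eye. The minimum peak spacing s
bounds the unit size from below by ceil(1/s) — a unit of n copies can only
move cellular load in steps of 1/n — giving 10–20 copies for 5–10%
spacings. Distribution comparison reports means, SDs, homoplasmic
fractions and a symmetric chi-square distance; "greater variation" is
carried by the SDs because literal homoplasmy (0 or 100% of molecules) and
apparent homoplasmy (single-color readout) are different observables.

## Synthetic data: what it emulates, and what not

`generate_scenario` produces per-passage per-cell tables
(true load, red/green/yellow dots) plus an event log, deterministic given
the scenario seed. It emulates: neutral drift or faithful-unit
segregation, bottleneck/regrowth culture structure, low-efficiency
dot readouts with per-cell count heterogeneity, rare metastable events,
and a nuclear-proxy growth advantage — implemented as an increased
division propensity inherited by descendants of the first cell that
becomes homogeneous for a reorganization-derived unit genotype (the
"randomly arising" lineage the hitchhiking narrative requires). It does
not emulate: mtDNA-genotype-dependent fitness, spatial or
mitochondrial-network structure, dot co-localization geometry beyond the
unit-cluster abstraction, or assay-specific artefacts (probe accessibility,
RCA product repulsion). Passing tests therefore demonstrate internal
consistency of the segregation/observation/analysis chain, not that real
cultures obey these dynamics.

## Parameter choices

| Parameter | Default | Why |
|---|---|---|
| founder loads 0.67 / 0.55 / 0.50 | presets | printed founder heteroplasmies of the V_3.2, G_55.2 and toy-cell configurations |
| copy numbers 1,800 / 350 / 72 | presets | printed qPCR copy-number estimates; 72 = 9 units × 8 copies |
| bottleneck fraction | 0.1 | the 1/10 split used for most clones |
| population cap | 10⁴ | scaled-down confluence (10⁶ in the study); between-cell spread is dominated by within-cell sampling, and a cap-insensitivity test (10³ vs 10⁴) backs the scaling |
| passages 81 / 32 | presets | the analysed passage ranges |
| detection efficiency | 60/1800 ≈ 3.3% | reproduces ~60 dots/cell for V_3.2; G_55.2 preset uses 0.15 (~50 dots at 350 copies, matching ≥40 dots in 80% of cells) |
| turnover (G_55.2 preset) | 2 pairs/molecule/cycle | mtDNA turnover is fast relative to the ~25 h division time of these cultures; at 350 copies this makes the great majority of lineages homoplasmic by passage 32, the behaviour the low-copy clone's simulation is expected to show. Default elsewhere is 0 |
| RFMT noise SD | off; 0.04–0.08 valid | the single-cell PCR-RFMT assay's printed SD range |
| criterion SD (scan) | 0.07 | the ~7% single-cell measurement SD at ≥20 dots/cell |
| stringency thresholds 20/40, bins 5%/10% | fixed | the published stringency/bin-width rules, including the >30%-of-cells requirement |
| peak min_fraction | 0.10 | smallest subpopulation the study treats as a prominent peak |
| lineage reps | 10⁴ (1e3 confirm) | keeps 3-SE Monte-Carlo bands at or below the printed precision of the quantities checked |

## Numerical choices and degenerate inputs

Founder mutant counts round half away from zero. Beta-binomial sampling is
exact for the urn (binomial with Beta(m, w) success probability), valid
for integer m, w ≥ 1; homoplasmic cells bypass it (absorbing state).
Vectorized turnover draws the number of composition-changing Moran events
from a binomial at the cycle's starting state and applies a fair-coin
random walk clipped to [0, total] — exact apart from within-cycle drift of
the change probability, negligible when changes per cycle are few relative
to the copy number (the regime of all presets); the scalar path uses exact
geometric skips. The strict-mode DP truncates totals at
N + 12√(Ng/2) + 32 with overflow lumped at the cap. Dead daughters
(zero molecules or zero units) are removed and counted, never silently
dropped. Load estimation with zero informative dots raises; empty
histograms raise; an unreachable scan criterion is reported as not
reached, not raised.

## Known limitations

* Strict-doubling populations do not regulate copy number; over hundreds
  of generations totals disperse, so the mode is not meant for
  passaging-scale runs (the relaxed default is).
* The oracle assumes neutrality throughout; it cannot be combined with the
  growth-advantage machinery of the synthetic generator.
* The binomial redistribution repair is one of several defensible
  conservation rules; conditioning on the pooled total instead would
  collapse the method onto the hypergeometric deal.
* Unit-model population simulations track genotype multisets per cell and
  scale as O(cells × genotypes); they are intended for U ≲ a few hundred.
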