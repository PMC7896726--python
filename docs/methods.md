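# Methods

## Setting

Two groups of populations with contrasting life histories — anadromous-like
("A", the ancestral, migratory condition) and landlocked-like ("L",
freshwater residents) — are compared through pooled whole-genome
sequencing.  Each population is observed as read counts over alleles at
segregating sites (sync format), obtained by sequencing pools of diploid
individuals.  Three signals are sought:

1. **Parallel selective sweeps in L** — alleles driven toward fixation in
   every landlocked population, visible as clusters of SNPs with a large
   group frequency difference and depleted diversity in L.
2. **Relaxed purifying selection in L** (equivalently, conserved function
   in A) — regions where every anadromous population keeps low
   heterozygosity while every landlocked population accumulates diversity.
3. **Population structure** summarized as a distance-based phylogeny.

## SNP filtering

Pools are merged into populations by summing counts.  Sites are retained
when exactly two bases (A/C/G/T; N and deletion counts are carried but
never treated as alleles) have non-zero global counts and the global minor
count is ≥ 2; per-population depth must be ≥ 5 everywhere (a site failing
anywhere is dropped everywhere).  Contigs can be excluded by exact name or
prefix (mitochondrial genome, unplaced scaffolds).

The heterozygosity branch applies one further filter: per population, the
modal ("peak") depth and the depth standard deviation are estimated from
the data, and a site is kept only if its depth lies within peak ± 1 sd in
*every* population.  Decisions the data cannot fix are made
deterministically: modal-depth ties resolve to the smaller depth; the sd is
the population (n-denominator) standard deviation; depth here means the
two-allele depth of the filtered site.  The band filter belongs only to
the heterozygosity branch because windowed Hp is sensitive to
coverage-driven variance; the differentiation branch uses the plain filter
stack.  Both stacks are exposed as named presets (`daf`, `hp`).

## Differentiation scan (dAF)

Per site, `p` is the reference-allele frequency per population;
`dAF = p̄_L − p̄_A` with unweighted means over the populations of each group
(populations, not pools, and not depth-weighted — pools are merged first).
Windows of 100 kb on a genome-anchored 50 kb grid count SNPs with
|dAF| ≥ 0.6; windows with ≥ 10 such SNPs are extended 50 kb per side,
clipped to the chromosome, and overlapping-or-touching intervals merge into
sweeps.  Consequently an unclipped sweep is at least
100 kb + 2·50 kb = 200 kb long.  The threshold is two-sided by default
(`--signed` restores a one-sided scan).  Extending before merging or
merging before extending yields the same union; this equivalence is
asserted in tests.

## Pooled heterozygosity (Hp, ZHp)

For a window with n SNPs, `Hp = (1/n) Σ 2pᵢ(1−pᵢ)` with pᵢ the global
major-allele frequency (2p(1−p) is symmetric, so major/minor orientation
cannot change Hp; global-major ties break lexicographically by base).
Windows are 50 kb at 1 bp step, restricted to lie fully inside the
chromosome; windows with fewer than 10 SNPs are discarded.

Enumerating every start explicitly is quadratic in genome size.  Window
membership changes only at start positions `p − window + 1` and `p + 1`
for a SNP at `p`, so admissible starts partition into maximal
constant-membership segments; Hp is computed once per segment via prefix
sums.  This is exact, not an approximation — the test suite checks segment
Hp, ZHp and region calls against naive per-start enumeration on toy
chromosomes.

Per population, `ZHp = (Hp − µ_Hp)/σ_Hp`, where µ and σ are taken over all
retained 1 bp-step windows — segment values weighted by segment width — so
the post-normalization width-weighted mean and sd are exactly 0 and 1.
`dZHp = mean(ZHp_A) − mean(ZHp_L)` (positive = diversity depleted in L).
A window is a **consistency call** when every population of one group has
ZHp strictly below 0 and every population of the other group strictly
above 0; exact zeros disqualify.  Qualifying windows expand to their full
extents and merge.  No significance level is attached to these calls; the
criterion is a sign-consistency rule across 9 populations, and isolated
background calls are expected.

**Cross-dataset confirmation** runs the identical Hp → ZHp → consistency
scan on an external per-group frequency panel (frequencies used as given)
and reports the maximal intervals where the sequencing-derived regions and
the panel's regions overlap.

## F_ST and phylogeny

Per SNP and population pair, Nei's fixation index
`F_ST = (p̄(1−p̄) − (p₁(1−p₁)+p₂(1−p₂))/2) / p̄(1−p̄)`, `p̄ = (p₁+p₂)/2`,
using reference-allele frequencies.  For two populations the estimator is
non-negative; it is undefined where p̄ ∈ {0, 1}, and such sites are skipped
(with a logged count) in the per-pair mean that fills the distance matrix.
The tree is standard Saitou–Nei neighbor joining — join the pair minimizing
`Q(i,j) = (n−2)d(i,j) − rᵢ − rⱼ`, ties broken by smallest index pair — with
the final three clusters resolved as an unrooted star.  Negative branch
lengths are retained and logged rather than clamped, matching the classical
Phylip behavior.  On additive matrices the tree reproduces every
leaf-to-leaf distance exactly.

## Gene annotation

Regions are annotated with genes from a GFF3 (type `gene` records only;
GFF 1-based inclusive coordinates converted to the internal 0-based
half-open convention).  Overlap is any-bp on half-open intervals, the
bedtools-intersect default; genes without a symbol attribute are reported
as `unknown`, and duplicate symbols from distinct gene records are kept.

## Synthetic Pool-seq generator

The generator reproduces the statistical structure the scan assumes, at
desk scale, with full ground truth:

* **Sites**: a Poisson process at 1 site / 200 bp over 2 chromosomes of
  2 Mb (defaults).
* **Neutral frequencies**: ancestral π ~ U(0.05, 0.95) per site; each
  population draws p ~ Beta(π(1−F)/F, (1−π)(1−F)/F) (Balding–Nichols),
  with per-population drift F spanning 0.05–0.15.  This matches the per-site
  frequency model the scan analyses, is seedable and fast, and has
  closed-form expectations used for calibration tests
  (E[2p(1−p)] = 2π(1−π)(1−F)); coalescent simulation is deliberately out of
  scope.
* **Planted features** (frequency-level; linkage is emulated by letting all
  sites of a feature share the effect):
  - *parallel_sweep_L* (default 150 kb): all L populations draw from a Beta
    concentrated at a shared derived allele (mean 0.97, concentration 150);
    the ancestral frequency inside the feature is U(0.05, 0.30), so the
    expected dAF is ≈ +0.80 and L heterozygosity collapses.
  - *low_het_A* (default 80 kb): all A populations concentrate near the
    major allele (mean 0.97) while L stays neutral.  The ancestral range is
    U(0.60, 0.75): close enough to the fixation target that |dAF| stays
    ≈ 2.5 noise-sd below the 0.6 sweep threshold, yet with π(1−π) above the
    genome average so the landlocked group's heterozygosity stays
    above-average — exactly the relaxed-selection signature.
* **Observed counts**: pool allele copies k ~ Binomial(2N, p) for a pool of
  N diploids (default pools of 10–20, several pools per population for the
  larger ones, exercising pool merging); depth d ~ Poisson(λ·m) with
  per-population λ spanning 17–244 and a per-site lognormal factor m
  (CV 0.3) shared by all pools; reference reads ~ Binomial(d, k/2N).  The
  shared factor models the strong cross-sample depth correlation that local
  mappability induces in real Pool-seq; without it, independent depths make
  the joint 9-population ±1 sd band filter retain only a few percent of
  sites, whereas with it retention sits near the ~25% regime reported for
  real data.  Zero depths are bumped to 1 (unrepresentable in sync;
  negligible at these λ).
* **Panel**: an independently re-sampled per-group frequency table over the
  same features (four groups, two per ecotype; drift 0.02 around π; marker
  density 1 site/kb — denser than a real 220K array genome-wide, chosen so
  50 kb windows clear the 10-SNP floor at desk scale).

What the simulator does *not* model: linkage beyond block-level effects,
recombination maps, demographic history beyond star-shaped drift,
sequencing error beyond binomial read sampling, reference bias, and indels.
Passing recovery tests therefore demonstrates the pipeline's correctness on
data satisfying its own model assumptions, not robustness to artifacts of
real libraries.

### A structural note on sweep/low-het co-detection

Inside a planted sweep with dAF ≈ 0.8 the anadromous group's frequency is
necessarily ≈ 0.17, whose heterozygosity 2·0.17·0.83 ≈ 0.28 lies *below*
the genome average (≈ 0.33): the consistency rule's "all A above average"
leg therefore fails inside sweeps about half the time, and sweeps are only
sometimes co-called as low-het-L regions.  This is a property of the
statistics, not a defect — the same asymmetry appears in real data, where
only a minority of sweeps overlap consistency regions.

## Problem sizes and determinism

Default simulations are 4 Mb × 9 populations (~20,000 sites, ~12 pools),
chosen so a full scan runs in well under a second and the 50-replicate
recovery studies in tests and `scripts/acceptance.py` finish in tens of
seconds.  All randomness flows from one integer seed through
`numpy.random.default_rng`; identical seeds give byte-identical output
files, and the pipeline itself is deterministic given its inputs (the run
manifest records input and output checksums).

## Known limitations

* The consistency criterion has no multiplicity control; region counts
  scale with genome size and population number.
* Pairwise F_ST averages skip sites where the estimator is undefined for
  that pair, which can make different pairs average over different site
  sets.
* The segment representation assumes integer, strictly per-chromosome
  sorted positions with at most one record per position.
* The minimum-depth and band filters act on the two retained alleles'
  depth, not the raw six-category depth (a deliberate, documented choice).
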