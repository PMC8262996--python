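# Methods

## The inference problem

Pairwise community turnover between microbiome samples can be driven by
deterministic selection (environmental filtering), by dispersal (organism
exchange between communities), or by ecological drift (stochastic birth and
death).  The pipeline partitions sample pairs among these processes with two
null-model deviations, computed per pair:

**beta-mean-nearest-taxon distance (βMNTD).**  With abundance weights
`w_i` (per-taxon weights over present taxa, by default `ln(1+x)`-transformed
counts renormalized to sum to 1) and patristic distances `d(i,j)` from the
rooted tree,

    βMNTD(j,k) = ½ [ Σ_{i∈j} w_ij · min_{m∈k} d(i,m)
                   + Σ_{m∈k} w_mk · min_{i∈j} d(m,i) ]

**βNTI** is the z-score of the observed βMNTD against a null in which taxon
identities are shuffled across all tips of the tree while abundances stay
fixed (default 1,000 randomizations, one shared shuffle applied to every
pair per randomization).  |βNTI| > 2 indicates that selection dominates the
pair — less turnover than expected (βNTI < −2, homogeneous selection, i.e.
filtering by similar environments) or more (βNTI > 2, variable selection).
The null keeps `d(i,i) = 0`, so taxa shared by both communities contribute
zero in both the observed and the null statistic; the signal is carried
entirely by the taxa found in only one of the two communities.

**Abundance-based Raup–Crick (RC).**  Observed Bray–Curtis dissimilarity is
ranked within a null distribution of probabilistically re-assembled
communities: each null realization rebuilds every sample with its observed
richness and read total, drawing which taxa occur without replacement with
probability proportional to metacommunity occupancy, then filling the
remaining reads multinomially proportional to metacommunity relative
abundance.  RC = 2·[(n_below + ½·n_ties)/n_rand − ½] ∈ [−1, 1].  For pairs
not dominated by selection, RC < −0.95 indicates homogeneous dispersal and
RC > 0.95 dispersal limitation; otherwise the pair is undominated (drift).

Classification is sequential — selection is evaluated before dispersal, and
the boundaries are inclusive toward the weaker interpretation (βNTI = ±2 is
not selection; RC = ±0.95 is not dispersal).

Per-pair nulls can degenerate: if two samples contain exactly the same taxa,
every shuffled βMNTD is zero and the z-score is undefined.  Such pairs are
reported as NaN with a warning, classified "unclassified", excluded from
process fractions, and counted — never silently dropped.

## Rarefaction replication and aggregation

All between-sample comparisons run on tables rarefied to a common depth
(default 19,600 reads/sample, 100 replicate tables).  Rarefaction is an
exact uniform draw without replacement (multivariate hypergeometric);
samples below the target depth are dropped with a logged warning.  βNTI and
RC are computed per replicate table, averaged per pair over replicates, and
the means are classified once (a per-replicate majority-vote alternative is
available via `aggregation="vote"`).  Averaging was chosen because votes
are unstable for pairs near a threshold.  Alpha diversity (bias-corrected
Chao1; root-inclusive Faith PD, stem included by default with an
`include_stem` switch) is likewise computed per replicate and averaged.

## Group summaries and shift tests

Pairs are grouped by shared/different host species and site
(`S.host&S.site`, `S.host&D.site`, `D.host&S.site`, `D.host&D.site`).
Within each group the relative importance of each process is its fraction
of classified pairs, with 95% percentile-bootstrap CIs over pairs.  The
host-induced shift of a process is the fraction difference between
`D.host&S.site` and the `S.host&S.site` baseline — the site contrast is
analogous (`S.host&D.site` vs baseline) — so the varied factor changes
while the other is held fixed.  Significance comes from a one-sample t test
on the bootstrap deltas (1,000 resamples), and the 10 tests (5 processes ×
2 contrasts) form one Benjamini–Hochberg family.  Pairwise quantities are
not independent; the bootstrap resamples pairs and the CIs should be read
accordingly.

## Spatial and comparative statistics

Community similarity is 1 − Bray–Curtis throughout.  Geographic distances
are great-circle (haversine, Earth radius 6371.0088 km).  The Mantel test
correlates the off-diagonal entries of two distance matrices and computes a
one-sided permutation p-value `(1 + #{r_perm ≥ r_obs})/(1 + n_perm)` under
simultaneous row/column permutation (999 permutations by default); the
partial Mantel correlates residuals after removing the linear effect of a
third matrix from both.  Distance-decay and latitude–diversity regressions
are ordinary least squares with slope inference from a bootstrap that
resamples samples — not pair entries — rebuilding the pair set each
resample, so the dependence structure of distance matrices is respected.
Slope differences are tested on the bootstrap slope distributions (unpaired
t by default, paired available).  Numerically degenerate residuals (e.g. a
covariate identical to one input) are treated as zero-signal rather than
amplified noise.

Core OTUs: a local core OTU at a site has within-site mean relative
abundance ≥ 0.1% and occurrence in ≥ ⌈0.8·n⌉ of the site's samples (so ≥ 8
of 10); a regional core OTU is local core at every site of a host.  The
mean-abundance reading of the 0.1% filter is the default; an
`any_sample` scope reproduces the display-tree variant (≥ 0.1% in at least
one sample).

## The synthetic-data generator

The generator exists to make the pipeline falsifiable: it assembles
communities under each process with recorded ground truth.  It emulates a
two-host, five-site, ten-replicate amplicon study — a few hundred OTUs on
a rooted tree, ~19,600 reads per sample, a log-normal regional abundance
spectrum — not any particular real dataset.

Building blocks: a Yule (pure-birth) time tree; Brownian-motion traits
(`sim_traits`, used for phylogenetic-signal checks and available as an
explicit optima input to the assembler); a log-normal metacommunity pool
(σ = 1.5).  Default pools cap single-taxon dominance at 10% of the pool
(excess redistributed proportionally): occasional uncapped draws put ~30%
of all reads on one taxon, which compresses every Bray–Curtis contrast and
makes the taxonomic null uninformative for the unlucky replicate.

Scenario mechanics (all Wright–Fisher drift is constant-N multinomial
resampling, the simplest model of chance birth–death):

* **Selection scenarios.**  Selection acts through a Gaussian filter
  `exp(−s·(optimum − E)²)` (default strength s = 12).  When the caller
  supplies Brownian optima, the filter is applied to them as-is.  By
  default, however, the generator designates a niche *clade* (~30% of the
  tree's tips; for variable selection, the two disjoint clades whose root
  nodes are phylogenetically farthest apart): clade members receive optima
  tightly clustered (sd 0.1) around the niche environment (±2), everything
  else near 0, so niches are perfectly phylogenetically conserved.  The
  niche clade's internal branches are shortened 10-fold, emulating the
  dense within-genus OTU radiations of real 16S trees, and per-sample
  log-normal "lottery" noise (σ = 1.3) multiplies the filtered weights so
  membership turns over among close relatives.  These three ingredients
  are load-bearing: measured across many seeds, a Gaussian filter on plain
  Brownian traits over a strict-clock Yule tree never concentrates
  eligibility into a dense clade, and because observed βMNTD cannot go
  below zero, βNTI is then bounded by −μ/σ of the shuffle null (≈ −2 at
  200 taxa) — homogeneous selection is undetectable in principle at desk
  scale without them.
* **Homogeneous dispersal.**  Ten generations of local drift with a 50%
  per-generation migrant fraction from one shared pool: strong mixing,
  weak local noise.
* **Dispersal limitation.**  Each isolated pool is seeded by a founder
  bottleneck (50 colonists drawn from the regional pool) and then drifts
  50 generations with no migration; samples are multinomial draws from
  their pool.  The founder effect is what pushes observed between-pool
  dissimilarity reliably past the Raup–Crick null, which adapts to pure
  drift through occupancy; `founder_size=0` restores pure drift (and with
  `drift_generations=0` yields identical pools, the neutral control).
* **Drift.**  Thirty generations of independent per-sample drift with 10%
  migration from the shared pool — calibrated so most pairs stay inside
  both null envelopes (the "no dominant process" regime).

The study-shaped bundle (`sim_study_design`) composes these: host pools
split by founder effect + drift (between-host pairs embody dispersal
limitation) with 10% recurrent immigration from the regional pool so every
host keeps a rare tail (without it, membership saturates at full depth and
same-host βNTI nulls degenerate); one host's samples are under shared
homogeneous selection on the niche clade (~90% of reads) over a thin
background layer, the other host's samples drift locally (effective local
population 2,000).  Site pools drift mildly from host pools; site latitude,
MAT and MAP decline monotonically across ~10° latitude.

What passing recovery tests does **not** show about real data: the
generator's niches are perfectly conserved and its tree radiations are
engineered, so recovery rates here are upper bounds; real 16S data have
sequencing noise, compositional artifacts, and imperfect trees that the
generator does not model.

## Reproducibility and problem sizes

Every stochastic routine takes an explicit seed and spawns per-replicate
streams with `numpy.random.SeedSequence`, so results are bit-identical
across runs and independent of evaluation order.  The test and acceptance
workloads use scaled problem sizes chosen to exercise every code path at
statistical resolution adequate for their tolerances: scenario recovery at
200 taxa × 20 samples × 2,000 reads with 200 randomizations; null
calibration over 30 independent 6-sample tables (450 pairs); the end-to-end
study bundle at its full 100 samples × 274 OTUs × 19,600 reads with 2
rarefied replicates and 200 randomizations.  Production analyses should use
the defaults (100 rarefactions, 1,000 randomizations).

## Known limitations

* βNTI is undefined for identical-membership pairs (degenerate null); deep
  sequencing of low-richness communities produces many such pairs, which
  are reported but unclassifiable.
* The tip-shuffle null uses the whole analysed taxon set as one pool;
  within-habitat constrained nulls are not implemented.
* The Raup–Crick metacommunity defaults to the analysed sample set;
  restricting it (e.g. per host) is supported via `reference_table` but the
  choice materially affects RC near its thresholds.
* Bootstrap CIs over pairs understate uncertainty from sample-level
  dependence; shift tests inherit this.
* Incidence-based Raup–Crick, UniFrac, NMDS/PERMANOVA/VPA are out of scope
  (the latter are available in established packages, e.g. vegan or
  scikit-bio, and the pipeline's outputs feed them directly).
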