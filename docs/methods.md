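# Methods

This note documents the models, conventions and numerical choices behind
`eelclines`, in the order data flow through the pipeline.

## Synthetic species pools

**Model.** Each of the 9 microsatellite loci carries 10–18 alleles on a
2-bp size lattice (distinct base size per locus). An ancestral frequency
spectrum per locus is drawn from a symmetric Dirichlet(1, …, 1); the two
species' spectra are then drawn from Dirichlet(p_anc · (1 − F)/F), the
Balding–Nichols construction under which F is the expected fixation
index. Diploid genotypes are sampled from each species spectrum under
Hardy–Weinberg proportions (100 individuals per pool by default,
emulating microsatellite sample sizes of real eel collections).

**Calibration.** A single global F is found by bisection on the
*realized* multi-locus Weir–Cockerham θ between the two emitted pools,
to a tolerance of ±0.005 around the target (default 0.0146, the
inter-species differentiation these markers show). Calibrating on the
realized value rather than the model parameter absorbs both the
finite-locus variance of the Dirichlet draws and the sampling noise of
100-individual pools. Bisection runs on a fixed per-seed stream, so a
configuration is bit-reproducible; it errors after 40 iterations if the
tolerance cannot be met, reporting the achieved θ.

**What the generator does and does not emulate.** It reproduces the
differentiation level, heterozygosity (mean Ho ≈ 0.8), and allele-count
range of the real pools. It does *not* simulate a mutation process:
allele sizes are labels on a lattice, so size-based statistics
(R_ST) estimate the same underlying differentiation as F_ST but with
much larger per-locus variance — the generator produces no extra
stepwise-mutation signal for size-weighted estimators to exploit.
Consequently a single 9-locus instance can show R_ST far from F_ST even
though the two agree in expectation; tests of their congruence use
larger simulated instances. Passing tests therefore show that the
*analysis chain* behaves correctly under eel-like differentiation, not
that the generator reproduces every feature of real microsatellite data
(no null alleles, no genotyping dropout, no linkage).

## cytb haplotypes and RFLP diagnosis

The European consensus is a random 362-bp sequence scrubbed of the HinfI
recognition motif (G^ANTC, with the wildcard restricted to A/C/G/T; an
input `N` never matches — a conservative rule for ambiguous bases). The
American consensus differs at 15 positions and carries GACTC at a
configurable diagnostic offset. Haplotypes mutate their consensus at up
to 2 positions, never touching the divergent or diagnostic sites, so the
two clusters are separated by ≥ ~11 differences while within-cluster
distances are ≤ 4. In the Hamming-distance minimum spanning tree this
guarantees each cluster is internally connected and joined by exactly
one inter-species edge of maximal weight. Amplicon (362 bp) and network
alignment (276 bp) lengths are independent parameters because the assay
and the network analysis used different fragments; the generator does
not reconcile them.

The species classifier calls *American* iff the sequence contains at
least one HinfI site anywhere in the amplicon. Whether the real assay
keys on one specific site or any site is not documented; "any site" is
the weaker assumption and the generator guarantees European sequences
are site-free.

The MST uses Kruskal's algorithm with edges sorted by (weight,
lexicographic pair of first-member sequence IDs), which makes
tie-breaking deterministic. Statistical-parsimony refinements (95 %
connection limits, loop retention) are out of scope.

## Summary statistics

* He uses Nei's unbiased correction (2n/(2n−1))(1 − Σp²); Ho is the
  fraction of heterozygous calls; F_IS = 1 − mean(Ho)/mean(He).
* F_ST is Weir–Cockerham (1984) θ with per-allele variance components;
  multi-locus values are ratios of summed components (never means of
  ratios), and negative per-locus components are retained.
* R_ST follows Slatkin's ratio form: S̄ the mean squared allele-size
  difference over pooled gene-copy pairs, S_W its within-group analogue
  weighted by gene-copy counts, R_ST = (S̄ − S_W)/S̄, multi-locus by
  summed components. Which estimator variant the original Arlequin runs
  used is not documented; this form is fixed and labeled.
* Hardy–Weinberg deviation is tested by Monte-Carlo permutation of gene
  copies within the sample (10,000 shuffles by default), with the
  heterozygote count as statistic (one-sided deficit test) — valid for
  many-allele loci where exact enumeration is impractical.
* Rarefied allelic richness uses the hypergeometric formula
  A_R(g) = Σ_a [1 − C(N−N_a, g)/C(N, g)] evaluated with log-gamma for
  stability; private-allele richness multiplies each allele's presence
  probability in the focal group's g-subsample by its absence
  probability in every other group's independent g-subsample.
* The chord distance convention is
  D_CE = sqrt(mean_l (1 − Σ_a sqrt(p1 p2))). Programs differ in the
  (2/π) and per-locus normalization factors; every downstream use
  (Mantel correlations, their p-values and monotonicity) is invariant to
  a global scale factor, so one convention is fixed and documented.
  Under it, spectra with disjoint support at every locus are at distance
  exactly 1.

## Supervised ancestry estimation

Q (proportion European) maximizes Σ log(q·p_E(a) + (1−q)·p_A(a)) over
the individual's non-missing allele copies. Pool frequencies are
smoothed by adding 0.5 to each count over the union of alleles observed
in either pool plus one shared pseudo-allele per locus; an allele absent
from both pools maps to the pseudo-allele. The 0.5 (Jeffreys-style)
constant matters only through alleles private to one pool — exactly the
informative signal — where it caps the per-copy log-likelihood ratio at
log(n_copies/0.5) instead of infinity; halving or doubling it shifts
individual Q̂ by < 0.02 in pools of 100 and does not move pool means.
The objective is concave in q, and bounded Brent iteration (xatol 1e-7)
with explicit endpoint checks finds the global optimum; agreement with a
10,001-point grid search is part of the test suite.

**Identifiability caveat.** At the calibrated eel-like differentiation
(F_ST ≈ 0.0146) the per-copy Fisher information is of order F_ST, so an
individual's Q̂ has a standard deviation of ≈ 0.25 and piles up at the
[0, 1] boundaries for extreme true q; the mean of Q̂ at true q = 0.1 is
consequently shrunk toward the middle (≈ 0.18) no matter how many
individuals are averaged. Mid-range ancestry — including the F1
expectation Q = 0.5 — is recovered without bias. Estimator-recovery
tests therefore run on strongly diverged pools (target F_ST = 0.15),
where all five tested levels are recovered within ±0.03. This mirrors
the real situation: individual assignment between these weakly diverged
species is noisy, and the analysis leans on group means and permutation
tests rather than individual calls.

Purity is classified at the standard thresholds (pure European iff
Q > 0.9, pure American iff Q < 0.1). The urn test draws groups of 16
Q-values without replacement within a draw (with replacement across
draws, 1000 draws by default) from each species pool and reports
one-tailed p-values toward the opposing pool; the tail convention is
fixed here since the original description does not state it.

Geographic-group comparisons Box-Cox-transform each group's Q values
with its own maximum-likelihood λ (values are in (0, 1), so no offset is
needed), test normality by Shapiro–Wilk, and compare pairs by two-sided
Wilcoxon rank-sum on both raw and transformed values. Because λ is
per-group, the transformed ranks can differ from the raw ranks, which is
why both p-values are reported. The rank-order probability of a
prescribed latitudinal ordering across independent groups is Π 1/k_i!
(1/144 for groups of 3 and 4).

## Cline simulation

**F1 mode.** Each of the 12 virtual populations is bred from 50
parental pairs: 100 parent slots filled with replacement from the pure
European pool, of which (k−1)·increment per 100 are replaced by American
draws for population k (population 1 receives none). Slots pair at
random; each pair contributes an equal share of the 100 offspring, each
offspring receiving one uniformly chosen allele per locus from each
parent. Replaced slots are chosen uniformly, so at high increments two
American parents can pair (producing pure American, not F1, offspring);
an optional `strict_f1` flag forces mixed pairings. The 50-pair /
100-offspring defaults make the two simulation modes sample-size
comparable.

**Admixed mode.** Population k contains (k−1)·increment admixed
individuals per 100 (rounded half up), the rest pure European. Each
admixed individual draws its Q from a binned distribution (0.05-wide
bins over [0.10, 0.90), sampled multinomially, returning bin midpoints —
the within-bin rule is not specified in the original description, and
the midpoint is the neutral choice). Per locus, the number of
European-origin gene copies is Binomial(2, Q) and each copy's allele is
a multinomial draw from its pool's spectrum. The default Q distribution
has triangular bin weights peaking at 0.55, emulating the observed mean
of intermediate ancestry values in real data (slightly above the F1
expectation of 0.5). Population-scale sampling uses the identity
Binomial(2, q) = Bernoulli(q) + Bernoulli(q) to vectorize.

**Common random numbers.** Within a replicate, all gene-flow levels
share a seed and the builders consume their RNG streams identically
regardless of the increment (a full permutation prefix selects American
slots; a full Q vector is drawn and a prefix used). Comparisons across
levels are therefore paired, which reduces the Monte-Carlo variance of
level contrasts by an order of magnitude without changing any marginal
distribution; the monotonicity experiments are stable at 20 replicates
as a result.

## IBD analysis

The Mantel statistic is the Pearson correlation of the n(n−1)/2
off-diagonal distance pairs; the trend-line slope b is the least-squares
slope of genetic on geographic distance. Significance uses simultaneous
row/column permutation of the genetic matrix, one-tailed toward positive
association (IBD is directional); 9,999 permutations by default, 999 in
the replicated experiments where thousands of tests run. p is computed
as (1 + #{r_perm ≥ r_obs})/(n_perm + 1), never zero.

Across scenarios, mean r is regressed linearly and mean b exponentially
(log-linearized when all b share a sign, nonlinear least squares
otherwise) on the per-step increment. Replicates aggregate by the plain
mean of r (not Fisher-z), matching how raw correlations are reported.
The inverse of the linear r-fit at a target correlation gives the
implied per-step increment; for a 12-population cline the mean hybrid
fraction is 5.5× and the maximum 11× that increment, and both are
always co-reported because "gene flow" can mean any of the three scales.
Extrapolations beyond the simulated r range carry an `out_of_range`
flag.

Default problem sizes — 12 populations × 100 individuals × 9 loci, 20–40
replicates per level, 199–999 Mantel permutations — keep the full
default pipeline under a minute on one CPU while leaving all the
qualitative contrasts far outside their Monte-Carlo error.

## Geography

The default distance matrix is a 1-D coastline transect of 12 sites at
equal 500-km spacing (max distance 5,500 km, roughly the Tiber–Iceland
coastline scale); an `irregular` option draws segment lengths
log-normally (σ = 0.5) around that spacing. The real pairwise matrix
used in the original analyses is not printed anywhere reproducible, so
the transect is the package's own stand-in; Mantel r is invariant to the
overall scale.

## Reproducibility

A single integer seed is expanded into independent streams by hashing
string labels (CRC-32) into a numpy `SeedSequence` alongside the seed
(`eelclines.random_utils`). Every CLI subcommand logs its seed in a
manifest; re-running with the same seed reproduces outputs
byte-for-byte.

## Known limitations

* No coalescent or forward-time mutation model; R_ST carries no
  stepwise-mutation signal beyond F_ST (see above).
* The ancestry estimator is supervised (two fixed pools); unsupervised
  clustering and model choice for the number of populations are out of
  scope.
* Single-generation clines only — no backcross dynamics, no selection
  on hybrids; admixture and introgression clines are deliberately not
  distinguished.
* Null-allele detection/correction and linkage-disequilibrium tests are
  not implemented.
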