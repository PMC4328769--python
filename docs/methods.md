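# Methods

This note documents the models, conventions and numerical choices behind
`radscape`. The package implements a desk-scale phylogeographic pipeline
for a species sampled in four disjunct mountain regions (Black Forest,
Massif Central, Pyrenees, Cantabrian Mountains; BF/MC/PY/CM throughout),
genotyped at two kinds of markers: short unlinked nuclear RAD loci
(diploid, 17 individuals) and a 658-bp mitochondrial barcode fragment
(haploid, 352 individuals).

## Coalescent engine and mutation model

Divergence histories are `Scenario` objects: a set of leaf regions, a
list of backward-in-time merge events (the derived region folds into the
ancestral one, which keeps its label and effective size) and per-region
diploid effective sizes N. Histories are pure divergence — no migration
or admixture. Genealogies are drawn with msprime under the matching
piecewise demography; within a population holding k lineages, pairs
coalesce at rate C(k,2)/(2N) per generation for nuclear loci. The
mitochondrial genome carries a fourfold smaller effective number of gene
copies, implemented by scaling every population size by 1/4 and sampling
one lineage per individual.

Mutations follow a finite-sites, 4-state symmetric (Jukes–Cantor) model
restricted to the variable fraction of each locus: a locus of length L
with invariant fraction f exposes round(L·(1−f)) mutable sites, so a
100-bp RAD stack at f = 0.98 has 2 mutable sites (which also caps the
number of SNPs per locus at 2), and the 658-bp mitochondrial fragment at
f = 0.95 has 33. The expected number of mutations on a genealogy is
μ · (total branch length) · L_variable. Invariant positions take their
state from a configurable base composition (default A 26.9 %, C 22.8 %,
G 22.5 %, T 27.8 %); the ancestral state at mutable sites is uniform, as
the symmetric model implies.

Study-shaped defaults: the RAD design samples 20/4/4/6 haploid lineages
(10/2/2/3 diploid individuals) in 3/1/2/2 sites across BF/MC/PY/CM with
12,514 loci of 100 bp at μ = 1e-7 per site per generation; the
mitochondrial design samples 219/7/61/65 sequences in 13/1/5/7 sites at
μ = 1e-6 with one 658-bp locus.

The observation model imposes realistic missingness: per locus ×
individual read depths are negative binomial (default mean 20,
dispersion 3, optional lognormal locus effect), and genotypes under a
depth floor (default 5×) are masked. All SNPs of a locus share one stack
per individual, so an individual is either fully called or fully missing
at a locus.

## Catalog filtering

`filter_catalog` applies, in order: (1) the per-genotype depth mask
(≥ 5× by default — the depth rule is taken per genotype, not per locus
mean, since individuals vary in coverage); (2) removal of loci with any
SNP showing more than two alleles (putative paralogs) or with more than
2 SNPs still segregating after the mask; (3) removal of loci called in
fewer than `min_individuals` individuals (9 of 17 for the main dataset,
11 for the ABC subset). Filtering is idempotent, and raising the
presence threshold can only shrink the retained set; both properties are
tested.

## Diversity and differentiation statistics

- p-distance: substitutions / compared sites, pairwise deletion.
- K2P distance: d = −½ln((1−2P−Q)·√(1−2Q)) with transition/transversion
  proportions P and Q over compared sites; a log-domain violation
  (saturation) is reported as an infinite distance.
- Individual heterozygosity: heterozygous / called SNP genotypes
  (per-SNP, the default; a per-locus averaging mode is available since
  reported "heterozygosity" percentages can be defined either way).
  Region values are the mean ± SD over member individuals.
- Haplotype diversity: Nei's unbiased H = n/(n−1)(1 − Σp²).
- Nucleotide diversity: mean pairwise p-distance proportion over all
  sequence pairs, pairwise deletion.
- Tajima's D: the 1989 standardization; sites with any missing call in
  the sample are dropped so π̂ and S refer to the same site set; S = 0
  yields a NaN sentinel.
- F_ST: Weir–Cockerham θ (ratio of sums over SNPs and alleles) for the
  diploid catalog; Hudson-style 1 − Hw/Hb for haploid sequences, on
  whole-haplotype identity for the mitochondrial tables (frequency-based
  rather than distance-based). Negative estimates are reported as
  computed; permutation of individuals across regions gives significance.

The ABC summary vector packs, per region: mean and variance of pairwise
differences, Tajima's D, segregating sites; per region pair: w (the mean
of the two within-region means), b (the between-region mean pairwise
differences) and F_ST — 4·4 + 6·3 = 34 statistics for four regions, in
sorted-region order. The per-pair w/b blocking is a documented package
convention (the statistic list itself does not fix it).

## Saturation diagnostics

Both diagnostics redraw L loci uniformly without replacement over a grid
and track a statistic's replicate distribution.

Heterozygosity: region level (default grid 10–1000 by 10, 1000
replicates) or individual level (100 replicates, matching the original
protocol's cost cap). Convergence is read from the curves: for a tracked
pair of individuals, the smallest grid L from which the mean ± SD bands
stay disjoint at every larger L; for regions, the smallest L from which
each SD stays below a configured fraction of its mean.

Topology: per replicate the subsample's SNP columns are concatenated
into one pseudo-haplotype per individual — heterozygous genotypes are
resolved to the site's major allele (ties toward the alphabetically
smaller base), a documented simplification — then pairwise K2P distances
feed Saitou–Nei neighbor joining (Q-matrix ties break toward the
smallest index pair), and the tree is compared to a constraint tree by
the symmetric-difference (Robinson–Foulds) count over nontrivial splits,
rescaled to [0,1] by its theoretical extremes for that reference:
d_min = b − k and d_max = b + k for a binary test tree with b = n−3
splits and a reference with k splits. The study constraint is
(((BF), MC₁, MC₂), (PY, CM)): one clade per region except the Massif
Central individuals, which float in the northern polytomy, plus the
north/south split — k = 4 for 17 individuals. The convergence point is
the smallest grid L whose mean distance is below the threshold there and
at every larger grid point ("constantly below"); the default threshold
0.025 (5 % of the nominal random rescaled distance of 0.5) is taken as a
configuration value rather than re-derived, since the min–max rescaling
above does not itself place random trees at 0.5.

Because distances are computed on SNP-only concatenations, deeply
diverged samples can push the K2P correction outside its log domain
(most SNP columns become fixed differences). Replicates with saturated
distances are skipped; the packaged demonstration scenario therefore
uses a moderate divergence (N = 5,000; splits at 20k/50k/120k
generations; μ = 2e-6) where within-region polymorphism keeps distances
finite. This is a method-applicability constraint worth knowing about
before applying the diagnostic to strongly diverged real data.

## Statistical-parsimony network

Haplotypes (identical sequences collapsed; N matches any base, with ties
resolved toward the lexicographically smallest fully called
representative) are joined in a minimum-spanning network over mutational
step (Hamming) distances: edges are added in increasing step order, and
within one distance class an edge is kept whenever its endpoints lay in
different components before the class started, so all equal-length
alternative connections survive (loops are reported, not broken — full
TCS-style ambiguity resolution is deliberately not reproduced, as the
network is used descriptively). Edges longer than the connection limit
are excluded, which may disconnect the network; a forced-connection
option bridges remaining components with their shortest links, flagged.

The connection limit is the largest step count j whose probability of
parsimony is still ≥ α (default 0.95), with a floor of one step. The
probability model treats per-site hit counts as Poisson with depth
matched, under the 4-state symmetric model, to the observed number of
differences j over m sites; the parsimony probability is then
P(single hit | differs)^j · P(no hit | identical)^(m−j). This is the
package's own transparent implementation of the statistical-parsimony
idea; for m = 658 and α = 0.95 it gives 8 steps (kept as a frozen
regression value), somewhat more conservative than classic TCS limits
for barcode-length fragments.

## Strict-clock dating

`strict_clock_time` converts a between-group p-distance (in %) to a
divergence time as T = d / r with the arthropod mitochondrial rate
r = 3.54 % divergence per My as default; the rate is interpreted as
between-lineage divergence accumulation, so 3.54 % ↔ 1.0 My.

## ABC model choice

Three divergence scenarios ship as built-ins (others are user-definable):
vicariance ((CM,PY),(MC,BF)); gradual colonization from the Cantabrian
Mountains (CM,(PY,(MC,BF))); and gradual colonization from the Pyrenees
(PY,(CM,(MC,BF))). Their default parameterization (N = 10,000 per
branch, splits at 100k/400k/1.2M generations) is the package's canonical
deep-split demonstration; ABC replaces all parameters with prior draws.

Priors are log-uniform: effective sizes 1–400,000 (nuclear) or
0.25–100,000 (mitochondrial quarter scale); divergence times
1,000–10,000,000 generations; mutation rates 1e-8–1e-6 (nuclear) or
1e-7–1e-5 (mitochondrial) per site per generation. Event times are drawn
independently and sorted; assigning the sorted draws to events in
template-time order preserves every root-path ordering constraint.

The reference table simulates an equal number of datasets per scenario
(table size is configurable; the desk-scale default is 10⁴ rows total)
and stores each dataset's 34-statistic vector. Statistics are
standardized by their table mean and SD; zero-spread statistics are
dropped with a warning, and NaN sentinels are imputed to 0 after
standardization with companion indicator columns, keeping the distance
space fixed.

- Direct (rejection) estimate: the scenario shares among the n closest
  rows in standardized Euclidean distance, with Wilson 95 % binomial
  intervals.
- Logistic estimate: a multinomial logistic regression of scenario
  identity on the centred statistics over the retained rows, evaluated
  at the observed point (the zero vector). The maximum-likelihood fit
  (statsmodels) supplies asymptotic intervals through the delta method
  on the intercept block; on separation or non-convergence the package
  falls back to a ridge-regularized fit (scikit-learn, C = 1), flagged,
  without intervals.

The packaged recovery experiment simulates pseudo-observed RAD datasets
(17 individuals, 30 loci — a desk-scale choice documented here; the
dataset size per simulated row is the experiment's main cost lever)
under the deep-split colonization-from-CM defaults, against a 10⁴-row
prior-drawn table with 500 retained rows. Logistic regression typically
identifies the true scenario in ≥ 95 % of replicates and is sharper than
the direct estimate, whose probabilities are smoothed toward the prior
by the rejection tolerance.

## What the synthetic data does and does not emulate

The generator reproduces the statistical structure the analyses assume:
unlinked loci with independent genealogies, regionally structured
coalescence, finite-sites mutation with invariant-site caps,
depth-driven missingness and study-shaped sampling. It does not emulate
read-level error, paralogy/assembly artifacts, selection, migration
after divergence, or spatial structure within regions. Passing tests
therefore demonstrate the pipeline's correctness and calibration under
the model's own assumptions, not robustness to assembly or alignment
artifacts in real RAD data. The planted-heterozygosity catalog used in
the band-separation experiment fixes per-SNP heterozygosity rates per
region (BF 2.5–2.6 %, MC 11.4 %, PY 3.5 %, CM 14.5 %) without any
coalescent noise between loci, so its bands separate at smaller L than
noisy real data would.

## Numerical conventions

- All randomness flows through integer seeds; msprime seeds are derived
  via `numpy.random.SeedSequence` and kept below 2³¹.
- Locus coordinates are 0-based, genotypes unphased (simulated catalogs
  store the lineage pairing they were generated with).
- Sorted region labels fix the order of every grouped output.
- Undefined statistics are NaN sentinels, never exceptions, so vector
  shapes are stable.
- NJ accepts only finite symmetric matrices; infinite (saturated) K2P
  distances must be handled by the caller (the saturation driver skips
  such replicates).
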