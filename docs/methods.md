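# Methods

`isopop` re-implements the statistical core of an archaeogenomic
analysis of the Isthmo-Colombian area: allele-frequency f-statistics
with block-jackknife uncertainty, qpWave-style rank tests for the
number of ancestry streams, admixture-graph fitting with the worst-|Z|
acceptance convention, nearly-unadmixed panel construction with
local-ancestry masking, ancient-DNA sample QC, and IBD/haplotype
summaries. Every analysis runs against a built-in synthetic-data
generator, so the statistical behaviour of each method can be scored
against known truth without any external data.

## Genotype model and containers

Genotypes are alternative-allele dosages (0/1/2, missing = −1) over an
array-style SNP panel, individuals × SNPs. Ancient individuals are
*pseudo-haploid*: one sequencing read is sampled per site and reported
as a haploid call coded 0/2. Population allele frequencies weight
diploid individuals as two observed chromosomes and pseudo-haploid
individuals as one; finite-sample corrections for f2/f3 use the
chromosome counts, so mixed diploid/pseudo-haploid panels are handled
consistently.

On-disk formats are the plain-text conventions of the field:
EIGENSTRAT triplets, PLINK text (import), whitespace Q matrices, and
TSV tables for local ancestry, IBD segments and pileups. Missingness
filters follow PLINK semantics — sites filtered before individuals,
both on strict inequality — and panel merging reconciles reversed
ref/alt coding by flipping dosages while dropping strand-ambiguous
(A/T, C/G) sites, the conservative choice when strand provenance is
unknown.

## f-statistics and the block jackknife

f2, f3 and f4 are SNP means of frequency products, e.g.
f4(W,X;Y,Z) = E[(p_W−p_X)(p_Y−p_Z)]. Standard errors use a weighted
leave-one-block-out jackknife (Busing weighting by block SNP count)
over contiguous genomic blocks, 5 Mb by default, which absorbs local
LD. Z = estimate/SE, and the two-sided normal tail at |Z| = 3.3 is
≈ 0.001, the rejection convention used throughout. Statistics based on
fewer than 30,000 SNPs carry a low-SNP flag. Admixture-f3 applies the
finite-sample correction for Var(p̂_C); outgroup-f3 (shared drift) runs
uncorrected, and its inverse supplies the distance matrix for the
neighbor-joining summary tree (scikit-bio's NJ, rooted on the
designated outgroup).

PCA standardizes modern genotypes by √(p(1−p)), mean-imputes residual
missingness, and projects sparse (low-coverage or masked) samples by
least squares onto the loadings restricted to their observed sites —
unbiased under missingness that is independent of genotype. An
optional eigenvalue-based deflation of in-analysis scores is provided
for comparability with projected samples.

## qpWave rank test

For left populations L and right references R, the matrix
F[i,j] = f4(l_i, l_0; r_j, r_0) has rank r when the lefts draw on r+1
independent ancestry streams relative to the rights. Each rank is
scored by the minimized generalized-least-squares residual of the best
rank-r approximation of F under the joint jackknife covariance of its
entries (alternating GLS on the two low-rank factors, initialized from
the SVD), referred to chi-square with (|L|−1−r)(|R|−1−r) degrees of
freedom. A rank-0 p-value above 0.01 (2 on the −log10 scale) means a
left pair is consistent with one shared stream. A near-singular
jackknife covariance is ridge-regularized with a warning; the clean
remedy is more blocks than matrix entries.

## Admixture graphs

A graph is a rooted DAG with drift edges (lengths in f2 units) and
admixture nodes mixing two parents with proportion α. Expected f2
between leaves uses the linear path-weight model: each drift edge
contributes length × (w_A − w_B)², where w is the probability that a
lineage from the leaf drifts through that edge (computed by dynamic
programming over the reverse topological order — no enumeration of
resolved trees is needed, so there is no combinatorial limit on the
number of admixture nodes). For validating the generator, an exact
second-moment recursion under the Balding–Nichols drift law computes
E[p_u p_v] node pair by node pair; it matches Monte-Carlo frequency
simulations to well under 1% and serves as the oracle in tests.

`AdmixtureGraphModel` fits a topology to the observed pairwise-f2
basis and its jackknife covariance by bound-constrained L-BFGS-B with
seeded multi-start (drift lengths ≥ 0, α ∈ [0,1]; fitted lengths come
out in the raw f2 units of the data). `GraphFitResults` reports the
objective, fitted parameters, zero-length branches (< 1e−6), and a
residual table with a Z score for every pairwise f2 and every f4 among
the leaves; the model-acceptance convention is worst |Z| < 3.

Three protocol helpers mirror the stepwise model exploration used to
build continental graphs: `trifurcation_test` fits all three binary
resolutions of a three-child node and declares a trifurcation when all
fit and the separating branch collapses (tolerance 1e−3 in raw f2
units — the sampling noise of a 20k-SNP panel sits near 1.5e−4, an
order of magnitude below any branch such a panel resolves);
`compare_placements` grafts a candidate population onto a base graph
unadmixed-on-an-edge or admixed-between-two-edges, refits, and ranks
placements by worst |Z|; `ancestry_proportions` re-backs one leaf of a
*fitted* graph with a test population, re-optimizes only the
parameters private to that leaf's lineage, and reads off ancestry
proportions as the lineage weights reaching named source nodes.

**Identifiability.** The admixture proportion enters expected f2 only
through products with branch lengths; from second moments alone, α in
a single-admixture graph is merely interval-identified unless each
source node has at least two sampled descendant leaves pinning the
drift up to the source. The synthetic study therefore gives each
southern ancestry stream two leaves — exactly the role played by the
paired early South/North American genomes in real analyses — and the
graph-fitting suite uses the minimal six-leaf configuration. This also
keeps the residual battery (15 f2 + 45 f4 statistics) small enough
that the max-of-many |Z| stays below 3 in ≈95% of correctly-specified
fits; with more leaves the worst-|Z| convention increasingly rejects
true models purely through multiplicity.

## Synthetic study generator

The generator emulates the study design rather than human genetics in
full: a ~20k-SNP array panel (scaled from ~500k) over 20 chromosomes
with a flat 1 cM/Mb map; root allele frequencies uniform on
(0.05, 0.95); drift via Balding–Nichols (Beta) transitions whose
variance is d·p(1−p), so edge lengths are f2 units normalized by root
heterozygosity; admixture as deterministic frequency mixing. The demo
world places an outgroup, African and European colonial sources, a
northern stream, and two southern streams whose source nodes feed an
Isthmian lineage admixed with α = 0.30. Continental drift scales
(f2 ≈ 0.02–0.14 before heterozygosity scaling) match the magnitudes
seen between human continental groups, which is what gives the f4
colonial screen realistic power at desk scale.

Colonial admixture is simulated as per-haplotype ancestry tracts from
a Markov jump chain along the genetic map (switch intensity 0.12/cM,
the tract scale of a ~12-generation-old admixture pulse) with
stationary proportions 85% Indigenous / 10% European / 5% African;
alleles are drawn from the labelled ancestral panel. Emitted
local-ancestry calls blur the truth with a configurable posterior
spread and label-flip rate, so masking filters can be stress-tested.

Ancient data are Poisson-depth read pileups: fragment lengths are
shifted-geometric (min 30 bp, decay 0.02/bp), terminal C→T (5′) and
G→A (3′) deamination decays geometrically inward from a configurable
terminal rate (default 0.2), and a contaminant panel can replace reads
at a configured rate. Sex-chromosome read counts are multinomial over
chromosome lengths scaled by copy number, with a Y mismapping floor
for XX individuals. IBD segments are Poisson counts per pair with
exponential lengths. Pedigree pairs share 2/1/0.5/0 alleles IBD for
identical / first- / second-degree / unrelated relationships.

What the generator does *not* emulate: linkage disequilibrium within
the panel (SNPs are exchangeable given the graph), mutation, selection,
phasing error, reference-alignment bias (except when constructed
deliberately), or realistic site-frequency spectra. Passing tests
therefore demonstrate that the estimators are correct under their own
model assumptions at desk scale, not that the pipeline is robust to
every artifact of real ancient DNA.

## Sample QC

Pseudo-haploid calling picks one uniformly random read per site after
base-quality (≥ 20) and mapping-quality (≥ 30) filters, discarding
reads matching neither allele. Damage profiles report T/(C+T) at
reference-C (alt ≠ T) sites by distance from the 5′ end and the G→A
mirror from the 3′ end. Molecular decay fits a shifted-geometric MLE
to read lengths. The error-rate excess compares derived-allele
fractions between a target and an error-free genome, polarized by a
homozygous outgroup. Molecular sex combines Ry = nY/(nX+nY)
(female < 0.016, male > 0.075, CI-based) with the per-autosome
X-alignment ratio Rx (male < 0.6, female > 0.8); thresholds follow the
methods that introduced the statistics and are configurable.
Mitochondrial contamination is the pooled non-consensus fraction at
haplogroup-diagnostic positions with a Clopper–Pearson CI.

READ-style kinship computes the pairwise pseudo-haploid mismatch rate
(P0) in 1 Mb windows, normalizes each pair's mean by the cohort
median (valid when most pairs are unrelated), and classifies with
READ's published cutoffs 0.90625 / 0.8125 / 0.625. KING-robust kinship
uses heterozygote concordance and opposite homozygotes; within each
population, pairs above the 97.5th percentile are flagged and the
member with more missing SNPs excluded, iterating to a fixed point —
the percentile rule accommodates the elevated baseline relatedness of
endogamous populations. Y-haplogroup classification labels each marker
ancestral/derived, treats all {C,T} and {G,A} markers as
damage-ambiguous, assigns the deepest branch with clean derived
support and no clean ancestral conflict on its path, and reports
deeper ambiguous-only support as tentative.

## Panel construction and masking

The nearly-unadmixed panel intersects three independent screens:
global Indigenous ancestry strictly above 95% (Q matrix); both
f4(ancientIndigenous, X; Europe, outgroup) and
f4(ancientIndigenous, X; Africa, outgroup) with |Z| < 3 (< 2 for the
strict panel; candidates with too few overlapping SNPs are undecided
and excluded); and genome-wide non-Indigenous Viterbi fraction
strictly below 5% (strict variant: < 1% African and < 2% European).
Masking sets a haplotype-SNP slot to missing when the Viterbi label is
non-Indigenous **and** the Indigenous posterior is below 0.9 — the
conjunction reading of the published rule; the disjunction is exposed
as an option. Masked individuals are retained when mean haplotype
missingness is at most 50% and each haplotype keeps at least 25% of
SNPs. Masked haplotypes re-enter frequency-based statistics as
pseudo-haploid samples (one row per haplotype), which keeps allele
frequencies unbiased under partial masking.

## IBD and painting summaries

Within-population sharing: segment lengths are binned (nine default
bins from 1 cM upward, configurable — the published figure does not
print its edges) and the per-bin total is divided by all n(n−1)/2
pairs, so non-sharing pairs dilute the average. Between-population
dating bins (1–5, 5–10, > 10 cM, proxies for progressively younger
sharing) average summed lengths over individual pairs passing the
noise filter of at least two segments above 5 cM and four below.
Copying-matrix summaries: TVD is half the L1 distance between
row-normalized copying vectors; cluster reduction iteratively merges
any cluster smaller than 5 or within TVD 0.03 of its nearest
neighbour into that neighbour (label order breaks ties; the merge
target is a design choice — the published criteria name only the
elimination rule); self-copy summaries total the length copied from
own-cluster donors, self excluded.

## Pipeline and reproducibility

`run_pipeline` chains simulation → sample QC → merge/missingness
filters → panel construction → masking → f3/f4/qpWave → graph fit →
IBD summaries into one run directory with a manifest recording
versions, the seed and every threshold in force (labelled published
vs convention). All randomness flows from a single seed through
`numpy.random.SeedSequence` spawns; reruns are byte-identical. The
default configuration (20k SNPs, 15–30 individuals per population,
3 ancient genomes at 1×) runs in well under a minute. The published
10,000-SNP floor for retaining an ancient individual is rescaled to
5,000 for the synthetic panel, since the original figure applies to a
545k-SNP array.

## Problem sizes used in tests

The suite runs at desk scale: 20k SNPs for calibration and power
loops (500 f4 replicates, 50 misspecified-graph fits, 60 qpWave
replicates per direction), 50k SNPs for single-shot graph parameter
recovery, 100–200k SNPs for Monte-Carlo oracle comparisons, and
10k SNPs / 130 pairs for kinship classification. These sizes were
chosen so each statistical property is measured with comfortable
Monte-Carlo margin while the whole suite stays fast.

## Known limitations

- No LD in the generator, so the block jackknife is exercised under
  independence; its robustness to real LD is inherited from the
  method, not demonstrated here.
- qpWave uses the estimated jackknife covariance in a plain chi-square;
  with few blocks the test is anticonservative (a Hotelling-style
  correction would be needed), so the suite keeps blocks ≫ matrix
  dimension.
- Graph fitting is local optimization with multi-start; no exhaustive
  topology search is attempted, matching the stepwise protocol.
- The worst-|Z| acceptance rule is a max over correlated statistics
  and inherits multiplicity: large leaf sets reject true models at
  rates well above the per-statistic tail probability.
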