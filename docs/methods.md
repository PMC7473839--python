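# Methods

`pedlink` implements a family-based gene-discovery workflow for complex
disorders with apparent dominant transmission: parametric multipoint
linkage in extended pedigrees narrows the genome to candidate regions,
rare variants shared by sequenced affected relatives are filtered within
those regions, the resulting candidate gene sets are tested for
association in independent case-control cohorts with meta-analysis, and
candidates are validated by familial co-segregation and gene-set
enrichment. Everything runs end to end on synthetic data with planted
risk loci, so each stage's statistical behaviour can be checked against
ground truth.

## Disease model and pedigree likelihoods

The disease locus is biallelic with risk-allele frequency *q* and
penetrances *f*(0), *f*(1), *f*(2) = P(affected | risk-allele copies).
The default is the dominant model used for the linkage scan: *q* = 0.01,
*f*(1) = *f*(2) = 0.99. The phenocopy rate *f*(0) is not pinned down by
the scan specification; we default to 0.005 so that unaffected
non-carriers dominate but segregation is imperfect, which matches
clinically ascertained multiplex families and keeps tests of imperfect
segregation non-degenerate. *f*(0) = 0 remains selectable. Individuals
of unknown phenotype contribute a penetrance factor of 1: they inform
transmission only.

**Single point.** `pedlink.linkage.pedigree_likelihood` computes the
exact joint likelihood of one marker and the disease locus at
recombination fraction θ by Elston–Stewart peeling. Each person's latent
state is an ordered pair of two-locus haplotypes (16 states); founders
carry Hardy–Weinberg priors with linkage equilibrium between the loci,
and transmission recombines with probability θ. Variable elimination in
reverse topological order peels nuclear families bottom-up; looped
pedigrees are rejected (break the loop by duplicating one member).
LOD(θ) = log10 L(θ) − log10 L(0.5). Marker allele frequencies are
estimated from founders with add-one smoothing.

**Multipoint.** `lod_multipoint` implements the inheritance-vector HMM.
One bit per meiosis records which parental haplotype was transmitted;
one meiosis per founder is fixed by founder-phase symmetry, leaving
2·(non-founders) − founders informative bits. The symmetry quotient is
exact for emissions, but the remaining meioses out of the same founder
become phase-*relative*, so their inter-locus transition is the mixture

    (1−θ)·K_θ⊗…⊗K_θ + θ·K_(1−θ)⊗…⊗K_(1−θ)

applied jointly over that founder's bits (K_t is the 2×2 kernel with
off-diagonal t), while meioses out of non-founder parents use the plain
per-bit kernel. This subtlety was caught by an exhaustive
inheritance-vector enumeration oracle and is covered by tests at machine
precision.

Marker emissions P(genotypes | vector) sum over founder-allele
assignments using a union-find with parity over founder allele slots
(hom calls pin a slot's allele, het calls impose inequality; each
component contributes either its pinned product of allele frequencies or
the two-colouring sum), compiled with numba. The phenotype emission
P(phenotypes | vector) is position-independent and computed once per
pedigree by peeling the disease genotypes conditional on the vector,
vectorised over all vectors at once.

Scores follow the scan convention: sliding windows of 10 markers (step
1), the disease locus evaluated at every marker position and optionally
at window midpoints against the unlinked likelihood; where windows
overlap, a position takes its value from the window whose centre is
nearest. Combined-family scores are sums of per-family LODs at the same
positions (locus homogeneity); heterogeneity (HLOD) is a noted
extension, not implemented. Exact computation is bounded at 20 meiosis
bits; larger pedigrees raise an error advising splitting rather than
silently approximating. Candidate regions are maximal runs with
LOD ≥ 2.0, bounded by the 1-LOD support interval around the run peak
(extend while LOD ≥ peak − 1, stop at the first drop, clip at
chromosome ends); 3.3 marks genome-wide significance. Haplotypes within
a region come from the Viterbi inheritance-vector path (dense transition
matrices, bounded at 12 bits) followed by maximum-likelihood
founder-allele assignment; slots not pinned by the data are flagged
ambiguous.

## Genotype QC

Pre-linkage filters use the standard family-study defaults: individual
call rate ≥ 0.97; marker MAF ≥ 0.05, missingness ≤ 0.05,
Mendelian-error rate ≤ 0.10 (errors / informative parent-offspring
checks; individual inconsistent genotypes at retained markers are set to
missing and logged), and an exact Hardy-Weinberg test with p > 1e-6.
The HWE test enumerates the conditional distribution of the heterozygote
count given allele counts and is computed on founders only, to avoid
pedigree-induced deviation. LD pruning removes, within sliding windows
of 50 markers stepping by 5, one member of any pair with squared dosage
correlation above 0.01 until none remains; removal prefers the marker
with higher missingness, then the later map position (deterministic).
r² is composite (genotype-dosage correlation, no phasing); founders-only
estimation is the default, all-sample estimation is available.

## Synthetic data

The generator is the study-condition definition, not a convenience:

- **Families.** A three-generation template: founding couple, 6
  children, 6 marry-in spouses, 6 grandchildren (20 members; 16 meiosis
  bits — the unique 20-member shape within the exact multipoint bound).
  One founder is planted as a heterozygous risk-allele carrier;
  affection is sampled from the penetrances; 10% of members are masked
  to unknown phenotype; families are ascertained by resampling until at
  least 8 members are affected, emulating multiplex-family recruitment.
- **Markers.** Biallelic SNPs on a scaled genome (2 chromosomes × 35
  markers, 2 cM / 2 Mb spacing by default) with founder MAFs uniform on
  [0.2, 0.5]; optional haplotype-pool LD blocks. Gene dropping follows
  the Haldane map, and on the planted chromosome the inheritance chain
  is conditioned on the disease-locus transmissions recorded during the
  affection simulation, so marker data and phenotypes carry a genuine
  linkage signal. Error-free runs are Mendelian-clean by construction.
- **WES calls.** Per-(variant, sample) records with Poisson read depths
  (mean 85), population MAFs (log-uniform rare spectrum, a configurable
  fraction absent from the frequency reference), gene symbols and effect
  classes: a configurable number of variants shared by all sequenced
  members inside and outside the planted region, plus private noise
  variants per sample.
- **Cohorts.** A liability-threshold model: genotypes from a Gaussian-
  copula AR(1) haplotype model within genes (default ρ = 0.4), liability
  = Σ β·dosage + N(0,1), cases above the population (1 − 0.05) quantile.
  Default cohort sizes emulate a four-country adult case-control sample
  (615/932, 597/2598, 340/2286, 294/1703). The gene panel is scaled down
  (hundreds of genes rather than an exome chip); under zero effect all
  SNPs are exactly null.

What the generator does **not** emulate: genotyping batch effects and
population stratification, sequencing artefacts, relatedness between
family and cohort samples, X-linked inheritance, copy-number variation,
and realistic genome-scale marker counts. Passing tests therefore show
the statistics behave correctly under the stated model, not that the
pipeline is robust to every artefact of real data.

## Variant funnel and gene sets

Shared rare variants satisfy three conjunctive criteria: ≥ 20 reads in
*every* sequenced member (per-sample rather than mean depth: stricter
and deterministic), population MAF < 1% (variants absent from the
frequency reference count as rare by default — truly novel variants have
no database entry; the decision is logged per variant), and the same
alternate allele called in all sequenced members (zygosity may differ).
Survivors are intersected with the linkage regions of the variant's own
family, padded by ±1 Mb with inclusive bounds, and collapsed to
per-family candidate gene sets plus their union; genes absent from the
downstream cohort panel are flagged but retained.

## Association

Per SNP: the Cochran–Armitage trend test on allele dosage (scores
0/1/2), signed by the direction of case enrichment. Logistic regression
is a noted extension; the synthetic cohorts carry no covariates. Per
gene: the mean of the SNP chi-squares, whose null is (1/k)·Σ λᵢ·χ²₁ with
λᵢ the eigenvalues of the inter-SNP dosage-correlation matrix (estimated
from the cohort's controls by default; an external reference panel can
be supplied through the same interface). The upper tail is evaluated by
Imhof numerical integration (adaptive quadrature of the oscillatory
integral; error estimate monitored) with a Satterthwaite moment-matching
fallback for non-convergence or the far tail (p < 1e-10), where the
quadrature loses relative accuracy. Negative eigenvalues from noisy
correlation estimates are clipped to zero with a warning. Gene p-values
map to probit Z-scores capped at |Z| = 8.

Cohorts are analysed separately and combined at the gene level by
fixed-effect weighting with the square root of each cohort's sample
size: Z_meta = Σ wᵢZᵢ / √(Σ wᵢ²); one-sided p on the risk direction.
Genes missing from a cohort are combined over the cohorts that carry
them (logged). Gene-set inference on the meta Z-scores: the
self-contained test is a one-sided intercept-only test of mean Z > 0
(normal theory, estimated variance); the competitive test regresses Z on
set membership with gene size and log gene size as covariates (dropping
collinear columns) and takes the one-sided t p-value on the membership
coefficient. Gene-based lookups within a set use the Bonferroni
threshold α / (genes in the set) with strict inequality (12 genes at
α = 0.05 gives p < 0.00417).

## Validation

Co-segregation summaries report, per affection group among genotyped
members, the count and percentage carrying at least one and all of the
candidate variants; percentages are rounded to the nearest integer
(report-parity convention), and unknown-phenotype members are tallied
separately, never entering the affected/unaffected denominators.
Enrichment of a candidate list against a GMT collection uses one-sided
(over-representation) hypergeometric tests with a protein-coding
background of 19,264 genes by default and Benjamini–Hochberg FDR across
terms, significant at adjusted p < 0.05. Set-size bounds are
configurable and unset by default.

## Numerical and scaling choices

- Likelihoods are scaled factor-by-factor (peak normalisation with a log
  accumulator); the HMM forward/backward passes renormalise per locus.
- A zero likelihood at a particular θ (e.g. an obligate recombinant at
  θ = 0) yields −inf rather than an error; impossibility at θ = 0.5
  indicates a Mendelian inconsistency and raises.
- Prune-pair ties, curve stitching and region bounds are deterministic
  as described, so every pipeline output is bit-reproducible per seed.
- Problem sizes in tests and in `scripts/acceptance.py` are scaled-down
  study miniatures chosen as the package's own defaults: 20-member
  families on a 2×35-marker genome for linkage recovery; an 800-2000
  gene panel with one 500/500 cohort for calibration; the end-to-end
  example uses 12-member families, one 20-marker chromosome and two
  cohorts of a few hundred samples.

## Known limitations

- Exact multipoint is bounded at 20 meiosis bits; the hybrid
  exact/approximate engines used for very large real pedigrees are out
  of scope, as are automated loop breaking and non-parametric (NPL)
  scores.
- Under the default study conditions (a single 20-member family,
  q = 0.01, penetrance 0.99, phenocopy 0.005, 10% unknown phenotypes),
  the information ceiling of the trait — measured as
  log₁₀(max_v P(phenotypes|v) / mean_v P(phenotypes|v)) — lies below 2
  in roughly a quarter to a third of simulated families, so a LOD ≥ 2
  region covering the planted locus is recovered in only ~70-75% of
  replicates even though the multipoint engine attains the ceiling.
  Larger or multiple jointly-analysed families are needed for higher
  single-run sensitivity; this mirrors practice, where region selection
  at LOD ≥ 2 is deliberately liberal and several families contribute.
- The haplotype Viterbi path maximises over the founder-phase quotient
  chain; reported haplotypes are one representative of each phase orbit.
- The competitive gene-set test assumes exchangeable gene Z-scores given
  covariates; inter-gene LD within a set is not modelled (the synthetic
  cohorts generate genes independently).
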