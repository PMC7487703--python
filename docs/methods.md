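# Methods

## The problem setting

A fully penetrant autosomal-recessive disease segregating in a closed
breed population leaves three connected signatures: a case/control
association peak at array SNPs in linkage disequilibrium with the causal
allele; a chromosomal interval over which affected individuals are
homozygous for a shared ancestral haplotype; and, when the causal variant
is a mobile-element insertion, clusters of read pairs whose mates map to
other chromosomes at the breakpoint. `recmap` implements the analysis
chain that follows these signatures from array genotypes to a candidate
variant, plus the cohort-representativeness analysis needed to interpret
allele frequencies estimated from a voluntary DNA-testing population.

## Association scan

The per-SNP test is the Pearson chi-square (1 df, no continuity
correction) on the 2×2 allele-count table, cases vs controls × alt vs
ref, missing genotypes excluded per SNP. QC runs in a fixed order —
samples by call rate, then SNPs by call rate, then SNPs by minor allele
frequency computed on the retained samples — with strict "less than"
exclusion at each threshold (defaults 0.90 / 0.97 / 0.05), so a SNP at
exactly the threshold is retained.

Genome-wide significance is assessed two ways. The Bonferroni line is
0.05 divided by the post-QC SNP count, since only tested SNPs enter the
family of hypotheses. The Max(T) permutation procedure permutes
phenotype labels preserving the case/control split, records the
genome-wide maximum chi-square of each permutation, and reports
p_genome(SNP) = (1 + #{max ≥ observed}) / (n_perm + 1); the +1
correction keeps empirical p-values off zero, and p_genome is by
construction monotone in the observed statistic. The default n_perm is
100,000; tests and the worked example use smaller counts because the
estimator's resolution (1/(n_perm+1)) is all that changes.

Confounding is diagnosed with the genomic inflation factor
λ = median(χ²) / 0.4549364 (the 1-df chi-square median). The
mixed-model correction is a deliberately simplified analogue of the
standard exact mixed-model association methods: the binary phenotype is
modeled as y = μ + g + e with cov(g) = σ²g·K for a genomic relationship
matrix K built from standardized, mean-imputed genotypes; a single
variance ratio δ = σ²e/σ²g is fitted once on the null model by 1-D
bounded maximum likelihood over the eigenbasis of K (log₁₀ δ ∈ [−5, 5]);
each SNP then gets a generalized-least-squares score test using the null
covariance. One null eigen-direction of K is expected (the genotype
standardization centers it) and is handled with a silent 10⁻⁶ ridge; a
warning is raised only when more directions collapse. The claim attached
to this component is behavioural — λ is reduced toward 1 on structured
cohorts while agreeing with the allelic test on unstructured ones — not
numerical identity with any specific mixed-model program.

## Homozygosity mapping

The critical region is operationalized as an anchored maximal shared
interval: the risk allele is the allele more frequent among cases at the
top SNP; the core set is the cases homozygous for it there; the region
extends SNP-by-SNP in both directions while, at each SNP, the fraction
of core cases homozygous for one shared allele is at least
`min_share_fraction` (default 1.0). Missing calls neither break sharing
nor count as support: they are removed from both numerator and
denominator. Interval endpoints are the outermost *passing* SNP
positions, not midpoints to the first failing SNP — matching how such
regions are reported from marker tables. Raising `min_share_fraction`
can only shrink the interval (monotonicity), and the implementation is
equivalent to a brute-force scan over all anchored contiguous intervals
(property-tested on instances up to 50 SNPs × 20 samples).

A case is concordant when homozygous for the shared allele at every
non-missing SNP inside the region. Note that concordance is
identity-by-state: a carrier phenocopy can occasionally be concordant if
its second haplotype matches the ancestral one by chance, which is the
same ambiguity real studies face.

## Recessive filtering, effect scores, concordance

A variant survives the segregation filter iff every case with a
non-missing call is homozygous-alternate and no control violates the
allow flags (default: controls may be heterozygous or homozygous
reference, never homozygous alternate). Missing calls are logged but do
not veto: multi-genome merges always contain missingness, and a variant
should not be discarded because one case was uncalled. The filter is
idempotent and anti-monotone in strictness.

Consequence labels are consumed from the VCF `CSQ` INFO key or a sidecar
TSV; no annotation engine is implemented. The scorer maps a closed
vocabulary onto four tiers — high (start/stop gained or lost, splice
donor/acceptor, nonsense, missense, frameshift, in-frame deletion),
moderate, low (synonymous-class), modifier (intronic, intergenic,
upstream/downstream, upstream insertion) — with strictly ordered numeric
scores 4 > 3 > 2 > 1.

Privateness of a candidate against an unrelated genome panel counts
carriers (genotype ≥ 1); an all-missing panel is an error, deliberately
distinct from "private". The concordance table tabulates hom-alt / het /
hom-ref counts per variant and phenotype class, lists discordant
individuals (case not hom-alt, control hom-alt) and recombinants
(individuals whose non-missing genotype differs across the variant set).

## Insertion detection and length

Two read-level signals count as support: mates on a different chromosome
(the mate aligned inside another copy of the repetitive element) and
soft-clips of at least 10 bp (reads crossing the breakpoint). Same-
chromosome aberrant-insert pairs are deliberately excluded — they add
little at interchromosomally-repetitive elements and complicate the
depth model; this is a noted possible extension. Sliding 200 bp windows
(step 50) become candidates when support ≥ 3 and support/depth ≥ 0.2;
overlapping candidate windows merge, and the reported breakpoint
interval is the span of clip-implied positions when clips exist (giving
target-site-scale resolution) rather than the window.

Insertion length from a sizing assay is the observed amplicon length
minus the reference-allele product length, reported in bp and in Kb
rounded to one decimal; an observed product smaller than the reference
product supports no insertion and is an error.

## Pedigree kinship and representativeness

Kinship uses the coancestry convention, φ(self) = ½(1 + F) with
φ(self) = 0.5 for non-inbred individuals — forced by the benchmark
values 0.25 (full sibs) and 0.125 (half sibs). The recursion treats an
unknown parent as a unique unrelated founder, memoizes on unordered
pairs, and recurses on the individual of greater pedigree depth (which
can never be an ancestor of the other). It is property-tested against an
independent path-counting oracle (sum over common ancestors and
disjoint path pairs of (½)^(n₁+n₂+1)(1+F_A)) on random pedigrees of up
to 12 dogs, and the resulting matrices are verified positive
semi-definite.

Cohort representativeness compares the observed mean pairwise kinship of
a test cohort with a resampling null: replicates draw the cohort size
without replacement from a birth-year-filtered reference pool (defaults
follow the motivating study: n = 261, 1500 replicates, birth years
2009–2017), and the empirical p is upper-tail with the +1 correction.
Because "significantly higher" is sometimes argued from the replicate
range rather than a tail probability, the result also records whether
the observed mean exceeds the replicate maximum, plus the 2.5/97.5
percentile band. Mean pairwise kinship is over the n(n−1)/2 unordered
off-diagonal pairs; the SD reported is the sample SD of those pairs
(ddof = 1) — the SD of replicate means is available from the replicate
vector itself, since sources are ambiguous about which they print.

MDS is classical: squared distances from the Gower transform
d²(i,j) = φ(i,i) + φ(j,j) − 2φ(i,j), double-centering,
eigendecomposition, coordinates scaled by √eigenvalue, signs fixed so
each component's largest-magnitude loading is positive. What similarity
the motivating analyses embedded is not documented; pedigree kinship is
chosen because it is deterministic and testable (reconstruction of d to
1e−8 at full rank). Outliers are flagged strictly outside the
0.5/99.5 percentiles (linear-interpolation quantiles; a value exactly at
a percentile is not flagged) on any of the first three components.
Flagged dogs are partitioned into families as connected components of
the dog–ancestor graph; `max_depth` counts generations beyond the
parents (0 = shared parents only, default 3).

## Allele frequencies and Hardy–Weinberg

q = (2·n_hom_mutant + n_het) / (2·total); carriers 2q(1−q); affecteds
q², assuming random mating and full penetrance. Report columns round
half-up through one guard digit (…decimals+1, then decimals), the
convention evidenced by the source-style genotype tables (0.08046 →
0.0805 → 0.081); raw values are always retained alongside, so no
downstream computation ever consumes a rounded number.

## The synthetic study

The generator emulates the study design, not the species' demography:

* **Pedigree**: 24 founders, 4 generations of matings between dogs of
  any earlier generation, Poisson litters (mean 1.5, min 1), giving
  ~85-dog cohorts; birth years follow generation. Popular-sire effects
  and line breeding are not modeled.
* **Genotypes**: 1200 SNPs on 4 × 20 Mb chromosomes (~67 kb spacing,
  array-like density), founder alt frequencies uniform on [0.05, 0.5].
  Gene drop recombines between adjacent loci with Haldane's map function
  at 1 cM/Mb, no interference, independent assortment across
  chromosomes.
* **Disease locus**: an untyped locus at 7,785,480 on chromosome "33"
  rides an ancestral haplotype spanning ±650 kb (a ~1.3 Mb LD block).
  The block markers' alt alleles exist only on that haplotype
  (`block_background_alt_bounds = (0, 0)`): the haplotype is private,
  as a young disease haplotype's marker configuration effectively is.
  The founder carrier-haplotype count is fixed at its expectation
  (frequency 0.40) rather than sampled, so the cohort's case supply does
  not drift with the small founder pool. Both choices exist because two
  earlier designs — sparser markers, and block alt alleles common off
  the disease haplotype — let carrier phenocopies anchor the
  homozygosity mapper on an identical-by-state SNP and broke the
  designed ≥95% recovery behaviour; the fix belongs in the generator's
  realism, not in the analysis.
* **Phenotypes**: hom-alt dogs are cases with penetrance 1.0; all other
  dogs are phenocopy cases with probability 0.05, yielding roughly 4
  phenocopies per 17 cases, the discordant-case fraction the analysis
  must tolerate. Phenocopies are sampled uniformly among non-hom-alt
  dogs; no mechanism is modeled.
* **Candidate region**: a symbolic `<INS:ME:LINE1>` insertion at the
  locus plus three linked SNVs copying the causal genotype, except in
  two recombinant carrier dogs where an outermost variant loses one alt
  allele; a 102-genome unrelated panel carries none of the alleles.
* **Reads**: one homozygous case is "sequenced": 150 bp pairs at 30×
  over ±1.5 kb of the site, insert 400 ± 50 bp. Carrier-haplotype
  fragments spanning the breakpoint become interchromosomal-mate pairs
  with probability 0.5, and breakpoint-crossing reads are soft-clipped
  at it. No base-level errors or qualities are simulated. Breakpoint-
  spanning carrier pairs carry an `:S` tag in the read id as calibration
  ground truth; detection never reads ids.

A master seed spawns independent streams per stage, so each stage is
reproducible in isolation and the whole study is byte-deterministic.

What passing tests on this generator do **not** show: robustness to
genotyping error and batch effects, to ascertainment-driven case
enrichment, to allele frequencies realistic for a managed breed (the
causal frequency is inflated so a ~85-dog pedigree yields a workable
case count — a deliberate scaled-down design), or to sequence-level
alignment artifacts.

## Problem sizes and numerical choices

The default test-suite simulations use the sizes above (~85 dogs × 1200
SNPs; 100-seed recovery batteries; permutation counts 200–5000), chosen
as the smallest sizes at which the designed behaviours are stable; the
full suite runs in well under a minute. Ties in the top-SNP choice break
to the smallest position on the smallest chromosome. Quantiles are
linear-interpolation throughout. The Max(T) estimator never returns 0.
Degenerate inputs raise rather than guess: no cases, empty panels,
all-missing columns, cycles in pedigrees, observed amplicons smaller
than the reference product.
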