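# Methods

This note records the models, the defaults that matter, and the choices made
where the design was genuinely open.  Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Population and trait model

The panel is a collection of fully inbred (homozygous) accessions.  A
genotype column is therefore a haplotype, and a run of linked SNPs defines a
multi-allelic locus whose alleles are the distinct local genotype strings.

The trait model is additive over detected loci:

    y_ijk = μ + G_i + E_j + R(E)_jk + GE_ij + ε_ijk

with genotype, environment, replication-within-environment and G×E all
random (an RCBD repeated at s site-years with r blocks each).  Entry-mean
heritability uses the standard plot-basis formulas:
h² = σg²/(σg² + σ²/r) within one environment and
h² = σg²/(σg² + σge²/s + σ²/(sr)) for the joint analysis; GCV = 100·σg/μ.

On balanced data the variance components come from the expected-mean-squares
identities (σ̂² = MS_err, σ̂ge² = (MS_GE − MS_err)/r,
σ̂g² = (MS_G − MS_GE)/(rs)); negative estimates are truncated to zero and the
raw values kept for audit.  Unbalanced data route to REML (statsmodels
MixedLM: accession intercept + accession×environment variance component,
environment and blocks as strata).  On balanced data the two agree exactly
in theory; the suite asserts relative agreement to 1e-3, which is the
iterative solver's stopping accuracy.

## Synthetic panel (`simpop`)

Defaults are the stated world of the motivating design: 366 accessions, 6
subpopulations, 20 chromosomes, 50 QTLs with 2–9 alleles each, μ = 20
(percent units, seed-oil-content-like), σg² = 8, σg²/σge² = 10, s = 4
environments × r = 2 replications, multi-environment h² = 0.90 (σ² is
solved from h² unless given directly), subpopulation drift F = 0.05,
environment-effect variance defaulting to σ².

Design points worth knowing:

- **Haplotype pools are perfect phylogenies.**  Each block's pool is built
  by infinite-sites mutation (every new haplotype copies an existing one and
  flips a fresh set of sites).  This makes |D'| = 1 for every within-block
  pair — the structure LD-block calling assumes — whereas unconstrained
  random pools would plant four-gamete violations inside blocks.  Between
  blocks, draws are independent (D' ≈ 0 across block boundaries).
- **Drift is Balding–Nichols-style on haplotype frequencies**: per group,
  frequencies ~ Dirichlet(p·(1−F)/F).  This reproduces allele-frequency
  differentiation among subpopulations without modeling pedigree history.
- **QTL effects** are drawn normal per pool haplotype, re-centered to an
  exact unweighted zero sum per locus, and globally rescaled so the
  realized genotypic variance equals σg².
- What a green test does **not** establish: the generator has no LD decay
  within blocks, no allele sharing between blocks, no missing data by
  default, and balanced group sizes — real RAD-seq panels have none of
  those simplifications.

## SNPLDB construction (`snpldb`)

D' is computed from the 2×2 haplotype counts; its CI by likelihood
profiling on a 201-point |D'| grid with allele frequencies at their MLEs
(5th/95th percentiles of the normalized likelihood mass).  A pair is
*strong LD* if CI_low ≥ 0.70 and CI_high ≥ 0.98; *recombinant* if
CI_high < 0.90; otherwise uninformative and excluded from the fraction.  A
candidate block needs ≥ 95% of informative pairs strong, span ≤ 200 kb
(matching the largest printed block spans) and ≤ 50 SNPs; longest
candidates are accepted greedily, leftovers become singletons.  Rare
haplotypes (< 1% by default) merge into the Hamming-nearest frequent
haplotype (ties: higher frequency, then lexicographic), which caps allele
counts near the observed 2–9 range at n ≈ 366; the merge rule is
switchable in principle but collapse-to-rare-class is not implemented.
Structure covariates are the top-10 eigenvectors of the double-centered
allele-sharing similarity matrix.

## Two-stage scan (`rtmgwas`)

Stage 1: per marker, an F-test of the allele factor (k−1 df) added to the
covariate-only model of across-environment accession means; markers with
p < 0.05 survive.  Stage 2: forward-backward stepwise.  The forward step
picks the candidate with the smallest partial-F p (ties: genome position)
and admits it only if the **Šidák-adjusted** p over the number of markers
the scan examined, 1−(1−p)^m, is below α; the backward step removes any
included marker whose raw partial p rises to ≥ α.  Zero-sum contrasts give
one effect per observed allele per locus, summing to zero; alleles absent
from the phenotyped set get no effect.

Why the Šidák step: α is meant to be an *experiment-wise* level — a scan
of pure noise should select anything at all with probability ≈ α.  A raw
min-p entry rule at α = 0.02 over hundreds of candidates would select in
essentially every null scan.  The flip side is conservatism: at n = 366
with ~550 markers, entry effectively requires a locus R² of roughly 5%,
so a trait architecture of 50 loci sharing 90% heritability yields only
its few largest loci.  Detecting dozens of sub-1% loci at this sample size
is incompatible with genuine experiment-wise control; the package sides
with calibration, and the total detected R² is bounded by (and typically
well below) ĥ².  Both sequential (selection-order) and partial
(last-entry) R² are reported; sequential is the default column, and the
two coincide on orthogonal designs.

## Differentiation and the QTL-allele matrix (`allelematrix`)

The matrix cell (locus, accession) is the effect of the carried allele;
rows sort by ascending positive-allele frequency and columns by ascending
phenotype for display.  Positive/negative allele counts use the strict
sign; exact zeros are counted separately.  Per-locus differentiation is a
Pearson chi-square on the allele × group count table; when any expected
count is below 5 the p-value comes from 10,000 fixed-margin Monte-Carlo
tables (flagged).  A BH-FDR column is added across loci; the raw p column
remains the headline to match standard practice.  The most frequent allele
is labeled "original" as row metadata only — no inference hangs on it.

## Cross prediction (`crosspred`)

"Continuously inbred progenies" are modeled at complete homozygosity
(F∞ selfed RILs): along a chromosome, parental origin is a two-state Markov
chain with switch probability R = 2r/(1+2r) (Haldane–Waddington), r from
the Haldane map function at d cM, d from physical distance at 2.5 cM/Mb by
default (a soybean-order average; overridable, and a map file can supply cM
directly).  The independent-assortment model forces R = 0.5.  Percentiles
are nearest-rank (the ⌈q·n⌉-th order statistic) for cross-platform
reproducibility; per-cross RNG streams derive from (seed, sorted parent
pair) so rankings are independent of enumeration order.  The exact
enumerator collapses non-segregating loci by combining adjacent switch
probabilities (R_eff = (1 − Π(1−2R_k))/2) and is the oracle for the
Monte-Carlo path.  A caveat the suite quantifies: when an atom boundary of
the exact progeny-value CDF falls within binomial noise of the target
quantile, the n = 2000 nearest-rank estimate legitimately lands on either
neighboring atom; multi-trait selection standardizes each trait's
predicted values and ranks by a weighted signed sum (equal weights by
default).

## Candidate genes (`genes`)

A gene qualifies if its interval overlaps the marker's or the gap (bases
strictly between the 1-based inclusive intervals) is < 100 kb; it must
contain ≥ 1 genotyped SNP; and at least one of its SNPs must associate with
the marker's allele classes by chi-square at α_gene = 0.05 (a default the
source procedure leaves unstated).  The shipped annotation is synthetic
(planted around detected markers to exercise every filter branch) and is
labeled as such; a real GFF3 can be supplied instead.

## Numerical conventions

- Missing genotype calls are imputed to the per-SNP major allele before
  haplotype calling (logged); heterozygous calls in these inbred panels are
  treated as call errors and set to missing on ingestion.
- Coordinates are 1-based inclusive throughout; marker ids follow
  `<chrom>_<pos>` for singletons and `<chrom>_BLOCK<k>_<start>_<end>` for
  blocks.
- h² is clipped to [0, 1]; an all-zero component set raises rather than
  returning 0.
- Exact progeny-value supports are rounded at 1e-9 before aggregation to
  remove summation-order float noise.
- All stochastic steps take explicit seeds or `numpy.random.Generator`s;
  identical seeds give byte-identical outputs.

## Known limitations

- No dominance, epistasis or G×E in the genetic model of cross prediction
  (additive only, as in the source procedure).
- No kinship-matrix mixed model; eigenvector covariates are the only
  structure correction.
- The scan's experiment-wise calibration trades away small-effect loci at
  germplasm-panel sample sizes (quantified above).
- AMOVA, GO/pathway annotation and external-database lookups are out of
  scope; the candidate-gene output can be joined to a user-supplied
  annotation table.
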