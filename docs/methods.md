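# Methods

## The prioritization model

`kdprio` treats variant prioritization as a deterministic funnel over
biallelic variant records.  Multi-allelic VCF sites are split on ingest
(one record per alternate allele, doses counting only that allele), so
every downstream rule reasons about a single alternate allele.  Coordinates
keep the VCF convention (1-based, closed); indels are taken as given and
not re-normalized.

**Confidence.**  "Call quality" is applied per sample as the phred genotype
quality (GQ), not the site QUAL, because the paired depth requirement is
per sample; per-sample filtering is also the stricter reading.  A
`quality_scope: sample|site` switch selects the alternative.  Missing
genotypes pass this stage (there is no quality to judge) and are handled
explicitly by the inheritance filters.  The exclusion of hyper-variable
genes is realised as a user-supplied blacklist (default empty): the
upstream commercial annotator's proprietary list cannot be redistributed,
so the package takes the set as an input.

**Inheritance.**  The recessive-homozygous rule and the three compound-het
rules are quantified over *all* affected / *no* unaffected members, so any
nuclear pedigree with at least one affected child and both parents
genotyped is supported, not only the 2-affected/4-unaffected design.  The
three compound-het rules constrain single variants; a *pair* additionally
requires trans configuration, which rule 3 resolves without phasing: a
variant heterozygous in exactly one (unaffected) parent is unambiguously
maternal or paternal, and a reported pair must combine one of each within
a gene.  Genes whose eligible variants all share one origin yield no
pairs; if several variants share an origin, all maternal × paternal
combinations are reported.  An unaffected sibling may carry one member of
a pair heterozygously (carrying one of two trans variants is consistent
with being unaffected, and is observed in the published family).  Missing
genotypes disqualify a variant under the default `strict` policy; the
`lenient` policy tolerates missing calls in unaffected siblings only —
the fully genotyped study family never exercises this case, which is why
it is configurable rather than fixed.

**Deleteriousness and rarity.**  Two deleteriousness modes exist because
the source filters were described both ways: by region (exon, promoter,
splice site, 3'UTR) and by consequence (frameshift, in-frame indel,
start/stop change, missense, splice loss).  Region mode is the default —
it is the definition that reproduces the published Tier 2 composition
(promoter and 3'UTR variants reach Tier 2; with consequence mode they
could not).  Rarity means allele frequency strictly below the threshold in
*every* queried population with data; a single common population
disqualifies, and a variant with no frequency data at all counts as rare
("not available" rule).  Input frequencies are fractions in [0, 1];
fixtures convert printed percentages.

**Tiering.**  Tier 1 requires, per branch: recessive-homozygous ∧
deleterious ∧ AF < 1% ∧ pathway ∧ differential expression, or
compound-het ∧ AF < 3% ∧ pathway ∧ differential expression (the
compound-het branch applies no separate deleteriousness gate, following
the branch as published).  Tier 2 requires recessive-homozygous ∧
deleterious ∧ GWAS nominal p < 0.05 ∧ differential expression, with **no
rarity cap** — the published Tier 2 risk-allele frequencies run to 83%,
and the implementation must not silently reapply the rare filter there.
GWAS p-values are used nominally (no multiple-testing correction), as in
the source analysis.  Differential expression is judged on fold-change
*magnitude*, max(FC, 1/FC) ≥ 1.2, because susceptibility genes may be
higher in either phase.  A variant qualifying for both tiers is labeled
Tier 1 (rarity plus pathway membership is the stronger evidence).  Every
variant receives exactly one assignment carrying the ordered
(stage, pass/fail) trail, so the output partitions the input and failures
are attributable to a stage.

## Statistical kernels

**Mann–Whitney.**  U is computed from midranks; the exact null
distribution is used when both samples have ≤ 12 observations and the
pooled sample is tie-free, otherwise the tie-corrected normal
approximation with continuity correction.  Two-sided p-values are clipped
at 1.

**Wilcoxon matched-pairs.**  Paired differential expression works on
per-subject log2(acute) − log2(convalescent) differences restricted to
subjects with both phases; zero differences are dropped (Wilcoxon's rule),
and an all-zero difference vector reports p = 1 directly.  The gene-level
fold change is 2^(mean log2 difference).  Genes with several probes are
represented by their smallest-raw-p probe (probes measure different
transcripts and are never averaged); Benjamini–Hochberg adjustment runs
across genes.

**eQTL scan.**  For each probe of each gene in the query set, acute-phase
expression is compared between genotype-dose groups with two-sided
rank-sum tests for every pair of observed doses (a Kruskal–Wallis
alternative sits behind `method="kruskal"`).  A gene's p is the minimum
over its probes and pairs, flagged against a nominal alpha (default 0.001)
with no correction inside the scan — this matches the nominal-p usage of
the source analysis and is deliberately anti-conservative: under the null
the flag rate is bounded by 3×alpha (three pairwise comparisons), and
measured near 2.4×alpha at the study's group sizes.  Conversely, at the
deep 0.001 tail the discrete rank statistic makes each individual test
slightly conservative (measured rejection rates 0.7–1.0 × alpha for group
sizes 23–70).  The calibration tests assert exactly these bounds rather
than pretending the nominal rate is attained pointwise.  A probe constant
across the compared samples reports p = 1.  For group sizes ≤ 12 the scan
falls back to the exact-capable per-pair test; above that it uses the
vectorized tie-corrected normal approximation.

**Fisher–Freeman–Halton.**  The exact r×c test enumerates every table with
the observed margins depth-first (cell ranges pruned by the remaining
margins, the last cell of each row forced), accumulating multivariate
hypergeometric probabilities in log space to avoid underflow.  The
two-sided p sums tables whose probability does not exceed the observed
table's within relative tolerance 1e-7 — the probability-ordering
convention (alternatives such as tail-doubling exist; this is the standard
Freeman–Halton rule and the one that reproduces the published ethnicity
p = 0.002).  Enumeration is guarded at 10⁷ candidate tables.  On 2×2
tables the test coincides with classical two-sided Fisher; the enumerated
probabilities sum to 1 within 1e-9, and R's `fisher.test` agrees to
6 significant digits on the packaged 3×2 table.

**LD.**  r² and D′ are computed by direct haplotype counting from phased
0/1 haplotypes (the estimator choice when none is mandated; the reference
values the package reproduces came from phased panels).  Both are
undefined for monomorphic sites and raise.  Tag grouping is greedy in
ascending position: a site joins the earliest group whose seed has
r² ≥ threshold (inclusive), otherwise seeds a new group; the
representative is the group's smallest position.  Unphased composite LD is
out of scope.

## The synthetic-data generator

The generator's defaults are the study's dimensions: a six-member family
(two affected sons, two unaffected siblings, unrelated unaffected parents)
with 200 background variants at allele frequencies U(0.05, 0.5); a
transcriptome cohort of 146 subjects (131 with paired acute/convalescent
samples) at a risk-allele frequency of 0.4, which reproduces the published
genotype-group sizes (≈ 54/69/23); 415 TF-target genes on 673 probes; a
161-subject clinical table.  Expression is log-normal with baseline
N(7, 1) and noise sd 0.5 on log2 — microarray intensities are unitless, so
the absolute scale is arbitrary.  Planted effects: an acute-phase log2
shift on designated DE genes (default 1.5× on IL6, 1.3× on TLR6), a
per-allele acute-phase shift of 1 noise-sd on the eQTL target, and
+20 mm/h ESR in homozygous-risk clinical subjects.

Family genotypes are built from founder haplotypes (Bernoulli at the
site's frequency) with children receiving one haplotype per parent — no de
novo events, so the Mendelian scan finds zero errors by construction.
Planted signals override the sampled genotypes with Mendelian-consistent
patterns: the compound-het pair puts one variant heterozygous in each
parent and both in both affected children; the recessive block makes both
parents heterozygous, affected children homozygous-alt and siblings
non-homozygous at every block site.  Population haplotypes for LD plant
blocks by seed-copying: each non-seed site copies the seed allele with
probability sqrt(r²_target), giving the target r² in expectation and
exactly 1 for full copying.  Genotype qualities are drawn above the
confidence thresholds except for a configurable planted low-quality
fraction, and are independent of genotype (no allele-balance model — the
purpose is to exercise the confidence filter, not to emulate a caller).

What passing tests on this generator do *not* show: robustness to
genotyping error and de novo mutation, annotation misclassification,
population stratification in the cohort analyses, correlated expression
between genes, or batch effects — none of which the generator emulates.

## Fixtures and their limits

The packaged fixtures transcribe the published worked examples: the
12-variant tier table, the family genotypes of the ten TLR6 variants plus
the three common intronic SNVs, and the ethnicity-by-genotype counts
(row sums 24/78/59).  Two reconstructions are synthetic and labeled as
such: the family genotypes of the five non-TLR6 tiered variants (not
printed; encoded as the canonical recessive pattern) and all genomic
positions (not printed; invented placeholders ordered so the published
representative-SNV choices — the earliest position in each LD group —
hold).  The rarity filter on fixtures queries the whole-dataset ("ALL")
frequency only, matching how the published rare filter was applied; the
per-subpopulation frequencies printed for TLR6 are intentionally not fed
to it.  Gene-level evidence values (fold changes, adjusted p) are
synthetic stand-ins chosen to satisfy the printed cutoffs, since only the
cutoffs, not the per-gene statistics, are published.  The repeat-length
variant in MEF2A is modeled as an ordinary deletion record; repeat-aware
genotyping is out of scope.

## Problem sizes in the test suite

The suite's simulation-backed checks use: 50 seeded families for
end-to-end tier recovery; 100 replicates of 415 genes × 146 subjects for
null eQTL calibration; 60 replicates for paired-DE recovery (50 pairs,
noise 0.1); 30 replicates for planted-eQTL ranking (120 genes); 20 seeded
cohorts for the clinical ESR shift; 2,000–20,000 haplotypes for LD
convergence.  These sizes were chosen so each check has clear statistical
margin while the whole suite stays interactive (well under a minute).

## Known limitations

- No X-linked or de novo prioritization modes; no statistical linkage.
- No in-silico pathogenicity scoring: deleteriousness is whatever the
  annotation input asserts.
- The eQTL scan's gene-level flag is nominal and uncorrected by design;
  interpret flag counts, not family-wise error.
- The exact r×c test is enumeration-only; tables beyond the 10⁷ guard
  need a Monte-Carlo approach that is not provided.
- Clinical summaries compare extreme homozygotes only (no trend test),
  mirroring the published analysis.
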