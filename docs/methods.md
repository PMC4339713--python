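# Methods

This note documents the models, numerical choices and limitations behind
`osseoprofile`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Differential expression by fold-change threshold

The experimental design this pipeline serves has one animal and no
biological replicates, so no dispersion can be estimated and no DE P-value
is meaningful. The criterion is a plain signed fold change of per-condition
mean FPKM:

- r = (x̄_implant + ε)/(x̄_control + ε); signed FC = r if r ≥ 1, else −1/r.
  The signed convention keeps |FC| ≥ 1 with the sign as direction, matching
  how such tables are conventionally printed (a −2.52 means 2.52-fold down).
- ε (pseudocount, default **0.1 FPKM**) guards the ratio against zero
  control means; as ε → 0 the pure ratio is recovered on strictly positive
  data. The noiseless-recovery tests use ε = 1e−9 so planted effects pass
  through exactly.
- The threshold comparison is **strict** (> 2.0 by default), i.e. a fold
  change of exactly 2 is not called.
- "Zero FPKM" exclusion removes transcripts at zero in **all** samples.
  Excluding on *any* zero would contradict the later interest in
  condition-specific genes (a transcript silent in control but expressed
  around the implant is a finding, not noise).
- The 4-week comparison uses whatever control samples carry the 4-week
  label. In the original single-animal design the surgical-defect controls
  were created one week before sacrifice only, so a 4-week implant sample is
  compared against a 1-week-old defect; the pipeline does not attempt to
  correct this asymmetry, it simply compares the labelled groups.
- Reported fold changes are rounded half-even to 2 decimals; P-values to 4.
  A Monte-Carlo P of exactly 0 is rendered `<1/n_draws` (e.g. `<0.0001` at
  10,000 draws) since 0 only means "below the resolution of the draw count".

Gene-level fold changes (used for category profiling and qPCR concordance)
sum transcript means within a gene before forming the ratio, consistent with
FPKM being additive over a gene's transcripts.

## Length-controlled permutation enrichment

Annotation richness increases with gene length, and DE gene sets are
themselves length-biased in length-sensitive assays, so a naive
over-representation test confounds the two. The control here is matched
sampling:

1. The annotated universe (every gene in the annotation, including genes
   with zero terms) is split into `n_length_bins` (default **10**) quantile
   bins of gene length. Bin edges are linear-interpolation quantiles; genes
   of identical length always share a bin, so a degenerate all-equal
   universe collapses to one bin, while distinct lengths give bin sizes
   differing by at most one.
2. Each of `n_draws` (default **10,000**) control sets replaces every test
   gene independently with a uniform draw from that gene's own bin. The pool
   is the whole universe — test genes are not excluded — and draws are
   independent, so a control set is a multiset; members count with
   multiplicity.
3. P = fraction of control sets whose term fraction is ≥ the test set's
   (ties included). One shared pool of control sets is drawn per run and
   reused across all terms, making a run O(n_draws·|test|) gene draws plus
   one sparse matrix product against the gene×term incidence matrix.
4. The significance cutoff is 1/N_terms, where N_terms counts GO terms
   attached to ≥ 1 universe gene. Up- and downregulated sets are separate
   runs; the three GO domains are tested jointly and only grouped in the
   report.

**Exact oracle.** Under the independence in step 2, the control-set term
count is a sum of independent Bernoulli variables whose success
probabilities are the term's prevalence in each test gene's bin — a
Poisson-binomial law, evaluated exactly by convolution in
`exact_pvalue`. The oracle exists for testing the Monte-Carlo estimator
(and is itself checked against brute-force enumeration on tiny instances);
it is not the production path, because the independence it assumes is a
modelling statement about the sampler, not about biology.

**Discreteness and calibration.** The P-value is a discrete, tie-inclusive
statistic and is therefore conservative when the attainable P levels are
coarse — small test sets, rare terms, or a test set that is a large fraction
of the universe (its own carriers then drag the bin prevalences along). The
calibration suite accordingly measures type-I error in a regime where
discreteness is mild: 2,000-gene universes, 100-gene test sets, term
prevalences 0.1–0.4. In that regime the rejection rate at α ∈ {0.01, 0.05}
sits inside α ± 3·SE over 500 replicates, and the same scenario with
length-coupled terms and a length-biased test set shows the point of the
method: the 10-bin matched test stays inside the band while a single-bin
(unmatched) variant rejects an order of magnitude too often. Users testing
very small gene sets against rare terms should expect conservative, not
inflated, P-values.

## Comparative Ct

ΔCt = Ct_target − Ct_reference per condition; ΔΔCt = ΔCt_implant −
ΔCt_control; relative quantity 2^(−ΔΔCt). Means are arithmetic over wells
(sample SD reported, 0 for singletons); triplicates are expected and a
deviation only warns, since partial plates are common. The reference
(housekeeping) gene is a required parameter — none is universal for bone.
Both amplicons are assumed to double per cycle (no Pfaffl efficiency
correction, no standard curves). ΔΔCt is invariant to adding a constant to
one condition's target *and* reference Cts (plate offsets cancel), which
the suite asserts numerically.

Concordance between RNA-Seq and qPCR fold changes is judged as direction
agreement on declared scales. The RNA-Seq side is log2 by construction
(the validation table's RNA-Seq column is the log2 of the linear category
fold changes). The qPCR column's scale is genuinely ambiguous in this style
of report — a printed 0.74 is downregulation if linear but upregulation if
log2 — so the scale is an explicit parameter (default log2), never a guess.

## Synthetic data

The generator emulates the magnitudes of the motivating experiment so that
full-scale summaries are comparable: 21,744 transcripts with ~63% undetected
(all-zero), 773/870 up/down planted at 1 week and 937/902 at 4 weeks with
299/481 overlaps, planted |log2| effects uniform on [1.2, 4.5]. Tests use
small fast configurations (300–2,000 genes).

- Gene lengths: log-normal(9.9, 1.2) bp — median ≈ 20 kb, right-skewed like
  a mammalian gene-length distribution.
- Baseline FPKM: log-normal(2.0, 1.5); expression noise is multiplicative
  log-normal with σ expressed in log2 units (default 0 — the planted-
  recovery contracts are exact at σ = 0, and noisy scenarios state their σ).
- Term assignment: Bernoulli per (gene, term) with per-term prevalence drawn
  log-uniformly; a coupling coefficient shifts membership logits by
  c·z(log length), producing the length-annotation confound the enrichment
  test must absorb (c = 0 gives independence).
- Enriched terms: membership among the planted target DE set is re-drawn at
  `multiplier × base prevalence` (capped at 1). This *updates the annotation
  universe in place*, since the enrichment signal lives in the annotation.
- Ct plates: reference gene at a constant expected Ct, target baseline
  constant, implant-side expectation shifted by −log2(fold), Gaussian noise
  σ (default 0.2 cycles) per well, triplicates.

What the generator does **not** model: fragment-level FPKM estimation (and
hence the length bias of FPKM itself), correlated noise between samples,
GO-graph structure (terms are independent labels; no ancestor propagation),
and annotation errors. Passing tests therefore demonstrate the pipeline's
arithmetic and the statistical behaviour of the sampler under its stated
null — not robustness to misannotation or to quantification artefacts.

## Problem sizes in the test suite

The suites run single-threaded in a few minutes: oracle cross-checks use
≤ 8-gene universes (enumerable exactly); calibration and discrimination use
500 replicates of 2,000-gene universes at 1,000–2,000 draws; power uses 100
replicates of 400-gene universes; the full-scale default configuration is
exercised once for the zero-fraction arithmetic. These sizes were chosen so
each statistical assertion has the stated resolution (3·SE bands over the
replicate counts given above).

## Known limitations

- With n = 1 per condition the fold-change criterion has no error control;
  the package deliberately reports no DE P-values.
- The permutation P is conservative for small sets/rare terms (see above);
  1/N_terms is a Bonferroni-flavoured rule, not an FDR.
- Whether the published N_terms counted all ontology terms or only those on
  analyzed genes is not stated in this style of report; this implementation
  counts terms attached to ≥ 1 universe gene and records the number in the
  run summary.
- Control sampling is with replacement across test genes (a control set may
  repeat a gene); the alternative without-replacement design was not
  specified and would make the exact oracle intractable.
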