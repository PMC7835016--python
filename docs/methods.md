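# Methods

This note documents the models, numerical choices and limitations behind
`survpanel`, in the order the pipeline runs them.

## Variant filtering and the mutation matrix

Three confidence filters are applied to called somatic variants: total
coverage ≥ 30, alt-allele depth ≥ 7, VAF ≥ 0.05. The removal conditions are
written as strict inequalities ("< 30", "< 7", "< 0.05"), so boundary records
are retained; this literal reading is frozen into the tests. VAF is always
recomputed from depths when both are present — a stored VAF disagreeing by
more than 1e-6 triggers a warning and the depth-derived value wins, keeping a
single source of truth.

Two different variant universes coexist deliberately:

* the **mutation matrix** (the GA's substrate) counts only coding
  nonsynonymous substitutions and indels (missense, nonsense,
  frameshift/inframe indel);
* **TMB** counts all coding *and* splicing variants, including synonymous
  ones. Synonymous inclusion is the default and can be switched off by
  filtering the input list, since the defining phrase "all somatic variants
  in the coding and splicing regions" is ambiguous about silent changes.

MAF `Variant_Classification` strings are mapped to the internal effect
vocabulary through an explicit table (`survpanel.variants.MAF_CLASSIFICATION_MAP`);
unknown strings raise at ingestion instead of being silently dropped.
Coordinates are 1-based closed; multi-allelic VCF records are split per alt
allele at ingestion.

## Survival statistics

* **Kaplan-Meier** is the standard product-limit estimator; censored times
  shrink the risk set without a step, and at tied times events precede
  censorings (a subject censored at *t* is still at risk at *t*).
* **Log-rank** uses the tie-aware hypergeometric variance at each distinct
  event time, chi-square with 1 df, two-sided. Because the GA evaluates the
  test hundreds of thousands of times per search, the implementation is a
  vectorized numpy path over time-sorted arrays, with the 1-df chi-square
  tail computed as `erfc(sqrt(x/2))`; it is cross-checked in the tests
  against a naive per-event-time implementation and against lifelines.
* **Cox proportional hazards** is delegated to lifelines' `CoxPHFitter`
  (Efron tie handling, Newton-type iteration with step-halving) behind the
  package's `cox_fit` surface. Non-convergence and monotone-likelihood
  (separation) are surfaced as flags; constant covariates are rejected by
  name before fitting. Categorical covariates are treatment-coded with the
  most frequent level as the reference (the encoding is recorded in the
  coefficient names, e.g. `lauren[diffuse]`). Efron rather than Breslow was
  chosen for its better behaviour under ties; one visible consequence is
  that duplicating a cohort shifts the point estimate by a fraction of a
  percent (the duplicate-invariance identity is exact only under Breslow).
* **Fisher's exact test** (two-sided, sum of hypergeometric probabilities
  ≤ the observed table's) and the **Wilcoxon rank-sum test** wrap
  scipy.stats. Wilcoxon uses exact enumeration for combined n ≤ 10 without
  ties and the tie-corrected normal approximation (no continuity
  correction) otherwise; fully degenerate input returns p = 1 with a
  warning.
* `cox_score_test` computes the partial-likelihood score statistic at β = 0
  directly; with one binary covariate and no ties it equals the log-rank
  chi-square, which the tests use as a cross-operation identity.

## GA panel selection

Fitness of a chromosome = mean log-rank p over `subsample_repeats` random
subsamples of `round_half_up(fraction × n)` patients drawn without
replacement (so 50% of 160 is exactly 80). Defaults follow the study
configuration: population 40, crossover 0.1, mutation 0.01, 50 000
generations, 100 repeats at fraction 0.5. Design choices where the procedure
was underdetermined:

* **Selection operator**: tournament of size max(2, population/10), elitism
  on by default — the defaults of the lightweight GA framework family this
  configuration originates from; both are configurable.
* **Subsample redraw**: the repeats are redrawn at every fitness evaluation
  from the run-level RNG stream, and fitness values are *not* memoized — the
  fitness is intentionally stochastic between evaluations while the whole
  run stays reproducible from its seed. The elite individual keeps its
  recorded fitness, which makes the per-generation best-fitness trajectory
  monotone non-increasing under elitism.
* **Degenerate splits** (a subsample whose mutant or wild-type group is
  empty, or with zero events) contribute the penalty p = 1; the all-zero
  chromosome scores exactly 1 without subsampling, so an uninformative panel
  can never win.
* Full-scale search (50 000 generations × 100 repeats) is a cluster-sized
  job; the test suite and the acceptance study run a reduced configuration
  (6 candidate genes, 200 generations, 20 repeats, n = 300) chosen so the
  planted two-gene panel is recoverable in minutes on one CPU.

A GA-selected panel is optimistically biased on its own training data; the
pipeline therefore always evaluates on a disjoint validation split, and a
property test confirms that on null cohorts the held-out log-rank rejection
rate stays at the nominal 5%.

## Immunogenomic scores

* **TMB** divides the qualifying variant count by a 33 Mb coding footprint
  (the RefSeq GRCh37 coding-exome estimate); the region size is a parameter.
* **Neoantigen candidates**: each nonsynonymous mutation supplies a 17-mer
  mutant peptide context with the altered residue centered (position 9,
  1-based) where flanks allow, truncated at protein termini. All 9-11-mer
  windows *containing the altered residue* are enumerated — windows that
  miss it are wild-type self peptides and are excluded. A full 17-mer with a
  centered mutation yields 9 + 8 + 7 = 24 windows. The burden counts windows
  with min-over-alleles predicted affinity strictly below 500 nM. Affinity
  prediction is an injectable interface; the package ships only
  deterministic toy predictors (a motif predictor for hand-countable
  fixtures and a hash-based pseudo-random one), since real class I binding
  prediction is an external tool. Identical windows arising from different
  mutations are counted per (window, mutation) pair.
* **Signature decomposition**: the 96-channel spectrum is count-normalized
  and fit by nonnegative least squares against the reference matrix; weights
  below 0.06 are pruned and the surviving set refit once; weights are
  rescaled onto the simplex only if their sum exceeds 1. `error_rate` is the
  residual 2-norm over the spectrum 2-norm. A sample's exposures are usable
  (`qc_pass`) iff error_rate < 0.15 **and** > 30 mutations, both strict.
  The dMMR fraction is the exact sum of the exposures labelled 6, 15, 20
  and 26, and is reported as NaN (with a warning) for QC failures.
* The repository cannot ship the published signature catalogue, so
  `synthetic_reference_signatures` builds a synthetic 96 × 30 stand-in
  (sparse Dirichlet columns, deterministic seed). All shipped checks are
  *recovery*-based — mixtures drawn from a reference must be recovered
  against that same reference — so they are valid for any well-conditioned
  catalogue; real analyses load the published TSV via
  `read_signature_matrix`.

## Synthetic cohorts

The generator emulates a stage II-III gastric-cancer exome cohort at the
structural level the analysis needs:

* Gene mutations are independent Bernoulli draws per candidate gene
  (default probability 0.02 over 48 genes, so a ~20-gene panel yields
  roughly a quarter of patients panel-mutant — the mutant-fraction regime
  reported for cohorts of this type). The reduced 6-gene test scenario uses
  0.15 per gene for the same reason.
* Survival is exponential with hazard `baseline × HR^(panel-mutant)`
  (baseline 0.03/month ≈ 23-month median OS; planted HR configurable), so
  proportional hazards holds by construction and Cox/log-rank recovery can
  be judged against the planted truth. Censoring is an independent uniform
  draw on [0, 120] months (~27% censored) — standard noninformative
  censoring.
* Read depths are negative-binomial (mean 100, dispersion 10) and VAFs
  Beta(2, 4); gene-incidence ("driver") variants are rejection-sampled to
  pass the confidence filters so that the generator's truth labels are
  *exactly* recoverable downstream, while separately generated noise
  variants (synonymous/noncoding/splice calls and sub-30× records) exercise
  the filters and the TMB/matrix distinction.
* Covariates (age, gender, Lauren class, stage) are drawn independently of
  panel status; the multivariate Cox adjustment therefore tests encoding
  and machinery, not confounding recovery.
* One `SeedSequence` per cohort spawns deterministic sub-streams for
  variants, survival, covariates and spectra, so partial re-runs stay
  aligned and a fixed seed reproduces the cohort bit-for-bit.

What the generator does **not** model: tumor purity, realistic gene lengths
or per-gene mutability differences, covariate-dependent hazards,
informative censoring, and correlated mutations. Passing tests therefore
demonstrate correctness of the machinery and recoverability of planted
effects under the stated model, not robustness to those real-data features.

## Numerical and degenerate-input conventions

* Two-sided p-values throughout.
* Log-rank variance terms with a risk set of 1 contribute 0; a comparison
  with zero total variance returns statistic 0, p = 1.
* Subsample and split sizes round half-up.
* Seeds are plain integers; every stochastic routine takes either a seed or
  a `numpy.random.Generator`.
* Degenerate inputs fail loudly (`DegenerateGroupsError`, named-covariate
  errors, offender-listing label errors) except where the procedure defines
  a penalty semantics (GA fitness p = 1).

## Known limitations

* The GA is a stochastic heuristic; different seeds can select different,
  similarly-fit panels, and selected panels are biased on training data
  (hence the mandatory held-out evaluation).
* The toy affinity predictors are placeholders for ranking machinery only;
  absolute neoantigen burdens are not biologically meaningful without a real
  predictor behind the interface.
* Signature decomposition assumes the generating signatures are in the
  reference; exposures are not identifiable for near-collinear catalogues.
* `cox_fit` inherits lifelines' behaviour under separation (flagged, not
  resolved); penalized fits are out of scope.
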