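# Methods

## Statistical model and pipeline

The pipeline treats each cohort as an independent experiment and only merges
results at the gene-list level; no effect sizes or p-values are pooled across
cohorts. This is deliberate: the cohorts sit on different array platforms
with different probe chemistry and annotation, so a combined model would
confound platform with biology. The cost is power; the benefit is that every
cross-cohort claim reduces to transparent counting rules.

**Normalization.** Raw linear intensities are floored at 0.01 (background
correction: values below the floor are set to it), log2-transformed, and each
sample column is shifted so its median equals the median of per-sample
medians. The original array-suite recipe fitted a lowess curve against the
50th-percentile signal; because every downstream statistic consumes only
group means, we implement the location component (median centering) and
expose a `sample_correction` hook in `preprocess.normalize_cohort` for users
who want an intensity-dependent correction. Median centering is idempotent,
rank-preserving within samples, and removes any constant per-sample offset,
which is what makes group fold ratios offset-invariant.

**Welch ANOVA.** Tissue groups have visibly unequal variances in this kind
of data, so the three-group location test is Welch's heteroscedastic one-way
ANOVA with Welch–Satterthwaite denominator degrees of freedom. The
implementation is vectorized across genes (moments per group, then the F
statistic in closed form), which keeps a 10,000-gene null simulation under a
second on one CPU. Genes where any group has zero variance get NaN
statistics — flagged and excluded from gene lists, never assigned p = 0.
Two independent cross-checks are kept in the test suite: an independently
coded scalar textbook implementation (agreement to 1e-10) and
`pingouin.welch_anova`.

**Multiple testing.** Benjamini–Hochberg step-up adjustment per cohort
(delegated to `statsmodels`), with NaNs passed through rather than ranked.
The working threshold is q < 0.01 per cohort; a cohort that yields no genes
at 0.01 may use 0.05, mirroring the published analysis where the smallest
cohort required the relaxed cut. Cohort eligibility for the meta-analysis is
a separate rule: at least 250 genes at q < 0.05 (`cohort_stats.cohort_eligible`).

**Fold changes.** Printed fold changes are ratios of *arithmetic* group
means on the linear scale, so that is what the pipeline computes (means of
2^log2 values), displayed with the signed convention (+r for r ≥ 1, −1/r
otherwise, magnitude always ≥ 1). Log-scale means would give geometric
means; with group-specific log2 noise sd in [0.3, 0.8] the two differ by up
to ~14 %, which matters at a 1.2-fold threshold. The choice of arithmetic
means is a documented decision, not a claim about what the original
software did internally.

**Harmonization and consensus.** Probes that map to no Entrez id or to more
than one are dropped. Multi-probe genes are represented by the probe with the
smallest Welch p (configurable to mean-collapse); this preserves the
strongest signal and the representative probe's q is carried rather than
re-adjusted. Presence means "on the platform after mapping". The rules, with
k = cohorts present:

- master: k ≥ 3;
- significance consensus: pass count ≥ ceil(0.75·k) (3/3, 3/4 or 4/4);
- directional consensus: cohorts with signed |fold| > 1.2 in one direction
  ≥ max(3, ceil(0.75·k)), with ties between directions flagging nothing;
- peak: among directional-consensus genes, cohorts clearing 3-fold (S→BE)
  or 2-fold (BE→EAC) in the consensus direction ≥ 3.

The denominator for the 75 % rules is cohorts-present (not all cohorts), with
the absolute ≥ 3 floor enforced everywhere. Peak filters apply only to the
directional-consensus pool, and the significance consensus precedes the
fold rules.

**Comparison modes.** `strict_gt` reads the thresholds literally
("greater than 3-fold") and is the default for live data. `inclusive_ge`
exists because printed tables round folds to one decimal: a printed −2.0 must
qualify against the 2-fold cut to reproduce the published BE→EAC table. The
fixture-reproduction path (`peak_filter_fixture`) therefore defaults to
inclusive.

**Clustering audit.** Samples are clustered by average-linkage (UPGMA)
agglomeration on the correlation distance 1 − Pearson r over a supplied
discriminatory gene list, with samples sorted by id first so input order
cannot change the tree. "Misclassified" — originally a by-eye reading of
dendrograms — is formalized as: cut the tree into three flat clusters, label
each cluster by its majority histology (ties: larger class overall, then
lexicographic), and flag samples whose label differs. Percentages are
rounded half away from zero to one decimal, matching how the published
counts (11/81 → 13.6 %, 5/80 → 6.3 %, 2/72 → 2.8 %) were reported.

**SVM evaluation.** The 11-gene panel (CA2, ANXA10, CDX1, EMP1, IGFBP7,
KRT1, KRT4, KRT20, LGALS4, TFF1, TSPAN1) is shipped as a constant: it cannot
be re-derived exactly from the printed tables. Leave-one-out cross-validation
trains a linear (first-order polynomial) SVM, one-vs-rest over the three
classes, with features standardized on each training fold only. The
regularization constant is C = 1 (not stated in the source analysis;
"diagonal scaling factor of one" is read as no kernel rescaling). Panel genes
missing from a platform are dropped with a count kept in the report. Reported
metrics: per-class sensitivity/specificity and a collapsed EAC-vs-noncancer
table.

**Literature mining.** Search plans follow the dictionary rules: a symbol
present in the English word list is searched case-sensitively in all-capitals
form only; names and past symbols in the word list are dropped; everything
else is case-insensitive. Matching is whole-token (tokens split on any
non-alphanumeric character), so `CA2` matches neither `CA22` nor `SCA2`, and
hyphenated variants like `TFF-1` deliberately do not match `TFF1` — exact
strings were searched, and that limitation is preserved. Multi-word gene
names match as consecutive token sequences. Methods and supplementary
sections are excluded; figure captions count. The repository ships a small
demonstration word list; real runs should point `load_word_list` at a full
spell-checker word library (e.g. a SCOWL build). The final human confirmation
stage is replaced by a snippet review report (matched term plus context).

**Enrichment.** A plain hypergeometric upper tail P(X ≥ k) per gene set with
B&H across sets at q < 0.05. This is explicitly *not* the proprietary
ontology service used originally (modified Fisher score, term clustering,
database snapshot); no equivalence with its term lists is claimed. The
default universe is the master list, with a flag for a supplied whole-genome
background.

## Synthetic data generator

`synthetic_cohorts.generate_cohorts` emulates the features the analysis
depends on: several platforms with overlapping gene panels (presence
recorded, so the ≥ 3-cohort rule has known truth), three tissue groups,
log2-normal intensities with per-gene per-group noise sd drawn uniformly
from [0.3, 0.8] (heteroscedasticity is what justifies Welch), planted fold
signatures, mixed-tissue samples, and annotation defects that corrupt
annotation rows only, never expression values.

Key defaults (all overridable in `SimulationConfig`): 4 cohorts; group sizes
(18, 20, 20) per cohort, near the per-cohort averages of the real combined
sample (72 S / 81 BE / 78 EAC over four cohorts); 2,000-gene master universe
(a scaled-down genome so simulations run in seconds); platform overlap 0.8;
baseline log2 mean 7 ± 1.5 across genes; contamination rate 0.05 with mixing
weight 0.5 (a contaminated sample is an equal convex mixture of two
tissue-mean profiles on the linear scale, before noise — the tissue-
heterogeneity explanation for misclassified biopsies); multimap rate 0.02
and unmapped rate 0.05.

A planted fold r is defined on linear-scale arithmetic group means — the
quantity the pipeline measures. Under log2-normal noise E[2^X] =
2^(μ + (ln2/2)σ²), so the generator plants a log2 offset of log2(r) −
(ln2/2)(σ_b² − σ_a²); the expected arithmetic-mean ratio is then exactly r
despite unequal group variances. Background genes keep identical log2 group
means (a true null for the Welch test); their arithmetic-mean ratios deviate
from 1 only by the small variance term, well below the 1.2-fold rule. An
S→BE signature shifts BE and EAC together, so the BE→EAC contrast stays null
for that gene. By default planted genes are forced onto ≥ 3 platforms and
exempted from annotation defects (`ensure_recoverable=False` disables this
for negative tests).

What the generator does **not** emulate: probe sequences and cross-
hybridization, dye/batch/scanner effects, dysplasia grades, correlated gene
modules, or platform-specific intensity response curves. Passing recovery
tests therefore shows the pipeline's rules behave correctly under the stated
statistical model, not that the model captures every artifact of real array
data.

## Problem sizes and numerical choices

- The end-to-end recovery run uses 4 cohorts × 2,000 genes × 60 samples with
  50 planted fourfold S→BE signatures; it completes in a few seconds and
  recovers 100 % of planted genes with zero background at the default
  thresholds. The null type-I simulation uses 10,000 genes with group sizes
  (10, 15, 20) and sds (1.0, 2.5, 0.6).
- Thresholds are compared strictly (`q < threshold`), matching the printed
  "p < 0.01" wording.
- Significance pass counts use cohorts-present as the denominator; absent
  platform cells are excluded, nonsignificant blanks count in the denominator
  only.
- UPGMA ties are resolved deterministically by sorting samples by id before
  building the distance matrix.
- Percent rounding is decimal half-away-from-zero (`ROUND_HALF_UP` on
  `Decimal`), not banker's rounding — 6.25 % prints as 6.3 %.
- All generator randomness flows from one `numpy.random.default_rng(seed)`;
  identical config and seed give byte-identical outputs.

## Known limitations

- The lowess intensity normalization is approximated by median centering
  (documented above); results on strongly intensity-dependent artifacts will
  differ from the original suite's output.
- Gene-level q values are the representative probe's cohort-level adjustment,
  not re-adjusted after collapsing probes.
- The bundled table transcriptions cover the printed peak tables and the
  cross-study literature table; the full 851-gene supplementary list is not
  transcribed, so cohort-level gene counts that depend on the raw external
  data (master-list size, consensus-list size) are out of scope, as are the
  published SVM sensitivities, which depend on the untranscribed expression
  matrices.
- One printed literature-table row (KRT5) lists one fewer study tag than its
  printed reference count; both are preserved as printed.
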