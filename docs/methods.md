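# Methods

## Signature assignment

The unit of assignment is the probe. After averaging over each cell type's
biological replicates, probe *p* is flagged for cell type *c* when

    value(p, c) >= t * median_{c'}( value(p, c') )    and    median > 0.

The boundary is inclusive ("at least *t*-fold"), and the median over an even
number of cell types is the usual interior median (mean of the two central
order statistics). Probes whose across-cell-type median is zero are excluded:
t × 0 = 0 would otherwise flag such a probe in every cell type with any
signal, which is a degenerate notion of specificity. A gene is a HECS gene of
*c* if **any** of its probes is flagged for *c*; multiple flagged probes of
one gene collapse to a single (gene, cell type) record. Note the rule's
built-in limit: a probe highly expressed in about half the cell types raises
its own median and stops being "specific" — this is by design, and it is why
the signature-sharing property only emerges once an atlas has enough cell
types (≥ 5 for a shared pair).

Signatures are keyed by Entrez id; symbols are display metadata, matched
case-insensitively when a user list is symbol-typed. Entrez ids are matched
as exact digit strings. The universe (enrichment background) is every
annotated gene on the array, regardless of flagging. Unannotated probes stay
in the atlas — they count toward top-k% probe selections — but can never
become signature genes.

## Enrichment

The one-sided Fisher exact p-value for a (list, cell type) pair is the
hypergeometric upper tail P(X ≥ k) with X ~ Hypergeom(N, K, n), evaluated
through scipy's log-space survival function (exactly 1 at k = 0).
Benjamini–Hochberg adjustment (statsmodels' step-up implementation) runs
across the cell types of the database for one list at a time — never pooled
across lists, since each list's tests form one family. The score is
−log₁₀(adjusted p); an adjusted p that underflows to exactly 0 is capped at
score 320 (just above −log₁₀ of the smallest positive double) so scores stay
finite and sortable. Result rows are sorted by score descending with ties
broken by cell-type label ascending, making rankings reproducible; scores are
carried at full precision and display rounding never feeds back into ranking.
Plain (not mid-p) tails are used.

## Weighted ranking

Per list: take the 10 highest-scoring cell types (tie at the boundary broken
by label, exactly 10 kept), drop those below score 2, divide by the list's
overall maximum score (which necessarily sits inside the top 10). Both knobs
(`top_m`, `min_score`) are configurable; the defaults are the method's
standard values. Excluded entries serialize as empty fields, not 0, so a
heatmap consumer can distinguish "filtered out" from "scored zero". Columns
are ordered by descending column-wise maximum, then label.

## Validation machinery

**Test lists.** The top-k% list of a cell type takes the ceil(k/100 × probes)
most highly expressed probes of that cell type's averaged profile (ties broken
by probe id ascending — deterministic), maps them through the annotation and
deduplicates; the ceiling guarantees a non-empty list on small arrays.

**ROC.** Instances are all (list, cell type) pairs; an instance is positive
when the cell type equals the list's truth label, optionally coarsened through
a truth-group map (so that, e.g., any stimulation state of the correct cell
type counts). A pair is predicted positive at cutoff *s* when its score ≥ *s*.
AUC is the trapezoid over the (FPR, TPR) points anchored at (0, 0) and (1, 1).
Bootstrap bands resample **lists** (not instances) with replacement, because
one list's ~dozens of scores are strongly dependent; percentile 2.5/97.5
bounds are reported, deterministic given the seed.

**Threshold sweep.** The database is rebuilt at each candidate threshold; per
cell type the gene pool of its top-10% probes is subsampled 3 times at sizes
drawn uniformly on [500, 4000]. Each drawn size is clamped to the pool size:
on a 5000-probe synthetic atlas the top-10% pool holds only a few hundred
genes, so the clamp makes the same protocol meaningful at desk scale; on an
atlas the size of a real platform the clamp is a no-op.

**Null calibration.** 150 random lists of 100–400 ids drawn uniformly without
replacement from the universe are enriched; **all** cell-type scores are
pooled (pooling only each list's maximum is a stricter alternative the caller
can emulate, but pooling everything matches how the score floor is used in
practice). Exact zeros — adjusted p = 1 — form an atom whose mass
`zero_fraction` is recorded; the strictly positive scores get a gamma MLE
(location fixed at 0), and the reported `score_at_alpha` solves
zero_fraction + (1 − zero_fraction)·F_gamma(q) = α, i.e. the zero-inflated
mixture quantile (0 when the atom alone reaches α). Zeros are excluded from
the fit because a gamma has no atom at 0; the mixture re-incorporates them.

## Synthetic atlas generator

The generator emulates the structure of purified-cell-type expression atlases:

| parameter | default | meaning |
|---|---|---|
| `n_cell_types` | 10 | purified cell types / tissues |
| `n_probes` | 5000 | array probes |
| `n_replicates` | 2 | biological replicates per cell type |
| `n_signature_probes_per_cell` | 50 | planted cell-specific probes |
| `signal_fold` | 50 | planted fold over baseline |
| `baseline_log_mean`, `baseline_log_sd` | ln 100, 1.0 | log-normal baseline intensity |
| `replicate_noise_cv` | 0.1 | multiplicative replicate noise CV |
| `multi_probe_gene_fraction` | 0.2 | genes carried by two probes |
| `unannotated_fraction` | 0.1 | probes with no gene annotation |
| `shared_signature_fraction` | 0.0 | signature probes shared within cell-type pairs |

Baseline intensities are log-normal (median ≈ 100, a typical linear-scale
array intensity); replicate noise is multiplicative log-normal with unit mean,
so non-negativity is structural and the CV is directly interpretable. A
replicate CV of 0.1 and a planted fold of 50 against a 15× threshold describe
a clearly separable regime — deliberate, because the planted-recovery and
ranking checks are about correctness of the machinery, not about power at the
detection boundary. Gene ids are synthetic digit strings (so they pass Entrez
parsing) with symbols `G<id>`.

What the generator does **not** emulate: probe-affinity effects, background
correction and normalization artifacts, correlated co-expression between cell
types, and realistic signature-size variation. Passing tests on synthetic
atlases therefore demonstrate that the algorithms implement their definitions
and recover planted structure; they do not certify performance on real
platform data, where annotation quality and cross-cell-type correlation
dominate.

## Numerical and design notes

- The sharing-percentage denominator is the overlap coefficient
  (100·|A∩B| / min(|A|, |B|)) by default, with Jaccard selectable; the method
  used is recorded in the output. Min-type denominators match how closely
  related cellular states share "most of" their signatures.
- Hypergeometric tails are validated against exact rational-arithmetic
  enumeration over all instances with N ≤ 25; the BH step against an
  independent hand-written step-up implementation.
- Problem sizes in the test and acceptance runs (5000 probes, 10 cell types,
  150 null lists, ≤ 1000 bootstrap resamples) are chosen so the whole suite
  runs in seconds while every rate or AUC is still estimated from hundreds to
  thousands of instances.
- All stochastic procedures take explicit integer seeds (numpy Generator);
  identical seeds give bit-identical output, and the CLI logs seeds into each
  output's provenance header.
- Known limitations: no identifier translation beyond the supplied annotation
  table; no missing values in the atlas matrix; depletion (under-
  representation) is out of scope — the test is one-sided for enrichment.
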