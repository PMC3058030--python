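# Methods

## Data model and assumptions

An experiment is a set of chromatographic *separations*, each an ordered
list of *fractions* (0-based `order_index`; IDs are opaque and never
ordered lexicographically). Fractions may point at a parent fraction in a
multi-level purification hierarchy; parent links must form a forest. Each
fraction carries replicate ICP-MS metal concentrations (non-negative,
instrument units such as ppb) and MS/MS protein observations with peptide
counts. Duplicate (fraction, protein) observation rows are treated as
peptide-level records and summed.

Two modelling reductions shape everything downstream:

1. **Presence/absence only.** MS/MS peptide counts are at best locally
   semi-quantitative, so the analysis reduces them to Boolean presence.
   No statistic in the pipeline uses peptide-count magnitudes.
2. **Dataset-wide inclusion filter.** Only proteins identified with two
   or more peptides are trusted. Whether that threshold applies per
   identification event or per dataset is a genuine reading choice; we
   apply it dataset-wide (a protein whose *maximum* per-fraction peptide
   count is ≥ `min_peptides` is kept with all its rows, including
   1-peptide fractions), on the argument that one confident
   identification validates the protein's other sightings. The threshold
   is configurable for users who prefer the stricter reading.

## Metal peaks

A peak is ≥ 2 contiguous fractions of one separation whose concentrations
stand substantially above the surrounding baseline in **every** replicate.
Manually curated peak tables are the primary input path and always take
precedence. The automatic detector formalizes "substantially above" as a
fold-over-local-median rule with two passes:

* per fraction, each replicate must exceed `fold` × the median of the
  nearest `window` fractions on each side (candidate excluded);
* each provisional run of ≥ `min_len` fractions is re-confirmed against a
  background that excludes the whole run, so a wide peak cannot inflate
  its own baseline.

Defaults `fold = 3`, `window = 5`, `min_len = 2`. Requiring all replicates
(not the mean) is deliberately conservative: a single noisy replicate
cannot create a peak. Raising `fold` can only remove flagged fractions.
Peaks never span separations. The detector makes no claim to reproduce
manually curated peak inventories; it exists so the pipeline can run
unsupervised and so the rule itself is testable.

## GMPA score

For protein *p* and metal *m*: `f` analysis fractions (the presence
matrix's columns — the level at which the data are most consistent; peak
fractions outside this universe are ignored), `f_m` peak fractions of *m*,
`f_p` fractions containing *p*, `f_pm` their intersection. The score is
`P(X ≥ f_pm)` for `X ~ Hypergeom(f, f_m, f_p)`, computed with scipy's
survival function rather than naive factorials. Properties relied on
elsewhere and enforced by tests: the score is in (0, 1], non-increasing in
`f_pm`, symmetric under swapping `f_m` and `f_p`, and exactly 1 when
`f_pm = 0` or `f_m = f`.

**Underflow.** Strong associations underflow double precision. Scores are
floored at 1e-300, and a log-scale score is computed alongside via
log-sum-exp over hypergeometric log-pmf terms, which stays accurate far
below the underflow limit; curve fitting happens entirely in log space
using that floored `ln_score`.

## Significance curves

Scores fall roughly exponentially with occurrence count, so a flat cutoff
is meaningless. Per metal we fit `ln(score) = a + b·occ` by least squares
over all scored proteins, then scale only the exponent:
`curve(occ) = exp(a + c·b·occ)`.

* **Reference metals.** `c` is the minimum over qualifying references of
  `(ln score_r − a) / (b·occ_r)` — the most stringent curve that still
  captures every qualifying known metalloprotein. A reference qualifies
  when it is scored and occurs in ≥ `min_occurrences` fractions
  (default 10); rarely seen references cannot anchor a curve and are
  excluded. A reference scoring above the regression intercept cannot be
  captured by exponent scaling at any positive ratio; rather than clip
  the ratio silently and break the capture guarantee, this raises an
  error. No upper clip is applied by default (`c_max = None`).
* **Extrapolated metals.** With no usable references, `c` is the
  arithmetic mean of the reference metals' ratios (mean of per-metal
  ratios, not a pool over reference proteins), applied to the metal's own
  regression. When no metal has references at all, the pipeline falls
  back to a manual ratio (default 1.0 — the regression itself).
* **Filter.** Significant = `score ≤ curve(occ)` (inclusive boundary,
  with 1e-9 log-space slack against round-off) **and**
  `occ ≥ min_occurrences`; under AND semantics the order of the two
  conditions is immaterial. With `b < 0` and `c ≥ 1` the significant set
  is a subset of the regression-curve set.

## Clustering and cluster counts

Significant proteins of a metal are clustered on their Boolean presence
vectors over all analysis fractions (not only peak fractions — the
co-occurrence structure outside peaks is informative too, and the choice
is configurable): Euclidean distance on raw 0/1 vectors, Ward linkage
(scipy's deterministic implementation; rows are canonically sorted by
protein ID first so input order never matters).

The tree is cut with a dynamic hybrid rule implemented in-package:

1. static cut: merges above `cut_height_fraction` × max merge height
   (default 0.99) always split;
2. branch-gap criterion: within a branch, merges whose height is within a
   relative tolerance `gap = (4 − deep_split)/10` of the branch top are
   treated as one multi-way split (Ward renders a k-way separation as a
   ladder of similar-height merges); the split is accepted when it
   separates ≥ 2 sub-branches of ≥ `min_cluster_size` proteins, and each
   sub-branch is then evaluated recursively;
3. leftover branches smaller than `min_cluster_size` stay unassigned
   (label 0).

Defaults `min_cluster_size = 3`, `deep_split = 2`. A branch of identical
profiles (merge height 0) is never split. Labels are renumbered by first
protein in canonical order, so identical inputs give identical labels.

A cluster's *core* is the set of fractions where ≥ 50 % of its proteins
are present (inclusive at exactly half); core overlap between clusters is
the Jaccard index of their core sets. Well-chosen parameters give tight
cores coinciding with metal peaks and near-zero pairwise overlap, which
justifies reading the cluster count as the number of distinct
metalloproteins needed to explain the metal's peaks. The greedy set cover
(protein covers a peak region iff it shares ≥ 1 fraction with it; ties
broken by lower GMPA score, then protein ID) reports the matching lower
bound side by side; the two are *not* forced into an inequality, as
greedy covers are approximate.

## InterPro-Metal classifier

Per-metal case-insensitive regexes run over each entry's name + abstract
(whitespace-normalized, identical for XML and TSV sources). The shipped
pattern file covers the ten metals of the motivating organism via element
names, oxidation-state adjectives and cofactor/family terms (heme and
Fe–S for Fe, molybdopterin for Mo, tungstopterin for W, cobalamin/corrin
for Co, zinc finger for Zn, …); it is data, versioned with the package,
and meant to be replaced. Ambiguity (e.g. transporter entries listing
many metals, or abstracts mentioning sister subfamilies with other
metals) is handled by curation scores, not pattern logic: a curation row
with score 0 excludes that (entry, metal) pair, any positive score keeps
it, absence of a row keeps it. Classification is monotone in patterns and
order-independent.

## Synthetic data

The generator emulates: multiple separations of ordered fractions;
per-metal replicate traces as lognormal baseline (mean 1.0, CV 0.2 —
lognormal keeps concentrations positive) multiplied by `peak_fold`
(default 8) inside rectangular planted peaks; planted metalloproteins
present in each fraction of their metal's peaks with `p_hit = 0.8` and
elsewhere with `p_bg = 0.02`; background proteins present anywhere with
probability 0.03; peptide counts `1 + Poisson(2)`, with 5 % of background
proteins forced single-peptide to exercise the inclusion filter. Same-
metal peaks are placed ≥ 6 fractions apart and ≥ 3 from separation edges
— distinct elution events with identifiable local baselines. Defaults are
desk-scale (8 × 60 fractions, 350 proteins); `paper_scale_config()` sizes
the same model to a full campaign (43 × 60 = 2,580 fractions, 870
proteins, 10 metals), which the whole pipeline processes in seconds. A
separate helper plants k disjoint co-elution groups for clustering tests.

What the generator does **not** emulate — and hence what green tests do
not establish about real data: chromatographic peak shapes and tailing,
enrichment across purification levels, correlated replicate noise,
isotope interference, protein abundance structure, and metals exchanging
between proteins during separation. Passing tests demonstrate that the
statistical machinery recovers planted structure under the stated noise
model, not that any particular biological inventory is correct.

## Numerical choices and degenerate inputs

* Score floor 1e-300; `ln_score` floored at ln(1e-300) ≈ −690.8.
* Regression requires ≥ 3 proteins with ≥ 1 occurrence; an all-ones score
  set fits a flat curve (a = b = 0), in which case any reference at or
  below the intercept is captured at ratio 1.
* Clustering requires ≥ 2 proteins; all-zero distances give one cluster.
* Empty observation tables are valid (zero-protein bundle, all-false
  matrix); empty peak sets give `f_m = 0` and all scores 1.
* TSV outputs use a fixed float format (`%.10g`) so reruns are
  byte-identical.

## Known limitations

* The significance-curve construction (scale the exponent, hold the
  intercept) is one defensible reading of anchoring curves on known
  metalloproteins; hand-set curves are supported via the manual source.
* The hybrid tree cut is a simplified reimplementation of the dynamic
  hybrid idea, not a port of any particular package; its `deep_split`
  mapping is heuristic.
* Keyword classification inherits every bias of annotation text; the
  default pattern file is a reconstruction, and real use demands curation.
* Cluster counts are estimates of *distinct co-eluting metal-associated
  groups*; adventitious binding and coincidental co-elution inflate them,
  incomplete separation deflates them.
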