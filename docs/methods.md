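# Methods

## Count model and simulation

Counts for gene *g* in sample *j* are negative binomial with mean
`s_j · μ_g · 2^LFC` and dispersion α (variance `μ + αμ²`); the planted
log2 effect LFC applies only in treated samples and only in the layer(s)
dictated by the gene's class. Baseline means μ_g are drawn log-uniformly
over `base_mean_range` (default 10–10,000), spanning weakly and strongly
expressed genes; the paired RNA and RPF counts are independent given their
means, matching independently prepared libraries. Defaults: 2,000 genes
(150 translation-only, 150 transcription-only, 50 opposite, 50 concordant,
1,600 null), effect |log2FC| = 2, α = 0.05, library-size factors 1, and
3 replicates per condition (typical of small sequencing designs; the
recovery analyses in `scripts/acceptance.py` use 4). For α < 1e-8 the
generator samples the Poisson limit directly, which makes the NB → Poisson
limit testable.

What the generator does **not** emulate: gene-length and GC biases, shared
noise between the RNA and RPF libraries of the same biological sample,
mean–dispersion trends, UTR/codon-level ribosome occupancy structure, and
batch effects. Passing recovery tests therefore demonstrate correctness of
the statistical machinery under the stated model, not performance on any
particular real dataset.

## Normalization and differential testing

Size factors are median-of-ratios within each assay (the geometric-mean
reference over genes observed in all samples), rescaled to geometric mean 1
so only relative depth remains; a matrix with no all-nonzero gene raises an
error pointing at total-count scaling. Rescaling one library by a constant
changes all normalized counts by a common factor that cancels in every fold
change — exactly so at pseudocount 0, which is how the invariance is
tested.

Per layer, log2 fold change is computed from condition means of normalized
counts with pseudocount c = 0.5 (guards against division by zero at low
counts), and the p-value is a two-sided moderated two-sample t-test on
`log2(normalized + c)`: per-gene pooled variances are shrunk toward a
common prior by empirical Bayes, with the prior scale and degrees of
freedom fitted by moment matching of `log s²` to a scaled-F model. At 3–4
replicates the raw variance estimates (2–3 df) are too unstable even for
fourfold effects, and variance moderation is the standard remedy in this
field; the unmoderated Welch test remains available via `method="welch"`.
FDR is controlled with Benjamini–Hochberg separately within the RNA, RPF
and TE layers, which are reported as separate analyses.

The TE layer's significance is the assay × condition interaction — the
contrast `(RPF_t − RPF_c) − (RNA_t − RNA_c)` on log2 normalized counts —
tested with the same moderated variance machinery (Welch–Satterthwaite
under `method="welch"`). Its estimate satisfies
`log2FC_TE = log2FC_RPF − log2FC_RNA` identically at c = 0. TE itself is
computed from condition means rather than per-replicate RNA↔RPF pairs,
since no pairing between the two library types is assumed; replicate-level
values can be formed from the normalized matrices if a paired design
exists.

Classification uses q < 0.05 (strict) and |log2FC| ≥ 1 (inclusive) by
default, both configurable and recorded in the output metadata. The classes
are a partition; "opposite" demands significance in both layers with
strictly opposing signs. On the TE scheme, genes significant only in RNA
fall into `te_unchanged`, and transcription-only genes are legitimately
antagonistic on the TE layer (mRNA up with flat RPF lowers TE).

The global TE comparison is the two-sided Wilcoxon rank-sum test on
per-gene log2 TE: exact null distribution when both samples are ≤ 25 and
untied, tie-corrected normal approximation otherwise; an all-tied input
returns p = 1 with a warning rather than NaN.

## Enrichment

For a term with K members among N universe genes and k hits in a query of
n, the p-value is the hypergeometric upper tail P(X ≥ k) and fold
enrichment is (k/n)/(K/N). Only terms with ≥ 1 query hit are reported;
annotation genes outside the universe are dropped with a logged count. The
default filter keeps FE strictly greater than 1.2 and k ≥ 15 (query-member
count, the convention of the common web tools). Intersection of two
annotation sources keeps terms present in both, ranked by the worse of the
two p-values (a term is only as trustworthy as its weaker evidence), ties
broken by larger fold enrichment then term id; the two member lists are
united so per-gene term frequencies see either source's evidence. The
background universe is the caller's choice — conventionally all genes that
survive expression filtering in the count matrix.

## Regeneration index

Profiles are normalized by the mean intensity over a small crush window
(default 0.1 mm) rather than the single crush-site sample, because a
one-pixel reference is noise-dominated. The index is the first position
where the (optionally moving-average smoothed, default window 0.2 mm)
normalized curve reaches 0.5, located by linear interpolation between
samples, hence exact for piecewise-linear profiles. Noise can create
multiple crossings; the first crossing after smoothing is used. A profile
that never reaches 0.5 is censored at its maximal position instead of
failing, keeping group statistics computable. For a noiseless exponential
with decay length λ the index is λ·ln 2, strictly increasing in λ. The
crush-window convention rescales the whole curve by the window mean of the
decay (≈ +3.6% on the index for λ = 2 with a 0.1 mm window); analyses
comparing groups are unaffected because the convention is common to all
profiles.

## Up-down threshold

The staircase starts at 10 g in the middle of the filament series
(4, 6, 8, 10, 15, 26, 60, 100 g), steps down after a withdrawal, up after
none, and runs four stimuli past the first pair of unlike responses. The
estimate is `10^(X_f + k·δ)` with X_f the log10 final force and δ the mean
absolute log10 spacing of the series (0.1997 = log10(25)/7; the series is
not log-uniform, so the mean spacing is used). The correction constant k is
computed per sequence as the maximum-likelihood location of a normal
psychometric function of log10 force with spread fixed at δ — the model
the classical tabulated constants summarize — which makes k available for
any protocol-legal sequence, including clamped ones. A geometric-midpoint
rule is available via `method="midpoint"`. Boundary conventions: no
withdrawal anywhere → the 100 g ceiling; withdrawal at every presentation
→ the weakest filament; estimates are clamped to the filament range, so
they always lie in [4, 100] g. Simulated series draw responses from a
logistic psychometric function of log10 force; a non-response at 100 g
terminates a series, and two consecutive responses at 4 g before any
crossing terminate it as floor-censored.

Thermal latencies are the arithmetic mean of 3 repetitions with a 30 s
cutoff; values at the cutoff are reported as a censored fraction rather
than treated as true latencies.

## Numerical conventions

* Ties at classification thresholds: strict `<` on q, inclusive `≥` on
  |log2FC|.
* Degenerate zero-variance genes: p = 1 when group means coincide, p → 0
  otherwise.
* Hypergeometric tails use scipy's survival function, verified against
  exact rational-arithmetic enumeration for N ≤ 20 to 1e-12.
* The discrete hypergeometric p-value is conservative; its calibration is
  tested on the continuity-randomized p-value, which is exactly uniform
  under the null.
* All generators take an explicit integer seed and are bit-reproducible.

## Known limitations

* The moderated t on log2 counts is a large-ish-count approximation; genes
  with means near zero lean on the pseudocount and are mainly protected by
  the fold-change cutoff, not by the test.
* No gene-length normalization: TE is a within-gene ratio, so length
  cancels, but cross-gene abundance comparisons are depth-normalized only.
* The enrichment module does no ontology-graph propagation or redundancy
  reduction; terms are treated as flat sets.
* The up-down estimator assumes the psychometric spread equals the filament
  spacing (the classical assumption); strongly shallower or steeper true
  psychometric functions bias any estimator of this family.
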