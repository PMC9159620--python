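"""Differential transcriptome/translatome analysis and TE classification.

The analysis has four stages:

1. median-of-ratios size-factor normalization, within each assay;
2. per-gene differential tests in the RNA and RPF layers (Welch t on
   log2 normalized counts, BH-adjusted within each layer);
3. translation efficiency TE = normalized RPF / normalized RNA per
   condition, with a TE-layer contrast (the assay x condition interaction)
   tested the same way;
4. assignment of each gene to a regulatory class: regulated only at the
   translational level, only at the transcriptional level, in both layers
   with opposing directions (antagonism), in both with the same direction,
   or unchanged — plus the analogous classification on the TE layer.

A global comparison of per-gene TE distributions between conditions uses
the two-sided Wilcoxon rank-sum test.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import polygamma
from statsmodels.stats.multitest import multipletests

from .containers import CONDITIONS, PairedCounts

LAYER_CLASSES = ("translation_only", "transcription_only", "opposite", "concordant", "unchanged")
TE_CLASSES = ("te_only", "te_opposite", "te_concordant", "te_unchanged")

DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_LFC_CUT = 1.0
DEFAULT_Q_CUT = 0.05


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    For each gene expressed in every sample, the ratio of its count to its
    geometric mean across samples is formed; a sample's factor is the median
    of those ratios.  Factors are then divided by their own geometric mean,
    so relative library depth is all that remains.

    Raises
    ------
    ValueError
        If no gene is nonzero in all samples; total-count scaling is the
        suggested fallback for such sparse matrices.
    """
    arr = counts.to_numpy(dtype=float)
    mask = (arr > 0).all(axis=1)
    if not mask.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; median-of-ratios is "
            "undefined — fall back to total-count scaling"
        )
    logs = np.log(arr[mask])
    log_ratios = logs - logs.mean(axis=1, keepdims=True)
    log_factors = np.median(log_ratios, axis=0)
    log_factors = log_factors - log_factors.mean()  # geometric mean 1
    return pd.Series(np.exp(log_factors), index=counts.columns, name="size_factor")


def normalized_counts(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    if factors is None:
        factors = size_factors(counts)
    return counts / factors


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    return multipletests(np.asarray(p, float), method="fdr_bh")[1]


def _welch_groups(log_treated: np.ndarray, log_control: np.ndarray) -> np.ndarray:
    """Row-wise two-sided Welch t-test p-values on log-scale replicates.

    Degenerate rows (zero variance in both groups) get p = 1 when the group
    means coincide and p -> 0 when they differ.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(log_treated, log_control, axis=1, equal_var=False)
    diff = log_treated.mean(axis=1) - log_control.mean(axis=1)
    p = np.where(np.isnan(p), np.where(diff == 0, 1.0, 0.0), p)
    return p


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (trigamma is strictly decreasing)."""
    return float(optimize.brentq(lambda x: polygamma(1, x) - y, 1e-8, 1e8))


def squeeze_variances(s2: np.ndarray, df: float) -> tuple[np.ndarray, float]:
    """Empirical-Bayes shrinkage of per-gene sample variances.

    Models s2_g ~ s0^2 * F(df, d0) (an inverse-chi-square prior on the true
    variances) and estimates the prior scale s0^2 and prior df d0 by moment
    matching on log s2.  Returns the posterior variances
    (d0*s0^2 + df*s2) / (d0 + df) and the total df d0 + df.  With near-
    constant observed variances the prior dominates (d0 -> inf).
    """
    s2 = np.asarray(s2, float)
    pos = s2[s2 > 0]
    if len(pos) < 2:
        return s2.copy(), float(df)
    z = np.log(pos)
    evar = z.var(ddof=1) - polygamma(1, df / 2)
    if evar <= 1e-10:
        d0 = np.inf
        log_s02 = z.mean() - polygamma(0, df / 2) + np.log(df / 2)
    else:
        d0 = 2 * _trigamma_inverse(evar)
        log_s02 = (
            z.mean()
            - polygamma(0, df / 2)
            + np.log(df / 2)
            + polygamma(0, d0 / 2)
            - np.log(d0 / 2)
        )
    s02 = np.exp(log_s02)
    if np.isinf(d0):
        return np.full_like(s2, s02), np.inf
    post = (d0 * s02 + df * s2) / (d0 + df)
    return post, float(d0 + df)


def _moderated_groups(log_treated: np.ndarray, log_control: np.ndarray) -> np.ndarray:
    """Row-wise moderated two-sample t-test p-values (pooled variance,
    empirical-Bayes shrunk across genes)."""
    n1, n2 = log_treated.shape[1], log_control.shape[1]
    df = n1 + n2 - 2
    with np.errstate(invalid="ignore"):
        ss = (
            log_treated.var(axis=1, ddof=1) * (n1 - 1)
            + log_control.var(axis=1, ddof=1) * (n2 - 1)
        )
    s2 = ss / df
    s2_post, df_total = squeeze_variances(s2, df)
    diff = log_treated.mean(axis=1) - log_control.mean(axis=1)
    se = np.sqrt(s2_post * (1 / n1 + 1 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    if np.isinf(df_total):
        p = 2 * stats.norm.sf(np.abs(t))
    else:
        p = 2 * stats.t.sf(np.abs(t), df_total)
    return np.where(np.isnan(p), np.where(diff == 0, 1.0, 0.0), p)


def differential(
    counts: pd.DataFrame,
    conditions: pd.Series,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    factors: pd.Series | None = None,
    method: str = "moderated",
) -> pd.DataFrame:
    """Per-gene differential expression within one assay.

    log2 fold change is computed from condition means of normalized counts
    (treated over control, both offset by ``pseudocount``); the p-value is a
    two-sided two-sample t-test on log2(normalized count + pseudocount)
    across replicates, BH-adjusted across genes.  The default
    ``method='moderated'`` shrinks per-gene variances across genes
    (empirical Bayes), which stabilizes the test at the 3-4 replicates
    typical of sequencing designs; ``method='welch'`` is the unmoderated
    unequal-variance test.
    """
    if method not in ("moderated", "welch"):
        raise ValueError("method must be 'moderated' or 'welch'")
    conditions = pd.Series(conditions).loc[list(counts.columns)]
    for c in CONDITIONS:
        if (conditions == c).sum() < 2:
            raise ValueError(f"condition {c!r} needs >= 2 replicates")
    norm = normalized_counts(counts, factors)
    ctrl = norm.loc[:, (conditions == "control").to_numpy()]
    trt = norm.loc[:, (conditions == "treated").to_numpy()]
    c = pseudocount
    mean_ctrl = ctrl.mean(axis=1)
    mean_trt = trt.mean(axis=1)
    lfc = np.log2((mean_trt + c) / (mean_ctrl + c))
    test = _moderated_groups if method == "moderated" else _welch_groups
    with np.errstate(divide="ignore"):
        p = test(np.log2(trt.to_numpy() + c), np.log2(ctrl.to_numpy() + c))
    return pd.DataFrame(
        {
            "log2fc": lfc,
            "p": p,
            "q": bh_adjust(p),
            "mean_control": mean_ctrl,
            "mean_treated": mean_trt,
        },
        index=counts.index,
    )


def compute_te(
    paired: PairedCounts,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-gene, per-condition translation efficiency.

    TE is the ratio of ribosome-protected fragment (RPF) abundance to total
    mRNA abundance: mean normalized RPF + c over mean normalized RNA + c,
    computed per condition.  Both the ratio and its log2 are returned.
    """
    c = pseudocount
    out = pd.DataFrame(index=paired.genes)
    means: dict[tuple[str, str], pd.Series] = {}
    for assay in ("RNA", "RPF"):
        counts = paired.matrix(assay)
        cond = paired.conditions(assay)
        norm = normalized_counts(counts)
        for condition in CONDITIONS:
            means[(assay, condition)] = norm.loc[:, (cond == condition).to_numpy()].mean(axis=1)
    for condition in CONDITIONS:
        te = (means[("RPF", condition)] + c) / (means[("RNA", condition)] + c)
        out[f"te_{condition}"] = te
        out[f"log2_te_{condition}"] = np.log2(te)
    return out


def _group_log(paired: PairedCounts, assay: str, condition: str, c: float) -> np.ndarray:
    counts = paired.matrix(assay)
    cond = paired.conditions(assay)
    norm = normalized_counts(counts)
    return np.log2(norm.loc[:, (cond == condition).to_numpy()].to_numpy() + c)


def te_differential(
    paired: PairedCounts,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    method: str = "moderated",
) -> pd.DataFrame:
    """TE-layer contrast: the assay x condition interaction per gene.

    The estimate is log2fc_te = log2fc_rpf - log2fc_rna on the normalized
    means; the p-value tests the interaction
    (RPF_treated - RPF_control) - (RNA_treated - RNA_control)
    on log2 replicate values.  ``method='moderated'`` pools the four group
    variances per gene and shrinks them across genes (empirical Bayes);
    ``method='welch'`` uses a Welch-Satterthwaite approximation instead.
    """
    if method not in ("moderated", "welch"):
        raise ValueError("method must be 'moderated' or 'welch'")
    c = pseudocount
    with np.errstate(divide="ignore"):
        groups = {
            (assay, condition): _group_log(paired, assay, condition, c)
            for assay in ("RNA", "RPF")
            for condition in CONDITIONS
        }
    d = (
        groups[("RPF", "treated")].mean(axis=1)
        - groups[("RPF", "control")].mean(axis=1)
        - groups[("RNA", "treated")].mean(axis=1)
        + groups[("RNA", "control")].mean(axis=1)
    )
    ns = [g.shape[1] for g in groups.values()]
    if method == "moderated":
        df = sum(n - 1 for n in ns)
        with np.errstate(invalid="ignore"):
            ss = np.sum(
                [g.var(axis=1, ddof=1) * (g.shape[1] - 1) for g in groups.values()], axis=0
            )
        s2_post, df_total = squeeze_variances(ss / df, df)
        var = s2_post * sum(1 / n for n in ns)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = d / np.sqrt(var)
            if np.isinf(df_total):
                p = 2 * stats.norm.sf(np.abs(t))
            else:
                p = 2 * stats.t.sf(np.abs(t), df_total)
    else:
        var_terms = []
        df_denoms = []
        for g in groups.values():
            n = g.shape[1]
            v = g.var(axis=1, ddof=1) / n
            var_terms.append(v)
            df_denoms.append(v**2 / (n - 1))
        var = np.sum(var_terms, axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            dof = var**2 / np.sum(df_denoms, axis=0)
            t = d / np.sqrt(var)
            p = 2 * stats.t.sf(np.abs(t), dof)
    p = np.where(np.isnan(p), np.where(d == 0, 1.0, 0.0), p)
    return pd.DataFrame({"stat_te": d, "p_te": p, "q_te": bh_adjust(p)}, index=paired.genes)


def analyze(
    paired: PairedCounts,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    method: str = "moderated",
) -> pd.DataFrame:
    """Full per-gene result table across the three layers.

    Columns: log2fc / p / q for the RNA, RPF and TE layers, per-condition
    TE values and per-assay mean normalized abundances.  FDR is controlled
    within each layer separately.
    """
    rna = differential(paired.rna, paired.rna_conditions, pseudocount, method=method)
    rpf = differential(paired.rpf, paired.rpf_conditions, pseudocount, method=method)
    te = compute_te(paired, pseudocount)
    tt = te_differential(paired, pseudocount, method=method)
    result = pd.DataFrame(index=paired.genes)
    result["log2fc_rna"] = rna["log2fc"]
    result["p_rna"] = rna["p"]
    result["q_rna"] = rna["q"]
    result["log2fc_rpf"] = rpf["log2fc"]
    result["p_rpf"] = rpf["p"]
    result["q_rpf"] = rpf["q"]
    result["log2fc_te"] = te["log2_te_treated"] - te["log2_te_control"]
    result["p_te"] = tt["p_te"]
    result["q_te"] = tt["q_te"]
    result["te_control"] = te["te_control"]
    result["te_treated"] = te["te_treated"]
    result["base_mean_rna"] = (rna["mean_control"] + rna["mean_treated"]) / 2
    result["base_mean_rpf"] = (rpf["mean_control"] + rpf["mean_treated"]) / 2
    return result


def _check_cuts(lfc_cut: float, q_cut: float) -> None:
    if lfc_cut < 0:
        raise ValueError("lfc_cut must be nonnegative")
    if not (0 < q_cut < 1):
        raise ValueError("q_cut must lie in (0, 1)")


def _significant(lfc: pd.Series, q: pd.Series, lfc_cut: float, q_cut: float) -> pd.Series:
    # strict < on q, >= on |log2fc| (tie-break convention)
    return (q < q_cut) & (lfc.abs() >= lfc_cut)


def _direction(sig: pd.Series, lfc: pd.Series) -> np.ndarray:
    return np.where(sig, np.where(lfc > 0, "up", "down"), "none")


def classify_layers(
    result: pd.DataFrame,
    lfc_cut: float = DEFAULT_LFC_CUT,
    q_cut: float = DEFAULT_Q_CUT,
) -> pd.DataFrame:
    """Assign each gene a regulatory class from the RNA and RPF layers.

    translation_only: significant in RPF but not RNA; transcription_only:
    the converse; opposite: significant in both with strictly opposing
    signs; concordant: significant in both with the same sign; unchanged
    otherwise.  The classes partition the gene list.
    """
    _check_cuts(lfc_cut, q_cut)
    sig_rna = _significant(result["log2fc_rna"], result["q_rna"], lfc_cut, q_cut)
    sig_rpf = _significant(result["log2fc_rpf"], result["q_rpf"], lfc_cut, q_cut)
    opposing = np.sign(result["log2fc_rna"]) != np.sign(result["log2fc_rpf"])
    layer_class = np.select(
        [
            sig_rpf & ~sig_rna,
            sig_rna & ~sig_rpf,
            sig_rna & sig_rpf & opposing,
            sig_rna & sig_rpf & ~opposing,
        ],
        ["translation_only", "transcription_only", "opposite", "concordant"],
        default="unchanged",
    )
    return pd.DataFrame(
        {
            "layer_class": layer_class,
            "dir_rna": _direction(sig_rna, result["log2fc_rna"]),
            "dir_rpf": _direction(sig_rpf, result["log2fc_rpf"]),
        },
        index=result.index,
    )


def classify_te(
    result: pd.DataFrame,
    lfc_cut: float = DEFAULT_LFC_CUT,
    q_cut: float = DEFAULT_Q_CUT,
) -> pd.DataFrame:
    """TE-layer analog of :func:`classify_layers`.

    te_only: significant TE change without an RNA change; te_opposite:
    significant in both TE and RNA with opposing signs (e.g. increased mRNA
    but lower TE); te_concordant: both significant, same sign; te_unchanged
    otherwise.
    """
    _check_cuts(lfc_cut, q_cut)
    sig_rna = _significant(result["log2fc_rna"], result["q_rna"], lfc_cut, q_cut)
    sig_te = _significant(result["log2fc_te"], result["q_te"], lfc_cut, q_cut)
    opposing = np.sign(result["log2fc_rna"]) != np.sign(result["log2fc_te"])
    te_class = np.select(
        [
            sig_te & ~sig_rna,
            sig_te & sig_rna & opposing,
            sig_te & sig_rna & ~opposing,
        ],
        ["te_only", "te_opposite", "te_concordant"],
        default="te_unchanged",
    )
    return pd.DataFrame(
        {
            "te_class": te_class,
            "dir_te": _direction(sig_te, result["log2fc_te"]),
            "dir_rna": _direction(sig_rna, result["log2fc_rna"]),
        },
        index=result.index,
    )


def select_genes(
    classification: pd.DataFrame,
    classes: tuple[str, ...] = ("te_only", "te_opposite"),
    direction: str = "down",
) -> list[str]:
    """Genes in the given TE classes whose TE moved in ``direction``.

    The default selection — genes with down-regulated TE in the TE-only and
    antagonistic groups — is the input for enrichment analysis.  Gene order
    follows the table.
    """
    scheme_col = "te_class" if "te_class" in classification.columns else "layer_class"
    valid = set(TE_CLASSES) | set(LAYER_CLASSES)
    unknown = set(classes) - valid
    if unknown:
        raise ValueError(f"unknown class labels {sorted(unknown)}")
    if direction not in ("up", "down", "any"):
        raise ValueError("direction must be 'up', 'down' or 'any'")
    dir_col = "dir_te" if scheme_col == "te_class" else "dir_rpf"
    keep = classification[scheme_col].isin(classes)
    if direction != "any":
        keep &= classification[dir_col] == direction
    return classification.index[keep].tolist()


def global_te_test(te_control: np.ndarray, te_treated: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test between per-gene log2 TE vectors.

    Uses the exact null distribution for small untied samples and the
    tie-corrected normal approximation otherwise.  An all-tied input has no
    rank information: the statistic is returned with p = 1 and a warning.
    """
    a = np.asarray(te_control, float)
    b = np.asarray(te_treated, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 values per group")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        warnings.warn("all TE values tied; rank-sum test is uninformative", stacklevel=2)
        return float(len(a) * len(b) / 2), 1.0
    small = max(len(a), len(b)) <= 25
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
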