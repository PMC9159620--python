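"""Normalization, differential tests, TE, classification, rank-sum test."""
import itertools

import numpy as np
import pandas as pd
import pytest

from translatome import diffexpr as dx
from translatome.containers import PairedCounts
from translatome.simulate import SimConfig, simulate_paired_counts


def _constant_paired(rna_value, rpf_value, n=3, genes=4):
    """PairedCounts with constant counts per assay (plus a second distinct
    gene row so size factors are defined)."""
    cols_rna = [f"RNA_{c}_{i}" for c in ("control", "treated") for i in range(n)]
    cols_rpf = [f"RPF_{c}_{i}" for c in ("control", "treated") for i in range(n)]
    rna = pd.DataFrame(rna_value, index=[f"g{i}" for i in range(genes)], columns=cols_rna)
    rpf = pd.DataFrame(rpf_value, index=[f"g{i}" for i in range(genes)], columns=cols_rpf)
    cond = ["control"] * n + ["treated"] * n
    return PairedCounts(
        rna=rna,
        rpf=rpf,
        rna_conditions=pd.Series(cond, index=cols_rna),
        rpf_conditions=pd.Series(cond, index=cols_rpf),
    )


class TestSizeFactors:
    def test_identical_samples_all_one(self):
        counts = pd.DataFrame({"a": [10, 20, 5], "b": [10, 20, 5], "c": [10, 20, 5]})
        assert np.allclose(dx.size_factors(counts), 1.0)

    def test_doubled_sample_scale_equivariance(self):
        rng = np.random.default_rng(0)
        base = rng.integers(10, 1000, size=500)
        counts = pd.DataFrame({"a": base, "b": base, "c": 2 * base})
        f = dx.size_factors(counts)
        assert f["c"] / f["a"] == pytest.approx(2.0, rel=1e-12)
        assert f["a"] == pytest.approx(f["b"], rel=1e-12)
        assert np.prod(f) ** (1 / 3) == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_median_of_ratios(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(
            rng.negative_binomial(20, 0.1, size=(300, 5)) + 1,
            columns=list("abcde"),
        )
        f = dx.size_factors(counts)
        # independent brute-force computation, plain python loops
        import statistics

        arr = counts.to_numpy(float)
        ref = []
        for row in arr:
            ref.append(float(np.exp(sum(np.log(v) for v in row) / len(row))))
        raw = []
        for j in range(arr.shape[1]):
            raw.append(statistics.median(arr[i, j] / ref[i] for i in range(arr.shape[0])))
        geo = float(np.exp(np.mean(np.log(raw))))
        expected = [r / geo for r in raw]
        assert np.allclose(f.to_numpy(), expected, atol=1e-12)

    def test_all_zero_row_matrix_raises(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [3, 0]})
        with pytest.raises(ValueError, match="total-count"):
            dx.size_factors(counts)


class TestDifferential:
    def test_fourfold_gene_converges_to_lfc_two(self):
        rng = np.random.default_rng(2)
        base = rng.integers(100, 10000, size=200)
        counts = pd.DataFrame(
            {f"c{i}": base for i in range(3)} | {f"t{i}": base for i in range(3)}
        )
        counts.iloc[0, 3:] = counts.iloc[0, 0] * 4  # one gene 4x in treated
        cond = pd.Series(
            ["control"] * 3 + ["treated"] * 3, index=counts.columns
        )
        res = dx.differential(counts, cond)
        assert res["log2fc"].iloc[0] == pytest.approx(2.0, abs=0.01)
        assert abs(res["log2fc"].iloc[1:]).max() < 0.01

    def test_null_data_rarely_significant(self):
        config = SimConfig(
            n_genes=2000,
            class_counts={
                "translation_only": 0,
                "transcription_only": 0,
                "opposite": 0,
                "concordant": 0,
                "null": 2000,
            },
            n_replicates=4,
            seed=3,
        )
        paired, _ = simulate_paired_counts(config)
        res = dx.differential(paired.rna, paired.rna_conditions)
        assert res["log2fc"].abs().median() < 0.2
        assert (res["q"] < 0.05).mean() <= 0.07

    def test_planted_translation_effect_power(self, paired_truth, analysis):
        _, truth = paired_truth
        tgenes = truth.index[truth.true_class == "translation_only"]
        assert (analysis.loc[tgenes, "q_rpf"] < 0.05).mean() >= 0.9

    def test_too_few_replicates_rejected(self):
        counts = pd.DataFrame({"a": [1, 2], "b": [1, 2], "c": [2, 3]})
        cond = pd.Series(["control", "control", "treated"], index=counts.columns)
        with pytest.raises(ValueError, match="replicates"):
            dx.differential(counts, cond)


class TestTranslationEfficiency:
    def test_direct_ratio(self):
        paired = _constant_paired(5, 10)
        te = dx.compute_te(paired, pseudocount=0.0)
        assert np.allclose(te["te_control"], 2.0)
        assert np.allclose(te["te_treated"], 2.0)

    def test_equal_layers_give_unit_te(self):
        paired = _constant_paired(7, 7)
        te = dx.compute_te(paired, pseudocount=0.0)
        assert np.allclose(te["te_control"], 1.0)
        assert np.allclose(te["log2_te_control"], 0.0)
        assert np.allclose(te["log2_te_treated"], 0.0)

    def test_translation_only_gene_shifts_te(self, paired_truth, analysis):
        _, truth = paired_truth
        high = truth.index[
            (truth.true_class == "translation_only")
            & (analysis["base_mean_rna"] > 200)
        ]
        delta = analysis.loc[high, "log2fc_te"] * np.sign(
            truth.loc[high, "true_log2fc_rpf"]
        )
        assert abs(delta.mean() - 2.0) < 0.3

    def test_te_identity_with_zero_pseudocount(self, paired_truth):
        paired, _ = paired_truth
        res = dx.analyze(paired, pseudocount=0.0)
        nonzero = (paired.rna > 0).all(axis=1) & (paired.rpf > 0).all(axis=1)
        err = (
            res.loc[nonzero, "log2fc_te"]
            - (res.loc[nonzero, "log2fc_rpf"] - res.loc[nonzero, "log2fc_rna"])
        ).abs()
        assert err.max() < 1e-9

    def test_q_dominates_p(self, analysis):
        for layer in ("rna", "rpf", "te"):
            assert (analysis[f"q_{layer}"] >= analysis[f"p_{layer}"] - 1e-15).all()


def _result_row(**kwargs):
    row = {
        "log2fc_rna": 0.0, "q_rna": 1.0,
        "log2fc_rpf": 0.0, "q_rpf": 1.0,
        "log2fc_te": 0.0, "q_te": 1.0,
    }
    row.update(kwargs)
    return row


class TestClassification:
    def test_translation_only_definition(self):
        res = pd.DataFrame([_result_row(q_rpf=0.001, log2fc_rpf=2.0, q_rna=0.8)])
        assert dx.classify_layers(res)["layer_class"].iloc[0] == "translation_only"

    def test_nonsignificant_is_unchanged(self):
        res = pd.DataFrame([_result_row()])
        assert dx.classify_layers(res)["layer_class"].iloc[0] == "unchanged"
        assert dx.classify_te(res)["te_class"].iloc[0] == "te_unchanged"

    def test_opposite_requires_both_layers(self):
        res = pd.DataFrame(
            [
                _result_row(
                    q_rna=0.01, log2fc_rna=1.2, q_rpf=0.01, log2fc_rpf=-1.5
                )
            ]
        )
        assert dx.classify_layers(res)["layer_class"].iloc[0] == "opposite"

    def test_te_antagonism(self):
        # increased mRNA with lower TE
        res = pd.DataFrame(
            [_result_row(q_te=0.01, log2fc_te=-1.5, q_rna=0.01, log2fc_rna=1.2)]
        )
        assert dx.classify_te(res)["te_class"].iloc[0] == "te_opposite"

    def test_threshold_edges(self):
        # |lfc| at the cutoff counts; q at the cutoff does not
        res = pd.DataFrame([_result_row(q_rpf=0.01, log2fc_rpf=1.0)])
        assert dx.classify_layers(res)["layer_class"].iloc[0] == "translation_only"
        res = pd.DataFrame([_result_row(q_rpf=0.05, log2fc_rpf=3.0)])
        assert dx.classify_layers(res)["layer_class"].iloc[0] == "unchanged"

    def test_invalid_cuts_rejected(self):
        res = pd.DataFrame([_result_row()])
        with pytest.raises(ValueError):
            dx.classify_layers(res, lfc_cut=-1)
        with pytest.raises(ValueError):
            dx.classify_te(res, q_cut=1.5)

    def test_classes_partition_genes(self, layer_classification, te_classification):
        n = len(layer_classification)
        assert layer_classification["layer_class"].isin(dx.LAYER_CLASSES).all()
        assert layer_classification["layer_class"].value_counts().sum() == n
        assert te_classification["te_class"].isin(dx.TE_CLASSES).all()
        assert te_classification["te_class"].value_counts().sum() == n

    def test_truth_table_recovery(self, paired_truth, layer_classification):
        _, truth = paired_truth
        joint = truth.join(layer_classification)
        for cls in ("translation_only", "transcription_only", "opposite", "concordant"):
            sub = joint[joint.true_class == cls]
            assert (sub.layer_class == cls).mean() >= 0.85, cls
        nulls = joint[joint.true_class == "null"]
        assert (nulls.layer_class == "opposite").mean() <= 0.01
        assert (nulls.layer_class != "unchanged").mean() <= 0.05

    def test_te_only_recovery(self, paired_truth, te_classification):
        _, truth = paired_truth
        joint = truth.join(te_classification)
        sub = joint[joint.true_class == "translation_only"]
        assert (sub.te_class == "te_only").mean() >= 0.85


class TestSelectGenes:
    def test_empty_table(self):
        empty = pd.DataFrame(columns=["te_class", "dir_te", "dir_rna"])
        assert dx.select_genes(empty) == []

    def test_direction_filter(self):
        table = pd.DataFrame(
            {
                "te_class": ["te_only", "te_only"],
                "dir_te": ["down", "up"],
                "dir_rna": ["none", "none"],
            },
            index=["gDown", "gUp"],
        )
        assert dx.select_genes(table, ("te_only",), "down") == ["gDown"]

    def test_unknown_class_rejected(self):
        table = pd.DataFrame({"te_class": [], "dir_te": [], "dir_rna": []})
        with pytest.raises(ValueError, match="unknown class"):
            dx.select_genes(table, ("bogus",), "down")

    def test_matches_brute_force_comprehension(self, te_classification):
        got = dx.select_genes(te_classification, ("te_only", "te_opposite"), "down")
        expected = [
            g
            for g in te_classification.index
            if te_classification.loc[g, "te_class"] in ("te_only", "te_opposite")
            and te_classification.loc[g, "dir_te"] == "down"
        ]
        assert got == expected


class TestBenjaminiHochberg:
    def test_matches_brute_force_step_up(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            p = rng.random(200)
            got = dx.bh_adjust(p)
            # brute-force step-up: q_(i) = min_{j >= i} m p_(j) / j, capped at 1
            m = len(p)
            order = np.argsort(p)
            q_sorted = np.minimum.accumulate(
                [min(1.0, m * p[order[j]] / (j + 1)) for j in range(m - 1, -1, -1)]
            )[::-1]
            expected = np.empty(m)
            expected[order] = q_sorted
            assert np.allclose(got, expected, atol=1e-12)


class TestGlobalTeTest:
    def test_identical_vectors_uninformative(self):
        with pytest.warns(UserWarning, match="tied"):
            stat, p = dx.global_te_test([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert p == 1.0

    def test_exact_small_sample_p(self):
        _, p = dx.global_te_test([1, 2, 3], [10, 20, 30])
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_exact_p_matches_rank_enumeration(self):
        # enumerate all C(6,3) assignments of ranks to the first group and
        # count rank sums at least as extreme as the observed one
        observed = sum([1, 2, 3])  # ranks of group a in the pooled ordering
        total = 0
        extreme = 0
        mean_sum = 3 * 7 / 2
        for combo in itertools.combinations(range(1, 7), 3):
            total += 1
            if abs(sum(combo) - mean_sum) >= abs(observed - mean_sum):
                extreme += 1
        _, p = dx.global_te_test([1, 2, 3], [10, 20, 30])
        assert p == pytest.approx(extreme / total, abs=1e-12)

    def test_null_calibration(self):
        rng = np.random.default_rng(7)
        rejections = 0
        reps = 400
        for _ in range(reps):
            a = rng.normal(size=200)
            b = rng.normal(size=200)
            _, p = dx.global_te_test(a, b)
            rejections += p < 0.05
        assert 0.03 <= rejections / reps <= 0.07

    def test_needs_two_values_per_group(self):
        with pytest.raises(ValueError):
            dx.global_te_test([1.0], [2.0, 3.0])


class TestInvariances:
    def test_sample_rescaling_leaves_results_unchanged(self, paired_truth):
        # median-of-ratios absorbs per-library scale up to a common factor
        # that cancels in every fold change (exactly so at pseudocount 0)
        paired, _ = paired_truth
        keep = (paired.rna > 0).all(axis=1) & (paired.rpf > 0).all(axis=1)
        res = dx.analyze(paired, pseudocount=0.0)
        rna2 = paired.rna.copy()
        rna2.iloc[:, 0] = rna2.iloc[:, 0] * 3  # triple one library
        scaled = PairedCounts(
            rna=rna2,
            rpf=paired.rpf,
            rna_conditions=paired.rna_conditions,
            rpf_conditions=paired.rpf_conditions,
        )
        res2 = dx.analyze(scaled, pseudocount=0.0)
        for col in ("log2fc_rna", "log2fc_rpf", "log2fc_te", "p_rna"):
            assert np.allclose(res.loc[keep, col], res2.loc[keep, col], atol=1e-9)
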