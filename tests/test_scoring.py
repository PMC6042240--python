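import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fibrosig import (
    ExpressionMatrix,
    SignatureDefinition,
    build_control_reference,
    compute_signature_score,
    filter_signature_genes,
)

from conftest import make_annot, random_dataset


def score_oracle(matrix, annot, k_map, mean, sd):
    """Double-loop z-sum, independent of the vectorized implementation."""
    raw = {}
    for s in matrix.sample_ids:
        total = 0.0
        for g in mean:
            x = matrix.data.loc[g, s]
            total += k_map[g] * (x - mean[g]) / sd[g]
        raw[s] = total
    ctr = [s for s in matrix.sample_ids if annot.loc[s, "group"] == "control"]
    cm = np.mean([raw[s] for s in ctr])
    return raw, {s: v - cm for s, v in raw.items()}


class TestFilter:
    @pytest.fixture
    def four_sample_data(self):
        # g_var: the hand-checked CV example; g_const: zero variance; g_zm: zero mean
        matrix = ExpressionMatrix(
            pd.DataFrame(
                {
                    "s1": [1.0, 5.0, -1.0],
                    "s2": [2.0, 5.0, 1.0],
                    "s3": [3.0, 5.0, -2.0],
                    "s4": [10.0, 5.0, 2.0],
                },
                index=["g_var", "g_const", "g_zm"],
            )
        )
        annot = make_annot({"s1": "control", "s2": "control", "s3": "case", "s4": "case"})
        sig = SignatureDefinition("s", [("g_var", 1), ("g_const", 1), ("g_zm", -1), ("g_gone", 1)])
        return matrix, annot, sig

    def test_cv_hand_example_and_degenerate_genes(self, four_sample_data):
        matrix, annot, sig = four_sample_data
        res = filter_signature_genes(matrix, annot, sig, cv_min=0.5, fdr_max=1.0)
        # values (1,2,3,10): mean 4, sample sd sqrt(50/3) -> cv ~ 1.0206
        assert res.table.loc["g_var", "cv"] == pytest.approx(np.sqrt(50 / 3) / 4, rel=1e-12)
        assert res.table.loc["g_var", "cv"] > 0.5
        assert res.table.loc["g_const", "cv"] == 0.0
        assert not res.table.loc["g_const", "kept"]
        reasons = dict(res.dropped)
        assert "zero mean" in reasons["g_zm"]
        assert "absent" in reasons["g_gone"]

    def test_kept_requires_both_conditions(self, four_sample_data):
        matrix, annot, sig = four_sample_data
        strict = filter_signature_genes(matrix, annot, sig, cv_min=0.5, fdr_max=1e-12)
        assert not strict.table["kept"].any()

    def test_bh_q_monotone_and_permissive_thresholds_keep_all(self):
        rng = np.random.default_rng(11)
        matrix, annot = random_dataset(rng, n_genes=10, n_samples=10)
        sig = SignatureDefinition("s", [(g, 1) for g in matrix.gene_ids])
        res = filter_signature_genes(matrix, annot, sig, cv_min=0.0, fdr_max=1.0)
        tab = res.table.sort_values("p_value")
        assert (np.diff(tab["q_value"]) >= -1e-15).all()
        assert (tab["q_value"] >= tab["p_value"] - 1e-15).all()
        assert res.table["kept"].all() or (res.table.loc[~res.table["kept"], "q_value"] >= 1.0).all()

    def test_too_few_samples_per_group(self, four_sample_data):
        matrix, annot, sig = four_sample_data
        annot = annot.copy()
        annot.loc["s2", "group"] = "case"
        with pytest.raises(ValueError, match=">= 2 samples per group"):
            filter_signature_genes(matrix, annot, sig)

    def test_rank_test_alternative(self, four_sample_data):
        matrix, annot, sig = four_sample_data
        res = filter_signature_genes(matrix, annot, sig, test="mannwhitney", fdr_max=1.0)
        assert set(res.table.columns) == {"cv", "p_value", "q_value", "kept"}


class TestControlReference:
    def test_two_point_sd_and_zero_sd_exclusion(self):
        matrix = ExpressionMatrix(
            pd.DataFrame(
                {"c1": [1.0, 2.0], "c2": [3.0, 2.0], "p1": [9.0, 9.0]},
                index=["g1", "g2"],
            )
        )
        annot = make_annot({"c1": "control", "c2": "control", "p1": "case"})
        ref = build_control_reference(matrix, annot, ["g1", "g2"])
        assert ref.gene_ids == ["g1"]
        assert ref.mean_ctr[0] == pytest.approx(2.0)
        assert ref.sd_ctr[0] == pytest.approx(np.sqrt(2.0))
        assert ref.excluded == [("g2", "zero control SD")]

    def test_all_genes_excluded_is_hard_error(self):
        matrix = ExpressionMatrix(
            pd.DataFrame({"c1": [2.0], "c2": [2.0], "p1": [5.0]}, index=["g1"])
        )
        annot = make_annot({"c1": "control", "c2": "control", "p1": "case"})
        with pytest.raises(ValueError, match="no scoreable genes"):
            build_control_reference(matrix, annot, ["g1"])

    def test_control_only_means_equal_row_means(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(4, 6)), index=list("abcd"), columns=[f"c{i}" for i in range(6)])
        matrix = ExpressionMatrix(df)
        annot = make_annot({s: "control" for s in matrix.sample_ids})
        ref = build_control_reference(matrix, annot, matrix.gene_ids)
        np.testing.assert_allclose(ref.mean_ctr, df.mean(axis=1).to_numpy())


class TestScore:
    def test_toy_worked_example(self, toy_scoring_data):
        matrix, annot, sig = toy_scoring_data
        ref = build_control_reference(matrix, annot, sig.genes)
        sv = compute_signature_score(matrix, annot, sig, ref)
        assert sv.normalized.loc["p1"] == pytest.approx(2 * np.sqrt(2), rel=1e-12)
        assert sv.raw.loc["c1"] == pytest.approx(0.0, abs=1e-12)
        assert sv.raw.loc["c2"] == pytest.approx(0.0, abs=1e-12)
        assert sv.control_mean_raw == pytest.approx(0.0, abs=1e-12)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            matrix, annot = random_dataset(rng)
            ks = {g: int(rng.choice([1, -1])) for g in matrix.gene_ids}
            sig = SignatureDefinition("s", list(ks.items()))
            ref = build_control_reference(matrix, annot, matrix.gene_ids)
            sv = compute_signature_score(matrix, annot, sig, ref)
            mean = dict(zip(ref.gene_ids, ref.mean_ctr))
            sd = dict(zip(ref.gene_ids, ref.sd_ctr))
            raw, norm = score_oracle(matrix, annot, ks, mean, sd)
            for i, s in enumerate(sv.sample_ids):
                assert sv.raw_score[i] == pytest.approx(raw[s], rel=1e-10)
                assert sv.normalized_score[i] == pytest.approx(norm[s], rel=1e-10, abs=1e-10)

    def test_control_mean_of_normalized_is_zero(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            matrix, annot = random_dataset(rng)
            sig = SignatureDefinition("s", [(g, 1) for g in matrix.gene_ids])
            ref = build_control_reference(matrix, annot, matrix.gene_ids)
            sv = compute_signature_score(matrix, annot, sig, ref)
            ctr = annot.index[annot["group"] == "control"]
            assert abs(sv.normalized.loc[ctr].mean()) < 1e-10

    def test_flipping_k_negates_scores(self):
        rng = np.random.default_rng(2)
        matrix, annot = random_dataset(rng, n_genes=6, n_samples=8)
        sig = SignatureDefinition("s", [(g, 1) for g in matrix.gene_ids])
        flipped = SignatureDefinition("s", [(g, -1) for g in matrix.gene_ids])
        ref = build_control_reference(matrix, annot, matrix.gene_ids)
        a = compute_signature_score(matrix, annot, sig, ref)
        b = compute_signature_score(matrix, annot, flipped, ref)
        np.testing.assert_allclose(a.raw_score, -b.raw_score, rtol=1e-12)
        np.testing.assert_allclose(a.normalized_score, -b.normalized_score, rtol=1e-12, atol=1e-12)

    def test_affine_invariance_per_gene(self):
        rng = np.random.default_rng(3)
        matrix, annot = random_dataset(rng, n_genes=5, n_samples=9)
        sig = SignatureDefinition("s", [(g, int(k)) for g, k in zip(matrix.gene_ids, rng.choice([1, -1], 5))])
        ref = build_control_reference(matrix, annot, matrix.gene_ids)
        base = compute_signature_score(matrix, annot, sig, ref)
        shifted = matrix.data.copy()
        shifted.loc["g2"] = shifted.loc["g2"] * 3.7 + 12.0  # positive scale + shift
        m2 = ExpressionMatrix(shifted)
        ref2 = build_control_reference(m2, annot, m2.gene_ids)
        moved = compute_signature_score(m2, annot, sig, ref2)
        np.testing.assert_allclose(moved.raw_score, base.raw_score, atol=1e-8)
        np.testing.assert_allclose(moved.normalized_score, base.normalized_score, atol=1e-8)

    def test_monotonicity_in_gene_value(self, toy_scoring_data):
        matrix, annot, sig = toy_scoring_data
        ref = build_control_reference(matrix, annot, sig.genes)
        base = compute_signature_score(matrix, annot, sig, ref).normalized.loc["p1"]
        up = matrix.data.copy()
        up.loc["g1", "p1"] += 1.0  # k=+1 gene
        higher = compute_signature_score(ExpressionMatrix(up), annot, sig, ref).normalized.loc["p1"]
        assert higher > base
        down = matrix.data.copy()
        down.loc["g2", "p1"] += 1.0  # k=-1 gene
        lower = compute_signature_score(ExpressionMatrix(down), annot, sig, ref).normalized.loc["p1"]
        assert lower < base

    def test_unannotated_sample_is_hard_error(self, toy_scoring_data):
        matrix, annot, sig = toy_scoring_data
        ref = build_control_reference(matrix, annot, sig.genes)
        with pytest.raises(ValueError, match="absent from annotation"):
            compute_signature_score(matrix, annot.drop("p1"), sig, ref)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        seed=st.integers(0, 2**31 - 1),
        scale=st.floats(0.01, 100.0),
        shift=st.floats(-50.0, 50.0),
    )
    def test_score_affine_invariance_property(self, seed, scale, shift):
        """Per-gene affine rescaling (reference rebuilt) never moves any score."""
        rng = np.random.default_rng(seed)
        matrix, annot = random_dataset(rng, n_genes=4, n_samples=6)
        sig = SignatureDefinition("s", [(g, int(k)) for g, k in zip(matrix.gene_ids, rng.choice([1, -1], 4))])
        ref = build_control_reference(matrix, annot, matrix.gene_ids)
        base = compute_signature_score(matrix, annot, sig, ref)
        df = matrix.data.copy()
        df.loc["g0"] = df.loc["g0"] * scale + shift
        ref2 = build_control_reference(ExpressionMatrix(df), annot, matrix.gene_ids)
        moved = compute_signature_score(ExpressionMatrix(df), annot, sig, ref2)
        np.testing.assert_allclose(moved.normalized_score, base.normalized_score, atol=1e-6)

    def test_normalize_none_keeps_raw(self, toy_scoring_data):
        matrix, annot, sig = toy_scoring_data
        ref = build_control_reference(matrix, annot, sig.genes)
        sv = compute_signature_score(matrix, annot, sig, ref, normalize="none")
        np.testing.assert_array_equal(sv.raw_score, sv.normalized_score)
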