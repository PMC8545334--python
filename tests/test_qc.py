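import numpy as np
import pandas as pd
import pytest

from conftest import make_matrix
from proteoflow import ExpressionMatrix, SampleDesign, qc
from proteoflow.errors import DesignError, ParameterError, ValidationError


class TestFilterMissing:
    def test_hand_counted_toy(self, toy_matrix):
        out, report = qc.filter_missing(toy_matrix, cutoff=0.25)
        assert out.n_proteins == 2
        assert report.removed == ["prot_half", "prot_empty"]
        assert report.n_kept == 2 and report.n_removed == 2

    def test_cutoff_one_keeps_everything(self, toy_matrix):
        out, _ = qc.filter_missing(toy_matrix, cutoff=1.0)
        assert out.n_proteins == toy_matrix.n_proteins

    def test_cutoff_zero_keeps_complete_rows_only(self, toy_matrix):
        out, _ = qc.filter_missing(toy_matrix, cutoff=0.0)
        assert out.protein_ids == ["prot_full"]

    def test_idempotent(self, toy_matrix):
        once, _ = qc.filter_missing(toy_matrix, cutoff=0.25)
        twice, _ = qc.filter_missing(once, cutoff=0.25)
        assert once.equals(twice)

    def test_per_group_keeps_proteins_quantifiable_in_one_condition(self):
        # complete in group A, fully missing in group B
        vals = pd.DataFrame(
            [[1.0, 2.0, np.nan, np.nan]],
            index=["p"], columns=["a1", "a2", "b1", "b2"],
        )
        m = ExpressionMatrix(vals)
        design = SampleDesign(["a1", "a2", "b1", "b2"], ["A", "A", "B", "B"])
        overall, _ = qc.filter_missing(m, cutoff=0.25, scope="overall")
        per_group, _ = qc.filter_missing(m, cutoff=0.25, scope="per_group",
                                         design=design)
        assert overall.n_proteins == 0
        assert per_group.n_proteins == 1

    @pytest.mark.parametrize("bad", [-0.1, 1.5])
    def test_cutoff_range_checked(self, toy_matrix, bad):
        with pytest.raises(ParameterError):
            qc.filter_missing(toy_matrix, cutoff=bad)


class TestPCA:
    def test_masked_cells_rejected(self, toy_matrix):
        with pytest.raises(ValidationError, match="complete"):
            qc.run_pca(toy_matrix)

    def test_duplicated_samples_have_equal_scores(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(30, 3))
        m = make_matrix(np.hstack([base, base]))  # samples duplicated in pairs
        res = qc.run_pca(m)
        s = res.scores.to_numpy()
        assert np.allclose(s[:3], s[3:])

    def test_rank_one_matrix_explains_everything_on_pc1(self):
        u = np.arange(1, 11, dtype=float)
        v = np.array([1.0, -2.0, 0.5, 3.0])
        m = make_matrix(np.outer(u, v))
        res = qc.run_pca(m)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-12)

    def test_full_rank_reconstruction_and_orthogonality(self):
        rng = np.random.default_rng(7)
        m = make_matrix(rng.normal(size=(50, 10)))  # 10 samples x 50 proteins
        res = qc.run_pca(m)
        X = m.values.to_numpy().T
        Xc = X - X.mean(axis=0)
        rec = res.scores.to_numpy() @ res.loadings.to_numpy().T
        assert np.max(np.abs(rec - Xc)) < 1e-10
        gram = res.scores.to_numpy().T @ res.scores.to_numpy()
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0)
        assert np.all(np.diff(res.explained_variance_ratio) <= 1e-12)

    def test_matches_sklearn(self):
        sklearn_pca = pytest.importorskip("sklearn.decomposition").PCA
        rng = np.random.default_rng(11)
        m = make_matrix(rng.normal(size=(40, 8)))
        ours = qc.run_pca(m)
        ref = sklearn_pca(n_components=7).fit(m.values.to_numpy().T)
        assert np.allclose(
            ours.explained_variance_ratio[:7], ref.explained_variance_ratio_,
            atol=1e-10,
        )
        # scores agree up to the fixed sign convention
        ref_scores = ref.transform(m.values.to_numpy().T)
        for j in range(7):
            a, b = ours.scores.to_numpy()[:, j], ref_scores[:, j]
            assert np.allclose(a, b, atol=1e-8) or np.allclose(a, -b, atol=1e-8)


class TestMultilevelPCA:
    def paired(self, n_subj=4, n_prot=20, seed=3, subject_sd=3.0, effect=0.4):
        rng = np.random.default_rng(seed)
        samples = [f"{c}{i}" for c in "AB" for i in range(n_subj)]
        conditions = ["A"] * n_subj + ["B"] * n_subj
        subjects = [f"s{i}" for i in range(n_subj)] * 2
        subj_eff = rng.normal(0, subject_sd, size=(n_prot, n_subj))
        X = rng.normal(0, 0.3, size=(n_prot, 2 * n_subj))
        X += np.hstack([subj_eff, subj_eff])
        X[: n_prot // 2, n_subj:] += effect
        m = make_matrix(X, samples=samples)
        return m, SampleDesign(samples, conditions, subjects)

    def test_deviations_sum_to_zero_per_subject(self):
        m, design = self.paired()
        within = qc.within_subject_deviations(m, design)
        subj = design.subject_map()
        for s in set(subj.values()):
            cols = [c for c in m.sample_ids if subj[c] == s]
            assert np.allclose(within.values[cols].sum(axis=1), 0, atol=1e-12)

    def test_invariant_to_per_subject_constant_shifts(self):
        m, design = self.paired()
        shifted = m.values.copy()
        shifts = {"s0": 5.0, "s1": -2.0, "s2": 100.0, "s3": 0.25}
        for col in shifted.columns:
            shifted[col] += shifts[design.subject_map()[col]]
        from proteoflow import ExpressionMatrix
        a = qc.run_multilevel_pca(m, design)
        b = qc.run_multilevel_pca(ExpressionMatrix(shifted), design)
        assert np.allclose(a.scores.to_numpy(), b.scores.to_numpy(), atol=1e-8)

    def test_identical_offsets_give_identical_within_rows(self):
        # two subjects with the same within-subject offsets
        offsets = np.array([[1.0, -1.0], [0.5, -0.5], [2.0, -2.0]])
        X = np.hstack([offsets + 10.0, offsets - 3.0])  # subject means differ
        samples = ["s1a", "s1b", "s2a", "s2b"]
        X = X.reshape(3, 4)
        m = make_matrix(X, samples=samples)
        design = SampleDesign(samples, ["A", "B", "A", "B"],
                              ["s1", "s1", "s2", "s2"])
        within = qc.within_subject_deviations(m, design)
        w = within.values.to_numpy()
        assert np.allclose(w[:, :2], w[:, 2:])

    def test_condition_separation_beats_standard_pca(self):
        m, design = self.paired(n_subj=6, n_prot=60, seed=9,
                                subject_sd=4.0, effect=0.6)
        std = qc.run_pca(m)
        ml = qc.run_multilevel_pca(m, design)
        is_b = np.array([c == "B" for c in design.conditions])

        def pc1_separation(res):
            pc1 = res.scores.to_numpy()[:, 0]
            a, b = pc1[~is_b], pc1[is_b]
            pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
            return abs(a.mean() - b.mean()) / pooled

        assert pc1_separation(ml) > pc1_separation(std)

    def test_singleton_subject_rejected(self):
        samples = ["a1", "a2", "b1"]
        design = SampleDesign(samples, ["A", "A", "B"], ["s1", "s2", "s1"])
        m = make_matrix(np.zeros((3, 3)), samples=samples)
        with pytest.raises(DesignError):
            qc.within_subject_deviations(m, design)


class TestSampleDesign:
    def test_duplicate_samples_rejected(self):
        with pytest.raises(DesignError):
            SampleDesign(["a", "a"], ["A", "B"])

    def test_partial_subjects_rejected(self):
        with pytest.raises(DesignError):
            SampleDesign(["a", "b"], ["A", "B"], ["s1", ""])
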