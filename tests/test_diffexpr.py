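import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from txrestore.diffexpr import (
    ContrastResult,
    adjust_bh,
    compute_contrast,
    fit_variance_prior,
)
from txrestore.errors import DesignError, ZeroVarianceWarning
from txrestore.io import ExpressionMatrix, StudyDesign

from .oracles import brute_force_bh


def _two_group(data: np.ndarray, n_a=3, n_b=3):
    cols = [f"A{i + 1}" for i in range(n_a)] + [f"B{i + 1}" for i in range(n_b)]
    matrix = ExpressionMatrix(
        pd.DataFrame(data, index=[f"g{i:03d}" for i in range(len(data))], columns=cols)
    )
    design = StudyDesign(
        sample_to_group={c: c[0] for c in cols}, baseline_group="B", disease_group="A"
    )
    return matrix, design


class TestOrdinaryT:
    def test_identical_groups_give_null_results(self):
        block = np.random.default_rng(0).normal(8, 1, (20, 3))
        matrix, design = _two_group(np.hstack([block, block]))
        res = compute_contrast(matrix, design, "A", "B", moderation="ordinary")
        assert (res.table["logFC"] == 0).all()
        assert (res.table["p"] == 1).all()
        assert (res.table["adj_p"] == 1).all()

    def test_single_gene_pooled_t_worked_example(self):
        # A = (2, 4, 6), B = (1, 3, 5): logFC = 1, pooled s^2 = 4,
        # SE = 2*sqrt(2/3), t = 0.6124, df = 4, two-sided p ~ 0.573
        matrix, design = _two_group(np.array([[2.0, 4, 6, 1, 3, 5]] * 2))
        res = compute_contrast(matrix, design, "A", "B", moderation="ordinary")
        row = res.table.iloc[0]
        assert row["logFC"] == pytest.approx(1.0)
        assert row["t"] == pytest.approx(1 / (2 * np.sqrt(2 / 3)), abs=1e-9)
        assert row["df"] == 4
        # cross-check p against an independent statistics routine
        t_ref, p_ref = stats.ttest_ind([2, 4, 6], [1, 3, 5], equal_var=True)
        assert row["t"] == pytest.approx(t_ref, abs=1e-12)
        assert row["p"] == pytest.approx(p_ref, abs=1e-12)
        assert row["p"] == pytest.approx(0.573, abs=5e-4)

    def test_antisymmetry_of_contrast_direction(self, two_group_matrix):
        matrix, design = two_group_matrix
        ab = compute_contrast(matrix, design, "A", "B", moderation="ordinary")
        ba = compute_contrast(matrix, design, "B", "A", moderation="ordinary")
        np.testing.assert_allclose(
            ab.table["logFC"], -ba.table["logFC"], atol=1e-12
        )
        np.testing.assert_allclose(ab.table["p"], ba.table["p"], atol=1e-12)

    def test_zero_variance_handling(self):
        rng = np.random.default_rng(1)
        data = rng.normal(8, 1, (10, 6))
        data[0] = [5, 5, 5, 5, 5, 5]  # no change, no variance
        data[1] = [5, 5, 5, 3, 3, 3]  # change, no variance
        matrix, design = _two_group(data)
        with pytest.warns(ZeroVarianceWarning):
            res = compute_contrast(matrix, design, "A", "B", moderation="ordinary")
        assert res.table.iloc[0]["t"] == 0
        assert res.table.iloc[0]["p"] == 1
        row1 = res.table.iloc[1]
        assert row1["logFC"] == 2
        assert 0 < row1["p"] < 0.05  # moderated fallback finds the shift

    def test_unknown_group_is_design_error(self, two_group_matrix):
        matrix, design = two_group_matrix
        with pytest.raises(DesignError):
            compute_contrast(matrix, design, "A", "NOPE")


class TestModeratedT:
    @staticmethod
    def _limma_style_fixture():
        """Heteroscedastic 60-gene two-group fixture (fixed seed)."""
        rng = np.random.default_rng(2024)
        n = 60
        base = rng.normal(8, 1.5, n)
        delta = np.where(rng.random(n) < 0.3, rng.uniform(-2, 2, n), 0.0)
        sd = 0.3 * np.sqrt(6 / rng.chisquare(6, n))
        a = base[:, None] + delta[:, None] + rng.normal(0, 1, (n, 3)) * sd[:, None]
        b = base[:, None] + rng.normal(0, 1, (n, 3)) * sd[:, None]
        return _two_group(np.hstack([a, b]))

    def test_matches_independent_empirical_bayes_reference(self):
        """Frozen expected values computed with the reference empirical-Bayes
        moderated-t implementation (R limma eBayes) on this exact fixture."""
        matrix, design = self._limma_style_fixture()
        res = compute_contrast(matrix, design, "A", "B", moderation="moderated")
        d0, s0_sq = fit_variance_prior(
            pooled_s2(matrix, design), df=4.0
        )
        assert d0 == pytest.approx(3.5739658602, abs=1e-8)
        assert s0_sq == pytest.approx(0.0841884995, abs=1e-8)
        expected = {
            # gene: (logFC, t, p) from the reference implementation
            "g000": (0.0493005884, 0.1570836659, 8.792852e-01),
            "g002": (-0.9602883481, -3.8979420794, 5.070142e-03),
            "g010": (0.0647326473, 0.2393956200, 8.171492e-01),
            "g042": (0.2275260877, 1.1837379296, 2.723343e-01),
        }
        for gene, (logfc, t, p) in expected.items():
            row = res.table.loc[gene]
            assert row["logFC"] == pytest.approx(logfc, abs=1e-8)
            assert row["t"] == pytest.approx(t, abs=1e-8)
            assert row["p"] == pytest.approx(p, rel=1e-5)
            assert row["df"] == pytest.approx(4 + 3.5739658602, abs=1e-8)

    def test_shared_variance_limit_uses_prior_only(self):
        # every gene has the same pooled variance -> d0 = inf and
        # t = logFC / (s0 * sqrt(1/n_a + 1/n_b)) for all genes
        rng = np.random.default_rng(5)
        shifts = rng.normal(0, 1, 20)
        a = np.column_stack([shifts + 0, shifts + 1, shifts + 2])
        b = np.zeros((20, 3)) + np.array([0.0, 1.0, 2.0])
        matrix, design = _two_group(np.hstack([a, b]))
        s2 = pooled_s2(matrix, design)
        d0, s0_sq = fit_variance_prior(s2, df=4.0)
        assert np.isinf(d0)
        res = compute_contrast(matrix, design, "A", "B", moderation="moderated")
        expected_t = res.table["logFC"] / (np.sqrt(s0_sq) * np.sqrt(2 / 3))
        np.testing.assert_allclose(res.table["t"], expected_t, atol=1e-10)

    def test_converges_to_ordinary_t_with_many_replicates(self):
        """Shrinkage washes out as replication grows: the worst-case gap
        between moderated and ordinary t shrinks and is small at n=50."""
        rng = np.random.default_rng(8)

        def max_gap(n_rep):
            data = rng.normal(8, 0.5, (200, 2 * n_rep))
            matrix, design = _two_group(data, n_a=n_rep, n_b=n_rep)
            mod = compute_contrast(matrix, design, "A", "B", moderation="moderated")
            ordi = compute_contrast(matrix, design, "A", "B", moderation="ordinary")
            return np.abs(mod.table["t"] - ordi.table["t"]).max()

        gap_small, gap_large = max_gap(4), max_gap(50)
        assert gap_large < gap_small
        assert gap_large < 0.5


def pooled_s2(matrix, design):
    a = matrix.subset_samples(design.samples_of("A")).values
    b = matrix.subset_samples(design.samples_of("B")).values
    return (
        ((a - a.mean(1, keepdims=True)) ** 2).sum(1)
        + ((b - b.mean(1, keepdims=True)) ** 2).sum(1)
    ) / (a.shape[1] + b.shape[1] - 2)


class TestAdjustBH:
    def test_step_up_worked_example(self):
        np.testing.assert_allclose(
            adjust_bh([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_is_identity(self):
        np.testing.assert_allclose(adjust_bh([1.0]), [1.0])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(1000):
            p = rng.random(rng.integers(1, 50))
            np.testing.assert_allclose(adjust_bh(p), brute_force_bh(p), atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.5])

    @settings(derandomize=True, max_examples=50)
    @given(
        p=st.lists(st.floats(0.001, 0.999), min_size=2, max_size=20),
        idx=st.integers(0, 19),
        bump=st.floats(0.001, 0.5),
    )
    def test_monotone_in_inputs(self, p, idx, bump):
        """Raising any single input p never lowers any adjusted p."""
        idx = idx % len(p)
        before = adjust_bh(p)
        p2 = list(p)
        p2[idx] = min(1.0, p2[idx] + bump)
        after = adjust_bh(p2)
        assert (after >= before - 1e-12).all()


class TestContrastInvariants:
    def test_adj_p_bounds_and_monotonicity(self, two_group_matrix):
        matrix, design = two_group_matrix
        res = compute_contrast(matrix, design, "A", "B")
        tbl = res.table.sort_values("p")
        assert (tbl["adj_p"] >= tbl["p"] - 1e-15).all()
        assert (tbl["adj_p"] <= 1).all()
        assert (np.diff(tbl["adj_p"]) >= -1e-15).all()
        assert ((tbl["p"] > 0) & (tbl["p"] <= 1)).all()

    def test_round_trip_through_frame(self, two_group_matrix):
        matrix, design = two_group_matrix
        res = compute_contrast(matrix, design, "A", "B")
        back = ContrastResult.from_frame(res.contrast_id, res.to_frame())
        pd.testing.assert_frame_equal(back.table, res.table, check_names=False)
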