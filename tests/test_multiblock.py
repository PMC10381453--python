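"""Multi-block contracts: Frobenius scaling, degenerate one-block fusion,
block-weight symmetry, the X'y super-weight oracle, block-scale invariance,
and correlation-loading geometry."""

import numpy as np
import pytest

import cartifuse as cf
from cartifuse.blocks import BlockSet
from conftest import make_block


def make_blockset(rng, shapes=((30, 12), (30, 8)), names=("A", "B")):
    blocks = []
    keys = [(f"s{i}", 0) for i in range(shapes[0][0])]
    for (n, p), name in zip(shapes, names):
        b = make_block(rng.normal(size=(n, p)), modality=name)
        b.row_keys = keys
        blocks.append(b)
    return BlockSet(blocks)


def labels_for(n, rng):
    y = (rng.random(n) < 0.5).astype(int)
    y[:2] = [0, 1]
    return y


class TestFrobeniusScale:
    def test_three_four_example(self):
        bs = BlockSet([make_block([[3.0, 4.0], [0.0, 0.0]], modality="A")])
        scaled, norms = cf.frobenius_scale(bs)
        assert norms["A"] == 5.0
        np.testing.assert_allclose(
            scaled.blocks[0].intensities, [[0.6, 0.8], [0.0, 0.0]]
        )

    def test_unit_norm_contract(self, rng):
        bs = make_blockset(rng)
        scaled, _ = cf.frobenius_scale(bs)
        for b in scaled.blocks:
            assert abs(np.linalg.norm(b.intensities) - 1.0) < 1e-12

    def test_scalar_multiples_scale_identically(self, rng):
        X = rng.normal(size=(10, 6))
        b1 = make_block(X, modality="A")
        b2 = make_block(X * 13.0, modality="A")
        s1, _ = cf.frobenius_scale(BlockSet([b1]))
        s2, _ = cf.frobenius_scale(BlockSet([b2]))
        np.testing.assert_allclose(
            s1.blocks[0].intensities, s2.blocks[0].intensities, atol=1e-12
        )

    def test_zero_norm_rejected(self):
        bs = BlockSet([make_block(np.zeros((3, 4)), modality="A")])
        with pytest.raises(ValueError, match="zero"):
            cf.frobenius_scale(bs)

    def test_training_norms_applied_to_new_rows(self, rng):
        bs = make_blockset(rng, shapes=((10, 5),), names=("A",))
        _, norms = cf.frobenius_scale(bs)
        other = make_blockset(rng, shapes=((4, 5),), names=("A",))
        scaled, used = cf.frobenius_scale(other, norms)
        assert used == norms
        np.testing.assert_allclose(
            scaled.blocks[0].intensities,
            other.blocks[0].intensities / norms["A"],
        )


class TestFitMBPLS:
    def test_one_block_fusion_degenerates_to_pls(self, rng):
        bs = make_blockset(rng, shapes=((25, 15),), names=("A",))
        y = labels_for(25, rng)
        mb = cf.fit_mbpls(bs, y, A=4)
        scaled, _ = cf.frobenius_scale(bs)
        plain = cf.fit_pls(scaled.blocks[0].intensities, y, A=4)
        np.testing.assert_allclose(
            mb.predict(bs), plain.predict(scaled.blocks[0].intensities), atol=1e-10
        )
        np.testing.assert_allclose(mb.block_weights, np.ones((1, 4)), atol=1e-12)

    def test_duplicated_block_weights_split_evenly(self, rng):
        X = rng.normal(size=(25, 10))
        keys = [(f"s{i}", 0) for i in range(25)]
        b1 = make_block(X, modality="A"); b1.row_keys = keys
        b2 = make_block(X.copy(), modality="B"); b2.row_keys = keys
        y = labels_for(25, rng)
        mb = cf.fit_mbpls(BlockSet([b1, b2]), y, A=3)
        np.testing.assert_allclose(mb.block_weights, 0.5, atol=1e-8)

    def test_block_weight_columns_sum_to_one(self, rng):
        bs = make_blockset(rng, shapes=((30, 12), (30, 8)), names=("A", "B"))
        mb = cf.fit_mbpls(bs, labels_for(30, rng), A=5)
        w = mb.block_weights
        assert np.all(w >= 0) and np.all(w <= 1)
        np.testing.assert_allclose(w.sum(axis=0), 1.0, atol=1e-12)

    def test_informative_block_dominates_lv1_with_xty_oracle(self, rng):
        """Only block A carries the class effect; its LV-1 weight must exceed
        the others', and the super-weight must equal normalised X'y."""
        n = 40
        y = np.array([0, 1] * 20)
        keys = [(f"s{i}", 0) for i in range(n)]
        A = rng.normal(size=(n, 10)) + 3.0 * (y - y.mean())[:, None]
        B = rng.normal(size=(n, 10))
        C = rng.normal(size=(n, 10))
        blocks = []
        for name, X in (("A", A), ("B", B), ("C", C)):
            b = make_block(X, modality=name); b.row_keys = keys
            blocks.append(b)
        bs = BlockSet(blocks)
        mb = cf.fit_mbpls(bs, y, A=2)
        w = mb.block_weights[:, 0]
        assert w[0] > w[1] and w[0] > w[2]
        # brute-force oracle: first super-weight is X_scaled' y_c, unit norm
        scaled, _ = cf.frobenius_scale(bs)
        Xs = scaled.concatenate()
        Xc = Xs - Xs.mean(axis=0)
        w_oracle = Xc.T @ (y - y.mean())
        w_oracle /= np.linalg.norm(w_oracle)
        np.testing.assert_allclose(np.abs(mb.inner.W[:, 0]), np.abs(w_oracle), atol=1e-10)

    def test_concatenated_pls_equivalence(self, rng):
        bs = make_blockset(rng, shapes=((30, 12), (30, 8)), names=("A", "B"))
        y = labels_for(30, rng)
        mb = cf.fit_mbpls(bs, y, A=4)
        scaled, _ = cf.frobenius_scale(bs)
        plain = cf.fit_pls(scaled.concatenate(), y, A=4)
        np.testing.assert_allclose(
            mb.predict(bs), plain.predict(scaled.concatenate()), atol=1e-12
        )

    def test_mismatched_row_keys_rejected(self, rng):
        b1 = make_block(rng.normal(size=(5, 4)), modality="A")
        b2 = make_block(rng.normal(size=(5, 4)), modality="B")
        b2.row_keys = [(f"t{i}", 0) for i in range(5)]
        with pytest.raises(ValueError, match="correspondence"):
            BlockSet([b1, b2])


class TestBlockScaleInvariance:
    def test_scaling_one_block_changes_nothing(self, rng):
        bs = make_blockset(rng, shapes=((30, 12), (30, 8)), names=("A", "B"))
        y = labels_for(30, rng)
        scaled_input = BlockSet(
            [bs.blocks[0].with_data(intensities=bs.blocks[0].intensities * 1e3),
             bs.blocks[1]]
        )
        m1 = cf.fit_mbpls(bs, y, A=3)
        m2 = cf.fit_mbpls(scaled_input, y, A=3)
        np.testing.assert_allclose(m2.predict(scaled_input), m1.predict(bs), atol=1e-8)
        np.testing.assert_allclose(m2.block_weights, m1.block_weights, atol=1e-8)
        V = rng.normal(size=(30, 4))
        np.testing.assert_allclose(
            cf.correlation_loadings(m2, V), cf.correlation_loadings(m1, V), atol=1e-8
        )


class TestCorrelationLoadings:
    def fitted(self, rng):
        bs = make_blockset(rng, shapes=((30, 12),), names=("A",))
        return cf.fit_mbpls(bs, labels_for(30, rng), A=3)

    def test_score_itself_maps_to_unit_circle(self, rng):
        mb = self.fitted(rng)
        t1 = mb.inner.T[:, 0]
        R = cf.correlation_loadings(mb, t1[:, None])
        np.testing.assert_allclose(R[0, 0], 1.0, atol=1e-10)
        np.testing.assert_allclose(R[0, 1], 0.0, atol=1e-8)

    def test_orthogonal_variable_maps_to_origin(self, rng):
        mb = self.fitted(rng)
        T = mb.inner.T[:, :2]
        v = rng.normal(size=30)
        vc = v - v.mean()
        Tc = T - T.mean(axis=0)
        v_orth = vc - Tc @ np.linalg.lstsq(Tc, vc, rcond=None)[0]
        R = cf.correlation_loadings(mb, v_orth[:, None])
        np.testing.assert_allclose(R[0], 0.0, atol=1e-8)

    def test_loadings_inside_unit_disc(self, rng):
        mb = self.fitted(rng)
        V = rng.normal(size=(30, 20))
        R = cf.correlation_loadings(mb, V)
        assert np.all(R[:, 0] ** 2 + R[:, 1] ** 2 <= 1 + 1e-12)

    def test_zero_variance_variable_is_missing_not_zero(self, rng):
        mb = self.fitted(rng)
        V = np.column_stack([np.full(30, 2.0), rng.normal(size=30)])
        R = cf.correlation_loadings(mb, V)
        assert np.isnan(R[0]).all()
        assert np.isfinite(R[1]).all()

    def test_matches_direct_pearson_oracle(self, rng):
        from scipy.stats import pearsonr

        mb = self.fitted(rng)
        V = rng.normal(size=(30, 5))
        R = cf.correlation_loadings(mb, V, lv_pair=(1, 3))
        for j in range(5):
            assert abs(R[j, 0] - pearsonr(V[:, j], mb.inner.T[:, 0]).statistic) < 1e-10
            assert abs(R[j, 1] - pearsonr(V[:, j], mb.inner.T[:, 2]).statistic) < 1e-10

    def test_unavailable_lv_rejected(self, rng):
        mb = self.fitted(rng)
        with pytest.raises(ValueError, match="LV"):
            cf.correlation_loadings(mb, rng.normal(size=(30, 2)), lv_pair=(1, 9))


def test_e1_subgroup_correlates_most_on_shifted_study(strong_study, strong_prepared):
    """The E1 subgroup carries an extra amplitude shift in the generator, so
    its design dummy must correlate with the first two global scores more
    strongly than the other subgroups' dummies (direct Pearson oracle)."""
    design = strong_study.design
    y = design.labels
    mb = cf.fit_mbpls(strong_prepared, y, A=4)
    dummies = {
        g: (design.subgroups == g).astype(float) for g in ("M1", "M2", "E1", "E2", "E3")
    }
    V = np.column_stack(list(dummies.values()))
    R = cf.correlation_loadings(mb, V)
    names = list(dummies)
    e1_row = np.abs(R[names.index("E1")])
    other_rows = np.abs(np.delete(R, names.index("E1"), axis=0))
    # on at least one of the two LVs E1 beats every other subgroup
    dominates = [(e1_row[j] > other_rows[:, j]).all() for j in (0, 1)]
    assert any(dominates)
    # oracle: plain Pearson against the score vectors
    t1 = mb.inner.T[:, 0]
    r_direct = np.corrcoef(dummies["E1"], t1)[0, 1]
    assert abs(R[names.index("E1"), 0] - r_direct) < 1e-10
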