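"""Unit and property tests for the constraint-matrix-equation machinery."""

import numpy as np
import pytest
import statsmodels.api as sm

from r2parse import corrmath as cm


class TestMultipleR2:
    @pytest.mark.parametrize(
        "c, r, expected",
        [
            ([0.5], [[1.0]], 0.25),
            ([0.3, 0.4], np.eye(2), 0.25),
        ],
    )
    def test_known_values(self, c, r, expected):
        assert cm.multiple_r2(c, r) == pytest.approx(expected, abs=1e-12)

    def test_matches_ols_r_squared(self, rng):
        """R2_M from correlations equals the OLS R2 of a two-predictor fit."""
        block_corr = np.array([[1.0, 0.4], [0.4, 1.0]])
        chol = np.linalg.cholesky(block_corr)
        g = rng.normal(size=(1000, 2)) @ chol.T
        y = 0.5 * g[:, 0] + 0.3 * g[:, 1] + rng.normal(size=1000)
        full = np.corrcoef(np.column_stack([y, g]), rowvar=False)
        r2m = cm.multiple_r2(full[0, 1:], full[1:, 1:])
        ols = sm.OLS(y, sm.add_constant(g)).fit()
        assert r2m == pytest.approx(ols.rsquared, abs=1e-6)

    def test_degenerate_ld_rejected_naming_pair(self):
        r = np.array([[1.0, 1.0 - 1e-13], [1.0 - 1e-13, 1.0]])
        with pytest.raises(cm.CollinearityError, match=r"\(0, 1\)"):
            cm.multiple_r2([0.5, 0.5], r)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            cm.multiple_r2([0.5, 0.3], [[1.0]])


class TestAdjugate:
    def test_two_by_two(self):
        r = 0.37
        expected = np.array([[1.0, -r], [-r, 1.0]])
        np.testing.assert_allclose(cm.adjugate([[1, r], [r, 1]]), expected)

    def test_identity(self):
        np.testing.assert_allclose(cm.adjugate(np.eye(3)), np.eye(3))

    def test_fundamental_identity_random(self, rng):
        m = rng.normal(size=(4, 4))
        lhs = m @ cm.adjugate(m)
        rhs = np.linalg.det(m) * np.eye(4)
        assert np.abs(lhs - rhs).max() < 1e-10

    def test_defined_for_singular(self):
        m = np.array([[1.0, 1.0], [1.0, 1.0]])
        adj = cm.adjugate(m)
        np.testing.assert_allclose(m @ adj, np.zeros((2, 2)), atol=1e-12)


class TestPredictR2General:
    def test_one_isnp_product_form(self):
        b = cm.CorrelationBundle([0.6], [[1.0]], [0.5])
        assert cm.predict_r2_general(b) == pytest.approx(0.36 * 0.25, abs=1e-14)

    def test_perfect_ld_inherits_isnp_r2(self):
        r_yb = 0.43
        b = cm.CorrelationBundle([r_yb], [[1.0]], [1.0])
        assert cm.predict_r2_general(b) == pytest.approx(r_yb**2, abs=1e-14)

    def test_two_isnp_printed_formula(self):
        c, r_bc, a = (0.5, 0.3), 0.2, (0.4, 0.1)
        b = cm.CorrelationBundle(c, [[1, r_bc], [r_bc, 1]], a)
        direct = (
            c[0] * (a[0] - r_bc * a[1]) + c[1] * (a[1] - a[0] * r_bc)
        ) ** 2 / (1 - r_bc**2) ** 2
        assert cm.predict_r2_general(b) == pytest.approx(direct, abs=1e-12)

    @pytest.mark.parametrize("p", [1, 2, 3, 4])
    def test_constraint_oracle(self, p, rng):
        """Setting r_YA to the constraint root leaves R2_M unchanged.

        The defining property R2_AB = R2_B, R2_ABC = R2_BC, ...: plugging
        r_YA = -beta/(2 alpha) into the augmented system reproduces the
        multiple coefficient of determination of the iSNPs alone.
        """
        for _ in range(250):
            bundle, _ = cm.random_psd_bundle(p, rng)
            r_ya = cm.constrained_r_y(bundle)
            sub = cm.multiple_r2(bundle.c_vec, bundle.r_mat)
            aug = cm.multiple_r2(
                np.concatenate([[r_ya], bundle.c_vec]), bundle.augmented()
            )
            assert abs(aug - sub) < 1e-10
            assert cm.predict_r2_general(bundle) == pytest.approx(
                r_ya**2, abs=1e-12
            )

    @pytest.mark.parametrize("p", [2, 3, 4])
    def test_sign_invariance(self, p, rng):
        """Flipping any single SNP's coding leaves the prediction unchanged."""
        bundle, _ = cm.random_psd_bundle(p, rng)
        base = cm.predict_r2_general(bundle)
        # flip the target SNP: a_vec negates
        flipped_a = cm.CorrelationBundle(
            bundle.c_vec, bundle.r_mat, -bundle.a_vec
        )
        assert cm.predict_r2_general(flipped_a) == pytest.approx(base, abs=1e-13)
        # flip each iSNP k: negate c_k, a_k and row/column k of r_mat
        for k in range(p):
            c = bundle.c_vec.copy()
            a = bundle.a_vec.copy()
            r = bundle.r_mat.copy()
            c[k] *= -1
            a[k] *= -1
            r[k, :] *= -1
            r[:, k] *= -1
            flipped = cm.CorrelationBundle(c, r, a)
            assert cm.predict_r2_general(flipped) == pytest.approx(
                base, abs=1e-13
            )

    def test_one_isnp_monotone_in_ld(self):
        values = [
            cm.predict_r2_general(cm.CorrelationBundle([0.6], [[1.0]], [a]))
            for a in np.linspace(0, 1, 25)
        ]
        assert np.all(np.diff(values) >= 0)

    @pytest.mark.parametrize("p", [2, 3, 4])
    def test_nesting(self, p, rng):
        """A target identical to an iSNP predicts that iSNP's own R2."""
        bundle, _ = cm.random_psd_bundle(p, rng)
        for k in range(p):
            nested = cm.CorrelationBundle(
                bundle.c_vec, bundle.r_mat, bundle.r_mat[k]
            )
            assert cm.predict_r2_general(nested) == pytest.approx(
                bundle.c_vec[k] ** 2, abs=1e-12
            )

    def test_collinear_isnps_rejected(self):
        b = cm.CorrelationBundle(
            [0.5, 0.5], [[1.0, 1.0], [1.0, 1.0]], [0.3, 0.3]
        )
        with pytest.raises(cm.CollinearityError, match="collinear iSNP set"):
            cm.predict_r2_general(b)

    def test_nonpsd_configuration_warns_not_clips(self):
        b = cm.CorrelationBundle(
            [0.9, 0.9], [[1.0, -0.95], [-0.95, 1.0]], [0.9, 0.9]
        )
        with pytest.warns(cm.NonPSDWarning):
            r2 = cm.predict_r2_general(b)
        assert r2 > 1.0


class TestClosedForm:
    def test_sign_of_r_yb_is_immaterial(self):
        b = cm.CorrelationBundle([-0.6], [[1.0]], [0.5])
        assert cm.predict_r2_closed_form(b) == pytest.approx(0.09, abs=1e-14)

    def test_orthogonal_isnps_collapse(self):
        b = cm.CorrelationBundle([0.5, 0.3], np.eye(2), [0.4, 0.1])
        assert cm.predict_r2_closed_form(b) == pytest.approx(
            (0.5 * 0.4 + 0.3 * 0.1) ** 2, abs=1e-14
        )

    def test_perfect_isnp_ld_rejected(self):
        b = cm.CorrelationBundle([0.5, 0.3], [[1, 1.0], [1.0, 1]], [0.4, 0.1])
        with pytest.raises(cm.CollinearityError):
            cm.predict_r2_closed_form(b)

    @pytest.mark.parametrize("p", [1, 2])
    def test_agrees_with_general_path_sweep(self, p, rng):
        for _ in range(1000):
            bundle, _ = cm.random_psd_bundle(p, rng)
            assert cm.predict_r2_closed_form(bundle) == pytest.approx(
                cm.predict_r2_general(bundle), abs=1e-12
            )


class TestPredictProfileVectorized:
    @pytest.mark.parametrize("p", [1, 2, 3, 4])
    def test_matches_per_target_adjugate_route(self, p, rng):
        c = rng.uniform(-0.6, 0.6, size=p)
        r, _ = cm.random_psd_bundle(p, rng)
        r_mat = r.r_mat
        a_mat = rng.uniform(-0.7, 0.7, size=(30, p))
        vec = cm.predict_r2_profile(c, r_mat, a_mat)
        import warnings

        for i in range(30):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", cm.NonPSDWarning)
                one = cm.predict_r2_general(
                    cm.CorrelationBundle(c, r_mat, a_mat[i])
                )
            assert vec[i] == pytest.approx(one, rel=1e-12, abs=1e-15)


class TestExpansionTermCounts:
    @pytest.mark.parametrize("p, expected", [(1, 1), (2, 16), (3, 324)])
    def test_counts(self, p, expected):
        assert cm.count_expansion_terms(p) == expected

    def test_unsupported(self):
        with pytest.raises(ValueError):
            cm.count_expansion_terms(5)
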