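"""Cost-landscape diagnostics tests.

Most tests run on small constructed ensembles (cheap, exact); the
landscape-level behaviour on real multistart ensembles is covered by the
acceptance suite.
"""

import numpy as np
import pytest

from fimdesign.diagnostics import (
    are_distinct,
    classify_fits,
    cost_profile,
    distinct_minima_count,
    pca_projection,
    principal_angles,
    random_subspace_null,
    residual_distance,
    sloppy_subspace,
)
from fimdesign.fitting import FitResult
from fimdesign.information import InformationSummary
from fimdesign.model import ParameterSet


def _fit(resid, cost=None, angle=90.0, names=("a", "b"), values=(1.0, 1.0),
         status="converged"):
    r = np.asarray(resid, dtype=float)
    return FitResult(
        params=ParameterSet(dict(zip(names, values))),
        cost=cost if cost is not None else 0.5 * float(r @ r),
        data_cost=cost if cost is not None else 0.5 * float(r @ r),
        residuals=r,
        convergence_angle=angle,
        status=status,
        n_data=len(r),
    )


class TestClassification:
    def test_low_cost_is_good(self):
        ens = classify_fits([_fit([1.0, 0.0]), _fit([10.0, 10.0])])
        assert ens.classification == ["good", "bad"]

    def test_order_invariant(self):
        fits = [_fit([10.0, 10.0]), _fit([1.0, 0.0]), _fit([1.1, 0.0])]
        a = classify_fits(fits).classification
        b = classify_fits(fits[::-1]).classification
        assert a == b[::-1]

    def test_unconverged_is_bad(self):
        ens = classify_fits([_fit([1.0]), _fit([1.0], status="not_converged")])
        assert ens.classification == ["good", "bad"]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            classify_fits([])


class TestResidualDistance:
    def test_identity_and_symmetry(self):
        a, b = _fit([1.0, 2.0]), _fit([2.0, 0.5])
        assert residual_distance(a, a) == 0.0
        assert residual_distance(a, b) == residual_distance(b, a)

    def test_triangle_inequality(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b, c = (_fit(rng.standard_normal(6)) for _ in range(3))
            assert residual_distance(a, c) <= (
                residual_distance(a, b) + residual_distance(b, c) + 1e-12
            )

    def test_dataset_mismatch_rejected(self):
        with pytest.raises(ValueError):
            residual_distance(_fit([1.0]), _fit([1.0, 2.0]))


class TestDistinctness:
    def test_identical_fits_indistinct(self):
        a = _fit([1.0, 2.0], angle=89.9)
        assert not are_distinct(a, a)

    def test_separated_basins_of_toy_problem(self):
        # least squares on r(x) = (x^2 - 1, 0.3 x): two minima near +-1
        # with clearly different residual vectors
        from scipy.optimize import least_squares

        def r(x):
            return np.array([x[0] ** 2 - 1.0, 0.3 * x[0]])

        fits = []
        for x0 in (2.0, -2.0):
            sol = least_squares(r, [x0])
            fits.append(
                _fit(sol.fun, names=("x",), values=(abs(sol.x[0]),),
                     angle=89.999)
            )
        assert are_distinct(fits[0], fits[1])

    def test_explicit_tolerance_overrides(self):
        a, b = _fit([0.0, 0.0], angle=45.0), _fit([0.1, 0.0], angle=45.0)
        assert not are_distinct(a, b, tolerance_distance=1.0)
        assert are_distinct(a, b, tolerance_distance=0.01)

    def test_count_uses_connected_components(self):
        # a-b indistinct, b-c indistinct, a-c distinct: one cluster
        a = _fit([0.00, 0.0], angle=45.0)
        b = _fit([0.60, 0.0], angle=45.0)
        c = _fit([1.20, 0.0], angle=45.0)
        tol = 0.7
        assert not are_distinct(a, b, tol) and not are_distinct(b, c, tol)
        assert are_distinct(a, c, tol)
        ens = classify_fits([a, b, c], threshold_factor=1e9)
        assert distinct_minima_count(ens, tolerance_distance=tol) == 1


class TestCostProfile:
    def test_endpoints_match_fit_costs(self, model, truth, startup, penalty):
        a = truth
        b = truth.scaled({"pro1_strength": 1.3, "h2": 0.8})
        prof = cost_profile(a, b, startup, model, penalty, n_points=5)
        from fimdesign.fitting import penalty_residuals, residuals

        for p, c in ((a, prof[0]), (b, prof[-1])):
            r = np.concatenate(
                [residuals(p, startup, model),
                 penalty_residuals(p, penalty, model.parameter_names)]
            )
            assert c == pytest.approx(0.5 * float(r @ r), rel=1e-8)

    def test_convex_toy_maximum_at_endpoint(self):
        # straight-line profile of a convex quadratic cost peaks at an end
        xa, xb = -2.0, 3.0
        ts = np.linspace(0, 1, 11)
        prof = [((1 - t) * xa + t * xb) ** 2 for t in ts]
        assert max(prof) in (prof[0], prof[-1])


class TestSubspaces:
    @pytest.fixture()
    def info(self):
        rng = np.random.default_rng(5)
        J = rng.standard_normal((60, 10)) * np.logspace(0, -6, 10)
        return InformationSummary.from_jacobian(J)

    def test_full_space(self, info):
        B = sloppy_subspace(info, 10)
        assert B.shape == (10, 10)
        assert np.allclose(B.T @ B, np.eye(10), atol=1e-10)

    def test_orthonormal_and_singular(self, info):
        B = sloppy_subspace(info, 3)
        assert np.allclose(B.T @ B, np.eye(3), atol=1e-10)
        s_small = np.sort(info.singular_values)[:3]
        for i in range(3):
            # |J v| equals one of the 3 smallest singular values
            jv = np.linalg.norm(info.jacobian @ B[:, i])
            assert min(abs(jv - s) for s in s_small) < 1e-8 * max(
                info.singular_values
            )

    def test_k_out_of_range(self, info):
        with pytest.raises(ValueError):
            sloppy_subspace(info, 0)
        with pytest.raises(ValueError):
            sloppy_subspace(info, 11)


class TestPCA:
    def _ensemble(self, X):
        fits = [
            _fit([0.0], names=tuple(f"p{i}" for i in range(X.shape[1])),
                 values=tuple(np.exp(row)))
            for row in X
        ]
        return classify_fits(fits, threshold_factor=1e9)

    def test_components_orthonormal_variance_ordered(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((30, 5)) * np.array([3.0, 2.0, 1.0, 0.5, 0.1])
        ens = self._ensemble(X)
        coords, basis = pca_projection(ens, 3)
        assert np.allclose(basis.T @ basis, np.eye(3), atol=1e-10)
        var = coords.var(axis=0)
        assert var[0] >= var[1] >= var[2]

    def test_collinear_ensemble(self):
        t = np.linspace(-1, 1, 10)
        X = np.outer(t, np.array([1.0, 2.0, -1.0]))
        coords, _ = pca_projection(self._ensemble(X), 2)
        assert coords[:, 0].var() > 0
        assert coords[:, 1].var() == pytest.approx(0.0, abs=1e-16)

    def test_needs_two_fits(self):
        ens = self._ensemble(np.zeros((1, 3)))
        with pytest.raises(ValueError):
            pca_projection(ens, 1)


class TestPrincipalAngles:
    def test_identical_subspaces(self):
        B = np.linalg.qr(np.random.default_rng(7).standard_normal((8, 3)))[0]
        assert np.allclose(principal_angles(B, B), 0.0, atol=1e-6)

    def test_orthogonal_subspaces(self):
        A = np.eye(6)[:, :2]
        B = np.eye(6)[:, 3:5]
        assert np.allclose(principal_angles(A, B), 90.0)

    def test_invariant_under_rotation_within_subspaces(self):
        rng = np.random.default_rng(8)
        A = np.linalg.qr(rng.standard_normal((10, 4)))[0]
        B = np.linalg.qr(rng.standard_normal((10, 4)))[0]
        RA = np.linalg.qr(rng.standard_normal((4, 4)))[0]
        RB = np.linalg.qr(rng.standard_normal((4, 4)))[0]
        a1 = principal_angles(A, B)
        a2 = principal_angles(A @ RA, B @ RB)
        assert np.allclose(a1, a2, atol=1e-8)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            principal_angles(np.eye(4)[:, :2], np.eye(5)[:, :2])


class TestRandomNull:
    def test_full_dimensional_subspaces_coincide(self):
        mean, sd = random_subspace_null(4, 4, reps=5, seed=0)
        assert mean == pytest.approx(0.0, abs=1e-5)

    def test_mean_decreases_with_p(self):
        means = [random_subspace_null(p, 20, reps=150, seed=p)[0]
                 for p in (1, 4, 8)]
        assert means[0] > means[1] > means[2]

    def test_p_larger_than_ambient_rejected(self):
        with pytest.raises(ValueError):
            random_subspace_null(5, 4, reps=1, seed=0)


@pytest.fixture(scope="module")
def ensemble(model, startup, penalty):
    from fimdesign.fitting import multistart

    res = multistart(startup, model, penalty, 30, 42, max_iter=250,
                     rtol=1e-6, atol=1e-8)
    return classify_fits(res)


class TestLandscape:
    """Multistart landscape structure on the startup data.

    Scaled-down version of the full landscape survey: a few dozen random
    starts instead of thousands, enough to exhibit the qualitative
    structure (many near-degenerate good minima, shallow barriers, and
    sloppy-subspace alignment)."""

    def test_good_fits_dominate_converged(self, ensemble):
        conv = [f for f in ensemble.fits if f.converged]
        assert len(conv) >= 5
        good = ensemble.good
        assert len(good) / len(conv) >= 0.5

    def test_several_shallow_minima(self, model, startup, penalty, ensemble):
        """Good fits split into multiple distinct minima (order tens at
        full scale), separated by barriers far below random-parameter
        costs."""
        n_distinct = distinct_minima_count(ensemble)
        assert 1 <= n_distinct <= len(ensemble.good)
        good = ensemble.good
        pair = None
        from fimdesign.diagnostics import are_distinct
        from itertools import combinations

        for a, b in combinations(good, 2):
            if are_distinct(a, b):
                pair = (a, b)
                break
        if pair is None:
            pytest.skip("all good fits in one basin at this scale")
        prof = cost_profile(pair[0].params, pair[1].params, startup, model,
                            penalty, n_points=9)
        barrier = np.nanmax(prof) - max(prof[0], prof[-1])
        # random parameter draws cost orders of magnitude more
        from fimdesign.fitting import residuals, sample_start

        rng = np.random.default_rng(1)
        rand_costs = []
        while len(rand_costs) < 10:
            s = sample_start(model, penalty, rng)
            try:
                r = residuals(s, startup, model)
                rand_costs.append(0.5 * float(r @ r))
            except Exception:
                continue
        assert barrier < np.median(rand_costs) / 10

    def test_pca_subspace_aligns_with_sloppy_directions(self, model, startup,
                                                        ensemble):
        """The ensemble's dominant-variance directions align with the
        least-constrained Fisher directions: their first principal angle
        is well below the random-subspace null."""
        from fimdesign.information import fisher_information

        good = ensemble.good
        assert len(good) >= 6
        best = min(good, key=lambda f: f.cost)
        info = fisher_information(best.params, startup, model,
                                  rtol=1e-6, atol=1e-8)
        k = 5
        _, pca_basis = pca_projection(ensemble, k)
        sl = sloppy_subspace(info, k)
        first = principal_angles(pca_basis, sl)[0]
        mean0, sd0 = random_subspace_null(k, model.n_parameters, 1000, 3)
        assert first < mean0 - 2 * sd0
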