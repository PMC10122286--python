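import subprocess
import textwrap

import numpy as np
import pytest
from scipy.special import expit

from myofibspat import (
    FiberSection,
    SurfaceSpec,
    boundary_polygon,
    build_tprs_basis,
    encode_binary,
    fit_logistic_gam,
    fit_multinomial_gam,
    generate_lattice_section,
    predict_probability_grid,
    select_lambda,
    simulate_surface_section,
)
from myofibspat.gam import GamFit, default_basis_dim


@pytest.fixture(scope="module")
def radial_section():
    pts = generate_lattice_section(35, 35, jitter=0.2, seed=21)
    return simulate_surface_section(pts, SurfaceSpec.radial(0.2, 0.8), seed=22)


class TestBasis:
    def test_k3_is_plain_glm_design(self, small_points):
        basis = build_tprs_basis(small_points.coords, 3)
        sc = basis.standardize(small_points.coords)
        np.testing.assert_allclose(
            basis.design, np.column_stack([np.ones(small_points.n), sc[:, 0], sc[:, 1]])
        )
        assert not basis.penalty.any()

    def test_affine_null_space_unpenalized(self, small_points):
        basis = build_tprs_basis(small_points.coords, 18)
        assert not basis.penalty[:3].any() and not basis.penalty[:, :3].any()
        b = np.zeros(18)
        b[:3] = [1.0, -2.0, 0.5]  # an affine surface
        assert b @ basis.penalty @ b == 0.0

    def test_penalty_positive_semidefinite(self, small_points):
        basis = build_tprs_basis(small_points.coords, 18)
        eigs = np.linalg.eigvalsh(basis.penalty)
        assert eigs.min() >= -1e-10

    def test_reevaluation_reproduces_design(self):
        rng = np.random.default_rng(5)
        coords = rng.random((50, 2)) * 10
        basis = build_tprs_basis(coords, 20)
        np.testing.assert_allclose(basis.evaluate(coords), basis.design, atol=1e-10)

    def test_k_exceeding_n_raises(self, small_points):
        with pytest.raises(ValueError, match="exceeds"):
            build_tprs_basis(small_points.coords[:10], 11)

    def test_duplicate_coordinates_warn(self):
        coords = np.array([[0.0, 0], [1, 0], [1, 0], [0, 1], [2, 2], [3, 1]])
        with pytest.warns(UserWarning, match="duplicate"):
            build_tprs_basis(coords, 4)


class TestLogisticGam:
    def test_large_lambda_equals_plain_glm(self, radial_section):
        import statsmodels.api as sm

        fit = fit_logistic_gam(radial_section, {"fast"}, K=20, lam=1e9)
        y = (encode_binary(radial_section, {"fast"}).z + 1) / 2
        glm = sm.GLM(y, fit.basis.design[:, :3], family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(fit.beta[:3], glm.params, atol=1e-4)
        assert np.abs(fit.beta[3:]).max() < 1e-4

    def test_flat_surface_recovery(self):
        pts = generate_lattice_section(32, 32, jitter=0.2, seed=31)
        sec = simulate_surface_section(pts, SurfaceSpec.constant(0.4), seed=32)
        fit = fit_logistic_gam(sec, {"fast"})
        p = fit.fitted_probabilities
        assert p.min() > 0.3 and p.max() < 0.5

    def test_smooth_surface_mae(self):
        spec = SurfaceSpec.linear_gradient(0.15, 0.85)
        maes = []
        for seed in range(5):
            pts = generate_lattice_section(45, 45, jitter=0.2, seed=40 + seed)
            sec = simulate_surface_section(pts, spec, seed=140 + seed)
            fit = fit_logistic_gam(sec, {"fast"})
            maes.append(np.abs(fit.predict(sec.coords) - spec.evaluate(sec.x, sec.y)).mean())
        assert np.mean(maes) < 0.05

    def test_edf_bounds_and_large_lambda_limit(self, radial_section):
        fit = fit_logistic_gam(radial_section, {"fast"}, K=20, lam=1e9)
        assert fit.edf == pytest.approx(3.0, abs=1e-3)
        small = fit_logistic_gam(radial_section, {"fast"}, K=20, lam=1e-3)
        assert 3.0 <= fit.edf <= small.edf <= 20.0

    def test_label_swap_gives_complementary_surface(self, radial_section):
        a = fit_logistic_gam(radial_section, {"fast"}, K=15, lam=2.0)
        b = fit_logistic_gam(radial_section, {"slow"}, K=15, lam=2.0)
        np.testing.assert_allclose(
            a.predict(radial_section.coords) + b.predict(radial_section.coords),
            1.0, atol=1e-10,
        )

    def test_scale_invariance_of_probabilities(self, radial_section):
        fit = fit_logistic_gam(radial_section, {"fast"}, K=15)
        scaled = FiberSection(
            x=radial_section.x * 37.0 + 5.0,
            y=radial_section.y * 37.0 - 11.0,
            type_label=radial_section.type_label,
        )
        fit2 = fit_logistic_gam(scaled, {"fast"}, K=15)
        np.testing.assert_allclose(
            fit.fitted_probabilities, fit2.fitted_probabilities, atol=1e-6
        )

    def test_auto_deviance_beats_plane(self, radial_section):
        auto = fit_logistic_gam(radial_section, {"fast"}, K=20, lam="auto")
        plane = fit_logistic_gam(radial_section, {"fast"}, K=20, lam=1e9)
        y = (encode_binary(radial_section, {"fast"}).z + 1) / 2

        def dev(fit):
            p = fit.fitted_probabilities
            return -2 * np.sum(y * np.log(p) + (1 - y) * np.log1p(-p))

        assert dev(auto) <= dev(plane) + 1e-8


class TestSelectLambda:
    def test_deterministic(self, radial_section):
        basis = build_tprs_basis(radial_section.coords, 15)
        a = select_lambda(radial_section, basis, fast_labels={"fast"})
        b = select_lambda(radial_section, basis, fast_labels={"fast"})
        assert a == b

    def test_pure_noise_selects_heavy_smoothing(self):
        pts = generate_lattice_section(30, 30, jitter=0.2, seed=51)
        sec = simulate_surface_section(pts, SurfaceSpec.constant(0.5), seed=52)
        with pytest.warns(UserWarning, match="boundary"):
            fit = fit_logistic_gam(sec, {"fast"}, K=15)
        assert fit.edf == pytest.approx(3.0, abs=1.0)

    def test_signal_selects_interior_lambda(self, radial_section):
        fit = fit_logistic_gam(radial_section, {"fast"}, K=20)
        assert 1e-4 < fit.lam < 1e8
        assert fit.edf > 4.0


class TestProbabilityGrid:
    def test_intercept_only_constant_surface(self, small_points):
        basis = build_tprs_basis(small_points.coords, 3)
        fit = GamFit(beta=np.array([0.7, 0.0, 0.0]), lam=0.0, basis=basis,
                     edf=1.0, converged=True, criterion="REML", criterion_value=0.0)
        boundary = boundary_polygon(small_points)
        surf = predict_probability_grid(fit, boundary, resolution=30)
        inside = surf.prob[surf.mask]
        np.testing.assert_allclose(inside, expit(0.7), atol=1e-12)

    def test_grid_matches_in_sample_predictions(self, radial_section):
        fit = fit_logistic_gam(radial_section, {"fast"}, K=15)
        np.testing.assert_allclose(
            fit.predict(radial_section.coords), fit.fitted_probabilities, atol=1e-10
        )

    def test_radial_pattern_edge_exceeds_center(self, radial_section):
        fit = fit_logistic_gam(radial_section, {"fast"})
        boundary = boundary_polygon(radial_section)
        surf = predict_probability_grid(fit, boundary, resolution=80)
        gx, gy = np.meshgrid(surf.grid_x, surf.grid_y, indexing="xy")
        cx, cy = radial_section.x.mean(), radial_section.y.mean()
        r = np.hypot(gx - cx, gy - cy)[surf.mask]
        p = surf.prob[surf.mask]
        rmax = r.max()
        outer = p[r > 0.8 * rmax].mean()
        inner = p[r < 0.2 * rmax].mean()
        assert outer > inner
        assert np.nanmin(surf.prob) >= 0 and np.nanmax(surf.prob) <= 1


def three_type_section(seed=61, size=38):
    """Tibialis-anterior-like pattern: I rare and deep, IIa deep, IIb superficial."""
    pts = generate_lattice_section(size, size, jitter=0.2, seed=seed)
    rng = np.random.default_rng(seed + 1)
    xs = (pts.x - pts.x.mean()) / pts.x.std()
    ys = (pts.y - pts.y.mean()) / pts.y.std()
    depth = (-xs + ys) / np.sqrt(2)  # "deep" = top-left
    eta_I = -1.2 + 0.9 * depth
    eta_IIa = 0.3 + 0.8 * depth
    e = np.exp(np.column_stack([np.zeros_like(eta_I), eta_I, eta_IIa]))
    P = e / e.sum(axis=1, keepdims=True)  # columns: IIb (ref), I, IIa
    u = rng.random(pts.n)
    cum = P.cumsum(axis=1)
    idx = (u[:, None] > cum).sum(axis=1)
    labels = np.array(["IIb", "I", "IIa"], object)[idx]
    return FiberSection(x=pts.x, y=pts.y, type_label=labels), P, depth


class TestMultinomialGam:
    def test_probabilities_sum_to_one(self):
        sec, _, _ = three_type_section()
        fit = fit_multinomial_gam(sec)
        proba = fit.predict_proba(sec.coords)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-10)
        boundary = boundary_polygon(sec)
        grids = fit.probability_grids(boundary, resolution=40)
        total = sum(g.prob for g in grids.values())
        mask = next(iter(grids.values())).mask
        np.testing.assert_allclose(total[mask], 1.0, atol=1e-10)

    def test_two_types_reduce_to_binary_gam(self, radial_section):
        mfit = fit_multinomial_gam(radial_section, K=15)
        bfit = fit_logistic_gam(radial_section, {mfit.types[1]}, K=15)
        np.testing.assert_allclose(mfit.coef[0], bfit.beta, atol=1e-6)
        assert mfit.lambdas[0] == pytest.approx(bfit.lam)

    def test_collapse_consistency_with_binary(self):
        sec, _, _ = three_type_section()
        mfit = fit_multinomial_gam(sec)
        c = list(mfit.types).index("I")
        p_multi = mfit.predict_proba(sec.coords)[:, c]
        bfit = fit_logistic_gam(sec, {"I"})  # IIa and IIb collapse to "slow"
        p_bin = bfit.predict(sec.coords)
        assert np.abs(p_multi - p_bin).mean() < 0.05

    def test_rare_deep_type_peaks_deep(self):
        sec, P, depth = three_type_section()
        fit = fit_multinomial_gam(sec)
        c = list(fit.types).index("I")
        p_I = fit.predict_proba(sec.coords)[:, c]
        # type I probability should be maximal in the deep region and modest
        assert depth[np.argmax(p_I)] > np.quantile(depth, 0.6)
        assert 0.1 < p_I.max() < 0.5

    def test_rare_type_warns(self):
        pts = generate_lattice_section(12, 12, jitter=0.2, seed=71)
        rng = np.random.default_rng(72)
        labels = np.array(["A"] * pts.n, object)
        labels[rng.choice(pts.n, 60, replace=False)] = "B"
        idx = rng.choice(np.flatnonzero(labels == "A"), 6, replace=False)
        labels[idx] = "C"
        sec = FiberSection(x=pts.x, y=pts.y, type_label=labels)
        with pytest.warns(UserWarning):
            fit_multinomial_gam(sec, K=12)


@pytest.mark.parametrize("criterion", ["REML"])
def test_against_mgcv_reference(criterion, radial_section):
    """Cross-check fitted probabilities against R mgcv on the same data."""
    import pandas as pd

    df = pd.DataFrame({
        "x": radial_section.x,
        "y": radial_section.y,
        "z": (encode_binary(radial_section, {"fast"}).z + 1) // 2,
    })
    csv = "/tmp/_mgcv_check.csv"
    out = "/tmp/_mgcv_fit.csv"
    df.to_csv(csv, index=False)
    script = textwrap.dedent(f"""
        suppressMessages(library(mgcv))
        d <- read.csv("{csv}")
        fit <- gam(z ~ s(x, y, k = 30), family = binomial, data = d, method = "{criterion}")
        write.csv(data.frame(p = fitted(fit)), "{out}", row.names = FALSE)
    """)
    proc = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True)
    assert proc.returncode == 0, proc.stderr
    p_ref = pd.read_csv(out)["p"].to_numpy()
    fit = fit_logistic_gam(radial_section, {"fast"}, K=30, criterion=criterion)
    assert np.abs(fit.fitted_probabilities - p_ref).mean() < 0.05


def test_default_basis_dimension_rule():
    assert default_basis_dim(1600) == 33
    assert default_basis_dim(40) == 13
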