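"""Inner-filter correction, binding models and the titration fit."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from fretbind import (
    BindingIsotherm,
    TitrationPoint,
    TitrationSeries,
    TitrationSpec,
    binding_model,
    correct_series,
    fit_binding,
    gen_titration,
    inner_filter_correct,
    quench_signal,
    read_titration,
)


def mass_balance_signal(L, Kd, F_max, n, R):
    """Independent oracle: bound-site fraction by bisection on the free
    ligand mass balance  Lf + n R Lf/(Kd + Lf) = L."""
    out = []
    for Lt in np.atleast_1d(np.asarray(L, float)):
        if Lt == 0:
            out.append(0.0)
            continue
        f = lambda lf: lf + n * R * lf / (Kd + lf) - Lt
        lf = brentq(f, 0.0, Lt, xtol=1e-15, rtol=1e-15)
        out.append(F_max * lf / (Kd + lf))
    return np.array(out)


def make_series(spec=None, **kwargs):
    return gen_titration(spec or TitrationSpec(**kwargs))


class TestInnerFilter:
    def test_identity_at_zero_absorbance(self):
        assert inner_filter_correct(123.4, 0.0, 0.0) == pytest.approx(123.4)

    def test_hand_computed_example(self):
        # A_exc=0.2 over 1 cm, A_em=0.5 per cm over 0.2 cm -> factor 10^0.15
        f = inner_filter_correct(100.0, 0.2, 0.5, path_exc=1.0, path_em=0.2)
        assert f == pytest.approx(100.0 * 10**0.15)
        assert f == pytest.approx(141.2537, rel=1e-6)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        a1=st.floats(min_value=0, max_value=2),
        a2=st.floats(min_value=0, max_value=2),
        da=st.floats(min_value=1e-6, max_value=1.0),
    )
    def test_correction_monotone_and_amplifying(self, a1, a2, da):
        base = inner_filter_correct(50.0, a1, a2)
        assert base >= 50.0
        assert inner_filter_correct(50.0, a1 + da, a2) > base
        assert inner_filter_correct(50.0, a1, a2 + da) > base

    def test_negative_absorbance_rejected(self):
        with pytest.raises(ValueError):
            inner_filter_correct(100.0, -0.1, 0.0)


class TestQuenchSignal:
    def test_reference_point_and_half_quench(self):
        pts = (
            TitrationPoint(0.0, 100.0, A_exc=0.0, A_em_1cm=0.0),
            TitrationPoint(5.0, 50.0, A_exc=0.0, A_em_1cm=0.0),
        )
        L, S = quench_signal(TitrationSeries(pts, receptor_total=5.0))
        assert S[0] == 0.0
        assert S[1] == pytest.approx(0.5)

    def test_invariant_under_intensity_rescaling(self):
        series = make_series(noise_sd=0.0, seed=3)
        _, S1 = quench_signal(series)
        scaled = TitrationSeries(
            tuple(
                TitrationPoint(p.ligand_total, p.F_obs * 37.0, p.A_exc, p.A_em_1cm)
                for p in series.points
            ),
            receptor_total=series.receptor_total,
            path_exc=series.path_exc,
            path_em=series.path_em,
        )
        _, S2 = quench_signal(scaled)
        np.testing.assert_allclose(S1, S2, rtol=1e-12)

    def test_missing_zero_ligand_reference_rejected(self):
        pts = (TitrationPoint(1.0, 90.0, 0.0, 0.0), TitrationPoint(5.0, 50.0, 0.0, 0.0))
        with pytest.raises(ValueError, match="zero-ligand"):
            quench_signal(TitrationSeries(pts, receptor_total=5.0))


class TestBindingModel:
    @pytest.mark.parametrize("model", ["quadratic_depletion", "hyperbolic"])
    def test_zero_ligand_and_saturation(self, model):
        assert binding_model(0.0, Kd=1.0, F_max=0.8, model=model) == 0.0
        high = binding_model(1e7, Kd=1.0, F_max=0.8, model=model)
        assert high == pytest.approx(0.8, rel=1e-5)

    def test_hyperbolic_half_saturation(self):
        assert binding_model(2.0, Kd=2.0, F_max=1.0, model="hyperbolic") == pytest.approx(0.5)

    def test_quadratic_matches_mass_balance_oracle(self):
        grid_L = np.array([0.1, 0.5, 1.0, 2.0, 5.0, 10.0, 50.0])
        for Kd in (0.1, 1.0, 10.0):
            for R in (1.0, 5.0):
                for n in (0.5, 1.0, 2.0):
                    got = binding_model(grid_L, Kd=Kd, F_max=1.0, n=n, receptor_total=R)
                    want = mass_balance_signal(grid_L, Kd, 1.0, n, R)
                    np.testing.assert_allclose(got, want, rtol=1e-9)

    def test_quadratic_approaches_hyperbola_at_weak_binding(self):
        # ligand depletion becomes negligible once Kd >> n * R
        L = np.linspace(0.5, 20, 20)
        Kd, R, n = 600.0, 5.0, 1.0  # Kd > 100 * n * R
        quad = binding_model(L, Kd=Kd, F_max=1.0, n=n, receptor_total=R)
        hyp = binding_model(L, Kd=Kd, F_max=1.0, model="hyperbolic")
        assert np.max(np.abs(quad - hyp) / hyp) < 0.01

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            binding_model(1.0, Kd=-1.0, F_max=1.0)
        with pytest.raises(ValueError, match="model"):
            binding_model(1.0, Kd=1.0, F_max=1.0, model="cooperative")


class TestFitBinding:
    def test_noiseless_roundtrip_quadratic(self):
        series = make_series(true_Kd=2.0, true_Fmax=1.0, noise_sd=0.0, seed=0,
                             ligand_concs=tuple(np.linspace(0, 20, 12)))
        fit = fit_binding(series, model="quadratic_depletion", n_fixed=1.0)
        assert fit.converged
        assert fit.Kd == pytest.approx(2.0, abs=1e-6)
        assert fit.F_max == pytest.approx(1.0, abs=1e-6)
        assert np.max(np.abs(fit.residuals)) < 1e-8

    def test_noiseless_roundtrip_hyperbolic(self):
        L = np.array([0.0, 0.2, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0])
        S = binding_model(L, Kd=1.5, F_max=0.6, model="hyperbolic")
        est = BindingIsotherm(model="hyperbolic", n=1.0).fit(L, S)
        assert est.Kd_ == pytest.approx(1.5, rel=1e-7)
        assert est.Fmax_ == pytest.approx(0.6, rel=1e-7)
        assert np.max(np.abs(est.residuals_)) < 1e-8 * 0.6
        # half-saturation at L = Kd by definition
        assert est.predict([1.5])[0] == pytest.approx(0.3, rel=1e-7)

    def test_scale_equivariance(self):
        L = np.linspace(0, 20, 12)
        S = binding_model(L, Kd=2.0, F_max=1.0, n=1.0, receptor_total=5.0)
        f1 = BindingIsotherm().fit(L, S)
        f2 = BindingIsotherm().fit(L, S * 37.0)
        assert f2.Kd_ == pytest.approx(f1.Kd_, rel=1e-8)
        assert f2.Fmax_ == pytest.approx(37.0 * f1.Fmax_, rel=1e-8)

    def test_point_order_invariance(self):
        rng = np.random.default_rng(5)
        L = np.linspace(0, 20, 12)
        S = binding_model(L, Kd=1.0, F_max=0.47) + rng.normal(0, 0.01, L.size)
        perm = rng.permutation(L.size)
        f1 = BindingIsotherm().fit(L, S)
        f2 = BindingIsotherm().fit(L[perm], S[perm])
        assert f2.Kd_ == pytest.approx(f1.Kd_, rel=1e-9)

    def test_fitted_stoichiometry_recovered(self):
        L = np.linspace(0, 40, 16)
        S = binding_model(L, Kd=1.0, F_max=0.5, n=2.0, receptor_total=5.0)
        est = BindingIsotherm(n=None).fit(L, S)
        assert est.n_ == pytest.approx(2.0, rel=1e-4)
        assert est.Kd_ == pytest.approx(1.0, rel=1e-4)

    def test_standard_errors_reported_under_noise(self):
        series = make_series(noise_sd=0.03, seed=11)
        fit = fit_binding(series)
        assert fit.se_Kd is not None and fit.se_Kd > 0
        assert fit.se_Fmax is not None and fit.se_Fmax > 0

    def test_bootstrap_ci_brackets_truth(self):
        series = make_series(true_Kd=1.0, noise_sd=0.03, seed=2)
        fit = fit_binding(series, n_bootstrap=200, random_state=0)
        lo, hi = fit.bootstrap_ci
        assert lo < fit.Kd < hi
        assert lo < 1.0 < hi

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="points"):
            BindingIsotherm().fit([0.0, 1.0], [0.0, 0.3])

    def test_span_warning(self):
        # all concentrations far above Kd: no sub-Kd information
        L = np.array([0.0, 50.0, 60.0, 70.0, 80.0, 100.0])
        S = binding_model(L, Kd=0.01, F_max=1.0, receptor_total=5.0)
        with pytest.warns(UserWarning, match="span"):
            BindingIsotherm().fit(L, S)

    def test_parameter_recovery_under_noise(self):
        """Median Kd over 500 seeded 3%-noise replicates within 15% of the
        1.0 µM truth, with dispersion comparable to a ±0.5 µM band."""
        kds = []
        for seed in range(500):
            series = make_series(true_Kd=1.0, true_Fmax=0.47, noise_sd=0.03, seed=seed)
            kds.append(fit_binding(series).Kd)
        kds = np.array(kds)
        assert np.median(kds) == pytest.approx(1.0, rel=0.15)
        assert np.std(kds) < 0.5


class TestTitrationIO:
    def test_series_sorted_and_validated(self):
        pts = (TitrationPoint(5.0, 50.0), TitrationPoint(0.0, 100.0))
        series = TitrationSeries(pts, receptor_total=5.0)
        assert series.points[0].ligand_total == 0.0
        with pytest.raises(ValueError):
            TitrationSeries(pts, receptor_total=0.0)
        with pytest.raises(ValueError):
            TitrationPoint(-1.0, 10.0)

    def test_beer_lambert_absorbances_filled_in(self):
        series = TitrationSeries(
            (TitrationPoint(0.0, 100.0), TitrationPoint(10.0, 60.0)),
            receptor_total=5.0, eps_exc=8624.0, eps_em=20983.0,
        )
        a_exc, a_em = series.absorbances()
        assert a_exc[1] == pytest.approx(8624.0 * 10e-6)
        assert a_em[1] == pytest.approx(20983.0 * 10e-6)

    def test_read_titration_roundtrip(self, tmp_path):
        series = make_series(noise_sd=0.0, seed=0)
        p = tmp_path / "titration.csv"
        series.to_dataframe().to_csv(p, index=False)
        back = read_titration(p, receptor_total=5.0)
        np.testing.assert_allclose(back.ligand_total, series.ligand_total)
        np.testing.assert_allclose(back.F_obs, series.F_obs, rtol=1e-9)
        np.testing.assert_allclose(correct_series(back), correct_series(series), rtol=1e-9)

    def test_read_titration_errors(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_titration(tmp_path / "nope.csv", receptor_total=5.0)
        bad = tmp_path / "bad.csv"
        bad.write_text("a,b\n1,2\n")
        with pytest.raises(ValueError, match="ligand_total_uM"):
            read_titration(bad, receptor_total=5.0)
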