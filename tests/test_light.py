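"""Platt irradiance-response fitting and derived parameters."""

import math

import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings, strategies as st

from phycoflux.light import (FitError, LightResponseData, PlattFit,
                             PlattModel, derive_params, fit_platt,
                             model_rate, summarize_treatment)
from phycoflux.synth import simulate_pe_experiment

E10 = np.array([0, 2, 5, 10, 20, 40, 80, 150, 250, 400], dtype=float)


def _curve(Ps, a, b, Rd, E=E10, mode="photosynthesis_O2", rid="r1"):
    rate = model_rate(E, Ps, a, b, Rd, mode)
    return LightResponseData(replicate_id=rid, mode=mode, irradiance=E,
                             rate=rate)


class TestModelRate:
    def test_dark_limit_is_minus_offset(self):
        assert model_rate(0.0, 1.5, 0.04, 0.002, 0.3) == pytest.approx(-0.3)
        assert model_rate(0.0, 0.4, 0.008, 0.001, 0.05,
                          "calcification") == pytest.approx(0.05)

    def test_saturation_limit_without_photoinhibition(self):
        assert model_rate(1e9, 1.5, 0.04, 0.0, 0.3) == pytest.approx(1.2)

    def test_direct_formula_evaluation(self):
        Ps, a, b, Rd, E = 1.5, 0.04, 0.002, 0.3, 50.0
        expected = (Ps * (1 - math.exp(-a * E / Ps))
                    * math.exp(-b * E / Ps) - Rd)
        assert model_rate(E, Ps, a, b, Rd) == pytest.approx(expected,
                                                            abs=1e-12)


class TestFit:
    def test_noiseless_recovery(self):
        fit = fit_platt(_curve(1.5, 0.04, 0.002, 0.3))
        for got, want in zip(fit.params, (1.5, 0.04, 0.002, 0.3)):
            assert abs(got - want) / want < 1e-6
        assert fit.converged

    def test_beta_zero_truth_stays_on_boundary(self):
        fit = fit_platt(_curve(1.5, 0.04, 0.0, 0.3))
        assert fit.beta < 1e-6
        assert fit.scale == pytest.approx(1.5, rel=1e-6)

    def test_calcification_mode_negative_dark_rate(self):
        fit = fit_platt(_curve(0.4, 0.008, 0.001, -0.02,
                               mode="calcification"))
        assert fit.offset == pytest.approx(-0.02, abs=1e-6)

    def test_degenerate_data_rejected(self):
        with pytest.raises(FitError):
            fit_platt(LightResponseData("r", "photosynthesis_O2",
                                        E10, np.ones_like(E10)))

    def test_deterministic(self):
        c = _curve(1.2, 0.05, 0.003, 0.2)
        f1, f2 = fit_platt(c), fit_platt(c)
        assert np.array_equal(f1.params, f2.params)

    def test_alpha_bias_small_under_noise(self, summer_truth):
        """Median relative bias of the initial slope stays below 5%
        at 5% measurement noise (simulation study, 200 seeds)."""
        truth = replace(summer_truth, rate_noise_frac=0.05)
        rel = []
        for seed in range(200):
            c = simulate_pe_experiment(truth, n_replicates=1, seed=seed)[0]
            rel.append(fit_platt(c).alpha / truth.alpha - 1.0)
        assert abs(float(np.median(rel))) < 0.05


class TestDerived:
    def test_beta_zero_limits(self):
        fit = PlattFit(1.5, 0.04, 0.0, 0.3, "photosynthesis_O2", 0.0, True)
        d = derive_params(fit)
        assert d.Pg_max == pytest.approx(1.5)
        assert d.Pn_max == pytest.approx(1.2)
        assert d.Ek == pytest.approx(1.5 / 0.04)

    def test_ec_closed_form_vs_root(self):
        fit = PlattFit(1.0, 0.05, 0.0, 0.1, "photosynthesis_O2", 0.0, True)
        d = derive_params(fit)
        closed = -(1.0 / 0.05) * math.log(1 - 0.1 / 1.0)
        assert d.Ec == pytest.approx(closed, abs=1e-9)
        assert d.Ec == pytest.approx(2.1072, abs=1e-4)

    def test_pg_max_matches_dense_grid_maximum(self):
        fit = PlattFit(1.5, 0.04, 0.004, 0.3, "photosynthesis_O2", 0.0, True)
        d = derive_params(fit)
        E = np.linspace(0, 5000, 2_000_001)
        gross = model_rate(E, 1.5, 0.04, 0.004, 0.0)
        assert abs(d.Pg_max - gross.max()) / d.Pg_max < 1e-6

    def test_ec_missing_when_respiration_exceeds_max(self):
        fit = PlattFit(0.5, 0.05, 0.0, 0.9, "photosynthesis_O2", 0.0, True)
        d = derive_params(fit)
        assert d.Ec is None and d.ec_reason

    def test_table_consistency_ek_from_printed_means(self):
        # Ek = Pg_max / alpha on treatment means
        assert 1.16 / 0.039 == pytest.approx(30, abs=1)
        d = derive_params(PlattFit(1.20, 0.039, 0.0, 0.26,
                                   "photosynthesis_O2", 0.0, True))
        assert d.Ek == pytest.approx(d.Pg_max / 0.039, rel=1e-12)

    @settings(derandomize=True, max_examples=40)
    @given(scale=st.floats(0.2, 3.0), alpha=st.floats(0.005, 0.1),
           beta=st.floats(0.0, 0.01))
    def test_monotone_in_scale_and_ek_identity(self, scale, alpha, beta):
        d1 = derive_params(PlattFit(scale, alpha, beta, 0.0,
                                    "photosynthesis_O2", 0.0, True))
        d2 = derive_params(PlattFit(scale * 1.1, alpha, beta, 0.0,
                                    "photosynthesis_O2", 0.0, True))
        assert d2.Pg_max > d1.Pg_max
        assert d1.Ek == pytest.approx(d1.Pg_max / alpha, rel=1e-12)

    def test_photoinhibited_curve_has_interior_maximum(self):
        Ps, a, b = 0.6, 0.05, 0.01
        E = np.linspace(0, 600, 6001)
        y = model_rate(E, Ps, a, b, 0.0)
        imax = int(np.argmax(y))
        assert 0 < imax < len(E) - 1
        assert y[-1] < y[imax]  # decline beyond the peak


class TestSummarize:
    def _fits(self, eks):
        fits, ders = [], []
        for ek in eks:
            f = PlattFit(ek * 0.04, 0.04, 0.0, 0.1, "photosynthesis_O2",
                         0.0, True)
            fits.append(f)
            ders.append(derive_params(f))
        return fits, ders

    def test_identical_replicates_zero_se(self):
        fits, ders = self._fits([30, 30, 30])
        s = summarize_treatment(fits, ders, "400T", "summer")
        assert s.se["Ek"] == pytest.approx(0.0, abs=1e-12)

    def test_two_replicate_hand_arithmetic(self):
        fits, ders = self._fits([28, 32])
        s = summarize_treatment(fits, ders, "400T", "summer")
        assert s.mean["Ek"] == pytest.approx(30)
        assert s.se["Ek"] == pytest.approx(2)

    def test_single_replicate_se_missing(self):
        fits, ders = self._fits([30])
        s = summarize_treatment(fits, ders, "400T", "summer")
        assert math.isnan(s.se["Ek"])

    def test_per_replicate_definition_not_ratio_of_means(self):
        """Treatment Ek is the mean of per-replicate Pg_max/alpha, not
        the ratio of the treatment means."""
        fits = [PlattFit(1.0, 0.03, 0.0, 0.1, "photosynthesis_O2", 0.0, True),
                PlattFit(2.0, 0.05, 0.0, 0.1, "photosynthesis_O2", 0.0, True)]
        ders = [derive_params(f) for f in fits]
        s = summarize_treatment(fits, ders, "x", "y")
        per_rep = np.mean([d.Ek for d in ders])
        ratio = np.mean([1.0, 2.0]) / np.mean([0.03, 0.05])
        assert s.mean["Ek"] == pytest.approx(per_rep)
        assert s.mean["Ek"] != pytest.approx(ratio)


def test_model_results_facade(summer_truth):
    curves = simulate_pe_experiment(summer_truth, n_replicates=3, seed=5)
    res = PlattModel(curves).fit()
    frame = res.params_frame()
    assert len(frame) == 3
    assert frame["scale"].iloc[0] == pytest.approx(summer_truth.Ps, rel=1e-6)
    text = res.summary()
    assert "Platt" in text and "replicates: 3" in text
    assert len(res.by_treatment()) == 1


def test_parameter_recovery_coverage_matches_t_expectation(summer_truth):
    """At 5% noise and n = 5, the ±2·SE band around the treatment mean
    covers the truth at close to the Student-t rate P(|t_4| < 2) = 88%;
    assert coverage within its binomial band (>= 78%) over 60 seeds."""
    truth = replace(summer_truth, rate_noise_frac=0.05)
    hits = 0
    runs = 60
    for seed in range(runs):
        curves = simulate_pe_experiment(truth, n_replicates=5, seed=seed)
        fits = [fit_platt(c) for c in curves]
        ders = [derive_params(f) for f in fits]
        s = summarize_treatment(fits, ders, "400T", "summer")
        hits += abs(s.mean["alpha"] - truth.alpha) <= 2 * s.se["alpha"]
    assert hits / runs >= 0.78
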