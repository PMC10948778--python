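"""Tests for preprocessing (dark/drift/normalization) and on-disk formats."""

import math

import numpy as np
import pytest

import trast as T
from trast.io import ParseError, import_raw, read_trast, write_trast
from trast.preprocess import drift_correct, preprocess_recording, subtract_dark
from trast.synthetic import RawPoint, RawRecording, scenario, simulate_recording


def _manual_recording(ref_counts, sci_counts, w0=5e-8, w_sci=1e-4):
    """Alternating reference/science recording with unit exposures."""
    points = []
    idx = 0
    for i, rc in enumerate(ref_counts):
        points.append(RawPoint(w=w0, is_reference=True, raw_counts=rc,
                               index=idx, exposure_s=1.0))
        idx += 1
        if i < len(sci_counts):
            points.append(RawPoint(w=w_sci * (1 + i), is_reference=False,
                                   raw_counts=sci_counts[i], index=idx,
                                   exposure_s=1.0))
            idx += 1
    scheme = T.PulseScheme(w=1e-2, w0=w0)
    return RawRecording(points=points, scheme=scheme, meta={"dark_rate": 0.0})


class TestSubtractDark:
    @pytest.mark.parametrize(
        "raw,dark,expected,clipped",
        [(1000.0, 100.0, 900.0, 0), (50.0, 100.0, 0.0, 1), (0.0, 0.0, 0.0, 0)],
    )
    def test_values(self, raw, dark, expected, clipped):
        net, n = subtract_dark(np.array([raw]), dark)
        assert net[0] == expected and n == clipped

    def test_pathology_warning(self):
        with pytest.warns(UserWarning, match="dark exceeds"):
            subtract_dark(np.array([10.0, 20.0, 500.0]), 100.0)

    def test_validation(self):
        with pytest.raises(ValueError):
            subtract_dark(np.array([-1.0]), 0.0)


class TestDriftCorrect:
    def test_constant_references_identity(self):
        rec = _manual_recording([1000.0] * 4, [800.0, 700.0, 600.0])
        corrected, report = drift_correct(rec, drift_model="interp")
        np.testing.assert_allclose(report.drift_factors, 1.0)
        sci = [p.raw_counts for p in rec.science_points]
        np.testing.assert_allclose(
            corrected[[not p.is_reference for p in rec.points]], sci
        )

    def test_linear_interpolation_midpoint(self):
        # references 1000 -> 900 over indices 0..2; science point at index 1
        # sits midway: factor 0.95
        rec = _manual_recording([1000.0, 900.0], [500.0])
        corrected, report = drift_correct(rec, drift_model="interp")
        assert report.drift_factors[1] == pytest.approx(0.95)
        assert corrected[1] == pytest.approx(500.0 / 0.95)
        assert report.drift_factors[0] == 1.0  # first reference exact

    def test_loglinear_recovers_exponential_drift(self):
        # per-step loss of 1%: reference trace 1000 * 0.99^i
        refs = [1000.0 * 0.99**i for i in (0, 2, 4, 6)]
        rec = _manual_recording(refs, [500.0, 400.0, 300.0])
        corrected, report = drift_correct(rec, drift_model="loglinear")
        np.testing.assert_allclose(
            report.drift_factors,
            0.99 ** np.array([p.index for p in rec.points], float),
            rtol=1e-10,
        )

    def test_requires_two_references(self):
        pts = [
            RawPoint(w=5e-8, is_reference=True, raw_counts=10.0, index=0,
                     exposure_s=1.0),
            RawPoint(w=1e-4, is_reference=False, raw_counts=10.0, index=1,
                     exposure_s=1.0),
        ]
        rec = RawRecording(points=pts, scheme=T.PulseScheme(w=1e-2), meta={})
        with pytest.raises(ValueError, match="at least 2 reference"):
            drift_correct(rec)

    def test_gross_drift_warning(self):
        rec = _manual_recording([1000.0, 100.0], [500.0])
        with pytest.warns(UserWarning, match="gross drift"):
            drift_correct(rec, drift_model="interp")


class TestNormalization:
    def test_w0_self_normalization_noiseless(self, two_state, beam):
        noise = T.NoiseModel(poisson=False, bleach_per_step=0.0, dark_rate=0.0)
        rec = simulate_recording(
            two_state, T.ExcitationConditions(I_exc=10.3), beam,
            T.PulseScheme(w=1e-2), T.default_w_grid(8), noise,
        )
        curve, report = preprocess_recording(rec)
        kbar = T.average_excitation_rate(beam, two_state.rates, 10.3)
        f_fwd = T.trast_point(two_state, kbar, curve.w_values)
        f_w0 = T.trast_point(two_state, kbar, rec.scheme.w0)
        np.testing.assert_allclose(curve.f_norm, f_fwd / f_w0, rtol=1e-9)
        assert report.normalization_rate > 0

    def test_poisson_sem_formula_interp_mode(self, two_state, beam):
        """In the interp drift mode the spec'd error propagation holds
        exactly: sem/f = sqrt(1/N_w + 1/N_w0)."""
        rec = simulate_recording(
            two_state, T.ExcitationConditions(I_exc=10.3), beam,
            T.PulseScheme(w=1e-2), T.default_w_grid(6),
            T.NoiseModel(seed=3, bleach_per_step=0.0, dark_rate=0.0),
        )
        curve, report = preprocess_recording(rec, drift_model="interp")
        n_w = np.asarray(curve.meta["n_net_counts"], float)
        n_w0 = 1.0 / curve.meta["anchor_rel_var"]
        np.testing.assert_allclose(
            curve.sem / curve.f_norm,
            np.sqrt(1.0 / n_w + 1.0 / n_w0),
            rtol=1e-12,
        )

    def test_drift_correction_efficacy(self):
        """With 1%-per-step bleaching, drift-corrected fitted rates deviate
        from the matching no-bleach run by < 5% (Monte Carlo, 20 seeds)."""
        dev_kox, dev_kred = [], []
        for s in range(20):
            fits = {}
            for bleach in (0.0, 0.01):
                sc = scenario(
                    "fig2a_intensity_series", seed=s,
                    noise=T.NoiseModel(bleach_per_step=bleach),
                    w_list=T.default_w_grid(20),
                )
                curves = [preprocess_recording(r)[0] for r in sc.recordings[:3]]
                fits[bleach] = T.fit_global(
                    curves, T.FitSpec(seed=s, multistart=1)
                )
            dev_kox.append(
                abs(fits[0.01].params["k_ox"] / fits[0.0].params["k_ox"] - 1)
            )
            dev_kred.append(
                np.max(np.abs(fits[0.01].params["k_red"]
                              / fits[0.0].params["k_red"] - 1))
            )
        assert np.median(dev_kox) < 0.05
        assert np.median(dev_kred) < 0.05


class TestCurveIO:
    @pytest.fixture
    def curve(self):
        return T.TrastCurve(
            w_values=np.array([1e-7, 1e-5, 1e-3]),
            f_norm=np.array([0.999, 0.93, 0.55]),
            sem=np.array([0.003, 0.004, float("nan")]),
            meta={"i_exc_kw_cm2": 10.3, "label": "Tyr", "custom_key": "kept",
                  "quencher_conc_M": 5e-4},
        )

    @pytest.mark.parametrize("ext", ["csv", "json"])
    def test_round_trip(self, curve, tmp_path, ext):
        path = tmp_path / f"c.{ext}"
        write_trast(curve, path)
        back = read_trast(path)
        np.testing.assert_array_equal(back.w_values, curve.w_values)
        np.testing.assert_array_equal(back.f_norm, curve.f_norm)
        np.testing.assert_array_equal(
            np.isnan(back.sem), np.isnan(curve.sem)
        )
        assert back.meta["custom_key"] == "kept"  # unknown keys preserved
        assert back.meta["i_exc_kw_cm2"] == 10.3
        assert back.meta["quencher_conc_M"] == 5e-4

    def test_missing_sem_column_warns(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("# label: x\npulse_width_s,f_norm\n1e-06,0.9\n1e-05,0.8\n")
        with pytest.warns(UserWarning, match="sem"):
            back = read_trast(p)
        assert np.all(np.isnan(back.sem))

    def test_non_ascending_w_rejected(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text(
            "pulse_width_s,f_norm,sem\n1e-05,0.9,0.01\n1e-06,0.8,0.01\n"
        )
        with pytest.raises(ParseError, match="ascending"):
            read_trast(p)

    def test_malformed_line_number(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("pulse_width_s,f_norm,sem\n1e-06,0.9,0.01\nbad,row\n")
        with pytest.raises(ParseError, match="line 3"):
            read_trast(p)


class TestRawIO:
    def test_raw_round_trip(self, two_state, beam, tmp_path):
        rec = simulate_recording(
            two_state, T.ExcitationConditions(I_exc=10.3), beam,
            T.PulseScheme(w=1e-2), T.default_w_grid(5), T.NoiseModel(seed=5),
        )
        path = tmp_path / "rec.json"
        T.write_raw_recording(rec, path)
        back = T.read_raw_recording(path)
        assert back.points == rec.points
        assert back.scheme == rec.scheme
        assert back.meta == rec.meta
        # importer registry round trip
        recs = import_raw(path, dialect="trast-json")
        assert recs[0].points == rec.points

    def test_unknown_dialect_lists_registered(self, tmp_path):
        with pytest.raises(KeyError, match="trast-json"):
            import_raw(tmp_path / "x.json", dialect="mystery")

    def test_zenodo_stub(self, tmp_path):
        with pytest.raises(NotImplementedError, match="zenodo"):
            import_raw(tmp_path / "x.dat", dialect="zenodo-10419469")


def test_end_to_end_identity(two_state, beam):
    """Noiseless, bleach-free, dark-free simulate → preprocess reproduces
    the forward model within 1e-9 at every pulse width."""
    noise = T.NoiseModel(poisson=False, bleach_per_step=0.0, dark_rate=0.0)
    w_list = T.default_w_grid(30)
    rec = simulate_recording(
        two_state, T.ExcitationConditions(I_exc=10.3), beam,
        T.PulseScheme(w=1e-2), w_list, noise,
    )
    curve, _ = preprocess_recording(rec)
    kbar = T.average_excitation_rate(beam, two_state.rates, 10.3)
    f_fwd = T.trast_point(two_state, kbar, w_list)
    f_w0 = T.trast_point(two_state, kbar, rec.scheme.w0)
    np.testing.assert_allclose(curve.f_norm * f_w0, f_fwd, rtol=1e-9, atol=0)
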