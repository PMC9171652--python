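"""Voltage-clamp analysis: leak subtraction, I-V, classification, tails."""

import numpy as np
import pytest

from coccophys.ephys import (
    CellRecording,
    EphysError,
    IVCurve,
    VoltageProtocol,
    classify_outward,
    density_at,
    iv_curve,
    leak_subtract,
    series_resistance_qc,
    tail_peaks_from_sweeps,
    tail_reversal_potential,
)
from coccophys.synth import EphysConfig, gen_current_family, predicted_density_at

PROTO = VoltageProtocol()


def ohmic_recording(r_seal: float = 1.0, n_t: int = 1000) -> CellRecording:
    steps = np.asarray(PROTO.step_levels)
    leak = np.tile((steps - PROTO.holding) / r_seal, (n_t, 1))
    return CellRecording(
        protocol=PROTO, sweeps=leak, sample_interval=1.0, Cm=40.0, R_seal=r_seal
    )


class TestLeakSubtract:
    def test_pure_leak_cancels_exactly(self):
        rec = leak_subtract(ohmic_recording())
        assert np.all(rec.sweeps == 0.0)

    def test_ohms_law_amount(self):
        # a +100 mV excursion across a 1 GOhm seal is 100 pA of leak
        proto = VoltageProtocol(holding=-80.0, step_levels=(20.0,))
        raw = CellRecording(
            protocol=proto, sweeps=np.zeros((10, 1)),
            sample_interval=1.0, Cm=40.0, R_seal=1.0,
        )
        rec = leak_subtract(raw)
        assert np.allclose(rec.sweeps, -100.0)

    def test_residual_is_known_conductance(self):
        cfg = EphysConfig(noise_sd=0.0)
        with_leak = gen_current_family(cfg, seed=0)
        pure = gen_current_family(
            EphysConfig(noise_sd=0.0, R_seal=1e12), seed=0
        )
        rec = leak_subtract(with_leak)
        assert np.allclose(rec.sweeps, pure.sweeps, atol=1e-9)

    def test_missing_seal_resistance(self):
        rec = CellRecording(
            protocol=PROTO, sweeps=np.zeros((10, len(PROTO.step_levels))),
            sample_interval=1.0, Cm=40.0, R_seal=None,
        )
        with pytest.raises(EphysError, match="R_seal"):
            leak_subtract(rec)


class TestIVCurve:
    def test_steady_state_density(self):
        # conductance reaching 200 pA steady state in a 40 pF cell -> 5 pA/pF
        sweeps = np.zeros((1000, len(PROTO.step_levels)))
        top = len(PROTO.step_levels) - 1
        t = np.arange(1000.0)
        sweeps[:, top] = 200.0 * (1.0 - np.exp(-t / 100.0))
        rec = CellRecording(
            protocol=PROTO, sweeps=sweeps, sample_interval=1.0,
            Cm=40.0, R_seal=1.0, leak_subtracted=True,
        )
        iv = iv_curve(rec)
        assert iv.current_density[top] == pytest.approx(5.0, rel=1e-3)

    def test_zero_family_flat(self):
        rec = CellRecording(
            protocol=PROTO, sweeps=np.zeros((1000, len(PROTO.step_levels))),
            sample_interval=1.0, Cm=40.0, R_seal=1.0, leak_subtracted=True,
        )
        assert all(d == 0.0 for d in iv_curve(rec).current_density)

    def test_doubling_cm_halves_density(self):
        cfg = EphysConfig()
        rec = leak_subtract(gen_current_family(cfg, seed=1))
        dense = iv_curve(rec)
        big = CellRecording(
            protocol=rec.protocol, sweeps=rec.sweeps, sample_interval=1.0,
            Cm=2 * cfg.Cm, R_seal=cfg.R_seal, leak_subtracted=True,
        )
        assert np.allclose(
            iv_curve(big).current_density,
            0.5 * np.asarray(dense.current_density),
        )

    def test_density_invariant_under_joint_scaling(self):
        cfg = EphysConfig()
        rec = leak_subtract(gen_current_family(cfg, seed=1))
        scaled = CellRecording(
            protocol=rec.protocol, sweeps=3.0 * rec.sweeps, sample_interval=1.0,
            Cm=3.0 * cfg.Cm, R_seal=cfg.R_seal, leak_subtracted=True,
        )
        assert np.allclose(
            iv_curve(scaled).current_density, iv_curve(rec).current_density
        )

    def test_requires_leak_subtraction(self):
        with pytest.raises(EphysError, match="leak"):
            iv_curve(ohmic_recording())


class TestClassification:
    @staticmethod
    def flat_iv(density: float) -> IVCurve:
        v = tuple(float(x) for x in range(-80, 41, 10))
        return IVCurve(voltages=v, current_density=(density,) * len(v))

    def test_small_current_is_defective(self):
        assert classify_outward(self.flat_iv(1.0)) == "defective"

    def test_large_current_is_responsive(self):
        assert classify_outward(self.flat_iv(10.0)) == "responsive"

    def test_threshold_boundary_is_responsive(self):
        assert classify_outward(self.flat_iv(2.5)) == "responsive"

    def test_extrapolation_to_45mv(self):
        # density rising 0.1 pA/pF per mV: 4.0 at +40 -> 4.5 at +45
        v = np.arange(-80.0, 41.0, 10.0)
        iv = IVCurve(
            voltages=tuple(v), current_density=tuple(0.1 * (v - 0.0))
        )
        assert density_at(iv, 45.0) == pytest.approx(4.5)

    def test_protocol_without_depolarized_steps_errors(self):
        iv = IVCurve(voltages=(-80.0, -70.0), current_density=(0.0, 0.0))
        with pytest.raises(EphysError, match="outside"):
            classify_outward(iv)

    def test_flip_tracks_generator_amplitude(self):
        # sweep the conductance amplitude through the 2.5 pA/pF point
        for g in np.linspace(0.2, 2.0, 16):
            cfg = EphysConfig(g_out=float(g))
            iv = iv_curve(leak_subtract(gen_current_family(cfg, seed=0)))
            expected = (
                "defective" if predicted_density_at(cfg) < 2.5 else "responsive"
            )
            assert classify_outward(iv) == expected


class TestTailAnalysis:
    def test_exact_linear_tails(self):
        pts = [(v, 0.5 * (v + 20.0)) for v in (-60.0, -40.0, -20.0, 0.0)]
        assert tail_reversal_potential(pts) == pytest.approx(-20.0, abs=1e-9)

    def test_noisy_tails_recover_reversal(self):
        rng = np.random.default_rng(3)
        v = np.arange(-40.0, 41.0, 10.0)
        pts = [(vv, 2.0 * (vv - 5.0) + rng.uniform(-0.1, 0.1)) for vv in v]
        assert tail_reversal_potential(pts) == pytest.approx(5.0, abs=0.5)

    def test_constant_tails_have_no_reversal(self):
        with pytest.raises(EphysError, match="no reversal"):
            tail_reversal_potential([(-40.0, 2.0), (-20.0, 2.0), (0.0, 2.0)])

    def test_too_few_points(self):
        with pytest.raises(EphysError, match=">= 3"):
            tail_reversal_potential([(-40.0, 1.0), (0.0, 2.0)])

    def test_peak_extraction_skips_capacitive_blank(self):
        t = np.arange(0.0, 100.0, 1.0)
        sweep = (10.0 * np.exp(-t / 15.0))[:, None]
        sweep[0, 0] = 500.0  # capacitive spike inside the blank window
        peaks = tail_peaks_from_sweeps(sweep, [-40.0], 1.0, tail_start=0.0)
        assert peaks[0][1] == pytest.approx(10.0 * np.exp(-2.0 / 15.0), rel=1e-9)

    def test_erev_recovery_unbiased_over_range(self):
        from coccophys.synth import gen_tail_family

        rng = np.random.default_rng(42)
        errs = []
        for _ in range(200):
            e_rev = float(rng.uniform(-80.0, 20.0))
            cfg = EphysConfig(E_rev=e_rev, noise_sd=0.0)
            sweeps, levels, start = gen_tail_family(cfg, seed=0)
            got = tail_reversal_potential(
                tail_peaks_from_sweeps(sweeps, levels, 1.0, start)
            )
            errs.append(got - e_rev)
        assert np.max(np.abs(errs)) < 0.1


class TestSeriesResistanceQC:
    def base(self, rs):
        return CellRecording(
            protocol=PROTO, sweeps=np.zeros((10, len(PROTO.step_levels))),
            sample_interval=1.0, Cm=40.0, R_seal=1.0, Rs_series=rs,
        )

    def test_constant_passes(self):
        assert series_resistance_qc(self.base((10.0, 10.0, 10.0))) is True

    def test_twenty_percent_rise_fails(self):
        assert series_resistance_qc(self.base((10.0, 11.0, 12.0))) is False

    def test_ten_percent_rise_passes(self):
        assert series_resistance_qc(self.base((10.0, 10.5, 11.0))) is True

    def test_missing_series_is_indeterminate(self):
        assert series_resistance_qc(self.base(None)) is None
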