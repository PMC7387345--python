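import numpy as np
import pytest

from p53combo.network import PTEN_CANCER
from p53combo.optimize import (
    IRRADIATION_RATIO,
    IrScanPoint,
    MultimodalRatioCurve,
    NoOptimumError,
    PlausibilityVerdict,
    RatioCurve,
    _verification_cycles,
    optimal_inhibitor_dose,
    ratio_curve,
    verify_protocol,
)
from p53combo.protocols import make_protocol


def _curve(doses, ratios):
    n = len(doses)
    return RatioCurve("p", "PTEN-cancer", 10.0, tuple(doses), tuple(ratios),
                      (np.nan,) * n, (np.nan,) * n)


class TestOptimalDose:
    def test_unimodal_peak(self):
        c = _curve((0, 1, 2, 3, 4), (0.0, 0.5, 1.2, 0.9, 0.4))
        assert optimal_inhibitor_dose(c) == 2

    def test_plateau_ties_break_low(self):
        c = _curve((0, 1, 2, 3), (0.0, 1.0, 1.0, 1.0))
        assert optimal_inhibitor_dose(c) == 1

    def test_all_zero_raises(self):
        c = _curve((0, 1, 2), (0.0, 0.0, 0.0))
        with pytest.raises(NoOptimumError):
            optimal_inhibitor_dose(c)

    def test_multimodal_warns(self):
        c = _curve((0, 1, 2, 3, 4), (0.0, 1.0, 0.2, 1.1, 0.0))
        with pytest.warns(MultimodalRatioCurve):
            d = optimal_inhibitor_dose(c)
        assert d == 3  # global maximum

    def test_argmax_equals_exhaustive_scan(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            r = np.abs(rng.normal(size=8))
            r[0] = 0.0
            c = _curve(tuple(range(8)), tuple(r))
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                got = optimal_inhibitor_dose(c)
            brute = c.doses[int(np.argmax(r))]
            assert got == brute


class TestRatioCurveValidation:
    def test_grid_must_start_at_zero(self, network):
        prot = make_protocol(24, 3, None, (6.0, 18.0), 0.0, "oral")
        with pytest.raises(ValueError, match="start at 0"):
            ratio_curve(network, prot, PTEN_CANCER, 10.0, (1.0, 2.0))

    def test_grid_must_ascend(self, network):
        prot = make_protocol(24, 3, None, (6.0, 18.0), 0.0, "oral")
        with pytest.raises(ValueError, match="ascending"):
            ratio_curve(network, prot, PTEN_CANCER, 10.0, (0.0, 2.0, 1.0))


class TestRatioCurveOnModel:
    def test_zero_dose_ratio_is_zero_for_resistant_cancer(self, network):
        """R(0) = 0: without inhibitor, PTEN-cancer cells are
        radiation-resistant so the normal/cancer IR_crit ratio vanishes."""
        prot = make_protocol(24, 6, None, (6.0, 18.0), 0.0, "oral")
        curve = ratio_curve(network, prot, PTEN_CANCER, 10.0, (0.0, 10.0),
                            tolerance=0.1)
        assert curve.ratios[0] == 0.0
        assert not np.isfinite(curve.ir_crit_cancer[0])
        # with a substantial dose the cancer cells become radiosensitive
        assert np.isfinite(curve.ir_crit_cancer[1])
        assert curve.ratios[1] > 0


class TestVerificationScaffolding:
    def test_seven_cycle_horizons(self):
        assert _verification_cycles(24) == 7
        assert _verification_cycles(36) == 7
        # shorter cycles run a matched ~168-h duration
        assert _verification_cycles(12) == 14
        assert _verification_cycles(18) == 9

    def test_scan_point_plausibility_thresholds(self):
        ok = IrScanPoint(1.0, 0.97, (0.9, 1.0), 0.05, (0.0, 0.12))
        assert ok.plausible
        assert ok.ir_normal == pytest.approx(1.0 / IRRADIATION_RATIO)
        bad_cancer = IrScanPoint(1.0, 0.90, (0.8, 0.96), 0.05, (0.0, 0.12))
        assert not bad_cancer.plausible
        bad_normal = IrScanPoint(1.0, 0.99, (0.9, 1.0), 0.15, (0.05, 0.3))
        assert not bad_normal.plausible
        unevaluated = IrScanPoint(1.0, 0.5, (0.3, 0.7), float("nan"),
                                  (float("nan"), float("nan")))
        assert not unevaluated.plausible

    def test_verdict_ir_opt_is_lowest_plausible(self):
        pts = (
            IrScanPoint(0.8, 0.80, (0.7, 0.9), 0.02, (0.0, 0.1)),
            IrScanPoint(1.0, 0.97, (0.9, 1.0), 0.04, (0.0, 0.1)),
            IrScanPoint(1.2, 0.99, (0.9, 1.0), 0.30, (0.2, 0.4)),
        )
        v = PlausibilityVerdict("p", "PTEN-cancer", 10.0, 5.0, 1.0, pts,
                                100, 0)
        assert v.plausible
        assert v.ir_opt == 1.0

    def test_verify_requires_finite_ircrit(self, network):
        # monotherapy-resistant cancer at zero inhibitor dose: the IR scan
        # range is undefined
        prot = make_protocol(24, 6, None, (6.0, 18.0), 0.0, "oral")
        with pytest.raises(ValueError, match="unbounded"):
            verify_protocol(network, prot, PTEN_CANCER, 0.0, 10.0, 2, 0,
                            n_ir=2)


class TestVerifyOnModel:
    def test_exposure_accounting_and_verdict(self, network):
        """Normal cells receive exactly IR/3 and a 1/specificity effective
        inhibitor dose; the verdict records both factors."""
        prot = make_protocol(24, 6, None, (6.0, 18.0), 10.0, "oral",
                             name="24h_6_18")
        v = verify_protocol(network, prot, PTEN_CANCER, 10.0, 10.0,
                            n_cells=20, seed0=1, n_ir=2)
        assert v.normal_ir_factor == pytest.approx(1 / 3)
        assert v.normal_dose_factor == pytest.approx(1 / 10)
        for p in v.scan:
            assert p.ir_normal == pytest.approx(p.ir_cancer / 3)
        irs = [p.ir_cancer for p in v.scan]
        assert irs[0] == pytest.approx(0.8 * v.ir_crit_cancer)
        assert irs[-1] == pytest.approx(1.5 * v.ir_crit_cancer)

    def test_verification_reproducible(self, network):
        prot = make_protocol(24, 6, None, (6.0, 18.0), 10.0, "oral")
        a = verify_protocol(network, prot, PTEN_CANCER, 10.0, 10.0, 10, 7,
                            n_ir=2)
        b = verify_protocol(network, prot, PTEN_CANCER, 10.0, 10.0, 10, 7,
                            n_ir=2)
        # repr comparison is NaN-tolerant (unevaluated arms are NaN)
        assert repr(a) == repr(b)
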