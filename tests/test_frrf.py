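import numpy as np
import pandas as pd
import pytest

from frrfprod.frrf import (
    InstrumentConfig,
    derive_photophys,
    electron_transport,
    photophys_table,
    qc_filter,
    rcii_concentration,
)


def frame(**overrides):
    base = {
        "date": "2018-07-23",
        "station_id": "12B",
        "basin": "north",
        "depth_m": 2.5,
        "excitation_combo": "444+512+633",
        "fo": 0.2,
        "fm": 0.5,
        "fo_prime": 0.2,
        "fm_prime": 0.4,
        "f_prime": 0.3,
        "sigma_psii": 5.0,
        "sigma_psii_prime": 4.5,
        "rsigma_psii": 0.045,
        "rsigma_psii_prime": 0.048,
        "par": 300.0,
    }
    base.update(overrides)
    return pd.DataFrame([base])


class TestQcFilter:
    def test_typical_row_kept(self):
        kept, rejected, _ = qc_filter(frame(rsigma_psii=0.045, rsigma_psii_prime=0.048))
        assert len(kept) == 1 and len(rejected) == 0

    def test_low_rsigma_rejected(self):
        kept, rejected, _ = qc_filter(frame(rsigma_psii=0.02))
        assert len(kept) == 0
        assert rejected["reject_reason"].iloc[0] == "rsigma_out_of_band"

    @pytest.mark.parametrize("value", [0.03, 0.08])
    def test_boundaries_inclusive(self, value):
        kept, rejected, _ = qc_filter(
            frame(rsigma_psii=value, rsigma_psii_prime=value)
        )
        assert len(kept) == 1 and len(rejected) == 0

    def test_missing_rsigma_gets_reason_code(self):
        kept, rejected, _ = qc_filter(frame(rsigma_psii=np.nan))
        assert len(kept) == 0
        assert rejected["reject_reason"].iloc[0] == "missing_rsigma"

    def test_partition_is_lossless(self, rng):
        rows = pd.concat(
            [frame(rsigma_psii=v) for v in rng.uniform(0.0, 0.12, 60)],
            ignore_index=True,
        )
        kept, rejected, _ = qc_filter(rows)
        assert len(kept) + len(rejected) == len(rows)
        assert set(kept.index).isdisjoint(rejected.index)

    def test_summary_reports_per_combination_stats(self):
        rows = pd.concat(
            [
                frame(excitation_combo="444", rsigma_psii=0.036),
                frame(excitation_combo="444", rsigma_psii=0.040),
                frame(excitation_combo="444+512+633", rsigma_psii=0.045),
            ],
            ignore_index=True,
        )
        _, _, summary = qc_filter(rows)
        summary = summary.set_index("excitation_combo")
        assert summary.loc["444", "n"] == 2
        assert summary.loc["444", "rsigma_median"] == pytest.approx(0.038)
        assert summary.loc["444+512+633", "rsigma_median"] == pytest.approx(0.045)


class TestPhotophysiology:
    def test_qp_endpoints(self):
        closed = derive_photophys(frame(f_prime=0.2))  # F' = Fo'
        assert closed["qp"].iloc[0] == pytest.approx(0.0)
        open_ = derive_photophys(frame(f_prime=0.4))  # F' = Fm'
        assert open_["qp"].iloc[0] == pytest.approx(1.0)

    def test_definition_arithmetic(self):
        out = derive_photophys(frame(fo=1.0, fm=2.0, fo_prime=1.0, fm_prime=3.0, f_prime=2.0))
        assert out["fv_fm"].iloc[0] == pytest.approx(0.5)
        assert out["npq_nsv"].iloc[0] == pytest.approx(0.5)

    def test_degenerate_ambient_yields_flagged(self):
        out = derive_photophys(frame(fm_prime=0.2, fo_prime=0.2, f_prime=0.2))
        assert not out["qp_defined"].iloc[0]
        assert np.isnan(out["qp"].iloc[0])


class TestRcii:
    def test_zero_fo_gives_zero(self):
        inst = InstrumentConfig()
        assert rcii_concentration(0.0, 5.0, inst) == 0.0

    def test_direct_evaluation(self):
        # K_R/E_FRRf = 1e12, Fo = 0.5, sigma = 5 -> 1e12 * 0.1 * 1e-9 = 100
        inst = InstrumentConfig(kr=1.0e12, e_frrf_power=1.0)
        assert rcii_concentration(0.5, 5.0, inst) == pytest.approx(100.0, rel=1e-12)

    def test_homogeneity(self):
        inst = InstrumentConfig()
        base = rcii_concentration(0.4, 4.0, inst)
        assert rcii_concentration(0.8, 4.0, inst) == pytest.approx(2 * base)
        assert rcii_concentration(0.4, 8.0, inst) == pytest.approx(base / 2)

    def test_zero_sigma_rejected(self):
        with pytest.raises(ValueError):
            rcii_concentration(0.5, 0.0, InstrumentConfig())


class TestElectronTransport:
    def test_dark_and_closed_limits(self):
        assert electron_transport(0.0, 4.5, 0.7) == 0.0
        assert electron_transport(500.0, 4.5, 0.0) == 0.0

    def test_jf_is_per_rcii(self):
        """Scaling the fluorescence signal (hence RCII) leaves J_f unchanged
        and scales JV_f linearly — J_f is an RCII-normalised rate."""
        inst = InstrumentConfig()
        base = photophys_table(frame(), inst)
        scaled = photophys_table(
            frame(fo=0.4, fm=1.0, fo_prime=0.4, fm_prime=0.8, f_prime=0.6), inst
        )
        assert scaled["j_f"].iloc[0] == pytest.approx(base["j_f"].iloc[0], rel=1e-12)
        assert scaled["rcii"].iloc[0] == pytest.approx(2 * base["rcii"].iloc[0], rel=1e-12)
        assert scaled["jv_f"].iloc[0] == pytest.approx(2 * base["jv_f"].iloc[0], rel=1e-12)

    def test_jv_f_consistency(self):
        out = photophys_table(frame(), InstrumentConfig(), scf=0.9)
        assert out["jv_f"].iloc[0] == pytest.approx(
            out["j_f"].iloc[0] * out["rcii"].iloc[0], rel=1e-12
        )


def test_instrument_validation():
    with pytest.raises(ValueError):
        InstrumentConfig(kr=-1.0)
    with pytest.raises(ValueError):
        InstrumentConfig(led_combination=(444, 999))
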