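"""Empirical/modeled MMNm construction and sensor selection."""

import numpy as np
import pytest
from dataclasses import replace

from mmnadd.mmn import (
    MMNmWave,
    SensorSelection,
    additivity_difference,
    empirical_mmnm,
    grand_average,
    modeled_mmnm,
    peak_latency,
    select_peak_sensors,
)
from mmnadd.paradigm import DeviantType
from mmnadd.preprocess import PreprocessParams
from mmnadd.simulate import make_layout, simulate_subject
from mmnadd.study import _preprocess_fast, build_mmnms


@pytest.fixture()
def quiet_evokeds(quiet_config, layout24):
    ep = simulate_subject(quiet_config, layout24, "musician", 1)
    evk, _ = _preprocess_fast(ep, PreprocessParams())
    return evk


@pytest.fixture()
def quiet_waves(quiet_evokeds):
    return build_mmnms(quiet_evokeds)


def _wave(data, dev=DeviantType.F, kind="empirical", subject="s0", group="musician"):
    return MMNmWave(
        data=data,
        channel_names=[f"MEG{i:03d}" for i in range(data.shape[0])],
        deviant_type=dev,
        kind=kind,
        subject_id=subject,
        group=group,
        paradigm="complex",
        fs_hz=250.0,
        t0_s=-0.1,
    )


class TestEmpiricalMmnm:
    def test_deviant_equal_standard_gives_zero(self, quiet_evokeds):
        std = quiet_evokeds[DeviantType.STD]
        fake_dev = std.copy()
        fake_dev.condition = DeviantType.F
        w = empirical_mmnm(fake_dev, std)
        assert not w.data.any()
        assert w.kind == "empirical"

    def test_peak_amplitude_matches_generator(self, quiet_config, layout24, quiet_evokeds):
        w = empirical_mmnm(quiet_evokeds[DeviantType.F], quiet_evokeds[DeviantType.STD])
        amp = quiet_config.features[DeviantType.F].amplitude
        # the 1 Hz two-pass high-pass removes a sizable share of the pulse's
        # low-frequency content, so the peak lands below the nominal amplitude
        assert 0.55 * amp < w.data.max() < amp
        t = w.times()
        assert abs(t[np.argmax(w.data.max(axis=0))] - 0.156) <= 0.004

    def test_antisymmetry(self, quiet_evokeds):
        dev, std = quiet_evokeds[DeviantType.F], quiet_evokeds[DeviantType.STD]
        w = empirical_mmnm(dev, std)
        swapped_std = dev.copy()
        swapped_std.condition = DeviantType.STD
        swapped_dev = std.copy()
        swapped_dev.condition = DeviantType.F
        v = empirical_mmnm(swapped_dev, swapped_std)
        assert np.allclose(v.data, -w.data)

    def test_standard_argument_enforced(self, quiet_evokeds):
        with pytest.raises(ValueError):
            empirical_mmnm(quiet_evokeds[DeviantType.F], quiet_evokeds[DeviantType.I])


class TestModeledMmnm:
    def test_double_and_triple_composition(self, quiet_waves):
        emp = {w.deviant_type: w for w in quiet_waves if w.kind == "empirical"}
        fi = modeled_mmnm([emp[DeviantType.F], emp[DeviantType.I]])
        assert fi.deviant_type is DeviantType.FI
        fil = modeled_mmnm([emp[DeviantType.F], emp[DeviantType.I], emp[DeviantType.L]])
        assert fil.deviant_type is DeviantType.FIL
        assert np.allclose(fi.data, emp[DeviantType.F].data + emp[DeviantType.I].data)

    def test_summation_commutes(self, quiet_waves):
        emp = {w.deviant_type: w for w in quiet_waves if w.kind == "empirical"}
        a = modeled_mmnm([emp[DeviantType.F], emp[DeviantType.I]])
        b = modeled_mmnm([emp[DeviantType.I], emp[DeviantType.F]])
        assert np.array_equal(a.data, b.data)

    def test_zero_wave_is_identity(self, quiet_waves):
        emp = {w.deviant_type: w for w in quiet_waves if w.kind == "empirical"}
        zero = emp[DeviantType.I].copy()
        zero.data = np.zeros_like(zero.data)
        s = modeled_mmnm([emp[DeviantType.F], zero])
        assert np.allclose(s.data, emp[DeviantType.F].data)

    def test_invalid_constituents_rejected(self, quiet_waves):
        emp = {w.deviant_type: w for w in quiet_waves if w.kind == "empirical"}
        with pytest.raises(ValueError):
            modeled_mmnm([emp[DeviantType.F]])
        with pytest.raises(ValueError):
            modeled_mmnm([emp[DeviantType.F], emp[DeviantType.FI]])


class TestAdditivityDifference:
    def test_zero_for_additive_noise_free_data(self, quiet_waves):
        by_key = {(w.deviant_type, w.kind): w for w in quiet_waves}
        for combo in DeviantType.combinations():
            d = additivity_difference(by_key[(combo, "empirical")], by_key[(combo, "modeled")])
            assert np.abs(d).max() < 1e-8

    def test_shrinkage_shows_as_negative_difference(self, quiet_config, layout24):
        cfg = replace(quiet_config, kappa={"musician": {"FI": 0.3}, "nonmusician": {}})
        ep = simulate_subject(cfg, layout24, "musician", 1)
        evk, _ = _preprocess_fast(ep, PreprocessParams())
        waves = {(w.deviant_type, w.kind): w for w in build_mmnms(evk)}
        emp, mod = waves[(DeviantType.FI, "empirical")], waves[(DeviantType.FI, "modeled")]
        d = additivity_difference(emp, mod)
        peak = np.unravel_index(np.argmax(mod.data), mod.data.shape)
        assert d[peak] == pytest.approx(-0.3 * mod.data[peak], rel=0.02)

    def test_swap_negates(self, quiet_waves):
        by_key = {(w.deviant_type, w.kind): w for w in quiet_waves}
        emp, mod = by_key[(DeviantType.FI, "empirical")], by_key[(DeviantType.FI, "modeled")]
        assert np.allclose(
            additivity_difference(emp, mod), -additivity_difference(mod, emp)
        )

    def test_matching_kinds_rejected(self, quiet_waves):
        by_key = {(w.deviant_type, w.kind): w for w in quiet_waves}
        with pytest.raises(ValueError):
            additivity_difference(by_key[(DeviantType.FI, "empirical")],
                                  by_key[(DeviantType.FI, "empirical")])


class TestGrandAverage:
    def test_single_wave_is_identity(self, quiet_waves):
        g = grand_average([quiet_waves[0]])
        assert np.array_equal(g.data, quiet_waves[0].data)

    def test_opposite_waves_cancel(self, quiet_waves):
        w = quiet_waves[0]
        neg = w.copy()
        neg.data = -w.data
        g = grand_average([w, neg])
        assert np.allclose(g.data, 0.0)

    def test_matches_loop_oracle(self, quiet_waves):
        g = grand_average(quiet_waves)
        acc = np.zeros_like(quiet_waves[0].data)
        for w in quiet_waves:
            acc += w.data
        assert np.allclose(g.data, acc / len(quiet_waves))

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            grand_average([])


class TestSensorSelection:
    def test_selection_is_2x9(self, layout24, quiet_waves):
        grand = grand_average([w for w in quiet_waves if w.kind == "empirical"])
        sel = select_peak_sensors(grand, layout24)
        assert sel.n_selected == 18
        assert len(sel.pairs_by_hemisphere["left"]) == 9
        assert len(sel.pairs_by_hemisphere["right"]) == 9
        assert not set(sel.pairs_by_hemisphere["left"]) & set(sel.pairs_by_hemisphere["right"])

    def test_planted_hotspot_found(self, layout24, quiet_waves):
        grand = grand_average(quiet_waves)
        grand.data = np.zeros_like(grand.data)
        k = int(layout24.hemisphere_indices("left")[3])
        t_idx = 60  # within 100-300 ms
        grand.data[k, t_idx] = 5.0
        right = int(layout24.hemisphere_indices("right")[2])
        grand.data[right, t_idx] = 3.0
        sel = select_peak_sensors(grand, layout24)
        assert sel.peak_pairs["left"] == k
        assert sel.peak_pairs["right"] == right

    def test_ties_broken_by_lowest_pair_id(self, layout24, quiet_waves):
        grand = grand_average(quiet_waves)
        grand.data = np.ones_like(grand.data)  # everything tied
        sel = select_peak_sensors(grand, layout24)
        assert sel.peak_pairs["left"] == int(layout24.hemisphere_indices("left").min())

    def test_too_small_hemisphere_rejected(self, quiet_waves):
        tiny = make_layout(12, seed=0)
        grand = grand_average(quiet_waves)
        grand.data = grand.data[:12]
        with pytest.raises(ValueError):
            select_peak_sensors(grand, tiny)

    def test_selection_stable_under_small_noise(self, layout24, quiet_waves):
        grand = grand_average([w for w in quiet_waves if w.kind == "empirical"])
        base = select_peak_sensors(grand, layout24)
        peak = grand.data.max()
        for seed in range(10):
            rng = np.random.default_rng(seed)
            noisy = grand.copy()
            noisy.data = grand.data + rng.normal(0, 0.05 * peak, grand.data.shape)
            sel = select_peak_sensors(noisy, layout24)
            assert sel.peak_pairs == base.peak_pairs

    def test_roundtrip_dict(self, layout24, quiet_waves):
        grand = grand_average(quiet_waves)
        sel = select_peak_sensors(grand, layout24)
        again = SensorSelection.from_dict(sel.to_dict())
        assert again.all_pairs == sel.all_pairs


class TestPeakLatency:
    def test_generator_latency_recovered(self, layout24, quiet_waves):
        grand = grand_average([w for w in quiet_waves if w.kind == "empirical"])
        sel = select_peak_sensors(grand, layout24)
        assert peak_latency(grand, sel) == pytest.approx(0.156, abs=0.004)

    def test_monotone_ramp_peaks_at_right_edge(self, layout24, quiet_waves):
        grand = grand_average(quiet_waves)
        grand.data = np.tile(np.linspace(0, 1, grand.data.shape[1]), (grand.data.shape[0], 1))
        sel = select_peak_sensors(grand, layout24)
        t = grand.times()
        in_window = t[(t >= 0.1) & (t <= 0.3)]
        assert peak_latency(grand, sel) == pytest.approx(in_window[-1])

    def test_scale_invariance(self, layout24, quiet_waves):
        grand = grand_average([w for w in quiet_waves if w.kind == "empirical"])
        sel = select_peak_sensors(grand, layout24)
        scaled = grand.copy()
        scaled.data = 7.3 * grand.data
        assert peak_latency(scaled, sel) == peak_latency(grand, sel)
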