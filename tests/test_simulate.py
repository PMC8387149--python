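import json
from dataclasses import replace

import numpy as np
import pytest

from flyburst.bursts import detect_bursts
from flyburst.effects import percent_change
from flyburst.errors import ConfigError
from flyburst.simulate import (
    ELONGATED_PRESET,
    WILDTYPE_PRESET,
    BehaviorGroupSpec,
    BehaviorSimConfig,
    DistSpec,
    make_fixture_suite,
    simulate_behavior,
    simulate_spike_train,
)


class TestSpikeTrainGenerator:
    def test_same_seed_identical_trains(self):
        cfg = replace(WILDTYPE_PRESET, seed=11)
        t1, g1 = simulate_spike_train(cfg)
        t2, g2 = simulate_spike_train(cfg)
        np.testing.assert_array_equal(t1.spikes, t2.spikes)
        assert g1 == g2

    @pytest.mark.parametrize("preset", [WILDTYPE_PRESET, ELONGATED_PRESET])
    def test_detector_recovers_ground_truth_exactly(self, preset, rng):
        # the generator's guards make truth exact even with noise spikes on
        for _ in range(5):
            train, truth = simulate_spike_train(preset, rng=rng)
            assert detect_bursts(train) == truth

    def test_noise_free_single_regime(self):
        cfg = replace(WILDTYPE_PRESET, noise_spike_rate_hz=0.0, seed=3)
        train, truth = simulate_spike_train(cfg)
        assert train.n_spikes == sum(b.n_spikes for b in truth)

    def test_spikes_respect_train_invariants(self, rng):
        train, _ = simulate_spike_train(WILDTYPE_PRESET, rng=rng)
        assert np.all(np.diff(train.spikes) > 0)
        assert train.spikes[0] >= 0 and train.spikes[-1] <= train.duration_s

    def test_all_ground_truth_bursts_have_three_spikes(self, rng):
        _, truth = simulate_spike_train(ELONGATED_PRESET, rng=rng)
        assert truth and all(b.n_spikes >= 3 for b in truth)

    @pytest.mark.parametrize(
        "bad",
        [
            {"duration_s": 0.0},
            {"isi_cap_s": 0.2},  # cap must stay below the detection threshold
            {"min_gap_s": 0.05},
            {"within_burst_isi": DistSpec("lognormal", 0.2, 0.3)},  # can't fit 3 spikes
        ],
    )
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ConfigError):
            replace(WILDTYPE_PRESET, **bad)

    def test_unknown_family_rejected(self):
        with pytest.raises(ConfigError):
            DistSpec("weibull", 1.0)


class TestBehaviorGenerator:
    def _cfg(self, **kw):
        spec = dict(
            genotype="g", assay="eshock", value=DistSpec("lognormal", 100.0, 0.3), n_animals=50
        )
        spec.update(kw)
        return BehaviorSimConfig(groups=(BehaviorGroupSpec(**spec),), seed=5)

    def test_same_seed_identical_records(self):
        cfg = self._cfg()
        assert simulate_behavior(cfg) == simulate_behavior(cfg)

    def test_tiny_scale_concentrates_at_location(self):
        cfg = self._cfg(value=DistSpec("lognormal", 100.0, 1e-4))
        values = [r.value for r in simulate_behavior(cfg)]
        np.testing.assert_allclose(values, 100.0, rtol=1e-3)

    def test_location_ratio_recovered_by_percent_change(self):
        groups = (
            BehaviorGroupSpec("ctrl", "eshock", DistSpec("gamma", 100.0, 0.3), 4000),
            BehaviorGroupSpec("mut", "eshock", DistSpec("gamma", 300.0, 0.3), 4000),
        )
        records = simulate_behavior(BehaviorSimConfig(groups=groups, seed=2))
        ctrl = [r.value for r in records if r.genotype == "ctrl"]
        mut = [r.value for r in records if r.genotype == "mut"]
        assert percent_change(mut, ctrl) == pytest.approx(200.0, abs=5.0)

    def test_onsets_censored_at_window(self):
        cfg = self._cfg(
            assay="heat", onset=DistSpec("lognormal", 100.0, 0.8), censor_time_s=120.0
        )
        records = simulate_behavior(cfg)
        onsets = [r.onset_time_s for r in records]
        assert any(o is None for o in onsets)
        assert all(o <= 120.0 for o in onsets if o is not None)

    def test_bad_assay_rejected(self):
        with pytest.raises(ConfigError):
            BehaviorGroupSpec("g", "swim", DistSpec("gamma", 1.0), 5)


class TestFixtureSuite:
    def test_suite_files_exist_with_expected_schema(self, fixture_suite):
        for key in ("spikes", "trace_metadata", "behavior", "manifest", "config"):
            assert fixture_suite[key].exists()
        manifest = json.loads(fixture_suite["manifest"].read_text())
        assert set(manifest["spike_genotypes"]) == {"wt_ref", "mut_long"}
        assert manifest["spike_genotypes"]["wt_ref"]["n_traces"] == 13

    def test_regeneration_is_byte_identical(self, fixture_suite, tmp_path):
        seed = json.loads(fixture_suite["manifest"].read_text())["root_seed"]
        again = make_fixture_suite(seed, tmp_path / "again")
        for key, path in fixture_suite.items():
            assert again[key].read_bytes() == path.read_bytes(), key

    def test_different_seed_changes_data(self, fixture_suite, tmp_path):
        other = make_fixture_suite(12345, tmp_path / "other")
        assert other["spikes"].read_bytes() != fixture_suite["spikes"].read_bytes()
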