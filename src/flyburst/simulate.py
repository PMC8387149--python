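"""Ground-truth-labeled synthetic spike trains and behavioral datasets.

The spike-train generator is an alternating renewal process: draw an
inter-burst gap, then a burst whose duration is drawn from a configurable
distribution and filled with spikes at a configurable within-burst ISI
distribution (at least three spikes, enforced by redraw), repeated until
the recording ends.  Isolated noise spikes are superposed as a thinned
Poisson process.  The generator returns the true burst list alongside the
train, and three guards make the ground truth exact by construction
against a detector with ISI threshold ``detect_max_isi_s``:

* within-burst ISIs above ``isi_cap_s`` (strictly below the threshold) are
  redrawn, so a generated burst can never be split;
* inter-burst gaps at or below ``min_gap_s`` (above the threshold) are
  redrawn, so adjacent bursts can never merge;
* noise spikes landing within a guard distance (1.05× the threshold) of any
  existing spike are rejected, so noise can never extend a burst or form a
  spurious one.

Behavioral samples are drawn per genotype from long-right-tailed
(lognormal or gamma) distributions with configurable location and scale;
heat-assay seizure onsets are right-censored at the exposure time.

Distribution specs are parameterised by mean and coefficient of variation
so presets can be stated directly in the units of the emulated quantity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .bursts import Burst
from .datatypes import ASSAYS, BehavioralRecord, SpikeTrain
from .errors import ConfigError
from .io import write_table

__all__ = [
    "DistSpec",
    "SpikeTrainSimConfig",
    "BehaviorGroupSpec",
    "BehaviorSimConfig",
    "simulate_spike_train",
    "simulate_behavior",
    "make_fixture_suite",
    "WILDTYPE_PRESET",
    "ELONGATED_PRESET",
]

_MAX_REDRAWS = 10_000


@dataclass(frozen=True)
class DistSpec:
    """A positive distribution given by family, mean and CV (SD/mean).

    Families: ``lognormal``, ``gamma``, ``exponential`` (CV fixed at 1).
    """

    family: str
    mean: float
    cv: float = 0.3

    def __post_init__(self) -> None:
        if self.family not in ("lognormal", "gamma", "exponential"):
            raise ConfigError(f"unknown distribution family {self.family!r}")
        if not (self.mean > 0 and np.isfinite(self.mean)):
            raise ConfigError(f"mean must be > 0, got {self.mean}")
        if self.family != "exponential" and not (self.cv > 0 and np.isfinite(self.cv)):
            raise ConfigError(f"cv must be > 0, got {self.cv}")

    def sample(self, rng: np.random.Generator, size=None) -> np.ndarray:
        if self.family == "exponential":
            return rng.exponential(self.mean, size=size)
        if self.family == "gamma":
            shape = 1.0 / self.cv**2
            return rng.gamma(shape, self.mean / shape, size=size)
        sigma2 = np.log1p(self.cv**2)
        mu = np.log(self.mean) - sigma2 / 2.0
        return rng.lognormal(mu, np.sqrt(sigma2), size=size)


@dataclass(frozen=True)
class SpikeTrainSimConfig:
    """Parameters of the alternating burst/gap renewal process.

    Defaults emulate a wild-type-like motor-neuron trace: 180 s recording,
    ≈175 ms bursts of ≈14 spikes at ≈0.47 bursts/s, with sparse isolated
    noise spikes.
    """

    duration_s: float = 180.0
    inter_burst_interval: DistSpec = field(
        default_factory=lambda: DistSpec("gamma", 1.955, 0.35)
    )
    burst_duration: DistSpec = field(
        default_factory=lambda: DistSpec("lognormal", 0.175, 0.30)
    )
    within_burst_isi: DistSpec = field(
        default_factory=lambda: DistSpec("lognormal", 0.0135, 0.40)
    )
    noise_spike_rate_hz: float = 0.01
    detect_max_isi_s: float = 0.100
    isi_cap_s: float = 0.095
    min_gap_s: float = 0.300
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.duration_s > 0:
            raise ConfigError(f"duration_s must be > 0, got {self.duration_s}")
        if self.noise_spike_rate_hz < 0:
            raise ConfigError("noise_spike_rate_hz must be >= 0")
        if not 0 < self.isi_cap_s < self.detect_max_isi_s:
            raise ConfigError(
                "isi_cap_s must lie strictly between 0 and detect_max_isi_s"
            )
        if self.min_gap_s <= self.detect_max_isi_s:
            raise ConfigError("min_gap_s must exceed detect_max_isi_s")
        if 2.0 * self.within_burst_isi.mean > self.burst_duration.mean:
            raise ConfigError(
                "within-burst mean ISI too long to fit 3 spikes in a mean-length burst"
            )


def _draw_capped(spec: DistSpec, cap: float, rng: np.random.Generator) -> float:
    for _ in range(_MAX_REDRAWS):
        x = float(spec.sample(rng))
        if x <= cap:
            return x
    raise ConfigError(f"could not draw {spec} below cap {cap}")


def _draw_floored(spec: DistSpec, floor: float, rng: np.random.Generator) -> float:
    for _ in range(_MAX_REDRAWS):
        x = float(spec.sample(rng))
        if x > floor:
            return x
    raise ConfigError(f"could not draw {spec} above floor {floor}")


def _draw_burst(config: SpikeTrainSimConfig, start: float, rng: np.random.Generator) -> List[float]:
    """Spike times of one burst starting at ``start``; >= 3 spikes by redraw."""
    for _ in range(_MAX_REDRAWS):
        dur = float(config.burst_duration.sample(rng))
        spikes = [start]
        while True:
            isi = _draw_capped(config.within_burst_isi, config.isi_cap_s, rng)
            t = spikes[-1] + isi
            if t > start + dur:
                break
            spikes.append(t)
        if len(spikes) >= 3:
            return spikes
    raise ConfigError("could not generate a >=3-spike burst; check ISI vs duration scales")


def simulate_spike_train(
    config: SpikeTrainSimConfig,
    trace_id: str = "sim",
    genotype: str = "",
    cell_type: str = "aCC",
    group_role: str = "control",
    rng: Optional[np.random.Generator] = None,
) -> Tuple[SpikeTrain, List[Burst]]:
    """Simulate one trace; returns the train and the true burst list.

    Reproducible given ``config.seed`` (or an explicit ``rng``, which
    takes precedence so many traces can share one stream).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    spikes: List[float] = []
    truth: List[Burst] = []
    t = 0.0
    while True:
        gap = _draw_floored(config.inter_burst_interval, config.min_gap_s, rng)
        start = t + gap
        if start >= config.duration_s:
            break
        burst_spikes = _draw_burst(config, start, rng)
        if burst_spikes[-1] > config.duration_s:
            break  # no partial bursts at the end of the recording
        spikes.extend(burst_spikes)
        truth.append(
            Burst(
                start_s=burst_spikes[0],
                end_s=burst_spikes[-1],
                n_spikes=len(burst_spikes),
            )
        )
        t = burst_spikes[-1]

    if config.noise_spike_rate_hz > 0:
        n_noise = rng.poisson(config.noise_spike_rate_hz * config.duration_s)
        guard = config.detect_max_isi_s * 1.05
        existing = np.array(sorted(spikes))
        accepted: List[float] = []
        for cand in np.sort(rng.uniform(0.0, config.duration_s, size=n_noise)):
            pool = np.concatenate([existing, np.array(accepted)]) if accepted else existing
            if pool.size and np.min(np.abs(pool - cand)) <= guard:
                continue  # would touch a burst or another noise spike
            accepted.append(float(cand))
        spikes.extend(accepted)

    spikes_arr = np.unique(np.array(spikes, dtype=float))
    train = SpikeTrain(
        trace_id=trace_id,
        spikes=spikes_arr,
        duration_s=config.duration_s,
        genotype=genotype,
        cell_type=cell_type,
        group_role=group_role,
    )
    return train, truth


#: wild-type-like preset: ≈175 ms bursts, ≈14 spikes/burst, ≈0.47 bursts/s
WILDTYPE_PRESET = SpikeTrainSimConfig()

#: elongated-bursting preset: much longer, more variable bursts with more
#: spikes, emulating the mutant phenotype (≈600 ms bursts, ≈23 spikes)
ELONGATED_PRESET = SpikeTrainSimConfig(
    inter_burst_interval=DistSpec("gamma", 1.955, 0.40),
    burst_duration=DistSpec("lognormal", 0.600, 0.50),
    within_burst_isi=DistSpec("lognormal", 0.027, 0.45),
)


@dataclass(frozen=True)
class BehaviorGroupSpec:
    """One genotype × assay sample: value distribution and cohort size.

    For the heat assay, ``onset`` (if given) is the seizure-onset time
    distribution, right-censored at ``censor_time_s`` (exposure window).
    """

    genotype: str
    assay: str
    value: DistSpec
    n_animals: int
    onset: Optional[DistSpec] = None
    censor_time_s: Optional[float] = None

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise ConfigError(f"unknown assay {self.assay!r}; allowed: {', '.join(ASSAYS)}")
        if self.n_animals < 1:
            raise ConfigError("n_animals must be >= 1")


@dataclass(frozen=True)
class BehaviorSimConfig:
    groups: Tuple[BehaviorGroupSpec, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ConfigError("BehaviorSimConfig needs at least one group")


def simulate_behavior(config: BehaviorSimConfig) -> List[BehavioralRecord]:
    """Draw per-genotype behavioral samples; reproducible given the seed.

    Values and onsets are independent marginals; a censored onset means
    the animal did not seize within the observation window.
    """
    rng = np.random.default_rng(config.seed)
    records: List[BehavioralRecord] = []
    for group in config.groups:
        values = group.value.sample(rng, size=group.n_animals)
        onsets: List[Optional[float]] = [None] * group.n_animals
        if group.onset is not None:
            raw = group.onset.sample(rng, size=group.n_animals)
            cutoff = group.censor_time_s if group.censor_time_s is not None else np.inf
            onsets = [float(o) if o <= cutoff else None for o in raw]
        for i in range(group.n_animals):
            records.append(
                BehavioralRecord(
                    animal_id=f"{group.genotype}_{group.assay}_{i:03d}",
                    genotype=group.genotype,
                    assay=group.assay,
                    value=float(values[i]),
                    onset_time_s=onsets[i],
                )
            )
    return records


def _spec_dict(spec: DistSpec) -> dict:
    return {"family": spec.family, "mean": spec.mean, "cv": spec.cv}


def default_fixture_behavior_groups() -> Tuple[BehaviorGroupSpec, ...]:
    """Behavioral groups of the packaged fixture suite.

    A wild-type-like control, a strong and a mild mechanically-sensitive
    mutant (vortex + electroshock), and a heat-sensitive mutant with its
    matched control (heat with censored onsets + electroshock).  Locations
    follow the magnitudes typical of these assays (electroshock control
    ≈ 97 s; strong mutant ≈ 3.4× control; vortex seizures of order
    10–170 s; heat exposure window 120 s).
    """
    ln = lambda mean, cv: DistSpec("lognormal", mean, cv)  # noqa: E731
    return (
        BehaviorGroupSpec("ctrl", "eshock", ln(97.0, 0.25), 25),
        BehaviorGroupSpec("bs_strong", "eshock", ln(334.0, 0.35), 25),
        BehaviorGroupSpec("bs_mild", "eshock", ln(153.0, 0.30), 25),
        BehaviorGroupSpec("hs_ctrl", "eshock", ln(100.0, 0.25), 20),
        BehaviorGroupSpec("hs_severe", "eshock", ln(220.0, 0.35), 20),
        BehaviorGroupSpec("ctrl", "vortex", ln(5.0, 0.50), 25),
        BehaviorGroupSpec("bs_strong", "vortex", ln(168.0, 0.30), 25),
        BehaviorGroupSpec("bs_mild", "vortex", ln(74.0, 0.30), 25),
        BehaviorGroupSpec(
            "hs_ctrl", "heat", ln(5.0, 0.50), 20, onset=ln(300.0, 0.60), censor_time_s=120.0
        ),
        BehaviorGroupSpec(
            "hs_severe", "heat", ln(350.0, 0.50), 20, onset=ln(45.0, 0.60), censor_time_s=120.0
        ),
    )


def make_fixture_suite(root_seed: int, out_dir: Union[str, Path]) -> Dict[str, Path]:
    """Write a small self-describing synthetic dataset for pipeline runs.

    Produces a wild-type-like reference genotype (13 traces), an
    elongated-bursting mutant genotype (12 traces), behavioral tables for
    mock mechanically- and heat-sensitive genotypes with controls, and a
    ``manifest.json`` recording every true generator parameter for use as
    a test oracle.  Byte-identical for a given ``root_seed``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spike_rows: List[dict] = []
    meta_rows: List[dict] = []
    truth_rows: List[dict] = []
    genotype_specs = {
        "wt_ref": (WILDTYPE_PRESET, 13, "wildtype_reference"),
        "mut_long": (ELONGATED_PRESET, 12, "mutant"),
    }
    for gi, (genotype, (preset, n_traces, role)) in enumerate(genotype_specs.items()):
        for i in range(n_traces):
            trace_id = f"{genotype}_{i:02d}"
            cfg = replace(preset, seed=0)  # seeding handled via the shared stream
            rng = np.random.default_rng(
                np.random.SeedSequence([int(root_seed), gi, i])
            )
            cell = "aCC" if i % 2 == 0 else "RP2"
            train, truth = simulate_spike_train(
                cfg, trace_id=trace_id, genotype=genotype, cell_type=cell,
                group_role=role, rng=rng,
            )
            spike_rows.extend(
                {"trace_id": trace_id, "spike_time_s": t} for t in train.spikes
            )
            meta_rows.append(
                {
                    "trace_id": trace_id,
                    "genotype": genotype,
                    "cell_type": cell,
                    "group_role": role,
                    "duration_s": cfg.duration_s,
                }
            )
            truth_rows.extend(
                {
                    "trace_id": trace_id,
                    "burst_index": k,
                    "start_s": b.start_s,
                    "end_s": b.end_s,
                    "n_spikes": b.n_spikes,
                }
                for k, b in enumerate(truth)
            )

    behavior_cfg = BehaviorSimConfig(
        groups=default_fixture_behavior_groups(),
        seed=int(np.random.SeedSequence([int(root_seed), 999]).generate_state(1)[0] % (2**31)),
    )
    behavior = simulate_behavior(behavior_cfg)
    behavior_rows = [
        {
            "animal_id": r.animal_id,
            "genotype": r.genotype,
            "assay": r.assay,
            "value": r.value,
            "onset_time_s": "" if r.onset_time_s is None else r.onset_time_s,
        }
        for r in behavior
    ]

    paths = {
        "spikes": out_dir / "spikes.tsv",
        "trace_metadata": out_dir / "trace_metadata.tsv",
        "true_bursts": out_dir / "true_bursts.tsv",
        "behavior": out_dir / "behavior.tsv",
        "manifest": out_dir / "manifest.json",
        "config": out_dir / "config.yaml",
    }
    write_table(pd.DataFrame(spike_rows), paths["spikes"])
    write_table(pd.DataFrame(meta_rows), paths["trace_metadata"])
    write_table(pd.DataFrame(truth_rows), paths["true_bursts"])
    write_table(pd.DataFrame(behavior_rows), paths["behavior"])

    manifest = {
        "root_seed": int(root_seed),
        "spike_genotypes": {
            genotype: {
                "n_traces": n,
                "group_role": role,
                "duration_s": preset.duration_s,
                "inter_burst_interval": _spec_dict(preset.inter_burst_interval),
                "burst_duration": _spec_dict(preset.burst_duration),
                "within_burst_isi": _spec_dict(preset.within_burst_isi),
                "noise_spike_rate_hz": preset.noise_spike_rate_hz,
            }
            for genotype, (preset, n, role) in genotype_specs.items()
        },
        "behavior_groups": [
            {
                "genotype": g.genotype,
                "assay": g.assay,
                "value": _spec_dict(g.value),
                "n_animals": g.n_animals,
                "onset": None if g.onset is None else _spec_dict(g.onset),
                "censor_time_s": g.censor_time_s,
            }
            for g in behavior_cfg.groups
        ],
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    config_text = f"""\
inputs:
  spikes: spikes.tsv
  trace_metadata: trace_metadata.tsv
  behavior: behavior.tsv
burst:
  max_isi_s: 0.1
  min_spikes: 3
classification:
  reference_genotype: wt_ref
  k: 1.5
bootstrap:
  n_boot: 5000
  ci_method: bca
  seed: {int(root_seed)}
comparisons:
  - {{id: eshock_bs_strong, group_a: ctrl, group_b: bs_strong, assay: eshock}}
  - {{id: eshock_bs_mild, group_a: ctrl, group_b: bs_mild, assay: eshock}}
  - {{id: eshock_hs_severe, group_a: hs_ctrl, group_b: hs_severe, assay: eshock}}
  - {{id: vortex_bs_strong, group_a: ctrl, group_b: bs_strong, assay: vortex}}
  - {{id: vortex_bs_mild, group_a: ctrl, group_b: bs_mild, assay: vortex}}
  - {{id: heat_hs_severe, group_a: hs_ctrl, group_b: hs_severe, assay: heat}}
regression:
  x_assay: eshock
  y_assay_by_genotype: {{bs_strong: vortex, bs_mild: vortex, hs_severe: heat}}
  control_by_genotype: {{bs_strong: ctrl, bs_mild: ctrl, hs_severe: hs_ctrl}}
heat_curve:
  t_max_s: 120
  checkpoint_step_s: 10
output_dir: out
"""
    paths["config"].write_text(config_text)
    return paths
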