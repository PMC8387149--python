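"""Config-driven end-to-end analysis runner.

``run_pipeline`` composes the stages — read spikes/behavior → detect bursts
→ per-trace and per-genotype summaries → reference-band classification and
elongated fractions → bootstrap effect sizes, percent changes, cumulative
heat-seizing curves → cross-assay effect-size regression — and writes one
TSV per product plus a plain-text run log.

All randomness derives from one root seed; each comparison draws from a
child stream keyed by its group labels, so adding comparisons never
perturbs existing results.  Product tables are byte-deterministic for a
given config; the run log carries timestamps and is the one
non-reproducible output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bursts import BurstParams, detect_bursts
from .classify import ReferenceBandClassifier, fraction_elongated
from .datatypes import BehavioralRecord
from .effects import (
    bootstrap_mean_difference,
    child_seed,
    cohens_d,
    cumulative_seizing_fraction,
    fit_effect_size_regression,
    percent_change,
)
from .errors import ConfigError
from .io import read_behavior, read_spike_trains, write_table
from .trace_stats import (
    MS_PER_S,
    genotype_table,
    summaries_to_frame,
    summarize_genotype,
    summarize_trace,
)

__all__ = ["RunConfig", "Comparison", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Comparison:
    """One two-group comparison: group_b measured against group_a (control)."""

    id: str
    group_a: str
    group_b: str
    assay: str


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run needs; loadable from a flat YAML file."""

    spikes_path: Path
    trace_metadata_path: Optional[Path]
    behavior_path: Optional[Path]
    output_dir: Path
    max_isi_s: float = 0.100
    min_spikes: int = 3
    reference_genotype: str = "CS"
    k: float = 1.5
    n_boot: int = 5000
    ci_method: str = "bca"
    seed: int = 0
    comparisons: Tuple[Comparison, ...] = ()
    regression_x_assay: str = "eshock"
    regression_y_assay_by_genotype: Dict[str, str] = field(default_factory=dict)
    regression_control_by_genotype: Dict[str, str] = field(default_factory=dict)
    heat_t_max_s: float = 120.0
    heat_checkpoint_step_s: float = 10.0

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        base = path.parent

        def resolve(rel: Optional[str]) -> Optional[Path]:
            return None if rel is None else (base / rel)

        inputs = raw.get("inputs", {})
        if "spikes" not in inputs:
            raise ConfigError(f"{path}: inputs.spikes is required")
        burst = raw.get("burst", {})
        cls_cfg = raw.get("classification", {})
        boot = raw.get("bootstrap", {})
        reg = raw.get("regression", {})
        heat = raw.get("heat_curve", {})
        comparisons = tuple(
            Comparison(
                id=str(c["id"]),
                group_a=str(c["group_a"]),
                group_b=str(c["group_b"]),
                assay=str(c["assay"]),
            )
            for c in raw.get("comparisons", [])
        )
        return cls(
            spikes_path=resolve(inputs["spikes"]),
            trace_metadata_path=resolve(inputs.get("trace_metadata")),
            behavior_path=resolve(inputs.get("behavior")),
            output_dir=base / raw.get("output_dir", "out"),
            max_isi_s=float(burst.get("max_isi_s", 0.100)),
            min_spikes=int(burst.get("min_spikes", 3)),
            reference_genotype=str(cls_cfg.get("reference_genotype", "CS")),
            k=float(cls_cfg.get("k", 1.5)),
            n_boot=int(boot.get("n_boot", 5000)),
            ci_method=str(boot.get("ci_method", "bca")),
            seed=int(boot.get("seed", 0)),
            comparisons=comparisons,
            regression_x_assay=str(reg.get("x_assay", "eshock")),
            regression_y_assay_by_genotype=dict(reg.get("y_assay_by_genotype", {})),
            regression_control_by_genotype=dict(reg.get("control_by_genotype", {})),
            heat_t_max_s=float(heat.get("t_max_s", 120.0)),
            heat_checkpoint_step_s=float(heat.get("checkpoint_step_s", 10.0)),
        )


def _behavior_values(records: Sequence[BehavioralRecord], genotype: str, assay: str) -> np.ndarray:
    return np.array(
        [r.value for r in records if r.genotype == genotype and r.assay == assay]
    )


def _stage(log_lines: List[str], stage: str, message: str) -> None:
    stamp = datetime.now(timezone.utc).isoformat(timespec="seconds")
    line = f"{stamp} [{stage}] {message}"
    log_lines.append(line)
    log.info("%s: %s", stage, message)


def run_pipeline(config: RunConfig) -> Dict[str, pd.DataFrame]:
    """Run every stage and write all product tables under ``config.output_dir``.

    Returns the product tables keyed by name.  Any stage failure raises
    with the stage name prefixed; tables already written stay on disk and
    the run log marks the run as aborted.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    lines: List[str] = []
    tables: Dict[str, pd.DataFrame] = {}
    _stage(lines, "start", f"flyburst {__version__}, root seed {config.seed}")
    stage = "read"
    try:
        trains = read_spike_trains(config.spikes_path, config.trace_metadata_path)
        _stage(lines, stage, f"{len(trains)} spike train(s) from {config.spikes_path}")
        behavior: List[BehavioralRecord] = []
        if config.behavior_path is not None:
            behavior = read_behavior(config.behavior_path)
            _stage(lines, stage, f"{len(behavior)} behavioral record(s)")

        stage = "bursts"
        params = BurstParams(max_isi_s=config.max_isi_s, min_spikes=config.min_spikes)
        bursts_by_trace = {t.trace_id: detect_bursts(t, params) for t in trains}
        burst_rows = [
            {
                "trace_id": tid,
                "burst_index": k,
                "start_s": b.start_s,
                "end_s": b.end_s,
                "n_spikes": b.n_spikes,
                "duration_s": b.duration_s,
            }
            for tid, bl in bursts_by_trace.items()
            for k, b in enumerate(bl)
        ]
        tables["bursts"] = pd.DataFrame(
            burst_rows,
            columns=["trace_id", "burst_index", "start_s", "end_s", "n_spikes", "duration_s"],
        )
        _stage(
            lines, stage,
            f"{len(burst_rows)} burst(s) (max_isi={params.max_isi_s}s, "
            f"min_spikes={params.min_spikes})",
        )

        stage = "trace_stats"
        summaries = [summarize_trace(t, bursts_by_trace[t.trace_id]) for t in trains]
        tables["trace_summaries"] = summaries_to_frame(summaries)
        genotypes = sorted({t.genotype for t in trains})
        geno_summaries = [summarize_genotype(summaries, g) for g in genotypes]
        tables["genotype_summaries"] = genotype_table(geno_summaries)
        _stage(lines, stage, f"{len(summaries)} trace summarie(s), {len(genotypes)} genotype(s)")

        stage = "classify"
        reference = [s for s in summaries if s.genotype == config.reference_genotype]
        if not reference:
            raise ConfigError(
                f"reference genotype {config.reference_genotype!r} has no traces"
            )
        clf = ReferenceBandClassifier(
            k=config.k, reference_genotype=config.reference_genotype
        ).fit(reference)
        labels = clf.predict(summaries)
        tables["trace_labels"] = pd.DataFrame(
            {
                "trace_id": [s.trace_id for s in summaries],
                "genotype": [s.genotype for s in summaries],
                "mean_burst_duration_ms": [
                    s.mean_burst_duration_s * MS_PER_S for s in summaries
                ],
                "label": labels,
            }
        )
        frac_rows = []
        for g in genotypes:
            sub = [lab for s, lab in zip(summaries, labels) if s.genotype == g]
            res = fraction_elongated(sub)
            frac_rows.append(
                {
                    "genotype": g,
                    "n_classifiable": res.n_classifiable,
                    "n_unclassifiable": res.n_unclassifiable,
                    "n_elongated": res.n_elongated,
                    "fraction_elongated": res.fraction,
                }
            )
        tables["elongated_fractions"] = pd.DataFrame(frac_rows)
        _stage(
            lines, stage,
            f"band [{clf.lower_s_ * MS_PER_S:.2f}, {clf.upper_s_ * MS_PER_S:.2f}] ms "
            f"from {clf.n_reference_traces_} reference trace(s)",
        )

        stage = "effects"
        effect_rows = []
        for comp in config.comparisons:
            a = _behavior_values(behavior, comp.group_a, comp.assay)
            b = _behavior_values(behavior, comp.group_b, comp.assay)
            if a.size < 2 or b.size < 2:
                raise ConfigError(
                    f"comparison {comp.id!r}: missing data for "
                    f"{comp.group_a!r}/{comp.group_b!r} in assay {comp.assay!r}"
                )
            eff = bootstrap_mean_difference(
                a,
                b,
                n_boot=config.n_boot,
                seed=child_seed(config.seed, comp.group_a, comp.group_b, comp.assay),
                ci_method=config.ci_method,
                group_a=comp.group_a,
                group_b=comp.group_b,
            )
            effect_rows.append(
                {
                    "comparison_id": comp.id,
                    "assay": comp.assay,
                    "group_a": comp.group_a,
                    "group_b": comp.group_b,
                    "n_a": eff.n_a,
                    "n_b": eff.n_b,
                    "mean_difference": eff.mean_difference,
                    "ci_low": eff.ci_low,
                    "ci_high": eff.ci_high,
                    "cohens_d": eff.cohens_d,
                    "percent_change": percent_change(b, a),
                    "n_boot": eff.n_boot,
                    "seed": config.seed,
                    "ci_method": eff.ci_method,
                }
            )
        tables["effect_sizes"] = pd.DataFrame(
            effect_rows,
            columns=[
                "comparison_id", "assay", "group_a", "group_b", "n_a", "n_b",
                "mean_difference", "ci_low", "ci_high", "cohens_d",
                "percent_change", "n_boot", "seed", "ci_method",
            ],
        )
        _stage(lines, stage, f"{len(effect_rows)} comparison(s), n_boot={config.n_boot}")

        stage = "heat_curve"
        heat_rows = []
        heat_genotypes = sorted({r.genotype for r in behavior if r.assay == "heat"})
        if heat_genotypes:
            checkpoints = np.arange(
                config.heat_checkpoint_step_s,
                config.heat_t_max_s + config.heat_checkpoint_step_s / 2,
                config.heat_checkpoint_step_s,
            )
            for g in heat_genotypes:
                onsets = [
                    r.onset_time_s for r in behavior if r.genotype == g and r.assay == "heat"
                ]
                curve = cumulative_seizing_fraction(onsets, checkpoints, t_max=config.heat_t_max_s)
                heat_rows.extend(
                    {"genotype": g, "time_s": float(t), "fraction_seizing": float(fr)}
                    for t, fr in zip(checkpoints, curve)
                )
        tables["cumulative_seizing"] = pd.DataFrame(
            heat_rows, columns=["genotype", "time_s", "fraction_seizing"]
        )
        _stage(lines, stage, f"{len(heat_genotypes)} genotype curve(s)")

        stage = "regression"
        reg_points = []
        for genotype, y_assay in sorted(config.regression_y_assay_by_genotype.items()):
            control = config.regression_control_by_genotype.get(genotype)
            if control is None:
                raise ConfigError(f"regression: no control mapped for genotype {genotype!r}")
            x_d = cohens_d(
                _behavior_values(behavior, control, config.regression_x_assay),
                _behavior_values(behavior, genotype, config.regression_x_assay),
            )
            y_d = cohens_d(
                _behavior_values(behavior, control, y_assay),
                _behavior_values(behavior, genotype, y_assay),
            )
            reg_points.append(
                {
                    "genotype": genotype,
                    "control": control,
                    "x_assay": config.regression_x_assay,
                    "y_assay": y_assay,
                    "x_cohens_d": x_d,
                    "y_cohens_d": y_d,
                }
            )
        tables["regression_points"] = pd.DataFrame(
            reg_points,
            columns=["genotype", "control", "x_assay", "y_assay", "x_cohens_d", "y_cohens_d"],
        )
        if len(reg_points) >= 2:
            res = fit_effect_size_regression(
                [p["x_cohens_d"] for p in reg_points],
                [p["y_cohens_d"] for p in reg_points],
                n_boot=config.n_boot,
                seed=child_seed(config.seed, "regression", config.regression_x_assay),
            )
            tables["regression"] = pd.DataFrame(
                [
                    {
                        "slope": res.slope,
                        "intercept": res.intercept,
                        "r_squared": res.r_squared,
                        "n_points": res.n_points,
                        "r2_ci_low": res.r2_ci_low,
                        "r2_ci_high": res.r2_ci_high,
                    }
                ]
            )
        else:
            tables["regression"] = pd.DataFrame(
                columns=["slope", "intercept", "r_squared", "n_points", "r2_ci_low", "r2_ci_high"]
            )
        _stage(lines, stage, f"{len(reg_points)} effect-size point(s)")
    except Exception as exc:
        _stage(lines, stage, f"ABORTED: {exc}")
        (out / "run_log.txt").write_text("\n".join(lines) + "\n")
        try:
            wrapped = type(exc)(f"[stage {stage}] {exc}")
        except Exception:  # exception types with non-trivial constructors
            wrapped = RuntimeError(f"[stage {stage}] {exc}")
        raise wrapped from exc

    for name, df in tables.items():
        write_table(df, out / f"{name}.tsv")
    _stage(lines, "done", f"{len(tables)} table(s) written to {out}")
    (out / "run_log.txt").write_text("\n".join(lines) + "\n")
    return tables
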