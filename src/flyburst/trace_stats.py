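"""Per-trace and per-genotype burst summary statistics.

Each trace yields six burst statistics (mean and SD of burst duration,
burst frequency, firing rate, spikes per burst, within-burst AP frequency);
genotype aggregates are unweighted means over traces, reported with burst
durations in milliseconds.

Conventions fixed here:

* "AP frequency per burst" is the mean over bursts of
  ``n_spikes / burst_duration`` (mean of ratios), the standard per-burst
  statistic; bursts of zero duration are excluded from that mean and logged.
* Burst-duration SD is the sample SD (ddof=1) over the bursts of one trace,
  then averaged across traces of a genotype.
* Rate denominators use the declared recording duration, not the last spike.
* Traces with no bursts carry NaN burst statistics ("flagged") but still
  have a firing rate; genotype means skip the NaNs and count them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .bursts import Burst
from .datatypes import SpikeTrain
from .errors import ValidationError

__all__ = [
    "TraceSummary",
    "GenotypeSummary",
    "summarize_trace",
    "summarize_genotype",
    "summaries_to_frame",
    "genotype_table",
]

log = logging.getLogger(__name__)

#: reported tables carry burst durations in ms; conversion is exact
MS_PER_S = 1000.0


@dataclass(frozen=True)
class TraceSummary:
    """The per-trace statistics; burst fields are NaN when undefined."""

    trace_id: str
    genotype: str
    n_bursts: int
    mean_burst_duration_s: float
    sd_burst_duration_s: float
    burst_frequency_hz: float
    firing_rate_hz: float
    mean_spikes_per_burst: float
    mean_ap_frequency_per_burst_hz: float

    @property
    def classifiable(self) -> bool:
        """True when the trace has at least one burst, so a mean duration exists."""
        return self.n_bursts > 0 and math.isfinite(self.mean_burst_duration_s)


@dataclass(frozen=True)
class GenotypeSummary:
    """Unweighted per-genotype means of the trace statistics."""

    genotype: str
    n_traces: int
    n_traces_with_bursts: int
    mean_burst_duration_s: float
    sd_burst_duration_s: float
    burst_frequency_hz: float
    firing_rate_hz: float
    mean_spikes_per_burst: float
    mean_ap_frequency_per_burst_hz: float


def summarize_trace(train: SpikeTrain, bursts: Sequence[Burst]) -> TraceSummary:
    """Summarise one trace from its detected bursts.

    ``bursts`` must come from the same train (checked loosely: counts and
    time bounds).  A zero-burst trace still gets its firing rate.
    """
    total_spikes_in_bursts = sum(b.n_spikes for b in bursts)
    if total_spikes_in_bursts > train.n_spikes:
        raise ValidationError(
            f"trace {train.trace_id!r}: bursts contain more spikes than the train"
        )
    n_bursts = len(bursts)
    firing_rate = train.n_spikes / train.duration_s
    if n_bursts == 0:
        return TraceSummary(
            trace_id=train.trace_id,
            genotype=train.genotype,
            n_bursts=0,
            mean_burst_duration_s=float("nan"),
            sd_burst_duration_s=float("nan"),
            burst_frequency_hz=0.0,
            firing_rate_hz=firing_rate,
            mean_spikes_per_burst=float("nan"),
            mean_ap_frequency_per_burst_hz=float("nan"),
        )
    durations = np.array([b.duration_s for b in bursts])
    counts = np.array([b.n_spikes for b in bursts], dtype=float)
    positive = durations > 0
    if not np.all(positive):
        log.warning(
            "trace %r: %d zero-duration burst(s) excluded from per-burst AP frequency",
            train.trace_id,
            int((~positive).sum()),
        )
    ap_freq = (
        float(np.mean(counts[positive] / durations[positive]))
        if positive.any()
        else float("nan")
    )
    return TraceSummary(
        trace_id=train.trace_id,
        genotype=train.genotype,
        n_bursts=n_bursts,
        mean_burst_duration_s=float(np.mean(durations)),
        sd_burst_duration_s=float(np.std(durations, ddof=1)) if n_bursts >= 2 else float("nan"),
        burst_frequency_hz=n_bursts / train.duration_s,
        firing_rate_hz=firing_rate,
        mean_spikes_per_burst=float(np.mean(counts)),
        mean_ap_frequency_per_burst_hz=ap_freq,
    )


def summarize_genotype(
    summaries: Sequence[TraceSummary], genotype: Optional[str] = None
) -> GenotypeSummary:
    """Unweighted per-column means over the traces of one genotype.

    Zero-burst traces are excluded from the burst-statistic means but
    included in the firing-rate mean; their count is logged and reported.
    """
    if genotype is not None:
        summaries = [s for s in summaries if s.genotype == genotype]
    if not summaries:
        raise ValidationError(f"no trace summaries for genotype {genotype!r}")
    if genotype is None:
        genotype = summaries[0].genotype
    with_bursts = [s for s in summaries if s.classifiable]
    n_flagged = len(summaries) - len(with_bursts)
    if n_flagged:
        log.info(
            "genotype %r: %d zero-burst trace(s) excluded from burst-statistic means",
            genotype,
            n_flagged,
        )

    def col(attr: str, pool: Sequence[TraceSummary]) -> float:
        if not pool:
            return float("nan")
        vals = np.array([getattr(s, attr) for s in pool])
        return float(np.nanmean(vals)) if np.isfinite(vals).any() else float("nan")

    return GenotypeSummary(
        genotype=genotype,
        n_traces=len(summaries),
        n_traces_with_bursts=len(with_bursts),
        mean_burst_duration_s=col("mean_burst_duration_s", with_bursts),
        sd_burst_duration_s=col("sd_burst_duration_s", with_bursts),
        burst_frequency_hz=col("burst_frequency_hz", summaries),
        firing_rate_hz=col("firing_rate_hz", summaries),
        mean_spikes_per_burst=col("mean_spikes_per_burst", with_bursts),
        mean_ap_frequency_per_burst_hz=col("mean_ap_frequency_per_burst_hz", with_bursts),
    )


def summaries_to_frame(summaries: Sequence[TraceSummary]) -> pd.DataFrame:
    """Trace-summary table with durations reported in ms."""
    rows = [
        {
            "trace_id": s.trace_id,
            "genotype": s.genotype,
            "n_bursts": s.n_bursts,
            "mean_burst_duration_ms": s.mean_burst_duration_s * MS_PER_S,
            "sd_burst_duration_ms": s.sd_burst_duration_s * MS_PER_S,
            "burst_frequency_hz": s.burst_frequency_hz,
            "firing_rate_hz": s.firing_rate_hz,
            "mean_spikes_per_burst": s.mean_spikes_per_burst,
            "mean_ap_frequency_per_burst_hz": s.mean_ap_frequency_per_burst_hz,
        }
        for s in summaries
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "trace_id",
            "genotype",
            "n_bursts",
            "mean_burst_duration_ms",
            "sd_burst_duration_ms",
            "burst_frequency_hz",
            "firing_rate_hz",
            "mean_spikes_per_burst",
            "mean_ap_frequency_per_burst_hz",
        ],
    )


def genotype_table(genotype_summaries: Sequence[GenotypeSummary]) -> pd.DataFrame:
    """Genotype table mirroring the standard report layout (durations in ms)."""
    rows = [
        {
            "genotype": g.genotype,
            "n_traces": g.n_traces,
            "n_traces_with_bursts": g.n_traces_with_bursts,
            "burst_duration_ms": g.mean_burst_duration_s * MS_PER_S,
            "burst_duration_sd_ms": g.sd_burst_duration_s * MS_PER_S,
            "burst_frequency_hz": g.burst_frequency_hz,
            "firing_rate_hz": g.firing_rate_hz,
            "ap_count_per_burst": g.mean_spikes_per_burst,
            "ap_frequency_per_burst_hz": g.mean_ap_frequency_per_burst_hz,
        }
        for g in genotype_summaries
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "genotype",
            "n_traces",
            "n_traces_with_bursts",
            "burst_duration_ms",
            "burst_duration_sd_ms",
            "burst_frequency_hz",
            "firing_rate_hz",
            "ap_count_per_burst",
            "ap_frequency_per_burst_hz",
        ],
    )
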