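"""Core record types shared across the pipeline.

A :class:`SpikeTrain` is one loose-patch recording (or one simulated trace)
reduced to its spike times; a :class:`BehavioralRecord` is one animal's
measurement in one seizure or locomotion assay.  Both validate their
invariants on construction so downstream stages can assume clean input.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ValidationError

#: allowed roles a trace's genotype can play in the analysis
GROUP_ROLES = ("wildtype_reference", "control", "mutant", "treated")

#: recognised behavioral assays; seizure assays measure duration in seconds,
#: locomotion assays distance in mm (adult: mm/h)
ASSAYS = (
    "vortex",
    "heat",
    "eshock",
    "locomotion_day",
    "locomotion_night",
    "larval_crawl",
)


@dataclass(frozen=True)
class SpikeTrain:
    """One recording: strictly increasing spike times (s) on [0, duration_s].

    Parameters
    ----------
    trace_id : str
        Unique identifier of the trace.
    spikes : array-like of float
        Spike times in seconds, strictly increasing.
    duration_s : float
        Declared recording length in seconds (default protocol: 180 s);
        the denominator for all per-trace rates.
    genotype, cell_type, group_role : str
        Metadata carried through to the output tables.  ``cell_type`` is
        typically "aCC" or "RP2".
    """

    trace_id: str
    spikes: np.ndarray
    duration_s: float
    genotype: str = ""
    cell_type: str = ""
    group_role: str = "control"

    def __post_init__(self) -> None:
        spikes = np.asarray(self.spikes, dtype=float)
        object.__setattr__(self, "spikes", spikes)
        if not np.isfinite(self.duration_s) or self.duration_s <= 0:
            raise ValidationError(
                f"trace {self.trace_id!r}: duration_s must be finite and > 0, "
                f"got {self.duration_s}"
            )
        if spikes.ndim != 1:
            raise ValidationError(f"trace {self.trace_id!r}: spikes must be 1-D")
        if spikes.size:
            if not np.all(np.isfinite(spikes)):
                raise ValidationError(f"trace {self.trace_id!r}: non-finite spike time")
            if np.any(np.diff(spikes) <= 0):
                raise ValidationError(
                    f"trace {self.trace_id!r}: spike times must be strictly increasing"
                )
            if spikes[0] < 0 or spikes[-1] > self.duration_s:
                raise ValidationError(
                    f"trace {self.trace_id!r}: spike times must lie in "
                    f"[0, {self.duration_s}]"
                )
        if self.group_role not in GROUP_ROLES:
            raise ValidationError(
                f"trace {self.trace_id!r}: unknown group_role {self.group_role!r}; "
                f"allowed: {', '.join(GROUP_ROLES)}"
            )

    @property
    def n_spikes(self) -> int:
        return int(self.spikes.size)

    def shifted(self, offset_s: float) -> "SpikeTrain":
        """Return a copy with all spike times shifted by ``offset_s`` seconds."""
        return SpikeTrain(
            trace_id=self.trace_id,
            spikes=self.spikes + offset_s,
            duration_s=self.duration_s + max(0.0, offset_s),
            genotype=self.genotype,
            cell_type=self.cell_type,
            group_role=self.group_role,
        )


@dataclass(frozen=True)
class BehavioralRecord:
    """One animal in one assay.

    ``value`` is seizure duration in seconds for the seizure assays and
    distance (mm or mm/h) for the locomotion assays.  ``onset_time_s`` is the
    within-assay seizure onset used for cumulative-incidence curves (heat
    assay); ``None`` means the animal never seized inside the observation
    window (right-censored).
    """

    animal_id: str
    genotype: str
    assay: str
    value: float
    onset_time_s: Optional[float] = None

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise ValidationError(
                f"animal {self.animal_id!r}: unknown assay {self.assay!r}; "
                f"allowed: {', '.join(ASSAYS)}"
            )
        if not np.isfinite(self.value) or self.value < 0:
            raise ValidationError(
                f"animal {self.animal_id!r}: value must be finite and >= 0, "
                f"got {self.value}"
            )
        if self.onset_time_s is not None:
            if not np.isfinite(self.onset_time_s) or self.onset_time_s < 0:
                raise ValidationError(
                    f"animal {self.animal_id!r}: onset_time_s must be >= 0, "
                    f"got {self.onset_time_s}"
                )
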