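"""ISI-threshold burst segmentation of spike trains.

A burst is a maximal run of at least ``min_spikes`` consecutive spikes in
which every successive inter-spike interval (ISI) is at most ``max_isi_s``;
the burst ends when no spike follows within ``max_isi_s`` of the last spike.
Defaults (100 ms, 3 spikes) are the standard criterion for larval motor
neuron recordings.  The ISI boundary is inclusive: an interval of exactly
``max_isi_s`` continues the burst.

Two implementations are provided: :func:`detect_bursts` (single explicit
linear pass, the production path) and :func:`detect_bursts_oracle`
(independent vectorised grouping) used to cross-validate the detector.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence, Union

import numpy as np
from sklearn.base import BaseEstimator

from .datatypes import SpikeTrain
from .errors import ValidationError

__all__ = [
    "Burst",
    "BurstParams",
    "BurstDetector",
    "detect_bursts",
    "detect_bursts_oracle",
]


@dataclass(frozen=True)
class Burst:
    """One detected burst: first/last spike times and spike count."""

    start_s: float
    end_s: float
    n_spikes: int

    def __post_init__(self) -> None:
        if self.end_s < self.start_s:
            raise ValidationError("burst end before start")
        if self.n_spikes < 2:
            raise ValidationError("a burst has at least 2 spikes")

    @property
    def duration_s(self) -> float:
        """First-to-last spike time; no padding by the ISI threshold."""
        return self.end_s - self.start_s


@dataclass(frozen=True)
class BurstParams:
    """Detection parameters: ISI threshold (s) and minimum spike count."""

    max_isi_s: float = 0.100
    min_spikes: int = 3

    def __post_init__(self) -> None:
        if not self.max_isi_s > 0:
            raise ValidationError(f"max_isi_s must be > 0, got {self.max_isi_s}")
        if self.min_spikes < 2:
            raise ValidationError(f"min_spikes must be >= 2, got {self.min_spikes}")


def _as_times(train: Union[SpikeTrain, Sequence[float], np.ndarray]) -> np.ndarray:
    if isinstance(train, SpikeTrain):
        return train.spikes
    times = np.asarray(train, dtype=float)
    if times.ndim != 1:
        raise ValidationError("spike times must be 1-D")
    if times.size and np.any(np.diff(times) <= 0):
        raise ValidationError("spike times must be strictly increasing")
    return times


def detect_bursts(
    train: Union[SpikeTrain, Sequence[float], np.ndarray],
    params: BurstParams | None = None,
    *,
    max_isi_s: float | None = None,
    min_spikes: int | None = None,
) -> List[Burst]:
    """Segment a spike train into bursts with a single linear scan.

    Parameters may be given as a :class:`BurstParams` or as keyword
    overrides; keywords win over ``params``.

    Returns
    -------
    list of Burst
        Disjoint, time-ordered; runs shorter than ``min_spikes`` are
        discarded (their spikes still count toward the overall firing rate,
        which is computed elsewhere from the full train).
    """
    p = params or BurstParams()
    p = BurstParams(
        max_isi_s=p.max_isi_s if max_isi_s is None else max_isi_s,
        min_spikes=p.min_spikes if min_spikes is None else min_spikes,
    )
    times = _as_times(train)
    bursts: List[Burst] = []
    if times.size == 0:
        return bursts

    run_start = 0
    for i in range(1, times.size + 1):
        # the run [run_start, i) ends at the last spike or at an ISI > threshold
        if i == times.size or times[i] - times[i - 1] > p.max_isi_s:
            n = i - run_start
            if n >= p.min_spikes:
                bursts.append(
                    Burst(start_s=float(times[run_start]), end_s=float(times[i - 1]), n_spikes=n)
                )
            run_start = i
    return bursts


def detect_bursts_oracle(
    train: Union[SpikeTrain, Sequence[float], np.ndarray],
    params: BurstParams | None = None,
) -> List[Burst]:
    """Reference burst detector via vectorised run labelling.

    Independent of :func:`detect_bursts`: spikes are grouped by the
    cumulative count of above-threshold gaps and groups are filtered by
    size.  Same contract, used to cross-check the linear-pass detector.
    """
    p = params or BurstParams()
    times = _as_times(train)
    if times.size == 0:
        return []
    labels = np.concatenate([[0], np.cumsum(np.diff(times) > p.max_isi_s)])
    bursts = []
    for lab in np.unique(labels):
        member = times[labels == lab]
        if member.size >= p.min_spikes:
            bursts.append(
                Burst(start_s=float(member[0]), end_s=float(member[-1]), n_spikes=int(member.size))
            )
    return bursts


class BurstDetector(BaseEstimator):
    """Stateless transformer wrapping :func:`detect_bursts`.

    sklearn-compatible so the detection parameters can travel through
    ``get_params``/``set_params`` and grid searches; ``fit`` is a no-op.

    Examples
    --------
    >>> BurstDetector(max_isi_s=0.1).transform([0.0, 0.05, 0.1, 0.5])
    [Burst(start_s=0.0, end_s=0.1, n_spikes=3)]
    """

    def __init__(self, max_isi_s: float = 0.100, min_spikes: int = 3):
        self.max_isi_s = max_isi_s
        self.min_spikes = min_spikes

    @property
    def params_(self) -> BurstParams:
        return BurstParams(max_isi_s=self.max_isi_s, min_spikes=self.min_spikes)

    def fit(self, X=None, y=None) -> "BurstDetector":  # noqa: D102 - stateless
        return self

    def transform(
        self, X: Union[SpikeTrain, Sequence[float], np.ndarray, Iterable[SpikeTrain]]
    ) -> Union[List[Burst], List[List[Burst]]]:
        """Detect bursts in one train, or in each train of a list of trains."""
        if isinstance(X, (list, tuple)) and X and all(isinstance(x, SpikeTrain) for x in X):
            return [detect_bursts(train, self.params_) for train in X]
        return detect_bursts(X, self.params_)

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)
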