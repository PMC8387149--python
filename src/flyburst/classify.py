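"""Reference-band classification of bursting traces.

A wild-type reference band is the mean ± k·SD (default k = 1.5) of the
per-trace mean burst durations across reference traces.  A test trace is
"elongated" when its mean burst duration exceeds the upper bound, "short"
below the lower bound, "normal" inside the band (bounds inclusive), and
"unclassifiable" when it has no bursts.  The per-genotype fraction of
elongated traces is the phenotype readout.

The band statistic is deliberately the distribution of per-trace means, not
the pooled burst-duration distribution: the phenotype is a property of a
trace, and trace means are far less skewed than individual burst durations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence, Union

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .errors import InsufficientReferenceError, ValidationError
from .trace_stats import TraceSummary

__all__ = [
    "ReferenceBand",
    "TraceLabel",
    "FractionResult",
    "ReferenceBandClassifier",
    "build_reference_band",
    "classify_trace",
    "fraction_elongated",
]

LABELS = ("normal", "elongated", "short", "unclassifiable")


@dataclass(frozen=True)
class ReferenceBand:
    """Normal range of per-trace mean burst duration for a reference genotype."""

    reference_genotype: str
    mean_s: float
    sd_s: float
    k: float
    n_reference_traces: int

    def __post_init__(self) -> None:
        if self.sd_s < 0 or not math.isfinite(self.sd_s):
            raise ValidationError(f"sd_s must be finite and >= 0, got {self.sd_s}")
        if self.n_reference_traces < 2:
            raise InsufficientReferenceError(
                "a reference band needs at least 2 classifiable traces"
            )

    @property
    def lower_s(self) -> float:
        return self.mean_s - self.k * self.sd_s

    @property
    def upper_s(self) -> float:
        return self.mean_s + self.k * self.sd_s


@dataclass(frozen=True)
class TraceLabel:
    trace_id: str
    label: str

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValidationError(f"unknown label {self.label!r}")


@dataclass(frozen=True)
class FractionResult:
    """Elongated fraction with its numerator/denominator made explicit."""

    n_elongated: int
    n_classifiable: int
    n_unclassifiable: int

    @property
    def fraction(self) -> float:
        return (
            self.n_elongated / self.n_classifiable
            if self.n_classifiable
            else float("nan")
        )


def _durations(
    reference: Union[Sequence[TraceSummary], Sequence[float], np.ndarray]
) -> np.ndarray:
    if len(reference) and isinstance(reference[0], TraceSummary):
        vals = np.array([s.mean_burst_duration_s for s in reference], dtype=float)
    else:
        vals = np.asarray(reference, dtype=float)
    return vals


class ReferenceBandClassifier(BaseEstimator):
    """mean ± k·SD outlier-band classifier for per-trace mean burst durations.

    Parameters
    ----------
    k : float, default 1.5
        Band half-width in reference standard deviations.
    reference_genotype : str
        Name recorded on the fitted band (metadata only).

    Attributes
    ----------
    mean_s_, sd_s_ : float
        Mean and sample SD (ddof=1) of the classifiable reference durations.
    lower_s_, upper_s_ : float
        Band bounds, ``mean ± k·SD``; at-bound values classify as normal.
    band_ : ReferenceBand
    """

    def __init__(self, k: float = 1.5, reference_genotype: str = ""):
        self.k = k
        self.reference_genotype = reference_genotype

    def fit(self, X, y=None) -> "ReferenceBandClassifier":
        """Fit the band on reference per-trace mean burst durations (s).

        ``X`` may be TraceSummary objects or raw durations; NaN entries
        (zero-burst traces) are dropped before fitting.
        """
        if self.k < 0:
            raise ValidationError(f"k must be >= 0, got {self.k}")
        vals = _durations(X)
        vals = vals[np.isfinite(vals)]
        if vals.size < 2:
            raise InsufficientReferenceError(
                f"need >= 2 classifiable reference traces, got {vals.size}"
            )
        self.n_reference_traces_ = int(vals.size)
        self.mean_s_ = float(np.mean(vals))
        self.sd_s_ = float(np.std(vals, ddof=1))
        self.lower_s_ = self.mean_s_ - self.k * self.sd_s_
        self.upper_s_ = self.mean_s_ + self.k * self.sd_s_
        self.band_ = ReferenceBand(
            reference_genotype=self.reference_genotype,
            mean_s=self.mean_s_,
            sd_s=self.sd_s_,
            k=self.k,
            n_reference_traces=self.n_reference_traces_,
        )
        return self

    def predict(self, X) -> np.ndarray:
        """Label each trace (by its mean burst duration); NaN → unclassifiable."""
        check_is_fitted(self, "band_")
        vals = _durations(X)
        labels = np.full(vals.shape, "normal", dtype=object)
        labels[vals > self.upper_s_] = "elongated"
        labels[vals < self.lower_s_] = "short"
        labels[~np.isfinite(vals)] = "unclassifiable"
        return labels


def build_reference_band(
    reference: Union[Sequence[TraceSummary], Sequence[float], np.ndarray],
    k: float = 1.5,
    reference_genotype: str = "",
) -> ReferenceBand:
    """Build a :class:`ReferenceBand` from reference traces (mean ± k·sample SD)."""
    clf = ReferenceBandClassifier(k=k, reference_genotype=reference_genotype).fit(reference)
    return clf.band_


def classify_trace(summary: Union[TraceSummary, float], band: ReferenceBand) -> TraceLabel:
    """Classify one trace against a band; bounds are inclusive (= normal)."""
    if isinstance(summary, TraceSummary):
        trace_id, value = summary.trace_id, summary.mean_burst_duration_s
    else:
        trace_id, value = "", float(summary)
    if not math.isfinite(value):
        label = "unclassifiable"
    elif value > band.upper_s:
        label = "elongated"
    elif value < band.lower_s:
        label = "short"
    else:
        label = "normal"
    return TraceLabel(trace_id=trace_id, label=label)


def fraction_elongated(labels: Sequence[Union[TraceLabel, str]]) -> FractionResult:
    """Elongated count over classifiable count; unclassifiable reported apart."""
    names: List[str] = [l.label if isinstance(l, TraceLabel) else str(l) for l in labels]
    for name in names:
        if name not in LABELS:
            raise ValidationError(f"unknown label {name!r}")
    n_unclass = sum(1 for n in names if n == "unclassifiable")
    n_class = len(names) - n_unclass
    n_elong = sum(1 for n in names if n == "elongated")
    # zero classifiable traces is not an error: the fraction is flagged NaN
    return FractionResult(
        n_elongated=n_elong, n_classifiable=n_class, n_unclassifiable=n_unclass
    )
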