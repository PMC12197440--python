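"""Repeatability, recovery and method-agreement statistics.

These are the summary statistics used to validate a densitometric method:
the coefficient of variation CV = 100 * sigma / mu of replicate measurements,
per-replicate percent recovery of spiked standards, and a one-way ANOVA
comparing two methods' results on the same samples.  Sample (n - 1) standard
deviations are used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ConfigError, InsufficientDataError, UndefinedStatError

__all__ = ["SummaryStat", "RecoveryRecord", "summarize", "cv", "recovery",
           "method_agreement"]


@dataclass(frozen=True)
class SummaryStat:
    mean: float
    sd: float
    n: int

    @property
    def cv_percent(self) -> float:
        if self.mean == 0:
            raise UndefinedStatError("CV undefined for zero mean")
        return 100.0 * self.sd / abs(self.mean)


@dataclass(frozen=True)
class RecoveryRecord:
    spiked: float
    measured: tuple[float, ...]
    recovery_percent: tuple[float, ...]
    mean: float
    sd: float


def summarize(values) -> SummaryStat:
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise InsufficientDataError("need n >= 2 for a standard deviation")
    return SummaryStat(mean=float(v.mean()), sd=float(v.std(ddof=1)), n=v.size)


def cv(values=None, *, mean: float | None = None, sd: float | None = None) -> float:
    """Coefficient of variation in percent, 100 * sd / mean.

    Pass either raw replicate values (sample sd, n - 1) or a (mean, sd) pair.
    """
    if values is not None:
        if mean is not None or sd is not None:
            raise ConfigError("pass either raw values or (mean, sd), not both")
        return summarize(values).cv_percent
    if mean is None or sd is None:
        raise ConfigError("need raw values or both mean and sd")
    return SummaryStat(mean=mean, sd=sd, n=2).cv_percent


def recovery(measured, spiked: float) -> RecoveryRecord:
    """Percent recovery per replicate, 100 * measured / spiked, with its
    mean and sample sd (sd is 0 for a single replicate)."""
    if spiked <= 0:
        raise ConfigError(f"spiked concentration must be > 0, got {spiked}")
    m = np.asarray(measured, dtype=float)
    if m.ndim != 1 or m.size == 0:
        raise InsufficientDataError("measured must be a non-empty 1-D sequence")
    rec = 100.0 * m / spiked
    sd = float(rec.std(ddof=1)) if rec.size > 1 else 0.0
    return RecoveryRecord(spiked=float(spiked), measured=tuple(map(float, m)),
                          recovery_percent=tuple(map(float, rec)),
                          mean=float(rec.mean()), sd=sd)


def method_agreement(group_a, group_b) -> tuple[float, float]:
    """One-way fixed-effects ANOVA across two groups (equivalent to a pooled
    two-sample t-test).  Returns (F, p).

    When both groups have zero within-group variance the F ratio is defined
    as 0 (p = 1) for equal means and +inf (p = 0) otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each group needs n >= 2")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return (0.0, 1.0) if a[0] == b[0] else (float("inf"), 0.0)
    f, p = stats.f_oneway(a, b)
    return float(f), float(p)
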