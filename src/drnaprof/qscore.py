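"""Phred quality-score conversions and calibration analysis.

Phred Q-scores encode error probabilities as P = 10^(-Q/10): Q10 is a
10% expected error rate, Q20 is 1%, and the conventional read pass
threshold of Q7 corresponds to ~20% expected error (80% expected
accuracy). A read-level Q-score is the Phred back-conversion of the
mean per-base error probability,

    read Q = -10 log10( (1/N) * sum_i 10^(-q_i/10) ).

Calibration is assessed by binning reads by their reported Q-score
(default bin width 0.2), comparing the mean observed error rate per bin
to the expected curve, and fitting (OLS) the empirical Q-scores
recomputed from per-base qualities against the reported ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import statsmodels.api as sm

from .errors import DegenerateFitError, EmptyInputError, InvalidParameterError
from .readmetrics import ReadErrorSummary

DEFAULT_BIN_WIDTH = 0.2


def q_to_error(q):
    """Expected error probability at Phred score ``q`` (scalar or array)."""
    return 10.0 ** (-np.asarray(q, dtype=float) / 10.0) if np.ndim(q) else 10.0 ** (-q / 10.0)


def error_to_q(p):
    """Phred score for error probability ``p``."""
    return -10.0 * np.log10(p)


def read_qscore_from_bases(per_base_q: Sequence[float]) -> float:
    """Read-level Q-score from per-base Phred qualities.

    Equals ``q`` when all ``q_i`` are equal, and always lies between
    min(q_i) and max(q_i).
    """
    q = np.asarray(per_base_q, dtype=float)
    if q.size == 0:
        raise EmptyInputError("per-base quality list is empty")
    return float(-10.0 * np.log10(np.mean(10.0 ** (-q / 10.0))))


@dataclass
class QscoreBin:
    """One reported-Q-score interval [lo, hi) with its error rates."""

    lo: float
    hi: float
    n_reads: int
    observed_error: float  # mean (1 - accuracy) of reads in the bin
    expected_error: float  # Phred expectation at the bin midpoint


def calibration_curve(
    summaries: Iterable[ReadErrorSummary],
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> list[QscoreBin]:
    """Observed vs expected error rate per reported-Q-score bin.

    Reads without a reported Q-score are skipped; bins are returned in
    increasing Q order, occupied bins only.
    """
    if bin_width <= 0:
        raise InvalidParameterError("bin width must be positive")
    groups: dict[int, list[float]] = {}
    n_used = 0
    for s in summaries:
        if s.reported_q is None or not math.isfinite(s.reported_q):
            continue
        n_used += 1
        idx = int(math.floor(s.reported_q / bin_width + 1e-9))
        groups.setdefault(idx, []).append(1.0 - s.accuracy)
    if n_used == 0:
        raise EmptyInputError("no reads with reported Q-scores")
    bins = []
    for idx in sorted(groups):
        lo = idx * bin_width
        mid = lo + bin_width / 2.0
        errs = groups[idx]
        bins.append(
            QscoreBin(
                lo=lo,
                hi=lo + bin_width,
                n_reads=len(errs),
                observed_error=float(np.mean(errs)),
                expected_error=float(q_to_error(mid)),
            )
        )
    return bins


@dataclass
class CalibrationFit:
    """OLS fit of empirical Q-scores on reported Q-scores."""

    slope: float
    intercept: float
    p_value: float  # of the slope
    n: int


def empirical_vs_reported_fit(
    reported_q: Sequence[float], empirical_q: Sequence[float]
) -> CalibrationFit:
    """Ordinary-least-squares fit of empirical on reported Q-scores.

    Quantifies the systematic deviation between the basecaller's
    reported read Q-score and the value recomputed from per-base FASTQ
    qualities. Requires n >= 3 and a non-constant predictor.
    """
    x = np.asarray(reported_q, dtype=float)
    y = np.asarray(empirical_q, dtype=float)
    if x.shape != y.shape:
        raise InvalidParameterError("reported and empirical lists must match in length")
    if x.size < 3:
        raise DegenerateFitError("need at least 3 points for a fit")
    if np.ptp(x) == 0:
        raise DegenerateFitError("reported Q-scores are constant")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return CalibrationFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        p_value=float(res.pvalues[1]),
        n=int(x.size),
    )
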