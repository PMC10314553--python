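"""Intra-rater reliability statistics.

A single examiner repeats each measurement twice (two sessions).  Random
("casual") error is summarized by Dahlberg's statistic, expressed also as a
percentage of the measurement magnitude; systematic agreement by the
intraclass correlation coefficient.  ICC(3,1) — two-way mixed effects,
consistency, single measurement — is the default model for a fixed single
rater; ICC(2,1) absolute agreement is available for sensitivity checks.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import StatisticsError, ValidationError


@dataclass
class RepeatedMeasures:
    """Paired repeated measurements of one variable.

    ``pairs`` holds (session-1, session-2) values per subject, in the
    variable's units.
    """

    variable: str
    pairs: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.pairs, dtype=float)
        if p.ndim != 2 or p.shape[1] != 2:
            raise ValidationError("pairs must be an (n, 2) array")
        if not np.all(np.isfinite(p)):
            raise ValidationError("repeated measurements must be finite")
        self.pairs = p

    @property
    def n(self) -> int:
        return self.pairs.shape[0]


def dahlberg_error(rm: RepeatedMeasures) -> float:
    """Dahlberg's casual error: d = sqrt( Σ (m1 − m2)² / 2n ).

    Same units as the measurements; under i.i.d. session noise of standard
    deviation σ it estimates σ.
    """
    if rm.n < 2:
        raise StatisticsError(f"Dahlberg error needs >= 2 pairs, got {rm.n}")
    d = rm.pairs[:, 0] - rm.pairs[:, 1]
    return float(np.sqrt(np.sum(d * d) / (2.0 * rm.n)))


def relative_error_percent(rm: RepeatedMeasures) -> float:
    """Dahlberg error as a percentage of the grand mean of both sessions."""
    mean = float(np.mean(rm.pairs))
    if abs(mean) < 1e-300:
        raise StatisticsError("relative error undefined: grand mean is zero")
    return 100.0 * dahlberg_error(rm) / mean


def icc_single_rater(rm: RepeatedMeasures, model: str = "ICC3") -> float:
    """Intraclass correlation for two sessions of a single rater.

    ``model="ICC3"`` (default) is the two-way mixed, consistency, single-
    measurement form (MS_subjects − MS_error)/(MS_subjects + (k−1)·MS_error);
    ``model="ICC2"`` the two-way random absolute-agreement form, which also
    penalizes a systematic session shift.
    """
    if rm.n < 3:
        raise StatisticsError(f"ICC needs >= 3 subjects, got {rm.n}")
    y = rm.pairs
    n, k = y.shape
    grand = y.mean()
    subj_means = y.mean(axis=1)
    sess_means = y.mean(axis=0)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_sess = n * np.sum((sess_means - grand) ** 2)
    ss_total = np.sum((y - grand) ** 2)
    ss_err = ss_total - ss_subj - ss_sess
    ms_subj = ss_subj / (n - 1)
    ms_sess = ss_sess / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    if ms_subj <= 0:
        raise StatisticsError("ICC degenerate: no between-subject variance")
    if model == "ICC3":
        return float((ms_subj - ms_err) / (ms_subj + (k - 1) * ms_err))
    if model == "ICC2":
        return float((ms_subj - ms_err) /
                     (ms_subj + (k - 1) * ms_err + k * (ms_sess - ms_err) / n))
    raise ValidationError(f"unknown ICC model {model!r}; use 'ICC3' or 'ICC2'")


def reliability_report(measures: Iterable[RepeatedMeasures],
                       model: str = "ICC3") -> pd.DataFrame:
    """Per-variable reliability table: n, ICC, Dahlberg error, relative %."""
    rows = []
    for rm in measures:
        rows.append({
            "variable": rm.variable,
            "n": rm.n,
            "icc": icc_single_rater(rm, model=model),
            "dahlberg": dahlberg_error(rm),
            "relative_error_percent": relative_error_percent(rm),
        })
    return pd.DataFrame(rows)
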