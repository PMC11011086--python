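"""Method agreement between automated and human sleep scoring.

Validating an automated scorer against a human observer uses two levels of
comparison:

* **frame level** — the percentage of jointly scored frames on which two
  state sequences assign the same asleep/awake label;
* **session level** — paired t-tests across sessions on total sleep
  duration, on percent of time asleep, and on bout counts, preceded by
  Anderson–Darling normality checks on the paired differences.

The paired t statistic is ``t = mean(d) / (sd(d)/sqrt(n))`` with the
sample (n-1) standard deviation, df = n-1, and a two-sided p-value from
the Student-t distribution (the regularized incomplete beta function).
Anderson–Darling uses the estimated-parameter normal case with Stephens'
small-sample correction ``A*^2 = A^2 (1 + 0.75/n + 2.25/n^2)`` and the
0.752 critical value at alpha = 0.05; the decision is reported with the
corrected statistic rather than an interpolated p-value.

A reference dataset of 11 kennel nights scored by both an automated system
and a human observer ships with the package (see
:func:`load_reference_sessions`) and drives the worked example.
"""

from __future__ import annotations

import importlib.resources
import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .sleep_state import SleepSummary, State, StateSequence, format_hms, parse_hms

__all__ = [
    "ZeroVarianceError",
    "TestResult",
    "SessionPair",
    "PairedSessions",
    "frame_agreement",
    "paired_t_test",
    "one_sample_t_test",
    "anderson_darling_normality",
    "percent_of_time",
    "column_summary",
    "symmetric_percent_difference",
    "comparison_report",
    "ReportTable",
    "load_reference_sessions",
    "AD_CRITICAL_5PCT",
]

# Stephens' critical value for A*^2, normal case with estimated mean and
# variance, alpha = 0.05.
AD_CRITICAL_5PCT = 0.752

DEFAULT_ALPHA = 0.05


class ZeroVarianceError(ValueError):
    """Raised when a test's input has no variability (degenerate case)."""


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test at a fixed alpha."""

    statistic: float
    df: int
    p: Optional[float]
    significant: bool
    alpha: float = DEFAULT_ALPHA

    def __post_init__(self) -> None:
        if self.p is not None and not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p must be in [0, 1], got {self.p}")


@dataclass
class SessionPair:
    """One session scored by both methods, plus optional supplied
    percent-difference values from the source dataset."""

    session_id: object
    system: SleepSummary
    manual: SleepSummary
    pct_diff_sleep: Optional[float] = None
    pct_diff_bouts: Optional[float] = None


@dataclass
class PairedSessions:
    """Sessions retained for comparison; both summaries present in each."""

    pairs: List[SessionPair] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)

    def column(self, which: str) -> np.ndarray:
        """Extract a numeric column across sessions."""
        getters = {
            "sleep_system_s": lambda p: p.system.total_sleep_s,
            "sleep_manual_s": lambda p: p.manual.total_sleep_s,
            "bouts_system": lambda p: p.system.bout_count,
            "bouts_manual": lambda p: p.manual.bout_count,
            "pct_diff_sleep": lambda p: p.pct_diff_sleep,
            "pct_diff_bouts": lambda p: p.pct_diff_bouts,
            "percent_system": lambda p: p.system.percent_asleep,
            "percent_manual": lambda p: p.manual.percent_asleep,
        }
        vals = [getters[which](p) for p in self.pairs]
        return np.array(vals, dtype=float)


def frame_agreement(a: StateSequence, b: StateSequence) -> float:
    """Percent of jointly known frames where two sequences agree.

    Frames where either sequence is UNKNOWN are excluded. Symmetric in its
    arguments. Raises if no frame is jointly known or the sequences differ
    in length or frame rate.
    """
    if len(a) != len(b):
        raise ValueError(f"sequence lengths differ: {len(a)} vs {len(b)}")
    if not math.isclose(a.fps, b.fps):
        raise ValueError(f"frame rates differ: {a.fps} vs {b.fps}")
    ca, cb = a.as_array(), b.as_array()
    known = (ca != 2) & (cb != 2)
    n_known = int(known.sum())
    if n_known == 0:
        raise ValueError("no jointly known frames to compare")
    matches = int((ca[known] == cb[known]).sum())
    return 100.0 * matches / n_known


def paired_t_test(x: Sequence[float], y: Sequence[float],
                  alpha: float = DEFAULT_ALPHA) -> TestResult:
    """Two-sided paired t-test on matched samples.

    ``t = mean(d) / (sd(d)/sqrt(n))`` with d = x - y and the sample (n-1)
    standard deviation; df = n - 1; p two-sided from the Student-t
    distribution.

    Raises
    ------
    ValueError
        Fewer than 2 pairs or mismatched lengths.
    ZeroVarianceError
        All differences identical (sd of d is zero).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    n = x.size
    if n < 2:
        raise ValueError(f"paired t-test requires n >= 2, got n = {n}")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise ZeroVarianceError("all paired differences are identical; t is undefined")
    t = d.mean() / (sd / math.sqrt(n))
    df = n - 1
    # Two-sided tail probability of Student-t (regularized incomplete beta).
    p = 2.0 * stats.t.sf(abs(t), df)
    return TestResult(statistic=float(t), df=df, p=float(min(p, 1.0)),
                      significant=bool(p < alpha), alpha=alpha)


def one_sample_t_test(x: Sequence[float], mu: float = 0.0,
                      alpha: float = DEFAULT_ALPHA) -> TestResult:
    """Two-sided one-sample t-test of mean(x) against ``mu``.

    Identical to a paired t-test on (x, constant mu); used when only the
    paired differences themselves are available.
    """
    x = np.asarray(x, dtype=float)
    return paired_t_test(x, np.full_like(x, mu), alpha=alpha)


def anderson_darling_normality(x: Sequence[float],
                               alpha: float = DEFAULT_ALPHA) -> TestResult:
    """Anderson–Darling normality test with estimated mean and variance.

    Computes A^2 on the standardized, sorted sample, applies the
    small-sample correction A*^2 = A^2 (1 + 0.75/n + 2.25/n^2), and flags
    significance when A*^2 exceeds Stephens' 0.752 critical value
    (alpha = 0.05). The reported statistic is A*^2; no p-value is
    interpolated (``p`` is None).

    Raises
    ------
    ValueError
        n < 5 (the correction and critical value are unreliable below).
    ZeroVarianceError
        Constant sample.
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    if n < 5:
        raise ValueError(f"Anderson-Darling requires n >= 5, got n = {n}")
    s = x.std(ddof=1)
    if s == 0:
        raise ZeroVarianceError("constant sample; normality test undefined")
    z = stats.norm.cdf((x - x.mean()) / s)
    # Clip away exact 0/1 so the logs stay finite for extreme outliers.
    eps = np.finfo(float).tiny
    z = np.clip(z, eps, 1 - 1e-16)
    i = np.arange(1, n + 1)
    a2 = -n - np.sum((2 * i - 1) * (np.log(z) + np.log1p(-z[::-1]))) / n
    a2_star = a2 * (1 + 0.75 / n + 2.25 / n ** 2)
    if alpha != 0.05:
        raise ValueError("only alpha = 0.05 is tabulated for this test")
    return TestResult(statistic=float(a2_star), df=n, p=None,
                      significant=bool(a2_star > AD_CRITICAL_5PCT), alpha=alpha)


def percent_of_time(summary: SleepSummary) -> float:
    """Percent of known time spent asleep: 100 * sleep / (sleep + awake)."""
    known = summary.total_sleep_s + summary.total_awake_s
    if not known > 0:
        raise ValueError("summary has no known (non-UNKNOWN) time")
    return 100.0 * summary.total_sleep_s / known


def column_summary(values: Sequence[float]) -> Tuple[float, Optional[float], float, float]:
    """(mean, sample sd, min, max) of a column; sd is None for n = 1."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty column")
    sd = float(v.std(ddof=1)) if v.size >= 2 else None
    return float(v.mean()), sd, float(v.min()), float(v.max())


def symmetric_percent_difference(a: float, b: float) -> float:
    """Symmetric percent difference, 100 |a-b| / ((a+b)/2).

    This package's own documented disagreement metric for paired session
    values; it is not the percent-difference definition of any particular
    source dataset.
    """
    if a == b:
        return 0.0
    denom = (a + b) / 2.0
    if denom == 0:
        raise ValueError("symmetric percent difference undefined for a + b = 0")
    return 100.0 * abs(a - b) / denom


@dataclass
class ReportTable:
    """Comparison report: per-session rows, column summaries, and tests."""

    rows: List[Dict[str, object]]
    column_summaries: Dict[str, Dict[str, Optional[float]]]
    tests: Dict[str, object]  # TestResult or the string "identical"
    alpha: float
    excluded_sessions: List[object] = field(default_factory=list)

    def to_json(self) -> str:
        def encode(obj):
            if isinstance(obj, TestResult):
                return {
                    "statistic": round(obj.statistic, 3),
                    "df": obj.df,
                    "p": None if obj.p is None else round(obj.p, 4),
                    "significant": obj.significant,
                    "alpha": obj.alpha,
                }
            return obj

        payload = {
            "alpha": self.alpha,
            "rows": self.rows,
            "column_summaries": self.column_summaries,
            "tests": {k: encode(v) for k, v in self.tests.items()},
            "excluded_sessions": self.excluded_sessions,
        }
        return json.dumps(payload, indent=2)

    def to_csv(self) -> str:
        """Per-session rows in the reference-table layout."""
        cols = ["session_id", "sleep_system", "sleep_manual", "pct_diff_sleep",
                "bouts_system", "bouts_manual", "pct_diff_bouts"]
        lines = [",".join(cols)]
        for r in self.rows:
            lines.append(",".join("" if r.get(c) is None else str(r.get(c)) for c in cols))
        return "\n".join(lines) + "\n"


def _run_test(tests: Dict[str, object], name: str, fn) -> None:
    try:
        tests[name] = fn()
    except ZeroVarianceError:
        tests[name] = "identical"


def comparison_report(paired: PairedSessions, alpha: float = DEFAULT_ALPHA) -> ReportTable:
    """Build the full method-agreement report for paired sessions.

    Per-session rows show H:MM:SS durations and bout counts alongside the
    supplied percent-difference columns (when present) and this package's
    symmetric percent difference of durations. Column summaries and three
    paired tests (sleep duration in seconds, percent of time asleep, bout
    count) follow, with Anderson–Darling normality checks on the paired
    differences when n >= 5.

    The percent-of-time test uses each summary's own ``percent_asleep``
    when available on both sides for every session; otherwise it falls
    back to a one-sample t-test on the supplied percent-difference values,
    signed by which method recorded more sleep.
    """
    if len(paired) < 2:
        raise ValueError(f"need at least 2 paired sessions, got {len(paired)}")

    rows: List[Dict[str, object]] = []
    for p in paired.pairs:
        rows.append({
            "session_id": p.session_id,
            "sleep_system": format_hms(p.system.total_sleep_s),
            "sleep_manual": format_hms(p.manual.total_sleep_s),
            "pct_diff_sleep": None if p.pct_diff_sleep is None else round(p.pct_diff_sleep, 2),
            "bouts_system": p.system.bout_count,
            "bouts_manual": p.manual.bout_count,
            "pct_diff_bouts": None if p.pct_diff_bouts is None else round(p.pct_diff_bouts, 2),
            "sym_pct_diff_sleep": round(
                symmetric_percent_difference(p.system.total_sleep_s,
                                             p.manual.total_sleep_s), 2),
        })

    summaries: Dict[str, Dict[str, Optional[float]]] = {}
    for name in ("sleep_system_s", "sleep_manual_s", "bouts_system", "bouts_manual",
                 "pct_diff_sleep", "pct_diff_bouts"):
        col = paired.column(name)
        if np.isnan(col).any():
            continue
        mean, sd, lo, hi = column_summary(col)
        summaries[name] = {"mean": mean, "sd": sd, "min": lo, "max": hi}

    tests: Dict[str, object] = {}
    sleep_sys = paired.column("sleep_system_s")
    sleep_man = paired.column("sleep_manual_s")
    bouts_sys = paired.column("bouts_system")
    bouts_man = paired.column("bouts_manual")

    _run_test(tests, "sleep_duration_t", lambda: paired_t_test(sleep_sys, sleep_man, alpha))
    _run_test(tests, "bout_count_t", lambda: paired_t_test(bouts_sys, bouts_man, alpha))

    pct_sys = paired.column("percent_system")
    pct_man = paired.column("percent_manual")
    if not (np.isnan(pct_sys).any() or np.isnan(pct_man).any()):
        _run_test(tests, "percent_of_time_t", lambda: paired_t_test(pct_sys, pct_man, alpha))
    else:
        supplied = paired.column("pct_diff_sleep")
        if not np.isnan(supplied).any():
            signed = supplied * np.where(sleep_sys >= sleep_man, 1.0, -1.0)
            _run_test(tests, "percent_of_time_t", lambda: one_sample_t_test(signed, 0.0, alpha))

    if len(paired) >= 5:
        _run_test(tests, "sleep_duration_normality",
                  lambda: anderson_darling_normality(sleep_sys - sleep_man))
        _run_test(tests, "bout_count_normality",
                  lambda: anderson_darling_normality(bouts_sys - bouts_man))

    return ReportTable(rows=rows, column_summaries=summaries, tests=tests, alpha=alpha)


def load_reference_sessions() -> PairedSessions:
    """Load the bundled 11-night reference dataset.

    Eleven overnight kennel sessions scored in parallel by an automated
    video system and a human observer: total sleep as H:MM:SS, bout
    counts, and the percent-difference columns as published with the data.
    Observation-window lengths were not published, so the summaries carry
    NaN awake/observed fields and no percent_asleep.
    """
    import csv as _csv

    ref = importlib.resources.files("dogsleep.data").joinpath("reference_sessions.csv")
    pairs: List[SessionPair] = []
    with ref.open(newline="") as fh:
        for row in _csv.DictReader(fh):
            def summary(side: str) -> SleepSummary:
                return SleepSummary(
                    subject_id=f"night{row['session']}-{side}",
                    total_sleep_s=float(parse_hms(row[f"sleep_{side}_hms"])),
                    total_awake_s=float("nan"),
                    total_unknown_s=float("nan"),
                    observed_s=float("nan"),
                    bout_count=int(row[f"bouts_{side}"]),
                    percent_asleep=None,
                )
            pairs.append(SessionPair(
                session_id=int(row["session"]),
                system=summary("system"),
                manual=summary("manual"),
                pct_diff_sleep=float(row["pct_diff_sleep"]),
                pct_diff_bouts=float(row["pct_diff_bouts"]),
            ))
    return PairedSessions(pairs)
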