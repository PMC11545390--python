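"""Paired and Welch t-tests and the 18-comparison battery.

Both tests are computed from their closed forms:

* paired: ``t = mean(d) / (sd(d)/sqrt(n))`` on the differences ``d = x - y``
  with the n-1 sample standard deviation and ``df = n - 1``;
* Welch: ``t = (mean_a - mean_b) / sqrt(s_a^2/n_a + s_b^2/n_b)`` with the
  Welch-Satterthwaite degrees of freedom.

Two-tailed p-values come from the Student-t survival function expressed via
the regularized incomplete beta function,
``p = I_{df/(df+t^2)}(df/2, 1/2)``.

The battery crosses the three speech markers (filler, proper-noun and
listen-back ratios) with six contrasts.  Partner contrasts are paired
within participant (sign convention: human - ai); group contrasts compare
independent high/low cognitive groups with Welch's test by default (sign:
high - low).  The source analysis labels some between-group comparisons as
paired; ``group_test="index_paired"`` reproduces that pairing-by-cohort-
index for forensic comparison, without asserting it as the defensible
choice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import betainc

from .errors import (
    CompletenessError,
    ConfigurationError,
    DegenerateVarianceError,
    SampleSizeError,
)
from .features import FEATURES, FeatureProfile
from .grouping import GroupAssignment

CONTRASTS: tuple[str, ...] = (
    "partner_all",
    "group_all",
    "partner_within_high",
    "partner_within_low",
    "group_within_ai",
    "group_within_human",
)


@dataclass(frozen=True)
class TTestResult:
    kind: str  # "paired" | "welch"
    t: float
    df: float
    p_two_tailed: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int


@dataclass(frozen=True)
class ComparisonResult:
    """One cell of the battery; ``result`` is None when the contrast was
    skipped, with the reason in ``error`` (never silently absent)."""

    feature: str
    contrast: str
    result: TTestResult | None
    error: str | None = None


def p_from_t(t: float, df: float) -> float:
    """Two-tailed p-value for a t statistic, via the regularized incomplete beta."""
    if df <= 0:
        raise ValueError(f"degrees of freedom must be > 0, got {df}")
    x = df / (df + t * t)
    return float(betainc(df / 2.0, 0.5, x))


def paired_t(x: Sequence[float], y: Sequence[float]) -> TTestResult:
    """Two-tailed paired-sample t-test on equal-length samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise SampleSizeError("paired samples must be 1-D and of equal length")
    n = x.size
    if n < 2:
        raise SampleSizeError(f"paired t-test needs n >= 2, got n = {n}")
    d = x - y
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        raise DegenerateVarianceError("differences have zero variance")
    t = float(d.mean() / (sd / math.sqrt(n)))
    df = float(n - 1)
    return TTestResult("paired", t, df, p_from_t(t, df),
                       float(x.mean()), float(y.mean()), n, n)


def welch_t(x: Sequence[float], y: Sequence[float]) -> TTestResult:
    """Two-sample t-test not assuming equal variances (Welch)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n_a, n_b = x.size, y.size
    if n_a < 2 or n_b < 2:
        raise SampleSizeError(f"Welch t-test needs n >= 2 per sample, got {n_a} and {n_b}")
    va = float(x.var(ddof=1))
    vb = float(y.var(ddof=1))
    if va == 0.0 and vb == 0.0:
        raise DegenerateVarianceError("both samples have zero variance")
    sa, sb = va / n_a, vb / n_b
    t = float((x.mean() - y.mean()) / math.sqrt(sa + sb))
    df = (sa + sb) ** 2 / (sa ** 2 / (n_a - 1) + sb ** 2 / (n_b - 1))
    return TTestResult("welch", t, float(df), p_from_t(t, float(df)),
                       float(x.mean()), float(y.mean()), int(n_a), int(n_b))


# ---------------------------------------------------------------------------
# Battery
# ---------------------------------------------------------------------------

def _index_profiles(
    profiles: Sequence[FeatureProfile],
) -> Mapping[str, Mapping[str, FeatureProfile]]:
    by_pid: dict[str, dict[str, FeatureProfile]] = {}
    for p in profiles:
        slot = by_pid.setdefault(p.participant_id, {})
        if p.partner in slot:
            raise CompletenessError(
                f"duplicate profile for ({p.participant_id!r}, {p.partner!r})"
            )
        slot[p.partner] = p
    incomplete = sorted(pid for pid, s in by_pid.items() if len(s) != 2)
    if incomplete:
        raise CompletenessError(
            f"participants missing a human or ai session: {incomplete}"
        )
    return by_pid


def run_battery(
    profiles: Sequence[FeatureProfile],
    assignments: Sequence[GroupAssignment],
    *,
    group_test: str = "welch",
    pooling: str = "mean",
) -> list[ComparisonResult]:
    """Run the full 3-feature x 6-contrast grid in deterministic order.

    ``pooling`` controls the all-partners group contrast: ``"mean"`` (default)
    averages each participant's two sessions, keeping observations
    independent; ``"stack"`` enters both sessions separately.
    ``group_test`` selects Welch (default) or index pairing for between-group
    contrasts.  Degenerate contrasts are reported per-cell via ``error``.
    """
    if group_test not in ("welch", "index_paired"):
        raise ConfigurationError(f"unknown group_test {group_test!r}")
    if pooling not in ("mean", "stack"):
        raise ConfigurationError(f"unknown pooling {pooling!r}")
    by_pid = _index_profiles(profiles)
    group_of = {a.participant_id: a.group for a in assignments}
    unassigned = sorted(set(by_pid) - set(group_of))
    if unassigned:
        raise CompletenessError(f"participants without group assignment: {unassigned}")
    pids = sorted(by_pid)
    high = [pid for pid in pids if group_of[pid] == "high"]
    low = [pid for pid in pids if group_of[pid] == "low"]

    def val(pid: str, partner: str, feature: str) -> float:
        return by_pid[pid][partner].ratio(feature)

    def pooled(pid: str, feature: str) -> list[float]:
        both = [val(pid, "human", feature), val(pid, "ai", feature)]
        return [sum(both) / 2.0] if pooling == "mean" else both

    def group_contrast(feature: str, xs_ids, ys_ids, values):
        if not xs_ids or not ys_ids:
            raise CompletenessError(
                f"empty group (high n={len(xs_ids)}, low n={len(ys_ids)})"
            )
        x = [v for pid in xs_ids for v in values(pid)]
        y = [v for pid in ys_ids for v in values(pid)]
        if group_test == "index_paired":
            if len(x) != len(y):
                raise CompletenessError(
                    f"index pairing needs equal group sizes, got {len(x)} and {len(y)}"
                )
            return paired_t(x, y)
        return welch_t(x, y)

    results: list[ComparisonResult] = []
    for feature in FEATURES:
        plans = {
            "partner_all": lambda f=feature: paired_t(
                [val(pid, "human", f) for pid in pids],
                [val(pid, "ai", f) for pid in pids],
            ),
            "group_all": lambda f=feature: group_contrast(
                f, high, low, lambda pid: pooled(pid, f)
            ),
            "partner_within_high": lambda f=feature: paired_t(
                [val(pid, "human", f) for pid in high],
                [val(pid, "ai", f) for pid in high],
            ),
            "partner_within_low": lambda f=feature: paired_t(
                [val(pid, "human", f) for pid in low],
                [val(pid, "ai", f) for pid in low],
            ),
            "group_within_ai": lambda f=feature: group_contrast(
                f, high, low, lambda pid: [val(pid, "ai", f)]
            ),
            "group_within_human": lambda f=feature: group_contrast(
                f, high, low, lambda pid: [val(pid, "human", f)]
            ),
        }
        for contrast in CONTRASTS:
            try:
                results.append(ComparisonResult(feature, contrast, plans[contrast]()))
            except (SampleSizeError, DegenerateVarianceError, CompletenessError) as exc:
                results.append(ComparisonResult(feature, contrast, None, str(exc)))
    return results


def significance_annotation(p: float) -> str:
    """Threshold annotation mirroring conventional reporting; raw p is kept."""
    if p < 0.01:
        return "p<0.01"
    if p < 0.05:
        return "p<0.05"
    return "ns"


def battery_to_frame(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    """Battery as a flat table, one row per (feature, contrast)."""
    rows = []
    for r in results:
        if r.result is None:
            rows.append({
                "feature": r.feature, "contrast": r.contrast, "kind": "skipped",
                "t": float("nan"), "df": float("nan"), "p": float("nan"),
                "mean_a": float("nan"), "mean_b": float("nan"),
                "n_a": 0, "n_b": 0, "annotation": r.error,
            })
        else:
            t = r.result
            rows.append({
                "feature": r.feature, "contrast": r.contrast, "kind": t.kind,
                "t": t.t, "df": t.df, "p": t.p_two_tailed,
                "mean_a": t.mean_a, "mean_b": t.mean_b,
                "n_a": t.n_a, "n_b": t.n_b,
                "annotation": significance_annotation(t.p_two_tailed),
            })
    return pd.DataFrame(rows, columns=[
        "feature", "contrast", "kind", "t", "df", "p",
        "mean_a", "mean_b", "n_a", "n_b", "annotation",
    ])


def holm_adjust(results: Sequence[ComparisonResult]) -> dict[tuple[str, str], float]:
    """Optional Holm step-down adjustment over the battery's raw p-values.

    Clearly non-default: the source analysis reports unadjusted p-values.
    """
    tested = [(r.feature, r.contrast, r.result.p_two_tailed)
              for r in results if r.result is not None]
    m = len(tested)
    order = sorted(range(m), key=lambda i: tested[i][2])
    adjusted: dict[tuple[str, str], float] = {}
    running = 0.0
    for rank, i in enumerate(order):
        feature, contrast, p = tested[i]
        running = max(running, min(1.0, (m - rank) * p))
        adjusted[(feature, contrast)] = running
    return adjusted
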