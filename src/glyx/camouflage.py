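"""Immunocamouflage metrics from flow-cytometry MFI measurements.

Relative protection of a membrane antigen (RhD, CD47, ...) is the percent
reduction in antibody-binding MFI on polymer-grafted cells relative to
unmodified controls:

    protection = 100 * (1 - MFI_modified / MFI_control)

Negative values (binding above control) are reported, not clipped — clipping
would hide failed grafting.  Crowded versus non-crowded grafting conditions
are summarized by the fold enhancement of protection and compared with
two-tailed Welch t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidParameterError

CONDITIONS = ("control", "noncrowded", "crowded")


@dataclass(frozen=True)
class ProtectionResult:
    """Antigen accessibility summary for one grafting condition."""

    antigen: str
    mfi_control: float
    mfi_modified: float
    relative_protection: float       # percent
    below_control: bool              # True when protection < 0

    @classmethod
    def from_mfis(cls, antigen: str, mfi_control: float,
                  mfi_modified: float) -> "ProtectionResult":
        p = relative_protection(mfi_modified, mfi_control)
        return cls(antigen=antigen, mfi_control=float(mfi_control),
                   mfi_modified=float(mfi_modified),
                   relative_protection=p, below_control=p < 0)


@dataclass(frozen=True)
class GroupComparison:
    """Welch two-sample comparison."""

    t_statistic: float
    welch_df: float
    p_value: float
    group_means: tuple
    group_sds: tuple
    n_per_group: tuple

    def __post_init__(self) -> None:
        if not self.welch_df > 0:
            raise InvalidParameterError("welch_df must be > 0")
        if not 0.0 <= self.p_value <= 1.0:
            raise InvalidParameterError("p_value must be in [0, 1]")


def relative_protection(mfi_modified: float, mfi_control: float) -> float:
    """Percent reduction in antibody-binding MFI versus unmodified control."""
    if not mfi_control > 0:
        raise InvalidParameterError("control MFI must be > 0")
    if mfi_modified < 0:
        raise InvalidParameterError("modified MFI must be >= 0")
    return 100.0 * (1.0 - mfi_modified / mfi_control)


def fold_enhancement(protection_crowded: float,
                     protection_noncrowded: float) -> float:
    """Ratio of crowded to non-crowded protection of an antigen."""
    if protection_noncrowded == 0:
        raise InvalidParameterError(
            "non-crowded protection is zero: fold undefined")
    return protection_crowded / protection_noncrowded


def event_mfi(events: Sequence[float]) -> float:
    """Reduce event-level intensities to one replicate MFI (median)."""
    events = np.asarray(events, dtype=float)
    if events.size == 0:
        raise InvalidParameterError("no events")
    return float(np.median(events))


def welch_compare(group_a: Sequence[float],
                  group_b: Sequence[float]) -> GroupComparison:
    """Two-tailed t-test with Welch's correction (Satterthwaite df)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidParameterError("need n >= 2 per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            # degenerate but well-defined: identical constant groups
            return GroupComparison(0.0, float(a.size + b.size - 2), 1.0,
                                   (float(a.mean()), float(b.mean())),
                                   (0.0, 0.0), (int(a.size), int(b.size)))
        raise InvalidParameterError("zero variance in both groups with "
                                    "different means")
    res = stats.ttest_ind(a, b, equal_var=False)
    return GroupComparison(
        t_statistic=float(res.statistic),
        welch_df=float(res.df),
        p_value=float(res.pvalue),
        group_means=(float(a.mean()), float(b.mean())),
        group_sds=(float(a.std(ddof=1)), float(b.std(ddof=1))),
        n_per_group=(int(a.size), int(b.size)),
    )


def analyze_protection(table: pd.DataFrame) -> pd.DataFrame:
    """Per-antigen protection, fold enhancement and Welch comparison.

    ``table`` is tidy with columns ``antigen``, ``condition`` (one of
    ``control``/``noncrowded``/``crowded``), ``replicate`` and ``mfi``.
    Protection per condition uses the mean replicate MFI against the mean
    control MFI; the Welch test compares crowded vs non-crowded replicate
    MFIs directly.
    """
    required = {"antigen", "condition", "mfi"}
    if not required.issubset(table.columns):
        raise InvalidParameterError(f"table needs columns {sorted(required)}")
    rows = []
    for antigen, sub in table.groupby("antigen", sort=True):
        by_cond = {c: sub.loc[sub["condition"] == c, "mfi"].to_numpy()
                   for c in CONDITIONS}
        for c in CONDITIONS:
            if by_cond[c].size == 0:
                raise InvalidParameterError(
                    f"antigen {antigen!r} lacks condition {c!r}")
        ctrl = float(by_cond["control"].mean())
        p_nc = relative_protection(float(by_cond["noncrowded"].mean()), ctrl)
        p_cr = relative_protection(float(by_cond["crowded"].mean()), ctrl)
        comp = welch_compare(by_cond["crowded"], by_cond["noncrowded"])
        rows.append({
            "antigen": antigen,
            "mfi_control": ctrl,
            "protection_noncrowded": p_nc,
            "protection_crowded": p_cr,
            "fold_enhancement": fold_enhancement(p_cr, p_nc),
            "welch_t": comp.t_statistic,
            "welch_df": comp.welch_df,
            "p_value": comp.p_value,
        })
    return pd.DataFrame(rows)
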