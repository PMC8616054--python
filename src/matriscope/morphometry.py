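"""Spheroid volumes and group comparisons (one-way ANOVA + Tukey HSD).

Aggregate size from two caliper-style measurements uses the standard
ellipsoid approximation ``V = (length x width^2) / 2``.  Group means
(volumes or protrusion counts) are compared with one-way ANOVA followed
by all-pairs Tukey HSD at alpha = 0.05; unbalanced designs use the
Tukey-Kramer harmonic-mean adjustment (as implemented in statsmodels).
Measurement units are whatever the input table carries — volumes come
out in the cube of the length unit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd


@dataclass
class VolumeRecord:
    """Single aggregate: group label, caliper length/width, volume."""

    group: str
    length: float
    width: float

    def __post_init__(self) -> None:
        if self.length <= 0 or self.width <= 0:
            raise ValueError("length and width must be positive")
        if self.width > self.length:
            warnings.warn(
                f"width {self.width} > length {self.length}; swapping "
                "(length is the major axis by convention)",
                stacklevel=2,
            )
            self.length, self.width = self.width, self.length

    @property
    def volume(self) -> float:
        return compute_volume(self.length, self.width)


@dataclass
class ComparisonResult:
    """One-way ANOVA with Tukey HSD post-hoc at fixed alpha."""

    F_statistic: float
    p_value: float
    pairwise: pd.DataFrame  # group1, group2, meandiff, p_adj, lower, upper, reject
    alpha: float = 0.05
    response: str = "volume"
    zero_within_variance: bool = False

    def significant_pairs(self) -> list[tuple[str, str]]:
        sig = self.pairwise[self.pairwise["reject"]]
        return list(zip(sig["group1"], sig["group2"]))

    def pair_p(self, a: str, b: str) -> float:
        pw = self.pairwise
        m = ((pw.group1 == a) & (pw.group2 == b)) | (
            (pw.group1 == b) & (pw.group2 == a)
        )
        if not m.any():
            raise KeyError(f"no comparison between {a!r} and {b!r}")
        return float(pw.loc[m, "p_adj"].iloc[0])


def compute_volume(length: float, width: float) -> float:
    """Aggregate volume (length x width^2) / 2, in the cubed input unit."""
    if length <= 0 or width <= 0:
        raise ValueError("length and width must be positive")
    return length * width * width / 2.0


def add_volumes(table: pd.DataFrame) -> pd.DataFrame:
    """Append a ``volume`` column computed from length and width."""
    out = table.copy()
    out["volume"] = [
        compute_volume(l, w) for l, w in zip(out["length"], out["width"])
    ]
    return out


def compare_groups(
    table: pd.DataFrame, response: str = "volume", alpha: float = 0.05
) -> ComparisonResult:
    """One-way ANOVA plus Tukey HSD on a tidy (group, response) table.

    ``response`` is ``"volume"`` (computed from length/width if absent)
    or ``"count"``.  Degenerate input — zero variance within every group
    but unequal means — is reported as F = inf, p = 0 with a flag;
    identical constant groups give F = 0, p = 1.
    """
    if response == "volume" and "volume" not in table.columns:
        table = add_volumes(table)
    if response not in table.columns:
        raise ValueError(f"table has no {response!r} column")
    groups = [np.asarray(g[response], dtype=float) for _, g in table.groupby("group")]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if min(len(g) for g in groups) < 2:
        raise ValueError("need at least 2 observations per group")

    grand = np.concatenate(groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    ss_between = sum(len(g) * (g.mean() - grand.mean()) ** 2 for g in groups)
    zero_within = False
    if ss_within == 0:
        if ss_between == 0:  # all observations identical
            F, p = 0.0, 1.0
        else:
            zero_within = True
            warnings.warn(
                "zero within-group variance with unequal means; p = 0",
                stacklevel=2,
            )
            F, p = float("inf"), 0.0
    else:
        F, p = stats.f_oneway(*groups)

    with warnings.catch_warnings():
        if zero_within or ss_within == 0:  # division by zero inside Tukey
            warnings.simplefilter("ignore", RuntimeWarning)
        tukey = pairwise_tukeyhsd(
            endog=table[response].astype(float).to_numpy(),
            groups=table["group"].to_numpy(),
            alpha=alpha,
        )
    pairwise = pd.DataFrame(
        tukey.summary().data[1:],
        columns=["group1", "group2", "meandiff", "p_adj", "lower", "upper", "reject"],
    )
    pairwise["p_adj"] = tukey.pvalues  # full precision, not table-rounded
    pairwise["meandiff"] = tukey.meandiffs
    pairwise["reject"] = tukey.reject
    return ComparisonResult(
        F_statistic=float(F),
        p_value=float(p),
        pairwise=pairwise,
        alpha=alpha,
        response=response,
        zero_within_variance=zero_within,
    )
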