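"""Group-comparison statistics for the characterization experiments.

The study design is a set of one-factor sweeps (acoustic power, cycles/pulse,
total sonication time, PRF) with N = 3 replicates per level. Each outcome
(lesion volume, temperature FWHM) is compared across levels with a classical
one-way ANOVA followed by Bonferroni-protected pairwise comparisons using the
pooled within-group mean square; lesion volume vs lethal-dose area is
summarized with Pearson correlation. Two-tailed p-values throughout,
significance at p <= 0.05.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateGroupError, InvalidInputError

__all__ = [
    "GroupData",
    "ComparisonResult",
    "one_way_anova",
    "pearson",
    "linear_fit_r2",
    "summarize_effects",
]

ALPHA = 0.05


@dataclass
class GroupData:
    """Replicate measurements at each level of one factor."""

    levels: list
    values: list[np.ndarray]  # one array of replicates per level

    def __post_init__(self) -> None:
        if len(self.levels) != len(self.values):
            raise InvalidInputError("levels and values length mismatch")
        if len(self.levels) < 2:
            raise InvalidInputError("need >= 2 levels")
        self.values = [np.asarray(v, dtype=float) for v in self.values]
        if any(len(v) < 2 for v in self.values):
            raise InvalidInputError("need >= 2 replicates per level for ANOVA")

    @classmethod
    def from_tidy(cls, df: pd.DataFrame, level_col: str = "level", value_col: str = "value"):
        groups = df.groupby(level_col, sort=True)[value_col]
        return cls(levels=list(groups.groups), values=[g.to_numpy() for _, g in groups])


@dataclass
class ComparisonResult:
    """One-way ANOVA with Bonferroni-adjusted pairwise comparisons."""

    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    pairwise: pd.DataFrame  # columns: level_a, level_b, t, p_raw, p_adjusted, significant
    alpha: float = ALPHA

    @property
    def significant(self) -> bool:
        return self.p_value <= self.alpha


def one_way_anova(data: GroupData, alpha: float = ALPHA) -> ComparisonResult:
    """Classical one-way ANOVA with Bonferroni-protected pairwise t-tests.

    F = MS_between / MS_within with (k-1, N-k) degrees of freedom. Pairwise
    comparisons are two-tailed t-tests that share the pooled within-group
    mean square (df = N-k); raw p-values are multiplied by the number of
    pairs m = k(k-1)/2 and capped at 1.
    """
    k = len(data.levels)
    ns = np.array([len(v) for v in data.values])
    n_total = int(ns.sum())
    means = np.array([v.mean() for v in data.values])
    for lvl, v in zip(data.levels, data.values):
        if np.allclose(v, v[0]):
            raise DegenerateGroupError(
                f"group {lvl!r} has zero within-group variance"
            )
    grand = np.concatenate(data.values).mean()
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(sum(((v - m) ** 2).sum() for v, m in zip(data.values, means)))
    df_b, df_w = k - 1, n_total - k
    ms_between = ss_between / df_b
    ms_within = ss_within / df_w
    f_stat = ms_between / ms_within
    p = float(sps.f.sf(f_stat, df_b, df_w))

    m = k * (k - 1) // 2
    rows = []
    for (ia, ib) in itertools.combinations(range(k), 2):
        se = np.sqrt(ms_within * (1.0 / ns[ia] + 1.0 / ns[ib]))
        t = (means[ia] - means[ib]) / se
        p_raw = 2.0 * float(sps.t.sf(abs(t), df_w))
        p_adj = min(1.0, m * p_raw)
        rows.append(
            {
                "level_a": data.levels[ia],
                "level_b": data.levels[ib],
                "t": t,
                "p_raw": p_raw,
                "p_adjusted": p_adj,
                "significant": p_adj <= alpha,
            }
        )
    return ComparisonResult(
        f_statistic=f_stat,
        p_value=p,
        df_between=df_b,
        df_within=df_w,
        pairwise=pd.DataFrame(rows),
        alpha=alpha,
    )


def pearson(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with its two-tailed p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise InvalidInputError("need aligned inputs of length >= 3")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise InvalidInputError("correlation undefined for constant input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def linear_fit_r2(x, y) -> float:
    """Coefficient of determination of the ordinary least-squares line."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise InvalidInputError("need aligned inputs of length >= 3")
    if np.allclose(x, x[0]):
        raise InvalidInputError("x is constant; fit undefined")
    if np.allclose(y, y[0]):
        return 0.0
    res = sps.linregress(x, y)
    return float(res.rvalue**2)


def summarize_effects(
    factors: dict[str, dict], alpha: float = ALPHA
) -> pd.DataFrame:
    """Per-factor significance summary of the characterization outcomes.

    ``factors`` maps factor name -> dict with keys:

    - ``levels``: factor levels (numeric, increasing),
    - ``volumes``: (n_levels, n_replicates) lesion volumes in mm^3,
    - ``fwhms``: (n_levels, n_replicates) temperature FWHM in mm,
    - ``lethal_areas``: per-level (or per-replicate) lethal-dose areas, mm^2.

    A factor "increases" an outcome (Yes) when the one-way ANOVA across its
    levels is significant at ``alpha`` and the level-mean trend is positive;
    the lethal-area column reports whether lethal area correlates positively
    (Pearson, p <= alpha) with lesion volume across the sweep.
    """
    rows = []
    for name, d in factors.items():
        levels = np.asarray(d["levels"], dtype=float)
        vols = np.asarray(d["volumes"], dtype=float)
        fwhms = np.asarray(d["fwhms"], dtype=float)
        areas = np.asarray(d["lethal_areas"], dtype=float)
        if vols.shape[0] != len(levels) or fwhms.shape[0] != len(levels):
            raise InvalidInputError(f"factor {name!r}: misaligned inputs")
        row = {"factor": name}
        for col, mat in (("volume_increase", vols), ("fwhm_increase", fwhms)):
            res = one_way_anova(GroupData(list(levels), list(mat)))
            slope = sps.linregress(levels, mat.mean(axis=1)).slope
            row[col] = "Yes" if (res.p_value <= alpha and slope > 0) else "No"
        vol_flat = vols.reshape(len(levels), -1)
        area_flat = areas.reshape(len(levels), -1)
        if area_flat.shape[1] == 1 and vol_flat.shape[1] > 1:
            area_flat = np.repeat(area_flat, vol_flat.shape[1], axis=1)
        r, p = pearson(vol_flat.ravel(), area_flat.ravel())
        row["lethal_area_increase"] = "Yes" if (p <= alpha and r > 0) else "No"
        rows.append(row)
    return pd.DataFrame(rows)
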