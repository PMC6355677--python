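"""Statistical layer: factorial ANOVA, Duncan's multiple range test, OLS fits.

Per-time-point fixed-effects ANOVA mirrors the day-wise genotype x treatment
F tables of greenhouse screens: one model per imaging day, no repeated-
measures structure.  Only balanced designs are accepted for the two-way
decomposition, which sidesteps the Type I/II/III sums-of-squares ambiguity —
for balanced data all three coincide and the closed-form mean-based
decomposition below is exact.

Duncan's new multiple range test ranks group means after a one-way ANOVA:
means are sorted in descending order and a stretch of p consecutive means is
declared homogeneous when its range does not exceed the least significant
range R_p = q_{(1-alpha)^(p-1)}(p, df_err) * sqrt(MSE / n), with the
studentized-range quantile taken at Duncan's protection level.  Maximal
homogeneous stretches receive the letter codes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class EffectRow:
    ss: float
    df: int
    ms: float
    F: float
    p: float


@dataclass
class AnovaResult:
    """Fixed-effects decomposition: per-effect SS/df/F/p plus the residual."""

    effects: dict[str, EffectRow]
    residual_ss: float
    residual_df: int
    total_ss: float

    @property
    def residual_ms(self) -> float:
        return self.residual_ss / self.residual_df if self.residual_df else np.nan

    def to_frame(self) -> pd.DataFrame:
        rows = [(name, e.ss, e.df, e.ms, e.F, e.p)
                for name, e in self.effects.items()]
        rows.append(("residual", self.residual_ss, self.residual_df,
                     self.residual_ms, np.nan, np.nan))
        return pd.DataFrame(rows, columns=["effect", "ss", "df", "ms", "F", "p"])


@dataclass
class MRTGrouping:
    """Duncan ranking: per-group mean, n and letter code, with the pooled
    error mean square and df the ranges were computed from."""

    table: pd.DataFrame          # group, mean, n, letters (sorted descending)
    alpha: float
    ms_error: float
    df_error: int
    n_effective: float
    used_harmonic_n: bool = False
    critical_ranges: dict[int, float] = field(default_factory=dict)

    def letters(self) -> dict[str, str]:
        return dict(zip(self.table["group"], self.table["letters"]))


@dataclass
class LinearFit:
    slope: float
    intercept: float
    r2: float
    p: float
    n: int


def _f_test(ss: float, df: int, ms_res: float, df_res: int) -> tuple[float, float]:
    ms = ss / df
    if ms_res == 0:
        return (np.inf, 0.0) if ms > 0 else (0.0, 1.0)
    F = ms / ms_res
    return F, float(sps.f.sf(F, df, df_res))


def anova_two_way(data: pd.DataFrame, *, value: str = "value",
                  genotype: str = "genotype",
                  treatment: str = "treatment") -> AnovaResult:
    """Balanced two-way fixed-effects ANOVA with interaction.

    ``data`` holds one row per observation.  Every genotype x treatment cell
    must contain the same number (>= 2) of replicates; unbalanced or singleton
    cells raise an error naming the offending cells (the designs this serves
    are balanced by construction).
    """
    sizes = data.groupby([genotype, treatment], sort=False)[value].size()
    if sizes.min() < 2 or sizes.nunique() > 1:
        common = int(sizes.mode().iloc[0])
        bad = sizes[(sizes < 2) | (sizes != common)].index.tolist()
        raise ValueError(f"unbalanced or singleton cells: {bad[:10]}")
    n = int(sizes.iloc[0])
    y = data[value].to_numpy(float)
    grand = y.mean()
    total_ss = float(((y - grand) ** 2).sum())

    mg = data.groupby(genotype, sort=False)[value].mean()
    mt = data.groupby(treatment, sort=False)[value].mean()
    mc = data.groupby([genotype, treatment], sort=False)[value].mean()
    a, b = len(mg), len(mt)

    ss_g = b * n * float(((mg - grand) ** 2).sum())
    ss_t = a * n * float(((mt - grand) ** 2).sum())
    ss_cells = n * float(((mc - grand) ** 2).sum())
    ss_int = ss_cells - ss_g - ss_t
    ss_res = total_ss - ss_cells
    df_g, df_t, df_int = a - 1, b - 1, (a - 1) * (b - 1)
    df_res = a * b * (n - 1)
    ms_res = ss_res / df_res

    effects = {}
    for name, ss, df in (("treatment", ss_t, df_t), ("genotype", ss_g, df_g),
                         ("interaction", ss_int, df_int)):
        if df == 0:
            continue
        F, p = _f_test(ss, df, ms_res, df_res)
        effects[name] = EffectRow(ss=ss, df=df, ms=ss / df, F=max(F, 0.0), p=p)
    return AnovaResult(effects=effects, residual_ss=ss_res,
                       residual_df=df_res, total_ss=total_ss)


def _as_groups(groups) -> dict[str, np.ndarray]:
    if isinstance(groups, Mapping):
        return {str(k): np.asarray(v, float) for k, v in groups.items()}
    return {f"g{i}": np.asarray(v, float) for i, v in enumerate(groups)}


def anova_one_way(groups: Mapping[str, Sequence[float]] |
                  Sequence[Sequence[float]]) -> AnovaResult:
    """One-way fixed-effects ANOVA over two or more groups (each n >= 2)."""
    g = _as_groups(groups)
    if len(g) < 2:
        raise ValueError("need at least 2 groups")
    small = [k for k, v in g.items() if v.size < 2]
    if small:
        raise ValueError(f"groups with n < 2: {small}")
    allv = np.concatenate(list(g.values()))
    grand = allv.mean()
    total_ss = float(((allv - grand) ** 2).sum())
    ss_b = float(sum(v.size * (v.mean() - grand) ** 2 for v in g.values()))
    ss_w = float(sum(((v - v.mean()) ** 2).sum() for v in g.values()))
    df_b = len(g) - 1
    df_w = allv.size - len(g)
    F, p = _f_test(ss_b, df_b, ss_w / df_w, df_w)
    return AnovaResult(
        effects={"group": EffectRow(ss=ss_b, df=df_b, ms=ss_b / df_b, F=F, p=p)},
        residual_ss=ss_w, residual_df=df_w, total_ss=total_ss)


@lru_cache(maxsize=4096)
def _duncan_q(alpha: float, span: int, df: int) -> float:
    # studentized-range quantile at Duncan's protection level (1-alpha)^(span-1)
    return float(sps.studentized_range.ppf((1.0 - alpha) ** (span - 1),
                                           span, df))


def duncan_mrt(groups: Mapping[str, Sequence[float]] |
               Sequence[Sequence[float]], alpha: float = 0.05) -> MRTGrouping:
    """Duncan's new multiple range test on a one-way layout.

    Unequal group sizes are handled with the harmonic mean of the n's and
    flagged.  Means sharing a letter are not significantly different at
    ``alpha`` under Duncan's protected range procedure.
    """
    g = _as_groups(groups)
    aov = anova_one_way(g)
    mse, dferr = aov.residual_ms, aov.residual_df
    if dferr < 1:
        raise ValueError("residual df < 1")
    names = list(g)
    means = np.array([g[k].mean() for k in names])
    ns = np.array([g[k].size for k in names])
    harmonic = len(ns) / float((1.0 / ns).sum())
    used_harm = ns.min() != ns.max()
    order = np.argsort(-means, kind="stable")
    m_sorted = means[order]
    k = len(names)
    se = np.sqrt(mse / harmonic)
    ranges = {p: (_duncan_q(alpha, p, int(dferr)) * se if mse > 0 else 0.0)
              for p in range(2, k + 1)}

    # maximal homogeneous stretches of the descending means (protected:
    # the widest non-significant span is never subdivided)
    def jmax(i: int) -> int:
        for j in range(k - 1, i, -1):
            if m_sorted[i] - m_sorted[j] <= ranges[j - i + 1]:
                return j
        return i

    letters = [""] * k
    code, prev_end = 0, -1
    for i in range(k):
        j = jmax(i)
        if j > prev_end or prev_end < i:
            lab = _letter(code)
            code += 1
            for idx in range(i, j + 1):
                letters[idx] += lab
            prev_end = j
    table = pd.DataFrame({
        "group": [names[o] for o in order],
        "mean": m_sorted,
        "n": ns[order],
        "letters": letters,
    })
    return MRTGrouping(table=table, alpha=alpha, ms_error=mse,
                       df_error=int(dferr), n_effective=float(harmonic),
                       used_harmonic_n=bool(used_harm),
                       critical_ranges=ranges)


def _letter(code: int) -> str:
    letters = "abcdefghijklmnopqrstuvwxyz"
    out = ""
    code += 1
    while code:
        code, rem = divmod(code - 1, 26)
        out = letters[rem] + out
    return out


def linear_fit(x: Sequence[float], y: Sequence[float]) -> LinearFit:
    """Ordinary least squares of y on x with r2 = squared Pearson correlation
    and the two-sided p-value for the slope."""
    xv = np.asarray(x, float)
    yv = np.asarray(y, float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if xv.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(xv) == 0:
        raise ValueError("x is constant")
    if np.ptp(yv) == 0:
        return LinearFit(slope=0.0, intercept=float(yv[0]), r2=0.0, p=1.0,
                         n=int(xv.size))
    res = sps.linregress(xv, yv)
    return LinearFit(slope=float(res.slope), intercept=float(res.intercept),
                     r2=float(res.rvalue ** 2), p=float(res.pvalue),
                     n=int(xv.size))


def anova_by_day(traits: pd.DataFrame, *, value: str = "db") -> pd.DataFrame:
    """Per-day two-way ANOVA report over a plant-level trait table
    (day x effect x F x p layout)."""
    rows = []
    for day, sub in traits.groupby("day", sort=True):
        res = anova_two_way(sub, value=value)
        for name, e in res.effects.items():
            rows.append((day, name, e.ss, e.df, e.F, e.p))
    return pd.DataFrame(rows, columns=["day", "effect", "ss", "df", "F", "p"])
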