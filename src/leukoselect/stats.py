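"""Two-way ANOVA and Tukey HSD for classifier-accuracy comparisons.

The accuracy grid produced by crossing classifiers with feature-selection
methods (with replicate runs per cell) is analysed with a balanced
fixed-effects two-way ANOVA with interaction, followed by Tukey's honestly
significant difference test for all-pairs comparisons under the studentized
range distribution.

Layout convention (matching the usual two-way accuracy table): the first
axis of the observation array is the "Columns" factor (e.g. classifier),
the second the "Rows" factor (e.g. selector), the third the replicates.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps

from .errors import DesignError

__all__ = ["AnovaRow", "AnovaTable", "TukeyComparison", "TukeyResult", "two_way_anova", "tukey_hsd"]


@dataclass(frozen=True)
class AnovaRow:
    source: str
    ss: float
    df: int
    ms: float | None
    f: float | None
    p: float | None


@dataclass(frozen=True)
class AnovaTable:
    """Rows: Columns, Rows, Interaction, Error, Total (Source/SS/df/MS/F/p)."""

    rows: tuple[AnovaRow, ...]

    def __getitem__(self, source: str) -> AnovaRow:
        for r in self.rows:
            if r.source == source:
                return r
        raise KeyError(source)

    def to_dict(self) -> dict:
        return {
            r.source: {"SS": r.ss, "df": r.df, "MS": r.ms, "F": r.f, "p": r.p} for r in self.rows
        }

    def render(self) -> str:
        lines = [f"{'Source':<12}{'SS':>12}{'df':>5}{'MS':>12}{'F':>10}{'Prob>F':>10}"]
        for r in self.rows:
            ms = f"{r.ms:.4f}" if r.ms is not None else "-"
            f = f"{r.f:.4f}" if r.f is not None else "-"
            p = f"{r.p:.4f}" if r.p is not None else "-"
            lines.append(f"{r.source:<12}{r.ss:>12.4f}{r.df:>5}{ms:>12}{f:>10}{p:>10}")
        return "\n".join(lines)


def two_way_anova(observations) -> AnovaTable:
    """Balanced fixed-effects two-way ANOVA with interaction.

    ``observations`` is an array of shape (a, b, r): ``a`` levels of the
    column factor, ``b`` levels of the row factor, ``r >= 2`` replicates per
    cell. Unbalanced input (including a ragged nested list) is a design
    error. F statistics are not available (``None``) when the error mean
    square vanishes.
    """
    try:
        y = np.asarray(observations, dtype=np.float64)
    except ValueError as exc:
        raise DesignError(f"design is not balanced: {exc}") from exc
    if y.ndim != 3:
        raise DesignError("observations must have shape (column levels, row levels, replicates)")
    a, b, r = y.shape
    if a < 2 or b < 2 or r < 2:
        raise DesignError("need >= 2 levels per factor and >= 2 replicates per cell")

    grand = y.mean()
    col_means = y.mean(axis=(1, 2))
    row_means = y.mean(axis=(0, 2))
    cell_means = y.mean(axis=2)

    ss_col = b * r * float(np.sum((col_means - grand) ** 2))
    ss_row = a * r * float(np.sum((row_means - grand) ** 2))
    ss_int = r * float(np.sum((cell_means - col_means[:, None] - row_means[None, :] + grand) ** 2))
    ss_err = float(np.sum((y - cell_means[:, :, None]) ** 2))
    ss_tot = float(np.sum((y - grand) ** 2))

    df_col, df_row = a - 1, b - 1
    df_int = df_col * df_row
    df_err = a * b * (r - 1)
    df_tot = a * b * r - 1

    ms_err = ss_err / df_err

    def effect(source: str, ss: float, df: int) -> AnovaRow:
        ms = ss / df
        if ms_err <= 0.0:
            return AnovaRow(source, ss, df, ms, None, None)
        f = ms / ms_err
        return AnovaRow(source, ss, df, ms, f, float(sps.f.sf(f, df, df_err)))

    return AnovaTable(
        rows=(
            effect("Columns", ss_col, df_col),
            effect("Rows", ss_row, df_row),
            effect("Interaction", ss_int, df_int),
            AnovaRow("Error", ss_err, df_err, ms_err, None, None),
            AnovaRow("Total", ss_tot, df_tot, None, None, None),
        )
    )


@dataclass(frozen=True)
class TukeyComparison:
    group_a: int
    group_b: int
    difference: float
    lower: float
    upper: float
    p_value: float

    def __post_init__(self) -> None:
        if not (self.lower <= self.difference <= self.upper):
            raise ValueError("confidence interval must contain the difference")


@dataclass(frozen=True)
class TukeyResult:
    comparisons: tuple[TukeyComparison, ...]
    alpha: float
    ms_within: float
    df_within: int

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "comparisons": [
                {
                    "group_a": c.group_a,
                    "group_b": c.group_b,
                    "difference": c.difference,
                    "lower": c.lower,
                    "upper": c.upper,
                    "p_value": c.p_value,
                }
                for c in self.comparisons
            ],
        }

    def render(self) -> str:
        lines = [f"{'Group A':>8}{'Group B':>8}{'Difference':>12}{'Lower':>10}{'Upper':>10}{'P-value':>10}"]
        for c in self.comparisons:
            lines.append(
                f"{c.group_a:>8}{c.group_b:>8}{c.difference:>12.4f}{c.lower:>10.4f}"
                f"{c.upper:>10.4f}{c.p_value:>10.4f}"
            )
        return "\n".join(lines)


def tukey_hsd(groups, alpha: float = 0.05) -> TukeyResult:
    """All-pairs mean comparisons with simultaneous studentized-range CIs.

    ``groups`` is a sequence of k >= 2 equal-size samples (each >= 2
    observations). For pair (i, j), ``difference`` = mean_i - mean_j; the
    interval is difference +/- q_{alpha;k,df} * sqrt(MSW / n) and the
    p-value comes from the same studentized range distribution.
    Unequal group sizes are a design error (Tukey-Kramer not implemented).
    """
    arrays = [np.asarray(g, dtype=np.float64).ravel() for g in groups]
    k = len(arrays)
    if k < 2:
        raise DesignError("need at least two groups")
    n = len(arrays[0])
    if n < 2:
        raise DesignError("each group needs at least 2 observations")
    if any(len(g) != n for g in arrays):
        raise DesignError("groups must have equal sizes")

    means = np.array([g.mean() for g in arrays])
    df_within = k * (n - 1)
    ms_within = float(sum(np.sum((g - g.mean()) ** 2) for g in arrays) / df_within)
    se = np.sqrt(ms_within / n)
    q_dist = sps.studentized_range(k, df_within)
    halfwidth = float(q_dist.ppf(1.0 - alpha)) * se

    comparisons = []
    for i, j in combinations(range(k), 2):
        diff = float(means[i] - means[j])
        if se > 0:
            p = float(q_dist.sf(abs(diff) / se))
        else:
            p = 1.0 if diff == 0 else 0.0
        comparisons.append(
            TukeyComparison(
                group_a=i + 1,
                group_b=j + 1,
                difference=diff,
                lower=diff - halfwidth,
                upper=diff + halfwidth,
                p_value=min(max(p, 0.0), 1.0),
            )
        )
    return TukeyResult(tuple(comparisons), alpha=alpha, ms_within=ms_within, df_within=df_within)
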