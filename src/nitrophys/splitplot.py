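"""Balanced split-plot ANOVA, LS means, and Tukey HSD letter display.

The experiment applies one factor to whole (main) plots nested in
replicate blocks and a second factor to sub-plots within each main
plot — here, nitrogen level on main plots and cultivar on sub-plots,
with r replicate blocks. The classical expected-mean-squares
decomposition of

    y_ijk = μ + ρ_j + α_i + (ρα)_ij + β_k + (αβ)_ik + ε_ijk

gives two error strata: the replicate×main-plot interaction tests the
main-plot factor, and the residual tests the sub-plot factor and the
interaction. For balanced data these F tests coincide with the
REML/mixed-model tests, LS means equal arithmetic cell means, and the
whole decomposition is exact and auditable.

Tukey HSD comparisons among the a·b cell means use the studentized
range. Comparisons within a main-plot level use the sub-plot residual
alone; comparisons crossing main plots combine the two error strata,
Var(diff) = 2·[(b−1)·MS_e + MS_mpe]/(r·b), with Satterthwaite degrees
of freedom. Letters are assigned by the insert-and-absorb algorithm,
alphabetical from the largest mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DesignError

__all__ = [
    "SplitPlotAnova",
    "check_balance",
    "anova_split_plot",
    "tukey_letters",
    "null_rejection_rates",
    "REPLICATE",
    "MAIN_PLOT",
    "SUB_PLOT",
]

#: Canonical design-column names of a trait table.
REPLICATE = "replicate"
MAIN_PLOT = "n_level"
SUB_PLOT = "cultivar"

_SOURCES = ("replicate", "main", "mainplot_error", "sub", "interaction", "residual")


@dataclass
class SplitPlotAnova:
    """ANOVA decomposition for one trait.

    ``anova_table`` has one row per source (replicate, main-plot
    factor, main-plot error, sub-plot factor, interaction, residual)
    with df, SS, MS, F, and p. F for the main-plot factor is tested
    against the main-plot error; sub-plot and interaction against the
    residual. ``cell_means`` maps (main level, sub level) to the LS
    mean (equal to the arithmetic cell mean in a balanced design).
    """

    trait: str
    anova_table: pd.DataFrame
    cell_means: dict[tuple[str, str], float]
    ms_mainplot_error: float
    df_mainplot_error: int
    ms_residual: float
    df_residual: int
    n_replicates: int
    n_sub: int
    degenerate: bool = False
    letters: dict[tuple[str, str], str] = field(default_factory=dict)

    @property
    def f_main(self) -> float:
        return float(self.anova_table.loc["main", "F"])

    @property
    def p_main(self) -> float:
        return float(self.anova_table.loc["main", "p"])

    @property
    def p_sub(self) -> float:
        return float(self.anova_table.loc["sub", "p"])

    @property
    def p_interaction(self) -> float:
        return float(self.anova_table.loc["interaction", "p"])


def check_balance(table: pd.DataFrame) -> tuple[list, list, list]:
    """Verify every replicate × main × sub cell occurs exactly once.

    Returns the sorted level lists (main, replicate, sub). Raises
    :class:`DesignError` on duplicates or missing cells.
    """
    for col in (REPLICATE, MAIN_PLOT, SUB_PLOT):
        if col not in table.columns:
            raise DesignError(f"trait table missing design column {col!r}")
    counts = table.groupby([MAIN_PLOT, REPLICATE, SUB_PLOT], sort=True).size()
    mains = sorted(table[MAIN_PLOT].unique())
    reps = sorted(table[REPLICATE].unique())
    subs = sorted(table[SUB_PLOT].unique())
    expected = len(mains) * len(reps) * len(subs)
    if (counts > 1).any():
        dup = counts[counts > 1].index.tolist()
        raise DesignError(f"duplicate design cells: {dup}")
    if len(counts) != expected:
        raise DesignError(
            f"unbalanced design: {len(counts)} of {expected} "
            "main x replicate x sub cells present"
        )
    return mains, reps, subs


def _decompose(y: np.ndarray) -> dict[str, np.ndarray]:
    """Sums-of-squares decomposition of ``y`` with shape (..., a, r, b).

    Broadcasts over any leading axes, so Monte-Carlo calibration can
    run thousands of simulated experiments in one call.
    """
    a, r, b = y.shape[-3:]
    gm = y.mean(axis=(-3, -2, -1), keepdims=True)
    mi = y.mean(axis=(-2, -1), keepdims=True)
    mj = y.mean(axis=(-3, -1), keepdims=True)
    mij = y.mean(axis=-1, keepdims=True)
    mk = y.mean(axis=(-3, -2), keepdims=True)
    mik = y.mean(axis=-2, keepdims=True)

    ss_rep = a * b * ((mj - gm) ** 2).sum(axis=(-3, -2, -1))
    ss_main = r * b * ((mi - gm) ** 2).sum(axis=(-3, -2, -1))
    ss_mpe = b * ((mij - mi - mj + gm) ** 2).sum(axis=(-3, -2, -1))
    ss_sub = a * r * ((mk - gm) ** 2).sum(axis=(-3, -2, -1))
    ss_int = r * ((mik - mi - mk + gm) ** 2).sum(axis=(-3, -2, -1))
    ss_tot = ((y - gm) ** 2).sum(axis=(-3, -2, -1))
    ss_res = np.clip(ss_tot - ss_rep - ss_main - ss_mpe - ss_sub - ss_int, 0.0, None)

    df = {
        "replicate": r - 1,
        "main": a - 1,
        "mainplot_error": (a - 1) * (r - 1),
        "sub": b - 1,
        "interaction": (a - 1) * (b - 1),
        "residual": a * (r - 1) * (b - 1),
    }
    ss = {
        "replicate": ss_rep,
        "main": ss_main,
        "mainplot_error": ss_mpe,
        "sub": ss_sub,
        "interaction": ss_int,
        "residual": ss_res,
    }
    ms = {k: ss[k] / df[k] if df[k] > 0 else np.full_like(ss[k], np.nan) for k in ss}

    with np.errstate(divide="ignore", invalid="ignore"):
        f_main = ms["main"] / ms["mainplot_error"]
        f_sub = ms["sub"] / ms["residual"]
        f_int = ms["interaction"] / ms["residual"]
    out = {"df": df, "ss": ss, "ms": ms}
    out["F"] = {"main": f_main, "sub": f_sub, "interaction": f_int}
    out["p"] = {
        "main": stats.f.sf(f_main, df["main"], df["mainplot_error"]),
        "sub": stats.f.sf(f_sub, df["sub"], df["residual"]),
        "interaction": stats.f.sf(f_int, df["interaction"], df["residual"]),
    }
    return out


def anova_split_plot(
    table: pd.DataFrame, trait: str, alpha: float = 0.05
) -> SplitPlotAnova:
    """Fit the balanced split-plot ANOVA for one trait column.

    Raises :class:`DesignError` on imbalance and sets the
    ``degenerate`` flag (F/p of sub-plot tests NaN) when the residual
    variance is exactly zero. Tukey letters at ``alpha`` are attached
    via :func:`tukey_letters`.
    """
    mains, reps, subs = check_balance(table)
    if trait not in table.columns:
        raise DesignError(f"trait column {trait!r} not in table")
    if len(reps) < 2:
        raise DesignError("split-plot ANOVA needs >= 2 replicates")
    a, r, b = len(mains), len(reps), len(subs)

    idx = {
        (m, rep, s): (mains.index(m), reps.index(rep), subs.index(s))
        for m in mains
        for rep in reps
        for s in subs
    }
    y = np.empty((a, r, b))
    for _, row in table.iterrows():
        i, j, k = idx[(row[MAIN_PLOT], row[REPLICATE], row[SUB_PLOT])]
        y[i, j, k] = row[trait]
    if not np.all(np.isfinite(y)):
        raise DesignError(f"trait {trait!r} has non-finite values")

    dec = _decompose(y)
    df, ss, ms = dec["df"], dec["ss"], dec["ms"]
    rows = []
    for source in _SOURCES:
        f = dec["F"].get(source, np.nan)
        p = dec["p"].get(source, np.nan)
        rows.append(
            {
                "source": source,
                "df": df[source],
                "ss": float(ss[source]),
                "ms": float(ms[source]) if df[source] > 0 else np.nan,
                "F": float(f) if np.ndim(f) == 0 else float(f),
                "p": float(p) if np.ndim(p) == 0 else float(p),
            }
        )
    anova_table = pd.DataFrame(rows).set_index("source")

    cell_means = {
        (m, s): float(y[mains.index(m), :, subs.index(s)].mean())
        for m in mains
        for s in subs
    }
    result = SplitPlotAnova(
        trait=trait,
        anova_table=anova_table,
        cell_means=cell_means,
        ms_mainplot_error=float(ms["mainplot_error"]),
        df_mainplot_error=df["mainplot_error"],
        ms_residual=float(ms["residual"]),
        df_residual=df["residual"],
        n_replicates=r,
        n_sub=b,
        degenerate=bool(ms["residual"] == 0.0),
    )
    if not result.degenerate:
        result.letters = tukey_letters(result, alpha=alpha)
    return result


def _comparison_se_df(
    res: SplitPlotAnova, cell_a: tuple, cell_b: tuple
) -> tuple[float, float]:
    """SE of a cell-mean difference and its (Satterthwaite) df."""
    r, b = res.n_replicates, res.n_sub
    ms_e, ms_m = res.ms_residual, res.ms_mainplot_error
    if cell_a[0] == cell_b[0]:  # same main-plot level: sub-plot stratum only
        return float(np.sqrt(2.0 * ms_e / r)), float(res.df_residual)
    combined = (b - 1) * ms_e + ms_m
    var = 2.0 * combined / (r * b)
    denom = ((b - 1) * ms_e) ** 2 / res.df_residual + ms_m**2 / res.df_mainplot_error
    df = combined**2 / denom if denom > 0 else np.nan
    return float(np.sqrt(var)), float(df)


def tukey_letters(res: SplitPlotAnova, alpha: float = 0.05) -> dict[tuple, str]:
    """Compact letter display over the main × sub cell means.

    All pairwise comparisons use the studentized-range critical value
    at ``alpha`` for k = number of cells; a pair with a non-estimable
    standard error is flagged not-tested (treated as not different)
    with a warning. Letters run alphabetically from the largest mean.
    """
    cells = sorted(res.cell_means, key=lambda c: -res.cell_means[c])
    k = len(cells)
    significant: set[frozenset] = set()
    for ca, cb in combinations(cells, 2):
        se, df = _comparison_se_df(res, ca, cb)
        if not np.isfinite(se) or se <= 0 or not np.isfinite(df) or df <= 0:
            warnings.warn(
                f"comparison {ca} vs {cb} not tested (non-estimable SE)",
                UserWarning,
                stacklevel=2,
            )
            continue
        q_crit = stats.studentized_range.ppf(1.0 - alpha, k, df)
        diff = abs(res.cell_means[ca] - res.cell_means[cb])
        if diff > q_crit * se / np.sqrt(2.0):
            significant.add(frozenset((ca, cb)))
    return _compact_letter_display(cells, significant)


def _compact_letter_display(
    ordered_cells: list, significant: set[frozenset]
) -> dict[tuple, str]:
    """Insert-and-absorb letter assignment.

    ``ordered_cells`` must be sorted by descending mean; columns are
    split on each significant pair and subset columns absorbed, then
    letters are assigned in order of the largest member mean so output
    is deterministic and invariant to input relabeling.
    """
    columns: list[set] = [set(ordered_cells)]
    for pair in significant:
        a, b = tuple(pair)
        for col in [c for c in columns if a in c and b in c]:
            columns.remove(col)
            columns.extend((col - {a}, col - {b}))
        # absorb: drop empties, duplicates, and proper subsets
        uniq: list[set] = []
        for c in columns:
            if c and c not in uniq:
                uniq.append(c)
        columns = [c for c in uniq if not any(c < d for d in uniq)]
    rank = {cell: i for i, cell in enumerate(ordered_cells)}
    columns.sort(key=lambda c: min(rank[m] for m in c))
    letters = {cell: "" for cell in ordered_cells}
    for letter_idx, col in enumerate(columns):
        ch = chr(ord("a") + letter_idx)
        for cell in col:
            letters[cell] += ch
    return {cell: "".join(sorted(s)) for cell, s in letters.items()}


def null_rejection_rates(
    n_sims: int = 10_000,
    replicates: int = 5,
    a: int = 2,
    b: int = 2,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict[str, float]:
    """Type-I error calibration of the three F tests under the null.

    Simulates ``n_sims`` balanced experiments of pure Gaussian noise
    (all effects zero) and returns the empirical rejection rate at
    ``alpha`` for the main-plot, sub-plot, and interaction tests. Each
    rate should sit near ``alpha`` — this is re-run per release.
    """
    rng = np.random.default_rng(seed)
    y = rng.standard_normal((n_sims, a, replicates, b))
    dec = _decompose(y)
    return {
        "main": float(np.mean(dec["p"]["main"] <= alpha)),
        "sub": float(np.mean(dec["p"]["sub"] <= alpha)),
        "interaction": float(np.mean(dec["p"]["interaction"] <= alpha)),
    }
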