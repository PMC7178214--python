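"""Case/control expression comparison for prioritized genes.

Per-gene two-sample t-tests between low- and high-phenotype groups
(pooled-variance "Student" by default, Welch by flag; raw p-values, the
significance convention of the emulated analysis), per-group Pearson
co-expression matrices, and a summary of the co-expression difference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionMatrix

__all__ = [
    "DgeResult",
    "dge_ttest",
    "coexpression",
    "coexpression_difference",
    "CoexpressionDiff",
    "dge_to_frame",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DgeResult:
    gene_id: str
    mean_low: float
    mean_high: float
    t_stat: float
    df: float
    p_value: float
    direction: str  # up_in_low | up_in_high | none
    degenerate: bool = False


def dge_ttest(
    matrix: ExpressionMatrix,
    variant: str = "student",
    alpha: float = 0.05,
) -> list[DgeResult]:
    """Two-sided two-sample t-test per gene, low vs high group.

    ``student`` pools the group variances; ``welch`` does not.  A direction
    is assigned only when p < alpha.  Genes with zero variance in both
    groups cannot be tested and are reported with p = 1 and a degenerate
    flag.
    """
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    low = matrix.group_values("low")
    high = matrix.group_values("high")
    if low.shape[1] < 2 or high.shape[1] < 2:
        raise ValueError("both groups need >= 2 samples")
    results = []
    n1, n2 = low.shape[1], high.shape[1]
    for g, x, y in zip(matrix.gene_ids, low, high):
        if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
            logger.warning("gene %s: zero variance in both groups", g)
            results.append(DgeResult(g, float(x.mean()), float(y.mean()),
                                     float("nan"), float("nan"), 1.0,
                                     "none", degenerate=True))
            continue
        res = stats.ttest_ind(x, y, equal_var=(variant == "student"))
        t, p = float(res.statistic), float(res.pvalue)
        df = float(res.df) if hasattr(res, "df") else float(n1 + n2 - 2)
        ml, mh = float(x.mean()), float(y.mean())
        if p < alpha:
            direction = "up_in_low" if ml > mh else "up_in_high"
        else:
            direction = "none"
        results.append(DgeResult(g, ml, mh, t, df, p, direction))
    return results


def coexpression(matrix: ExpressionMatrix, group: str) -> pd.DataFrame:
    """Gene x gene Pearson correlation within one group.

    Constant genes get zero correlations (unit diagonal kept) and are
    recorded under ``result.attrs['constant_genes']`` and logged.
    """
    if group not in ("low", "high"):
        raise ValueError("group must be 'low' or 'high'")
    values = matrix.group_values(group)
    if values.shape[1] < 3:
        raise ValueError("co-expression needs >= 3 samples in the group")
    sd = values.std(axis=1)
    constant = [g for g, s in zip(matrix.gene_ids, sd) if s == 0.0]
    with np.errstate(divide="ignore", invalid="ignore"):
        C = np.corrcoef(values)
    C = np.atleast_2d(C)
    C[np.isnan(C)] = 0.0
    C = np.clip((C + C.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    if constant:
        logger.warning("constant genes in %s group: %s", group, constant)
        idx = [matrix.gene_ids.index(g) for g in constant]
        C[idx, :] = 0.0
        C[:, idx] = 0.0
        np.fill_diagonal(C, 1.0)
    out = pd.DataFrame(C, index=matrix.gene_ids, columns=matrix.gene_ids)
    out.attrs["constant_genes"] = constant
    return out


@dataclass
class CoexpressionDiff:
    diff: pd.DataFrame          # corr_low - corr_high
    mean_abs_diff: float        # mean |d_ij| over i < j
    top_pairs: pd.DataFrame     # gene_a, gene_b, r_low, r_high, diff, abs_diff


def coexpression_difference(
    corr_low: pd.DataFrame, corr_high: pd.DataFrame, top_k: int = 10
) -> CoexpressionDiff:
    """Element-wise difference of the two co-expression matrices with the
    most-changed gene pairs ranked by |difference|."""
    if list(corr_low.index) != list(corr_high.index) or \
            list(corr_low.columns) != list(corr_high.columns):
        raise ValueError("co-expression matrices have mismatched gene order")
    D = corr_low - corr_high
    genes = list(corr_low.index)
    iu = np.triu_indices(len(genes), k=1)
    d = D.to_numpy()[iu]
    rows = [
        {
            "gene_a": genes[i],
            "gene_b": genes[j],
            "r_low": float(corr_low.iat[i, j]),
            "r_high": float(corr_high.iat[i, j]),
            "diff": float(D.iat[i, j]),
            "abs_diff": float(abs(D.iat[i, j])),
        }
        for i, j in zip(*iu)
    ]
    pairs = pd.DataFrame(rows).sort_values(
        ["abs_diff", "gene_a", "gene_b"], ascending=[False, True, True]
    ).head(top_k).reset_index(drop=True)
    return CoexpressionDiff(
        diff=D,
        mean_abs_diff=float(np.abs(d).mean()) if d.size else 0.0,
        top_pairs=pairs,
    )


def dge_to_frame(results: Iterable[DgeResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
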