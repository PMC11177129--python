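"""Weighted exploratory stage: prevalence, the 2x2 joint/marginal table with
its odds ratio, and chi-square association screening of predictors against
the 4-level joint outcome.

Weighted chi-square uses the plain Pearson statistic on weighted counts (no
survey-design correction); a caveat is logged when weights are non-unit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dale import JointProbability, odds_ratio_2x2, plackett_joint

logger = logging.getLogger(__name__)


@dataclass
class CrossTab:
    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray        # raw weighted sums
    display: np.ndarray       # rounded for presentation
    row_margin: np.ndarray
    col_margin: np.ndarray
    total: float
    col_percent: np.ndarray   # column percentages, as in a Table-1 layout

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.row_labels,
                            columns=self.col_labels)


@dataclass
class AssociationTest:
    predictor: str
    statistic: float
    df: int
    p: float
    warning: str | None = None


def weighted_crosstab(data: pd.DataFrame, row: str, col: str,
                      weighted: bool = False,
                      weight_col: str = "weight") -> CrossTab:
    """Cross-classification with weighted counts and column percentages."""
    w = data[weight_col].to_numpy(float) if weighted else np.ones(len(data))
    r = data[row].astype(str)
    c = data[col].astype(str)
    rlabs = sorted(r.unique())
    clabs = sorted(c.unique())
    if not rlabs or not clabs:
        raise ValueError("empty cell set")
    counts = np.zeros((len(rlabs), len(clabs)))
    for i, rl in enumerate(rlabs):
        for j, cl in enumerate(clabs):
            counts[i, j] = w[((r == rl) & (c == cl)).to_numpy()].sum()
    colm = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        colpct = np.where(colm > 0, 100.0 * counts / colm, 0.0)
    return CrossTab(row_labels=rlabs, col_labels=clabs, counts=counts,
                    display=np.round(counts).astype(int),
                    row_margin=counts.sum(axis=1), col_margin=colm,
                    total=float(counts.sum()), col_percent=colpct)


def joint_marginal_summary(data: pd.DataFrame, outcome1: str = "y1",
                           outcome2: str = "y2", weighted: bool = False,
                           weight_col: str = "weight"
                           ) -> tuple[JointProbability, CrossTab]:
    """Empirical joint/marginal probabilities of the two outcomes and their
    odds ratio, from the (optionally weighted) 2x2 table."""
    tab = weighted_crosstab(data, outcome1, outcome2, weighted, weight_col)
    # rows/cols sorted as "0","1"
    def cell(y1, y2):
        try:
            return tab.counts[tab.row_labels.index(str(y1)),
                              tab.col_labels.index(str(y2))]
        except ValueError:
            return 0.0
    n = tab.total
    n11, n10 = cell(1, 1), cell(1, 0)
    n01, n00 = cell(0, 1), cell(0, 0)
    p11, p10, p01, p00 = n11 / n, n10 / n, n01 / n, n00 / n
    pi1, pi2 = p11 + p10, p11 + p01
    if min(pi1, pi2, 1 - pi1, 1 - pi2) <= 0:
        logger.warning("degenerate margin: odds ratio undefined")
        psi = float("nan")
    else:
        try:
            psi = odds_ratio_2x2(n11, n10, n01, n00)
        except ValueError:
            psi = float("nan")
    jp = JointProbability(p00=p00, p01=p01, p10=p10, p11=p11,
                          pi1=pi1, pi2=pi2, psi=psi)
    return jp, tab


def table2_from_counts(n11: float, n10: float, n01: float, n00: float
                       ) -> JointProbability:
    """Joint/marginal summary directly from four 2x2 cell counts."""
    n = n11 + n10 + n01 + n00
    return JointProbability(p00=n00 / n, p01=n01 / n, p10=n10 / n, p11=n11 / n,
                            pi1=(n11 + n10) / n, pi2=(n11 + n01) / n,
                            psi=odds_ratio_2x2(n11, n10, n01, n00))


def chisq_screen(data: pd.DataFrame, predictors: list[str],
                 outcome1: str = "y1", outcome2: str = "y2",
                 weighted: bool = False,
                 weight_col: str = "weight") -> list[AssociationTest]:
    """Pearson chi-square of each predictor against the 4-level joint outcome.

    The joint outcome takes levels 00/01/10/11; expected cells below 1
    attach a warning (no automatic exact test).
    """
    df = data.copy()
    df["__joint__"] = (df[outcome1].astype(int).astype(str)
                       + df[outcome2].astype(int).astype(str))
    if weighted and not np.allclose(df[weight_col], 1.0):
        logger.warning("chi-square on weighted counts without design "
                       "correction; p-values are approximate")
    out = []
    for pred in predictors:
        tab = weighted_crosstab(df, pred, "__joint__", weighted, weight_col)
        obs = tab.counts
        keep_r = obs.sum(axis=1) > 0
        keep_c = obs.sum(axis=0) > 0
        obs = obs[np.ix_(keep_r, keep_c)]
        exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
        stat = float(np.sum((obs - exp) ** 2 / exp))
        dof = (obs.shape[0] - 1) * (obs.shape[1] - 1)
        p = float(stats.chi2.sf(stat, dof)) if dof > 0 else 1.0
        warn = "expected cell < 1" if np.any(exp < 1) else None
        if warn:
            logger.warning("%s: %s", pred, warn)
        out.append(AssociationTest(predictor=pred, statistic=stat, df=dof,
                                   p=p, warning=warn))
    return out


def prevalence(data: pd.DataFrame, outcome: str, weighted: bool = False,
               weight_col: str = "weight") -> float:
    """Weighted prevalence of a binary outcome, in percent (1 decimal)."""
    w = data[weight_col].to_numpy(float) if weighted else np.ones(len(data))
    if w.sum() <= 0:
        raise ValueError("zero total weight")
    y = data[outcome].to_numpy(float)
    return round(100.0 * float(np.sum(w * y) / w.sum()), 1)
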