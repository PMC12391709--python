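"""Delphi expert-consultation statistics and the item cut-off rule.

Experts score candidate trigger items on a bounded Likert scale (default
1-5; full mark = scale maximum). Per item we compute the mean importance
score Mj, the full-mark frequency Kj (percent of experts awarding the
maximum), and the coefficient of variation Vj = sample SD / mean. Cut-offs
are computed across items: mean - SD for Mj and Kj (keep items at or above),
mean + SD for Vj (keep items at or below). An item failing all three
criteria is dropped; passing all three retains it; anything mixed goes to
panel discussion. Panel-level quality measures are the positive coefficient
(response rate), the authority coefficient Cr = (Ca + Cs)/2 per expert
(judgement basis + familiarity), and Kendall's coefficient of concordance W
with tie correction.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._utils import round_half_up

__all__ = [
    "ItemDecision",
    "DelphiItemStats",
    "Cutoffs",
    "PanelStats",
    "item_stats",
    "cutoffs",
    "select_items",
    "kendall_w",
    "panel_stats",
]


class ItemDecision(str, enum.Enum):
    retain = "retain"
    discuss = "discuss"
    drop = "drop"


@dataclass(frozen=True)
class DelphiItemStats:
    item: str
    mj: float  # mean importance score
    kj: float  # % of experts awarding the full mark
    vj: Optional[float]  # sample SD / mean; None when the mean is 0


@dataclass(frozen=True)
class Cutoffs:
    mj_cut: float  # retain at >= (mean - SD over items)
    kj_cut: float  # retain at >= (mean - SD over items)
    vj_cut: float  # retain at <= (mean + SD over items)


@dataclass(frozen=True)
class PanelStats:
    positive_coefficient: float  # responders / invited, in percent
    cr_mean: Optional[float]  # authority coefficient, mean over experts
    cr_sd: Optional[float]
    kendall_w: Optional[float]


def _as_matrix(scores: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, list[str]]:
    if isinstance(scores, pd.DataFrame):
        return scores.to_numpy(dtype=float), [str(c) for c in scores.columns]
    arr = np.asarray(scores, dtype=float)
    return arr, [f"item_{j + 1}" for j in range(arr.shape[1])]


def item_stats(
    scores: pd.DataFrame | np.ndarray, scale_max: int = 5
) -> list[DelphiItemStats]:
    """Per-item Mj, Kj, Vj from an experts x items score matrix.

    Scores must lie in [1, scale_max]; Kj counts scores equal to scale_max;
    Vj uses the sample (n-1) standard deviation and is None for a zero mean.
    """
    mat, items = _as_matrix(scores)
    if mat.ndim != 2 or mat.shape[0] < 2 or mat.shape[1] < 1:
        raise ValueError("need >=2 experts and >=1 item")
    if np.any(mat < 1) or np.any(mat > scale_max):
        raise ValueError(f"scores outside [1, {scale_max}]")
    n_experts = mat.shape[0]
    out = []
    for j, item in enumerate(items):
        col = mat[:, j]
        mj = float(col.mean())
        kj = 100.0 * float((col == scale_max).sum()) / n_experts
        vj = float(col.std(ddof=1) / mj) if mj > 0 else None
        out.append(DelphiItemStats(item=item, mj=mj, kj=kj, vj=vj))
    return out


def cutoffs(stats: Sequence[DelphiItemStats]) -> Cutoffs:
    """Across-item cut-offs: mean - SD for Mj/Kj, mean + SD for Vj (sample SD)."""
    if len(stats) < 2:
        raise ValueError("need >=2 items to place cut-offs")
    mj = np.array([s.mj for s in stats], dtype=float)
    kj = np.array([s.kj for s in stats], dtype=float)
    vj = np.array([s.vj for s in stats if s.vj is not None], dtype=float)
    if len(vj) < 2:
        raise ValueError("need >=2 defined Vj values")
    return Cutoffs(
        mj_cut=float(mj.mean() - mj.std(ddof=1)),
        kj_cut=float(kj.mean() - kj.std(ddof=1)),
        vj_cut=float(vj.mean() + vj.std(ddof=1)),
    )


def select_items(
    stats: Sequence[DelphiItemStats], cuts: Cutoffs
) -> dict[str, ItemDecision]:
    """Three-criteria rule: fail all -> drop; pass all -> retain; mixed -> discuss.

    "Pass" is non-strict: Mj >= cut, Kj >= cut, Vj <= cut, so that a
    degenerate panel (all items identical, SD 0) retains everything.
    An undefined Vj counts as a failure of that criterion.
    """
    decisions = {}
    for s in stats:
        passes = [
            s.mj >= cuts.mj_cut,
            s.kj >= cuts.kj_cut,
            s.vj is not None and s.vj <= cuts.vj_cut,
        ]
        if all(passes):
            decisions[s.item] = ItemDecision.retain
        elif not any(passes):
            decisions[s.item] = ItemDecision.drop
        else:
            decisions[s.item] = ItemDecision.discuss
    return decisions


def kendall_w(scores: pd.DataFrame | np.ndarray) -> float:
    """Kendall's coefficient of concordance across experts, tie-corrected.

    Each expert's scores are ranked across items (mid-ranks for ties);
    W = 12 S / (m^2 (n^3 - n) - m sum_i T_i) with S the sum of squared
    deviations of item rank sums and T_i = sum over tie groups of (t^3 - t)
    for expert i. W = 1 means identical rankings; W = 0 no agreement.
    """
    mat, _ = _as_matrix(scores)
    if mat.ndim != 2 or mat.shape[0] < 2 or mat.shape[1] < 2:
        raise ValueError("concordance needs >=2 experts and >=2 items")
    m, n = mat.shape
    ranks = np.vstack([rankdata(row) for row in mat])
    rank_sums = ranks.sum(axis=0)
    s = float(((rank_sums - rank_sums.mean()) ** 2).sum())
    tie_term = 0.0
    for row in mat:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float((counts**3 - counts).sum())
    denom = m**2 * (n**3 - n) - m * tie_term
    if denom <= 0:  # every expert gave a constant row: no information
        return 0.0
    return s * 12.0 / denom


def panel_stats(
    n_invited: int,
    n_responded: int,
    judgement_basis: Sequence[float] | None = None,
    familiarity: Sequence[float] | None = None,
    scores: pd.DataFrame | np.ndarray | None = None,
) -> PanelStats:
    """Panel-level quality measures.

    Positive coefficient = responders / invited (percent). Authority
    Cr = (Ca + Cs)/2 per expert, reported as mean +/- sample SD; omitted
    (None) with no Ca/Cs input. Kendall's W is computed when a score matrix
    is supplied.
    """
    if not (0 <= n_responded <= n_invited) or n_invited == 0:
        raise ValueError("invalid response counts")
    cr_mean = cr_sd = None
    if judgement_basis is not None and familiarity is not None:
        ca = np.asarray(judgement_basis, dtype=float)
        cs = np.asarray(familiarity, dtype=float)
        if ca.shape != cs.shape or ca.ndim != 1 or len(ca) == 0:
            raise ValueError("judgement_basis and familiarity must be equal-length vectors")
        if np.any((ca < 0) | (ca > 1) | (cs < 0) | (cs > 1)):
            raise ValueError("Ca and Cs coefficients must lie in [0, 1]")
        cr = (ca + cs) / 2.0
        cr_mean = float(cr.mean())
        cr_sd = float(cr.std(ddof=1)) if len(cr) > 1 else 0.0
    w = kendall_w(scores) if scores is not None else None
    return PanelStats(
        positive_coefficient=round_half_up(100.0 * n_responded / n_invited, 2),
        cr_mean=cr_mean,
        cr_sd=cr_sd,
        kendall_w=w,
    )
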