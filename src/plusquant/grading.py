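"""Multi-expert ordinal grading statistics.

Images are graded 1-5 (Normal, pre-Plus, Plus1, Plus2, Plus3) by several
experts.  This module derives the reference standard diagnosis (RSD,
majority vote with a flagged deterministic tie rule), the continuous
average score, the conventional 3-level collapse (Normal / pre-Plus /
Plus), linearly weighted Cohen kappa for agreement, and per-expert
MSE/MAE against the average score.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

N_LEVELS = 5


@dataclass
class GradeTable:
    """Per-image integer grades from multiple experts.

    ``grades`` is a DataFrame indexed by image_id with one column per
    expert; missing grades are NaN and excluded pairwise.
    """

    grades: pd.DataFrame
    tie_rule: str = "round_half_up"

    def __post_init__(self):
        vals = self.grades.to_numpy(dtype=float)
        ok = np.isnan(vals) | (np.isin(vals, range(1, N_LEVELS + 1)))
        if not ok.all():
            raise ValueError("grades must be integers in 1..5 (or missing)")

    @property
    def experts(self) -> list:
        return list(self.grades.columns)

    def average_scores(self) -> pd.Series:
        return self.grades.mean(axis=1, skipna=True)

    def rsd(self) -> pd.DataFrame:
        rows = [
            compute_rsd(r.dropna().astype(int).tolist(), tie_rule=self.tie_rule)
            for _, r in self.grades.iterrows()
        ]
        return pd.DataFrame(rows, index=self.grades.index, columns=["rsd", "tie_flag"])

    def collapsed(self) -> "GradeTable":
        return GradeTable(self.grades.map(lambda g: g if pd.isna(g) else collapse_3level(int(g))),
                          tie_rule=self.tie_rule)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "GradeTable":
        df = pd.read_csv(path).set_index("image_id")
        return cls(df, **kwargs)


@dataclass
class AgreementReport:
    pairwise_kappa: dict  # (expert_i, expert_j) -> float
    kappa_vs_rsd: dict  # expert -> float
    mse_vs_avg: dict  # expert -> float
    mae_vs_avg: dict  # expert -> float
    low_n: bool = False


def compute_rsd(grades: list, tie_rule: str = "round_half_up") -> tuple:
    """Majority grade with a flagged deterministic tie rule.

    Returns ``(rsd, tie_flag)``.  A strict majority (unique modal grade)
    sets no flag.  Ties — which the study protocol resolved in expert
    adjudication sessions — are resolved by ``tie_rule``:
    ``round_half_up`` (default) rounds the mean grade, half away from
    zero; ``lowest``/``highest`` pick among the tied modes.
    """
    if len(grades) < 2:
        raise ValueError("need at least 2 grades")
    counts = Counter(int(g) for g in grades)
    top = max(counts.values())
    modes = sorted(g for g, c in counts.items() if c == top)
    if len(modes) == 1:
        return modes[0], False
    if tie_rule == "round_half_up":
        mean = float(np.mean(grades))
        rsd = int(np.floor(mean + 0.5))
    elif tie_rule == "lowest":
        rsd = modes[0]
    elif tie_rule == "highest":
        rsd = modes[-1]
    else:
        raise ValueError(f"unknown tie rule {tie_rule!r}")
    return rsd, True


def average_score(grades: list) -> float:
    """Arithmetic mean of the assigned 1-5 grades."""
    if len(grades) < 1:
        raise ValueError("need at least 1 grade")
    return float(np.mean(grades))


def collapse_3level(grade: int) -> int:
    """Collapse 5-level grades to 3: 1->1, 2->2, {3,4,5}->3 ('Plus')."""
    if grade not in (1, 2, 3, 4, 5):
        raise ValueError(f"grade {grade} outside 1..5")
    return grade if grade <= 2 else 3


def weighted_kappa_linear(a, b, n_levels: int = N_LEVELS) -> float:
    """Cohen's weighted kappa with linear weights.

    kappa = 1 - sum(w*O) / sum(w*E), with w_ij = |i-j|/(n_levels-1), O the
    observed joint proportions and E the product of the marginals
    (population proportions).  Both raters constant and equal gives
    kappa = 1 by convention.
    """
    a = np.asarray(a, dtype=int)
    b = np.asarray(b, dtype=int)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length grade lists of length >= 2")
    if a.min() < 1 or a.max() > n_levels or b.min() < 1 or b.max() > n_levels:
        raise ValueError("grades outside 1..n_levels")
    obs = np.zeros((n_levels, n_levels))
    for i, j in zip(a - 1, b - 1):
        obs[i, j] += 1
    obs /= obs.sum()
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0))
    idx = np.arange(n_levels)
    w = np.abs(idx[:, None] - idx[None, :]) / (n_levels - 1)
    denom = float((w * exp).sum())
    if denom == 0.0:
        log.info("zero expected disagreement (constant equal raters): kappa = 1")
        return 1.0
    return 1.0 - float((w * obs).sum()) / denom


def rater_losses(table: GradeTable, n_levels: int = N_LEVELS) -> AgreementReport:
    """Pairwise kappas, kappa vs RSD, and per-expert MSE/MAE vs the average score."""
    avg = table.average_scores()
    rsd = table.rsd()["rsd"]
    low_n = len(table.grades) < 2
    if low_n:
        log.warning("agreement computed on a single image; estimates unreliable")
    pairwise = {}
    for e1, e2 in itertools.combinations(table.experts, 2):
        both = table.grades[[e1, e2]].dropna()
        if len(both) >= 2:
            k = weighted_kappa_linear(both[e1].astype(int), both[e2].astype(int), n_levels)
            pairwise[(e1, e2)] = k
            pairwise[(e2, e1)] = k
    kappa_rsd, mse, mae = {}, {}, {}
    for e in table.experts:
        present = table.grades[e].dropna()
        if len(present) >= 2:
            kappa_rsd[e] = weighted_kappa_linear(
                present.astype(int), rsd.loc[present.index].astype(int), n_levels
            )
        resid = present - avg.loc[present.index]
        mse[e] = float((resid**2).mean())
        mae[e] = float(resid.abs().mean())
    return AgreementReport(pairwise, kappa_rsd, mse, mae, low_n=low_n)
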