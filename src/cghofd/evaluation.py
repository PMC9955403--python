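"""Accuracy metrics and protocol gradings for (predicted, reference) BP pairs.

Conventions: errors are prediction minus reference; SDE uses the (n-1)
sample divisor; the AAMI rule uses strict inequalities (|ME| < 5 mmHg and
SDE < 8 mmHg); BHS cumulative percentages are evaluated at |e| <= 5/10/15
mmHg against grade thresholds A (60/85/95), B (50/75/90), C (40/65/85).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["EvalReport", "AnovaComparison", "eval_report", "bhs_grade",
           "anova_compare"]

_BHS_THRESHOLDS = {
    "A": (60.0, 85.0, 95.0),
    "B": (50.0, 75.0, 90.0),
    "C": (40.0, 65.0, 85.0),
}


@dataclass
class EvalReport:
    n: int
    ME: float
    SDE_of_ME: float
    MAE: float
    SDE_of_MAE: float
    RMSE: float
    R2: float
    bhs_cum: tuple[float, float, float]
    bhs_grade: str
    aami_pass: bool
    bland_altman: tuple[float, float, float]   # bias, lower LoA, upper LoA

    def to_dict(self) -> dict:
        return {"n": self.n, "ME": self.ME, "SDE_of_ME": self.SDE_of_ME,
                "MAE": self.MAE, "SDE_of_MAE": self.SDE_of_MAE,
                "RMSE": self.RMSE, "R2": self.R2,
                "bhs_cum": list(self.bhs_cum), "bhs_grade": self.bhs_grade,
                "aami_pass": self.aami_pass,
                "bland_altman": list(self.bland_altman)}

    @classmethod
    def average(cls, reports: list["EvalReport"]) -> "EvalReport":
        """Mean of metric values across repeats (BHS re-graded on the means)."""
        if len(reports) == 1:
            return reports[0]
        me = float(np.mean([r.ME for r in reports]))
        sde = float(np.mean([r.SDE_of_ME for r in reports]))
        cum = tuple(float(np.mean([r.bhs_cum[i] for r in reports]))
                    for i in range(3))
        return cls(n=int(np.mean([r.n for r in reports])),
                   ME=me, SDE_of_ME=sde,
                   MAE=float(np.mean([r.MAE for r in reports])),
                   SDE_of_MAE=float(np.mean([r.SDE_of_MAE for r in reports])),
                   RMSE=float(np.mean([r.RMSE for r in reports])),
                   R2=float(np.mean([r.R2 for r in reports])),
                   bhs_cum=cum, bhs_grade=bhs_grade(*cum),
                   aami_pass=bool(abs(me) < 5.0 and sde < 8.0),
                   bland_altman=(me, me - 1.96 * sde, me + 1.96 * sde))


@dataclass
class AnovaComparison:
    groups: dict[str, list[float]]
    F_stat: float
    p_value: float
    alpha: float = 0.05
    significant: bool = field(init=False)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")
        self.significant = self.p_value < self.alpha


def eval_report(pred: np.ndarray, ref: np.ndarray) -> EvalReport:
    """Full metric set for one prediction/reference pair of vectors."""
    pred = np.asarray(pred, float).ravel()
    ref = np.asarray(ref, float).ravel()
    if pred.shape != ref.shape:
        raise ValueError("pred and ref must have equal lengths")
    n = len(pred)
    if n < 2:
        raise ValueError("need at least two pairs")
    e = pred - ref
    me = float(e.mean())
    sde = float(e.std(ddof=1))
    ae = np.abs(e)
    mae = float(ae.mean())
    sde_mae = float(ae.std(ddof=1))
    rmse = float(np.sqrt(np.mean(e ** 2)))
    sstot = float(((ref - ref.mean()) ** 2).sum())
    ssres = float((e ** 2).sum())
    r2 = 1.0 - ssres / sstot if sstot > 0 else (1.0 if ssres == 0 else 0.0)
    cum = tuple(float(100.0 * np.mean(ae <= thr)) for thr in (5.0, 10.0, 15.0))
    return EvalReport(n=n, ME=me, SDE_of_ME=sde, MAE=mae, SDE_of_MAE=sde_mae,
                      RMSE=rmse, R2=r2, bhs_cum=cum, bhs_grade=bhs_grade(*cum),
                      aami_pass=bool(abs(me) < 5.0 and sde < 8.0),
                      bland_altman=(me, me - 1.96 * sde, me + 1.96 * sde))


def bhs_grade(cum5: float, cum10: float, cum15: float) -> str:
    """Map cumulative |error| percentages at 5/10/15 mmHg to a BHS grade.

    All three thresholds must hold simultaneously; returns 'fail' when even
    grade C is missed.
    """
    cum = (cum5, cum10, cum15)
    if any(not (0.0 <= c <= 100.0) for c in cum):
        raise ValueError("percentages must lie in [0, 100]")
    if not (cum5 <= cum10 <= cum15):
        raise ValueError("cumulative percentages must be non-decreasing")
    for grade, req in _BHS_THRESHOLDS.items():
        if all(c >= r for c, r in zip(cum, req)):
            return grade
    return "fail"


def anova_compare(groups: dict[str, np.ndarray], alpha: float = 0.05
                  ) -> AnovaComparison:
    """One-way ANOVA across named samples of per-repeat RMSE values."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(v, float).ravel() for v in groups.values()]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("every group needs at least two values")
    flat = np.concatenate(arrays)
    if np.ptp(flat) == 0:  # identical samples everywhere: F = 0, p = 1
        return AnovaComparison(groups={k: np.asarray(v, float).tolist()
                                       for k, v in groups.items()},
                               F_stat=0.0, p_value=1.0, alpha=alpha)
    f, p = stats.f_oneway(*arrays)
    if not np.isfinite(p):
        f, p = 0.0, 1.0
    return AnovaComparison(groups={k: np.asarray(v, float).tolist()
                                   for k, v in groups.items()},
                           F_stat=float(f), p_value=float(p), alpha=alpha)
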