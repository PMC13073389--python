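"""Age+eGFR heuristic, decision curves, reclassification/NRI, calibration, ROC.

The screening heuristic is the plain sum ``age + eGFR``: it is *decreasing*
in risk (old age and low eGFR both lower it), with category cuts at 115
(low risk at or above) and 100 (high risk below).  The conventional
comparator stratifies on eGFR alone at 60 and 45 mL/min/1.73 m^2.  All
category boundaries are half-open, with the boundary value belonging to
the upper (lower-risk) side: score 115 is low risk, score 100 moderate;
eGFR 60 is low risk, eGFR 45 moderate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "CATEGORIES",
    "RiskCategoryScheme",
    "DecisionCurve",
    "ReclassificationTable",
    "RocResult",
    "age_egfr_score",
    "classify_age_egfr",
    "classify_conventional",
    "net_benefit",
    "decision_curve",
    "reclassification_table",
    "nri",
    "roc_metrics",
    "calibration_table",
    "c_statistic",
    "load_reference_reclassification",
]

#: Risk categories in increasing order of risk.
CATEGORIES = ("low", "moderate", "high")
_CAT_INDEX = {c: i for i, c in enumerate(CATEGORIES)}


@dataclass(frozen=True)
class RiskCategoryScheme:
    """An ordered three-level risk categorisation with its classifier."""

    name: str
    categories: tuple[str, ...]
    classify: Callable[..., str]


def age_egfr_score(age: float, egfr: float) -> float:
    """The additive screening heuristic: age (years) + eGFR."""
    if not (np.isfinite(age) and np.isfinite(egfr) and age > 0 and egfr > 0):
        raise ValueError("age and egfr must be finite and positive")
    return age + egfr


def classify_age_egfr(score: float) -> str:
    """Category of an age+eGFR score: >=115 low, [100, 115) moderate, <100 high."""
    if not np.isfinite(score):
        raise ValueError("score must be finite")
    if score >= 115:
        return "low"
    if score >= 100:
        return "moderate"
    return "high"


def classify_conventional(egfr: float) -> str:
    """eGFR-only category: >=60 low, [45, 60) moderate, <45 high."""
    if not egfr > 0:
        raise ValueError("egfr must be > 0")
    if egfr >= 60:
        return "low"
    if egfr >= 45:
        return "moderate"
    return "high"


AGE_EGFR_SCHEME = RiskCategoryScheme("age_plus_egfr", CATEGORIES, classify_age_egfr)
CONVENTIONAL_SCHEME = RiskCategoryScheme("egfr_only", CATEGORIES, classify_conventional)


# ---------------------------------------------------------------------------
# Decision curve analysis
# ---------------------------------------------------------------------------


def net_benefit(tp: float, fp: float, n: float, pt: float) -> float:
    """Net benefit TP/N - (FP/N) * pt / (1 - pt) at threshold probability pt."""
    if not 0 < pt < 1:
        raise ValueError("pt must be in (0, 1)")
    if tp < 0 or fp < 0 or n <= 0 or tp + fp > n:
        raise ValueError("require tp, fp >= 0 and tp + fp <= n, n > 0")
    return tp / n - (fp / n) * pt / (1.0 - pt)


@dataclass(frozen=True)
class DecisionCurve:
    """Net-benefit values per strategy over a grid of threshold probabilities."""

    thresholds: np.ndarray
    net_benefits: dict[str, np.ndarray]
    prevalence: float

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.net_benefits)
        df.insert(0, "pt", self.thresholds)
        return df


def decision_curve(
    outcomes: Sequence[int],
    rule_classifications: Mapping[str, Sequence[int]],
    pt_grid: Sequence[float] | None = None,
) -> DecisionCurve:
    """Decision curves for fixed binary treat/no-treat rules.

    Each rule is a binary vector of treat decisions; TP and FP counts are
    fixed across pt (the rules are thresholds, not risk probabilities), so
    only the FP penalty weight pt/(1-pt) varies.  Treat-all and treat-none
    reference strategies are always included.  The default pt grid is
    0.05-0.60 in steps of 0.01.
    """
    y = np.asarray(outcomes).astype(int)
    if pt_grid is None:
        pt_grid = np.round(np.arange(0.05, 0.6001, 0.01), 10)
    pts = np.asarray(pt_grid, dtype=float)
    if np.any((pts <= 0) | (pts >= 1)):
        raise ValueError("pt grid must lie in (0, 1)")
    n = len(y)
    if n == 0:
        raise ValueError("outcomes must be non-empty")
    odds = pts / (1.0 - pts)
    prevalence = float(y.mean())
    curves: dict[str, np.ndarray] = {}
    for name, decisions in rule_classifications.items():
        d = np.asarray(decisions).astype(int)
        if len(d) != n:
            raise ValueError(f"rule {name!r} length {len(d)} != outcomes length {n}")
        tp = int(np.sum((d == 1) & (y == 1)))
        fp = int(np.sum((d == 1) & (y == 0)))
        curves[name] = tp / n - (fp / n) * odds
    curves["treat_all"] = prevalence - (1.0 - prevalence) * odds
    curves["treat_none"] = np.zeros_like(pts)
    return DecisionCurve(thresholds=pts, net_benefits=curves, prevalence=prevalence)


# ---------------------------------------------------------------------------
# Reclassification and NRI
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReclassificationTable:
    """3x3 reclassification counts split by event status.

    Rows index the conventional (reference) category, columns the new
    category, both in low < moderate < high order.  "Upward" means moving
    to a higher-risk category; upward moves are correct for individuals
    with the event, downward moves for those without.
    """

    events: np.ndarray  # (3, 3) int
    non_events: np.ndarray  # (3, 3) int
    categories: tuple[str, ...] = CATEGORIES

    def __post_init__(self):
        for name in ("events", "non_events"):
            m = getattr(self, name)
            if m.shape != (3, 3) or np.any(m < 0):
                raise ValueError(f"{name} must be a non-negative 3x3 count matrix")

    @staticmethod
    def _up_down(matrix):
        up = int(np.sum(np.triu(matrix, k=1)))
        down = int(np.sum(np.tril(matrix, k=-1)))
        return up, down

    def summary(self) -> pd.DataFrame:
        """Correct / incorrect / net reclassification counts per event status."""
        up_e, down_e = self._up_down(self.events)
        up_ne, down_ne = self._up_down(self.non_events)
        return pd.DataFrame(
            {
                "events": {
                    "correct": up_e,
                    "incorrect": down_e,
                    "net": up_e - down_e,
                    "total": int(self.events.sum()),
                },
                "non_events": {
                    "correct": down_ne,
                    "incorrect": up_ne,
                    "net": down_ne - up_ne,
                    "total": int(self.non_events.sum()),
                },
            }
        )


def reclassification_table(
    conventional_cats: Sequence[str],
    new_cats: Sequence[str],
    outcomes: Sequence[int],
) -> ReclassificationTable:
    """Cross-tabulate conventional vs new categories split by event status."""
    conv = np.asarray([_CAT_INDEX[c] for c in conventional_cats])
    new = np.asarray([_CAT_INDEX[c] for c in new_cats])
    y = np.asarray(outcomes).astype(bool)
    if not (len(conv) == len(new) == len(y)):
        raise ValueError("inputs must have equal lengths")
    counts = np.zeros((2, 3, 3), dtype=np.int64)
    np.add.at(counts, (y.astype(int), conv, new), 1)
    return ReclassificationTable(events=counts[1], non_events=counts[0])


def nri(rt: ReclassificationTable) -> tuple[float, float]:
    """Additive and absolute net reclassification improvement, in percent.

    additive = 100 * [(up_e - down_e)/N_e + (down_ne - up_ne)/N_ne];
    absolute = 100 * (net_e + net_ne)/(N_e + N_ne).
    """
    up_e, down_e = ReclassificationTable._up_down(rt.events)
    up_ne, down_ne = ReclassificationTable._up_down(rt.non_events)
    n_e = int(rt.events.sum())
    n_ne = int(rt.non_events.sum())
    if n_e == 0 or n_ne == 0:
        raise ValueError("both event and non-event totals must be positive")
    additive = 100.0 * ((up_e - down_e) / n_e + (down_ne - up_ne) / n_ne)
    absolute = 100.0 * ((up_e - down_e) + (down_ne - up_ne)) / (n_e + n_ne)
    return additive, absolute


def load_reference_reclassification() -> ReclassificationTable:
    """Packaged reference counts: age+eGFR vs conventional eGFR categories
    for the eGFR<30-by-age-80 outcome in the historical checkup cohort."""
    text = resources.files("ckdrisk.data").joinpath("reclassification_counts.json").read_text()
    payload = json.loads(text)
    return ReclassificationTable(
        events=np.asarray(payload["events"], dtype=np.int64),
        non_events=np.asarray(payload["non_events"], dtype=np.int64),
        categories=tuple(payload["categories"]),
    )


# ---------------------------------------------------------------------------
# Discrimination and calibration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RocResult:
    """Empirical ROC with per-threshold operating points and the Youden cut."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    youden: float
    optimal_threshold: float


def _check_two_classes(y):
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    return y


def roc_metrics(scores: Sequence[float], outcomes: Sequence[int]) -> RocResult:
    """Empirical ROC over all distinct thresholds of a higher-is-riskier score."""
    y = _check_two_classes(outcomes)
    s = np.asarray(scores, dtype=float)
    fpr, tpr, thr = _sk_roc_curve(y, s)
    j = tpr - fpr
    k = int(np.argmax(j))
    return RocResult(
        thresholds=thr,
        sensitivity=tpr,
        specificity=1.0 - fpr,
        fpr=fpr,
        tpr=tpr,
        auc=float(_sk_auc(fpr, tpr)),
        youden=float(j[k]),
        optimal_threshold=float(thr[k]),
    )


def c_statistic(scores: Sequence[float], outcomes: Sequence[int]) -> float:
    """Concordance: fraction of event/non-event pairs where the event scores
    strictly higher, counting ties as one half (rank-based, exact)."""
    y = _check_two_classes(outcomes)
    s = np.asarray(scores, dtype=float)
    n1 = int(y.sum())
    n0 = len(y) - n1
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def calibration_table(
    predicted: Sequence[float],
    outcomes: Sequence[int],
    n_strata: int = 10,
) -> pd.DataFrame:
    """Observed event rates versus mean predicted risk in equal-frequency strata.

    Strata are prediction quantiles (duplicate edges collapsed, so constant
    predictions yield a single effective stratum).  Columns: ``stratum``,
    ``mean_predicted``, ``observed_rate``, ``count``.
    """
    p = np.asarray(predicted, dtype=float)
    y = np.asarray(outcomes).astype(int)
    if len(p) != len(y):
        raise ValueError("inputs must have equal lengths")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("predicted probabilities must lie in [0, 1]")
    if n_strata < 2:
        raise ValueError("n_strata must be >= 2")
    strata = pd.qcut(p, q=n_strata, labels=False, duplicates="drop")
    if np.all(pd.isna(strata)):  # constant predictions: one stratum
        strata = np.zeros(len(p), dtype=int)
    df = pd.DataFrame({"stratum": strata, "predicted": p, "outcome": y})
    out = (
        df.groupby("stratum", observed=True)
        .agg(mean_predicted=("predicted", "mean"), observed_rate=("outcome", "mean"), count=("outcome", "size"))
        .reset_index()
    )
    return out
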