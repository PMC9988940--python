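"""Discrimination analysis: how well each descriptor separates pathogenic
from benign missense variants.

AUROC is computed as the Mann-Whitney U statistic divided by n1*n0 (ties
count one half), which equals the probability that a random pathogenic
variant outscores a random benign one. 95% confidence intervals use the
DeLong structural-components estimator (a seeded stratified bootstrap is
available as an alternative); the p-value against AUC = 0.5 comes from the
two-sided normal approximation of the Mann-Whitney U test. Descriptors are
oriented before reporting: pLDDT higher-is-pathogenic, rASA and harmonized
ΔΔG lower-is-pathogenic (destabilization associates with pathogenicity);
"auto" flips so the reported AUC is >= 0.5 and records the applied
orientation.
"""

from __future__ import annotations

import enum
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "Orientation",
    "AurocResult",
    "CorrelationMatrix",
    "SubsetSpec",
    "EvaluationReport",
    "SingleClassError",
    "auroc",
    "roc_points",
    "correlate",
    "subset_by_confidence",
    "evaluate_all",
    "DEFAULT_ORIENTATIONS",
    "DESCRIPTOR_COLUMNS",
]

DESCRIPTOR_COLUMNS = (
    "plddt",
    "rasa",
    "ddg_mcsm",
    "ddg_maestro",
    "ddg_cupsat",
    "ddg_saafec",
    "ddg_mupro",
)


class Orientation(str, enum.Enum):
    HIGHER_IS_PATHOGENIC = "higher_is_pathogenic"
    LOWER_IS_PATHOGENIC = "lower_is_pathogenic"
    AUTO = "auto"


#: field orientation of each descriptor: high AlphaFold confidence and low
#: accessibility / destabilizing (negative harmonized ΔΔG) indicate pathogenic
DEFAULT_ORIENTATIONS: dict[str, Orientation] = {
    "plddt": Orientation.HIGHER_IS_PATHOGENIC,
    "rasa": Orientation.LOWER_IS_PATHOGENIC,
    **{
        f"ddg_{p}": Orientation.LOWER_IS_PATHOGENIC
        for p in ("mcsm", "maestro", "cupsat", "saafec", "mupro")
    },
}


class SingleClassError(ValueError):
    """Both classes are required to evaluate discrimination."""


@dataclass(frozen=True)
class AurocResult:
    descriptor: str
    orientation: Orientation
    auc: float
    ci_low: float
    ci_high: float
    p_value: float
    n_pathogenic: int
    n_benign: int
    degenerate_ci: bool = False

    def to_dict(self) -> dict:
        return {
            "descriptor": self.descriptor,
            "orientation": self.orientation.value,
            "auc": self.auc,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "n_pathogenic": self.n_pathogenic,
            "n_benign": self.n_benign,
            "degenerate_ci": self.degenerate_ci,
        }


def _clean(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be matching 1-d arrays")
    ok = np.isfinite(s) & pd.notna(y)
    s, y = s[ok], y[ok].astype(int)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    if (y == 1).sum() == 0 or (y == 0).sum() == 0:
        raise SingleClassError("need both pathogenic and benign observations")
    return s, y


def _mann_whitney_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    n1, n0 = len(pos), len(neg)
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> float:
    """DeLong estimator of Var(AUC) from the placement components."""
    m, n = len(pos), len(neg)
    all_scores = np.concatenate([pos, neg])
    tz = stats.rankdata(all_scores)
    tx = stats.rankdata(pos)
    ty = stats.rankdata(neg)
    v10 = (tz[:m] - tx) / n  # placements of pathogenic among benign
    v01 = 1.0 - (tz[m:] - ty) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def auroc(
    scores,
    labels,
    orientation: Orientation | str = Orientation.AUTO,
    descriptor: str = "",
    ci_method: str = "delong",
    n_boot: int = 2000,
    seed: Optional[int] = None,
    alpha: float = 0.05,
) -> AurocResult:
    """Oriented AUROC with confidence interval and Mann-Whitney p-value.

    Missing scores/labels are excluded pairwise. With ``orientation="auto"``
    the scores are flipped if needed so the reported AUC is >= 0.5, and the
    orientation actually applied is recorded. If every score is identical
    the AUC is 0.5 with a degenerate-CI flag.
    """
    orientation = Orientation(orientation)
    s, y = _clean(scores, labels)
    sign = -1.0 if orientation is Orientation.LOWER_IS_PATHOGENIC else 1.0
    s_or = sign * s
    pos, neg = s_or[y == 1], s_or[y == 0]

    if np.ptp(s_or) == 0.0:
        return AurocResult(
            descriptor=descriptor,
            orientation=(
                Orientation.HIGHER_IS_PATHOGENIC
                if orientation is Orientation.AUTO
                else orientation
            ),
            auc=0.5,
            ci_low=0.5,
            ci_high=0.5,
            p_value=1.0,
            n_pathogenic=len(pos),
            n_benign=len(neg),
            degenerate_ci=True,
        )

    auc = _mann_whitney_auc(pos, neg)
    applied = orientation
    if orientation is Orientation.AUTO:
        if auc < 0.5:
            pos, neg = -pos, -neg
            auc = 1.0 - auc
            applied = Orientation.LOWER_IS_PATHOGENIC
        else:
            applied = Orientation.HIGHER_IS_PATHOGENIC

    z = stats.norm.ppf(1 - alpha / 2)
    if ci_method == "delong":
        var = _delong_variance(pos, neg)
        half = z * np.sqrt(max(var, 0.0))
        ci_low, ci_high = auc - half, auc + half
        degenerate = var == 0.0
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        reps = np.empty(n_boot)
        for b in range(n_boot):
            bp = rng.choice(pos, size=len(pos), replace=True)
            bn = rng.choice(neg, size=len(neg), replace=True)
            reps[b] = _mann_whitney_auc(bp, bn)
        ci_low, ci_high = np.quantile(reps, [alpha / 2, 1 - alpha / 2])
        ci_low, ci_high = min(ci_low, auc), max(ci_high, auc)
        degenerate = False
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")

    p = float(
        stats.mannwhitneyu(pos, neg, alternative="two-sided", method="asymptotic").pvalue
    )
    return AurocResult(
        descriptor=descriptor,
        orientation=applied,
        auc=auc,
        ci_low=float(np.clip(ci_low, 0.0, 1.0)),
        ci_high=float(np.clip(ci_high, 0.0, 1.0)),
        p_value=p,
        n_pathogenic=len(pos),
        n_benign=len(neg),
        degenerate_ci=degenerate,
    )


def roc_points(
    scores, labels, orientation: Orientation | str = Orientation.HIGHER_IS_PATHOGENIC
) -> np.ndarray:
    """Stepwise ROC curve over the unique thresholds of the oriented scores.

    Returns an (k, 2) array of (FPR, TPR) beginning at (0, 0) and ending at
    (1, 1); its trapezoidal area equals the Mann-Whitney AUC (ties traced as
    diagonal segments).
    """
    orientation = Orientation(orientation)
    s, y = _clean(scores, labels)
    if orientation is Orientation.AUTO:
        base = _mann_whitney_auc(s[y == 1], s[y == 0])
        orientation = (
            Orientation.LOWER_IS_PATHOGENIC
            if base < 0.5
            else Orientation.HIGHER_IS_PATHOGENIC
        )
    if orientation is Orientation.LOWER_IS_PATHOGENIC:
        s = -s
    order = np.argsort(-s, kind="mergesort")
    s, y = s[order], y[order]
    n1, n0 = int((y == 1).sum()), int((y == 0).sum())
    tp = np.cumsum(y == 1)
    fp = np.cumsum(y == 0)
    last_of_group = np.r_[s[1:] != s[:-1], True]
    tpr = np.r_[0.0, tp[last_of_group] / n1, 1.0]
    fpr = np.r_[0.0, fp[last_of_group] / n0, 1.0]
    pts = np.column_stack([fpr, tpr])
    # drop a duplicated terminal point if the last threshold already hits (1,1)
    if len(pts) >= 2 and np.all(pts[-1] == pts[-2]):
        pts = pts[:-1]
    return pts


@dataclass(frozen=True)
class CorrelationMatrix:
    method: str
    matrix: pd.DataFrame  # symmetric, diagonal 1 (NaN where insufficient n)
    n_pairs: pd.DataFrame  # pairwise-complete counts

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "matrix": self.matrix.to_dict(),
            "n_pairs": self.n_pairs.to_dict(),
        }


def correlate(
    table: pd.DataFrame,
    descriptors: Optional[Sequence[str]] = None,
    method: str = "spearman",
    stratify_by_label: bool = False,
    min_pairs: int = 3,
):
    """Pairwise-complete correlation over descriptor columns.

    With ``stratify_by_label`` returns ``{"benign": ..., "pathogenic": ...}``
    matrices computed within each class. Cells with fewer than ``min_pairs``
    complete pairs are set to NaN (flagged absent).
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown correlation method {method!r}")
    if descriptors is None:
        descriptors = [c for c in DESCRIPTOR_COLUMNS if c in table.columns]
    if stratify_by_label:
        out = {}
        for name, value in (("benign", 0), ("pathogenic", 1)):
            sub = table[table["label"] == value]
            out[name] = correlate(sub, descriptors, method, False, min_pairs)
        return out
    sub = table[list(descriptors)]
    notna = sub.notna().astype(int)
    n_pairs = notna.T @ notna
    corr = sub.corr(method=method, min_periods=min_pairs)
    corr = corr.mask(n_pairs < min_pairs)
    return CorrelationMatrix(method=method, matrix=corr, n_pairs=n_pairs)


def subset_by_confidence(
    table: pd.DataFrame, min_plddt: float = 50.0
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Keep rows with pLDDT >= min_plddt (inclusive); report per-class counts."""
    kept = table[table["plddt"] >= min_plddt]
    counts = {
        "pathogenic": int((kept["label"] == 1).sum()),
        "benign": int((kept["label"] == 0).sum()),
    }
    if kept.empty:
        logger.warning("confidence subset pLDDT >= %s is empty", min_plddt)
    return kept, counts


@dataclass(frozen=True)
class SubsetSpec:
    """A named row filter: minimum pLDDT (inclusive) and/or maximum rASA
    (strict, the burial filter)."""

    name: str
    min_plddt: Optional[float] = None
    max_rasa: Optional[float] = None

    def apply(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table
        if self.min_plddt is not None:
            out = out[out["plddt"] >= self.min_plddt]
        if self.max_rasa is not None:
            out = out[out["rasa"] < self.max_rasa]
        return out


@dataclass
class EvaluationReport:
    """AUROC per descriptor per subset, plus label-stratified correlations."""

    results: dict[str, dict[str, AurocResult]]
    subset_counts: dict[str, dict[str, int]]
    correlations: dict[str, dict[str, CorrelationMatrix]]

    def to_table(self) -> pd.DataFrame:
        """Long-form frame: one row per (subset, descriptor)."""
        rows = []
        for subset, per_desc in self.results.items():
            for desc, res in per_desc.items():
                d = res.to_dict()
                d["subset"] = subset
                rows.append(d)
        return pd.DataFrame(rows)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "results": {
                s: {d: r.to_dict() for d, r in per.items()}
                for s, per in self.results.items()
            },
            "subset_counts": self.subset_counts,
            "correlations": {
                s: {lbl: m.to_dict() for lbl, m in per.items()}
                for s, per in self.correlations.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2, default=float))


def evaluate_all(
    table: pd.DataFrame,
    subsets: Sequence[SubsetSpec] = (),
    descriptors: Optional[Sequence[str]] = None,
    orientations: Optional[dict[str, Orientation]] = None,
    ci_method: str = "delong",
    seed: Optional[int] = None,
    correlation_method: str = "spearman",
) -> EvaluationReport:
    """Evaluate every descriptor on the total set and each named subset.

    Descriptors entirely missing in a subset are skipped with a log entry;
    single-class subsets propagate :class:`SingleClassError`.
    """
    if descriptors is None:
        descriptors = [c for c in DESCRIPTOR_COLUMNS if c in table.columns]
    if orientations is None:
        orientations = DEFAULT_ORIENTATIONS
    frames = {"total": table}
    counts = {
        "total": {
            "pathogenic": int((table["label"] == 1).sum()),
            "benign": int((table["label"] == 0).sum()),
        }
    }
    for spec in subsets:
        sub = spec.apply(table)
        frames[spec.name] = sub
        counts[spec.name] = {
            "pathogenic": int((sub["label"] == 1).sum()),
            "benign": int((sub["label"] == 0).sum()),
        }
    results: dict[str, dict[str, AurocResult]] = {}
    correlations: dict[str, dict[str, CorrelationMatrix]] = {}
    for name, frame in frames.items():
        per: dict[str, AurocResult] = {}
        for desc in descriptors:
            if frame[desc].notna().sum() == 0:
                logger.info("%s: descriptor %s entirely missing; skipped", name, desc)
                continue
            per[desc] = auroc(
                frame[desc],
                frame["label"],
                orientation=orientations.get(desc, Orientation.AUTO),
                descriptor=desc,
                ci_method=ci_method,
                seed=seed,
            )
        results[name] = per
        correlations[name] = correlate(
            frame, descriptors, method=correlation_method, stratify_by_label=True
        )
    return EvaluationReport(
        results=results, subset_counts=counts, correlations=correlations
    )
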