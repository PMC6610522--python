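"""Segmentation metrics and study-level analyses.

Evaluation binarises both prediction and truth to WMH vs non-WMH (labels 0
and 1 both count as negative) before filling the confusion table, then derives

    sensitivity = TP / (TP + FN)
    PPV         = TP / (TP + FP)
    DSC         = 2 TP / (2 TP + FP + FN)

Scans can additionally be grouped by WMH burden (Large >= 10,000 mm^3,
Medium [4,000, 10,000), Small [1, 4,000)), compared across models with
rank-based tests (pairwise Wilcoxon rank-sum, overall Kruskal-Wallis with an
ANOVA-style table on ranks), and split longitudinally (train on year-1 scans,
test on years 2 and 3 of the same subjects).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractViolation, ParameterError
from .io import Volume
from .preprocess import LABEL_WMH

__all__ = [
    "ConfusionCounts",
    "VolumeGroup",
    "VOLUME_GROUPS",
    "LongitudinalSplit",
    "confusion_counts",
    "dsc",
    "sensitivity",
    "ppv",
    "wmh_volume",
    "assign_volume_group",
    "compare_models",
    "longitudinal_split",
    "longitudinal_report",
    "boxplot_summary",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ContractViolation("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class VolumeGroup:
    name: str
    low: float  # inclusive, mm^3
    high: float  # exclusive


VOLUME_GROUPS = (
    VolumeGroup("Large", 10_000.0, np.inf),
    VolumeGroup("Medium", 4_000.0, 10_000.0),
    VolumeGroup("Small", 1.0, 4_000.0),
)


def confusion_counts(pred: Volume | np.ndarray, truth: Volume | np.ndarray) -> ConfusionCounts:
    """Binarise both label volumes to WMH vs everything else and count."""
    p = np.asarray(pred.data if isinstance(pred, Volume) else pred)
    t = np.asarray(truth.data if isinstance(truth, Volume) else truth)
    if p.shape != t.shape:
        raise ContractViolation(f"prediction {p.shape} vs truth {t.shape}")
    pw = p == LABEL_WMH
    tw = t == LABEL_WMH
    return ConfusionCounts(
        tp=int((pw & tw).sum()),
        fp=int((pw & ~tw).sum()),
        fn=int((~pw & tw).sum()),
        tn=int((~pw & ~tw).sum()),
    )


def _safe_ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name}: zero denominator, returning 0", RuntimeWarning, stacklevel=3)
        return 0.0
    return num / den


def dsc(c: ConfusionCounts) -> float:
    """Dice similarity coefficient; two empty masks score 1 by convention."""
    if c.tp == 0 and c.fp == 0 and c.fn == 0:
        return 1.0
    return _safe_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn, "DSC")


def sensitivity(c: ConfusionCounts) -> float:
    return _safe_ratio(c.tp, c.tp + c.fn, "sensitivity")


def ppv(c: ConfusionCounts) -> float:
    return _safe_ratio(c.tp, c.tp + c.fp, "PPV")


def wmh_volume(labels: Volume, voxel_size: Sequence[float] | None = None) -> float:
    """WMH volume in mm^3: voxel count times voxel volume.

    ``voxel_size`` overrides the volume's affine-derived spacing (phantom
    sidecars may carry the authoritative value).
    """
    vs = np.asarray(voxel_size if voxel_size is not None else labels.voxel_size, float)
    if (vs <= 0).any():
        raise ParameterError("voxel dimensions must be positive")
    return float((np.asarray(labels.data) == LABEL_WMH).sum()) * float(np.prod(vs))


def assign_volume_group(volume_mm3: float) -> VolumeGroup | None:
    """Map a WMH volume to its burden group; below 1 mm^3 is ungrouped."""
    if volume_mm3 < 1.0:
        log.info("WMH volume %.3f mm^3 below 1: ungrouped", volume_mm3)
        return None
    for g in VOLUME_GROUPS:
        if g.low <= volume_mm3 < g.high:
            return g
    return None  # unreachable: groups partition [1, inf)


def compare_models(dsc_per_case: Mapping[str, Sequence[float]]) -> dict:
    """Rank-based comparison of per-case DSC distributions across models.

    Returns pairwise Wilcoxon rank-sum p-values, the Kruskal-Wallis test over
    all models, and an ANOVA-style table on the pooled ranks (source, SS, df,
    MS, statistic, p).
    """
    names = list(dsc_per_case)
    if len(names) < 2:
        raise ParameterError("need at least two models to compare")
    groups = {k: np.asarray(v, dtype=float) for k, v in dsc_per_case.items()}
    for k, v in groups.items():
        if v.size < 2:
            warnings.warn(f"model {k!r} has fewer than 2 cases; tests skipped", RuntimeWarning)
            return {"pairwise": pd.DataFrame(), "kruskal": None, "anova_table": pd.DataFrame()}

    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            stat, p = stats.ranksums(groups[a], groups[b])
            rows.append({"model_a": a, "model_b": b, "statistic": stat, "p_value": p})
    pairwise = pd.DataFrame(rows)

    samples = [groups[k] for k in names]
    if np.ptp(np.concatenate(samples)) == 0:
        kw_stat, kw_p = 0.0, 1.0  # identical samples: no evidence of difference
    else:
        kw_stat, kw_p = stats.kruskal(*samples)

    # ANOVA-style table on ranks (the classical Kruskal-Wallis presentation)
    pooled = np.concatenate(samples)
    ranks = stats.rankdata(pooled)
    split_at = np.cumsum([len(s) for s in samples])[:-1]
    rank_groups = np.split(ranks, split_at)
    grand = ranks.mean()
    ss_between = sum(len(r) * (r.mean() - grand) ** 2 for r in rank_groups)
    df = len(names) - 1
    table = pd.DataFrame(
        [
            {
                "source": "Models",
                "SS": ss_between,
                "df": df,
                "MS": ss_between / df,
                "statistic": kw_stat,
                "p_value": kw_p,
            }
        ]
    )
    return {"pairwise": pairwise, "kruskal": {"statistic": kw_stat, "p_value": kw_p}, "anova_table": table}


@dataclass
class LongitudinalSplit:
    """Scan ids for year-1 training and later-year testing, keyed by year."""

    train: list
    test_by_year: dict[int, list]


def longitudinal_split(catalog: pd.DataFrame) -> LongitudinalSplit:
    """Split a (subject, year, scan_id) catalogue: year 1 trains, years 2+3 test.

    Subjects without a year-1 scan are excluded with a warning; an empty test
    set raises, because the longitudinal evaluation is then undefined.
    """
    req = {"subject", "year", "scan_id"}
    if not req.issubset(catalog.columns):
        raise ContractViolation(f"catalog needs columns {sorted(req)}")
    has_y1 = set(catalog.loc[catalog["year"] == 1, "subject"])
    dropped = sorted(set(catalog["subject"]) - has_y1)
    if dropped:
        warnings.warn(f"subjects without a year-1 scan excluded: {dropped}", RuntimeWarning)
    kept = catalog[catalog["subject"].isin(has_y1)]
    train = kept.loc[kept["year"] == 1, "scan_id"].tolist()
    test_by_year = {
        int(y): sub["scan_id"].tolist()
        for y, sub in kept[kept["year"] > 1].groupby("year")
    }
    if not test_by_year:
        raise ParameterError("no year-2/3 scans: empty longitudinal test set")
    return LongitudinalSplit(train=train, test_by_year=test_by_year)


def longitudinal_report(split: LongitudinalSplit, dsc_by_scan: Mapping) -> pd.DataFrame:
    """Mean DSC per follow-up year over the test scans."""
    rows = [
        {
            "year": y,
            "n_scans": len(ids),
            "mean_dsc": float(np.mean([dsc_by_scan[i] for i in ids])),
        }
        for y, ids in sorted(split.test_by_year.items())
    ]
    return pd.DataFrame(rows)


def boxplot_summary(values: Sequence[float]) -> dict:
    """Quartiles, median and mean of a score distribution (JSON-friendly)."""
    v = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return {
        "n": int(v.size),
        "mean": float(v.mean()),
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "min": float(v.min()),
        "max": float(v.max()),
        "std": float(v.std(ddof=1)) if v.size > 1 else 0.0,
    }
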