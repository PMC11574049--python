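"""Method-agreement statistics: IoU/Dice, Spearman, two-way absolute-agreement
ICC with qualitative bands, and Kruskal-Wallis with Dunn post-hoc.

All rank statistics use midranks for ties. The ICC is the single-measure
absolute-agreement form of the two-way model (McGraw-Wong ICC(A,1)); the
average-measure variant ICC(A,k) is available as an option.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .imaging_io import BinaryMask

logger = logging.getLogger(__name__)

__all__ = [
    "MethodTable",
    "AgreementReport",
    "iou",
    "dice",
    "spearman_rho",
    "icc_two_way_mixed_absolute",
    "icc_band",
    "kruskal_wallis",
    "dunn_posthoc",
    "build_report",
]


# ---------------------------------------------------------------------------
# segmentation overlap


def _as_bool(a) -> np.ndarray:
    return a.pixels if isinstance(a, BinaryMask) else np.asarray(a, dtype=bool)


def iou(a, b) -> float:
    """Intersection over union of two same-shape binary masks; both-empty = 1."""
    a, b = _as_bool(a), _as_bool(b)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def dice(a, b) -> float:
    """Dice coefficient 2|A∩B| / (|A|+|B|); both-empty = 1."""
    a, b = _as_bool(a), _as_bool(b)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    total = a.sum() + b.sum()
    if total == 0:
        return 1.0
    return float(2 * np.logical_and(a, b).sum() / total)


# ---------------------------------------------------------------------------
# rank statistics


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman correlation with midranks; two-tailed p from the
    t-approximation with n-2 df. rho = +-1 returns p = 0."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant series: Spearman correlation undefined")
    rx, ry = _midranks(x), _midranks(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) == 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1 - rho**2))
    p = float(2 * sps.t.sf(abs(t), df=n - 2))
    return rho, p


def _anova_mean_squares(table: np.ndarray) -> tuple[float, float, float]:
    """Two-way (subjects x methods, one observation per cell) mean squares:
    rows, columns, residual."""
    n, k = table.shape
    grand = table.mean()
    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((table - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = max(ss_err / ((n - 1) * (k - 1)), 0.0)
    return ms_rows, ms_cols, ms_err


def icc_two_way_mixed_absolute(
    table, average_measure: bool = False
) -> tuple[float, float, str]:
    """Single-measure absolute-agreement ICC from the two-way layout
    (subjects x methods), with p from F = MS_rows/MS_err on
    (n-1, (n-1)(k-1)) df. Returns (estimate, p, band).

    ``average_measure=True`` returns the ICC(A,k) variant instead.
    """
    values = np.asarray(table, dtype=np.float64)
    if values.ndim != 2:
        raise ValueError("table must be 2-D (subjects x methods)")
    n, k = values.shape
    if n < 3 or k < 2:
        raise ValueError("need >= 3 subjects and >= 2 methods")
    if np.ptp(values) == 0:
        logger.warning("degenerate ICC input: all values identical; estimate defined as 1")
        return 1.0, 0.0, icc_band(1.0)
    msr, msc, mse = _anova_mean_squares(values)
    if average_measure:
        denom = msr + (msc - mse) / n
        est = (msr - mse) / denom if denom != 0 else 1.0
    else:
        denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
        est = (msr - mse) / denom if denom != 0 else 1.0
    if mse == 0:
        p = 0.0
    else:
        f = msr / mse
        p = float(sps.f.sf(f, n - 1, (n - 1) * (k - 1)))
    return float(est), p, icc_band(est)


def icc_band(estimate: float) -> str:
    """Qualitative agreement band: <0.5 poor, [0.5,0.75) moderate,
    [0.75,0.9) good, >=0.9 excellent."""
    if estimate > 1:
        raise ValueError("ICC estimate cannot exceed 1")
    if estimate < 0.5:
        return "poor"
    if estimate < 0.75:
        return "moderate"
    if estimate < 0.9:
        return "good"
    return "excellent"


def _tie_term(pooled: np.ndarray) -> float:
    """Sum of t^3 - t over tie groups of the pooled sample."""
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts**3 - counts))


def kruskal_wallis(groups: list) -> tuple[float, int, float]:
    """Kruskal-Wallis H with tie correction; p from chi-square with k-1 df."""
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    df = len(groups) - 1
    if np.ptp(pooled) == 0:
        return 0.0, df, 1.0
    ranks = _midranks(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += len(g) * (r.mean() - (n_total + 1) / 2) ** 2
        start += len(g)
    h *= 12 / (n_total * (n_total + 1))
    correction = 1 - _tie_term(pooled) / (n_total**3 - n_total)
    if correction > 0:
        h /= correction
    p = float(sps.chi2.sf(h, df))
    return float(h), df, p


def dunn_posthoc(groups: list, labels: list[str] | None = None) -> pd.DataFrame:
    """Dunn pairwise z tests on the joint midranks with tie-corrected
    variance; Bonferroni-adjusted two-tailed normal p values.

    Returns a DataFrame with columns group_a, group_b, z, p_raw, p_adjusted.
    """
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    labels = labels or [f"group{i}" for i in range(len(groups))]
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    ranks = _midranks(pooled)
    mean_ranks, sizes = [], []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start : start + len(g)].mean())
        sizes.append(len(g))
        start += len(g)
    var_base = n_total * (n_total + 1) / 12 - _tie_term(pooled) / (12 * (n_total - 1))
    pairs = list(itertools.combinations(range(len(groups)), 2))
    m = len(pairs)
    rows = []
    for i, j in pairs:
        se_sq = var_base * (1 / sizes[i] + 1 / sizes[j])
        if se_sq <= 0:
            z = 0.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(se_sq)
        p_raw = float(2 * sps.norm.sf(abs(z)))
        rows.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "z": float(z),
                "p_raw": p_raw,
                "p_adjusted": min(1.0, m * p_raw),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# report assembly


@dataclass
class MethodTable:
    """Complete n_images x k_methods matrix of one measure."""

    values: np.ndarray
    image_ids: list[str]
    method_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.image_ids), len(self.method_names)):
            raise ValueError("values shape must be (n_images, n_methods)")
        if np.isnan(self.values).any():
            raise ValueError("MethodTable cannot hold missing cells")

    @classmethod
    def from_long(cls, df: pd.DataFrame, value_col: str) -> "MethodTable":
        """Pivot a long (image_id, method, value) frame; rows with any
        missing cell are dropped with a warning."""
        wide = df.pivot(index="image_id", columns="method", values=value_col)
        incomplete = wide.index[wide.isna().any(axis=1)]
        if len(incomplete):
            logger.warning(
                "dropping %d image(s) with missing cells: %s",
                len(incomplete),
                ", ".join(map(str, incomplete)),
            )
            wide = wide.dropna()
        return cls(
            values=wide.to_numpy(),
            image_ids=[str(i) for i in wide.index],
            method_names=[str(c) for c in wide.columns],
        )


@dataclass
class AgreementReport:
    descriptives: dict = field(default_factory=dict)
    spearman: dict = field(default_factory=dict)
    icc: dict = field(default_factory=dict)
    kruskal: dict = field(default_factory=dict)
    dunn: list = field(default_factory=list)
    n_images: int = 0
    methods: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_images": self.n_images,
            "methods": self.methods,
            "descriptives": self.descriptives,
            "spearman": self.spearman,
            "icc": self.icc,
            "kruskal_wallis": self.kruskal,
            "dunn": self.dunn,
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "AgreementReport":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            descriptives=d["descriptives"],
            spearman=d["spearman"],
            icc=d["icc"],
            kruskal=d["kruskal_wallis"],
            dunn=d["dunn"],
            n_images=d["n_images"],
            methods=d["methods"],
        )


def build_report(
    quant_table: pd.DataFrame,
    manual_counts: pd.DataFrame | None = None,
    automated_methods: list[str] | None = None,
) -> AgreementReport:
    """Assemble the cross-method agreement report.

    ``quant_table`` is the long quantification frame (columns image_id,
    method, n_puncta, mfi_au, fiber_area_um2). ``manual_counts`` optionally
    adds per-image manual counts (columns image_id, rater, n_puncta); raters
    are averaged into one "manual" count column that joins the count-based
    comparisons only.
    """
    counts = quant_table[["image_id", "method", "n_puncta"]].copy()
    if manual_counts is not None and len(manual_counts):
        manual = (
            manual_counts.groupby("image_id")["n_puncta"].mean().reset_index()
        )
        manual["method"] = "manual"
        counts = pd.concat([counts, manual[["image_id", "method", "n_puncta"]]])

    count_table = MethodTable.from_long(counts, "n_puncta")
    if len(count_table.image_ids) < 3 or len(count_table.method_names) < 2:
        missing = sorted(
            set(quant_table["image_id"]) - set(count_table.image_ids)
        )
        raise ValueError(
            f"insufficient overlap across methods (complete images: "
            f"{len(count_table.image_ids)}; incomplete: {missing})"
        )

    methods = count_table.method_names
    report = AgreementReport(n_images=len(count_table.image_ids), methods=methods)

    for j, m in enumerate(methods):
        col = count_table.values[:, j]
        report.descriptives.setdefault("n_puncta", {})[m] = {
            "mean": float(col.mean()),
            "sd": float(col.std(ddof=1)),
        }

    for i, j in itertools.combinations(range(len(methods)), 2):
        try:
            rho, p = spearman_rho(count_table.values[:, i], count_table.values[:, j])
            report.spearman[f"{methods[i]} vs {methods[j]}"] = {"rho": rho, "p": p}
        except ValueError as exc:
            logger.warning("spearman skipped for %s/%s: %s", methods[i], methods[j], exc)

    auto = automated_methods or [m for m in methods if m != "manual"]
    auto = [m for m in auto if m in set(quant_table["method"])]
    if len(auto) >= 2:
        for measure in ("n_puncta", "mfi_au", "fiber_area_um2"):
            sub = quant_table[quant_table["method"].isin(auto)]
            mt = MethodTable.from_long(sub[["image_id", "method", measure]], measure)
            if len(mt.image_ids) >= 3:
                est, p, band = icc_two_way_mixed_absolute(mt.values)
                report.icc[measure] = {"estimate": est, "p": p, "band": band}
            for j, m in enumerate(mt.method_names):
                col = mt.values[:, j]
                report.descriptives.setdefault(measure, {})[m] = {
                    "mean": float(col.mean()),
                    "sd": float(col.std(ddof=1)),
                }

    groups = [count_table.values[:, j] for j in range(len(methods))]
    if all(len(g) >= 2 for g in groups):
        h, df, p = kruskal_wallis(groups)
        report.kruskal = {"H": h, "df": df, "p": p}
        report.dunn = dunn_posthoc(groups, labels=methods).to_dict(orient="records")
    return report
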