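"""Per-class confusion metrics, summary statistics, and the report tables.

The evaluation convention is one-vs-rest per diagnostic class: for a
target class, PC (perfect classification) counts its instances predicted
correctly, MC (missed classification) its instances predicted as the
other class, and FA (false alarm) the other class's instances predicted
as the target.  From these

    sensitivity = PC / (PC + FA) * 100
    specificity = PC / (PC + MC) * 100
    accuracy    = (sensitivity + specificity) / 2
    PI          = (PC - MC - FA) / PC * 100
    GDR         = (PC - MC) / (PC + FA) * 100

Zero denominators flag the metric as undefined (NaN) rather than
silently zeroing it.  The report bundle mirrors a per-class table layout:
accuracy, perfect-classification %, PI, and a pooled performance table
(PC, PI, accuracy, GDR, error rate = 100 - PC%), plus moment, canonical
correlation, and average-Pearson summaries of the selected features.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats

from .exceptions import ParameterError

__all__ = [
    "ConfusionCounts",
    "MetricsRow",
    "confusion_counts",
    "classification_metrics",
    "mse",
    "moment_summary",
    "canonical_correlation",
    "pearson_matrix",
    "build_report_tables",
    "write_report_bundle",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest counts for a target class."""

    target_class: str
    PC: int
    MC: int
    FA: int

    def __post_init__(self) -> None:
        if min(self.PC, self.MC, self.FA) < 0:
            raise ParameterError("counts must be non-negative")

    @property
    def n_target(self) -> int:
        return self.PC + self.MC


@dataclass(frozen=True)
class MetricsRow:
    """Percent-scale metrics of one evaluation; NaN marks undefined entries."""

    sensitivity: float
    specificity: float
    accuracy: float
    PI: float
    GDR: float
    MSE: float = math.nan


def confusion_counts(truth, predicted, target_class) -> ConfusionCounts:
    """One-vs-rest confusion counts of equal-length label sequences."""
    t = np.asarray(truth)
    p = np.asarray(predicted)
    if t.size == 0:
        raise ParameterError("empty label sequences")
    if t.shape != p.shape:
        raise ParameterError("truth and predicted must have equal length")
    is_target = t == target_class
    pred_target = p == target_class
    return ConfusionCounts(
        target_class=str(target_class),
        PC=int(np.sum(is_target & pred_target)),
        MC=int(np.sum(is_target & ~pred_target)),
        FA=int(np.sum(~is_target & pred_target)),
    )


def classification_metrics(counts: ConfusionCounts) -> MetricsRow:
    """Sensitivity/specificity/accuracy/PI/GDR from one-vs-rest counts."""
    pc, mc, fa = counts.PC, counts.MC, counts.FA
    sens = 100.0 * pc / (pc + fa) if pc + fa > 0 else math.nan
    spec = 100.0 * pc / (pc + mc) if pc + mc > 0 else math.nan
    acc = (sens + spec) / 2.0
    pi = 100.0 * (pc - mc - fa) / pc if pc > 0 else math.nan
    gdr = 100.0 * (pc - mc) / (pc + fa) if pc + fa > 0 else math.nan
    return MetricsRow(sensitivity=sens, specificity=spec, accuracy=acc, PI=pi, GDR=gdr)


def mse(observed, target) -> float:
    """Mean squared error between observed and target sequences."""
    o = np.asarray(observed, dtype=float).ravel()
    t = np.asarray(target, dtype=float).ravel()
    if o.size == 0:
        raise ParameterError("empty input")
    if o.shape != t.shape:
        raise ParameterError("observed and target must have equal length")
    return float(np.mean((o - t) ** 2))


def moment_summary(values) -> dict:
    """Sample mean/variance plus skewness and excess kurtosis.

    Kurtosis uses the excess convention (Gaussian -> 0).  Zero variance
    leaves skewness and kurtosis undefined (NaN).
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 4:
        raise ParameterError("need at least 4 values for the kurtosis")
    var = float(np.var(x, ddof=1))
    if var == 0.0:
        skew = kurt = math.nan
    else:
        skew = float(stats.skew(x, bias=True))
        kurt = float(stats.kurtosis(x, fisher=True, bias=True))
    return {"mean": float(x.mean()), "variance": var, "skewness": skew, "kurtosis": kurt}


def canonical_correlation(x, y, ridge: float = 1e-9) -> float:
    """First canonical correlation between two variable sets.

    Standard generalized-eigen formulation: the largest singular value of
    Sxx^{-1/2} Sxy Syy^{-1/2}, with a trace-scaled ridge on the
    within-set covariances.
    """
    xm = np.atleast_2d(np.asarray(x, dtype=float))
    ym = np.atleast_2d(np.asarray(y, dtype=float))
    if xm.shape[0] == 1:
        xm = xm.T
    if ym.shape[0] == 1:
        ym = ym.T
    if xm.shape[0] != ym.shape[0]:
        raise ParameterError("X and Y must have matched row counts")
    if xm.shape[0] < 3:
        raise ParameterError("need at least 3 rows")
    xc = xm - xm.mean(axis=0)
    yc = ym - ym.mean(axis=0)
    n = xm.shape[0]
    sxx = xc.T @ xc / (n - 1)
    syy = yc.T @ yc / (n - 1)
    sxy = xc.T @ yc / (n - 1)
    sxx += ridge * max(np.trace(sxx) / sxx.shape[0], 1e-30) * np.eye(sxx.shape[0])
    syy += ridge * max(np.trace(syy) / syy.shape[0], 1e-30) * np.eye(syy.shape[0])
    try:
        wx = sla.fractional_matrix_power(sxx, -0.5)
        wy = sla.fractional_matrix_power(syy, -0.5)
        m = np.real(wx) @ sxy @ np.real(wy)
        sv = sla.svdvals(m)
    except sla.LinAlgError as exc:  # pragma: no cover
        raise ParameterError("covariance rank-deficient beyond the ridge guard") from exc
    if sv.size == 0 or not np.isfinite(sv).all():
        raise ParameterError("covariance rank-deficient beyond the ridge guard")
    return float(np.clip(sv.max(), 0.0, 1.0))


def pearson_matrix(features) -> float:
    """Mean signed off-diagonal Pearson correlation across feature columns.

    Constant columns are excluded from the pairing (their correlations are
    undefined).
    """
    f = np.asarray(features, dtype=float)
    if f.ndim != 2 or f.shape[1] < 2:
        raise ParameterError("need a 2-D matrix with at least 2 columns")
    keep = f.std(axis=0) > 0
    if keep.sum() < 2:
        return math.nan
    r = np.corrcoef(f[:, keep], rowvar=False)
    iu = np.triu_indices_from(r, k=1)
    vals = r[iu]
    vals = vals[np.isfinite(vals)]
    return float(vals.mean()) if vals.size else math.nan


# ---------------------------------------------------------------------------
# report tables
# ---------------------------------------------------------------------------

_CLASS_SLUG = {"normal": "normal", "schizophrenia": "schizophrenia"}


def build_report_tables(results: pd.DataFrame,
                        feature_summaries: Mapping[str, pd.DataFrame] | None = None
                        ) -> dict[str, pd.DataFrame]:
    """Pivot per-repetition results into the per-class report tables.

    ``results`` must be tidy with columns: optimizer, classifier,
    repetition, target_class, PC, MC, FA, n_target, sensitivity,
    specificity, accuracy, PI, GDR (and optionally mse, overall_accuracy).
    Metrics are averaged over repetitions first (matching the "average"
    table captions); missing cells stay absent, never imputed.
    """
    required = {"optimizer", "classifier", "repetition", "target_class",
                "PC", "n_target", "accuracy", "PI", "GDR"}
    missing = required - set(results.columns)
    if missing:
        raise ParameterError(f"results missing columns: {sorted(missing)}")
    df = results.copy()
    df["pc_pct"] = 100.0 * df["PC"] / df["n_target"]

    tables: dict[str, pd.DataFrame] = {}
    for cls, slug in _CLASS_SLUG.items():
        sub = df[df["target_class"] == cls]
        if sub.empty:
            continue
        cell = sub.groupby(["optimizer", "classifier"]).mean(numeric_only=True)
        tables[f"accuracy_{slug}"] = cell["accuracy"].unstack("classifier")
        tables[f"pc_{slug}"] = cell["pc_pct"].unstack("classifier")
        tables[f"pi_{slug}"] = cell["PI"].unstack("classifier")
        pooled = sub.groupby("classifier").mean(numeric_only=True)
        perf = pd.DataFrame(
            {
                "perfect_classification": pooled["pc_pct"],
                "performance_index": pooled["PI"],
                "accuracy": pooled["accuracy"],
                "GDR": pooled["GDR"],
                "error_rate": 100.0 - pooled["pc_pct"],
            }
        ).T
        tables[f"performance_{slug}"] = perf
    if feature_summaries:
        for name, table in feature_summaries.items():
            tables[name] = table
    return tables


#: File names mirror the source tables' ordering: moments (1-2), CCA (3, 5),
#: PCC (4, 6), accuracy (7-8), perfect classification (9-10), PI (11-12),
#: pooled performance (13-14).
_TABLE_FILES = {
    "moments_normal": "table01_moments_normal.csv",
    "moments_schizophrenia": "table02_moments_schizophrenia.csv",
    "cca_features": "table03_cca_features.csv",
    "pcc_features": "table04_pcc_features.csv",
    "cca_optimizers": "table05_cca_optimizers.csv",
    "pcc_optimizers": "table06_pcc_optimizers.csv",
    "accuracy_normal": "table07_accuracy_normal.csv",
    "accuracy_schizophrenia": "table08_accuracy_schizophrenia.csv",
    "pc_normal": "table09_pc_normal.csv",
    "pc_schizophrenia": "table10_pc_schizophrenia.csv",
    "pi_normal": "table11_pi_normal.csv",
    "pi_schizophrenia": "table12_pi_schizophrenia.csv",
    "performance_normal": "table13_performance_normal.csv",
    "performance_schizophrenia": "table14_performance_schizophrenia.csv",
}


def write_report_bundle(tables: Mapping[str, pd.DataFrame], out_dir) -> list[str]:
    """Write each table as CSV (5-decimal rendering) and return the paths."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    written = []
    for key, table in tables.items():
        fname = _TABLE_FILES.get(key, f"{key}.csv")
        path = os.path.join(out_dir, fname)
        table.to_csv(path, float_format="%.5f")
        written.append(path)
    return written
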