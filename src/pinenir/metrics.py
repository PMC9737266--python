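"""Figures of merit for calibration and discrimination models.

* RMSE — ``sqrt(sum((c_i - chat_i)^2) / n)``; the same formula serves as
  RMSEC (calibration), RMSECV (cross-validation) and RMSEP (validation),
  the role being pure labeling.
* R^2 — coefficient of determination ``1 - SSE/SST`` about the mean of the
  evaluated set (a squared-Pearson variant is available behind a flag).
* RER — range error ratio ``(Ymax - Ymin)/RMSEP`` with the extremes taken
  over the parameter's full reference range; higher is better
  (RER ~ 10 marks a usable calibration).
* Confusion matrices — rows are true classes, columns predicted; cells are
  reported as ``"93.3%(14/15)"`` and the overall score is
  ``100 * trace / total``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["rmse", "r_squared", "rer", "confusion", "ConfusionMatrix",
           "RegressionReport", "report_table", "format_report_table"]


def rmse(measured, predicted) -> float:
    """Root mean square error between measured and predicted values."""
    c = np.asarray(measured, dtype=float).ravel()
    ch = np.asarray(predicted, dtype=float).ravel()
    if c.size == 0:
        raise ValueError("rmse of empty vectors")
    if c.size != ch.size:
        raise ValueError(f"length mismatch: {c.size} vs {ch.size}")
    return float(np.sqrt(np.mean((c - ch) ** 2)))


def r_squared(measured, predicted, squared_correlation: bool = False) -> float:
    """Coefficient of determination 1 - SSE/SST (may be negative).

    With ``squared_correlation=True`` returns the squared Pearson
    correlation between measured and predicted instead.
    """
    c = np.asarray(measured, dtype=float).ravel()
    ch = np.asarray(predicted, dtype=float).ravel()
    if c.size != ch.size:
        raise ValueError("length mismatch")
    if c.size < 2:
        raise ValueError("r_squared needs at least 2 points")
    sst = float(np.sum((c - c.mean()) ** 2))
    if sst == 0:
        raise ValueError("zero variance of measured values: R^2 undefined")
    if squared_correlation:
        sp = float(np.sum((ch - ch.mean()) ** 2))
        if sp == 0:
            return 0.0
        r = float(np.sum((c - c.mean()) * (ch - ch.mean()))) / np.sqrt(sst * sp)
        return r ** 2
    sse = float(np.sum((c - ch) ** 2))
    return 1.0 - sse / sst


def rer(y_max: float, y_min: float, rmsep: float) -> float:
    """Range error ratio (Ymax - Ymin)/RMSEP over the full reference range."""
    if not y_max > y_min:
        raise ValueError(f"y_max ({y_max}) must exceed y_min ({y_min})")
    if not rmsep > 0:
        raise ValueError("rmsep must be positive")
    return (y_max - y_min) / rmsep


# ---------------------------------------------------------------------------
# Confusion matrices
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    class_labels: tuple[str, ...]
    counts: np.ndarray  # rows true, columns predicted

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def correct(self) -> int:
        return int(np.trace(self.counts))

    @property
    def overall_pct(self) -> float:
        return 100.0 * self.correct / self.total

    def row_percentages(self) -> np.ndarray:
        totals = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * self.counts / totals
        return np.where(totals > 0, pct, 0.0)

    def cell(self, i: int, j: int) -> str:
        """One cell in the report style, e.g. ``"93.3%(14/15)"``."""
        n = int(self.counts[i].sum())
        k = int(self.counts[i, j])
        pct = 100.0 * k / n if n else 0.0
        return f"{_fmt_pct(pct)}%({k}/{n})"

    def overall_line(self) -> str:
        return (f"total correct predictions: "
                f"{_fmt_pct(self.overall_pct)}%({self.correct}/{self.total})")

    def to_frame(self) -> pd.DataFrame:
        cells = [[self.cell(i, j) for j in range(len(self.class_labels))]
                 for i in range(len(self.class_labels))]
        return pd.DataFrame(cells, index=pd.Index(self.class_labels, name="Real"),
                            columns=pd.Index(self.class_labels, name="Predicted"))

    def __str__(self) -> str:
        return self.to_frame().to_string() + "\n" + self.overall_line()


def _fmt_pct(pct: float) -> str:
    """Percent at 1 d.p., with exact integers shown bare ('100', '0')."""
    r = round(pct, 1)
    return f"{int(r)}" if float(r).is_integer() else f"{r:.1f}"


def confusion(true_labels, predicted_labels, class_order) -> ConfusionMatrix:
    """Count matrix over ``class_order``; unseen labels raise ``ValueError``."""
    t = np.asarray(true_labels, dtype=object)
    p = np.asarray(predicted_labels, dtype=object)
    if t.size != p.size:
        raise ValueError("label vectors differ in length")
    order = tuple(class_order)
    unseen = sorted((set(t) | set(p)) - set(order))
    if unseen:
        raise ValueError(f"label(s) not in class order {order}: {unseen}")
    idx = {c: i for i, c in enumerate(order)}
    counts = np.zeros((len(order), len(order)), dtype=int)
    for a, b in zip(t, p):
        counts[idx[a], idx[b]] += 1
    return ConfusionMatrix(order, counts)


# ---------------------------------------------------------------------------
# Calibration report rows
# ---------------------------------------------------------------------------

REPORT_COLUMNS = ["Parameter", "LV", "Best Spectral Region",
                  "Best Pre-Processing Technique(s)",
                  "RMSEC", "RMSECV", "RMSEP", "R2C", "R2P", "RER"]


@dataclass
class RegressionReport:
    """One summary row for a calibrated parameter (full precision)."""
    parameter: str
    n_lv: int
    region_combo: tuple[str, ...]
    preprocess: str
    rmsec: float
    rmsecv: float
    rmsep: float
    r2_c: float
    r2_p: float
    rer: float
    extra: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        return {
            "Parameter": self.parameter,
            "LV": self.n_lv,
            "Best Spectral Region": " + ".join(self.region_combo),
            "Best Pre-Processing Technique(s)": self.preprocess,
            "RMSEC": self.rmsec, "RMSECV": self.rmsecv, "RMSEP": self.rmsep,
            "R2C": self.r2_c, "R2P": self.r2_p, "RER": self.rer,
        }


def report_table(rows: list[RegressionReport]) -> pd.DataFrame:
    """Full-precision summary table in the standard column order."""
    return pd.DataFrame([r.to_row() for r in rows], columns=REPORT_COLUMNS)


def _sigfig(x: float, sig: int = 3) -> str:
    if x == 0:
        return "0"
    return f"{x:.{sig}g}"


def format_report_table(rows: list[RegressionReport]) -> pd.DataFrame:
    """Display rounding: errors to 3 significant figures, R^2 to 2 d.p.,
    RER to 1 d.p. Underlying stored values stay full precision."""
    df = report_table(rows).copy()
    for col in ("RMSEC", "RMSECV", "RMSEP"):
        df[col] = df[col].map(lambda v: _sigfig(float(v)))
    for col in ("R2C", "R2P"):
        df[col] = df[col].map(lambda v: f"{float(v):.2f}")
    df["RER"] = df["RER"].map(lambda v: f"{float(v):.1f}")
    return df
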