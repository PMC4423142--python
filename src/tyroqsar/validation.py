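"""Cross-validation statistics, Y-randomization and the leverage-based
applicability domain (Williams plot).

A QSAR model is only trustworthy inside the chemical space it was calibrated
on. The applicability domain is drawn in the (leverage, standardized
residual) plane: compounds with leverage above the warning value
h* = 3(k+1)/n extrapolate structurally, and compounds with |standardized
residual| > 2 are response outliers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

from .models import LinearModel, fit_ols, q2_press

__all__ = [
    "ADRecord",
    "YRandomizationResult",
    "q2_loo",
    "r2_prediction",
    "y_randomization",
    "warning_leverage",
    "williams_table",
    "plot_williams",
]


def q2_loo(X: pd.DataFrame, y: pd.Series,
           names: Sequence[str] | None = None) -> tuple[float, float]:
    """Leave-one-out Q² and RMS_CV for an OLS model on the named columns.

    Uses the hat-matrix shortcut (deleted residual e_i/(1−h_ii)), which is
    algebraically identical to refitting n times.
    """
    names = list(names if names is not None else X.columns)
    return q2_press(X, y, names)


def r2_prediction(model: LinearModel, X_val: pd.DataFrame,
                  y_val: pd.Series) -> float:
    """Squared Pearson correlation between predicted and observed activities.

    Being correlation-based it is sign-blind (predictions equal to the
    negated observations also give 1); NaN when either vector has zero
    variance.
    """
    if len(X_val) == 0:
        raise ValueError("validation set is empty")
    pred = model.predict(X_val).to_numpy(dtype=float)
    obs = y_val.loc[X_val.index].to_numpy(dtype=float)
    if np.std(pred) == 0 or np.std(obs) == 0:
        return float("nan")
    return float(np.corrcoef(pred, obs)[0, 1] ** 2)


@dataclass
class YRandomizationResult:
    """R²/Q²_LOO of models refitted on permuted activities."""

    table: pd.DataFrame          # iteration, r2, q2_loo
    original_r2: float
    original_q2: float
    all_below: bool


def y_randomization(X: pd.DataFrame, y: pd.Series, names: Sequence[str],
                    n_iter: int = 10, seed: int | None = None) -> YRandomizationResult:
    """Refit the fixed descriptor subset on permuted activity vectors.

    A robust model's calibration R² and Q²_LOO must exceed every permuted
    counterpart; ``all_below`` summarizes that check. The identity permutation
    is rejected and redrawn.
    """
    names = list(names)
    rng = np.random.default_rng(seed)
    orig = fit_ols(X, y, names)
    orig_q2, _ = q2_press(X, y, names)
    rows = []
    yv = y.loc[X.index].to_numpy(dtype=float)
    for it in range(1, n_iter + 1):
        perm = rng.permutation(len(yv))
        while np.array_equal(perm, np.arange(len(yv))):
            perm = rng.permutation(len(yv))
        yp = pd.Series(yv[perm], index=X.index)
        m = fit_ols(X, yp, names)
        q2, _ = q2_press(X, yp, names)
        rows.append({"iteration": it, "r2": m.r2, "q2_loo": q2})
    table = pd.DataFrame(rows, columns=["iteration", "r2", "q2_loo"])
    all_below = bool(len(table) == 0 or
                     ((table["r2"] < orig.r2) & (table["q2_loo"] < orig_q2)).all())
    return YRandomizationResult(table, orig.r2, orig_q2, all_below)


def warning_leverage(k: int, n: int) -> float:
    """Warning leverage h* = 3(k+1)/n for k descriptors and n calibration rows."""
    if n <= 0:
        raise ValueError("calibration size must be positive")
    return 3.0 * (k + 1) / n


@dataclass(frozen=True)
class ADRecord:
    """One Williams-plot row: leverage, standardized residual and flags."""

    compound_id: str
    set_label: str               # calibration | validation
    leverage: float
    std_residual: float
    response_outlier: bool       # |std residual| > residual_cut
    high_leverage: bool          # leverage > h*


def williams_table(model: LinearModel, X_cal: pd.DataFrame, y_cal: pd.Series,
                   X_val: pd.DataFrame | None = None,
                   y_val: pd.Series | None = None,
                   residual_cut: float = 2.0,
                   residual_scale: str = "se") -> pd.DataFrame:
    """Leverages and standardized residuals for the Williams plot.

    Leverage of a query row x_q is x_qᵀ(X_cᵀX_c)⁻¹x_q with X_c the
    intercept-augmented calibration matrix restricted to the model's
    descriptors. Residuals are standardized by the calibration residual
    standard error (``residual_scale="se"``) or by the per-point deleted
    standard error (``"deleted"``). Flags: ``response_outlier`` when
    |standardized residual| > ``residual_cut`` and ``high_leverage`` when
    leverage > h* = 3(k+1)/n.
    """
    names = model.names
    Zc = np.column_stack([np.ones(len(X_cal)), X_cal[names].to_numpy(dtype=float)])
    G = np.linalg.inv(Zc.T @ Zc)
    hstar = warning_leverage(len(names), len(X_cal))
    s = model.s_e

    def leverages(X: pd.DataFrame) -> np.ndarray:
        Z = np.column_stack([np.ones(len(X)), X[names].to_numpy(dtype=float)])
        return np.einsum("ij,jk,ik->i", Z, G, Z)

    rows = []
    for X, y, label in ((X_cal, y_cal, "calibration"), (X_val, y_val, "validation")):
        if X is None or len(X) == 0:
            continue
        h = leverages(X)
        resid = y.loc[X.index].to_numpy(dtype=float) - model.predict(X).to_numpy()
        if residual_scale == "se":
            std = resid / s
        elif residual_scale == "deleted":
            hh = np.clip(h, None, 1 - 1e-12) if label == "calibration" else np.zeros_like(h)
            std = resid / (s * np.sqrt(1.0 - hh)) if label == "calibration" else resid / s
        else:
            raise ValueError(f"unknown residual_scale {residual_scale!r}")
        for cid, hv, sr in zip(X.index, h, std):
            rows.append({
                "id": cid, "set": label,
                "leverage": float(hv), "std_residual": float(sr),
                "response_outlier": bool(abs(sr) > residual_cut),
                "high_leverage": bool(hv > hstar),
            })
    out = pd.DataFrame(rows)
    out.attrs["h_star"] = hstar
    out.attrs["k"] = len(names)
    out.attrs["n_calibration"] = len(X_cal)
    return out


def plot_williams(table: pd.DataFrame, path: str,
                  residual_cut: float = 2.0) -> None:
    """Scatter the Williams table to a PNG with h* and ±residual_cut lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for label, marker in (("calibration", "o"), ("validation", "s")):
        sub = table[table["set"] == label]
        ax.scatter(sub["leverage"], sub["std_residual"], marker=marker, label=label)
    hstar = table.attrs.get("h_star")
    if hstar is not None:
        ax.axvline(hstar, ls="--", color="k", lw=0.8)
    for yline in (-residual_cut, residual_cut):
        ax.axhline(yline, ls="--", color="k", lw=0.8)
    ax.set_xlabel("leverage h")
    ax.set_ylabel("standardized residual")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
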