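"""Descriptor-matrix cleanup and calibration/validation splitting.

The cleanup mirrors the standard QSAR workflow: drop constant and
near-constant columns, then resolve collinear descriptor pairs (|r| above a
cutoff) by keeping, in each pair, the member more correlated with the
activity. Splitting is a seeded uniform 80/20 draw by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FilterResult",
    "SplitResult",
    "drop_near_constant",
    "collinearity_filter",
    "split_calibration_validation",
]


@dataclass
class FilterResult:
    """A filtered descriptor matrix plus a removal log."""

    matrix: pd.DataFrame
    removed: list[dict] = field(default_factory=list)


@dataclass(frozen=True)
class SplitResult:
    """Disjoint calibration/validation row ids."""

    calibration_ids: tuple
    validation_ids: tuple
    seed: int | None

    def __post_init__(self) -> None:
        if set(self.calibration_ids) & set(self.validation_ids):
            raise ValueError("calibration and validation sets overlap")


def drop_near_constant(X: pd.DataFrame, min_unique_fraction: float = 0.1,
                       min_sd: float = 1e-8) -> FilterResult:
    """Remove constant and near-constant descriptor columns.

    A column is dropped when it contains missing values, its standard
    deviation is below ``min_sd``, or its most frequent value covers more
    than ``1 − min_unique_fraction`` of the rows. The defaults (sd 1e-8,
    frequency 0.9) encode "near constant" since no numeric threshold is
    standard.
    """
    removed = []
    keep = []
    n = len(X)
    freq_cut = 1.0 - min_unique_fraction
    for col in X.columns:
        v = X[col].to_numpy(dtype=float)
        if np.isnan(v).any():
            removed.append({"column": col, "reason": "missing_values"})
            continue
        if np.std(v) < min_sd:
            removed.append({"column": col, "reason": "constant"})
            continue
        top = pd.Series(v).value_counts().iloc[0]
        if top / n > freq_cut:
            removed.append({"column": col, "reason": "near_constant"})
            continue
        keep.append(col)
    if not keep:
        raise ValueError("all descriptor columns were removed as (near-)constant")
    return FilterResult(X[keep].copy(), removed)


def collinearity_filter(X: pd.DataFrame, y: pd.Series,
                        r_cut: float = 0.9) -> FilterResult:
    """Resolve collinear descriptor pairs against the activity.

    Pairs with |Pearson r| > ``r_cut`` are visited in descending |r|; in each
    pair the member with the lower |corr(·, y)| is dropped (ties keep the
    earlier column). After the pass no surviving pair exceeds the cutoff.
    """
    y = y.loc[X.index]
    cols = list(X.columns)
    vals = X.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(vals, rowvar=False)
        y_corr = np.abs(np.array([
            np.corrcoef(vals[:, k], y.to_numpy(dtype=float))[0, 1]
            for k in range(len(cols))
        ]))
    y_corr = np.nan_to_num(y_corr)
    corr = np.nan_to_num(corr)
    iu = np.triu_indices(len(cols), k=1)
    strengths = np.abs(corr[iu])
    order = np.argsort(-strengths, kind="stable")
    dropped: set[int] = set()
    removed = []
    for idx in order:
        if strengths[idx] <= r_cut:
            break
        a, b = iu[0][idx], iu[1][idx]
        if a in dropped or b in dropped:
            continue
        # keep the member more correlated with the activity; tie -> earlier column
        loser = b if y_corr[a] >= y_corr[b] else a
        winner = a + b - loser
        dropped.add(loser)
        removed.append({
            "column": cols[loser],
            "reason": "collinear",
            "pair_r": float(corr[a, b]),
            "kept": cols[winner],
        })
    keep = [c for k, c in enumerate(cols) if k not in dropped]
    return FilterResult(X[keep].copy(), removed)


def split_calibration_validation(X: pd.DataFrame, y: pd.Series | None = None,
                                 validation_fraction: float = 0.2,
                                 seed: int | None = None,
                                 mode: str = "random") -> SplitResult:
    """Seeded split into calibration and validation rows.

    ``random`` draws round(fraction × n) validation rows uniformly without
    replacement. ``systematic`` sorts rows by activity and takes every k-th
    row into validation, a deterministic alternative for reproducibility
    studies.
    """
    if not 0.0 < validation_fraction < 1.0:
        raise ValueError("validation_fraction must be in (0, 1)")
    ids = list(X.index)
    n = len(ids)
    n_val = int(round(validation_fraction * n))
    if n - n_val < 1:
        raise ValueError("split leaves an empty calibration set")
    if mode == "random":
        rng = np.random.default_rng(seed)
        val_pos = sorted(rng.choice(n, size=n_val, replace=False).tolist())
    elif mode == "systematic":
        if y is None:
            raise ValueError("systematic mode needs the activity vector")
        ranked = np.argsort(y.loc[ids].to_numpy(dtype=float), kind="stable")
        step = max(1, n // max(n_val, 1))
        val_pos = sorted(ranked[1::step][:n_val].tolist())
    else:
        raise ValueError(f"unknown split mode {mode!r}")
    val = tuple(ids[k] for k in val_pos)
    cal = tuple(i for i in ids if i not in set(val))
    return SplitResult(cal, val, seed)
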