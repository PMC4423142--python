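"""Ordinary least squares, stepwise descriptor selection, and the combined
data splitting–feature selection (CDFS) strategy.

CDFS addresses the instability of a single calibration/validation split on a
30-compound dataset: the data are re-split several times (10 by default), a
stepwise MLR model is built on each calibration part, the well-fitting models
are pooled into a descriptor union, and a final stepwise pass restricted to
that union yields the general model — chosen, among the nested models visited,
as the one with the highest leave-one-out Q² (ties broken toward fewer
descriptors).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import SplitResult, split_calibration_validation

__all__ = [
    "LinearModel",
    "CDFSResult",
    "fit_ols",
    "stepwise_mlr",
    "cdfs_general_model",
]


@dataclass
class LinearModel:
    """A fitted MLR model: descriptor subset, coefficients and statistics.

    ``s_e`` is the calibration residual standard error sqrt(RSS/(n−p−1));
    cross-validation statistics (q2_loo, rms_cv) and the external-prediction
    correlation r2_p are attached by the validation routines.
    """

    names: list[str]
    coef: np.ndarray
    intercept: float
    coef_se: np.ndarray
    intercept_se: float
    n: int
    r2: float
    s_e: float
    q2_loo: float | None = None
    rms_cv: float | None = None
    r2_p: float | None = None
    warning: str | None = None

    @property
    def k(self) -> int:
        return len(self.names)

    def predict(self, X: pd.DataFrame) -> pd.Series:
        missing = [c for c in self.names if c not in X.columns]
        if missing:
            raise KeyError(f"missing descriptor columns: {missing}")
        vals = X[self.names].to_numpy(dtype=float) if self.names else np.zeros((len(X), 0))
        return pd.Series(vals @ self.coef + self.intercept, index=X.index)

    def to_json(self) -> str:
        d = asdict(self)
        d["coef"] = list(map(float, self.coef))
        d["coef_se"] = list(map(float, self.coef_se))
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "LinearModel":
        d = json.loads(text)
        d["coef"] = np.asarray(d["coef"], dtype=float)
        d["coef_se"] = np.asarray(d["coef_se"], dtype=float)
        return cls(**d)


def _design(X: pd.DataFrame, names: Sequence[str]) -> np.ndarray:
    cols = X[list(names)].to_numpy(dtype=float) if names else np.zeros((len(X), 0))
    return np.column_stack([np.ones(len(X)), cols])


def fit_ols(X: pd.DataFrame, y: pd.Series, names: Sequence[str] | None = None) -> LinearModel:
    """Least-squares fit of y on the named descriptor columns (with intercept).

    Raises on rank deficiency. With an empty subset the intercept-only model
    (R² = 0) is returned.
    """
    names = list(names if names is not None else X.columns)
    yv = y.loc[X.index].to_numpy(dtype=float)
    Z = _design(X, names)
    n, p1 = Z.shape
    if n <= p1 and names:
        raise ValueError(f"need more rows ({n}) than parameters ({p1})")
    if np.linalg.matrix_rank(Z) < p1:
        raise ValueError("design matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(Z, yv, rcond=None)
    resid = yv - Z @ beta
    rss = float(resid @ resid)
    tss = float(np.sum((yv - yv.mean()) ** 2))
    dof = n - p1
    sigma2 = rss / dof if dof > 0 else np.nan
    se = np.sqrt(np.diag(np.linalg.inv(Z.T @ Z)) * sigma2) if dof > 0 else np.full(p1, np.nan)
    return LinearModel(
        names=names,
        coef=beta[1:].copy(),
        intercept=float(beta[0]),
        coef_se=se[1:].copy(),
        intercept_se=float(se[0]),
        n=n,
        r2=1.0 - rss / tss if tss > 0 else np.nan,
        s_e=float(np.sqrt(sigma2)) if dof > 0 else np.nan,
    )


def q2_press(X: pd.DataFrame, y: pd.Series, names: Sequence[str]) -> tuple[float, float]:
    """Leave-one-out Q² and RMS_CV via the hat-matrix shortcut.

    For OLS the deleted residual is e_i/(1 − h_ii), so PRESS needs a single
    fit. Q² = 1 − PRESS/Σ(y − ȳ)², RMS_CV = sqrt(PRESS/n).
    """
    yv = y.loc[X.index].to_numpy(dtype=float)
    Z = _design(X, list(names))
    n, p1 = Z.shape
    if np.linalg.matrix_rank(Z) < p1:
        raise ValueError("design matrix is rank deficient")
    G = np.linalg.inv(Z.T @ Z)
    H = Z @ G @ Z.T
    h = np.diag(H)
    resid = yv - H @ yv
    if np.any(1.0 - h <= 1e-12):
        raise ValueError("a leave-one-out fold is singular (leverage 1)")
    press = float(np.sum((resid / (1.0 - h)) ** 2))
    tss = float(np.sum((yv - yv.mean()) ** 2))
    return 1.0 - press / tss, float(np.sqrt(press / n))


# ---------------------------------------------------------------------------
# stepwise selection
# ---------------------------------------------------------------------------

def _forward_pvalues(X: pd.DataFrame, y: np.ndarray, selected: list[str]) -> pd.Series:
    """Partial-F p-values for adding each remaining candidate to the model.

    Computed by projecting y and every candidate out of the current design
    (QR), then converting the residual correlation to the add-one F test —
    identical to the t-test on the new coefficient, but vectorized.
    """
    Z = _design(X, selected)
    n = Z.shape[0]
    Q, _ = np.linalg.qr(Z)
    ry = y - Q @ (Q.T @ y)
    cand = [c for c in X.columns if c not in selected]
    C = X[cand].to_numpy(dtype=float)
    RC = C - Q @ (Q.T @ C)
    norm_c = np.linalg.norm(RC, axis=0)
    norm_y = np.linalg.norm(ry)
    df2 = n - len(selected) - 2
    pvals = np.ones(len(cand))
    if df2 > 0 and norm_y > 0:
        ok = norm_c > 1e-10 * np.sqrt(n)
        r = np.zeros(len(cand))
        r[ok] = (RC[:, ok].T @ ry) / (norm_c[ok] * norm_y)
        r = np.clip(r, -1.0, 1.0)
        with np.errstate(divide="ignore"):
            F = r**2 * df2 / (1.0 - r**2)
        pvals[ok] = stats.f.sf(F[ok], 1, df2)
    return pd.Series(pvals, index=cand)


def stepwise_mlr(X: pd.DataFrame, y: pd.Series,
                 p_enter: float = 0.05, p_remove: float = 0.10,
                 max_terms: int | None = None,
                 return_path: bool = False):
    """Classic forward-entry / backward-removal stepwise MLR.

    At each cycle the candidate with the smallest partial-F p-value below
    ``p_enter`` is added (ties: earlier column), then any included term whose
    removal p-value exceeds ``p_remove`` is dropped (largest first). Stops at
    a fixed point or ``max_terms`` (default n/5, the usual rule of thumb for
    small QSAR calibration sets). With ``return_path`` the sequence of visited
    subsets is returned alongside the final model.
    """
    if len(X) <= 3:
        raise ValueError("stepwise needs more than 3 rows")
    yv = y.loc[X.index].to_numpy(dtype=float)
    if max_terms is None:
        max_terms = max(1, round(len(X) / 5))
    selected: list[str] = []
    path: list[list[str]] = []
    seen: set[tuple[str, ...]] = set()
    warning = None
    for _ in range(10 * len(X.columns)):
        changed = False
        if len(selected) < max_terms:
            pvals = _forward_pvalues(X, yv, selected)
            if len(pvals) and pvals.min() < p_enter:
                selected.append(pvals.idxmin())
                changed = True
        # backward sweep
        while len(selected) > 0:
            model = fit_ols(X, pd.Series(yv, index=X.index), selected)
            t = model.coef / model.coef_se
            df = model.n - model.k - 1
            p = 2.0 * stats.t.sf(np.abs(t), df)
            worst = int(np.argmax(p))
            if p[worst] > p_remove:
                selected.pop(worst)
                changed = True
            else:
                break
        key = tuple(selected)
        if key not in seen:
            seen.add(key)
            path.append(list(selected))
        if not changed:
            break
    if not selected:
        warning = "no candidate met the entry threshold; intercept-only model"
    model = fit_ols(X, pd.Series(yv, index=X.index), selected)
    model.warning = warning
    if return_path:
        return model, path
    return model


# ---------------------------------------------------------------------------
# CDFS
# ---------------------------------------------------------------------------

@dataclass
class CDFSResult:
    """Per-split models, the pooled descriptor union and the general model."""

    split_models: list[LinearModel]
    split_results: list[SplitResult]
    retained: list[bool]
    pooled_descriptors: list[str]
    general_model: LinearModel
    general_split: SplitResult
    seed: int | None
    split_seeds: list[int] = field(default_factory=list)

    def report_table(self) -> pd.DataFrame:
        """Per-split model summary (descriptors, R²_c, S.E, R²_p, Q²_LOO, RMS_CV)."""
        rows = []
        for i, (m, kept) in enumerate(zip(self.split_models, self.retained), start=1):
            rows.append({
                "split": i,
                "descriptors": ", ".join(m.names),
                "R2_c": m.r2,
                "SE": m.s_e,
                "R2_p": m.r2_p,
                "Q2_LOO": m.q2_loo,
                "RMS_CV": m.rms_cv,
                "retained": kept,
            })
        return pd.DataFrame(rows)


def cdfs_general_model(X: pd.DataFrame, y: pd.Series,
                       n_splits: int = 10, keep_threshold: float = 0.95,
                       validation_fraction: float = 0.2,
                       seed: int | None = None,
                       p_enter: float = 0.05, p_remove: float = 0.10,
                       max_terms: int | None = None,
                       threshold_on: str = "r2") -> CDFSResult:
    """Combined data splitting–feature selection.

    For each of ``n_splits`` seeded 80/20 splits a stepwise model is fitted on
    the calibration part and retained when its calibration fit exceeds
    ``keep_threshold`` (``threshold_on`` = ``"r2"`` compares R²_c, ``"r"``
    compares R). Retained models' descriptors are pooled; a final stepwise run
    restricted to the pool on a fresh seeded split yields candidate nested
    models. Every candidate the procedure has visited — the final stepwise
    path and the retained per-split models (all subsets of the pool) — is
    scored by Q²_LOO on the designated calibration, and the maximizer (ties:
    fewer descriptors) becomes the general model. Scoring the retained models
    too guards against a single unlucky greedy path on the designated split.
    """
    from .validation import r2_prediction

    if threshold_on not in ("r2", "r"):
        raise ValueError("threshold_on must be 'r2' or 'r'")
    rng = np.random.default_rng(seed)
    split_seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=n_splits + 1)]
    split_models, split_results, retained = [], [], []
    pooled: list[str] = []
    retained_subsets: list[list[str]] = []
    for s in split_seeds[:-1]:
        split = split_calibration_validation(X, y, validation_fraction, seed=s)
        Xc, yc = X.loc[list(split.calibration_ids)], y.loc[list(split.calibration_ids)]
        model = stepwise_mlr(Xc, yc, p_enter, p_remove, max_terms)
        if model.names:
            model.q2_loo, model.rms_cv = q2_press(Xc, yc, model.names)
            model.r2_p = r2_prediction(model, X.loc[list(split.validation_ids)],
                                       y.loc[list(split.validation_ids)])
        stat = model.r2 if threshold_on == "r2" else np.sqrt(max(model.r2, 0.0))
        keep = bool(model.names) and stat > keep_threshold
        split_models.append(model)
        split_results.append(split)
        retained.append(keep)
        if keep:
            pooled.extend(n for n in model.names if n not in pooled)
            retained_subsets.append(list(model.names))
    if not any(retained):
        raise ValueError(
            f"no split produced a model with calibration fit above {keep_threshold}; "
            "consider relaxing keep_threshold")
    # final stepwise restricted to the pooled union, on a designated fresh split
    final_split = split_calibration_validation(X, y, validation_fraction,
                                               seed=split_seeds[-1])
    Xc = X.loc[list(final_split.calibration_ids), pooled]
    yc = y.loc[list(final_split.calibration_ids)]
    _, path = stepwise_mlr(Xc, yc, p_enter, p_remove, max_terms, return_path=True)
    candidates = list(dict.fromkeys(
        tuple(sorted(s)) for s in path + retained_subsets if s))
    best, best_key = None, None
    for subset in candidates:
        subset = list(subset)
        q2, rms = q2_press(Xc, yc, subset)
        key = (q2, -len(subset))
        if best_key is None or key > best_key:
            m = fit_ols(Xc, yc, subset)
            m.q2_loo, m.rms_cv = q2, rms
            best, best_key = m, key
    if best is None:
        raise ValueError("final stepwise selected no descriptors from the pooled set")
    best.r2_p = r2_prediction(best, X.loc[list(final_split.validation_ids)],
                              y.loc[list(final_split.validation_ids)])
    assert set(best.names) <= set(pooled)
    return CDFSResult(split_models, split_results, retained, pooled, best,
                      final_split, seed, split_seeds)
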