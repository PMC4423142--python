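"""Synthetic inputs with the statistical structure the analysis assumes.

Two generators cover the pipeline's needs without any external data:

* :func:`make_regression_dataset` — a descriptor matrix with correlated
  column blocks (to exercise the collinearity filter) and a sparse linear
  activity signal with known support, emulating a 30-compound × few-hundred-
  descriptor post-filter matrix.
* :func:`make_point_cloud_molecule` — small pseudo-molecules (random 3D point
  clouds joined by a random spanning tree) as descriptor unit-test substrate.

:func:`make_qsar_bundle` is the canonical end-to-end fixture: n=30, p=291,
5-descriptor truth at signal-to-noise ratio 10, with a 24/6 split. All
generators are byte-reproducible from their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .molecule import Atom, Molecule, default_property_table
from .preprocess import SplitResult, split_calibration_validation

__all__ = [
    "SyntheticBundle",
    "make_regression_dataset",
    "make_point_cloud_molecule",
    "make_qsar_bundle",
]


@dataclass
class SyntheticBundle:
    """A descriptor matrix, activity vector and the generating truth."""

    X: pd.DataFrame
    y: pd.Series
    support: list[str]
    beta: np.ndarray
    intercept: float
    noise_sd: float
    seed: int | None


def _qsar_names(p: int) -> list[str]:
    """Canonical-style descriptor names (MoRSE then RDF grids) for synthetic columns."""
    names = []
    for w in "umepv":
        for k in range(1, 33):
            names.append(f"Mor{k:02d}{w}")
    for w in "umepv":
        for r in range(10, 156, 5):
            names.append(f"RDF{r:03d}{w}")
    if p > len(names):
        raise ValueError(f"at most {len(names)} synthetic columns supported")
    return names[:p]


def make_regression_dataset(n: int = 30, p: int = 291, k_true: int = 5,
                            beta_range: tuple[float, float] = (1.0, 5.0),
                            noise_sd: float | None = None,
                            snr: float = 10.0,
                            n_collinear_blocks: int = 5,
                            block_size: int = 4,
                            block_rho: float = 0.95,
                            intercept: float = 5.5,
                            seed: int | None = None) -> SyntheticBundle:
    """Sparse linear regression data with correlated descriptor blocks.

    The first ``n_collinear_blocks`` groups of ``block_size`` columns share a
    latent factor giving pairwise correlation ≈ ``block_rho``; the true
    support is drawn outside the blocks. Coefficient magnitudes follow a
    geometric cascade from max(beta_range) down to min(beta_range), with
    random signs: one dominant descriptor plus progressively weaker
    refinements, the structure real QSAR activities show (one lead descriptor
    carries most of the variance). ``noise_sd`` defaults to
    sd(signal)/``snr``.
    """
    if k_true > p:
        raise ValueError("k_true cannot exceed p")
    if not 0.0 <= block_rho < 1.0:
        raise ValueError("block_rho must be in [0, 1)")
    n_block_cols = n_collinear_blocks * block_size
    if n_block_cols > p:
        raise ValueError("collinear blocks exceed the number of columns")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    for b in range(n_collinear_blocks):
        factor = rng.standard_normal(n)
        sl = slice(b * block_size, (b + 1) * block_size)
        X[:, sl] = (np.sqrt(block_rho) * factor[:, None]
                    + np.sqrt(1.0 - block_rho) * X[:, sl])
    names = _qsar_names(p)
    support_idx = sorted(rng.choice(np.arange(n_block_cols, p), size=k_true,
                                    replace=False).tolist())
    beta = (np.geomspace(max(beta_range), min(beta_range), k_true)
            * rng.choice([-1.0, 1.0], size=k_true))
    signal = X[:, support_idx] @ beta
    if noise_sd is None:
        noise_sd = float(np.std(signal) / snr) if k_true else 0.0
    y = intercept + signal + rng.normal(0.0, noise_sd, size=n)
    ids = pd.Index([f"c{i + 1:02d}" for i in range(n)], name="id")
    frame = pd.DataFrame(X, index=ids, columns=names)
    return SyntheticBundle(frame, pd.Series(y, index=ids, name="pic50"),
                           [names[k] for k in support_idx], beta,
                           intercept, noise_sd, seed)


def make_point_cloud_molecule(n_atoms: int = 8,
                              elements: tuple[str, ...] = ("C", "N", "O", "H", "S"),
                              box: float = 5.0,
                              seed: int | None = None) -> Molecule:
    """A random 3D point cloud joined into a random spanning tree.

    The tree guarantees a connected bond graph so every topological lag is
    defined; elements are drawn uniformly from ``elements``.
    """
    if n_atoms < 2:
        raise ValueError("need at least 2 atoms")
    rng = np.random.default_rng(seed)
    table = default_property_table()
    coords = rng.uniform(0.0, box, size=(n_atoms, 3))
    symbols = rng.choice(elements, size=n_atoms)
    atoms = [Atom(str(s), table.atomic_number(str(s)), c)
             for s, c in zip(symbols, coords)]
    # uniform-ish random tree: attach node i to a random earlier node
    bonds = [(int(rng.integers(0, i)), i, 1.0) for i in range(1, n_atoms)]
    return Molecule(f"cloud{seed}", atoms, bonds)


def make_qsar_bundle(seed: int | None = 0) -> tuple[SyntheticBundle, SplitResult]:
    """The canonical n=30, p=291 bundle with a 24/6 calibration/validation split."""
    bundle = make_regression_dataset(n=30, p=291, k_true=5, snr=10.0, seed=seed)
    split = split_calibration_validation(bundle.X, bundle.y,
                                         validation_fraction=0.2, seed=seed)
    return bundle, split
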