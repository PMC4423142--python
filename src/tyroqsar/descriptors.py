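"""Molecular descriptors used by the MMP-2 inhibitor QSAR models.

Implements the named descriptor families that survived into the published
models: first-order information content (IC1), 3D-MoRSE signals, radial
distribution function (RDF) values, Geary topological autocorrelation (GATS),
WHIM directional indices (size L, symmetry G, accessibility E), GETAWAY
leverage autocorrelations (HATS, R, R-maximal), Randic-style shape profiles
(SP), and the PM3-derived quantum indices (hardness, softness,
electronegativity, electrophilicity) plus the dipole x-component.

Naming follows the DRAGON catalogue: ``Mor24m`` is 3D-MoRSE signal 24 weighted
by atomic mass, ``RDF115e`` the RDF at 11.5 Å weighted by Sanderson
electronegativity, ``GATS8p`` the Geary coefficient at topological lag 8
weighted by polarizability, ``G3p``/``E3u`` WHIM components, ``HATS3p`` and
``R7e0`` GETAWAY autocorrelations, ``SP20`` the 20th shape profile. Canonical
names parse bijectively back to (family, index, weight).

Undefined values (zero weight variance, empty lag, zero hardness) propagate as
NaN so that downstream filtering can treat the column as near-constant rather
than silently reading a zero.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .molecule import (
    AtomPropertyTable,
    Molecule,
    QuantumRecord,
    carbon_scaled_weights,
    geom_distance_matrix,
    topo_distance_matrix,
)

__all__ = [
    "DescriptorSpec",
    "QuantumIndices",
    "parse_descriptor_name",
    "ic1",
    "morse_signal",
    "rdf_value",
    "gats",
    "molecular_influence_leverages",
    "getaway_autocorr",
    "whim_set",
    "shape_profile",
    "quantum_indices",
    "compute_descriptor",
    "build_descriptor_table",
    "PUBLISHED_DESCRIPTORS",
    "RDF_SMOOTHING_DEFAULT",
]

#: Gaussian smoothing parameter B (Å⁻²) for RDF descriptors
RDF_SMOOTHING_DEFAULT = 100.0

#: the 26 descriptors appearing across the published models and final equations
PUBLISHED_DESCRIPTORS = [
    "IC1", "RDF135e", "Mor24m", "RDF035u", "E3u", "RDF120m", "Mor15e",
    "G3p", "R7e0", "dipx", "GATS8p", "RDF065m", "SP20", "Mor28e", "Mor09e",
    "G2u", "Mor27u", "RDF115m", "RDF115e", "HATS3p", "G3m", "Mor26m",
    "Mor32e", "RDF035v", "RDF135m", "HATS7e",
]


@dataclass(frozen=True)
class DescriptorSpec:
    """A parsed descriptor name: family, integer index and weight scheme."""

    family: str            # IC | MoRSE | RDF | WHIM_L | WHIM_G | WHIM_E | GATS | HATS | R | Rmax | SP | quantum | dipole
    index: int             # order / signal / radius*10 / lag / component / k
    weight: str | None     # u m e p v, or None for weight-free families
    name: str

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.name


_PATTERNS: list[tuple[re.Pattern, str]] = [
    (re.compile(r"^IC(\d)$"), "IC"),
    (re.compile(r"^Mor(\d{2})([umepv])$"), "MoRSE"),
    (re.compile(r"^RDF(\d{3})([umepv])$"), "RDF"),
    (re.compile(r"^GATS(\d+)([umepv])$"), "GATS"),
    (re.compile(r"^HATS(\d+)([umepv])$"), "HATS"),
    (re.compile(r"^R(\d+)([umepv])0$"), "Rmax"),
    (re.compile(r"^R(\d+)([umepv])$"), "R"),
    (re.compile(r"^SP(\d{2})$"), "SP"),
    (re.compile(r"^L([123])([umepv])$"), "WHIM_L"),
    (re.compile(r"^G([123])([umepv])$"), "WHIM_G"),
    (re.compile(r"^E([123])([umepv])$"), "WHIM_E"),
]

_QUANTUM_NAMES = {"eta": 0, "softness": 1, "chi": 2, "omega": 3}
_DIPOLE_NAMES = {"dipx": 0, "dipy": 1, "dipz": 2}


def parse_descriptor_name(name: str) -> DescriptorSpec:
    """Parse a canonical descriptor name into a :class:`DescriptorSpec`.

    Raises ValueError for names outside the implemented catalogue.
    """
    if name in _DIPOLE_NAMES:
        return DescriptorSpec("dipole", _DIPOLE_NAMES[name], None, name)
    if name in _QUANTUM_NAMES:
        return DescriptorSpec("quantum", _QUANTUM_NAMES[name], None, name)
    for pattern, family in _PATTERNS:
        m = pattern.match(name)
        if m:
            groups = m.groups()
            index = int(groups[0])
            weight = groups[1] if len(groups) > 1 else None
            if family == "MoRSE" and not 1 <= index <= 32:
                raise ValueError(f"MoRSE signal out of range in {name!r} (1..32)")
            return DescriptorSpec(family, index, weight, name)
    raise ValueError(f"unknown descriptor name {name!r}")


@dataclass(frozen=True)
class QuantumIndices:
    """Conceptual-DFT style reactivity indices derived from E_HOMO/E_LUMO."""

    eta: float       # hardness
    softness: float  # 1/eta
    chi: float       # electronegativity
    omega: float     # electrophilicity chi^2 / (2 eta)


def quantum_indices(q: QuantumRecord, convention: str = "as_printed") -> QuantumIndices:
    """Hardness, softness, electronegativity and electrophilicity.

    ``as_printed`` uses η = ½(E_HOMO + E_LUMO) and χ = ½(E_HOMO − E_LUMO);
    ``textbook`` uses the conventional η = ½(E_LUMO − E_HOMO) and
    χ = −½(E_HOMO + E_LUMO). In both, S = 1/η and ω = χ²/(2η); S and ω are
    NaN when η = 0.
    """
    if convention == "as_printed":
        eta = 0.5 * (q.e_homo + q.e_lumo)
        chi = 0.5 * (q.e_homo - q.e_lumo)
    elif convention == "textbook":
        eta = 0.5 * (q.e_lumo - q.e_homo)
        chi = -0.5 * (q.e_homo + q.e_lumo)
    else:
        raise ValueError(f"unknown convention {convention!r}")
    if eta == 0:
        return QuantumIndices(eta, math.nan, chi, math.nan)
    return QuantumIndices(eta, 1.0 / eta, chi, chi * chi / (2.0 * eta))


# ---------------------------------------------------------------------------
# topological information content
# ---------------------------------------------------------------------------

def ic1(mol: Molecule) -> float:
    """First-order neighborhood-symmetry information content, in bits.

    Atoms are partitioned into equivalence classes by (atomic number, degree,
    multiset of neighbor (atomic number, bond order)); IC1 is the Shannon
    entropy of the class-size distribution. It grows with molecular size and
    branching heterogeneity, which is why it dominates the activity models.
    """
    if mol.n_atoms == 0:
        raise ValueError("IC1 undefined for an atom-free molecule")
    neighbors: list[list[tuple[int, float]]] = [[] for _ in range(mol.n_atoms)]
    for i, j, order in mol.bonds:
        neighbors[i].append((mol.atoms[j].atomic_number, order))
        neighbors[j].append((mol.atoms[i].atomic_number, order))
    keys = [
        (mol.atoms[i].atomic_number, len(neighbors[i]), tuple(sorted(neighbors[i])))
        for i in range(mol.n_atoms)
    ]
    counts = Counter(keys)
    n = mol.n_atoms
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


# ---------------------------------------------------------------------------
# geometry-based pairwise descriptors
# ---------------------------------------------------------------------------

def _pair_arrays(mol: Molecule, weight: str, table: AtomPropertyTable | None):
    w = carbon_scaled_weights(mol, weight, table)
    dist = geom_distance_matrix(mol)
    iu = np.triu_indices(mol.n_atoms, k=1)
    return w[iu[0]] * w[iu[1]], dist[iu]


def morse_signal(mol: Molecule, signal: int, weight: str = "u",
                 table: AtomPropertyTable | None = None) -> float:
    """3D-MoRSE descriptor: Σ_{i<j} w_i w_j sin(s r_ij)/(s r_ij).

    Signal k maps to the scattering parameter s = k − 1 Å⁻¹ (the 32-signal
    catalogue spans s = 0 … 31), so signal 1 reduces to the weighted pair
    count.
    """
    if not 1 <= signal <= 32:
        raise ValueError("MoRSE signal must be in 1..32")
    s = float(signal - 1)
    ww, r = _pair_arrays(mol, weight, table)
    if r.size == 0:
        return 0.0
    x = s * r
    with np.errstate(invalid="ignore", divide="ignore"):
        sinc = np.where(x == 0.0, 1.0, np.sin(x) / x)
    return float(np.sum(ww * sinc))


def rdf_value(mol: Molecule, radius: float, weight: str = "u",
              smoothing: float = RDF_SMOOTHING_DEFAULT,
              table: AtomPropertyTable | None = None) -> float:
    """Radial distribution function: Σ_{i<j} w_i w_j exp(−B (R − r_ij)²)."""
    if radius <= 0 or smoothing <= 0:
        raise ValueError("radius and smoothing must be positive")
    ww, r = _pair_arrays(mol, weight, table)
    if r.size == 0:
        return 0.0
    return float(np.sum(ww * np.exp(-smoothing * (radius - r) ** 2)))


def gats(mol: Molecule, lag: int, weight: str = "u",
         table: AtomPropertyTable | None = None) -> float:
    """Geary autocorrelation of an atomic property at a topological lag.

    c(lag) = [(n−1) Σ_{d_ij=lag} (w_i − w_j)²] / [2 Δ Σ_i (w_i − w̄)²] with
    sums over ordered pairs and Δ the ordered-pair count at the lag. NaN when
    no pair sits at the lag or the weights have zero variance.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    w = carbon_scaled_weights(mol, weight, table)
    n = mol.n_atoms
    denom_var = np.sum((w - w.mean()) ** 2)
    topo = topo_distance_matrix(mol)
    mask = topo == lag
    delta = int(mask.sum())  # ordered pairs (matrix is symmetric)
    if delta == 0 or denom_var == 0:
        return math.nan
    diffs = (w[:, None] - w[None, :]) ** 2
    num = (n - 1) * float(diffs[mask].sum())
    return num / (2.0 * delta * float(denom_var))


# ---------------------------------------------------------------------------
# GETAWAY: molecular influence matrix and leverage autocorrelations
# ---------------------------------------------------------------------------

def molecular_influence_leverages(mol: Molecule) -> np.ndarray:
    """Diagonal of the molecular influence (hat) matrix of centered coordinates.

    h = diag(M (MᵀM)⁻¹ Mᵀ) with M the centered n×3 coordinate matrix; the
    pseudo-inverse handles planar or linear geometries, so Σ h_i equals the
    coordinate rank (3, 2 or 1).
    """
    M = mol.coords - mol.coords.mean(axis=0)
    if np.allclose(M, 0.0):
        raise ValueError("all atoms coincident: influence matrix undefined")
    h = np.einsum("ij,jk,ik->i", M, np.linalg.pinv(M.T @ M), M)
    return h


def getaway_autocorr(mol: Molecule, lag: int, weight: str = "u",
                     kind: str = "HATS",
                     table: AtomPropertyTable | None = None) -> float:
    """GETAWAY autocorrelation over atom pairs at a topological lag.

    ``HATS``: Σ (w_i √h_i)(w_j √h_j); ``R``: Σ (√(h_i h_j)/r_ij) w_i w_j;
    ``Rmax``: the largest single R summand. Sums run over unordered pairs
    whose bond-graph distance equals ``lag``; an empty pair set gives 0.
    """
    if kind not in ("HATS", "R", "Rmax"):
        raise ValueError(f"unknown GETAWAY kind {kind!r}")
    h = molecular_influence_leverages(mol)
    w = carbon_scaled_weights(mol, weight, table)
    topo = topo_distance_matrix(mol)
    geom = geom_distance_matrix(mol)
    iu = np.triu_indices(mol.n_atoms, k=1)
    at_lag = topo[iu] == lag
    if not np.any(at_lag):
        return 0.0
    i_idx, j_idx = iu[0][at_lag], iu[1][at_lag]
    if kind == "HATS":
        terms = (w[i_idx] * np.sqrt(h[i_idx])) * (w[j_idx] * np.sqrt(h[j_idx]))
        return float(terms.sum())
    r = geom[i_idx, j_idx]
    if np.any(r == 0):
        raise ValueError("coincident atoms at the requested lag: R undefined")
    terms = np.sqrt(h[i_idx] * h[j_idx]) / r * (w[i_idx] * w[j_idx])
    return float(terms.max() if kind == "Rmax" else terms.sum())


# ---------------------------------------------------------------------------
# WHIM
# ---------------------------------------------------------------------------

def whim_set(mol: Molecule, weight: str = "u",
             table: AtomPropertyTable | None = None,
             symmetry_tol: float = 1e-4) -> dict[str, float]:
    """Directional WHIM indices {L1..3, G1..3, E1..3} for one weighting scheme.

    Eigen-decompose the weighted covariance of centered coordinates (weights
    normalized to sum 1). L_m are the eigenvalues in descending order (size),
    E_m = L_m² n / Σ_i t_im⁴ an inverse-kurtosis accessibility index of the
    scores t_im, and G_m a symmetry index in (0, 1]: with n_s the number of
    atoms having a counterpart at −t_im (or lying on the plane) within
    ``symmetry_tol`` × the score scale, and n_a = n − n_s,

        G_m = [1 − ((n_s/n) log2(n_s/n) + (n_a/n) log2(1/n))]⁻¹,

    which equals 1 exactly when every atom is matched.
    """
    n = mol.n_atoms
    if n < 2:
        raise ValueError("WHIM needs at least 2 atoms")
    w = carbon_scaled_weights(mol, weight, table)
    w = w / w.sum()
    xyz = mol.coords
    center = (w[:, None] * xyz).sum(axis=0)
    X = xyz - center
    if np.allclose(X, 0.0):
        raise ValueError("all atoms coincident: WHIM undefined")
    cov = (w[:, None] * X).T @ X
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0.0, None)
    scores = X @ evecs
    out: dict[str, float] = {}
    for m in range(3):
        t = scores[:, m]
        L = float(evals[m])
        out[f"L{m + 1}"] = L
        quart = float(np.sum(t ** 4))
        out[f"E{m + 1}"] = (L * L * n / quart) if quart > 0 else 0.0
        out[f"G{m + 1}"] = _whim_symmetry(t, symmetry_tol)
    return out


def _whim_symmetry(t: np.ndarray, rel_tol: float) -> float:
    n = t.size
    tol = rel_tol * max(1.0, float(np.max(np.abs(t))))
    matched = 0
    for i in range(n):
        if abs(t[i]) <= tol:
            matched += 1
            continue
        if np.any(np.abs(t + t[i]) <= tol):
            matched += 1
    n_s, n_a = matched, n - matched
    if n_a == 0:
        return 1.0
    acc = (n_s / n) * math.log2(n_s / n) if n_s else 0.0
    acc += (n_a / n) * math.log2(1.0 / n)
    return 1.0 / (1.0 - acc)


# ---------------------------------------------------------------------------
# shape profiles
# ---------------------------------------------------------------------------

def shape_profile(mol: Molecule, k: int) -> float:
    """k-th average interatomic-distance moment scaled by 1/k!.

    SP_k = [ (2/(n(n−1))) Σ_{i<j} r_ij^k ] / k!. The factorial scaling keeps
    high-order profiles (the models use SP20) in a numerically sane range.
    """
    if k < 1:
        raise ValueError("shape profile order must be >= 1")
    n = mol.n_atoms
    if n < 2:
        return 0.0
    _, r = _pair_arrays(mol, "u", None)
    mean_moment = float(np.mean(r.astype(float) ** k))
    return mean_moment / math.factorial(k)


# ---------------------------------------------------------------------------
# dispatch and table assembly
# ---------------------------------------------------------------------------

def compute_descriptor(mol: Molecule, spec: DescriptorSpec | str,
                       quantum: QuantumRecord | None = None,
                       table: AtomPropertyTable | None = None,
                       rdf_smoothing: float = RDF_SMOOTHING_DEFAULT,
                       quantum_convention: str = "as_printed") -> float:
    """Compute a single named descriptor for one molecule."""
    if isinstance(spec, str):
        spec = parse_descriptor_name(spec)
    fam = spec.family
    if fam in ("quantum", "dipole"):
        if quantum is None:
            raise ValueError(
                f"descriptor {spec.name} needs a quantum record for molecule {mol.id!r}")
        if fam == "dipole":
            return float(quantum.dipole[spec.index])
        qi = quantum_indices(quantum, convention=quantum_convention)
        return (qi.eta, qi.softness, qi.chi, qi.omega)[spec.index]
    if fam == "IC":
        if spec.index != 1:
            raise ValueError("only first-order information content is implemented")
        return ic1(mol)
    if fam == "MoRSE":
        return morse_signal(mol, spec.index, spec.weight, table)
    if fam == "RDF":
        return rdf_value(mol, spec.index / 10.0, spec.weight, rdf_smoothing, table)
    if fam == "GATS":
        return gats(mol, spec.index, spec.weight, table)
    if fam in ("HATS", "R", "Rmax"):
        return getaway_autocorr(mol, spec.index, spec.weight, kind=fam, table=table)
    if fam.startswith("WHIM_"):
        return whim_set(mol, spec.weight, table)[f"{fam[-1]}{spec.index}"]
    if fam == "SP":
        return shape_profile(mol, spec.index)
    raise ValueError(f"unhandled descriptor family {fam!r}")  # pragma: no cover


def build_descriptor_table(mols: Sequence[Molecule],
                           specs: Iterable[DescriptorSpec | str] | None = None,
                           quantum: Mapping[str, QuantumRecord] | None = None,
                           table: AtomPropertyTable | None = None,
                           hydrogens: bool = True,
                           rdf_smoothing: float = RDF_SMOOTHING_DEFAULT,
                           quantum_convention: str = "as_printed") -> pd.DataFrame:
    """Descriptor matrix: one row per molecule, one named column per descriptor.

    ``specs`` defaults to the 26-descriptor preset of the published models.
    ``quantum`` maps molecule id to its :class:`QuantumRecord`; it is required
    whenever a quantum or dipole descriptor is requested. ``hydrogens=False``
    computes everything on H-depleted structures.
    """
    names = [s if isinstance(s, str) else s.name
             for s in (specs if specs is not None else PUBLISHED_DESCRIPTORS)]
    parsed = [parse_descriptor_name(n) for n in names]
    needs_quantum = any(s.family in ("quantum", "dipole") for s in parsed)
    rows = []
    ids = []
    for mol in mols:
        q = None
        if needs_quantum:
            if quantum is None or mol.id not in quantum:
                raise ValueError(f"no quantum record for molecule {mol.id!r}")
            q = quantum[mol.id]
        work = mol if hydrogens else mol.without_hydrogens()
        # WHIM decompositions are shared across the components of one scheme
        whim_cache: dict[str, dict[str, float]] = {}
        row = []
        for s in parsed:
            if s.family.startswith("WHIM_"):
                if s.weight not in whim_cache:
                    whim_cache[s.weight] = whim_set(work, s.weight, table)
                row.append(whim_cache[s.weight][f"{s.family[-1]}{s.index}"])
            else:
                row.append(compute_descriptor(work, s, q, table, rdf_smoothing,
                                              quantum_convention))
        rows.append(row)
        ids.append(mol.id)
    return pd.DataFrame(rows, index=pd.Index(ids, name="id"), columns=names)
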