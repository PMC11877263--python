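"""Molecular descriptors: Coulomb matrices and the global SLATM spectrum.

Both featurizers are scikit-learn transformers whose samples are
:class:`~mflearn.molecules.Molecule` objects and whose output is a dense
``(n_molecules, n_features)`` float matrix of fixed width, suitable for
kernel regression.

Conventions (documented because dialects of both descriptors exist):

* Coulomb matrix: ``M_ii = 0.5 Z_i^2.4``, ``M_ij = Z_i Z_j / d_ij`` with
  interatomic distances converted to Bohr (1 Å = 1.8897259886 Bohr); the
  matrix is zero-padded to ``max_atoms`` and returned flattened row-major
  in full (not the upper triangle).  With ``sort_rows=True`` rows and
  columns are symmetrically reordered by descending row L2 norm (ties:
  descending Z, then original index), which restores atom-index
  invariance at the price of sorting discontinuities.
* SLATM (global variant): concatenation of one-body element counts,
  London-weighted Gaussian-smeared pair-distance spectra on a radial
  midpoint grid over (0, cutoff], and Axilrod–Teller–Muto-weighted
  smeared angle spectra on an angular midpoint grid over [0, π].  Channel
  order is fixed by the ascending element universe with pairs/triples in
  lexicographic order.  The London/ATM prefactors use distances in Bohr;
  grids and smearing widths are in Å / rad.
"""

from __future__ import annotations

import hashlib
import json
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .molecules import Molecule

__all__ = [
    "ANGSTROM_TO_BOHR",
    "CoulombMatrix",
    "SLATM",
    "make_descriptor",
    "descriptor_config_hash",
    "save_descriptors",
    "load_descriptors",
]

#: CODATA conversion used inside descriptor construction only.
ANGSTROM_TO_BOHR = 1.8897259886

_MIN_PAIR_DISTANCE = 1e-6  # Å; below this, atoms are considered coincident


def _distance_matrix(coords: np.ndarray) -> np.ndarray:
    diff = coords[:, None, :] - coords[None, :, :]
    return np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))


class CoulombMatrix(TransformerMixin, BaseEstimator):
    """Flattened (optionally row-sorted) Coulomb matrix featurizer.

    Parameters
    ----------
    max_atoms : int or None
        Padding size.  If None, learned in :meth:`fit` as the largest
        molecule seen.
    sort_rows : bool
        Sort rows/columns by descending L2 norm (index-invariant variant).
    angstrom_to_bohr : float
        Unit conversion applied to interatomic distances.
    """

    def __init__(self, max_atoms: int | None = None, sort_rows: bool = True,
                 angstrom_to_bohr: float = ANGSTROM_TO_BOHR):
        self.max_atoms = max_atoms
        self.sort_rows = sort_rows
        self.angstrom_to_bohr = angstrom_to_bohr

    @property
    def kind(self) -> str:
        return "sorted_cm" if self.sort_rows else "unsorted_cm"

    def fit(self, X: Sequence[Molecule], y=None):
        mols = list(X)
        if not mols:
            raise ValueError("need at least one molecule to fit")
        largest = max(m.n_atoms for m in mols)
        if self.max_atoms is None:
            self.max_atoms_ = largest
        else:
            if self.max_atoms < largest:
                raise ValueError(f"max_atoms={self.max_atoms} smaller than largest molecule ({largest} atoms)")
            self.max_atoms_ = int(self.max_atoms)
        self.n_features_out_ = self.max_atoms_ ** 2
        return self

    def transform(self, X: Sequence[Molecule]) -> np.ndarray:
        if not hasattr(self, "max_atoms_"):
            raise RuntimeError("CoulombMatrix must be fitted before transform")
        mols = list(X)
        out = np.zeros((len(mols), self.n_features_out_))
        for i, mol in enumerate(mols):
            out[i] = self._build(mol)
        return out

    def _build(self, mol: Molecule) -> np.ndarray:
        n = mol.n_atoms
        if n > self.max_atoms_:
            raise ValueError(f"molecule {mol.id!r} has {n} atoms > max_atoms ({self.max_atoms_})")
        Z = mol.atomic_numbers.astype(np.float64)
        D = _distance_matrix(mol.coordinates)
        off = ~np.eye(n, dtype=bool)
        if n > 1 and D[off].min() <= _MIN_PAIR_DISTANCE:
            raise ValueError(f"molecule {mol.id!r} has coincident atoms (d <= {_MIN_PAIR_DISTANCE} Å)")
        M = np.zeros((n, n))
        if n > 1:
            with np.errstate(divide="ignore"):
                M[off] = np.outer(Z, Z)[off] / (D[off] * self.angstrom_to_bohr)
        np.fill_diagonal(M, 0.5 * Z ** 2.4)
        if self.sort_rows:
            norms = np.linalg.norm(M, axis=1)
            # descending norm; ties: descending Z, then original index
            order = np.lexsort((np.arange(n), -Z, -norms))
            M = M[np.ix_(order, order)]
        padded = np.zeros((self.max_atoms_, self.max_atoms_))
        padded[:n, :n] = M
        return padded.ravel()


def _norm_gauss(grid: np.ndarray, mu: float, width: float) -> np.ndarray:
    return np.exp(-((grid - mu) ** 2) / (2.0 * width**2)) / (width * np.sqrt(2.0 * np.pi))


class SLATM(TransformerMixin, BaseEstimator):
    """Global Spectral London and Axilrod–Teller–Muto featurizer.

    Parameters default to a 4.8 Å cutoff with 0.05 Å radial and 0.05 rad
    angular smearing; grid steps default to 0.03 Å / 0.03 rad.  The element
    universe is learned in :meth:`fit` unless supplied.
    """

    def __init__(self, elements: Sequence[int] | None = None, cutoff: float = 4.8,
                 radial_smear: float = 0.05, angular_smear: float = 0.05,
                 radial_step: float = 0.03, angular_step: float = 0.03,
                 angstrom_to_bohr: float = ANGSTROM_TO_BOHR):
        self.elements = elements
        self.cutoff = cutoff
        self.radial_smear = radial_smear
        self.angular_smear = angular_smear
        self.radial_step = radial_step
        self.angular_step = angular_step
        self.angstrom_to_bohr = angstrom_to_bohr

    kind = "slatm"

    def fit(self, X: Sequence[Molecule], y=None):
        for name in ("cutoff", "radial_smear", "angular_smear", "radial_step", "angular_step"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.elements is None:
            universe: set[int] = set()
            for mol in X:
                universe.update(int(z) for z in mol.atomic_numbers)
            if not universe:
                raise ValueError("need at least one molecule to infer the element universe")
            self.elements_ = tuple(sorted(universe))
        else:
            self.elements_ = tuple(sorted(int(z) for z in self.elements))
        E = self.elements_
        self.pairs_ = [(a, b) for i, a in enumerate(E) for b in E[i:]]
        # triples keyed (a, b, c): b is the apex element, a <= c
        self.triples_ = sorted(
            (a, b, c) for b in E for i, a in enumerate(E) for c in E[i:]
        )
        # midpoint grids: radial over (0, cutoff], angular over [0, pi]
        n_r = int(np.floor(self.cutoff / self.radial_step))
        self.r_grid_ = (np.arange(n_r) + 0.5) * self.radial_step
        n_t = int(np.ceil(np.pi / self.angular_step))
        self.t_grid_ = (np.arange(n_t) + 0.5) * self.angular_step
        nE, nP, nT = len(E), len(self.pairs_), len(self.triples_)
        self._pair_slice = {
            p: slice(nE + k * n_r, nE + (k + 1) * n_r) for k, p in enumerate(self.pairs_)
        }
        base3 = nE + nP * n_r
        self._triple_slice = {
            t: slice(base3 + k * n_t, base3 + (k + 1) * n_t) for k, t in enumerate(self.triples_)
        }
        self.n_features_out_ = base3 + nT * n_t
        return self

    def channel_slice(self, kind: str, key) -> slice:
        """Slice of the output vector for a channel.

        ``kind`` is ``"one"`` (key: element Z), ``"two"`` (key: (Za, Zb),
        Za <= Zb) or ``"three"`` (key: (Za, Zb, Zc), apex Zb, Za <= Zc).
        """
        if kind == "one":
            return slice(self.elements_.index(key), self.elements_.index(key) + 1)
        if kind == "two":
            return self._pair_slice[tuple(key)]
        if kind == "three":
            return self._triple_slice[tuple(key)]
        raise ValueError(f"unknown channel kind {kind!r}")

    def transform(self, X: Sequence[Molecule]) -> np.ndarray:
        if not hasattr(self, "elements_"):
            raise RuntimeError("SLATM must be fitted before transform")
        mols = list(X)
        out = np.zeros((len(mols), self.n_features_out_))
        for i, mol in enumerate(mols):
            out[i] = self._build(mol)
        return out

    def _build(self, mol: Molecule) -> np.ndarray:
        Z = mol.atomic_numbers
        missing = sorted(set(int(z) for z in Z) - set(self.elements_))
        if missing:
            raise ValueError(f"molecule {mol.id!r}: elements {missing} outside the element universe")
        v = np.zeros(self.n_features_out_)
        # one-body: element counts
        for z in Z:
            v[self.channel_slice("one", int(z))] += 1.0
        n = mol.n_atoms
        if n < 2:
            return v
        D = _distance_matrix(mol.coordinates)
        off = ~np.eye(n, dtype=bool)
        if D[off].min() <= _MIN_PAIR_DISTANCE:
            raise ValueError(f"molecule {mol.id!r} has coincident atoms")
        to_bohr = self.angstrom_to_bohr
        # two-body: London-weighted smeared pair distances
        r_bohr = self.r_grid_ * to_bohr
        for i in range(n):
            for j in range(i + 1, n):
                d = D[i, j]
                if d > self.cutoff:
                    continue
                za, zb = sorted((int(Z[i]), int(Z[j])))
                london = 0.5 * za * zb / r_bohr**6
                v[self._pair_slice[(za, zb)]] += (
                    _norm_gauss(self.r_grid_, d, self.radial_smear) * london * self.radial_step
                )
        if n < 3:
            return v
        # three-body: ATM-weighted smeared angles at each apex
        cos_grid = np.cos(self.t_grid_)
        for j in range(n):  # apex
            for i in range(n):
                if i == j:
                    continue
                for k in range(i + 1, n):
                    if k == j:
                        continue
                    d_ij, d_jk, d_ik = D[i, j], D[j, k], D[i, k]
                    if d_ij > self.cutoff or d_jk > self.cutoff or d_ik > self.cutoff:
                        continue
                    # triangle angles at apex j and at the two ends
                    cos_j = (d_ij**2 + d_jk**2 - d_ik**2) / (2 * d_ij * d_jk)
                    cos_i = (d_ij**2 + d_ik**2 - d_jk**2) / (2 * d_ij * d_ik)
                    cos_k = (d_jk**2 + d_ik**2 - d_ij**2) / (2 * d_jk * d_ik)
                    theta = np.arccos(np.clip(cos_j, -1.0, 1.0))
                    za, zc = sorted((int(Z[i]), int(Z[k])))
                    zb = int(Z[j])
                    denom = (d_ij * d_jk * d_ik * to_bohr**3) ** 3
                    atm = za * zb * zc * (1.0 + cos_grid * cos_i * cos_k) / denom
                    v[self._triple_slice[(za, zb, zc)]] += (
                        _norm_gauss(self.t_grid_, theta, self.angular_smear) * atm * self.angular_step
                    )
        return v


def make_descriptor(kind: str, **kwargs):
    """Factory: ``unsorted_cm`` | ``sorted_cm`` | ``slatm`` -> transformer."""
    if kind == "unsorted_cm":
        return CoulombMatrix(sort_rows=False, **kwargs)
    if kind == "sorted_cm":
        return CoulombMatrix(sort_rows=True, **kwargs)
    if kind == "slatm":
        return SLATM(**kwargs)
    raise ValueError(f"unknown descriptor kind {kind!r}")


def descriptor_config_hash(transformer) -> str:
    """Stable short hash of a descriptor configuration (class + params)."""
    payload = {"class": type(transformer).__name__, **transformer.get_params()}
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def save_descriptors(path, ids: Sequence[str], X: np.ndarray, config_hash: str) -> None:
    """Cache a descriptor matrix to an HDF5 file keyed by molecule IDs."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.attrs["config_hash"] = config_hash
        fh.create_dataset("ids", data=np.array(list(ids), dtype="S64"))
        fh.create_dataset("X", data=np.asarray(X))


def load_descriptors(path, expected_hash: str | None = None):
    """Load a cached descriptor matrix; returns (ids, X)."""
    import h5py

    with h5py.File(path, "r") as fh:
        stored = fh.attrs["config_hash"]
        if expected_hash is not None and stored != expected_hash:
            raise ValueError(f"descriptor cache hash mismatch: {stored} != {expected_hash}")
        ids = [s.decode() for s in fh["ids"][()]]
        X = fh["X"][()]
    return ids, X
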