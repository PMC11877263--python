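"""Synthetic multi-fidelity benchmark generator.

Real coupled-cluster training sets are expensive and rarely shared, so the
package ships a generator that emulates the *statistical* structure the
multi-fidelity methods assume: small CHNO molecules (jittered copies of
five template geometries with randomly permuted atom order), and an
ordered hierarchy of label surfaces whose adjacent-level mean absolute
differences decrease systematically toward the target fidelity while the
per-calculation cost increases.

Labels are built from smooth deterministic functions of the geometry:

* target surface  y_F = sum_Z a_Z + sum_pairs Gaussian wells (narrow,
  width ~0.35 Å) of the interatomic distances — size-extensive and rich
  enough that small training sets cannot saturate it;
* fidelity gaps   y_f = y_F + sum_{g=f}^{F-1} Delta_g + noise, where each
  Delta_g is a *smoother* surface (wide wells, ~1.2 Å, plus a per-element
  offset) rescaled so the generated population's mean |Delta_g| equals
  ``difference_scales[g-1]`` exactly.

The smoothness asymmetry (gaps smoother than the target surface) is the
regime in which Δ-type and multi-fidelity models pay off; the amplitudes
are tunable so the benefit can be switched off (all scales zero makes
every fidelity identical, which the exactness tests exploit).

Energies are not physically meaningful; they are kcal/mol-scaled test
surfaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .molecules import (
    DEFAULT_FIDELITY_NAMES,
    FidelityHierarchy,
    Molecule,
    MultiFidelityDataset,
)

__all__ = [
    "TEMPLATES",
    "SyntheticSpec",
    "generate_molecules",
    "generate_fidelity_labels",
    "make_benchmark",
    "mask_top_fidelity",
]


def _template(name: str, symbols_z: list[int], coords) -> Molecule:
    return Molecule(id=name, atomic_numbers=np.array(symbols_z),
                    coordinates=np.array(coords, dtype=np.float64))


#: Small CHNO template geometries (Å), approximate equilibrium structures.
TEMPLATES: tuple[Molecule, ...] = (
    _template("methane", [6, 1, 1, 1, 1], [
        [0.0, 0.0, 0.0], [0.629, 0.629, 0.629], [-0.629, -0.629, 0.629],
        [-0.629, 0.629, -0.629], [0.629, -0.629, -0.629]]),
    _template("water", [8, 1, 1], [
        [0.0, 0.0, 0.119], [0.0, 0.763, -0.477], [0.0, -0.763, -0.477]]),
    _template("ammonia", [7, 1, 1, 1], [
        [0.0, 0.0, 0.112], [0.938, 0.0, -0.261], [-0.469, 0.813, -0.261],
        [-0.469, -0.813, -0.261]]),
    _template("formaldehyde", [6, 8, 1, 1], [
        [0.0, 0.0, 0.0], [0.0, 0.0, 1.21], [0.94, 0.0, -0.54], [-0.94, 0.0, -0.54]]),
    _template("ethane", [6, 6, 1, 1, 1, 1, 1, 1], [
        [0.0, 0.0, 0.765], [0.0, 0.0, -0.765],
        [1.02, 0.0, 1.16], [-0.51, 0.88, 1.16], [-0.51, -0.88, 1.16],
        [-1.02, 0.0, -1.16], [0.51, -0.88, -1.16], [0.51, 0.88, -1.16]]),
)

_MIN_DISTANCE = 0.3  # Å; jittered geometries below this are redrawn
_MAX_RETRIES = 100


@dataclass
class SyntheticSpec:
    """Study conditions of the synthetic benchmark.

    ``difference_scales[g-1]`` is the mean absolute energy gap (kcal/mol)
    between adjacent fidelities g and g+1 and must decrease strictly
    toward the target; ``unit_costs`` must increase strictly with
    fidelity.  ``noise_sd`` is the per-label Gaussian noise applied to
    every fidelity below the target.
    """

    n_molecules: int = 512
    template_set: tuple[Molecule, ...] = TEMPLATES
    jitter_sd: float = 0.05
    n_fidelities: int = 4
    difference_scales: tuple[float, ...] = (25.0, 10.0, 4.0)
    noise_sd: float = 0.5
    unit_costs: tuple[float, ...] = (1.0, 30.0, 300.0, 3000.0)
    fidelity_names: tuple[str, ...] = DEFAULT_FIDELITY_NAMES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be positive")
        if self.jitter_sd < 0 or self.noise_sd < 0:
            raise ValueError("jitter_sd and noise_sd must be nonnegative")
        if self.n_fidelities < 2:
            raise ValueError("need at least two fidelities")
        if len(self.difference_scales) != self.n_fidelities - 1:
            raise ValueError("need one difference scale per adjacent fidelity pair")
        scales = np.asarray(self.difference_scales, dtype=np.float64)
        if np.any(scales < 0):
            raise ValueError("difference scales must be nonnegative")
        nonzero = scales[scales > 0]
        if np.any(np.diff(nonzero) >= 0):
            raise ValueError("difference scales must decrease strictly toward the target")
        if len(self.unit_costs) != self.n_fidelities or len(self.fidelity_names) < self.n_fidelities:
            raise ValueError("unit_costs and fidelity_names must cover every fidelity")

    @property
    def hierarchy(self) -> FidelityHierarchy:
        return FidelityHierarchy(names=self.fidelity_names[: self.n_fidelities],
                                 unit_costs=self.unit_costs)


def generate_molecules(spec: SyntheticSpec) -> list[Molecule]:
    """Seeded sample of jittered, atom-permuted template geometries.

    Atom order is randomly permuted per molecule: real geometry files
    carry no canonical atom order, and the permutation makes the
    index-invariance (or lack of it) of descriptors observable.
    Geometries with atoms closer than 0.3 Å are rejected and redrawn.
    """
    rng = np.random.default_rng(spec.seed)
    molecules: list[Molecule] = []
    for k in range(spec.n_molecules):
        base = spec.template_set[rng.integers(len(spec.template_set))]
        for attempt in range(_MAX_RETRIES):
            coords = base.coordinates + rng.normal(0.0, spec.jitter_sd, base.coordinates.shape)
            if base.n_atoms == 1:
                break
            diff = coords[:, None, :] - coords[None, :, :]
            d = np.sqrt((diff**2).sum(-1))
            if d[~np.eye(base.n_atoms, dtype=bool)].min() > _MIN_DISTANCE:
                break
        else:
            raise RuntimeError(f"could not draw a clash-free jittered geometry after {_MAX_RETRIES} tries")
        perm = rng.permutation(base.n_atoms)
        molecules.append(Molecule(id=f"mol{k}", atomic_numbers=base.atomic_numbers[perm],
                                  coordinates=coords[perm]))
    return molecules


def _pair_distances(mol: Molecule):
    """(za, zb, d) for all atom pairs, element keys sorted, distances in Å."""
    n = mol.n_atoms
    Z = mol.atomic_numbers
    out = []
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.linalg.norm(mol.coordinates[i] - mol.coordinates[j]))
            za, zb = sorted((int(Z[i]), int(Z[j])))
            out.append((za, zb, d))
    return out


class _PairSurface:
    """Smooth, atom-order-invariant energy surface: per-element terms plus
    Gaussian wells of the interatomic distances."""

    def __init__(self, rng: np.random.Generator, elements: Sequence[int],
                 atom_scale: float, well_scale: float, well_width: float,
                 center_range: tuple[float, float]):
        self.atom_term = {z: rng.uniform(-atom_scale, atom_scale) for z in elements}
        self.wells = {}
        for i, za in enumerate(elements):
            for zb in elements[i:]:
                self.wells[(za, zb)] = (
                    rng.uniform(-well_scale, well_scale),
                    rng.uniform(*center_range),
                    well_width,
                )

    def __call__(self, mol: Molecule) -> float:
        e = sum(self.atom_term[int(z)] for z in mol.atomic_numbers)
        for za, zb, d in _pair_distances(mol):
            amp, mu, w = self.wells[(za, zb)]
            e += amp * np.exp(-((d - mu) ** 2) / (2 * w**2))
        return float(e)


def generate_fidelity_labels(molecules: Sequence[Molecule], spec: SyntheticSpec) -> MultiFidelityDataset:
    """Label the molecules at every fidelity of the hierarchy.

    The target surface uses narrow pair wells (hard to learn from few
    samples); each adjacent-fidelity gap Delta_g uses wide wells (easy to
    learn) and is rescaled so the population mean |Delta_g| equals
    ``difference_scales[g-1]``.  Fidelities below the target receive
    i.i.d. Gaussian label noise of sd ``noise_sd``.  Deterministic given
    the spec seed.
    """
    rng = np.random.default_rng([spec.seed, 104729])
    elements = sorted({int(z) for m in molecules for z in m.atomic_numbers})
    F = spec.n_fidelities
    target = _PairSurface(rng, elements, atom_scale=60.0, well_scale=30.0,
                          well_width=0.35, center_range=(0.8, 2.2))
    y_F = np.array([target(m) for m in molecules])
    labels = np.empty((len(molecules), F))
    labels[:, F - 1] = y_F
    # cumulative gaps: y_f = y_F + sum_{g=f}^{F-1} Delta_g + noise
    gap_values = []
    for g in range(1, F):
        surf = _PairSurface(rng, elements, atom_scale=1.0, well_scale=1.0,
                            well_width=1.2, center_range=(1.0, 3.0))
        raw = np.array([surf(m) for m in molecules])
        scale = spec.difference_scales[g - 1]
        mean_abs = float(np.mean(np.abs(raw)))
        gap_values.append(raw * (scale / mean_abs) if scale > 0 and mean_abs > 0 else np.zeros_like(raw))
    for f in range(F - 1, 0, -1):
        noise = rng.normal(0.0, spec.noise_sd, len(molecules)) if spec.noise_sd > 0 else 0.0
        labels[:, f - 1] = y_F + sum(gap_values[f - 1:]) + noise
    return MultiFidelityDataset(list(molecules), labels, spec.hierarchy)


def make_benchmark(spec: SyntheticSpec | None = None) -> MultiFidelityDataset:
    """Generate molecules and labels in one call (default spec if None)."""
    spec = spec if spec is not None else SyntheticSpec()
    return generate_fidelity_labels(generate_molecules(spec), spec)


def mask_top_fidelity(dataset: MultiFidelityDataset, fraction: float, seed: int = 0) -> MultiFidelityDataset:
    """Drop the top-fidelity label for a seeded random fraction of molecules.

    Emulates the realistic regime where only part of the data carries
    target-fidelity (e.g., coupled-cluster) labels; downward closure is
    preserved because only the most expensive level is masked.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    labels = dataset.labels.copy()
    n = dataset.n_molecules
    k = int(round(fraction * n))
    drop = np.random.default_rng(seed).permutation(n)[:k]
    labels[drop, dataset.hierarchy.F - 1] = np.nan
    return MultiFidelityDataset(dataset.molecules, labels, dataset.hierarchy)
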