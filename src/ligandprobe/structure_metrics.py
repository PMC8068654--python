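"""Geometry and displacement-parameter diagnostics.

Covers the simple but decisive measurements in a ligand-assignment
argument: metal-ligand distances (e.g. Mo to the homocitrate alcohol and
carboxylate oxygens), average B factors of a selection, principal-axis
analysis of anisotropic displacement tensors, and the angle between a
diatomic bond and the direction of maximum anisotropy.  The last one
matters because an apparently elongated (diatomic-looking) blob can be an
artefact of anisotropic data: if the two atoms of a modelled N2 always lie
along the axis of maximum anisotropy, the elongation tracks the data
pathology, not chemistry.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np

from .model_map_io import StructureModel

__all__ = [
    "AnisotropyResult",
    "DistanceRecord",
    "measure_distance",
    "average_b",
    "anisotropy",
    "bond_axis_alignment",
]


@dataclasses.dataclass(frozen=True)
class AnisotropyResult:
    atom_key: tuple[str, str]
    eigenvalues: tuple[float, float, float]  # descending, A^2
    axes: np.ndarray  # rows are the orthonormal principal axes

    @property
    def ratio(self) -> float:
        """Smallest / largest eigenvalue, 1 for an isotropic atom."""
        return self.eigenvalues[2] / self.eigenvalues[0]

    @property
    def major_axis(self) -> np.ndarray:
        return self.axes[0]


@dataclasses.dataclass(frozen=True)
class DistanceRecord:
    pair: tuple[tuple[str, str], tuple[str, str]]
    distance: float


def measure_distance(
    model: StructureModel, a: tuple[str, str], b: tuple[str, str]
) -> DistanceRecord:
    """Euclidean distance in A between two atoms addressed by (chain, name)."""
    pa = model.find(*a).position
    pb = model.find(*b).position
    return DistanceRecord(pair=(a, b), distance=float(np.linalg.norm(pa - pb)))


def average_b(model: StructureModel, selection: Sequence[str], chain: str | None = None) -> float:
    """Arithmetic mean of b_iso over the named atoms."""
    atoms = model.select(selection, chain=chain)
    if not atoms:
        raise ValueError("empty selection")
    return float(np.mean([a.b_iso for a in atoms]))


def anisotropy(
    u_aniso: np.ndarray, atom_key: tuple[str, str] = ("", ""), tol: float = 1e-8
) -> AnisotropyResult:
    """Principal-axis decomposition of an anisotropic displacement tensor."""
    u = np.asarray(u_aniso, dtype=float)
    if u.shape != (3, 3) or not np.allclose(u, u.T, atol=tol):
        raise ValueError("u_aniso must be a symmetric 3x3 tensor")
    evals, evecs = np.linalg.eigh(u)
    if evals[0] < -tol:
        raise ValueError(f"negative eigenvalue {evals[0]:.3g} beyond tolerance")
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    axes = evecs[:, order].T
    return AnisotropyResult(
        atom_key=atom_key,
        eigenvalues=(float(evals[0]), float(evals[1]), float(evals[2])),
        axes=axes,
    )


def bond_axis_alignment(
    model: StructureModel,
    a: tuple[str, str],
    b: tuple[str, str],
    mode: str = "pair",
) -> float:
    """Angle (degrees, folded to [0, 90]) between the a->b bond and the
    major anisotropy axis.

    ``mode="pair"`` (default) uses the averaged tensor (U_a + U_b) / 2;
    ``mode="a"`` / ``mode="b"`` use a single atom's tensor.  The fold to
    [0, 90] reflects the sign ambiguity of eigenvectors.
    """
    at_a, at_b = model.find(*a), model.find(*b)
    if at_a.u_aniso is None or at_b.u_aniso is None:
        missing = [k for k, at in ((a, at_a), (b, at_b)) if at.u_aniso is None]
        raise ValueError(f"missing anisotropic tensor for {missing}")
    if mode == "pair":
        u = 0.5 * (at_a.u_aniso + at_b.u_aniso)
    elif mode == "a":
        u = at_a.u_aniso
    elif mode == "b":
        u = at_b.u_aniso
    else:
        raise ValueError(f"unknown mode {mode!r}")
    bond = at_b.position - at_a.position
    n = np.linalg.norm(bond)
    if n == 0:
        raise ValueError("coincident atoms have no bond axis")
    major = anisotropy(u).major_axis
    cosang = abs(float(np.dot(bond / n, major)))
    return math.degrees(math.acos(min(cosang, 1.0)))
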