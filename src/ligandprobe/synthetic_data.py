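"""Synthetic FeMo-cluster fixtures and Gaussian-atom density maps.

The generator produces the ingredients needed to test ligand-identification
statistics with known ground truth: an idealized MoFe7S9C cluster with the
canonical atom names (Fe1-Fe7, Mo, S1A-S5A, S1B-S4B, central carbide C, plus
the anchoring Cys thiolate and the two homocitrate oxygens O7/O6), ligand
substitution at the three mu2 belt-sulfide sites (2B, 3A, 5A), and density
maps built as sums of normalized 3-D Gaussians.

Each atom contributes ``occupancy * n_electrons`` electrons integrated over
all space, with covariance ``(B / 8 pi^2) I + aniso_smear``.  An optional
reciprocal-space cutoff at d_min produces the Fourier truncation ripples
seen around electron-rich clusters in real band-limited maps; when
``aniso_smear`` is set the cutoff becomes ellipsoidal, mimicking
direction-dependent resolution.  Seeded Gaussian noise is added last.

Single-Gaussian form factors are used instead of multi-term Cromer-Mann
fits: the tests need exact normalization and linearity, not scattering
accuracy.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np

from .model_map_io import (
    AtomRecord,
    DensityGrid,
    StructureModel,
    B_TO_U,
    SULFIDE_ELECTRONS,
)

__all__ = [
    "MapSynthesisSpec",
    "LigandVariant",
    "build_femo_fixture",
    "substitute_ligand",
    "synthesize_map",
    "synthesize_anomalous_map",
    "DEFAULT_ANOMALOUS_WEIGHTS",
]

#: Relative anomalous scattering weights near 7100 eV, where the signal
#: mainly reflects S and Mo (Fe contributes weakly below its K edge).
#: Free parameters of the generator; chosen so Mo >> S > Fe > light atoms.
DEFAULT_ANOMALOUS_WEIGHTS: dict[str, float] = {"S": 1.0, "Fe": 0.25, "Mo": 4.0}

#: electron totals of the candidate occupants of a mu2 site
OCCUPANT_ELECTRONS = {"S2-": 18, "N2": 14, "N2H2": 16}


@dataclasses.dataclass
class MapSynthesisSpec:
    """Parameters of one synthetic map.

    grid_spacing and padding in A; band_limit is a d_min in A (None
    disables truncation ripples); aniso_smear a symmetric 3x3 tensor in
    A^2 added to every atom's displacement; noise_sd in map units.

    ``grid_origin``/``grid_shape`` override the automatic bounding box —
    needed when several model variants must be rendered on one common
    grid (e.g. to form difference maps).
    """

    model: StructureModel
    grid_spacing: float = 0.25
    padding: float = 4.0
    band_limit: float | None = None
    aniso_smear: np.ndarray | None = None
    noise_sd: float = 0.0
    seed: int = 0
    anomalous_weights: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_ANOMALOUS_WEIGHTS)
    )
    grid_origin: np.ndarray | None = None
    grid_shape: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        if self.grid_spacing <= 0:
            raise ValueError("grid_spacing must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.aniso_smear is not None:
            u = np.asarray(self.aniso_smear, dtype=float)
            if u.shape != (3, 3) or not np.allclose(u, u.T):
                raise ValueError("aniso_smear must be a symmetric 3x3 tensor")
            self.aniso_smear = u
        if any(w < 0 for w in self.anomalous_weights.values()):
            raise ValueError("anomalous weights must be non-negative")


@dataclasses.dataclass
class LigandVariant:
    """What occupies a mu2 belt site: sulfide or an N2-derived diatomic."""

    site: str
    occupant: str
    orientation: np.ndarray = dataclasses.field(
        default_factory=lambda: np.array([0.0, 0.0, 1.0])
    )

    def __post_init__(self) -> None:
        if self.site not in ("2B", "3A", "5A"):
            raise ValueError(f"unknown mu2 site {self.site!r}")
        if self.occupant not in OCCUPANT_ELECTRONS:
            raise ValueError(f"unknown occupant {self.occupant!r}")
        v = np.asarray(self.orientation, dtype=float)
        n = np.linalg.norm(v)
        if n == 0:
            raise ValueError("orientation must be a nonzero vector")
        self.orientation = v / n


# --------------------------------------------------------------------------
# fixture geometry
#
# Idealized scaffold: central carbide at the origin, six belt Fe (Fe2-Fe7)
# on a trigonal prism with Fe-C = 2.0 A, apical Fe1 below and Mo above.
# The three mu2 sulfides (S2B, S3A, S5A) sit on the waist, each bridging one
# Fe of each triangle (S2B bridges Fe2/Fe6); the six mu3 sulfides cap the
# Fe1 and Mo ends.  Only topology and names matter for the tests.

_BELT_R = math.sqrt(4.0 - 0.49)  # Fe-C = 2.0 with half-height 0.7
_BELT_H = 0.7


def _cyl(r: float, angle_deg: float, z: float) -> np.ndarray:
    a = math.radians(angle_deg)
    return np.array([r * math.cos(a), r * math.sin(a), z])


def _femo_coordinates() -> dict[str, tuple[str, np.ndarray]]:
    """name -> (element, position) for the cluster plus Cys-S and O7/O6."""
    mu2_r = 3.604  # gives Fe-S(mu2) ~ 2.30 A on this scaffold
    cap_r, cap_z = 2.2, 1.9
    coords: dict[str, tuple[str, np.ndarray]] = {
        "C": ("C", np.zeros(3)),
        "FE2": ("Fe", _cyl(_BELT_R, 0, -_BELT_H)),
        "FE3": ("Fe", _cyl(_BELT_R, 120, -_BELT_H)),
        "FE4": ("Fe", _cyl(_BELT_R, 240, -_BELT_H)),
        "FE6": ("Fe", _cyl(_BELT_R, 60, _BELT_H)),
        "FE7": ("Fe", _cyl(_BELT_R, 180, _BELT_H)),
        "FE5": ("Fe", _cyl(_BELT_R, 300, _BELT_H)),
        "FE1": ("Fe", np.array([0.0, 0.0, -2.4])),
        "MO": ("Mo", np.array([0.0, 0.0, 2.4])),
        # mu2 belt sulfides on the waist, at the bisector of their Fe pair
        "S2B": ("S", _cyl(mu2_r, 30, 0.0)),    # bridges Fe2/Fe6
        "S5A": ("S", _cyl(mu2_r, 150, 0.0)),   # bridges Fe3/Fe7
        "S3A": ("S", _cyl(mu2_r, 270, 0.0)),   # bridges Fe4/Fe5
        # mu3 caps: Fe1 end (between two bottom Fe, bonded to Fe1)
        "S1A": ("S", _cyl(cap_r, 60, -cap_z)),
        "S2A": ("S", _cyl(cap_r, 180, -cap_z)),
        "S4A": ("S", _cyl(cap_r, 300, -cap_z)),
        # mu3 caps: Mo end
        "S1B": ("S", _cyl(cap_r, 0, cap_z)),
        "S3B": ("S", _cyl(cap_r, 120, cap_z)),
        "S4B": ("S", _cyl(cap_r, 240, cap_z)),
    }
    # Cys thiolate anchoring Fe1
    coords["SG"] = ("S", np.array([0.0, 0.0, -4.7]))
    # homocitrate oxygens chelating Mo: alcohol O7 and carboxylate O6
    mo = coords["MO"][1]
    u1 = np.array([0.62, 0.45, 0.64])
    u2 = np.array([-0.50, 0.60, 0.62])
    coords["O7"] = ("O", mo + 2.10 * u1 / np.linalg.norm(u1))
    coords["O6"] = ("O", mo + 2.13 * u2 / np.linalg.norm(u2))
    return coords


def build_femo_fixture(
    chain: str = "A",
    b_iso: float = 15.0,
    cell: Sequence[float] | None = None,
    center: Sequence[float] | None = None,
) -> StructureModel:
    """Idealized FeMo cluster with canonical atom names.

    Contains Mo, Fe1-Fe7, the nine cluster sulfides (as S2- with 18
    electrons each), the central carbide, the Cys-275 SG thiolate (neutral
    S, 16 electrons) and the homocitrate O7/O6 oxygens — 10 sulfur atoms in
    total, matching the per-chain sulfur population of the cluster region.
    """
    coords = _femo_coordinates()
    shift = np.zeros(3) if center is None else np.asarray(center, dtype=float)
    atoms = []
    serial = 0
    for name, (element, pos) in coords.items():
        serial += 1
        if name == "SG":
            res_name, res_num, n_el = "CYS", 275, 16.0
        elif name in ("O7", "O6"):
            res_name, res_num, n_el = "HCA", 601, 8.0
        else:
            res_name, res_num = "ICS", 500
            n_el = float(SULFIDE_ELECTRONS) if element == "S" else None
        atoms.append(
            AtomRecord(
                serial=serial,
                name=name,
                element=element,
                chain=chain,
                residue_name=res_name,
                residue_number=res_num,
                position=pos + shift,
                b_iso=b_iso,
                n_electrons=n_el,
            )
        )
    if cell is None:
        cell = (20.0, 20.0, 20.0, 90.0, 90.0, 90.0)
    return StructureModel(atoms, cell, label=f"femo_{chain}")


def substitute_ligand(model: StructureModel, variant: LigandVariant) -> StructureModel:
    """Replace the sulfide at a mu2 site by the variant's occupant.

    For N2 the sulfur atom is removed and two N atoms (bond length 1.10 A)
    are placed symmetrically about the former S position along the variant
    orientation; N2H2 adds two trans H at standard imine-like geometry.
    For S2- the site is re-occupied by a single sulfide (identity except
    for bookkeeping), which is useful for paired-model comparisons.
    """
    site_atom_name = f"S{variant.site}"
    out = model.copy()
    idx = next(
        (i for i, a in enumerate(out.atoms) if a.name == site_atom_name), None
    )
    if idx is None:
        raise KeyError(f"site atom {site_atom_name!r} not present in model")
    old = out.atoms[idx]
    serial_base = max(a.serial for a in out.atoms)
    replacement: list[AtomRecord] = []
    if variant.occupant == "S2-":
        replacement.append(
            dataclasses.replace(
                old, n_electrons=float(SULFIDE_ELECTRONS), position=old.position.copy()
            )
        )
    else:
        axis = variant.orientation
        half = 0.55 * axis  # N-N bond 1.10 A
        n1 = old.position - half
        n2 = old.position + half
        for tag, pos in (("1", n1), ("2", n2)):
            serial_base += 1
            replacement.append(
                AtomRecord(
                    serial=serial_base,
                    name=f"N{variant.site}{tag}",
                    element="N",
                    chain=old.chain,
                    residue_name="LN2",
                    residue_number=old.residue_number,
                    position=pos,
                    occupancy=old.occupancy,
                    b_iso=old.b_iso,
                )
            )
        if variant.occupant == "N2H2":
            # trans H on each N, N-H 1.03 A at ~120 deg from the N-N axis
            perp = np.cross(axis, [1.0, 0.0, 0.0])
            if np.linalg.norm(perp) < 1e-6:
                perp = np.cross(axis, [0.0, 1.0, 0.0])
            perp = perp / np.linalg.norm(perp)
            cos60, sin60 = math.cos(math.radians(60)), math.sin(math.radians(60))
            for tag, npos, ax_sgn, perp_sgn in (
                ("1", n1, -1.0, 1.0),   # H away from N2, perp up
                ("2", n2, 1.0, -1.0),   # trans: perp down
            ):
                serial_base += 1
                replacement.append(
                    AtomRecord(
                        serial=serial_base,
                        name=f"H{variant.site}{tag}",
                        element="H",
                        chain=old.chain,
                        residue_name="LN2",
                        residue_number=old.residue_number,
                        position=npos
                        + 1.03 * (ax_sgn * cos60 * axis + perp_sgn * sin60 * perp),
                        occupancy=old.occupancy,
                        b_iso=old.b_iso,
                    )
                )
    out.atoms[idx : idx + 1] = replacement
    return StructureModel(out.atoms, out.cell, label=f"{model.label}|{variant.site}:{variant.occupant}")


# --------------------------------------------------------------------------
# map synthesis


def _grid_geometry(spec: MapSynthesisSpec) -> tuple[np.ndarray, np.ndarray]:
    if spec.grid_origin is not None and spec.grid_shape is not None:
        return (
            np.asarray(spec.grid_origin, dtype=float),
            np.asarray(spec.grid_shape, dtype=int),
        )
    pos = spec.model.positions()
    lo = pos.min(axis=0) - spec.padding
    hi = pos.max(axis=0) + spec.padding
    # snap the origin to a voxel multiple so written maps round-trip cleanly
    lo = np.floor(lo / spec.grid_spacing) * spec.grid_spacing
    n = np.ceil((hi - lo) / spec.grid_spacing).astype(int)
    if (n < 4).any():
        raise ValueError("grid too small to hold model plus padding")
    return lo, n


def _atom_weight(atom: AtomRecord, anomalous: bool, spec: MapSynthesisSpec) -> float:
    if anomalous:
        return atom.occupancy * spec.anomalous_weights.get(atom.element, 0.0)
    return atom.occupancy * atom.n_electrons


def _render(spec: MapSynthesisSpec, anomalous: bool) -> DensityGrid:
    origin, shape = _grid_geometry(spec)
    d = spec.grid_spacing
    values = np.zeros(tuple(shape))
    for atom in spec.model.atoms:
        w = _atom_weight(atom, anomalous, spec)
        if w == 0.0:
            continue
        cov = (atom.u_aniso if atom.u_aniso is not None
               else atom.b_iso * B_TO_U * np.eye(3))
        if spec.aniso_smear is not None:
            cov = cov + spec.aniso_smear
        evals = np.linalg.eigvalsh(cov)
        if evals.min() <= 0:
            raise ValueError(f"non-positive displacement covariance for {atom.name}")
        cutoff = 5.0 * math.sqrt(evals.max())
        ijk0 = np.floor((atom.position - cutoff - origin) / d).astype(int)
        ijk1 = np.ceil((atom.position + cutoff - origin) / d).astype(int) + 1
        ijk0 = np.clip(ijk0, 0, shape)
        ijk1 = np.clip(ijk1, 0, shape)
        if (ijk1 <= ijk0).any():
            continue
        ax = [origin[k] + d * np.arange(ijk0[k], ijk1[k]) - atom.position[k]
              for k in range(3)]
        dx, dy, dz = np.meshgrid(*ax, indexing="ij", sparse=True)
        prec = np.linalg.inv(cov)
        quad = (
            prec[0, 0] * dx * dx + prec[1, 1] * dy * dy + prec[2, 2] * dz * dz
            + 2 * (prec[0, 1] * dx * dy + prec[0, 2] * dx * dz + prec[1, 2] * dy * dz)
        )
        norm = w / ((2 * math.pi) ** 1.5 * math.sqrt(np.linalg.det(cov)))
        values[ijk0[0]:ijk1[0], ijk0[1]:ijk1[1], ijk0[2]:ijk1[2]] += (
            norm * np.exp(-0.5 * quad)
        )

    if spec.band_limit is not None:
        values = _band_limit(values, d, spec.band_limit, spec.aniso_smear)

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        values = values + rng.normal(0.0, spec.noise_sd, size=values.shape)

    cell = (shape[0] * d, shape[1] * d, shape[2] * d, 90.0, 90.0, 90.0)
    return DensityGrid(values, cell, origin)


def _band_limit(
    values: np.ndarray,
    spacing: float,
    d_min: float,
    aniso: np.ndarray | None,
) -> np.ndarray:
    """Sharp reciprocal-space cutoff at |s| = 1/d_min.

    With an anisotropic smear the cutoff becomes an ellipsoid: each
    reciprocal axis is shrunk in proportion to the smear along it, so
    directions with larger apparent displacement lose resolution first.
    """
    freqs = [np.fft.fftfreq(n, d=spacing) for n in values.shape]
    if aniso is None:
        scale = np.ones(3)
    else:
        diag = np.clip(np.diag(aniso), 0.0, None)
        lo = diag.min()
        # axis with the largest smear keeps the least reciprocal extent
        scale = np.sqrt((lo + 1.0) / (diag + 1.0))
    sx, sy, sz = np.meshgrid(
        freqs[0] / scale[0], freqs[1] / scale[1], freqs[2] / scale[2],
        indexing="ij", sparse=True,
    )
    s2 = sx * sx + sy * sy + sz * sz
    mask = s2 <= (1.0 / d_min) ** 2
    ft = np.fft.fftn(values)
    return np.real(np.fft.ifftn(ft * mask))


def synthesize_map(spec: MapSynthesisSpec) -> DensityGrid:
    """Electron-density map: each atom a normalized Gaussian carrying
    ``occupancy * n_electrons`` electrons."""
    return _render(spec, anomalous=False)


def synthesize_anomalous_map(spec: MapSynthesisSpec) -> DensityGrid:
    """Anomalous map: atoms weighted by ``anomalous_weights[element]``
    (default 0 for elements without an entry) instead of electron count."""
    return _render(spec, anomalous=True)
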