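"""Coordinate models and density grids, with PDB / CCP4 round-trip I/O.

The two containers here — :class:`StructureModel` and :class:`DensityGrid` —
are deliberately small.  A structure is an ordered list of atom records with
a unit cell; a grid is a scalar field sampled on a (possibly triclinic) box
with an explicit Cartesian origin.  File I/O is delegated to :mod:`gemmi`;
map mean and rmsd are always recomputed from the stored array because
deposited headers are not trustworthy.

Map values at grid point ``g`` convert to sigma units as
``(values[g] - mean) / rmsd``.  The conversion is affine, so voxel ranking
is identical in raw and sigma units.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "StructureModel",
    "DensityGrid",
    "read_structure",
    "write_structure",
    "read_map",
    "write_map",
]

# 8 * pi**2 converts between B (A^2) and mean-square displacement U (A^2)
B_TO_U = 1.0 / (8.0 * math.pi**2)

#: electron count of the sulfide dianion (S has 16 electrons, S2- has 18)
SULFIDE_ELECTRONS = 18


@dataclasses.dataclass
class AtomRecord:
    """One ATOM/HETATM record.

    ``n_electrons`` defaults to the element's atomic number but is
    overridable so that ionic species (e.g. S2- with 18 electrons) scatter
    with their true electron count.
    """

    serial: int
    name: str
    element: str
    chain: str
    residue_name: str
    residue_number: int
    position: np.ndarray
    occupancy: float = 1.0
    b_iso: float = 20.0
    u_aniso: np.ndarray | None = None
    n_electrons: float | None = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError(f"position must be a 3-vector, got {self.position.shape}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")
        if self.b_iso < 0:
            raise ValueError(f"negative b_iso {self.b_iso}")
        if self.n_electrons is None:
            el = gemmi.Element(self.element)
            if el.atomic_number == 0:
                raise ValueError(f"unknown element symbol: {self.element!r}")
            self.n_electrons = float(el.atomic_number)
        if self.n_electrons < 0:
            raise ValueError("n_electrons must be non-negative")
        if self.u_aniso is not None:
            u = np.asarray(self.u_aniso, dtype=float)
            if u.shape != (3, 3) or not np.allclose(u, u.T, atol=1e-8):
                raise ValueError("u_aniso must be a symmetric 3x3 tensor")
            if np.linalg.eigvalsh(u).min() < -1e-8:
                raise ValueError("u_aniso has a negative eigenvalue")
            self.u_aniso = u

    @property
    def key(self) -> tuple[str, str]:
        """(chain, name) pair used to address atoms throughout the package."""
        return (self.chain, self.name)


class StructureModel:
    """An ordered collection of atoms with a unit cell.

    (chain, name, residue_number) triples must be unique.
    """

    def __init__(
        self,
        atoms: Iterable[AtomRecord],
        cell: Sequence[float] = (1.0, 1.0, 1.0, 90.0, 90.0, 90.0),
        label: str = "",
    ) -> None:
        self.atoms: list[AtomRecord] = list(atoms)
        self.cell = tuple(float(x) for x in cell)
        if len(self.cell) != 6:
            raise ValueError("cell needs 6 lattice parameters")
        self.label = label
        seen: set[tuple[str, str, int]] = set()
        for a in self.atoms:
            triple = (a.chain, a.name, a.residue_number)
            if triple in seen:
                raise ValueError(f"duplicate atom {triple}")
            seen.add(triple)

    def __iter__(self) -> Iterator[AtomRecord]:
        return iter(self.atoms)

    def __len__(self) -> int:
        return len(self.atoms)

    def find(self, chain: str, name: str) -> AtomRecord:
        for a in self.atoms:
            if a.chain == chain and a.name == name:
                return a
        raise KeyError(f"no atom {name!r} in chain {chain!r}")

    def select(self, names: Sequence[str], chain: str | None = None) -> list[AtomRecord]:
        """Atoms whose name is in ``names`` (optionally restricted to a chain),
        in the order given by ``names``."""
        out = []
        missing = []
        for nm in names:
            hits = [
                a
                for a in self.atoms
                if a.name == nm and (chain is None or a.chain == chain)
            ]
            if not hits:
                missing.append(nm)
            out.extend(hits)
        if missing:
            raise KeyError(f"atoms not found: {', '.join(missing)}")
        return out

    def copy(self) -> "StructureModel":
        return StructureModel(
            [dataclasses.replace(a, position=a.position.copy()) for a in self.atoms],
            self.cell,
            self.label,
        )

    def total_electrons(self) -> float:
        return float(sum(a.occupancy * a.n_electrons for a in self.atoms))

    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])


class DensityGrid:
    """A 3-D scalar field on a box described by 6 lattice parameters.

    The grid point (i, j, k) sits at
    ``origin + orth @ (i/nx, j/ny, k/nz)`` where ``orth`` is the
    orthogonalization matrix of ``cell``; the stored value is the density at
    that point (voxel centers, 0-based indices).  ``mean`` and ``rmsd`` are
    computed from the data.
    """

    def __init__(
        self,
        values: np.ndarray,
        cell: Sequence[float],
        origin: Sequence[float] = (0.0, 0.0, 0.0),
    ) -> None:
        self.values = np.asarray(values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-D array")
        self.cell = tuple(float(x) for x in cell)
        if any(self.cell[i] <= 0 for i in range(3)):
            raise ValueError(f"non-positive cell edge in {self.cell}")
        self.origin = np.asarray(origin, dtype=float)
        self._unit_cell = gemmi.UnitCell(*self.cell)
        self._orth = np.array(self._unit_cell.orth.mat.tolist())
        self._frac = np.array(self._unit_cell.frac.mat.tolist())

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def rmsd(self) -> float:
        return float(self.values.std())

    @property
    def voxel_volume(self) -> float:
        return self._unit_cell.volume / self.values.size

    @property
    def spacing(self) -> np.ndarray:
        """Grid step along each cell axis, in A."""
        return np.array([self.cell[i] / self.shape[i] for i in range(3)])

    def sigma_values(self) -> np.ndarray:
        """The whole array in sigma units."""
        rmsd = self.rmsd
        if rmsd == 0:
            raise ValueError("constant map has no sigma scale")
        return (self.values - self.mean) / rmsd

    def to_sigma(self, value: float | np.ndarray) -> float | np.ndarray:
        return (value - self.mean) / self.rmsd

    def grid_positions(self, indices: np.ndarray) -> np.ndarray:
        """Cartesian positions (A) of integer grid indices, shape (n, 3)."""
        frac = np.asarray(indices, dtype=float) / np.array(self.shape)
        return self.origin + frac @ self._orth.T

    def cart_to_index(self, pos: Sequence[float]) -> np.ndarray:
        """Fractional (continuous) grid index of a Cartesian position."""
        rel = np.asarray(pos, dtype=float) - self.origin
        return (self._frac @ rel) * np.array(self.shape)

    def copy(self) -> "DensityGrid":
        return DensityGrid(self.values.copy(), self.cell, self.origin.copy())


# --------------------------------------------------------------------------
# structure I/O


def _from_gemmi(st: gemmi.Structure, label: str) -> StructureModel:
    atoms: list[AtomRecord] = []
    serial = 0
    for model in st:
        for chain in model:
            for res in chain:
                for at in res:
                    serial += 1
                    if at.element.atomic_number == 0:
                        raise ValueError(
                            f"unknown element symbol {at.element.name!r} "
                            f"for atom {at.name!r}"
                        )
                    u = None
                    if at.aniso.nonzero():
                        u = np.array(
                            [
                                [at.aniso.u11, at.aniso.u12, at.aniso.u13],
                                [at.aniso.u12, at.aniso.u22, at.aniso.u23],
                                [at.aniso.u13, at.aniso.u23, at.aniso.u33],
                            ]
                        )
                    atoms.append(
                        AtomRecord(
                            serial=serial,
                            name=at.name,
                            element=at.element.name,
                            chain=chain.name,
                            residue_name=res.name,
                            residue_number=res.seqid.num,
                            position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                            occupancy=at.occ,
                            b_iso=at.b_iso,
                            u_aniso=u,
                        )
                    )
        break  # first model only
    cell = st.cell
    return StructureModel(
        atoms, (cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma), label
    )


def read_structure(path: str | Path, dialect: str = "pdb") -> StructureModel:
    """Read a coordinate file (PDB fixed-column dialect).

    ANISOU records populate ``u_aniso`` in A^2 (the 1e-4 A^2 integer
    convention of the format is undone by the parser).
    """
    if dialect != "pdb":
        raise ValueError(f"unsupported dialect {dialect!r}")
    path = Path(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    return _from_gemmi(st, label=path.stem)


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write a model as fixed-column PDB (CRYST1 + ATOM/HETATM + ANISOU)."""
    st = gemmi.Structure()
    st.cell = gemmi.UnitCell(*model.cell)
    st.spacegroup_hm = "P 1"
    gm = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for a in model.atoms:
        if len(a.name) > 4:
            raise ValueError(f"atom name {a.name!r} does not fit fixed columns")
        ch = chains.get(a.chain)
        if ch is None:
            ch = gemmi.Chain(a.chain)
            chains[a.chain] = ch
        res = None
        if len(ch) and ch[-1].seqid.num == a.residue_number and ch[-1].name == a.residue_name:
            res = ch[-1]
        else:
            res = gemmi.Residue()
            res.name = a.residue_name
            res.seqid = gemmi.SeqId(a.residue_number, " ")
            res.het_flag = "H" if a.residue_name not in _AMINO else "A"
            ch.add_residue(res)
            res = ch[-1]
        at = gemmi.Atom()
        at.name = a.name
        at.element = gemmi.Element(a.element)
        at.pos = gemmi.Position(*a.position)
        at.occ = a.occupancy
        at.b_iso = a.b_iso
        if a.u_aniso is not None:
            u = a.u_aniso
            at.aniso = gemmi.SMat33f(
                u[0, 0], u[1, 1], u[2, 2], u[0, 1], u[0, 2], u[1, 2]
            )
        res.add_atom(at)
    for ch in chains.values():
        gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


_AMINO = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


# --------------------------------------------------------------------------
# map I/O

_ORIGIN_WORDS = (50, 51, 52)  # MRC ORIGIN header words


def read_map(path: str | Path) -> DensityGrid:
    """Read a CCP4/MRC volumetric map.

    Axis order is normalized to X-fastest... canonical (x, y, z) indexing;
    mean and rmsd come from the data, not from the header.
    """
    path = Path(path)
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot read map {path}: {exc}") from exc
    origin = np.array([m.header_float(w) for w in _ORIGIN_WORDS])
    m.setup(float("nan"))
    cell = m.grid.unit_cell
    if min(cell.a, cell.b, cell.c) <= 0:
        raise ValueError(f"non-positive cell in {path}")
    values = np.asarray(m.grid.array, dtype=np.float64)
    if not np.isfinite(values).all():
        raise ValueError(f"map {path} has missing grid sections")
    return DensityGrid(values, (cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma), origin)


def write_map(grid: DensityGrid, path: str | Path) -> None:
    """Write a grid as a CCP4/MRC map (mode 2, float32).

    The Cartesian origin is stored in the MRC ORIGIN header words, so
    write/read round-trips preserve absolute positions.
    """
    g = gemmi.FloatGrid(np.ascontiguousarray(grid.values, dtype=np.float32))
    g.set_unit_cell(gemmi.UnitCell(*grid.cell))
    m = gemmi.Ccp4Map()
    m.grid = g
    m.update_ccp4_header()
    for w, x in zip(_ORIGIN_WORDS, grid.origin):
        m.set_header_float(w, float(x))
    m.write_ccp4_map(str(path))
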