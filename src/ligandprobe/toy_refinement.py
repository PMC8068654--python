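"""Desk-scale restrained refinement and the quantum-refinement combination.

Crystallographic refinement minimizes

    E_cryst = w_A * E_Xray + E_MM                               (level 1)

where E_Xray measures disagreement between observed and model structure-
factor amplitudes and E_MM is the empirical (molecular-mechanics-like)
restraint energy.  Quantum refinement swaps the restraints of a chemically
interesting region ("system 1") for an explicit energy of that region:

    E_cqx = w_MM * (w_A * E_Xray + E_MM - E_MM1) + E_QM1        (level 2)

with E_MM1 the restraint energy of system 1 (subtracted to avoid double
counting) and w_MM rescaling the statistical-unit restraints against the
physical-unit region energy.  Standard weights: w_A = 1.5368 (the CNS
default) and w_MM = 1/3.

This implementation is deliberately small: structure factors come from
direct summation over Gaussian atoms, E_Xray is a least-squares amplitude
residual after an optimal linear scale (a maximum-likelihood target would
need an error model that adds nothing to the energy-combination logic, and
the X-ray functional is pluggable), and the system-1 backend is a plain
callback returning energy and gradient for the region atoms — a harmonic
surrogate in the tests, a genuine QM engine in principle.  Coordinates
only are refined; B factors and occupancies stay fixed.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable, Sequence

import gemmi
import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .model_map_io import AtomRecord, StructureModel

__all__ = [
    "ReflectionSet",
    "EnergyWeights",
    "EnergyBreakdown",
    "BondRestraint",
    "AngleRestraint",
    "generate_indices",
    "direct_structure_factors",
    "exray_energy",
    "restraint_energy",
    "restraints_from_model",
    "combined_energy",
    "minimize",
    "DEFAULT_WA",
    "DEFAULT_WMM",
]

DEFAULT_WA = 1.5368
DEFAULT_WMM = 1.0 / 3.0

Backend = Callable[[list[AtomRecord]], tuple[float, np.ndarray]]


@dataclasses.dataclass
class ReflectionSet:
    indices: np.ndarray            # (n, 3) integer Miller indices
    cell: tuple[float, ...]        # 6 lattice parameters
    f_obs: np.ndarray | None = None
    f_calc: np.ndarray | None = None  # complex

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        uniq = {tuple(h) for h in self.indices}
        if len(uniq) != len(self.indices):
            raise ValueError("duplicate Miller indices")
        if self.f_obs is not None:
            self.f_obs = np.asarray(self.f_obs, dtype=float)
            if (self.f_obs < 0).any():
                raise ValueError("negative observed amplitude")


@dataclasses.dataclass(frozen=True)
class EnergyWeights:
    w_a: float = DEFAULT_WA
    w_mm: float = DEFAULT_WMM

    def __post_init__(self) -> None:
        if self.w_a <= 0 or self.w_mm <= 0:
            raise ValueError("weights must be positive")


@dataclasses.dataclass(frozen=True)
class EnergyBreakdown:
    """All terms of one evaluation; the combined values are derived
    exactly from the stored terms, so the level-1/level-2 identities hold
    to round-off by construction."""

    e_xray: float
    e_mm: float
    e_mm1: float
    e_qm1: float
    weights: EnergyWeights
    gradient: np.ndarray  # (n_atoms, 3)

    @property
    def e_cryst(self) -> float:
        return self.weights.w_a * self.e_xray + self.e_mm

    @property
    def e_cqx(self) -> float:
        w = self.weights
        return w.w_mm * (w.w_a * self.e_xray + self.e_mm - self.e_mm1) + self.e_qm1


@dataclasses.dataclass(frozen=True)
class BondRestraint:
    a: tuple[str, str]
    b: tuple[str, str]
    d0: float
    k: float = 1.0


@dataclasses.dataclass(frozen=True)
class AngleRestraint:
    a: tuple[str, str]
    b: tuple[str, str]  # vertex
    c: tuple[str, str]
    theta0: float       # degrees
    k: float = 1.0


def generate_indices(
    cell: Sequence[float], d_min: float, include_f000: bool = True
) -> np.ndarray:
    """Unique Miller indices to resolution d_min (one Friedel mate each)."""
    uc = gemmi.UnitCell(*cell)
    hmax = [int(math.floor(edge / d_min)) for edge in (uc.a, uc.b, uc.c)]
    out = []
    for h in range(-hmax[0], hmax[0] + 1):
        for k in range(-hmax[1], hmax[1] + 1):
            for l in range(-hmax[2], hmax[2] + 1):
                if (h, k, l) == (0, 0, 0):
                    continue
                # keep one hemisphere: first nonzero index positive
                if h < 0 or (h == 0 and (k < 0 or (k == 0 and l < 0))):
                    continue
                if uc.calculate_d((h, k, l)) >= d_min:
                    out.append((h, k, l))
    if include_f000:
        out.insert(0, (0, 0, 0))
    return np.array(out, dtype=int)


def _frac_matrix(cell: Sequence[float]) -> np.ndarray:
    return np.array(gemmi.UnitCell(*cell).frac.mat.tolist())


def _atom_factors(model: StructureModel, indices: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-(reflection, atom) complex contributions and phase-gradient
    directions.  Returns (terms (n_h, n_a) complex, q (n_h, 3))."""
    uc = gemmi.UnitCell(*model.cell)
    frac = _frac_matrix(model.cell)
    pos = model.positions()
    xfrac = pos @ frac.T                                    # (n_a, 3)
    inv_d2 = np.array([uc.calculate_1_d2(tuple(h)) for h in indices])
    w = np.array([a.occupancy * a.n_electrons for a in model.atoms])
    b = np.array([a.b_iso for a in model.atoms])
    falloff = np.exp(-np.outer(inv_d2, b) / 4.0)            # (n_h, n_a)
    phase = np.exp(2j * math.pi * (indices @ xfrac.T))      # (n_h, n_a)
    terms = w[None, :] * falloff * phase
    q = indices @ frac                                      # (n_h, 3): d(h.xfrac)/dx_cart
    return terms, q


def direct_structure_factors(
    model: StructureModel, indices: np.ndarray
) -> ReflectionSet:
    """F(h) = sum_j occ_j f_j exp(-B_j s^2 / 4) exp(2 pi i h . x_frac,j)
    with a single-Gaussian form factor equal to n_electrons at s = 0."""
    if not len(model):
        raise ValueError("empty model")
    terms, _ = _atom_factors(model, np.asarray(indices, dtype=int))
    return ReflectionSet(
        indices=np.asarray(indices, dtype=int),
        cell=model.cell,
        f_calc=terms.sum(axis=1),
    )


def exray_energy(
    model: StructureModel, reflections: ReflectionSet
) -> tuple[float, np.ndarray]:
    """Least-squares amplitude residual after the optimal linear scale.

    E = sum_h (k |F_calc| - F_obs)^2 with k minimizing E.  The gradient
    with respect to Cartesian coordinates is analytic; because k is at its
    optimum, treating it as fixed gives the exact total derivative.
    """
    if reflections.f_obs is None:
        raise ValueError("reflections carry no observed amplitudes")
    if len(reflections.indices) == 0:
        raise ValueError("empty reflection set")
    terms, q = _atom_factors(model, reflections.indices)
    f_calc = terms.sum(axis=1)
    amp = np.abs(f_calc)
    fo = reflections.f_obs
    denom = float(np.sum(amp**2))
    if denom == 0:
        raise ValueError("all calculated amplitudes vanish")
    k = float(np.sum(fo * amp)) / denom
    resid = k * amp - fo
    energy = float(np.sum(resid**2))
    # d|F|/dx_{j,c} = 2 pi q_c * (-Im(conj(F) term_j)) / |F|
    safe_amp = np.where(amp > 1e-12, amp, 1.0)
    coef = 2.0 * k * resid / safe_amp                       # (n_h,)
    im = -np.imag(np.conj(f_calc)[:, None] * terms)         # (n_h, n_a)
    grad = 2.0 * math.pi * np.einsum("h,ha,hc->ac", coef, im, q)
    return energy, grad


def restraint_energy(
    model: StructureModel,
    restraints: Sequence[BondRestraint | AngleRestraint],
) -> tuple[float, np.ndarray]:
    """Harmonic bond and angle restraints: sum k (d - d0)^2 + k (th - th0)^2
    (angles in radians internally), with analytic gradients."""
    index = {a.key: i for i, a in enumerate(model.atoms)}
    pos = model.positions()
    grad = np.zeros_like(pos)
    energy = 0.0
    for r in restraints:
        if isinstance(r, BondRestraint):
            try:
                ia, ib = index[r.a], index[r.b]
            except KeyError as exc:
                raise KeyError(f"restraint references missing atom {exc}") from exc
            d = pos[ia] - pos[ib]
            dist = float(np.linalg.norm(d))
            delta = dist - r.d0
            energy += r.k * delta**2
            if dist > 1e-12:
                g = 2.0 * r.k * delta * d / dist
                grad[ia] += g
                grad[ib] -= g
        elif isinstance(r, AngleRestraint):
            try:
                ia, ib, ic = index[r.a], index[r.b], index[r.c]
            except KeyError as exc:
                raise KeyError(f"restraint references missing atom {exc}") from exc
            u = pos[ia] - pos[ib]
            v = pos[ic] - pos[ib]
            nu, nv = np.linalg.norm(u), np.linalg.norm(v)
            uh, vh = u / nu, v / nv
            w = float(np.clip(np.dot(uh, vh), -1.0, 1.0))
            theta = math.acos(w)
            delta = theta - math.radians(r.theta0)
            energy += r.k * delta**2
            sin = math.sqrt(max(1.0 - w * w, 1e-12))
            dw_da = (vh - w * uh) / nu
            dw_dc = (uh - w * vh) / nv
            fac = -2.0 * r.k * delta / sin
            grad[ia] += fac * dw_da
            grad[ic] += fac * dw_dc
            grad[ib] -= fac * (dw_da + dw_dc)
        else:
            raise TypeError(f"unknown restraint type {type(r)!r}")
    return energy, grad


def restraints_from_model(
    model: StructureModel, cutoff: float = 2.7, k: float = 10.0
) -> list[BondRestraint]:
    """Bond restraints at the model's current distances for all atom pairs
    within ``cutoff`` A — convenient for parameter-recovery experiments
    where the starting geometry is the truth."""
    out = []
    atoms = model.atoms
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            d = float(np.linalg.norm(atoms[i].position - atoms[j].position))
            if d <= cutoff:
                out.append(BondRestraint(atoms[i].key, atoms[j].key, d0=d, k=k))
    return out


def _region_restraints(
    restraints: Sequence[BondRestraint | AngleRestraint],
    region: set[tuple[str, str]],
) -> list[BondRestraint | AngleRestraint]:
    """Restraints whose atoms all belong to system 1."""
    kept = []
    for r in restraints:
        keys = (r.a, r.b) if isinstance(r, BondRestraint) else (r.a, r.b, r.c)
        if all(kk in region for kk in keys):
            kept.append(r)
    return kept


def combined_energy(
    model: StructureModel,
    reflections: ReflectionSet,
    restraints: Sequence[BondRestraint | AngleRestraint],
    region: Sequence[tuple[str, str]],
    weights: EnergyWeights = EnergyWeights(),
    system1_backend: Backend | None = None,
) -> EnergyBreakdown:
    """Evaluate every term of the two-level energy and its gradient.

    ``region`` selects system 1; ``system1_backend`` receives the region's
    atom records (current coordinates) and returns (energy, gradient over
    region atoms).  A restraint belongs to E_MM1 only if all of its atoms
    are inside the region.
    """
    region_set = set(region)
    if not region_set:
        raise ValueError("empty system-1 region")
    keys = {a.key for a in model.atoms}
    if not region_set <= keys:
        raise ValueError(f"region atoms not in model: {sorted(region_set - keys)}")

    e_xray, g_xray = exray_energy(model, reflections)
    e_mm, g_mm = restraint_energy(model, restraints)
    e_mm1, g_mm1 = restraint_energy(model, _region_restraints(restraints, region_set))

    region_atoms = [a for a in model.atoms if a.key in region_set]
    if system1_backend is None:
        e_qm1, g_qm1_local = e_mm1, None
    else:
        try:
            e_qm1, g_qm1_local = system1_backend(region_atoms)
        except Exception as exc:
            raise RuntimeError(f"system-1 backend failed: {exc}") from exc
        if not math.isfinite(e_qm1):
            raise ValueError("system-1 backend returned non-finite energy")
    g_qm1 = np.zeros_like(g_xray)
    if g_qm1_local is None:
        g_qm1 = g_mm1.copy()
    else:
        local = {a.key: i for i, a in enumerate(region_atoms)}
        for i, a in enumerate(model.atoms):
            if a.key in local:
                g_qm1[i] = np.asarray(g_qm1_local)[local[a.key]]

    w = weights
    grad = w.w_mm * (w.w_a * g_xray + g_mm - g_mm1) + g_qm1
    return EnergyBreakdown(
        e_xray=e_xray, e_mm=e_mm, e_mm1=e_mm1, e_qm1=e_qm1,
        weights=w, gradient=grad,
    )


def rmsd_between(
    a: StructureModel, b: StructureModel, remove_translation: bool = True
) -> float:
    """Positional RMSD between two models with identical atom order.

    Amplitude-only X-ray targets are invariant under a global translation
    (the P1 origin is free), so by default the mean displacement is removed
    before comparing — the meaningful recovery error is the internal one.
    """
    pa, pb = a.positions(), b.positions()
    if pa.shape != pb.shape:
        raise ValueError("models differ in atom count")
    d = pa - pb
    if remove_translation:
        d = d - d.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(d**2, axis=1))))


def minimize(
    model: StructureModel,
    energy_fn: Callable[[StructureModel], tuple[float, np.ndarray]],
    gtol: float = 1e-5,
    max_iter: int = 500,
) -> tuple[StructureModel, list[float]]:
    """Gradient-based coordinate minimization (L-BFGS with line search).

    ``energy_fn(model) -> (energy, gradient (n, 3))``.  Returns the
    refined model and the trace of accepted energies (non-increasing).
    Deterministic given identical inputs.
    """
    work = model.copy()
    x0 = work.positions().ravel()

    def objective(x: np.ndarray) -> tuple[float, np.ndarray]:
        for a, p in zip(work.atoms, x.reshape(-1, 3)):
            a.position = p
        e, g = energy_fn(work)
        if not math.isfinite(e):
            raise ValueError("non-finite energy during minimization")
        return e, g.ravel()

    trace: list[float] = [objective(x0)[0]]

    def callback(xk: np.ndarray) -> None:
        trace.append(objective(xk)[0])

    res = _scipy_minimize(
        objective, x0, jac=True, method="L-BFGS-B",
        callback=callback,
        options={"maxiter": max_iter, "gtol": gtol, "ftol": 1e-12},
    )
    for a, p in zip(work.atoms, res.x.reshape(-1, 3)):
        a.position = p
    if not trace or res.fun <= trace[-1]:
        trace.append(float(res.fun))
    return work, trace
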