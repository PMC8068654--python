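import numpy as np
import pytest

from ligandprobe import (
    AngleRestraint,
    BondRestraint,
    EnergyWeights,
    LigandVariant,
    ReflectionSet,
    StructureModel,
    combined_energy,
    direct_structure_factors,
    exray_energy,
    generate_indices,
    minimize,
    restraint_energy,
    restraints_from_model,
    substitute_ligand,
)
from ligandprobe.model_map_io import AtomRecord
from ligandprobe.toy_refinement import rmsd_between


@pytest.fixture(scope="module")
def observed(femo_boxed):
    idx = generate_indices(femo_boxed.cell, 1.5)
    truth = direct_structure_factors(femo_boxed, idx)
    return ReflectionSet(idx, femo_boxed.cell, f_obs=np.abs(truth.f_calc))


def five_atom_model():
    rng = np.random.default_rng(42)
    atoms = [
        AtomRecord(i + 1, f"X{i}", el, "A", "LIG", i + 1,
                   5.0 + rng.uniform(-2, 2, 3), b_iso=12.0)
        for i, el in enumerate(["S", "Fe", "N", "O", "C"])
    ]
    return StructureModel(atoms, (10, 10, 10, 90, 90, 90))


class TestStructureFactors:
    def test_f000_equals_total_electrons(self, femo_boxed):
        rs = direct_structure_factors(femo_boxed, np.array([[0, 0, 0]]))
        assert rs.f_calc[0] == pytest.approx(femo_boxed.total_electrons())
        assert abs(rs.f_calc[0].imag) < 1e-9

    def test_friedel_symmetry(self, femo_boxed):
        idx = np.array([[1, 2, 3], [-1, -2, -3], [2, 0, -1], [-2, 0, 1]])
        rs = direct_structure_factors(femo_boxed, idx)
        assert rs.f_calc[1] == pytest.approx(np.conj(rs.f_calc[0]))
        assert rs.f_calc[3] == pytest.approx(np.conj(rs.f_calc[2]))

    def test_origin_atom_has_zero_phase_and_shift_rule(self):
        cell = (10, 10, 10, 90, 90, 90)
        m0 = StructureModel(
            [AtomRecord(1, "S", "S", "A", "LIG", 1, (0, 0, 0), b_iso=10.0)], cell
        )
        idx = np.array([[1, 0, 0], [2, 1, 0], [3, -1, 2]])
        f0 = direct_structure_factors(m0, idx).f_calc
        assert np.allclose(np.angle(f0), 0.0, atol=1e-12)
        dx = np.array([0.7, 0.0, 0.0])
        m1 = StructureModel(
            [AtomRecord(1, "S", "S", "A", "LIG", 1, dx, b_iso=10.0)], cell
        )
        f1 = direct_structure_factors(m1, idx).f_calc
        expected = f0 * np.exp(2j * np.pi * idx @ (dx / 10.0))
        assert np.allclose(f1, expected)

    def test_duplicate_indices_rejected(self, femo_boxed):
        with pytest.raises(ValueError, match="duplicate"):
            ReflectionSet(np.array([[1, 0, 0], [1, 0, 0]]), femo_boxed.cell)


class TestExrayEnergy:
    def test_zero_at_truth(self, femo_boxed, observed):
        e, g = exray_energy(femo_boxed, observed)
        assert e == pytest.approx(0.0, abs=1e-12)
        assert np.abs(g).max() < 1e-6

    def test_scale_freedom(self, femo_boxed, observed):
        pert = femo_boxed.copy()
        pert.atoms[0].position = pert.atoms[0].position + 0.2
        e1, _ = exray_energy(pert, observed)
        doubled = ReflectionSet(
            observed.indices, observed.cell, f_obs=2 * observed.f_obs
        )
        e2, _ = exray_energy(pert, doubled)
        # energy is quadratic in the data scale; the relative residual
        # sqrt(E)/||f_obs|| is invariant
        assert e2 == pytest.approx(4 * e1, rel=1e-9)

    def test_gradient_matches_finite_differences(self):
        m = five_atom_model()
        idx = generate_indices(m.cell, 2.0)
        f_obs = np.abs(direct_structure_factors(m, idx).f_calc)
        # perturb so the gradient is nonzero
        pert = m.copy()
        rng = np.random.default_rng(0)
        for a in pert.atoms:
            a.position = a.position + rng.normal(0, 0.15, 3)
        obs = ReflectionSet(idx, m.cell, f_obs=f_obs)
        e0, g = exray_energy(pert, obs)
        h = 1e-6
        for ia in (0, 2, 4):
            for c in range(3):
                p = pert.copy()
                p.atoms[ia].position[c] += h
                e1, _ = exray_energy(p, obs)
                num = (e1 - e0) / h
                assert g[ia, c] == pytest.approx(num, rel=1e-4, abs=1e-8)


class TestRestraints:
    def test_zero_at_ideal_geometry(self, femo_boxed):
        rs = restraints_from_model(femo_boxed)
        e, g = restraint_energy(femo_boxed, rs)
        assert e == pytest.approx(0.0, abs=1e-18)
        assert np.abs(g).max() < 1e-9

    def test_stretched_bond_closed_form(self):
        atoms = [
            AtomRecord(1, "A1", "S", "A", "LIG", 1, (0, 0, 0)),
            AtomRecord(2, "A2", "S", "A", "LIG", 2, (2.5, 0, 0)),
        ]
        m = StructureModel(atoms, (10, 10, 10, 90, 90, 90))
        k, d0, delta = 3.0, 2.3, 0.2
        e, g = restraint_energy(m, [BondRestraint(("A", "A1"), ("A", "A2"), d0, k)])
        assert e == pytest.approx(k * delta**2)
        assert g[1, 0] == pytest.approx(2 * k * delta)

    def test_gradient_matches_finite_differences(self):
        m = five_atom_model()
        restraints = restraints_from_model(m, cutoff=3.5, k=2.0) + [
            AngleRestraint(("A", "X0"), ("A", "X1"), ("A", "X2"), theta0=100.0, k=1.5)
        ]
        e0, g = restraint_energy(m, restraints)
        h = 1e-7
        for ia in range(len(m)):
            for c in range(3):
                p = m.copy()
                p.atoms[ia].position[c] += h
                e1, _ = restraint_energy(p, restraints)
                assert g[ia, c] == pytest.approx((e1 - e0) / h, rel=1e-4, abs=1e-6)

    def test_dangling_restraint(self, femo_boxed):
        bad = [BondRestraint(("A", "MO"), ("B", "ZZ"), 2.0)]
        with pytest.raises(KeyError):
            restraint_energy(femo_boxed, bad)


class TestCombinedEnergy:
    def region(self, model):
        return [a.key for a in model.atoms if a.residue_name == "ICS"]

    def test_identities_with_surrogate_backend(self, femo_boxed, observed):
        # when the system-1 energy equals its restraint energy,
        # E_cqx = w_mm (w_a E_xray + E_mm) + (1 - w_mm) E_mm1
        pert = femo_boxed.copy()
        pert.atoms[0].position = pert.atoms[0].position + 0.1
        rs = restraints_from_model(femo_boxed)
        w = EnergyWeights()
        bd = combined_energy(pert, observed, rs, self.region(pert), w)
        assert bd.e_qm1 == bd.e_mm1
        expected = w.w_mm * (w.w_a * bd.e_xray + bd.e_mm) + (1 - w.w_mm) * bd.e_mm1
        assert bd.e_cqx == pytest.approx(expected, rel=1e-12)
        # level-1 identity holds by construction
        assert bd.e_cryst == pytest.approx(w.w_a * bd.e_xray + bd.e_mm, rel=1e-15)

    def test_wmm_one_reduces_to_level_one(self, femo_boxed, observed):
        pert = femo_boxed.copy()
        pert.atoms[3].position = pert.atoms[3].position + 0.15
        rs = restraints_from_model(femo_boxed)
        w = EnergyWeights(w_a=1.5368, w_mm=1.0)
        bd = combined_energy(pert, observed, rs, self.region(pert), w)
        assert bd.e_cqx == pytest.approx(bd.e_cryst, rel=1e-12)

    def test_custom_backend_and_failure_propagation(self, femo_boxed, observed):
        rs = restraints_from_model(femo_boxed)
        region = self.region(femo_boxed)

        def harmonic(atoms):
            pos = np.array([a.position for a in atoms])
            center = pos.mean(axis=0)
            e = float(np.sum((pos - center) ** 2))
            return e, 2 * (pos - center)

        bd = combined_energy(femo_boxed, observed, rs, region,
                             system1_backend=harmonic)
        assert bd.e_qm1 > 0

        def broken(atoms):
            raise RuntimeError("scf blew up")

        with pytest.raises(RuntimeError, match="scf blew up"):
            combined_energy(femo_boxed, observed, rs, region,
                            system1_backend=broken)

    def test_empty_region_rejected(self, femo_boxed, observed):
        with pytest.raises(ValueError, match="region"):
            combined_energy(femo_boxed, observed, [], [])


class TestMinimize:
    def make_energy(self, observed, restraints, w=EnergyWeights()):
        def efun(m):
            ex, gx = exray_energy(m, observed)
            em, gm = restraint_energy(m, restraints)
            return w.w_a * ex + em, w.w_a * gx + gm

        return efun

    def test_immediate_convergence_at_truth(self, femo_boxed, observed):
        rs = restraints_from_model(femo_boxed)
        refined, trace = minimize(femo_boxed, self.make_energy(observed, rs))
        assert rmsd_between(refined, femo_boxed, remove_translation=False) < 1e-3

    def test_recovers_perturbed_coordinates(self, femo_boxed, observed):
        rs = restraints_from_model(femo_boxed)
        efun = self.make_energy(observed, rs)
        rng = np.random.default_rng(1)
        start = femo_boxed.copy()
        for a in start.atoms:
            a.position = a.position + rng.normal(0, 0.3 / np.sqrt(3), 3)
        refined, trace = minimize(start, efun, gtol=1e-7, max_iter=1000)
        assert rmsd_between(refined, femo_boxed) < 0.05
        assert all(a >= b - 1e-9 for a, b in zip(trace, trace[1:]))

    def test_sulfide_truth_penalizes_n2_model(self, femo_boxed, observed):
        # data synthesized from the all-sulfide cluster: refining an
        # N2-at-2B model always leaves a larger X-ray residual
        w = EnergyWeights()
        n2 = substitute_ligand(femo_boxed, LigandVariant("2B", "N2"))
        results = {}
        for label, model0 in (("S2-", femo_boxed), ("N2", n2)):
            rs = restraints_from_model(model0)
            efun = self.make_energy(observed, rs, w)
            wins = []
            for seed in range(10):
                rng = np.random.default_rng(seed)
                start = model0.copy()
                for a in start.atoms:
                    a.position = a.position + rng.normal(0, 0.05, 3)
                refined, _ = minimize(start, efun, max_iter=300)
                wins.append(exray_energy(refined, observed)[0])
            results[label] = wins
        assert all(
            en > es for en, es in zip(results["N2"], results["S2-"])
        )
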