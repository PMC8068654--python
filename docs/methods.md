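# Methods

## The problem and the model of the data

A crystallographic claim that a sulfide ligand has been replaced by an
N₂-derived diatomic is, at bottom, a claim about electron count (18 vs 14
or 16 electrons at one site) and peak shape (spherical vs elongated).
`ligandprobe` turns both into explicit statistics computed from three
inputs: a coordinate model, a 2mFo−DFc-style density map, and optionally
an anomalous map and an mFo−DFc difference map.  Every statistic also has
a synthetic analogue with known ground truth, generated by the package
itself, so the whole pipeline is testable without deposited data.

## Density containers and units

A `DensityGrid` stores a scalar field on a box described by six lattice
parameters, with voxel values taken as point samples at voxel centers
(0-based indices) and an explicit Cartesian origin.  Positions are Å in
the orthogonalized frame; the grid owns the fractional↔Cartesian
conversion.  Map mean and rmsd are always recomputed from the array —
deposited headers are not trusted — and σ-units are the affine transform
(v − mean)/rmsd, which preserves voxel ranking.  Maps are read and
written through gemmi's CCP4/MRC support with the Cartesian origin kept
in the MRC ORIGIN header words; axis order is normalized on read.  Only
P1-style direct interpretation is supported; symmetry expansion is out of
scope.

## Sphere integration

ρ(site) = Σ value × voxel-volume over voxels whose **centers** fall
within radius R of the site (default R = 1.05 Å, the covalent radius of
S).  No partial-voxel weighting: the midpoint rule is simple and
converges — halving the spacing at least halves the error against the
closed-form isotropic-Gaussian sphere integral

    ρ_exact = N [ erf(√a R) − 2 √(a/π) R e^(−aR²) ],   a = 4π²/B,

which the tests use as an independent oracle (≤ 2 % error at 0.25 Å
spacing).  One numerical caveat, found while validating: if the sphere
center sits exactly on a lattice point the boundary-voxel pattern is
commensurate across spacings and the convergence stalls at a small
plateau; convergence tests therefore use a generic off-lattice center.
Values are reported in the map's native unit × Å³; absolute e-units
depend on the deposited map scaling, which the package does not
re-derive.  `peak_appearance_level` reports the maximum σ value inside
the sphere — the highest contour at which the site shows any density.

## Population statistics

Site integrals are compared against reference populations (all S atoms,
or the ten S atoms of the same cluster) by z = (ρ − mean)/sd with the
**sample** (n−1) standard deviation and the **leave-in** convention (the
target atom stays in its reference population).  Both conventions were
fixed by verifying that they reproduce the published per-atom tables for
the 6UG0 re-evaluation, including the S2B anomalous cluster z of −1.68.
The "significance" of a deviation z in a population of n atoms is the
two-sided Student-t probability 1 − 2·P(T_{n−1} > |z|).  The Student form
is a reconstruction — it reproduces the published 0.87 for z = −1.68 at
df = 9, where a normal tail gives ≈ 0.91 — and the normal alternative is
exposed via `method="normal"`.  Note that at the rounded z = 1.7 the t
formula gives 0.877; the published 0.87 corresponds to the unrounded
deviation.  Significance is strictly increasing in |z| and also in df
(thinner tails), approaching the normal value as df → ∞.

## Difference-density region scores

The real-space difference-density Z score used by validation programs is
not publicly specified, so the package implements a documented surrogate
with the same intent.  For a region (union of spheres of radius 1.05 Å
around the group's atoms) the σ-values of the difference map are split by
sign; each signed set contributes χ²_eff = Σ v² / f with the oversampling
factor f = (d_min/2)³ / V_voxel (one independent sample per Shannon
volume), compared against a χ² with dof = count/f, and mapped to a
standard-normal equivalent clipped at zero (Wilson–Hilferty tail for
underflowing survival values).  rszd = max(rszd_pos, rszd_neg).
Properties: flipping the map sign swaps the two scores exactly; on
pure-noise maps the median score over 200 seeds is ≈ 0.5 (an honest
|Z|); a 4-electron deficit at a ligand site separates the mismatched
model from the matched one in 20/20 noise realizations at noise sd 0.05
map units.  Absolute published per-region values are **not**
reproducible without the original refined models and program internals;
only printed row sums, orderings and the surrogate's calibration are
validated.  Model reports sum the per-region rszd values; ranking is
ascending by total, ties broken by the largest single-region score, then
label.

## Geometry and displacement diagnostics

Distances are Euclidean in Å.  Anisotropic displacement tensors U (Å²)
are eigendecomposed with eigenvalues sorted descending; the anisotropy
ratio is λ₃/λ₁.  `bond_axis_alignment` measures the angle between a
diatomic's bond vector and the major axis of the averaged tensor
(U_a + U_b)/2, folded to [0°, 90°] because eigenvectors are sign-
ambiguous; per-atom modes are available since the pair-average choice is
a convention.  A diatomic whose bond hugs the maximum-anisotropy axis is
the signature of an elongation artefact from direction-dependent
resolution.

## Synthetic data generator

The fixture is an idealized MoFe₇S₉C cluster: central carbide at the
origin, six belt Fe on a trigonal prism (Fe–C = 2.0 Å), apical Fe1 and
Mo, the three μ₂ belt sulfides on the waist (S2B bridging Fe2/Fe6, S3A
Fe4/Fe5, S5A Fe3/Fe7, Fe–S ≈ 2.3 Å), six μ₃ caps, a Cys thiolate on Fe1
and the homocitrate O7/O6 oxygens chelating Mo at 2.10/2.13 Å.  Only
topology and atom names match the real cofactor; no published
coordinates are used, and all tests are relative, so idealized geometry
suffices.  Cluster sulfides carry 18 electrons (S²⁻), the Cys S 16.
`substitute_ligand` swaps a μ₂ sulfide for N₂ (two N, 1.10 Å bond,
centred on the former S position along a caller-chosen orientation) or
trans-N₂H₂ (adds two H, total 16 e).

Maps are sums of single-Gaussian atoms: each atom contributes
occupancy × n_electrons × N(x; Σ) with Σ = (B/8π²)·I + aniso_smear, so
the all-space integral of each atom is exactly its electron count.
Single-term Gaussians (not Cromer–Mann multi-term fits) keep
normalization exact, which is what the tests need; scattering accuracy
is not a goal.  Atoms are rendered within a 5σ cutoff.  An optional
sharp reciprocal-space cutoff at 1/d_min reproduces Fourier truncation
ripples (negative lobes around electron-rich clusters); when an
anisotropic smear is set the cutoff becomes ellipsoidal — the axis with
the largest smear keeps the least reciprocal extent — mimicking
direction-dependent data resolution.  Seeded Gaussian noise is added
last (`numpy` default_rng, bit-reproducible per seed).  The anomalous
generator replaces electron counts by per-element weights, default
{S: 1, Fe: 0.25, Mo: 4}: free parameters chosen to match the qualitative
7100 eV situation (Mo ≫ S > Fe ≫ light atoms); no published calibration
exists at that energy.  Because atoms add independently, a map of a
model union equals the sum of the submodel maps up to float
addition-order round-off.

What the generator does **not** emulate: solvent and bulk-solvent
contrast, crystallographic symmetry, protein atoms beyond the cluster's
first shell, maximum-likelihood map weighting, and correlated (non-white)
noise.  Passing synthetic tests therefore demonstrates correctness of
the statistics and their discrimination power under idealized imaging,
not performance on real deposited maps.

## Refinement energies

Structure factors come from direct summation over Gaussian atoms,
F(h) = Σ occ·n_e·exp(−B s²/4)·exp(2πi h·x_frac), so F(000) equals the
total electron count and Friedel symmetry is exact.  E_Xray is the
least-squares amplitude residual Σ (k|F_c| − F_o)² after the optimal
linear scale k; since k is at its optimum the gradient with k held fixed
is the exact total derivative.  A maximum-likelihood target would need
an error model that is orthogonal to the energy-combination logic, which
is the point of this module; the X-ray functional is a pluggable
callable.  Restraints are harmonic bonds k(d−d₀)² and angles k(θ−θ₀)²
with analytic gradients (verified against central differences to 1e−4
relative).

The two-level combination is evaluated term by term:
E_cryst = w_A·E_Xray + E_MM and
E_cqx = w_MM(w_A·E_Xray + E_MM − E_MM1) + E_QM1, with defaults
w_A = 1.5368 (the CNS default) and w_MM = 1/3.  The combined values are
derived properties of the stored terms, so the identities hold to
round-off on every evaluation.  E_MM1 contains exactly those restraints
whose atoms all lie in system 1 (junction handling beyond this rule is
out of scope).  The system-1 backend is a callback receiving the region's
atom records and returning (energy, gradient); tests use harmonic
surrogates, and by default E_QM1 falls back to E_MM1, which collapses
level 2 onto a rescaled level 1.  Energy units are arbitrary; no attempt
is made to reproduce any program's internal scaling.

Minimization is coordinate-only (B factors and occupancies fixed) via
L-BFGS with line search; the accepted-energy trace is non-increasing and
the optimizer is deterministic.  One consequence of the amplitude-only
target in P1 deserves emphasis: |F| is invariant under a global
translation of the model, so the origin is a gauge freedom.  Recovery
experiments therefore measure RMSD after removing the mean displacement
(`rmsd_between(..., remove_translation=True)`); the internal structure is
recovered to ≲ 1e−4 Å from 0.3 Å perturbations on noiseless complete
data to 1.5 Å.

## Problem sizes and numerical choices

Test and acceptance runs use the 21-atom cluster fixture in a 14 Å P1
box (≈ 1700 reflections to 1.5 Å), 0.25–0.4 Å map spacings with 2–4 Å
padding, 20 noise seeds for discrimination experiments and 200 for null
calibration — sizes chosen so each experiment is statistically stable
while the whole suite stays interactive.  Degenerate inputs fail loudly:
spheres that leave the grid, empty selections or regions, zero-sd
reference populations, non-positive cells, missing anisotropic tensors,
duplicate Miller indices and non-finite energies all raise with the
offending atom or value named.

## Known limitations

- Absolute e-unit calibration of deposited maps is not re-derived; all
  cross-map comparisons should stay within one map's unit system.
- The difference-score surrogate matches the published scores only at
  the level of sums and orderings, by construction.
- No crystallographic symmetry, ML targets, bulk solvent, anisotropic-B
  refinement, or real QM energies; the backend hook is the extension
  point for the latter.
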