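# Methods

## Scope

`rdcens` determines low-population conformational states of a two-domain
protein from residual dipolar couplings (RDCs). The chain of reasoning it
implements: RDCs measured in partially aligning media report on the average
orientation of internuclear bond vectors; imposing them as *replica-averaged*
restraints on a simulated ensemble yields, by the maximum-entropy principle,
the least-biased ensemble compatible with the data; free-energy surfaces over
an interdomain "breathing" angle then expose a minor, sparsely populated
basin whose weight is set by the data, not by the force field. The package
implements every stage of that loop at desk scale, together with a synthetic
data generator whose ground truth makes the loop falsifiable.

## RDC model

For a bond with unit vector **u** (direction cosines in the molecular frame)
and alignment tensor **A** (symmetric, traceless, 3×3):

    D = D_max Σ_ij A_ij u_i u_j                       [Hz]

The replica-averaged calculated coupling is the plain mean over M replicas,
`D_calc = (1/M) Σ_m D_m`, and the restraint energy added to the
conformational potential is the unweighted quadratic penalty

    E_RDC = α Σ_i (D_exp,i − D_calc,i)²               [kJ/mol]
    E_tot = Σ_m E_pot(replica m) + E_RDC

with α a single global weight in kJ/mol/Hz². The N–H dipolar constant is
fixed at D_max = −21,700 Hz; the absolute alignment magnitude is absorbed
into a single per-medium scale of the tensor model (the two are not
separately identifiable), so only the product is meaningful. Agreement is
quantified with the standard normalisation
Q = √(Σ(D_calc−D_exp)² / ΣD_exp²), per medium and pooled.

## Alignment tensor from shape and charge

A medium is modelled as two parallel planar obstructions a spacing L apart
(default 70 Å). For each wall-normal direction **n** (deterministic spherical
Fibonacci grid, 350 directions by default; minimum 100 enforced), the weight
is the fraction of centre positions at which the molecule, padded by a probe
radius (2 Å), avoids both walls; for a charged medium, admissible positions
are additionally Boltzmann-weighted by a screened single-wall potential
(Debye length 15 Å, wall coupling in kT per unit atomic charge) acting on
per-atom charges, averaged over placements. The tensor is the weighted
orientational average `A = scale · (⟨n nᵀ⟩ − I/3)`. This reproduces the
qualitative behaviour expected of obstruction-based predictors — vanishing
alignment for a sphere, axially symmetric tensors for rods (verified against
a brute-force random-orientation average), covariance under rotation,
invariance under translation — without any fitting to the data being
restrained. A five-parameter SVD fit (`svd_fit_tensor`) is provided as an
oracle/validation mode only; it requires ≥5 non-degenerate couplings and
raises a conditioning error otherwise.

During sampling, a replica's tensor is re-predicted immediately after any
accepted rigid domain rotation and otherwise every 10 accepted moves (the
cached tensor may lag small local jitter, which is harmless; it must not lag
a 9–40° domain rotation). A short-run check confirms the data mismatch is
insensitive to the refresh interval between 1 and 20.

## Sampler

The thermostatted molecular dynamics of the original protocol is replaced by
Metropolis Monte Carlo: the restraint formalism is integrator-agnostic, and
MC needs no force-field machinery. Proposals per replica are

* single-atom Gaussian jitter (σ = 0.06 Å),
* "breathing" rotations of the β-domain about the axis normal to the
  interdomain plane (σ = 1.5°) — this maps the plane to itself, so forward
  and reverse proposals are symmetric,
* "twist" rotations about the hinge→domain axis (σ = 0.6°) — the domain-
  region centre of mass lies on the axis, so the breathing angle is
  untouched,
* composite basin hops: with the hop offset (Δθ, Δψ) between the two basin
  centres, half the breathing proposals jump by ±(Δθ, Δψ) plus small noise.
  The mixture density is even under negation of the increment pair, so
  detailed balance holds; hops give interbasin exchange a direct channel
  instead of relying on diffusive barrier crossing.

Moves are accepted on ΔE_tot, where ΔE_RDC is evaluated through the change
in the replica-averaged couplings — the replica coupling of the restraint is
honoured exactly. Energies are in kJ/mol with k_B = 0.0083145 kJ/mol/K.

The annealing protocol keeps the structure of the full-scale original:
equilibration at 310 K during which α is ramped geometrically to its target
(default 10 kJ/mol/Hz², ramp capped if the acceptance rate falls below 20%),
then cycles alternating a 500 K segment with a 310 K segment, collecting
frames only in the final window of the low-temperature segment of the last
cycles. Two details matter in practice and are deliberate choices:

* **Thermalize before ramping.** Replicas start at the potential minimum,
  where acceptance is transiently low; a short unrestrained thermalization
  (10 ps) precedes the ramp so the acceptance guard measures restraint
  strain, not the start-up transient.
* **α between pinning and noise-chasing.** α must be large enough that
  moving one replica between basins changes E_RDC by several k_BT (so the
  data pin the replica populations), but small enough that α times the
  squared noise level stays comparable to k_BT (so the restraint does not
  finance spurious states by fitting noise). The default 10 kJ/mol/Hz²
  satisfies both for the default synthetic conditions.

The scheduler's arithmetic is exposed separately
(`count_collected_frames`, `count_integrator_steps`) and reproduces the
full-scale protocol numbers exactly (24,000 frames from 16 replicas × last
30 of 50 cycles × 50 ps at 1 frame/ps; 125,000 steps for a 250 ps cycle at
2 fs).

## Toy conformational potential

Two near-rigid domains (all-pairs harmonic distance restraints, 60
kJ/mol/Å²) joined by a short hinge; bonds 300 kJ/mol/Å²; the β-domain is
tethered to the hinge by a centre-of-mass distance term that is exactly
invariant under both breathing and twist rotations, so neither basin carries
spurious strain. The interdomain term is a **smooth minimum (log-sum-exp,
softness 2.5 kJ/mol) of two harmonic basins** in the plane of two hinge
coordinates: the breathing angle θ (curvature 8 kJ/mol/deg²) and the twist ψ
of the β-domain about the interdomain axis (8 kJ/mol/deg²). The ground basin
sits at (58°, ψ₀), depth 18 kJ/mol; the minor basin at (49°, ψ₀+40°), depth
15.5 kJ/mol, giving an unrestrained minor population near 25% at 310 K —
clearly distinct from both the 13% target and the 0% null.

Two design points here were forced by identifiability, discovered the hard
way and worth recording:

1. **The minor state must be a discrete rearrangement, not a point on the
   breathing coordinate.** If the two states differ only by a rigid rotation
   along one smooth coordinate, the back-calculated couplings are nearly
   linear in that coordinate over the 9° separation; the population-averaged
   data then constrain only the *mean* angle, and small within-well shifts
   of the majority replicas can compensate any population split (replica-
   permutation entropy then pushes the split toward 50/50). Adding a 40°
   twist to the minor state makes the two-state fingerprint strongly
   non-collinear with the within-well derivative directions, and one
   replica's state change becomes a >2σ event relative to the 5% data noise.

2. **No flat plateaus.** With Gaussian-well basins the landscape is flat
   between and beyond the wells; at 500 K replicas scatter across the
   plateaus and the rugged restraint surface freezes them there on cooling
   (a glassy, poorly reproducible state). Harmonic bowls give every
   configuration a gradient toward one of the two states.

## Synthetic data generator

The generator defines the study conditions; its defaults are the scenario
the pipeline targets. Ground/minor mixture 87/13 (`p_minor = 0.13`); basin
centres 58°/49° in θ, 40° apart in ψ; per-frame jitter of θ (σ 0.6°), ψ
(σ 0.55°) and atom coordinates (σ 0.04 Å) chosen to match the Boltzmann
fluctuations of the toy potential at 310 K — the generating distribution and
the sampling distribution must agree, otherwise the averaged data are
systematically unmatchable and population estimates bias; RDC noise additive
Gaussian at 5% of the per-medium RMS coupling (mirroring the 5% intensity-
uncertainty convention used for scalar couplings), with the noise level
recorded in the sigma column. The toy protein carries 19 residues (8+3+8) of
four atoms each (N, H, CA, C): N–H bond vectors are the RDC-active spins,
residue orientations are drawn deterministically from the seed so the bond
vectors cover the sphere (keeping SVD fits well-conditioned), and the
N/CA/C triads make backbone φ dihedrals — hence Karplus back-calculation —
well defined. One domain carries a few negative, the other a few positive
formal charges so the steric and electrostatic media genuinely differ.

HNHA cross/diagonal intensities are synthesised by inverting the tangent-
squared intensity relation at ξ = 13.05 ms with multiplicative noise; NOE
upper bounds are observed maximum distances plus slack (satisfied by
construction), with an optional fraction of bounds deliberately placed below
the minimum observed distance (violated in every structure).

What the generator does *not* emulate: real protein geometry or chemistry,
anisotropic domain flexibility, internal side-chain dynamics,
r⁻⁶-averaged NOE intensities, or any coupling between alignment and
conformation beyond molecular shape and charge. Passing tests therefore
demonstrate the correctness and self-consistency of the machinery and the
statistical identifiability of a two-state mixture under these idealised
conditions — not accuracy on experimental data.

## NMR validation

3J(HN–Hα) couplings are extracted from HNHA intensity ratios on the
principal branch, J = arctan(√(−I_X/I_D)) / (2πξ), with first-order error
propagation using max(5% of intensity, noise level) per intensity; positive
ratios and out-of-branch couplings are hard errors; glycines are discarded
by residue-name filter. Back-calculation uses a configurable Karplus curve
(defaults A = 7.09, B = −1.42, C = 1.55 Hz) averaged over the ensemble.
NOEs are evaluated per individual structure (distance ≤ bound + 0.5 Å
tolerance), never r⁻⁶-averaged. The consolidated report carries Q factors,
3J RMSD, NOE satisfied/violated fractions and full row bookkeeping
(used/discarded/excluded counts).

## Landscape analysis

θ is the angle at the hinge-region Cα centre of mass between the vectors to
the α- and β-domain region centres; RMSD uses least-squares superposition
(Kabsch) over an explicit selection (for the toy system, the two domain
cores excluding the hinge). Free-energy surfaces are histogram estimates,
F = −k_B T ln H on populated bins (undefined, not zero, elsewhere), with
default bins of 1° × 0.1 Å — comfortably resolving the 9° basin separation.
The basin partition defaults to the θ = 50° boundary (smaller θ = the
closed, "unlocked" side); non-rectangular basins can be given as a polygon
in the (θ, RMSD) plane. Both mean and mode of θ are reported per basin
because the centre statistic is not uniquely defined. Contact occupancy uses
a 3.5 Å / 120° geometric criterion, evaluated per basin when labels are
supplied.

## Problem sizes and numerical choices

* Desk-scale schedule (`desk_schedule`): 14 cycles of a nominal 40 ps (10 ps
  at 500 K, 30 ps at 310 K), 25 MC moves per replica per nominal ps,
  equilibration 40 ps, frames at 1/ps from the final 10 ps of the last 6
  cycles → 960 frames from 16 replicas. Earlier cycles anneal away
  metastable "defect" states (a single replica parked in the wrong basin
  with the rest compensating) that can persist for several cycles.
* Synthetic data: 200 frames per dataset; 38 restraints (19 N–H bonds × 2
  media).
* Population recovery is validated over 5 independent seeds; the null
  control (p = 0) over 3.
* Orientation grid 350 directions (800 in oracle comparisons); electrostatic
  placements 9 per direction.
* Tie-breaks and degenerate inputs: zero-length bond vectors, collinear
  shapes, all-zero experimental couplings, empty selections and
  non-divisible schedules are all hard errors, never silent fallbacks.
* Determinism: every stochastic operation takes an explicit seed; a run is
  bit-reproducible from its seed.

## Known limitations

* The intrinsic resolution of the population estimate at M = 16 replicas is
  about one replica (±6 percentage points instantaneously); averaging over
  collection windows and cycles brings the practical error below ±3 points
  under default conditions, but single-seed estimates near the resolution
  limit should be read with that granularity in mind.
* The alignment model is a planar-obstruction caricature; absolute tensor
  magnitudes are not meaningful, only relative structure.
* α is a global scalar; per-restraint weighting (e.g. by σ_i) is not
  implemented.
* The sampler's moves are tailored to the two-domain hinge topology;
  arbitrary topologies would need their own move set.
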