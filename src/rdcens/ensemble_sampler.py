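"""Replica ensemble sampling under E_Tot = E_Pot + E_RDC.

The physical content of replica-averaged restraining — a quadratic penalty on
the deviation of the replica-mean back-calculated couplings from experiment,
added to a conformational potential — is integrator-agnostic. At desk scale
the thermostatted molecular dynamics of the original protocol is replaced by
Metropolis Monte Carlo on a toy two-domain potential: local atom jitters plus
rigid hinge rotations of one domain, accepted on the change of the *total*
energy so that the replica coupling through the averaged restraint is
honoured. The simulated-annealing cycle structure (low/high temperature
segments, a restraint-weight ramp during equilibration, frame collection in
the low-temperature window of the final cycles) is kept intact so the
protocol arithmetic is testable, with the wall-clock scale set by the number
of Monte Carlo moves standing in for a picosecond.

Temperatures are in kelvin, energies in kJ/mol (k_B = 0.0083145 kJ/mol/K).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._geometry import angle_deg, rotation_about_axis
from .alignment_tensor import (
    MediumSpec,
    fibonacci_directions,
    orientation_weights,
)
from .errors import ScheduleError
from .io_formats import KB_KJ_MOL_K, Conformation, Ensemble, RDCTable
from .rdc_restraints import BondVectorSet, ReplicaSet, restraint_energy

__all__ = [
    "ToyPotential",
    "AnnealingSchedule",
    "MoveSet",
    "RestraintModel",
    "SamplerState",
    "EnsembleSampler",
    "SampleResult",
    "total_energy",
    "count_integrator_steps",
    "count_collected_frames",
    "rotate_hinge_domain",
]


# ---------------------------------------------------------------------------
# Toy conformational potential
# ---------------------------------------------------------------------------

def _wrap_deg(x: float) -> float:
    """Wrap an angle difference into (-180, 180]."""
    return (x + 180.0) % 360.0 - 180.0


def rotate_hinge_domain(
    coords: np.ndarray,
    region_indices,
    rotate_indices: np.ndarray,
    pivot_indices: np.ndarray,
    d_theta: float,
    d_psi: float,
) -> np.ndarray:
    """Rigidly rotate the mobile domain about the hinge pivot.

    ``d_theta`` rotates about the interdomain-plane normal (breathing; the
    plane maps to itself), then ``d_psi`` rotates about the hinge-to-domain
    axis (twist; the breathing angle is unchanged because the domain-region
    centre of mass lies on the axis). Used by both the Monte Carlo proposals
    and the synthetic-state builders so generated states live exactly on the
    sampler's move manifold.
    """
    r1, r2, r3 = region_indices
    new = coords.copy()
    sel = rotate_indices
    pivot = coords[pivot_indices].mean(axis=0)
    if d_theta != 0.0:
        c1, c2, c3 = (new[r].mean(axis=0) for r in (r1, r2, r3))
        normal = np.cross(c1 - c2, c3 - c2)
        if np.linalg.norm(normal) < 1e-9:
            normal = np.array([0.0, 0.0, 1.0])
        R = rotation_about_axis(normal, d_theta)
        new[sel] = (new[sel] - pivot) @ R.T + pivot
    if d_psi != 0.0:
        c1, c2, c3 = (new[r].mean(axis=0) for r in (r1, r2, r3))
        axis = c3 - c2
        if np.linalg.norm(axis) < 1e-9:
            axis = np.array([1.0, 0.0, 0.0])
        R = rotation_about_axis(axis, d_psi)
        new[sel] = (new[sel] - pivot) @ R.T + pivot
    return new


@dataclass
class ToyPotential:
    """Two near-rigid domains joined by a hinge with a double-basin term.

    Bonded and domain-rigidifying terms are harmonic in inter-atomic
    distances. The interdomain term couples two hinge coordinates — the
    breathing angle theta and, when ``twist_indices`` is set, the twist psi
    of the second domain about the interdomain axis (the dihedral of a
    marker group) — through a smooth minimum of two harmonic basins
    (:meth:`hinge_energy`). Distinct twist values for the two basins make
    the minor state a genuine discrete rearrangement rather than a point on
    the breathing coordinate.
    """

    bond_pairs: np.ndarray          # (n_bonds, 2) atom indices
    bond_lengths: np.ndarray        # Angstrom, reference values
    pair_pairs: np.ndarray          # (n_pairs, 2) rigidity restraints
    pair_lengths: np.ndarray
    region_indices: tuple[np.ndarray, np.ndarray, np.ndarray]
    theta_a: float = 58.0
    theta_b: float = 49.0
    depth_a: float = 18.0
    depth_b: float = 15.5
    k_theta: float = 8.0            # kJ/mol/deg^2, curvature of each basin
    twist_indices: np.ndarray | None = None   # marker atoms defining psi
    twist_a_deg: float = 0.0
    twist_b_deg: float = 0.0
    k_twist: float = 8.0            # kJ/mol/deg^2
    smoothing: float = 2.5          # kJ/mol, softness of the basin switch
    k_bond: float = 300.0           # kJ/mol/A^2
    k_pair: float = 60.0
    theta_wall_low: float = 20.0
    theta_wall_high: float = 120.0
    k_wall: float = 0.5             # kJ/mol/deg^2
    # centre-of-mass tether keeping the mobile domain attached to the hinge;
    # invariant under both breathing and twist rotations, so neither basin
    # carries tether strain
    tether_group: np.ndarray | None = None
    tether_pivot: np.ndarray | None = None
    tether_length: float = 0.0
    k_tether: float = 20.0

    def __post_init__(self) -> None:
        for t in (self.theta_a, self.theta_b):
            if not 0.0 < t < 180.0:
                raise ValueError("basin centres must lie in (0, 180) degrees")
        self.bond_pairs = np.asarray(self.bond_pairs, int)
        self.pair_pairs = np.asarray(self.pair_pairs, int)
        self.bond_lengths = np.asarray(self.bond_lengths, float)
        self.pair_lengths = np.asarray(self.pair_lengths, float)

    def theta(self, coords: np.ndarray) -> float:
        """Breathing angle (degrees) at the hinge-region centre of mass."""
        r1, r2, r3 = self.region_indices
        return angle_deg(
            coords[r1].mean(axis=0), coords[r2].mean(axis=0), coords[r3].mean(axis=0)
        )

    def psi(self, coords: np.ndarray) -> float:
        """Twist (degrees) of domain 2 about the hinge-to-domain axis."""
        if self.twist_indices is None:
            return 0.0
        from ._geometry import dihedral_deg

        r1, r2, r3 = self.region_indices
        return dihedral_deg(
            coords[r1].mean(axis=0),
            coords[r2].mean(axis=0),
            coords[r3].mean(axis=0),
            coords[self.twist_indices].mean(axis=0),
        )

    def hinge_energy(self, theta: float, psi: float = 0.0) -> float:
        """Smooth minimum of two harmonic basins in (theta, psi).

        Each basin is a paraboloid of curvature ``k_theta``/``k_twist``
        around its centre, offset by its depth; the soft minimum (log-sum-exp
        with softness ``smoothing``) switches between them. Unlike a sum of
        Gaussian wells this leaves no flat plateaus: every configuration
        feels a gradient toward one of the two states, which keeps
        high-temperature excursions bounded and recoverable.
        """
        va = -self.depth_a + 0.5 * self.k_theta * (theta - self.theta_a) ** 2
        vb = -self.depth_b + 0.5 * self.k_theta * (theta - self.theta_b) ** 2
        if self.twist_indices is not None:
            va += 0.5 * self.k_twist * _wrap_deg(psi - self.twist_a_deg) ** 2
            vb += 0.5 * self.k_twist * _wrap_deg(psi - self.twist_b_deg) ** 2
        g = self.smoothing
        lo = min(va, vb)
        e = lo - g * math.log1p(math.exp(-(max(va, vb) - lo) / g))
        if theta < self.theta_wall_low:
            e += self.k_wall * (self.theta_wall_low - theta) ** 2
        elif theta > self.theta_wall_high:
            e += self.k_wall * (theta - self.theta_wall_high) ** 2
        return e

    def energy(self, coords: np.ndarray) -> float:
        """Total conformational energy (kJ/mol); raises on non-finite input."""
        d = coords[self.bond_pairs[:, 0]] - coords[self.bond_pairs[:, 1]]
        d_bond = np.sqrt(np.einsum("ij,ij->i", d, d))
        e = self.k_bond * float(((d_bond - self.bond_lengths) ** 2).sum())
        if len(self.pair_pairs):
            d = coords[self.pair_pairs[:, 0]] - coords[self.pair_pairs[:, 1]]
            d_pair = np.sqrt(np.einsum("ij,ij->i", d, d))
            e += self.k_pair * float(((d_pair - self.pair_lengths) ** 2).sum())
        r1, r2, r3 = self.region_indices
        c1 = coords[r1].mean(axis=0)
        c2 = coords[r2].mean(axis=0)
        c3 = coords[r3].mean(axis=0)
        if self.tether_group is not None:
            t = coords[self.tether_group].mean(axis=0) - coords[
                self.tether_pivot
            ].mean(axis=0)
            dist = math.sqrt(t[0] * t[0] + t[1] * t[1] + t[2] * t[2])
            e += self.k_tether * (dist - self.tether_length) ** 2
        theta = angle_deg(c1, c2, c3)
        if self.twist_indices is not None:
            from ._geometry import dihedral_deg

            psi = dihedral_deg(c1, c2, c3, coords[self.twist_indices].mean(axis=0))
        else:
            psi = 0.0
        e += self.hinge_energy(theta, psi)
        if not math.isfinite(e):
            raise FloatingPointError("non-finite conformational energy")
        return e


# ---------------------------------------------------------------------------
# Schedules
# ---------------------------------------------------------------------------

@dataclass
class AnnealingSchedule:
    """Simulated-annealing cycle and frame-collection rule.

    The default settings reproduce the full protocol (50 cycles between 310
    and 500 K, 250 ps per cycle, frames at 1/ps in the final 50 ps of the
    final 30 cycles); tests and worked examples run scaled-down versions.
    ``moves_per_ps`` maps one nominal picosecond onto Monte Carlo moves per
    replica.
    """

    t_low_K: float = 310.0
    t_high_K: float = 500.0
    cycles: int = 50
    cycle_ps: float = 250.0
    timestep_fs: float = 2.0
    frames_per_ps: int = 1
    collect_window_ps: float = 50.0
    retain_last_cycles: int = 30
    high_fraction: float = 0.5
    moves_per_ps: int = 20
    equilibration_ps: float = 50.0

    def __post_init__(self) -> None:
        if not (self.t_high_K > self.t_low_K > 0):
            raise ScheduleError("need t_high > t_low > 0")
        if self.cycles < 1:
            raise ScheduleError("at least one cycle required")
        if self.retain_last_cycles > self.cycles:
            raise ScheduleError("cannot retain more cycles than are run")
        if self.collect_window_ps > self.low_segment_ps + 1e-9:
            raise ScheduleError(
                "collection window exceeds the low-temperature segment"
            )

    @property
    def low_segment_ps(self) -> float:
        return self.cycle_ps * (1.0 - self.high_fraction)

    @property
    def high_segment_ps(self) -> float:
        return self.cycle_ps * self.high_fraction


def count_integrator_steps(schedule: AnnealingSchedule) -> int:
    """Molecular-dynamics steps one cycle would take at ``timestep_fs``."""
    steps = schedule.cycle_ps * 1000.0 / schedule.timestep_fs
    if abs(steps - round(steps)) > 1e-9:
        raise ScheduleError(
            f"cycle of {schedule.cycle_ps} ps is not divisible by "
            f"{schedule.timestep_fs} fs"
        )
    return int(round(steps))


def count_collected_frames(schedule: AnnealingSchedule, n_replicas: int) -> int:
    """Frames the collection rule emits: replicas x retained cycles x window x rate."""
    per_cycle = schedule.collect_window_ps * schedule.frames_per_ps
    if abs(per_cycle - round(per_cycle)) > 1e-9:
        raise ScheduleError("collection window must hold a whole number of frames")
    return int(round(per_cycle)) * schedule.retain_last_cycles * n_replicas


# ---------------------------------------------------------------------------
# Restraint bookkeeping and sampler
# ---------------------------------------------------------------------------

@dataclass
class MoveSet:
    """Proposal distribution for one replica.

    Move kinds: per-atom Gaussian jitter; "breathing" rotations of one domain
    about the axis normal to the interdomain plane (changing theta only);
    "twist" rotations about the hinge-to-domain axis (changing psi only); and,
    when ``hop_delta`` is set, composite basin hops that jump (theta, psi) by
    approximately the interbasin offset in either direction. Breathing
    rotations map the interdomain plane to itself and twists fix the
    hinge-to-domain axis, so each increment is realised exactly and reverse
    proposals are drawn with the same density: the mixture is symmetric and
    detailed balance holds.
    """

    sigma_atom_ang: float = 0.06
    p_hinge: float = 0.25
    sigma_hinge_deg: float = 1.5
    p_twist: float = 0.1
    sigma_twist_deg: float = 0.6
    hop_delta: tuple[float, float] | None = None   # (d_theta, d_psi) between basins
    hop_sigma_deg: float = 0.5
    rotate_indices: np.ndarray | None = None   # atoms moved by domain rotations
    pivot_indices: np.ndarray | None = None    # atoms whose COM is the pivot

    def breathing_step(self, rng: np.random.Generator) -> tuple[float, float]:
        """Draw a (d_theta, d_psi) increment from a symmetric mixture.

        Half the proposals are local breathing steps; when ``hop_delta`` is
        set the other half jump by approximately +-hop_delta, accelerating
        interbasin exchange. The mixture density is even under negation of
        the increment pair.
        """
        if self.hop_delta is None or rng.random() < 0.5:
            return float(rng.normal(0.0, self.sigma_hinge_deg)), 0.0
        sign = 1.0 if rng.random() < 0.5 else -1.0
        dt = sign * self.hop_delta[0] + rng.normal(0.0, self.hop_sigma_deg)
        dp = sign * self.hop_delta[1] + rng.normal(0.0, self.hop_sigma_deg)
        return float(dt), float(dp)


@dataclass
class RestraintModel:
    """Everything needed to evaluate the replica-averaged RDC restraint."""

    bonds: BondVectorSet
    rdc: RDCTable
    media: dict[str, MediumSpec]
    d_max_hz: float = -21700.0
    tensor_update_interval: int = 10
    n_orientations: int = 350

    def __post_init__(self) -> None:
        self._dirs = fibonacci_directions(self.n_orientations)
        # per-medium row -> bond mapping and experimental values
        self._rows: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for medium in self.rdc.media:
            if medium not in self.media:
                from .errors import MappingError

                raise MappingError(f"no medium spec for {medium!r}")
            rows = self.rdc.for_medium(medium)
            self._rows[medium] = (
                self.bonds.match_rows(rows),
                rows["d_exp"].to_numpy(float),
            )

    @property
    def active_media(self) -> list[str]:
        return list(self._rows)

    def predict_A(self, coords: np.ndarray, charges: np.ndarray, medium: str) -> np.ndarray:
        spec = self.media[medium]
        centred = coords - coords.mean(axis=0)
        w = orientation_weights(centred, charges, spec, self._dirs)
        total = w.sum()
        if total <= 0:
            raise ValueError("molecule does not fit in the medium")
        outer = np.einsum("ki,kj,k->ij", self._dirs, self._dirs, w) / total
        A = spec.scale * (outer - np.eye(3) / 3.0)
        A = 0.5 * (A + A.T)
        return A - np.eye(3) * (np.trace(A) / 3.0)

    def rdc_from_coords(
        self, coords: np.ndarray, A: np.ndarray, i_from: np.ndarray, i_to: np.ndarray
    ) -> np.ndarray:
        vec = coords[i_to] - coords[i_from]
        u = vec / np.linalg.norm(vec, axis=1)[:, None]
        return self.d_max_hz * np.einsum("bi,ij,bj->b", u, A, u)

    def energy_from_means(self, d_calc: dict[str, np.ndarray], alpha: float) -> float:
        e = 0.0
        for medium, (idx, d_exp) in self._rows.items():
            e += float(np.sum((d_exp - d_calc[medium][idx]) ** 2))
        return alpha * e

    def mismatch(self, d_calc: dict[str, np.ndarray]) -> float:
        """Mean squared deviation (Hz^2) between mean-calculated and experimental."""
        sq, n = 0.0, 0
        for medium, (idx, d_exp) in self._rows.items():
            sq += float(np.sum((d_exp - d_calc[medium][idx]) ** 2))
            n += len(idx)
        return sq / n


@dataclass
class SamplerState:
    """Mutable state of a replica Monte Carlo run (fully seeded)."""

    rng: np.random.Generator
    coords: list[np.ndarray]
    e_pot: np.ndarray
    alpha: float = 0.0
    tensors: dict[str, list[np.ndarray]] = field(default_factory=dict)
    d_m: dict[str, np.ndarray] = field(default_factory=dict)      # (M, n_bonds)
    d_calc: dict[str, np.ndarray] = field(default_factory=dict)   # (n_bonds,)
    e_rdc: float = 0.0
    accepted: int = 0
    attempted: int = 0
    since_refresh: np.ndarray | None = None

    @property
    def n_replicas(self) -> int:
        return len(self.coords)

    @property
    def acceptance(self) -> float:
        return self.accepted / self.attempted if self.attempted else 0.0


@dataclass
class SampleResult:
    """Collected ensemble plus per-frame metadata and the energy trace."""

    ensemble: Ensemble
    frames: pd.DataFrame        # cycle, replica, ps, theta, e_pot
    trace: pd.DataFrame         # ps, segment, T, alpha, e_pot, e_rdc, e_tot
    state: SamplerState
    acceptance: float


class EnsembleSampler:
    """Metropolis sampler for M replicas coupled through the averaged restraint."""

    def __init__(
        self,
        potential,
        moves: MoveSet | None = None,
        restraint: RestraintModel | None = None,
        template: Conformation | None = None,
    ) -> None:
        self.potential = potential
        self.moves = moves or MoveSet()
        self.restraint = restraint
        self.template = template
        if restraint is not None:
            if template is None:
                raise ValueError("a template conformation is required with restraints")
            self._i_from, self._i_to = restraint.bonds.atom_indices(template)

    # -- state management ---------------------------------------------------

    def init_state(
        self, initial: list[np.ndarray], seed: int, alpha: float = 0.0
    ) -> SamplerState:
        coords = [np.array(c, float) for c in initial]
        state = SamplerState(
            rng=np.random.default_rng(seed),
            coords=coords,
            e_pot=np.array([self.potential.energy(c) for c in coords]),
            alpha=alpha,
            since_refresh=np.zeros(len(coords), int),
        )
        if self.restraint is not None:
            self._refresh_all(state)
        return state

    def _refresh_tensor(self, state: SamplerState, m: int) -> None:
        r = self.restraint
        charges = self.template.charges
        for medium in r.active_media:
            A = r.predict_A(state.coords[m], charges, medium)
            state.tensors[medium][m] = A
            state.d_m[medium][m] = r.rdc_from_coords(
                state.coords[m], A, self._i_from, self._i_to
            )
        state.since_refresh[m] = 0

    def _refresh_all(self, state: SamplerState) -> None:
        r = self.restraint
        mm = state.n_replicas
        n_bonds = len(r.bonds)
        for medium in r.active_media:
            state.tensors[medium] = [None] * mm
            state.d_m[medium] = np.zeros((mm, n_bonds))
        for m in range(mm):
            self._refresh_tensor(state, m)
        for medium in r.active_media:
            state.d_calc[medium] = state.d_m[medium].mean(axis=0)
        state.e_rdc = r.energy_from_means(state.d_calc, state.alpha)

    def recompute_energies(self, state: SamplerState) -> tuple[float, float, float]:
        """Recompute (E_tot, sum E_pot, E_RDC) from coordinates and cached tensors."""
        e_pot = float(sum(self.potential.energy(c) for c in state.coords))
        e_rdc = 0.0
        if self.restraint is not None:
            d_calc = {}
            for medium in self.restraint.active_media:
                d = np.stack(
                    [
                        self.restraint.rdc_from_coords(
                            state.coords[m], state.tensors[medium][m],
                            self._i_from, self._i_to,
                        )
                        for m in range(state.n_replicas)
                    ]
                )
                d_calc[medium] = d.mean(axis=0)
            e_rdc = self.restraint.energy_from_means(d_calc, state.alpha)
        return e_pot + e_rdc, e_pot, e_rdc

    # -- proposals and Metropolis step --------------------------------------

    def _propose(self, state: SamplerState, m: int) -> tuple[np.ndarray, bool]:
        """Propose new coordinates; the flag marks rigid domain rotations."""
        rng = state.rng
        coords = state.coords[m]
        mv = self.moves
        kind = rng.random() if mv.rotate_indices is not None else 1.0
        if kind < mv.p_hinge:
            dt, dp = mv.breathing_step(rng)
            new = self._rotate_domain(coords, dt, dp)
            return new, True
        if kind < mv.p_hinge + mv.p_twist:
            dp = rng.normal(0.0, mv.sigma_twist_deg)
            new = self._rotate_domain(coords, 0.0, dp)
            return new, True
        new = coords.copy()
        i = rng.integers(coords.shape[0])
        new[i] = coords[i] + rng.normal(0.0, mv.sigma_atom_ang, size=3)
        return new, False

    def _rotate_domain(
        self, coords: np.ndarray, d_theta: float, d_psi: float
    ) -> np.ndarray:
        mv = self.moves
        return rotate_hinge_domain(
            coords,
            self.potential.region_indices,
            mv.rotate_indices,
            mv.pivot_indices,
            d_theta,
            d_psi,
        )

    def mc_move(self, state: SamplerState, m: int, T: float) -> bool:
        """One Metropolis proposal on replica ``m`` at temperature ``T`` (K)."""
        if T <= 0:
            raise ValueError("temperature must be positive")
        state.attempted += 1
        new, is_rotation = self._propose(state, m)
        e_pot_new = self.potential.energy(new)
        d_e = e_pot_new - state.e_pot[m]
        new_dm: dict[str, np.ndarray] = {}
        new_dcalc: dict[str, np.ndarray] = {}
        new_erdc = 0.0
        r = self.restraint
        use_rdc = r is not None and state.alpha > 0.0
        if use_rdc:
            mm = state.n_replicas
            for medium in r.active_media:
                dm = r.rdc_from_coords(
                    new, state.tensors[medium][m], self._i_from, self._i_to
                )
                new_dm[medium] = dm
                new_dcalc[medium] = (
                    state.d_calc[medium] + (dm - state.d_m[medium][m]) / mm
                )
            new_erdc = r.energy_from_means(new_dcalc, state.alpha)
            d_e += new_erdc - state.e_rdc
        if d_e <= 0.0:
            accept = True
        else:
            accept = state.rng.random() < math.exp(
                -min(d_e / (KB_KJ_MOL_K * T), 700.0)
            )
        if accept:
            state.coords[m] = new
            state.e_pot[m] = e_pot_new
            if use_rdc:
                for medium in r.active_media:
                    state.d_m[medium][m] = new_dm[medium]
                    state.d_calc[medium] = new_dcalc[medium]
                state.e_rdc = new_erdc
            state.accepted += 1
            if r is not None:
                state.since_refresh[m] += 1
                # domain rotations change the molecular shape enough that the
                # cached tensor must not lag them; jitter moves refresh on the
                # regular interval
                if is_rotation or state.since_refresh[m] >= r.tensor_update_interval:
                    self._refresh_tensor(state, m)
                    for medium in r.active_media:
                        state.d_calc[medium] = state.d_m[medium].mean(axis=0)
                    state.e_rdc = r.energy_from_means(state.d_calc, state.alpha)
        return accept

    def run_ps(self, state: SamplerState, T: float, moves_per_ps: int) -> None:
        """One nominal picosecond: ``moves_per_ps`` moves on every replica."""
        for m in range(state.n_replicas):
            for _ in range(moves_per_ps):
                self.mc_move(state, m, T)

    # -- annealing protocol --------------------------------------------------

    def run_annealing(
        self,
        initial: list[np.ndarray],
        schedule: AnnealingSchedule,
        seed: int,
        alpha_target: float = 0.0,
        ramp_stages: int = 40,
        ramp_start_fraction: float = 0.01,
        min_ramp_acceptance: float = 0.2,
        thermalize_ps: float = 10.0,
    ) -> SampleResult:
        """Equilibrate (with an alpha ramp), anneal, and collect frames.

        Fully reproducible from ``seed``. Frames are collected once per
        ``1/frames_per_ps`` nominal picosecond during the final
        ``collect_window_ps`` of the low-temperature segment of the last
        ``retain_last_cycles`` cycles, for every replica.
        """
        state = self.init_state(initial, seed, alpha=0.0)
        trace_rows: list[dict] = []
        frames: list[dict] = []
        frame_coords: list[np.ndarray] = []
        mpp = schedule.moves_per_ps

        def record(ps: float, segment: str, T: float) -> None:
            e_pot = float(state.e_pot.sum())
            trace_rows.append(
                dict(ps=ps, segment=segment, T=T, alpha=state.alpha,
                     e_pot=e_pot, e_rdc=state.e_rdc,
                     e_tot=e_pot + state.e_rdc)
            )

        # unrestrained thermalization (replicas start at the potential
        # minimum, where acceptance is transiently low), then a geometric
        # alpha ramp capped by the acceptance rate
        clock = 0.0
        n_therm = int(round(thermalize_ps))
        n_eq = max(1, int(round(schedule.equilibration_ps)) - n_therm)
        for _ in range(n_therm):
            self.run_ps(state, schedule.t_low_K, mpp)
            clock += 1.0
            record(clock, "therm", schedule.t_low_K)
        if self.restraint is not None and alpha_target > 0.0:
            alphas = alpha_target * np.geomspace(
                ramp_start_fraction, 1.0, min(ramp_stages, n_eq)
            )
        else:
            alphas = np.zeros(0)
        ramp_frozen = False
        for ps in range(n_eq):
            if ps < len(alphas) and not ramp_frozen:
                acc0, att0 = state.accepted, state.attempted
                self._set_alpha(state, float(alphas[ps]))
                self.run_ps(state, schedule.t_low_K, mpp)
                att = state.attempted - att0
                if att and (state.accepted - acc0) / att < min_ramp_acceptance:
                    ramp_frozen = True
            else:
                self.run_ps(state, schedule.t_low_K, mpp)
            clock += 1.0
            record(clock, "equil", schedule.t_low_K)
        if self.restraint is not None and alpha_target > 0.0 and not ramp_frozen:
            self._set_alpha(state, alpha_target)

        high_ps = int(round(schedule.high_segment_ps))
        low_ps = int(round(schedule.low_segment_ps))
        collect_from = low_ps - int(round(schedule.collect_window_ps))
        stride = 1.0 / schedule.frames_per_ps
        first_retained = schedule.cycles - schedule.retain_last_cycles
        template = self.template
        for cycle in range(schedule.cycles):
            for _ in range(high_ps):
                self.run_ps(state, schedule.t_high_K, mpp)
                clock += 1.0
            record(clock, "high", schedule.t_high_K)
            next_collect = collect_from + stride
            for p in range(low_ps):
                self.run_ps(state, schedule.t_low_K, mpp)
                clock += 1.0
                while cycle >= first_retained and p + 1 >= next_collect - 1e-9:
                    for m in range(state.n_replicas):
                        frame_coords.append(state.coords[m].copy())
                        frames.append(
                            dict(
                                cycle=cycle + 1,
                                replica=m + 1,
                                ps=clock,
                                theta=self.potential.theta(state.coords[m])
                                if hasattr(self.potential, "theta")
                                else np.nan,
                                e_pot=float(state.e_pot[m]),
                            )
                        )
                    next_collect += stride
            record(clock, "low", schedule.t_low_K)

        if template is not None:
            confs = [
                template.with_coords(c, model_id=i + 1)
                for i, c in enumerate(frame_coords)
            ]
        else:
            confs = [_bare_conformation(c, i + 1) for i, c in enumerate(frame_coords)]
        ensemble = Ensemble(confs) if confs else None
        return SampleResult(
            ensemble=ensemble,
            frames=pd.DataFrame(frames),
            trace=pd.DataFrame(trace_rows),
            state=state,
            acceptance=state.acceptance,
        )

    def _set_alpha(self, state: SamplerState, alpha: float) -> None:
        state.alpha = alpha
        if self.restraint is not None:
            state.e_rdc = self.restraint.energy_from_means(state.d_calc, alpha)


def _bare_conformation(coords: np.ndarray, model_id: int) -> Conformation:
    n = coords.shape[0]
    return Conformation(
        chain_ids=np.full(n, "A"),
        res_ids=np.arange(1, n + 1),
        res_names=np.full(n, "GLY"),
        atom_names=np.array([f"X{i}" for i in range(n)]),
        elements=np.full(n, "C"),
        coords=coords,
        model_id=model_id,
    )


def total_energy(
    replicas: ReplicaSet,
    potential,
    rdc: RDCTable,
    bonds: BondVectorSet,
    alpha: float,
    d_max_hz: float,
) -> tuple[float, float, float]:
    """(E_tot, sum of per-replica E_pot, E_RDC of the replica average)."""
    from .rdc_restraints import replica_average_rdc

    e_pot = float(sum(potential.energy(c.coords) for c in replicas.conformations))
    d_calc = {
        medium: replica_average_rdc(replicas, bonds, d_max_hz, medium)
        for medium in rdc.media
    }
    e_rdc = restraint_energy(d_calc, rdc, bonds, alpha)
    return e_pot + e_rdc, e_pot, e_rdc
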