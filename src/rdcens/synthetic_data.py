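"""Synthetic two-domain toy systems with known ground truth.

The generator emulates the experimental situation the pipeline is built for:
a two-domain protein whose ground state and low-population minor state differ
by an interdomain breathing angle, observed through population-averaged RDCs
in a steric and a charged alignment medium (with noise), HNHA intensities
encoding known scalar couplings, and NOE upper bounds. Every dataset ships
with its :class:`GroundTruth` so pipeline-level recovery is verifiable.

The toy protein carries four atoms per residue (N, H, CA, C): CA scaffolds
define the two compact domains and the hinge, pseudo N-H bond vectors supply
the RDC-active spins, and the N/CA/C triads make backbone phi dihedrals (and
hence Karplus back-calculation) well defined. Residue local frames are drawn
deterministically from the seed so bond orientations cover the sphere, which
keeps SVD tensor fits well conditioned.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .alignment_tensor import AlignmentTensor, MediumSpec, predict_tensor
from .errors import BranchError
from .io_formats import (
    Conformation,
    Ensemble,
    HNHATable,
    NOETable,
    RDCTable,
)
from .landscape_analysis import RegionDefinition, breathing_angle
from .rdc_restraints import BondVectorSet, calc_rdc
from .ensemble_sampler import ToyPotential, _wrap_deg, rotate_hinge_domain

__all__ = [
    "GeneratorSpec",
    "GroundTruth",
    "ToySystem",
    "make_toy_protein",
    "make_two_state_ensemble",
    "make_rdc_tables",
    "make_hnha_table",
    "make_noe_table",
]


@dataclass
class GeneratorSpec:
    """Study conditions for the synthetic two-state system.

    Defaults encode the scenario the pipeline targets: an 87/13 ground/minor
    mixture separated by 9 degrees of breathing angle (58 vs 49 degrees) plus
    a 40-degree twist of the beta domain (a discrete rearrangement, so the
    two-state RDC fingerprint is identifiable against within-basin motion),
    thermal jitter matched to the toy potential's 310 K fluctuations, and 5%
    relative noise on the averaged RDCs.
    """

    residues_per_domain: int = 8
    hinge_residues: int = 3
    theta_ground_deg: float = 58.0
    theta_minor_deg: float = 49.0
    twist_minor_deg: float = 40.0
    twist_jitter_deg: float = 0.55
    p_minor: float = 0.13
    jitter_ang: float = 0.04
    theta_jitter_deg: float = 0.6
    rdc_noise_rel: float = 0.05
    domain_radius_ang: float = 12.0
    medium_scale: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_minor < 1.0:
            raise ValueError("minor-state population must be in [0, 1)")
        sep = abs(self.theta_ground_deg - self.theta_minor_deg)
        if sep <= 3.0 * max(self.theta_jitter_deg, 1e-9):
            raise ValueError(
                "basin centres must be separated by more than 3x the theta jitter"
            )
        if self.residues_per_domain < 4 or self.hinge_residues < 1:
            raise ValueError("domains need >= 4 residues, hinge >= 1")


@dataclass
class GroundTruth:
    """Per-frame labels and the generating quantities of a synthetic dataset."""

    labels: np.ndarray                      # 'ground' | 'minor' per frame
    thetas: np.ndarray                      # realised breathing angles (deg)
    populations: dict[str, float]
    tensors: dict[str, dict[str, AlignmentTensor]]  # medium -> state -> tensor
    true_j: pd.DataFrame | None = None      # res_id, j_true (Hz)


@dataclass
class ToySystem:
    """A toy protein with everything the sampler and analyses need."""

    spec: GeneratorSpec
    conformation: Conformation              # ground-state structure
    bonds: BondVectorSet
    regions: RegionDefinition
    potential: ToyPotential
    media: dict[str, MediumSpec]
    domain_a_res: list[int]
    hinge_res: list[int]
    domain_b_res: list[int]
    rotate_indices: np.ndarray = field(repr=False)
    pivot_indices: np.ndarray = field(repr=False)
    rmsd_selection: tuple = None

    def conformation_at_theta(
        self,
        theta_deg: float,
        rng: np.random.Generator | None = None,
        jitter_ang: float = 0.0,
    ) -> Conformation:
        """Ground-twist geometry hinged to the requested breathing angle."""
        return self.conformation_at(theta_deg, None, rng, jitter_ang)

    def conformation_at(
        self,
        theta_deg: float,
        psi_deg: float | None = None,
        rng: np.random.Generator | None = None,
        jitter_ang: float = 0.0,
    ) -> Conformation:
        """Geometry hinged to breathing angle ``theta_deg`` and twist
        ``psi_deg`` (default: the ground-state twist), optionally jittered."""
        coords = _hinge_to_targets(
            self.conformation.coords,
            self.potential.region_indices,
            self.rotate_indices,
            self.pivot_indices,
            self.potential,
            theta_deg,
            psi_deg,
        )
        if rng is not None and jitter_ang > 0.0:
            coords = coords + rng.normal(0.0, jitter_ang, coords.shape)
        return self.conformation.with_coords(coords)

    def state_conformation(self, label: str) -> Conformation:
        """The idealised 'ground' or 'minor' state structure."""
        p = self.potential
        if label == "ground":
            return self.conformation_at(p.theta_a, p.twist_a_deg)
        if label == "minor":
            return self.conformation_at(p.theta_b, p.twist_b_deg)
        raise ValueError(f"unknown state label {label!r}")

    @property
    def hop_delta(self) -> tuple[float, float]:
        """(d_theta, d_psi) move increments carrying ground into minor."""
        p = self.potential
        coords = self.conformation.coords
        args = (p.region_indices, self.rotate_indices, self.pivot_indices)
        probe_t = rotate_hinge_domain(coords, *args, 1.0, 0.0)
        s_t = 1.0 if p.theta(probe_t) > p.theta(coords) else -1.0
        probe_p = rotate_hinge_domain(coords, *args, 0.0, 1.0)
        s_p = 1.0 if _wrap_deg(p.psi(probe_p) - p.psi(coords)) > 0 else -1.0
        return (
            s_t * (p.theta_b - p.theta_a),
            s_p * _wrap_deg(p.twist_b_deg - p.twist_a_deg),
        )


def _domain_scaffold(n: int, radius: float, rng: np.random.Generator) -> np.ndarray:
    """Compact, non-degenerate CA cluster: points on a coarse helix."""
    k = np.arange(n)
    ang = np.radians(100.0) * k
    rise = 2.8
    pts = np.column_stack(
        [
            0.45 * radius * np.cos(ang),
            0.45 * radius * np.sin(ang),
            rise * (k - (n - 1) / 2.0),
        ]
    )
    return pts + rng.normal(0.0, 0.15, pts.shape)


def make_toy_protein(spec: GeneratorSpec) -> ToySystem:
    """Build the two-domain toy protein in its ground state (deterministic)."""
    rng = np.random.default_rng(spec.seed)
    nd, nh = spec.residues_per_domain, spec.hinge_residues
    n_res = 2 * nd + nh
    theta = np.radians(spec.theta_ground_deg)
    d = spec.domain_radius_ang + 6.0
    u_a = np.array([np.cos(theta / 2), np.sin(theta / 2), 0.0])
    u_b = np.array([np.cos(theta / 2), -np.sin(theta / 2), 0.0])

    ca = np.zeros((n_res, 3))
    rot_a = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
    rot_b = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
    ca[:nd] = _domain_scaffold(nd, spec.domain_radius_ang, rng) @ rot_a.T + d * u_a
    for k in range(nh):
        frac = (k + 1.0) / (nh + 1.0)
        ca[nd + k] = (1 - frac) * 0.35 * d * u_a + frac * 0.35 * d * u_b
    ca[nd + nh:] = (
        _domain_scaffold(nd, spec.domain_radius_ang, rng) @ rot_b.T + d * u_b
    )

    # per-residue local frames -> N, C, H satellites around each CA
    frames = Rotation.random(n_res, random_state=int(rng.integers(2**31)))
    atoms_per = 4  # order: N, H, CA, C
    coords = np.zeros((n_res * atoms_per, 3))
    names, res_ids, res_names, elements = [], [], [], []
    offsets = {
        "N": np.array([-1.35, 0.75, 0.0]),
        "H": np.array([-1.35, 0.75, 0.0]),
        "C": np.array([1.35, 0.75, 0.0]),
    }
    for i in range(n_res):
        R = frames[i].as_matrix()
        n_pos = ca[i] + R @ offsets["N"]
        h_dir = R @ np.array([-0.6, 0.8, 0.0])
        base = i * atoms_per
        coords[base + 0] = n_pos
        coords[base + 1] = n_pos + 1.02 * h_dir / np.linalg.norm(h_dir)
        coords[base + 2] = ca[i]
        coords[base + 3] = ca[i] + R @ offsets["C"]
        for nm, el in (("N", "N"), ("H", "H"), ("CA", "C"), ("C", "C")):
            names.append(nm)
            elements.append(el)
            res_ids.append(i + 1)
            res_names.append("ALA")

    charges = np.zeros(n_res * atoms_per)
    for r in range(1, nd, 2):                      # alpha-domain: negative
        charges[(r) * atoms_per + 2] = -1.0
    for r in range(nd + nh, n_res, 2):             # beta-domain: positive
        charges[r * atoms_per + 2] = 1.0

    conf = Conformation(
        chain_ids=np.full(n_res * atoms_per, "A"),
        res_ids=np.array(res_ids),
        res_names=np.array(res_names),
        atom_names=np.array(names),
        elements=np.array(elements),
        coords=coords,
        charges=charges,
    )

    domain_a = list(range(1, nd + 1))
    hinge = list(range(nd + 1, nd + nh + 1))
    domain_b = list(range(nd + nh + 1, n_res + 1))
    mid = nd // 2
    regions = RegionDefinition(
        region_1=domain_a[mid - 2 : mid + 2],
        region_2=hinge,
        region_3=domain_b[mid - 2 : mid + 2],
    )

    bonds = BondVectorSet(
        pd.DataFrame(
            dict(
                res_id=np.arange(1, n_res + 1),
                pair="N-H",
                atom_from="N",
                atom_to="H",
            )
        )
    )

    rotate_pre = np.nonzero(np.isin(conf.res_ids, domain_b))[0]
    pivot_pre = conf.select(hinge, "CA")
    region_pre = (
        conf.select(regions.region_1, "CA"),
        conf.select(regions.region_2, "CA"),
        conf.select(regions.region_3, "CA"),
    )
    # snap the built geometry to the exact ground-state breathing angle
    def theta_of(coords):
        c1, c2, c3 = (coords[r].mean(axis=0) for r in region_pre)
        v1, v3 = c1 - c2, c3 - c2
        cosang = np.dot(v1, v3) / (np.linalg.norm(v1) * np.linalg.norm(v3))
        return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))

    delta = spec.theta_ground_deg - theta_of(conf.coords)
    for sign in (1.0, -1.0):
        cand = rotate_hinge_domain(
            conf.coords, region_pre, rotate_pre, pivot_pre, sign * delta, 0.0
        )
        if abs(theta_of(cand) - spec.theta_ground_deg) < 1e-6:
            conf = conf.with_coords(cand)
            break
    else:  # pragma: no cover - degenerate geometry
        raise RuntimeError("could not snap the scaffold to the ground angle")

    # twist marker: the two beta-domain CA atoms furthest from the
    # hinge-to-domain axis make the twist dihedral well conditioned
    c2 = conf.coords[region_pre[1]].mean(axis=0)
    c3 = conf.coords[region_pre[2]].mean(axis=0)
    u = (c3 - c2) / np.linalg.norm(c3 - c2)
    b_ca = conf.select(domain_b, "CA")
    rel = conf.coords[b_ca] - c2
    dist_axis = np.linalg.norm(rel - np.outer(rel @ u, u), axis=1)
    twist_idx = b_ca[np.argsort(-dist_axis)[:2]]

    potential = _build_potential(
        conf, spec, domain_a, hinge, domain_b, regions, twist_idx,
        rotate_pre, pivot_pre,
    )
    media = {
        "steric": MediumSpec(kind="steric", scale=spec.medium_scale),
        "electrostatic": MediumSpec(
            kind="electrostatic",
            wall_charge=0.8,
            debye_length_ang=15.0,
            scale=spec.medium_scale,
        ),
    }
    rotate_idx = np.nonzero(np.isin(conf.res_ids, domain_b))[0]
    pivot_idx = conf.select(hinge, "CA")
    return ToySystem(
        spec=spec,
        conformation=conf,
        bonds=bonds,
        regions=regions,
        potential=potential,
        media=media,
        domain_a_res=domain_a,
        hinge_res=hinge,
        domain_b_res=domain_b,
        rotate_indices=rotate_idx,
        pivot_indices=pivot_idx,
        rmsd_selection=(domain_a + domain_b, "CA"),
    )


def _build_potential(
    conf: Conformation,
    spec: GeneratorSpec,
    domain_a: list[int],
    hinge: list[int],
    domain_b: list[int],
    regions: RegionDefinition,
    twist_indices: np.ndarray,
    rotate_indices: np.ndarray,
    pivot_indices: np.ndarray,
) -> ToyPotential:
    idx = conf.atom_index
    bond_pairs = []
    n_res = 2 * spec.residues_per_domain + spec.hinge_residues
    for r in range(1, n_res + 1):
        bond_pairs += [
            (idx(r, "N"), idx(r, "CA")),
            (idx(r, "CA"), idx(r, "C")),
            (idx(r, "N"), idx(r, "H")),
        ]
    # sequential links within each segment are stiff; the two junctions stay
    # soft so the hinge can flex (they are added as weak rigidity pairs below)
    segments = [domain_a, hinge, domain_b]
    soft_pairs = []
    for seg in segments:
        for r1, r2 in zip(seg[:-1], seg[1:]):
            bond_pairs.append((idx(r1, "C"), idx(r2, "N")))
    # the alpha-domain/hinge junction is a weak spring; the hinge/beta-domain
    # junction is replaced by the COM tether below so that twisting the beta
    # domain carries no junction strain
    soft_pairs.append((idx(domain_a[-1], "C"), idx(hinge[0], "N")))

    pair_pairs = list(soft_pairs)
    # domains are near-rigid over all their atoms so bond-vector orientations
    # fluctuate about the domain frame instead of diffusing freely
    for seg in (domain_a, domain_b):
        atoms = np.nonzero(np.isin(conf.res_ids, seg))[0]
        for i in range(len(atoms)):
            for j in range(i + 1, len(atoms)):
                pair_pairs.append((atoms[i], atoms[j]))
    for r in hinge:  # keep each hinge residue internally rigid
        pair_pairs += [
            (idx(r, "N"), idx(r, "C")),
            (idx(r, "H"), idx(r, "CA")),
            (idx(r, "H"), idx(r, "C")),
        ]

    coords = conf.coords
    bond_pairs = np.array(bond_pairs)
    pair_pairs = np.array(pair_pairs)
    bond_lengths = np.linalg.norm(
        coords[bond_pairs[:, 0]] - coords[bond_pairs[:, 1]], axis=1
    )
    pair_lengths = np.linalg.norm(
        coords[pair_pairs[:, 0]] - coords[pair_pairs[:, 1]], axis=1
    )
    region_idx = (
        conf.select(regions.region_1, "CA"),
        conf.select(regions.region_2, "CA"),
        conf.select(regions.region_3, "CA"),
    )
    # twist basin centres: the ground-state twist, and the twist of the minor
    # reference built by rotating the beta domain about the interdomain axis
    from ._geometry import dihedral_deg

    def psi_of(c):
        c1, c2, c3 = (c[r].mean(axis=0) for r in region_idx)
        return dihedral_deg(c1, c2, c3, c[twist_indices].mean(axis=0))

    psi_a = psi_of(coords)
    probe = rotate_hinge_domain(
        coords, region_idx, rotate_indices, pivot_indices, 0.0, 1.0
    )
    s_p = 1.0 if _wrap_deg(psi_of(probe) - psi_a) > 0 else -1.0
    minor_ref = rotate_hinge_domain(
        coords, region_idx, rotate_indices, pivot_indices,
        0.0, s_p * spec.twist_minor_deg,
    )
    psi_b = psi_of(minor_ref)

    tether_group = np.nonzero(np.isin(conf.res_ids, domain_b))[0]
    tether_len = float(
        np.linalg.norm(
            coords[tether_group].mean(axis=0)
            - coords[pivot_indices].mean(axis=0)
        )
    )

    return ToyPotential(
        bond_pairs=bond_pairs,
        bond_lengths=bond_lengths,
        pair_pairs=pair_pairs,
        pair_lengths=pair_lengths,
        region_indices=region_idx,
        tether_group=tether_group,
        tether_pivot=np.asarray(pivot_indices, int),
        tether_length=tether_len,
        theta_a=spec.theta_ground_deg,
        theta_b=spec.theta_minor_deg,
        depth_a=18.0,
        depth_b=15.5,
        twist_indices=np.asarray(twist_indices, int),
        twist_a_deg=psi_a,
        twist_b_deg=psi_b,
        # safety walls well outside the basins; the harmonic basin bowls
        # already confine ordinary excursions
        theta_wall_low=min(spec.theta_minor_deg, spec.theta_ground_deg) - 15.0,
        theta_wall_high=max(spec.theta_minor_deg, spec.theta_ground_deg) + 20.0,
    )


def _hinge_to_targets(
    coords: np.ndarray,
    region_indices,
    rotate_indices: np.ndarray,
    pivot_indices: np.ndarray,
    potential: ToyPotential,
    theta_target: float,
    psi_target: float | None = None,
) -> np.ndarray:
    """Rigidly hinge the mobile domain onto exact (theta, psi) targets.

    The breathing and twist rotations are each applied with the sign that
    moves the coordinate toward its target (the response is exactly one
    degree per degree, so a single trial per sign suffices).
    """
    args = (region_indices, rotate_indices, pivot_indices)
    out = coords
    cur = potential.theta(out)
    delta = theta_target - cur
    if abs(delta) > 1e-12:
        for sign in (1.0, -1.0):
            cand = rotate_hinge_domain(out, *args, sign * delta, 0.0)
            if abs(potential.theta(cand) - theta_target) < 1e-6:
                out = cand
                break
        else:  # pragma: no cover - degenerate geometry
            raise RuntimeError("hinge rotation failed to reach the target angle")
    if psi_target is not None and potential.twist_indices is not None:
        cur_p = potential.psi(out)
        delta_p = _wrap_deg(psi_target - cur_p)
        if abs(delta_p) > 1e-12:
            for sign in (1.0, -1.0):
                cand = rotate_hinge_domain(out, *args, 0.0, sign * delta_p)
                if abs(_wrap_deg(potential.psi(cand) - psi_target)) < 1e-6:
                    out = cand
                    break
            else:  # pragma: no cover
                raise RuntimeError("twist rotation failed to reach the target")
    return out


def make_two_state_ensemble(
    system: ToySystem, n_frames: int, seed: int | None = None
) -> tuple[Ensemble, GroundTruth]:
    """Draw frames from the two basins with probability (1-p, p), jittered."""
    spec = system.spec
    if n_frames < 1:
        raise ValueError("need at least one frame")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    labels = np.where(rng.random(n_frames) < spec.p_minor, "minor", "ground")
    pot = system.potential
    confs, thetas = [], []
    for i, label in enumerate(labels):
        if label == "minor":
            theta_c, psi_c = spec.theta_minor_deg, pot.twist_b_deg
        else:
            theta_c, psi_c = spec.theta_ground_deg, pot.twist_a_deg
        theta = theta_c + rng.normal(0.0, spec.theta_jitter_deg)
        psi = psi_c + rng.normal(0.0, spec.twist_jitter_deg)
        conf = system.conformation_at(theta, psi, rng, spec.jitter_ang)
        conf.model_id = i + 1
        confs.append(conf)
        thetas.append(breathing_angle(conf, system.regions))
    ensemble = Ensemble(confs)

    state_tensors: dict[str, dict[str, AlignmentTensor]] = {}
    for medium, mspec in system.media.items():
        state_tensors[medium] = {
            "ground": predict_tensor(system.state_conformation("ground"), mspec),
            "minor": predict_tensor(system.state_conformation("minor"), mspec),
        }
    # ensemble-averaged Karplus couplings are the ground truth the HNHA
    # synthesiser inverts; non-terminal residues only (phi needs C of i-1)
    from .nmr_validation import backcalc_j

    res_ids = sorted(set(int(r) for r in system.conformation.res_ids))[1:]
    true_j = backcalc_j(ensemble, res_ids).rename(columns={"j_calc": "j_true"})

    truth = GroundTruth(
        labels=labels,
        thetas=np.array(thetas),
        populations={
            "minor": float(np.mean(labels == "minor")),
            "ground": float(np.mean(labels == "ground")),
        },
        tensors=state_tensors,
        true_j=true_j,
    )
    return ensemble, truth


def make_rdc_tables(
    ensemble: Ensemble,
    system: ToySystem,
    noise_rel: float | None = None,
    seed: int | None = None,
    d_max_hz: float = -21700.0,
    n_orientations: int = 350,
) -> RDCTable:
    """Population-and-noise averaged experimental-style RDC table (both media).

    D_exp is the weight-averaged back-calculated coupling over all frames
    (per-frame shape/charge-predicted tensors), plus Gaussian noise of
    ``noise_rel`` times the per-medium RMS coupling; the sigma column records
    that noise level.
    """
    spec = system.spec
    noise_rel = spec.rdc_noise_rel if noise_rel is None else noise_rel
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    w = ensemble.effective_weights()
    frames_d = {}
    for medium, mspec in system.media.items():
        per_frame = np.stack(
            [
                calc_rdc(
                    c,
                    predict_tensor(c, mspec, n_orientations),
                    system.bonds,
                    d_max_hz,
                )
                for c in ensemble
            ]
        )
        frames_d[medium] = np.average(per_frame, axis=0, weights=w)
    rows = []
    for medium, d_mean in frames_d.items():
        sigma = noise_rel * float(np.sqrt(np.mean(d_mean**2)))
        noisy = d_mean + rng.normal(0.0, sigma, d_mean.shape)
        for b, d in enumerate(noisy):
            rows.append(
                dict(
                    res_id=int(system.bonds.df["res_id"].iloc[b]),
                    pair=system.bonds.df["pair"].iloc[b],
                    medium=medium,
                    d_exp=float(d),
                    sigma=max(sigma, 1e-6),
                )
            )
    return RDCTable(pd.DataFrame(rows))


def make_hnha_table(
    true_j: pd.DataFrame,
    noise_rel: float = 0.05,
    seed: int = 0,
    xi_s: float = 0.01305,
    diag_intensity: float = 100.0,
) -> HNHATable:
    """Invert the tangent-squared intensity relation to synthesise HNHA data.

    ``true_j`` needs columns ``res_id`` and ``j_true`` (Hz, inside the
    principal branch). Multiplicative Gaussian noise of relative size
    ``noise_rel`` is applied to both intensities; the noise column records
    the corresponding absolute level on the diagonal intensity.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for _, row in true_j.iterrows():
        j = float(row["j_true"])
        arg = 2.0 * np.pi * xi_s * j
        if not 0.0 <= arg < np.pi / 2.0:
            raise BranchError(f"true J = {j} Hz outside the principal branch")
        ratio = -np.tan(arg) ** 2
        i_d = diag_intensity * (1.0 + noise_rel * rng.standard_normal())
        i_x = ratio * diag_intensity * (1.0 + noise_rel * rng.standard_normal())
        rows.append(
            dict(
                res_id=int(row["res_id"]),
                res_name="ALA",
                i_cross=i_x,
                i_diag=i_d,
                noise=noise_rel * diag_intensity,
            )
        )
    return HNHATable(pd.DataFrame(rows))


def make_noe_table(
    ensemble: Ensemble,
    coverage: float = 0.3,
    slack_ang: float = 0.5,
    violated_fraction: float = 0.0,
    seed: int = 0,
    assumed_tolerance_ang: float = 0.5,
) -> NOETable:
    """Upper bounds satisfied by construction, with optional injected violations.

    Bounds are the maximum observed CA-CA distance plus ``slack_ang`` for a
    random ``coverage`` fraction of residue pairs. A ``violated_fraction`` of
    rows instead gets a bound below the minimum observed distance minus the
    assumed analysis tolerance, so those rows are violated in every structure.
    """
    if not 0.0 < coverage <= 1.0:
        raise ValueError("coverage must be in (0, 1]")
    rng = np.random.default_rng(seed)
    ref = ensemble[0]
    res = np.unique(ref.res_ids)
    pairs = [
        (int(a), int(b)) for i, a in enumerate(res) for b in res[i + 2 :]
    ]
    k = max(1, int(round(coverage * len(pairs))))
    chosen = [pairs[i] for i in rng.choice(len(pairs), size=k, replace=False)]
    n_violated = int(round(violated_fraction * k))
    stack = ensemble.coords_stack()
    rows = []
    for p, (r1, r2) in enumerate(chosen):
        i = ref.atom_index(r1, "CA")
        j = ref.atom_index(r2, "CA")
        d = np.linalg.norm(stack[:, i] - stack[:, j], axis=1)
        if p < n_violated:
            bound = max(0.1, float(d.min()) - assumed_tolerance_ang - 0.2)
        else:
            bound = float(d.max()) + slack_ang
        rows.append(
            dict(res_1=r1, atom_1="CA", res_2=r2, atom_2="CA", bound=bound)
        )
    return NOETable(pd.DataFrame(rows))
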