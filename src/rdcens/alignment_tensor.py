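"""Alignment tensors: structure-based prediction and SVD fitting.

A partially aligning medium is modelled as a pair of parallel planar
obstructions ("walls") a fixed spacing apart. For a given orientation of the
molecule the fraction of centre positions that avoid wall overlap sets the
steric weight of that orientation; for a charged medium, admissible positions
are additionally Boltzmann-weighted by a screened (Debye-Hueckel) single-wall
potential acting on per-atom charges. The alignment tensor is the weighted
orientational average

    A_ij = scale * ( <n_i n_j> - delta_ij / 3 )

of the wall-normal direction n expressed in the molecular frame, evaluated on
a deterministic spherical Fibonacci grid. This reproduces the qualitative
behaviour of obstruction-based alignment predictors (weak alignment for
near-spherical molecules, axially symmetric tensors for rods) while staying
cheap enough to recompute during sampling.

The SVD fit solves the classic five-parameter linear inverse problem
D_i = D_max * u_i^T A u_i for the independent tensor components; it is kept
as an oracle/validation mode, since for averaging over broad conformational
ensembles a structure-based tensor is preferable.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConditioningError, ResolutionError
from .io_formats import MEDIA, Conformation, MediumSettings, RDCTable

__all__ = [
    "AlignmentTensor",
    "MediumSpec",
    "fibonacci_directions",
    "predict_tensor",
    "svd_fit_tensor",
]


@dataclass
class AlignmentTensor:
    """Symmetric, traceless 3x3 order matrix for one alignment medium."""

    A: np.ndarray
    medium: str

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, float)
        if self.A.shape != (3, 3):
            raise ValueError("alignment tensor must be 3x3")
        if not np.allclose(self.A, self.A.T, atol=1e-12):
            raise ValueError("alignment tensor must be symmetric to 1e-12")
        if abs(np.trace(self.A)) > 1e-10:
            raise ValueError("alignment tensor must be traceless to 1e-10")
        if np.max(np.abs(np.linalg.eigvalsh(self.A))) >= 1.0:
            raise ValueError("order parameters must have magnitude < 1")
        if self.medium not in MEDIA:
            raise ValueError(f"unknown medium {self.medium!r}")

    @property
    def eigenvalues(self) -> np.ndarray:
        """Eigenvalues sorted by increasing magnitude (Azz last)."""
        w = np.linalg.eigvalsh(self.A)
        return w[np.argsort(np.abs(w))]

    @property
    def rhombicity(self) -> float:
        axx, ayy, azz = self.eigenvalues
        if azz == 0.0:
            return 0.0
        return float(abs(ayy - axx) / abs(azz))

    def components(self) -> np.ndarray:
        """Five independent components (Axx, Ayy, Axy, Axz, Ayz)."""
        a = self.A
        return np.array([a[0, 0], a[1, 1], a[0, 1], a[0, 2], a[1, 2]])

    @classmethod
    def from_components(cls, comps, medium: str) -> "AlignmentTensor":
        axx, ayy, axy, axz, ayz = (float(c) for c in comps)
        azz = -axx - ayy
        return cls(
            np.array([[axx, axy, axz], [axy, ayy, ayz], [axz, ayz, azz]]), medium
        )

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            [dict(zip(("A_xx", "A_yy", "A_xy", "A_xz", "A_yz"), self.components()),
                  medium=self.medium)]
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "AlignmentTensor":
        row = pd.read_csv(path, sep="\t").iloc[0]
        return cls.from_components(
            [row["A_xx"], row["A_yy"], row["A_xy"], row["A_xz"], row["A_yz"]],
            row["medium"],
        )


@dataclass
class MediumSpec:
    """Planar-obstruction alignment medium.

    ``spacing_ang`` is the wall-to-wall distance; alignment weakens as it
    grows past the molecular extent. ``wall_charge`` (kT per unit atomic
    charge at wall contact) and ``debye_length_ang`` only act for the
    electrostatic kind.
    """

    kind: str = "steric"
    spacing_ang: float = 70.0
    probe_radius_ang: float = 2.0
    wall_charge: float = 0.0
    debye_length_ang: float = 15.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in MEDIA:
            raise ValueError(f"medium kind must be one of {MEDIA}")
        if self.scale <= 0:
            raise ValueError("scale must be > 0")
        if self.spacing_ang <= 0 or self.debye_length_ang <= 0:
            raise ValueError("lengths must be > 0")

    @classmethod
    def from_settings(cls, kind: str, s: MediumSettings) -> "MediumSpec":
        return cls(
            kind=kind,
            spacing_ang=s.spacing_ang,
            probe_radius_ang=s.probe_radius_ang,
            wall_charge=s.wall_charge if kind == "electrostatic" else 0.0,
            debye_length_ang=s.debye_length_ang,
            scale=s.scale,
        )


def fibonacci_directions(n: int) -> np.ndarray:
    """``(n, 3)`` near-uniform unit vectors on the sphere (deterministic)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + 5.0**0.5) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def orientation_weights(
    coords: np.ndarray,
    charges: np.ndarray,
    medium: MediumSpec,
    directions: np.ndarray,
    n_placements: int = 9,
) -> np.ndarray:
    """Steric (and optionally electrostatic) weight of each wall-normal direction."""
    coords = coords - coords.mean(axis=0)
    proj = coords @ directions.T  # (n_atoms, n_dir)
    rp = medium.probe_radius_ang
    hi = proj.max(axis=0) + rp
    lo = proj.min(axis=0) - rp
    free = np.maximum(0.0, medium.spacing_ang - (hi - lo))
    w = free / medium.spacing_ang
    if medium.kind == "electrostatic" and medium.wall_charge != 0.0 and np.any(charges):
        lam = medium.debye_length_ang
        qmask = charges != 0.0
        q = charges[qmask]
        pq = proj[qmask]                                    # (n_q, n_dir)
        ok = free > 0.0
        # admissible centre offsets, parametrised t in [0, 1] per direction
        t = np.linspace(0.0, 1.0, n_placements)
        z0 = -lo[None, ok] + t[:, None] * free[None, ok]    # (n_pl, n_ok)
        z_atom = pq[:, ok][None, :, :] + z0[:, None, :]     # wall-1 distance
        u = q[None, :, None] * medium.wall_charge * (
            np.exp(-z_atom / lam)
            + np.exp(-(medium.spacing_ang - z_atom) / lam)
        )
        boltz = np.zeros_like(w)
        boltz[ok] = np.exp(-u.sum(axis=1)).mean(axis=0)
        w = w * boltz
    return w


def predict_tensor(
    conformation: Conformation,
    medium: MediumSpec,
    n_orientations: int = 350,
) -> AlignmentTensor:
    """Predict the alignment tensor of a conformation from shape and charge."""
    if n_orientations < 100:
        raise ResolutionError(
            f"orientation grid of {n_orientations} is below the minimum of 100"
        )
    coords = conformation.coords
    if coords.shape[0] < 4:
        raise ValueError("need at least 4 atoms to define a shape")
    centred = coords - coords.mean(axis=0)
    if np.linalg.matrix_rank(centred, tol=1e-8) < 2:
        raise ValueError("atoms are collinear; shape-based alignment undefined")
    dirs = fibonacci_directions(n_orientations)
    w = orientation_weights(centred, conformation.charges, medium, dirs)
    total = w.sum()
    if total <= 0.0:
        raise ValueError(
            "molecule does not fit between the obstructions in any orientation"
        )
    outer = np.einsum("ki,kj,k->ij", dirs, dirs, w) / total
    A = medium.scale * (outer - np.eye(3) / 3.0)
    A = 0.5 * (A + A.T)
    A -= np.eye(3) * (np.trace(A) / 3.0)
    return AlignmentTensor(A, medium.kind)


def svd_fit_tensor(
    conformation: Conformation,
    rdc: RDCTable,
    bonds,
    medium: str,
    d_max_hz: float,
    cond_limit: float = 1e8,
) -> tuple[AlignmentTensor, np.ndarray]:
    """Fit the five independent tensor components to one medium's RDCs.

    Returns the least-squares tensor together with the per-row residuals
    D_calc - D_exp (Hz). Raises :class:`ConditioningError` when fewer than
    five couplings are available or the bond orientations are degenerate.
    """
    from .rdc_restraints import BondVectorSet  # local import avoids a cycle

    assert isinstance(bonds, BondVectorSet)
    rows = rdc.for_medium(medium)
    if len(rows) < 5:
        raise ConditioningError(
            f"{len(rows)} RDCs in medium {medium!r}; at least 5 are required"
        )
    u = bonds.unit_vectors(conformation)
    idx = bonds.match_rows(rows)
    u = u[idx]
    x, y, z = u[:, 0], u[:, 1], u[:, 2]
    design = d_max_hz * np.column_stack(
        [x * x - z * z, y * y - z * z, 2 * x * y, 2 * x * z, 2 * y * z]
    )
    if np.linalg.cond(design) > cond_limit:
        raise ConditioningError("bond orientations are degenerate (ill-conditioned fit)")
    d_exp = rows["d_exp"].to_numpy(float)
    comps, *_ = np.linalg.lstsq(design, d_exp, rcond=None)
    tensor = AlignmentTensor.from_components(comps, medium)
    residuals = design @ comps - d_exp
    return tensor, residuals
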