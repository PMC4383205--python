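"""RDC back-calculation, replica averaging, restraint energy and Q factors.

For a bond with unit vector u (direction cosines with respect to the
molecular frame) and alignment tensor A, the coupling is

    D = D_max * sum_ij A_ij u_i u_j        (Hz)

The replica-averaged calculated coupling is the plain mean over M replicas,
and the restraint energy is the unweighted quadratic penalty

    E_RDC = alpha * sum_i (D_exp_i - D_calc_i)^2   (kJ/mol),

with alpha a single global weight (kJ/mol/Hz^2). The Bax normalisation
Q = sqrt( sum (D_calc - D_exp)^2 / sum D_exp^2 ) is used for validation.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment_tensor import AlignmentTensor
from .errors import MappingError, SelectionError, UndefinedQError
from .io_formats import Conformation, RDCTable

__all__ = [
    "BondVectorSet",
    "RestraintConfig",
    "ReplicaSet",
    "calc_rdc",
    "replica_average_rdc",
    "restraint_energy",
    "restraint_gradient",
    "q_factor",
    "export_calculated",
]


@dataclass
class BondVectorSet:
    """Internuclear vectors (e.g. backbone N-H) resolvable in a topology.

    ``df`` columns: ``res_id``, ``pair`` (label such as ``N-H``),
    ``atom_from`` (e.g. N), ``atom_to`` (e.g. H).
    """

    df: pd.DataFrame
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        required = {"res_id", "pair", "atom_from", "atom_to"}
        missing = required - set(self.df.columns)
        if missing:
            raise SelectionError(f"bond table missing columns {sorted(missing)}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def atom_indices(self, conformation: Conformation) -> tuple[np.ndarray, np.ndarray]:
        """(from, to) atom index arrays, cached per topology identity."""
        key = id(conformation.atom_names)  # annotations are shared across frames
        if key not in self._cache:
            i_from = np.array(
                [conformation.atom_index(r, a)
                 for r, a in zip(self.df["res_id"], self.df["atom_from"])]
            )
            i_to = np.array(
                [conformation.atom_index(r, a)
                 for r, a in zip(self.df["res_id"], self.df["atom_to"])]
            )
            self._cache[key] = (i_from, i_to)
        return self._cache[key]

    def unit_vectors(self, conformation: Conformation) -> np.ndarray:
        """``(n_bonds, 3)`` unit vectors in the molecular frame."""
        i_from, i_to = self.atom_indices(conformation)
        vec = conformation.coords[i_to] - conformation.coords[i_from]
        norm = np.linalg.norm(vec, axis=1)
        if np.any(norm == 0):
            raise SelectionError("zero-length bond vector")
        return vec / norm[:, None]

    def match_rows(self, rows: pd.DataFrame) -> np.ndarray:
        """Bond index for each table row; unmatched rows are a hard error."""
        lookup = {
            (int(r), p): i
            for i, (r, p) in enumerate(zip(self.df["res_id"], self.df["pair"]))
        }
        idx = []
        for _, row in rows.iterrows():
            key = (int(row["res_id"]), row["pair"])
            if key not in lookup:
                raise MappingError(
                    f"experimental RDC for residue {key[0]} pair {key[1]!r} has "
                    "no calculated counterpart"
                )
            idx.append(lookup[key])
        return np.array(idx, dtype=int)


@dataclass
class RestraintConfig:
    """Weight, dipolar constant and replica count of the RDC restraint."""

    alpha: float = 1.0            # kJ/mol/Hz^2
    d_max_hz: float = -21700.0
    n_replicas: int = 16
    ramp: list[tuple[int, float]] | None = None  # (step, alpha) pairs

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.d_max_hz == 0:
            raise ValueError("d_max must be nonzero")
        if self.n_replicas < 1:
            raise ValueError("at least one replica required")


@dataclass
class ReplicaSet:
    """M conformations sharing one topology with per-replica, per-medium tensors."""

    conformations: list[Conformation]
    tensors: dict[str, list[AlignmentTensor]]

    def __post_init__(self) -> None:
        ref = self.conformations[0]
        for c in self.conformations[1:]:
            if not ref.same_topology(c):
                from .errors import TopologyError

                raise TopologyError("replicas must share one topology")
        for medium, ts in self.tensors.items():
            if len(ts) != len(self.conformations):
                raise ValueError(f"need one {medium} tensor per replica")

    @property
    def n_replicas(self) -> int:
        return len(self.conformations)


def calc_rdc(
    conformation: Conformation,
    tensor: AlignmentTensor,
    bonds: BondVectorSet,
    d_max_hz: float,
) -> np.ndarray:
    """Back-calculated couplings (Hz), one per bond in ``bonds``."""
    u = bonds.unit_vectors(conformation)
    return d_max_hz * np.einsum("bi,ij,bj->b", u, tensor.A, u)


def replica_average_rdc(
    replicas: ReplicaSet, bonds: BondVectorSet, d_max_hz: float, medium: str
) -> np.ndarray:
    """Mean coupling over replicas, each with its own tensor."""
    per = [
        calc_rdc(c, t, bonds, d_max_hz)
        for c, t in zip(replicas.conformations, replicas.tensors[medium])
    ]
    return np.mean(per, axis=0)


def _matched_arrays(
    d_calc_by_medium: dict[str, np.ndarray], rdc: RDCTable, bonds: BondVectorSet
) -> tuple[np.ndarray, np.ndarray]:
    calc, exp = [], []
    for medium in rdc.media:
        rows = rdc.for_medium(medium)
        if medium not in d_calc_by_medium:
            raise MappingError(f"no calculated couplings for medium {medium!r}")
        idx = bonds.match_rows(rows)
        calc.append(d_calc_by_medium[medium][idx])
        exp.append(rows["d_exp"].to_numpy(float))
    return np.concatenate(calc), np.concatenate(exp)


def restraint_energy(
    d_calc_by_medium: dict[str, np.ndarray],
    rdc: RDCTable,
    bonds: BondVectorSet,
    alpha: float,
) -> float:
    """E_RDC = alpha * sum_i (D_exp_i - D_calc_i)^2 over every table row (kJ/mol)."""
    calc, exp = _matched_arrays(d_calc_by_medium, rdc, bonds)
    return float(alpha * np.sum((exp - calc) ** 2))


def restraint_gradient(
    replicas: ReplicaSet,
    rdc: RDCTable,
    bonds: BondVectorSet,
    alpha: float,
    d_max_hz: float,
) -> list[np.ndarray]:
    """Gradient of E_RDC with respect to each replica's coordinates.

    Tensors are treated as constants of the current configuration (the
    restraint convention); consistency with finite differences under the same
    convention is part of the test suite. Returns one ``(n_atoms, 3)`` array
    per replica.
    """
    m = replicas.n_replicas
    d_calc = {
        medium: replica_average_rdc(replicas, bonds, d_max_hz, medium)
        for medium in rdc.media
    }
    grads = [np.zeros_like(c.coords) for c in replicas.conformations]
    ref = replicas.conformations[0]
    i_from, i_to = bonds.atom_indices(ref)
    for medium in rdc.media:
        rows = rdc.for_medium(medium)
        idx = bonds.match_rows(rows)
        resid = d_calc[medium][idx] - rows["d_exp"].to_numpy(float)  # (n_rows,)
        for r, conf in enumerate(replicas.conformations):
            A = replicas.tensors[medium][r].A
            vec = conf.coords[i_to] - conf.coords[i_from]
            norm = np.linalg.norm(vec, axis=1)
            u = vec / norm[:, None]
            Au = u @ A                       # (n_bonds, 3)
            uAu = np.einsum("bi,bi->b", u, Au)
            # dD/d(vec) for D = d_max * u^T A u with u = vec/|vec|
            dD_dvec = d_max_hz * 2.0 * (Au - uAu[:, None] * u) / norm[:, None]
            coeff = 2.0 * alpha * resid / m  # chain rule through the replica mean
            contrib = coeff[:, None] * dD_dvec[idx]
            np.add.at(grads[r], i_to[idx], contrib)
            np.add.at(grads[r], i_from[idx], -contrib)
    return grads


def q_factor(
    d_calc_by_medium: dict[str, np.ndarray], rdc: RDCTable, bonds: BondVectorSet
) -> dict[str, float]:
    """Bax Q factor per medium plus a pooled value under key ``"pooled"``."""
    out: dict[str, float] = {}
    all_calc, all_exp = [], []
    for medium in rdc.media:
        rows = rdc.for_medium(medium)
        idx = bonds.match_rows(rows)
        calc = d_calc_by_medium[medium][idx]
        exp = rows["d_exp"].to_numpy(float)
        denom = np.sum(exp**2)
        if denom == 0:
            raise UndefinedQError(f"all experimental couplings zero in {medium!r}")
        out[medium] = float(np.sqrt(np.sum((calc - exp) ** 2) / denom))
        all_calc.append(calc)
        all_exp.append(exp)
    calc = np.concatenate(all_calc)
    exp = np.concatenate(all_exp)
    out["pooled"] = float(np.sqrt(np.sum((calc - exp) ** 2) / np.sum(exp**2)))
    return out


def export_calculated(
    d_calc_by_medium: dict[str, np.ndarray],
    rdc: RDCTable,
    bonds: BondVectorSet,
    path,
) -> pd.DataFrame:
    """Write the experimental table with an added ``d_calc`` column (TSV).

    Rows keep the table's order; each is matched to its calculated coupling
    (unmatched rows raise, as everywhere else). Returns the DataFrame.
    """
    out = rdc.df.copy()
    d_calc = np.empty(len(out))
    for medium in rdc.media:
        rows = rdc.for_medium(medium)
        idx = bonds.match_rows(rows)
        mask = (out["medium"] == medium).to_numpy()
        d_calc[np.nonzero(mask)[0]] = d_calc_by_medium[medium][idx]
    out["d_calc"] = d_calc
    out.to_csv(path, sep="\t", index=False)
    return out
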