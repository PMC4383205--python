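"""Breathing angle, RMSD, free-energy surfaces, basins and contact occupancy.

The breathing angle theta is the angle at the hinge-region centre of mass
between the vectors to the alpha-domain and beta-domain centres of mass
(C-alpha atoms by default). Free-energy surfaces are histogram estimates,
F = -k_B T ln H(theta, RMSD) on populated bins, undefined (NaN) elsewhere.
Basins are rectangular in theta by default (boundary 50 degrees: smaller
theta = the closed/"unlocked" side), configurable per partition.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._geometry import angle_deg, superpose
from .errors import SelectionError
from .io_formats import KB_KJ_MOL_K, Conformation, Ensemble

__all__ = [
    "RegionDefinition",
    "LandscapeGrid",
    "BasinPartition",
    "breathing_angle",
    "rmsd_to_reference",
    "free_energy_surface",
    "basin_population",
    "contact_occupancy",
    "potential_energy_profile",
]


@dataclass
class RegionDefinition:
    """Three disjoint residue selections defining the breathing angle.

    ``region_1`` sits in the alpha-domain, ``region_2`` in the hinge and
    ``region_3`` in the beta-domain; the angle is measured at region 2.
    """

    region_1: list[int]
    region_2: list[int]
    region_3: list[int]
    atom_name: str = "CA"

    def __post_init__(self) -> None:
        sets = [set(self.region_1), set(self.region_2), set(self.region_3)]
        if any(not s for s in sets):
            raise SelectionError("every region must be non-empty")
        if sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2]:
            raise SelectionError("regions must be disjoint")

    def atom_indices(self, conformation: Conformation) -> tuple[np.ndarray, ...]:
        return tuple(
            conformation.select(region, self.atom_name)
            for region in (self.region_1, self.region_2, self.region_3)
        )


def breathing_angle(conformation: Conformation, regions: RegionDefinition) -> float:
    """Interdomain angle theta (degrees, in [0, 180])."""
    i1, i2, i3 = regions.atom_indices(conformation)
    c = conformation.coords
    return angle_deg(c[i1].mean(axis=0), c[i2].mean(axis=0), c[i3].mean(axis=0))


def rmsd_to_reference(
    conformation: Conformation,
    reference: Conformation,
    selection: tuple[list[int], str | list[str]] | np.ndarray,
) -> float:
    """C-alpha (or custom-selection) RMSD after least-squares superposition.

    ``selection`` is either ``(residue ids, atom name(s))`` resolved in both
    structures, or a ready-made atom index array valid for both.
    """
    if isinstance(selection, np.ndarray):
        idx_a = idx_b = selection
    else:
        res_ids, atom_names = selection
        idx_a = conformation.select(res_ids, atom_names)
        idx_b = reference.select(res_ids, atom_names)
    if len(idx_a) != len(idx_b):
        raise SelectionError("selection resolves to different sizes")
    if len(idx_a) < 3:
        raise SelectionError("need at least 3 atoms for superposition")
    _, rmsd = superpose(conformation.coords[idx_a], reference.coords[idx_b])
    return rmsd


@dataclass
class LandscapeGrid:
    """2-D histogram over (theta, RMSD) with its free-energy transform."""

    theta_edges: np.ndarray
    rmsd_edges: np.ndarray
    counts: np.ndarray
    temperature_K: float

    def __post_init__(self) -> None:
        self.theta_edges = np.asarray(self.theta_edges, float)
        self.rmsd_edges = np.asarray(self.rmsd_edges, float)
        self.counts = np.asarray(self.counts)
        if np.any(np.diff(self.theta_edges) <= 0) or np.any(
            np.diff(self.rmsd_edges) <= 0
        ):
            raise ValueError("bin edges must be strictly increasing")

    @property
    def free_energy(self) -> np.ndarray:
        """-k_B T ln H on populated bins, NaN where H = 0 (kJ/mol)."""
        with np.errstate(divide="ignore"):
            f = -KB_KJ_MOL_K * self.temperature_K * np.log(
                self.counts.astype(float)
            )
        f[self.counts == 0] = np.nan
        return f

    def to_tsv(self, path) -> None:
        tc = 0.5 * (self.theta_edges[:-1] + self.theta_edges[1:])
        rc = 0.5 * (self.rmsd_edges[:-1] + self.rmsd_edges[1:])
        f = self.free_energy
        rows = [
            dict(theta_bin=tc[i], rmsd_bin=rc[j], H=int(self.counts[i, j]),
                 F=f[i, j])
            for i in range(len(tc))
            for j in range(len(rc))
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def free_energy_surface(
    ensemble: Ensemble,
    regions: RegionDefinition,
    reference: Conformation,
    selection,
    temperature_K: float = 310.0,
    theta_bin_deg: float = 1.0,
    rmsd_bin_ang: float = 0.1,
) -> LandscapeGrid:
    """Histogram the ensemble's (theta, RMSD) pairs and attach F = -kT ln H."""
    thetas = np.array([breathing_angle(c, regions) for c in ensemble])
    rmsds = np.array(
        [rmsd_to_reference(c, reference, selection) for c in ensemble]
    )
    t_edges = _edges(thetas, theta_bin_deg)
    r_edges = _edges(rmsds, rmsd_bin_ang)
    counts, _, _ = np.histogram2d(thetas, rmsds, bins=[t_edges, r_edges])
    return LandscapeGrid(t_edges, r_edges, counts.astype(int), temperature_K)


def _edges(values: np.ndarray, width: float) -> np.ndarray:
    lo = np.floor(values.min() / width) * width
    hi = np.ceil(values.max() / width) * width
    if hi <= lo:
        hi = lo + width
    n = int(round((hi - lo) / width))
    return lo + width * np.arange(n + 1)


def _points_in_polygon(x: np.ndarray, y: np.ndarray, vertices) -> np.ndarray:
    """Even-odd ray-casting point-in-polygon test (vectorised over points)."""
    vx = np.array([v[0] for v in vertices], float)
    vy = np.array([v[1] for v in vertices], float)
    inside = np.zeros(len(x), dtype=bool)
    j = len(vertices) - 1
    for i in range(len(vertices)):
        crosses = (vy[i] > y) != (vy[j] > y)
        with np.errstate(divide="ignore", invalid="ignore"):
            x_cross = (vx[j] - vx[i]) * (y - vy[i]) / (vy[j] - vy[i]) + vx[i]
        inside ^= crosses & (x < x_cross)
        j = i
    return inside


@dataclass
class BasinPartition:
    """Two-basin partition of the reaction-coordinate plane.

    By default the partition is rectangular in theta: conformations below
    ``boundary_deg`` belong to ``label_below`` (the closed, "unlocked" side).
    A non-rectangular basin can be given as ``polygon``, a list of
    (theta, RMSD) vertices enclosing the ``label_below`` region; classifying
    with a polygon requires per-frame RMSD values.
    """

    boundary_deg: float = 50.0
    label_below: str = "unlocked"
    label_above: str = "locked"
    polygon: list[tuple[float, float]] | None = None

    def classify(
        self, thetas: np.ndarray, rmsds: np.ndarray | None = None
    ) -> np.ndarray:
        thetas = np.asarray(thetas, float)
        if self.polygon is not None:
            if rmsds is None:
                raise ValueError(
                    "a polygonal partition needs per-frame RMSD values"
                )
            inside = _points_in_polygon(
                thetas, np.asarray(rmsds, float), self.polygon
            )
            return np.where(inside, self.label_below, self.label_above)
        return np.where(
            thetas < self.boundary_deg, self.label_below, self.label_above
        )


def basin_population(
    ensemble: Ensemble,
    regions: RegionDefinition,
    partition: BasinPartition,
    reference: Conformation | None = None,
    selection=None,
    thetas: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-basin fraction, mean/mode theta and (optionally) mean RMSD.

    Fractions use ensemble weights when present and sum to 1 exactly.
    Precomputed ``thetas`` may be passed to avoid recomputation.
    """
    if thetas is None:
        thetas = np.array([breathing_angle(c, regions) for c in ensemble])
    thetas = np.asarray(thetas, float)
    w = ensemble.effective_weights()
    rmsds = None
    if reference is not None and selection is not None:
        rmsds = np.array(
            [rmsd_to_reference(c, reference, selection) for c in ensemble]
        )
    labels = partition.classify(thetas, rmsds)
    rows = []
    for label in (partition.label_below, partition.label_above):
        mask = labels == label
        frac = float(w[mask].sum() / w.sum())
        row = dict(basin=label, fraction=frac, n_frames=int(mask.sum()))
        if mask.any():
            row["theta_mean"] = float(np.average(thetas[mask], weights=w[mask]))
            row["theta_mode"] = _mode(thetas[mask], w[mask])
            if rmsds is not None:
                row["rmsd_mean"] = float(np.average(rmsds[mask], weights=w[mask]))
        else:
            row["theta_mean"] = np.nan
            row["theta_mode"] = np.nan
            if rmsds is not None:
                row["rmsd_mean"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def _mode(values: np.ndarray, weights: np.ndarray, width: float = 1.0) -> float:
    edges = _edges(values, width)
    h, _ = np.histogram(values, bins=edges, weights=weights)
    i = int(np.argmax(h))
    return float(0.5 * (edges[i] + edges[i + 1]))


def contact_occupancy(
    ensemble: Ensemble,
    donors: list[tuple[int, str]],
    acceptors: list[tuple[int, str]],
    distance_cutoff_ang: float = 3.5,
    angle_cutoff_deg: float = 120.0,
    hydrogens: list[tuple[int, str]] | None = None,
    labels: np.ndarray | None = None,
) -> pd.DataFrame:
    """Fraction of conformations in which each donor/acceptor pair is formed.

    Donors and acceptors are matched element-wise as ``(residue, atom)``
    pairs. A pair is formed when the donor-acceptor distance is at most the
    cutoff and, if ``hydrogens`` supplies a matching hydrogen per pair, the
    donor-H...acceptor angle is at least ``angle_cutoff_deg``. With per-frame
    ``labels`` (e.g. basin assignments) occupancies are also reported per
    label.
    """
    if not donors or not acceptors:
        raise SelectionError("empty donor or acceptor selection")
    if len(donors) != len(acceptors):
        raise SelectionError("donor and acceptor selections must pair up")
    ref = ensemble[0]
    di = [ref.atom_index(r, a) for r, a in donors]
    ai = [ref.atom_index(r, a) for r, a in acceptors]
    hi = [ref.atom_index(r, a) for r, a in hydrogens] if hydrogens else None
    formed = np.zeros((len(ensemble), len(donors)), dtype=bool)
    for f, conf in enumerate(ensemble):
        c = conf.coords
        dist = np.linalg.norm(c[di] - c[ai], axis=1)
        ok = dist <= distance_cutoff_ang
        if hi is not None:
            ang = np.array(
                [angle_deg(c[d], c[h], c[a]) for d, h, a in zip(di, hi, ai)]
            )
            ok &= ang >= angle_cutoff_deg
        formed[f] = ok
    rows = []
    for p, (dn, ac) in enumerate(zip(donors, acceptors)):
        row = dict(
            donor=f"{dn[0]}:{dn[1]}", acceptor=f"{ac[0]}:{ac[1]}",
            occupancy=float(formed[:, p].mean()),
        )
        if labels is not None:
            for label in np.unique(labels):
                mask = labels == label
                row[f"occupancy_{label}"] = (
                    float(formed[mask, p].mean()) if mask.any() else np.nan
                )
        rows.append(row)
    return pd.DataFrame(rows)


def potential_energy_profile(
    thetas: np.ndarray, e_pot: np.ndarray, theta_bin_deg: float = 1.0
) -> pd.DataFrame:
    """Mean and standard error of per-frame E_pot per theta bin.

    Empty bins are absent from the output (undefined, never reported as 0).
    """
    thetas = np.asarray(thetas, float)
    e_pot = np.asarray(e_pot, float)
    if thetas.shape != e_pot.shape:
        raise ValueError("need one energy per frame")
    if not np.all(np.isfinite(e_pot)):
        raise ValueError("every frame must carry a finite potential energy")
    edges = _edges(thetas, theta_bin_deg)
    idx = np.clip(np.digitize(thetas, edges) - 1, 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        mask = idx == b
        if not mask.any():
            continue
        vals = e_pot[mask]
        rows.append(
            dict(
                theta_bin=0.5 * (edges[b] + edges[b + 1]),
                e_pot_mean=float(vals.mean()),
                e_pot_sem=float(vals.std(ddof=1) / np.sqrt(len(vals)))
                if len(vals) > 1
                else np.nan,
                n=int(mask.sum()),
            )
        )
    return pd.DataFrame(rows)
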