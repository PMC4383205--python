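"""Independent-data validation: HNHA 3J extraction, Karplus back-calculation,
NOE satisfaction and a consolidated report.

The HNHA experiment encodes the three-bond HN-Halpha scalar coupling in the
ratio of cross- and diagonal-peak intensities,

    I_X / I_D = -tan^2(2 pi xi 3J),      xi = 13.05 ms by default,

inverted on the principal branch as 3J = arctan(sqrt(-I_X/I_D)) / (2 pi xi).
Intensity uncertainties (a relative floor or the spectrum noise level,
whichever is larger) are propagated to 3J by first-order error propagation.
Back-calculation uses a configurable Karplus parameterisation
3J(phi) = A cos^2(phi - 60) + B cos(phi - 60) + C averaged over the ensemble.
NOEs are evaluated per individual structure against upper distance bounds
plus a tolerance.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._geometry import dihedral_deg
from .errors import BranchError, SelectionError
from .io_formats import Conformation, Ensemble, HNHATable, NOETable, RDCTable

__all__ = [
    "JCouplingResult",
    "ValidationReport",
    "KarplusCoefficients",
    "j_from_hnha",
    "hnha_error",
    "extract_j_couplings",
    "backcalc_j",
    "noe_satisfaction",
    "build_report",
]

XI_DEFAULT_S = 0.01305


@dataclass
class JCouplingResult:
    res_id: int
    j_hz: float
    error_hz: float
    xi_s: float = XI_DEFAULT_S
    flag: str = "measured"   # measured | below-noise | discarded

    def __post_init__(self) -> None:
        if self.flag != "discarded":
            if self.j_hz < 0 or self.error_hz < 0:
                raise ValueError("coupling and error must be nonnegative")


@dataclass
class KarplusCoefficients:
    """3J(phi) = a cos^2(phi-60) + b cos(phi-60) + c, phi in degrees, J in Hz."""

    a: float = 7.09
    b: float = -1.42
    c: float = 1.55

    def j(self, phi_deg: np.ndarray | float) -> np.ndarray | float:
        x = np.cos(np.radians(np.asarray(phi_deg, float) - 60.0))
        return self.a * x * x + self.b * x + self.c


def ratio_from_j(j_hz: float, xi_s: float = XI_DEFAULT_S) -> float:
    """Forward map J -> I_X/I_D; J must lie on the principal branch."""
    arg = 2.0 * math.pi * xi_s * j_hz
    if not 0.0 <= arg < math.pi / 2.0:
        raise BranchError(
            f"J = {j_hz} Hz is outside the principal branch (0, {1/(4*xi_s):.2f} Hz)"
        )
    return -math.tan(arg) ** 2


def j_from_hnha(
    i_cross: float, i_diag: float, xi_s: float = XI_DEFAULT_S
) -> float:
    """Principal-branch 3J (Hz) from one cross/diagonal intensity pair."""
    if i_diag == 0:
        raise ValueError("diagonal intensity must be nonzero")
    ratio = i_cross / i_diag
    if ratio > 0:
        raise BranchError(
            f"I_X/I_D = {ratio:.3g} > 0 violates the tangent-squared sign convention"
        )
    return math.atan(math.sqrt(-ratio)) / (2.0 * math.pi * xi_s)


def hnha_error(
    i_cross: float,
    i_diag: float,
    noise: float,
    xi_s: float = XI_DEFAULT_S,
    relative_floor: float = 0.05,
) -> float:
    """First-order propagated 3J uncertainty (Hz).

    Each intensity carries max(relative_floor * |intensity|, noise level).
    """
    sig_x = max(relative_floor * abs(i_cross), noise)
    sig_d = max(relative_floor * abs(i_diag), noise)
    r = i_cross / i_diag
    sig_r = math.hypot(sig_x / abs(i_diag), r * sig_d / i_diag)
    t2 = -r  # tan^2 term, >= 0 on the branch
    if t2 < 0:
        raise BranchError("positive intensity ratio")
    if t2 == 0.0:
        # derivative of atan(sqrt(x)) diverges at 0; quote the half-width of
        # the interval [0, sqrt(sig_r)] reachable within one sigma instead
        return math.atan(math.sqrt(sig_r)) / (2.0 * math.pi * xi_s)
    dj_dr = 1.0 / (2.0 * math.pi * xi_s) / (1.0 + t2) / (2.0 * math.sqrt(t2))
    return abs(dj_dr) * sig_r


def extract_j_couplings(
    table: HNHATable,
    xi_s: float = XI_DEFAULT_S,
    relative_floor: float = 0.05,
    exclude_res_names: tuple[str, ...] = ("GLY",),
) -> list[JCouplingResult]:
    """Extract 3J per residue, flagging glycines/overlaps as discarded and
    cross-peaks below the noise level as ``below-noise``."""
    out = []
    has_names = "res_name" in table.df.columns
    for _, row in table.df.iterrows():
        res = int(row["res_id"])
        if has_names and str(row["res_name"]).upper() in exclude_res_names:
            out.append(JCouplingResult(res, math.nan, math.nan, xi_s, "discarded"))
            continue
        j = j_from_hnha(row["i_cross"], row["i_diag"], xi_s)
        err = hnha_error(
            row["i_cross"], row["i_diag"], row["noise"], xi_s, relative_floor
        )
        flag = "below-noise" if abs(row["i_cross"]) < row["noise"] else "measured"
        out.append(JCouplingResult(res, j, err, xi_s, flag))
    return out


def phi_dihedral(conformation: Conformation, res_id: int) -> float:
    """Backbone phi (degrees) from C(i-1), N(i), CA(i), C(i)."""
    c = conformation.coords
    try:
        p = [
            c[conformation.atom_index(res_id - 1, "C")],
            c[conformation.atom_index(res_id, "N")],
            c[conformation.atom_index(res_id, "CA")],
            c[conformation.atom_index(res_id, "C")],
        ]
    except SelectionError as exc:
        raise SelectionError(f"phi undefined for residue {res_id}: {exc}") from exc
    return dihedral_deg(*p)


def backcalc_j(
    ensemble: Ensemble,
    res_ids: list[int],
    karplus: KarplusCoefficients | None = None,
) -> pd.DataFrame:
    """Ensemble-averaged Karplus 3J per residue (weights honoured)."""
    karplus = karplus or KarplusCoefficients()
    w = ensemble.effective_weights()
    rows = []
    for res in res_ids:
        js = np.array(
            [karplus.j(phi_dihedral(c, res)) for c in ensemble], dtype=float
        )
        rows.append(dict(res_id=res, j_calc=float(np.average(js, weights=w))))
    return pd.DataFrame(rows)


def noe_satisfaction(
    ensemble: Ensemble, noes: NOETable, tolerance_ang: float = 0.5
) -> tuple[pd.DataFrame, list[int]]:
    """Per-structure satisfied fraction; unresolvable pairs listed separately.

    An NOE is satisfied in a structure when the pair distance is at most
    bound + tolerance. Returns (per-structure DataFrame with ``satisfied``
    and ``violated`` fractions, indices of excluded table rows).
    """
    ref = ensemble[0]
    pairs, excluded = [], []
    for k, row in noes.df.iterrows():
        try:
            i = ref.atom_index(int(row["res_1"]), row["atom_1"])
            j = ref.atom_index(int(row["res_2"]), row["atom_2"])
        except SelectionError:
            excluded.append(int(k))
            continue
        pairs.append((i, j, float(row["bound"])))
    if not pairs:
        raise SelectionError("no NOE pair could be resolved in the topology")
    idx_i = np.array([p[0] for p in pairs])
    idx_j = np.array([p[1] for p in pairs])
    bounds = np.array([p[2] for p in pairs])
    rows = []
    for s, conf in enumerate(ensemble, start=1):
        d = np.linalg.norm(conf.coords[idx_i] - conf.coords[idx_j], axis=1)
        sat = float(np.mean(d <= bounds + tolerance_ang))
        rows.append(dict(model=s, satisfied=sat, violated=1.0 - sat))
    return pd.DataFrame(rows), excluded


@dataclass
class ValidationReport:
    """Aggregated validation metrics for one ensemble."""

    q_factors: dict[str, float] = field(default_factory=dict)
    j_rmsd_hz: float | None = None
    noe_satisfied_mean: float | None = None
    noe_violated_mean: float | None = None
    noe_per_structure: pd.DataFrame | None = None
    counts: dict[str, int] = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        rows = [
            dict(metric=f"q_{m}", value=v) for m, v in self.q_factors.items()
        ]
        if self.j_rmsd_hz is not None:
            rows.append(dict(metric="j_rmsd_hz", value=self.j_rmsd_hz))
        if self.noe_satisfied_mean is not None:
            rows.append(dict(metric="noe_satisfied", value=self.noe_satisfied_mean))
            rows.append(dict(metric="noe_violated", value=self.noe_violated_mean))
        for k, v in self.counts.items():
            rows.append(dict(metric=f"n_{k}", value=v))
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    def summary(self) -> str:
        lines = ["ensemble validation"]
        for m, v in self.q_factors.items():
            lines.append(f"  Q ({m}): {v:.3f}")
        if self.j_rmsd_hz is not None:
            lines.append(f"  3J RMSD: {self.j_rmsd_hz:.3f} Hz")
        if self.noe_satisfied_mean is not None:
            lines.append(
                f"  NOE satisfied/violated: {100 * self.noe_satisfied_mean:.1f}%"
                f" / {100 * self.noe_violated_mean:.1f}%"
            )
        return "\n".join(lines)


def j_rmsd(extracted: list[JCouplingResult], calculated: pd.DataFrame) -> float:
    """RMS deviation (Hz) between extracted and back-calculated couplings."""
    calc = dict(zip(calculated["res_id"], calculated["j_calc"]))
    diffs = [
        r.j_hz - calc[r.res_id]
        for r in extracted
        if r.flag != "discarded" and r.res_id in calc
    ]
    if not diffs:
        raise ValueError("no overlapping residues between extraction and calculation")
    return float(np.sqrt(np.mean(np.square(diffs))))


def build_report(
    ensemble: Ensemble,
    bonds=None,
    rdc: RDCTable | None = None,
    media: dict | None = None,
    d_max_hz: float = -21700.0,
    hnha: HNHATable | None = None,
    karplus: KarplusCoefficients | None = None,
    xi_s: float = XI_DEFAULT_S,
    noes: NOETable | None = None,
    noe_tolerance_ang: float = 0.5,
    n_orientations: int = 350,
) -> ValidationReport:
    """Validate an ensemble against whichever independent data are supplied.

    RDC Q factors use per-frame structure-predicted tensors (shape/charge
    model, same route as the generator and sampler) averaged over the
    ensemble; 3J validation compares HNHA-extracted to Karplus back-calculated
    couplings; NOEs are checked per structure.
    """
    if rdc is None and hnha is None and noes is None:
        raise ValueError("at least one validation input is required")
    from .alignment_tensor import predict_tensor
    from .rdc_restraints import calc_rdc, q_factor

    report = ValidationReport()
    w = ensemble.effective_weights()
    if rdc is not None:
        if bonds is None or media is None:
            raise ValueError("RDC validation needs bond vectors and media specs")
        d_calc = {}
        for medium in rdc.media:
            per_frame = np.stack(
                [
                    calc_rdc(
                        c,
                        predict_tensor(c, media[medium], n_orientations),
                        bonds,
                        d_max_hz,
                    )
                    for c in ensemble
                ]
            )
            d_calc[medium] = np.average(per_frame, axis=0, weights=w)
        report.q_factors = q_factor(d_calc, rdc, bonds)
        report.counts["rdc_rows"] = len(rdc)
    if hnha is not None:
        extracted = extract_j_couplings(hnha, xi_s)
        usable = [r for r in extracted if r.flag != "discarded"]
        calc = backcalc_j(ensemble, [r.res_id for r in usable], karplus)
        report.j_rmsd_hz = j_rmsd(usable, calc)
        report.counts["hnha_rows"] = len(hnha)
        report.counts["hnha_used"] = len(usable)
        report.counts["hnha_discarded"] = len(extracted) - len(usable)
    if noes is not None:
        per_structure, excluded = noe_satisfaction(ensemble, noes, noe_tolerance_ang)
        report.noe_per_structure = per_structure
        report.noe_satisfied_mean = float(per_structure["satisfied"].mean())
        report.noe_violated_mean = float(per_structure["violated"].mean())
        report.counts["noe_rows"] = len(noes)
        report.counts["noe_excluded"] = len(excluded)
    return report
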