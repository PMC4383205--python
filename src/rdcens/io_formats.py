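"""Coordinate and NMR-table containers plus readers/writers and run configuration.

Conformations are stored as flat numpy annotation arrays (one entry per atom),
mirroring the layout of ``biotite.structure.AtomArray``; multi-model PDB is the
ensemble interchange format, with optional per-model weights in a sidecar TSV
(the PDB format has no weight field). All coordinates are in Angstrom.

NMR tables (RDC, NOE, HNHA) are tab-separated text with a one-line header and
are held in pandas DataFrames wrapped by thin validating classes.
"""
from __future__ import annotations

import dataclasses
import io
import os
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import yaml

import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .errors import (
    ConfigError,
    FormatError,
    TableValidationError,
    TopologyError,
)

MEDIA = ("steric", "electrostatic")

# Boltzmann constant in kJ/mol/K; energies are kJ/mol throughout the package.
KB_KJ_MOL_K = 0.0083145


# ---------------------------------------------------------------------------
# Conformations and ensembles
# ---------------------------------------------------------------------------

@dataclass
class Conformation:
    """One set of labelled atom coordinates.

    Parameters
    ----------
    chain_ids, res_ids, res_names, atom_names, elements
        Per-atom annotation arrays of equal length.
    coords
        ``(n_atoms, 3)`` array, Angstrom.
    charges
        Optional per-atom formal charges (used by electrostatic alignment
        media); default zero.
    model_id
        1-based model index the conformation came from.
    """

    chain_ids: np.ndarray
    res_ids: np.ndarray
    res_names: np.ndarray
    atom_names: np.ndarray
    elements: np.ndarray
    coords: np.ndarray
    charges: np.ndarray | None = None
    model_id: int = 1

    def __post_init__(self) -> None:
        self.chain_ids = np.asarray(self.chain_ids, dtype="U4")
        self.res_ids = np.asarray(self.res_ids, dtype=int)
        self.res_names = np.asarray(self.res_names, dtype="U5")
        self.atom_names = np.asarray(self.atom_names, dtype="U6")
        self.elements = np.asarray(self.elements, dtype="U2")
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.atom_names)
        if self.coords.shape != (n, 3):
            raise TopologyError(
                f"coordinate array shape {self.coords.shape} does not match "
                f"{n} atoms"
            )
        if self.charges is None:
            self.charges = np.zeros(n)
        else:
            self.charges = np.asarray(self.charges, dtype=float)
            if self.charges.shape != (n,):
                raise TopologyError("charge array length mismatch")
        if not np.all(np.isfinite(self.coords)):
            raise TopologyError("non-finite coordinates")
        keys = list(zip(self.chain_ids, self.res_ids, self.atom_names))
        if len(set(keys)) != n:
            raise TopologyError("(chain, residue, atom name) keys not unique")
        self._index = {k: i for i, k in enumerate(keys)}

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def atom_index(self, res_id: int, atom_name: str, chain_id: str | None = None) -> int:
        """Index of one atom; the chain defaults to the first chain present."""
        chain = chain_id if chain_id is not None else str(self.chain_ids[0])
        try:
            return self._index[(chain, int(res_id), atom_name)]
        except KeyError:
            from .errors import SelectionError

            raise SelectionError(
                f"atom {atom_name!r} of residue {res_id} (chain {chain!r}) "
                "not found in topology"
            ) from None

    def select(self, res_ids: Sequence[int], atom_names: Sequence[str] | str = "CA") -> np.ndarray:
        """Atom indices of the given residues restricted to ``atom_names``."""
        if isinstance(atom_names, str):
            atom_names = [atom_names]
        wanted_res = set(int(r) for r in res_ids)
        mask = np.isin(self.res_ids, list(wanted_res)) & np.isin(
            self.atom_names, list(atom_names)
        )
        found_res = set(self.res_ids[mask].tolist())
        missing = wanted_res - found_res
        if missing:
            from .errors import SelectionError

            raise SelectionError(f"residues without matching atoms: {sorted(missing)}")
        return np.nonzero(mask)[0]

    def same_topology(self, other: "Conformation") -> bool:
        return (
            self.n_atoms == other.n_atoms
            and np.array_equal(self.chain_ids, other.chain_ids)
            and np.array_equal(self.res_ids, other.res_ids)
            and np.array_equal(self.atom_names, other.atom_names)
        )

    def with_coords(self, coords: np.ndarray, model_id: int | None = None) -> "Conformation":
        """Copy sharing annotations but with new coordinates."""
        return Conformation(
            chain_ids=self.chain_ids,
            res_ids=self.res_ids,
            res_names=self.res_names,
            atom_names=self.atom_names,
            elements=self.elements,
            coords=np.array(coords, float),
            charges=self.charges,
            model_id=self.model_id if model_id is None else model_id,
        )


@dataclass
class Ensemble:
    """Ordered conformations sharing one topology, with optional weights."""

    conformations: list[Conformation]
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.conformations:
            raise TopologyError("an ensemble needs at least one conformation")
        ref = self.conformations[0]
        for i, c in enumerate(self.conformations[1:], start=2):
            if not ref.same_topology(c):
                raise TopologyError(f"model {i} does not share the topology of model 1")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, float)
            if self.weights.shape != (len(self.conformations),):
                raise TopologyError("one weight per conformation required")
            if np.any(self.weights < 0):
                raise TopologyError("weights must be nonnegative")
            if abs(self.weights.sum() - 1.0) > 1e-9:
                raise TopologyError("weights must sum to 1 within 1e-9")

    def __len__(self) -> int:
        return len(self.conformations)

    def __iter__(self) -> Iterator[Conformation]:
        return iter(self.conformations)

    def __getitem__(self, i: int) -> Conformation:
        return self.conformations[i]

    def effective_weights(self) -> np.ndarray:
        if self.weights is not None:
            return self.weights
        n = len(self)
        return np.full(n, 1.0 / n)

    def coords_stack(self) -> np.ndarray:
        """``(n_models, n_atoms, 3)`` coordinate array."""
        return np.stack([c.coords for c in self.conformations])


def _stack_to_ensemble(stack: struc.AtomArrayStack) -> Ensemble:
    charges = (
        stack.charge.astype(float)
        if "charge" in stack.get_annotation_categories()
        else None
    )
    confs = []
    for m in range(stack.stack_depth()):
        confs.append(
            Conformation(
                chain_ids=stack.chain_id,
                res_ids=stack.res_id,
                res_names=stack.res_name,
                atom_names=stack.atom_name,
                elements=stack.element,
                coords=stack.coord[m],
                charges=charges,
                model_id=m + 1,
            )
        )
    return Ensemble(confs)


def read_conformations(path: str | os.PathLike) -> Ensemble:
    """Read a (multi-model) PDB file into an :class:`Ensemble`.

    A sidecar ``<path>.weights.tsv`` written by :func:`write_conformations`
    is picked up automatically.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure(extra_fields=["charge"])
    except struc.BadStructureError as exc:
        raise TopologyError(f"inconsistent models in {path}: {exc}") from exc
    except Exception as exc:  # biotite raises InvalidFileError subclasses
        if "model" in str(exc).lower() and "atom" in str(exc).lower():
            raise TopologyError(f"inconsistent models in {path}: {exc}") from exc
        raise FormatError(f"cannot parse PDB file {path}: {exc}") from exc
    ens = _stack_to_ensemble(stack)
    sidecar = str(path) + ".weights.tsv"
    if os.path.exists(sidecar):
        wdf = pd.read_csv(sidecar, sep="\t")
        ens = Ensemble(ens.conformations, weights=wdf["weight"].to_numpy())
    return ens


def write_conformations(ensemble: Ensemble, path: str | os.PathLike) -> None:
    """Write an ensemble as a multi-model PDB (weights to a sidecar TSV)."""
    ref = ensemble[0]
    n = ref.n_atoms
    stack = struc.AtomArrayStack(len(ensemble), n)
    stack.chain_id = ref.chain_ids
    stack.res_id = ref.res_ids
    stack.res_name = ref.res_names
    stack.atom_name = ref.atom_names
    stack.element = ref.elements
    stack.hetero = np.zeros(n, dtype=bool)
    stack.set_annotation("charge", np.rint(ref.charges).astype(int))
    stack.coord = ensemble.coords_stack()
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))
    if ensemble.weights is not None:
        wdf = pd.DataFrame(
            {"model": np.arange(1, len(ensemble) + 1), "weight": ensemble.weights}
        )
        wdf.to_csv(str(path) + ".weights.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# NMR tables
# ---------------------------------------------------------------------------

def _read_tsv(path: str | os.PathLike, required: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:
        raise FormatError(f"cannot parse table {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    return df


@dataclass
class RDCTable:
    """Experimental residual dipolar couplings, keyed by (residue, pair, medium).

    Columns: ``res_id``, ``pair`` (e.g. ``N-H``), ``medium``
    (``steric`` | ``electrostatic``), ``d_exp`` (Hz), ``sigma`` (Hz).
    """

    df: pd.DataFrame

    COLUMNS = ("res_id", "pair", "medium", "d_exp", "sigma")

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True)
        bad_media = set(df["medium"]) - set(MEDIA)
        if bad_media:
            raise TableValidationError(f"unknown medium id(s): {sorted(bad_media)}")
        if (df["sigma"] <= 0).any():
            rows = df.index[df["sigma"] <= 0].tolist()
            raise TableValidationError(f"sigma must be > 0 (rows {rows})")
        keys = df[["res_id", "pair", "medium"]].apply(tuple, axis=1)
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].tolist()
            raise TableValidationError(f"duplicate (residue, pair, medium) keys: {dup}")
        if not np.all(np.isfinite(df["d_exp"].to_numpy(float))):
            raise TableValidationError("non-finite d_exp")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def for_medium(self, medium: str) -> pd.DataFrame:
        return self.df[self.df["medium"] == medium].reset_index(drop=True)

    @property
    def media(self) -> list[str]:
        return [m for m in MEDIA if (self.df["medium"] == m).any()]

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def read_rdc_table(path: str | os.PathLike) -> RDCTable:
    """Read a tab-separated RDC table; every row is validated, none dropped."""
    df = _read_tsv(path, RDCTable.COLUMNS)
    return RDCTable(df[list(RDCTable.COLUMNS)])


@dataclass
class NOETable:
    """Upper distance bounds between atom pairs.

    Columns: ``res_1``, ``atom_1``, ``res_2``, ``atom_2``, ``bound`` (Angstrom).
    """

    df: pd.DataFrame

    COLUMNS = ("res_1", "atom_1", "res_2", "atom_2", "bound")

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True)
        if (df["bound"] <= 0).any():
            raise TableValidationError("NOE bounds must be > 0")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def read_noe_table(path: str | os.PathLike) -> NOETable:
    return NOETable(_read_tsv(path, NOETable.COLUMNS)[list(NOETable.COLUMNS)])


@dataclass
class HNHATable:
    """HNHA cross/diagonal peak intensities per residue.

    Columns: ``res_id``, ``res_name`` (optional, used for the glycine filter),
    ``i_cross``, ``i_diag``, ``noise`` (same arbitrary intensity units).
    """

    df: pd.DataFrame

    COLUMNS = ("res_id", "i_cross", "i_diag", "noise")

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True)
        if (df["i_diag"] == 0).any():
            raise TableValidationError("i_diag must be nonzero for usable rows")
        if (df["noise"] < 0).any():
            raise TableValidationError("noise level must be >= 0")
        if df["res_id"].duplicated().any():
            raise TableValidationError("duplicate residue ids in HNHA table")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def read_hnha_table(path: str | os.PathLike) -> HNHATable:
    df = _read_tsv(path, HNHATable.COLUMNS)
    cols = list(HNHATable.COLUMNS)
    if "res_name" in df.columns:
        cols.insert(1, "res_name")
    return HNHATable(df[cols])


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class SamplerSettings:
    replicas: int = 16
    cycles: int = 50
    t_low_K: float = 310.0
    t_high_K: float = 500.0
    cycle_ps: float = 250.0
    timestep_fs: float = 2.0
    frames_per_ps: int = 1
    collect_window_ps: float = 50.0
    retain_last_cycles: int = 30
    moves_per_ps: int = 20
    equilibration_ps: float = 50.0
    seed: int = 0


@dataclass
class RestraintSettings:
    alpha_target: float = 2.0          # kJ/mol/Hz^2
    d_max_hz: float = -21700.0         # N-H dipolar interaction constant
    tensor_update_interval: int = 10   # accepted moves between tensor refreshes
    ramp_stages: int = 40
    ramp_start_fraction: float = 0.01


@dataclass
class LandscapeSettings:
    theta_bin_deg: float = 1.0
    rmsd_bin_ang: float = 0.1
    basin_boundary_deg: float = 50.0
    temperature_K: float = 310.0
    # residue-list selections (None: use the toy system's built-in regions)
    region_1: list | None = None
    region_2: list | None = None
    region_3: list | None = None
    rmsd_residues: list | None = None


@dataclass
class ValidationSettings:
    karplus_a: float = 7.09
    karplus_b: float = -1.42
    karplus_c: float = 1.55
    xi_s: float = 0.01305
    intensity_floor: float = 0.05
    noe_tolerance_ang: float = 0.5


@dataclass
class MediumSettings:
    spacing_ang: float = 70.0
    probe_radius_ang: float = 2.0
    wall_charge: float = 0.8       # kT per unit atomic charge at contact
    debye_length_ang: float = 15.0
    scale: float = 1.0


@dataclass
class RunConfig:
    sampler: SamplerSettings = field(default_factory=SamplerSettings)
    restraint: RestraintSettings = field(default_factory=RestraintSettings)
    landscape: LandscapeSettings = field(default_factory=LandscapeSettings)
    validation: ValidationSettings = field(default_factory=ValidationSettings)
    steric: MediumSettings = field(default_factory=MediumSettings)
    electrostatic: MediumSettings = field(default_factory=MediumSettings)


def _apply_section(obj, data: dict, section: str):
    valid = {f.name for f in dataclasses.fields(obj)}
    for key, value in data.items():
        if key not in valid:
            raise ConfigError(f"unknown key {section}.{key!r}")
        setattr(obj, key, value)
    return obj


def load_config(path: str | os.PathLike | io.IOBase) -> RunConfig:
    """Load a YAML run configuration, applying defaults and rejecting unknown keys."""
    if isinstance(path, io.IOBase):
        data = yaml.safe_load(path)
    else:
        with open(path) as fh:
            data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("top-level config must be a mapping")
    cfg = RunConfig()
    sections = {f.name: getattr(cfg, f.name) for f in dataclasses.fields(cfg)}
    for key, value in data.items():
        if key not in sections:
            raise ConfigError(f"unknown key {key!r}")
        if not isinstance(value, dict):
            raise ConfigError(f"section {key!r} must be a mapping")
        _apply_section(sections[key], value, key)
    return cfg
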