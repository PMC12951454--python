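"""Domain containers and file formats.

The pipeline works on three kinds of input: coordinate files (fixed-column
PDB, with multi-MODEL files acting as the trajectory container), protein
sequences (FASTA), and delimited tables of per-residue NMR observables.
All cutoffs and thresholds live in a single :class:`AnalysisConfig` that can
be round-tripped through a YAML file.

The PDB reader implements a deliberately small dialect: element is taken
from columns 77-78 when present and otherwise inferred from the atom name,
waters are recognised by residue name (``HOH``/``WAT``/``TIP3``/``SOL`` by
default), and every MODEL must contain the same atoms in the same order.
Anything else is a :class:`FormatError` carrying the offending line number.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

__all__ = [
    "FormatError",
    "AtomRecord",
    "SolvatedSystem",
    "FrameSeries",
    "AnalysisConfig",
    "ObservableTable",
    "WATER_RESIDUE_NAMES",
    "read_structure",
    "write_trajectory",
    "read_fasta",
    "write_fasta",
    "read_observable_table",
    "write_observable_table",
    "read_config",
    "write_config",
]

#: Residue names recognised as water molecules.
WATER_RESIDUE_NAMES = frozenset({"HOH", "WAT", "TIP3", "SOL"})

AMINO_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


class FormatError(ValueError):
    """Raised when an input file violates the expected dialect."""


@dataclass
class AtomRecord:
    """One atom: identity, coordinates and nonbonded parameters.

    Partial charges (e) and Lennard-Jones parameters (sigma in Angstrom,
    epsilon in kcal/mol) are not stored in PDB files; they are filled in by
    the synthetic generator or a side-car parameter table and default to 0.
    """

    atom_id: int
    atom_name: str
    element: str
    residue_name: str
    residue_index: int
    chain_id: str
    position: np.ndarray
    partial_charge: float = 0.0
    lj_sigma: float = 0.0
    lj_epsilon: float = 0.0
    is_water: bool = False
    is_hydrogen: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError(f"atom {self.atom_id}: position must be a 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.atom_id}: element must be non-empty")
        if self.is_hydrogen != (self.element.upper() == "H"):
            raise ValueError(f"atom {self.atom_id}: is_hydrogen inconsistent with element")
        if self.lj_sigma < 0 or self.lj_epsilon < 0:
            raise ValueError(f"atom {self.atom_id}: LJ parameters must be non-negative")


@dataclass
class SolvatedSystem:
    """A solute plus explicit 3-site waters.

    ``water_molecules`` lists (O, H, H) atom-id triples; ``solute_atom_ids``
    holds everything that is not water.  The two sets are disjoint and cover
    all atoms.
    """

    atoms: list[AtomRecord]
    bonds: list[tuple[int, int]] = field(default_factory=list)
    water_molecules: list[tuple[int, int, int]] = field(default_factory=list)
    solute_atom_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = {a.atom_id for a in self.atoms}
        if len(ids) != len(self.atoms):
            raise ValueError("duplicate atom ids")
        by_id = {a.atom_id: a for a in self.atoms}
        water_ids: set[int] = set()
        for triple in self.water_molecules:
            if len(triple) != 3:
                raise ValueError("water molecules must be (O, H, H) triples")
            heavies = [i for i in triple if not by_id[i].is_hydrogen]
            if len(heavies) != 1:
                raise ValueError(f"water triple {triple} must have exactly one heavy atom")
            water_ids.update(triple)
        solute_ids = set(self.solute_atom_ids)
        if solute_ids & water_ids:
            raise ValueError("solute and water atom-id sets overlap")
        if solute_ids | water_ids != ids:
            raise ValueError("solute and water atom-id sets do not cover all atoms")
        for a, b in self.bonds:
            if a not in ids or b not in ids:
                raise ValueError(f"bond ({a}, {b}) references a missing atom")

    # -- convenience views -------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_waters(self) -> int:
        return len(self.water_molecules)

    def atom(self, atom_id: int) -> AtomRecord:
        return self._by_id()[atom_id]

    def _by_id(self) -> dict[int, AtomRecord]:
        if not hasattr(self, "_by_id_cache") or len(self._by_id_cache) != len(self.atoms):
            self._by_id_cache = {a.atom_id: a for a in self.atoms}
        return self._by_id_cache

    def index_of(self, atom_id: int) -> int:
        if not hasattr(self, "_index_cache") or len(self._index_cache) != len(self.atoms):
            self._index_cache = {a.atom_id: i for i, a in enumerate(self.atoms)}
        return self._index_cache[atom_id]

    @property
    def solute_heavy_ids(self) -> list[int]:
        """Solute atoms that are not hydrogen (the shell reference set)."""
        by_id = self._by_id()
        return [i for i in self.solute_atom_ids if not by_id[i].is_hydrogen]

    @property
    def water_oxygen_ids(self) -> list[int]:
        """One oxygen id per water, in water-index order."""
        by_id = self._by_id()
        out = []
        for triple in self.water_molecules:
            out.append(next(i for i in triple if not by_id[i].is_hydrogen))
        return out

    def water_index_of(self, atom_id: int) -> int | None:
        """Index of the water molecule containing ``atom_id``, or None."""
        if not hasattr(self, "_water_of_cache") or len(self._water_of_cache) < 3 * len(self.water_molecules):
            self._water_of_cache = {
                aid: wi for wi, triple in enumerate(self.water_molecules) for aid in triple
            }
        return self._water_of_cache.get(atom_id)

    def base_positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)


@dataclass
class FrameSeries:
    """Ordered coordinate frames with time stamps (ps).

    ``frames`` has shape (n_frames, n_atoms, 3) in Angstrom; ``times`` is
    strictly increasing.  ``box`` optionally holds orthorhombic box lengths.
    """

    n_atoms: int
    frames: np.ndarray
    times: np.ndarray
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1] != self.n_atoms or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.times.shape != (self.frames.shape[0],):
            raise ValueError("times must have one entry per frame")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,):
                raise ValueError("box must hold three orthorhombic lengths")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame_spacing(self) -> float:
        """Uniform spacing in ps; raises if the spacing is not uniform."""
        if self.n_frames < 2:
            return 0.0
        dts = np.diff(self.times)
        if not np.allclose(dts, dts[0], rtol=1e-9, atol=1e-9):
            raise ValueError("frame spacing is not uniform")
        return float(dts[0])


@dataclass
class AnalysisConfig:
    """All cutoffs and thresholds used across the pipeline.

    Distances in Angstrom, times in ps, temperature coefficients in ppb/K.
    ``burn_in_time`` discards the pre-equilibration part of a trajectory
    before any cumulative statistics are formed.
    """

    primary_cutoff: float = 3.5
    secondary_cutoff: float = 10.0
    hb_distance_cutoff: float = 3.5
    hb_angle_cutoff: float = 30.0
    energy_cutoff: float = 12.0
    dielectric: float = 1.0
    burn_in_time: float = 40000.0
    hdx_threshold: float = 0.2
    tempco_threshold: float = -5.0
    charge_scheme: str = "KR_DE"
    seed: int = 0
    # secondary knobs (exposed rather than guessed as unique truth)
    hb_distance_mode: str = "donor_acceptor"  # or "hydrogen_acceptor"
    include_sulfur: bool = False
    water_residue_names: tuple[str, ...] = tuple(sorted(WATER_RESIDUE_NAMES))

    def __post_init__(self) -> None:
        if not (0 < self.primary_cutoff < self.secondary_cutoff):
            raise ValueError("require 0 < primary_cutoff < secondary_cutoff")
        if not (0 < self.hb_angle_cutoff < 90):
            raise ValueError("hb_angle_cutoff must lie in (0, 90) degrees")
        if self.energy_cutoff <= 0:
            raise ValueError("energy_cutoff must be positive")
        if self.charge_scheme not in ("KR_DE", "KRH_DE"):
            raise ValueError(f"unknown charge scheme {self.charge_scheme!r}")
        if self.hb_distance_mode not in ("donor_acceptor", "hydrogen_acceptor"):
            raise ValueError(f"unknown hb_distance_mode {self.hb_distance_mode!r}")


@dataclass
class ObservableTable:
    """Residue-indexed NMR observations in long form.

    ``kind`` is one of ``tempseries`` (residue, temperature_K, shift_ppm),
    ``hdx`` (residue, time_h, intensity) or ``relaxation`` (residue, r1, r2,
    hetnoe, field_1H).  ``metadata`` carries generator ground truth when the
    table is synthetic.
    """

    kind: str
    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    REQUIRED = {
        "tempseries": ("residue", "temperature_K", "shift_ppm"),
        "hdx": ("residue", "time_h", "intensity"),
        "relaxation": ("residue", "r1", "r2", "hetnoe", "field_1H"),
    }
    KEY_COLUMNS = {
        "tempseries": ("residue", "temperature_K"),
        "hdx": ("residue", "time_h"),
        "relaxation": ("residue",),
    }

    def __post_init__(self) -> None:
        if self.kind not in self.REQUIRED:
            raise ValueError(f"unknown observable kind {self.kind!r}")
        missing = [c for c in self.REQUIRED[self.kind] if c not in self.data.columns]
        if missing:
            raise FormatError(f"{self.kind} table missing columns: {missing}")
        keys = list(self.KEY_COLUMNS[self.kind])
        dup = self.data.duplicated(subset=keys)
        if dup.any():
            raise FormatError(f"duplicate residue keys at rows {list(self.data.index[dup])}")


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

_ELEMENT_GUESSES = ("CL", "BR", "NA", "MG", "ZN", "FE", "CA", "MN", "K")


def _element_from_name(name: str) -> str:
    """Infer an element symbol from the raw 4-char PDB atom-name field.

    Two-letter elements (ions, halogens) start in column 13; names that
    start in column 14 (" CA ", " OG1") are organic atoms whose element is
    the first letter.
    """
    bare = name.strip().lstrip("0123456789")
    if not bare:
        raise FormatError(f"cannot infer element from atom name {name!r}")
    upper = bare.upper()
    starts_col13 = len(name) == 4 and name[0] not in (" ", "1", "2", "3", "4")
    if starts_col13 and upper[:2] in _ELEMENT_GUESSES:
        return upper[:2].capitalize()
    return upper[0]


def _parse_pdb_atom_line(line: str, lineno: int) -> dict:
    try:
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise FormatError(f"line {lineno}: unparseable coordinate field") from exc
    name = line[12:16]
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = _element_from_name(name)
    element = element.capitalize() if len(element) > 1 else element.upper()
    try:
        serial = int(line[6:11])
    except ValueError:
        serial = -1
    try:
        resseq = int(line[22:26])
    except ValueError as exc:
        raise FormatError(f"line {lineno}: unparseable residue number") from exc
    return {
        "serial": serial,
        "name": name.strip(),
        "resname": line[17:20].strip(),
        "chain": line[21].strip() or "A",
        "resseq": resseq,
        "xyz": (x, y, z),
        "element": element,
    }


def read_structure(
    path: str | Path,
    dialect: str = "pdb",
    water_residue_names: Iterable[str] = WATER_RESIDUE_NAMES,
    dt: float = 1.0,
) -> tuple[SolvatedSystem, FrameSeries]:
    """Read a (possibly multi-model) PDB into a system plus frame series.

    Each MODEL becomes one frame; a file without MODEL records yields a
    single frame.  PDB files carry no time stamps, so frames are stamped
    ``0, dt, 2*dt, ...`` ps.  Waters are identified by residue name and
    assembled into (O, H, H) triples.
    """
    if dialect != "pdb":
        raise ValueError(f"unsupported dialect {dialect!r}")
    path = Path(path)
    water_names = {n.upper() for n in water_residue_names}

    models: list[list[dict]] = []
    current: list[dict] = []
    in_model = False
    saw_model_records = False
    box = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "CRYST1":
                try:
                    box = np.array([float(line[6:15]), float(line[15:24]), float(line[24:33])])
                except ValueError:
                    box = None
            elif rec == "MODEL ":
                saw_model_records = True
                in_model = True
                current = []
            elif rec == "ENDMDL":
                in_model = False
                models.append(current)
                current = []
            elif rec in ("ATOM  ", "HETATM"):
                current.append(_parse_pdb_atom_line(line, lineno))
    if current:
        if saw_model_records and in_model:
            models.append(current)  # unterminated final MODEL
        elif not saw_model_records:
            models.append(current)
    if not models or not models[0]:
        raise FormatError(f"{path}: no ATOM/HETATM records found")

    n_atoms = len(models[0])
    for mi, model in enumerate(models):
        if len(model) != n_atoms:
            raise FormatError(
                f"{path}: model {mi + 1} has {len(model)} atoms, expected {n_atoms}"
            )

    atoms: list[AtomRecord] = []
    for i, rec in enumerate(models[0]):
        element = rec["element"]
        atoms.append(
            AtomRecord(
                atom_id=i,
                atom_name=rec["name"],
                element=element,
                residue_name=rec["resname"],
                residue_index=rec["resseq"],
                chain_id=rec["chain"],
                position=np.array(rec["xyz"]),
                is_water=rec["resname"].upper() in water_names,
                is_hydrogen=element.upper() == "H",
            )
        )

    # group waters into (O, H, H) triples by residue
    waters: list[tuple[int, int, int]] = []
    bonds: list[tuple[int, int]] = []
    residue_groups: dict[tuple, list[int]] = {}
    for a in atoms:
        if a.is_water:
            residue_groups.setdefault((a.chain_id, a.residue_index, a.residue_name), []).append(a.atom_id)
    for key, ids in residue_groups.items():
        heavies = [i for i in ids if not atoms[i].is_hydrogen]
        hydros = [i for i in ids if atoms[i].is_hydrogen]
        if len(heavies) != 1 or len(hydros) != 2:
            raise FormatError(f"{path}: water residue {key} is not a 3-site (O, H, H) molecule")
        waters.append((heavies[0], hydros[0], hydros[1]))
        bonds.extend([(heavies[0], hydros[0]), (heavies[0], hydros[1])])
    water_ids = {i for t in waters for i in t}
    solute_ids = [a.atom_id for a in atoms if a.atom_id not in water_ids]

    system = SolvatedSystem(atoms=atoms, bonds=bonds, water_molecules=waters, solute_atom_ids=solute_ids)
    frames = np.array([[rec["xyz"] for rec in model] for model in models])
    times = np.arange(len(models), dtype=float) * dt
    series = FrameSeries(n_atoms=n_atoms, frames=frames, times=times, box=box)
    return system, series


def write_trajectory(path: str | Path, system: SolvatedSystem, series: FrameSeries) -> None:
    """Write a multi-model PDB (one MODEL per frame, fixed columns)."""
    if series.n_atoms != system.n_atoms:
        raise ValueError("system and series atom counts differ")
    path = Path(path)
    lines: list[str] = []
    if series.box is not None:
        a, b, c = series.box
        lines.append(f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}  90.00  90.00  90.00 P 1           1")
    multi = series.n_frames > 1
    for fi in range(series.n_frames):
        if multi:
            lines.append(f"MODEL     {fi + 1:4d}")
        for ai, atom in enumerate(system.atoms):
            x, y, z = series.frames[fi, ai]
            name = atom.atom_name
            # PDB convention: 4-char field, single-letter elements start in col 14
            fname = f" {name:<3s}" if len(name) < 4 else name[:4]
            record = "HETATM" if atom.is_water else "ATOM  "
            lines.append(
                f"{record}{(ai + 1) % 100000:5d} {fname}{'':1s}{atom.residue_name:<3s} "
                f"{atom.chain_id[:1]:1s}{atom.residue_index % 10000:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                f"{atom.element.upper():>2s}"
            )
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA records as (id, sequence) pairs.

    Sequences are uppercased; characters outside the 20 one-letter amino
    acid codes plus X are rejected with the offending record named.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = "".join(str(rec.seq).split()).upper()
        bad = sorted(set(seq) - AMINO_ALPHABET)
        if bad:
            raise FormatError(f"record {rec.id!r}: illegal characters {bad}")
        records.append((rec.id, seq))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(path: str | Path, records: Sequence[tuple[str, str]], width: int = 60) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Observable tables and config
# ---------------------------------------------------------------------------

def read_observable_table(path: str | Path, kind: str) -> ObservableTable:
    """Read a delimited table of NMR observations.

    Delimiter is sniffed (tab or comma).  Numeric columns are parsed
    strictly: a non-numeric entry raises with its row index; empty cells
    become missing values (NaN), never zero.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    required = ObservableTable.REQUIRED.get(kind)
    if required is None:
        raise ValueError(f"unknown observable kind {kind!r}")
    for col in df.columns:
        if col == "residue":
            df[col] = pd.to_numeric(df[col], errors="raise").astype(int)
            continue
        raw = df[col]
        parsed = pd.to_numeric(raw, errors="coerce")
        bad = parsed.isna() & raw.notna() & (raw.str.strip() != "")
        if bad.any():
            raise FormatError(f"{path}: non-numeric value in column {col!r} at row {int(bad.idxmax())}")
        df[col] = parsed
    return ObservableTable(kind=kind, data=df)


def write_observable_table(path: str | Path, table: ObservableTable, sep: str = "\t") -> None:
    table.data.to_csv(path, sep=sep, index=False)


def parameter_table(system: SolvatedSystem) -> pd.DataFrame:
    """Side-car nonbonded parameter table keyed by (atom_name, residue_name).

    PDB files carry no charges or LJ parameters; this table preserves them
    across a write/read round trip.  Atom names must determine the
    parameters uniquely within a residue name.
    """
    rows: dict[tuple[str, str], tuple[float, float, float]] = {}
    for a in system.atoms:
        key = (a.atom_name, a.residue_name)
        val = (a.partial_charge, a.lj_sigma, a.lj_epsilon)
        if key in rows and rows[key] != val:
            raise ValueError(f"ambiguous parameters for atom {key}")
        rows[key] = val
    return pd.DataFrame(
        [(an, rn, q, s, e) for (an, rn), (q, s, e) in sorted(rows.items())],
        columns=["atom_name", "residue_name", "charge", "sigma", "epsilon"],
    )


def apply_parameters(system: SolvatedSystem, table: pd.DataFrame) -> SolvatedSystem:
    """Fill in charges/LJ from a side-car parameter table, in place."""
    lookup = {
        (str(r.atom_name), str(r.residue_name)): (float(r.charge), float(r.sigma), float(r.epsilon))
        for r in table.itertuples()
    }
    for atom in system.atoms:
        key = (atom.atom_name, atom.residue_name)
        if key in lookup:
            atom.partial_charge, atom.lj_sigma, atom.lj_epsilon = lookup[key]
    return system


def read_config(path: str | Path) -> AnalysisConfig:
    """Read an AnalysisConfig from a YAML file mirroring its field names."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(raw) - known
    if unknown:
        raise FormatError(f"unknown config keys: {sorted(unknown)}")
    if "water_residue_names" in raw:
        raw["water_residue_names"] = tuple(raw["water_residue_names"])
    return AnalysisConfig(**raw)


def write_config(path: str | Path, config: AnalysisConfig) -> None:
    payload = dataclasses.asdict(config)
    payload["water_residue_names"] = list(payload["water_residue_names"])
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
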