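"""Domain types and I/O for protein-surfactant systems.

Coordinates are stored in angstroms (the native PDB unit) throughout;
energies are computed in kJ/mol and electrostatic cutoffs are accepted in
nanometres, with a single conversion point in :mod:`surfbind.energy`.
Atom indexing is 0-based internally; PDB serial numbers are preserved on
each :class:`AtomRecord` for reporting.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GROUP_LABELS",
    "AMINO_ACIDS",
    "DEFAULT_WATER_RESNAMES",
    "DEFAULT_ION_RESNAMES",
    "AtomRecord",
    "Frame",
    "Trajectory",
    "MolecularSystem",
    "AnalysisConfig",
    "PDBParseError",
    "StructureError",
    "ParameterTableError",
    "GroupAssignmentError",
    "read_pdb",
    "write_pdb",
    "read_param_table",
    "assign_groups",
    "infer_donors_acceptors",
    "derive_seed",
]

#: Closed set of per-atom group labels used for energy/charge decomposition.
GROUP_LABELS = frozenset(
    {"head", "alpha", "tail", "protein", "water", "ion", "other"}
)

#: Ligand group labels (the amphiphile partition).
LIGAND_GROUPS = frozenset({"head", "alpha", "tail"})

AMINO_ACIDS = frozenset(
    """ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR
    TRP TYR VAL HSD HSE HSP HID HIE HIP""".split()
)

DEFAULT_WATER_RESNAMES = frozenset({"HOH", "SOL", "WAT", "TIP3", "SPC"})

DEFAULT_ION_RESNAMES = frozenset(
    {"NA", "CL", "K", "MG", "CA", "ZN", "BR", "SOD", "CLA", "NA+", "CL-"}
)


class PDBParseError(ValueError):
    """A PDB record could not be parsed (message names the line)."""


class StructureError(ValueError):
    """Models of a multi-model file are structurally inconsistent."""


class ParameterTableError(ValueError):
    """A per-atom parameter table is malformed or does not match the system."""


class GroupAssignmentError(ValueError):
    """Head/alpha/tail group assignment failed."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity, residue membership, and force-field parameters.

    ``charge`` is the partial charge in electron units; ``c6`` and ``c12``
    are the GROMOS-style Lennard-Jones dispersion/repulsion coefficients in
    kJ mol^-1 nm^6 and kJ mol^-1 nm^12 respectively.
    """

    serial: int
    name: str
    element: str
    residue_name: str
    residue_index: int
    chain: str = "A"
    charge: float = 0.0
    c6: float = 0.0
    c12: float = 0.0
    group: str = "other"

    def __post_init__(self) -> None:
        if self.serial <= 0:
            raise ValueError(f"atom serial must be positive, got {self.serial}")
        if self.c6 < 0 or self.c12 < 0:
            raise ValueError(
                f"LJ coefficients must be nonnegative (atom {self.serial}: "
                f"c6={self.c6}, c12={self.c12})"
            )
        if self.group not in GROUP_LABELS:
            raise ValueError(
                f"unknown group {self.group!r} for atom {self.serial}; "
                f"allowed: {sorted(GROUP_LABELS)}"
            )


@dataclass
class Frame:
    """Coordinates (angstrom) of every atom at one time point (ps)."""

    time: float
    coordinates: np.ndarray
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must have shape (n_atoms, 3)")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,) or np.any(self.box <= 0):
                raise ValueError("box must be three positive lengths (angstrom)")

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]


@dataclass(eq=False)
class MolecularSystem:
    """An ordered atom table plus hydrogen-bond donor/acceptor definitions.

    ``donors`` is a list of ``(donor_heavy_index, hydrogen_index)`` pairs;
    the hydrogen index may be ``None`` for heavy-atom-only (distance-only)
    structures. ``acceptors`` is a list of acceptor atom indices. Indices
    are 0-based positions in ``atoms``.
    """

    atoms: list[AtomRecord]
    donors: list[tuple[int, int | None]] = field(default_factory=list)
    acceptors: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            dupes = sorted({s for s in serials if serials.count(s) > 1})
            raise StructureError(f"duplicate atom serials: {dupes}")
        n = len(self.atoms)
        for d, h in self.donors:
            if not (0 <= d < n) or (h is not None and not (0 <= h < n)):
                raise StructureError(f"donor pair ({d}, {h}) out of range")
            if h is not None and self.atoms[h].element.upper() != "H":
                raise StructureError(
                    f"donor hydrogen index {h} is element "
                    f"{self.atoms[h].element!r}, not H"
                )
        for a in self.acceptors:
            if not (0 <= a < n):
                raise StructureError(f"acceptor index {a} out of range")

    # -- cached column views -------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @cached_property
    def serials(self) -> np.ndarray:
        return np.array([a.serial for a in self.atoms], dtype=int)

    @cached_property
    def names(self) -> np.ndarray:
        return np.array([a.name for a in self.atoms], dtype=object)

    @cached_property
    def elements(self) -> np.ndarray:
        return np.array([a.element.upper() for a in self.atoms], dtype=object)

    @cached_property
    def residue_names(self) -> np.ndarray:
        return np.array([a.residue_name for a in self.atoms], dtype=object)

    @cached_property
    def residue_indices(self) -> np.ndarray:
        return np.array([a.residue_index for a in self.atoms], dtype=int)

    @cached_property
    def chains(self) -> np.ndarray:
        return np.array([a.chain for a in self.atoms], dtype=object)

    @cached_property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=float)

    @cached_property
    def c6(self) -> np.ndarray:
        return np.array([a.c6 for a in self.atoms], dtype=float)

    @cached_property
    def c12(self) -> np.ndarray:
        return np.array([a.c12 for a in self.atoms], dtype=float)

    @cached_property
    def groups(self) -> np.ndarray:
        return np.array([a.group for a in self.atoms], dtype=object)

    # -- masks ---------------------------------------------------------------

    @property
    def heavy_mask(self) -> np.ndarray:
        return self.elements != "H"

    @property
    def ligand_mask(self) -> np.ndarray:
        return np.isin(self.groups, sorted(LIGAND_GROUPS))

    def group_mask(self, *labels: str) -> np.ndarray:
        bad = set(labels) - GROUP_LABELS
        if bad:
            raise ValueError(f"unknown group labels {sorted(bad)}")
        return np.isin(self.groups, list(labels))

    def residue_tuples(self) -> list[tuple[str, int, str]]:
        """Unique (chain, residue_index, residue_name) in first-seen order."""
        seen: dict[tuple[str, int, str], None] = {}
        for a in self.atoms:
            seen.setdefault((a.chain, a.residue_index, a.residue_name))
        return list(seen)

    def with_atoms(self, atoms: Sequence[AtomRecord]) -> "MolecularSystem":
        return MolecularSystem(
            atoms=list(atoms),
            donors=list(self.donors),
            acceptors=list(self.acceptors),
        )


@dataclass
class Trajectory:
    """Time-ordered frames sharing one atom table."""

    system: MolecularSystem
    frames: list[Frame]

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("a trajectory needs at least one frame")
        n = self.system.n_atoms
        for i, f in enumerate(self.frames):
            if f.n_atoms != n:
                raise StructureError(
                    f"frame {i} has {f.n_atoms} atoms, system has {n}"
                )
        t = self.times
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames], dtype=float)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def stride(self) -> float:
        """Sampling interval in ps (from the first two frames; 0 if single)."""
        t = self.times
        return float(t[1] - t[0]) if len(t) > 1 else 0.0

    @property
    def coords(self) -> np.ndarray:
        """All coordinates stacked, shape (n_frames, n_atoms, 3), angstrom."""
        return np.stack([f.coordinates for f in self.frames])

    def window_mask(self, window: tuple[float, float] | None) -> np.ndarray:
        if window is None:
            return np.ones(self.n_frames, dtype=bool)
        lo, hi = window
        t = self.times
        return (t >= lo) & (t <= hi)


@dataclass
class AnalysisConfig:
    """Tunable parameters of the analysis pipeline.

    Distances for contacts and hydrogen bonds are in angstrom; the Coulomb
    cutoff follows force-field convention and is in nanometres. The H-bond
    angle criterion is the hydrogen-donor-acceptor angle in degrees; set
    ``distance_only=True`` (or supply donors without hydrogens) for
    heavy-atom-only structures such as docking poses.
    """

    contact_cutoff: float = 3.5          # angstrom
    hbond_da_cutoff: float = 3.5         # angstrom, donor-acceptor
    hbond_angle_cutoff: float = 30.0     # degrees, H-D-A
    distance_only: bool = False
    coulomb_cutoff: float = 1.0          # nm
    electrostatics_scheme: str = "reaction_field_zero"
    include_ions: bool = True
    temperature: float = 298.0           # K
    analysis_window: tuple[float, float] | None = None  # (start, end) ps
    seed: int = 0
    water_resnames: frozenset[str] = DEFAULT_WATER_RESNAMES

    def __post_init__(self) -> None:
        for name in ("contact_cutoff", "hbond_da_cutoff", "coulomb_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.hbond_angle_cutoff is not None and self.hbond_angle_cutoff <= 0:
            raise ValueError("hbond_angle_cutoff must be > 0 (or None)")
        if self.electrostatics_scheme not in {
            "plain_cutoff",
            "reaction_field_zero",
        }:
            raise ValueError(
                "electrostatics_scheme must be 'plain_cutoff' or "
                "'reaction_field_zero'"
            )
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0 K")
        if self.analysis_window is not None:
            lo, hi = self.analysis_window
            if not lo < hi:
                raise ValueError("analysis_window start must be < end")
            self.analysis_window = (float(lo), float(hi))
        self.water_resnames = frozenset(self.water_resnames)

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Load from a key-value (YAML) text file mirroring the field names."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must be a key-value mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "analysis_window" in data and data["analysis_window"] is not None:
            data["analysis_window"] = tuple(data["analysis_window"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["water_resnames"] = sorted(self.water_resnames)
        if self.analysis_window is not None:
            d["analysis_window"] = list(self.analysis_window)
        return d

    def content_hash(self) -> str:
        """Stable hash of the configuration, recorded on every report table."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def derive_seed(base_seed: int, label: str) -> int:
    """Derive a stable sub-seed (< 2^31) from a base seed and a stage name.

    Each randomized stage hashes its own name so that adding a stage does
    not shift the random streams of the others.
    """
    digest = hashlib.sha256(f"{base_seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

_COORD_SLICES = ((30, 38), (38, 46), (46, 54))


def _validate_pdb_lines(lines: list[str], path: str) -> None:
    """Check fixed-column fields of ATOM/HETATM records, naming bad lines."""
    for lineno, line in enumerate(lines, start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        if len(line.rstrip("\n")) < 54:
            raise PDBParseError(
                f"{path}:{lineno}: record too short for coordinates"
            )
        try:
            int(line[6:11])
        except ValueError:
            raise PDBParseError(
                f"{path}:{lineno}: atom serial field {line[6:11]!r} is not "
                "an integer"
            ) from None
        for lo, hi in _COORD_SLICES:
            text = line[lo:hi]
            try:
                float(text)
            except ValueError:
                raise PDBParseError(
                    f"{path}:{lineno}: coordinate field {text!r} is not a "
                    "number"
                ) from None


def _guess_element(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return "X"
    if len(stripped) >= 2 and stripped[:2].upper() in {"CL", "BR", "NA", "MG", "ZN"}:
        return stripped[:2].capitalize()
    return stripped[0].upper()


def _classify_residue(
    resname: str, water_resnames: Iterable[str] = DEFAULT_WATER_RESNAMES
) -> str:
    if resname in AMINO_ACIDS:
        return "protein"
    if resname in water_resnames:
        return "water"
    if resname in DEFAULT_ION_RESNAMES:
        return "ion"
    return "other"


def read_pdb(
    path: str | Path, stride: float = 1.0
) -> tuple[MolecularSystem, Trajectory]:
    """Read a (possibly multi-model) PDB file.

    MODEL/ENDMDL blocks become trajectory frames at ``stride`` ps apart
    (PDB files carry no time information). Charges and LJ coefficients
    default to zero until a parameter table is merged; group labels are
    pre-classified as protein/water/ion/other by residue name.

    Parsing is delegated to Biopython after a fixed-column validation pass
    that reports the offending line on malformed records.
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    lines = path.read_text().splitlines()
    _validate_pdb_lines(lines, str(path))

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(path.stem, str(path))
    models = list(structure)
    if not models:
        raise PDBParseError(f"{path}: no ATOM/HETATM records found")

    def model_atoms(model):
        out = []
        for chain in model:
            for residue in chain:
                for atom in residue:
                    out.append((chain.id, residue, atom))
        return out

    first = model_atoms(models[0])
    atoms: list[AtomRecord] = []
    for chain_id, residue, atom in first:
        resname = residue.get_resname().strip()
        element = (atom.element or "").strip() or _guess_element(atom.get_name())
        atoms.append(
            AtomRecord(
                serial=int(atom.serial_number),
                name=atom.get_name(),
                element=element,
                residue_name=resname,
                residue_index=int(residue.id[1]),
                chain=str(chain_id),
                group=_classify_residue(resname),
            )
        )
    system = MolecularSystem(atoms=atoms)

    frames: list[Frame] = []
    ref_names = [a.name for a in atoms]
    for i, model in enumerate(models):
        entries = model_atoms(model)
        if len(entries) != len(ref_names):
            raise StructureError(
                f"{path}: model {i + 1} has {len(entries)} atoms, "
                f"model 1 has {len(ref_names)}"
            )
        names = [a.get_name() for _, _, a in entries]
        if names != ref_names:
            raise StructureError(
                f"{path}: model {i + 1} atom ordering differs from model 1"
            )
        coords = np.array([a.coord for _, _, a in entries], dtype=float)
        frames.append(Frame(time=i * stride, coordinates=coords))

    return system, Trajectory(system=system, frames=frames)


def write_pdb(
    system: MolecularSystem,
    frames: Frame | Sequence[Frame],
    path: str | Path,
) -> None:
    """Write ATOM/HETATM records; multiple frames become MODEL blocks."""
    if isinstance(frames, Frame):
        frames = [frames]
    multi = len(frames) > 1
    with open(path, "w") as fh:
        for imodel, frame in enumerate(frames, start=1):
            if frame.n_atoms != system.n_atoms:
                raise StructureError("frame/system atom count mismatch")
            if multi:
                fh.write(f"MODEL     {imodel:4d}\n")
            for atom, (x, y, z) in zip(system.atoms, frame.coordinates):
                record = "ATOM  " if atom.residue_name in AMINO_ACIDS else "HETATM"
                name = atom.name
                if len(name) < 4:
                    name = f" {name:<3s}"
                fh.write(
                    f"{record}{atom.serial:5d} {name:<4s}"
                    f"{atom.residue_name:>4s} {atom.chain[:1]:1s}"
                    f"{atom.residue_index:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {atom.element[:2]:>2s}\n"
                )
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Parameter tables and group assignment
# ---------------------------------------------------------------------------

PARAM_COLUMNS = ("serial", "charge_e", "c6", "c12", "group")


def read_param_table(
    system: MolecularSystem, path: str | Path
) -> MolecularSystem:
    """Merge a per-atom parameter table (TSV) onto a system by serial.

    The table must have a header row with columns
    ``serial, charge_e, c6, c12, group``. Every table row must match a
    system atom; system atoms missing from the table keep zero parameters
    and are reported via a warning.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    missing_cols = set(PARAM_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ParameterTableError(
            f"parameter table missing columns {sorted(missing_cols)}; "
            f"expected {PARAM_COLUMNS}"
        )
    if df["serial"].duplicated().any():
        dupes = sorted(df.loc[df["serial"].duplicated(), "serial"].unique())
        raise ParameterTableError(f"duplicate serials in table: {dupes}")
    bad_groups = set(df["group"]) - GROUP_LABELS
    if bad_groups:
        raise ParameterTableError(
            f"unknown group labels {sorted(bad_groups)}; "
            f"allowed: {sorted(GROUP_LABELS)}"
        )
    serial_to_pos = {a.serial: i for i, a in enumerate(system.atoms)}
    unknown = sorted(set(df["serial"].astype(int)) - set(serial_to_pos))
    if unknown:
        raise ParameterTableError(
            f"table serial(s) {unknown} not present in the system"
        )
    atoms = list(system.atoms)
    matched = set()
    for row in df.itertuples(index=False):
        pos = serial_to_pos[int(row.serial)]
        matched.add(pos)
        atoms[pos] = dataclasses.replace(
            atoms[pos],
            charge=float(row.charge_e),
            c6=float(row.c6),
            c12=float(row.c12),
            group=str(row.group),
        )
    unmatched = [a.serial for i, a in enumerate(atoms) if i not in matched]
    if unmatched:
        warnings.warn(
            f"{len(unmatched)} system atom(s) not in parameter table "
            f"(serials {unmatched[:10]}{'...' if len(unmatched) > 10 else ''}); "
            "their charge/LJ parameters remain zero",
            stacklevel=2,
        )
    return system.with_atoms(atoms)


def assign_groups(
    system: MolecularSystem,
    head_atoms: Sequence[str],
    alpha_atoms: Sequence[str] = (),
    *,
    ligand_resname: str | None = None,
    water_resnames: Iterable[str] = DEFAULT_WATER_RESNAMES,
) -> MolecularSystem:
    """Partition ligand atoms into head/alpha/tail by atom name.

    ``head_atoms`` and ``alpha_atoms`` name atoms of the ligand residue;
    remaining ligand atoms become ``tail``. Non-ligand atoms are labelled
    protein/water/ion by residue name. If ``ligand_resname`` is omitted,
    any residue that is not a standard amino acid, water, or ion is taken
    as the ligand.
    """
    overlap = set(head_atoms) & set(alpha_atoms)
    if overlap:
        raise GroupAssignmentError(
            f"atom(s) {sorted(overlap)} listed as both head and alpha"
        )
    water_resnames = frozenset(water_resnames)

    def is_ligand(resname: str) -> bool:
        if ligand_resname is not None:
            return resname == ligand_resname
        return _classify_residue(resname, water_resnames) == "other"

    ligand_names = {a.name for a in system.atoms if is_ligand(a.residue_name)}
    if not ligand_names:
        raise GroupAssignmentError("no ligand atoms found in the system")
    for label, requested in (("head", head_atoms), ("alpha", alpha_atoms)):
        missing = sorted(set(requested) - ligand_names)
        if missing:
            raise GroupAssignmentError(
                f"{label} atom name(s) {missing} not found in the ligand "
                "residue"
            )

    head, alpha = set(head_atoms), set(alpha_atoms)
    atoms = []
    for a in system.atoms:
        if is_ligand(a.residue_name):
            if a.name in head:
                group = "head"
            elif a.name in alpha:
                group = "alpha"
            else:
                group = "tail"
        else:
            group = _classify_residue(a.residue_name, water_resnames)
        atoms.append(dataclasses.replace(a, group=group))
    return system.with_atoms(atoms)


def infer_donors_acceptors(
    system: MolecularSystem,
    frame: Frame,
    bond_cutoff: float = 1.25,
) -> MolecularSystem:
    """Populate donors/acceptors geometrically for a hydrogen-bearing system.

    Donors are (N/O, H) pairs with the hydrogen within ``bond_cutoff``
    angstrom of the heavy atom; acceptors are all N and O atoms. For
    heavy-atom-only structures supply donors explicitly instead and use
    distance-only H-bond detection.
    """
    el = system.elements
    coords = frame.coordinates
    heavy_idx = np.flatnonzero((el == "N") | (el == "O"))
    h_idx = np.flatnonzero(el == "H")
    donors: list[tuple[int, int | None]] = []
    if len(h_idx) and len(heavy_idx):
        d = np.linalg.norm(
            coords[h_idx][:, None, :] - coords[heavy_idx][None, :, :], axis=-1
        )
        nearest = np.argmin(d, axis=1)
        for k, h in enumerate(h_idx):
            if d[k, nearest[k]] <= bond_cutoff:
                donors.append((int(heavy_idx[nearest[k]]), int(h)))
    return MolecularSystem(
        atoms=list(system.atoms),
        donors=donors,
        acceptors=[int(i) for i in heavy_idx],
    )
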