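"""Binding-site contacts, hydrogen bonds, water bridges, existence series.

A contact is a protein residue with at least one heavy atom within the
cutoff (default 3.5 angstrom) of any ligand heavy atom. A hydrogen bond
requires donor-acceptor distance <= 3.5 angstrom and hydrogen-donor-
acceptor angle <= 30 degrees; for heavy-atom-only structures (docking
poses) the angle criterion can be skipped. A bond is *bifurcated* when its
donor hydrogen (or donor heavy atom in distance-only mode) satisfies the
criteria with two or more acceptors in the same frame, or its acceptor
with two or more donors; each bifurcated interaction is counted as two
bonds in totals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_io import AnalysisConfig, Frame, MolecularSystem, Trajectory

__all__ = [
    "Contact",
    "HBond",
    "HBondSeries",
    "WaterBridge",
    "pair_distances",
    "binding_site_residues",
    "detect_hbonds",
    "hbond_totals",
    "hbond_summary",
    "hbond_series",
    "water_bridges",
    "bridge_series",
    "waters_near_group",
]


def pair_distances(
    xa: np.ndarray, xb: np.ndarray, box: np.ndarray | None = None
) -> np.ndarray:
    """All-pairs distances (angstrom), minimum image if a box is given."""
    diff = xa[:, None, :] - xb[None, :, :]
    if box is not None:
        diff -= box * np.round(diff / box)
    return np.sqrt(np.sum(diff * diff, axis=-1))


def _min_image(vec: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    if box is not None:
        vec = vec - box * np.round(vec / box)
    return vec


@dataclass(frozen=True)
class Contact:
    """A protein residue within the contact cutoff of the ligand."""

    residue_name: str
    residue_index: int
    chain: str
    ligand_atom: str       # name of the closest ligand heavy atom
    min_distance: float    # angstrom


@dataclass(frozen=True)
class HBond:
    donor: int                   # donor heavy atom index
    hydrogen: int | None         # None in distance-only mode
    acceptor: int
    distance: float              # donor-acceptor, angstrom
    angle: float | None          # H-D-A, degrees; None in distance-only mode
    bifurcated: bool = False

    @property
    def kind(self) -> str:
        return "bifurcated" if self.bifurcated else "regular"


@dataclass(frozen=True)
class WaterBridge:
    """One water simultaneously hydrogen-bonded to protein and ligand."""

    protein_atom: int
    water_residue: int
    ligand_atom: int


def binding_site_residues(
    frame: Frame,
    system: MolecularSystem,
    cutoff: float = 3.5,
) -> list[Contact]:
    """Protein residues with a heavy atom within ``cutoff`` of the ligand.

    Hydrogens are excluded on both sides; the reported distance is the
    minimum heavy-atom distance for the residue, with the closest ligand
    atom named.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    heavy = system.heavy_mask
    lig_idx = np.flatnonzero(system.ligand_mask & heavy)
    if lig_idx.size == 0:
        raise ValueError(
            "no ligand heavy atoms labelled head/alpha/tail; run "
            "assign_groups first"
        )
    prot_idx = np.flatnonzero(system.group_mask("protein") & heavy)
    contacts: list[Contact] = []
    if prot_idx.size == 0:
        return contacts
    d = pair_distances(
        frame.coordinates[prot_idx], frame.coordinates[lig_idx], frame.box
    )
    resids = system.residue_indices[prot_idx]
    chains = system.chains[prot_idx]
    for chain, resid in dict.fromkeys(zip(chains, resids)):
        rows = (chains == chain) & (resids == resid)
        sub = d[rows]
        if sub.min() <= cutoff:
            i, j = np.unravel_index(np.argmin(sub), sub.shape)
            contacts.append(
                Contact(
                    residue_name=str(
                        system.residue_names[prot_idx[rows][i]]
                    ),
                    residue_index=int(resid),
                    chain=str(chain),
                    ligand_atom=str(system.names[lig_idx[j]]),
                    min_distance=float(sub.min()),
                )
            )
    contacts.sort(key=lambda c: (c.chain, c.residue_index))
    return contacts


def _distance_only(system: MolecularSystem, config: AnalysisConfig) -> bool:
    if config.distance_only or config.hbond_angle_cutoff is None:
        return True
    return any(h is None for _, h in system.donors)


def detect_hbonds(
    frame: Frame,
    system: MolecularSystem,
    config: AnalysisConfig | None = None,
    subset_a: np.ndarray | None = None,
    subset_b: np.ndarray | None = None,
) -> list[HBond]:
    """Detect hydrogen bonds in one frame and classify them.

    With ``subset_a``/``subset_b`` (atom index arrays) only bonds whose
    donor heavy atom lies in one subset and acceptor in the other are
    returned; classification (bifurcated vs regular) is evaluated on that
    filtered set, mirroring per-complex bookkeeping.
    """
    config = config or AnalysisConfig()
    if not system.donors or not system.acceptors:
        raise ValueError("system has no donors and/or no acceptors defined")
    dist_only = _distance_only(system, config)

    coords = frame.coordinates
    acceptors = np.asarray(system.acceptors, dtype=int)
    sa = None if subset_a is None else set(np.asarray(subset_a, dtype=int).tolist())
    sb = None if subset_b is None else set(np.asarray(subset_b, dtype=int).tolist())

    candidates: list[HBond] = []
    for d_idx, h_idx in system.donors:
        vec = _min_image(coords[acceptors] - coords[d_idx], frame.box)
        da = np.linalg.norm(vec, axis=1)
        ok = (da <= config.hbond_da_cutoff) & (acceptors != d_idx)
        if h_idx is not None:
            ok &= acceptors != h_idx
        angles = np.full(len(acceptors), np.nan)
        if not dist_only and h_idx is not None:
            dh = _min_image(coords[h_idx] - coords[d_idx], frame.box)
            dh_norm = np.linalg.norm(dh)
            with np.errstate(invalid="ignore", divide="ignore"):
                cosang = (vec @ dh) / (da * dh_norm)
            angles = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            ok &= angles <= config.hbond_angle_cutoff
        for k in np.flatnonzero(ok):
            a_idx = int(acceptors[k])
            if sa is not None and sb is not None:
                in_ab = d_idx in sa and a_idx in sb
                in_ba = d_idx in sb and a_idx in sa
                if not (in_ab or in_ba):
                    continue
            candidates.append(
                HBond(
                    donor=int(d_idx),
                    hydrogen=None if dist_only else h_idx,
                    acceptor=a_idx,
                    distance=float(da[k]),
                    angle=None if dist_only else float(angles[k]),
                )
            )

    # classify: a donor hydrogen (or donor heavy atom in distance-only
    # mode) shared by >=2 acceptors, or an acceptor shared by >=2 donors
    donor_key = lambda b: b.donor if b.hydrogen is None else b.hydrogen
    from collections import Counter

    donor_counts = Counter(donor_key(b) for b in candidates)
    acceptor_counts = Counter(b.acceptor for b in candidates)
    out = []
    for b in candidates:
        bif = donor_counts[donor_key(b)] >= 2 or acceptor_counts[b.acceptor] >= 2
        out.append(
            HBond(
                donor=b.donor,
                hydrogen=b.hydrogen,
                acceptor=b.acceptor,
                distance=b.distance,
                angle=b.angle,
                bifurcated=bif,
            )
        )
    return out


def hbond_totals(n_bifurcated: int, n_regular: int) -> int:
    """Total bond count: each bifurcated interaction contributes two bonds."""
    if n_bifurcated < 0 or n_regular < 0:
        raise ValueError("counts must be >= 0")
    return 2 * n_bifurcated + n_regular


def hbond_summary(bonds: list[HBond]) -> dict:
    """Summarize one frame's bonds in the Table-1 style bookkeeping.

    ``n_bifurcated`` counts bifurcation hubs (a shared hydrogen/donor or a
    shared acceptor); when every hub is two-fold the total equals
    ``2*n_bifurcated + n_regular``.
    """
    from collections import Counter

    donor_key = lambda b: (0, b.donor if b.hydrogen is None else b.hydrogen)
    donor_counts = Counter(donor_key(b) for b in bonds)
    acceptor_counts = Counter((1, b.acceptor) for b in bonds)
    hubs = {
        k for k, v in (donor_counts | acceptor_counts).items() if v >= 2
    }
    n_regular = sum(1 for b in bonds if not b.bifurcated)
    distances = [b.distance for b in bonds]
    return {
        "n_bifurcated": len(hubs),
        "n_regular": n_regular,
        "n_total": len(bonds),
        "avg_distance": float(np.mean(distances)) if distances else np.nan,
    }


@dataclass
class HBondSeries:
    """Per-frame existence of identified bonds (bond x frame boolean matrix).

    ``lengths`` pools the donor-acceptor distances of all present bonds
    over all frames, for bond-length distribution analysis.
    """

    bonds: list[tuple]
    matrix: np.ndarray     # bool, (n_bonds, n_frames)
    dt: float              # ps between frames
    lengths: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=bool)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.bonds):
            raise ValueError("matrix must be (n_bonds, n_frames)")
        if self.lengths is None:
            self.lengths = np.empty(0)
        self.lengths = np.asarray(self.lengths, dtype=float)

    @classmethod
    def from_array(cls, values: np.ndarray, dt: float) -> "HBondSeries":
        values = np.atleast_2d(np.asarray(values, dtype=bool))
        return cls(
            bonds=[("series", i) for i in range(values.shape[0])],
            matrix=values,
            dt=dt,
        )

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[1]

    @property
    def occupancy(self) -> float:
        return float(self.matrix.mean())

    def length_distribution(
        self, bin_width: float = 0.1
    ) -> tuple[np.ndarray, np.ndarray]:
        """Histogram of bond lengths (edges, counts); mean is taken from the
        raw samples, not the bins."""
        if self.lengths.size == 0:
            return np.empty(0), np.empty(0, dtype=int)
        lo = np.floor(self.lengths.min() / bin_width) * bin_width
        hi = np.ceil(self.lengths.max() / bin_width) * bin_width + bin_width / 2
        edges = np.arange(lo, hi + bin_width, bin_width)
        counts, edges = np.histogram(self.lengths, bins=edges)
        return edges, counts

    @property
    def mean_length(self) -> float:
        return float(self.lengths.mean()) if self.lengths.size else np.nan


def hbond_series(
    trajectory: Trajectory,
    system: MolecularSystem | None = None,
    config: AnalysisConfig | None = None,
    subset_a: np.ndarray | None = None,
    subset_b: np.ndarray | None = None,
) -> HBondSeries:
    """Bond-existence matrix over a trajectory.

    Rows are the union of all (donor, hydrogen, acceptor) triples ever
    observed; an entry is True iff the criteria are met in that frame.
    """
    system = system or trajectory.system
    if trajectory.n_frames == 0:
        raise ValueError("trajectory has no frames")
    per_frame = [
        detect_hbonds(f, system, config, subset_a, subset_b)
        for f in trajectory.frames
    ]
    keys: dict[tuple, int] = {}
    for bonds in per_frame:
        for b in bonds:
            keys.setdefault((b.donor, b.hydrogen, b.acceptor), len(keys))
    matrix = np.zeros((len(keys), trajectory.n_frames), dtype=bool)
    lengths: list[float] = []
    for j, bonds in enumerate(per_frame):
        for b in bonds:
            matrix[keys[(b.donor, b.hydrogen, b.acceptor)], j] = True
            lengths.append(b.distance)
    return HBondSeries(
        bonds=list(keys),
        matrix=matrix,
        dt=trajectory.stride,
        lengths=np.array(lengths),
    )


def water_bridges(
    frame: Frame,
    system: MolecularSystem,
    config: AnalysisConfig | None = None,
) -> list[WaterBridge]:
    """Waters hydrogen-bonded to both a protein atom and a ligand atom.

    Water may act as donor or acceptor on either side. Returns one bridge
    per (protein atom, water residue, ligand atom) combination, sorted.
    """
    config = config or AnalysisConfig()
    water = system.group_mask("water")
    if not water.any():
        return []
    prot_idx = np.flatnonzero(system.group_mask("protein"))
    lig_idx = np.flatnonzero(system.ligand_mask)
    water_idx = np.flatnonzero(water)
    if prot_idx.size == 0 or lig_idx.size == 0:
        return []
    bonds_pw = detect_hbonds(frame, system, config, prot_idx, water_idx)
    bonds_lw = detect_hbonds(frame, system, config, lig_idx, water_idx)
    resid = system.residue_indices

    def partner(bonds, other_idx):
        other = set(other_idx.tolist())
        out: dict[int, set[int]] = {}
        for b in bonds:
            if b.donor in other:
                out.setdefault(int(resid[b.acceptor]), set()).add(b.donor)
            else:
                out.setdefault(int(resid[b.donor]), set()).add(b.acceptor)
        return out

    prot_by_water = partner(bonds_pw, prot_idx)
    lig_by_water = partner(bonds_lw, lig_idx)
    bridges = [
        WaterBridge(protein_atom=p, water_residue=w, ligand_atom=l)
        for w in sorted(set(prot_by_water) & set(lig_by_water))
        for p in sorted(prot_by_water[w])
        for l in sorted(lig_by_water[w])
    ]
    return bridges


def bridge_series(
    trajectory: Trajectory,
    system: MolecularSystem | None = None,
    config: AnalysisConfig | None = None,
) -> HBondSeries:
    """Existence series of water bridges (rows = bridge triples)."""
    system = system or trajectory.system
    per_frame = [water_bridges(f, system, config) for f in trajectory.frames]
    keys: dict[tuple, int] = {}
    for bridges in per_frame:
        for b in bridges:
            keys.setdefault(
                (b.protein_atom, b.water_residue, b.ligand_atom), len(keys)
            )
    matrix = np.zeros((len(keys), trajectory.n_frames), dtype=bool)
    for j, bridges in enumerate(per_frame):
        for b in bridges:
            matrix[keys[(b.protein_atom, b.water_residue, b.ligand_atom)], j] = True
    return HBondSeries(bonds=list(keys), matrix=matrix, dt=trajectory.stride)


def waters_near_group(
    trajectory: Trajectory,
    group: str | np.ndarray,
    cutoff_nm: float = 0.35,
    window: tuple[float, float] | None = None,
    system: MolecularSystem | None = None,
) -> tuple[np.ndarray, float]:
    """Per-frame count of waters within ``cutoff_nm`` of a group, and the
    time-average over the analysis window.

    A water counts if *any* of its atoms is within the cutoff of *any*
    atom of the group.
    """
    if cutoff_nm <= 0:
        raise ValueError("cutoff must be > 0")
    system = system or trajectory.system
    cutoff = cutoff_nm * 10.0  # nm -> angstrom
    if isinstance(group, str):
        grp_idx = np.flatnonzero(system.group_mask(group))
    else:
        grp_idx = np.asarray(group, dtype=int)
    water_idx = np.flatnonzero(system.group_mask("water"))
    counts = np.zeros(trajectory.n_frames, dtype=int)
    if water_idx.size and grp_idx.size:
        water_resid = system.residue_indices[water_idx]
        for j, f in enumerate(trajectory.frames):
            d = pair_distances(
                f.coordinates[water_idx], f.coordinates[grp_idx], f.box
            )
            near = d.min(axis=1) <= cutoff
            counts[j] = len(np.unique(water_resid[near]))
    mask = trajectory.window_mask(window)
    average = float(counts[mask].mean()) if mask.any() else 0.0
    return counts, average
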