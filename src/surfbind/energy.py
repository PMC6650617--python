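"""Pairwise Coulomb / Lennard-Jones energies and group decomposition.

Energies are in kJ/mol with inter-site distances in nm (the single
angstrom-to-nm conversion point for the package lives here). The
Lennard-Jones potential uses the GROMOS C6/C12 form with geometric
combination, V = C12/r^12 - C6/r^6. Electrostatics are either a plain
truncated Coulomb or the reaction-field-zero form,

    V(r) = f q_i q_j (1/r + k_rf r^2 - c_rf),  k_rf = 1/(2 r_c^3),
    c_rf = 3/(2 r_c),

which vanishes continuously at the cutoff r_c; this is the default scheme
for reported ligand-surrounding energies, matching decomposable reruns of
mesh-Ewald trajectories. No intra-group or bonded terms are computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .model_io import AnalysisConfig, Frame, MolecularSystem, Trajectory

__all__ = [
    "COULOMB_CONSTANT",
    "ANGSTROM_PER_NM",
    "GroupEnergy",
    "EnergySeries",
    "GroupCharges",
    "ChargeTransfer",
    "ScalingFit",
    "coulomb_pair",
    "lj_pair",
    "resolve_group",
    "group_interaction_energy",
    "energy_timeseries",
    "group_charge_sums",
    "charge_transfer",
    "head_charge_magnitude",
    "charge_energy_scaling",
]

#: f = 1/(4 pi eps0) in kJ mol^-1 nm e^-2
COULOMB_CONSTANT = 138.935458
ANGSTROM_PER_NM = 10.0

_SCHEMES = ("plain_cutoff", "reaction_field_zero")


def coulomb_pair(
    q_i: float | np.ndarray,
    q_j: float | np.ndarray,
    r: float | np.ndarray,
    scheme: str = "plain_cutoff",
    r_c: float = 1.0,
) -> float | np.ndarray:
    """Coulomb pair energy (kJ/mol); q in e, r and r_c in nm.

    Zero beyond the cutoff. The reaction-field-zero form is continuous at
    r_c by construction.
    """
    if scheme not in _SCHEMES:
        raise ValueError(f"scheme must be one of {_SCHEMES}")
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr <= 0):
        raise ValueError("distance must be > 0")
    qq = COULOMB_CONSTANT * np.asarray(q_i, dtype=float) * np.asarray(q_j, dtype=float)
    if scheme == "plain_cutoff":
        energy = qq / r_arr
    else:
        k_rf = 1.0 / (2.0 * r_c**3)
        c_rf = 3.0 / (2.0 * r_c)
        energy = qq * (1.0 / r_arr + k_rf * r_arr**2 - c_rf)
    energy = np.where(r_arr <= r_c, energy, 0.0)
    return float(energy) if np.isscalar(r) else energy


def lj_pair(
    c6_i: float | np.ndarray,
    c6_j: float | np.ndarray,
    c12_i: float | np.ndarray,
    c12_j: float | np.ndarray,
    r: float | np.ndarray,
    r_c: float | None = 1.0,
) -> float | np.ndarray:
    """Lennard-Jones pair energy with geometric combination (kJ/mol).

    C6 = sqrt(c6_i c6_j), C12 = sqrt(c12_i c12_j); V = C12/r^12 - C6/r^6,
    truncated at the cutoff (pass ``r_c=None`` for no truncation).
    """
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr <= 0):
        raise ValueError("distance must be > 0")
    c6 = np.sqrt(np.asarray(c6_i, dtype=float) * np.asarray(c6_j, dtype=float))
    c12 = np.sqrt(np.asarray(c12_i, dtype=float) * np.asarray(c12_j, dtype=float))
    r6 = r_arr**6
    energy = c12 / (r6 * r6) - c6 / r6
    if r_c is not None:
        energy = np.where(r_arr <= r_c, energy, 0.0)
    return float(energy) if np.isscalar(r) else energy


@dataclass(frozen=True)
class GroupEnergy:
    """Summed cross-pair Coulomb and LJ energies between two atom groups."""

    group_a: str
    group_b: str
    e_coulomb: float   # kJ/mol
    e_lj: float        # kJ/mol
    scheme: str

    @property
    def total(self) -> float:
        return self.e_coulomb + self.e_lj


def resolve_group(
    system: MolecularSystem,
    group: str | np.ndarray,
    include_ions: bool = True,
) -> np.ndarray:
    """Atom indices for a group spec: a label, ``"ligand"``,
    ``"surrounding"`` (protein + water, plus ions by default), or an
    explicit index array."""
    if isinstance(group, str):
        if group == "ligand":
            return np.flatnonzero(system.ligand_mask)
        if group == "surrounding":
            labels = ["protein", "water"] + (["ion"] if include_ions else [])
            return np.flatnonzero(system.group_mask(*labels))
        return np.flatnonzero(system.group_mask(group))
    return np.asarray(group, dtype=int)


def group_interaction_energy(
    frame: Frame,
    system: MolecularSystem,
    group_a: str | np.ndarray,
    group_b: str | np.ndarray,
    config: AnalysisConfig | None = None,
) -> GroupEnergy:
    """Total Coulomb + LJ energy over all cross pairs of two disjoint groups.

    Minimum-image distances are used when the frame has a box; pairs
    beyond the Coulomb cutoff contribute nothing to either term.
    """
    config = config or AnalysisConfig()
    idx_a = resolve_group(system, group_a, config.include_ions)
    idx_b = resolve_group(system, group_b, config.include_ions)
    if np.intersect1d(idx_a, idx_b).size:
        raise ValueError("groups overlap; energies require disjoint groups")
    name_a = group_a if isinstance(group_a, str) else f"[{len(idx_a)} atoms]"
    name_b = group_b if isinstance(group_b, str) else f"[{len(idx_b)} atoms]"
    if idx_a.size == 0 or idx_b.size == 0:
        return GroupEnergy(str(name_a), str(name_b), 0.0, 0.0,
                           config.electrostatics_scheme)

    diff = frame.coordinates[idx_a][:, None, :] - frame.coordinates[idx_b][None, :, :]
    if frame.box is not None:
        diff -= frame.box * np.round(diff / frame.box)
    r_nm = np.sqrt(np.sum(diff * diff, axis=-1)) / ANGSTROM_PER_NM

    q = system.charges
    c6, c12 = system.c6, system.c12
    e_coul = coulomb_pair(
        q[idx_a][:, None],
        q[idx_b][None, :],
        r_nm,
        scheme=config.electrostatics_scheme,
        r_c=config.coulomb_cutoff,
    )
    e_lj = lj_pair(
        c6[idx_a][:, None],
        c6[idx_b][None, :],
        c12[idx_a][:, None],
        c12[idx_b][None, :],
        r_nm,
        r_c=config.coulomb_cutoff,
    )
    return GroupEnergy(
        group_a=str(name_a),
        group_b=str(name_b),
        e_coulomb=float(np.sum(e_coul)),
        e_lj=float(np.sum(e_lj)),
        scheme=config.electrostatics_scheme,
    )


def _block_sem(x: np.ndarray, n_blocks: int = 5) -> float:
    """Standard error of the mean by block averaging."""
    if len(x) < n_blocks:
        n_blocks = max(len(x), 1)
    if n_blocks < 2:
        return 0.0
    means = np.array([b.mean() for b in np.array_split(x, n_blocks)])
    return float(means.std(ddof=1) / np.sqrt(n_blocks))


@dataclass
class EnergySeries:
    """Per-frame ligand-surrounding energies with window statistics."""

    times: np.ndarray          # ps
    e_coulomb: np.ndarray      # kJ/mol per frame
    e_lj: np.ndarray
    window: tuple[float, float] | None
    mean_coulomb: float
    sem_coulomb: float
    mean_lj: float
    sem_lj: float
    scheme: str
    n_blocks: int = 5


def energy_timeseries(
    trajectory: Trajectory,
    system: MolecularSystem | None = None,
    config: AnalysisConfig | None = None,
    group_a: str | np.ndarray = "ligand",
    group_b: str | np.ndarray = "surrounding",
) -> EnergySeries:
    """Per-frame group-pair energies plus analysis-window mean and the
    block-averaged (5 blocks) standard error."""
    system = system or trajectory.system
    config = config or AnalysisConfig()
    e_coul = np.empty(trajectory.n_frames)
    e_lj = np.empty(trajectory.n_frames)
    for j, f in enumerate(trajectory.frames):
        ge = group_interaction_energy(f, system, group_a, group_b, config)
        e_coul[j], e_lj[j] = ge.e_coulomb, ge.e_lj
    mask = trajectory.window_mask(config.analysis_window)
    if not mask.any():
        raise ValueError(
            f"analysis window {config.analysis_window} excludes all frames"
        )
    return EnergySeries(
        times=trajectory.times,
        e_coulomb=e_coul,
        e_lj=e_lj,
        window=config.analysis_window,
        mean_coulomb=float(e_coul[mask].mean()),
        sem_coulomb=_block_sem(e_coul[mask]),
        mean_lj=float(e_lj[mask].mean()),
        sem_lj=_block_sem(e_lj[mask]),
        scheme=config.electrostatics_scheme,
    )


@dataclass(frozen=True)
class GroupCharges:
    """Ligand partial-charge sums (e) by group.

    ``tail_with_alpha`` includes the alpha-methylene group, the
    tail-inclusive convention; the net charge is always
    head + tail_with_alpha. With ``alpha_in_head`` grouping the alpha sum
    moves into the head and ``tail_with_alpha`` holds the bare tail, so
    the identity still holds.
    """

    head: float
    alpha: float
    tail_with_alpha: float
    net: float


def group_charge_sums(
    system: MolecularSystem, alpha_in_head: bool = False
) -> GroupCharges:
    """Sum ligand partial charges per group.

    ``alpha_in_head=True`` adopts the head-inclusive convention
    (alpha-methylene counted with the head); the default counts it with
    the tail.
    """
    groups = system.groups
    lig = system.ligand_mask
    if not lig.any():
        raise ValueError("no ligand atoms grouped as head/alpha/tail")
    # an atom of the ligand residue(s) left as 'other' means the grouping
    # is incomplete
    lig_res = {
        (a.chain, a.residue_index)
        for a, m in zip(system.atoms, lig)
        if m
    }
    ungrouped = [
        a.serial
        for a in system.atoms
        if (a.chain, a.residue_index) in lig_res and a.group == "other"
    ]
    if ungrouped:
        raise ValueError(
            f"ligand atom(s) with serial {ungrouped} are ungrouped"
        )
    q = system.charges
    head = float(q[groups == "head"].sum())
    alpha = float(q[groups == "alpha"].sum())
    tail = float(q[groups == "tail"].sum())
    if alpha_in_head:
        return GroupCharges(
            head=head + alpha,
            alpha=alpha,
            tail_with_alpha=tail,
            net=head + alpha + tail,
        )
    return GroupCharges(
        head=head,
        alpha=alpha,
        tail_with_alpha=alpha + tail,
        net=head + alpha + tail,
    )


@dataclass(frozen=True)
class ChargeTransfer:
    """Change in ligand net charge upon binding (bound - free), in e."""

    delta: float
    magnitude: float


def charge_transfer(free: GroupCharges, bound: GroupCharges) -> ChargeTransfer:
    if not (np.isfinite(free.net) and np.isfinite(bound.net)):
        raise ValueError("net charges must be finite")
    delta = bound.net - free.net
    return ChargeTransfer(delta=delta, magnitude=abs(delta))


def head_charge_magnitude(*charges: float) -> float:
    """|q_head| feature for charge-energy scaling plots.

    For a single-moiety head this is the absolute head-group charge; for a
    zwitterionic head it is the mean of the absolute charges of the
    oppositely charged sub-heads.
    """
    if not charges:
        raise ValueError("need at least one head-group charge")
    return float(np.mean(np.abs(charges)))


@dataclass(frozen=True)
class ScalingFit:
    slope: float
    intercept: float
    r_value: float


def charge_energy_scaling(
    points: list[tuple[float, float]] | np.ndarray
) -> ScalingFit:
    """Ordinary least-squares line through (|q_head|, E_coulomb) points."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (|q|, E) points")
    if np.ptp(pts[:, 0]) == 0:
        raise ValueError("zero variance in |q|; cannot fit a line")
    fit = stats.linregress(pts[:, 0], pts[:, 1])
    return ScalingFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_value=float(fit.rvalue),
    )
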