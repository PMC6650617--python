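"""Synthetic-data generators with known ground truth.

Every analysis stage in this package is exercised on inputs whose correct
answer is known analytically: two-state (telegraph) hydrogen-bond
existence series with prescribed breaking/reforming rates, small random
point-charge/Lennard-Jones complexes, linear-interaction-energy training
tables built from known coefficients, and Gaussian-jittered trajectories
with known per-atom variance. All generators are deterministic under a
fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_io import AtomRecord, Frame, MolecularSystem, Trajectory

__all__ = [
    "TelegraphSpec",
    "ToyComplexSpec",
    "LIETrainingSpec",
    "gen_telegraph_series",
    "gen_toy_complex",
    "gen_lie_training",
    "gen_jitter_trajectory",
]


@dataclass(frozen=True)
class TelegraphSpec:
    """Two-state Markov chain standing in for H-bond on/off dynamics.

    ``k_off`` is the bond-breaking rate and ``k_on`` the reforming rate,
    both in ps^-1; the chain is sampled every ``dt`` ps with per-step
    switching probability ``1 - exp(-k*dt)``. The stationary on-probability
    of the underlying process is ``k_on / (k_on + k_off)``.
    """

    k_off: float
    k_on: float
    dt: float
    n_steps: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_off <= 0 or self.k_on <= 0:
            raise ValueError("k_off and k_on must be > 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")


@dataclass(frozen=True)
class ToyComplexSpec:
    """A small random protein/ligand/water point complex.

    Charges are drawn uniformly in ``(-charge_range, +charge_range)`` e and
    LJ coefficients uniformly from the given ranges (kJ mol^-1 nm^6 /
    nm^12, roughly carbon-like by default). Waters are rigid 3-site
    molecules with fixed SPC-like charges so that bridge detection sees
    chemically sensible donors and acceptors.
    """

    n_protein: int = 20
    n_ligand: int = 6
    n_water: int = 3
    charge_range: float = 0.5
    c6_range: tuple[float, float] = (5e-4, 3e-3)
    c12_range: tuple[float, float] = (5e-7, 4e-6)
    box: float = 30.0  # angstrom
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_protein, self.n_ligand, self.n_water) < 0:
            raise ValueError("atom counts must be >= 0")
        if self.box <= 7.0:  # 2 x default contact cutoff
            raise ValueError("box must exceed twice the contact cutoff")


@dataclass(frozen=True)
class LIETrainingSpec:
    """Training table generated from known LIE coefficients.

    ``dg_exp = beta*du_el + alpha*du_vdw + gamma + N(0, noise_sd)``, with
    the bound-minus-free energy differences drawn uniformly from the given
    ranges (kJ/mol).
    """

    alpha: float = 0.5
    beta: float = 0.16
    gamma: float = 0.0
    n_ligands: int = 50
    noise_sd: float = 1.0
    el_range: tuple[float, float] = (-50.0, 10.0)
    vdw_range: tuple[float, float] = (-70.0, -5.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ligands < 2:
            raise ValueError("n_ligands must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def gen_telegraph_series(spec: TelegraphSpec) -> np.ndarray:
    """Sample a boolean two-state chain (True = bond present).

    The dwell time in each state of the sampled chain is geometric with
    success probability ``1 - exp(-k*dt)``, so continuous on-segments have
    mean duration ``dt / (1 - exp(-k_off*dt)) ~= 1/k_off`` for small
    ``k_off*dt``. Sampling draws whole dwell segments, which is equivalent
    to stepping the chain and much faster for long series.
    """
    if spec.dt >= 10.0 / max(spec.k_off, spec.k_on):
        warnings.warn(
            "sampling interval dt is much longer than the fastest dwell "
            "time; the series will be undersampled",
            stacklevel=2,
        )
    p_break = -np.expm1(-spec.k_off * spec.dt)  # on -> off per step
    p_form = -np.expm1(-spec.k_on * spec.dt)    # off -> on per step
    rng = np.random.default_rng(spec.seed)
    pi_on = p_form / (p_form + p_break)
    state = bool(rng.random() < pi_on)

    out = np.empty(spec.n_steps, dtype=bool)
    pos = 0
    while pos < spec.n_steps:
        p = p_break if state else p_form
        dwell = int(rng.geometric(p)) if p < 1.0 else 1
        end = min(pos + dwell, spec.n_steps)
        out[pos:end] = state
        pos = end
        state = not state
    return out


_WATER_GEOMETRY = np.array(
    [
        [0.0, 0.0, 0.0],
        [0.9572, 0.0, 0.0],
        [-0.2400, 0.9266, 0.0],
    ]
)  # angstrom; O-H 0.9572, H-O-H 104.52 deg

_SPC_CHARGES = (-0.8476, 0.4238, 0.4238)
_OW_C6, _OW_C12 = 2.617e-3, 2.634e-6  # SPC oxygen, kJ mol^-1 nm^6 / nm^12


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    m = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def gen_toy_complex(spec: ToyComplexSpec) -> tuple[MolecularSystem, Frame]:
    """Generate a random point complex with known parameters.

    Sites are placed uniformly in the box with a minimum inter-site
    distance of 0.8 angstrom (rejection sampling; water hydrogens ride on
    their oxygen). The ligand is split into a head half and a tail half.
    Donors are the water O-H pairs; acceptors are all N and O atoms.
    """
    rng = np.random.default_rng(spec.seed)
    positions: list[np.ndarray] = []

    def place_site() -> np.ndarray:
        for _ in range(10_000):
            cand = rng.uniform(0.0, spec.box, size=3)
            if not positions:
                return cand
            d = np.linalg.norm(np.array(positions) - cand, axis=1)
            if d.min() >= 0.8:
                return cand
        raise RuntimeError(
            "could not place an atom with 0.8 A separation after 10^4 "
            "attempts; use a larger box"
        )

    atoms: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    serial = 1

    protein_elements = ["C", "N", "O", "C"]
    protein_resnames = ["ALA", "LEU", "SER", "VAL", "GLY"]
    for i in range(spec.n_protein):
        site = place_site()
        positions.append(site)
        coords.append(site)
        el = protein_elements[i % 4]
        atoms.append(
            AtomRecord(
                serial=serial,
                name=f"{el}{i + 1}",
                element=el,
                residue_name=protein_resnames[(i // 4) % 5],
                residue_index=i // 4 + 1,
                chain="A",
                charge=float(rng.uniform(-spec.charge_range, spec.charge_range)),
                c6=float(rng.uniform(*spec.c6_range)),
                c12=float(rng.uniform(*spec.c12_range)),
                group="protein",
            )
        )
        serial += 1

    n_head = (spec.n_ligand + 1) // 2
    for i in range(spec.n_ligand):
        site = place_site()
        positions.append(site)
        coords.append(site)
        el = "O" if i % 3 == 0 else "C"
        atoms.append(
            AtomRecord(
                serial=serial,
                name=f"L{i + 1}",
                element=el,
                residue_name="LIG",
                residue_index=1,
                chain="B",
                charge=float(rng.uniform(-spec.charge_range, spec.charge_range)),
                c6=float(rng.uniform(*spec.c6_range)),
                c12=float(rng.uniform(*spec.c12_range)),
                group="head" if i < n_head else "tail",
            )
        )
        serial += 1

    donors: list[tuple[int, int | None]] = []
    for i in range(spec.n_water):
        site = place_site()
        positions.append(site)
        rot = _random_rotation(rng)
        w = site + _WATER_GEOMETRY @ rot.T
        o_index = len(coords)
        for j, (name, q) in enumerate(zip(("OW", "HW1", "HW2"), _SPC_CHARGES)):
            coords.append(w[j])
            atoms.append(
                AtomRecord(
                    serial=serial,
                    name=name,
                    element="O" if j == 0 else "H",
                    residue_name="SOL",
                    residue_index=i + 1,
                    chain="W",
                    charge=q,
                    c6=_OW_C6 if j == 0 else 0.0,
                    c12=_OW_C12 if j == 0 else 0.0,
                    group="water",
                )
            )
            serial += 1
        donors.append((o_index, o_index + 1))
        donors.append((o_index, o_index + 2))

    elements = np.array([a.element for a in atoms], dtype=object)
    acceptors = [int(i) for i in np.flatnonzero((elements == "N") | (elements == "O"))]
    system = MolecularSystem(atoms=atoms, donors=donors, acceptors=acceptors)
    frame = Frame(
        time=0.0,
        coordinates=np.array(coords),
        box=np.array([spec.box] * 3),
    )
    return system, frame


def gen_lie_training(spec: LIETrainingSpec) -> pd.DataFrame:
    """Generate a (du_el, du_vdw, dg_exp) training table from known truth."""
    rng = np.random.default_rng(spec.seed)
    du_el = rng.uniform(*spec.el_range, size=spec.n_ligands)
    du_vdw = rng.uniform(*spec.vdw_range, size=spec.n_ligands)
    noise = (
        rng.normal(0.0, spec.noise_sd, size=spec.n_ligands)
        if spec.noise_sd > 0
        else np.zeros(spec.n_ligands)
    )
    dg = spec.beta * du_el + spec.alpha * du_vdw + spec.gamma + noise
    return pd.DataFrame({"du_el": du_el, "du_vdw": du_vdw, "dg_exp": dg})


def gen_jitter_trajectory(
    system: MolecularSystem,
    reference: Frame,
    sigma: float,
    n_frames: int,
    seed: int = 0,
    stride: float = 2.0,
) -> Trajectory:
    """Reference structure plus i.i.d. Gaussian noise per coordinate.

    Each frame is ``reference + N(0, sigma^2)`` per axis (sigma in
    angstrom), so the analytic per-atom fluctuation is ``sigma*sqrt(3)``.
    Frames are ``stride`` ps apart.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    frames = []
    for i in range(n_frames):
        noise = (
            rng.normal(0.0, sigma, size=reference.coordinates.shape)
            if sigma > 0
            else 0.0
        )
        frames.append(
            Frame(
                time=i * stride,
                coordinates=reference.coordinates + noise,
                box=None if reference.box is None else reference.box.copy(),
            )
        )
    return Trajectory(system=system, frames=frames)
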