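"""Linear interaction energy (LIE) binding free energies.

The LIE estimate is

    dG_bind = beta * <dU_el> + alpha * <dU_vdw> + gamma

where <dU_el> and <dU_vdw> are the differences of the average
ligand-surrounding electrostatic and van der Waals energies between the
bound (solvated protein complex) and free (ligand in water) states. The
scaling factors are obtained by ordinary least squares against
experimental free energies of chemically related ligands; gamma is fixed
at zero unless explicitly freed. The published coefficients for the
BSA-surfactant calibration are beta=0.16, alpha=0.5, gamma=0.

Experimental dissociation constants convert through dG = R*T*ln(K_D)
(K_D in mol/L), so binding favourability corresponds to K_D < 1 M;
magnitudes are often quoted alongside the signed values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GAS_CONSTANT_KJ = 8.314e-3  # kJ mol^-1 K^-1

__all__ = [
    "PUBLISHED_BETA",
    "PUBLISHED_ALPHA",
    "PUBLISHED_GAMMA",
    "LIEModel",
    "LigandEnergies",
    "BindingResult",
    "lie_predict",
    "lie_calibrate",
    "delta_g_from_kd",
    "average_experimental",
    "mean_abs_error",
]

#: Published calibration for the BSA-surfactant training set.
PUBLISHED_BETA = 0.16
PUBLISHED_ALPHA = 0.5
PUBLISHED_GAMMA = 0.0


@dataclass
class LIEModel:
    """LIE scaling factors plus training diagnostics."""

    alpha: float = PUBLISHED_ALPHA     # van der Waals coefficient
    beta: float = PUBLISHED_BETA       # electrostatic coefficient
    gamma: float = PUBLISHED_GAMMA     # constant offset, kJ/mol
    mae: float | None = None           # training mean absolute error
    residuals: np.ndarray | None = None


@dataclass
class LigandEnergies:
    """Bound/free ensemble-average energies (kJ/mol) with standard errors."""

    el_bound: float
    vdw_bound: float
    el_free: float
    vdw_free: float
    se_el_bound: float = 0.0
    se_vdw_bound: float = 0.0
    se_el_free: float = 0.0
    se_vdw_free: float = 0.0

    def __post_init__(self) -> None:
        for name in ("el_bound", "vdw_bound", "el_free", "vdw_free"):
            v = getattr(self, name)
            if v is None or not np.isfinite(v):
                raise ValueError(f"missing or non-finite energy average {name}")


@dataclass
class BindingResult:
    """Predicted binding free energy with propagated uncertainty."""

    dg_predicted: float            # kJ/mol
    dg_error: float                # kJ/mol, 1-sigma propagated
    dg_experimental: float | None = None
    abs_error: float | None = field(default=None)

    def __post_init__(self) -> None:
        if self.dg_experimental is not None and self.abs_error is None:
            self.abs_error = abs(self.dg_predicted - self.dg_experimental)


def lie_predict(
    energies: LigandEnergies,
    model: LIEModel | None = None,
    dg_experimental: float | None = None,
) -> BindingResult:
    """Predict dG_bind from bound/free energy averages.

    The uncertainty is propagated linearly:
    ``sqrt(beta^2 var(dU_el) + alpha^2 var(dU_vdw))`` with the variance of
    each difference the sum of the squared standard errors of its two
    ensemble averages.
    """
    model = model or LIEModel()
    du_el = energies.el_bound - energies.el_free
    du_vdw = energies.vdw_bound - energies.vdw_free
    dg = model.beta * du_el + model.alpha * du_vdw + model.gamma
    var_el = energies.se_el_bound**2 + energies.se_el_free**2
    var_vdw = energies.se_vdw_bound**2 + energies.se_vdw_free**2
    err = float(np.sqrt(model.beta**2 * var_el + model.alpha**2 * var_vdw))
    return BindingResult(
        dg_predicted=float(dg),
        dg_error=err,
        dg_experimental=dg_experimental,
    )


def lie_calibrate(
    training: pd.DataFrame, fix_gamma: bool = True
) -> LIEModel:
    """Fit (beta, alpha[, gamma]) by ordinary least squares.

    ``training`` needs columns ``du_el``, ``du_vdw``, ``dg_exp`` (kJ/mol).
    With gamma fixed at zero two rows suffice; freeing gamma needs three.
    """
    required = {"du_el", "du_vdw", "dg_exp"}
    missing = required - set(training.columns)
    if missing:
        raise ValueError(f"training table missing columns {sorted(missing)}")
    n = len(training)
    n_params = 2 if fix_gamma else 3
    if n < n_params:
        raise ValueError(
            f"need at least {n_params} training rows, got {n}"
        )
    cols = [training["du_el"].to_numpy(), training["du_vdw"].to_numpy()]
    if not fix_gamma:
        cols.append(np.ones(n))
    design = np.column_stack(cols)
    if np.linalg.matrix_rank(design) < n_params:
        raise ValueError("rank-deficient design; training energies are "
                         "collinear")
    y = training["dg_exp"].to_numpy()
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    beta, alpha = float(coef[0]), float(coef[1])
    gamma = float(coef[2]) if not fix_gamma else 0.0
    residuals = y - design @ coef
    return LIEModel(
        alpha=alpha,
        beta=beta,
        gamma=gamma,
        mae=float(np.mean(np.abs(residuals))),
        residuals=residuals,
    )


def delta_g_from_kd(k_d: float, temperature: float = 298.0) -> float:
    """dG = R*T*ln(K_D) in kJ/mol, K_D in mol/L.

    A dissociation constant below 1 M gives a negative (favourable) dG.
    """
    if k_d <= 0:
        raise ValueError("K_D must be > 0")
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    return GAS_CONSTANT_KJ * temperature * float(np.log(k_d))


def average_experimental(values: list[float] | np.ndarray) -> float:
    """Arithmetic mean across literature values, rounded to 2 decimals for
    reporting."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("need at least one experimental value")
    return float(round(values.mean(), 2))


def mean_abs_error(
    predicted: list[float] | np.ndarray, experimental: list[float] | np.ndarray
) -> float:
    """Mean absolute error (kJ/mol) between paired predictions and
    experimental values."""
    p = np.asarray(predicted, dtype=float)
    e = np.asarray(experimental, dtype=float)
    if p.shape != e.shape or p.size == 0:
        raise ValueError("predicted and experimental must be equal nonzero "
                         "length")
    return float(np.mean(np.abs(p - e)))
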