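"""Gauss-Newton image reconstruction in log-magnitude/phase form.

Measurements enter as complex log values ``gamma = ln|E| + j phi`` with the
phase unwrapped along each transmitter's receiver sequence.  Measured
phantom data are calibrated against a homogeneous-tank measurement by
log-domain subtraction and re-based onto the model's own homogeneous
prediction, cancelling antenna and system factors the model does not
represent.  Each iteration performs one forward sweep (ns solves sharing a
single LU factorization), assembles the collapsed nodal-adjoint Jacobian
from the same field solutions, log-transforms it, and applies a
Levenberg-Marquardt-regularized normal-equation update to the complex k^2
image on the zone nodes.  Iterations stop when the relative residual error
(normalized to the first iteration) decreases by less than ``stop_delta``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.constants import epsilon_0, mu_0

from .forward import (
    DDASolver,
    DielectricProperties,
    FrequencySpec,
    MeasurementSet,
    PropertyMap,
)
from .geometry import AntennaArray, ImagingZone
from .jacobian import jacobian_matrix, JacobianMatrix, log_transform_jacobian

__all__ = [
    "ReconstructionConfig",
    "CalibratedData",
    "ReconstructionResult",
    "log_measurements",
    "calibrate",
    "gauss_newton_update",
    "relative_error",
    "reconstruct",
]


@dataclass(frozen=True)
class ReconstructionConfig:
    """Iteration controls.

    ``regularization_lambda`` is the Levenberg-Marquardt parameter relative
    to the mean diagonal of J^H J; it decays geometrically by ``lm_decay``
    each iteration.  ``step_clamp`` optionally bounds the per-iteration
    update as a fraction of |k2_background|.
    """

    max_iterations: int = 25
    stop_delta: float = 1e-3
    regularization_lambda: float = 0.1
    lm_decay: float = 0.9
    step_clamp: float | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.stop_delta > 0:
            raise ValueError("stop_delta must be positive")
        if self.regularization_lambda < 0:
            raise ValueError("regularization_lambda must be >= 0")
        if not 0 < self.lm_decay <= 1:
            raise ValueError("lm_decay must be in (0, 1]")


@dataclass
class CalibratedData:
    """Log-domain calibrated measurements, in canonical pair order."""

    pairs: np.ndarray
    values: np.ndarray  # complex: ln|E| + j unwrapped phase


@dataclass
class ReconstructionResult:
    """Per-iteration images, error trace and termination status."""

    eps_r_iterates: list = field(default_factory=list)
    sigma_iterates: list = field(default_factory=list)
    errors: list = field(default_factory=list)  # e_i, e_1 = 1
    n_iterations: int = 0
    converged: bool = False
    status: str = ""
    final_map: PropertyMap | None = None


def log_measurements(m: MeasurementSet) -> np.ndarray:
    """Complex log of a measurement set with per-transmitter phase unwrapping.

    The phase is unwrapped along each transmitter's receivers in ascending
    receiver order (2-pi jump correction); magnitudes must be nonzero.
    """
    vals = np.asarray(m.values)
    if np.any(vals == 0):
        k = int(np.flatnonzero(vals == 0)[0])
        s, r = m.pairs[k]
        raise ValueError(f"zero-magnitude measurement for pair ({s}, {r})")
    out = np.empty(len(vals), dtype=complex)
    out.real = np.log(np.abs(vals))
    phases = np.angle(vals)
    for s in np.unique(m.pairs[:, 0]):
        rows = np.flatnonzero(m.pairs[:, 0] == s)
        rows = rows[np.argsort(m.pairs[rows, 1])]
        out.imag[rows] = np.unwrap(phases[rows])
    return out


def calibrate(
    inhomog: MeasurementSet,
    homog: MeasurementSet,
    computed_homog: MeasurementSet,
) -> CalibratedData:
    """Re-base measured phantom data onto the model's homogeneous prediction.

    ``gamma_cal = [log(inhomog) - log(homog)] + log(computed_homog)``: the
    measured log-domain perturbation caused by the phantom is added to what
    the forward model predicts for the bare tank.
    """
    for other in (homog, computed_homog):
        if not np.array_equal(inhomog.pairs, other.pairs):
            raise ValueError("measurement sets have mismatched (s, r) ordering")
    values = (
        log_measurements(inhomog)
        - log_measurements(homog)
        + log_measurements(computed_homog)
    )
    return CalibratedData(inhomog.pairs.copy(), values)


def relative_error(residual_norms) -> np.ndarray:
    """Error sequence normalized to the first iteration: e_i = ||r_i|| / ||r_1||."""
    norms = np.asarray(residual_norms, dtype=float)
    if norms.size == 0:
        raise ValueError("empty residual-norm sequence")
    if norms[0] == 0:
        raise ValueError("zero first-iteration residual norm")
    return norms / norms[0]


def gauss_newton_update(
    J_log: JacobianMatrix,
    residual: np.ndarray,
    cfg: ReconstructionConfig,
    lam: float | None = None,
) -> np.ndarray:
    """Regularized normal-equation step ``(J^H J + lam s I) dk2 = J^H r``.

    ``s`` is the mean diagonal of J^H J, making ``lam`` a relative
    Levenberg-Marquardt weight.  ``lam`` defaults to the configured value.
    """
    if J_log.domain != "log-transformed":
        raise ValueError("gauss_newton_update expects a log-transformed Jacobian")
    lam = cfg.regularization_lambda if lam is None else float(lam)
    J = J_log.entries
    H = J.conj().T @ J
    scale = float(np.mean(H.diagonal().real))
    rhs = J.conj().T @ np.asarray(residual)
    A = H + (lam * scale) * np.eye(H.shape[0])
    try:
        return linalg.solve(A, rhs, assume_a="her")
    except linalg.LinAlgError as exc:  # singular at lam = 0
        raise linalg.LinAlgError(
            f"normal equations singular (lambda={lam}); increase regularization"
        ) from exc


def _clamped(k2: np.ndarray, freq: FrequencySpec) -> np.ndarray:
    """Project node k^2 values onto the passive physical set (eps_r>=1, sigma>=0)."""
    w = freq.omega
    eps_r = np.maximum(k2.real / (w**2 * mu_0 * epsilon_0), 1.0)
    sigma = np.maximum(-k2.imag / (w * mu_0), 0.0)
    return w**2 * mu_0 * (epsilon_0 * eps_r - 1j * sigma / w)


def reconstruct(
    calibrated: CalibratedData,
    zone: ImagingZone,
    array: AntennaArray,
    freq: FrequencySpec,
    background: DielectricProperties,
    cfg: ReconstructionConfig = ReconstructionConfig(),
) -> ReconstructionResult:
    """Iterative Gauss-Newton reconstruction from calibrated log-domain data.

    Starts from the homogeneous background map.  Per iteration: forward
    sweep, residual, collapsed-adjoint Jacobian from the sweep's fields,
    log transform, LM update applied to the zone's k^2 image.  Terminates
    on the stopping rule |e_i - e_{i-1}| < stop_delta, on max_iterations,
    or aborts if the error grows for 3 consecutive iterations.
    """
    pmap = PropertyMap.homogeneous(zone, background, freq)
    solver = DDASolver(zone, array, freq, pmap.k2_background)
    result = ReconstructionResult()
    norms: list[float] = []
    grow = 0

    for it in range(1, cfg.max_iterations + 1):
        fields, mset = solver.sweep(pmap)
        gamma = log_measurements(mset)
        residual = calibrated.values - gamma
        norms.append(float(np.linalg.norm(residual)))
        eps_r, sigma = pmap.eps_sigma(freq)
        result.eps_r_iterates.append(eps_r.copy())
        result.sigma_iterates.append(sigma.copy())
        result.n_iterations = it
        result.final_map = pmap

        if norms[0] <= 1e-12 * max(1.0, float(np.linalg.norm(calibrated.values))):
            result.errors = [0.0] * len(norms)
            result.converged = True
            result.status = "zero initial residual (data match the starting map)"
            return result

        errors = relative_error(norms)
        result.errors = list(errors)
        if it >= 2:
            if abs(errors[-1] - errors[-2]) < cfg.stop_delta:
                result.converged = True
                result.status = f"stopping rule met at iteration {it}"
                return result
            grow = grow + 1 if errors[-1] > errors[-2] else 0
            if grow >= 3:
                result.converged = False
                result.status = f"diverged: error grew 3 consecutive iterations (it {it})"
                return result

        J = jacobian_matrix(fields, zone, array, freq)
        J_log = log_transform_jacobian(J, mset.values)
        lam = cfg.regularization_lambda * cfg.lm_decay ** (it - 1)
        dk2 = gauss_newton_update(J_log, residual, cfg, lam=lam)
        if cfg.step_clamp is not None:
            cap = cfg.step_clamp * abs(pmap.k2_background)
            mag = np.abs(dk2)
            over = mag > cap
            dk2[over] *= cap / mag[over]
        pmap = PropertyMap(
            zone, _clamped(pmap.k2_nodes + dk2, freq), pmap.k2_background
        )

    result.converged = False
    result.status = f"max_iterations ({cfg.max_iterations}) reached"
    return result
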