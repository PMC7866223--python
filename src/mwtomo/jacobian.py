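"""Sensitivity (Jacobian) matrix via the collapsed nodal-adjoint formula.

The adjoint method expresses the derivative of the field received at
antenna r while transmitting from antenna s, with respect to the complex
squared wavenumber k^2 at parameter node tau, as a weighted product of the
two forward fields launched from s and from r.  When the forward-solution
grid and the parameter grid coincide and the nodal basis functions are
interpolatory (value 1 at their node, 0 at every other node), the general
dual-mesh quadrature collapses to a single term per node:

    J[(s, r), tau] = -(1 / (j w mu0 |Jr|)) (A_tau / M) Es(p_tau) Er(p_tau)

so an entire row is one elementwise vector product of two already-computed
field distributions times a constant.  Building the full matrix therefore
costs ns forward solves (one per antenna, shared with the residual
computation) and ns x nr vector products - no extra solves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.constants import mu_0

from .forward import (
    DDASolver,
    FieldSolution,
    FrequencySpec,
    PropertyMap,
    measurement_pairs,
)
from .geometry import AntennaArray, ImagingZone

__all__ = [
    "JacobianMatrix",
    "jacobian_row_collapsed",
    "jacobian_row_general",
    "jacobian_matrix",
    "log_transform_jacobian",
    "finite_difference_jacobian_column",
    "COUNTERS",
    "reset_counters",
]

#: number of collapsed row products performed since the last reset.
COUNTERS = {"row_products": 0}


def reset_counters() -> None:
    COUNTERS["row_products"] = 0


@dataclass
class JacobianMatrix:
    """(ns*nr) x np complex sensitivity matrix.

    Rows follow the canonical measurement order; columns follow the
    imaging-zone unknown ordering.  Entries are derivatives with respect to
    complex k^2 (units m^2 per unit field); ``domain`` records whether rows
    are raw complex-field derivatives or log-transformed ones.
    """

    entries: np.ndarray
    pairs: np.ndarray
    domain: str = "complex-field"


def _adjoint_constant(freq: FrequencySpec, amplitude: float) -> complex:
    if not amplitude > 0:
        raise ValueError("source amplitude |Jr| must be positive")
    return -1.0 / (1j * freq.omega * mu_0 * amplitude)


def jacobian_row_collapsed(
    Es: FieldSolution,
    Er: FieldSolution,
    zone: ImagingZone,
    freq: FrequencySpec,
    amplitude: float = 1.0,
) -> np.ndarray:
    """One Jacobian row as a single vector-vector product.

    ``row[tau] = -(1/(j w mu0 |Jr|)) (A_tau/M) Es(p_tau) Er(p_tau)``; the
    area weight ``A_tau/M`` equals h^2 at interior nodes and the true
    (smaller) per-node area at zone-boundary nodes.
    """
    if len(Es.E_nodes) != zone.n_nodes or len(Er.E_nodes) != zone.n_nodes:
        raise ValueError("field solutions do not match the imaging zone")
    COUNTERS["row_products"] += 1
    weight = zone.node_area / zone.M
    # canonical operand order: complex multiplication is not bitwise
    # commutative under FMA, and swapping (s, r) must reproduce the row exactly
    lo, hi = sorted((Es, Er), key=lambda f: f.transmitter)
    return (_adjoint_constant(freq, amplitude) * weight) * (lo.E_nodes * hi.E_nodes)


def jacobian_row_general(
    Es: FieldSolution,
    Er: FieldSolution,
    zone: ImagingZone,
    freq: FrequencySpec,
    amplitude: float = 1.0,
) -> np.ndarray:
    """One row by the general dual-mesh quadrature (verification path).

    Performs the explicit double summation over parameter nodes and their
    incident elements with vertex quadrature of the interpolatory nodal
    basis (value 1 at its own node, 0 at the others): each in-zone cell of
    area A_e contributes (A_e / M) phi_tau(p_n) Es(p_n) Er(p_n) for each of
    its M vertices n.  On the overlapping grid this reproduces the
    collapsed row to machine precision.
    """
    if len(Es.E_nodes) != zone.n_nodes or len(Er.E_nodes) != zone.n_nodes:
        raise ValueError("field solutions do not match the imaging zone")
    h2 = zone.grid.h**2
    prod = Es.E_nodes * Er.E_nodes
    row = np.zeros(zone.n_nodes, dtype=complex)
    verts = zone.cell_vertex_positions()
    for cell_vs in verts:
        for n in cell_vs:
            # phi_tau(p_n) = delta_{tau n}: only tau = n survives
            row[n] += (h2 / zone.M) * prod[n]
    return _adjoint_constant(freq, amplitude) * row


def jacobian_matrix(
    fields: list[FieldSolution],
    zone: ImagingZone,
    array: AntennaArray,
    freq: FrequencySpec,
) -> JacobianMatrix:
    """Assemble all rows from the per-antenna field solutions.

    ``fields`` must hold one solution per antenna (the same ns solves used
    for the measurement residual); no forward solve happens here.
    """
    if len(fields) != array.n_antennas:
        raise ValueError("need one field solution per antenna")
    pairs = measurement_pairs(array.n_antennas)
    entries = np.empty((len(pairs), zone.n_nodes), dtype=complex)
    for k, (s, r) in enumerate(pairs):
        entries[k] = jacobian_row_collapsed(
            fields[s], fields[r], zone, freq, array.amplitude
        )
    return JacobianMatrix(entries, pairs, "complex-field")


def log_transform_jacobian(
    J: JacobianMatrix, received: np.ndarray
) -> JacobianMatrix:
    """Convert complex-field rows to log-magnitude/phase rows.

    Dividing row (s, r) by the received field E(s, r) applies the chain
    rule for the complex logarithm: the real part becomes d ln|E| / dk^2
    and the imaginary part the phase sensitivity.  Rows with a vanishing
    received field are degenerate nulls and rejected.
    """
    received = np.asarray(received)
    if len(received) != len(J.entries):
        raise ValueError("need one received field value per Jacobian row")
    dead = np.flatnonzero(received == 0)
    if len(dead):
        s, r = J.pairs[dead[0]]
        raise ValueError(
            f"zero received field for pair ({s}, {r}); cannot log-transform"
        )
    return JacobianMatrix(J.entries / received[:, None], J.pairs.copy(), "log-transformed")


def finite_difference_jacobian_column(
    pmap: PropertyMap,
    zone: ImagingZone,
    array: AntennaArray,
    freq: FrequencySpec,
    tau,
    delta: float,
    log_domain: bool = False,
) -> np.ndarray:
    """Central-difference column of the Jacobian: two full forward sweeps.

    ``tau`` is either a position in the unknown ordering or a grid node
    ``(i, j)`` (which must belong to the zone).  With ``log_domain`` the
    difference is taken on the log-magnitude/unwrapped-phase measurements.
    This is the independent oracle for the adjoint rows; it is O(ns) solves
    per column versus zero for the collapsed formula.
    """
    if np.ndim(tau) == 0:
        t = int(tau)
        if not 0 <= t < zone.n_nodes:
            raise ValueError(f"node position {t} outside the imaging zone")
    else:
        t = zone.node_position(tau)
    solver = DDASolver(zone, array, freq, pmap.k2_background)

    def measure(k2_t: complex) -> np.ndarray:
        k2 = pmap.k2_nodes.copy()
        k2[t] = k2_t
        _, mset = solver.sweep(PropertyMap(zone, k2, pmap.k2_background))
        if log_domain:
            from .reconstruct import log_measurements

            return log_measurements(mset)
        return mset.values

    mp = measure(pmap.k2_nodes[t] + delta)
    mm = measure(pmap.k2_nodes[t] - delta)
    return (mp - mm) / (2.0 * delta)
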