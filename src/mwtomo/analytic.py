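"""Analytic reference solution: line-source scattering by a dielectric cylinder.

Independent oracle for the volume-integral solver: the total field of a 2D
line current in a (possibly lossy) homogeneous background in the presence
of a homogeneous circular cylinder, by the classical cylindrical-harmonic
series.  Under the e^{+jwt} convention the incident field is expanded with
the addition theorem

    H0^(2)(k_b |r - r_s|) = sum_n J_n(k_b rho<) H_n^(2)(k_b rho>) e^{j n (phi - phi_s)}

and mode coefficients follow from continuity of E and dE/drho at the
cylinder surface (TM polarization, non-magnetic media).
"""

from __future__ import annotations

import numpy as np
from scipy.constants import mu_0
from scipy.special import h2vp, hankel2, jv, jvp

__all__ = ["cylinder_line_source_field"]


def cylinder_line_source_field(
    k_b: complex,
    k_cyl: complex,
    radius: float,
    center,
    source_pos,
    obs_points,
    omega: float,
    amplitude: float = 1.0,
    n_terms: int | None = None,
) -> np.ndarray:
    """Total field at exterior observation points.

    Parameters
    ----------
    k_b, k_cyl : complex
        Background and cylinder wavenumbers (Im <= 0 branch).
    radius : float
        Cylinder radius (m); source and observation points must be outside.
    center, source_pos : array-like
        Cylinder center and line-source position (m).
    obs_points : (m, 2) array-like
        Exterior observation points.
    omega : float
        Angular frequency (rad/s).
    amplitude : float
        Line-current amplitude |J|.
    n_terms : int, optional
        Series truncation order; defaults to ``|k_b| radius + 20``.
    """
    center = np.asarray(center, dtype=float)
    src = np.asarray(source_pos, dtype=float) - center
    obs = np.atleast_2d(np.asarray(obs_points, dtype=float)) - center
    rho_s, phi_s = np.hypot(*src), np.arctan2(src[1], src[0])
    rho, phi = np.hypot(obs[:, 0], obs[:, 1]), np.arctan2(obs[:, 1], obs[:, 0])
    if rho_s <= radius or np.any(rho <= radius):
        raise ValueError("source and observation points must lie outside the cylinder")

    if n_terms is None:
        n_terms = int(np.ceil(abs(k_b) * radius)) + 20
    pref = -(omega * mu_0 * amplitude / 4.0)

    total = pref * hankel2(0, k_b * np.hypot(obs[:, 0] - src[0], obs[:, 1] - src[1]))
    xb, xc = k_b * radius, k_cyl * radius
    for n in range(-n_terms, n_terms + 1):
        c_n = pref * hankel2(n, k_b * rho_s)  # incident mode coefficient
        # continuity of E and dE/drho at rho = radius
        den = hankel2(n, xb) * k_cyl * jvp(n, xc) - k_b * h2vp(n, xb) * jv(n, xc)
        a_n = c_n * (k_b * jvp(n, xb) * jv(n, xc) - jv(n, xb) * k_cyl * jvp(n, xc)) / den
        total = total + a_n * hankel2(n, k_b * rho) * np.exp(1j * n * (phi - phi_s))
    return total
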