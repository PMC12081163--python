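"""Mie scattering for homogeneous spheres (real refractive indices).

Implements the standard Lorenz-Mie series with the logarithmic-derivative
downward recurrence (Bohren & Huffman) for the expansion coefficients
``a_n, b_n``, and the usual efficiency sums for Qext, Qsca and the
asymmetry parameter g.  Absorption is neglected (real indices), which is
appropriate for polystyrene microspheres in water at visible wavelengths.
"""

from __future__ import annotations

import numpy as np

__all__ = ["mie_ab", "mie_efficiencies", "rayleigh_qsca"]


def mie_ab(m: float, x: float) -> tuple[np.ndarray, np.ndarray]:
    """Mie coefficients a_n, b_n for relative index ``m`` and size parameter ``x``.

    The series is truncated at the Wiscombe order ``x + 4.05 x^{1/3} + 2``.
    """
    if x <= 0:
        raise ValueError(f"size parameter must be positive, got {x}")
    nmax = int(np.ceil(x + 4.05 * x ** (1 / 3) + 2))
    nmx = max(nmax, int(np.ceil(abs(m * x)))) + 16
    # logarithmic derivative D_n(mx) by downward recurrence
    D = np.zeros(nmx + 1, dtype=complex)
    mx = m * x
    for n in range(nmx, 0, -1):
        D[n - 1] = n / mx - 1.0 / (D[n] + n / mx)
    a = np.zeros(nmax, dtype=complex)
    b = np.zeros(nmax, dtype=complex)
    # Riccati-Bessel psi_n(x), chi_n(x) by upward recurrence
    psi_prev, psi = np.cos(x), np.sin(x)
    chi_prev, chi = -np.sin(x), np.cos(x)
    for n in range(1, nmax + 1):
        psi_n = (2 * n - 1) / x * psi - psi_prev
        chi_n = (2 * n - 1) / x * chi - chi_prev
        zeta_n = psi_n - 1j * chi_n
        zeta_prev = psi - 1j * chi
        dn = D[n]
        a[n - 1] = ((dn / m + n / x) * psi_n - psi) / ((dn / m + n / x) * zeta_n - zeta_prev)
        b[n - 1] = ((dn * m + n / x) * psi_n - psi) / ((dn * m + n / x) * zeta_n - zeta_prev)
        psi_prev, psi = psi, psi_n
        chi_prev, chi = chi, chi_n
    return a, b


def mie_efficiencies(m: float, x: float) -> dict:
    """Qext, Qsca and asymmetry parameter g for a single sphere."""
    a, b = mie_ab(m, x)
    n = np.arange(1, len(a) + 1, dtype=float)
    qext = 2.0 / x**2 * np.sum((2 * n + 1) * np.real(a + b))
    qsca = 2.0 / x**2 * np.sum((2 * n + 1) * (np.abs(a) ** 2 + np.abs(b) ** 2))
    t1 = np.sum(
        n[:-1] * (n[:-1] + 2) / (n[:-1] + 1)
        * np.real(a[:-1] * np.conj(a[1:]) + b[:-1] * np.conj(b[1:]))
    )
    t2 = np.sum((2 * n + 1) / (n * (n + 1)) * np.real(a * np.conj(b)))
    g = 4.0 / (x**2 * qsca) * (t1 + t2)
    return {"Qext": float(qext), "Qsca": float(qsca), "g": float(g)}


def rayleigh_qsca(m: float, x: float) -> float:
    """Rayleigh-limit scattering efficiency (valid for x << 1)."""
    return float(8.0 / 3.0 * x**4 * abs((m**2 - 1) / (m**2 + 2)) ** 2)
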