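"""Independent oracles used by the test suite.

These implementations deliberately share no code with the package: the
cylinder heating oracle is the classical eigenfunction (Bessel) series for
convective heating of an infinite cylinder, and the kinetics oracles are
closed-form constant-temperature solutions.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq
from scipy.special import j0, j1

R_GAS = 8.314


def bessel_eigenvalues(biot: float, n_terms: int) -> np.ndarray:
    """Positive roots of lam*J1(lam) = Bi*J0(lam)."""
    f = lambda lam: lam * j1(lam) - biot * j0(lam)
    roots = []
    x, step = 1e-9, 0.05
    while len(roots) < n_terms:
        if f(x) * f(x + step) < 0:
            roots.append(brentq(f, x, x + step))
        x += step
    return np.array(roots)


def cylinder_average_theta(fourier: np.ndarray, biot: float, n_terms: int = 120) -> np.ndarray:
    """Volume-averaged (T-Te)/(T0-Te) of a convectively heated cylinder.

    theta_bar = sum_n 4 Bi^2 / (lam_n^2 (lam_n^2 + Bi^2)) exp(-lam_n^2 Fo).
    """
    lam = bessel_eigenvalues(biot, n_terms)
    coeff = 4.0 * biot**2 / (lam**2 * (lam**2 + biot**2))
    return (coeff[None, :] * np.exp(-np.outer(fourier, lam**2))).sum(axis=1)


def arrhenius(k_ref: float, t_ref: float, ea: float, temp_k: float) -> float:
    return k_ref * np.exp(-(ea / R_GAS) * (1.0 / temp_k - 1.0 / t_ref))


def monophasic_isothermal(k: float, t: np.ndarray) -> np.ndarray:
    return np.exp(-k * np.asarray(t, float))


def biphasic_isothermal(frac: float, k1: float, k2: float, t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, float)
    return frac * np.exp(-k1 * t) + (1.0 - frac) * np.exp(-k2 * t)


def pectin_isothermal(kb: float, km: float, kd: float, dm0: float, t: np.ndarray):
    """Closed-form pools at constant temperature.

    PME = e^{-kd t};  Pm = dm0 * exp(-kb t - km/kd (1 - e^{-kd t}))
    (limit km*t as kd -> 0);  Pe, Psol by quadrature-free integration is not
    closed form, so only Pm and PME are returned here.
    """
    t = np.asarray(t, float)
    pme = np.exp(-kd * t)
    if kd > 0:
        demeth = (km / kd) * (1.0 - np.exp(-kd * t))
    else:
        demeth = km * t
    pm = dm0 * np.exp(-kb * t - demeth)
    return pm, pme
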