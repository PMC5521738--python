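"""Hartley-modulating-function (HMF) spectra of piecewise-linear profiles.

The HMF method converts the identification of a linear ODE
dE/dt = K E into a linear regression in the frequency domain.  Multiplying
the ODE by modulating functions phi_m that vanish at both ends of the
record and integrating by parts removes the need to differentiate the
data: every required inner product reduces to Hartley transforms

    H(omega) = int_0^T E(t) cas(omega t) dt,      cas(x) = sin(x) + cos(x),

of the piecewise-linear interpolant of the sampled profile, which have an
exact closed form per segment.

Conventions
-----------
* All time arguments are relative to the start of the record, so the
  record spans [0, T] with fundamental frequency omega0 = 2*pi/T.
* System order is n = 1 throughout (first-order kinetics).
* The frequency index n + m - j vanishes for (m = -1, j = 0) and
  (m = 0, j = 1).  The analytic Hartley integral is zero there, which
  degrades the regression, so the index is replaced by a small eps
  (default 1e-6) in all spectral computations.
* The derivative spectrum follows the Hartley derivative theorem; the
  overall sign convention is fixed by the constant
  :data:`DERIV_SIGN` = cas'(pi/2) = -1, calibrated once against the
  unambiguous time-domain definition (see
  :func:`derivative_spectrum_oracle`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.special import comb

#: Sign fixed by the derivative theorem: d/dx cas(x) evaluated at pi/2.
DERIV_SIGN = -1.0

#: Replacement for a vanishing frequency index n + m - j.
DEFAULT_EPS_FREQ = 1e-6


def cas(x):
    """Hartley kernel cas(x) = sin(x) + cos(x)."""
    return np.sin(x) + np.cos(x)


def cas_deriv(x):
    """d/dx cas(x) = cos(x) - sin(x) = cas(-x)."""
    return np.cos(x) - np.sin(x)


@dataclass(frozen=True)
class ModulatingFunctionSpec:
    """Parameters defining the modulating-function family.

    Parameters
    ----------
    T:
        Record length in weeks (last minus first sample age).
    n:
        Order of the highest derivative in the identified system (1 for
        first-order kinetics; higher orders are out of scope).
    eps_freq:
        Replacement value for a vanishing frequency index.
    """

    T: float
    n: int = 1
    eps_freq: float = DEFAULT_EPS_FREQ

    @property
    def omega0(self) -> float:
        """Fundamental frequency 2*pi/T (rad/week)."""
        return 2.0 * np.pi / self.T

    def freq_index(self, m: int, j: int, degenerate_eps: bool = True) -> float:
        """Frequency index n + m - j, optionally eps-substituted when zero."""
        q = self.n + m - j
        if q == 0 and degenerate_eps:
            return self.eps_freq
        return float(q)


def modulating_function(
    spec: ModulatingFunctionSpec, m: int, t, degenerate_eps: bool = False
):
    """Evaluate phi_m(t) = sum_j (-1)^j C(n,j) cas((n+m-j) omega0 t).

    With integer frequency indices phi_m vanishes exactly at t = 0 and
    t = T for every integer m.  ``degenerate_eps=True`` applies the same
    eps substitution as the spectral computations, which perturbs the
    endpoint value at t = T by O(eps) for m in {-1, 0}; it is used when a
    time-domain integral must mirror the frequency-domain convention.
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    for j in range(spec.n + 1):
        q = spec.freq_index(m, j, degenerate_eps)
        out = out + (-1.0) ** j * comb(spec.n, j) * cas(q * spec.omega0 * t)
    return out


def modulating_function_deriv(
    spec: ModulatingFunctionSpec, m: int, t, degenerate_eps: bool = True
):
    """Evaluate d/dt phi_m(t) by term-wise differentiation."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    for j in range(spec.n + 1):
        q = spec.freq_index(m, j, degenerate_eps)
        w = q * spec.omega0
        out = out + (-1.0) ** j * comb(spec.n, j) * w * cas_deriv(w * t)
    return out


def _check_profile(times: np.ndarray, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.ndim != 1 or times.size < 2:
        raise ValueError("profile needs at least two time points")
    if values.shape != times.shape:
        raise ValueError("times and values must have matching shape")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    return times, values


def hartley_transform(times, values, omega: float) -> float:
    """Hartley transform of the piecewise-linear interpolant of a profile.

    Evaluates ``int_{t_first}^{t_last} E(t) cas(omega t) dt`` exactly,
    segment by segment, using the closed-form antiderivatives of
    ``(a t + b) cas(omega t)``.  ``times`` are relative to the record
    start (first entry 0 for a complete profile).  ``omega = 0`` falls
    back to the plain trapezoid area of the interpolant (cas(0) = 1).
    """
    times, values = _check_profile(times, values)
    if omega == 0.0:
        return float(np.trapezoid(values, times))
    w = float(omega)
    t1 = times[:-1]
    t2 = times[1:]
    slope = np.diff(values) / np.diff(times)
    intercept = values[:-1] - slope * t1

    if abs(w) * float(times[-1]) < 1e-2:
        # The closed form divides by w and w^2, which loses ~|wT|^-2 digits
        # of precision for the eps-substituted frequencies; a short Taylor
        # expansion of cas(wt) = sum_k c_k (wt)^k is exact to machine
        # precision in this regime.
        cas_coeff = [1.0, 1.0, -0.5, -1.0 / 6, 1.0 / 24, 1.0 / 120, -1.0 / 720, -1.0 / 5040]
        total = 0.0
        for k, c in enumerate(cas_coeff):
            # int (a t + b) t^k dt over each segment
            seg = slope * (t2 ** (k + 2) - t1 ** (k + 2)) / (k + 2) + intercept * (
                t2 ** (k + 1) - t1 ** (k + 1)
            ) / (k + 1)
            total += c * w**k * float(np.sum(seg))
        return total

    def antideriv_const(t):
        # int cas(w t) dt
        return (np.sin(w * t) - np.cos(w * t)) / w

    def antideriv_linear(t):
        # int t cas(w t) dt
        return t * (np.sin(w * t) - np.cos(w * t)) / w + cas(w * t) / w**2

    seg = slope * (antideriv_linear(t2) - antideriv_linear(t1)) + intercept * (
        antideriv_const(t2) - antideriv_const(t1)
    )
    return float(np.sum(seg))


def hmf_spectrum(times, values, m: int, spec: ModulatingFunctionSpec) -> float:
    """m-th HMF spectral component Hbar(m omega0) of a profile.

    Hbar(m omega0) = sum_j (-1)^j C(n,j) H((n+m-j) omega0), with the
    degenerate frequency index replaced by eps.  Equivalent to the
    time-domain inner product int_0^T phi_m(t) E(t) dt.
    """
    total = 0.0
    for j in range(spec.n + 1):
        q = spec.freq_index(m, j)
        total += (-1.0) ** j * comb(spec.n, j) * hartley_transform(
            times, values, q * spec.omega0
        )
    return float(total)


def hmf_derivative_spectrum(
    times, values, m: int, spec: ModulatingFunctionSpec, i: int = 1
) -> float:
    """HMF spectrum Hbar^1(m omega0) of the first derivative of a profile.

    By the Hartley derivative theorem (for a record with phi_m vanishing
    at both endpoints) the spectrum of dE/dt is obtained without
    differencing the data:

        Hbar^1(m omega0)
            = sum_j (-1)^j C(n,j) * DERIV_SIGN * (q_j omega0)^i
              * H((-1)^i q_j omega0),   q_j = n + m - j (eps-substituted).

    Only first-order systems (i = 1) are supported.
    """
    if i != 1:
        raise NotImplementedError("only first-order systems (i = 1) are supported")
    total = 0.0
    for j in range(spec.n + 1):
        q = spec.freq_index(m, j)
        w = q * spec.omega0
        total += (
            (-1.0) ** j
            * comb(spec.n, j)
            * DERIV_SIGN
            * w
            * hartley_transform(times, values, -w)
        )
    return float(total)


def derivative_spectrum_oracle(
    times, values, m: int, spec: ModulatingFunctionSpec
) -> float:
    """Independent time-domain reference for :func:`hmf_derivative_spectrum`.

    Computes -int phi'_m(t) E(t) dt by adaptive quadrature on each linear
    segment of the interpolant; this equals int phi_m dE/dt dt because
    phi_m vanishes at the record endpoints.  The eps substitution is
    applied inside phi'_m so both routes share one convention.
    """
    times, values = _check_profile(times, values)

    def integrand(t, a, b):
        return modulating_function_deriv(spec, m, t) * (a * t + b)

    total = 0.0
    for k in range(times.size - 1):
        t1, t2 = times[k], times[k + 1]
        a = (values[k + 1] - values[k]) / (t2 - t1)
        b = values[k] - a * t1
        val, _ = quad(integrand, t1, t2, args=(a, b), epsabs=1e-12, epsrel=1e-12, limit=200)
        total += val
    return float(-total)


def spectra_matrix(
    profiles: list[tuple[np.ndarray, np.ndarray]],
    m_set: list[int],
    spec: ModulatingFunctionSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """Hbar and Hbar^1 for several profiles over a whole m-set.

    Returns two arrays of shape (len(m_set), n_profiles): entry (r, c) is
    the spectrum of profile c at m_set[r].
    """
    H = np.empty((len(m_set), len(profiles)))
    H1 = np.empty_like(H)
    for c, (times, values) in enumerate(profiles):
        for r, m in enumerate(m_set):
            H[r, c] = hmf_spectrum(times, values, m, spec)
            H1[r, c] = hmf_derivative_spectrum(times, values, m, spec)
    return H, H1
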