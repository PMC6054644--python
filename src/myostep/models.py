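"""Load- and substrate-dependence models for processive motor data.

This module collects the closed-form models fitted to per-force and
per-[ATP] statistics of a processive motor:

* **Bell-type exponentials** for the force dependence of run length,
  detachment rate, forward/backward step-count ratio and stepping rates,
  ``y(F) = y0 * exp(s * |F| * d / kBT)`` with ``s = -1`` (decay) or
  ``+1`` (growth).  ``d`` is the distance parameter (nm) quantifying force
  sensitivity; assistive and resistive branches carry independent
  parameters.
* **Michaelis-Menten** saturation curves for velocity or ATPase rate
  versus substrate concentration.
* The **stall force** implied by a fitted forward/backward step-ratio
  model, i.e. the force at which the ratio equals one.
* The **finite-oscillation-window correction** for run lengths measured
  under assistive load in an ultrafast force-clamp dumbbell assay.  With
  an exponential true run length of mean ``L`` and a uniform attachment
  position inside an oscillation window of width ``D``, the measured run
  is censored at the window edge; the measured-run-length density,
  expectation and its numerical inversion are provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import optimize

#: Thermal energy at T = 298 K, in pN nm.
KBT_ROOM = 4.114

__all__ = [
    "KBT_ROOM",
    "BellFit",
    "MMFit",
    "bell_predict",
    "fit_bell",
    "stall_force",
    "michaelis_menten",
    "fit_michaelis_menten",
    "truncated_survival",
    "truncated_pdf",
    "expected_measured_runlength",
    "correct_run_length",
    "corrected_run_length_error",
]


# ---------------------------------------------------------------------------
# Bell-type exponential force dependence
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BellFit:
    """Fitted exponential force-dependence model.

    ``predict(F) = amplitude0 * exp(s * |F| * distance / kBT)`` with
    ``s = -1`` for ``sign == "decay"`` and ``+1`` for ``"growth"``.

    Attributes
    ----------
    amplitude0:
        Extrapolated value at zero force (nm for run length, 1/s for
        rates, dimensionless for step-count ratios).
    distance:
        Distance parameter in nm; larger means more force sensitive.
    branch:
        Which force branch the fit describes, ``"assistive"`` (F < 0) or
        ``"resistive"`` (F > 0).
    """

    amplitude0: float
    distance: float
    amplitude0_se: float
    distance_se: float
    sign: Literal["decay", "growth"]
    branch: Literal["assistive", "resistive"]
    kBT: float = KBT_ROOM
    covariance: np.ndarray | None = field(default=None, repr=False, compare=False)

    def predict(self, force):
        return bell_predict(force, self)


def _bell_sign(sign: str) -> float:
    if sign == "decay":
        return -1.0
    if sign == "growth":
        return +1.0
    raise ValueError(f"sign must be 'decay' or 'growth', got {sign!r}")


def _check_branch(force, branch: str) -> np.ndarray:
    f = np.atleast_1d(np.asarray(force, dtype=float))
    if branch == "resistive" and np.any(f < 0):
        raise ValueError("resistive-branch model evaluated at negative (assistive) force")
    if branch == "assistive" and np.any(f > 0):
        raise ValueError("assistive-branch model evaluated at positive (resistive) force")
    return np.abs(f)


def bell_predict(force, fit: BellFit):
    """Evaluate a Bell model at signed force(s); branch must match."""
    mag = _check_branch(force, fit.branch)
    s = _bell_sign(fit.sign)
    out = fit.amplitude0 * np.exp(s * mag * fit.distance / fit.kBT)
    return float(out[0]) if np.isscalar(force) else out


def fit_bell(
    force,
    y,
    sem=None,
    *,
    sign: Literal["decay", "growth"] = "decay",
    branch: Literal["assistive", "resistive"] = "resistive",
    kBT: float = KBT_ROOM,
    method: Literal["nls", "loglinear"] = "nls",
) -> BellFit:
    """Fit ``y = A * exp(s*|F|*d/kBT)`` to per-force values.

    Parameters
    ----------
    force, y:
        Signed forces (one branch only) and the measured quantity.
    sem:
        Optional standard errors used as weights.
    method:
        ``"nls"`` (default): weighted nonlinear least squares on the
        natural scale.  ``"loglinear"``: weighted linear regression on
        ``log y`` with delta-method errors, available as a cross-check.

    Non-positive ``y`` values are excluded with a warning (the model is
    strictly positive).  At least three distinct force levels required.
    """
    mag = _check_branch(force, branch)
    y = np.asarray(y, dtype=float)
    w = None if sem is None else np.asarray(sem, dtype=float)
    keep = np.isfinite(y) & (y > 0)
    if not np.all(keep):
        warnings.warn("excluding non-positive/non-finite y values from Bell fit")
        mag, y = mag[keep], y[keep]
        if w is not None:
            w = w[keep]
    if len(np.unique(mag)) < 3:
        raise ValueError("Bell fit needs at least 3 distinct force levels")

    s = _bell_sign(sign)
    # log-linear starting point (always computed; also the 'loglinear' result)
    logy = np.log(y)
    lw = None if w is None else np.maximum(w / y, 1e-12)  # delta method on log scale
    W = np.ones_like(y) if lw is None else 1.0 / lw**2
    X = np.vstack([np.ones_like(mag), s * mag / kBT]).T
    WX = X * W[:, None]
    beta, *_ = np.linalg.lstsq(WX.T @ X, WX.T @ logy, rcond=None)
    a0, d0 = float(np.exp(beta[0])), float(max(beta[1], 0.0))

    if method == "loglinear":
        resid = logy - X @ beta
        dof = max(len(y) - 2, 1)
        s2 = float(resid @ (W * resid)) / dof
        cov = s2 * np.linalg.inv(WX.T @ X)
        a_se = a0 * float(np.sqrt(cov[0, 0]))
        d_se = float(np.sqrt(cov[1, 1]))
        return BellFit(a0, d0, a_se, d_se, sign, branch, kBT, cov)

    def model(f, a, d):
        return a * np.exp(s * f * d / kBT)

    try:
        popt, pcov = optimize.curve_fit(
            model, mag, y, p0=[a0, max(d0, 1e-3)], sigma=w,
            absolute_sigma=False, maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"Bell fit did not converge: {exc}") from exc
    perr = np.sqrt(np.diag(pcov))
    return BellFit(float(popt[0]), float(popt[1]), float(perr[0]), float(perr[1]),
                   sign, branch, kBT, pcov)


def stall_force(R0: float, d: float, kBT: float = KBT_ROOM) -> float:
    """Force at which the fitted step-count ratio model equals one.

    For ``R(F) = R0 * exp(-F*d/kBT)`` the stall force is
    ``F* = (kBT/d) * ln(R0)``; it only exists for ``R0 > 1`` (forward
    stepping dominates at zero load) and ``d > 0``.
    """
    if d <= 0:
        raise ValueError("distance parameter must be positive")
    if R0 <= 1:
        raise ValueError("R0 <= 1: ratio model never crosses one at positive force")
    return kBT / d * float(np.log(R0))


# ---------------------------------------------------------------------------
# Michaelis-Menten
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MMFit:
    """Michaelis-Menten fit: ``v(S) = vmax * S / (Kapp + S)``.

    ``vmax`` is the saturating velocity (nm/s) or turnover rate (1/s);
    ``Kapp`` the substrate concentration (µM) at half saturation.
    """

    vmax: float
    Kapp: float
    vmax_se: float
    Kapp_se: float
    covariance: np.ndarray | None = field(default=None, repr=False, compare=False)

    def predict(self, substrate):
        return michaelis_menten(np.asarray(substrate, dtype=float), self.vmax, self.Kapp)


def michaelis_menten(substrate, vmax, Kapp):
    s = np.asarray(substrate, dtype=float)
    return vmax * s / (Kapp + s)


def fit_michaelis_menten(substrate, rate, sem=None) -> MMFit:
    """Least-squares Michaelis-Menten fit to (substrate, rate) samples.

    Requires at least three distinct substrate levels; raises on
    non-convergence with diagnostics.
    """
    s = np.asarray(substrate, dtype=float)
    v = np.asarray(rate, dtype=float)
    if len(np.unique(s)) < 3:
        raise ValueError("Michaelis-Menten fit needs >= 3 distinct substrate levels")
    vmax0 = float(np.max(v)) * 1.1
    k0 = float(np.median(s))
    try:
        popt, pcov = optimize.curve_fit(
            michaelis_menten, s, v, p0=[vmax0, max(k0, 1e-6)],
            sigma=None if sem is None else np.asarray(sem, dtype=float),
            absolute_sigma=False, maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(
            f"Michaelis-Menten fit did not converge (p0={[vmax0, k0]}, "
            f"n={len(v)}): {exc}") from exc
    perr = np.sqrt(np.diag(pcov))
    return MMFit(float(popt[0]), float(popt[1]), float(perr[0]), float(perr[1]), pcov)


# ---------------------------------------------------------------------------
# Finite-oscillation-window (truncated exponential) run-length correction
# ---------------------------------------------------------------------------

def _check_LD(L: float, D: float) -> None:
    if L <= 0 or D <= 0:
        raise ValueError("L and D must be positive")


def truncated_survival(x, L: float, D: float):
    """P(measured run > x) under window censoring.

    Product of the exponential run-length survival ``exp(-x/L)`` and the
    uniform-attachment survival ``1 - x/D`` on [0, D]; zero beyond D.
    """
    _check_LD(L, D)
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr < 0):
        raise ValueError("x must be non-negative")
    out = np.where(x_arr <= D, np.exp(-x_arr / L) * (1.0 - x_arr / D), 0.0)
    return float(out) if np.isscalar(x) else out


def truncated_pdf(x, L: float, D: float):
    """Density of the measured (window-censored) run length on [0, D]."""
    _check_LD(L, D)
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr < 0):
        raise ValueError("x must be non-negative")
    out = np.where(
        x_arr <= D,
        np.exp(-x_arr / L) * (1.0 / L + 1.0 / D - x_arr / (D * L)),
        0.0,
    )
    return float(out) if np.isscalar(x) else out


def expected_measured_runlength(L: float, D: float) -> float:
    """Mean measured run length ``<Lm>`` for true mean L and window D.

    ``<Lm> = (1/D) * [L^2 (exp(-D/L) - 1) + L D]``; increases from 0 to
    D/2 as L grows, and tends to L as D -> infinity.
    """
    _check_LD(L, D)
    r = D / L
    if r < 1e-4:
        # series in r avoids catastrophic cancellation for L >> D
        return D / 2.0 - D * r / 6.0 + D * r * r / 24.0
    return (L * L * (np.exp(-r) - 1.0) + L * D) / D


def _dLm_dL(L: float, D: float) -> float:
    """Closed-form derivative of the expected measured run length in L."""
    r = D / L
    if r < 1e-4:
        return r * r / 6.0 - r**3 / 12.0
    e = np.exp(-r)
    return (2.0 * L * (e - 1.0) + D * e) / D + 1.0


def correct_run_length(Lm: float, D: float, tol: float = 1e-3) -> float:
    """Invert the window-censoring expectation: recover the true mean L.

    The expectation is strictly increasing in L with supremum D/2, so a
    measured mean ``Lm`` admits a unique solution iff ``0 < Lm < D/2``.
    Solved by bracketing + Brent's method to ``tol`` nm.
    """
    if D <= 0:
        raise ValueError("D must be positive")
    if not 0 < Lm < D / 2:
        raise ValueError(
            f"measured mean run length Lm={Lm:g} outside (0, D/2)={D / 2:g}: "
            "no finite true run length reproduces it (geometric ceiling of the "
            "oscillation window)")
    lo = Lm  # censoring can only shorten runs, so L >= Lm
    hi = max(2.0 * Lm, D)
    while expected_measured_runlength(hi, D) < Lm:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover - unreachable for Lm < D/2
            raise RuntimeError("failed to bracket run-length correction root")
    if expected_measured_runlength(lo, D) > Lm:
        lo = tol / 10.0
    root = optimize.brentq(
        lambda L: expected_measured_runlength(L, D) - Lm, lo, hi, xtol=tol)
    return float(root)


def corrected_run_length_error(Lm: float, sem_Lm: float, D: float) -> float:
    """Delta-method standard error of the corrected run length.

    ``se(L) = se(Lm) / (d<Lm>/dL)`` evaluated at the corrected L.
    """
    L = correct_run_length(Lm, D)
    return float(sem_Lm / _dLm_dL(L, D))
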