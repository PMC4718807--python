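"""Assay statistics: enzyme kinetics, one-site binding, spindle angles.

Michaelis–Menten initial rates and one-site saturation-binding curves are fit
by nonlinear least squares (Levenberg–Marquardt via scipy), with asymptotic
standard errors from the covariance of the fit. Spindle orientation is the
acute angle between two undirected 2-D axes, binned into a radial histogram
over [0°, 90°].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


class FitError(RuntimeError):
    pass


@dataclass(frozen=True)
class KineticsFit:
    """Michaelis–Menten parameters; kcat = Vmax/E0 for the enzyme amount used."""

    vmax: float
    km: float
    kcat: float
    se_vmax: float
    se_km: float
    rss: float
    e0: float
    valid: bool


def _mm(S: np.ndarray, vmax: float, km: float) -> np.ndarray:
    return vmax * S / (km + S)


def fit_michaelis_menten(data: pd.DataFrame, e0: float) -> KineticsFit:
    """Fit v = Vmax·S/(KM+S) to columns ``substrate``/``rate``.

    Initialization: Vmax at the largest observed rate, KM at the substrate
    level whose rate is closest to half of it.
    """
    if e0 <= 0:
        raise ValueError("enzyme concentration E0 must be positive")
    S = np.asarray(data["substrate"], dtype=float)
    v = np.asarray(data["rate"], dtype=float)
    if len(np.unique(S)) < 3:
        raise ValueError("need at least 3 distinct substrate levels")
    vmax0 = float(v.max())
    km0 = float(S[np.argmin(np.abs(v - vmax0 / 2.0))])
    km0 = max(km0, 1e-12)
    try:
        popt, pcov = curve_fit(_mm, S, v, p0=[vmax0, km0], maxfev=20000)
    except RuntimeError as exc:
        raise FitError(
            f"Michaelis–Menten fit did not converge (p0=Vmax {vmax0:g}, "
            f"KM {km0:g}, n={len(S)})"
        ) from exc
    vmax, km = map(float, popt)
    se = np.sqrt(np.diag(pcov))
    rss = float(np.sum((v - _mm(S, *popt)) ** 2))
    return KineticsFit(
        vmax=vmax,
        km=km,
        kcat=vmax / e0,
        se_vmax=float(se[0]),
        se_km=float(se[1]),
        rss=rss,
        e0=e0,
        valid=km > 0,
    )


@dataclass(frozen=True)
class BindingFit:
    kd: float
    r_free: float
    r_bound: float
    se_kd: float
    se_amplitude: float
    rss: float
    detectable: bool  # False when the amplitude CI spans zero


def _one_site(L: np.ndarray, r0: float, amp: float, kd: float) -> np.ndarray:
    return r0 + amp * L / (kd + L)


def fit_one_site_binding(data: pd.DataFrame, ci_z: float = 1.96) -> BindingFit:
    """Fit r(L) = r_free + (r_bound − r_free)·L/(Kd + L).

    The hyperbolic form assumes the labeled probe is at trace concentration
    (no ligand depletion). When the 95% confidence interval of the fitted
    amplitude contains zero the result is flagged as no detectable binding.
    """
    L = np.asarray(data["titrant"], dtype=float)
    r = np.asarray(data["anisotropy"], dtype=float)
    if len(np.unique(L)) < 4:
        raise ValueError("need at least 4 distinct titrant levels")
    order = np.argsort(L)
    r0_init = float(r[order[0]])
    amp_init = float(r[order[-1]] - r[order[0]])
    mid = r0_init + amp_init / 2.0
    kd_init = float(max(L[np.argmin(np.abs(r - mid))], np.min(L[L > 0], initial=1.0)))
    try:
        popt, pcov = curve_fit(
            _one_site, L, r, p0=[r0_init, amp_init or 1e-3, kd_init], maxfev=20000
        )
    except RuntimeError as exc:
        raise FitError("one-site binding fit did not converge") from exc
    r0, amp, kd = map(float, popt)
    se = np.sqrt(np.abs(np.diag(pcov)))
    rss = float(np.sum((r - _one_site(L, *popt)) ** 2))
    detectable = bool(
        np.isfinite(se[1]) and (abs(amp) - ci_z * se[1] > 0) and kd > 0
    )
    return BindingFit(
        kd=kd,
        r_free=r0,
        r_bound=r0 + amp,
        se_kd=float(se[2]),
        se_amplitude=float(se[1]),
        rss=rss,
        detectable=detectable,
    )


def spindle_angle(p1, p2, a1, a2) -> float:
    """Acute angle in degrees between the spindle axis (p1→p2) and a
    reference axis (a1→a2), both undirected 2-D segments.

    Invariant to endpoint order, translation, rotation and uniform scaling;
    always in [0°, 90°].
    """
    u = np.asarray(p2, dtype=float) - np.asarray(p1, dtype=float)
    v = np.asarray(a2, dtype=float) - np.asarray(a1, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("degenerate segment: identical endpoints")
    cosang = abs(float(np.dot(u, v))) / (nu * nv)
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def radial_histogram(angles, bin_width: float = 10.0) -> pd.DataFrame:
    """Counts of angles in half-open bins [0,10), …, last bin closed at 90°."""
    a = np.asarray(angles, dtype=float)
    bad = a[(a < 0) | (a > 90)]
    if bad.size:
        raise ValueError(f"angle out of [0, 90]: {bad[0]!r}")
    edges = np.arange(0.0, 90.0 + bin_width, bin_width)
    counts, _ = np.histogram(a, bins=edges)  # numpy closes the last bin
    return pd.DataFrame(
        {
            "bin_start": edges[:-1],
            "bin_end": edges[1:],
            "count": counts,
        }
    )
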