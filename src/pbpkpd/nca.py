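"""Non-compartmental analysis of a concentration-time profile.

Cmax/Tmax by direct maximum; AUC0-t by linear trapezoid (a log-down variant
is selectable); the terminal slope lambda_z by log-linear regression over the
last 3..6 positive concentrations, choosing the point count with the best
adjusted R^2; AUC0-inf = AUC0-t + Clast/lambda_z; MRT = AUMC0-inf/AUC0-inf
with the standard tail extrapolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, PreconditionError


@dataclass
class NCAResult:
    cmax: float
    tmax: float
    auc_0_t: float
    auc_0_inf: float | None
    mrt: float | None
    lambda_z: float | None
    n_points_lambda_z: int
    extrapolated_fraction: float | None

    @property
    def extrapolation_ok(self) -> bool:
        return self.lambda_z is not None


def _auc_linear(t, c):
    return float(np.trapezoid(c, t))


def _auc_linlog(t, c):
    """Linear up / log down trapezoid."""
    auc = 0.0
    for i in range(len(t) - 1):
        dt = t[i + 1] - t[i]
        c0, c1 = c[i], c[i + 1]
        if c1 < c0 and c1 > 0 and c0 > 0:
            auc += dt * (c0 - c1) / np.log(c0 / c1)
        else:
            auc += dt * (c0 + c1) / 2.0
    return float(auc)


def _lambda_z(t, c) -> tuple[float | None, int, float]:
    """Best adjusted-R^2 log-linear fit over the last 3..6 points after Tmax."""
    imax = int(np.argmax(c))
    mask = np.arange(len(t)) > imax
    mask &= c > 0
    tt, cc = t[mask], np.log(c[mask])
    best = (None, 0, -np.inf)
    for n in range(3, min(6, len(tt)) + 1):
        ts, cs = tt[-n:], cc[-n:]
        slope, intercept = np.polyfit(ts, cs, 1)
        if slope >= 0:
            continue
        resid = cs - (slope * ts + intercept)
        ss_tot = np.sum((cs - cs.mean()) ** 2)
        if ss_tot == 0:
            continue
        r2 = 1 - np.sum(resid**2) / ss_tot
        adj = 1 - (1 - r2) * (n - 1) / (n - 2)
        if adj > best[2]:
            best = (-float(slope), n, float(adj))
    return best[0], best[1], best[2]


def run_nca(times_h, conc_ng_ml, method: str = "linear") -> NCAResult:
    """Summarize a profile; extrapolated fields are None when no valid
    terminal phase exists (fewer than 3 decaying positive points)."""
    t = np.asarray(times_h, dtype=float)
    c = np.asarray(conc_ng_ml, dtype=float)
    if t.ndim != 1 or t.shape != c.shape:
        raise PreconditionError("times and concentrations must align")
    if np.any(np.diff(t) <= 0):
        raise PreconditionError("times must be strictly increasing")
    if np.any(c < 0):
        raise DomainError("negative concentrations")
    if np.count_nonzero(c > 0) < 3:
        raise PreconditionError("need >= 3 positive concentrations")

    imax = int(np.argmax(c))
    cmax, tmax = float(c[imax]), float(t[imax])
    auc_t = _auc_linear(t, c) if method == "linear" else _auc_linlog(t, c)

    lz, n_lz, _ = _lambda_z(t, c)
    if lz is None:
        return NCAResult(cmax, tmax, auc_t, None, None, None, 0, None)

    pos = np.nonzero(c > 0)[0]
    t_last, c_last = t[pos[-1]], c[pos[-1]]
    auc_inf = auc_t + c_last / lz
    aumc_t = _auc_linear(t, t * c)
    aumc_inf = aumc_t + c_last * t_last / lz + c_last / lz**2
    mrt = aumc_inf / auc_inf
    return NCAResult(
        cmax,
        tmax,
        auc_t,
        float(auc_inf),
        float(mrt),
        float(lz),
        n_lz,
        float((auc_inf - auc_t) / auc_inf),
    )
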