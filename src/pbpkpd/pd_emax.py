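"""Direct-link sigmoid Emax pharmacodynamics driven by brain concentration.

Effect model:  E = E0 + Emax * C^gamma / (EC50^gamma + C^gamma), with C the
brain tissue concentration (ng/mL) and no effect compartment (the compound's
brain equilibration is fast and no hysteresis was observed, so effect is an
instantaneous function of brain level).  The effect scale is whatever the
behavioral endpoint uses (here: time spent in the open arms of an elevated
plus-maze, on the scale where the vehicle baseline is 0.63); the model is
unit-agnostic and carries the baseline through ``e0``.

Fitting fixes E0 at the measured vehicle baseline and estimates Emax, EC50
and gamma by least squares on the untransformed effect scale (lmfit), with
R^2 / AIC reported for model selection and a non-identifiability flag when
the data do not bracket the half-maximal region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lmfit import Model

from .errors import DomainError, PreconditionError


@dataclass
class EmaxParams:
    e0: float
    emax: float
    ec50: float
    gamma: float

    def __post_init__(self):
        if self.ec50 <= 0:
            raise DomainError("ec50 must be > 0")
        if self.gamma <= 0:
            raise DomainError("gamma must be > 0")
        if self.emax < 0:
            raise DomainError("emax must be >= 0")


def effect_at(params: EmaxParams, conc) -> np.ndarray | float:
    """Effect at one or many concentrations (ng/mL)."""
    c = np.asarray(conc, dtype=float)
    if np.any(c < 0):
        raise DomainError("concentration must be >= 0")
    cg = np.power(c, params.gamma, where=c > 0, out=np.zeros_like(c, dtype=float))
    e = params.e0 + params.emax * cg / (params.ec50**params.gamma + cg)
    return float(e) if np.isscalar(conc) else e


@dataclass
class EmaxFitResult:
    params: EmaxParams
    stderr: dict
    r2: float
    aic: float
    n: int
    identifiable: bool
    message: str = ""


def _hill(c, emax, ec50, gamma, e0):
    cg = np.power(np.asarray(c, dtype=float), gamma)
    return e0 + emax * cg / (ec50**gamma + cg)


def fit_emax(
    conc,
    effect,
    fixed_e0: float,
    weights=None,
    ec50_init: float | None = None,
) -> EmaxFitResult:
    """Least-squares Hill fit with fixed baseline.

    Non-identifiable designs (concentrations that never approach EC50, or
    relative EC50 standard error > 100%) are flagged, never silently
    reported as successes.
    """
    c = np.asarray(conc, dtype=float)
    e = np.asarray(effect, dtype=float)
    if c.size < 4:
        raise PreconditionError("need >= 4 (conc, effect) observations")
    if np.any(c < 0):
        raise DomainError("concentrations must be >= 0")

    span = e.max() - fixed_e0
    model = Model(_hill, independent_vars=["c"])
    pars = model.make_params(
        emax=dict(value=max(span, 1e-6), min=0),
        ec50=dict(value=ec50_init or max(np.median(c[c > 0]), 1e-6), min=1e-9),
        gamma=dict(value=1.5, min=0.05, max=15),
        e0=dict(value=fixed_e0, vary=False),
    )
    fit = model.fit(e, pars, c=c, weights=weights)

    ss_tot = float(np.sum((e - e.mean()) ** 2))
    r2 = 1 - float(np.sum(fit.residual**2)) / ss_tot if ss_tot > 0 else 1.0
    p = fit.params
    est = EmaxParams(
        e0=fixed_e0,
        emax=float(p["emax"].value),
        ec50=float(p["ec50"].value),
        gamma=float(p["gamma"].value),
    )
    stderr = {
        k: (float(p[k].stderr) if p[k].stderr is not None else np.nan)
        for k in ("emax", "ec50", "gamma")
    }
    cmax = float(c.max())
    identifiable = True
    message = ""
    if cmax < est.ec50:
        identifiable = False
        message = "no observed concentration reaches the fitted EC50"
    elif not np.isfinite(stderr["ec50"]) or stderr["ec50"] > est.ec50:
        identifiable = False
        message = "EC50 uncertainty exceeds the estimate (flat design)"
    return EmaxFitResult(
        params=est,
        stderr=stderr,
        r2=r2,
        aic=float(fit.aic),
        n=int(c.size),
        identifiable=identifiable,
        message=message,
    )


@dataclass
class PDProfile:
    times: np.ndarray
    effect: np.ndarray
    driving_conc: np.ndarray


def pd_profile(params: EmaxParams, pbpk_result) -> PDProfile:
    """Pointwise (direct-link) effect over a simulated brain profile."""
    conc = np.asarray(pbpk_result.brain_conc, dtype=float)
    return PDProfile(
        times=np.asarray(pbpk_result.times, dtype=float),
        effect=effect_at(params, conc),
        driving_conc=conc,
    )
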