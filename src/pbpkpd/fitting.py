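"""Parameter sensitivity analysis (PSA) and least-squares model refinement.

The uncertain parameters of the oral PBPK chain -- the ASF coefficients
C1-C4, hepatic clearance, brain Kp, luminal solubility and the diffusion
coefficient -- are registered tunables.  ``psa_sweep`` varies one of them
over a log-spaced grid with everything else at baseline; ``fit_parameters``
refines any subset jointly against observed concentration datasets (e.g.
both rat dose levels simultaneously) by bounded least squares on
log-concentrations (data span more than an order of magnitude; a linear
scale is selectable).  Multi-start optimization is reproducible through a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import trapezoid
from scipy.optimize import least_squares

from .engine import PBPKModel, simulate
from .errors import PreconditionError, SpeciesLookupError
from .parameters import DoseRegimen, ObservedDataset

DEFAULT_SEED = 20171010
_CONC_FLOOR_NG_ML = 1e-9


def _set_c(model: PBPKModel, name: str, value: float) -> PBPKModel:
    from dataclasses import replace

    return model.replace(asf=replace(model.asf, **{name: value}))


TUNABLES = {
    "c1": _set_c,
    "c2": _set_c,
    "c3": _set_c,
    "c4": _set_c,
    "clhep": lambda m, n, v: m.replace(
        clearance=type(m.clearance)(clhep_ml_min_kg=v)
    ),
    "kp_brain": lambda m, n, v: m.replace(kpset=m.kpset.with_override("brain", v)),
    "solubility": lambda m, n, v: m.replace(
        compound=m.compound.model_copy(update={"solubility_mg_ml": v})
    ),
    "diffusion_coeff": lambda m, n, v: m.replace(
        compound=m.compound.model_copy(update={"diffusion_coeff_1e5_cm2_s": v})
    ),
}


def baseline_value(model: PBPKModel, name: str) -> float:
    if name in ("c1", "c2", "c3", "c4"):
        return getattr(model.asf, name)
    if name == "clhep":
        return model.clearance.clhep_ml_min_kg
    if name == "kp_brain":
        return model.kpset["brain"]
    if name == "solubility":
        return model.compound.solubility_mg_ml
    if name == "diffusion_coeff":
        return model.compound.diffusion_coeff_1e5_cm2_s
    raise SpeciesLookupError(f"unregistered tunable {name!r}")


def apply_params(model: PBPKModel, values: dict[str, float]) -> PBPKModel:
    for name, value in values.items():
        try:
            setter = TUNABLES[name]
        except KeyError:
            raise SpeciesLookupError(f"unregistered tunable {name!r}") from None
        model = setter(model, name, value)
    return model


@dataclass
class PSAResult:
    parameter: str
    values: np.ndarray
    metrics: pd.DataFrame  # columns: value, cmax, auc [, sse]
    baseline: float


def _profile_metrics(res) -> tuple[float, float]:
    return res.cmax_plasma, float(trapezoid(res.plasma_conc, res.times))


def psa_sweep(
    model: PBPKModel,
    regimen: DoseRegimen,
    param: str,
    lo: float,
    hi: float,
    n: int = 9,
    datasets: "list[tuple[DoseRegimen, ObservedDataset]] | None" = None,
    grid_dt_h: float = 0.05,
    rtol: float = 1e-8,
) -> PSAResult:
    """One-at-a-time sensitivity sweep, log-spaced over [lo, hi].

    The baseline value is always part of the sweep, so the baseline row
    reproduces the unperturbed simulation exactly.  When ``datasets`` are
    given an SSE-vs-observations column is added.
    """
    if not (0 < lo < hi):
        raise PreconditionError("need 0 < lo < hi for a log-spaced sweep")
    base = baseline_value(model, param)
    values = np.unique(np.concatenate([np.geomspace(lo, hi, n), [base]]))
    rows = []
    for v in values:
        m = apply_params(model, {param: v})
        res = simulate(m, regimen, grid_dt_h=grid_dt_h, rtol=rtol)
        cmax, auc = _profile_metrics(res)
        row = {"value": v, "cmax": cmax, "auc": auc}
        if datasets:
            row["sse"] = sum(
                _sse(m, reg, ds, scale="log", rtol=rtol) for reg, ds in datasets
            )
        rows.append(row)
    return PSAResult(param, values, pd.DataFrame(rows), base)


def _residuals_one(
    model: PBPKModel,
    regimen: DoseRegimen,
    dataset: ObservedDataset,
    scale: str,
    rtol: float,
) -> np.ndarray:
    res = simulate(model, regimen, rtol=rtol)
    out = []
    df = dataset.data[~dataset.data["censored"]]
    for matrix, sub in df.groupby("matrix"):
        sim = res.conc_at(sub["time_h"].to_numpy(), matrix=matrix)
        obs = sub["conc_ng_ml"].to_numpy()
        if scale == "log":
            out.append(
                np.log(np.maximum(sim, _CONC_FLOOR_NG_ML))
                - np.log(np.maximum(obs, _CONC_FLOOR_NG_ML))
            )
        else:
            out.append(sim - obs)
    return np.concatenate(out) if out else np.empty(0)


def _sse(model, regimen, dataset, scale, rtol) -> float:
    r = _residuals_one(model, regimen, dataset, scale, rtol)
    return float(np.sum(r**2))


@dataclass
class FitResult:
    params: dict[str, float]
    objective: float
    objective_initial: float
    converged: bool
    n_evaluations: int
    non_identifiable: list[str] = field(default_factory=list)
    predictions: pd.DataFrame | None = None
    message: str = ""


def fit_parameters(
    model: PBPKModel,
    datasets: "list[tuple[DoseRegimen, ObservedDataset]]",
    free: dict[str, tuple[float, float]],
    objective_scale: str = "log",
    n_starts: int = 5,
    seed: int = DEFAULT_SEED,
    rtol: float = 1e-6,
    check_identifiability: bool = True,
    x0: dict[str, float] | None = None,
) -> FitResult:
    """Joint bounded least squares over all datasets.

    ``free`` maps tunable names to (lo, hi) bounds; optimization runs in
    log10 parameter space (all tunables are positive).  ``n_starts - 1``
    extra starts are drawn log-uniformly within bounds from ``seed``.  A
    non-converged optimizer still returns the best point found, flagged.
    """
    if not free:
        raise PreconditionError("at least one free parameter is required")
    if not datasets:
        raise PreconditionError("at least one dataset is required")
    names = list(free)
    lo = np.log10([free[k][0] for k in names])
    hi = np.log10([free[k][1] for k in names])

    def unpack(x):
        return {k: 10.0**v for k, v in zip(names, x)}

    nfev = 0

    def resid(x):
        nonlocal nfev
        nfev += 1
        m = apply_params(model, unpack(x))
        return np.concatenate(
            [_residuals_one(m, reg, ds, objective_scale, rtol) for reg, ds in datasets]
        )

    if x0 is None:
        start0 = np.array(
            [np.clip(np.log10(baseline_value(model, k)), l, h)
             for k, l, h in zip(names, lo, hi)]
        )
    else:
        start0 = np.log10([x0[k] for k in names])
    rng = np.random.default_rng(seed)
    starts = [start0] + [
        lo + rng.random(len(names)) * (hi - lo) for _ in range(max(n_starts - 1, 0))
    ]

    obj0 = float(np.sum(resid(start0) ** 2))
    best = None
    converged = False
    for s in starts:
        # finite-difference step of ~1% in log10 space: large enough to see
        # through solver truncation noise, small enough for a good Jacobian
        sol = least_squares(
            resid, s, bounds=(lo, hi), method="trf",
            diff_step=5e-3, xtol=1e-5, ftol=1e-7, gtol=1e-8,
        )
        cost = 2 * sol.cost
        if best is None or cost < best[0]:
            best = (cost, sol.x)
            converged = bool(sol.status > 0)
    objective, x_best = best
    params = unpack(x_best)

    non_ident = []
    if check_identifiability:
        for i, (k, xk) in enumerate(zip(names, x_best)):
            # an estimate pinned to a bound is not informed by the data
            if min(xk - lo[i], hi[i] - xk) < 1e-3:
                non_ident.append(k)
                continue
            # flatness probe: halving/doubling the parameter leaves the
            # objective essentially unchanged
            span = []
            for f in (np.log10(0.5), np.log10(2.0)):
                x_try = x_best.copy()
                x_try[i] = np.clip(xk + f, lo[i], hi[i])
                span.append(float(np.sum(resid(x_try) ** 2)))
            ref = max(objective, 1e-12)
            if max(abs(s - objective) for s in span) / ref < 1e-3:
                non_ident.append(k)

    # predicted-vs-observed table at the optimum
    m_best = apply_params(model, params)
    pred_rows = []
    for reg, ds in datasets:
        res = simulate(m_best, reg, rtol=rtol)
        df = ds.data[~ds.data["censored"]]
        for matrix, sub in df.groupby("matrix"):
            sim = res.conc_at(sub["time_h"].to_numpy(), matrix=matrix)
            for t, o, s_ in zip(sub["time_h"], sub["conc_ng_ml"], sim):
                pred_rows.append(
                    {
                        "regimen": reg.label,
                        "matrix": matrix,
                        "time_h": t,
                        "observed": o,
                        "predicted": s_,
                    }
                )
    return FitResult(
        params=params,
        objective=float(objective),
        objective_initial=obj0,
        converged=converged,
        n_evaluations=nfev,
        non_identifiable=non_ident,
        predictions=pd.DataFrame(pred_rows),
        message="" if converged else "optimizer did not report convergence",
    )
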