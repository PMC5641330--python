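"""Synthetic datasets with known ground truth for every pipeline input.

The study this package reproduces deposited no raw data, so fitting and
recovery workflows are exercised on generated data: noisy plasma/brain
concentration profiles from a specified PBPK parameterization, microsomal
depletion curves, Caco-2 transport runs, and elevated-plus-maze (EPM) effect
observations from a specified Emax model.

Noise structure (documented assumptions, since the study reports only
mean +/- SD/SEM): concentrations carry proportional lognormal error (the
standard bioanalytical model); behavioral effects carry additive Gaussian
error.  Every generator is a pure function of its arguments and a mandatory
seed; concentrations below the assay quantification limit (0.5 ng/mL) are
censored with flags, never silently zeroed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .assays import TransportObservation
from .engine import PBPKModel, PBPKResult, simulate
from .errors import PreconditionError
from .parameters import DoseRegimen, ObservedDataset
from .pd_emax import EmaxParams, effect_at

LLOQ_NG_ML = 0.5


def gen_pk_dataset(
    model: PBPKModel,
    regimen: DoseRegimen,
    sampling_times_h,
    cv: float,
    seed: int,
    matrices=("plasma",),
    n_subjects: int = 1,
    lloq_ng_ml: float = LLOQ_NG_ML,
    group_mean: bool = False,
    result: PBPKResult | None = None,
    dose_label: float | None = None,
) -> ObservedDataset:
    """Noisy concentration-time dataset from a true model.

    Per-subject profiles are the true simulation multiplied by lognormal
    noise with coefficient of variation ``cv`` (sigma^2 = ln(1+cv^2), mean 1).
    ``group_mean=True`` emits the arithmetic group mean per time (the form the
    source figures publish); censoring applies before averaging is skipped in
    that case (means are reported uncensored).
    """
    times = np.asarray(sampling_times_h, dtype=float)
    if times.max() > regimen.horizon_h:
        raise PreconditionError("sampling times outside the simulation horizon")
    if cv < 0:
        raise PreconditionError("cv must be >= 0")
    rng = np.random.default_rng(seed)
    res = result if result is not None else simulate(model, regimen)
    sigma = np.sqrt(np.log1p(cv**2))
    dose = dose_label if dose_label is not None else sum(a for _, a in regimen.doses)
    rows = []
    for matrix in matrices:
        true = res.conc_at(times, matrix=matrix)
        for subj in range(n_subjects):
            noise = (
                rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=times.size)
                if cv > 0
                else np.ones(times.size)
            )
            obs = true * noise
            for t, c in zip(times, obs):
                rows.append(
                    {
                        "time_h": t,
                        "conc_ng_ml": c,
                        "matrix": matrix,
                        "dose": dose,
                        "species": model.physiology.species,
                        "subject": subj,
                        "censored": bool(c < lloq_ng_ml),
                    }
                )
    df = pd.DataFrame(rows)
    if group_mean:
        df = (
            df.groupby(["matrix", "time_h"], as_index=False)
            .agg(
                conc_ng_ml=("conc_ng_ml", "mean"),
                dose=("dose", "first"),
                species=("species", "first"),
            )
            .assign(censored=lambda d: d.conc_ng_ml < lloq_ng_ml)
        )
    return ObservedDataset(data=df, metadata=f"synthetic seed={seed} cv={cv}")


def gen_epm_dataset(
    params: EmaxParams,
    brain_result: PBPKResult,
    sampling_times_min,
    noise_sd: float,
    seed: int,
    group_size: int = 10,
) -> pd.DataFrame:
    """EPM effect observations along a simulated brain profile.

    Returns a frame with one row per (time, subject) plus group means/SEM:
    columns time_min, conc_ng_ml, effect, and the per-time aggregates.
    The design mirrors the source study: sampling 5-180 min, n = 10 rats per
    time group.
    """
    times_min = np.asarray(sampling_times_min, dtype=float)
    rng = np.random.default_rng(seed)
    conc = brain_result.conc_at(times_min / 60.0, matrix="brain")
    true_effect = effect_at(params, conc)
    rows = []
    for t, c, e in zip(times_min, conc, true_effect):
        obs = e + rng.normal(0.0, noise_sd, size=group_size)
        for subj, eo in enumerate(obs):
            rows.append(
                {
                    "time_min": t,
                    "conc_ng_ml": c,
                    "effect": eo,
                    "subject": subj,
                }
            )
    df = pd.DataFrame(rows)
    agg = (
        df.groupby("time_min")
        .agg(
            conc_ng_ml=("conc_ng_ml", "first"),
            effect_mean=("effect", "mean"),
            effect_sem=("effect", lambda x: x.std(ddof=1) / np.sqrt(len(x))),
        )
        .reset_index()
    )
    return df.merge(agg[["time_min", "effect_mean", "effect_sem"]], on="time_min")


def gen_depletion_curve(
    k_per_min: float,
    c0_ng_ml: float,
    timepoints_min,
    cv: float,
    seed: int,
):
    """Microsomal substrate-depletion curve with lognormal assay noise."""
    rng = np.random.default_rng(seed)
    t = np.asarray(timepoints_min, dtype=float)
    true = c0_ng_ml * np.exp(-k_per_min * t)
    sigma = np.sqrt(np.log1p(cv**2))
    noise = (
        rng.lognormal(-0.5 * sigma**2, sigma, size=t.size) if cv > 0 else np.ones(t.size)
    )
    return t, true * noise


def gen_transport_run(
    papp_cm_s: float,
    direction: str,
    timepoints_min,
    seed: int,
    cv: float = 0.0,
    membrane_area_cm2: float = 0.6,
    initial_conc_um: float = 50.0,
    receiver_volume_ml: float = 0.6,
    sample_volume_ml: float = 0.05,
    simulate_withdrawal: bool = True,
) -> TransportObservation:
    """Caco-2 transport run with true linear flux and sampling withdrawal.

    The true cumulative transported amount grows linearly with slope
    Papp*A*C0; when ``simulate_withdrawal`` each 50 uL draw removes its share
    of the receiver content, as in the bench protocol.
    """
    rng = np.random.default_rng(seed)
    t_min = np.asarray(timepoints_min, dtype=float)
    slope_nmol_s = papp_cm_s * membrane_area_cm2 * initial_conc_um  # nmol/s
    sigma = np.sqrt(np.log1p(cv**2)) if cv > 0 else 0.0
    measured = []
    removed = 0.0
    for t in t_min:
        true_cum = slope_nmol_s * t * 60.0
        in_receiver = true_cum - removed if simulate_withdrawal else true_cum
        noise = rng.lognormal(-0.5 * sigma**2, sigma) if cv > 0 else 1.0
        obs = in_receiver * noise
        measured.append(obs)
        if simulate_withdrawal:
            removed += (sample_volume_ml / receiver_volume_ml) * in_receiver
    return TransportObservation(
        direction=direction,
        times_min=t_min,
        receiver_amount_nmol=np.asarray(measured),
        membrane_area_cm2=membrane_area_cm2,
        initial_conc_um=initial_conc_um,
        receiver_volume_ml=receiver_volume_ml,
        sample_volume_ml=sample_volume_ml,
    )
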