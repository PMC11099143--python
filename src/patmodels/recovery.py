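"""Parameter-recovery harness.

Simulates analysis-ready trial tables directly (balanced long-trial
factorials with exogenous standardized Dhr, skipping the beat-level cardiac
plumbing), fits the corresponding model, and aggregates bias / RMSE /
interval coverage across replicates.  This is the package's main validation
surface: with the canonical group-level parameter sets as generating values
and no subject heterogeneity, pooled ML must recover the generating
coefficients as the trial count grows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cardiac import standardize_predictors
from .choice import ApproachAvoidModel
from .exceptions import DataError
from .params import ParamSet
from .simulate import RTParams, simulate_choices, simulate_rts
from .task import ACTION_CONTEXTS, TaskConfig


def simulate_analysis_table(
    params: ParamSet,
    n_subjects: int,
    n_runs: int = 3,
    seed=0,
    rt_params: RTParams | None = None,
    random_effect_scale: float = 0.0,
) -> pd.DataFrame:
    """Analysis-set table of balanced long trials with simulated choices.

    Each subject contributes ``n_runs`` repetitions of the 5 x 5 x 2
    factorial (50 long trials per run).  Dhr is exogenous and standardized:
    drawn N(0, 1) and z-scored pooled, independent of the conditions.
    Optionally adds shifted-lognormal RTs on active-response trials.
    """
    if n_subjects < 1 or n_runs < 1:
        raise DataError("need at least one subject and one run")
    seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = seq.spawn(3)
    config = TaskConfig()
    cells = [
        (m, s, ac)
        for m in config.money_levels
        for s in config.shock_levels
        for ac in ACTION_CONTEXTS
    ]
    n_cell = len(cells)
    per_sub = n_runs * n_cell
    money = np.tile([c[0] for c in cells], n_runs * n_subjects)
    shocks = np.tile([c[1] for c in cells], n_runs * n_subjects)
    ac = np.tile([c[2] for c in cells], n_runs * n_subjects)
    frame = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n_subjects), per_sub),
            "run": np.tile(np.repeat(np.arange(n_runs), n_cell), n_subjects),
            "trial": np.tile(np.arange(per_sub), n_subjects),
            "money": money,
            "shocks": shocks,
            "action_context": ac,
            "is_long": True,
        }
    )
    rng = np.random.default_rng(streams[0])
    dhr = rng.normal(0.0, 1.0, len(frame))
    frame["dhr"] = (dhr - dhr.mean()) / dhr.std()
    frame, _ = standardize_predictors(frame, dhr_col="dhr")
    frame["choice"] = simulate_choices(frame, params, streams[1], random_effect_scale)
    frame["choice_code"] = np.where(frame["choice"] == "approach", 1.0, -1.0)
    if rt_params is not None:
        frame["rt"] = simulate_rts(frame, rt_params, streams[2], random_effect_scale)
    return frame


def recover_parameters(
    params: ParamSet,
    n_subjects: int,
    n_trials: int,
    n_replicates: int,
    seed=0,
    n_boot: int = 200,
    coverage_mass: float = 0.90,
) -> pd.DataFrame:
    """Simulate -> fit -> aggregate recovery report.

    ``n_trials`` is the per-subject long-trial count and must be a multiple
    of 50 (one factorial repetition).  Reports, per coefficient: generating
    value, mean estimate, bias, RMSE, and the fraction of
    ``coverage_mass`` bootstrap HDIs covering the generating value.
    Non-convergent replicates are counted, not fatal.
    """
    if n_trials <= 0:
        raise DataError("n_trials must be positive")
    if n_trials % 50 != 0:
        raise DataError("n_trials must be a multiple of 50 (one factorial per run)")
    n_runs = n_trials // 50
    truth = params.as_array()
    est, covered, n_fail = [], [], 0
    root = np.random.SeedSequence(seed)
    for rep_seed in root.spawn(n_replicates):
        table = simulate_analysis_table(params, n_subjects, n_runs, seed=rep_seed)
        fit = ApproachAvoidModel(table, params.kind).fit(n_boot=n_boot, seed=rep_seed.spawn(1)[0])
        if not fit.converged:
            n_fail += 1
        est.append(fit.params.to_numpy())
        if n_boot > 0:
            h = fit.hdi(coverage_mass)
            covered.append(
                (h["lower"].to_numpy() <= truth) & (truth <= h["upper"].to_numpy())
            )
    est = np.vstack(est)
    report = pd.DataFrame(
        {
            "generating": truth,
            "mean_estimate": est.mean(axis=0),
            "bias": est.mean(axis=0) - truth,
            "rmse": np.sqrt(np.mean((est - truth) ** 2, axis=0)),
        },
        index=list(params.values.index),
    )
    if covered:
        report[f"coverage_{int(coverage_mass * 100)}"] = np.vstack(covered).mean(axis=0)
    report.attrs["n_nonconverged"] = n_fail
    report.attrs["n_replicates"] = n_replicates
    return report
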