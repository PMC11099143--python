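"""Generative simulator for complete PAT datasets.

Produces everything the analysis pipeline consumes: trial schedules,
beat-by-beat cardiac traces exhibiting anticipatory bradycardia, approach /
avoid choices from the decision-value models, shifted-lognormal response
times for button-press trials, and probabilistic money / shock / nothing
outcomes.  All randomness flows from a single root seed through named
substreams, so a given (config, agent, seed) triple is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import cardiac as cardiac_mod
from .exceptions import ConfigurationError, DataError
from .params import ParamSet, design_matrix, reference_params, terms_for_kind
from .task import TaskConfig, build_schedule

#: Seconds after anticipation onset at which the cardiac ramp reaches its
#: full deceleration; it then stays flat through the end of the screen, so
#: the 5-7 s scoring window sits entirely on the plateau.
RAMP_END = 5.0
_TRACE_PRE = 3.5  # s of baseline beats before onset (first BPM stamp falls
# one IBI later, and must precede the baseline window even after phase jitter)
_TRACE_POST = 7.5  # s of beats after onset


@dataclass
class CardiacParams:
    """Generator of subject baselines and trial-wise decelerations (BPM)."""

    baseline_bpm_mean: float = 65.0
    baseline_bpm_sd: float = 7.0
    decel_mean: float = -1.77
    decel_subject_sd: float = 1.0
    decel_trial_sd: float = 2.0
    beat_noise_sd: float = 0.5  # additive BPM noise per beat

    def validate(self) -> None:
        if self.baseline_bpm_mean <= 0:
            raise ConfigurationError("baseline BPM mean must be positive")
        for name in ("baseline_bpm_sd", "decel_subject_sd", "decel_trial_sd", "beat_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be nonnegative")


@dataclass
class RTParams:
    """Shifted-lognormal response-time generator: rt = shift + exp(N(mu, sigma)).

    ``mu`` is linear in standardized money, shocks, the choice code
    (+1 approach / -1 avoid), standardized Dhr and their products.  The
    default slopes mirror the group-level RT effects (faster avoid responses,
    reward speeding of approach, threat slowing of approach, and slower
    responses at weaker bradycardia, i.e. a positive Dhr coefficient).
    """

    coefficients: dict = field(
        default_factory=lambda: {
            "intercept": float(np.log(0.25)),
            "choice": -0.04,
            "money:choice": 0.04,
            "shocks:choice": -0.04,
            "dhr": 0.03,
        }
    )
    shift: float = 0.2
    sigma: float = 0.25

    def validate(self) -> None:
        if self.sigma <= 0:
            raise ConfigurationError("RT sigma must be strictly positive")
        if self.shift < 0:
            raise ConfigurationError("RT shift must be nonnegative")


@dataclass
class AgentParams:
    """Everything the synthetic participant needs."""

    choice_params: ParamSet = field(default_factory=lambda: reference_params("base"))
    rt_params: RTParams = field(default_factory=RTParams)
    cardiac_params: CardiacParams = field(default_factory=CardiacParams)
    #: Per-subject coefficient SDs as a fraction of |group coefficient|.
    random_effect_scale: float = 0.5

    @property
    def model_kind(self) -> str:
        return self.choice_params.kind

    def validate(self) -> None:
        self.rt_params.validate()
        self.cardiac_params.validate()
        if self.random_effect_scale < 0:
            raise ConfigurationError("random_effect_scale must be nonnegative")


def _substreams(seed, n: int) -> list[np.random.Generator]:
    seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in seq.spawn(n)]


def _bpm_profile(t: np.ndarray, onset: float, baseline: float, decel: float) -> np.ndarray:
    """Instantaneous BPM: flat baseline, linear ramp to ``baseline + decel``
    over [onset, onset + RAMP_END], then flat."""
    frac = np.clip((t - onset) / RAMP_END, 0.0, 1.0)
    return baseline + decel * frac


def simulate_cardiac(
    trials: pd.DataFrame, cardiac: CardiacParams, seed, with_traces: bool = True
) -> tuple[dict, pd.DataFrame]:
    """Draw latent decelerations and beat-by-beat traces for long trials.

    The latent per-trial deceleration delta ~ Normal(decel_mean + subject
    offset, decel_trial_sd) is independent of money / shocks / action context
    by construction.  Beats follow the inhomogeneous rate of
    :func:`_bpm_profile` with additive per-beat BPM noise.

    Returns ``(traces, table)`` where ``traces`` maps
    ``(subject, run, trial)`` to beat times on the run clock and ``table``
    is ``trials`` plus a ``dhr_true`` column (NaN on short trials).
    ``with_traces=False`` skips beat generation (the latent decelerations
    are drawn from their own stream, so they are unchanged).
    """
    cardiac.validate()
    rng_subj, rng_trial, rng_beat = _substreams(seed, 3)
    out = trials.copy()
    dhr_true = np.full(len(out), np.nan)
    traces: dict = {}

    subjects = out["subject"].unique()
    baselines = {}
    offsets = {}
    for s in subjects:
        b = rng_subj.normal(cardiac.baseline_bpm_mean, cardiac.baseline_bpm_sd)
        baselines[s] = max(b, 30.0)  # keep physiological
        offsets[s] = rng_subj.normal(0.0, cardiac.decel_subject_sd)

    for i, row in enumerate(out.itertuples(index=False)):
        if not row.is_long:
            continue
        b = baselines[row.subject]
        delta = rng_trial.normal(cardiac.decel_mean + offsets[row.subject], cardiac.decel_trial_sd)
        dhr_true[i] = delta
        if not with_traces:
            continue
        # Beat times by stepping the inhomogeneous rate, with phase jitter.
        t0 = row.onset - _TRACE_PRE
        t_end = row.onset + _TRACE_POST
        t = t0 + rng_beat.uniform(0.0, 0.8 * 60.0 / b)
        beats = [t]
        while t < t_end:
            # One beat per integrated cycle: the IBI reflects the rate at the
            # interval midpoint (one fixed-point refinement of 1/rate), not at
            # the interval start, so the stamped BPM series tracks the ramp
            # with minimal lag.
            ibi0 = 60.0 / _bpm_profile(np.array([t]), row.onset, b, delta)[0]
            bpm = _bpm_profile(np.array([t + ibi0 / 2.0]), row.onset, b, delta)[0]
            if cardiac.beat_noise_sd > 0:
                bpm += rng_beat.normal(0.0, cardiac.beat_noise_sd)
            bpm = max(bpm, 20.0)
            t = t + 60.0 / bpm
            beats.append(t)
        traces[(row.subject, row.run, row.trial)] = np.asarray(beats)

    out["dhr_true"] = dhr_true
    return traces, out


def _subject_params(params: ParamSet, scale: float, subjects, rng) -> dict:
    """Per-subject coefficient vectors with Normal(0, (scale*|b|)^2) deviations."""
    base = params.as_array()
    sds = scale * np.abs(base)
    return {
        s: base + (rng.normal(0.0, sds) if scale > 0 else 0.0) for s in subjects
    }


def simulate_choices(
    trials: pd.DataFrame,
    params: ParamSet,
    seed,
    random_effect_scale: float = 0.0,
) -> np.ndarray:
    """Bernoulli approach/avoid choices from a decision-value model.

    ``trials`` must carry the standardized feature columns (``z_money``,
    ``z_shocks``, ``z_dms``, ``z_dhr``, ``ac_code``).  Missing Dhr is an
    error: every simulated trial needs a bradycardia state (use 0 for trials
    where none is defined).
    """
    if "z_dhr" not in trials or trials["z_dhr"].isna().any():
        raise DataError("z_dhr must be present and non-missing for every trial")
    rng = np.random.default_rng(seed)
    X = design_matrix(trials, params.kind).to_numpy()
    subjects = trials["subject"].to_numpy()
    per_subject = _subject_params(params, random_effect_scale, np.unique(subjects), rng)
    beta = np.vstack([per_subject[s] for s in subjects])
    dv = np.sum(X * beta, axis=1)
    p = 1.0 / (1.0 + np.exp(-dv))
    return np.where(rng.random(len(p)) < p, "approach", "avoid")


def simulate_rts(
    trials: pd.DataFrame, rt: RTParams, seed, random_effect_scale: float = 0.0
) -> np.ndarray:
    """Shifted-lognormal RTs for button-press (active-response) trials.

    Trials whose response is passive (withheld press) get NaN.  ``trials``
    must carry standardized features plus ``choice`` / ``choice_code``.
    """
    rt.validate()
    rng = np.random.default_rng(seed)
    active = cardiac_mod.is_active_response(trials["choice"], trials["action_context"])
    mu = np.zeros(len(trials))
    from .params import term_column

    subjects = trials["subject"].to_numpy()
    uniq = np.unique(subjects)
    for term, coef in rt.coefficients.items():
        if random_effect_scale > 0:
            devs = {s: rng.normal(coef, random_effect_scale * abs(coef)) for s in uniq}
            coefs = np.array([devs[s] for s in subjects])
        else:
            coefs = coef
        mu = mu + coefs * term_column(trials, term)
    rts = rt.shift + np.exp(rng.normal(mu, rt.sigma))
    return np.where(active, rts, np.nan)


def sample_outcomes(choices, config: TaskConfig, seed) -> np.ndarray:
    """Categorical money / shocks / nothing outcome per trial."""
    config.validate()
    rng = np.random.default_rng(seed)
    choices = np.asarray(choices, dtype=object)
    labels = np.array(["money", "shocks", "nothing"], dtype=object)
    p_app = np.asarray(config.p_outcome_approach)
    p_avd = np.asarray(config.p_outcome_avoid)
    cum = np.where(
        (choices == "approach")[:, None],
        np.cumsum(p_app)[None, :],
        np.cumsum(p_avd)[None, :],
    )
    u = rng.random(len(choices))
    idx = np.sum(u[:, None] >= cum, axis=1)
    return labels[np.minimum(idx, 2)]


def simulate_dataset(
    config: TaskConfig,
    agent: AgentParams,
    n_subjects: int,
    seed,
) -> tuple[pd.DataFrame, dict]:
    """End-to-end synthetic dataset: schedule, cardiac traces, choices, RTs,
    outcomes.

    Choices are generated from features standardized over the long trials
    (the eventual analysis set); short trials use the same level scaling with
    the Dhr term at 0 (no cardiac state is defined for them).  Returns the
    trial table and the beat-time traces.
    """
    agent.validate()
    seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = seq.spawn(5)
    table = build_schedule(config, n_subjects, np.random.default_rng(streams[0]))
    traces, table = simulate_cardiac(table, agent.cardiac_params, streams[1])
    if len(table) == 0:
        table["choice"] = np.array([], dtype=object)
        table["rt"] = np.array([], dtype=float)
        table["outcome"] = np.array([], dtype=object)
        return table, traces

    long_mask = table["is_long"].to_numpy(dtype=bool)
    zlong, stats = cardiac_mod.standardize_predictors(
        table.loc[long_mask], dhr_col="dhr_true"
    )
    ztable, _ = cardiac_mod.standardize_predictors(table, dhr_col="dhr_true", stats=stats)
    ztable.loc[~long_mask, "z_dhr"] = 0.0

    ztable["choice"] = simulate_choices(
        ztable, agent.choice_params, streams[2], agent.random_effect_scale
    )
    ztable["choice_code"] = np.where(ztable["choice"] == "approach", 1.0, -1.0)
    ztable["rt"] = simulate_rts(ztable, agent.rt_params, streams[3], agent.random_effect_scale)
    ztable["outcome"] = sample_outcomes(ztable["choice"], config, streams[4])

    cols = [
        "subject", "run", "trial", "money", "shocks", "action_context", "ami",
        "onset", "is_long", "choice", "rt", "outcome", "dhr_true",
    ]
    return ztable[cols].copy(), traces


def write_trial_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def write_beat_files(traces: dict, outdir) -> list:
    """One plain-text file per subject: ``run trial beat_time`` per line."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    by_subject: dict = {}
    for (subject, run, trial), beats in sorted(traces.items()):
        by_subject.setdefault(subject, []).append((run, trial, beats))
    paths = []
    for subject, entries in sorted(by_subject.items()):
        path = outdir / f"sub-{subject:03d}_beats.txt"
        with open(path, "w") as fh:
            for run, trial, beats in entries:
                for t in beats:
                    fh.write(f"{run}\t{trial}\t{t:.6f}\n")
        paths.append(path)
    return paths


def read_beat_files(indir) -> dict:
    """Inverse of :func:`write_beat_files`."""
    from pathlib import Path

    traces: dict = {}
    for path in sorted(Path(indir).glob("sub-*_beats.txt")):
        subject = int(path.stem.split("-")[1].split("_")[0])
        data: dict = {}
        with open(path) as fh:
            for line in fh:
                run, trial, t = line.split()
                data.setdefault((int(run), int(trial)), []).append(float(t))
        for (run, trial), beats in data.items():
            traces[(subject, run, trial)] = np.asarray(beats)
    return traces
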