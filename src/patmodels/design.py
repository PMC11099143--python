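"""Model-based fMRI regressor construction at toy scale.

Trial-wise decision values computed from fixed group-level parameter sets
are nearly collinear across model variants (rank correlations ~0.998), so
the freezing-model regressors enter the GLM as trial-wise difference scores
DVdiff = DV_base - DV_variant; positive values mean the variant predicts
relatively more avoidance.  Difference scores decorrelate the regressors
because each variant deviates from the base model by a single bradycardia
interaction that is (by design) independent of the shared value terms.

Design matrices follow the standard event-related construction: boxcars at
microtime resolution, parametric modulators demeaned across their events
(orthogonalization with respect to the unmodulated regressor only; shared
variance among modulators is deliberately left to the error term), canonical
double-gamma HRF convolution, downsampling to the TR grid, and a
discrete-cosine high-pass drift set.
"""

from __future__ import annotations

import warnings as _warnings

import numpy as np
import pandas as pd
from scipy.stats import gamma as _gamma
from scipy.stats import spearmanr

from .choice import decision_value
from .exceptions import DataError, ModelError
from .params import ParamSet

TR_DEFAULT = 1.5
MICROTIME = 0.1
HIGHPASS_CUTOFF = 1.0 / 128.0

# Canonical double-gamma HRF constants (SPM-convention shapes).
HRF_PEAK_DELAY = 6.0
HRF_UNDERSHOOT_DELAY = 16.0
HRF_PEAK_DISP = 1.0
HRF_UNDERSHOOT_DISP = 1.0
HRF_UNDERSHOOT_RATIO = 1.0 / 6.0


def trial_dvs_from_params(trials: pd.DataFrame, params: ParamSet, kind: str | None = None) -> np.ndarray:
    """Trial-wise decision values from fixed group-level parameters."""
    if kind is not None and kind != params.kind:
        raise ModelError(f"requested kind {kind!r} but parameter set is {params.kind!r}")
    return decision_value(trials, params)


def dv_diff(dv_base, dv_mod) -> np.ndarray:
    """Difference score DV_base - DV_variant (positive => variant predicts
    relatively more avoidance)."""
    dv_base = np.asarray(dv_base, dtype=float)
    dv_mod = np.asarray(dv_mod, dtype=float)
    if dv_base.shape != dv_mod.shape:
        raise DataError("DV vectors must have equal length and trial order")
    return dv_base - dv_mod


def split_by_sign(dvdiff) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks (positive, negative); exactly-zero trials join neither."""
    dvdiff = np.asarray(dvdiff, dtype=float)
    return dvdiff > 0, dvdiff < 0


def regressor_correlations(
    frame: pd.DataFrame, col_a: str, col_b: str, method: str = "spearman"
) -> dict:
    """Per-subject rank correlation of two trial-wise regressors.

    Returns mean and SD across subjects plus the per-subject series.
    Subjects with a constant vector (undefined correlation) are excluded
    with a warning.
    """
    if method not in ("spearman", "pearson"):
        raise DataError(f"unknown correlation method {method!r}")
    per_subject = {}
    for subject, sub in frame.groupby("subject"):
        a = sub[col_a].to_numpy(dtype=float)
        b = sub[col_b].to_numpy(dtype=float)
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            _warnings.warn(f"subject {subject}: constant regressor, correlation undefined")
            continue
        if method == "spearman":
            r = spearmanr(a, b).statistic
        else:
            r = np.corrcoef(a, b)[0, 1]
        per_subject[subject] = float(r)
    values = np.array(list(per_subject.values()))
    if values.size == 0:
        raise DataError("no subject had a defined correlation")
    return {
        "mean": float(values.mean()),
        "sd": float(values.std(ddof=1)) if values.size > 1 else 0.0,
        "per_subject": per_subject,
    }


def canonical_hrf(t, dt_normalize: float = MICROTIME) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, unit peak amplitude.

    Positive gamma peaking near 5-6 s minus a 1/6-scaled undershoot peaking
    near 16 s; zero for t <= 0.
    """
    t = np.asarray(t, dtype=float)
    peak = _gamma.pdf(t, HRF_PEAK_DELAY / HRF_PEAK_DISP, scale=HRF_PEAK_DISP)
    under = _gamma.pdf(t, HRF_UNDERSHOOT_DELAY / HRF_UNDERSHOOT_DISP, scale=HRF_UNDERSHOOT_DISP)
    h = peak - HRF_UNDERSHOOT_RATIO * under
    ref = np.arange(0.0, 32.0, dt_normalize)
    ref_h = _gamma.pdf(ref, HRF_PEAK_DELAY, scale=HRF_PEAK_DISP) - HRF_UNDERSHOOT_RATIO * _gamma.pdf(
        ref, HRF_UNDERSHOOT_DELAY, scale=HRF_UNDERSHOOT_DISP
    )
    return h / ref_h.max()


class DesignMatrix:
    """TR-grid design matrix with column-role metadata."""

    def __init__(self, frame: pd.DataFrame, roles: dict, tr: float):
        self.frame = frame
        self.roles = roles
        self.tr = tr

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def columns(self):
        return list(self.frame.columns)

    def to_tsv(self, path) -> None:
        out = self.frame.copy()
        out.columns = [f"{c} [{self.roles[c]}]" for c in out.columns]
        out.to_csv(path, sep="\t", index=False)


def build_design_matrix(
    events: pd.DataFrame,
    modulators: dict | None = None,
    tr: float = TR_DEFAULT,
    microtime: float = MICROTIME,
    highpass: float | None = HIGHPASS_CUTOFF,
    run_duration: float | None = None,
) -> DesignMatrix:
    """HRF-convolved design matrix on the TR grid.

    ``events`` needs ``onset`` and ``duration`` columns (seconds).  Each
    entry of ``modulators`` maps a column name to one value per event; the
    values are demeaned across events *before* convolution (this is the
    orthogonalization against the unmodulated regressor; no serial
    orthogonalization among modulators is performed).  Drift is modelled by
    a discrete-cosine set up to the ``highpass`` cutoff plus a constant.
    """
    onsets = events["onset"].to_numpy(dtype=float)
    durations = events["duration"].to_numpy(dtype=float)
    if len(onsets) == 0:
        raise DataError("no events")
    order = np.argsort(onsets)
    if np.any(np.diff(onsets[order]) <= 0) and len(onsets) > 1:
        dup = np.flatnonzero(np.diff(onsets[order]) <= 0)
        raise DataError(f"overlapping duplicate events at onsets {onsets[order][dup]}")
    if abs((tr / microtime) - round(tr / microtime)) > 1e-9:
        raise DataError("tr must be an integer multiple of the microtime resolution")

    if run_duration is None:
        run_duration = float(np.max(onsets + durations) + 32.0)
    n_mt = int(np.ceil(run_duration / microtime))
    t_mt = np.arange(n_mt) * microtime
    hrf = canonical_hrf(np.arange(0.0, 32.0, microtime))

    def event_boxcars(values: np.ndarray) -> np.ndarray:
        col = np.zeros(n_mt)
        for onset, dur, v in zip(onsets, durations, values):
            i0 = int(round(onset / microtime))
            i1 = max(i0 + 1, int(round((onset + dur) / microtime)))
            col[i0 : min(i1, n_mt)] += v
        return col

    step = int(round(tr / microtime))
    tr_idx = np.arange(0, n_mt, step)

    cols, roles = {}, {}
    unmod = np.convolve(event_boxcars(np.ones(len(onsets))), hrf)[:n_mt]
    cols["anticipation"] = unmod[tr_idx]
    roles["anticipation"] = "unmodulated"

    for name, values in (modulators or {}).items():
        values = np.asarray(values, dtype=float)
        if values.shape != onsets.shape:
            raise DataError(f"modulator {name!r}: one value per event required")
        if values.size == 0 or np.ptp(values) == 0 and np.all(values == 0):
            _warnings.warn(f"modulator {name!r} is empty; column dropped")
            continue
        demeaned = values - values.mean()
        conv = np.convolve(event_boxcars(demeaned), hrf)[:n_mt]
        cols[name] = conv[tr_idx]
        roles[name] = "parametric"

    n_tr = len(tr_idx)
    if highpass:
        total_time = n_tr * tr
        n_basis = int(np.floor(2 * total_time * highpass))
        k_grid = np.arange(n_tr)
        for k in range(1, n_basis + 1):
            cols[f"drift_{k}"] = np.cos(np.pi * k * (2 * k_grid + 1) / (2 * n_tr))
            roles[f"drift_{k}"] = "drift"
    cols["constant"] = np.ones(n_tr)
    roles["constant"] = "constant"

    frame = pd.DataFrame(cols)
    dm = DesignMatrix(frame, roles, tr)
    dm.microtime_events = {
        "onsets": onsets,
        "durations": durations,
    }
    return dm


def simulate_bold_and_recover(
    design: DesignMatrix, true_betas: dict, noise_sd: float, seed=0
) -> pd.DataFrame:
    """Generate BOLD = X @ beta + noise and recover betas by OLS.

    ``true_betas`` maps column names to effect sizes (unnamed columns get 0).
    Raises on rank deficiency, naming the collinear columns.
    """
    X = design.values
    names = design.columns
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name columns whose removal restores full column rank
        bad = []
        for j in range(X.shape[1]):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                bad.append(names[j])
        raise ModelError(f"rank-deficient design; collinear columns: {bad}")
    unknown = set(true_betas) - set(names)
    if unknown:
        raise DataError(f"true_betas refer to unknown columns: {sorted(unknown)}")
    beta = np.array([float(true_betas.get(c, 0.0)) for c in names])
    rng = np.random.default_rng(seed)
    bold = X @ beta + rng.normal(0.0, noise_sd, X.shape[0])
    est, *_ = np.linalg.lstsq(X, bold, rcond=None)
    resid = bold - X @ est
    dof = max(X.shape[0] - X.shape[1], 1)
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return pd.DataFrame(
        {"true": beta, "estimate": est, "se": np.sqrt(np.diag(cov))}, index=names
    )


def write_events_tsv(events: pd.DataFrame, modulator, path) -> None:
    """FSL-style 3-column timing file: onset, duration, modulation."""
    out = pd.DataFrame(
        {
            "onset": events["onset"].to_numpy(dtype=float),
            "duration": events["duration"].to_numpy(dtype=float),
            "modulation": np.asarray(modulator, dtype=float),
        }
    )
    out.to_csv(path, sep="\t", index=False, header=False)
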