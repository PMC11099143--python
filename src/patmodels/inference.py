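"""Shared inference utilities: HDIs, significance labels, subject bootstrap,
and the Results container every fitted model returns.

Inferential conventions: a coefficient is labelled 'significant' when its 95%
highest-density interval excludes zero, 'marginal' when only the 90% HDI
does, and 'ns' otherwise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import DataError

MIN_HDI_SAMPLES = 100


def hdi(samples, mass: float = 0.95) -> tuple[float, float]:
    """Narrowest contiguous interval holding ``mass`` of the samples.

    Computed by scanning all windows of ``ceil(mass * n)`` consecutive order
    statistics and returning the shortest.
    """
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n < MIN_HDI_SAMPLES:
        raise DataError(f"need >= {MIN_HDI_SAMPLES} samples for an HDI, got {n}")
    if not 0 < mass < 1:
        raise DataError("mass must be in (0, 1)")
    n_inc = max(2, int(np.ceil(mass * n)))
    widths = x[n_inc - 1 :] - x[: n - n_inc + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + n_inc - 1])


def label_significance(hdi90: tuple[float, float], hdi95: tuple[float, float]) -> str:
    """Two-interval significance rule (see module docstring)."""
    lo95, hi95 = hdi95
    lo90, hi90 = hdi90
    if lo95 > 0 or hi95 < 0:
        return "significant"
    if lo90 > 0 or hi90 < 0:
        return "marginal"
    return "ns"


def data_fingerprint(frame: pd.DataFrame, columns=None) -> int:
    """Order-insensitive hash of the analysis rows, used to refuse comparing
    models fitted on different data."""
    if columns is None:
        columns = [
            c
            for c in ("subject", "choice_code", "z_money", "z_shocks", "z_dms", "z_dhr", "ac_code")
            if c in frame.columns
        ]
    h = pd.util.hash_pandas_object(frame[columns], index=False).to_numpy()
    return int(np.bitwise_xor.reduce(h) + np.uint64(len(h)))


def subject_bootstrap(
    frame: pd.DataFrame,
    fit_fn,
    n_boot: int,
    seed,
    subject_col: str = "subject",
) -> np.ndarray:
    """Nonparametric bootstrap over subjects (clusters).

    ``fit_fn(frame) -> 1-D coefficient array`` is re-evaluated on each
    resample of subjects drawn with replacement.  Returns an
    ``(n_boot, k)`` array.
    """
    subjects = frame[subject_col].unique()
    indices = {s: np.flatnonzero(frame[subject_col].to_numpy() == s) for s in subjects}
    rng = np.random.default_rng(seed)
    draws = []
    for _ in range(n_boot):
        picked = rng.choice(subjects, size=len(subjects), replace=True)
        idx = np.concatenate([indices[s] for s in picked])
        draws.append(fit_fn(frame.iloc[idx]))
    return np.vstack(draws)


class FitResults:
    """Estimates, uncertainty and diagnostics of one fitted model.

    Attributes
    ----------
    params : pd.Series
        Point estimates, indexed by coefficient name.
    samples : pd.DataFrame or None
        Bootstrap or posterior draws, one column per coefficient.
    llf : float
        Maximized log-likelihood.
    """

    def __init__(
        self,
        model_name: str,
        params: pd.Series,
        samples: pd.DataFrame | None,
        llf: float,
        nobs: int,
        method: str,
        kind: str | None = None,
        converged: bool = True,
        warnings: tuple = (),
        fingerprint: int | None = None,
        extra: dict | None = None,
    ):
        self.model_name = model_name
        self.params = params
        self.samples = samples
        self.llf = float(llf)
        self.nobs = int(nobs)
        self.method = method
        self.kind = kind
        self.converged = bool(converged)
        self.warnings = tuple(warnings)
        self.fingerprint = fingerprint
        self.extra = dict(extra or {})

    @property
    def k_params(self) -> int:
        return len(self.params)

    @property
    def aic(self) -> float:
        return 2 * self.k_params - 2 * self.llf

    def hdi(self, mass: float = 0.95) -> pd.DataFrame:
        if self.samples is None:
            raise DataError("no samples available; fit with n_boot > 0")
        rows = {c: hdi(self.samples[c], mass) for c in self.params.index}
        return pd.DataFrame(rows, index=["lower", "upper"]).T

    def significance(self) -> pd.Series:
        h90, h95 = self.hdi(0.90), self.hdi(0.95)
        return pd.Series(
            {
                c: label_significance(tuple(h90.loc[c]), tuple(h95.loc[c]))
                for c in self.params.index
            },
            name="significance",
        )

    def coefficient_table(self) -> pd.DataFrame:
        tab = pd.DataFrame({"estimate": self.params})
        if self.samples is not None:
            h90, h95 = self.hdi(0.90), self.hdi(0.95)
            tab["hdi90_lo"], tab["hdi90_hi"] = h90["lower"], h90["upper"]
            tab["hdi95_lo"], tab["hdi95_hi"] = h95["lower"], h95["upper"]
            tab["significance"] = self.significance()
        return tab

    def summary(self) -> str:
        lines = [
            f"{self.model_name} ({self.method})",
            f"kind: {self.kind}  nobs: {self.nobs}  llf: {self.llf:.3f}  "
            f"AIC: {self.aic:.3f}  converged: {self.converged}",
        ]
        if self.warnings:
            lines.append("warnings: " + "; ".join(self.warnings))
        with pd.option_context("display.width", 120):
            lines.append(self.coefficient_table().round(4).to_string())
        return "\n".join(lines)

    def plot_coefficients(self, mass: float = 0.95, ax=None):
        from .plotting import plot_coefficients

        return plot_coefficients(self, mass=mass, ax=ax)

    def to_dict(self) -> dict:
        out = {
            "model_name": self.model_name,
            "kind": self.kind,
            "method": self.method,
            "nobs": self.nobs,
            "llf": self.llf,
            "aic": self.aic,
            "converged": self.converged,
            "warnings": list(self.warnings),
            "estimates": {k: float(v) for k, v in self.params.items()},
            "extra": self.extra,
        }
        if self.samples is not None:
            h90, h95 = self.hdi(0.90), self.hdi(0.95)
            out["hdi90"] = {c: [float(h90.loc[c, "lower"]), float(h90.loc[c, "upper"])] for c in self.params.index}
            out["hdi95"] = {c: [float(h95.loc[c, "lower"]), float(h95.loc[c, "upper"])] for c in self.params.index}
            out["significance"] = self.significance().to_dict()
        return out
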