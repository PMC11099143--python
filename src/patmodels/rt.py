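"""Shifted-lognormal response-time model.

Only button-press (active-response) trials carry RTs.  The likelihood is

    rt = shift + exp(Normal(mu, sigma)),   mu = X @ beta

with ``X`` the full money x shocks x choice x Dhr factorial over
standardized features (16 terms).  For a known shift the ML solution is an
ordinary least-squares fit of ``log(rt - shift)``; an unknown shift is
profiled over a 50-point grid on [0, min rt).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .exceptions import DataError
from .inference import FitResults, data_fingerprint, subject_bootstrap
from .params import term_column

RT_VARIABLES = ("money", "shocks", "choice", "dhr")
N_SHIFT_GRID = 50


def rt_terms(variables=RT_VARIABLES) -> tuple[str, ...]:
    """All interaction terms of the RT location model (full factorial)."""
    terms = ["intercept"]
    for r in range(1, len(variables) + 1):
        for combo in combinations(variables, r):
            terms.append(":".join(combo))
    return tuple(terms)


def _design(frame: pd.DataFrame, terms) -> np.ndarray:
    return np.column_stack([term_column(frame, t) for t in terms])


def shifted_lognormal_loglik(rt, mu, sigma: float, shift: float) -> float:
    """Exact log-density sum of the shifted lognormal."""
    rt = np.asarray(rt, dtype=float)
    z = rt - shift
    if np.any(z <= 0):
        return -np.inf
    y = np.log(z)
    return float(
        np.sum(-y - 0.5 * np.log(2 * np.pi * sigma**2) - (y - mu) ** 2 / (2 * sigma**2))
    )


class ShiftedLognormalRTModel:
    """RT model over active-response trials.

    ``data`` must carry ``rt`` (seconds, non-missing rows only are used),
    the standardized features and ``subject``.
    """

    def __init__(self, data: pd.DataFrame, terms=None):
        data = data.loc[np.isfinite(data["rt"].to_numpy(dtype=float))]
        if len(data) == 0:
            raise DataError("no trials with response times")
        self.data = data.copy()
        self.terms = tuple(terms) if terms is not None else rt_terms()
        self.exog = _design(self.data, self.terms)
        self.rt = self.data["rt"].to_numpy(dtype=float)
        self.fingerprint = data_fingerprint(self.data)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, terms=None) -> "ShiftedLognormalRTModel":
        return cls(data, terms)

    def _ml_for_shift(self, shift: float):
        z = self.rt - shift
        if np.any(z <= 0):
            return None  # this candidate shift is rejected
        y = np.log(z)
        beta, *_ = np.linalg.lstsq(self.exog, y, rcond=None)
        resid = y - self.exog @ beta
        sigma = float(np.sqrt(np.mean(resid**2)))
        sigma = max(sigma, 1e-12)
        llf = shifted_lognormal_loglik(self.rt, self.exog @ beta, sigma, shift)
        return beta, sigma, llf

    def fit(self, shift: float | None = None, n_boot: int = 500, seed: int | None = 0) -> FitResults:
        """ML fit; ``shift=None`` profiles the shift over a grid on [0, min rt)."""
        warnings = []
        if shift is not None:
            out = self._ml_for_shift(float(shift))
            if out is None:
                raise DataError(f"shift {shift} is not below every response time")
            best_shift = float(shift)
        else:
            grid = np.linspace(0.0, float(self.rt.min()), N_SHIFT_GRID + 1)[:-1]
            fits = [(s, self._ml_for_shift(s)) for s in grid]
            fits = [(s, f) for s, f in fits if f is not None]
            best_shift, out = max(fits, key=lambda sf: sf[1][2])
            warnings.append(f"shift profiled on a {N_SHIFT_GRID}-point grid")
        beta, sigma, llf = out

        samples = None
        if n_boot > 0:
            def refit(sub: pd.DataFrame) -> np.ndarray:
                y = np.log(sub["rt"].to_numpy(dtype=float) - best_shift)
                Xb = _design(sub, self.terms)
                b, *_ = np.linalg.lstsq(Xb, y, rcond=None)
                return b

            draws = subject_bootstrap(self.data, refit, n_boot, seed)
            samples = pd.DataFrame(draws, columns=list(self.terms))

        return FitResults(
            model_name="ShiftedLognormalRTModel",
            params=pd.Series(beta, index=list(self.terms)),
            samples=samples,
            llf=llf,
            nobs=len(self.rt),
            method="ml" if shift is not None else "ml_profiled_shift",
            kind="rt",
            warnings=warnings,
            fingerprint=self.fingerprint,
            extra={"sigma": sigma, "shift": best_shift},
        )


def fit_rt_model(data: pd.DataFrame, terms=None, **kwargs) -> FitResults:
    return ShiftedLognormalRTModel(data, terms).fit(**kwargs)
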