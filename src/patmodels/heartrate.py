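"""Gaussian condition model of trial-wise bradycardia.

Regresses raw Dhr (BPM) on the full money x shocks x action-context
factorial over standardized condition codes.  The intercept is the grand
anticipatory heart-rate change: a negative value is the group-level
bradycardia effect.  Slopes near zero confirm that the cardiac state is not
driven by the trial conditions.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .exceptions import DataError, ModelError
from .inference import FitResults, data_fingerprint, subject_bootstrap
from .params import term_column

HR_VARIABLES = ("money", "shocks", "ac")


def hr_terms() -> tuple[str, ...]:
    terms = ["intercept"]
    for r in range(1, len(HR_VARIABLES) + 1):
        for combo in combinations(HR_VARIABLES, r):
            terms.append(":".join(combo))
    return tuple(terms)


class HeartRateModel:
    """OLS of Dhr on the condition factorial, subject-bootstrap uncertainty."""

    def __init__(self, data: pd.DataFrame):
        data = data.loc[np.isfinite(data["dhr"].to_numpy(dtype=float))]
        if len(data) == 0:
            raise DataError("no trials with a Dhr value")
        self.data = data.copy()
        self.terms = hr_terms()
        self.exog = np.column_stack([term_column(self.data, t) for t in self.terms])
        self.endog = self.data["dhr"].to_numpy(dtype=float)
        self.fingerprint = data_fingerprint(self.data)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame) -> "HeartRateModel":
        return cls(data)

    def fit(self, n_boot: int = 500, seed: int | None = 0) -> FitResults:
        rank = np.linalg.matrix_rank(self.exog)
        if rank < self.exog.shape[1]:
            raise ModelError(
                f"rank-deficient design ({rank} < {self.exog.shape[1]}); "
                "check for constant or aliased condition columns"
            )
        beta, *_ = np.linalg.lstsq(self.exog, self.endog, rcond=None)
        resid = self.endog - self.exog @ beta
        sigma2 = float(np.mean(resid**2))
        n = len(self.endog)
        llf = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)

        samples = None
        if n_boot > 0:
            def refit(sub: pd.DataFrame) -> np.ndarray:
                Xb = np.column_stack([term_column(sub, t) for t in self.terms])
                b, *_ = np.linalg.lstsq(Xb, sub["dhr"].to_numpy(dtype=float), rcond=None)
                return b

            draws = subject_bootstrap(self.data, refit, n_boot, seed)
            samples = pd.DataFrame(draws, columns=list(self.terms))

        return FitResults(
            model_name="HeartRateModel",
            params=pd.Series(beta, index=list(self.terms)),
            samples=samples,
            llf=llf,
            nobs=n,
            method="ols",
            kind="heartrate",
            fingerprint=self.fingerprint,
            extra={"sigma": float(np.sqrt(sigma2))},
        )


def fit_hr_model(data: pd.DataFrame, **kwargs) -> FitResults:
    return HeartRateModel(data).fit(**kwargs)
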