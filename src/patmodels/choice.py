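"""Decision-value choice models and their likelihood-based fitting.

The model family shares eight base coefficients (intercept, money, shocks,
money:shocks, action context, Dhr, money:ac, shocks:ac) over standardized
features; each 'freezing' variant adds exactly one bradycardia interaction
(shocks:dhr for aversive value, dms:dhr for value comparison, ac:dhr for
action invigoration).  The decision value maps to an approach probability
through the logistic function, and choices are Bernoulli.

The primary fit is pooled maximum likelihood (all subjects' trials pooled)
with cluster-bootstrap uncertainty over subjects.  An optional hierarchical
method adds per-subject random intercepts via a variational mixed logistic
fit; on data without subject heterogeneity its point estimates agree with
pooled ML within bootstrap uncertainty.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from .exceptions import DataError, ModelError
from .inference import FitResults, data_fingerprint, subject_bootstrap
from .params import ParamSet, design_matrix, terms_for_kind

P_CLAMP = 1e-12
#: |coefficient| above which we declare (quasi-)separation and clamp.
SEPARATION_BOUND = 12.0


def decision_value(frame: pd.DataFrame, params: ParamSet) -> np.ndarray:
    """Trial-wise decision value DV (unbounded): X @ beta for the model kind."""
    X = design_matrix(frame, params.kind).to_numpy()
    return X @ params.as_array()


def p_approach(dv) -> np.ndarray:
    """Logistic map from decision value to approach probability."""
    return expit(np.asarray(dv, dtype=float))


def choice_loglik(frame: pd.DataFrame, params: ParamSet) -> float:
    """Bernoulli log-likelihood of observed choices under a parameter set.

    Choices are read from ``choice_code`` (+1 approach / -1 avoid) or
    ``choice``.  Probabilities are clamped at :data:`P_CLAMP` for stability.
    """
    if len(frame) == 0:
        raise DataError("empty data: log-likelihood undefined")
    y = _choice_indicator(frame)
    p = np.clip(p_approach(decision_value(frame, params)), P_CLAMP, 1 - P_CLAMP)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))


def _choice_indicator(frame: pd.DataFrame) -> np.ndarray:
    if "choice_code" in frame:
        return (frame["choice_code"].to_numpy(dtype=float) > 0).astype(float)
    if "choice" in frame:
        return (frame["choice"].to_numpy(dtype=object) == "approach").astype(float)
    raise DataError("frame carries neither 'choice_code' nor 'choice'")


def _fit_logistic_ml(X: np.ndarray, y: np.ndarray, start=None):
    """Pooled ML logistic fit; returns (beta, llf, converged)."""

    def nll_grad(beta):
        eta = X @ beta
        p = expit(eta)
        pc = np.clip(p, P_CLAMP, 1 - P_CLAMP)
        nll = -np.sum(y * np.log(pc) + (1 - y) * np.log1p(-pc))
        grad = X.T @ (p - y)
        return nll, grad

    x0 = np.zeros(X.shape[1]) if start is None else np.asarray(start, dtype=float)
    res = minimize(
        nll_grad, x0, jac=True, method="L-BFGS-B",
        options={"maxiter": 1000, "ftol": 1e-14, "gtol": 1e-8},
    )
    return res.x, -res.fun, bool(res.success)


class ApproachAvoidModel:
    """Logistic approach/avoid model over standardized PAT trial features.

    Parameters
    ----------
    data : pd.DataFrame
        Analysis-set table (post-exclusion, standardized): must carry the
        feature columns required by ``kind`` plus ``subject`` and the choice.
    kind : str
        'base', 'av', 'vc', 'ai' or 'full' (all Dhr interactions at once).
    """

    def __init__(self, data: pd.DataFrame, kind: str = "base"):
        if len(data) == 0:
            raise DataError("cannot model an empty trial table")
        self.kind = kind
        self.terms = terms_for_kind(kind)
        self.data = data
        self.exog = design_matrix(data, kind).to_numpy()
        self.endog = _choice_indicator(data)
        self.fingerprint = data_fingerprint(data)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, kind: str = "base") -> "ApproachAvoidModel":
        return cls(data, kind)

    def loglik(self, params: ParamSet) -> float:
        if params.kind != self.kind:
            raise ModelError(f"parameter kind {params.kind!r} != model kind {self.kind!r}")
        return choice_loglik(self.data, params)

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        method: str = "pooled_ml",
        n_boot: int = 500,
        seed: int | None = 0,
    ) -> FitResults:
        """Fit the model.

        ``pooled_ml`` maximizes the pooled Bernoulli likelihood; uncertainty
        comes from ``n_boot`` nonparametric bootstrap resamples over subjects
        (set ``n_boot=0`` to skip).  ``hierarchical`` adds per-subject random
        intercepts (variational approximation) and samples the approximate
        posterior.
        """
        if method == "pooled_ml":
            return self._fit_pooled(n_boot, seed)
        if method == "hierarchical":
            return self._fit_hierarchical(seed)
        raise ModelError(f"unknown fit method {method!r}")

    def _fit_pooled(self, n_boot: int, seed) -> FitResults:
        warnings = []
        y = self.endog
        if y.min() == y.max():
            warnings.append("complete separation: all choices identical")
        beta, llf, ok = _fit_logistic_ml(self.exog, y)
        if np.any(np.abs(beta) > SEPARATION_BOUND):
            warnings.append("separation suspected: estimates clamped")
            beta = np.clip(beta, -SEPARATION_BOUND, SEPARATION_BOUND)
            eta = self.exog @ beta
            p = np.clip(expit(eta), P_CLAMP, 1 - P_CLAMP)
            llf = float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))
        if not ok:
            warnings.append("optimizer did not report convergence")

        samples = None
        if n_boot > 0:
            def refit(sub: pd.DataFrame) -> np.ndarray:
                Xb = design_matrix(sub, self.kind).to_numpy()
                yb = _choice_indicator(sub)
                b, _, _ = _fit_logistic_ml(Xb, yb, start=beta)
                return np.clip(b, -SEPARATION_BOUND, SEPARATION_BOUND)

            draws = subject_bootstrap(self.data, refit, n_boot, seed)
            samples = pd.DataFrame(draws, columns=list(self.terms))

        return FitResults(
            model_name="ApproachAvoidModel",
            params=pd.Series(beta, index=list(self.terms)),
            samples=samples,
            llf=llf,
            nobs=len(y),
            method="pooled_ml",
            kind=self.kind,
            converged=ok,
            warnings=warnings,
            fingerprint=self.fingerprint,
        )

    def _fit_hierarchical(self, seed) -> FitResults:
        from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

        subjects = self.data["subject"].to_numpy()
        codes, _ = pd.factorize(subjects)
        n_sub = codes.max() + 1
        exog_vc = np.zeros((len(codes), n_sub))
        exog_vc[np.arange(len(codes)), codes] = 1.0
        ident = np.zeros(n_sub, dtype=int)
        model = BinomialBayesMixedGLM(self.endog, self.exog, exog_vc, ident)
        fit = model.fit_vb()
        beta = fit.fe_mean
        sd = fit.fe_sd
        rng = np.random.default_rng(seed)
        draws = rng.normal(beta, sd, size=(2000, len(beta)))
        p = np.clip(expit(self.exog @ beta), P_CLAMP, 1 - P_CLAMP)
        llf = float(np.sum(self.endog * np.log(p) + (1 - self.endog) * np.log1p(-p)))
        return FitResults(
            model_name="ApproachAvoidModel",
            params=pd.Series(beta, index=list(self.terms)),
            samples=pd.DataFrame(draws, columns=list(self.terms)),
            llf=llf,
            nobs=len(self.endog),
            method="hierarchical",
            kind=self.kind,
            converged=True,
            warnings=("marginal llf evaluated at posterior-mean fixed effects",),
            fingerprint=self.fingerprint,
            extra={"vcp_mean": [float(v) for v in np.atleast_1d(fit.vcp_mean)]},
        )


def fit_choice_model(
    data: pd.DataFrame, kind: str, method: str = "pooled_ml", **kwargs
) -> FitResults:
    """Functional wrapper: build and fit an :class:`ApproachAvoidModel`."""
    return ApproachAvoidModel(data, kind).fit(method=method, **kwargs)
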