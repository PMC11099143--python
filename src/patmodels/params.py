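"""Decision-value parameter sets.

The approach-avoidance decision value (DV) is a linear predictor over
standardized trial features:

    DV = b0 + bm*m + bs*s + bms*m*s + bac*ac + bhr*dhr + bmac*m*ac + bsac*s*ac
         [+ one bradycardia-interaction term, depending on the model kind]

with ``m``/``s`` the z-scored money and shock levels, ``ac`` the sum-to-zero
action-context code (-1 active, +1 passive) and ``dhr`` the z-scored
anticipatory heart-rate change (more negative = stronger bradycardia).
The four model kinds are:

``base``
    no bradycardia interaction;
``av`` (aversive value)
    adds ``shocks:dhr`` -- bradycardia amplifies threat-induced avoidance;
``vc`` (value comparison)
    adds ``dms:dhr`` with ``dms = money - shocks`` -- bradycardia sharpens
    the reward-threat comparison;
``ai`` (action invigoration)
    adds ``ac:dhr`` -- bradycardia shifts the active/passive balance.

``full`` is the saturated variant carrying all Dhr interactions at once
(used for the single-model test of all bradycardia effects).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DataError, ModelError

BASE_TERMS: tuple[str, ...] = (
    "intercept",
    "money",
    "shocks",
    "money:shocks",
    "ac",
    "dhr",
    "money:ac",
    "shocks:ac",
)

EXTRA_TERMS: dict[str, tuple[str, ...]] = {
    "base": (),
    "av": ("shocks:dhr",),
    "vc": ("dms:dhr",),
    "ai": ("ac:dhr",),
    "full": (
        "money:dhr",
        "shocks:dhr",
        "ac:dhr",
        "money:shocks:dhr",
        "money:ac:dhr",
        "shocks:ac:dhr",
    ),
}

MODEL_KINDS = tuple(EXTRA_TERMS)

#: Column in the analysis-set table backing each elementary variable.
_VARIABLE_COLUMNS = {
    "money": "z_money",
    "shocks": "z_shocks",
    "dms": "z_dms",
    "dhr": "z_dhr",
    "ac": "ac_code",
    "choice": "choice_code",
}


def terms_for_kind(kind: str) -> tuple[str, ...]:
    """Ordered coefficient names of a model kind."""
    if kind not in EXTRA_TERMS:
        raise ModelError(f"unknown model kind {kind!r}; expected one of {MODEL_KINDS}")
    return BASE_TERMS + EXTRA_TERMS[kind]


def term_column(frame: pd.DataFrame, term: str) -> np.ndarray:
    """Evaluate one design term (a product of standardized variables)."""
    if term == "intercept":
        return np.ones(len(frame))
    out = np.ones(len(frame))
    for part in term.split(":"):
        col = _VARIABLE_COLUMNS.get(part)
        if col is None:
            raise ModelError(f"unknown model term component {part!r}")
        if col not in frame.columns:
            raise DataError(f"column {col!r} required by term {term!r} is missing")
        out = out * frame[col].to_numpy(dtype=float)
    return out


def design_matrix(frame: pd.DataFrame, kind: str) -> pd.DataFrame:
    """Design matrix (one column per coefficient) for a model kind."""
    terms = terms_for_kind(kind)
    cols = {t: term_column(frame, t) for t in terms}
    return pd.DataFrame(cols, index=frame.index)


@dataclass(frozen=True)
class ParamSet:
    """Coefficient vector of one decision-value model.

    ``values`` is indexed by the term names of ``kind`` (see
    :func:`terms_for_kind`); construction validates the match.
    """

    kind: str
    values: pd.Series = field(repr=False)

    def __post_init__(self):
        expected = terms_for_kind(self.kind)
        got = tuple(self.values.index)
        if got != expected:
            raise ModelError(
                f"parameter set for kind {self.kind!r} must carry terms "
                f"{expected}, got {got}"
            )

    @classmethod
    def from_dict(cls, kind: str, coefficients: dict[str, float]) -> "ParamSet":
        expected = terms_for_kind(kind)
        missing = [t for t in expected if t not in coefficients]
        extra = [t for t in coefficients if t not in expected]
        if missing or extra:
            raise ModelError(
                f"kind {kind!r}: missing terms {missing}, unexpected terms {extra}"
            )
        return cls(kind, pd.Series({t: float(coefficients[t]) for t in expected}))

    def __getitem__(self, term: str) -> float:
        return float(self.values[term])

    def as_array(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def to_dict(self) -> dict[str, float]:
        return {k: float(v) for k, v in self.values.items()}


# Canonical group-level estimates for each model variant, used as the default
# generating values for simulation and as the fixed coefficients from which
# trial-wise DV regressors are computed.  Rows share the eight base terms and
# differ only in which single bradycardia interaction they carry.
_REFERENCE_ROWS: dict[str, dict[str, float]] = {
    "base": {
        "intercept": 0.73, "money": 1.54, "shocks": -1.10, "money:shocks": 0.41,
        "ac": 0.07, "dhr": 0.05, "money:ac": -0.28, "shocks:ac": 0.09,
    },
    "av": {
        "intercept": 0.73, "money": 1.54, "shocks": -1.11, "money:shocks": 0.40,
        "ac": 0.07, "dhr": 0.04, "money:ac": -0.28, "shocks:ac": 0.09,
        "shocks:dhr": 0.07,
    },
    "vc": {
        "intercept": 0.73, "money": 1.55, "shocks": -1.11, "money:shocks": 0.40,
        "ac": 0.07, "dhr": 0.03, "money:ac": -0.28, "shocks:ac": 0.09,
        "dms:dhr": -0.09,
    },
    "ai": {
        "intercept": 0.73, "money": 1.54, "shocks": -1.10, "money:shocks": 0.40,
        "ac": 0.07, "dhr": 0.05, "money:ac": -0.28, "shocks:ac": 0.09,
        "ac:dhr": 0.05,
    },
}


def reference_params(kind: str) -> ParamSet:
    """The canonical group-level :class:`ParamSet` for ``kind``."""
    if kind not in _REFERENCE_ROWS:
        raise ModelError(f"no reference parameter set for kind {kind!r}")
    return ParamSet.from_dict(kind, _REFERENCE_ROWS[kind])
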