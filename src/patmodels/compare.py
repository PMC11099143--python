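"""Information-criterion comparison of choice-model fits on identical data."""

from __future__ import annotations

import pandas as pd

from .exceptions import ModelError
from .inference import FitResults


def compare_models(fits) -> pd.DataFrame:
    """Rank fitted choice models by AIC (pooled ML fits).

    All fits must share a data fingerprint (same trials, same choices); a
    mismatch raises rather than silently comparing incomparable likelihoods.
    Ties in the criterion break toward fewer parameters.
    """
    fits = list(fits)
    if len(fits) < 2:
        raise ModelError("need at least two fits to compare")
    prints = {f.fingerprint for f in fits}
    if len(prints) != 1 or None in prints:
        raise ModelError("fits were not produced on identical data (fingerprint mismatch)")
    methods = {f.method for f in fits}
    if len(methods) != 1:
        raise ModelError(f"cannot mix fit methods in one comparison: {sorted(methods)}")

    rows = []
    for f in fits:
        rows.append(
            {"model": f.kind, "llf": f.llf, "k_params": f.k_params, "aic": f.aic}
        )
    table = pd.DataFrame(rows).set_index("model")
    table = table.sort_values(["aic", "k_params"], kind="stable")
    table["delta_aic"] = table["aic"] - table["aic"].min()
    table["rank"] = range(1, len(table) + 1)
    return table
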