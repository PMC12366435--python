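"""Packaged reference values: the published discriminator table.

The published analysis reports, for each of the 46 significant
lexicogrammatical items, the bootstrap mean and SD of its logistic
coefficient and the derived two-sided p-value (all printed to 4 decimals).
Those printed rows are packaged here as data: they seed the synthetic
preset's effect signs and anchor the p-value-formula checks.
"""

from __future__ import annotations

import json
from importlib import resources as _ir

import pandas as pd

_CACHE: pd.DataFrame | None = None


def reference_table() -> pd.DataFrame:
    """The 46 published rows: lexicogrammar, mean, sd, p_value (4-dp floats)."""
    global _CACHE
    if _CACHE is None:
        ref = _ir.files("tagdisc") / "resources" / "table1_reference.json"
        payload = json.loads(ref.read_text(encoding="utf-8"))
        _CACHE = pd.DataFrame(payload["rows"])
    return _CACHE.copy()


def reference_items() -> tuple[str, ...]:
    """Names of the 46 published discriminator items, table order."""
    return tuple(reference_table()["lexicogrammar"])


def positive_mean_items() -> tuple[str, ...]:
    """The items whose published coefficient mean is positive (ASD-increased)."""
    df = reference_table()
    return tuple(df.loc[df["mean"] > 0, "lexicogrammar"])
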