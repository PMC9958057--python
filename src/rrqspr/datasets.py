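"""Packaged study data: the 26-molecule benzenoid property table, the
published reduced-reverse Randić (α = −1) descriptor column for those
molecules, the published linear/quadratic model coefficients, and the HAP
conjugate edge partition.

The 26 benzenoid hydrocarbons are keyed by ordinal (``sno``) only — the
source study never names them, so no structures are guessed and the
descriptor column is shipped as data rather than recomputed.  Loaders return
defensive copies; fixtures are validated on load.
"""

from __future__ import annotations

import json
from copy import deepcopy
from importlib import resources

import pandas as pd

from .indices import SymbolicEdgePartition
from .qspr import CHI2_CRITICAL_25DF_5PCT, RegressionModel

__all__ = [
    "PROPERTY_COLUMNS",
    "load_fixture",
    "available_fixtures",
    "load_benzenoid_properties",
    "load_benzenoid_ti",
    "load_published_models",
    "load_hap_partition",
]

#: the twelve physico-chemical property columns of the benzenoid table
PROPERTY_COLUMNS = ["BP", "CT", "CP", "CV", "GE", "LogP", "MR", "HL", "PI", "MW", "EM", "HAC"]


def _read_text(name: str) -> str:
    return resources.files("rrqspr.data").joinpath(name).read_text()


def load_benzenoid_properties() -> pd.DataFrame:
    """26 benzenoid hydrocarbons × 12 properties, indexed by ordinal."""
    with resources.as_file(resources.files("rrqspr.data").joinpath("benzenoid_properties.csv")) as p:
        df = pd.read_csv(p, index_col="sno")
    if df.shape != (26, 12):
        raise ValueError(f"benzenoid property table has shape {df.shape}, expected (26, 12)")
    if list(df.columns) != PROPERTY_COLUMNS:
        raise ValueError("unexpected property columns")
    if df.isna().any().any():
        raise ValueError("benzenoid property table has missing cells")
    if not (df["EM"] < df["MW"]).all():
        raise ValueError("exact mass must be below molecular weight")
    if not ((df["HAC"] > 0) & (df["HAC"] == df["HAC"].astype(int))).all():
        raise ValueError("heavy atom count must be a positive integer")
    return df


def load_benzenoid_ti() -> pd.Series:
    """Published RRR(α=−1) descriptor values for the 26 benzenoid molecules."""
    with resources.as_file(resources.files("rrqspr.data").joinpath("benzenoid_ti.csv")) as p:
        df = pd.read_csv(p, index_col="sno")
    s = df["RRR_-1"]
    if len(s) != 26 or s.isna().any():
        raise ValueError("descriptor column must have 26 complete values")
    return s


def load_published_models() -> dict:
    """Published model coefficients: per property, the winning descriptor and
    its linear (α₁, γ) and quadratic (α₁, α₂, γ) coefficients, as
    :class:`~rrqspr.qspr.RegressionModel` objects without diagnostics."""
    obj = json.loads(_read_text("published_models.json"))
    out = {"chi2_critical": obj["chi2_critical"], "linear": {}, "quadratic": {}}
    for prop, row in obj["linear"].items():
        out["linear"][prop] = RegressionModel(
            1, alpha1=row["alpha1"], gamma=row["gamma"],
            property_name=prop, index_name=row["index"],
        )
    for prop, row in obj["quadratic"].items():
        out["quadratic"][prop] = RegressionModel(
            2, alpha1=row["alpha1"], alpha2=row["alpha2"], gamma=row["gamma"],
            property_name=prop, index_name=row["index"],
        )
    return out


def load_hap_partition() -> SymbolicEdgePartition:
    """Reduced-reverse edge partition of the (HAP)_n conjugate (nine classes)."""
    sp = SymbolicEdgePartition.from_json(_read_text("hap_partition.json"))
    if len(sp.classes) != 9:
        raise ValueError(f"HAP partition has {len(sp.classes)} classes, expected 9")
    return sp


_REGISTRY = {
    "benzenoid_properties": load_benzenoid_properties,
    "benzenoid_ti": load_benzenoid_ti,
    "published_models": load_published_models,
    "hap_partition": load_hap_partition,
    "chi2_critical": lambda: CHI2_CRITICAL_25DF_5PCT,
}


def available_fixtures() -> list[str]:
    return sorted(_REGISTRY)


def load_fixture(name: str):
    """Load a packaged fixture by name (defensive copy)."""
    try:
        loader = _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(available_fixtures())}"
        ) from None
    obj = loader()
    if isinstance(obj, (pd.DataFrame, pd.Series)):
        return obj.copy()
    if isinstance(obj, (int, float, str)):
        return obj
    return deepcopy(obj)
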