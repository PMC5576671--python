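"""Univariate community responses: densities, richness, Shannon diversity.

Fish densities are square-root transformed before modelling; every
response is then z-standardized over the full set of transects so that
model coefficients are comparable across responses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .survey import DensityTable


def shannon(abundances) -> float:
    """Shannon diversity H' in nats, from species relative abundances.

    H' = -sum p_i ln p_i over species with positive abundance.
    """
    a = np.asarray(abundances, dtype=float)
    if (a < 0).any():
        raise ValueError("abundances must be nonnegative")
    total = a.sum()
    if total == 0:
        raise ValueError("Shannon index undefined for an all-zero abundance vector")
    p = a[a > 0] / total
    p = p[p > 0]  # proportions can underflow for denormal abundances
    return float(-(p * np.log(p)).sum())


def richness(abundances) -> int:
    """Number of species with positive abundance."""
    a = np.asarray(abundances, dtype=float)
    return int((a > 0).sum())


@dataclass
class ResponseVector:
    """A per-sample response with its grouping labels and transform tag."""

    name: str
    values: pd.Series
    sample_info: pd.DataFrame
    transform_tag: Literal["raw", "sqrt", "z", "sqrt+z"]

    def to_frame(self) -> pd.DataFrame:
        out = self.sample_info.copy()
        out[self.name] = self.values
        out["transform_tag"] = self.transform_tag
        return out


def transform_standardize(values, transform: Literal["sqrt", "none"] = "sqrt",
                          ddof: int = 0) -> np.ndarray:
    """Optional element-wise square root, then z-score over the whole vector."""
    x = np.asarray(values, dtype=float)
    if transform == "sqrt":
        if (x < 0).any():
            raise ValueError("square-root transform requires nonnegative values")
        x = np.sqrt(x)
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    sd = x.std(ddof=ddof)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot standardize a zero-variance vector")
    return (x - x.mean()) / sd


def response_table(table: DensityTable, transform: Literal["sqrt", "none"] = "sqrt",
                   standardize: bool = True) -> pd.DataFrame:
    """Per-sample responses ready for mixed modelling.

    Returns the grouping columns plus ``density`` (total individuals per
    100 m^2, transformed/standardized as requested), ``richness`` and
    ``shannon`` (raw scale unless ``standardize``).  Samples with no fish
    at all get Shannon = 0 by convention so the response is defined on
    every transect.
    """
    vals = table.values.to_numpy()
    total = vals.sum(axis=1)
    rich = (vals > 0).sum(axis=1).astype(float)
    shan = np.array([shannon(v) if v.sum() > 0 else 0.0 for v in vals])
    out = table.sample_info.copy()
    if standardize:
        out["density"] = transform_standardize(total, transform)
        out["richness"] = transform_standardize(rich, "none")
        out["shannon"] = transform_standardize(shan, "none")
        out.attrs["transform_tag"] = ("sqrt+z" if transform == "sqrt" else "z")
    else:
        out["density"] = np.sqrt(total) if transform == "sqrt" else total
        out["richness"] = rich
        out["shannon"] = shan
        out.attrs["transform_tag"] = transform
    return out
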