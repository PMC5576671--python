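"""Pairwise species covariation: synchrony vs compensatory dynamics.

For every unordered pair of species observed under both management
levels, the density of the alphabetically later species is regressed on
the alphabetically earlier one across site x season points (site-level
mean densities), with a site random intercept; the regression slope
measures how the two species covary over the monsoon cycle within that
management level.  A positive mean slope indicates synchronized dynamics
(e.g. unselective fishing pressing on all species at once); a negative
one indicates compensation.  The mean slopes of the two management
levels are compared with a paired t-test over the common pairs.

Because "correlation slope" is used loosely in the field for either a
regression slope or a correlation coefficient, a Pearson correlation per
pair is available behind ``statistic="correlation"``; slopes are the
default.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .lmm import CommunityLMM
from .survey import DensityTable

logger = logging.getLogger(__name__)


@dataclass
class PairSlopeTable:
    """Per-pair slopes within one management level."""

    table: pd.DataFrame          # species_i, species_j, slope, n, fit_tag
    management: str
    statistic: str = "slope"
    excluded: list[tuple[str, str, str]] = None  # (sp_i, sp_j, reason)

    def mean_slope(self) -> float:
        return float(self.table["slope"].mean())

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out.insert(2, "management", self.management)
        out.to_csv(path, index=False)


def shared_species(table: DensityTable) -> list[str]:
    """Species observed (density > 0 somewhere) in both management levels."""
    present = {}
    for mgmt, grp in table.sample_info.groupby("management"):
        vals = table.values.loc[grp.index]
        present[mgmt] = set(np.asarray(table.species)[(vals > 0).any(axis=0)])
    if len(present) < 2:
        raise ValueError("table does not contain both management levels")
    common = set.intersection(*present.values())
    return sorted(common)


def pairwise_slopes(table: DensityTable, management: str,
                    species: list[str] | None = None,
                    statistic: str = "slope",
                    min_points: int = 3) -> PairSlopeTable:
    """Fit a slope for every unordered species pair within one management.

    ``table`` must be a site-level, mean-aggregated density table (one
    value per species, site and season).  The pair's canonical
    orientation is alphabetical: the later species is regressed on the
    earlier one.  Pairs whose predictor has zero variance are excluded
    and logged.  The mixed model falls back to ordinary least squares
    (tagged) when the site variance is zero or the fit is singular.
    """
    if table.level != "site" or table.aggregation != "mean":
        raise ValueError("pairwise slopes are defined on site-level mean densities")
    if species is None:
        species = shared_species(table)
    if len(species) < 2:
        raise ValueError("need at least 2 shared species")
    mask = table.sample_info["management"] == management
    if mask.sum() == 0:
        raise ValueError(f"no samples with management {management!r}")
    vals = table.values.loc[mask]
    sites = table.sample_info.loc[mask, "site"].to_numpy()

    rows = []
    excluded: list[tuple[str, str, str]] = []
    for sp_i, sp_j in itertools.combinations(sorted(species), 2):
        x = vals[sp_i].to_numpy(dtype=float)
        y = vals[sp_j].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < min_points:
            excluded.append((sp_i, sp_j, "too few points"))
            logger.warning("pair (%s, %s): only %d usable points, skipped",
                           sp_i, sp_j, ok.sum())
            continue
        if np.ptp(x[ok]) == 0:
            excluded.append((sp_i, sp_j, "zero-variance predictor"))
            logger.info("pair (%s, %s): predictor has zero variance, excluded",
                        sp_i, sp_j)
            continue
        if statistic == "correlation":
            if np.ptp(y[ok]) == 0:
                excluded.append((sp_i, sp_j, "zero-variance response"))
                continue
            r = float(np.corrcoef(x[ok], y[ok])[0, 1])
            rows.append({"species_i": sp_i, "species_j": sp_j, "slope": r,
                         "n": int(ok.sum()), "fit_tag": "pearson"})
            continue
        slope, tag = _pair_slope(x[ok], y[ok], sites[ok])
        rows.append({"species_i": sp_i, "species_j": sp_j, "slope": slope,
                     "n": int(ok.sum()), "fit_tag": tag})
    return PairSlopeTable(table=pd.DataFrame(
        rows, columns=["species_i", "species_j", "slope", "n", "fit_tag"]),
        management=management, statistic=statistic, excluded=excluded)


def _pair_slope(x: np.ndarray, y: np.ndarray, sites: np.ndarray
                ) -> tuple[float, str]:
    df = pd.DataFrame({"x": x, "y": y, "site": sites})
    if np.ptp(y) > 0 and len(np.unique(sites)) >= 2:
        try:
            fit = CommunityLMM.from_dataframe(df, "y", fixed=("x",),
                                              group="site").fit(reml=True)
            tag = "lmm" if fit.sigma2_site > 0 else "lmm(site-var=0)"
            sl = fit.model.design_info.term_slices["x"]
            return float(fit.params.iloc[sl.start]), tag
        except (ValueError, np.linalg.LinAlgError):
            pass
    slope = float(np.polyfit(x, y, 1)[0])
    return slope, "ols-fallback"


@dataclass
class SlopeComparison:
    """Paired comparison of mean pair slopes between management levels."""

    mean_mpa: float
    mean_open: float
    t: float
    df: int
    p: float
    n_pairs: int
    degenerate: bool = False

    def summary(self) -> str:
        tail = " (degenerate: zero-variance differences)" if self.degenerate else ""
        return (f"mean slope MPA = {self.mean_mpa:.4f}, "
                f"open = {self.mean_open:.4f}; paired t({self.df}) = "
                f"{self.t:.4f}, P = {self.p:.4f}, n = {self.n_pairs}{tail}")

    def to_json_dict(self) -> dict:
        return {"mean_mpa": self.mean_mpa, "mean_open": self.mean_open,
                "t": self.t, "df": self.df, "p": self.p,
                "n_pairs": self.n_pairs, "degenerate": self.degenerate}


def compare_mean_slopes(mpa: PairSlopeTable, open_: PairSlopeTable
                        ) -> SlopeComparison:
    """Paired t-test of per-pair slope differences (open - MPA).

    Only pairs present in both tables enter the test; the intersection is
    logged when pairs are dropped.  All-zero differences give t = 0,
    p = 1; nonzero differences with zero variance are degenerate and
    reported with an infinite t.
    """
    key = ["species_i", "species_j"]
    a = mpa.table.set_index(key)["slope"]
    b = open_.table.set_index(key)["slope"]
    common = a.index.intersection(b.index)
    if len(common) < len(a) or len(common) < len(b):
        logger.info("paired comparison restricted to %d common pairs "
                    "(MPA %d, open %d)", len(common), len(a), len(b))
    if len(common) < 2:
        raise ValueError("need at least 2 common species pairs")
    diffs = (b.loc[common] - a.loc[common]).to_numpy(dtype=float)
    n = len(diffs)
    mean_mpa = float(a.loc[common].mean())
    mean_open = float(b.loc[common].mean())
    sd = diffs.std(ddof=1)
    if sd == 0:
        if np.allclose(diffs, 0):
            return SlopeComparison(mean_mpa, mean_open, 0.0, n - 1, 1.0, n,
                                   degenerate=True)
        t = float(np.inf * np.sign(diffs.mean()))
        return SlopeComparison(mean_mpa, mean_open, t, n - 1, 0.0, n,
                               degenerate=True)
    t = float(diffs.mean() / (sd / np.sqrt(n)))
    p = float(2 * stats.t.sf(abs(t), n - 1))
    return SlopeComparison(mean_mpa, mean_open, t, n - 1, p, n)


def plot_slopes(mpa: PairSlopeTable, open_: PairSlopeTable, ax=None):
    """Distribution of pair slopes per management level."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for tbl, color in ((mpa, "seagreen"), (open_, "darkorange")):
        vals = tbl.table["slope"].to_numpy()
        ax.hist(vals, bins=30, alpha=0.5, color=color,
                label=f"{tbl.management} (mean {vals.mean():.3f})")
        ax.axvline(vals.mean(), color=color, lw=2)
    ax.axvline(0, color="k", lw=0.8, ls=":")
    ax.set_xlabel("pairwise slope")
    ax.set_ylabel("number of species pairs")
    ax.legend()
    return ax
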