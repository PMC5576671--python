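"""Bray-Curtis dissimilarity and non-metric multidimensional scaling.

nMDS embeds samples in a low-dimensional space so that the rank order of
configuration distances matches the rank order of the input
dissimilarities; fit quality is Kruskal's stress-1,

    stress = sqrt( sum_ij (d_ij - dhat_ij)^2 / sum_ij d_ij^2 ),

where d are configuration distances and dhat the disparities obtained by
isotonic (monotone) regression of d on the input dissimilarities.  The
optimizer alternates isotonic regression with a Guttman transform
(nonmetric SMACOF) and keeps the best configuration over restarts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression


@dataclass
class DissimilarityMatrix:
    """Symmetric sample x sample dissimilarities with labels."""

    data: np.ndarray
    ids: list[str]
    method: str = "bray-curtis"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.ids)
        if self.data.shape != (n, n):
            raise ValueError("matrix shape does not match number of ids")
        if not np.isfinite(self.data).all():
            raise ValueError("dissimilarities must be finite")
        if not np.allclose(self.data, self.data.T):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(self.data), 0.0):
            raise ValueError("dissimilarity matrix must have a zero diagonal")
        if (self.data < 0).any():
            raise ValueError("dissimilarities must be nonnegative")

    def __len__(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.data, checks=False)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.ids, columns=self.ids)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)

    @classmethod
    def from_csv(cls, path, method: str = "bray-curtis") -> "DissimilarityMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=float), [str(i) for i in df.index], method)


def bray_curtis(table) -> DissimilarityMatrix:
    """Bray-Curtis dissimilarities between the rows of a density table.

    d(x, y) = sum_i |x_i - y_i| / sum_i (x_i + y_i); a pair of all-zero
    samples is assigned d = 0 so age-class-filtered tables with empty
    samples stay well defined.
    """
    if hasattr(table, "values") and hasattr(table, "sample_info"):
        values = table.values.to_numpy(dtype=float)
        ids = list(table.values.index)
    else:
        df = pd.DataFrame(table)
        values = df.to_numpy(dtype=float)
        ids = [str(i) for i in df.index]
    if (values < 0).any():
        raise ValueError("Bray-Curtis requires nonnegative abundances")
    diff = np.abs(values[:, None, :] - values[None, :, :]).sum(axis=2)
    tot = (values[:, None, :] + values[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(tot > 0, diff / np.where(tot > 0, tot, 1.0), 0.0)
    np.fill_diagonal(d, 0.0)
    return DissimilarityMatrix((d + d.T) / 2.0, ids, "bray-curtis")


# ---------------------------------------------------------------------------
# nMDS
# ---------------------------------------------------------------------------

@dataclass
class NMDSResults:
    """Fitted ordination: per-sample coordinates and Kruskal stress-1."""

    coords: pd.DataFrame
    stress: float
    converged: bool
    n_restarts: int
    seed: int | None
    stress_history: list[float] = field(default_factory=list)
    restart_stresses: list[float] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.coords.shape[1]

    def to_csv(self, path) -> None:
        self.coords.to_csv(path)

    def plot(self, sample_info: pd.DataFrame | None = None, ax=None):
        """Scatter the configuration; with site/season info, draw per-site
        seasonal trajectories (chronological order)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        xy = self.coords.to_numpy()
        ax.scatter(xy[:, 0], xy[:, 1], s=25, zorder=3)
        if sample_info is not None and {"site", "season"} <= set(sample_info.columns):
            from .survey import SEASONS
            order = {s: i for i, s in enumerate(SEASONS)}
            for site, grp in sample_info.groupby("site"):
                idx = grp.sort_values("season", key=lambda s: s.map(order)).index
                pts = self.coords.loc[idx].to_numpy()
                ax.plot(pts[:, 0], pts[:, 1], "-", alpha=0.6, label=str(site))
            ax.legend(fontsize="small")
        ax.set_xlabel("nMDS1")
        ax.set_ylabel("nMDS2")
        ax.set_title(f"stress = {self.stress:.4f}")
        return ax


def _stress1(d: np.ndarray, dhat: np.ndarray) -> float:
    denom = float((d ** 2).sum())
    if denom == 0:
        return 0.0
    return float(np.sqrt(((d - dhat) ** 2).sum() / denom))


def _pcoa_init(dmat: np.ndarray, k: int) -> np.ndarray:
    n = dmat.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (dmat ** 2) @ j
    w, v = np.linalg.eigh(g)
    order = np.argsort(w)[::-1][:k]
    coords = v[:, order] * np.sqrt(np.clip(w[order], 0.0, None))
    return coords


class NMDS:
    """Non-metric MDS model over a dissimilarity matrix.

    Parameters
    ----------
    dissimilarity : DissimilarityMatrix
    n_components : embedding dimensionality (2 is the conventional choice
        for community ordination plots).
    """

    def __init__(self, dissimilarity: DissimilarityMatrix, n_components: int = 2):
        if len(dissimilarity) < n_components + 1:
            raise ValueError("need at least n_components + 1 samples")
        self.d = dissimilarity
        self.k = n_components

    def fit(self, n_restarts: int = 20, max_iter: int = 300, tol: float = 1e-7,
            seed: int | None = None) -> NMDSResults:
        """Best configuration over restarts.

        The first restart starts from the metric (principal-coordinate)
        solution, the others from random Gaussian configurations.  Within a
        restart, stress-1 is tracked after every isotonic + Guttman step
        and iteration stops as soon as the improvement falls below ``tol``
        (or stress would increase), so the recorded stress path is
        non-increasing.
        """
        rng = np.random.default_rng(seed)
        delta = self.d.condensed()
        best: tuple[float, np.ndarray, bool, list[float]] | None = None
        restart_stresses = []
        for r in range(n_restarts):
            if r == 0:
                x0 = _pcoa_init(self.d.data, self.k)
            else:
                x0 = rng.normal(size=(len(self.d), self.k))
            stress, coords, conv, hist = self._one_run(x0, delta, max_iter, tol)
            restart_stresses.append(stress)
            if best is None or stress < best[0]:
                best = (stress, coords, conv, hist)
        stress, coords, conv, hist = best
        coords = coords - coords.mean(axis=0)
        df = pd.DataFrame(coords, index=list(self.d.ids),
                          columns=[f"nMDS{i + 1}" for i in range(self.k)])
        return NMDSResults(coords=df, stress=stress, converged=conv,
                           n_restarts=n_restarts, seed=seed,
                           stress_history=hist, restart_stresses=restart_stresses)

    def _one_run(self, x: np.ndarray, delta: np.ndarray, max_iter: int,
                 tol: float):
        n = x.shape[0]
        iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
        d = pdist(x)
        dhat = iso.fit_transform(delta, d)
        stress = _stress1(d, dhat)
        history = [stress]
        converged = False
        for _ in range(max_iter):
            # Guttman transform with current disparities
            dsq = squareform(d, checks=False)
            dhat_sq = squareform(dhat, checks=False)
            with np.errstate(divide="ignore", invalid="ignore"):
                b = np.where(dsq > 0, -dhat_sq / np.where(dsq > 0, dsq, 1.0), 0.0)
            np.fill_diagonal(b, -b.sum(axis=1))
            x_new = b @ x / n
            d_new = pdist(x_new)
            dhat_new = iso.fit_transform(delta, d_new)
            stress_new = _stress1(d_new, dhat_new)
            if stress_new > stress - tol:
                converged = stress_new >= stress - tol and np.isfinite(stress_new)
                if stress_new < stress:
                    x, d, dhat, stress = x_new, d_new, dhat_new, stress_new
                    history.append(stress)
                break
            x, d, dhat, stress = x_new, d_new, dhat_new, stress_new
            history.append(stress)
        return stress, x, converged, history


def nmds(dissimilarity: DissimilarityMatrix, n_components: int = 2,
         n_restarts: int = 20, max_iter: int = 300, tol: float = 1e-7,
         seed: int | None = None) -> NMDSResults:
    """Functional wrapper around :class:`NMDS`."""
    return NMDS(dissimilarity, n_components).fit(
        n_restarts=n_restarts, max_iter=max_iter, tol=tol, seed=seed)
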