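"""PERMANOVA with strata-constrained permutations, and SIMPER.

PERMANOVA partitions a dissimilarity matrix by a sequence of categorical
predictors (sequential, i.e. Type I, sums of squares on the
Gower-centred inner-product matrix) and tests each term's pseudo-F
against permutations of the sample labels.  When sites are revisited
across seasons, permutations are constrained to shuffle samples only
within each site (the strata), which respects the repeated-measures
structure of the survey.

SIMPER decomposes the average between-group Bray-Curtis dissimilarity
into per-species contributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ordination import DissimilarityMatrix


def _dummy(codes: pd.Series) -> np.ndarray:
    """Treatment-coded dummy columns (first level dropped)."""
    levels = sorted(pd.unique(codes))
    if len(levels) < 2:
        raise ValueError(f"predictor {codes.name!r} is constant")
    return np.column_stack([(codes == lv).to_numpy(float) for lv in levels[1:]])


def _term_matrix(term: str, data: pd.DataFrame) -> np.ndarray:
    parts = term.split(":")
    mats = []
    for p in parts:
        if p not in data.columns:
            raise KeyError(f"term {term!r}: column {p!r} not in predictor table")
        mats.append(_dummy(data[p]))
    out = mats[0]
    for m in mats[1:]:
        out = np.einsum("ij,ik->ijk", out, m).reshape(out.shape[0], -1)
    return out


def _hat(x: np.ndarray) -> tuple[np.ndarray, int]:
    q, r = np.linalg.qr(x)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    q = q[:, keep]
    return q @ q.T, int(keep.sum())


@dataclass
class PermanovaResults:
    """Sequential pseudo-F table with permutation p-values."""

    table: pd.DataFrame
    n_permutations: int
    strata: pd.Series | None
    seed: int | None

    def summary(self) -> str:
        lines = ["PERMANOVA (sequential SS, Bray-Curtis)",
                 f"permutations: {self.n_permutations}"
                 + ("" if self.strata is None else
                    f", constrained within strata ({self.strata.name})"), ""]
        lines.append(self.table.to_string(float_format=lambda v: f"{v:.4f}"))
        return "\n".join(lines)


class Permanova:
    """Permutational multivariate ANOVA over a dissimilarity matrix.

    Parameters
    ----------
    dissimilarity : DissimilarityMatrix
    data : per-sample predictor table aligned with the matrix ids.
    terms : model terms in the order their sums of squares are stripped
        out (``a:b`` denotes an interaction).
    strata : optional column name in ``data``; permutations then shuffle
        samples only within each level of that column.
    """

    def __init__(self, dissimilarity: DissimilarityMatrix, data: pd.DataFrame,
                 terms: tuple[str, ...] = ("season", "management", "season:management"),
                 strata: str | None = None):
        if list(data.index) != list(dissimilarity.ids):
            data = data.loc[list(dissimilarity.ids)]
        self.d = dissimilarity
        self.data = data
        self.terms = tuple(terms)
        self.strata = strata
        n = len(dissimilarity)
        j = np.eye(n) - np.ones((n, n)) / n
        self.g = -0.5 * j @ (dissimilarity.data ** 2) @ j
        # cumulative hat matrices for sequential SS
        x = np.ones((n, 1))
        self._hats = []
        self._dfs = []
        rank_prev = 1
        for term in self.terms:
            x = np.column_stack([x, _term_matrix(term, data)])
            h, rank = _hat(x)
            self._hats.append(h)
            self._dfs.append(rank - rank_prev)
            rank_prev = rank
        self._rank_full = rank_prev
        if self.strata is not None:
            counts = data[self.strata].value_counts()
            if (counts < 2).any():
                raise ValueError("every stratum must contain at least 2 samples")

    # -- permutation machinery --------------------------------------------

    def permutations(self, n_perm: int, seed: int | None = None):
        """Yield index permutations honouring the strata constraint."""
        rng = np.random.default_rng(seed)
        n = len(self.d)
        if self.strata is None:
            for _ in range(n_perm):
                yield rng.permutation(n)
        else:
            groups = [np.flatnonzero((self.data[self.strata] == lv).to_numpy())
                      for lv in pd.unique(self.data[self.strata])]
            for _ in range(n_perm):
                perm = np.arange(n)
                for idx in groups:
                    perm[idx] = idx[rng.permutation(len(idx))]
                yield perm

    def _seq_f(self, g: np.ndarray) -> np.ndarray:
        ss_total = float(np.trace(g))
        ss_terms = []
        prev = float(np.sum(g)) / g.shape[0]  # tr(H0 G); ~0 once G is centred
        for h in self._hats:
            cur = float(np.sum(h * g))
            ss_terms.append(cur - prev)
            prev = cur
        ss_res = ss_total - prev
        df_res = len(self.d) - self._rank_full
        ms_res = ss_res / df_res
        f = np.array([ss / df / ms_res for ss, df in zip(ss_terms, self._dfs)])
        return f, np.asarray(ss_terms), ss_res, ss_total

    def fit(self, n_perm: int = 999, seed: int | None = None) -> PermanovaResults:
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        f_obs, ss_terms, ss_res, ss_total = self._seq_f(self.g)
        exceed = np.zeros(len(self.terms))
        for perm in self.permutations(n_perm, seed):
            gp = self.g[np.ix_(perm, perm)]
            f_perm, *_ = self._seq_f(gp)
            exceed += f_perm >= f_obs - 1e-12
        pvals = (1.0 + exceed) / (1.0 + n_perm)
        n = len(self.d)
        df_res = n - self._rank_full
        rows = []
        for term, df, ss, f, p in zip(self.terms, self._dfs, ss_terms, f_obs, pvals):
            rows.append({"term": term, "df": df, "SumOfSqs": ss,
                         "R2": ss / ss_total, "F": f, "p": p})
        rows.append({"term": "Residual", "df": df_res, "SumOfSqs": ss_res,
                     "R2": ss_res / ss_total, "F": np.nan, "p": np.nan})
        rows.append({"term": "Total", "df": n - 1, "SumOfSqs": ss_total,
                     "R2": 1.0, "F": np.nan, "p": np.nan})
        table = pd.DataFrame(rows).set_index("term")
        strata_series = self.data[self.strata] if self.strata else None
        return PermanovaResults(table=table, n_permutations=n_perm,
                                strata=strata_series, seed=seed)


def permanova(dissimilarity: DissimilarityMatrix, data: pd.DataFrame,
              terms=("season", "management", "season:management"),
              strata: str | None = None, n_perm: int = 999,
              seed: int | None = None) -> PermanovaResults:
    """Functional wrapper around :class:`Permanova`."""
    return Permanova(dissimilarity, data, terms, strata).fit(n_perm, seed)


# ---------------------------------------------------------------------------
# SIMPER
# ---------------------------------------------------------------------------

@dataclass
class SimperResults:
    """Per-species contributions to between-group dissimilarity."""

    table: pd.DataFrame          # ranked by contribution
    groups: tuple[str, str]
    overall: float               # mean between-group Bray-Curtis
    n_permutations: int = 0

    def summary(self) -> str:
        head = (f"SIMPER: {self.groups[0]} vs {self.groups[1]}; "
                f"mean between-group dissimilarity {self.overall:.4f}")
        return head + "\n\n" + self.table.to_string(
            float_format=lambda v: f"{v:.4f}")


def _simper_contrib(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Mean per-species contribution over all between-group sample pairs."""
    n_pairs = a.shape[0] * b.shape[0]
    contrib = np.zeros(a.shape[1])
    for x in a:
        diff = np.abs(x[None, :] - b)              # (nb, p)
        tot = (x[None, :] + b).sum(axis=1)         # (nb,)
        ok = tot > 0
        contrib += (diff[ok] / tot[ok, None]).sum(axis=0)
    return contrib / n_pairs


def simper(table, groups: pd.Series | str, n_perm: int = 0,
           seed: int | None = None) -> SimperResults:
    """Species contributions to the mean between-group Bray-Curtis.

    ``groups`` is a two-level label per sample (or the name of a column in
    the table's sample_info).  With ``n_perm`` > 0, a per-species
    permutation p-value tests whether the species' contribution exceeds
    what random group assignment would give.
    """
    if hasattr(table, "values") and hasattr(table, "sample_info"):
        values = table.values
        if isinstance(groups, str):
            groups = table.sample_info[groups]
    else:
        values = pd.DataFrame(table)
    groups = pd.Series(groups, index=values.index)
    levels = sorted(pd.unique(groups))
    if len(levels) != 2:
        raise ValueError(f"SIMPER needs exactly two groups, got {levels}")
    mask_a = (groups == levels[0]).to_numpy()
    mask_b = (groups == levels[1]).to_numpy()
    if mask_a.sum() == 0 or mask_b.sum() == 0:
        raise ValueError("both groups must be non-empty")
    v = values.to_numpy(dtype=float)
    contrib = _simper_contrib(v[mask_a], v[mask_b])
    overall = float(contrib.sum())
    out = pd.DataFrame({
        "species": list(values.columns),
        "contribution": contrib,
        "mean_" + str(levels[0]): v[mask_a].mean(axis=0),
        "mean_" + str(levels[1]): v[mask_b].mean(axis=0),
    })
    out = out.sort_values("contribution", ascending=False, kind="stable")
    out["cumulative_pct"] = (100.0 * out["contribution"].cumsum() / overall
                             if overall > 0 else 0.0)
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        labels = np.where(mask_a, 0, 1)
        exceed = np.zeros(v.shape[1])
        order = {sp: i for i, sp in enumerate(values.columns)}
        base = contrib
        for _ in range(n_perm):
            lp = rng.permutation(labels)
            cp = _simper_contrib(v[lp == 0], v[lp == 1])
            exceed += cp >= base - 1e-15
        pvals = (1.0 + exceed) / (1.0 + n_perm)
        out["p_perm"] = [pvals[order[sp]] for sp in out["species"]]
    return SimperResults(table=out.reset_index(drop=True),
                         groups=(str(levels[0]), str(levels[1])),
                         overall=overall, n_permutations=n_perm)
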