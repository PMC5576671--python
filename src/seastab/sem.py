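"""Piecewise structural equation models over mixed-effects regressions.

A causal hypothesis — here, season acting on fish density directly and/or
indirectly through seagrass cover — is written as a DAG.  Each endogenous
node is fitted as a linear mixed model (site random intercept) on its
parents.  The DAG's testable implications form the d-separation basis
set: one conditional-independence claim per non-adjacent variable pair,
conditioning on the union of both variables' parents.  The claims'
p-values combine into Fisher's C = -2 sum ln p ~ chi^2 with 2k degrees of
freedom; the model is accepted (no missing paths) when the C test's p
exceeds 0.05.

Season is a three-level factor and enters every regression as its
sum-coded dummy columns, tested jointly; the sign of its coefficients is
not interpretable (a composite variable), and they are flagged as such.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .lmm import CommunityLMM, CommunityLMMResults, nakagawa_r2

#: Claims whose mixed-model p-value underflows are floored here (with a
#: warning) so Fisher's C stays finite.
P_FLOOR = 1e-300


@dataclass
class PathModel:
    """DAG of causal claims with a designated composite factor.

    ``nodes`` are data column names; ``composites`` marks multi-level
    factor nodes (by default ``season``), which may appear only as
    sources.
    """

    nodes: list[str]
    edges: list[tuple[str, str]]
    composites: tuple[str, ...] = ("season",)
    group: str = "site"

    def __post_init__(self) -> None:
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("path model must be acyclic")
        for comp in self.composites:
            if comp in self.nodes and g.in_degree(comp) > 0:
                raise ValueError(f"composite factor {comp!r} must be exogenous")
        for node in self.endogenous():
            if g.in_degree(node) < 1:  # pragma: no cover - defensive
                raise ValueError(f"endogenous node {node!r} has no parents")

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for u, v in self.edges:
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(f"edge ({u!r}, {v!r}) uses an unknown node")
            g.add_edge(u, v)
        return g

    def endogenous(self) -> list[str]:
        g = self.graph()
        return [n for n in self.nodes if g.in_degree(n) > 0]

    @classmethod
    def seagrass_mediation(cls, response: str = "density",
                           direct: bool = False) -> "PathModel":
        """season -> cover -> fish, optionally with a direct season -> fish
        path (the indirect-only variant is the topology expected inside a
        habitat-mediated system)."""
        edges = [("season", "cover"), ("cover", response)]
        if direct:
            edges.append(("season", response))
        return cls(nodes=["season", "cover", response], edges=edges)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"nodes": self.nodes, "edges": [list(e) for e in self.edges],
                       "composites": list(self.composites), "group": self.group},
                      fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PathModel":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(nodes=d["nodes"], edges=[tuple(e) for e in d["edges"]],
                   composites=tuple(d.get("composites", ("season",))),
                   group=d.get("group", "site"))


@dataclass(frozen=True)
class IndependenceClaim:
    """x independent of y given the conditioning set (y is regressed)."""

    x: str
    y: str
    conditioning: tuple[str, ...]

    def __str__(self) -> str:
        cond = ", ".join(self.conditioning) or "{}"
        return f"{self.x} _||_ {self.y} | {{{cond}}}"


def basis_set(model: PathModel) -> list[IndependenceClaim]:
    """d-separation basis set of the DAG.

    One claim per non-adjacent pair: the causally later variable is
    regressed on the earlier one plus the union of both variables'
    parents.  Output order is deterministic and independent of the node
    listing order (lexicographic topological order).
    """
    g = model.graph()
    order = list(nx.lexicographical_topological_sort(g))
    pos = {n: i for i, n in enumerate(order)}
    claims = []
    for i, u in enumerate(order):
        for v in order[i + 1:]:
            if g.has_edge(u, v) or g.has_edge(v, u):
                continue
            # u precedes v in the topological order, so v (the causally
            # later variable) is the one regressed; a composite factor can
            # only play the exogenous role
            x, y = (v, u) if v in model.composites else (u, v)
            cond = (set(g.predecessors(x)) | set(g.predecessors(y))) - {x, y}
            claims.append(IndependenceClaim(
                x=x, y=y, conditioning=tuple(sorted(cond, key=pos.__getitem__))))
    return claims


def fishers_c(pvalues) -> tuple[float, int, float]:
    """Fisher's C over the basis-set p-values: C = -2 sum ln p ~ chi^2_2k.

    An empty claim list gives C = 0, p = 1 (a saturated model has no
    testable implications).
    """
    ps = np.asarray(list(pvalues), dtype=float)
    if ps.size == 0:
        return 0.0, 0, 1.0
    if (ps <= 0).any() or (ps > 1).any():
        raise ValueError("basis-set p-values must lie in (0, 1]")
    c = float(-2.0 * np.log(ps).sum())
    df = 2 * ps.size
    return c, df, float(stats.chi2.sf(c, df))


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class SemResults:
    """Fitted piecewise SEM: paths, basis-set tests, Fisher's C, R^2."""

    paths: pd.DataFrame
    claims: pd.DataFrame
    fisher_c: float
    df: int
    pvalue: float
    r2_conditional: dict[str, float]
    node_results: dict[str, CommunityLMMResults] = field(repr=False,
                                                         default_factory=dict)

    @property
    def accepted(self) -> bool:
        """Model retained when the C test does not reject (p > 0.05)."""
        return self.pvalue > 0.05

    def summary(self) -> str:
        lines = [
            f"Piecewise SEM: Fisher's C = {self.fisher_c:.4f}, "
            f"df = {self.df}, P = {self.pvalue:.4f} "
            f"({'accepted' if self.accepted else 'rejected'})", "",
            "Paths:",
            self.paths.to_string(float_format=lambda v: f"{v:.4f}"),
        ]
        if len(self.claims):
            lines += ["", "Independence claims:",
                      self.claims.to_string(float_format=lambda v: f"{v:.4f}")]
        lines += ["", "Conditional R2: "
                  + ", ".join(f"{k} = {v:.3f}" for k, v in
                              self.r2_conditional.items())]
        return "\n".join(lines)

    def to_json_dict(self) -> dict:
        return {
            "fisher_c": self.fisher_c, "df": self.df, "pvalue": self.pvalue,
            "accepted": self.accepted,
            "paths": self.paths.to_dict(orient="records"),
            "claims": self.claims.to_dict(orient="records"),
            "r2_conditional": self.r2_conditional,
        }


class PiecewiseSEM:
    """Model object: a path model plus the data it is fitted on."""

    def __init__(self, model: PathModel, data: pd.DataFrame,
                 management_subset: str | None = None):
        if management_subset is not None:
            if "management" not in data.columns:
                raise KeyError("data has no 'management' column to subset on")
            data = data[data["management"] == management_subset]
            if not len(data):
                raise ValueError(f"no rows with management {management_subset!r}")
        missing = [n for n in model.nodes if n not in data.columns]
        if missing:
            raise KeyError(f"data lacks columns for node(s) {missing}")
        if model.group not in data.columns:
            raise KeyError(f"data lacks the grouping column {model.group!r}")
        self.model = model
        self.data = data.reset_index(drop=True)

    def _fit_node(self, response: str, predictors: list[str]
                  ) -> CommunityLMMResults:
        try:
            m = CommunityLMM.from_dataframe(self.data, response,
                                            fixed=tuple(predictors),
                                            group=self.model.group)
            return m.fit(reml=True)
        except (ValueError, np.linalg.LinAlgError) as err:
            raise ValueError(
                f"node {response!r} model is unidentifiable: {err}") from err

    def _predictor_p(self, fit: CommunityLMMResults, predictor: str,
                     ddf: str) -> float:
        if predictor in self.model.composites:
            _, _, _, p = fit.f_test_term(predictor, ddf=ddf)
            return p
        sl = fit.model.design_info.term_slices[predictor]
        l = np.zeros(fit.k_fixed)
        l[sl.start] = 1.0
        _, _, _, p = fit.contrast(l, ddf=ddf)
        return p

    def fit(self, ddf: str = "satterthwaite") -> SemResults:
        g = self.model.graph()
        path_rows = []
        r2 = {}
        node_results = {}
        sds = {c: float(self.data[c].std(ddof=1))
               for c in self.model.nodes if c not in self.model.composites}
        for node in self.model.endogenous():
            parents = sorted(g.predecessors(node))
            fit = self._fit_node(node, parents)
            node_results[node] = fit
            _, r2c = nakagawa_r2(fit)
            r2[node] = r2c
            for parent in parents:
                if parent in self.model.composites:
                    sl = fit.model.design_info.term_slices[parent]
                    coefs = fit.params.iloc[sl]
                    p = self._predictor_p(fit, parent, ddf)
                    for name, coef in coefs.items():
                        path_rows.append({
                            "response": node, "predictor": name,
                            "coef": float(coef), "std_coef": np.nan,
                            "p": p, "sign_interpretable": False})
                else:
                    sl = fit.model.design_info.term_slices[parent]
                    coef = float(fit.params.iloc[sl.start])
                    l = np.zeros(fit.k_fixed)
                    l[sl.start] = 1.0
                    _, _, _, p = fit.contrast(l, ddf=ddf)
                    std = coef * sds[parent] / sds[node] if sds[node] > 0 else np.nan
                    path_rows.append({
                        "response": node, "predictor": parent,
                        "coef": coef, "std_coef": std, "p": p,
                        "sign_interpretable": True})

        claim_rows = []
        pvals = []
        for claim in basis_set(self.model):
            predictors = list(claim.conditioning) + [claim.x]
            fit = self._fit_node(claim.y, predictors)
            p = self._predictor_p(fit, claim.x, ddf)
            if p <= 0.0:
                warnings.warn(f"claim {claim}: p underflowed, floored at "
                              f"{P_FLOOR}", RuntimeWarning, stacklevel=2)
                p = P_FLOOR
            pvals.append(p)
            claim_rows.append({"claim": str(claim), "x": claim.x, "y": claim.y,
                               "conditioning": ",".join(claim.conditioning),
                               "p": p})
        c, df, p_c = fishers_c(pvals)
        return SemResults(
            paths=pd.DataFrame(path_rows),
            claims=pd.DataFrame(claim_rows,
                                columns=["claim", "x", "y", "conditioning", "p"]),
            fisher_c=c, df=df, pvalue=p_c, r2_conditional=r2,
            node_results=node_results)


def fit_psem(model: PathModel, data: pd.DataFrame,
             management_subset: str | None = None,
             ddf: str = "satterthwaite") -> SemResults:
    """Functional wrapper around :class:`PiecewiseSEM`."""
    return PiecewiseSEM(model, data, management_subset).fit(ddf=ddf)
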