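"""Driver attribution: correlation screens, permutation importance, path model.

The attribution stage asks which soil indicators and which side of the
microbial community (bacterial vs fungal diversity) drive the overall
multifunctionality score. It combines

* pairwise Pearson correlations and per-indicator Mantel tests,
* a bagged-tree permutation-importance screen (out-of-bag increase in MSE,
  normalised by the response variance so the retention cutoff is
  scale-free), and
* a recursive path model over observed variables: each endogenous node is
  a least-squares linear function of its parents on a DAG, and effects of
  any ancestor on any outcome decompose exactly into direct (its edge) and
  indirect (sum over longer directed paths of coefficient products) parts.

The path model is deliberately *not* a latent-variable structural equation
model: all nodes are measured composites, which keeps the decomposition
exact and testable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.tree import DecisionTreeRegressor

from .community import DistanceMatrix, mantel

__all__ = [
    "pearson_matrix",
    "mantel_screen",
    "ImportanceConfig",
    "ImportanceResult",
    "importance_screen",
    "PathModelSpec",
    "PathModel",
    "PathResults",
    "fit_path_model",
    "effects_table",
    "DEFAULT_PATH_SPEC",
]


def pearson_matrix(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r and two-sided p for every pair of numeric columns.

    p-values come from t = r sqrt((n-2) / (1-r^2)) with n-2 degrees of
    freedom. Pairs involving a constant column are flagged with NaN.
    """
    frame = table.select_dtypes(include=[np.number]).astype(float)
    n = len(frame)
    if n < 3:
        raise ValueError("need at least 3 rows for correlation p-values")
    cols = list(frame.columns)
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    constant = [c for c in cols if np.ptp(frame[c].to_numpy()) == 0]
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            if a in constant or b in constant:
                r.loc[a, b] = r.loc[b, a] = np.nan
                p.loc[a, b] = p.loc[b, a] = np.nan
                continue
            res = stats.pearsonr(frame[a], frame[b])
            r.loc[a, b] = r.loc[b, a] = res.statistic
            p.loc[a, b] = p.loc[b, a] = res.pvalue
    for c in constant:
        r.loc[c, c] = np.nan
        p.loc[c, c] = np.nan
    return r, p


def _standardized(values: np.ndarray) -> np.ndarray:
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError("constant column cannot be standardized")
    return (values - values.mean()) / sd


def mantel_screen(
    diversity: pd.DataFrame | DistanceMatrix,
    indicators: pd.DataFrame,
    n_permutations: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Mantel test of each indicator against a community/diversity distance.

    The community side is either a ready distance matrix or an
    alpha-diversity table, in which case the distance is Euclidean over
    standardized diversity indices. Each indicator contributes the absolute
    difference of its standardized values as its own distance matrix.
    """
    ind = indicators.drop(columns=["treatment"], errors="ignore")
    if isinstance(diversity, DistanceMatrix):
        shared = [p for p in diversity.labels if p in ind.index]
        if len(shared) < 4:
            raise ValueError(f"need >= 4 shared plots, got {len(shared)}")
        keep = [diversity.labels.index(p) for p in shared]
        dcom = DistanceMatrix(tuple(shared), diversity.values[np.ix_(keep, keep)])
    else:
        shared = [p for p in diversity.index if p in ind.index]
        if len(shared) < 4:
            raise ValueError(f"need >= 4 shared plots, got {len(shared)}")
        z = np.column_stack(
            [_standardized(diversity.loc[shared, c].to_numpy(dtype=float))
             for c in diversity.columns]
        )
        from scipy.spatial.distance import pdist, squareform

        dcom = DistanceMatrix(tuple(shared), squareform(pdist(z)))
    rows = []
    for i, code in enumerate(ind.columns):
        z = _standardized(ind.loc[shared, code].to_numpy(dtype=float))
        dmat = DistanceMatrix(tuple(shared), np.abs(z[:, None] - z[None, :]))
        res = mantel(dcom, dmat, n_permutations=n_permutations, seed=seed + i)
        rows.append({"indicator": code, "r": res.statistic, "p": res.p_value,
                     "n_permutations": res.n_permutations, "exhaustive": res.exhaustive})
    return pd.DataFrame(rows).set_index("indicator")


@dataclass(frozen=True)
class ImportanceConfig:
    """Bagged-tree permutation-importance settings.

    ``n_trees`` bootstrap trees, each split on a random subset of
    ``max_features`` features (default ceil(p/3)); importance is the mean
    out-of-bag increase in MSE when a feature is permuted, divided by the
    response variance; features whose importance exceeds ``cutoff`` are
    selected (set ``select_above=False`` for the opposite convention).
    """

    n_trees: int = 500
    max_features: int | None = None
    cutoff: float = 0.01
    select_above: bool = True
    seed: int = 0


@dataclass
class ImportanceResult:
    """Permutation importances with significance and the selected set."""

    importances: pd.Series
    p_values: pd.Series
    selected: list[str]
    r_squared: float
    config: ImportanceConfig

    @property
    def ranking(self) -> list[str]:
        return list(self.importances.sort_values(ascending=False).index)


def importance_screen(
    features: pd.DataFrame,
    response: pd.Series,
    config: ImportanceConfig = ImportanceConfig(),
) -> ImportanceResult:
    """Permutation importance of each feature for the response.

    Fits a bagged ensemble of regression trees (bootstrap rows, random
    feature subsets per split) and measures, per tree, how much the
    out-of-bag MSE rises when one feature's OOB values are shuffled. The
    reported importance is the across-tree mean of that increase divided by
    the response variance; the one-sided p-value tests whether the per-tree
    increases exceed zero. Fully deterministic under ``config.seed``.
    """
    x = features.drop(columns=["treatment"], errors="ignore").astype(float)
    y = pd.Series(response).astype(float).reindex(x.index)
    if len(x) < 8:
        raise ValueError("need at least 8 rows for the importance screen")
    if y.isna().any():
        raise ValueError("response missing for some rows")
    var_y = float(y.var(ddof=1))
    if var_y == 0:
        raise ValueError("response is constant")
    constant = [c for c in x.columns if np.ptp(x[c].to_numpy()) == 0]
    if constant:
        raise ValueError(f"constant feature columns: {constant}")

    n, p = x.shape
    max_feat = config.max_features or math.ceil(p / 3)
    rng = np.random.default_rng(config.seed)
    xa, ya = x.to_numpy(), y.to_numpy()
    increases = np.full((config.n_trees, p), np.nan)
    oob_sum = np.zeros(n)
    oob_count = np.zeros(n)
    for t in range(config.n_trees):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        if oob.size < 2:
            continue
        tree = DecisionTreeRegressor(
            max_features=max_feat, random_state=int(rng.integers(2**31 - 1))
        )
        tree.fit(xa[boot], ya[boot])
        pred = tree.predict(xa[oob])
        mse = float(((ya[oob] - pred) ** 2).mean())
        oob_sum[oob] += pred
        oob_count[oob] += 1
        for j in range(p):
            xp = xa[oob].copy()
            xp[:, j] = xp[rng.permutation(oob.size), j]
            mse_perm = float(((ya[oob] - tree.predict(xp)) ** 2).mean())
            increases[t, j] = mse_perm - mse

    norm = increases / var_y
    importances = pd.Series(np.nanmean(norm, axis=0), index=x.columns, name="importance")
    p_values = pd.Series(
        [stats.ttest_1samp(norm[:, j], 0.0, alternative="greater",
                           nan_policy="omit").pvalue for j in range(p)],
        index=x.columns, name="p",
    )
    covered = oob_count > 0
    oob_pred = oob_sum[covered] / oob_count[covered]
    ss_res = float(((ya[covered] - oob_pred) ** 2).sum())
    ss_tot = float(((ya[covered] - ya[covered].mean()) ** 2).sum())
    r2 = 1 - ss_res / ss_tot if ss_tot > 0 else np.nan
    if config.select_above:
        selected = importances[importances > config.cutoff].index.tolist()
    else:
        selected = importances[importances < config.cutoff].index.tolist()
    return ImportanceResult(importances, p_values, selected, r2, config)


@dataclass(frozen=True)
class PathModelSpec:
    """DAG of observed variables for recursive path analysis."""

    edges: tuple[tuple[str, str], ...]
    exogenous_covariances: Mapping[tuple[str, str], float] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "edges", tuple((str(a), str(b)) for a, b in self.edges))
        g = self.graph
        if not nx.is_directed_acyclic_graph(g):
            cycle = [a for a, _ in nx.find_cycle(g)]
            raise ValueError(f"path model must be acyclic; cycle: {cycle}")

    @property
    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_edges_from(self.edges)
        return g

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(nx.topological_sort(self.graph))

    @property
    def endogenous(self) -> tuple[str, ...]:
        g = self.graph
        return tuple(n for n in self.nodes if g.in_degree(n) > 0)

    @property
    def exogenous(self) -> tuple[str, ...]:
        g = self.graph
        return tuple(n for n in self.nodes if g.in_degree(n) == 0)


#: Default diversity -> soil functions -> SMF attribution model.
DEFAULT_PATH_SPEC = PathModelSpec(
    (
        ("bacterial_diversity", "cycling"),
        ("bacterial_diversity", "regulation"),
        ("bacterial_diversity", "storage"),
        ("fungal_diversity", "cycling"),
        ("cycling", "supply"),
        ("cycling", "storage"),
        ("storage", "SMF"),
        ("regulation", "SMF"),
        ("supply", "SMF"),
    )
)


class PathModel:
    """Recursive path model over observed variables.

    Parameters
    ----------
    data
        One column per node of ``spec``.
    spec
        The DAG. Every endogenous node is modelled as a linear function of
        its parents.
    standardize
        ``True`` z-scores all columns before fitting (standardized
        coefficients); ``"auto"`` (default) does so unless the frame is
        flagged as already standardized (``data.attrs["standardized"]``),
        as the synthetic path generator marks its output.
    """

    def __init__(self, data: pd.DataFrame, spec: PathModelSpec = DEFAULT_PATH_SPEC,
                 standardize: bool | str = "auto") -> None:
        missing = [n for n in spec.nodes if n not in data.columns]
        if missing:
            raise KeyError(f"data is missing path-model nodes: {missing}")
        g = spec.graph
        max_indeg = max(dict(g.in_degree()).values())
        if len(data) <= max_indeg + 2:
            raise ValueError(
                f"need more than {max_indeg + 2} rows for the largest equation"
            )
        if standardize == "auto":
            standardize = not bool(data.attrs.get("standardized", False))
        self.data = data
        self.spec = spec
        self.standardize = bool(standardize)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "PathModel":
        return cls(data, **kwargs)

    def fit(self) -> "PathResults":
        frame = self.data[list(self.spec.nodes)].astype(float)
        if self.standardize:
            frame = (frame - frame.mean()) / frame.std(ddof=1)
        g = self.spec.graph
        rows = []
        r2: dict[str, float] = {}
        for node in self.spec.endogenous:
            parents = sorted(g.predecessors(node))
            design = frame[parents].to_numpy()
            cond = np.linalg.cond(design)
            if cond > 1e8:
                raise ValueError(
                    f"collinear parents in equation for {node!r} "
                    f"(condition number {cond:.3g}): {parents}"
                )
            ols = sm.OLS(frame[node].to_numpy(), sm.add_constant(design)).fit()
            r2[node] = float(ols.rsquared)
            for i, parent in enumerate(parents, start=1):
                rows.append(
                    {"source": parent, "target": node,
                     "coefficient": float(ols.params[i]),
                     "se": float(ols.bse[i]), "p": float(ols.pvalues[i])}
                )
        edges = pd.DataFrame(rows)
        return PathResults(self, edges, r2)


class PathResults:
    """Fitted path coefficients with exact effect decomposition."""

    def __init__(self, model: PathModel, edges: pd.DataFrame, r_squared: dict[str, float]):
        self.model = model
        self.edges = edges
        self.r_squared = r_squared
        nodes = list(model.spec.nodes)
        self._pos = {n: i for i, n in enumerate(nodes)}
        b = np.zeros((len(nodes), len(nodes)))
        for _, row in edges.iterrows():
            b[self._pos[row["source"]], self._pos[row["target"]]] = row["coefficient"]
        self._b = b
        # DAG adjacency is nilpotent: total effects are a finite power sum
        total = np.zeros_like(b)
        power = np.eye(len(nodes))
        for _ in range(len(nodes)):
            power = power @ b
            total += power
        self._total = total

    def effect(self, source: str, outcome: str) -> dict[str, float]:
        """Direct, indirect and total effect of ``source`` on ``outcome``."""
        i, j = self._pos[source], self._pos[outcome]
        direct = float(self._b[i, j])
        total = float(self._total[i, j])
        return {"direct": direct, "indirect": total - direct, "total": total}

    def effects_table(self, outcome: str = "SMF") -> pd.DataFrame:
        """Effect decomposition of every ancestor of ``outcome``."""
        g = self.model.spec.graph
        if outcome not in g:
            raise KeyError(f"{outcome!r} is not a node of the fitted model")
        ancestors = [n for n in self.model.spec.nodes if n in nx.ancestors(g, outcome)]
        rows = [{"source": a, **self.effect(a, outcome)} for a in ancestors]
        return pd.DataFrame(rows).set_index("source")

    def summary(self) -> str:
        lines = ["Recursive path model (observed variables)", ""]
        lines.append("Standardized coefficients:" if self.model.standardize
                     else "Coefficients (data taken as pre-standardized):")
        lines.append(self.edges.round(4).to_string(index=False))
        lines.append("")
        lines.append("R^2 per endogenous node:")
        for node, r2 in self.r_squared.items():
            lines.append(f"  {node}: {r2:.3f}")
        g = self.model.spec.graph
        sinks = [n for n in self.model.spec.nodes if g.out_degree(n) == 0]
        for sink in sinks:
            lines.append("")
            lines.append(f"Effects on {sink}:")
            lines.append(self.effects_table(sink).round(4).to_string())
        return "\n".join(lines)


def fit_path_model(data: pd.DataFrame, spec: PathModelSpec = DEFAULT_PATH_SPEC,
                   standardize: bool | str = "auto") -> PathResults:
    """Fit each endogenous node on its parents by least squares."""
    return PathModel(data, spec, standardize=standardize).fit()


def effects_table(fit: PathResults, outcome: str = "SMF") -> pd.DataFrame:
    """Direct/indirect/total effects of every ancestor of ``outcome``."""
    return fit.effects_table(outcome)
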