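"""Soil multifunctionality (SMF) scoring.

The averaging approach to ecosystem multifunctionality: every plot-level
indicator is z-scored across plots, indicators are grouped into named soil
functions (nutrient supply, storage, cycling, environmental regulation),
each function is summarised by the mean z-score of its indicators, and the
overall SMF index of a plot is the mean z-score over all indicators.

The module exposes both a functional surface (:func:`standardize`,
:func:`function_indices`, :func:`smf`, :func:`compare_groups`,
:func:`regress_indicator_on_smf`) and a model object
(:class:`MultifunctionalityModel` / :class:`MultifunctionalityResults`)
that bundles the whole scoring pipeline for one indicator table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "INDICATOR_CODES",
    "FunctionScheme",
    "TABLE1_SCHEME",
    "GroupComparison",
    "MultifunctionalityModel",
    "MultifunctionalityResults",
    "standardize",
    "function_indices",
    "smf",
    "compare_groups",
    "regress_indicator_on_smf",
]

#: Canonical plot-level indicator codes, in table order.
#: MC moisture content (%), BD bulk density (g cm^-3), TPO total porosity (%),
#: EC electrical conductivity, pH; AP available phosphorus (mg kg^-1),
#: AK available potassium (mg kg^-1), NH4N ammonium N, NO3N nitrate N;
#: TC/TN/TP/TK totals (g kg^-1); UE urease, AKP alkaline phosphatase,
#: CBH cellobiohydrolase, NAG beta-1,4-N-acetylglucosaminidase,
#: BG beta-1,4-glucosidase, PPO polyphenol oxidase, POD peroxidase
#: (enzyme activities).
INDICATOR_CODES: tuple[str, ...] = (
    "MC", "BD", "TPO", "EC", "pH",
    "AP", "AK", "NH4N", "NO3N",
    "TC", "TN", "TP", "TK",
    "UE", "AKP", "CBH", "NAG", "BG", "PPO", "POD",
)


@dataclass(frozen=True)
class FunctionScheme:
    """Assignment of indicator codes to named soil functions.

    Parameters
    ----------
    groups
        Mapping from function name to the tuple of indicator codes it
        aggregates. Groups must be disjoint.
    """

    groups: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for name, codes in self.groups.items():
            if not codes:
                raise ValueError(f"function {name!r} has no indicators")
            dup = seen.intersection(codes)
            if dup:
                raise ValueError(f"indicators assigned to several functions: {sorted(dup)}")
            seen.update(codes)

    @property
    def indicators(self) -> tuple[str, ...]:
        """All indicator codes, in group order."""
        return tuple(c for codes in self.groups.values() for c in codes)

    @property
    def sizes(self) -> dict[str, int]:
        return {name: len(codes) for name, codes in self.groups.items()}

    @property
    def n_indicators(self) -> int:
        return len(self.indicators)


#: Default grouping of the 20 indicators into the four soil functions.
TABLE1_SCHEME = FunctionScheme(
    {
        "environmental_regulation": ("MC", "BD", "TPO", "EC", "pH"),
        "nutrient_supply": ("AP", "AK", "NH4N", "NO3N"),
        "nutrient_storage": ("TC", "TN", "TP", "TK"),
        "nutrient_cycling": ("UE", "AKP", "CBH", "NAG", "BG", "PPO", "POD"),
    }
)


def _indicator_frame(table: pd.DataFrame, indicators: Sequence[str] | None) -> pd.DataFrame:
    if indicators is None:
        indicators = [c for c in table.columns if c != "treatment"]
    missing = [c for c in indicators if c not in table.columns]
    if missing:
        raise KeyError(f"indicator columns missing from table: {missing}")
    frame = table[list(indicators)]
    bad = [c for c in frame.columns if not np.issubdtype(frame[c].dtype, np.number)]
    if bad:
        raise TypeError(f"non-numeric indicator columns: {bad}")
    return frame.astype(float)


def standardize(
    table: pd.DataFrame,
    indicators: Sequence[str] | None = None,
    ddof: int = 1,
    directions: Mapping[str, int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Z-score each indicator across plots.

    Z_ij = (X_ij - mu_j) / sd_j, with mu_j and sd_j taken over all plots.
    The sample standard deviation (``ddof=1``) is used by default.

    Parameters
    ----------
    table
        Plot x indicator table; a ``treatment`` column, if present, is
        ignored.
    indicators
        Columns to standardize (default: every non-treatment column).
    directions
        Optional per-indicator sign map (+1/-1). Off by default: indicators
        enter with their measured orientation.

    Returns
    -------
    (zscores, params)
        ``zscores`` has one column per indicator with mean 0 and SD 1;
        ``params`` records ``mean`` and ``sd`` per indicator for audit.
    """
    frame = _indicator_frame(table, indicators)
    if len(frame) < 2:
        raise ValueError("need at least 2 plots to standardize")
    mu = frame.mean(axis=0)
    sd = frame.std(axis=0, ddof=ddof)
    constant = sd[sd == 0].index.tolist()
    if constant:
        raise ValueError(f"constant indicator column(s), zero SD: {constant}")
    z = (frame - mu) / sd
    if directions:
        unknown = set(directions) - set(frame.columns)
        if unknown:
            raise KeyError(f"direction map names unknown indicators: {sorted(unknown)}")
        for code, sign in directions.items():
            if sign not in (-1, 1):
                raise ValueError(f"direction for {code!r} must be +1 or -1")
            z[code] = sign * z[code]
    params = pd.DataFrame({"mean": mu, "sd": sd})
    return z, params


def function_indices(z: pd.DataFrame, scheme: FunctionScheme = TABLE1_SCHEME) -> pd.DataFrame:
    """Per-plot single-function indices: mean z-score within each function group."""
    missing = [c for c in scheme.indicators if c not in z.columns]
    if missing:
        raise KeyError(f"scheme references indicators absent from z-table: {missing}")
    return pd.DataFrame(
        {name: z[list(codes)].mean(axis=1) for name, codes in scheme.groups.items()},
        index=z.index,
    )


def smf(z: pd.DataFrame, scheme: FunctionScheme = TABLE1_SCHEME) -> pd.Series:
    """Per-plot soil multifunctionality index: mean of all indicator z-scores.

    Algebraically identical to the n_f/N-weighted mean of the function
    indices, where n_f is the number of indicators in function f.
    """
    missing = [c for c in scheme.indicators if c not in z.columns]
    if missing:
        raise KeyError(f"z-table is missing scheme indicators: {missing}")
    return z[list(scheme.indicators)].mean(axis=1).rename("SMF")


def _compact_letter_display(
    names: Sequence[str], means: Mapping[str, float], significant: set[frozenset]
) -> dict[str, str]:
    """Assign display letters so groups share a letter iff not separated.

    Letters are the maximal cliques of the non-significance graph, ordered
    by the best member mean; every non-significant pair shares at least one
    clique and significant pairs never do.
    """
    g = nx.Graph()
    g.add_nodes_from(names)
    for a in names:
        for b in names:
            if a < b and frozenset((a, b)) not in significant:
                g.add_edge(a, b)
    cliques = sorted(
        (sorted(c) for c in nx.find_cliques(g)),
        key=lambda c: -max(means[m] for m in c),
    )
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters: dict[str, list[str]] = {n: [] for n in names}
    for letter, clique in zip(alphabet, cliques):
        for member in clique:
            letters[member].append(letter)
    return {n: "".join(sorted(ls)) for n, ls in letters.items()}


@dataclass
class GroupComparison:
    """One-way ANOVA with Fisher LSD pairwise comparisons.

    Attributes
    ----------
    summary
        Per-treatment mean, SD, n and compact display letter.
    f_statistic, p_value
        One-way ANOVA F and its p-value.
    pairwise
        Per pair: mean difference, t, two-sided p (unadjusted LSD by
        default; Holm-adjusted column included for protection).
    alpha
        Significance level used for the letters.
    """

    summary: pd.DataFrame
    f_statistic: float
    p_value: float
    pairwise: pd.DataFrame
    alpha: float = 0.05
    df_error: int = 0
    mse: float = field(default=np.nan)


def compare_groups(
    values: pd.Series,
    treatments: pd.Series,
    alpha: float = 0.05,
    adjust: str | None = None,
) -> GroupComparison:
    """One-way ANOVA across treatments followed by LSD post hoc tests.

    LSD pairwise tests use the pooled within-group mean square with N - g
    degrees of freedom and are unadjusted (that is Fisher's LSD); pass
    ``adjust="holm"`` to base the letters on Holm-adjusted p-values.
    """
    values = pd.Series(values).astype(float)
    treatments = pd.Series(treatments).reindex(values.index)
    if treatments.isna().any():
        raise ValueError("treatment labels missing for some plots")
    groups = {t: values[treatments == t].to_numpy() for t in pd.unique(treatments)}
    if len(groups) < 2:
        raise ValueError("need at least 2 treatment groups")
    small = [t for t, v in groups.items() if len(v) < 2]
    if small:
        raise ValueError(f"groups with fewer than 2 plots: {small}")

    n_total = len(values)
    g = len(groups)
    grand = values.mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in groups.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    df_b, df_w = g - 1, n_total - g
    mse = ss_within / df_w
    if mse == 0:
        f_stat = 0.0 if ss_between == 0 else np.inf
        p_val = 1.0 if ss_between == 0 else 0.0
    else:
        f_stat = (ss_between / df_b) / mse
        p_val = float(stats.f.sf(f_stat, df_b, df_w))

    names = list(groups)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            va, vb = groups[a], groups[b]
            diff = va.mean() - vb.mean()
            se = np.sqrt(mse * (1 / len(va) + 1 / len(vb)))
            if se == 0:
                t_stat = 0.0 if diff == 0 else np.inf * np.sign(diff)
                p = 1.0 if diff == 0 else 0.0
            else:
                t_stat = diff / se
                p = float(2 * stats.t.sf(abs(t_stat), df_w))
            rows.append({"group_a": a, "group_b": b, "diff": diff, "t": t_stat, "p": p})
    pairwise = pd.DataFrame(rows)
    if len(pairwise):
        from statsmodels.stats.multitest import multipletests

        pairwise["p_holm"] = multipletests(pairwise["p"].to_numpy(), method="holm")[1]

    p_col = "p_holm" if adjust == "holm" else "p"
    significant = {
        frozenset((r["group_a"], r["group_b"]))
        for _, r in pairwise.iterrows()
        if r[p_col] < alpha
    }
    means = {t: float(v.mean()) for t, v in groups.items()}
    letters = _compact_letter_display(names, means, significant)
    summary = pd.DataFrame(
        {
            "mean": [means[t] for t in names],
            "sd": [float(np.std(groups[t], ddof=1)) for t in names],
            "n": [len(groups[t]) for t in names],
            "letter": [letters[t] for t in names],
        },
        index=pd.Index(names, name="treatment"),
    )
    return GroupComparison(summary, float(f_stat), p_val, pairwise, alpha, df_w, float(mse))


def regress_indicator_on_smf(
    table: pd.DataFrame,
    smf_values: pd.Series,
    indicators: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Simple OLS of SMF on each indicator separately.

    Returns one row per indicator with slope, intercept, R^2 and the
    two-sided p-value of the slope. Constant indicators are flagged and
    left unfit.
    """
    frame = _indicator_frame(table, indicators)
    if not frame.index.equals(smf_values.index):
        raise ValueError("indicator table and SMF vector index different plots")
    rows = []
    for code in frame.columns:
        x = frame[code].to_numpy()
        if np.ptp(x) == 0:
            rows.append(
                {"indicator": code, "slope": np.nan, "intercept": np.nan,
                 "r_squared": np.nan, "p": np.nan, "constant": True}
            )
            continue
        res = stats.linregress(x, smf_values.to_numpy())
        rows.append(
            {"indicator": code, "slope": res.slope, "intercept": res.intercept,
             "r_squared": res.rvalue ** 2, "p": res.pvalue, "constant": False}
        )
    return pd.DataFrame(rows).set_index("indicator")


class MultifunctionalityModel:
    """Averaging-approach multifunctionality model for one indicator table.

    Parameters
    ----------
    data
        Plot x indicator DataFrame indexed by plot id, with a ``treatment``
        column and one column per indicator of the scheme.
    scheme
        Grouping of indicators into soil functions (default: the 20-indicator,
        four-function scheme in :data:`TABLE1_SCHEME`).
    ddof
        Degrees-of-freedom correction for the standardization SD (1 = sample SD).
    directions
        Optional per-indicator sign map applied after z-scoring.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        scheme: FunctionScheme = TABLE1_SCHEME,
        treatment_col: str = "treatment",
        ddof: int = 1,
        directions: Mapping[str, int] | None = None,
    ) -> None:
        if treatment_col not in data.columns:
            raise KeyError(f"treatment column {treatment_col!r} not in data")
        if data.index.has_duplicates:
            dup = data.index[data.index.duplicated()].tolist()
            raise ValueError(f"duplicate plot ids: {dup}")
        missing = [c for c in scheme.indicators if c not in data.columns]
        if missing:
            raise KeyError(f"data is missing scheme indicators: {missing}")
        self.data = data
        self.scheme = scheme
        self.treatment_col = treatment_col
        self.ddof = ddof
        self.directions = dict(directions) if directions else None

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "MultifunctionalityModel":
        return cls(data, **kwargs)

    def fit(self) -> "MultifunctionalityResults":
        z, params = standardize(
            self.data, self.scheme.indicators, ddof=self.ddof, directions=self.directions
        )
        findex = function_indices(z, self.scheme)
        smf_vec = smf(z, self.scheme)
        return MultifunctionalityResults(self, z, params, findex, smf_vec)


class MultifunctionalityResults:
    """Fitted multifunctionality scores and downstream comparisons."""

    def __init__(
        self,
        model: MultifunctionalityModel,
        zscores: pd.DataFrame,
        standardization: pd.DataFrame,
        function_index_table: pd.DataFrame,
        smf_vector: pd.Series,
    ) -> None:
        self.model = model
        self.zscores = zscores
        self.standardization = standardization
        self.function_indices = function_index_table
        self.smf = smf_vector

    @property
    def treatments(self) -> pd.Series:
        return self.model.data[self.model.treatment_col]

    def compare_groups(self, which: str = "SMF", **kwargs) -> GroupComparison:
        """ANOVA + LSD on SMF (default) or a named function index."""
        if which == "SMF":
            values = self.smf
        elif which in self.function_indices.columns:
            values = self.function_indices[which]
        elif which in self.zscores.columns:
            values = self.zscores[which]
        else:
            raise KeyError(f"unknown quantity {which!r}")
        return compare_groups(values, self.treatments, **kwargs)

    def indicator_regressions(self) -> pd.DataFrame:
        """OLS of SMF on each indicator of the scheme."""
        return regress_indicator_on_smf(self.model.data, self.smf, self.model.scheme.indicators)

    def treatment_contrast(self, treatment: str, reference: str = "CK") -> float:
        """Mean SMF difference between a treatment and the reference."""
        t = self.treatments
        for label in (treatment, reference):
            if (t == label).sum() == 0:
                raise KeyError(f"no plots with treatment {label!r}")
        return float(self.smf[t == treatment].mean() - self.smf[t == reference].mean())

    def summary(self) -> str:
        """Plain-text summary of function indices and SMF by treatment."""
        by_t = pd.concat([self.function_indices, self.smf], axis=1).groupby(self.treatments).mean()
        comp = self.compare_groups("SMF")
        lines = [
            "Soil multifunctionality (averaging approach)",
            f"  plots: {len(self.smf)}   indicators: {self.model.scheme.n_indicators}"
            f"   functions: {len(self.model.scheme.groups)}",
            "",
            "Mean function indices and SMF by treatment (z units):",
            by_t.round(3).to_string(),
            "",
            f"SMF one-way ANOVA: F = {comp.f_statistic:.3f}, p = {comp.p_value:.4g}",
            "LSD letters (alpha = {:.2f}):".format(comp.alpha),
            comp.summary.round(3).to_string(),
        ]
        return "\n".join(lines)
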