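"""Synthetic study-data generators with known ground truth.

The field campaign this package models — a randomized block comparison of a
monoculture pecan stand (CK) against three understory intercropping systems
(CPS, CPH, CPL), 3 replicate plots each — did not publish its plot-level
measurements, only raw sequences. These generators emulate the study design
so that every downstream stage (scoring, diversity, ordination, permutation
tests, path model) is testable against planted truth:

* :func:`generate_indicator_table` — 12 plots x 20 soil indicators drawn
  from a multivariate normal with exchangeable correlation inside each soil
  function group and treatment mean shifts expressed in within-treatment SD
  units (so a planted shift is directly comparable to a z-score effect).
* :func:`generate_asv_table` — Dirichlet-multinomial ASV counts with a
  phylum-structured mean profile, per-treatment evenness (Dirichlet
  concentration), and log-normal sequencing depths.
* :func:`generate_path_dataset` — observations from a linear recursive
  system over a DAG, the ground truth for path-model recovery.

Each operation draws from its own RNG stream derived from ``(seed, tag)``,
so adding a generator never perturbs the output of another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .multifunctionality import INDICATOR_CODES, TABLE1_SCHEME

__all__ = [
    "DesignConfig",
    "IndicatorEffectConfig",
    "CommunityConfig",
    "PlantedPathConfig",
    "ASVTable",
    "generate_indicator_table",
    "generate_asv_table",
    "generate_path_dataset",
    "default_indicator_effects",
    "default_bacterial_community",
    "default_fungal_community",
    "default_path_config",
]

# fixed stream tags: one RNG stream per generator operation
_TAG_INDICATOR = 101
_TAG_ASV = 102
_TAG_PATH = 103


@dataclass(frozen=True)
class DesignConfig:
    """Experimental design: treatments x replicate plots.

    Defaults mirror the study layout: four treatments (CK monoculture,
    CPS, CPH, CPL intercropping) with three replicate plots each.
    """

    treatments: tuple[str, ...] = ("CK", "CPS", "CPH", "CPL")
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("replicates must be >= 2")
        if len(set(self.treatments)) != len(self.treatments):
            raise ValueError("treatment labels must be unique")

    @property
    def n_plots(self) -> int:
        return len(self.treatments) * self.replicates

    def plot_ids(self) -> list[str]:
        return [f"{t}-{r}" for t in self.treatments for r in range(1, self.replicates + 1)]

    def plot_treatments(self) -> list[str]:
        return [t for t in self.treatments for _ in range(self.replicates)]


# Plausible plot means for a slightly alkaline orchard Vertisol
# (site background: pH 7.5-8.5, TN 1.02 g/kg, AP 17.2 mg/kg, AK 178.7 mg/kg,
# organic matter 17.5 g/kg ~ TC 10 g/kg). Enzyme activities in kit units.
_BASELINES: dict[str, float] = {
    "MC": 24.0, "BD": 1.32, "TPO": 50.0, "EC": 150.0, "pH": 7.9,
    "AP": 17.2, "AK": 178.7, "NH4N": 8.5, "NO3N": 12.4,
    "TC": 10.2, "TN": 1.02, "TP": 0.65, "TK": 15.8,
    "UE": 0.85, "AKP": 1.60, "CBH": 0.42, "NAG": 0.55,
    "BG": 1.10, "PPO": 2.30, "POD": 1.80,
}
# within-treatment SD ~ 8% of the baseline, a typical plot-to-plot CV
_NOISE_SD: dict[str, float] = {k: 0.08 * abs(v) for k, v in _BASELINES.items()}


def _expand_shifts(
    shifts: Mapping[str, float | Mapping[str, float]],
    indicators: Sequence[str],
) -> dict[tuple[str, str], float]:
    out: dict[tuple[str, str], float] = {}
    for treatment, value in shifts.items():
        if isinstance(value, Mapping):
            for code, s in value.items():
                out[(treatment, code)] = float(s)
        else:
            for code in indicators:
                out[(treatment, code)] = float(value)
    return out


@dataclass(frozen=True)
class IndicatorEffectConfig:
    """Means, treatment shifts and correlation structure for indicators.

    ``treatment_shifts`` maps treatment -> shift, either one scalar applied
    to all indicators or a per-indicator mapping, always in units of the
    within-treatment SD (``noise_sd``). ``within_function_correlation`` is
    the exchangeable correlation among indicators of the same soil function
    (indicators of one function share drivers); cross-function noise is
    independent.
    """

    baseline: Mapping[str, float] = field(default_factory=lambda: dict(_BASELINES))
    treatment_shifts: Mapping[str, float | Mapping[str, float]] = field(
        default_factory=lambda: {"CPS": 0.74, "CPH": 0.55, "CPL": -0.20}
    )
    within_function_correlation: float = 0.4
    noise_sd: Mapping[str, float] = field(default_factory=lambda: dict(_NOISE_SD))

    def __post_init__(self) -> None:
        missing = [c for c in INDICATOR_CODES if c not in self.baseline]
        if missing:
            raise ValueError(f"baseline missing indicators: {missing}")
        missing_sd = [c for c in INDICATOR_CODES if c not in self.noise_sd]
        if missing_sd:
            raise ValueError(f"noise_sd missing indicators: {missing_sd}")
        if any(self.noise_sd[c] < 0 for c in INDICATOR_CODES):
            raise ValueError("noise_sd must be non-negative")


def default_indicator_effects(**overrides) -> IndicatorEffectConfig:
    """Study-condition defaults: CPS +0.74, CPH +0.55, CPL -0.20 SD on all indicators."""
    return IndicatorEffectConfig(**overrides)


def _covariance(effects: IndicatorEffectConfig) -> np.ndarray:
    rho = effects.within_function_correlation
    sds = np.array([effects.noise_sd[c] for c in INDICATOR_CODES])
    corr = np.eye(len(INDICATOR_CODES))
    pos = {c: i for i, c in enumerate(INDICATOR_CODES)}
    for codes in TABLE1_SCHEME.groups.values():
        for a in codes:
            for b in codes:
                if a != b:
                    corr[pos[a], pos[b]] = rho
    cov = corr * np.outer(sds, sds)
    eigmin = float(np.linalg.eigvalsh(corr).min())
    if eigmin < -1e-10:
        raise ValueError(
            f"within_function_correlation rho={rho} gives a non positive "
            f"semi-definite correlation (min eigenvalue {eigmin:.3g})"
        )
    return cov


def generate_indicator_table(
    design: DesignConfig = DesignConfig(),
    effects: IndicatorEffectConfig | None = None,
) -> pd.DataFrame:
    """Draw a plot x indicator table from the planted-effect model.

    Returns a DataFrame indexed by plot id with a ``treatment`` column and
    the 20 canonical indicator columns. Byte-identical under identical
    configs and seed.
    """
    effects = effects or default_indicator_effects()
    cov = _covariance(effects)
    shifts = _expand_shifts(effects.treatment_shifts, INDICATOR_CODES)
    rng = np.random.default_rng([design.seed, _TAG_INDICATOR])
    base = np.array([effects.baseline[c] for c in INDICATOR_CODES])
    sds = np.array([effects.noise_sd[c] for c in INDICATOR_CODES])
    rows = []
    for treatment in design.treatments:
        shift = np.array([shifts.get((treatment, c), 0.0) for c in INDICATOR_CODES])
        mean = base + shift * sds
        draw = rng.multivariate_normal(mean, cov, size=design.replicates, method="svd")
        rows.append(draw)
    table = pd.DataFrame(
        np.vstack(rows), index=pd.Index(design.plot_ids(), name="plot_id"),
        columns=list(INDICATOR_CODES),
    )
    table.insert(0, "treatment", design.plot_treatments())
    return table


@dataclass
class ASVTable:
    """ASV count table with taxonomy.

    ``counts``: samples x ASVs non-negative integer DataFrame;
    ``taxonomy``: per-ASV ranks kingdom..genus (may be "unassigned").
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame

    RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.index.has_duplicates or self.counts.columns.has_duplicates:
            raise ValueError("sample and ASV ids must be unique")
        missing = self.counts.columns.difference(self.taxonomy.index)
        if len(missing):
            raise ValueError(f"taxonomy missing ASV ids: {list(missing)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass(frozen=True)
class CommunityConfig:
    """Dirichlet-multinomial community model for one marker gene.

    ``phylum_profile`` fixes the expected phylum-level relative abundances;
    ``evenness`` maps treatment -> Dirichlet concentration (higher = samples
    closer to the mean profile, i.e. more even replicates);
    ``depth_distribution`` is (log-mean-scale mean, log sd, minimum depth)
    of the log-normal read-depth law.
    """

    n_taxa: int = 300
    phylum_profile: Mapping[str, float] = field(
        default_factory=lambda: {
            "Ascomycota": 0.55, "Basidiomycota": 0.38,
            "Zygomycota": 0.015, "other": 0.055,
        }
    )
    evenness: Mapping[str, float] = field(
        default_factory=lambda: {"CK": 300.0, "CPS": 500.0, "CPH": 450.0, "CPL": 150.0}
    )
    depth_mean: float = 20000.0
    depth_log_sd: float = 0.4
    min_depth: int = 1000
    kingdom: str = "Fungi"

    def __post_init__(self) -> None:
        total = float(sum(self.phylum_profile.values()))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"phylum_profile must sum to 1, got {total}")
        if any(v <= 0 for v in self.evenness.values()):
            raise ValueError("Dirichlet concentrations must be > 0")
        if self.min_depth < 1:
            raise ValueError("depth law must yield depth >= 1 (min_depth < 1)")
        if self.n_taxa < len(self.phylum_profile):
            raise ValueError("need at least one ASV per phylum")


def default_fungal_community(**overrides) -> CommunityConfig:
    """Fungal (ITS) defaults: Ascomycota/Basidiomycota-dominated profile."""
    return CommunityConfig(**overrides)


def default_bacterial_community(**overrides) -> CommunityConfig:
    """Bacterial (16S) defaults with the dominant-phylum profile of the system."""
    overrides.setdefault(
        "phylum_profile",
        {
            "Proteobacteria": 0.30, "Acidobacteria": 0.225,
            "Gemmatimonadetes": 0.085, "Actinobacteria": 0.06,
            "Chloroflexi": 0.045, "other": 0.285,
        },
    )
    overrides.setdefault("kingdom", "Bacteria")
    overrides.setdefault(
        "evenness", {"CK": 800.0, "CPS": 900.0, "CPH": 850.0, "CPL": 750.0}
    )
    return CommunityConfig(**overrides)


def _allocate_taxa(n_taxa: int, profile: Mapping[str, float]) -> list[str]:
    """Largest-remainder allocation of ASVs to phyla, >= 1 per phylum."""
    phyla = list(profile)
    raw = np.array([profile[p] for p in phyla]) * n_taxa
    counts = np.maximum(np.floor(raw).astype(int), 1)
    while counts.sum() > n_taxa:
        counts[int(np.argmax(counts))] -= 1
    rema = raw - counts
    while counts.sum() < n_taxa:
        i = int(np.argmax(rema))
        counts[i] += 1
        rema[i] = -np.inf
    return [p for p, k in zip(phyla, counts) for _ in range(k)]


def generate_asv_table(
    design: DesignConfig = DesignConfig(),
    community: CommunityConfig | None = None,
) -> ASVTable:
    """Simulate Dirichlet-multinomial ASV counts for every plot.

    Sample proportions are Dirichlet around a fixed mean profile whose
    phylum sums equal ``phylum_profile`` exactly; read depths are log-normal
    (mean ``depth_mean``) truncated below at ``min_depth``; counts are
    multinomial. Expected phylum relative abundances therefore match the
    profile up to Monte-Carlo error.
    """
    community = community or default_fungal_community()
    rng = np.random.default_rng([design.seed, _TAG_ASV])
    phylum_of = _allocate_taxa(community.n_taxa, community.phylum_profile)

    # rank-abundance shape within each phylum: log-normal weights,
    # renormalised so phylum sums hit the profile exactly
    weights = rng.lognormal(0.0, 1.0, size=community.n_taxa)
    base = np.empty(community.n_taxa)
    phyla = np.array(phylum_of)
    for phylum, share in community.phylum_profile.items():
        mask = phyla == phylum
        base[mask] = weights[mask] / weights[mask].sum() * share

    mu = math.log(community.depth_mean) - community.depth_log_sd**2 / 2
    sample_ids = design.plot_ids()
    counts = np.zeros((len(sample_ids), community.n_taxa), dtype=np.int64)
    for i, treatment in enumerate(design.plot_treatments()):
        theta = community.evenness.get(treatment)
        if theta is None:
            raise KeyError(f"no Dirichlet concentration for treatment {treatment!r}")
        p = rng.dirichlet(theta * base)
        depth = max(int(round(rng.lognormal(mu, community.depth_log_sd))), community.min_depth)
        counts[i] = rng.multinomial(depth, p)

    asv_ids = [f"ASV{j+1:04d}" for j in range(community.n_taxa)]
    genus = [f"{phylum_of[j]}_genus{j % 7 + 1}" for j in range(community.n_taxa)]
    taxonomy = pd.DataFrame(
        {
            "kingdom": community.kingdom,
            "phylum": phylum_of,
            "class": "unassigned",
            "order": "unassigned",
            "family": "unassigned",
            "genus": genus,
        },
        index=pd.Index(asv_ids, name="asv_id"),
    )
    count_df = pd.DataFrame(counts, index=pd.Index(sample_ids, name="sample_id"), columns=asv_ids)
    return ASVTable(count_df, taxonomy)


_DEFAULT_EDGES: dict[tuple[str, str], float] = {
    ("bacterial_diversity", "cycling"): 0.63,
    ("bacterial_diversity", "regulation"): 0.38,
    ("bacterial_diversity", "storage"): -0.33,
    ("fungal_diversity", "cycling"): 0.45,
    ("cycling", "supply"): 0.84,
    ("cycling", "storage"): 0.94,
    ("storage", "SMF"): 0.93,
    ("regulation", "SMF"): 0.61,
    ("supply", "SMF"): 0.30,
}


@dataclass(frozen=True)
class PlantedPathConfig:
    """Ground-truth linear recursive system over a DAG.

    Exogenous nodes are standard normal; each endogenous node is the
    coefficient-weighted sum of its parents plus Gaussian residual noise.
    """

    coefficients: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(_DEFAULT_EDGES)
    )
    residual_sd: Mapping[str, float] | float = 0.3
    n_samples: int = 500
    seed: int = 0

    @property
    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for (a, b), coef in self.coefficients.items():
            g.add_edge(a, b, coefficient=float(coef))
        return g

    def residual_for(self, node: str) -> float:
        if isinstance(self.residual_sd, Mapping):
            return float(self.residual_sd.get(node, 0.0))
        return float(self.residual_sd)


def default_path_config(**overrides) -> PlantedPathConfig:
    """The default diversity -> functions -> SMF system with planted coefficients."""
    return PlantedPathConfig(**overrides)


def generate_path_dataset(config: PlantedPathConfig = PlantedPathConfig()) -> pd.DataFrame:
    """Simulate node values from the planted recursive system.

    The returned frame carries ``attrs["standardized"] = True``: its columns
    are already on the coefficient scale (exogenous nodes are exactly
    standard normal), so a downstream path fit should not rescale them if
    planted coefficients are to be recovered.
    """
    g = config.graph
    if not nx.is_directed_acyclic_graph(g):
        cycle = [a for a, _ in nx.find_cycle(g)]
        raise ValueError(f"path model must be acyclic; cycle: {cycle}")
    rng = np.random.default_rng([config.seed, _TAG_PATH])
    data: dict[str, np.ndarray] = {}
    for node in nx.topological_sort(g):
        parents = list(g.predecessors(node))
        if not parents:
            data[node] = rng.standard_normal(config.n_samples)
        else:
            value = np.zeros(config.n_samples)
            for p in parents:
                value += g.edges[p, node]["coefficient"] * data[p]
            sd = config.residual_for(node)
            if sd > 0:
                value = value + sd * rng.standard_normal(config.n_samples)
            data[node] = value
    frame = pd.DataFrame(data)
    frame.attrs["standardized"] = True
    return frame
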