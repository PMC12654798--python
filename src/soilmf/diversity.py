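"""Alpha diversity, relative abundance, and per-taxon group tests.

Indices follow the common ecological conventions: Chao1 richness with the
bias-corrected form when no doubletons are present, Shannon entropy in nats
(configurable to bits), and the Gini-Simpson index 1 - sum(p^2) so that
larger values mean more diverse communities.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import ASVTable

__all__ = [
    "chao1",
    "shannon",
    "simpson",
    "alpha_table",
    "rarefy",
    "relative_abundance",
    "kruskal_wallis_per_taxon",
]


def _clean_counts(counts) -> np.ndarray:
    x = np.asarray(counts, dtype=float)
    if x.ndim != 1:
        raise ValueError("counts must be a 1-D vector")
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    if x.sum() == 0:
        raise ValueError("empty community: all counts are zero")
    return x


def chao1(counts) -> float:
    """Chao1 richness estimate.

    S_obs + F1^2 / (2 F2) with F1 singletons and F2 doubletons; when no
    doubletons are present the bias-corrected form
    S_obs + F1 (F1 - 1) / (2 (F2 + 1)) is used.
    """
    x = _clean_counts(counts)
    obs = int((x > 0).sum())
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    if f2 > 0:
        return obs + f1 * f1 / (2 * f2)
    return obs + f1 * (f1 - 1) / (2 * (f2 + 1))


def shannon(counts, base: float | None = None) -> float:
    """Shannon entropy H = -sum p ln p over present taxa (nats by default)."""
    x = _clean_counts(counts)
    p = x[x > 0] / x.sum()
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def simpson(counts) -> float:
    """Gini-Simpson diversity 1 - sum(p^2); higher = more diverse."""
    x = _clean_counts(counts)
    p = x / x.sum()
    return float(1.0 - (p**2).sum())


def inverse_simpson(counts) -> float:
    """Inverse Simpson 1 / sum(p^2)."""
    x = _clean_counts(counts)
    p = x / x.sum()
    return float(1.0 / (p**2).sum())


def rarefy(asv: ASVTable, depth: int, seed: int = 0) -> ASVTable:
    """Subsample every sample to a common depth without replacement.

    Optional sensitivity-analysis preprocessing; indices are computed on
    raw counts by default. Samples shallower than ``depth`` are rejected.
    """
    rng = np.random.default_rng(seed)
    counts = asv.counts.to_numpy()
    totals = counts.sum(axis=1)
    shallow = [s for s, t in zip(asv.sample_ids, totals) if t < depth]
    if shallow:
        raise ValueError(f"samples shallower than rarefaction depth {depth}: {shallow}")
    out = np.zeros_like(counts)
    for i, row in enumerate(counts):
        pool = np.repeat(np.arange(row.size), row)
        keep = rng.choice(pool, size=depth, replace=False)
        out[i] = np.bincount(keep, minlength=row.size)
    return ASVTable(
        pd.DataFrame(out, index=asv.counts.index, columns=asv.counts.columns),
        asv.taxonomy,
    )


def alpha_table(asv: ASVTable, base: float | None = None) -> pd.DataFrame:
    """Per-sample alpha diversity: observed richness, Chao1, Shannon, Simpson.

    Raises with the offending sample ids if any sample has zero reads.
    """
    counts = asv.counts
    empty = [s for s, t in zip(asv.sample_ids, counts.sum(axis=1)) if t == 0]
    if empty:
        raise ValueError(f"samples with no reads: {empty}")
    rows = {
        "observed_richness": [(row > 0).sum() for _, row in counts.iterrows()],
        "chao1": [chao1(row) for _, row in counts.iterrows()],
        "shannon": [shannon(row, base=base) for _, row in counts.iterrows()],
        "simpson": [simpson(row) for _, row in counts.iterrows()],
    }
    return pd.DataFrame(rows, index=counts.index)


def relative_abundance(asv: ASVTable, rank: str = "phylum") -> pd.DataFrame:
    """Per-sample relative abundances aggregated at a taxonomy rank.

    Rows sum to 1; ASVs without an assignment at the rank pool into
    ``"unassigned"``.
    """
    if rank not in ASVTable.RANKS:
        raise KeyError(f"unknown rank {rank!r}; valid ranks: {list(ASVTable.RANKS)}")
    labels = asv.taxonomy.loc[asv.counts.columns, rank].fillna("unassigned")
    grouped = asv.counts.T.groupby(labels.to_numpy()).sum().T
    totals = grouped.sum(axis=1)
    if (totals == 0).any():
        empty = grouped.index[totals == 0].tolist()
        raise ValueError(f"samples with no reads: {empty}")
    return grouped.div(totals, axis=0)


def kruskal_wallis_per_taxon(
    abundance: pd.DataFrame, groups: Sequence[str]
) -> pd.DataFrame:
    """Tie-corrected Kruskal-Wallis test of each taxon across groups.

    H is computed on average ranks with the tie correction
    H / (1 - sum(t^3 - t) / (N^3 - N)); p comes from the chi-square
    distribution with g - 1 degrees of freedom. Taxa whose values are all
    identical (tie-correction denominator zero) get H = 0, p = 1 and a
    ``degenerate`` flag.
    """
    groups = pd.Series(list(groups), index=abundance.index)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    sizes = groups.value_counts()
    if (sizes < 2).any():
        raise ValueError(f"groups with fewer than 2 samples: {sizes[sizes < 2].index.tolist()}")
    rows = []
    for taxon in abundance.columns:
        values = [abundance.loc[groups == lab, taxon].to_numpy() for lab in labels]
        flat = np.concatenate(values)
        if np.ptp(flat) == 0:
            rows.append({"taxon": taxon, "H": 0.0, "p": 1.0, "degenerate": True})
            continue
        h, p = stats.kruskal(*values)
        rows.append({"taxon": taxon, "H": float(h), "p": float(p), "degenerate": False})
    return pd.DataFrame(rows).set_index("taxon")
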