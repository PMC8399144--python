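"""Missing-aware simple-matching dissimilarity, APD ranking, duplicate graphs.

This is the analytical core of the package. For two samples the genotypic
dissimilarity is the complement of the simple matching coefficient computed
over pairwise-complete loci:

    d(i, j) = #{loci where both calls observed and states differ}
              / #{loci where both calls observed}

Heterozygotes are first-class states — ``AA`` vs ``AG`` is a full mismatch,
with no allele-sharing half-weight. The denominator varies by pair (only loci
non-missing in both members count), which is what makes the statistic usable
on GBS data with up to 50% marker missingness.

The average pairwise dissimilarity (APD) of sample *i* is the mean of
``d(i, j)`` over all other samples: high APD marks the genetically distinct
accessions of a collection, low APD the redundant ones. Near-duplicate pairs
are pairs whose dissimilarity corresponds to at most a small number of
"equivalent different loci" (``round(d * n_markers)``); the pairs form a
graph whose connected components each contribute ``size - 1`` genetically
duplicated (GD) samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .matrix import DissimilarityMatrix, GenotypeMatrix

__all__ = [
    "pairwise_dissimilarity",
    "apd",
    "select_extremes",
    "equivalent_loci",
    "duplicate_report",
    "report_from_pairs",
    "DuplicateReport",
]


def pairwise_dissimilarity(matrix: GenotypeMatrix) -> DissimilarityMatrix:
    """Pairwise simple-matching dissimilarity over pairwise-complete loci.

    Pairs sharing no observed locus get ``d = NaN`` with a warning listing
    them; APD computation refuses such matrices.
    """
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples")
    codes = matrix.state_codes()  # -1 for missing
    n = matrix.n_samples
    d = np.zeros((n, n))
    shared = np.zeros((n, n), dtype=np.int64)
    obs = codes >= 0
    for i in range(n - 1):
        both = obs[i] & obs[i + 1 :]
        ns = both.sum(axis=1)
        mismatch = (both & (codes[i] != codes[i + 1 :])).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            dij = np.where(ns > 0, mismatch / np.maximum(ns, 1), np.nan)
        d[i, i + 1 :] = dij
        d[i + 1 :, i] = dij
        shared[i, i + 1 :] = ns
        shared[i + 1 :, i] = ns
    np.fill_diagonal(shared, (obs.sum(axis=1)))
    dm = DissimilarityMatrix(ids=list(matrix.samples), d=d, shared_loci=shared)
    undef = dm.undefined_pairs()
    if undef:
        warnings.warn(
            f"{len(undef)} sample pair(s) share no observed locus; "
            f"dissimilarity undefined for: {undef[:10]}{'...' if len(undef) > 10 else ''}",
            stacklevel=2,
        )
    return dm


def apd(dm: DissimilarityMatrix) -> pd.DataFrame:
    """Average pairwise dissimilarity per sample, ranked.

    Returns a DataFrame indexed by sample id with columns ``apd`` (mean of
    the off-diagonal dissimilarities of that sample), ``rank`` (1 = most
    distinct, i.e. descending APD; ties share the smaller-id-first order),
    and ``z`` (APD standardized by the collection mean and SD).
    """
    undef = dm.undefined_pairs()
    if undef:
        raise ValueError(
            f"APD undefined: {len(undef)} pair(s) share no observed locus "
            f"(e.g. {undef[:5]}); exclude those samples or filter markers less harshly"
        )
    n = dm.n
    mask = ~np.eye(n, dtype=bool)
    values = np.array([dm.d[i, mask[i]].mean() for i in range(n)])
    mean, sd = values.mean(), values.std(ddof=1) if n > 1 else 0.0
    z = (values - mean) / sd if sd > 0 else np.zeros_like(values)
    order = sorted(range(n), key=lambda i: (-values[i], dm.ids[i]))
    rank = np.empty(n, dtype=int)
    for r, i in enumerate(order, start=1):
        rank[i] = r
    return pd.DataFrame(
        {"apd": values, "rank": rank, "z": z},
        index=pd.Index(dm.ids, name="sample"),
    )


def select_extremes(
    apd_table: pd.DataFrame, n_distinct: int, n_redundant: int
) -> dict:
    """Top-n most distinct and bottom-n most redundant samples by APD.

    Ties at either cutoff break by lexicographically smaller sample id (which
    the descending order places first among equals for the distinct set and
    likewise for the redundant set). Also reports how many samples sit more
    than 1/2/3 SD above the mean and more than 1 SD below it.
    """
    if n_distinct + n_redundant > len(apd_table):
        raise ValueError("n_distinct + n_redundant exceeds the number of samples")
    # two-key sort: id ascending within equal apd
    idx = sorted(apd_table.index, key=lambda s: (-apd_table.at[s, "apd"], s))
    distinct = idx[:n_distinct]
    asc = sorted(apd_table.index, key=lambda s: (apd_table.at[s, "apd"], s))
    redundant = asc[:n_redundant]
    z = apd_table["z"]
    return {
        "distinct": list(distinct),
        "redundant": list(redundant),
        "n_above_1sd": int((z > 1).sum()),
        "n_above_2sd": int((z > 2).sum()),
        "n_above_3sd": int((z > 3).sum()),
        "n_below_1sd": int((z < -1).sum()),
    }


def equivalent_loci(d: float, n_markers: int) -> int:
    """Number of differing loci a dissimilarity corresponds to: round(d * n).

    Rounding is half away from zero (so 0.5 -> 1), matching how such values
    are conventionally printed.
    """
    if not 0.0 <= d <= 1.0:
        raise ValueError("dissimilarity must be in [0, 1]")
    x = d * n_markers
    return int(np.floor(x + 0.5))


@dataclass
class DuplicateReport:
    """Near-duplicate pairs, their graph components, and GD-sample counts."""

    pairs: list[tuple[str, str, float, int]]  # (a, b, d, equivalent_loci)
    components: list[list[str]]
    gd_per_component: list[int]
    total_samples: int
    total_gd: int
    min_percent_identity: float  # 100 * (1 - max d among reported pairs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.pairs, columns=["sample1", "sample2", "dissimilarity", "equivalent_loci"]
        )


def duplicate_report(
    dm: DissimilarityMatrix,
    max_equivalent_loci: int = 37,
    n_markers: int | None = None,
) -> DuplicateReport:
    """All pairs at most ``max_equivalent_loci`` differing loci apart, as a graph.

    ``n_markers`` defaults to the maximum shared-locus count in ``dm`` (the
    marker total when any pair is complete). Each connected component of the
    pair graph contributes ``size - 1`` GD samples: the component needs one
    representative, the rest are duplicates of it.
    """
    if max_equivalent_loci < 0:
        raise ValueError("max_equivalent_loci must be >= 0")
    if n_markers is None:
        n_markers = int(dm.shared_loci.max())
    pairs = []
    g = nx.Graph()
    for i in range(dm.n - 1):
        for j in range(i + 1, dm.n):
            dij = dm.d[i, j]
            if np.isnan(dij):
                continue
            eq = equivalent_loci(dij, n_markers)
            if eq <= max_equivalent_loci:
                pairs.append((dm.ids[i], dm.ids[j], float(dij), eq))
                g.add_edge(dm.ids[i], dm.ids[j])
    components = [sorted(c) for c in nx.connected_components(g)]
    components.sort(key=lambda c: (-len(c), c))
    gd = [len(c) - 1 for c in components]
    max_d = max((p[2] for p in pairs), default=0.0)
    return DuplicateReport(
        pairs=sorted(pairs),
        components=components,
        gd_per_component=gd,
        total_samples=g.number_of_nodes(),
        total_gd=sum(gd),
        min_percent_identity=100.0 * (1.0 - max_d),
    )


def report_from_pairs(
    pairs: list[tuple[str, str, float]], n_markers: int, max_equivalent_loci: int = 37
) -> DuplicateReport:
    """Duplicate report built directly from an edge list of (a, b, d).

    Convenience path for re-analyzing a published or precomputed list of
    low-dissimilarity pairs without the full matrix.
    """
    ids: list[str] = []
    for a, b, _ in pairs:
        for s in (a, b):
            if s not in ids:
                ids.append(s)
    n = len(ids)
    d = np.full((n, n), np.nan)
    np.fill_diagonal(d, 0.0)
    pos = {s: i for i, s in enumerate(ids)}
    for a, b, dd in pairs:
        d[pos[a], pos[b]] = d[pos[b], pos[a]] = dd
    shared = np.full((n, n), n_markers, dtype=np.int64)
    dm = DissimilarityMatrix(ids=ids, d=d, shared_loci=shared)
    return duplicate_report(dm, max_equivalent_loci=max_equivalent_loci, n_markers=n_markers)
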