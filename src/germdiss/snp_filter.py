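"""Cleaning cascade for raw called-SNP genotype matrices.

GBS SNP tables arrive with technical-replicate discordance, monomorphic and
singleton markers, spurious multi-state markers, and heavy marker-specific
missingness. The cascade here runs in a fixed order —

    replicate concordance -> monomorphic -> singleton -> excess-state
    -> missingness tiers (e.g. <=50% / <=30% / <=15%)

— each step idempotent, with a :class:`FilterReport` whose bookkeeping exactly
balances the input marker count. Missingness thresholds are inclusive, and
their denominators use the post-concordance sample set (control replicates
removed, one keeper retained).

Conventions where raw-data pipelines differ:

* replicate concordance treats missing calls as non-informative — a marker
  fails only on an observed conflict among the control replicates;
* a "singleton" marker is one whose minor allele is carried by exactly one
  sample, whether heterozygous or homozygous;
* the excess-state rule removes markers with more than ``max_states``
  (default 3) distinct non-missing genotype states, the tri-state biallelic
  expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import MISSING, GenotypeMatrix

__all__ = [
    "FilterReport",
    "replicate_concordance_filter",
    "drop_monomorphic",
    "drop_singletons",
    "drop_excess_states",
    "missingness_tier",
    "summarize",
    "run_cascade",
]


@dataclass
class FilterReport:
    """Marker bookkeeping across the cascade; removed + retained balances."""

    n_input: int = 0
    removed: dict[str, int] = field(default_factory=dict)
    retained_tiers: dict[str, int] = field(default_factory=dict)

    @property
    def n_after_rules(self) -> int:
        return self.n_input - sum(self.removed.values())

    def check_balance(self) -> None:
        if self.n_after_rules < 0:
            raise AssertionError("filter bookkeeping does not balance")


# ---------------------------------------------------------------------------
# individual rules
# ---------------------------------------------------------------------------

def replicate_concordance_filter(
    matrix: GenotypeMatrix, control_ids: list[str], keep: str | None = None
) -> GenotypeMatrix:
    """Keep markers whose control-replicate calls agree; drop extra replicates.

    A marker passes when its non-missing calls across all control replicates
    are one identical state (missing calls are non-informative). All control
    replicates except the keeper (default: the first id) are removed from the
    sample set of the output.
    """
    if len(control_ids) < 2:
        raise ValueError("need at least 2 control replicate ids")
    for cid in control_ids:
        if cid not in matrix.samples:
            raise ValueError(f"control id {cid!r} not present in matrix")
    keep = keep or control_ids[0]
    if keep not in control_ids:
        raise ValueError(f"keeper {keep!r} is not one of the control ids")

    idx = [matrix.samples.index(c) for c in control_ids]
    sub = matrix.calls[idx, :]  # (n_controls, m)
    ok = np.ones(matrix.n_markers, dtype=bool)
    for j in range(matrix.n_markers):
        obs = sub[:, j]
        obs = obs[obs != MISSING]
        ok[j] = len(np.unique(obs)) <= 1
    out = matrix.take_markers(ok)
    survivors = [s for s in matrix.samples if s not in set(control_ids) - {keep}]
    return out.take_samples(survivors)


def _state_census(matrix: GenotypeMatrix) -> list[np.ndarray]:
    """Distinct non-missing states per marker."""
    out = []
    for j in range(matrix.n_markers):
        col = matrix.calls[:, j]
        out.append(np.unique(col[col != MISSING]))
    return out


def drop_monomorphic(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Remove markers with exactly one distinct non-missing state."""
    keep = np.array([len(s) != 1 for s in _state_census(matrix)], dtype=bool)
    return matrix.take_markers(keep)


def _minor_allele_carriers(col: np.ndarray) -> int:
    """Number of samples carrying the rarest allele at this marker (0 if monoallelic)."""
    obs = col[col != MISSING]
    if obs.size == 0:
        return 0
    counts: dict[str, int] = {}
    for st in obs:
        for a in st:
            counts[a] = counts.get(a, 0) + 1
    if len(counts) < 2:
        return 0
    minor = min(sorted(counts), key=lambda a: counts[a])
    return int(sum(1 for st in obs if minor in st))


def drop_singletons(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Remove markers whose minor allele is carried by exactly one sample."""
    keep = np.array(
        [_minor_allele_carriers(matrix.calls[:, j]) != 1 for j in range(matrix.n_markers)],
        dtype=bool,
    )
    return matrix.take_markers(keep)


def drop_excess_states(matrix: GenotypeMatrix, max_states: int = 3) -> GenotypeMatrix:
    """Remove markers with more than ``max_states`` distinct genotype states."""
    if max_states < 2:
        raise ValueError("max_states must be >= 2")
    keep = np.array([len(s) <= max_states for s in _state_census(matrix)], dtype=bool)
    return matrix.take_markers(keep)


def missingness_tier(matrix: GenotypeMatrix, max_missing: float) -> GenotypeMatrix:
    """Retain markers whose missing fraction is <= ``max_missing`` (inclusive)."""
    if not 0.0 <= max_missing <= 1.0:
        raise ValueError("max_missing must be in [0, 1]")
    keep = matrix.marker_missingness() <= max_missing + 1e-12
    return matrix.take_markers(keep)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def minor_allele_frequencies(matrix: GenotypeMatrix) -> np.ndarray:
    """Per-marker MAF from diploid allele counts over non-missing calls.

    Markers with no observed calls get NaN.
    """
    maf = np.full(matrix.n_markers, np.nan)
    for j in range(matrix.n_markers):
        col = matrix.calls[:, j]
        obs = col[col != MISSING]
        if obs.size == 0:
            continue
        counts: dict[str, int] = {}
        for st in obs:
            for a in st:
                counts[a] = counts.get(a, 0) + 1
        total = 2 * obs.size
        if len(counts) < 2:
            maf[j] = 0.0
        else:
            maf[j] = min(counts.values()) / total
    return maf


def summarize(matrix: GenotypeMatrix, n_bins: int = 10) -> dict:
    """Per-chromosome SNP counts, missingness histogram, and MAF histogram.

    Both histograms partition the full marker set (bins cover [0, 0.5] for
    MAF and [0, 1] for missingness, right-inclusive at the top edge).
    """
    chrom_counts = (
        matrix.markers["chrom"].value_counts().sort_index().to_dict()
        if matrix.n_markers
        else {}
    )
    missing = matrix.marker_missingness()
    miss_hist, miss_edges = np.histogram(missing, bins=n_bins, range=(0.0, 1.0))
    maf = minor_allele_frequencies(matrix)
    maf_obs = maf[~np.isnan(maf)]
    maf_hist, maf_edges = np.histogram(maf_obs, bins=n_bins, range=(0.0, 0.5))
    return {
        "chromosome_counts": chrom_counts,
        "missingness_hist": (miss_hist.tolist(), miss_edges.tolist()),
        "maf_hist": (maf_hist.tolist(), maf_edges.tolist()),
        "n_maf_undefined": int(np.isnan(maf).sum()),
        "maf": maf,
    }


# ---------------------------------------------------------------------------
# cascade
# ---------------------------------------------------------------------------

def run_cascade(
    matrix: GenotypeMatrix,
    control_ids: list[str] | None = None,
    tiers: tuple[float, ...] = (0.5, 0.3, 0.15),
    max_states: int = 3,
) -> tuple[dict[float, GenotypeMatrix], FilterReport]:
    """Full cleaning cascade; returns one matrix per missingness tier.

    Order: replicate concordance (if ``control_ids``), monomorphic, singleton,
    excess-state, then each inclusive missingness threshold in ``tiers``.
    Tier matrices are nested: a looser threshold is a superset of a tighter one.
    """
    report = FilterReport(n_input=matrix.n_markers)
    current = matrix
    if control_ids:
        before = current.n_markers
        current = replicate_concordance_filter(current, control_ids)
        report.removed["replicate_discordant"] = before - current.n_markers
    before = current.n_markers
    current = drop_monomorphic(current)
    report.removed["monomorphic"] = before - current.n_markers
    before = current.n_markers
    current = drop_singletons(current)
    report.removed["singleton"] = before - current.n_markers
    before = current.n_markers
    current = drop_excess_states(current, max_states=max_states)
    report.removed["excess_states"] = before - current.n_markers

    out: dict[float, GenotypeMatrix] = {}
    for t in sorted(tiers, reverse=True):
        tiered = missingness_tier(current, t)
        out[t] = tiered
        report.retained_tiers[f"{t:g}"] = tiered.n_markers
    loosest = max(tiers)
    report.removed["missingness"] = current.n_markers - out[loosest].n_markers
    report.check_balance()
    return out, report
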