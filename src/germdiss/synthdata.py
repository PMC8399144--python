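"""Synthetic genebank collections with known structure.

Emulates the statistical texture of a genotyping-by-sequencing (GBS) survey of
a selfing crop collection: a few hundred inbred accessions drawn from a small
number of latent genetic groups, tens of thousands of biallelic SNPs spread
over chromosomes, a minor-allele-frequency spectrum concentrated below 0.1,
heavy marker-specific missingness (up to 50%), planted near-duplicate
accession pairs, and technical replicates of one control sample carrying a
small genotyping error rate.

The genetic model is deliberately minimal (Balding–Nichols style): each marker
has an ancestral alternate-allele frequency drawn from a Beta sampler; each
group's frequency is drawn around it with spread controlled by a single
divergence parameter ``fst_like_divergence``; genotypes are then
Hardy–Weinberg draws within groups. There is no linkage, no coalescent
history, and no read-level error model — the generator exists to give every
downstream stage (filtering, dissimilarity, APD ranking, duplicate graphs,
PCoA/NJ/AMOVA) inputs with known truth, not to be demographically realistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import MISSING, GenotypeMatrix, canonical_state, write_tsv, write_vcf

__all__ = ["SimConfig", "TruthLabels", "simulate_collection", "write_genotypes", "write_truth"]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a simulated collection.

    Notes on defaults: they mirror the study conditions this generator
    emulates — 3 latent groups, 20 chromosomes, MAF mostly < 0.1
    (Beta(0.5, 6) allele-frequency sampler), per-marker missingness uniform on
    [0, 0.5], and 6 control replicates with a 0.5% per-locus error rate.
    ``n_samples`` counts base accessions; planted duplicate copies and the
    extra control replicates are appended beyond it.
    """

    n_samples: int = 571
    n_markers: int = 20000
    n_chromosomes: int = 20
    n_groups: int = 3
    fst_like_divergence: float = 0.15
    maf_beta: tuple[float, float] = (0.5, 6.0)
    missing_rate_range: tuple[float, float] = (0.0, 0.5)
    n_duplicate_pairs: int = 0
    duplicate_mismatch_loci: int = 0
    n_control_replicates: int = 0
    replicate_error_rate: float = 0.005
    seed: int = 0

    def validate(self) -> None:
        for f in ("n_samples", "n_markers", "n_chromosomes", "n_groups"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be a positive count, got {getattr(self, f)}")
        if not 0.0 <= self.fst_like_divergence < 1.0:
            raise ValueError(f"fst_like_divergence must be in [0, 1), got {self.fst_like_divergence}")
        a, b = self.maf_beta
        if a <= 0 or b <= 0:
            raise ValueError(f"maf_beta parameters must be positive, got {self.maf_beta}")
        lo, hi = self.missing_rate_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(f"missing_rate_range must satisfy 0 <= lo <= hi <= 1, got {self.missing_rate_range}")
        if self.n_duplicate_pairs < 0:
            raise ValueError(f"n_duplicate_pairs must be >= 0, got {self.n_duplicate_pairs}")
        if not 0 <= self.duplicate_mismatch_loci < self.n_markers:
            raise ValueError(
                f"duplicate_mismatch_loci must be in [0, n_markers), got {self.duplicate_mismatch_loci}"
            )
        if self.n_control_replicates < 0:
            raise ValueError(f"n_control_replicates must be >= 0, got {self.n_control_replicates}")
        if not 0.0 <= self.replicate_error_rate <= 1.0:
            raise ValueError(f"replicate_error_rate must be in [0, 1], got {self.replicate_error_rate}")
        if self.n_duplicate_pairs > self.n_samples:
            raise ValueError("n_duplicate_pairs cannot exceed n_samples")


@dataclass
class TruthLabels:
    """Ground truth emitted alongside a simulated collection."""

    group_of_sample: dict[str, int]
    duplicate_pairs: list[tuple[str, str, int]] = field(default_factory=list)
    control_replicate_ids: list[str] = field(default_factory=list)


def _flip_state(rng: np.random.Generator, state: str, states: np.ndarray) -> str:
    """A uniformly chosen genotype state at this marker different from ``state``."""
    others = [s for s in states if s != state]
    return others[rng.integers(len(others))]


def simulate_collection(config: SimConfig) -> tuple[GenotypeMatrix, TruthLabels]:
    """Simulate a genotyped collection with planted structure and ground truth.

    Procedure (all draws from one generator seeded by ``config.seed``):

    1. Per marker: chromosome/position, REF/ALT bases, ancestral alternate
       allele frequency from ``Beta(*maf_beta)``.
    2. Per group: allele frequency ``Beta(p(1-F)/F, (1-p)(1-F)/F)`` around the
       ancestral ``p`` with ``F = fst_like_divergence`` (``p`` itself if F=0).
    3. Per base sample (groups assigned round-robin): Hardy–Weinberg genotype
       draws from its group's frequencies.
    4. Per-marker missingness rate uniform on ``missing_rate_range``, applied
       independently per sample.
    5. Duplicates: copy a source row (including its missing pattern) and flip
       exactly ``duplicate_mismatch_loci`` non-missing loci to a different
       state — the planted mismatch count is exact.
    6. Control replicates: sample 0 is the control; ``n_control_replicates-1``
       perturbed copies (per-locus error ``replicate_error_rate``) are
       appended, for ``n_control_replicates`` control samples in total.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, m = config.n_samples, config.n_markers

    # markers: chromosome, position, REF/ALT alleles
    chrom_idx = np.sort(rng.integers(0, config.n_chromosomes, size=m))
    pos = np.zeros(m, dtype=np.int64)
    for c in range(config.n_chromosomes):
        sel = chrom_idx == c
        # strictly increasing positions via cumulative gaps (unique by construction)
        pos[sel] = np.cumsum(rng.integers(1, 5000, size=sel.sum()))
    chroms = np.array([f"Chr{c + 1:02d}" for c in chrom_idx])
    marker_ids = [f"M{j:06d}" for j in range(m)]
    ref_i = rng.integers(0, 4, size=m)
    alt_i = (ref_i + rng.integers(1, 4, size=m)) % 4
    ref, alt = _BASES[ref_i], _BASES[alt_i]
    # three genotype states per marker: hom-ref, het, hom-alt
    states = np.empty((m, 3), dtype="<U2")
    for j in range(m):
        states[j, 0] = ref[j] * 2
        states[j, 1] = canonical_state(ref[j], alt[j])
        states[j, 2] = alt[j] * 2

    p_anc = np.clip(rng.beta(*config.maf_beta, size=m), 1e-4, 1 - 1e-4)
    F = config.fst_like_divergence
    if F > 0:
        scale = (1 - F) / F
        p_grp = rng.beta(p_anc * scale, (1 - p_anc) * scale, size=(config.n_groups, m))
        p_grp = np.clip(p_grp, 0.0, 1.0)
    else:
        p_grp = np.tile(p_anc, (config.n_groups, 1))

    group = np.arange(n) % config.n_groups
    p = p_grp[group]  # (n, m) per-sample alt allele frequency
    u = rng.random((n, m))
    gcode = np.zeros((n, m), dtype=np.int8)  # 0 hom-ref, 1 het, 2 hom-alt
    hom_ref = (1 - p) ** 2
    gcode[u >= hom_ref] = 1
    gcode[u >= hom_ref + 2 * p * (1 - p)] = 2
    calls = states[np.arange(m)[None, :], gcode]

    miss_rate = rng.uniform(*config.missing_rate_range, size=m)
    miss = rng.random((n, m)) < miss_rate[None, :]
    calls[miss] = MISSING

    sample_ids = [f"S{i:04d}" for i in range(n)]
    truth = TruthLabels(group_of_sample={s: int(g) for s, g in zip(sample_ids, group)})

    rows = [calls]
    ids = list(sample_ids)
    groups = list(group)

    # planted near-duplicates (sources exclude the control sample 0)
    if config.n_duplicate_pairs:
        candidates = np.arange(1 if config.n_control_replicates else 0, n)
        sources = rng.choice(candidates, size=config.n_duplicate_pairs, replace=False)
        for src in sources:
            row = calls[src].copy()
            nonmiss = np.nonzero(row != MISSING)[0]
            k = config.duplicate_mismatch_loci
            if k > nonmiss.size:
                raise ValueError(
                    f"duplicate_mismatch_loci={k} exceeds the {nonmiss.size} non-missing loci of {sample_ids[src]}"
                )
            flip = rng.choice(nonmiss, size=k, replace=False)
            for j in flip:
                row[j] = _flip_state(rng, row[j], states[j])
            dup_id = f"{sample_ids[src]}_dup"
            rows.append(row[None, :])
            ids.append(dup_id)
            groups.append(group[src])
            truth.group_of_sample[dup_id] = int(group[src])
            truth.duplicate_pairs.append((sample_ids[src], dup_id, k))

    # control technical replicates of sample 0
    if config.n_control_replicates >= 2:
        truth.control_replicate_ids.append(sample_ids[0])
        for r in range(2, config.n_control_replicates + 1):
            row = calls[0].copy()
            nonmiss = np.nonzero(row != MISSING)[0]
            err = nonmiss[rng.random(nonmiss.size) < config.replicate_error_rate]
            for j in err:
                row[j] = _flip_state(rng, row[j], states[j])
            rep_id = f"{sample_ids[0]}_rep{r}"
            rows.append(row[None, :])
            ids.append(rep_id)
            groups.append(group[0])
            truth.group_of_sample[rep_id] = int(group[0])
            truth.control_replicate_ids.append(rep_id)
    elif config.n_control_replicates == 1:
        truth.control_replicate_ids.append(sample_ids[0])

    all_calls = np.vstack(rows)
    markers = pd.DataFrame(
        {"chrom": chroms, "pos": pos}, index=pd.Index(marker_ids, name="marker")
    )
    maturities = np.array(["000", "00", "0", "unknown"])[rng.integers(0, 4, size=len(ids))]
    meta = pd.DataFrame(
        {
            "origin": [f"POP{g + 1}" for g in groups],
            "maturity": maturities,
            "is_control": [s in truth.control_replicate_ids for s in ids],
        },
        index=pd.Index(ids, name="sample"),
    )
    gm = GenotypeMatrix(samples=ids, calls=all_calls, markers=markers, sample_meta=meta)
    return gm, truth


def write_genotypes(matrix: GenotypeMatrix, path: str | Path, format: str = "tsv") -> Path:
    """Write a genotype matrix as ``tsv`` (lossless round-trip) or ``vcf``."""
    if matrix.n_samples == 0 or matrix.n_markers == 0:
        raise ValueError("refusing to write an empty genotype matrix")
    if format == "tsv":
        return write_tsv(matrix, path)
    if format == "vcf":
        return write_vcf(matrix, path)
    raise ValueError(f"unknown format {format!r}; use 'tsv' or 'vcf'")


def write_truth(truth: TruthLabels, path: str | Path) -> Path:
    """Truth labels as a CSV sidecar (one row per sample, duplicates/controls flagged)."""
    path = Path(path)
    dup_partner = {}
    for a, b, k in truth.duplicate_pairs:
        dup_partner[a] = (b, k)
        dup_partner[b] = (a, k)
    rows = []
    for s, g in truth.group_of_sample.items():
        partner, k = dup_partner.get(s, ("", ""))
        rows.append(
            {
                "sample": s,
                "group": g,
                "duplicate_partner": partner,
                "planted_mismatches": k,
                "is_control_replicate": s in truth.control_replicate_ids,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
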