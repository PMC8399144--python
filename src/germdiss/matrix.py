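"""Genotype and dissimilarity containers with file I/O.

The central object is :class:`GenotypeMatrix`, a samples x markers table of
diploid genotype calls. A call is a two-letter state such as ``"AA"`` or
``"AG"`` (alleles sorted alphabetically, so heterozygotes have one canonical
spelling); missing calls are the sentinel ``"NN"``. Marker metadata
(chromosome, 1-based position) ride along in a DataFrame, as does optional
per-sample metadata (origin group, maturity group, control-replicate flag).

Readers/writers cover VCF 4.x (via cyvcf2 for parsing) and a tab-delimited
genotype table whose two leading ``##chrom`` / ``##pos`` comment rows make the
single file round-trip losslessly. Square dissimilarity matrices are written
in PHYLIP-compatible square format.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = "NN"

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "DissimilarityMatrix",
    "read_genotypes",
    "read_tsv",
    "read_vcf",
    "write_tsv",
    "write_vcf",
    "read_square_dm",
    "write_square_dm",
]


def canonical_state(a1: str, a2: str) -> str:
    """Canonical two-letter genotype state: alleles in alphabetical order."""
    return a1 + a2 if a1 <= a2 else a2 + a1


@dataclass
class GenotypeMatrix:
    """Samples x markers diploid genotype calls with marker/sample metadata.

    Attributes
    ----------
    samples : list of str
        Ordered, unique sample identifiers (rows of ``calls``).
    calls : ndarray of shape (n_samples, n_markers), dtype ``<U2``
        Genotype states; missing calls are :data:`MISSING`.
    markers : DataFrame indexed by marker id
        Columns ``chrom`` (str) and ``pos`` (positive int, 1-based).
    sample_meta : DataFrame indexed by sample id, optional
        Columns ``origin``, ``maturity``, ``is_control`` where available.
    """

    samples: list[str]
    calls: np.ndarray
    markers: pd.DataFrame
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype="<U2")
        if self.calls.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        if len(self.markers) and (self.markers["pos"].to_numpy() <= 0).any():
            raise ValueError("marker positions must be positive (1-based)")

    # -- basic views -------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean (n_samples, n_markers) mask of missing calls."""
        return self.calls == MISSING

    def marker_missingness(self) -> np.ndarray:
        """Per-marker fraction of missing calls across samples."""
        return self.missing_mask.mean(axis=0)

    def state_codes(self) -> np.ndarray:
        """Integer-coded calls (int16); missing is -1, equal states share a code."""
        states, inv = np.unique(self.calls, return_inverse=True)
        codes = inv.reshape(self.calls.shape).astype(np.int16)
        miss = np.nonzero(states == MISSING)[0]
        if miss.size:
            codes[codes == miss[0]] = -1
        return codes

    # -- subsetting --------------------------------------------------------

    def take_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to marker indices/boolean mask ``keep``."""
        keep = np.asarray(keep)
        return GenotypeMatrix(
            samples=list(self.samples),
            calls=self.calls[:, keep],
            markers=self.markers.iloc[keep],
            sample_meta=self.sample_meta,
        )

    def take_samples(self, sample_ids: list[str]) -> "GenotypeMatrix":
        """New matrix restricted to the given sample ids, in the given order."""
        idx = [self.samples.index(s) for s in sample_ids]
        meta = None
        if self.sample_meta is not None:
            meta = self.sample_meta.loc[sample_ids]
        return GenotypeMatrix(
            samples=list(sample_ids),
            calls=self.calls[idx, :],
            markers=self.markers,
            sample_meta=meta,
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.samples == other.samples
            and list(self.markers.index) == list(other.markers.index)
            and (self.markers["chrom"].to_list() == other.markers["chrom"].to_list())
            and (self.markers["pos"].to_list() == other.markers["pos"].to_list())
            and bool((self.calls == other.calls).all())
        )


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise simple-matching dissimilarities with shared-locus counts.

    ``d[i, j]`` is defined over loci non-missing in both samples; where no loci
    are shared it is NaN and ``shared_loci[i, j]`` is 0.
    """

    ids: list[str]
    d: np.ndarray
    shared_loci: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("dissimilarity matrix shape inconsistent with ids")
        if self.shared_loci is None:
            self.shared_loci = np.zeros((n, n), dtype=np.int64)
        valid = ~np.isnan(self.d)
        if not np.allclose(self.d[valid], np.asarray(self.d.T)[valid.T], atol=1e-12):
            raise ValueError("dissimilarity matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    def undefined_pairs(self) -> list[tuple[str, str]]:
        """Pairs (i<j) whose dissimilarity is undefined (no shared loci)."""
        iu, ju = np.triu_indices(self.n, k=1)
        bad = np.isnan(self.d[iu, ju])
        return [(self.ids[i], self.ids[j]) for i, j in zip(iu[bad], ju[bad])]


# ---------------------------------------------------------------------------
# Tab-delimited genotype table
# ---------------------------------------------------------------------------

def write_tsv(matrix: GenotypeMatrix, path: str | Path) -> Path:
    """Write a genotype matrix to a tab-delimited table.

    Layout: two comment rows carrying chromosome and position per marker,
    then a header row of marker ids, then one row per sample. Missing calls
    are ``"NN"``. This file alone round-trips through :func:`read_tsv`.
    """
    path = Path(path)
    with open(path, "w") as fh:
        ids = list(matrix.markers.index.astype(str))
        fh.write("##chrom\t" + "\t".join(matrix.markers["chrom"].astype(str)) + "\n")
        fh.write("##pos\t" + "\t".join(matrix.markers["pos"].astype(str)) + "\n")
        fh.write("sample\t" + "\t".join(ids) + "\n")
        for i, s in enumerate(matrix.samples):
            fh.write(s + "\t" + "\t".join(matrix.calls[i]) + "\n")
    return path


def read_tsv(path: str | Path) -> GenotypeMatrix:
    """Read the tab-delimited genotype dialect written by :func:`write_tsv`."""
    path = Path(path)
    with open(path) as fh:
        chrom_line = fh.readline().rstrip("\n").split("\t")
        pos_line = fh.readline().rstrip("\n").split("\t")
        if chrom_line[0] != "##chrom" or pos_line[0] != "##pos":
            raise ValueError(f"{path}: not a germdiss genotype table (missing ##chrom/##pos header)")
        header = fh.readline().rstrip("\n").split("\t")
        marker_ids = header[1:]
        samples: list[str] = []
        rows: list[list[str]] = []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts or parts == [""]:
                continue
            samples.append(parts[0])
            rows.append(parts[1:])
    markers = pd.DataFrame(
        {"chrom": chrom_line[1:], "pos": [int(p) for p in pos_line[1:]]},
        index=pd.Index(marker_ids, name="marker"),
    )
    calls = np.array(rows, dtype="<U2") if rows else np.empty((0, len(marker_ids)), dtype="<U2")
    return GenotypeMatrix(samples=samples, calls=calls, markers=markers)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> Path:
    """Write a minimal standard-conformant VCF 4.2 (GT only, diploid, unphased).

    Each marker needs at least one non-missing call or two observed alleles to
    define REF/ALT; fully missing markers are written with REF=N, ALT=".".
    Missing genotypes are ``./.``.
    """
    path = Path(path)
    n, m = matrix.calls.shape
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        for j, (mid, row) in enumerate(matrix.markers.iterrows()):
            col = matrix.calls[:, j]
            alleles: list[str] = []
            for st in col:
                if st == MISSING:
                    continue
                for a in st:
                    if a not in alleles:
                        alleles.append(a)
            alleles.sort()
            if not alleles:
                ref, alts = "N", ["."]
            else:
                ref = alleles[0]
                alts = alleles[1:] or ["."]
            aidx = {a: k for k, a in enumerate([ref] + [a for a in alts if a != "."])}
            gts = []
            for st in col:
                if st == MISSING:
                    gts.append("./.")
                else:
                    gts.append(f"{aidx[st[0]]}/{aidx[st[1]]}")
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{mid}\t{ref}\t{','.join(alts)}\t.\t.\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )
    return path


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read diploid GT calls from a VCF into a :class:`GenotypeMatrix`."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    marker_ids: list[str] = []
    chroms: list[str] = []
    poss: list[int] = []
    cols: list[np.ndarray] = []
    for var in vcf:
        alleles = [var.REF] + list(var.ALT)
        col = np.full(len(samples), MISSING, dtype="<U2")
        for i, gt in enumerate(var.genotypes):
            a1, a2 = gt[0], gt[1]
            if a1 < 0 or a2 < 0:
                continue
            col[i] = canonical_state(alleles[a1], alleles[a2])
        marker_ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        cols.append(col)
    vcf.close()
    calls = (
        np.column_stack(cols) if cols else np.empty((len(samples), 0), dtype="<U2")
    )
    markers = pd.DataFrame(
        {"chrom": chroms, "pos": poss}, index=pd.Index(marker_ids, name="marker")
    )
    return GenotypeMatrix(samples=samples, calls=calls, markers=markers)


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    """Dispatch on extension: ``.vcf`` -> VCF reader, otherwise genotype table."""
    path = Path(path)
    if path.suffix.lower() in {".vcf", ".gz"} or path.name.endswith(".vcf.gz"):
        return read_vcf(path)
    return read_tsv(path)


# ---------------------------------------------------------------------------
# Square dissimilarity matrix (PHYLIP-compatible)
# ---------------------------------------------------------------------------

def write_square_dm(dm: DissimilarityMatrix, path: str | Path, digits: int = 6) -> Path:
    """Write a square tab-delimited distance matrix, PHYLIP-style count header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"{dm.n}\n")
        for i, sid in enumerate(dm.ids):
            vals = "\t".join(f"{v:.{digits}f}" if np.isfinite(v) else "nan" for v in dm.d[i])
            fh.write(f"{sid}\t{vals}\n")
    return path


def read_square_dm(path: str | Path) -> DissimilarityMatrix:
    path = Path(path)
    with open(path) as fh:
        n = int(fh.readline().split()[0])
        ids, rows = [], []
        for _ in range(n):
            parts = fh.readline().split()
            ids.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    return DissimilarityMatrix(ids=ids, d=np.array(rows))
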