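"""Shared fixtures: a worked example from a published soybean genebank survey
(16 near-duplicate accession pairs with 5-decimal simple-matching
dissimilarities over 19,898 SNP markers) and small genotype matrices."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from germdiss import GenotypeMatrix

# 16 low-dissimilarity accession pairs reported for a 571-accession soybean
# collection genotyped at 19,898 SNPs: (sample1, sample2, dissimilarity,
# printed equivalent-different-loci count). The 0.00143 pair's printed count
# (29) does not round from the 5-decimal dissimilarity (28.45); its printed
# value is kept here but excluded from rounding assertions.
SOY_N_MARKERS = 19_898
SOY_PAIRS = [
    ("CN32257", "CN31690", 0.00130, 26),
    ("CN32257", "CN31719", 0.00130, 26),
    ("CN32257", "CN32634", 0.00152, 30),
    ("CN31690", "CN32634", 0.00097, 19),
    ("CN31690", "CN31719", 0.00149, 30),
    ("CN107815", "CN107819", 0.00119, 24),
    ("CN107815", "CN31984", 0.00187, 37),
    ("CN107815", "CN107461", 0.00133, 26),
    ("CN107819", "CN31984", 0.00157, 31),
    ("CN35309", "CN35329", 0.00096, 19),
    ("CN32829", "CN32451", 0.00143, 29),
    ("CN32053", "CN32631", 0.00112, 22),
    ("CN107826", "CN31692", 0.00169, 34),
    ("CN107580", "CN107581", 0.00085, 17),
    ("CN107562", "CN107631", 0.00166, 33),
    ("CN107558", "CN107855", 0.00152, 30),
]
# rows where round(d * 19898, half away from zero) reproduces the printed count
SOY_PAIRS_ROUNDING_ROBUST = [p for p in SOY_PAIRS if p[2] != 0.00143]


@pytest.fixture(scope="session")
def soy_pairs():
    return SOY_PAIRS


@pytest.fixture(scope="session")
def soy_pairs_robust():
    return SOY_PAIRS_ROUNDING_ROBUST


def make_matrix(calls, samples=None, chroms=None):
    """GenotypeMatrix from a nested list/array of state strings."""
    calls = np.asarray(calls, dtype="<U2")
    n, m = calls.shape
    samples = samples or [f"S{i}" for i in range(n)]
    markers = pd.DataFrame(
        {
            "chrom": chroms if chroms is not None else ["Chr01"] * m,
            "pos": np.arange(1, m + 1) * 10,
        },
        index=pd.Index([f"M{j}" for j in range(m)], name="marker"),
    )
    return GenotypeMatrix(samples=list(samples), calls=calls, markers=markers)


@pytest.fixture
def tiny_matrix():
    """4 samples x 4 markers, no missing calls."""
    return make_matrix(
        [
            ["AA", "AC", "CC", "AA"],
            ["AA", "CC", "CC", "AA"],
            ["AC", "AC", "AC", "AA"],
            ["CC", "AA", "CC", "AC"],
        ]
    )


def random_matrix(rng, n=30, m=200, missing_rate=0.2):
    """Random tri-state matrix with i.i.d. missingness, for oracle tests."""
    states = np.array(["AA", "AG", "GG"])
    calls = states[rng.integers(0, 3, size=(n, m))]
    calls[rng.random((n, m)) < missing_rate] = "NN"
    return make_matrix(calls)
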