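"""Structure-level analyses on a cleaned dissimilarity matrix.

* PCoA — classical scaling (Gower double-centering of -d²/2); coordinates on
  positive-eigenvalue axes only, percent variance over positive eigenvalues.
* Neighbor-joining (Saitou–Nei) with a deterministic tie rule and Newick
  export; negative branch lengths are clamped to zero with the deficit moved
  to the sister branch, preserving the pair's path length.
* Distance-based AMOVA (Excoffier-style sums of squared distances) on samples
  treated as single multilocus genotypes, two-level design (among/within
  groups), Phi_ST, and a label-permutation p-value. The degrees of freedom
  follow the sample-level convention df_among = G-1, df_within = N-G; software
  that weights by allele copies will print different df on the same data.
* Evanno ΔK post-processing of external model-based clustering log-likelihood
  tables: ΔK = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / SD(L at K).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import DissimilarityMatrix

__all__ = [
    "PcoaResult",
    "AmovaResult",
    "DeltaKResult",
    "pcoa",
    "nj_tree",
    "amova",
    "pairwise_group_distances",
    "evanno_delta_k",
]


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

@dataclass
class PcoaResult:
    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray  # all eigenvalues, descending
    percent_explained: np.ndarray  # per positive axis, over positive eigenvalues

    @property
    def n_positive(self) -> int:
        return len(self.percent_explained)


def _as_square(dm: DissimilarityMatrix | np.ndarray) -> tuple[np.ndarray, list[str]]:
    if isinstance(dm, DissimilarityMatrix):
        return np.asarray(dm.d, dtype=float), list(dm.ids)
    d = np.asarray(dm, dtype=float)
    return d, [str(i) for i in range(d.shape[0])]


def pcoa(dm: DissimilarityMatrix | np.ndarray, n_axes: int = 3) -> PcoaResult:
    """Classical scaling (principal coordinate analysis) of a distance matrix.

    Gower-center ``-d**2 / 2``, eigendecompose, scale eigenvectors by the
    square root of their (positive) eigenvalues. Negative eigenvalues — which
    arise whenever the dissimilarity is not Euclidean-embeddable, as for the
    simple matching complement — are excluded both from the coordinates and
    from the percent-explained denominator.
    """
    d, ids = _as_square(dm)
    if np.isnan(d).any():
        raise ValueError("PCoA input contains undefined (NaN) dissimilarities")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("PCoA input must be symmetric")
    n = d.shape[0]
    a = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = j @ a @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(abs(evals).max(), 1.0) * 1e-10
    pos = evals > tol
    pos_vals = evals[pos]
    coords = evecs[:, pos] * np.sqrt(pos_vals)
    k = min(n_axes, coords.shape[1])
    pct = 100.0 * pos_vals / pos_vals.sum() if pos_vals.size else np.array([])
    frame = pd.DataFrame(
        coords[:, :k],
        index=pd.Index(ids, name="sample"),
        columns=[f"PCo{i + 1}" for i in range(k)],
    )
    return PcoaResult(coordinates=frame, eigenvalues=evals, percent_explained=pct)


# ---------------------------------------------------------------------------
# Neighbor-joining
# ---------------------------------------------------------------------------

_NEWICK_RESERVED = set("()[]:;,' \t\n")


def _quote(label: str) -> str:
    if any(c in _NEWICK_RESERVED for c in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def nj_tree(dm: DissimilarityMatrix | np.ndarray, precision: int = 6) -> str:
    """Saitou–Nei neighbor-joining; returns an unrooted Newick string.

    Deterministic: the minimum-Q pair with the smallest (i, j) index pair
    under the current taxon ordering is joined at each step. Negative branch
    lengths are clamped to 0 and the deficit transferred to the sister branch
    so the joined pair's summed length stays equal to their distance.
    Branch lengths are written with ``precision`` significant digits.
    """

    def _fmt_bl(x: float) -> str:
        return f"{x:.{precision}g}"

    d, ids = _as_square(dm)
    n = d.shape[0]
    if n < 3:
        raise ValueError("neighbor-joining needs at least 3 taxa")
    if np.isnan(d).any():
        raise ValueError("NJ input contains undefined (NaN) dissimilarities")
    d = d.copy()
    # each active node is a newick fragment (without trailing branch length)
    nodes: list[str] = [_quote(s) for s in ids]
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # smallest Q; ties -> smallest (i, j) in current ordering
        fi, fj = divmod(int(np.argmin(q)), m)
        if fi > fj:
            fi, fj = fj, fi
        dij = sub[fi, fj]
        li = 0.5 * dij + (r[fi] - r[fj]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        ai, aj = active[fi], active[fj]
        new = f"({nodes[ai]}:{_fmt_bl(li)},{nodes[aj]}:{_fmt_bl(lj)})"
        # distances from the new node to the others
        du = 0.5 * (sub[fi, :] + sub[fj, :] - dij)
        nodes.append(new)
        d = np.pad(d, ((0, 1), (0, 1)))
        for k_pos, ak in enumerate(active):
            d[-1, ak] = d[ak, -1] = du[k_pos]
        d[-1, -1] = 0.0
        active = [a for a in active if a not in (ai, aj)] + [d.shape[0] - 1]
        nodes_len = len(nodes)
        assert nodes_len == d.shape[0]
    a, b, c = active
    dab, dac, dbc = d[a, b], d[a, c], d[b, c]
    la = max(0.0, 0.5 * (dab + dac - dbc))
    lb = max(0.0, 0.5 * (dab + dbc - dac))
    lc = max(0.0, 0.5 * (dac + dbc - dab))
    return f"({nodes[a]}:{_fmt_bl(la)},{nodes[b]}:{_fmt_bl(lb)},{nodes[c]}:{_fmt_bl(lc)});"


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

@dataclass
class AmovaResult:
    df_among: int
    df_within: int
    ss_among: float
    ss_within: float
    sigma2_among: float  # as computed; may be negative
    sigma2_within: float
    percent_among: float  # display values; negative components truncated to 0
    percent_within: float
    phi_st: float
    p_value: float
    n_permutations: int

    def to_dict(self) -> dict:
        return {
            "among": {
                "df": self.df_among,
                "sum_of_squares": self.ss_among,
                "variance_component": self.sigma2_among,
                "percent_of_variation": self.percent_among,
            },
            "within": {
                "df": self.df_within,
                "sum_of_squares": self.ss_within,
                "variance_component": self.sigma2_within,
                "percent_of_variation": self.percent_within,
            },
            "phi_st": self.phi_st,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
        }


def _ssd_parts(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    """(SSD_total, SSD_within) from a squared-distance matrix and group codes."""
    n = d2.shape[0]
    ssd_total = d2.sum() / (2 * n)
    ssd_within = 0.0
    for g in range(n_groups):
        sel = codes == g
        ng = int(sel.sum())
        if ng > 1:
            ssd_within += d2[np.ix_(sel, sel)].sum() / (2 * ng)
    return float(ssd_total), float(ssd_within)


def _phi(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = d2.shape[0]
    sizes = np.bincount(codes, minlength=n_groups)
    ssd_t, ssd_w = _ssd_parts(d2, codes, n_groups)
    ssd_a = ssd_t - ssd_w
    df_a, df_w = n_groups - 1, n - n_groups
    s2_w = ssd_w / df_w if df_w > 0 else 0.0
    n0 = (n - (sizes**2).sum() / n) / df_a
    s2_a = (ssd_a / df_a - s2_w) / n0 if n0 > 0 else 0.0
    tot = s2_a + s2_w
    return s2_a / tot if tot > 0 else 0.0


def amova(
    dm: DissimilarityMatrix | np.ndarray,
    grouping: dict[str, object] | list | np.ndarray,
    n_permutations: int = 999,
    seed: int | None = None,
) -> AmovaResult:
    """Two-level distance-based AMOVA with a permutation test on Phi_ST.

    Works on squared pairwise dissimilarities among samples treated as single
    multilocus genotypes. ``grouping`` maps sample id to group (or is a
    sequence aligned with the matrix ids). The p-value permutes sample-to-
    group assignment: p = (#{Phi_perm >= Phi_obs} + 1) / (B + 1).
    """
    d, ids = _as_square(dm)
    if np.isnan(d).any():
        raise ValueError("AMOVA input contains undefined (NaN) dissimilarities")
    if isinstance(grouping, dict):
        labels = [grouping[s] for s in ids]
    else:
        labels = list(grouping)
        if len(labels) != len(ids):
            raise ValueError("grouping length does not match the matrix")
    uniq = sorted(set(labels), key=str)
    if len(uniq) < 2:
        raise ValueError("AMOVA needs at least 2 groups")
    codes = np.array([uniq.index(g) for g in labels])
    sizes = np.bincount(codes, minlength=len(uniq))
    if (sizes == 0).any():
        raise ValueError("every group must contain at least one sample")
    n, g = len(ids), len(uniq)
    d2 = d.astype(float) ** 2

    ssd_t, ssd_w = _ssd_parts(d2, codes, g)
    ssd_a = ssd_t - ssd_w
    df_a, df_w = g - 1, n - g
    s2_w = ssd_w / df_w if df_w > 0 else 0.0
    n0 = (n - (sizes**2).sum() / n) / df_a
    s2_a = (ssd_a / df_a - s2_w) / n0
    # percent display: negative components truncated to 0
    a_disp, w_disp = max(s2_a, 0.0), max(s2_w, 0.0)
    tot_disp = a_disp + w_disp
    pct_a = 100.0 * a_disp / tot_disp if tot_disp > 0 else 0.0
    pct_w = 100.0 * w_disp / tot_disp if tot_disp > 0 else 100.0
    tot = s2_a + s2_w
    phi = s2_a / tot if tot > 0 else 0.0

    p = np.nan
    if n_permutations > 0 and df_w > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        perm = codes.copy()
        for _ in range(n_permutations):
            rng.shuffle(perm)
            if _phi(d2, perm, g) >= phi - 1e-12:
                hits += 1
        p = (hits + 1) / (n_permutations + 1)
    return AmovaResult(
        df_among=df_a,
        df_within=df_w,
        ss_among=ssd_a,
        ss_within=ssd_w,
        sigma2_among=s2_a,
        sigma2_within=s2_w,
        percent_among=pct_a,
        percent_within=pct_w,
        phi_st=phi,
        p_value=p,
        n_permutations=n_permutations if df_w > 0 else 0,
    )


def pairwise_group_distances(
    dm: DissimilarityMatrix | np.ndarray,
    grouping: dict[str, object] | list | np.ndarray,
    n_permutations: int = 999,
    seed: int | None = None,
    correction: str | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Phi_ST and permutation p for every pair of groups (two-group AMOVA each).

    Returns a long-format DataFrame (group1, group2, phi_st, p_value,
    significant). ``correction`` may be any statsmodels multipletests method
    (e.g. ``"bonferroni"``); default is none, reporting raw significance at
    ``alpha``. Pairs of two singleton groups have no within-group degrees of
    freedom: Phi is reported as 1 if the two samples differ (0 otherwise) and
    p is NaN.
    """
    d, ids = _as_square(dm)
    if isinstance(grouping, dict):
        labels = [grouping[s] for s in ids]
    else:
        labels = list(grouping)
    uniq = sorted(set(labels), key=str)
    rows = []
    rng = np.random.default_rng(seed)
    for i in range(len(uniq)):
        for j in range(i + 1, len(uniq)):
            g1, g2 = uniq[i], uniq[j]
            sel = [k for k, lab in enumerate(labels) if lab in (g1, g2)]
            sub = d[np.ix_(sel, sel)]
            sub_labels = [labels[k] for k in sel]
            if len(sel) == 2:  # singleton vs singleton
                phi = 1.0 if sub[0, 1] > 0 else 0.0
                rows.append((g1, g2, phi, np.nan))
                continue
            res = amova(
                sub,
                sub_labels,
                n_permutations=n_permutations,
                seed=int(rng.integers(2**31 - 1)),
            )
            rows.append((g1, g2, res.phi_st, res.p_value))
    out = pd.DataFrame(rows, columns=["group1", "group2", "phi_st", "p_value"])
    pvals = out["p_value"].to_numpy()
    ok = ~np.isnan(pvals)
    sig = np.zeros(len(out), dtype=bool)
    if correction is None:
        sig[ok] = pvals[ok] < alpha
    elif ok.any():
        from statsmodels.stats.multitest import multipletests

        sig[ok] = multipletests(pvals[ok], alpha=alpha, method=correction)[0]
    out["significant"] = sig
    return out


# ---------------------------------------------------------------------------
# Evanno delta-K
# ---------------------------------------------------------------------------

@dataclass
class DeltaKResult:
    table: pd.DataFrame  # index K; columns mean_lnl, sd_lnl, delta_k
    best_k: int | None  # argmax of delta_k over defined interior K

    def __repr__(self) -> str:  # pragma: no cover
        return f"DeltaKResult(best_k={self.best_k})\n{self.table}"


def evanno_delta_k(loglik: pd.DataFrame) -> DeltaKResult:
    """Evanno ΔK from a table of clustering log-likelihoods.

    ``loglik`` is long format with columns ``K``, ``run``, ``lnl`` (or wide
    with K as index and one column per run). For each interior K with
    SD > 0 over runs:

        ΔK = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / SD(L at K)

    ΔK at boundary K, or where SD = 0, is NaN (flagged, not an error). The
    supported K is the argmax of the defined ΔK values.
    """
    if {"K", "run", "lnl"} <= set(loglik.columns):
        wide = loglik.pivot(index="K", columns="run", values="lnl")
    else:
        wide = loglik
    wide = wide.sort_index()
    ks = wide.index.to_numpy()
    if len(ks) < 3:
        raise ValueError("need at least 3 consecutive K values")
    if not np.array_equal(np.diff(ks), np.ones(len(ks) - 1)):
        raise ValueError("K values must be consecutive integers")
    if wide.notna().sum(axis=1).min() < 2:
        raise ValueError("need at least 2 runs per K")
    mean = wide.mean(axis=1).to_numpy()
    sd = wide.std(axis=1, ddof=1).to_numpy()
    delta = np.full(len(ks), np.nan)
    for i in range(1, len(ks) - 1):
        if sd[i] > 0:
            delta[i] = abs(mean[i + 1] - 2 * mean[i] + mean[i - 1]) / sd[i]
    table = pd.DataFrame(
        {"mean_lnl": mean, "sd_lnl": sd, "delta_k": delta},
        index=pd.Index(ks, name="K"),
    )
    best = None
    if np.isfinite(delta).any():
        best = int(ks[np.nanargmax(delta)])
    return DeltaKResult(table=table, best_k=best)
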