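"""Marker-based population structure: Weir–Cockerham F_ST with bootstrap
CIs, and distance-based PCA with balanced flock subsampling.

F_ST uses the Weir & Cockerham (1984) theta for each flock pair,
aggregated over loci as a ratio of sums, with a seeded locus bootstrap
for percentile confidence intervals. The PCA operates on 1 - IBS
(allele-sharing) distances via classical multidimensional scaling of
the double-centred distance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix


def _locus_components(calls_a: np.ndarray, calls_b: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus Weir–Cockerham variance components (a, b, c) for two pops."""
    comps = []
    for calls in (calls_a, calls_b):
        obs = calls >= 0
        n = obs.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(calls >= 0, calls, 0).sum(axis=0) / (2.0 * n)
            h = (calls == 1).sum(axis=0) / n
        comps.append((n, p, h))
    (n1, p1, h1), (n2, p2, h2) = comps
    r = 2.0
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        inner = pbar * (1 - pbar) - (r - 1.0) / r * s2
        a = nbar / nc * (s2 - (inner - hbar / 4.0) / (nbar - 1.0))
        b = nbar / (nbar - 1.0) * (inner - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
        c = hbar / 2.0
    ok = np.isfinite(a) & np.isfinite(b) & np.isfinite(c) & (n1 > 0) & (n2 > 0)
    return a[ok], b[ok], c[ok]


def wc_theta(calls_a: np.ndarray, calls_b: np.ndarray) -> float:
    """Weir–Cockerham theta between two populations, ratio of sums over loci."""
    a, b, c = _locus_components(calls_a, calls_b)
    denom = float((a + b + c).sum())
    return float(a.sum()) / denom if denom != 0 else 0.0


def _bootstrap_theta(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                     n_boot: int, rng: np.random.Generator,
                     alpha: float = 0.05) -> tuple[float, float]:
    L = len(a)
    thetas = np.empty(n_boot)
    for k in range(n_boot):
        idx = rng.integers(0, L, size=L)
        denom = (a[idx] + b[idx] + c[idx]).sum()
        thetas[k] = a[idx].sum() / denom if denom != 0 else 0.0
    return (float(np.quantile(thetas, alpha / 2)),
            float(np.quantile(thetas, 1 - alpha / 2)))


@dataclass
class FstMatrix:
    fst: pd.DataFrame
    ci_lo: pd.DataFrame
    ci_hi: pd.DataFrame
    excluded_flocks: list

    def per_flock_mean(self) -> pd.Series:
        m = self.fst.copy()
        np.fill_diagonal(m.values, np.nan)
        return m.mean(axis=1)


def pairwise_fst(g: GenotypeMatrix, *, min_n: int = 10, n_boot: int = 100,
                 seed: int | None = None, alpha: float = 0.05) -> FstMatrix:
    """Pairwise flock F_ST with locus-bootstrap percentile CIs.

    Flocks with at most ``min_n`` genotyped animals are excluded (strict
    ``> min_n`` rule).
    """
    rng = np.random.default_rng(seed)
    flocks = g.animals["flock"].to_numpy()
    counts = pd.Series(flocks).value_counts()
    keep = sorted([str(f) for f in counts.index[counts > min_n]])
    excluded = sorted([str(f) for f in counts.index[counts <= min_n]])
    fst = pd.DataFrame(0.0, index=keep, columns=keep)
    lo = pd.DataFrame(0.0, index=keep, columns=keep)
    hi = pd.DataFrame(0.0, index=keep, columns=keep)
    for i, fa in enumerate(keep):
        for fb in keep[i + 1:]:
            ca = g.calls[flocks.astype(str) == fa]
            cb = g.calls[flocks.astype(str) == fb]
            a, b, c = _locus_components(ca, cb)
            denom = float((a + b + c).sum())
            theta = float(a.sum()) / denom if denom != 0 else 0.0
            ci = _bootstrap_theta(a, b, c, n_boot, rng, alpha)
            fst.loc[fa, fb] = fst.loc[fb, fa] = theta
            lo.loc[fa, fb] = lo.loc[fb, fa] = ci[0]
            hi.loc[fa, fb] = hi.loc[fb, fa] = ci[1]
    return FstMatrix(fst, lo, hi, excluded)


# ---------------------------------------------------------------------------
# distance-based PCA


def ibs_distance(calls: np.ndarray) -> np.ndarray:
    """1 - mean proportion of shared alleles over non-missing loci."""
    X = calls.astype(float)
    X[X < 0] = np.nan
    n = X.shape[0]
    D = np.zeros((n, n))
    M = ~np.isnan(X)
    X0 = np.nan_to_num(X)
    # |g_i - g_j| summed over loci both observed, vectorised by row
    for i in range(n):
        diff = np.abs(X0[i] - X0)
        both = M[i] & M
        diff[~both] = 0.0
        cnt = both.sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            D[i] = np.where(cnt > 0, diff.sum(axis=1) / (2.0 * cnt), np.nan)
    np.fill_diagonal(D, 0.0)
    return D


def classical_mds(D: np.ndarray, n_components: int = 3) -> dict:
    """Principal coordinates of a distance matrix (Torgerson MDS)."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals[vals > 0]
    coords = vecs[:, :n_components] * np.sqrt(np.maximum(vals[:n_components], 0.0))
    return {"coords": coords,
            "variance_fraction": np.maximum(vals[:n_components], 0.0) / pos.sum(),
            "negative_eigenvalue_sum": float(vals[vals < 0].sum())}


@dataclass
class PcaReplicate:
    replicate: int
    table: pd.DataFrame          # animal, flock, PC1..PC3
    variance_fraction: np.ndarray
    negative_eigenvalue_sum: float


def pca_replicates(g: GenotypeMatrix, *, min_n: int = 10, per_flock_cap: int = 20,
                   n_reps: int = 5, seed: int | None = None,
                   n_components: int = 3) -> list[PcaReplicate]:
    """Balanced-subsample IBS-distance PCAs.

    Flocks with more than ``per_flock_cap`` genotyped animals contribute a
    random ``per_flock_cap``-animal subset per replicate (drawn
    independently across replicates, without replacement within one);
    smaller flocks (still > ``min_n``) contribute all animals every time.
    """
    rng = np.random.default_rng(seed)
    flocks = g.animals["flock"].astype(str).to_numpy()
    counts = pd.Series(flocks).value_counts()
    keep = [str(f) for f in counts.index[counts > min_n]]
    out = []
    for rep in range(n_reps):
        rows: list[int] = []
        for f in sorted(keep):
            members = np.nonzero(flocks == f)[0]
            if len(members) > per_flock_cap:
                members = rng.choice(members, size=per_flock_cap, replace=False)
            rows.extend(members.tolist())
        rows = sorted(rows)
        D = ibs_distance(g.calls[rows])
        mds = classical_mds(D, n_components)
        tab = pd.DataFrame({"animal": g.animals["animal"].to_numpy()[rows],
                            "flock": flocks[rows]})
        for k in range(n_components):
            tab[f"PC{k + 1}"] = mds["coords"][:, k]
        out.append(PcaReplicate(rep + 1, tab, mds["variance_fraction"],
                                mds["negative_eigenvalue_sum"]))
    return out
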