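"""Effective population size: pedigree estimators and the LD method.

The pedigree family expresses Ne = 1/(2·ΔF) with ΔF measured in several
ways (individual increase in inbreeding over three pedigree-depth
definitions, regression of F on birth year, log regression of (1-F) on
generation number, and increase in pairwise coancestry). The genomic
estimator uses the squared correlation of additive genotypes between
physically unlinked loci: in a finite random-mating population the
sample-corrected mean r² at unlinked loci is ≈ 1/(3Ne).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .pedigree import Pedigree
from .relatedness import coancestry_matrix
from .genotypes import GenotypeMatrix

INF_NE = float("inf")  # sentinel when the inbreeding/LD signal is absent


@dataclass
class NeEstimate:
    method: str
    ne: float
    ci_lo: float | None = None
    ci_hi: float | None = None
    detail: dict | None = None

    def as_row(self) -> dict:
        return {"method": self.method, "ne": self.ne,
                "ci_lo": self.ci_lo, "ci_hi": self.ci_hi}


def _ne_from_delta_f(delta_f: float) -> float:
    return 1.0 / (2.0 * delta_f) if delta_f > 0 else INF_NE


def individual_delta_f(F: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Per-animal rate ΔF_i = 1 - (1 - F_i)^(1/(t_i - 1)); only t_i > 1 usable."""
    t = np.asarray(t, dtype=float)
    usable = t > 1
    out = np.full(len(F), np.nan)
    out[usable] = 1.0 - np.power(1.0 - F[usable], 1.0 / (t[usable] - 1.0))
    return out


def ne_individual_increase(F: np.ndarray, t: np.ndarray, method: str
                           ) -> NeEstimate:
    """Ne from the mean individual increase in inbreeding over depth ``t``."""
    dfi = individual_delta_f(np.asarray(F, float), t)
    dfi = dfi[np.isfinite(dfi)]
    if len(dfi) == 0:
        raise ValueError("no animal with pedigree depth t > 1")
    return NeEstimate(method, _ne_from_delta_f(float(dfi.mean())),
                      detail={"mean_delta_f": float(dfi.mean()), "n": len(dfi)})


def ne_regression_birth_year(ped: Pedigree, F: np.ndarray,
                             generation_length: float = 3.1) -> NeEstimate:
    """Ne from the slope of F on birth year scaled to a generation."""
    y = ped.birth_year
    ok = np.isfinite(y)
    years = np.unique(y[ok])
    if len(years) < 3:
        raise ValueError("need >= 3 birth-year cohorts")
    res = sstats.linregress(y[ok], np.asarray(F, float)[ok])
    dfg = float(res.slope) * generation_length
    return NeEstimate("regression_birth_year", _ne_from_delta_f(dfg),
                      detail={"slope_per_year": float(res.slope),
                              "delta_f_per_generation": dfg})


def ne_log_regression(cohort_mean_f: np.ndarray,
                      generation_number: np.ndarray) -> NeEstimate:
    """Ne from the regression of ln(1 - F̄) on generation number.

    Under a constant rate, F̄_g = 1 - (1-ΔF)^g, so the slope is
    ln(1-ΔF) and Ne = 1/(2(1 - e^slope)).
    """
    f = np.asarray(cohort_mean_f, dtype=float)
    if np.any(f >= 1):
        raise ValueError("cohort mean F must be < 1")
    res = sstats.linregress(np.asarray(generation_number, float), np.log1p(-f))
    dfg = 1.0 - math.exp(float(res.slope))
    return NeEstimate("log_regression", _ne_from_delta_f(dfg),
                      detail={"slope": float(res.slope),
                              "delta_f_per_generation": dfg})


def ne_coancestry(ped: Pedigree, ids, t: np.ndarray, *,
                  max_animals: int = 10_000, seed: int | None = None
                  ) -> NeEstimate:
    """Ne from the increase in coancestry over all pairs of ``ids``.

    For a pair (j,k), Δc = 1 - (1 - f_jk)^(1/((t_j + t_k)/2)) and
    Ne = 1/(2·mean Δc). Large id sets are subsampled to ``max_animals``
    (seeded) before the kinship matrix is formed.
    """
    ids = np.asarray(list(ids))
    if len(ids) > max_animals:
        rng = np.random.default_rng(seed)
        ids = rng.choice(ids, size=max_animals, replace=False)
    pos = ped.positions(ids)
    f = coancestry_matrix(ped, ids)
    tt = np.asarray(t, dtype=float)[pos]
    iu = np.triu_indices(len(ids), k=1)
    tbar = 0.5 * (tt[iu[0]] + tt[iu[1]])
    ok = tbar > 0
    dc = 1.0 - np.power(1.0 - f[iu][ok], 1.0 / tbar[ok])
    if len(dc) == 0:
        raise ValueError("no usable pair for coancestry-based Ne")
    return NeEstimate("coancestry_increase", _ne_from_delta_f(float(dc.mean())),
                      detail={"mean_delta_c": float(dc.mean()), "n_pairs": int(ok.sum())})


# ---------------------------------------------------------------------------
# LD method


def _expected_r2_null(S: int) -> float:
    """Expected squared genotypic correlation with no LD, sample size S.

    For the squared Pearson correlation between two independent variates
    estimated from S observations, E[r²] = 1/(S-1) exactly; this is the
    matching null for the genotype-correlation r² used here.
    """
    return 1.0 / (S - 1)


def _invert_r2(r2_adj: float) -> float:
    """Map the drift component of r² to Ne (random-mating correction).

    Uses the quadratic inversion 1/(2r²')·(1/3 + sqrt(1/9 - 2.76 r²'))
    whose large-Ne limit is 1/(3 r²'); falls back to the limit form when
    the discriminant is negative (very small samples / strong LD).
    """
    if r2_adj <= 0:
        return INF_NE
    disc = 1.0 / 9.0 - 2.76 * r2_adj
    if disc >= 0:
        return (1.0 / 3.0 + math.sqrt(disc)) / (2.0 * r2_adj)
    return 1.0 / (3.0 * r2_adj)


def ne_ld(g: GenotypeMatrix, *, maf_cutoff: float = 0.02,
          alpha: float = 0.05) -> NeEstimate:
    """LD-based Ne from mean r² between different-chromosome SNP pairs.

    Only pairs on different chromosomes enter (physically unlinked), loci
    below ``maf_cutoff`` are screened out, r² is the squared Pearson
    correlation of additive codes with pairwise deletion of missing
    calls, and the no-LD expectation for the sample size is subtracted
    before inversion. The CI is a jackknife over loci.
    """
    calls = g.calls
    S = calls.shape[0]
    if S < 10:
        raise ValueError("LD-based Ne needs at least 10 genotyped animals")
    maf = g.maf()
    keep = np.nonzero(maf >= maf_cutoff)[0]
    chrom = g.snps["chrom"].to_numpy()[keep]
    X = calls[:, keep].astype(float)
    X[calls[:, keep] < 0] = np.nan
    # z-score with nan handling; correlation via pairwise products
    mean = np.nanmean(X, axis=0)
    std = np.nanstd(X, axis=0)
    std[std == 0] = np.nan
    Z = (X - mean) / std
    M = ~np.isnan(Z)
    Z0 = np.where(M, Z, 0.0)
    num = Z0.T @ Z0
    cnt = M.astype(float).T @ M.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / cnt
    r2 = r * r
    inter = chrom[:, None] != chrom[None, :]
    valid = inter & np.isfinite(r2) & (cnt >= 10)
    np.fill_diagonal(valid, False)
    n_pairs = int(valid.sum()) // 2
    if n_pairs == 0:
        raise ValueError("no inter-chromosomal SNP pair available")
    r2v = np.where(valid, r2, 0.0)
    total = float(r2v.sum()) / 2.0
    mean_r2 = total / n_pairs
    null = _expected_r2_null(S)
    r2_adj = mean_r2 - null
    ne = _invert_r2(r2_adj)

    # delete-one-locus jackknife on the adjusted mean r²
    row_sum = r2v.sum(axis=1)
    row_cnt = valid.sum(axis=1)
    loo = (total - row_sum) / np.maximum(n_pairs - row_cnt, 1)
    L = len(loo)
    jk_var = (L - 1) / L * float(np.sum((loo - loo.mean()) ** 2))
    half = sstats.norm.ppf(1 - alpha / 2) * math.sqrt(jk_var)
    lo_r2, hi_r2 = r2_adj - half, r2_adj + half
    return NeEstimate("ld_method", ne, ci_lo=_invert_r2(hi_r2),
                      ci_hi=_invert_r2(lo_r2),
                      detail={"mean_r2": mean_r2, "r2_adj": r2_adj,
                              "expected_null_r2": null, "n_pairs": n_pairs,
                              "n_loci": L, "sample_size": S})


# ---------------------------------------------------------------------------
# the full pedigree battery


def pedigree_ne_battery(ped: Pedigree, F: np.ndarray, stats,
                        *, generation_length: float = 3.1,
                        coancestry_ids=None, coancestry_seed: int | None = None,
                        max_coancestry_animals: int = 10_000) -> pd.DataFrame:
    """The seven pedigree-based Ne estimates as one table."""
    ests = [
        ne_individual_increase(F, stats.max_generations, "max_gen"),
        ne_individual_increase(F, stats.complete_generations, "complete_gen"),
        ne_individual_increase(F, stats.equivalent_generations, "equivalent_gen"),
    ]
    # "individual increase": per-animal ΔF over each animal's own realised
    # depth, taken as the equivalent-generations depth of the full pedigree
    # restricted to animals with usable depth (reference-cohort variant)
    t_ind = stats.equivalent_generations
    recent = t_ind >= np.median(t_ind[t_ind > 1]) if np.any(t_ind > 1) else t_ind > 1
    dfi = individual_delta_f(F, np.where(recent, t_ind, 0.0))
    dfi = dfi[np.isfinite(dfi)]
    ests.append(NeEstimate("individual_F", _ne_from_delta_f(float(dfi.mean()))
                           if len(dfi) else INF_NE))
    ests.append(ne_regression_birth_year(ped, F, generation_length))
    y = ped.birth_year
    ok = np.isfinite(y)
    gen = np.floor((y[ok] - y[ok].min()) / generation_length)
    tab = pd.DataFrame({"g": gen, "F": F[ok]}).groupby("g")["F"].mean()
    ests.append(ne_log_regression(tab.to_numpy(), tab.index.to_numpy()))
    ids = coancestry_ids if coancestry_ids is not None else ped.animals
    ests.append(ne_coancestry(ped, ids, stats.equivalent_generations,
                              max_animals=max_coancestry_animals,
                              seed=coancestry_seed))
    return pd.DataFrame([e.as_row() for e in ests])
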