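"""Pedigree relatedness: inbreeding F, coancestry, average relatedness, ΔF.

Inbreeding is computed with the Meuwissen & Luo indirect algorithm, which
obtains each animal's F from the L·D decomposition of the numerator
relationship matrix A without ever materialising A. Coancestry for
subsets uses the tabular method restricted to the ancestor closure, and
average relatedness (row means of A) is obtained from two triangular
solves against the pedigree structure, so the whole-pedigree AR vector is
O(n).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .pedigree import Pedigree, PedigreeError


def _mendelian_variance(i: int, sire: np.ndarray, dam: np.ndarray,
                        F: np.ndarray) -> float:
    """Within-family segregation variance D_i of the A = T D T' decomposition."""
    si, di = sire[i], dam[i]
    if si >= 0 and di >= 0:
        return 0.5 - 0.25 * (F[si] + F[di])
    if si >= 0:
        return 0.75 - 0.25 * F[si]
    if di >= 0:
        return 0.75 - 0.25 * F[di]
    return 1.0


def inbreeding(ped: Pedigree) -> np.ndarray:
    """Per-animal inbreeding coefficients (Meuwissen–Luo indirect method).

    For each animal, ancestors are visited youngest-first while the
    L-coefficients (expected genome fractions transmitted along pedigree
    paths) accumulate; F is the resulting diagonal element of A minus 1.
    Animals sharing both parents share F, so full-sib families are
    computed once.
    """
    n = len(ped)
    s, d = ped.sire_idx, ped.dam_idx
    F = np.zeros(n)
    cache: dict[tuple[int, int], float] = {}
    for i in range(n):
        si, di = s[i], d[i]
        if si < 0 or di < 0:
            continue  # unknown parent: no closed loop is possible
        key = (si, di)
        if key in cache:
            F[i] = cache[key]
            continue
        # L-vector over the ancestors of a (virtual) progeny of si x di
        L: dict[int, float] = {}
        heap: list[int] = []
        for p in (si, di):
            if p not in L:
                L[p] = 0.0
                heapq.heappush(heap, -p)
            L[p] += 0.5
        acc = 0.0
        while heap:
            j = -heapq.heappop(heap)
            lj = L.pop(j)
            acc += lj * lj * _mendelian_variance(j, s, d, F)
            for p in (s[j], d[j]):
                if p >= 0:
                    if p not in L:
                        L[p] = 0.0
                        heapq.heappush(heap, -p)
                    L[p] += 0.5 * lj
        f_i = acc + (0.5 - 0.25 * (F[si] + F[di])) - 1.0
        # guard against summation-order dust on deep pedigrees
        F[i] = cache[key] = f_i if abs(f_i) > 1e-14 else 0.0
    return F


def relationship_matrix(ped: Pedigree, positions: np.ndarray | None = None
                        ) -> np.ndarray:
    """Dense numerator relationship matrix A by the tabular method.

    When ``positions`` is given, A is built only over the ancestor closure
    of those animals and the sub-block for ``positions`` is returned.
    Intended for subsets; memory is O(closure^2).
    """
    if positions is None:
        closure = np.arange(len(ped), dtype=np.int64)
        want = closure
    else:
        want = np.asarray(positions, dtype=np.int64)
        closure = ped.ancestor_closure(ped.animals[want])
    remap = {int(g): k for k, g in enumerate(closure)}
    m = len(closure)
    A = np.zeros((m, m))
    s, d = ped.sire_idx, ped.dam_idx
    for k, g in enumerate(closure):
        sk = remap.get(int(s[g]), -1)
        dk = remap.get(int(d[g]), -1)
        # tabular recurrence: a_kj = (a_sj + a_dj)/2 for j < k
        if sk >= 0 and dk >= 0:
            A[k, :k] = 0.5 * (A[sk, :k] + A[dk, :k])
            A[k, k] = 1.0 + 0.5 * A[sk, dk]
        elif sk >= 0:
            A[k, :k] = 0.5 * A[sk, :k]
            A[k, k] = 1.0
        elif dk >= 0:
            A[k, :k] = 0.5 * A[dk, :k]
            A[k, k] = 1.0
        else:
            A[k, k] = 1.0
        A[:k, k] = A[k, :k]
    sel = np.asarray([remap[int(g)] for g in want])
    return A[np.ix_(sel, sel)]


@dataclass
class RelatednessResult:
    """Inbreeding + average relatedness with an on-demand kinship accessor."""

    ped: Pedigree
    F: np.ndarray
    AR: np.ndarray

    def coancestry(self, ids) -> np.ndarray:
        """Kinship matrix f = A/2 for the given animal ids."""
        return coancestry_matrix(self.ped, ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"animal": self.ped.animals, "F": self.F, "AR": self.AR})


def coancestry_matrix(ped: Pedigree, ids) -> np.ndarray:
    """Pairwise kinship f(i,j) = a_ij / 2 for ``ids`` (tabular, closure-restricted)."""
    pos = ped.positions(ids)
    return relationship_matrix(ped, pos) / 2.0


def average_relatedness(ped: Pedigree, F: np.ndarray | None = None) -> np.ndarray:
    """AR_i = mean of row i of A = twice the mean coancestry of i with the
    whole pedigree (self included).

    Uses A = (I-P)^-1 D (I-P)^-T with P the half-parent incidence matrix:
    a backward pass accumulates x = (I-P)^-T 1 (each animal's expected
    long-term contribution weight), then a forward pass maps D·x back
    through descent. Exact, O(n), no dense matrix.
    """
    n = len(ped)
    s, d = ped.sire_idx, ped.dam_idx
    if F is None:
        F = inbreeding(ped)
    x = np.ones(n)
    for i in range(n - 1, -1, -1):
        if s[i] >= 0:
            x[s[i]] += 0.5 * x[i]
        if d[i] >= 0:
            x[d[i]] += 0.5 * x[i]
    D = np.array([_mendelian_variance(i, s, d, F) for i in range(n)])
    y = D * x
    z = np.zeros(n)
    for i in range(n):
        z[i] = y[i]
        if s[i] >= 0:
            z[i] += 0.5 * z[s[i]]
        if d[i] >= 0:
            z[i] += 0.5 * z[d[i]]
    return z / n


def relatedness(ped: Pedigree) -> RelatednessResult:
    F = inbreeding(ped)
    return RelatednessResult(ped, F, average_relatedness(ped, F))


# ---------------------------------------------------------------------------
# inbreeding trend


@dataclass
class InbreedingTrend:
    """Cohort mean F, per-generation ΔF, and a zero-slope regression test."""

    table: pd.DataFrame  # cohort, n, mean_F, delta_F
    slope: float
    slope_p: float

    @property
    def mean_delta_f(self) -> float:
        return float(self.table["delta_F"].dropna().mean())


def delta_f(f_prev: float, f_curr: float) -> float:
    """Per-generation rate of inbreeding ΔF = (F_t - F_{t-1}) / (1 - F_{t-1})."""
    return (f_curr - f_prev) / (1.0 - f_prev)


def inbreeding_trend(ped: Pedigree, F: np.ndarray | None = None, *,
                     by: str = "generation", generation_length: float = 3.1
                     ) -> InbreedingTrend:
    """ΔF series over birth-year cohorts.

    ``by='generation'`` groups years into cohorts of ``generation_length``
    years (cohort = floor((year - min_year)/L)); ``by='year'`` uses one
    cohort per birth year. The regression tests whether ΔF changes across
    cohorts (slope of ΔF on cohort index).
    """
    if F is None:
        F = inbreeding(ped)
    years = ped.birth_year
    ok = np.isfinite(years)
    if by == "generation":
        cohort = np.floor((years[ok] - years[ok].min()) / generation_length)
    elif by == "year":
        cohort = years[ok]
    else:
        raise ValueError(f"unknown cohorting {by!r}")
    tab = (pd.DataFrame({"cohort": cohort, "F": F[ok]})
           .groupby("cohort")["F"].agg(["size", "mean"]).reset_index()
           .rename(columns={"size": "n", "mean": "mean_F"}))
    if len(tab) < 2:
        raise PedigreeError("need at least two cohorts for an inbreeding trend")
    prev = tab["mean_F"].shift(1)
    tab["delta_F"] = (tab["mean_F"] - prev) / (1.0 - prev)
    dfv = tab["delta_F"].dropna()
    if len(dfv) >= 3 and np.ptp(dfv.to_numpy()) > 0:
        res = sstats.linregress(np.arange(len(dfv)), dfv.to_numpy())
        slope, pval = float(res.slope), float(res.pvalue)
    else:
        slope, pval = 0.0, 1.0
    return InbreedingTrend(tab, slope, pval)
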