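"""Flock differentiation from pedigree coancestries.

Nei's minimum distance D_ij = (f_ii + f_jj)/2 - f_ij and Wright's
F_ST = (f̄ - f̃)/(1 - f̃), where within-flock mean coancestries include
the self-kinship f(i,i) = (1 + F_i)/2 (mean-coancestry convention).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .pedigree import Pedigree
from .relatedness import coancestry_matrix


def _mean_coancestry(f: np.ndarray, a: np.ndarray, b: np.ndarray,
                     include_self: bool = True) -> float:
    block = f[np.ix_(a, b)]
    if a is b and not include_self:
        n = len(a)
        return float((block.sum() - np.trace(block)) / (n * (n - 1)))
    return float(block.mean())


def nei_minimum_distance(f: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray,
                         include_self: bool = True) -> float:
    """Nei's minimum distance between two groups from a kinship matrix."""
    fii = _mean_coancestry(f, idx_a, idx_a, include_self)
    fjj = _mean_coancestry(f, idx_b, idx_b, include_self)
    fij = _mean_coancestry(f, idx_a, idx_b)
    return (fii + fjj) / 2.0 - fij


def pedigree_fst(f: np.ndarray, groups: dict[str, np.ndarray], *,
                 include_self: bool = True, weight_by_pairs: bool = True
                 ) -> dict:
    """Coancestry-based F_ST = (f̄ - f̃)/(1 - f̃) over a flock partition.

    f̄ is the mean within-flock coancestry (flock means weighted by their
    number of pairs by default, or equally), f̃ the mean coancestry over
    all animals in the partition.
    """
    if len(groups) < 2:
        raise ValueError("F_ST needs at least two flocks")
    all_idx = np.concatenate(list(groups.values()))
    f_tilde = _mean_coancestry(f, all_idx, all_idx, include_self)
    within = {}
    weights = {}
    for name, idx in groups.items():
        within[name] = _mean_coancestry(f, idx, idx, include_self)
        n = len(idx)
        weights[name] = n * n if include_self else n * (n - 1)
    if weight_by_pairs:
        w = np.array([weights[k] for k in groups], dtype=float)
    else:
        w = np.ones(len(groups))
    f_bar = float(np.average([within[k] for k in groups], weights=w))
    return {"fst": (f_bar - f_tilde) / (1.0 - f_tilde),
            "f_bar": f_bar, "f_tilde": f_tilde,
            "within_flock": within}


def flock_differentiation(ped: Pedigree, *, flocks: dict[str, list] | None = None,
                          include_self: bool = True,
                          weight_by_pairs: bool = True) -> dict:
    """Nei's D matrix and pedigree F_ST across flocks of a pedigree.

    ``flocks`` maps flock name to animal ids; by default the pedigree's
    own flock labels are used (animals without a flock are skipped).
    """
    if flocks is None:
        lab = ped.flock
        flocks = {}
        for name in pd.unique(lab):
            if name is None or (isinstance(name, float) and np.isnan(name)):
                continue
            flocks[name] = list(ped.animals[lab == name])
    ids = [a for members in flocks.values() for a in members]
    f = coancestry_matrix(ped, ids)
    offsets = {}
    k = 0
    for name, members in flocks.items():
        offsets[name] = np.arange(k, k + len(members))
        k += len(members)
    names = list(flocks)
    D = pd.DataFrame(0.0, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            d = nei_minimum_distance(f, offsets[a], offsets[b], include_self)
            D.loc[a, b] = D.loc[b, a] = d
    fst = pedigree_fst(f, offsets, include_self=include_self,
                       weight_by_pairs=weight_by_pairs)
    return {"nei_D": D, **fst}
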