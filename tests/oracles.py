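"""Independent brute-force oracles used only by the test suite.

Each oracle recomputes a quantity by a different route than the library
(path counting instead of the indirect algorithm, exhaustive window
enumeration instead of cumulative sums, downward instead of upward gene
flow), on inputs small enough for exhaustive computation.
"""

from __future__ import annotations

import numpy as np

from flockdiv.pedigree import Pedigree


# ---------------------------------------------------------------------------
# Wright path-counting inbreeding


def _paths_to_ancestors(ped: Pedigree, i: int, path=()):
    """Yield (ancestor, path_tuple) for every distinct ancestor path from i."""
    for p in (ped.sire_idx[i], ped.dam_idx[i]):
        if p >= 0:
            newpath = path + (int(p),)
            yield int(p), newpath
            yield from _paths_to_ancestors(ped, int(p), newpath)


def wright_f(ped: Pedigree, i: int, _cache=None) -> float:
    """F by Wright's path counting: sum over common-ancestor loops of
    (1/2)^(n1+n2+1) (1+F_A), over pairs of parent-side paths sharing no
    intermediate animal."""
    if _cache is None:
        _cache = {}
    if i in _cache:
        return _cache[i]
    s, d = ped.sire_idx[i], ped.dam_idx[i]
    if s < 0 or d < 0:
        _cache[i] = 0.0
        return 0.0
    sire_paths = [(int(s), ())] + list(_paths_to_ancestors(ped, int(s)))
    dam_paths = [(int(d), ())] + list(_paths_to_ancestors(ped, int(d)))
    total = 0.0
    for anc_a, pa in sire_paths:
        for anc_b, pb in dam_paths:
            if anc_a != anc_b:
                continue
            # loop validity: the two paths share only the common ancestor
            ia = set(pa[:-1]) | {int(s)} if pa else {int(s)}
            ib = set(pb[:-1]) | {int(d)} if pb else {int(d)}
            ia.discard(anc_a)
            ib.discard(anc_b)
            if ia & ib:
                continue
            n1 = len(pa) if pa else 0
            n2 = len(pb) if pb else 0
            total += 0.5 ** (n1 + n2 + 1) * (1.0 + wright_f(ped, anc_a, _cache))
    _cache[i] = total
    return total


# ---------------------------------------------------------------------------
# equivalent generations by exhaustive path enumeration


def equivalent_generations_direct(ped: Pedigree, i: int) -> float:
    """Σ (1/2)^n over all ancestor paths, enumerated explicitly."""
    total = 0.0
    stack = [(int(i), 0)]
    while stack:
        a, depth = stack.pop()
        for p in (ped.sire_idx[a], ped.dam_idx[a]):
            if p >= 0:
                total += 0.5 ** (depth + 1)
                stack.append((int(p), depth + 1))
    return total


# ---------------------------------------------------------------------------
# downward gene-flow contribution (gene-origin oracle)


def _origin_paths(ped: Pedigree, i: int):
    """Enumerate (probability, path) for a random gene of animal ``i``.

    A path is the tuple of animals the gene passes through, starting at
    ``i``; it terminates where the gene originates — at a founder or at a
    missing-parent slot (the phantom-founder origin stays on the last
    listed animal).
    """
    s, d = int(ped.sire_idx[i]), int(ped.dam_idx[i])
    for p in (s, d):
        if p < 0:
            yield 0.5, (i,)
        else:
            for prob, sub in _origin_paths(ped, p):
                yield 0.5 * prob, (i,) + sub


def contribution_by_path_enumeration(ped: Pedigree, candidate: int,
                                     reference, severed: set[int]) -> float:
    """Expected reference gene-pool share explained by ``candidate``.

    A gene is credited to the candidate when its origin path contains the
    candidate as a proper ancestor, or terminates at the candidate's own
    missing-parent slot — and contains no severed animal other than the
    candidate itself. Founders' own genes count as self-origin.
    """
    ref = ped.positions(reference)
    total = 0.0
    for r in ref:
        r = int(r)
        if ped.sire_idx[r] < 0 and ped.dam_idx[r] < 0:
            paths = [(1.0, (r,))]
        else:
            paths = list(_origin_paths(ped, r))
        for prob, path in paths:
            if candidate not in path:
                continue
            proper_ancestor = path.index(candidate) > 0
            self_origin = path[-1] == candidate
            if not (proper_ancestor or self_origin):
                continue
            if any(a in severed and a != candidate for a in path):
                continue
            total += prob
    return total / len(ref)


def greedy_ancestors_oracle(ped: Pedigree, reference, n_rounds: int):
    """Greedy marginal-contribution selection via exhaustive path enumeration."""
    chosen: list[int] = []
    marginals: list[float] = []
    for _ in range(n_rounds):
        best, best_c = -1, 0.0
        for j in range(len(ped)):
            if j in chosen:
                continue
            c = contribution_by_path_enumeration(ped, j, ped.animals[
                ped.positions(reference)], set(chosen))
            if c > best_c + 1e-9:
                best, best_c = j, c
        if best < 0:
            break
        chosen.append(best)
        marginals.append(best_c)
    return chosen, marginals


# ---------------------------------------------------------------------------
# brute-force ROH window scan


def roh_eligible_bruteforce(het: np.ndarray, mis: np.ndarray, window: int,
                            max_het: int, max_mis: int, threshold: float
                            ) -> np.ndarray:
    """Per-SNP eligibility by explicit enumeration of every sliding window."""
    m = len(het)
    W = min(window, m)
    starts = range(0, m - W + 1)
    hom = [het[a:a + W].sum() <= max_het and mis[a:a + W].sum() <= max_mis
           for a in starts]
    eligible = np.zeros(m, dtype=bool)
    for j in range(m):
        overlapping = [hom[a] for a in starts if a <= j <= a + W - 1]
        eligible[j] = sum(overlapping) / len(overlapping) >= threshold
    return eligible


def roh_segments_bruteforce(calls: np.ndarray, pos: np.ndarray, params
                            ) -> list[tuple[int, int]]:
    """Segments for one animal/chromosome by the explicit scan."""
    het = calls == 1
    mis = calls < 0
    eligible = roh_eligible_bruteforce(het, mis, params.window_snps,
                                       params.max_het_in_window,
                                       params.max_missing_in_window,
                                       params.window_threshold)
    segs = []
    i = 0
    m = len(calls)
    while i < m:
        if not eligible[i]:
            i += 1
            continue
        j = i
        while (j + 1 < m and eligible[j + 1]
               and pos[j + 1] - pos[j] <= params.max_gap_bp):
            j += 1
        if j - i + 1 >= params.min_snps and pos[j] - pos[i] + 1 >= params.min_length_bp:
            segs.append((int(pos[i]), int(pos[j])))
        i = j + 1
    return segs
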