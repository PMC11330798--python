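"""Probability of gene origin: effective founders, effective ancestors, GCI.

All contributions are *expected* genome fractions obtained by exact
upward recursion (each animal's genome splits half to each known parent;
the fraction flowing into a missing-parent slot is attributed to the
animal itself as a phantom founder), not by Monte-Carlo gene dropping.
Effective ancestors follow the greedy marginal-contribution scheme of
Boichard: after an ancestor is picked, its parent links are severed so
later rounds only credit gene flow not already explained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pedigree import Pedigree


def _upward_contributions(ped: Pedigree, reference, blocked: set[int] = frozenset()
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Propagate reference genome weights up the pedigree.

    Returns ``(through, self_founder_s, self_founder_d)`` where
    ``through[j]`` is the expected fraction of the reference gene pool
    that passes through animal j (its total contribution), and the
    self-founder arrays hold the fractions attributed to j itself because
    its sire/dam is unknown. Animals in ``blocked`` absorb weight without
    passing it to their parents.
    """
    n = len(ped)
    s, d = ped.sire_idx, ped.dam_idx
    w = np.zeros(n)
    ref_pos = ped.positions(reference)
    w[ref_pos] += 1.0 / len(ref_pos)
    self_s = np.zeros(n)
    self_d = np.zeros(n)
    through = np.zeros(n)
    for i in range(n - 1, -1, -1):
        if w[i] == 0.0:
            continue
        through[i] = w[i]
        if i in blocked:
            continue
        half = 0.5 * w[i]
        if s[i] >= 0:
            w[s[i]] += half
        else:
            self_s[i] = half
        if d[i] >= 0:
            w[d[i]] += half
        else:
            self_d[i] = half
    return through, self_s, self_d


def _effective_number(p: np.ndarray) -> float:
    return 1.0 / float(np.sum(np.square(p)))


@dataclass
class GeneOriginResult:
    founders: pd.DataFrame        # founder, q
    fe: float
    ancestors: pd.DataFrame       # rank, animal, marginal, accumulated, ...
    fa: float
    n50: int
    gci_table: pd.DataFrame | None = None

    @property
    def fe_over_fa(self) -> float:
        return self.fe / self.fa

    def summary(self) -> dict:
        out = {"fe": self.fe, "fa": self.fa, "fe_over_fa": self.fe_over_fa,
               "n50": self.n50}
        if self.gci_table is not None:
            out["mean_gci"] = float(self.gci_table["gci"].mean())
        return out


def founder_contributions(ped: Pedigree, reference, *, pooled: bool = True
                          ) -> tuple[pd.DataFrame, float]:
    """Founder gene-pool shares q_k of a reference population and f_e = 1/Σq².

    ``pooled`` attributes the unexplained fraction of an animal with one
    or both parents unknown to a single phantom founder per animal;
    ``pooled=False`` keeps each unknown-parent slot as a distinct phantom.
    """
    through, self_s, self_d = _upward_contributions(ped, reference)
    founder = ped.is_founder
    rows: list[tuple[str, float]] = []
    for i in np.nonzero(self_s + self_d + founder * through)[0]:
        name = ped.animals[i]
        if founder[i]:
            rows.append((name, float(through[i])))
        elif pooled:
            rows.append((name, float(self_s[i] + self_d[i])))
        else:
            if self_s[i] > 0:
                rows.append((f"{name}:sire_slot", float(self_s[i])))
            if self_d[i] > 0:
                rows.append((f"{name}:dam_slot", float(self_d[i])))
    tab = pd.DataFrame(rows, columns=["founder", "q"]).sort_values(
        "q", ascending=False, ignore_index=True)
    q = tab["q"].to_numpy()
    assert abs(q.sum() - 1.0) < 1e-9, "founder contributions must sum to 1"
    return tab, _effective_number(q)


def _marginal_contributions(ped: Pedigree, reference, blocked: set[int]
                            ) -> np.ndarray:
    """Per-candidate marginal contribution conditional on ``blocked`` ancestors.

    A candidate is credited with the reference genes that pass through it
    as a proper ancestor (upward weight from descendants, stopped at
    blocked animals) plus, for its own reference membership, only the
    phantom-founder fraction from unknown-parent slots — genes inherited
    from known parents belong to those ancestors. Descent weight is
    discounted by the fraction of the candidate's genome not already
    traced through a blocked ancestor above it.
    """
    n = len(ped)
    s, d = ped.sire_idx, ped.dam_idx
    own = np.zeros(n)
    ref_pos = ped.positions(reference)
    own[ref_pos] += 1.0 / len(ref_pos)
    w = own.copy()
    for i in range(n - 1, -1, -1):
        if w[i] == 0.0 or i in blocked:
            continue
        if s[i] >= 0:
            w[s[i]] += 0.5 * w[i]
        if d[i] >= 0:
            w[d[i]] += 0.5 * w[i]
    # unexplained[i]: fraction of i's genome not routed through a blocked
    # proper ancestor (phantom slots count as unexplained origins)
    unexplained = np.ones(n)
    for i in range(n):
        if s[i] < 0 and d[i] < 0:
            continue
        acc = 0.0
        for p in (s[i], d[i]):
            if p < 0:
                acc += 0.5
            elif p not in blocked:
                acc += 0.5 * unexplained[p]
        unexplained[i] = acc
    miss_frac = 0.5 * ((s < 0).astype(float) + (d < 0).astype(float))
    marg = (w - own) * unexplained + own * miss_frac
    if blocked:
        marg[list(blocked)] = 0.0
    return marg


def effective_ancestors(ped: Pedigree, reference, *, min_contribution: float = 1e-6,
                        max_ancestors: int | None = None
                        ) -> tuple[pd.DataFrame, float, int]:
    """Greedy marginal-contribution ancestor decomposition.

    Each round recomputes every candidate's marginal contribution to the
    reference gene pool conditional on the already-selected ancestors
    (whose parent links are severed so gene flow through them is no
    longer credited), then selects the largest (ties: larger
    unconditional contribution, earlier birth year, lexicographic id).
    Returns the ancestor table, f_a = 1/Σp², and n50 (ancestors
    explaining half the gene pool; 0 when the accumulated curve never
    reaches 0.5).
    """
    raw = _marginal_contributions(ped, reference, set())
    years = ped.birth_year
    selected: list[int] = []
    marginals: list[float] = []
    limit = max_ancestors if max_ancestors is not None else len(ped)
    blocked: set[int] = set()
    while len(selected) < limit:
        marg = _marginal_contributions(ped, reference, blocked)
        best, best_key = -1, None
        for j in np.nonzero(marg > min_contribution)[0]:
            y = years[j] if np.isfinite(years[j]) else np.inf
            key = (-marg[j], -raw[j], y, str(ped.animals[j]))
            if best_key is None or key < best_key:
                best, best_key = int(j), key
        if best < 0:
            break
        selected.append(best)
        marginals.append(float(marg[best]))
        blocked.add(best)
    p = np.asarray(marginals)
    acc = np.cumsum(p)
    child_count = np.zeros(len(ped), dtype=int)
    for par in (ped.sire_idx, ped.dam_idx):
        idx, cnt = np.unique(par[par >= 0], return_counts=True)
        child_count[idx] += cnt
    n_prog = child_count[selected]
    tab = pd.DataFrame({
        "rank": np.arange(1, len(selected) + 1),
        "animal": ped.animals[selected],
        "marginal": p,
        "accumulated": acc,
        "n_progeny": n_prog,
        "flock": ped.flock[selected],
        "birth_year": [years[i] if np.isfinite(years[i]) else None for i in selected],
    })
    fa = _effective_number(p) if len(p) else float("nan")
    reach = np.nonzero(acc >= 0.5)[0]
    n50 = int(reach[0]) + 1 if len(reach) else 0
    return tab, fa, n50


def accumulated_contributions(marginals) -> np.ndarray:
    """Accumulated gene-pool share explained by the top-k ancestors."""
    return np.cumsum(np.asarray(marginals, dtype=float))


def gci(ped: Pedigree, ids=None, *, pooled: bool = True) -> pd.DataFrame:
    """Genetic conservation index: per-animal 1/Σ p_ik² over founder shares.

    A balanced founder representation gives a high GCI; a founder itself
    scores 1. Phantom-founder handling matches :func:`founder_contributions`.
    """
    if ids is None:
        ids = ped.animals
    rows = []
    for a in ids:
        through, self_s, self_d = _upward_contributions(ped, [a])
        founder = ped.is_founder
        shares = []
        for i in np.nonzero(through)[0]:
            if founder[i]:
                shares.append(through[i])
            elif pooled:
                if self_s[i] + self_d[i] > 0:
                    shares.append(self_s[i] + self_d[i])
            else:
                shares.extend([v for v in (self_s[i], self_d[i]) if v > 0])
        rows.append((a, _effective_number(np.asarray(shares))))
    return pd.DataFrame(rows, columns=["animal", "gci"])


def gene_origin(ped: Pedigree, reference, *, pooled: bool = True,
                with_gci: bool = False, max_ancestors: int | None = None
                ) -> GeneOriginResult:
    founders, fe = founder_contributions(ped, reference, pooled=pooled)
    ancestors, fa, n50 = effective_ancestors(ped, reference,
                                             max_ancestors=max_ancestors)
    gci_tab = gci(ped, reference, pooled=pooled) if with_gci else None
    return GeneOriginResult(founders, fe, ancestors, fa, n50, gci_tab)
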