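"""Sliding-window runs of homozygosity, F_ROH, and inbreeding-measure
correlations.

Detection follows the detectRUNS-style sliding-window scheme: a 50-SNP
window slides one SNP at a time along each chromosome; a window with at
most one heterozygous and at most one missing call is *homozygous*; a
SNP is eligible when the proportion of windows overlapping it that are
homozygous reaches the window threshold (denominator = windows actually
overlapping the SNP, so chromosome ends are handled by truncation).
Maximal runs of consecutive eligible SNPs are then filtered by SNP
count, physical length and maximum inter-SNP gap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

# size-class boundaries in Mb: [1,6], (6,12], (12,24], (24,48], (48, inf)
CLASS_EDGES_MB = (1.0, 6.0, 12.0, 24.0, 48.0)
CLASS_LABELS = ("1-6Mb", ">6-12Mb", ">12-24Mb", ">24-48Mb", ">48Mb")


@dataclass
class RohParams:
    window_snps: int = 50
    max_het_in_window: int = 1
    max_missing_in_window: int = 1
    window_threshold: float = 0.05
    min_snps: int = 30
    min_length_bp: int = 1_000_000
    max_gap_bp: int = 250_000


def size_class(length_bp: int) -> str:
    mb = length_bp / 1e6
    for hi, lab in zip(CLASS_EDGES_MB[1:], CLASS_LABELS[:-1]):
        if mb <= hi:
            return lab
    return CLASS_LABELS[-1]


def _eligible_snps(het: np.ndarray, mis: np.ndarray, p: RohParams) -> np.ndarray:
    """Boolean eligibility per SNP from sliding homozygous windows."""
    m = len(het)
    W = min(p.window_snps, m)
    K = m - W + 1  # number of window start positions
    cs_het = np.concatenate([[0], np.cumsum(het)])
    cs_mis = np.concatenate([[0], np.cumsum(mis)])
    hom_win = ((cs_het[W:] - cs_het[:-W]) <= p.max_het_in_window) & \
              ((cs_mis[W:] - cs_mis[:-W]) <= p.max_missing_in_window)
    cs_hom = np.concatenate([[0], np.cumsum(hom_win)])
    j = np.arange(m)
    lo = np.maximum(0, j - W + 1)
    hi = np.minimum(j, K - 1)
    n_windows = hi - lo + 1
    n_hom = cs_hom[hi + 1] - cs_hom[lo]
    return n_hom / n_windows >= p.window_threshold


def _runs_from_eligible(eligible: np.ndarray, pos: np.ndarray, p: RohParams
                        ) -> list[tuple[int, int]]:
    """Maximal eligible runs split at large gaps, filtered by minima.

    Returns (start_index, end_index) inclusive SNP-index pairs.
    """
    out: list[tuple[int, int]] = []
    i = 0
    m = len(eligible)
    while i < m:
        if not eligible[i]:
            i += 1
            continue
        j = i
        while j + 1 < m and eligible[j + 1] and pos[j + 1] - pos[j] <= p.max_gap_bp:
            j += 1
        n = j - i + 1
        length = pos[j] - pos[i] + 1
        if n >= p.min_snps and length >= p.min_length_bp:
            out.append((i, j))
        i = j + 1
    return out


def detect_roh(g: GenotypeMatrix, params: RohParams | None = None) -> pd.DataFrame:
    """Detect ROH segments for every animal and chromosome.

    Returns a table ``animal, chrom, start_bp, end_bp, n_snps, length_bp,
    length_mb, size_class`` (1-based inclusive coordinates, length =
    end - start + 1).
    """
    p = params or RohParams()
    chroms = g.snps["chrom"].to_numpy()
    pos_all = g.snps["pos"].to_numpy()
    rows = []
    for c in pd.unique(chroms):
        idx = np.nonzero(chroms == c)[0]
        pos = pos_all[idx]
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"SNP positions unsorted on chromosome {c}")
        sub = g.calls[:, idx]
        for a in range(g.n_animals):
            calls = sub[a]
            het = calls == 1
            mis = calls < 0
            if len(idx) == 0:
                continue
            eligible = _eligible_snps(het, mis, p)
            for i, j in _runs_from_eligible(eligible, pos, p):
                length = int(pos[j] - pos[i] + 1)
                rows.append({"animal": g.animals["animal"].iloc[a],
                             "chrom": c, "start_bp": int(pos[i]),
                             "end_bp": int(pos[j]), "n_snps": j - i + 1,
                             "length_bp": length, "length_mb": length / 1e6,
                             "size_class": size_class(length)})
    return pd.DataFrame(rows, columns=["animal", "chrom", "start_bp", "end_bp",
                                       "n_snps", "length_bp", "length_mb",
                                       "size_class"])


def genome_length_bp(g: GenotypeMatrix) -> int:
    """Genome span covered by SNPs: sum over chromosomes of max - min position."""
    spans = g.snps.groupby("chrom")["pos"].agg(["min", "max"])
    return int((spans["max"] - spans["min"]).sum())


@dataclass
class RohSummary:
    per_animal: pd.DataFrame     # animal, n_roh, total_length_bp, f_roh, per-class
    genome_length_bp: int

    def population_means(self) -> dict:
        out = {"mean_f_roh": float(self.per_animal["f_roh"].mean()),
               "mean_n_roh": float(self.per_animal["n_roh"].mean())}
        for lab in CLASS_LABELS:
            out[f"mean_f_roh_{lab}"] = float(self.per_animal[f"f_roh_{lab}"].mean())
        return out


def f_roh(segments: pd.DataFrame, g: GenotypeMatrix) -> RohSummary:
    """Per-animal F_ROH (ROH length / SNP-covered genome) with per-class split.

    Per-class values sum exactly to the total by construction.
    """
    glen = genome_length_bp(g)
    if glen <= 0:
        raise ValueError("zero genome length: no SNP span to normalise by")
    animals = g.animals["animal"]
    base = pd.DataFrame({"animal": animals})
    if len(segments):
        tot = segments.groupby("animal")["length_bp"].agg(["size", "sum"])
        per_class = segments.pivot_table(index="animal", columns="size_class",
                                         values="length_bp", aggfunc="sum",
                                         fill_value=0)
    else:
        tot = pd.DataFrame(columns=["size", "sum"])
        per_class = pd.DataFrame()
    base["n_roh"] = base["animal"].map(tot["size"]).fillna(0).astype(int) \
        if len(tot) else 0
    base["total_length_bp"] = base["animal"].map(tot["sum"]).fillna(0).astype(np.int64) \
        if len(tot) else 0
    base["f_roh"] = base["total_length_bp"] / glen
    for lab in CLASS_LABELS:
        col = per_class[lab] if lab in per_class.columns else pd.Series(dtype=float)
        base[f"f_roh_{lab}"] = base["animal"].map(col).fillna(0.0) / glen
    return RohSummary(base, glen)


def inbreeding_correlations(f_ped: np.ndarray, f_wright: np.ndarray,
                            f_roh_vec: np.ndarray) -> pd.DataFrame:
    """Pearson correlations among pedigree F, individual Wright's F, F_ROH."""
    m = np.column_stack([f_ped, f_wright, f_roh_vec]).astype(float)
    ok = np.all(np.isfinite(m), axis=1)
    if ok.sum() < 3:
        raise ValueError("need >= 3 animals with all three inbreeding measures")
    m = m[ok]
    names = ["F_pedigree", "F_wright", "F_roh"]
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(m.T)
    corr = (corr + corr.T) / 2.0
    sd = m.std(axis=0)
    degenerate = sd <= 1e-12 + 1e-9 * np.abs(m).max(axis=0)
    np.fill_diagonal(corr, 1.0)
    corr[degenerate, :] = np.nan
    corr[:, degenerate] = np.nan
    return pd.DataFrame(corr, index=names, columns=names)
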