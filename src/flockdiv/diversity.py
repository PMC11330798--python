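"""Genotype QC, marker thinning, MAF spectrum, heterozygosity, LD decay.

The pipeline distinguishes three nested marker sets, mirroring common
SNP-array practice: the *full* set (post-QC mapped autosomal SNPs, after
one-SNP-per-window thinning) feeds ROH detection and the MAF spectrum;
the *reduced* set additionally drops rare SNPs (MAF < 0.01) and feeds
heterozygosity, LD decay, FST and PCA; the *thinned* set is a random 50%
of the reduced set and feeds the LD-based Ne.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix


@dataclass
class QcReport:
    animals_removed_unknown_parentage: int = 0
    animals_removed_call_rate: int = 0
    snps_removed_unmapped_or_call_rate: int = 0
    snps_after_thinning: int | None = None
    snps_after_maf: int | None = None
    counts: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "counts"}
        d.update(self.counts)
        return d


def apply_qc(g: GenotypeMatrix, *, animal_call_rate: float = 0.90,
             snp_call_rate: float = 0.90,
             unknown_parentage: np.ndarray | None = None,
             unmapped_chroms: tuple[str, ...] = ("0", "", "X", "Y", "MT")
             ) -> tuple[GenotypeMatrix, QcReport]:
    """Drop low-call-rate animals, then unmapped/low-call-rate SNPs.

    SNP call rates are recomputed after the animal drop. ``unknown_parentage``
    is a boolean mask of animals excluded a priori (no pedigree link).
    """
    rep = QcReport()
    out = g
    if unknown_parentage is not None:
        keep = ~np.asarray(unknown_parentage, dtype=bool)
        rep.animals_removed_unknown_parentage = int((~keep).sum())
        out = out.subset(animal_mask=keep)
    # iterate to a fixed point so QC on its own output is a no-op (SNP
    # removal can push an animal's call rate below threshold and vice versa)
    while True:
        low_a = out.call_rate_animals() < animal_call_rate
        rep.animals_removed_call_rate += int(low_a.sum())
        out = out.subset(animal_mask=~low_a)
        if out.n_animals == 0:
            raise ValueError("quality control removed every animal")
        chrom = out.snps["chrom"].astype(str).to_numpy()
        mapped = ~np.isin(chrom, unmapped_chroms)
        keep_s = mapped & (out.call_rate_snps() > snp_call_rate)
        rep.snps_removed_unmapped_or_call_rate += int((~keep_s).sum())
        out = out.subset(snp_mask=keep_s)
        if out.n_snps == 0:
            raise ValueError("quality control removed every SNP")
        if not low_a.any() and keep_s.all():
            break
    rep.counts = {"animals_after_qc": out.n_animals, "snps_after_qc": out.n_snps}
    return out, rep


def thin_by_window(g: GenotypeMatrix, window_bp: int = 30_000,
                   seed: int | None = None) -> GenotypeMatrix:
    """Keep one SNP, chosen uniformly at random, per non-overlapping
    ``window_bp`` window on each chromosome (seeded, deterministic)."""
    rng = np.random.default_rng(seed)
    keep = np.zeros(g.n_snps, dtype=bool)
    chroms = g.snps["chrom"].to_numpy()
    pos = g.snps["pos"].to_numpy()
    for c in pd.unique(chroms):
        idx = np.nonzero(chroms == c)[0]
        win = pos[idx] // window_bp
        for w in np.unique(win):
            members = idx[win == w]
            keep[rng.choice(members)] = True
    return g.subset(snp_mask=keep)


def thin_random(g: GenotypeMatrix, fraction: float = 0.5,
                seed: int | None = None) -> GenotypeMatrix:
    """Random marker thinning (each SNP kept independently with prob ``fraction``)."""
    rng = np.random.default_rng(seed)
    return g.subset(snp_mask=rng.random(g.n_snps) < fraction)


def maf_filter(g: GenotypeMatrix, min_maf: float = 0.01) -> GenotypeMatrix:
    """Drop SNPs with MAF strictly below ``min_maf`` (MAF == cutoff kept)."""
    return g.subset(snp_mask=g.maf() >= min_maf)


def maf_spectrum(g: GenotypeMatrix, bin_width: float = 0.05) -> dict:
    """MAF counts per bin [0,0.05), ..., [0.45,0.50]; fixed SNPs tallied apart."""
    maf = g.maf()
    maf = maf[np.isfinite(maf)]
    edges = np.arange(0.0, 0.5 + bin_width / 2, bin_width)
    counts, _ = np.histogram(maf, bins=edges)  # last bin closed at 0.50
    labels = [f"[{lo:.2f},{hi:.2f})" for lo, hi in zip(edges[:-1], edges[1:])]
    labels[-1] = labels[-1][:-1] + "]"
    return {
        "bins": pd.DataFrame({"bin": labels, "count": counts}),
        "n_fixed": int((maf == 0.0).sum()),
        "fraction_maf_gt_0.30": float((maf > 0.30).mean()),
    }


def heterozygosity(g: GenotypeMatrix) -> dict:
    """Expected/observed heterozygosity and the heterozygosity-deficit F.

    Per SNP, H_E = 2p(1-p) from the allele frequency and H_O = fraction
    of heterozygous calls; population values are means over SNPs.
    F = (H_E - H_O)/H_E is emitted both from the population means and as
    the mean of per-SNP F (the two differ by averaging order).
    """
    p = g.allele_freq()
    he = 2.0 * p * (1.0 - p)
    obs = g.calls >= 0
    het = g.calls == 1
    with np.errstate(invalid="ignore"):
        ho = np.where(obs.sum(axis=0) > 0, het.sum(axis=0) / obs.sum(axis=0), np.nan)
    ok = np.isfinite(he) & np.isfinite(ho)
    if not np.any(he[ok] > 0):
        raise ValueError("all SNPs monomorphic: H_E is zero everywhere")
    he_m, ho_m = float(he[ok].mean()), float(ho[ok].mean())
    poly = ok & (he > 0)
    per_snp_f = (he[poly] - ho[poly]) / he[poly]
    return {"he": he_m, "ho": ho_m,
            "wright_f": (he_m - ho_m) / he_m,
            "wright_f_mean_per_snp": float(per_snp_f.mean()),
            "per_snp_he": he, "per_snp_ho": ho}


def individual_wright_f(g: GenotypeMatrix) -> np.ndarray:
    """Per-animal F = 1 - H_O,i / H̄_E (individual observed heterozygosity
    against the population mean expected heterozygosity)."""
    p = g.allele_freq()
    he_mean = float(np.nanmean(2.0 * p * (1.0 - p)))
    obs = g.calls >= 0
    ho_i = np.where(obs.sum(axis=1) > 0,
                    (g.calls == 1).sum(axis=1) / obs.sum(axis=1), np.nan)
    return 1.0 - ho_i / he_mean


def _pairwise_r2(X: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation of additive codes, pairwise-complete."""
    X = X.astype(float)
    X[X < 0] = np.nan
    M = ~np.isnan(X)
    mean = np.nanmean(X, axis=0)
    Xc = np.where(M, X - mean, 0.0)
    num = Xc.T @ Xc
    cnt = M.astype(float).T @ M.astype(float)
    ss = (Xc * Xc).T @ M.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / np.sqrt(ss * ss.T)
    return r * r


def ld_decay(g: GenotypeMatrix, *, max_dist_bp: int = 1_000_000,
             bin_edges: np.ndarray | None = None) -> dict:
    """Within-chromosome LD decay: mean r² per physical-distance bin.

    Also reports adjacent-SNP mean distance and mean r². Composite
    (genotypic) r² on unphased additive codes; missing calls excluded
    pairwise.
    """
    if bin_edges is None:
        bin_edges = np.linspace(0, max_dist_bp, 11)
    chroms = g.snps["chrom"].to_numpy()
    pos = g.snps["pos"].to_numpy()
    dists: list[np.ndarray] = []
    r2s: list[np.ndarray] = []
    adj_d: list[np.ndarray] = []
    adj_r2: list[np.ndarray] = []
    for c in pd.unique(chroms):
        idx = np.nonzero(chroms == c)[0]
        if len(idx) < 2:
            continue
        r2 = _pairwise_r2(g.calls[:, idx].copy())
        dp = np.abs(pos[idx][:, None] - pos[idx][None, :])
        iu = np.triu_indices(len(idx), k=1)
        d, r = dp[iu], r2[iu]
        okp = np.isfinite(r) & (d <= max_dist_bp)
        dists.append(d[okp])
        r2s.append(r[okp])
        ad = np.diff(pos[idx]).astype(float)
        ar = r2[np.arange(len(idx) - 1), np.arange(1, len(idx))]
        oka = np.isfinite(ar)
        adj_d.append(ad[oka])
        adj_r2.append(ar[oka])
    d = np.concatenate(dists) if dists else np.array([])
    r = np.concatenate(r2s) if r2s else np.array([])
    which = np.digitize(d, bin_edges[1:-1])
    rows = []
    for b in range(len(bin_edges) - 1):
        sel = which == b
        rows.append({"bin_mid_bp": 0.5 * (bin_edges[b] + bin_edges[b + 1]),
                     "n_pairs": int(sel.sum()),
                     "mean_r2": float(r[sel].mean()) if sel.any() else np.nan})
    ad = np.concatenate(adj_d) if adj_d else np.array([])
    ar = np.concatenate(adj_r2) if adj_r2 else np.array([])
    return {"decay": pd.DataFrame(rows),
            "adjacent_mean_dist_bp": float(ad.mean()) if len(ad) else np.nan,
            "adjacent_mean_r2": float(ar.mean()) if len(ar) else np.nan}


@dataclass
class DatasetStages:
    """The full/reduced/thinned marker-set lineage."""

    full: GenotypeMatrix
    reduced: GenotypeMatrix
    thinned: GenotypeMatrix
    report: QcReport


def build_stages(g: GenotypeMatrix, *, animal_call_rate: float = 0.90,
                 snp_call_rate: float = 0.90, window_bp: int = 30_000,
                 min_maf: float = 0.01, thin_fraction: float = 0.5,
                 unknown_parentage: np.ndarray | None = None,
                 seed: int | None = None) -> DatasetStages:
    qc, rep = apply_qc(g, animal_call_rate=animal_call_rate,
                       snp_call_rate=snp_call_rate,
                       unknown_parentage=unknown_parentage)
    rng = np.random.default_rng(seed)
    full = thin_by_window(qc, window_bp, seed=int(rng.integers(2**31 - 1)))
    rep.snps_after_thinning = full.n_snps
    reduced = maf_filter(full, min_maf)
    rep.snps_after_maf = reduced.n_snps
    thinned = thin_random(reduced, thin_fraction, seed=int(rng.integers(2**31 - 1)))
    rep.counts["snps_thinned_for_ne"] = thinned.n_snps
    return DatasetStages(full, reduced, thinned, rep)
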