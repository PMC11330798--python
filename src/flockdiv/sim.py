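"""Synthetic-data generators with known ground truth.

Three simulators make every pipeline stage testable at desk scale:

* :func:`simulate_pedigree` — a multi-flock, overlapping-generation
  sheep-style pedigree (few rams service many ewes; rams migrate between
  flocks at a configurable rate), plus :func:`simulate_random_mating_pedigree`
  for discrete-generation constant-size populations where the true Ne is
  known.
* :func:`gene_drop` — founder haplotypes dropped through a pedigree with
  Haldane (Poisson) recombination; founder-allele tags are tracked so the
  realised identity-by-descent autozygosity of every animal is exact.
* :func:`wright_fisher` — a constant-size random-mating population of
  unlinked SNPs, the oracle for the LD-based Ne estimator and
  heterozygosity-decay checks.

Founder haplotypes are drawn site-independently (linkage equilibrium in
founders): LD among descendants arises purely from co-segregation within
the pedigree, which suffices for decay/monotonicity checks but does not
emulate ancestral LD of a real breed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .pedigree import Pedigree, load_pedigree


@dataclass
class PedSimConfig:
    n_flocks: int = 8
    founders_per_flock: int = 30       # founder ewes + rams per flock
    n_years: int = 12
    ewes_per_flock: int = 25
    sires_per_flock_per_year: int = 3
    ram_migration_rate: float = 0.10   # P(sire drawn from another flock)
    litter_probs: tuple = (0.25, 0.55, 0.20)   # P(1, 2, 3 lambs); prolific breed
    max_parent_age: int = 4
    seed: int = 0


def simulate_pedigree(cfg: PedSimConfig) -> Pedigree:
    """Overlapping-generation multi-flock pedigree.

    Each year every flock keeps a fixed number of breeding ewes (1 to
    ``max_parent_age`` years old, youngest replacements first) and a few
    service sires drawn from males of breeding age — from a random other
    flock with probability ``ram_migration_rate``. Litters follow
    ``litter_probs``; lamb sex is 1:1.
    """
    rng = np.random.default_rng(cfg.seed)
    rows = []  # animal, sire, dam, birth_year, flock, sex
    males: dict[int, list[tuple[str, int]]] = {f: [] for f in range(cfg.n_flocks)}
    females: dict[int, list[tuple[str, int]]] = {f: [] for f in range(cfg.n_flocks)}
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"A{counter:06d}"

    year0 = 2000
    for f in range(cfg.n_flocks):
        for k in range(cfg.founders_per_flock):
            a = new_id()
            sex = "male" if k < max(2, cfg.founders_per_flock // 6) else "female"
            rows.append((a, None, None, year0, f"F{f:02d}", sex))
            (males if sex == "male" else females)[f].append((a, year0))

    for year in range(year0 + 1, year0 + 1 + cfg.n_years):
        newborns: dict[int, list[tuple[str, int, str]]] = {f: [] for f in range(cfg.n_flocks)}
        for f in range(cfg.n_flocks):
            ewes = [(a, y) for a, y in females[f]
                    if 1 <= year - y <= cfg.max_parent_age]
            if len(ewes) > cfg.ewes_per_flock:
                idx = rng.choice(len(ewes), size=cfg.ewes_per_flock, replace=False)
                ewes = [ewes[i] for i in idx]
            sires = []
            for _ in range(cfg.sires_per_flock_per_year):
                src = f
                if cfg.n_flocks > 1 and rng.random() < cfg.ram_migration_rate:
                    src = int(rng.choice([x for x in range(cfg.n_flocks) if x != f]))
                cand = [(a, y) for a, y in males[src]
                        if 1 <= year - y <= cfg.max_parent_age]
                if cand:
                    sires.append(cand[int(rng.integers(len(cand)))][0])
            if not sires:
                raise ValueError(f"no candidate sire for flock {f} in {year}")
            for dam, _ in ewes:
                sire = sires[int(rng.integers(len(sires)))]
                litter = 1 + rng.choice(len(cfg.litter_probs), p=cfg.litter_probs)
                for _ in range(int(litter)):
                    a = new_id()
                    sex = "male" if rng.random() < 0.5 else "female"
                    rows.append((a, sire, dam, year, f"F{f:02d}", sex))
                    newborns[f].append((a, year, sex))
        for f in range(cfg.n_flocks):
            for a, y, sex in newborns[f]:
                (males if sex == "male" else females)[f].append((a, y))
            # cull animals past breeding age to bound the candidate pools
            males[f] = [(a, y) for a, y in males[f] if year - y < cfg.max_parent_age]
            females[f] = [(a, y) for a, y in females[f] if year - y < cfg.max_parent_age]

    df = pd.DataFrame(rows, columns=["animal", "sire", "dam", "birth_year",
                                     "flock", "sex"])
    return load_pedigree(df)


def simulate_random_mating_pedigree(n: int, n_generations: int, seed: int = 0,
                                    flock: str = "F00") -> Pedigree:
    """Discrete-generation constant-size random-mating pedigree (true Ne ≈ n).

    Each generation has n/2 males and n/2 females; every offspring draws
    its sire and dam uniformly from the previous generation.
    """
    rng = np.random.default_rng(seed)
    half = n // 2
    rows = []
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"R{counter:06d}"

    prev_m = [new_id() for _ in range(half)]
    prev_f = [new_id() for _ in range(n - half)]
    for a in prev_m:
        rows.append((a, None, None, 2000, flock, "male"))
    for a in prev_f:
        rows.append((a, None, None, 2000, flock, "female"))
    for g in range(1, n_generations + 1):
        cur_m, cur_f = [], []
        for k in range(n):
            a = new_id()
            sire = prev_m[int(rng.integers(len(prev_m)))]
            dam = prev_f[int(rng.integers(len(prev_f)))]
            sex = "male" if k < half else "female"
            rows.append((a, sire, dam, 2000 + g, flock, sex))
            (cur_m if sex == "male" else cur_f).append(a)
        prev_m, prev_f = cur_m, cur_f
    df = pd.DataFrame(rows, columns=["animal", "sire", "dam", "birth_year",
                                     "flock", "sex"])
    return load_pedigree(df)


def add_planned_mating(ped: Pedigree, sire, dam, *, animal_id: str | None = None,
                       birth_year: int | None = None) -> Pedigree:
    """Append one designed offspring (e.g. a full-sib mating) to a pedigree."""
    df = ped.to_frame()
    aid = animal_id or f"PL{len(df):06d}"
    flock = df.loc[df["animal"] == sire, "flock"].iloc[0]
    year = birth_year
    if year is None:
        ys = df.loc[df["animal"].isin([sire, dam]), "birth_year"].dropna()
        year = int(ys.max()) + 2 if len(ys) else None
    row = pd.DataFrame([{"animal": aid, "sire": sire, "dam": dam,
                         "birth_year": year, "flock": flock, "sex": "female"}])
    return load_pedigree(pd.concat([df, row], ignore_index=True))


# ---------------------------------------------------------------------------
# gene dropping


@dataclass
class GenomeSimConfig:
    n_chromosomes: int = 5
    chromosome_length_bp: int = 100_000_000
    snps_per_chromosome: int = 400
    cm_per_mb: float = 1.0
    founder_maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.0
    seed: int = 0


@dataclass
class GeneDropResult:
    genotypes: GenotypeMatrix
    true_autozygosity: np.ndarray   # per animal, fraction of IBD loci


def gene_drop(ped: Pedigree, cfg: GenomeSimConfig) -> GeneDropResult:
    """Drop founder haplotypes through a pedigree with Haldane recombination.

    Every founder gamete (including the unknown-parent side of animals
    with one missing parent) receives a globally unique haplotype tag per
    chromosome; crossover counts are Poisson in the map length and the
    realised autozygosity of an animal is the fraction of SNPs at which
    its two tags coincide.
    """
    rng = np.random.default_rng(cfg.seed)
    n = len(ped)
    s, d = ped.sire_idx, ped.dam_idx
    chrom_cm = cfg.chromosome_length_bp / 1e6 * cfg.cm_per_mb
    morgans = chrom_cm / 100.0

    pos_list, snp_rows = [], []
    for c in range(cfg.n_chromosomes):
        # sample-with-topup instead of choice(arange(L)): L may be 1e8
        want = cfg.snps_per_chromosome
        pos = np.unique(rng.integers(1, cfg.chromosome_length_bp,
                                     size=2 * want, dtype=np.int64))
        while len(pos) < want:
            extra = rng.integers(1, cfg.chromosome_length_bp, size=2 * want,
                                 dtype=np.int64)
            pos = np.unique(np.concatenate([pos, extra]))
        pos = np.sort(rng.choice(pos, size=want, replace=False))
        pos_list.append(pos)
        for k, p in enumerate(pos):
            snp_rows.append((f"snp{c + 1}_{k + 1}", str(c + 1),
                             p / 1e6 * cfg.cm_per_mb, int(p)))
    snps = pd.DataFrame(snp_rows, columns=["snp", "chrom", "cm", "pos"])

    n_tags = 0

    def fresh_tag() -> int:
        nonlocal n_tags
        n_tags += 1
        return n_tags - 1

    # per chromosome: tags[animal, 2, n_snps]
    m = cfg.snps_per_chromosome
    all_tags = [np.zeros((n, 2, m), dtype=np.int32) for _ in range(cfg.n_chromosomes)]

    def founder_gamete(c: int) -> np.ndarray:
        t = fresh_tag()
        return np.full(m, t, dtype=np.int32)

    def meiosis(c: int, parent: int) -> np.ndarray:
        """One recombinant gamete from ``parent`` on chromosome ``c``."""
        pos = pos_list[c]
        n_x = rng.poisson(morgans)
        cuts = np.sort(rng.uniform(0, cfg.chromosome_length_bp, size=n_x))
        phase = int(rng.integers(2))
        which = (phase + np.searchsorted(cuts, pos)) % 2
        tg = all_tags[c][parent]
        return np.where(which == 0, tg[0], tg[1])

    for i in range(n):
        for c in range(cfg.n_chromosomes):
            gam = []
            for par in (s[i], d[i]):
                gam.append(meiosis(c, par) if par >= 0 else founder_gamete(c))
            all_tags[c][i, 0] = gam[0]
            all_tags[c][i, 1] = gam[1]

    # founder alleles per tag: Bernoulli at a per-SNP frequency
    lo, hi = cfg.founder_maf_range
    calls = np.empty((n, cfg.n_chromosomes * m), dtype=np.int8)
    auto_num = np.zeros(n)
    for c in range(cfg.n_chromosomes):
        freqs = rng.uniform(lo, hi, size=m)
        alleles = (rng.random((n_tags, m)) < freqs).astype(np.int8)
        t = all_tags[c]
        gmat = alleles[t[:, 0, :], np.arange(m)] + alleles[t[:, 1, :], np.arange(m)]
        calls[:, c * m:(c + 1) * m] = gmat
        auto_num += (t[:, 0, :] == t[:, 1, :]).sum(axis=1)
    autozygosity = auto_num / (cfg.n_chromosomes * m)

    if cfg.missing_rate > 0:
        mask = rng.random(calls.shape) < cfg.missing_rate
        calls[mask] = -1

    animals = ped.to_frame()[["animal", "flock", "birth_year", "sex"]].copy()
    g = GenotypeMatrix(calls, snps, animals).sort_by_position()
    return GeneDropResult(g, autozygosity)


# ---------------------------------------------------------------------------
# Wright–Fisher oracle


def wright_fisher(n_diploid: int, n_generations: int, n_snps: int,
                  init_maf: tuple[float, float] = (0.1, 0.5),
                  seed: int = 0, sample_size: int | None = None,
                  flock: str = "WF") -> GenotypeMatrix:
    """Constant-size random-mating population of unlinked SNPs.

    Each offspring draws two distinct parents; transmission is Mendelian
    and free-recombining (every SNP segregates independently). The final
    generation (optionally subsampled) is returned with SNPs placed on
    distinct chromosomes so every pair is physically unlinked.
    """
    rng = np.random.default_rng(seed)
    lo, hi = init_maf
    freqs = rng.uniform(lo, hi, size=n_snps)
    H = (rng.random((2, n_diploid, n_snps)) < freqs).astype(np.int8)
    for _ in range(n_generations):
        sires = rng.integers(0, n_diploid, size=n_diploid)
        dams = (sires + 1 + rng.integers(0, n_diploid - 1, size=n_diploid)) % n_diploid
        Hn = np.empty_like(H)
        for k, parents in enumerate((sires, dams)):
            pick = rng.integers(0, 2, size=(n_diploid, n_snps))
            Hn[k] = np.where(pick == 0, H[0][parents], H[1][parents])
        H = Hn
    calls = (H[0] + H[1]).astype(np.int8)
    if sample_size is not None and sample_size < n_diploid:
        rows = rng.choice(n_diploid, size=sample_size, replace=False)
        calls = calls[rows]
    snps = pd.DataFrame({"snp": [f"wf{j}" for j in range(n_snps)],
                         "chrom": [str(j + 1) for j in range(n_snps)],
                         "cm": 0.0,
                         "pos": np.full(n_snps, 1, dtype=np.int64)})
    animals = pd.DataFrame({"animal": [f"W{i:05d}" for i in range(calls.shape[0])],
                            "flock": flock, "birth_year": np.nan, "sex": "unknown"})
    return GenotypeMatrix(calls, snps, animals)
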