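"""SNP-array genotype container and text IO (PLINK .ped/.map, additive matrix).

Genotypes are held as an animals × SNPs matrix of additive codes
{0, 1, 2} with -1 for a missing call, alongside a SNP map (id,
chromosome, cM, bp) and per-animal metadata (flock, birth year, sex).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

MISSING_CALL = -1
_MISSING_TOKENS = {"NA", "-9", "00", "", "nan", "None"}


@dataclass
class GenotypeMatrix:
    calls: np.ndarray          # (n_animals, n_snps) int8; -1 = missing
    snps: pd.DataFrame         # snp, chrom, cm, pos  (pos sorted within chrom)
    animals: pd.DataFrame      # animal, flock, birth_year, sex

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.animals), len(self.snps)):
            raise ValueError("calls shape does not match animal/SNP tables")
        bad = ~np.isin(self.calls, (-1, 0, 1, 2))
        if bad.any():
            raise ValueError("additive codes must be in {0,1,2} or -1 for missing")

    @property
    def n_animals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    def subset(self, animal_mask=None, snp_mask=None) -> "GenotypeMatrix":
        am = np.ones(self.n_animals, bool) if animal_mask is None else np.asarray(animal_mask)
        sm = np.ones(self.n_snps, bool) if snp_mask is None else np.asarray(snp_mask)
        return GenotypeMatrix(self.calls[np.ix_(np.nonzero(am)[0], np.nonzero(sm)[0])],
                              self.snps.loc[sm].reset_index(drop=True),
                              self.animals.loc[am].reset_index(drop=True))

    def sort_by_position(self) -> "GenotypeMatrix":
        order = self.snps.sort_values(["chrom", "pos"], kind="stable").index.to_numpy()
        return GenotypeMatrix(self.calls[:, order],
                              self.snps.iloc[order].reset_index(drop=True),
                              self.animals)

    # -- per-SNP statistics -------------------------------------------------

    def call_rate_animals(self) -> np.ndarray:
        return (self.calls >= 0).mean(axis=1)

    def call_rate_snps(self) -> np.ndarray:
        return (self.calls >= 0).mean(axis=0)

    def allele_freq(self) -> np.ndarray:
        """Frequency of the counted allele from non-missing calls."""
        obs = self.calls >= 0
        n = obs.sum(axis=0)
        tot = np.where(self.calls >= 0, self.calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(n > 0, tot / (2.0 * n), np.nan)

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)


# ---------------------------------------------------------------------------
# PLINK .ped/.map text dialect


def read_plink_text(prefix: str | Path, metadata: pd.DataFrame | None = None
                    ) -> GenotypeMatrix:
    """Read PLINK ``PREFIX.ped``/``PREFIX.map`` (text, allele pairs).

    Additive codes count copies of the allele that is lexicographically
    larger at each SNP (for the writer's 1/2 coding this is allele "2");
    ``0`` denotes a missing allele. Optional ``metadata`` (animal, flock,
    birth_year) overrides the .ped family/phenotype columns.
    """
    prefix = Path(prefix)
    mp = pd.read_csv(prefix.with_suffix(".map"), sep=r"\s+", header=None,
                     names=["chrom", "snp", "cm", "pos"], dtype={"chrom": str})
    ped = pd.read_csv(prefix.with_suffix(".ped"), sep=r"\s+", header=None, dtype=str)
    n_snps = len(mp)
    if ped.shape[1] != 6 + 2 * n_snps:
        raise ValueError(f".ped has {ped.shape[1]} columns, expected {6 + 2*n_snps}")
    fam = ped.iloc[:, :6]
    alleles = ped.iloc[:, 6:].to_numpy(dtype="U4")
    a1 = alleles[:, 0::2]
    a2 = alleles[:, 1::2]
    calls = np.full(a1.shape, MISSING_CALL, dtype=np.int8)
    for j in range(n_snps):
        col = np.concatenate([a1[:, j], a2[:, j]])
        seen = sorted(set(col) - {"0"})
        if not seen:
            continue
        counted = seen[-1]  # lexicographically larger allele
        ok = (a1[:, j] != "0") & (a2[:, j] != "0")
        calls[ok, j] = (a1[ok, j] == counted).astype(np.int8) + \
                       (a2[ok, j] == counted).astype(np.int8)
    sexmap = {"1": "male", "2": "female"}
    animals = pd.DataFrame({
        "animal": fam.iloc[:, 1].to_numpy(),
        "flock": fam.iloc[:, 0].to_numpy(),
        "birth_year": np.nan,
        "sex": [sexmap.get(s, "unknown") for s in fam.iloc[:, 4]],
    })
    if metadata is not None:
        meta = metadata.set_index("animal")
        for col in ("flock", "birth_year", "sex"):
            if col in meta.columns:
                vals = meta[col].reindex(animals["animal"]).to_numpy()
                use = pd.notna(vals)
                animals.loc[use, col] = vals[use]
    snps = mp[["snp", "chrom", "cm", "pos"]].copy()
    snps["pos"] = snps["pos"].astype(np.int64)
    return GenotypeMatrix(calls, snps, animals).sort_by_position()


def write_plink_text(g: GenotypeMatrix, prefix: str | Path) -> None:
    """Write ``PREFIX.ped``/``PREFIX.map`` with 1/2 allele coding (0 = missing)."""
    prefix = Path(prefix)
    g.snps[["chrom", "snp", "cm", "pos"]].to_csv(
        prefix.with_suffix(".map"), sep="\t", header=False, index=False)
    sexmap = {"male": "1", "female": "2"}
    pair = {0: ("1", "1"), 1: ("1", "2"), 2: ("2", "2"), MISSING_CALL: ("0", "0")}
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, row in g.animals.iterrows():
            toks = [str(row["flock"]) if pd.notna(row["flock"]) else "0",
                    str(row["animal"]), "0", "0",
                    sexmap.get(row.get("sex", "unknown"), "0"), "-9"]
            for c in g.calls[i]:
                toks.extend(pair[int(c)])
            fh.write(" ".join(toks) + "\n")


# ---------------------------------------------------------------------------
# additive 0/1/2 matrix + map dialect


def read_additive(matrix_path: str | Path, map_path: str | Path,
                  metadata: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Read an additive-coded matrix (rows = animals, first column = id)
    plus a SNP map TSV with columns ``snp, chrom, cm, pos``."""
    mat = pd.read_csv(matrix_path, sep=None, engine="python", dtype=str)
    snps = pd.read_csv(map_path, sep=None, engine="python", dtype={"chrom": str})
    ids = mat.iloc[:, 0]
    body = mat.iloc[:, 1:].to_numpy(dtype="U8")
    calls = np.full(body.shape, MISSING_CALL, dtype=np.int8)
    for code in ("0", "1", "2"):
        calls[body == code] = int(code)
    animals = pd.DataFrame({"animal": ids.to_numpy(), "flock": None,
                            "birth_year": np.nan, "sex": "unknown"})
    if metadata is not None:
        meta = metadata.set_index("animal")
        for col in ("flock", "birth_year", "sex"):
            if col in meta.columns:
                vals = meta[col].reindex(animals["animal"]).to_numpy()
                use = pd.notna(vals)
                animals.loc[use, col] = vals[use]
    snps = snps[["snp", "chrom", "cm", "pos"]].copy()
    snps["pos"] = snps["pos"].astype(np.int64)
    return GenotypeMatrix(calls, snps, animals).sort_by_position()


def write_additive(g: GenotypeMatrix, matrix_path: str | Path,
                   map_path: str | Path) -> None:
    body = pd.DataFrame(g.calls.astype(object), columns=g.snps["snp"])
    body = body.mask(body == MISSING_CALL, "NA")
    body.insert(0, "animal", g.animals["animal"].to_numpy())
    body.to_csv(matrix_path, sep="\t", index=False)
    g.snps[["snp", "chrom", "cm", "pos"]].to_csv(map_path, sep="\t", index=False)
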