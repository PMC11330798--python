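"""Stage orchestration: pedigree stage and genomic stage.

Each stage reads its inputs, runs the relevant analysis modules, and
writes machine-readable TSV/JSON outputs plus a provenance block listing
every threshold and seed used, so a rerun with the same config is
byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diversity, effective_size, ped_structure, roh, structure
from .gene_origin import gene_origin as _gene_origin
from .genotypes import GenotypeMatrix, read_additive, read_plink_text
from .pedigree import (Pedigree, SubgroupSpec, generation_interval,
                       generation_stats, load_pedigree, resolve_subgroup)
from .relatedness import inbreeding_trend, relatedness

log = logging.getLogger("flockdiv")


@dataclass
class RunConfig:
    out_dir: str = "results"
    subgroups: list[SubgroupSpec] = field(default_factory=list)
    generation_length: float = 3.1
    animal_call_rate: float = 0.90
    snp_call_rate: float = 0.90
    window_bp: int = 30_000
    min_maf: float = 0.01
    thin_fraction: float = 0.5
    ld_maf_cutoff: float = 0.02
    fst_min_n: int = 10
    fst_n_boot: int = 100
    pca_cap: int = 20
    pca_reps: int = 5
    max_coancestry_animals: int = 10_000
    max_ancestors: int | None = 200
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        subs = [SubgroupSpec(name=s.get("name", f"SG{i + 1}"),
                             birth_year_range=tuple(s["birth_year_range"])
                             if s.get("birth_year_range") else None,
                             min_complete_generations=s.get("min_complete_generations"),
                             id_whitelist=set(s["id_whitelist"])
                             if s.get("id_whitelist") else None,
                             sires_of=None if not s.get("sires_of") else
                             SubgroupSpec(**s["sires_of"]))
                for i, s in enumerate(raw.pop("subgroups", []))]
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        cfg.subgroups = subs
        return cfg

    def provenance(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "subgroups"}
        d["subgroups"] = [s.name for s in self.subgroups]
        return d


def _write_json(path: Path, obj) -> None:
    def default(x):
        if isinstance(x, (np.integer,)):
            return int(x)
        if isinstance(x, (np.floating,)):
            return float(x)
        if isinstance(x, np.ndarray):
            return x.tolist()
        return str(x)

    path.write_text(json.dumps(obj, indent=2, default=default, sort_keys=True) + "\n")


def run_pedigree_stage(ped: Pedigree, cfg: RunConfig) -> dict:
    """Full pedigree analysis: subgroup summary table, ancestor list,
    inbreeding trend, Ne battery, flock differentiation."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    stats = generation_stats(ped)
    rel = relatedness(ped)
    log.info("pedigree: %d animals, %d founders", len(ped), int(ped.is_founder.sum()))

    gi = generation_interval(ped)
    trend = inbreeding_trend(ped, rel.F, by="generation",
                             generation_length=cfg.generation_length)

    groups = {"full_population": set(ped.animals)}
    for spec in cfg.subgroups:
        groups[spec.name] = resolve_subgroup(ped, spec, stats)
        if not groups[spec.name]:
            log.warning("subgroup %s resolved to no animals", spec.name)

    table1 = []
    ancestors_tab = None
    for name, ids in groups.items():
        if not ids:
            continue
        pos = ped.positions(ids)
        go = _gene_origin(ped, list(ids), with_gci=len(ids) <= 2000,
                          max_ancestors=cfg.max_ancestors)
        flocks = {f for f in ped.flock[pos] if f is not None}
        row = {
            "subgroup": name, "n": len(ids), "flocks": len(flocks),
            "mean_F_pct": 100.0 * float(rel.F[pos].mean()),
            "mean_AR_pct": 100.0 * float(rel.AR[pos].mean()),
            "mean_max_generations": float(stats.max_generations[pos].mean()),
            "max_max_generations": float(stats.max_generations[pos].max()),
            "mean_complete_generations": float(stats.complete_generations[pos].mean()),
            "mean_equivalent_generations": float(stats.equivalent_generations[pos].mean()),
            "fe": go.fe, "fa": go.fa, "fe_over_fa": go.fe_over_fa, "n50": go.n50,
        }
        if go.gci_table is not None:
            row["mean_gci"] = float(go.gci_table["gci"].mean())
        table1.append(row)
        if name == "full_population":
            ancestors_tab = go.ancestors
            go.founders.to_csv(out / "founders.tsv", sep="\t", index=False)
            _write_json(out / "gene_origin.json", go.summary())
    pd.DataFrame(table1).to_csv(out / "table1.tsv", sep="\t", index=False)
    if ancestors_tab is not None:
        ancestors_tab.to_csv(out / "ancestors.tsv", sep="\t", index=False)

    rel.to_frame().to_csv(out / "relatedness.tsv", sep="\t", index=False,
                          float_format="%.8g")
    trend.table.to_csv(out / "trend.tsv", sep="\t", index=False)

    ne_tab = effective_size.pedigree_ne_battery(
        ped, rel.F, stats, generation_length=cfg.generation_length,
        coancestry_seed=int(rng.integers(2**31 - 1)),
        max_coancestry_animals=cfg.max_coancestry_animals)
    ne_tab.to_csv(out / "ne_estimates.tsv", sep="\t", index=False)

    diff = ped_structure.flock_differentiation(ped)
    diff["nei_D"].to_csv(out / "nei_D.tsv", sep="\t")
    mean_f, mean_ar = float(rel.F.mean()), float(rel.AR.mean())
    summary = {
        "generation_interval": gi,
        "mean_F": mean_f, "mean_AR": mean_ar,
        # mean F above half the mean AR indicates mating among relatives
        "mating_among_relatives": bool(mean_f > mean_ar / 2.0),
        "delta_F_per_generation": trend.mean_delta_f,
        "delta_F_slope": trend.slope, "delta_F_slope_p": trend.slope_p,
        "pedigree_fst": diff["fst"], "mean_nei_D": float(
            diff["nei_D"].to_numpy()[np.triu_indices(len(diff["nei_D"]), 1)].mean())
        if len(diff["nei_D"]) > 1 else float("nan"),
        "ne": {r["method"]: r["ne"] for r in ne_tab.to_dict("records")},
        "provenance": cfg.provenance(),
    }
    _write_json(out / "pedigree_summary.json", summary)
    return summary


def run_genomic_stage(g: GenotypeMatrix, cfg: RunConfig,
                      f_pedigree: pd.Series | None = None) -> dict:
    """Full genomic analysis over the full/reduced/thinned marker lineage."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed + 1)

    stages = diversity.build_stages(
        g, animal_call_rate=cfg.animal_call_rate, snp_call_rate=cfg.snp_call_rate,
        window_bp=cfg.window_bp, min_maf=cfg.min_maf,
        thin_fraction=cfg.thin_fraction, seed=int(rng.integers(2**31 - 1)))
    log.info("marker lineage: %d raw -> %d QC -> %d full -> %d reduced -> %d thinned",
             g.n_snps, stages.report.counts["snps_after_qc"],
             stages.full.n_snps, stages.reduced.n_snps, stages.thinned.n_snps)

    spectrum = diversity.maf_spectrum(stages.full)
    spectrum["bins"].to_csv(out / "maf_bins.tsv", sep="\t", index=False)
    het = diversity.heterozygosity(stages.reduced)
    ld = diversity.ld_decay(stages.reduced)
    ld["decay"].to_csv(out / "ld_decay.tsv", sep="\t", index=False)

    try:
        ne = effective_size.ne_ld(stages.thinned, maf_cutoff=cfg.ld_maf_cutoff)
        ne_row = ne.as_row()
    except ValueError as e:
        log.warning("LD-based Ne skipped: %s", e)
        ne_row = {"method": "ld_method", "ne": float("nan")}

    segments = roh.detect_roh(stages.full)
    segments.to_csv(out / "roh_segments.tsv", sep="\t", index=False)
    summary_roh = roh.f_roh(segments, stages.full)
    summary_roh.per_animal.to_csv(out / "froh.tsv", sep="\t", index=False,
                                  float_format="%.8g")

    corr = None
    if f_pedigree is not None:
        fw = diversity.individual_wright_f(stages.reduced)
        fr = summary_roh.per_animal.set_index("animal")["f_roh"]
        common = stages.reduced.animals["animal"]
        fp = f_pedigree.reindex(common).to_numpy(dtype=float)
        try:
            corr = roh.inbreeding_correlations(fp, fw, fr.reindex(common).to_numpy())
            corr.to_csv(out / "inbreeding_correlations.tsv", sep="\t")
        except ValueError as e:
            log.warning("inbreeding correlations skipped: %s", e)

    flock_counts = stages.reduced.animals["flock"].value_counts()
    fst_done = (flock_counts > cfg.fst_min_n).sum() >= 2
    if fst_done:
        fm = structure.pairwise_fst(stages.reduced, min_n=cfg.fst_min_n,
                                    n_boot=cfg.fst_n_boot,
                                    seed=int(rng.integers(2**31 - 1)))
        fm.fst.to_csv(out / "fst_matrix.tsv", sep="\t")
        pd.concat({"lo": fm.ci_lo, "hi": fm.ci_hi}, axis=1).to_csv(
            out / "fst_ci.tsv", sep="\t")
        reps = structure.pca_replicates(stages.reduced, min_n=cfg.fst_min_n,
                                        per_flock_cap=cfg.pca_cap,
                                        n_reps=cfg.pca_reps,
                                        seed=int(rng.integers(2**31 - 1)))
        for r in reps:
            r.table.to_csv(out / f"pca_rep{r.replicate}.tsv", sep="\t", index=False)
        pd.DataFrame([{"replicate": r.replicate,
                       **{f"PC{k + 1}_varfrac": r.variance_fraction[k]
                          for k in range(len(r.variance_fraction))}}
                      for r in reps]).to_csv(out / "pca_variance.tsv", sep="\t",
                                             index=False)
        iu = np.triu_indices(len(fm.fst), 1)
        mean_fst = float(fm.fst.to_numpy()[iu].mean()) if len(fm.fst) > 1 else float("nan")
    else:
        log.warning("all flocks have <= %d genotyped animals: F_ST and PCA skipped",
                    cfg.fst_min_n)
        mean_fst = float("nan")

    summary = {
        "qc": stages.report.as_dict(),
        "maf": {"n_fixed": spectrum["n_fixed"],
                "fraction_maf_gt_0.30": spectrum["fraction_maf_gt_0.30"]},
        "he": het["he"], "ho": het["ho"], "wright_f": het["wright_f"],
        "wright_f_mean_per_snp": het["wright_f_mean_per_snp"],
        "ld": {"adjacent_mean_dist_bp": ld["adjacent_mean_dist_bp"],
               "adjacent_mean_r2": ld["adjacent_mean_r2"]},
        "ne_ld": ne_row,
        "roh": summary_roh.population_means(),
        "marker_fst_mean": mean_fst,
        "fst_and_pca_run": bool(fst_done),
        "inbreeding_correlations": None if corr is None else corr.to_dict(),
        "provenance": cfg.provenance(),
    }
    _write_json(out / "diversity.json", summary)
    return summary


def load_genotypes(plink_prefix: str | None = None,
                   additive_matrix: str | None = None,
                   additive_map: str | None = None,
                   metadata: pd.DataFrame | None = None) -> GenotypeMatrix:
    if plink_prefix:
        return read_plink_text(plink_prefix, metadata)
    if additive_matrix and additive_map:
        return read_additive(additive_matrix, additive_map, metadata)
    raise ValueError("need a PLINK prefix or an additive matrix + map")


__all__ = ["RunConfig", "run_pedigree_stage", "run_genomic_stage",
           "load_genotypes", "load_pedigree"]
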