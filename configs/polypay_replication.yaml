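# Run configuration for a U.S. Polypay-style national-scheme analysis.
# The restricted NSIP/USSES pedigree and genotype files are not bundled;
# point the CLI at your own exports:
#   flockdiv pedigree --ped pedigree.csv --config configs/polypay_replication.yaml --out out/
#   flockdiv genomic --ped pedigree.csv --plink genotypes --config configs/polypay_replication.yaml --out out/

generation_length: 3.1        # years per generation for cohorting and Ne scaling
animal_call_rate: 0.90
snp_call_rate: 0.90
window_bp: 30000              # one SNP per 30-kb window
min_maf: 0.01                 # reduced set keeps MAF >= 0.01
thin_fraction: 0.5            # additional thinning for the LD-based Ne
ld_maf_cutoff: 0.02
fst_min_n: 10                 # flocks need > 10 genotyped animals
fst_n_boot: 100
pca_cap: 20
pca_reps: 5
max_coancestry_animals: 10000
seed: 1

subgroups:
  - name: SG1_current_generation
    birth_year_range: [2020, 2022]
  - name: SG2_min_four_complete_generations
    birth_year_range: [2020, 2022]
    min_complete_generations: 4
  # SG3 (genotyped animals) needs the genotyped id list:
  # - name: SG3_genotyped
  #   id_whitelist: [...]
  - name: SG4_sires_of_current_generation
    sires_of:
      name: SG1_base
      birth_year_range: [2020, 2022]
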