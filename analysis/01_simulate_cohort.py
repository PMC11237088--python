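#!/usr/bin/env python
"""Simulate the synthetic cohort every later step analyzes.

Generates 80 donors (65% disease, 35% control, mirroring the cohort
composition the pipeline targets): HWE genotypes with local LD written as
VCF, ~8k single-nucleus counts with a disease-enriched subpopulation,
five planted cis-eQTL effects, 5% planted QC violations, and donor trait
tables with a genotype x pathology interaction. Everything lands under
results/cohort/ with a YAML manifest of seeds and checksums.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from cellink.io import write_counts, write_manifest, write_tsv, write_vcf
from cellink.synth import (
    CONDITION_A,
    CONDITION_B,
    SimConfig,
    sim_cells,
    sim_donor_traits,
    sim_genotypes,
)

SEED = 2026
OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(n_donors=80, n_variants=120, n_genes=300,
                    n_cells_per_donor=(80, 120), ld_decay=0.9, seed=SEED)
    geno = sim_genotypes(cfg)
    write_vcf(geno, OUT / "genotypes.vcf")

    rng = np.random.default_rng(SEED + 1)
    starts = np.sort(rng.integers(geno.variants["pos"].min() - 100_000,
                                  geno.variants["pos"].max() + 100_000,
                                  size=cfg.n_genes))
    # plant five cis effects on body genes near the variant span
    from cellink.synth import _gene_table

    gene_names = list(_gene_table(cfg.n_genes).index)
    genes = pd.DataFrame({"gene_id": gene_names, "chrom": "chr1",
                          "start": starts,
                          "end": starts + rng.integers(2_000, 50_000, cfg.n_genes)})
    write_tsv(genes, OUT / "genes.tsv")

    body = [g for g in gene_names if not g.startswith(("MT-", "RP", "HB"))]
    effects = []
    gtab = genes.set_index("gene_id")
    for g in body[:5]:
        near = geno.variants[
            (geno.variants["pos"] >= gtab.loc[g, "start"] - 250_000)
            & (geno.variants["pos"] <= gtab.loc[g, "end"] + 250_000)]
        if len(near):
            effects.append({"gene": g, "variant": near["variant"].iloc[len(near) // 2],
                            "beta": 0.6})
    effects = pd.DataFrame(effects)
    write_tsv(effects, OUT / "planted_eqtl.tsv")

    cells = sim_cells(cfg, {CONDITION_A: 0.3, CONDITION_B: 0.05},
                      qc_violation_frac=0.05, geno=geno, eqtl_effects=effects,
                      mean_umi=4000.0)
    cells.obs["cell_type"] = "Oli"
    write_counts(cells, OUT / "counts")

    traits = sim_donor_traits(geno, main_beta=0.4, interaction_beta=-0.15,
                              pathology_model="quantitative", seed=SEED + 5)
    cond = cells.obs.groupby("donor", observed=True)["condition"].first()
    donors = traits.donors.copy()
    donors["disease_status"] = (cond.reindex(donors["donor"]).to_numpy()
                                == CONDITION_A).astype(int)
    write_tsv(donors, OUT / "donors.tsv")
    write_tsv(traits.measurements, OUT / "measurements.tsv")

    from cellink.io import file_checksum
    manifest = {
        "seed": SEED,
        "config": {"n_donors": cfg.n_donors, "n_variants": cfg.n_variants,
                   "n_genes": cfg.n_genes, "subpop_fractions": {CONDITION_A: 0.3,
                                                                CONDITION_B: 0.05},
                   "qc_violation_frac": 0.05, "planted_eqtl_beta": 0.6},
        "checksums": {p.name: file_checksum(p) for p in sorted(OUT.glob("*.tsv"))},
    }
    write_manifest(manifest, OUT / "manifest.yaml")

    n_ad = int((donors["disease_status"] == 1).sum())
    print(f"cohort: {cfg.n_donors} donors ({n_ad} {CONDITION_A} / "
          f"{cfg.n_donors - n_ad} {CONDITION_B}), {geno.n_variants} variants, "
          f"{cells.n_obs} nuclei")
    print(f"planted: {len(effects)} cis-eQTL effects (beta 0.6 on log scale), "
          f"subpopulation at 30% vs 5% frequency, "
          f"{int(cells.obs['qc_violation'].sum())} QC-violating nuclei")
    print(f"wrote {OUT}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
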