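"""End-to-end orchestration of the synthetic-cohort analysis.

``run_pipeline`` executes the selected stages in dependency order
(simulate -> qc -> eqtl -> coloc | cit | da -> enrich) against a single
output directory, fanning a global seed out to per-stage seeds through a
fixed offset table so any stage can be rerun in isolation, and records
configs, seeds and output checksums in a YAML manifest.
"""

from __future__ import annotations

import datetime
import importlib.metadata
from pathlib import Path

import numpy as np
import pandas as pd

from . import cit as cit_mod
from . import coloc as coloc_mod
from . import da as da_mod
from . import enrich as enrich_mod
from . import eqtl as eqtl_mod
from . import qc as qc_mod
from . import synth
from .io import (
    GenotypeMatrix,
    file_checksum,
    read_counts,
    read_tsv,
    read_vcf,
    write_counts,
    write_manifest,
    write_tsv,
    write_vcf,
)

__all__ = ["PipelineError", "run_pipeline", "validate_inputs", "STAGES", "stage_seed"]

STAGES = ("simulate", "qc", "eqtl", "coloc", "cit", "da", "enrich")

#: per-stage seed offsets; stage seed = (global_seed * 1000 + offset) mod 2^31
_STAGE_OFFSET = {s: i + 1 for i, s in enumerate(STAGES)}

_REQUIRES = {
    "simulate": (),
    "qc": ("counts",),
    "eqtl": ("counts_filtered", "genotypes.vcf", "genes.tsv", "donors.tsv"),
    "coloc": (),
    "cit": (),
    "da": ("counts_filtered",),
    "enrich": ("da_cells.tsv", "donors.tsv"),
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def stage_seed(global_seed: int, stage: str) -> int:
    return (int(global_seed) * 1000 + _STAGE_OFFSET[stage]) % (2**31)


def _default_config() -> dict:
    return {
        "seed": 0,
        "stages": list(STAGES),
        "simulate": {
            "n_donors": 60,
            "n_variants": 60,
            "n_genes": 120,
            "n_cells_per_donor": [60, 100],
            "subpop_fractions": {synth.CONDITION_A: 0.3, synth.CONDITION_B: 0.05},
            "qc_violation_frac": 0.05,
            "eqtl_beta": 0.6,
            "n_eqtl": 3,
            "mean_umi": 600.0,
        },
        # thresholds adapted to the demo's reduced gene panel: the
        # genes-per-UMI metric saturates when only ~10^2 genes exist
        "qc": {"min_genes": 30, "min_log10_genes_per_umi": 0.5},
        "eqtl": {"cis_window": 250_000, "n_expression_pcs": 5, "ld_r2_threshold": 0.8,
                 "fdr_threshold": 0.05},
        "coloc": {"region_size": 60, "causal_index": 20, "n_panel": 1500,
                  "effect_size": 1.0, "p1": 1e-4, "p2": 1e-4, "p12": 1e-5},
        "cit": {"n_trios_per_kind": 8, "n": 500, "effect": 0.5, "perms": 500},
        "da": {"k_grid": [50, 100, 200, 400], "thresholds": [-0.8, 0.8], "n_pcs": 20,
               "resolution": 0.01},
        "enrich": {"n_perm": 2000},
    }


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _validate_config(config: dict) -> dict:
    cfg = _merge(_default_config(), config or {})
    unknown = [s for s in cfg["stages"] if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stage(s) {unknown}; valid: {list(STAGES)}")
    cfg["stages"] = [s for s in STAGES if s in cfg["stages"]]
    if not isinstance(cfg["seed"], int):
        raise ValueError("seed must be an integer")
    return cfg


def _check_stage_inputs(stages: list[str], outdir: Path) -> None:
    produced = set()
    if "simulate" in stages:
        produced |= {"counts", "genotypes.vcf", "genes.tsv", "donors.tsv"}
    if "qc" in stages:
        produced |= {"counts_filtered"}
    if "da" in stages:
        produced |= {"da_cells.tsv"}
    for stage in stages:
        for req in _REQUIRES[stage]:
            if req in produced or (outdir / req).exists():
                continue
            raise PipelineError(stage, f"missing required input {req!r} under {outdir}")


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(cfg: dict, outdir: Path, seed: int) -> dict:
    sc = cfg["simulate"]
    config = synth.SimConfig(
        n_donors=sc["n_donors"], n_variants=sc["n_variants"], n_genes=sc["n_genes"],
        n_cells_per_donor=tuple(sc["n_cells_per_donor"]), seed=seed,
    )
    geno = synth.sim_genotypes(config)
    write_vcf(geno, outdir / "genotypes.vcf")

    # gene coordinates tiled along the simulated chromosome
    rng = np.random.default_rng(seed + 101)
    var = synth._gene_table(config.n_genes)
    span = geno.variants["pos"].max() - geno.variants["pos"].min()
    starts = np.sort(rng.integers(geno.variants["pos"].min() - 100_000,
                                  geno.variants["pos"].max() + 100_000,
                                  size=len(var)))
    genes = pd.DataFrame(
        {"gene_id": var.index, "chrom": "chr1", "start": starts,
         "end": starts + rng.integers(2_000, 50_000, size=len(var))}
    )
    write_tsv(genes, outdir / "genes.tsv")

    # plant cis effects for the first few body genes near their spans
    n_eqtl = sc["n_eqtl"]
    body_genes = [g for g in var.index if not g.startswith(("MT-", "RP", "HB"))]
    effects = []
    for g in body_genes[:n_eqtl]:
        grow = genes.set_index("gene_id").loc[g]
        near = geno.variants[
            (geno.variants["pos"] >= grow.start - 250_000)
            & (geno.variants["pos"] <= grow.end + 250_000)
        ]
        if near.empty:
            continue
        effects.append({"gene": g, "variant": near["variant"].iloc[len(near) // 2],
                        "beta": sc["eqtl_beta"]})
    effects = pd.DataFrame(effects)
    write_tsv(effects, outdir / "planted_eqtl.tsv")

    cells = synth.sim_cells(
        config,
        subpop_fraction_by_condition=sc["subpop_fractions"],
        qc_violation_frac=sc["qc_violation_frac"],
        geno=geno,
        eqtl_effects=effects if len(effects) else None,
        mean_umi=sc["mean_umi"],
    )
    cells.obs["cell_type"] = "Oli"
    write_counts(cells, outdir / "counts")

    donors = synth.sim_donor_traits(geno, main_beta=0.4, interaction_beta=-0.15,
                                    seed=seed + 5)
    cond = cells.obs.groupby("donor", observed=True)["condition"].first()
    dtab = donors.donors.copy()
    dtab["disease_status"] = (cond.reindex(dtab["donor"]).to_numpy() == synth.CONDITION_A).astype(int)
    write_tsv(dtab, outdir / "donors.tsv")
    write_tsv(donors.measurements, outdir / "measurements.tsv")
    return {"n_cells": int(cells.n_obs), "n_variants": int(geno.n_variants)}


def _stage_qc(cfg: dict, outdir: Path, seed: int) -> dict:
    adata = read_counts(outdir / "counts")
    for col in ("mito", "ribo", "hemoglobin"):
        adata.var[col] = adata.var[col].astype(bool)
    qcfg = qc_mod.QcConfig(**cfg["qc"])
    filtered, report = qc_mod.apply_cell_filters(adata, qcfg)
    write_counts(filtered, outdir / "counts_filtered")
    write_tsv(report.to_frame(), outdir / "qc_report.tsv")
    return {"n_input": report.n_input, "n_removed": report.n_removed}


def _stage_eqtl(cfg: dict, outdir: Path, seed: int) -> dict:
    adata = read_counts(outdir / "counts_filtered")
    geno = read_vcf(outdir / "genotypes.vcf")
    genes = read_tsv(outdir / "genes.tsv")
    donors = read_tsv(outdir / "donors.tsv").set_index("donor")
    econf = eqtl_mod.EqtlConfig(
        cis_window=cfg["eqtl"]["cis_window"],
        n_expression_pcs=cfg["eqtl"]["n_expression_pcs"],
        ld_r2_threshold=cfg["eqtl"]["ld_r2_threshold"],
        fdr_threshold=cfg["eqtl"]["fdr_threshold"],
    )
    norm = eqtl_mod.normalize_cells(adata)
    pb = eqtl_mod.aggregate_pseudobulk(norm, "Oli", cell_type_col="cell_type")
    geno_qc, vrec = eqtl_mod.variant_qc(geno)
    write_tsv(vrec, outdir / "variant_qc.tsv")
    kept = eqtl_mod.ld_prune(geno_qc, econf.ld_r2_threshold)
    geno_pruned = geno_qc.subset_variants(kept)
    covars = donors.loc[[d for d in pb.index if d in donors.index],
                        ["age", "sex", "education", "disease_status"]]
    res = eqtl_mod.map_cis_eqtl(pb.loc[covars.index], geno_pruned, genes,
                                covars=covars, config=econf)
    # auxiliary external-study p-values: enriched at the planted pairs
    planted = read_tsv(outdir / "planted_eqtl.tsv") if (outdir / "planted_eqtl.tsv").exists() else pd.DataFrame(columns=["gene"])
    rng = np.random.default_rng(seed + 17)
    planted_genes = set(planted["gene"]) if len(planted) else set()
    aux = np.where(
        res["gene"].isin(planted_genes),
        rng.beta(0.1, 1.0, size=len(res)),
        rng.uniform(size=len(res)),
    )
    aux = np.clip(aux, 1e-12, 1.0)
    res["aux_p"] = aux
    res["cfdr"] = eqtl_mod.conditional_fdr(res["p"].to_numpy(), aux)
    res["significant"] = res["cfdr"] <= econf.fdr_threshold
    write_tsv(res, outdir / "eqtl_results.tsv")
    return {"n_tests": int(len(res)), "n_significant": int(res["significant"].sum())}


def _stage_coloc(cfg: dict, outdir: Path, seed: int) -> dict:
    cc = cfg["coloc"]
    sim_cfg = synth.SimConfig(n_donors=cc["n_panel"], effect_size=cc["effect_size"],
                              seed=seed)
    t1, t2 = synth.sim_gwas_pair(True, cc["region_size"], cc["causal_index"], sim_cfg)
    res = coloc_mod.colocalize(t1, t2, p1=cc["p1"], p2=cc["p2"], p12=cc["p12"])
    write_tsv(res.to_frame(), outdir / "coloc_posteriors.tsv")
    pv = res.per_variant.rename("pp_h4").reset_index()
    write_tsv(pv, outdir / "coloc_per_variant.tsv")
    return {"PP4": res.pp["PP4"]}


def _stage_cit(cfg: dict, outdir: Path, seed: int) -> dict:
    cc = cfg["cit"]
    trios, results, kinds = [], [], []
    i = 0
    for kind in ("causal", "reactive", "independent", "confounded"):
        for _ in range(cc["n_trios_per_kind"]):
            sc = synth.TrioScenario(
                kind=kind, n=cc["n"],
                beta_LG=cc["effect"] if kind != "reactive" else 0.0,
                beta_GT=0.0 if kind == "independent" else cc["effect"],
                beta_LT_direct=0.0 if kind == "causal" else cc["effect"],
                seed=seed + i,
            )
            trio = synth.sim_trio(sc)
            trios.append(trio)
            results.append(cit_mod.cit_test(trio))
            kinds.append(kind)
            i += 1
    results = cit_mod.cit_fdr(results, trios, B=cc["perms"], seed=seed + 999)
    rows = [{"kind": k, **r.row()} for k, r in zip(kinds, results)]
    df = pd.DataFrame(rows)
    write_tsv(df, outdir / "cit_results.tsv")
    called = df.groupby("kind")["call"].apply(lambda s: (s == "causal").mean())
    return {f"called_{k}": float(v) for k, v in called.items()}


def _stage_da(cfg: dict, outdir: Path, seed: int) -> dict:
    adata = read_counts(outdir / "counts_filtered")
    norm = eqtl_mod.normalize_cells(adata)
    X = norm.X.toarray() if hasattr(norm.X, "toarray") else np.asarray(norm.X)
    X = X - X.mean(axis=0)
    n_pcs = min(cfg["da"]["n_pcs"], min(X.shape) - 1)
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    emb = U[:, :n_pcs] * S[:n_pcs]
    dconf = da_mod.DaConfig(
        k_grid=tuple(k for k in cfg["da"]["k_grid"] if k < adata.n_obs),
        measure_thresholds=tuple(cfg["da"]["thresholds"]),
        n_pcs=n_pcs, cluster_resolution=cfg["da"]["resolution"], seed=seed,
    )
    res = da_mod.run_da(emb, adata.obs["condition"].to_numpy(), dconf,
                        cond_a=synth.CONDITION_A)
    out = pd.DataFrame({
        "cell": adata.obs_names,
        "donor": adata.obs["donor"].to_numpy(),
        "condition": adata.obs["condition"].to_numpy(),
        "da_measure": res.measure,
    })
    out["da_selected"] = out.index.isin(res.da_cells)
    out["da_subpop"] = np.nan
    if res.labels is not None:
        out.loc[res.labels.index, "da_subpop"] = res.labels.to_numpy()
    write_tsv(out, outdir / "da_cells.tsv")
    return {"n_da_cells": int(len(res.da_cells))}


def _stage_enrich(cfg: dict, outdir: Path, seed: int) -> dict:
    da_cells = read_tsv(outdir / "da_cells.tsv")
    donors = read_tsv(outdir / "donors.tsv").set_index("donor")
    sel = da_cells[da_cells["da_selected"] & da_cells["da_subpop"].notna()].copy()
    rows = []
    if len(sel):
        sel["cluster"] = sel["da_subpop"].astype(int)
        memberships = enrich_mod.collapse_to_donors(sel, cluster_col="cluster")
        # restore the full cohort as background
        cohort = set(da_cells["donor"].unique())
        for mem in memberships.values():
            mem.cohort = cohort
        condition = da_cells.groupby("donor")["condition"].first() == synth.CONDITION_A
        cat = enrich_mod.categorical_enrichment(memberships, condition, "condition")
        for r in cat:
            rows.append({"cluster": r.cluster, "trait": r.trait, "kind": "categorical",
                         "statistic": r.statistic, "p": r.p, "fdr": r.fdr})
        for mem in memberships.values():
            if len(mem.members) >= 2:
                r = enrich_mod.quantitative_enrichment(
                    mem, donors["trait"], n_perm=cfg["enrich"]["n_perm"], seed=seed)
                rows.append({"cluster": r.cluster, "trait": "donor_trait",
                             "kind": "quantitative", "statistic": r.statistic,
                             "p": r.p, "fdr": None})
    df = pd.DataFrame(rows, columns=["cluster", "trait", "kind", "statistic", "p", "fdr"])
    write_tsv(df, outdir / "cluster_trait_enrichment.tsv")

    assoc = enrich_mod.genotype_trait_assoc(
        donors["dosage"].to_numpy(), donors["trait"].to_numpy(),
        covariates=donors[["age", "sex", "education"]],
        interaction=donors["pathology"].to_numpy(), log_transform=True,
    )
    write_tsv(pd.DataFrame([assoc]), outdir / "genotype_trait_assoc.tsv")
    return {"n_enrichments": int(len(df)), "assoc_p": assoc["p"]}


_STAGE_FN = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "eqtl": _stage_eqtl,
    "coloc": _stage_coloc,
    "cit": _stage_cit,
    "da": _stage_da,
    "enrich": _stage_enrich,
}

_OUTPUTS = {
    "simulate": ["genotypes.vcf", "genes.tsv", "donors.tsv", "measurements.tsv",
                 "planted_eqtl.tsv", "counts/matrix.mtx", "counts/genes.tsv",
                 "counts/cells.tsv"],
    "qc": ["counts_filtered/matrix.mtx", "qc_report.tsv"],
    "eqtl": ["variant_qc.tsv", "eqtl_results.tsv"],
    "coloc": ["coloc_posteriors.tsv", "coloc_per_variant.tsv"],
    "cit": ["cit_results.tsv"],
    "da": ["da_cells.tsv"],
    "enrich": ["cluster_trait_enrichment.tsv", "genotype_trait_assoc.tsv"],
}


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Run the selected stages and write a reproducible manifest.

    Raises :class:`PipelineError` naming the stage on any failure; config
    and input validation happen before any stage runs.
    """
    cfg = _validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _check_stage_inputs(cfg["stages"], outdir)

    try:
        version = importlib.metadata.version("cellink")
    except importlib.metadata.PackageNotFoundError:
        version = "unknown"
    manifest: dict = {
        "package_version": version,
        "created": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "global_seed": cfg["seed"],
        "config": {k: v for k, v in cfg.items() if k != "stages"},
        "stages": {},
        "checksums": {},
    }
    for stage in cfg["stages"]:
        seed = stage_seed(cfg["seed"], stage)
        try:
            summary = _STAGE_FN[stage](cfg, outdir, seed)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc
        manifest["stages"][stage] = {"seed": seed, "summary": summary}
        for rel in _OUTPUTS[stage]:
            f = outdir / rel
            if f.exists():
                manifest["checksums"][rel] = file_checksum(f)
    write_manifest(manifest, outdir / "manifest.yaml")
    return manifest


# ---------------------------------------------------------------------------
# input validation


def validate_inputs(paths: dict) -> list[dict]:
    """Structural validation of pipeline inputs.

    ``paths`` may contain ``vcf``, ``counts`` (a directory with
    matrix.mtx/genes.tsv/cells.tsv), ``genes`` and ``donors``. Issues are
    returned (never raised mid-parse) as dicts with file/line context; an
    empty list means fully consistent inputs.
    """
    issues: list[dict] = []
    vcf_donors: set | None = None
    cell_donors: set | None = None

    if "vcf" in paths:
        p = Path(paths["vcf"])
        if not p.exists():
            issues.append({"file": str(p), "line": None, "issue": "missing file"})
        else:
            header_seen = False
            for ln, line in enumerate(p.read_text().splitlines(), 1):
                if line.startswith("##"):
                    continue
                if line.startswith("#CHROM"):
                    header_seen = True
                    vcf_donors = set(line.split("\t")[9:])
                    continue
                fields = line.split("\t")
                if len(fields) < 10:
                    issues.append({"file": str(p), "line": ln,
                                   "issue": f"malformed VCF line ({len(fields)} fields)"})
                    continue
                try:
                    if int(fields[1]) <= 0:
                        issues.append({"file": str(p), "line": ln, "issue": "nonpositive position"})
                except ValueError:
                    issues.append({"file": str(p), "line": ln, "issue": "non-integer position"})
            if not header_seen:
                issues.append({"file": str(p), "line": None, "issue": "no #CHROM header"})

    if "counts" in paths:
        d = Path(paths["counts"])
        for name in ("matrix.mtx", "genes.tsv", "cells.tsv"):
            if not (d / name).exists():
                issues.append({"file": str(d / name), "line": None, "issue": "missing file"})
        cells_f = d / "cells.tsv"
        if cells_f.exists():
            cells = pd.read_csv(cells_f, sep="\t")
            if "donor" not in cells.columns:
                issues.append({"file": str(cells_f), "line": 1, "issue": "no donor column"})
            else:
                cell_donors = set(cells["donor"].unique())

    if "genes" in paths:
        p = Path(paths["genes"])
        if not p.exists():
            issues.append({"file": str(p), "line": None, "issue": "missing file"})
        else:
            genes = pd.read_csv(p, sep="\t")
            need = {"gene_id", "chrom", "start", "end"}
            if not need <= set(genes.columns):
                issues.append({"file": str(p), "line": 1,
                               "issue": f"missing columns {sorted(need - set(genes.columns))}"})
            else:
                bad = genes[(genes["start"] > genes["end"]) | (genes["start"] <= 0)]
                for i in bad.index:
                    issues.append({"file": str(p), "line": int(i) + 2,
                                   "issue": f"bad span for {genes.loc[i, 'gene_id']}"})

    if vcf_donors is not None and cell_donors is not None:
        only_cells = sorted(cell_donors - vcf_donors)
        if only_cells:
            issues.append({"file": "(cross-file)", "line": None,
                           "issue": f"donor(s) in expression but absent from VCF: {only_cells[:5]}"})
    return issues
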