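"""Synthetic cohort generation with planted effects.

Every downstream stage of the pipeline is exercised on data produced here:
HWE genotypes with geometric local LD, negative-binomial single-nucleus
counts with a condition-enriched subpopulation and planted cis-eQTL
effects, (L, G, T) mediation trios under four generative models, paired
GWAS/eQTL summary tracks with shared or distinct causal variants, and donor
trait tables with genotype main effects and pathology interactions.

All generators are fully determined by their seed. The default cohort
composition mirrors the primary study population: roughly 65% of donors
carry the disease condition ("AD") and 35% the control condition ("CT").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .cit import TrioData
from .coloc import SummaryTrack
from .io import GenotypeMatrix

__all__ = [
    "SimConfig",
    "TrioScenario",
    "DonorTable",
    "sim_genotypes",
    "sim_cells",
    "sim_trio",
    "sim_gwas_pair",
    "sim_donor_traits",
    "CONDITION_A",
    "CONDITION_B",
]

CONDITION_A = "AD"
CONDITION_B = "CT"

#: fraction of donors assigned the disease condition (roughly two cases
#: per control, typical of aged postmortem AD cohorts)
DEFAULT_CASE_DONOR_FRACTION = 0.65


@dataclass
class SimConfig:
    """Knobs shared by the cohort-level generators.

    ``maf_range`` mirrors the retained-variant spectrum after the MAF >= 0.05
    filter; ``ld_decay`` is the adjacent-variant haplotype copy probability
    of a first-order Markov chain, so adjacent-genotype correlation decays
    geometrically with marker distance in the chain.
    """

    n_donors: int = 100
    n_variants: int = 200
    n_genes: int = 500
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_decay: float = 0.6
    n_cells_per_donor: tuple[int, int] = (100, 200)
    effect_size: float = 0.5
    noise_sd: float = 1.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_donors < 2:
            raise ValueError("n_donors must be at least 2")
        lo, hi = self.maf_range
        if not (0.05 <= lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0.05 <= lo <= hi <= 0.5")
        if not 0 <= self.ld_decay < 1:
            raise ValueError("ld_decay must lie in [0, 1)")
        if self.n_cells_per_donor[0] < 1 or self.n_cells_per_donor[0] > self.n_cells_per_donor[1]:
            raise ValueError("n_cells_per_donor must be a nonempty count range")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")


def _donor_ids(n: int) -> list[str]:
    return [f"D{i + 1:04d}" for i in range(n)]


def sim_genotypes(config: SimConfig) -> GenotypeMatrix:
    """HWE genotypes on one chromosome with geometric LD.

    Haplotypes follow a first-order Markov chain: each allele copies its
    left neighbor with probability ``ld_decay`` and is otherwise drawn fresh
    from the variant's allele frequency, so the correlation between markers
    ``d`` steps apart decays like ``ld_decay**d``. Dosages are alt-allele
    counts over two independent haplotypes; a fraction ``missing_rate`` of
    calls is set missing at random.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_donors, config.n_variants
    freqs = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)

    hap = np.empty((2 * n, m), dtype=np.int8)
    hap[:, 0] = rng.random(2 * n) < freqs[0]
    for j in range(1, m):
        copy = rng.random(2 * n) < config.ld_decay
        fresh = rng.random(2 * n) < freqs[j]
        hap[:, j] = np.where(copy, hap[:, j - 1], fresh)
    dosages = (hap[0::2] + hap[1::2]).astype(float)

    if config.missing_rate > 0:
        miss = rng.random(dosages.shape) < config.missing_rate
        dosages[miss] = np.nan

    pos = 1_000_000 + np.cumsum(rng.integers(500, 5000, size=m))
    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, size=m)
    alt_idx = (ref_idx + rng.integers(1, 4, size=m)) % 4
    variants = pd.DataFrame(
        {
            "variant": [f"v{j + 1:05d}" for j in range(m)],
            "chrom": "chr1",
            "pos": pos,
            "ref": bases[ref_idx],
            "alt": bases[alt_idx],
        }
    )
    dos = pd.DataFrame(dosages, index=_donor_ids(n), columns=variants["variant"])
    return GenotypeMatrix(dosages=dos, variants=variants)


# ---------------------------------------------------------------------------
# single-nucleus counts


def _gene_table(n_genes: int) -> pd.DataFrame:
    """Gene names with small mitochondrial/ribosomal/hemoglobin sets."""
    if n_genes < 30:
        raise ValueError("need at least 30 genes to carry the QC gene sets")
    mito = [f"MT-G{i + 1}" for i in range(8)]
    ribo = [f"RPS{i + 1}" for i in range(4)] + [f"RPL{i + 1}" for i in range(4)]
    hgb = ["HBA1", "HBB"]
    rest = [f"G{i + 1:04d}" for i in range(n_genes - len(mito) - len(ribo) - len(hgb))]
    names = mito + ribo + hgb + rest
    var = pd.DataFrame(index=pd.Index(names, name="gene"))
    var["mito"] = var.index.str.startswith("MT-")
    var["ribo"] = var.index.str.startswith(("RPS", "RPL"))
    var["hemoglobin"] = var.index.str.startswith("HB")
    return var


def sim_cells(
    config: SimConfig,
    subpop_fraction_by_condition: dict[str, float] | None = None,
    qc_violation_frac: float = 0.0,
    case_donor_fraction: float = DEFAULT_CASE_DONOR_FRACTION,
    geno: GenotypeMatrix | None = None,
    eqtl_effects: pd.DataFrame | None = None,
    mean_umi: float = 3000.0,
) -> ad.AnnData:
    """Negative-binomial single-nucleus counts with a planted subpopulation.

    Each donor carries one condition; a designated subpopulation has a
    distinct mean expression profile and appears with condition-dependent
    frequency ``subpop_fraction_by_condition`` (default: absent). A fraction
    ``qc_violation_frac`` of cells is corrupted to violate QC rules (half
    with very few detected genes, half with a high mitochondrial share);
    their true status is recorded in ``obs['qc_violation']``. If ``geno``
    and ``eqtl_effects`` (columns gene, variant, beta) are given, per-donor
    gene means are scaled by ``exp(beta * (dosage - 1))``, planting additive
    cis effects on the log scale.
    """
    if subpop_fraction_by_condition is None:
        subpop_fraction_by_condition = {CONDITION_A: 0.0, CONDITION_B: 0.0}
    for cond, frac in subpop_fraction_by_condition.items():
        if not 0 <= frac <= 1:
            raise ValueError(f"subpopulation fraction for {cond} outside [0, 1]")
    if not 0 <= qc_violation_frac < 1:
        raise ValueError("qc_violation_frac must lie in [0, 1)")

    rng = np.random.default_rng(config.seed + 1)
    donors = geno.donors if geno is not None else _donor_ids(config.n_donors)
    n_donors = len(donors)
    n_cases = int(round(case_donor_fraction * n_donors))
    conditions = np.array([CONDITION_A] * n_cases + [CONDITION_B] * (n_donors - n_cases))
    rng.shuffle(conditions)

    var = _gene_table(config.n_genes)
    n_genes = len(var)

    # baseline relative expression; housekeeping sets pinned so a healthy
    # cell sits at ~2% mito, ~2% ribo, ~0.001% hemoglobin (nuclei carry
    # essentially no hemoglobin message; the QC threshold is 0.1%)
    rel = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    rel[var["mito"].to_numpy()] = 0.02 / var["mito"].sum()
    rel[var["ribo"].to_numpy()] = 0.02 / var["ribo"].sum()
    rel[var["hemoglobin"].to_numpy()] = 0.00001 / var["hemoglobin"].sum()
    body = ~(var["mito"] | var["ribo"] | var["hemoglobin"]).to_numpy()
    rel[body] *= 0.9599 / rel[body].sum()
    base_mean = mean_umi * rel / rel.sum()

    # the subpopulation is a distinct cell state: a random fifth of the
    # body genes shifted up or down four-fold
    sub_mean = base_mean.copy()
    shifted = rng.random(n_genes) < 0.2
    shifted &= body
    updown = np.where(rng.random(n_genes) < 0.5, 4.0, 0.25)
    sub_mean[shifted] = sub_mean[shifted] * updown[shifted]
    sub_mean *= base_mean.sum() / sub_mean.sum()

    theta = rng.lognormal(mean=np.log(10.0), sigma=0.5, size=n_genes)

    # per-donor eQTL scaling
    donor_scale = np.ones((n_donors, n_genes))
    if eqtl_effects is not None:
        if geno is None:
            raise ValueError("eqtl_effects requires genotypes")
        gene_pos = {g: i for i, g in enumerate(var.index)}
        for row in eqtl_effects.itertuples(index=False):
            dose = geno.dosages[row.variant].to_numpy(float)
            dose = np.nan_to_num(dose, nan=1.0)
            donor_scale[:, gene_pos[row.gene]] *= np.exp(row.beta * (dose - 1.0))

    blocks, obs_rows = [], []
    cell_counter = 0
    for d_idx, donor in enumerate(donors):
        n_cells = int(rng.integers(config.n_cells_per_donor[0], config.n_cells_per_donor[1] + 1))
        if n_cells == 0:
            raise ValueError("zero cells requested for a donor")
        cond = conditions[d_idx]
        sub_frac = subpop_fraction_by_condition.get(cond, 0.0)
        is_sub = rng.random(n_cells) < sub_frac
        lib = rng.lognormal(mean=0.0, sigma=0.3, size=n_cells)

        mu = np.where(is_sub[:, None], sub_mean[None, :], base_mean[None, :])
        mu = mu * donor_scale[d_idx][None, :] * lib[:, None]
        lam = rng.gamma(shape=theta[None, :], scale=mu / theta[None, :])
        counts = rng.poisson(lam).astype(np.int32)

        is_bad = rng.random(n_cells) < qc_violation_frac
        bad_idx = np.flatnonzero(is_bad)
        for i, ci in enumerate(bad_idx):
            if i % 2 == 0:
                # low-complexity cell: keep a handful of genes
                keep = rng.choice(n_genes, size=25, replace=False)
                mask = np.zeros(n_genes, dtype=bool)
                mask[keep] = True
                counts[ci, ~mask] = 0
            else:
                # dying cell: mitochondrial reads swamp the library
                tot = counts[ci].sum()
                mito_idx = np.flatnonzero(var["mito"].to_numpy())
                counts[ci, mito_idx] += rng.multinomial(
                    int(0.25 * max(tot, 200)), np.ones(len(mito_idx)) / len(mito_idx)
                )

        blocks.append(sp.csr_matrix(counts))
        for i in range(n_cells):
            obs_rows.append(
                {
                    "cell": f"C{cell_counter + i + 1:07d}",
                    "donor": donor,
                    "condition": cond,
                    "subpop": bool(is_sub[i]),
                    "qc_violation": bool(is_bad[i]),
                }
            )
        cell_counter += n_cells

    X = sp.vstack(blocks).tocsr()
    obs = pd.DataFrame(obs_rows).set_index("cell")
    adata = ad.AnnData(X=X, obs=obs, var=var.copy())
    adata.uns["condition_a"] = CONDITION_A
    return adata


# ---------------------------------------------------------------------------
# mediation trios


@dataclass
class TrioScenario:
    """Generative model for one (L, G, T) trio.

    ``kind`` selects the wiring: ``causal`` (L -> G -> T), ``reactive``
    (L -> T -> G), ``independent`` (L -> G and L -> T with no G-T edge), or
    ``confounded`` (a latent C drives both G and T). Slopes are standardized
    effects; all noise is Gaussian with ``noise_sd``.
    """

    kind: str = "causal"
    beta_LG: float = 0.5
    beta_GT: float = 0.5
    beta_LT_direct: float = 0.0
    beta_conf: float = 0.5
    n: int = 500
    maf: float = 0.3
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        kinds = {"causal", "reactive", "independent", "confounded"}
        if self.kind not in kinds:
            raise ValueError(f"unknown scenario kind {self.kind!r}; one of {sorted(kinds)}")
        if self.kind == "causal" and self.beta_LT_direct != 0:
            raise ValueError("causal scenario requires beta_LT_direct = 0")
        if self.kind == "independent" and self.beta_GT != 0:
            raise ValueError("independent scenario requires beta_GT = 0")
        if self.n < 10:
            raise ValueError("n must be at least 10")
        if not 0 < self.maf <= 0.5:
            raise ValueError("maf must lie in (0, 0.5]")


def sim_trio(scenario: TrioScenario) -> TrioData:
    """Draw one trio under the scenario's generative model."""
    rng = np.random.default_rng(scenario.seed)
    s = scenario
    L = rng.binomial(2, s.maf, size=s.n).astype(float)
    e = lambda: rng.normal(0.0, s.noise_sd, size=s.n)  # noqa: E731
    if s.kind == "causal":
        G = s.beta_LG * L + e()
        T = s.beta_GT * G + e()
    elif s.kind == "reactive":
        T = s.beta_LT_direct * L + e()
        G = s.beta_GT * T + e()
    elif s.kind == "independent":
        G = s.beta_LG * L + e()
        T = s.beta_LT_direct * L + e()
    else:  # confounded
        C = rng.normal(size=s.n)
        G = s.beta_LG * L + s.beta_conf * C + e()
        T = s.beta_LT_direct * L + s.beta_conf * C + e()
    return TrioData(
        L=L, G=G, T=T, donor_ids=_donor_ids(s.n), scenario=s.kind
    )


# ---------------------------------------------------------------------------
# paired summary tracks


def _marginal_ols_tracks(dosages: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant simple-regression slope and standard error (vectorized)."""
    n = len(y)
    xc = dosages - dosages.mean(axis=0)
    yc = y - y.mean()
    sxx = (xc**2).sum(axis=0)
    beta = xc.T @ yc / sxx
    rss = (yc**2).sum() - beta**2 * sxx
    se = np.sqrt(rss / (n - 2) / sxx)
    return beta, se


def sim_gwas_pair(
    shared: bool,
    region_size: int,
    causal_index: int,
    config: SimConfig,
    causal_index2: int | None = None,
    case_fraction: float = 0.087,
) -> tuple[SummaryTrack, SummaryTrack]:
    """Two summary-statistic tracks over a shared genotype panel.

    Track 1 is a quantitative trait (per-variant OLS beta/se); track 2 is
    case-control, with cases called by thresholding a Gaussian liability at
    the requested ``case_fraction`` and per-variant effects fit by logistic
    regression. ``shared=True`` plants one causal variant for both traits;
    otherwise the second trait's causal variant defaults to the position
    half a region away.
    """
    if region_size < 2:
        raise ValueError("region_size must be at least 2 (H3 undefined otherwise)")
    if not 0 <= causal_index < region_size:
        raise ValueError("causal_index outside the region")

    panel_cfg = SimConfig(
        n_donors=config.n_donors,
        n_variants=region_size,
        maf_range=config.maf_range,
        ld_decay=config.ld_decay,
        seed=config.seed,
    )
    geno = sim_genotypes(panel_cfg)
    dos = geno.dosages.to_numpy()
    rng = np.random.default_rng(config.seed + 7)
    n = dos.shape[0]

    if shared:
        c2 = causal_index
    else:
        c2 = causal_index2 if causal_index2 is not None else (causal_index + region_size // 2) % region_size
        if c2 == causal_index:
            raise ValueError("distinct-causal simulation needs two different variants")

    x1 = (dos[:, causal_index] - dos[:, causal_index].mean())
    x1 = x1 / max(x1.std(), 1e-12)
    y1 = config.effect_size * x1 + rng.normal(0, config.noise_sd, n)
    beta1, se1 = _marginal_ols_tracks(dos, y1)

    x2 = (dos[:, c2] - dos[:, c2].mean())
    x2 = x2 / max(x2.std(), 1e-12)
    liab = config.effect_size * x2 + rng.normal(0, config.noise_sd, n)
    cases = (liab >= np.quantile(liab, 1.0 - case_fraction)).astype(float)

    import statsmodels.api as sm

    beta2 = np.empty(region_size)
    se2 = np.empty(region_size)
    for j in range(region_size):
        X = sm.add_constant(dos[:, j])
        try:
            fit = sm.Logit(cases, X).fit(disp=0, maxiter=100)
            beta2[j], se2[j] = fit.params[1], fit.bse[1]
        except Exception:
            beta2[j], se2[j] = 0.0, np.inf

    freqs = dos.mean(axis=0) / 2.0
    maf = np.minimum(freqs, 1.0 - freqs)
    maf = np.clip(maf, 1e-4, 0.5)
    from scipy import stats as _st

    common = {"variant": geno.variants["variant"], "maf": maf, "n": n}
    t1 = SummaryTrack(
        pd.DataFrame(
            {**common, "beta": beta1, "se": se1,
             "p": 2 * _st.t.sf(np.abs(beta1 / se1), n - 2)}
        ),
        n=n, name="expression",
    )
    z2 = np.where(np.isfinite(se2), beta2 / np.where(se2 > 0, se2, np.inf), 0.0)
    t2 = SummaryTrack(
        pd.DataFrame(
            {**common, "beta": beta2, "se": se2,
             "p": 2 * _st.norm.sf(np.abs(z2))}
        ),
        n=n, case_fraction=case_fraction, name="disease",
    )
    return t1, t2


# ---------------------------------------------------------------------------
# donor traits


@dataclass
class DonorTable:
    """Donor-level traits plus a longitudinal measurement series."""

    donors: pd.DataFrame
    measurements: pd.DataFrame = field(repr=False)


DEFAULT_COVARIATE_BETAS = {"age": 0.03, "sex": 0.3, "education": -0.05}


def sim_donor_traits(
    geno: GenotypeMatrix,
    main_beta: float,
    interaction_beta: float,
    pathology_model: str = "quantitative",
    seed: int = 0,
    variant: str | None = None,
    noise_sd: float = 1.0,
    covariate_betas: dict[str, float] | None = None,
) -> DonorTable:
    """Quantitative donor trait with genotype and pathology-interaction effects.

    trait = covariate effects + main_beta * dosage
          + interaction_beta * dosage * pathology + Gaussian noise.

    ``pathology_model`` is ``"quantitative"`` (gamma-distributed burden, as
    for amyloid or tangle density) or ``"semiquantitative"`` (integer stages
    0-6, as for Braak staging). The measurement series carries 1-4
    timestamped values per donor (days before death) for the windowed
    last-measurement selection.
    """
    if pathology_model not in {"quantitative", "semiquantitative"}:
        raise ValueError("pathology_model must be quantitative or semiquantitative")
    if covariate_betas is None:
        covariate_betas = dict(DEFAULT_COVARIATE_BETAS)
    rng = np.random.default_rng(seed)
    donors = geno.donors
    n = len(donors)
    vid = variant if variant is not None else geno.variants["variant"].iloc[0]
    dosage = geno.dosages[vid].to_numpy(float)

    age = rng.normal(85.0, 6.0, n)
    sex = rng.integers(0, 2, n).astype(float)
    education = np.round(rng.normal(16.0, 2.5, n))
    if pathology_model == "quantitative":
        pathology = rng.gamma(2.0, 2.0, n) * (rng.random(n) > 0.15)
    else:
        pathology = rng.integers(0, 7, n).astype(float)

    trait = (
        covariate_betas.get("age", 0.0) * (age - 85.0)
        + covariate_betas.get("sex", 0.0) * sex
        + covariate_betas.get("education", 0.0) * (education - 16.0)
        + main_beta * np.nan_to_num(dosage, nan=1.0)
        + interaction_beta * np.nan_to_num(dosage, nan=1.0) * pathology
        + rng.normal(0.0, noise_sd, n)
    )

    donor_df = pd.DataFrame(
        {
            "donor": donors,
            "dosage": dosage,
            "age": age,
            "sex": sex,
            "education": education,
            "pathology": pathology,
            "trait": trait,
        }
    )

    rows = []
    for i, d in enumerate(donors):
        n_meas = int(rng.integers(1, 5))
        days = np.sort(rng.integers(0, 2200, size=n_meas))
        for day in days:
            rows.append(
                {
                    "donor": d,
                    "measurement": "trait",
                    "value": trait[i] + rng.normal(0.0, 0.05 * noise_sd),
                    "days_before_death": int(day),
                }
            )
    return DonorTable(donors=donor_df, measurements=pd.DataFrame(rows))
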