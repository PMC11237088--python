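"""Variant QC, pseudobulk construction, cis-eQTL mapping, and conditional FDR.

Single-nucleus counts are library-size normalized (size factors scaled to
unit mean, log1p transform), averaged per donor within one cell type, and
regressed on alt-allele dosage with fixed covariates and expression
principal components. Variants pass QC at MAF >= 0.05, missing call rate
<= 0.1 and Hardy-Weinberg exact p >= 1e-6, and are LD-pruned greedily by
position at r^2 > 0.8 before testing. Significance uses the conditional
false discovery rate: primary p-values are conditioned on auxiliary
p-values for the same gene-variant pairs from an external study, boosting
power where signals are shared.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .io import GenotypeMatrix

__all__ = [
    "EqtlConfig",
    "normalize_cells",
    "aggregate_pseudobulk",
    "hwe_exact_test",
    "variant_qc",
    "ld_prune",
    "expression_pcs",
    "map_cis_eqtl",
    "test_interaction",
    "conditional_fdr",
]


@dataclass
class EqtlConfig:
    cis_window: int = 250_000
    n_expression_pcs: int = 20
    covariate_names: tuple[str, ...] = ("age", "sex", "race", "disease_status")
    ld_r2_threshold: float = 0.8
    fdr_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.cis_window <= 0:
            raise ValueError("cis_window must be positive")


# ---------------------------------------------------------------------------
# normalization and pseudobulk


def normalize_cells(adata: ad.AnnData) -> ad.AnnData:
    """Library-size normalization with unit-mean size factors.

    size factor = total counts / mean(total counts); the normalized value is
    log(1 + count / size factor). Factors are stored in
    ``obs['size_factor']`` and the scheme name in ``uns``.
    """
    X = adata.X
    total = np.asarray(X.sum(axis=1)).ravel()
    zero = np.flatnonzero(total == 0)
    if zero.size:
        raise ValueError(f"all-zero cell(s): {list(adata.obs_names[zero[:5]])}")
    sf = total / total.mean()
    out = adata.copy()
    if sp.issparse(X):
        scaled = sp.diags(1.0 / sf) @ X.tocsr()
        scaled.data = np.log1p(scaled.data)
        out.X = scaled
    else:
        out.X = np.log1p(np.asarray(X) / sf[:, None])
    out.obs["size_factor"] = sf
    out.uns["normalization"] = "library-size factors (unit mean), log1p"
    return out


def aggregate_pseudobulk(
    adata: ad.AnnData,
    cell_type: str | None = None,
    cell_type_col: str = "cell_type",
    donor_col: str = "donor",
) -> pd.DataFrame:
    """Donor x gene matrix of mean normalized expression for one cell type.

    Donors with zero cells of the type are excluded (listed in
    ``df.attrs['excluded_donors']``), never imputed. ``cell_type=None``
    aggregates over all cells.
    """
    if cell_type is not None:
        if cell_type_col not in adata.obs.columns:
            raise ValueError(f"obs lacks a {cell_type_col!r} column")
        known = set(adata.obs[cell_type_col].unique())
        if cell_type not in known:
            raise ValueError(f"unknown cell type {cell_type!r}; known: {sorted(known)}")
        sub = adata[(adata.obs[cell_type_col] == cell_type).to_numpy()]
    else:
        sub = adata
    donors = sub.obs[donor_col].to_numpy()
    uniq = sorted(pd.unique(donors))
    X = sub.X
    rows = []
    for d in uniq:
        mask = donors == d
        rows.append(np.asarray(X[mask].mean(axis=0)).ravel())
    pb = pd.DataFrame(rows, index=pd.Index(uniq, name="donor"), columns=sub.var_names)
    all_donors = pd.unique(adata.obs[donor_col])
    pb.attrs["excluded_donors"] = sorted(set(all_donors) - set(uniq))
    pb.attrs["cell_type"] = cell_type
    return pb


# ---------------------------------------------------------------------------
# variant QC


def hwe_exact_test(hom_ref: int, het: int, hom_alt: int) -> float:
    """Exact Hardy-Weinberg test p-value.

    Conditional on the observed allele counts, the p-value sums the
    probabilities of all heterozygote counts whose HWE probability does not
    exceed that of the observed configuration.
    """
    if min(hom_ref, het, hom_alt) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = hom_ref + het + hom_alt
    if n < 1:
        raise ValueError("at least one genotype required")
    n_alt = 2 * hom_alt + het
    n_ref = 2 * hom_ref + het
    rare = min(n_alt, n_ref)

    # enumerate all heterozygote counts with the parity of the rare allele
    hets = np.arange(rare % 2, rare + 1, 2)
    # log P(het = h | n, rare) via log-factorials
    from scipy.special import gammaln

    hom_rare = (rare - hets) // 2
    hom_common = n - hets - hom_rare
    logp = (
        gammaln(n + 1)
        - gammaln(hom_rare + 1)
        - gammaln(hets + 1)
        - gammaln(hom_common + 1)
        + hets * np.log(2.0)
        + gammaln(rare + 1)
        + gammaln(2 * n - rare + 1)
        - gammaln(2 * n + 1)
    )
    p_all = np.exp(logp - logp.max())
    p_all = p_all / p_all.sum()
    p_obs = p_all[hets == het]
    if p_obs.size == 0:
        raise ValueError("heterozygote count inconsistent with allele counts")
    return float(min(p_all[p_all <= p_obs[0] * (1 + 1e-12)].sum(), 1.0))


def variant_qc(
    geno: GenotypeMatrix,
    maf_min: float = 0.05,
    max_missing: float = 0.1,
    hwe_min_p: float = 1e-6,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Per-variant MAF / missingness / HWE statistics and filtering.

    Returns the genotype matrix restricted to passing variants plus a record
    table carrying all three statistics for every variant. An all-missing
    variant is removed with ``missing_rate`` 1 and no numeric error.
    """
    dos = geno.dosages.to_numpy()
    n = dos.shape[0]
    records = []
    for j, vid in enumerate(geno.dosages.columns):
        col = dos[:, j]
        obs = col[np.isfinite(col)]
        missing_rate = 1.0 - obs.size / n
        if obs.size == 0:
            records.append(
                {"variant": vid, "maf": np.nan, "missing_rate": 1.0,
                 "hwe_p": np.nan, "pass_qc": False}
            )
            continue
        freq = obs.mean() / 2.0
        maf = min(freq, 1.0 - freq)
        counts = [(obs == g).sum() for g in (0.0, 1.0, 2.0)]
        hwe_p = hwe_exact_test(*counts)
        ok = (maf >= maf_min) and (missing_rate <= max_missing) and (hwe_p >= hwe_min_p)
        records.append(
            {"variant": vid, "maf": maf, "missing_rate": missing_rate,
             "hwe_p": hwe_p, "pass_qc": bool(ok)}
        )
    rec = pd.DataFrame(records)
    kept = rec.loc[rec["pass_qc"], "variant"].tolist()
    return geno.subset_variants(kept), rec


def ld_prune(
    geno: GenotypeMatrix,
    r2_threshold: float = 0.8,
    window: int = 250_000,
) -> list[str]:
    """Greedy position-ordered LD pruning.

    Scanning variants by position, a variant is dropped when its dosage r^2
    with any already-kept variant within ``window`` bp exceeds the
    threshold. Deterministic: the first variant by position of a correlated
    pair is kept.
    """
    order = geno.variants.sort_values(["chrom", "pos"], kind="stable")
    kept: list[tuple[str, str, int]] = []  # (variant, chrom, pos)
    dos = geno.dosages
    for rec in order.itertuples(index=False):
        x = dos[rec.variant].to_numpy(float)
        drop = False
        for kvid, kchrom, kpos in reversed(kept):
            if kchrom != rec.chrom or rec.pos - kpos > window:
                break
            y = dos[kvid].to_numpy(float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3:
                continue
            xo, yo = x[ok], y[ok]
            if xo.std() == 0 or yo.std() == 0:
                continue
            r = np.corrcoef(xo, yo)[0, 1]
            if r * r > r2_threshold:
                drop = True
                break
        if not drop:
            kept.append((rec.variant, rec.chrom, rec.pos))
    return [v for v, _, _ in kept]


# ---------------------------------------------------------------------------
# covariates and association model


def expression_pcs(pb: pd.DataFrame, k: int) -> pd.DataFrame:
    """Top-k principal components of the donor x gene pseudobulk matrix.

    Genes are centered and scaled to unit variance (constant genes dropped
    with a warning). Sign convention: each component's largest-magnitude
    gene loading is made positive, so repeated runs are byte-identical.
    """
    n, g = pb.shape
    if k >= min(n, g):
        raise ValueError(f"k={k} must be below min(donors, genes)={min(n, g)}")
    X = pb.to_numpy(float)
    sd = X.std(axis=0, ddof=0)
    const = sd == 0
    if const.any():
        warnings.warn(f"dropping {const.sum()} constant gene(s) before scaling", stacklevel=2)
        X = X[:, ~const]
        sd = sd[~const]
    Z = (X - X[:, :].mean(axis=0)) / sd
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    scores = U[:, :k] * S[:k]
    for j in range(k):
        i_max = np.argmax(np.abs(Vt[j]))
        if Vt[j, i_max] < 0:
            scores[:, j] *= -1
    return pd.DataFrame(
        scores, index=pb.index, columns=[f"PC{j + 1}" for j in range(k)]
    )


def _ols_dosage_test(y: np.ndarray, dose: np.ndarray, covar: np.ndarray) -> dict | None:
    """OLS of y on [1, dose, covar]; t-test on the dosage slope."""
    ok = np.isfinite(dose) & np.isfinite(y)
    y, dose, covar = y[ok], dose[ok], covar[ok]
    n = len(y)
    if n < 3 or np.ptp(dose) == 0:
        return None
    X = np.column_stack([np.ones(n), dose, covar])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        return None
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = n - X.shape[1]
    if df <= 0:
        return None
    sigma2 = resid @ resid / df
    XtX_inv = np.linalg.inv(X.T @ X)
    se = float(np.sqrt(sigma2 * XtX_inv[1, 1]))
    t = float(beta[1] / se) if se > 0 else np.inf
    p = float(2 * stats.t.sf(abs(t), df))
    return {"beta": float(beta[1]), "se": se, "t": t, "p": max(p, 1e-300), "n": n}


def map_cis_eqtl(
    pb: pd.DataFrame,
    geno: GenotypeMatrix,
    genes: pd.DataFrame,
    covars: pd.DataFrame | None = None,
    config: EqtlConfig | None = None,
    pcs: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Cis-eQTL linear model scan.

    For each gene, variants whose position lies within ``cis_window`` bp of
    the transcribed span (inclusive distance, 1-based coordinates) are
    tested by OLS of pseudobulk expression on dosage plus covariates plus
    expression PCs. ``genes`` needs columns gene_id, chrom, start, end.
    Pairs with a singular design are skipped with a reason code.
    """
    if config is None:
        config = EqtlConfig()
    donors = [d for d in pb.index if d in set(geno.donors)]
    pbd = pb.loc[donors]
    dosd = geno.dosages.loc[donors]

    if pcs is None and config.n_expression_pcs > 0:
        k = min(config.n_expression_pcs, min(pbd.shape) - 1)
        pcs = expression_pcs(pbd, k) if k > 0 else None
    covar_blocks = []
    if covars is not None:
        covar_blocks.append(covars.loc[donors].to_numpy(float))
    if pcs is not None:
        covar_blocks.append(pcs.loc[donors].to_numpy(float))
    covar = (
        np.hstack(covar_blocks) if covar_blocks else np.empty((len(donors), 0))
    )

    vtab = geno.variants.set_index("variant")
    results, skipped = [], []
    for grow in genes.itertuples(index=False):
        if grow.gene_id not in pbd.columns:
            continue
        y = pbd[grow.gene_id].to_numpy(float)
        near = vtab[
            (vtab["chrom"] == grow.chrom)
            & (vtab["pos"] >= grow.start - config.cis_window)
            & (vtab["pos"] <= grow.end + config.cis_window)
        ]
        for vid in near.index:
            fit = _ols_dosage_test(y, dosd[vid].to_numpy(float), covar)
            if fit is None:
                skipped.append({"gene": grow.gene_id, "variant": vid, "reason": "singular_design"})
                continue
            results.append({"gene": grow.gene_id, "variant": vid, **fit})
    df = pd.DataFrame(results, columns=["gene", "variant", "beta", "se", "t", "p", "n"])
    df.attrs["skipped"] = pd.DataFrame(skipped, columns=["gene", "variant", "reason"])
    return df


def test_interaction(
    expr: np.ndarray,
    dose: np.ndarray,
    diagnosis: np.ndarray,
    covars: np.ndarray | None = None,
) -> dict:
    """Diagnosis x dosage interaction test.

    Fits expression ~ dosage + diagnosis + dosage:diagnosis (+ covariates)
    and returns the interaction slope, its SE and two-sided p, plus the
    main dosage slope. ``diagnosis`` is a 0/1 label; both strata must be
    populated.
    """
    expr = np.asarray(expr, float)
    dose = np.asarray(dose, float)
    dx = np.asarray(diagnosis, float)
    ok = np.isfinite(expr) & np.isfinite(dose) & np.isfinite(dx)
    expr, dose, dx = expr[ok], dose[ok], dx[ok]
    if covars is not None:
        covars = np.asarray(covars, float)[ok]
    if (dx == 0).sum() == 0 or (dx == 1).sum() == 0:
        raise ValueError("both diagnosis strata must be represented")
    n = len(expr)
    cols = [np.ones(n), dose, dx, dose * dx]
    if covars is not None:
        cols.append(covars)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular interaction design (constant dosage in a stratum?)")
    beta, _, _, _ = np.linalg.lstsq(X, expr, rcond=None)
    resid = expr - X @ beta
    df = n - X.shape[1]
    sigma2 = resid @ resid / max(df, 1)
    XtX_inv = np.linalg.inv(X.T @ X)
    se_int = float(np.sqrt(sigma2 * XtX_inv[3, 3]))
    t = beta[3] / se_int if se_int > 0 else np.inf
    return {
        "beta_int": float(beta[3]),
        "se": se_int,
        "p": float(2 * stats.t.sf(abs(t), df)) if df > 0 else 0.0,
        "beta_dose": float(beta[1]),
    }


# ---------------------------------------------------------------------------
# conditional FDR


def conditional_fdr(primary_p: np.ndarray, aux_p: np.ndarray) -> np.ndarray:
    """Empirical conditional false discovery rate.

    For each pair i,

        cfdr_i = p_i * #{j: aux_j <= aux_i} / #{j: p_j <= p_i and aux_j <= aux_i}

    (pi0 conservatively 1), clipped at 1 and monotonized to be
    non-decreasing in p within groups of equal auxiliary p-value. With an
    uninformative (constant) auxiliary this reduces to p / ecdf(p). Empty
    input returns an empty array.
    """
    p = np.asarray(primary_p, float)
    a = np.asarray(aux_p, float)
    if p.shape != a.shape:
        raise ValueError("primary and auxiliary p-value vectors must align")
    n = p.size
    if n == 0:
        return np.empty(0)
    if ((p <= 0) | (p > 1)).any() or ((a <= 0) | (a > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")

    order_a = np.argsort(a, kind="stable")
    cfdr = np.empty(n)
    # count, for each i, aux <= aux_i and joint counts; O(n^2) worst case is
    # avoided by sweeping in aux order with a sorted structure over p
    a_sorted = a[order_a]
    n_aux_le = np.searchsorted(np.sort(a), a, side="right")

    import bisect

    seen_p: list[float] = []
    joint = np.empty(n, dtype=int)
    i = 0
    while i < n:
        # pull in all pairs with tied aux first so ties count symmetrically
        j = i
        while j < n and a_sorted[j] == a_sorted[i]:
            bisect.insort(seen_p, p[order_a[j]])
            j += 1
        for k in range(i, j):
            idx = order_a[k]
            joint[idx] = bisect.bisect_right(seen_p, p[idx])
        i = j

    cfdr = p * n_aux_le / np.maximum(joint, 1)
    cfdr = np.minimum(cfdr, 1.0)

    # monotonize within equal-aux groups: non-decreasing in p
    df = pd.DataFrame({"p": p, "a": a, "cfdr": cfdr, "i": np.arange(n)})
    for _, grp in df.groupby("a", sort=False):
        if len(grp) > 1:
            g = grp.sort_values("p", kind="stable")
            cfdr[g["i"].to_numpy()] = np.maximum.accumulate(g["cfdr"].to_numpy())
    return cfdr
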