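"""Donor-collapsed cluster-trait association and genotype-trait regression.

Nuclei are collapsed to donors (a donor belongs to a cluster if it
contributes at least one cell), then cluster membership is tested against
binary traits by Fisher's exact test (BH FDR across clusters) and against
quantitative traits by a permutation scheme: the observed member mean is
contrasted with the means of random donor subsets of the same size, and
the deviation quantified as a z-score. The module also provides the
generic set-overlap Fisher test, windowed selection of the last antemortem
measurement before death, and OLS genotype-trait association with optional
neuropathology interaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DonorMembership",
    "EnrichmentResult",
    "collapse_to_donors",
    "categorical_enrichment",
    "quantitative_enrichment",
    "set_overlap_enrichment",
    "last_measurement_before_death",
    "genotype_trait_assoc",
    "detection_share",
]


@dataclass
class DonorMembership:
    cluster: str | int
    members: set = field(repr=False)
    cohort: set = field(repr=False)

    def __post_init__(self) -> None:
        if not set(self.members) <= set(self.cohort):
            raise ValueError("members must be a subset of the cohort")


@dataclass
class EnrichmentResult:
    cluster: str | int
    trait: str
    statistic: float  # odds ratio (categorical) or z (quantitative)
    p: float
    fdr: float | None = None
    n_perm: int | None = None
    degenerate: bool = False
    p_normal: float | None = None  # z-derived p, alongside the empirical one


def collapse_to_donors(
    cell_meta: pd.DataFrame,
    cluster_col: str = "cluster",
    donor_col: str = "donor",
    min_cells: int = 1,
) -> dict:
    """One DonorMembership per cluster; a donor is a member when it
    contributes at least ``min_cells`` cells to the cluster."""
    cohort = set(cell_meta[donor_col].unique())
    memberships = {}
    counts = cell_meta.groupby([cluster_col, donor_col], observed=True).size()
    for cluster in cell_meta[cluster_col].unique():
        per_donor = counts.loc[cluster] if cluster in counts.index.get_level_values(0) else pd.Series(dtype=int)
        members = set(per_donor[per_donor >= min_cells].index)
        memberships[cluster] = DonorMembership(cluster=cluster, members=members, cohort=cohort)
    return memberships


def _haldane_or(table: np.ndarray) -> float:
    t = table.astype(float)
    if (t == 0).any():
        t = t + 0.5
    return float(t[0, 0] * t[1, 1] / (t[0, 1] * t[1, 0]))


def categorical_enrichment(
    memberships: dict,
    trait: pd.Series,
    trait_name: str = "trait",
) -> list[EnrichmentResult]:
    """Fisher exact test of cluster membership against a binary donor trait,
    BH-corrected across all clusters in the call."""
    results = []
    for cluster, mem in memberships.items():
        cohort = [d for d in mem.cohort if d in trait.index and pd.notna(trait.loc[d])]
        members = set(cohort) & mem.members
        non = set(cohort) - members
        if len(members) == 0 or len(non) == 0:
            results.append(
                EnrichmentResult(cluster=cluster, trait=trait_name, statistic=np.nan,
                                 p=1.0, degenerate=True)
            )
            continue
        tpos = {d for d in cohort if bool(trait.loc[d])}
        a = len(members & tpos)
        b = len(members - tpos)
        c = len(non & tpos)
        d = len(non - tpos)
        table = np.array([[a, b], [c, d]])
        _, p = stats.fisher_exact(table, alternative="two-sided")
        results.append(
            EnrichmentResult(cluster=cluster, trait=trait_name,
                             statistic=_haldane_or(table), p=float(p))
        )
    ps = [r.p for r in results]
    fdr = multipletests(ps, method="fdr_bh")[1]
    for r, f in zip(results, fdr):
        r.fdr = float(f)
    return results


def quantitative_enrichment(
    membership: DonorMembership,
    trait: pd.Series,
    n_perm: int = 10_000,
    seed: int = 0,
    trait_name: str = "trait",
) -> EnrichmentResult:
    """Permutation z-score for a quantitative donor trait.

    The observed statistic is the mean trait over member donors; the null is
    the distribution of means over random same-size donor subsets drawn
    without replacement from the cohort (exhaustive enumeration when the
    number of subsets is at most ``n_perm``). z = (obs - mean) / sd of the
    null; the two-sided empirical p uses the add-one estimator on the
    sampled path and the exact proportion on the exhaustive path.
    """
    trait = trait.dropna()
    cohort = sorted(d for d in membership.cohort if d in trait.index)
    members = [d for d in cohort if d in membership.members]
    m, n = len(members), len(cohort)
    if m < 2:
        raise ValueError("need at least 2 members with nonmissing trait")
    values = trait.loc[cohort].to_numpy(float)
    obs = trait.loc[members].mean()

    n_subsets = comb(n, m)
    if n_subsets <= n_perm:
        null = np.array([values[list(ix)].mean() for ix in combinations(range(n), m)])
        exhaustive = True
    else:
        rng = np.random.default_rng(seed)
        keys = rng.random((n_perm, n))
        idx = np.argpartition(keys, m - 1, axis=1)[:, :m]
        null = values[idx].mean(axis=1)
        exhaustive = False

    mu = null.mean()
    sd = null.std(ddof=0)
    if sd == 0:
        return EnrichmentResult(
            cluster=membership.cluster, trait=trait_name, statistic=0.0,
            p=1.0, n_perm=len(null), degenerate=True, p_normal=1.0,
        )
    z = (obs - mu) / sd
    dev = np.abs(null - mu)
    if exhaustive:
        p = float(np.mean(dev >= abs(obs - mu) * (1 - 1e-12)))
    else:
        p = float((1 + np.sum(dev >= abs(obs - mu))) / (len(null) + 1))
    return EnrichmentResult(
        cluster=membership.cluster, trait=trait_name, statistic=float(z),
        p=min(max(p, np.nextafter(0, 1)), 1.0), n_perm=len(null),
        p_normal=float(2 * stats.norm.sf(abs(z))),
    )


def set_overlap_enrichment(setA, setB, background) -> tuple[float, float]:
    """Two-sided Fisher exact test of the overlap of two gene sets over a
    background; returns (odds ratio with Haldane correction at zero cells,
    p-value)."""
    A, B, bg = set(setA), set(setB), set(background)
    if not (A | B) <= bg:
        raise ValueError("background must contain both sets")
    a = len(A & B)
    b = len(A - B)
    c = len(B - A)
    d = len(bg - A - B)
    table = np.array([[a, b], [c, d]])
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return _haldane_or(table), float(p)


def last_measurement_before_death(
    series: pd.DataFrame,
    window_days: int = 1095,
    donor_col: str = "donor",
    value_col: str = "value",
    days_col: str = "days_before_death",
) -> pd.Series:
    """Per donor, the measurement closest to death among those taken at most
    ``window_days`` before death (inclusive boundary). Donors with no
    qualifying measurement are absent from the result, never imputed."""
    if (series[days_col] < 0).any():
        raise ValueError("days before death must be nonnegative")
    ok = series[series[days_col] <= window_days]
    if ok.empty:
        return pd.Series(dtype=float, name=value_col)
    picked = ok.loc[ok.groupby(donor_col)[days_col].idxmin()]
    return picked.set_index(donor_col)[value_col]


def genotype_trait_assoc(
    dosage: np.ndarray,
    trait: np.ndarray,
    covariates: pd.DataFrame | None = None,
    interaction: np.ndarray | None = None,
    log_transform: bool = False,
) -> dict:
    """OLS association between allele dosage and a donor trait.

    With ``interaction`` (a neuropathology variable), the model gains
    pathology and dosage:pathology terms and the interaction slope is
    reported alongside the main effect. ``log_transform`` applies
    log(x + 1) to the pathology variable (for quantitative burdens such as
    amyloid or tangles; semiquantitative stages are used as numeric).
    """
    import statsmodels.api as sm

    dosage = np.asarray(dosage, float)
    trait = np.asarray(trait, float)
    parts = {"dosage": dosage}
    if covariates is not None:
        for c in covariates.columns:
            parts[c] = covariates[c].to_numpy(float)
    if interaction is not None:
        path = np.asarray(interaction, float)
        if log_transform:
            if (path < 0).any():
                raise ValueError("cannot log-transform negative pathology values")
            path = np.log1p(path)
        parts["pathology"] = path
        parts["dosage_x_pathology"] = dosage * path
    X = pd.DataFrame(parts)
    ok = np.isfinite(trait) & np.isfinite(X.to_numpy(float)).all(axis=1)
    X, y = X.loc[ok], trait[ok]
    if len(y) < 10:
        raise ValueError(f"need at least 10 complete cases, got {len(y)}")
    if np.ptp(X["dosage"]) == 0:
        raise ValueError("dosage is constant among complete cases")
    Xc = sm.add_constant(X)
    rank = np.linalg.matrix_rank(Xc.to_numpy(float))
    if rank < Xc.shape[1]:
        corr = Xc.drop(columns="const").corr().abs()
        np.fill_diagonal(corr.values, 0)
        worst = corr.stack().idxmax()
        raise ValueError(f"singular design; near-collinear columns: {list(worst)}")
    fit = sm.OLS(y, Xc).fit()
    out = {
        "beta": float(fit.params["dosage"]),
        "se": float(fit.bse["dosage"]),
        "p": float(fit.pvalues["dosage"]),
        "n": int(len(y)),
    }
    if interaction is not None:
        out["beta_int"] = float(fit.params["dosage_x_pathology"])
        out["se_int"] = float(fit.bse["dosage_x_pathology"])
        out["p_int"] = float(fit.pvalues["dosage_x_pathology"])
    return out


def detection_share(n_detected: int, n_total: int) -> float:
    """Percentage of subjects in which a cell population was detected."""
    if not 0 <= n_detected <= n_total or n_total == 0:
        raise ValueError("need 0 <= n_detected <= n_total with n_total > 0")
    return 100.0 * n_detected / n_total
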