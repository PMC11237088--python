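"""Causal inference test (CIT) for (locus L, mediator G, trait T) trios.

The test asks whether a mediator G (here: expression of a candidate causal
gene) transmits the effect of a genetic locus L onto a quantitative trait T
(here: expression of another gene). Four conditions must hold jointly:

1. L and G are associated,
2. L and T are associated,
3. L is associated with G given T,
4. L is independent of T given G.

Conditions 1-3 are ordinary nested-model F-tests. Condition 4 is an
equivalence-type test: the observed F statistic for L in ``T ~ G + L`` is
compared against a non-central F distribution whose noncentrality is the
conditional-model F implied by the *marginal* L-T association under the
no-mediation hypothesis (where all G-T correlation is induced by L, i.e.
r_GT = r_LT * r_LG, so the marginal effect survives conditioning on G up
to that attenuation). A small p4 then means the conditional L-T
association is significantly smaller than a direct L-T effect of the
observed marginal size could explain - evidence that G mediates. The
omnibus p-value is the intersection-union max of the four, and a
permutation scheme (permuting T across donors within each trio) supplies
a false discovery rate for a collection of trios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TrioData",
    "CitResult",
    "DegenerateTrioError",
    "cit_test",
    "cit_fdr",
    "build_downstream_network",
]


class DegenerateTrioError(ValueError):
    """Raised when a trio cannot support the test (e.g. G and T collinear)."""


@dataclass
class TrioData:
    """Aligned per-donor (L, G, T) vectors with optional covariates.

    L is an allele dosage in {0, 1, 2}; G and T are quantitative.
    """

    L: np.ndarray
    G: np.ndarray
    T: np.ndarray
    covariates: pd.DataFrame | None = None
    donor_ids: list[str] | None = None
    scenario: str | None = None

    def __post_init__(self) -> None:
        self.L = np.asarray(self.L, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        self.T = np.asarray(self.T, dtype=float)
        n = len(self.L)
        if len(self.G) != n or len(self.T) != n:
            raise ValueError("L, G, T must have equal length")
        if self.covariates is not None and len(self.covariates) != n:
            raise ValueError("covariates must align with L, G, T")

    def complete_cases(self) -> "TrioData":
        ok = np.isfinite(self.L) & np.isfinite(self.G) & np.isfinite(self.T)
        if self.covariates is not None:
            ok &= np.isfinite(self.covariates.to_numpy(float)).all(axis=1)
        if ok.all():
            return self
        return TrioData(
            L=self.L[ok],
            G=self.G[ok],
            T=self.T[ok],
            covariates=None if self.covariates is None else self.covariates.loc[ok].reset_index(drop=True),
            donor_ids=None if self.donor_ids is None else [d for d, k in zip(self.donor_ids, ok) if k],
            scenario=self.scenario,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"L": self.L, "G": self.G, "T": self.T})
        if self.donor_ids is not None:
            df.insert(0, "donor", self.donor_ids)
        if self.covariates is not None:
            df = pd.concat([df, self.covariates.reset_index(drop=True)], axis=1)
        return df


@dataclass
class CitResult:
    """Component p-values, omnibus p, and (after permutation) the q-value."""

    p1: float
    p2: float
    p3: float
    p4: float
    p_cit: float
    q: float | None = None
    call: str | None = None
    meta: dict = field(default_factory=dict)

    def row(self) -> dict:
        return {
            "p_LG": self.p1,
            "p_LT": self.p2,
            "p_LG_given_T": self.p3,
            "p_ind_LT_given_G": self.p4,
            "p_cit": self.p_cit,
            "q": self.q,
            "call": self.call,
        }


def _rss(y: np.ndarray, X: np.ndarray) -> tuple[float, int]:
    """Residual sum of squares and model rank from a least-squares fit."""
    beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if res.size:
        return float(res[0]), rank
    r = y - X @ beta
    return float(r @ r), rank


def _ftest_added(y: np.ndarray, X_reduced: np.ndarray, X_full: np.ndarray) -> tuple[float, float, int, int]:
    """F-test of the columns added in X_full over X_reduced; returns
    (F, p, df1, df2)."""
    rss_r, rank_r = _rss(y, X_reduced)
    rss_f, rank_f = _rss(y, X_full)
    df1 = rank_f - rank_r
    df2 = len(y) - rank_f
    if df1 <= 0 or df2 <= 0:
        raise DegenerateTrioError("test degrees of freedom are not positive")
    num = max(rss_r - rss_f, 0.0) / df1
    den = rss_f / df2
    if den <= 0:
        return np.inf, 0.0, df1, df2
    F = num / den
    return F, float(stats.f.sf(F, df1, df2)), df1, df2


def _implied_ncp(r_lt2: float, r_lg2: float, df2: int) -> float:
    """Noncentrality of the conditional L-T test implied by the marginal
    association under no mediation.

    If the marginal L-T effect is direct, the G-T correlation it induces is
    r_GT = r_LT * r_LG, and the population partial correlation of T and L
    given G becomes

        pr0^2 = r_LT^2 (1 - r_LG^2) / (1 - r_LT^2 r_LG^2),

    so the conditional F statistic is noncentral with ncp = df2 * pr0^2 /
    (1 - pr0^2). Comparing the observed conditional F against this
    distribution asks whether conditioning on G removed *more* of the L-T
    association than collinearity alone could.
    """
    pr0_sq = r_lt2 * (1.0 - r_lg2) / max(1.0 - r_lt2 * r_lg2, 1e-12)
    pr0_sq = min(pr0_sq, 1.0 - 1e-12)
    return max(df2 * pr0_sq / (1.0 - pr0_sq), 1e-12)


def _l_columns(L: np.ndarray, genotype_factor: bool) -> np.ndarray:
    """Dosage as one numeric column, or genotype as a 2-df factor."""
    if not genotype_factor:
        return L[:, None]
    cols = []
    for level in (1.0, 2.0):
        if (L == level).any():
            cols.append((L == level).astype(float))
    if not cols:
        raise DegenerateTrioError("L is constant")
    return np.column_stack(cols)


def cit_test(trio: TrioData, genotype_factor: bool = False) -> CitResult:
    """Run the four-condition causal inference test on one trio.

    Returns a :class:`CitResult` without a q-value; use :func:`cit_fdr` to
    attach permutation FDR values across a collection of trios.
    """
    trio = trio.complete_cases()
    n = len(trio.L)
    if n < 10:
        raise ValueError(f"need at least 10 complete cases, got {n}")
    if len(np.unique(trio.L)) < 2:
        raise DegenerateTrioError("L is constant")
    if np.ptp(trio.G) == 0 or np.ptp(trio.T) == 0:
        raise DegenerateTrioError("G and T must be nonconstant")
    r_gt = np.corrcoef(trio.G, trio.T)[0, 1]
    if abs(r_gt) >= 1.0 - 1e-12:
        raise DegenerateTrioError("G and T are perfectly collinear")

    ones = np.ones((n, 1))
    C = (
        np.empty((n, 0))
        if trio.covariates is None
        else trio.covariates.to_numpy(float)
    )
    Lc = _l_columns(trio.L, genotype_factor)
    G, T = trio.G, trio.T

    base = np.hstack([ones, C])
    # 1) L and G associated
    F_lg, p1, df1, df2_lg = _ftest_added(G, base, np.hstack([base, Lc]))
    # 2) L and T associated
    F_marg, p2, _, df2_marg = _ftest_added(T, base, np.hstack([base, Lc]))
    # 3) L associated with G, given T
    base_T = np.hstack([base, T[:, None]])
    _, p3, _, _ = _ftest_added(G, base_T, np.hstack([base_T, Lc]))
    # 4) equivalence test of L independent of T given G: observed F for L in
    #    T ~ G + L versus the non-central F implied by the marginal L-T
    #    association under no mediation
    base_G = np.hstack([base, G[:, None]])
    F_obs, _, df1_4, df2_4 = _ftest_added(T, base_G, np.hstack([base_G, Lc]))
    # (partial, given covariates) squared correlations from the F statistics
    r_lt2 = df1 * F_marg / (df1 * F_marg + df2_marg)
    r_lg2 = df1 * F_lg / (df1 * F_lg + df2_lg)
    ncp = _implied_ncp(r_lt2, r_lg2, df2_4)
    p4 = float(stats.ncf.cdf(F_obs, df1_4, df2_4, ncp))

    p_cit = max(p1, p2, p3, p4)
    return CitResult(p1=p1, p2=p2, p3=p3, p4=p4, p_cit=p_cit, meta={"n": n})


# ---------------------------------------------------------------------------
# permutation FDR


def _perm_components_fast(trio: TrioData, B: int, rng: np.random.Generator) -> np.ndarray:
    """Component p-values (B x 4) for B permutations of L (no covariates,
    numeric L). All four component tests reduce to (partial) correlations."""
    L, G, T = trio.L, trio.G, trio.T
    n = len(L)
    Lc = (L - L.mean()) / L.std()
    Gc = (G - G.mean()) / G.std()
    Tc = (T - T.mean()) / T.std()

    order = np.argsort(rng.random((B, n)), axis=1)
    Lp = Lc[order]  # B x n, each row a permutation of standardized L

    r_gt = float(Gc @ Tc) / n
    r_lg = (Lp @ Gc) / n
    r_lt = (Lp @ Tc) / n

    eps = 1e-12
    # p1: marginal L*-G
    F1 = (n - 2) * r_lg**2 / np.maximum(1 - r_lg**2, eps)
    p1 = stats.f.sf(F1, 1, n - 2)
    # p2: marginal L*-T
    F2 = (n - 2) * r_lt**2 / np.maximum(1 - r_lt**2, eps)
    p2 = stats.f.sf(F2, 1, n - 2)
    # p3: L* in G ~ L* + T  (partial corr of G, L* given T)
    pr3 = (r_lg - r_gt * r_lt) / np.sqrt(
        np.maximum((1 - r_gt**2) * (1 - r_lt**2), eps)
    )
    F3 = (n - 3) * pr3**2 / np.maximum(1 - pr3**2, eps)
    p3 = stats.f.sf(F3, 1, n - 3)
    # p4: F for L* in T ~ G + L* against the no-mediation-implied
    # non-central F (same construction as cit_test)
    pr4 = (r_lt - r_gt * r_lg) / np.sqrt(
        np.maximum((1 - r_gt**2) * (1 - r_lg**2), eps)
    )
    F4 = (n - 3) * pr4**2 / np.maximum(1 - pr4**2, eps)
    pr0_sq = r_lt**2 * (1 - r_lg**2) / np.maximum(1 - r_lt**2 * r_lg**2, eps)
    pr0_sq = np.minimum(pr0_sq, 1 - 1e-12)
    ncp = np.maximum((n - 3) * pr0_sq / (1 - pr0_sq), 1e-12)
    p4 = stats.ncf.cdf(F4, 1, n - 3, ncp)

    return np.column_stack([p1, p2, p3, p4])


def _perm_components_general(
    trio: TrioData, B: int, rng: np.random.Generator, genotype_factor: bool
) -> np.ndarray:
    out = np.empty((B, 4))
    for b in range(B):
        perm = rng.permutation(len(trio.L))
        t = TrioData(
            L=trio.L[perm], G=trio.G, T=trio.T, covariates=trio.covariates
        )
        try:
            r = cit_test(t, genotype_factor=genotype_factor)
            out[b] = (r.p1, r.p2, r.p3, r.p4)
        except DegenerateTrioError:
            out[b] = 1.0
    return out


def _pooled_q(p_obs: np.ndarray, p_perm_flat: np.ndarray, B: int) -> np.ndarray:
    """q(p) = pi0 * [mean over permutations of #{p* <= p}] / max(1, #{p_obs <= p}),
    clipped at 1 and monotonized to be non-decreasing in p.

    pi0 (the null fraction) is the Storey estimate #{p_obs > 1/2} / (N/2),
    clipped to [0, 1]; without it the estimator is conservative by 1/pi0
    when most of the collection carries true signal.
    """
    perm_sorted = np.sort(p_perm_flat)
    obs_sorted = np.sort(p_obs)
    pi0 = min(1.0, float(np.mean(p_obs > 0.5)) * 2.0)
    n_perm_le = np.searchsorted(perm_sorted, p_obs, side="right") / B
    n_obs_le = np.searchsorted(obs_sorted, p_obs, side="right")
    q = np.minimum(pi0 * n_perm_le / np.maximum(n_obs_le, 1), 1.0)
    # running minimum from the largest p downward (the usual q-value
    # monotonization): q is non-decreasing in p and never exceeds the raw
    # estimate at any larger p
    rev = np.argsort(p_obs, kind="stable")[::-1]
    q[rev] = np.minimum.accumulate(q[rev])
    return q


def cit_fdr(
    results: list[CitResult],
    trios: list[TrioData],
    B: int = 1000,
    seed: int = 0,
    fdr_threshold: float = 0.05,
    genotype_factor: bool = False,
) -> list[CitResult]:
    """Attach permutation q-values to a collection of CIT results.

    For each trio, the locus L is permuted across donors B times (making
    every component test null while preserving the G-T relationship) and
    the four component p-values recomputed. Each component's pooled
    permutation distribution yields

        q_j(p) = [mean over b of #{p*_j,b <= p}] / max(1, #{p_j,obs <= p}),

    clipped at 1 and monotonized to be non-decreasing in p; the omnibus
    q-value is the intersection-union max of the four component q-values.
    Trios with ``q < fdr_threshold`` are called causal.
    """
    if not trios:
        raise ValueError("need at least one trio")
    if len(results) != len(trios):
        raise ValueError("results and trios must align")
    if B < 100:
        warnings.warn(f"B={B} permutations gives unstable q-values", stacklevel=2)

    rng = np.random.default_rng(seed)
    n_trios = len(trios)
    perm_p = np.empty((n_trios, B, 4))
    for i, trio in enumerate(trios):
        t = trio.complete_cases()
        if t.covariates is None and not genotype_factor:
            perm_p[i] = _perm_components_fast(t, B, rng)
        else:
            perm_p[i] = _perm_components_general(t, B, rng, genotype_factor)

    comp_obs = np.array([[r.p1, r.p2, r.p3, r.p4] for r in results])
    q_comp = np.empty((n_trios, 4))
    for j in range(4):
        q_comp[:, j] = _pooled_q(comp_obs[:, j], perm_p[:, :, j].ravel(), B)
    q = q_comp.max(axis=1)

    out = []
    for r, qi in zip(results, q):
        out.append(
            CitResult(
                p1=r.p1, p2=r.p2, p3=r.p3, p4=r.p4, p_cit=r.p_cit,
                q=float(qi),
                call="causal" if qi < fdr_threshold else "not-called",
                meta=r.meta,
            )
        )
    return out


def build_downstream_network(
    L: np.ndarray,
    G: np.ndarray,
    candidates: pd.DataFrame,
    corr_threshold: float = 0.3,
    B: int = 1000,
    seed: int = 0,
    covariates: pd.DataFrame | None = None,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Screen candidate downstream genes of a mediator G.

    ``candidates`` is a donors x genes expression table. Candidates whose
    |correlation| with G falls below ``corr_threshold`` are not tested. Each
    surviving gene is submitted as the trait T of a trio (L, G, T); the
    permutation FDR is computed across all tested genes, and genes with
    q < ``fdr_threshold`` form the downstream set.
    """
    L = np.asarray(L, float)
    G = np.asarray(G, float)
    rows = []
    trios, results = [], []
    for gene in candidates.columns:
        T = candidates[gene].to_numpy(float)
        r = np.corrcoef(G, T)[0, 1] if np.ptp(T) > 0 else np.nan
        if not np.isfinite(r) or abs(r) < corr_threshold:
            rows.append({"gene": gene, "corr_with_G": r, "status": "prefiltered"})
            continue
        trio = TrioData(L=L, G=G, T=T, covariates=covariates)
        try:
            res = cit_test(trio)
        except DegenerateTrioError as exc:
            rows.append({"gene": gene, "corr_with_G": r, "status": f"degenerate: {exc}"})
            continue
        trios.append((gene, r, trio))
        results.append(res)

    if results:
        results = cit_fdr(
            results, [t for _, _, t in trios], B=B, seed=seed,
            fdr_threshold=fdr_threshold,
        )
        for (gene, r, _), res in zip(trios, results):
            rows.append(
                {"gene": gene, "corr_with_G": r, "status": "tested", **res.row()}
            )
    df = pd.DataFrame(rows)
    if "q" in df.columns:
        df["downstream"] = (df["status"] == "tested") & (df["q"] < fdr_threshold)
        df = df.sort_values(
            ["downstream", "q", "p_cit"], ascending=[False, True, True]
        ).reset_index(drop=True)
    else:
        df["downstream"] = False
    return df
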