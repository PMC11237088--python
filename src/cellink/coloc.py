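"""Approximate-Bayes-factor colocalization of two association tracks.

Given per-variant summary statistics for two traits over one region, the
module computes Wakefield approximate Bayes factors per variant and the
posterior probabilities of the five standard hypotheses:

* H0 - no association with either trait,
* H1 / H2 - association with one trait only,
* H3 - both traits associated, distinct causal variants,
* H4 - both traits associated, one shared causal variant.

All sums over variants are accumulated in log space so that regions with a
thousand or more strongly associated variants do not overflow. Under H4 a
per-variant posterior identifies the most likely shared causal variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import norm

__all__ = [
    "SummaryTrack",
    "ColocResult",
    "compute_labf",
    "colocalize",
    "DEFAULT_PRIORS",
]

#: default prior probabilities that a variant is causal for trait 1 only,
#: trait 2 only, or both (the cited method's defaults).
DEFAULT_PRIORS = {"p1": 1e-4, "p2": 1e-4, "p12": 1e-5}

#: default prior effect variance W: sd 0.15 for a quantitative trait,
#: sd 0.2 on the log-odds scale for a case-control trait.
DEFAULT_W = {"quantitative": 0.15**2, "case_control": 0.2**2}


@dataclass
class SummaryTrack:
    """Per-variant association statistics for one trait over one region.

    ``table`` needs a ``variant`` column and, per variant, either
    (``beta``, ``se``) or (``p``, ``maf``, ``n``). ``case_fraction`` being
    set marks the trait as case-control; its sampling-variance approximation
    then divides by s(1-s).
    """

    table: pd.DataFrame
    n: float | None = None
    case_fraction: float | None = None
    trait_type: str = "quantitative"
    name: str = "trait"

    def __post_init__(self) -> None:
        if self.case_fraction is not None:
            self.trait_type = "case_control"
        cols = self.table.columns
        if "variant" not in cols:
            raise ValueError("summary track requires a 'variant' column")
        has_beta_se = {"beta", "se"}.issubset(cols)
        has_p = {"p", "maf"}.issubset(cols) and (
            "n" in cols or self.n is not None
        )
        if not (has_beta_se or has_p):
            raise ValueError(
                "each variant needs (beta, se) or (p, maf, n) statistics"
            )
        if "maf" in cols:
            maf = self.table["maf"].to_numpy(float)
            bad = (maf <= 0) | (maf > 0.5)
            if bad.any():
                raise ValueError(
                    f"maf outside (0, 0.5] for variant(s) "
                    f"{list(self.table.loc[bad, 'variant'].head())}"
                )

    @property
    def variants(self) -> pd.Index:
        return pd.Index(self.table["variant"])


@dataclass
class ColocResult:
    """Posterior probabilities PP0..PP4 plus the per-variant H4 posterior."""

    pp: dict[str, float]
    per_variant: pd.Series = field(repr=False)
    n_variants: int = 0
    priors: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PRIORS))

    def to_frame(self) -> pd.DataFrame:
        row = {**self.pp, "n_variants": self.n_variants, **self.priors}
        return pd.DataFrame([row])


def _variance_approx(track: SummaryTrack) -> np.ndarray:
    """1/(2 N f (1-f)) sampling-variance approximation from (maf, n)."""
    tab = track.table
    maf = tab["maf"].to_numpy(float)
    n = tab["n"].to_numpy(float) if "n" in tab.columns else np.full(len(tab), track.n)
    V = 1.0 / (2.0 * n * maf * (1.0 - maf))
    if track.trait_type == "case_control":
        s = track.case_fraction
        if s is None or not 0 < s < 1:
            raise ValueError("case-control track requires case_fraction in (0,1)")
        V = V / (s * (1.0 - s))
    return V


def compute_labf(
    track: SummaryTrack,
    W: float | None = None,
    use_se: bool = True,
) -> np.ndarray:
    """Log approximate Bayes factor per variant.

    z = beta/se (or |z| back-computed from the two-sided p-value), V = se^2
    or the (maf, n) approximation, and

        lABF = 0.5 * [ ln(V / (V + W)) + z^2 * W / (V + W) ].

    ``use_se=False`` forces the sample-size variance approximation even when
    standard errors are present (mirrors summary tracks distributed without
    se).
    """
    if W is None:
        W = DEFAULT_W[track.trait_type]
    if W <= 0:
        raise ValueError("prior effect variance W must be positive")
    tab = track.table
    have_se = use_se and {"beta", "se"}.issubset(tab.columns)
    if have_se:
        se = tab["se"].to_numpy(float)
        if (se <= 0).any():
            bad = tab.loc[se <= 0, "variant"].tolist()
            raise ValueError(f"non-positive se for variant(s) {bad[:5]}")
        z = tab["beta"].to_numpy(float) / se
        V = se**2
    else:
        p = tab["p"].to_numpy(float)
        z = norm.isf(np.clip(p, 1e-300, 1.0) / 2.0)  # sign-free |z|
        V = _variance_approx(track)
    r = W / (V + W)
    return 0.5 * (np.log1p(-r) + z**2 * r)


def colocalize(
    track1: SummaryTrack,
    track2: SummaryTrack,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
    W1: float | None = None,
    W2: float | None = None,
    use_se: bool = True,
    _allow_single_variant: bool = False,
) -> ColocResult:
    """Five-hypothesis colocalization over the shared variant set.

    The intersection of the two variant sets is taken (in track1 order) and
    the unnormalized hypothesis weights are accumulated with log-sum-exp:

        h0 = 1,  h1 = p1*S1,  h2 = p2*S2,
        h3 = p1*p2*(S1*S2 - S12),  h4 = p12*S12,

    with S1 = sum exp(lABF1), S2 = sum exp(lABF2) and
    S12 = sum exp(lABF1 + lABF2).
    """
    shared = [v for v in track1.table["variant"] if v in set(track2.table["variant"])]
    if len(shared) < 2 and not _allow_single_variant:
        raise ValueError(
            f"only {len(shared)} shared variant(s); H3 requires at least 2"
        )
    t1 = SummaryTrack(
        track1.table.set_index("variant").loc[shared].reset_index(),
        n=track1.n, case_fraction=track1.case_fraction,
        trait_type=track1.trait_type, name=track1.name,
    )
    t2 = SummaryTrack(
        track2.table.set_index("variant").loc[shared].reset_index(),
        n=track2.n, case_fraction=track2.case_fraction,
        trait_type=track2.trait_type, name=track2.name,
    )
    l1 = compute_labf(t1, W=W1, use_se=use_se)
    l2 = compute_labf(t2, W=W2, use_se=use_se)

    logS1 = logsumexp(l1)
    logS2 = logsumexp(l2)
    logS12 = logsumexp(l1 + l2)

    log_h = np.empty(5)
    log_h[0] = 0.0
    log_h[1] = np.log(p1) + logS1
    log_h[2] = np.log(p2) + logS2
    # h3 = p1*p2*(S1*S2 - S12), stable via log1p of the ratio
    diff = logS12 - (logS1 + logS2)
    if diff >= 0:
        # S12 >= S1*S2 only from rounding (or a single variant): clip at 0
        log_h[3] = -np.inf
    else:
        log_h[3] = np.log(p1) + np.log(p2) + logS1 + logS2 + np.log1p(-np.exp(diff))
    log_h[4] = np.log(p12) + logS12

    log_total = logsumexp(log_h)
    pp = np.exp(log_h - log_total)
    per_variant = pd.Series(
        np.exp(l1 + l2 - logS12), index=pd.Index(shared, name="variant")
    )
    return ColocResult(
        pp={f"PP{i}": float(pp[i]) for i in range(5)},
        per_variant=per_variant,
        n_variants=len(shared),
        priors={"p1": p1, "p2": p2, "p12": p12},
    )
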