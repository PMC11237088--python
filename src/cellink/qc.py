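"""Cell-level quality filtering.

Nuclei are removed when they detect too few genes, when mitochondrial,
ribosomal or hemoglobin reads dominate the library, when library complexity
(log10 genes per log10 UMI) is low, or when total UMI falls outside a
data-driven window: a logistic CDF is fitted to the empirical CDF of
log10 UMI and the cutoffs placed ln(4) scale units either side of the
inflection point, i.e. at the 20th/80th points of the fitted curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "QcConfig",
    "SigmoidFit",
    "FilterReport",
    "fit_sigmoid_cutoffs",
    "compute_cell_stats",
    "apply_cell_filters",
    "RULE_ORDER",
]

LN4 = float(np.log(4.0))

#: fixed order in which rules claim a removed cell in the report
RULE_ORDER = (
    "gene_count",
    "mito",
    "ribo",
    "hemoglobin",
    "genes_per_umi",
    "umi_range",
)


@dataclass
class QcConfig:
    min_genes: int = 200
    max_mito_frac: float = 0.05
    max_ribo_frac: float = 0.05
    max_hemoglobin_frac: float = 0.001
    min_log10_genes_per_umi: float = 0.8
    sigmoid_scale_multiplier: float = LN4

    def __post_init__(self) -> None:
        for name in ("max_mito_frac", "max_ribo_frac", "max_hemoglobin_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.sigmoid_scale_multiplier <= 0:
            raise ValueError("sigmoid_scale_multiplier must be positive")


@dataclass
class SigmoidFit:
    """Fitted logistic CDF location/scale and the derived UMI cutoffs."""

    mu: float
    s: float
    lower_cutoff: float
    upper_cutoff: float
    converged: bool
    method: str = "logistic-cdf-least-squares"


@dataclass
class FilterReport:
    """Removal counts per rule (first failing rule claims each cell)."""

    n_input: int
    removed_by_rule: dict[str, int]
    retained_cells: list[str] = field(repr=False)
    thresholds: dict = field(default_factory=dict)
    first_fail: pd.Series | None = field(default=None, repr=False)

    @property
    def n_removed(self) -> int:
        return sum(self.removed_by_rule.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [{"rule": r, "n_removed": self.removed_by_rule.get(r, 0)} for r in RULE_ORDER]
        rows.append({"rule": "retained", "n_removed": len(self.retained_cells)})
        return pd.DataFrame(rows)


def _logistic_cdf(x: np.ndarray, mu: float, s: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(x - mu) / s))


def fit_sigmoid_cutoffs(log10_umi: np.ndarray, config: QcConfig | None = None) -> SigmoidFit:
    """Least-squares fit of a logistic CDF to the empirical CDF of log10 UMI.

    The cutoffs are ``mu +/- multiplier * s`` (multiplier defaults to ln 4,
    so the fitted curve evaluates to exactly 0.2 and 0.8 at the cutoffs).
    If the optimizer fails, ``converged=False`` and the 1st/99th percentiles
    stand in for the cutoffs.
    """
    if config is None:
        config = QcConfig()
    x = np.asarray(log10_umi, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 50:
        raise ValueError(f"need at least 50 finite values, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("log10 UMI values have zero spread")

    xs = np.sort(x)
    n = xs.size
    ecdf = (np.arange(1, n + 1) - 0.5) / n

    mu0 = float(np.median(xs))
    iqr = float(np.subtract(*np.percentile(xs, [75, 25])))
    s0 = max(iqr / (2 * np.log(3.0)), 1e-6)  # logistic IQR = 2 s ln 3

    def resid(theta):
        return _logistic_cdf(xs, theta[0], theta[1]) - ecdf

    converged = True
    try:
        sol = least_squares(
            resid, x0=[mu0, s0],
            bounds=([xs[0] - np.ptp(xs), 1e-9], [xs[-1] + np.ptp(xs), np.ptp(xs)]),
        )
        mu, s = float(sol.x[0]), float(sol.x[1])
        converged = bool(sol.success) and s > 0
    except Exception:
        converged = False
        mu, s = mu0, s0

    if not converged:
        lo, hi = np.percentile(xs, [1, 99])
        return SigmoidFit(mu=mu, s=s, lower_cutoff=float(lo), upper_cutoff=float(hi), converged=False)

    m = config.sigmoid_scale_multiplier
    return SigmoidFit(
        mu=mu, s=s,
        lower_cutoff=mu - m * s,
        upper_cutoff=mu + m * s,
        converged=True,
    )


def compute_cell_stats(adata: ad.AnnData) -> pd.DataFrame:
    """Per-cell totals needed by the filters.

    Requires boolean gene-set columns ``mito``, ``ribo`` and ``hemoglobin``
    in ``adata.var``; raises a configuration error when absent.
    """
    missing = [c for c in ("mito", "ribo", "hemoglobin") if c not in adata.var.columns]
    if missing:
        raise ValueError(
            f"gene-set annotation missing from var: {missing}; "
            "mark mitochondrial/ribosomal/hemoglobin genes before filtering"
        )
    X = adata.X
    total = np.asarray(X.sum(axis=1)).ravel()
    n_genes = np.asarray((X > 0).sum(axis=1)).ravel()

    def set_sum(col):
        mask = adata.var[col].to_numpy()
        return np.asarray(X[:, mask].sum(axis=1)).ravel()

    with np.errstate(divide="ignore", invalid="ignore"):
        stats = pd.DataFrame(
            {
                "total_umi": total,
                "n_genes": n_genes,
                "mito_frac": np.divide(set_sum("mito"), total, out=np.zeros_like(total, dtype=float), where=total > 0),
                "ribo_frac": np.divide(set_sum("ribo"), total, out=np.zeros_like(total, dtype=float), where=total > 0),
                "hemoglobin_frac": np.divide(set_sum("hemoglobin"), total, out=np.zeros_like(total, dtype=float), where=total > 0),
            },
            index=adata.obs_names,
        )
    stats["log10_umi"] = np.log10(np.maximum(stats["total_umi"], 1.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        stats["log10_genes_per_umi"] = np.where(
            (stats["total_umi"] > 1) & (stats["n_genes"] > 0),
            np.log10(np.maximum(stats["n_genes"], 1)) / np.log10(np.maximum(stats["total_umi"], 2)),
            0.0,
        )
    return stats


def apply_cell_filters(
    adata: ad.AnnData,
    config: QcConfig | None = None,
    sigmoid_fit: SigmoidFit | None = None,
    doublet_flags: pd.Series | None = None,
) -> tuple[ad.AnnData, FilterReport]:
    """Apply all QC rules; each removed cell is attributed to the first
    failing rule in :data:`RULE_ORDER`.

    ``sigmoid_fit`` may be supplied (e.g. to re-apply a frozen fit); by
    default it is fitted to the input's log10 UMI distribution. Externally
    computed doublet flags are passed through to the report but do not
    remove cells here.
    """
    if config is None:
        config = QcConfig()
    stats = compute_cell_stats(adata)
    if sigmoid_fit is None:
        sigmoid_fit = fit_sigmoid_cutoffs(stats["log10_umi"].to_numpy(), config)

    fails = {
        "gene_count": stats["n_genes"] < config.min_genes,
        "mito": stats["mito_frac"] > config.max_mito_frac,
        "ribo": stats["ribo_frac"] > config.max_ribo_frac,
        "hemoglobin": stats["hemoglobin_frac"] > config.max_hemoglobin_frac,
        "genes_per_umi": stats["log10_genes_per_umi"] < config.min_log10_genes_per_umi,
        "umi_range": (stats["log10_umi"] < sigmoid_fit.lower_cutoff)
        | (stats["log10_umi"] > sigmoid_fit.upper_cutoff),
    }

    first_fail = pd.Series(pd.NA, index=stats.index, dtype="object")
    for rule in RULE_ORDER:
        claim = fails[rule] & first_fail.isna()
        first_fail[claim] = rule

    keep = first_fail.isna()
    removed_by_rule = {r: int((first_fail == r).sum()) for r in RULE_ORDER}
    filtered = adata[keep.to_numpy()].copy()
    for col in stats.columns:
        filtered.obs[col] = stats.loc[keep, col].to_numpy()
    if doublet_flags is not None:
        filtered.obs["doublet_flag"] = doublet_flags.reindex(filtered.obs_names).to_numpy()

    report = FilterReport(
        n_input=adata.n_obs,
        removed_by_rule=removed_by_rule,
        retained_cells=list(filtered.obs_names),
        thresholds={
            "min_genes": config.min_genes,
            "max_mito_frac": config.max_mito_frac,
            "max_ribo_frac": config.max_ribo_frac,
            "max_hemoglobin_frac": config.max_hemoglobin_frac,
            "min_log10_genes_per_umi": config.min_log10_genes_per_umi,
            "umi_lower_cutoff": sigmoid_fit.lower_cutoff,
            "umi_upper_cutoff": sigmoid_fit.upper_cutoff,
            "sigmoid_mu": sigmoid_fit.mu,
            "sigmoid_s": sigmoid_fit.s,
            "sigmoid_converged": sigmoid_fit.converged,
            "sigmoid_method": sigmoid_fit.method,
        },
        first_fail=first_fail,
    )
    return filtered, report
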