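#!/usr/bin/env python
"""Detect the condition-enriched subpopulation among the filtered nuclei.

Embeds the QC-passed nuclei with PCA (top 40 PCs of library-normalized
log counts), computes multiscale kNN condition-composition scores over
the k grid, fits the logistic DA measure, selects cells beyond +/-0.8,
and partitions them into subpopulations by community detection at
resolution 0.01. Recovery is scored against the generator's truth
labels.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from cellink.da import DaConfig, run_da
from cellink.eqtl import normalize_cells
from cellink.io import read_counts, write_tsv
from cellink.synth import CONDITION_A

ROOT = Path(__file__).resolve().parents[1] / "results"


def main():
    cells = read_counts(ROOT / "qc" / "counts_filtered")
    norm = normalize_cells(cells)
    X = norm.X.toarray()
    X = X - X.mean(axis=0)
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    emb = U[:, :40] * S[:40]

    cond = cells.obs["condition"].to_numpy()
    res = run_da(emb, cond, DaConfig(seed=0), cond_a=CONDITION_A)

    truth = cells.obs["subpop"].to_numpy().astype(bool)
    sel = np.zeros(cells.n_obs, dtype=bool)
    sel[res.da_cells] = True
    precision = truth[sel].mean() if sel.any() else float("nan")
    recall = sel[truth].mean()

    out = pd.DataFrame({
        "cell": cells.obs_names,
        "donor": cells.obs["donor"].to_numpy(),
        "condition": cond,
        "true_subpop": truth,
        "da_measure": res.measure,
        "da_selected": sel,
    })
    out["da_subpop"] = np.nan
    if res.labels is not None:
        out.iloc[res.labels.index, out.columns.get_loc("da_subpop")] = res.labels.to_numpy()
    write_tsv(out, ROOT / "da" / "da_cells.tsv")

    n_clusters = 0 if res.labels is None else res.labels.nunique()
    print(f"k grid used: {res.k_grid}")
    print(f"{sel.sum()} DA nuclei selected beyond +/-0.8 "
          f"({n_clusters} subpopulation(s) at resolution 0.01)")
    print(f"recovery of the planted subpopulation: precision {precision:.3f}, "
          f"recall {recall:.3f} (n_true = {truth.sum()})")
    print(f"wrote {ROOT / 'da'}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
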