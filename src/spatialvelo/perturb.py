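"""In-silico gene deletion and state-driver-marker selection.

Deletion analysis retrains the model from scratch (same seed and
configuration) on the dataset without one gene, and compares the velocity of
every shared gene across cells between the two runs by cosine similarity:
genes whose velocity changes most (lowest similarity) are the ones most
dependent on the deleted gene — a regulatory-influence readout.

State driver markers are genes whose velocity differs significantly between
a cell group and the rest (Welch two-sample t-test on the velocity matrix),
ranked by the t statistic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import SpatialVeloDataset
from .estimator import SpatialVelocityModel

__all__ = ["in_silico_deletion", "state_driver_markers"]


def _velocity_for(dataset, model_params: dict) -> tuple[np.ndarray, list]:
    model = SpatialVelocityModel(**model_params)
    model.fit(dataset)
    return model.predict(dataset), list(dataset.adata.var_names)


def in_silico_deletion(dataset: SpatialVeloDataset, gene: str,
                       model_params: dict | None = None) -> pd.Series:
    """Per-gene cosine similarity of velocities with vs without ``gene``.

    The dataset must already be preprocessed (stage 'scaled'); both runs use
    the identical seed and configuration so the only difference is the
    deleted gene. Lower similarity = more impacted by the deletion.
    """
    names = list(dataset.adata.var_names)
    if gene not in names:
        raise KeyError(f"gene {gene!r} not in dataset")
    if dataset.n_genes < 3:
        raise ValueError("too few genes to delete one")
    model_params = model_params or {}
    V_full, full_names = _velocity_for(dataset, model_params)
    keep = [n for n in names if n != gene]
    reduced = SpatialVeloDataset(dataset.adata[:, keep].copy(), stage="raw")
    reduced.stage = "scaled"
    V_del, del_names = _velocity_for(reduced, model_params)

    sims = {}
    full_idx = {n: i for i, n in enumerate(full_names)}
    for i, n in enumerate(del_names):
        a = V_full[:, full_idx[n]]
        b = V_del[:, i]
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        sims[n] = float(a @ b / (na * nb)) if na > 0 and nb > 0 else np.nan
    return pd.Series(sims, name=f"cosine_similarity_after_deleting_{gene}")


def state_driver_markers(V, labels, group: str, n_top: int = 10,
                         gene_names=None) -> pd.DataFrame:
    """Top velocity-marker genes for a cell group by Welch t-test.

    Per gene, compares velocity in ``group`` cells against all other cells;
    genes with degenerate (zero) variance in both groups are skipped.
    Returns the ``n_top`` genes ranked by t statistic, with p-values.
    """
    V = np.asarray(V, dtype=float)
    labels = np.asarray(labels)
    mask = labels == group
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise ValueError("need at least 2 cells inside and outside the group")
    gene_names = (list(gene_names) if gene_names is not None
                  else [f"gene_{i}" for i in range(V.shape[1])])
    rows = []
    for g in range(V.shape[1]):
        a, b = V[mask, g], V[~mask, g]
        if a.var() == 0 and b.var() == 0:
            continue  # degenerate: no separation information
        t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append({"gene": gene_names[g], "t_statistic": float(t),
                     "p_value": float(p)})
    table = pd.DataFrame(rows).sort_values(
        "t_statistic", ascending=False, kind="stable").reset_index(drop=True)
    return table.head(n_top)
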