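"""Delta-delta-Ct differential expression and hierarchical clustering.

For each assay the group difference of mean normalized Ct values
(patients minus controls) is the delta-delta Ct; the fold change is
``2 ** (-ddCt)`` since expression is proportional to ``2 ** (-Ct)``.
Assays with fold change >= 2 (or <= 0.5) and a two-sided Wilcoxon
Mann-Whitney p below alpha are called up- (down-) regulated.  Raw p-values
drive the default call; Benjamini-Hochberg q-values are reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .data import CtMatrix, MirsigError, SampleSheet

EXACT_MAX_COMBINED_N = 20


def wilcoxon_rank_sum(x, y, exact_max_combined_n: int = EXACT_MAX_COMBINED_N) -> float:
    """Two-sided Wilcoxon Mann-Whitney p-value.

    Uses the exact null distribution for small tie-free samples (combined n
    at or below ``exact_max_combined_n``), otherwise the normal approximation
    with tie and continuity correction.  Identical pooled values give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if min(len(x), len(y)) < 2:
        raise MirsigError("each group needs at least 2 values")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    if not has_ties and len(pooled) <= exact_max_combined_n:
        method = "exact"
    else:
        method = "asymptotic"
    return float(
        mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


def differential_expression(
    nm: CtMatrix,
    sheet: SampleSheet,
    fc_min: float = 2.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-assay ddCt, fold change, Wilcoxon p/q and regulation call.

    Returns a DataFrame indexed by assay with columns ``mean_ct_patient``,
    ``mean_ct_control``, ``delta_delta_ct``, ``fold_change``, ``p_value``,
    ``q_value`` and ``regulation`` (up / down / none).
    """
    V = nm.values
    labels = sheet.labels(V.columns)
    pat = V.columns[labels == 1]
    ctl = V.columns[labels == 0]
    if len(pat) < 2 or len(ctl) < 2:
        raise MirsigError(
            f"both groups need >= 2 samples (got {len(pat)} patients, "
            f"{len(ctl)} controls)"
        )
    mean_pat = V[pat].mean(axis=1)
    mean_ctl = V[ctl].mean(axis=1)
    ddct = mean_pat - mean_ctl
    fc = np.power(2.0, -ddct)
    n_comb = len(pat) + len(ctl)
    if n_comb > EXACT_MAX_COMBINED_N:
        # large cohorts always use the normal approximation: one vectorized call
        with np.errstate(invalid="ignore"):
            pvals = mannwhitneyu(
                V[pat].to_numpy(),
                V[ctl].to_numpy(),
                alternative="two-sided",
                method="asymptotic",
                axis=1,
            ).pvalue
        flat = (V.nunique(axis=1) == 1).to_numpy()
        pvals = np.where(flat, 1.0, pvals)
    else:
        pvals = np.array(
            [wilcoxon_rank_sum(V.loc[a, pat], V.loc[a, ctl]) for a in V.index]
        )
    qvals = multipletests(pvals, method="fdr_bh")[1]
    regulation = np.where(
        (fc >= fc_min) & (pvals < alpha),
        "up",
        np.where((fc <= 1.0 / fc_min) & (pvals < alpha), "down", "none"),
    )
    return pd.DataFrame(
        {
            "mean_ct_patient": mean_pat,
            "mean_ct_control": mean_ctl,
            "delta_delta_ct": ddct,
            "fold_change": fc,
            "p_value": pvals,
            "q_value": qvals,
            "regulation": regulation,
        },
        index=V.index,
    )


def differentially_expressed_assays(de_table: pd.DataFrame) -> list:
    return list(de_table.index[de_table["regulation"] != "none"])


@dataclass
class ClusteringResult:
    linkage: np.ndarray
    leaf_order: list
    clusters: pd.Series  # sample -> flat cluster id at the requested k


def hierarchical_clustering(
    nm: CtMatrix,
    subset=None,
    k: int = 2,
    distance: str = "correlation",
    linkage_method: str = "average",
) -> ClusteringResult:
    """Agglomerative clustering of samples over a subset of assays.

    Default distance is 1 - Pearson correlation between sample profiles with
    average linkage; the tree is cut into ``k`` flat clusters.
    """
    V = nm.values if subset is None else nm.values.loc[list(subset)]
    if V.shape[0] == 0:
        raise MirsigError("clustering needs a nonempty assay subset")
    n = V.shape[1]
    if k > n:
        raise MirsigError(f"k={k} exceeds the number of samples ({n})")
    X = V.T.to_numpy()  # samples x assays
    d = pdist(X, metric=distance)
    d = np.clip(d, 0.0, None)  # guard tiny negative float error in correlation
    Z = hierarchy.linkage(d, method=linkage_method)
    flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    order = hierarchy.leaves_list(Z)
    samples = list(V.columns)
    return ClusteringResult(
        linkage=Z,
        leaf_order=[samples[i] for i in order],
        clusters=pd.Series(flat, index=samples),
    )
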