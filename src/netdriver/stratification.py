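"""Tumor stratification from binary driver profiles and survival evaluation.

Samples are clustered by consensus over repeated randomly initialized NMF
factorizations of the binary patient x driver matrix (200 runs by default);
the co-clustering fraction matrix is then cut by average-linkage hierarchical
clustering into k groups.  Cluster separation in outcome is assessed by the
multi-group log-rank test with Kaplan-Meier summaries per cluster.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import NMF

from .driver_call import DriverCall

logger = logging.getLogger(__name__)


@dataclass
class ConsensusClustering:
    k: int
    assignments: pd.Series  # sample -> cluster label (1..k)
    consensus: pd.DataFrame  # sample x sample co-clustering fraction
    n_runs: int
    n_degenerate: int = 0


def profile_matrix(calls: list[DriverCall]) -> pd.DataFrame:
    """Binary sample x driver-gene matrix; samples without drivers are dropped."""
    pairs = {(c.sample, c.gene) for c in calls}
    samples = sorted({s for s, _ in pairs})
    genes = sorted({g for _, g in pairs})
    if len(samples) < 2:
        raise ValueError("need at least 2 samples with at least one driver each")
    mat = pd.DataFrame(0, index=samples, columns=genes, dtype=np.int8)
    for s, g in pairs:
        mat.loc[s, g] = 1
    return mat


def nmf_consensus(
    matrix: pd.DataFrame,
    k: int,
    n_runs: int = 200,
    seed: int = 0,
    max_redraws: int = 50,
) -> ConsensusClustering:
    """Consensus clustering over randomly initialized NMF runs.

    Each run factorizes the sample x gene matrix with multiplicative updates
    (Frobenius objective) and assigns every sample to its dominant basis
    component; a run producing an empty cluster is redrawn (capped).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k >= len(matrix):
        raise ValueError("k must be smaller than the number of samples")
    rng = np.random.default_rng(seed)
    X = matrix.to_numpy(float)
    n = X.shape[0]
    co = np.zeros((n, n))
    done = 0
    degenerate = 0
    while done < n_runs:
        state = int(rng.integers(0, 2**31 - 1))
        model = NMF(
            n_components=k,
            init="random",
            solver="mu",
            beta_loss="frobenius",
            max_iter=500,
            random_state=state,
            tol=1e-5,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            W = model.fit_transform(X)
        labels = W.argmax(axis=1)
        if len(np.unique(labels)) < k:
            degenerate += 1
            if degenerate <= max_redraws:
                continue
            logger.warning("degenerate NMF run cap reached; accepting run with an empty cluster")
        co += (labels[:, None] == labels[None, :]).astype(float)
        done += 1
    consensus = co / n_runs
    np.fill_diagonal(consensus, 1.0)
    dist = 1.0 - consensus
    dist = (dist + dist.T) / 2
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return ConsensusClustering(
        k=k,
        assignments=pd.Series(labels, index=matrix.index, name="cluster"),
        consensus=pd.DataFrame(consensus, index=matrix.index, columns=matrix.index),
        n_runs=n_runs,
        n_degenerate=degenerate,
    )


def survival_separation(
    assignments: pd.Series, survival: pd.DataFrame
) -> tuple[float, float, pd.DataFrame]:
    """Multi-group log-rank test across clusters.

    ``survival`` has columns ``time`` and ``event`` indexed by sample.
    Returns (test statistic, p-value, per-cluster Kaplan-Meier summary).
    """
    shared = [s for s in assignments.index if s in survival.index]
    if not shared:
        raise ValueError("no samples shared between assignments and survival table")
    groups = assignments.loc[shared]
    surv = survival.loc[shared]
    if groups.nunique() < 2:
        raise ValueError("need at least 2 clusters for a log-rank test")
    for cl, sub in surv.groupby(groups):
        if sub["event"].sum() == 0:
            warnings.warn(f"cluster {cl} has no events; retained in the test")
    res = multivariate_logrank_test(surv["time"], groups, surv["event"])
    rows = []
    for cl, sub in surv.groupby(groups):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"])
        rows.append(
            (cl, len(sub), int(sub["event"].sum()), float(kmf.median_survival_time_),
             float(sub["time"].mean()))
        )
    summary = pd.DataFrame(
        rows, columns=["cluster", "n", "events", "median_survival", "mean_time"]
    )
    return float(res.test_statistic), float(res.p_value), summary
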