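"""Per-patient deregulated gene calling.

A gene is *deregulated* in a patient when it is significantly differentially
expressed at the cohort level (tumors vs normals, BH-corrected q < 0.05) and
its per-sample |log2 fold change| against the median normal exceeds the
threshold F (strict inequality).  Cohort-level significance supplies the
statistical gate; the per-sample fold change supplies patient specificity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_model import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DeregulationProfile:
    """Deregulated genes of one sample with their signed log2 fold changes."""

    sample: str
    dereg: dict[str, float]

    @property
    def n_dereg(self) -> int:
        return len(self.dereg)

    @property
    def genes(self) -> set[str]:
        return set(self.dereg)


def _common_genes(tumors: ExpressionMatrix, normals: ExpressionMatrix) -> list[str]:
    common = [g for g in tumors.genes if g in set(normals.genes)]
    if not common:
        raise ValueError("tumor and normal matrices share no genes")
    return common


def cohort_de_qvalues(
    tumors: ExpressionMatrix,
    normals: ExpressionMatrix,
    method: str = "wilcoxon",
) -> pd.Series:
    """Per-gene two-sided differential-expression q-values (BH-corrected).

    ``method`` is ``"wilcoxon"`` (Mann-Whitney rank-sum, default; robust to
    the expression scale) or ``"ttest"`` (Welch).
    """
    if len(normals.samples) < 2:
        raise ValueError(
            "at least 2 normal samples are required for the cohort test; "
            "supply a precomputed q-value table instead"
        )
    genes = _common_genes(tumors, normals)
    t = tumors.data.loc[genes].to_numpy(float)
    n = normals.data.loc[genes].to_numpy(float)
    if method == "wilcoxon":
        res = stats.mannwhitneyu(t, n, axis=1, alternative="two-sided")
        pvals = np.asarray(res.pvalue, float)
    elif method == "ttest":
        res = stats.ttest_ind(t, n, axis=1, equal_var=False)
        pvals = np.asarray(res.pvalue, float)
    else:
        raise ValueError(f"unknown test method {method!r}")
    pvals = np.nan_to_num(pvals, nan=1.0)
    qvals = multipletests(pvals, method="fdr_bh")[1]
    return pd.Series(qvals, index=genes, name="q")


def sample_log2_fold_changes(
    tumors: ExpressionMatrix,
    normals: ExpressionMatrix,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-sample log2 fold change of each gene against the median normal.

    Linear-scale input uses ``log2((x + pc) / (median + pc))`` when zeros or
    negative values are present (with a warning); log2-scale input uses the
    difference ``x - median``.  Returns genes x samples.
    """
    genes = _common_genes(tumors, normals)
    t = tumors.data.loc[genes]
    ref = normals.data.loc[genes].median(axis=1)
    if tumors.scale == "log2":
        fc = t.sub(ref, axis=0)
    else:
        tv = t.to_numpy(float)
        rv = ref.to_numpy(float)
        if (tv <= 0).any() or (rv <= 0).any():
            logger.warning(
                "non-positive linear expression values; applying pseudocount %g", pseudocount
            )
            tv = tv + pseudocount
            rv = rv + pseudocount
        fc = pd.DataFrame(np.log2(tv / rv[:, None]), index=genes, columns=t.columns)
    return fc


def call_deregulated(
    qvalues: pd.Series,
    fcs: pd.DataFrame,
    F: float,
    alpha: float = 0.05,
) -> dict[str, DeregulationProfile]:
    """Call per-sample deregulation: q < alpha AND |log2FC| > F (both strict)."""
    genes = [g for g in fcs.index if g in qvalues.index]
    if not genes:
        raise ValueError("q-values and fold changes share no genes")
    q = qvalues.loc[genes].to_numpy()
    fc = fcs.loc[genes].to_numpy()
    sig = q < alpha
    profiles: dict[str, DeregulationProfile] = {}
    gene_arr = np.asarray(genes)
    for j, sample in enumerate(fcs.columns):
        mask = sig & (np.abs(fc[:, j]) > F)
        profiles[sample] = DeregulationProfile(
            sample=str(sample),
            dereg={g: float(v) for g, v in zip(gene_arr[mask], fc[mask, j])},
        )
    return profiles


def deregulation_table(profiles: dict[str, DeregulationProfile]) -> pd.DataFrame:
    """Long-format (sample, gene, log2_fc) table for export."""
    rows = [
        (s, g, fc)
        for s, prof in sorted(profiles.items())
        for g, fc in sorted(prof.dereg.items())
    ]
    return pd.DataFrame(rows, columns=["sample", "gene", "log2_fc"])
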