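"""Phenotype gene calling.

Phenotype genes are deregulated genes explained in a large fraction of
patients (default >= 5%) whose explained frequency is also higher than
expected under a permutation null in which each sample's mutated gene labels
are shuffled independently (deregulation untouched).  Empirical p-values over
the null (default 500 permutations) are BH-corrected and genes with q < 0.1
are kept.  These genes nucleate the patient-specific modules.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .deregulation import DeregulationProfile
from .io_model import GeneNetwork, MutationMatrix, ParameterSet
from .network_search import explained_frequency, explained_genes

logger = logging.getLogger(__name__)


@dataclass
class PhenotypeGeneSet:
    """Significant, frequently explained genes with their statistics."""

    table: pd.DataFrame  # index gene; columns frequency, p, q (all candidates)
    genes: set[str]  # the called subset

    def __len__(self) -> int:
        return len(self.genes)

    def called_table(self) -> pd.DataFrame:
        return self.table.loc[sorted(self.genes)]


def permute_mutations_per_sample(
    mutations: MutationMatrix, seed: int | np.random.Generator
) -> MutationMatrix:
    """Independently shuffle each sample's mutation labels among all genes.

    Each sample keeps its mutation count; which genes carry them is
    randomized per sample, so recurrence across samples is destroyed.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    arr = mutations.data.to_numpy()
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        out[:, j] = arr[rng.permutation(arr.shape[0]), j]
    return MutationMatrix(
        pd.DataFrame(out, index=mutations.data.index, columns=mutations.data.columns)
    )


def null_explained_frequencies(
    network: GeneNetwork,
    mutations: MutationMatrix,
    profiles: dict[str, DeregulationProfile],
    params: ParameterSet,
    n_perm: int = 500,
    seed: int = 0,
) -> list[dict[str, float]]:
    """Explained frequencies of ``n_perm`` per-sample mutation-permuted cohorts."""
    rng = np.random.default_rng(seed)
    nulls = []
    samples = mutations.samples
    for _ in range(n_perm):
        perm = permute_mutations_per_sample(mutations, rng)
        maps = [
            explained_genes(network, profiles[s], perm.mutated_genes(s), params)
            for s in samples
        ]
        nulls.append(explained_frequency(maps))
    return nulls


def empirical_pvalues(
    observed: dict[str, float],
    nulls: list[dict[str, float]],
    strict: bool = False,
) -> dict[str, float]:
    """Add-one-corrected permutation p-values per gene.

    p(g) = (1 + #{null frequency >= observed}) / (1 + n_perm); ``strict=True``
    counts only null frequencies strictly above the observed one.
    """
    if not nulls:
        raise ValueError("at least one permutation required")
    n_perm = len(nulls)
    pvals: dict[str, float] = {}
    for g, obs in observed.items():
        if strict:
            hits = sum(null.get(g, 0.0) > obs for null in nulls)
        else:
            hits = sum(null.get(g, 0.0) >= obs for null in nulls)
        pvals[g] = (1 + hits) / (1 + n_perm)
    return pvals


def call_phenotype_genes(
    observed: dict[str, float],
    pvalues: dict[str, float],
    freq_threshold: float = 0.05,
    fdr: float = 0.1,
) -> PhenotypeGeneSet:
    """BH-correct over candidates (observed frequency > 0) and apply both gates."""
    candidates = sorted(g for g, f in observed.items() if f > 0)
    if not candidates:
        warnings.warn("no candidate phenotype genes (nothing explained anywhere)")
        return PhenotypeGeneSet(
            table=pd.DataFrame(columns=["frequency", "p", "q"]), genes=set()
        )
    p = np.array([pvalues[g] for g in candidates])
    q = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame(
        {"frequency": [observed[g] for g in candidates], "p": p, "q": q}, index=candidates
    )
    called = {
        g
        for g, row in table.iterrows()
        if row["q"] < fdr and row["frequency"] >= freq_threshold
    }
    logger.info("called %d phenotype gene(s) of %d candidates", len(called), len(candidates))
    return PhenotypeGeneSet(table=table, genes=called)
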