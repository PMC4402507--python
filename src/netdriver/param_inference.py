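"""Data-driven selection of the L, D, F parameters.

Rationale: with well-chosen parameters a real cohort shows far more
mutation-deregulation association than gene-label-permuted cohorts, in which
the per-sample and per-gene frequency structure is preserved but the coupling
between mutations and deregulation is destroyed.  Each grid cell is scored by
the Jensen-Shannon divergence between the explained-frequency spectrum of the
real cohort and the aggregate spectrum of the permuted cohorts; the feasible
cell with the highest score wins.  Cells whose median per-sample deregulated
count is extreme (more than half the network's genes, or below a floor) are
excluded to avoid degenerate optima.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import jensenshannon

from .deregulation import DeregulationProfile, call_deregulated, cohort_de_qvalues, sample_log2_fold_changes
from .io_model import Cohort, GeneNetwork, MutationMatrix, ParameterSet
from .network_search import explained_frequency, explained_genes

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ParameterGrid:
    """Grid-search ranges; defaults span the method's standard search space."""

    L: tuple[int, ...] = tuple(range(2, 21, 2))
    D: tuple[int, ...] = tuple(range(10, 101, 5))
    F: tuple[float, ...] = (1.0, 1.5, 2.0, 2.5, 3.0)


@dataclass
class GridSearchResult:
    best: ParameterSet
    scores: dict[tuple[int, int, float], float]
    feasible: dict[tuple[int, int, float], bool]
    median_dereg: dict[float, float]
    n_random: int


def js_divergence(P, Q) -> float:
    """Base-2 Jensen-Shannon divergence between two probability vectors, in [0, 1]."""
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    if P.shape != Q.shape:
        raise ValueError("P and Q must have the same length")
    if (P < 0).any() or (Q < 0).any():
        raise ValueError("probability vectors must be non-negative")
    if not np.isclose(P.sum(), 1.0) or not np.isclose(Q.sum(), 1.0):
        raise ValueError("probability vectors must sum to 1")
    d = jensenshannon(P, Q, base=2)  # sqrt of the divergence
    d = 0.0 if np.isnan(d) else float(d)
    return d * d


def frequency_spectrum(freqs: dict[str, float], n_samples: int, network: GeneNetwork) -> np.ndarray:
    """Spectrum of explained-in-k-samples counts over network genes, k = 0..n_samples.

    Genes outside the network are ignored; network genes never explained sit
    at k = 0, so the counts always sum to the number of network genes.
    """
    counts = np.zeros(n_samples + 1, dtype=float)
    nodes = network.nodes
    n_explained = 0
    for g, f in freqs.items():
        if g not in nodes:
            continue
        k = int(round(f * n_samples))
        counts[k] += 1
        n_explained += 1
    counts[0] += len(nodes) - n_explained
    return counts


def normalize_spectrum(counts: np.ndarray) -> np.ndarray:
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty spectrum")
    return counts / total


def permute_gene_labels(
    mutations: MutationMatrix,
    profiles: dict[str, DeregulationProfile],
    seed: int | np.random.Generator,
    expression_genes: list[str] | None = None,
) -> tuple[MutationMatrix, dict[str, DeregulationProfile]]:
    """Shuffle gene labels of the mutation matrix and, independently, of the
    deregulation profiles.

    One label bijection is drawn per data type and applied across all samples,
    so per-sample counts and per-gene cross-sample frequencies are preserved
    (attached to the permuted labels) while the mutation-deregulation coupling
    is destroyed.  ``expression_genes`` is the measured transcriptome universe
    over which the expression-side bijection acts; it defaults to the union of
    deregulated genes when no wider universe is supplied.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    mut_genes = np.asarray(mutations.genes)
    perm_mut = dict(zip(mut_genes, mut_genes[rng.permutation(len(mut_genes))]))
    new_mut = mutations.data.copy()
    new_mut.index = [perm_mut[g] for g in mut_genes]
    if expression_genes is None:
        expression_genes = sorted({g for p in profiles.values() for g in p.dereg})
    expr_arr = np.asarray(expression_genes)
    perm_expr = (
        dict(zip(expr_arr, expr_arr[rng.permutation(len(expr_arr))])) if len(expr_arr) else {}
    )
    new_profiles = {
        s: DeregulationProfile(sample=s, dereg={perm_expr[g]: fc for g, fc in p.dereg.items()})
        for s, p in profiles.items()
    }
    return MutationMatrix(new_mut), new_profiles


def _cohort_explained_freq(
    network: GeneNetwork,
    mutations: MutationMatrix,
    profiles: dict[str, DeregulationProfile],
    params: ParameterSet,
) -> dict[str, float]:
    maps = [
        explained_genes(network, profiles[s], mutations.mutated_genes(s), params)
        for s in mutations.samples
    ]
    return explained_frequency(maps)


def infer_parameters(
    cohort: Cohort,
    network: GeneNetwork,
    grid: ParameterGrid = ParameterGrid(),
    n_random: int = 50,
    seed: int = 0,
    min_median_dereg: int = 300,
    max_median_dereg_fraction: float = 0.5,
    de_method: str = "wilcoxon",
) -> GridSearchResult:
    """Grid search maximizing the real-vs-permuted Jensen-Shannon divergence.

    Ties are broken deterministically toward smaller L, then D, then F.  The
    aggregate random spectrum is the mean of the per-permutation normalized
    spectra.
    """
    if n_random < 2:
        raise ValueError("n_random must be >= 2")
    rng = np.random.default_rng(seed)
    n_samples = len(cohort.samples)
    n_net_genes = len(network.nodes)
    qvals = cohort_de_qvalues(cohort.tumors, cohort.normals, method=de_method)
    fcs = sample_log2_fold_changes(cohort.tumors, cohort.normals)

    scores: dict[tuple[int, int, float], float] = {}
    feasible: dict[tuple[int, int, float], bool] = {}
    median_dereg: dict[float, float] = {}
    for F in grid.F:
        profiles = call_deregulated(qvals, fcs, F=F)
        med = float(np.median([p.n_dereg for p in profiles.values()]))
        median_dereg[F] = med
        ok = min_median_dereg <= med <= max_median_dereg_fraction * n_net_genes
        expr_universe = list(fcs.index)
        permuted = [
            permute_gene_labels(cohort.mutations, profiles, rng, expression_genes=expr_universe)
            for _ in range(n_random)
        ]
        for L in grid.L:
            for D in grid.D:
                params = ParameterSet(L=L, D=D, F=F)
                feasible[(L, D, F)] = ok
                real = normalize_spectrum(
                    frequency_spectrum(
                        _cohort_explained_freq(network, cohort.mutations, profiles, params),
                        n_samples,
                        network,
                    )
                )
                rand_spectra = [
                    normalize_spectrum(
                        frequency_spectrum(
                            _cohort_explained_freq(network, pm, pp, params), n_samples, network
                        )
                    )
                    for pm, pp in permuted
                ]
                scores[(L, D, F)] = js_divergence(real, np.mean(rand_spectra, axis=0))
    candidates = [cell for cell, ok in feasible.items() if ok]
    if not candidates:
        detail = ", ".join(f"F={F}: median={m:.0f}" for F, m in sorted(median_dereg.items()))
        raise ValueError(f"no feasible grid cell (per-sample deregulated-count medians: {detail})")
    best_cell = max(candidates, key=lambda c: (scores[c], (-c[0], -c[1], -c[2])))
    logger.info("selected parameters L=%d D=%d F=%g (JSD=%.4f)", *best_cell, scores[best_cell])
    return GridSearchResult(
        best=ParameterSet(*best_cell),
        scores=scores,
        feasible=feasible,
        median_dereg=median_dereg,
        n_random=n_random,
    )
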