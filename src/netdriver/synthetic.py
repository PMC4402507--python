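"""Synthetic networks and cohorts with planted driver structure.

The generator emulates the statistical structure the detection model
assumes: a scale-free-like interaction network; a recurrent pool of driver
genes whose radius-limited network neighborhoods are transcriptionally
shifted in the samples that carry them; passenger and decoy mutations with
no expression consequence; and matched normal samples of pure baseline
noise.  Expression is simulated on the log2 scale throughout.  Effect
propagation is a radius-limited BFS that mirrors — but is generated
independently of — the detector's path rule, so recovery is non-trivial
without being tautological.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .io_model import Cohort, ExpressionMatrix, GeneNetwork, MutationMatrix


@dataclass
class SyntheticCohort:
    network: GeneNetwork
    mutations: MutationMatrix
    tumors: ExpressionMatrix
    normals: ExpressionMatrix
    truth: dict[str, set[str]]  # sample -> planted driver genes
    manifest: dict

    @property
    def cohort(self) -> Cohort:
        return Cohort(self.mutations, self.tumors, self.normals)


def generate_network(
    n_genes: int = 1500,
    mean_degree: float = 6.0,
    hub_fraction: float = 0.01,
    seed: int = 0,
    hub_degree: int = 60,
) -> GeneNetwork:
    """Connected scale-free-like network with a configurable hub tail.

    A Barabasi-Albert graph supplies the heavy-tailed backbone; the top
    ``hub_fraction`` of nodes are then wired up to at least ``hub_degree``
    neighbors so that hub exclusion (degree > D) is always exercised.
    """
    if n_genes < 50:
        raise ValueError("n_genes must be >= 50")
    m = int(round(mean_degree / 2))
    if m < 1 or m >= n_genes:
        raise ValueError("infeasible mean_degree for this n_genes")
    rng = np.random.default_rng(seed)
    g = nx.barabasi_albert_graph(n_genes, m, seed=int(rng.integers(2**31 - 1)))
    n_hubs = max(1, int(round(hub_fraction * n_genes)))
    by_degree = sorted(g.nodes, key=lambda v: (-g.degree(v), v))
    for hub in by_degree[:n_hubs]:
        candidates = [v for v in g.nodes if v != hub and not g.has_edge(hub, v)]
        need = hub_degree - g.degree(hub)
        if need > 0:
            for v in rng.choice(candidates, size=min(need, len(candidates)), replace=False):
                g.add_edge(hub, int(v))
    width = len(str(n_genes))
    mapping = {v: f"G{v:0{width}d}" for v in g.nodes}
    return GeneNetwork(nx.relabel_nodes(g, mapping))


def _effect_targets(
    network: GeneNetwork, driver: str, radius: int, max_transit_degree: int
) -> set[str]:
    """Radius-limited BFS neighborhood through non-hub nodes; includes the driver."""
    graph = network.graph
    visited = {driver}
    frontier = [driver]
    for _ in range(radius):
        nxt = []
        for u in frontier:
            if u != driver and graph.degree(u) > max_transit_degree:
                continue
            for v in graph.neighbors(u):
                if v not in visited:
                    visited.add(v)
                    nxt.append(v)
        frontier = nxt
    return visited


def generate_cohort(
    network: GeneNetwork,
    n_samples: int = 60,
    drivers_per_sample: int = 3,
    passenger_rate: float = 7.0,
    effect_size: float = 4.0,
    effect_radius: int = 2,
    noise_sd: float = 0.5,
    decoy_rate: float = 0.0,
    n_normals: int = 30,
    seed: int = 0,
    driver_pool_size: int = 5,
    max_transit_degree: int = 50,
    baseline_mean: float = 7.0,
    baseline_sd: float = 1.5,
    hotspot_passengers: int = 2,
    hotspot_rate: float = 0.7,
) -> SyntheticCohort:
    """Simulate a tumor cohort with planted, recurrent driver genes.

    Each sample draws ``drivers_per_sample`` drivers from a pool of
    ``driver_pool_size`` non-hub genes; genes within ``effect_radius`` of a
    carried driver are shifted by ``effect_size`` log2 units (direction fixed
    per gene), on top of Gaussian baseline noise.  Passenger mutations arrive
    at ``passenger_rate`` per sample (Poisson) and decoys at ``decoy_rate``
    of each sample's mutation count, both without expression consequence.
    ``hotspot_passengers`` genes are recurrently mutated (at ``hotspot_rate``)
    yet phenotypically inert, emulating frequently mutated long genes that
    confound naive frequency ranking.  Decoys are drawn from a dedicated
    random substream, so the base cohort is bit-identical across decoy rates
    for a given seed.
    """
    rng = np.random.default_rng(seed)
    genes = sorted(network.nodes)
    gene_idx = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)
    non_hub = [g for g in genes if network.degree(g) <= max_transit_degree]
    if driver_pool_size > len(non_hub):
        raise ValueError("driver pool larger than the set of non-hub genes")
    pool = sorted(rng.choice(non_hub, size=driver_pool_size, replace=False))
    targets = {d: _effect_targets(network, d, effect_radius, max_transit_degree) for d in pool}
    hotspots = sorted(
        rng.choice([g for g in genes if g not in set(pool)],
                   size=hotspot_passengers, replace=False)
    ) if hotspot_passengers else []

    baseline = rng.normal(baseline_mean, baseline_sd, size=n_genes)
    sign = rng.choice([-1.0, 1.0], size=n_genes)

    samples = [f"T{i:03d}" for i in range(n_samples)]
    normals = [f"N{i:03d}" for i in range(n_normals)]
    mut = np.zeros((n_genes, n_samples), dtype=np.int8)
    expr_t = np.empty((n_genes, n_samples))
    truth: dict[str, set[str]] = {}

    for j, s in enumerate(samples):
        drivers = set(rng.choice(pool, size=drivers_per_sample, replace=False))
        truth[s] = drivers
        perturbed: set[str] = set()
        for d in drivers:
            perturbed |= targets[d]
        values = baseline + rng.normal(0.0, noise_sd, size=n_genes)
        for g in perturbed:
            i = gene_idx[g]
            values[i] += sign[i] * effect_size
        expr_t[:, j] = values
        for d in drivers:
            mut[gene_idx[d], j] = 1
        for g in hotspots:
            if rng.random() < hotspot_rate:
                mut[gene_idx[g], j] = 1
        n_passengers = rng.poisson(passenger_rate)
        free = [g for g in genes if mut[gene_idx[g], j] == 0]
        for g in rng.choice(free, size=min(n_passengers, len(free)), replace=False):
            mut[gene_idx[g], j] = 1

    expr_n = baseline[:, None] + rng.normal(0.0, noise_sd, size=(n_genes, n_normals))
    mutations = MutationMatrix(pd.DataFrame(mut, index=genes, columns=samples))
    if decoy_rate > 0:
        mutations = inject_decoys(mutations, decoy_rate, seed=seed)

    manifest = {
        "seed": int(seed),
        "n_samples": n_samples,
        "drivers_per_sample": drivers_per_sample,
        "passenger_rate": passenger_rate,
        "effect_size": effect_size,
        "effect_radius": effect_radius,
        "noise_sd": noise_sd,
        "decoy_rate": decoy_rate,
        "n_normals": n_normals,
        "driver_pool_size": driver_pool_size,
        "max_transit_degree": max_transit_degree,
        "baseline_mean": baseline_mean,
        "baseline_sd": baseline_sd,
        "hotspot_passengers": hotspot_passengers,
        "hotspot_rate": hotspot_rate,
        "driver_pool": [str(g) for g in pool],
        "hotspot_genes": [str(g) for g in hotspots],
    }
    return SyntheticCohort(
        network=network,
        mutations=mutations,
        tumors=ExpressionMatrix(pd.DataFrame(expr_t, index=genes, columns=samples), scale="log2"),
        normals=ExpressionMatrix(pd.DataFrame(expr_n, index=genes, columns=normals), scale="log2"),
        truth=truth,
        manifest=manifest,
    )


def inject_decoys(
    mutations: MutationMatrix, decoy_rate: float, seed: int = 0
) -> MutationMatrix:
    """Add decoy mutations to random unmutated genes, per sample.

    The number of decoys per sample is ``decoy_rate`` times the sample's
    mutation count, stochastically rounded.  Decoys emulate erroneous
    mutation calls; they never carry a planted expression consequence.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7919]))
    data = mutations.data.copy()
    arr = data.to_numpy()
    for j in range(arr.shape[1]):
        n_mut = int(arr[:, j].sum())
        exact = decoy_rate * n_mut
        n_decoy = int(np.floor(exact)) + int(rng.random() < (exact % 1))
        free = np.flatnonzero(arr[:, j] == 0)
        if n_decoy and len(free):
            picked = rng.choice(free, size=min(n_decoy, len(free)), replace=False)
            arr[picked, j] = 1
    return MutationMatrix(pd.DataFrame(arr, index=data.index, columns=data.columns))


# ---------------------------------------------------------------------------
# evaluation of the in-silico experiments
# ---------------------------------------------------------------------------

def evaluate_fpr(
    calls_by_sample: dict[str, set[str]], truth: dict[str, set[str]]
) -> tuple[pd.Series, float]:
    """Per-sample false positive rate of driver calls against planted truth.

    FPR(sample) = called-but-not-planted / called; samples with zero calls
    are excluded from the distribution.  Returns (per-sample series, median).
    """
    rows = {}
    for s, called in calls_by_sample.items():
        if not called:
            continue
        fp = len(called - truth.get(s, set()))
        rows[s] = fp / len(called)
    series = pd.Series(rows, dtype=float).sort_index()
    if series.empty:
        raise ValueError("no sample has any driver call")
    return series, float(series.median())


@dataclass
class StabilityRecovery:
    stability: float | None
    recovery: float
    recovery_common: float | None
    recovery_rare: float | None
    n_subset: int
    n_full: int


def evaluate_stability_recovery(
    full_genes: set[str],
    subset_genes: set[str],
    mutation_frequency: dict[str, float] | None = None,
    common_threshold: float = 0.05,
) -> StabilityRecovery:
    """Precision (stability) and sensitivity (recovery) of subset predictions
    against full-cohort predictions, optionally stratified at 5% mutation
    frequency into common and rare drivers."""
    inter = full_genes & subset_genes
    stability = len(inter) / len(subset_genes) if subset_genes else None
    recovery = len(inter) / len(full_genes) if full_genes else 0.0
    rec_common = rec_rare = None
    if mutation_frequency is not None and full_genes:
        common = {g for g in full_genes if mutation_frequency.get(g, 0.0) > common_threshold}
        rare = full_genes - common
        rec_common = len(inter & common) / len(common) if common else None
        rec_rare = len(inter & rare) / len(rare) if rare else None
    return StabilityRecovery(
        stability=stability,
        recovery=recovery,
        recovery_common=rec_common,
        recovery_rare=rec_rare,
        n_subset=len(subset_genes),
        n_full=len(full_genes),
    )


def frequency_ranking(mutations: MutationMatrix) -> pd.Series:
    """Mutation-frequency baseline: genes ranked by fraction of mutated samples."""
    freq = mutations.data.mean(axis=1).sort_values(ascending=False, kind="stable")
    return freq


# ---------------------------------------------------------------------------
# in-silico validation experiments
# ---------------------------------------------------------------------------

def _experiment_params():
    """Analysis settings for the in-silico validation experiments.

    Matched to the generator manifest (propagation radius 2, hub bound 50,
    F at half the planted log2 shift); the grid-search criterion is nearly
    flat on desk-scale cohorts, so the experiments fix the parameters rather
    than re-inferring them per replicate.
    """
    from .io_model import ParameterSet

    return ParameterSet(L=2, D=50, F=2.0)


def _experiment_grid():
    from .param_inference import ParameterGrid

    # reduced grid for desk-scale synthetic cohorts
    return ParameterGrid(L=(2, 4), D=(20, 50), F=(1.0, 1.5, 2.0, 2.5, 3.0))


def decoy_fpr_experiment(
    decoy_rates: tuple[float, ...] = (0.025, 0.10),
    n_seeds: int = 20,
    seed: int = 0,
    n_perm: int = 100,
    generator_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Decoy-mutation tolerance experiment.

    For each seed: generate a default cohort, inject decoys at each rate,
    run the full pipeline and score the per-sample FPR against planted
    truth.  Returns a long table (seed, decoy_rate, sample, fpr).
    """
    from .io_model import Cohort
    from .pipeline import RunConfig, run_pipeline

    rows = []
    base_seed = np.random.SeedSequence(seed).generate_state(1)[0] % (2**31 - 1)
    params = _experiment_params()
    for k in range(n_seeds):
        s = int((base_seed + k) % (2**31 - 1))
        net = generate_network(seed=s)
        sc = generate_cohort(net, seed=s, **(generator_kwargs or {}))
        for rate in decoy_rates:
            mutations = inject_decoys(sc.mutations, rate, seed=s)
            cohort = Cohort(mutations, sc.tumors, sc.normals)
            cfg = RunConfig(params=params, n_perm=n_perm, seed=s, de_method="ttest")
            res = run_pipeline(cfg, cohort=cohort, network=net)
            series, _ = evaluate_fpr(res.calls_by_sample(), sc.truth)
            for sample, fpr in series.items():
                rows.append((s, rate, sample, float(fpr)))
    return pd.DataFrame(rows, columns=["seed", "decoy_rate", "sample", "fpr"])


def subsampling_experiment(
    n_full: int = 100,
    subset_sizes: tuple[int, ...] = (20, 50),
    n_replicates: int = 20,
    seed: int = 0,
    n_perm: int = 100,
    generator_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Subsampling stability/recovery experiment.

    One full cohort is analyzed end to end; random subsets are re-analyzed
    with the same parameters and their cohort-level driver gene sets
    compared with the full run's.  Returns a table
    (subset_size, replicate, stability, recovery, recovery_common,
    recovery_rare).
    """
    from .pipeline import RunConfig, run_pipeline

    s = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31 - 1))
    net = generate_network(seed=s)
    sc = generate_cohort(net, n_samples=n_full, seed=s, **(generator_kwargs or {}))
    params = _experiment_params()
    cfg = RunConfig(params=params, n_perm=n_perm, seed=s, de_method="ttest")
    full = run_pipeline(cfg, cohort=sc.cohort, network=net)
    full_genes = full.driver_genes()
    mut_freq = frequency_ranking(sc.mutations).to_dict()
    rng = np.random.default_rng(s)
    rows = []
    samples = np.asarray(sc.mutations.samples)
    for size in subset_sizes:
        for rep in range(n_replicates):
            chosen = sorted(rng.choice(samples, size=size, replace=False))
            sub_cfg = RunConfig(params=params, n_perm=n_perm, seed=s + rep + 1, de_method="ttest")
            sub = run_pipeline(sub_cfg, cohort=sc.cohort.subset(chosen), network=net)
            sr = evaluate_stability_recovery(full_genes, sub.driver_genes(), mut_freq)
            rows.append(
                (size, rep, sr.stability, sr.recovery, sr.recovery_common, sr.recovery_rare)
            )
    return pd.DataFrame(
        rows,
        columns=["subset_size", "replicate", "stability", "recovery",
                 "recovery_common", "recovery_rare"],
    )
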