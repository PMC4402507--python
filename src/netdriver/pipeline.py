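"""End-to-end orchestration: deregulation -> parameters -> explained genes ->
phenotype genes -> set cover -> modules and impact ranking.

`RunConfig` carries every tunable with its default; `run_pipeline` executes
the stages in order on an in-memory cohort (or reads inputs from the
configured paths), optionally writing the driver tables, module files and a
run manifest to an output directory.  A single seed is expanded into
per-stage substreams so that identical config + seed reproduces identical
outputs byte for byte.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .deregulation import (
    call_deregulated,
    cohort_de_qvalues,
    deregulation_table,
    sample_log2_fold_changes,
)
from .driver_call import (
    DriverCall,
    build_cover_instance,
    call_table,
    greedy_set_cover,
    impact_scores,
    nominate_drivers,
)
from .io_model import (
    Cohort,
    GeneNetwork,
    ParameterSet,
    align_cohort,
    read_expression_matrix,
    read_mutation_matrix,
    read_network,
)
from .network_search import association_table, explained_frequency, explained_genes
from .param_inference import ParameterGrid, infer_parameters
from .phenotype import (
    PhenotypeGeneSet,
    call_phenotype_genes,
    empirical_pvalues,
    null_explained_frequencies,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline tunables; defaults are the method's standard settings."""

    network_path: str | None = None
    mutations_path: str | None = None
    tumors_path: str | None = None
    normals_path: str | None = None
    expression_scale: str = "linear"

    params: ParameterSet | None = None  # fixed L/D/F; None -> grid inference
    grid: ParameterGrid = field(default_factory=ParameterGrid)
    n_random: int = 50  # permuted cohorts per grid cell
    min_median_dereg: int = 300
    max_median_dereg_fraction: float = 0.5

    alpha: float = 0.05  # cohort DE FDR level
    de_method: str = "wilcoxon"
    freq_threshold: float = 0.05  # phenotype frequency gate
    fdr: float = 0.1  # phenotype significance gate
    n_perm: int = 500  # phenotype permutation count

    mode: str = "sensitive"
    seed: int = 0
    outdir: str | None = None
    write_deregulation: bool = False

    def __post_init__(self) -> None:
        for name, v in (("alpha", self.alpha), ("freq_threshold", self.freq_threshold),
                        ("fdr", self.fdr)):
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.mode not in ("stringent", "sensitive"):
            raise ValueError(f"mode must be stringent or sensitive, got {self.mode!r}")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.expression_scale not in ("linear", "log2"):
            raise ValueError(f"unknown expression scale {self.expression_scale!r}")

    def manifest_dict(self) -> dict:
        d = {
            k: v
            for k, v in self.__dict__.items()
            if k not in ("params", "grid") and not k.endswith("_path")
        }
        d["params"] = (
            None
            if self.params is None
            else {"L": self.params.L, "D": self.params.D, "F": self.params.F}
        )
        d["grid"] = {"L": list(self.grid.L), "D": list(self.grid.D), "F": list(self.grid.F)}
        for k in ("network_path", "mutations_path", "tumors_path", "normals_path"):
            d[k] = getattr(self, k)
        return d


@dataclass
class PipelineResult:
    params: ParameterSet
    profiles: dict
    maps: dict
    phenotype: PhenotypeGeneSet
    calls: list[DriverCall]
    ranking: object  # pd.DataFrame
    manifest: dict

    def calls_by_sample(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {s: set() for s in self.maps}
        for c in self.calls:
            out[c.sample].add(c.gene)
        return out

    def driver_genes(self) -> set[str]:
        return {c.gene for c in self.calls}


def load_inputs(config: RunConfig) -> tuple[Cohort, GeneNetwork]:
    network = read_network(config.network_path)
    mutations = read_mutation_matrix(config.mutations_path)
    tumors = read_expression_matrix(config.tumors_path, scale=config.expression_scale)
    normals = read_expression_matrix(config.normals_path, scale=config.expression_scale)
    return align_cohort(mutations, tumors, normals), network


def run_pipeline(
    config: RunConfig,
    cohort: Cohort | None = None,
    network: GeneNetwork | None = None,
) -> PipelineResult:
    """Execute every stage on the given (or loaded) cohort and network."""
    t0 = time.time()
    if cohort is None or network is None:
        cohort, network = load_inputs(config)
    seed_rng = np.random.default_rng(config.seed)
    infer_seed = int(seed_rng.integers(2**31 - 1))
    perm_seed = int(seed_rng.integers(2**31 - 1))
    timings: dict[str, float] = {}

    t = time.time()
    qvals = cohort_de_qvalues(cohort.tumors, cohort.normals, method=config.de_method)
    fcs = sample_log2_fold_changes(cohort.tumors, cohort.normals)
    timings["differential_expression"] = time.time() - t

    t = time.time()
    if config.params is not None:
        params = config.params
    else:
        result = infer_parameters(
            cohort,
            network,
            grid=config.grid,
            n_random=config.n_random,
            seed=infer_seed,
            min_median_dereg=config.min_median_dereg,
            max_median_dereg_fraction=config.max_median_dereg_fraction,
            de_method=config.de_method,
        )
        params = result.best
    timings["parameter_inference"] = time.time() - t

    t = time.time()
    profiles = call_deregulated(qvals, fcs, F=params.F, alpha=config.alpha)
    maps = {
        s: explained_genes(network, profiles[s], cohort.mutations.mutated_genes(s), params)
        for s in cohort.samples
    }
    timings["explained_genes"] = time.time() - t

    t = time.time()
    observed = explained_frequency(list(maps.values()))
    nulls = null_explained_frequencies(
        network, cohort.mutations, profiles, params, n_perm=config.n_perm, seed=perm_seed
    )
    pvals = empirical_pvalues(observed, nulls)
    phenotype = call_phenotype_genes(
        observed, pvals, freq_threshold=config.freq_threshold, fdr=config.fdr
    )
    timings["phenotype_genes"] = time.time() - t

    t = time.time()
    if phenotype.genes:
        instance = build_cover_instance(list(maps.values()), phenotype)
        selection = greedy_set_cover(instance)
        nominations = nominate_drivers(instance, selection, mode=config.mode)
        calls, ranking = impact_scores(nominations, maps, profiles, mode=config.mode)
    else:
        import pandas as pd

        logger.warning("no phenotype genes called; no drivers can be nominated")
        calls, ranking = [], pd.DataFrame(columns=["gene", "n_samples", "overall_impact"])
    timings["driver_calling"] = time.time() - t

    manifest = {
        "version": __version__,
        "config": config.manifest_dict(),
        "selected_parameters": {"L": params.L, "D": params.D, "F": params.F},
        "n_samples": len(cohort.samples),
        "n_network_genes": len(network.nodes),
        "n_phenotype_genes": len(phenotype.genes),
        "n_driver_calls": len(calls),
        "stage_seconds": {k: round(v, 3) for k, v in timings.items()},
        "total_seconds": round(time.time() - t0, 3),
    }
    result = PipelineResult(
        params=params,
        profiles=profiles,
        maps=maps,
        phenotype=phenotype,
        calls=calls,
        ranking=ranking,
        manifest=manifest,
    )
    if config.outdir is not None:
        write_artifacts(result, config, Path(config.outdir))
    return result


def write_artifacts(result: PipelineResult, config: RunConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    call_table(result.calls).to_csv(outdir / "drivers.tsv", sep="\t", index=False)
    result.ranking.to_csv(outdir / "driver_ranking.tsv", sep="\t", index=False)
    result.phenotype.called_table().to_csv(outdir / "phenotype_genes.tsv", sep="\t")
    association_table(list(result.maps.values())).to_csv(
        outdir / "explained_associations.tsv", sep="\t", index=False
    )
    if config.write_deregulation:
        deregulation_table(result.profiles).to_csv(
            outdir / "deregulation.tsv", sep="\t", index=False
        )
    modules_dir = outdir / "modules"
    modules_dir.mkdir(exist_ok=True)
    written = set()
    for c in result.calls:
        if c.module is None or id(c.module) in written:
            continue
        written.add(id(c.module))
        name = f"{c.sample}_{'_'.join(sorted(c.module.drivers))}.sif"
        with open(modules_dir / name, "w") as fh:
            for key, path in sorted(result.maps[c.sample].path_witness.items()):
                if key[0] in c.module.drivers and key[1] in c.module.phenotype_members:
                    for a, b in zip(path, path[1:]):
                        fh.write(f"{a}\tpp\t{b}\n")
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(result.manifest, fh, sort_keys=True)
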