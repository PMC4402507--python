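"""Driver nomination by parsimony, module construction and impact ranking.

Mutated genes associated with phenotype genes define a bipartite cover
problem over (sample, phenotype gene) pairs.  A greedy minimum set cover
keeps the smallest gene set explaining all observed phenotype-gene events;
genes never needed by the cover are *back-seat drivers* (bystanders dragged
in by network proximity to a real driver) and are discarded.  Remaining
drivers get per-patient modules (explained genes, merged on shared phenotype
genes, trimmed to driver-phenotype paths) and an impact score: the sum of
|log2 fold change| over module genes, averaged across patients for the
cohort-level ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .deregulation import DeregulationProfile
from .io_model import Cohort, Database, GeneNetwork, ParameterSet
from .network_search import ExplainedMap, explained_frequency, explained_genes
from .phenotype import PhenotypeGeneSet

logger = logging.getLogger(__name__)

Element = tuple[str, str]  # (sample, phenotype gene)


@dataclass
class CoverInstance:
    universe: set[Element]
    coverage: dict[str, set[Element]]
    patient_support: dict[str, int]
    non_associating: set[str] = field(default_factory=set)


@dataclass
class DriverModule:
    sample: str
    drivers: set[str]
    members: set[str]  # deregulated genes retained after trimming
    phenotype_members: set[str]


@dataclass
class DriverCall:
    sample: str
    gene: str
    covered_phenotype_genes: set[str]
    module: DriverModule | None
    impact: float
    mode: str


def associations_from_maps(
    maps: list[ExplainedMap], phenotype: PhenotypeGeneSet
) -> list[tuple[str, str, str]]:
    """(sample, mutated gene, phenotype gene) triples underlying the cover problem."""
    triples = []
    for emap in maps:
        for m in sorted(emap.assoc):
            for g in sorted(emap.assoc[m] & phenotype.genes):
                triples.append((emap.sample, m, g))
    return triples


def build_cover_instance(
    maps: list[ExplainedMap],
    phenotype: PhenotypeGeneSet,
    extra_associations: list[tuple[str, str, str]] | None = None,
) -> CoverInstance:
    """Assemble the (sample, phenotype gene) cover universe.

    ``extra_associations`` lets discovery mode pool a database cohort's
    associations with the new cohort's before solving the cover jointly.
    """
    if len(phenotype.genes) == 0:
        raise ValueError("phenotype gene set is empty")
    triples = associations_from_maps(maps, phenotype)
    if extra_associations:
        triples = triples + list(extra_associations)
    universe: set[Element] = set()
    coverage: dict[str, set[Element]] = {}
    support_samples: dict[str, set[str]] = {}
    for sample, mut, pheno in triples:
        el = (sample, pheno)
        universe.add(el)
        coverage.setdefault(mut, set()).add(el)
        support_samples.setdefault(mut, set()).add(sample)
    non_associating = {m for emap in maps for m in emap.assoc} - set(coverage)
    if not universe:
        raise ValueError("no phenotype gene is explained in any sample")
    return CoverInstance(
        universe=universe,
        coverage=coverage,
        patient_support={g: len(s) for g, s in support_samples.items()},
        non_associating=non_associating,
    )


def greedy_set_cover(instance: CoverInstance) -> list[tuple[str, set[Element]]]:
    """Greedy cover: most uncovered elements first; ties broken by larger
    patient support, then lexicographically by gene name."""
    uncovered = set(instance.universe)
    remaining = dict(instance.coverage)
    selection: list[tuple[str, set[Element]]] = []
    while uncovered:
        best = min(
            remaining,
            key=lambda g: (
                -len(remaining[g] & uncovered),
                -instance.patient_support.get(g, 0),
                g,  # lexicographically smallest wins the final tie
            ),
        )
        newly = remaining.pop(best) & uncovered
        assert newly, "pre-condition: universe is coverable"
        uncovered -= newly
        selection.append((best, newly))
    return selection


def nominate_drivers(
    instance: CoverInstance,
    selection: list[tuple[str, set[Element]]],
    mode: str = "sensitive",
) -> dict[str, dict[str, set[str]]]:
    """Per-sample driver nominations: sample -> gene -> covered phenotype genes.

    Stringent mode keeps a gene in exactly the samples where the greedy cover
    needed it.  Sensitive mode (default) keeps a gene in every sample where
    it explains a phenotype gene, discarding it everywhere only when the
    cover never needed it in any sample (a back-seat driver everywhere).
    """
    if mode not in ("stringent", "sensitive"):
        raise ValueError(f"unknown mode {mode!r}")
    selected_new: dict[str, set[Element]] = {g: newly for g, newly in selection}
    calls: dict[str, dict[str, set[str]]] = {}
    if mode == "stringent":
        for gene, newly in selection:
            for sample, pheno in newly:
                calls.setdefault(sample, {}).setdefault(gene, set()).add(pheno)
    else:
        for gene, elements in instance.coverage.items():
            if gene not in selected_new:
                continue  # back-seat driver in all patients
            for sample, pheno in elements:
                calls.setdefault(sample, {}).setdefault(gene, set()).add(pheno)
    return calls


def build_modules(
    sample: str,
    drivers: dict[str, set[str]],
    explained: ExplainedMap,
    profile: DeregulationProfile,
) -> list[DriverModule]:
    """Merged, trimmed per-patient modules.

    Each driver seeds a module from its explained genes; modules sharing a
    phenotype gene are merged transitively; members not on any stored
    shortest witness path between a module driver and a module phenotype
    gene are trimmed.
    """
    driver_list = sorted(drivers)
    parent = {d: d for d in driver_list}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    pheno_of = {d: set(drivers[d]) for d in driver_list}
    for i, a in enumerate(driver_list):
        for b in driver_list[i + 1 :]:
            if pheno_of[a] & pheno_of[b]:
                union(a, b)

    groups: dict[str, list[str]] = {}
    for d in driver_list:
        groups.setdefault(find(d), []).append(d)

    modules = []
    for members_drivers in groups.values():
        pheno_members: set[str] = set()
        kept: set[str] = set()
        for d in members_drivers:
            assert explained.assoc.get(d), "driver must explain at least one gene"
            pheno_members |= pheno_of[d]
        dereg = profile.genes
        for d in members_drivers:
            for p in sorted(pheno_of[d]):
                path = explained.path_witness[(d, p)]
                # witness nodes that are deregulated; includes the driver
                # itself only for the zero-length self-explanation path
                kept.update(n for n in path if n in dereg)
        modules.append(
            DriverModule(
                sample=sample,
                drivers=set(members_drivers),
                members=kept,
                phenotype_members=pheno_members,
            )
        )
    return modules


def impact_scores(
    calls: dict[str, dict[str, set[str]]],
    maps: dict[str, ExplainedMap],
    profiles: dict[str, DeregulationProfile],
    mode: str = "sensitive",
    signed: bool = False,
) -> tuple[list[DriverCall], pd.DataFrame]:
    """Per-driver per-sample impacts and the cohort-level ranking.

    Impact of a driver in a sample is the sum over its (merged) module's
    member genes of |log2FC| (or the signed sum with ``signed=True``); the
    overall impact is the mean over samples where the gene is called a
    driver.  Drivers sharing a merged module each receive the full module
    impact.
    """
    out_calls: list[DriverCall] = []
    per_gene: dict[str, list[float]] = {}
    for sample in sorted(calls):
        drivers = calls[sample]
        modules = build_modules(sample, drivers, maps[sample], profiles[sample])
        module_of = {d: m for m in modules for d in m.drivers}
        for gene in sorted(drivers):
            mod = module_of[gene]
            fc = profiles[sample].dereg
            vals = [fc[g] for g in mod.members if g in fc]
            impact = float(sum(vals)) if signed else float(sum(abs(v) for v in vals))
            out_calls.append(
                DriverCall(
                    sample=sample,
                    gene=gene,
                    covered_phenotype_genes=set(drivers[gene]),
                    module=mod,
                    impact=impact,
                    mode=mode,
                )
            )
            per_gene.setdefault(gene, []).append(impact)
    ranking = pd.DataFrame(
        {
            "gene": list(per_gene),
            "n_samples": [len(v) for v in per_gene.values()],
            "overall_impact": [sum(v) / len(v) for v in per_gene.values()],
        }
    ).sort_values(["overall_impact", "gene"], ascending=[False, True], ignore_index=True)
    return out_calls, ranking


def call_table(calls: list[DriverCall]) -> pd.DataFrame:
    rows = [
        (
            c.sample,
            c.gene,
            round(c.impact, 6),
            ";".join(sorted(c.covered_phenotype_genes)),
            len(c.module.members) if c.module else 0,
        )
        for c in calls
    ]
    return pd.DataFrame(
        rows, columns=["sample", "gene", "impact", "covered_phenotype_genes", "module_size"]
    )


# ---------------------------------------------------------------------------
# database / discovery orchestration
# ---------------------------------------------------------------------------

def run_database_mode(
    cohort: Cohort,
    network: GeneNetwork,
    params: ParameterSet,
    *,
    n_perm: int = 500,
    freq_threshold: float = 0.05,
    fdr: float = 0.1,
    alpha: float = 0.05,
    seed: int = 0,
    de_method: str = "wilcoxon",
    provenance: dict | None = None,
) -> Database:
    """Precompute parameters, phenotype genes and associations for reuse.

    ``params`` may come from :func:`netdriver.param_inference.infer_parameters`
    or be fixed by the caller.
    """
    from .deregulation import call_deregulated, cohort_de_qvalues, sample_log2_fold_changes
    from .phenotype import call_phenotype_genes, empirical_pvalues, null_explained_frequencies

    qvals = cohort_de_qvalues(cohort.tumors, cohort.normals, method=de_method)
    fcs = sample_log2_fold_changes(cohort.tumors, cohort.normals)
    profiles = call_deregulated(qvals, fcs, F=params.F, alpha=alpha)
    maps = [
        explained_genes(network, profiles[s], cohort.mutations.mutated_genes(s), params)
        for s in cohort.samples
    ]
    observed = explained_frequency(maps)
    nulls = null_explained_frequencies(
        network, cohort.mutations, profiles, params, n_perm=n_perm, seed=seed
    )
    pvals = empirical_pvalues(observed, nulls)
    pheno = call_phenotype_genes(observed, pvals, freq_threshold=freq_threshold, fdr=fdr)
    return Database(
        parameters=params,
        phenotype_genes=pheno.called_table(),
        cohort_explained=observed,
        network_hash=network.topology_hash(),
        provenance=dict(provenance or {}, n_samples=len(cohort.samples), n_perm=n_perm),
        cohort_associations=associations_from_maps(maps, pheno),
    )


def run_discovery_mode(
    db: Database,
    cohort: Cohort,
    network: GeneNetwork,
    *,
    mode: str = "sensitive",
    alpha: float = 0.05,
    de_method: str = "wilcoxon",
) -> tuple[list[DriverCall], pd.DataFrame]:
    """Call drivers for a new cohort using a precomputed database.

    The set cover pools database-cohort and discovery-cohort associations,
    but calls are emitted for discovery samples only.
    """
    from .deregulation import call_deregulated, cohort_de_qvalues, sample_log2_fold_changes

    if db.network_hash != network.topology_hash():
        raise ValueError("network does not match the one used to build the database")
    if len(db.phenotype_genes) == 0:
        raise ValueError("database has no phenotype genes; rebuild it before discovery")
    pheno = PhenotypeGeneSet(table=db.phenotype_genes, genes=set(db.phenotype_genes.index))
    params = db.parameters
    qvals = cohort_de_qvalues(cohort.tumors, cohort.normals, method=de_method)
    fcs = sample_log2_fold_changes(cohort.tumors, cohort.normals)
    profiles = call_deregulated(qvals, fcs, F=params.F, alpha=alpha)
    maps = {
        s: explained_genes(network, profiles[s], cohort.mutations.mutated_genes(s), params)
        for s in cohort.samples
    }
    discovery_samples = set(cohort.samples)
    # drop duplicated triples when the discovery cohort overlaps the database cohort
    extra = [t for t in db.cohort_associations if t[0] not in discovery_samples]
    instance = build_cover_instance(list(maps.values()), pheno, extra_associations=extra)
    selection = greedy_set_cover(instance)
    nominations = nominate_drivers(instance, selection, mode=mode)
    nominations = {s: d for s, d in nominations.items() if s in discovery_samples}
    if not nominations:
        logger.warning("no drivers nominated for any discovery sample")
        return [], pd.DataFrame(columns=["gene", "n_samples", "overall_impact"])
    calls, ranking = impact_scores(nominations, maps, profiles, mode=mode)
    return calls, ranking
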