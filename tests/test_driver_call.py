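import itertools
import math

import numpy as np
import pandas as pd
import pytest

from netdriver.deregulation import DeregulationProfile
from netdriver.driver_call import (
    CoverInstance,
    build_cover_instance,
    build_modules,
    greedy_set_cover,
    impact_scores,
    nominate_drivers,
    run_database_mode,
    run_discovery_mode,
)
from netdriver.io_model import Cohort, GeneNetwork, ParameterSet
from netdriver.network_search import ExplainedMap, explained_genes
from netdriver.phenotype import PhenotypeGeneSet


def pheno_set(genes):
    table = pd.DataFrame(
        {"frequency": [0.3] * len(genes), "p": [0.001] * len(genes), "q": [0.002] * len(genes)},
        index=sorted(genes),
    )
    return PhenotypeGeneSet(table=table, genes=set(genes))


def emap(sample, assoc, witnesses=None):
    m = ExplainedMap(sample=sample, assoc={k: set(v) for k, v in assoc.items()})
    for mut, genes in assoc.items():
        for g in genes:
            m.path_witness[(mut, g)] = witnesses.get((mut, g)) if witnesses else [mut, g]
    return m


class TestBuildCoverInstance:
    def test_assembles_universe_and_support(self):
        maps = [
            emap("s1", {"G": {"P1", "P2", "x"}}),
            emap("s2", {"G": {"P1"}, "H": {"x"}}),
        ]
        inst = build_cover_instance(maps, pheno_set({"P1", "P2"}))
        assert inst.coverage["G"] == {("s1", "P1"), ("s1", "P2"), ("s2", "P1")}
        assert inst.patient_support["G"] == 2
        # H explains only non-phenotype genes: absent from coverage,
        # remembered as non-associating
        assert "H" not in inst.coverage
        assert "H" in inst.non_associating

    def test_empty_universe_is_an_error(self):
        maps = [emap("s1", {"G": {"x"}})]
        with pytest.raises(ValueError, match="no phenotype gene is explained"):
            build_cover_instance(maps, pheno_set({"P1"}))


class TestGreedySetCover:
    def _instance(self):
        u = {("s", "a"), ("s", "b"), ("s", "c")}
        return CoverInstance(
            universe=u,
            coverage={
                "G1": {("s", "a"), ("s", "b")},
                "G2": {("s", "c")},
                "G3": {("s", "c")},
            },
            patient_support={"G1": 1, "G2": 2, "G3": 1},
        )

    def test_largest_coverage_then_support_tie_break(self):
        selection = greedy_set_cover(self._instance())
        assert [g for g, _ in selection] == ["G1", "G2"]

    def test_lexicographic_final_tie_break(self):
        u = {("s", "a")}
        inst = CoverInstance(
            universe=u,
            coverage={"ZZ": set(u), "AA": set(u)},
            patient_support={"ZZ": 1, "AA": 1},
        )
        assert greedy_set_cover(inst)[0][0] == "AA"

    def test_single_gene_covering_everything(self):
        u = {("s", "a"), ("s", "b")}
        inst = CoverInstance(universe=u, coverage={"G": set(u)}, patient_support={"G": 1})
        assert [g for g, _ in greedy_set_cover(inst)] == ["G"]

    def test_within_log_bound_of_brute_force_optimum(self):
        rng = np.random.default_rng(23)
        for _ in range(40):
            n_el = int(rng.integers(3, 9))
            n_sets = int(rng.integers(2, 13))
            universe = {("s", f"e{i}") for i in range(n_el)}
            coverage = {}
            elements = sorted(universe)
            for k in range(n_sets):
                size = int(rng.integers(1, n_el + 1))
                picked = rng.choice(len(elements), size=size, replace=False)
                coverage[f"G{k}"] = {elements[i] for i in picked}
            if set().union(*coverage.values()) != universe:
                continue
            inst = CoverInstance(
                universe=universe,
                coverage=coverage,
                patient_support={g: 1 for g in coverage},
            )
            selection = greedy_set_cover(inst)
            covered = set().union(*(newly for _, newly in selection))
            assert covered == universe
            opt = next(
                r
                for r in range(1, n_sets + 1)
                for combo in itertools.combinations(coverage, r)
                if set().union(*(coverage[g] for g in combo)) == universe
            )
            assert len(selection) <= (math.log(len(universe)) + 1) * opt
            # deterministic: rerun reproduces the exact selection
            assert greedy_set_cover(inst) == selection


class TestNominateDrivers:
    def _setup(self):
        maps = [
            emap("s1", {"G": {"P1"}, "B": {"P1"}}),
            emap("s2", {"G": {"P2"}}),
        ]
        inst = build_cover_instance(maps, pheno_set({"P1", "P2"}))
        selection = greedy_set_cover(inst)
        return inst, selection

    def test_sensitive_keeps_gene_wherever_it_associates(self):
        inst, selection = self._setup()
        calls = nominate_drivers(inst, selection, mode="sensitive")
        assert set(calls["s1"]) == {"G"} and set(calls["s2"]) == {"G"}
        # B newly covered nothing anywhere: back-seat driver, removed
        assert all("B" not in c for c in calls.values())

    def test_stringent_restricts_to_samples_where_needed(self):
        maps = [
            emap("s1", {"G": {"P1"}}),
            emap("s2", {"G": {"P1"}, "H": {"P1", "P2"}}),
        ]
        inst = build_cover_instance(maps, pheno_set({"P1", "P2"}))
        selection = greedy_set_cover(inst)
        stringent = nominate_drivers(inst, selection, mode="stringent")
        sensitive = nominate_drivers(inst, selection, mode="sensitive")
        for s in sensitive:
            assert set(stringent.get(s, {})) <= set(sensitive[s])

    def test_unknown_mode_rejected(self):
        inst, selection = self._setup()
        with pytest.raises(ValueError, match="mode"):
            nominate_drivers(inst, selection, mode="bogus")


class TestBuildModules:
    def test_shared_phenotype_gene_merges_modules(self):
        witnesses = {
            ("G1", "P1"): ["G1", "x", "P1"],
            ("G2", "P1"): ["G2", "y", "P1"],
        }
        m = emap("s", {"G1": {"x", "P1"}, "G2": {"y", "P1"}}, witnesses)
        profile = DeregulationProfile("s", {"x": 1.5, "y": -2.0, "P1": 2.5})
        modules = build_modules("s", {"G1": {"P1"}, "G2": {"P1"}}, m, profile)
        assert len(modules) == 1
        assert modules[0].drivers == {"G1", "G2"}
        assert modules[0].members == {"x", "y", "P1"}

    def test_dangling_deregulated_gene_trimmed(self):
        witnesses = {("G", "P1"): ["G", "a", "P1"], ("G", "z"): ["G", "z"]}
        m = emap("s", {"G": {"a", "P1", "z"}}, witnesses)
        profile = DeregulationProfile("s", {"a": 2.1, "P1": 3.0, "z": 2.2})
        modules = build_modules("s", {"G": {"P1"}}, m, profile)
        assert modules[0].members == {"a", "P1"}  # z lies on no driver-phenotype path

    def test_disjoint_phenotype_genes_stay_separate(self):
        m = emap("s", {"G1": {"P1"}, "G2": {"P2"}})
        profile = DeregulationProfile("s", {"P1": 2.0, "P2": -2.0})
        modules = build_modules("s", {"G1": {"P1"}, "G2": {"P2"}}, m, profile)
        assert len(modules) == 2
        for mod in modules:
            assert mod.phenotype_members <= {"P1", "P2"}
            # phenotype members survive trimming
            assert mod.phenotype_members <= mod.members


class TestImpactScores:
    def test_sum_of_absolute_fold_changes(self):
        witnesses = {("G", "P1"): ["G", "a", "P1"], ("G", "b"): ["G", "b"]}
        m = emap("s", {"G": {"a", "P1", "b"}}, witnesses)
        profiles = {"s": DeregulationProfile("s", {"a": 1.5, "P1": -2.0, "b": 2.5})}
        calls, ranking = impact_scores({"s": {"G": {"P1"}}}, {"s": m}, profiles)
        # module trims b; impact = |1.5| + |-2.0|
        assert calls[0].impact == pytest.approx(3.5)

    def test_overall_impact_averages_over_called_samples(self):
        maps, profiles, noms = {}, {}, {}
        for s, fc in (("s1", 2.0), ("s2", 3.0)):
            maps[s] = emap(s, {"G": {"P1"}})
            profiles[s] = DeregulationProfile(s, {"P1": fc})
            noms[s] = {"G": {"P1"}}
        calls, ranking = impact_scores(noms, maps, profiles)
        assert ranking.loc[0, "gene"] == "G"
        assert ranking.loc[0, "overall_impact"] == pytest.approx(2.5)
        assert ranking.loc[0, "n_samples"] == 2


class TestDatabaseDiscovery:
    @pytest.fixture(scope="class")
    def db_setup(self, small_cohort):
        net, sc = small_cohort
        params = ParameterSet(L=2, D=50, F=2.0)
        db = run_database_mode(
            sc.cohort, net, params, n_perm=40, seed=5, de_method="ttest"
        )
        return net, sc, db

    def test_database_contains_phenotype_genes_and_associations(self, db_setup):
        net, sc, db = db_setup
        assert len(db.phenotype_genes) > 0
        assert db.network_hash == net.topology_hash()
        assert all(len(t) == 3 for t in db.cohort_associations)

    def test_discovery_on_database_cohort_matches_direct_calling(self, db_setup):
        net, sc, db = db_setup
        calls, _ = run_discovery_mode(db, sc.cohort, net, de_method="ttest")
        from netdriver.deregulation import (
            call_deregulated,
            cohort_de_qvalues,
            sample_log2_fold_changes,
        )

        q = cohort_de_qvalues(sc.tumors, sc.normals, method="ttest")
        fc = sample_log2_fold_changes(sc.tumors, sc.normals)
        profiles = call_deregulated(q, fc, F=db.parameters.F)
        maps = {
            s: explained_genes(net, profiles[s], sc.mutations.mutated_genes(s), db.parameters)
            for s in sc.cohort.samples
        }
        pheno = PhenotypeGeneSet(
            table=db.phenotype_genes, genes=set(db.phenotype_genes.index)
        )
        inst = build_cover_instance(list(maps.values()), pheno)
        noms = nominate_drivers(inst, greedy_set_cover(inst))
        direct = {(s, g) for s, d in noms.items() for g in d}
        assert {(c.sample, c.gene) for c in calls} == direct

    def test_network_mismatch_rejected(self, db_setup):
        net, sc, db = db_setup
        other = GeneNetwork.from_edges([("A", "B")])
        with pytest.raises(ValueError, match="network"):
            run_discovery_mode(db, sc.cohort, other)

    def test_empty_phenotype_database_rejected(self, db_setup):
        net, sc, db = db_setup
        from dataclasses import replace

        empty = replace(db, phenotype_genes=pd.DataFrame(columns=["frequency", "p", "q"]))
        with pytest.raises(ValueError, match="no phenotype genes"):
            run_discovery_mode(empty, sc.cohort, net)

    def test_sample_without_mutations_yields_no_calls_no_error(self, db_setup):
        net, sc, db = db_setup
        mut = sc.mutations.data.copy()
        mut.iloc[:, 0] = 0  # strip the first sample's mutations
        cohort = Cohort(type(sc.mutations)(mut), sc.tumors, sc.normals)
        calls, _ = run_discovery_mode(db, cohort, net, de_method="ttest")
        first = sc.cohort.samples[0]
        assert all(c.sample != first for c in calls)
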