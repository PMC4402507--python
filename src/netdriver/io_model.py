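"""Core domain types and readers/writers.

Gene identity is by symbol string, case-sensitive; no alias resolution is
attempted.  Matrices are carried as pandas DataFrames with genes as rows and
samples as columns; the interaction network is an undirected
:class:`networkx.Graph` wrapped in :class:`GeneNetwork`.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DATABASE_SCHEMA_VERSION = 1

#: MAF variant classes that do not alter the protein product and are skipped
#: when building the binary mutation matrix.
SILENT_VARIANT_CLASSES = frozenset({"silent", "synonymous", "rna", "intron", "utr", "igr"})

QUALIFYING_VARIANT_CLASSES = frozenset(
    {
        "missense",
        "missense_mutation",
        "nonsense",
        "nonsense_mutation",
        "frame_shift_del",
        "frame_shift_ins",
        "in_frame_del",
        "in_frame_ins",
        "indel",
        "splice_site",
        "nonstop_mutation",
        "translation_start_site",
    }
)


class SchemaVersionError(ValueError):
    """Raised when a serialized database carries an unsupported schema version."""


@dataclass(frozen=True)
class GeneNetwork:
    """Undirected gene interaction network.

    Wraps a :class:`networkx.Graph`; nodes are gene symbols, edges are
    unordered gene pairs with no self-loops.
    """

    graph: nx.Graph

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, gene: str) -> int:
        return self.graph.degree(gene)

    def neighbors(self, gene: str) -> list[str]:
        return sorted(self.graph.neighbors(gene))

    def __contains__(self, gene: str) -> bool:
        return gene in self.graph

    def degree_map(self) -> dict[str, int]:
        return dict(self.graph.degree())

    def topology_hash(self) -> str:
        """Stable hash of the node/edge sets, used to pair a database with a network."""
        edges = sorted(tuple(sorted(e)) for e in self.graph.edges)
        payload = json.dumps([sorted(self.graph.nodes), edges]).encode()
        return hashlib.sha256(payload).hexdigest()

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]], isolated: Iterable[str] = ()) -> "GeneNetwork":
        g = nx.Graph()
        g.add_nodes_from(isolated)
        n_loops = 0
        for a, b in edges:
            if a == b:
                n_loops += 1
                g.add_node(a)
                continue
            g.add_edge(a, b)
        if n_loops:
            logger.info("dropped %d self-loop edge(s)", n_loops)
        return cls(g)


@dataclass(frozen=True)
class MutationMatrix:
    """Binary somatic alteration status, genes x samples.

    A cell is 1 when the gene carries a non-synonymous SNV, an indel or a
    copy-number alteration in that sample; amplification and deletion are not
    distinguished downstream, so status is strictly binary.
    """

    data: pd.DataFrame  # genes x samples, values in {0, 1}

    def __post_init__(self) -> None:
        vals = self.data.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mutation matrix must be binary")
        if self.data.index.duplicated().any():
            raise ValueError("duplicate gene identifiers in mutation matrix")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    def mutated_genes(self, sample: str) -> set[str]:
        col = self.data[sample]
        return set(col.index[col.to_numpy() == 1])

    def with_samples(self, samples: list[str]) -> "MutationMatrix":
        return MutationMatrix(self.data[samples])


@dataclass(frozen=True)
class ExpressionMatrix:
    """Expression values, genes x samples, with a declared scale.

    ``scale`` is ``"linear"`` (raw intensities / counts) or ``"log2"``.
    Per-sample fold changes honour the scale: ratios on linear input,
    differences on log2 input.
    """

    data: pd.DataFrame
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"unknown expression scale {self.scale!r}")
        if self.data.index.duplicated().any():
            raise ValueError("duplicate gene identifiers in expression matrix")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    def with_samples(self, samples: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data[samples], self.scale)


@dataclass(frozen=True)
class ParameterSet:
    """Path-search and perturbation thresholds.

    L: maximum path length in edges; D: maximum degree of an intermediate
    path node (hub exclusion); F: threshold on |log2 fold change|.
    """

    L: int
    D: int
    F: float

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.D < 1:
            raise ValueError("D must be >= 1")
        if self.F <= 0:
            raise ValueError("F must be > 0")


@dataclass
class Cohort:
    """Joint tumor cohort: mutations plus tumor and normal expression.

    Samples are the intersection of mutation and tumor-expression samples;
    mismatched samples are dropped with a warning at construction time via
    :func:`align_cohort`.
    """

    mutations: MutationMatrix
    tumors: ExpressionMatrix
    normals: ExpressionMatrix

    @property
    def samples(self) -> list[str]:
        return self.mutations.samples

    def subset(self, samples: list[str]) -> "Cohort":
        return Cohort(
            self.mutations.with_samples(samples),
            self.tumors.with_samples(samples),
            self.normals,
        )


@dataclass
class Database:
    """Pre-computed cohort information for discovery-mode runs."""

    parameters: ParameterSet
    phenotype_genes: pd.DataFrame  # index gene, columns frequency, p, q
    cohort_explained: dict[str, float]  # gene -> explained frequency
    network_hash: str
    provenance: dict = field(default_factory=dict)
    #: (sample, mutated_gene, phenotype_gene) association triples of the
    #: database cohort; discovery mode pools these with the new cohort's.
    cohort_associations: list[tuple[str, str, str]] = field(default_factory=list)


def align_cohort(
    mutations: MutationMatrix, tumors: ExpressionMatrix, normals: ExpressionMatrix
) -> Cohort:
    """Restrict to samples with both mutation and expression data."""
    shared = [s for s in mutations.samples if s in set(tumors.samples)]
    dropped = (set(mutations.samples) | set(tumors.samples)) - set(shared)
    if dropped:
        logger.warning("dropping %d sample(s) lacking joint mutation+expression data: %s",
                       len(dropped), sorted(dropped))
    if not shared:
        raise ValueError("no samples shared between mutation and expression matrices")
    return Cohort(mutations.with_samples(shared), tumors.with_samples(shared), normals)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_network(path: str | Path, format: str = "edge-list-tsv") -> GeneNetwork:
    """Read an undirected network from a 2-column edge list or a 3-column SIF file.

    Duplicate edges are collapsed; self-loops are dropped (the node is kept,
    possibly isolated) and counted in the log.
    """
    path = Path(path)
    if format not in ("edge-list-tsv", "sif"):
        raise ValueError(f"unknown network format {format!r}")
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if format == "edge-list-tsv":
                if len(fields) != 2:
                    raise ValueError(f"{path}:{lineno}: expected 2 fields, got {len(fields)}")
                edges.append((fields[0], fields[1]))
            else:  # sif: node relation node
                if len(fields) != 3:
                    raise ValueError(f"{path}:{lineno}: expected 3 fields (SIF), got {len(fields)}")
                edges.append((fields[0], fields[2]))
    if not edges:
        raise ValueError(f"{path}: no edges found")
    return GeneNetwork.from_edges(edges)


def read_mutation_matrix(
    path: str | Path,
    format: str = "binary-tsv",
    cnv_path: str | Path | None = None,
) -> MutationMatrix:
    """Read mutation status as a binary TSV or as a MAF-lite table merged with CNV calls.

    MAF-lite columns: gene, sample, variant_class.  CNV columns: gene, sample,
    call in {amp, del, neutral}.  A gene is mutated in a sample if it has a
    qualifying (non-silent) variant or a non-neutral CNV call.
    """
    path = Path(path)
    if format == "binary-tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        vals = df.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            bad = np.argwhere(~np.isin(vals, (0, 1)))[0]
            raise ValueError(
                f"{path}: non-binary value at gene {df.index[bad[0]]!r}, sample {df.columns[bad[1]]!r}"
            )
        return MutationMatrix(df.astype(np.int8))
    if format != "maf-lite":
        raise ValueError(f"unknown mutation format {format!r}")

    maf = pd.read_csv(path, sep="\t")
    required = {"gene", "sample", "variant_class"}
    if not required.issubset(maf.columns):
        raise ValueError(f"{path}: MAF-lite requires columns {sorted(required)}")
    pairs: set[tuple[str, str]] = set()
    for gene, sample, vc in maf[["gene", "sample", "variant_class"]].itertuples(index=False):
        vc_norm = str(vc).lower()
        if vc_norm in QUALIFYING_VARIANT_CLASSES:
            pairs.add((str(gene), str(sample)))
        elif vc_norm in SILENT_VARIANT_CLASSES:
            continue
        else:
            warnings.warn(f"unknown variant_class {vc!r}; row skipped")
    if cnv_path is not None:
        cnv = pd.read_csv(cnv_path, sep="\t")
        if not {"gene", "sample", "call"}.issubset(cnv.columns):
            raise ValueError(f"{cnv_path}: CNV table requires columns gene, sample, call")
        for gene, sample, call in cnv[["gene", "sample", "call"]].itertuples(index=False):
            if call not in ("amp", "del", "neutral"):
                raise ValueError(f"{cnv_path}: unknown CNV call {call!r}")
            if call != "neutral":
                pairs.add((str(gene), str(sample)))
    if not pairs:
        raise ValueError("no qualifying mutations found")
    genes = sorted({g for g, _ in pairs})
    samples = sorted({s for _, s in pairs})
    df = pd.DataFrame(0, index=genes, columns=samples, dtype=np.int8)
    for g, s in pairs:
        df.loc[g, s] = 1
    return MutationMatrix(df)


def read_expression_matrix(path: str | Path, scale: str = "linear") -> ExpressionMatrix:
    """Read a genes x samples expression TSV with a declared scale."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.columns.isnull().any() or df.index.isnull().any():
        raise ValueError(f"{path}: missing header field")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene row {dup!r}")
    try:
        df = df.astype(float)
    except ValueError:
        obj = df.apply(pd.to_numeric, errors="coerce")
        bad = np.argwhere(obj.isnull().to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric cell at gene {df.index[bad[0]]!r}, sample {df.columns[bad[1]]!r}"
        ) from None
    if df.isnull().to_numpy().any():
        bad = np.argwhere(df.isnull().to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric cell at gene {df.index[bad[0]]!r}, sample {df.columns[bad[1]]!r}"
        )
    return ExpressionMatrix(df, scale=scale)


# ---------------------------------------------------------------------------
# database serialization (versioned JSON archive)
# ---------------------------------------------------------------------------

def write_database(db: Database, path: str | Path) -> None:
    """Serialize a database to a single versioned JSON file."""
    if len(db.phenotype_genes) == 0:
        warnings.warn("database has an empty phenotype gene set")
    payload = {
        "schema_version": DATABASE_SCHEMA_VERSION,
        "parameters": {"L": db.parameters.L, "D": db.parameters.D, "F": db.parameters.F},
        "phenotype_genes": {
            g: {"frequency": float(r["frequency"]), "p": float(r["p"]), "q": float(r["q"])}
            for g, r in db.phenotype_genes.iterrows()
        },
        "cohort_explained": {g: float(f) for g, f in db.cohort_explained.items()},
        "network_hash": db.network_hash,
        "provenance": db.provenance,
        "cohort_associations": [list(t) for t in db.cohort_associations],
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_database(path: str | Path) -> Database:
    payload = json.loads(Path(path).read_text())
    version = payload.get("schema_version")
    if version != DATABASE_SCHEMA_VERSION:
        raise SchemaVersionError(
            f"unsupported database schema version {version!r} (expected {DATABASE_SCHEMA_VERSION})"
        )
    pheno = pd.DataFrame.from_dict(payload["phenotype_genes"], orient="index")
    if len(pheno) == 0:
        pheno = pd.DataFrame(columns=["frequency", "p", "q"])
    pheno = pheno[["frequency", "p", "q"]] if len(pheno) else pheno
    p = payload["parameters"]
    return Database(
        parameters=ParameterSet(L=int(p["L"]), D=int(p["D"]), F=float(p["F"])),
        phenotype_genes=pheno.sort_index(),
        cohort_explained=dict(payload["cohort_explained"]),
        network_hash=payload["network_hash"],
        provenance=dict(payload.get("provenance", {})),
        cohort_associations=[tuple(t) for t in payload.get("cohort_associations", [])],
    )


def write_matrix_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")
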