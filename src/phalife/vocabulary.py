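"""Protein-cluster token vocabulary construction.

Phage proteins are grouped into homology clusters from an all-against-all
similarity search (12-column tabular alignment format, e-values as edge
weights), using Markov clustering (MCL) on the similarity graph. Every
surviving multi-member cluster becomes one token of a closed vocabulary;
singleton clusters are removed. The vocabulary additionally carries five
special tokens ([PAD], [UNK], [CLS], [SEP], [MASK]) used by the sentence
encoder and the masked-LM training task.

E-values are transformed to similarity weights w = -log10(max(e, 1e-200)),
the standard practice for running MCL on BLAST-style graphs: MCL needs
larger-is-stronger non-negative weights, while e-values are
smaller-is-stronger.
"""

from __future__ import annotations

import gzip
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence, TextIO

import networkx as nx
import numpy as np

__all__ = [
    "SimilarityEdge",
    "ProteinCluster",
    "ProteinVocabulary",
    "SPECIAL_TOKENS",
    "PAD", "UNK", "CLS", "SEP", "MASK",
    "read_alignment_table",
    "build_similarity_graph",
    "markov_cluster",
    "build_vocabulary",
]

# Special-token ids, fixed repo-wide.
PAD, UNK, CLS, SEP, MASK = 0, 1, 2, 3, 4
SPECIAL_TOKENS = ("[PAD]", "[UNK]", "[CLS]", "[SEP]", "[MASK]")

#: floor applied to e-values before the -log10 transform (DIAMOND reports 0.0
#: for very strong hits; log of 0 is undefined).
EVALUE_FLOOR = 1e-200


@dataclass(frozen=True)
class SimilarityEdge:
    """One row of an all-against-all protein alignment table."""

    query_id: str
    subject_id: str
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative e-value {self.evalue} for "
                             f"{self.query_id} vs {self.subject_id}")


@dataclass(frozen=True)
class ProteinCluster:
    """A set of homologous proteins; one future vocabulary token.

    ``representative_id`` is the lexicographically smallest member, used as
    the cluster-side target of downstream best-hit token assignment.
    """

    cluster_id: int
    members: frozenset[str]
    representative_id: str

    @classmethod
    def from_members(cls, cluster_id: int, members: Iterable[str]) -> "ProteinCluster":
        mem = frozenset(members)
        if not mem:
            raise ValueError("cluster must have at least one member")
        return cls(cluster_id, mem, min(mem))

    @property
    def size(self) -> int:
        return len(self.members)


class AlignmentFormatError(ValueError):
    """A malformed row in a tabular alignment file, with its line number."""


def _open_text(path: str | Path) -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_alignment_table(path: str | Path) -> Iterator[SimilarityEdge]:
    """Stream a 12-column tabular alignment file (plain or gzip).

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend
    sstart send evalue bitscore. Only qseqid, sseqid, evalue and bitscore
    are retained. Malformed rows raise :class:`AlignmentFormatError` naming
    the offending line.
    """
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise AlignmentFormatError(
                    f"line {lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}")
            try:
                yield SimilarityEdge(fields[0], fields[1],
                                     float(fields[10]), float(fields[11]))
            except ValueError as exc:
                raise AlignmentFormatError(f"line {lineno}: {exc}") from exc


def evalue_to_weight(evalue: float) -> float:
    """Similarity weight for an e-value: -log10 with a 1e-200 floor."""
    return float(-np.log10(max(evalue, EVALUE_FLOOR)))


def build_similarity_graph(
    edges: Iterable[SimilarityEdge],
    evalue_cutoff: float = 1e-5,
) -> nx.Graph:
    """Build the undirected weighted protein-similarity graph.

    Edges with e-value above ``evalue_cutoff`` are dropped. For a pair
    reported in both directions the stronger (larger) transformed weight is
    kept. Self-alignments contribute their node but no edge.
    """
    if evalue_cutoff <= 0:
        raise ValueError("evalue_cutoff must be > 0")
    g = nx.Graph()
    for edge in edges:
        if edge.evalue > evalue_cutoff:
            continue
        g.add_node(edge.query_id)
        g.add_node(edge.subject_id)
        if edge.query_id == edge.subject_id:
            continue  # self-loops re-added uniformly inside MCL
        w = evalue_to_weight(edge.evalue)
        u, v = edge.query_id, edge.subject_id
        if g.has_edge(u, v):
            if w > g[u][v]["weight"]:
                g[u][v]["weight"] = w
        else:
            g.add_edge(u, v, weight=w)
    return g


class MCLConvergenceWarning(UserWarning):
    pass


def _mcl_interpret(m: np.ndarray, eps: float = 1e-6) -> list[set[int]]:
    """Read clusters off a (near-)idempotent MCL matrix.

    Attractors are nodes with positive mass on their own diagonal; each
    attractor's row support is a cluster; overlapping attractor sets are
    merged (connected attractor systems). Any node left unassigned by a
    non-converged matrix joins the cluster of its strongest incoming row.
    """
    n = m.shape[0]
    attractors = [i for i in range(n) if m[i, i] > eps]
    clusters: list[set[int]] = []
    for a in attractors:
        support = set(np.nonzero(m[a] > eps)[0].tolist())
        merged = [c for c in clusters if c & support]
        for c in merged:
            support |= c
            clusters.remove(c)
        clusters.append(support)
    assigned = set().union(*clusters) if clusters else set()
    for j in range(n):
        if j in assigned:
            continue
        i = int(np.argmax(m[:, j]))
        home = next((c for c in clusters if i in c), None)
        if home is None:
            home = {i}
            clusters.append(home)
        home.add(j)
        assigned.add(j)
    return clusters


def markov_cluster(
    graph: nx.Graph,
    inflation: float = 2.0,
    self_loop_weight: float | str = "max",
    max_iter: int = 100,
    tol: float = 1e-6,
    prune: float = 1e-8,
) -> list[ProteinCluster]:
    """Markov clustering of a non-negative weighted graph.

    Standard MCL: build a column-stochastic matrix with self-loops added,
    then alternate expansion (matrix squaring) and inflation (elementwise
    power ``inflation`` followed by column renormalisation) until the
    maximum column-wise change drops below ``tol`` or ``max_iter`` is
    reached (the latter emits :class:`MCLConvergenceWarning` and returns
    the current interpretation). Entries below ``prune`` are zeroed each
    iteration for sparsity.

    ``self_loop_weight="max"`` gives every node a self-loop equal to its
    maximum incident edge weight (1.0 for isolated nodes); a float applies
    uniformly. Nodes are sorted lexicographically before matrix
    construction, so the output is deterministic. Isolated nodes come out
    as singleton clusters. Returned clusters are sorted by
    (descending size, lexicographically smallest member) and numbered from 0.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    nodes = sorted(graph.nodes)
    n = len(nodes)
    if n == 0:
        return []
    index = {v: i for i, v in enumerate(nodes)}
    m = np.zeros((n, n))
    for u, v, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        if w < 0:
            raise ValueError(f"negative edge weight on {u}--{v}")
        m[index[u], index[v]] = w
        m[index[v], index[u]] = w
    if self_loop_weight == "max":
        loops = np.maximum(m.max(axis=0), 1.0 * (m.max(axis=0) == 0))
    else:
        loops = np.full(n, float(self_loop_weight))
    np.fill_diagonal(m, loops)

    m = m / m.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(max_iter):
        prev = m
        m = m @ m                      # expansion
        m = np.power(m, inflation)     # inflation
        m[m < prune] = 0.0
        colsum = m.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        m = m / colsum
        if np.abs(m - prev).max() < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"MCL did not converge within {max_iter} iterations; "
            "returning the current cluster interpretation",
            MCLConvergenceWarning)

    raw = _mcl_interpret(m)
    member_sets = sorted(
        (sorted(nodes[i] for i in c) for c in raw),
        key=lambda ms: (-len(ms), ms[0]))
    return [ProteinCluster.from_members(cid, ms)
            for cid, ms in enumerate(member_sets)]


@dataclass
class ProteinVocabulary:
    """Closed token vocabulary over protein clusters plus special tokens.

    Token ids are contiguous: specials occupy 0..4 and cluster tokens
    5..V-1, assigned to clusters sorted by (descending size, smallest
    member). Every cluster token maps to a cluster with >= 2 members.
    """

    clusters: list[ProteinCluster] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._token_by_cluster = {c.cluster_id: len(SPECIAL_TOKENS) + i
                                  for i, c in enumerate(self.clusters)}
        self._cluster_by_token = {t: cid
                                  for cid, t in self._token_by_cluster.items()}
        self._token_by_rep = {c.representative_id: len(SPECIAL_TOKENS) + i
                              for i, c in enumerate(self.clusters)}

    @property
    def size(self) -> int:
        """Total token count V (specials + cluster tokens)."""
        return len(SPECIAL_TOKENS) + len(self.clusters)

    @property
    def cluster_token_ids(self) -> range:
        return range(len(SPECIAL_TOKENS), self.size)

    def token_for_cluster(self, cluster_id: int) -> int:
        return self._token_by_cluster[cluster_id]

    def cluster_for_token(self, token_id: int) -> int:
        return self._cluster_by_token[token_id]

    def token_for_representative(self, representative_id: str) -> int:
        """Token id of the cluster whose representative this is.

        Raises KeyError naming the representative when it is unknown.
        """
        try:
            return self._token_by_rep[representative_id]
        except KeyError:
            raise KeyError(
                f"unknown cluster representative {representative_id!r}"
            ) from None

    # ---------------------------------------------------------------- I/O
    def save(self, prefix: str | Path, params: dict | None = None) -> None:
        """Write ``<prefix>.vocab.tsv`` plus a ``<prefix>.vocab.json`` sidecar."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        with open(f"{prefix}.vocab.tsv", "w") as fh:
            fh.write("token_id\tcluster_id\tsize\trepresentative_id\tmembers\n")
            for c in self.clusters:
                fh.write(f"{self.token_for_cluster(c.cluster_id)}\t"
                         f"{c.cluster_id}\t{c.size}\t{c.representative_id}\t"
                         f"{','.join(sorted(c.members))}\n")
        sidecar = {
            "special_tokens": {name: i for i, name in enumerate(SPECIAL_TOKENS)},
            "size": self.size,
            "build_params": params or {},
        }
        with open(f"{prefix}.vocab.json", "w") as fh:
            json.dump(sidecar, fh, indent=2)
            fh.write("\n")

    @classmethod
    def load(cls, prefix: str | Path) -> "ProteinVocabulary":
        clusters = []
        with open(f"{prefix}.vocab.tsv") as fh:
            header = fh.readline()
            if not header.startswith("token_id"):
                raise ValueError(f"{prefix}.vocab.tsv: missing header")
            for line in fh:
                _tid, cid, _size, _rep, members = line.rstrip("\n").split("\t")
                clusters.append(
                    ProteinCluster.from_members(int(cid), members.split(",")))
        return cls(clusters)

    def write_representative_fasta(
        self, path: str | Path, sequences: dict[str, str]
    ) -> None:
        """FASTA of cluster representatives, the target of token assignment."""
        with open(path, "w") as fh:
            for c in self.clusters:
                fh.write(f">{c.representative_id}\n"
                         f"{sequences[c.representative_id]}\n")


class EmptyVocabularyWarning(UserWarning):
    pass


def build_vocabulary(clusters: Sequence[ProteinCluster]) -> ProteinVocabulary:
    """Token vocabulary from a cluster partition, singletons removed.

    Surviving clusters are sorted by (descending size, lexicographically
    smallest member) and assigned token ids 5, 6, ...; the result is
    independent of the input ordering. If every cluster is a singleton the
    vocabulary holds only the special tokens and a warning is emitted.
    """
    survivors = [c for c in clusters if c.size >= 2]
    survivors.sort(key=lambda c: (-c.size, c.representative_id))
    if clusters and not survivors:
        warnings.warn("all clusters are singletons; vocabulary holds only "
                      "special tokens", EmptyVocabularyWarning)
    renumbered = [ProteinCluster.from_members(c.cluster_id, c.members)
                  for c in survivors]
    return ProteinVocabulary(renumbered)
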