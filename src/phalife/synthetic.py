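"""Seeded synthetic universe for hermetic end-to-end testing.

Generates a self-contained toy world with the statistical structure the
classifier assumes: a set of protein clusters (each seeded by a random
ancestor and filled with point-mutated copies), genomes built as ordered
mosaics of back-translated genes, lifestyle labels with a planted
composition signal (marker clusters enriched in temperate genomes, the way
integrase-like genes mark real temperate phages), and alignment tables
synthesized from the ground truth, so the vocabulary and tokenizer modules
run without any external aligner. E-values are drawn as 10^-k with k high
within clusters; cross-cluster pairs are absent.

Everything is deterministic given the seed; the ground-truth cluster map
and gene layout are emitted for oracle checks. The generator makes no
attempt at realistic phage genomics (no recombination, no host
contamination, no sequencing error, uniform codon usage).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .model import CLASS_NAMES
from .pretrain import FragmentRecord
from .tokenizer import (ProteinCall, TokenSentence, assign_tokens,
                        encode_sentence, window_tokens)
from .vocabulary import ProteinVocabulary, SimilarityEdge

__all__ = [
    "SyntheticSpec",
    "SyntheticUniverse",
    "generate_universe",
    "FragmentTokenizer",
    "make_bigram_corpus",
    "make_uniform_corpus",
    "random_genome_lengths",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"
# fixed back-translation table: one codon per amino acid, stop = TAA
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}
_STOP = "TAA"


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the toy universe.

    ``marker_clusters`` are cluster indices whose genes are
    ``marker_enrichment`` times more likely in temperate genomes; with
    enrichment 1 the labels carry no signal. ``mutation_rate`` is the
    per-residue substitution probability between a cluster's ancestor and
    each member. ``n_singletons`` adds lone proteins that appear in the
    all-vs-all table only as self-hits, exercising singleton removal.
    """

    n_clusters: int = 20
    proteins_per_cluster: int = 6
    n_genomes_per_class: int = 60
    genes_per_genome: tuple[int, int] = (15, 30)
    marker_clusters: tuple[int, ...] = (0, 1, 2, 3, 4)
    # 10x enrichment puts per-gene marker probability at 0.77 vs 0.25,
    # separating genome-level marker composition by ~3 sigma so the optimal
    # (Bayes) classifier on multi-gene fragments is nearly always right
    marker_enrichment: float = 10.0
    mutation_rate: float = 0.05
    protein_length: int = 100
    spacer_length: int = 20
    n_singletons: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not set(self.marker_clusters) <= set(range(self.n_clusters)):
            raise ValueError("marker_clusters must be a subset of the "
                             f"{self.n_clusters} clusters")
        if not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must be in [0, 1]")
        if self.marker_enrichment <= 0:
            raise ValueError("marker_enrichment must be positive")
        if self.genes_per_genome[0] > self.genes_per_genome[1]:
            raise ValueError("genes_per_genome range is inverted")


@dataclass(frozen=True)
class GeneAnnotation:
    """Ground-truth gene layout entry on a synthetic genome."""

    start: int
    end: int
    strand: str
    protein_id: str
    cluster: int


@dataclass
class SyntheticUniverse:
    """All generated artifacts plus the ground truth behind them."""

    spec: SyntheticSpec
    proteins: dict[str, str]
    cluster_of: dict[str, int]
    genomes: dict[str, str]
    genome_genes: dict[str, list[GeneAnnotation]]
    labels: dict[str, str]
    all_vs_all: list[tuple]
    query_hits: list[tuple]

    # ------------------------------------------------------- conveniences
    def alignment_edges(self) -> Iterator[SimilarityEdge]:
        for row in self.all_vs_all:
            yield SimilarityEdge(row[0], row[1], float(row[10]),
                                 float(row[11]))

    def query_hit_edges(self) -> list[SimilarityEdge]:
        return [SimilarityEdge(r[0], r[1], float(r[10]), float(r[11]))
                for r in self.query_hits]

    def protein_calls(self) -> dict[str, list[ProteinCall]]:
        """Precomputed gene calls per genome, for the tokenizer backend."""
        out: dict[str, list[ProteinCall]] = {}
        for gid, genes in self.genome_genes.items():
            out[gid] = [ProteinCall(gid, i, g.start, g.end, g.strand,
                                    self.proteins[g.protein_id])
                        for i, g in enumerate(genes)]
        return out

    def true_partition(self) -> dict[int, set[str]]:
        """Ground-truth cluster -> member proteins (singletons included)."""
        part: dict[int, set[str]] = {}
        for pid, c in self.cluster_of.items():
            part.setdefault(c, set()).add(pid)
        return part

    # --------------------------------------------------------------- I/O
    def write(self, out_dir: str | Path) -> None:
        """Write FASTA/TSV artifacts consumed verbatim by the CLIs."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "proteins.faa", "w") as fh:
            for pid in sorted(self.proteins):
                fh.write(f">{pid}\n{self.proteins[pid]}\n")
        with open(out / "genomes.fna", "w") as fh:
            for gid in sorted(self.genomes):
                fh.write(f">{gid}\n{self.genomes[gid]}\n")
        with open(out / "genome_proteins.faa", "w") as fh:
            for gid in sorted(self.genome_genes):
                for i, g in enumerate(self.genome_genes[gid]):
                    fh.write(f">{gid}_{i} # {g.start} # {g.end} # {g.strand}\n"
                             f"{self.proteins[g.protein_id]}\n")
        with open(out / "labels.tsv", "w") as fh:
            fh.write("genome_id\tlifestyle\n")
            for gid in sorted(self.labels):
                fh.write(f"{gid}\t{self.labels[gid]}\n")
        for name, rows in (("all_vs_all.tsv", self.all_vs_all),
                           ("query_hits.tsv", self.query_hits)):
            with open(out / name, "w") as fh:
                for row in rows:
                    fh.write("\t".join(str(x) for x in row) + "\n")
        with open(out / "cluster_map.tsv", "w") as fh:
            fh.write("protein_id\tcluster\n")
            for pid in sorted(self.cluster_of):
                fh.write(f"{pid}\t{self.cluster_of[pid]}\n")


def _mutate(aa: str, rate: float, rng: np.random.Generator) -> str:
    chars = list(aa)
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    for i in hits:
        choices = _AA.replace(chars[i], "")
        chars[i] = choices[rng.integers(len(choices))]
    return "".join(chars)


def _tab_row(q: str, s: str, evalue: float, bitscore: float,
             alen: int) -> tuple:
    """A plausible 12-column tabular alignment row."""
    return (q, s, 95.0, alen, max(1, alen // 20), 0, 1, alen, 1, alen,
            f"{evalue:.1e}", f"{bitscore:.1f}")


def generate_universe(spec: SyntheticSpec) -> SyntheticUniverse:
    """Build the whole toy universe deterministically from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)

    # --- protein clusters: ancestor + point-mutated members
    proteins: dict[str, str] = {}
    cluster_of: dict[str, int] = {}
    for c in range(spec.n_clusters):
        ancestor = "".join(_AA[i] for i in
                           rng.integers(len(_AA), size=spec.protein_length))
        for m in range(spec.proteins_per_cluster):
            pid = f"P{c:03d}_{m}"
            proteins[pid] = _mutate(ancestor, spec.mutation_rate, rng)
            cluster_of[pid] = c
    for j in range(spec.n_singletons):
        pid = f"S{j:03d}"
        proteins[pid] = "".join(_AA[i] for i in
                                rng.integers(len(_AA), size=spec.protein_length))
        cluster_of[pid] = spec.n_clusters + j

    # --- all-vs-all table: self-hits for everyone, within-cluster pairs
    all_vs_all: list[tuple] = []
    for pid in sorted(proteins):
        all_vs_all.append(_tab_row(pid, pid, 1e-180, 400.0,
                                   spec.protein_length))
    for c in range(spec.n_clusters):
        members = [f"P{c:03d}_{m}" for m in range(spec.proteins_per_cluster)]
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                k = int(rng.integers(50, 181))
                bits = 150.0 + float(rng.integers(0, 200))
                all_vs_all.append(_tab_row(members[i], members[j],
                                           10.0 ** -k, bits,
                                           spec.protein_length))

    # --- genomes as ordered gene mosaics with a planted class signal
    base = np.ones(spec.n_clusters) / spec.n_clusters
    temperate_p = base.copy()
    temperate_p[list(spec.marker_clusters)] *= spec.marker_enrichment
    temperate_p /= temperate_p.sum()
    class_probs = {"temperate": temperate_p, "virulent": base}

    genomes: dict[str, str] = {}
    genome_genes: dict[str, list[GeneAnnotation]] = {}
    labels: dict[str, str] = {}
    query_hits: list[tuple] = []
    lo, hi = spec.genes_per_genome
    for label, prefix in zip(CLASS_NAMES, ("T", "V")):
        for g in range(spec.n_genomes_per_class):
            gid = f"{prefix}{g:03d}"
            labels[gid] = label
            n_genes = int(rng.integers(lo, hi, endpoint=True))
            clusters = rng.choice(spec.n_clusters, size=n_genes,
                                  p=class_probs[label])
            parts: list[str] = []
            genes: list[GeneAnnotation] = []
            pos = 0
            for i, c in enumerate(clusters):
                m = int(rng.integers(spec.proteins_per_cluster))
                pid = f"P{c:03d}_{m}"
                dna = "".join(_CODON[a] for a in proteins[pid]) + _STOP
                genes.append(GeneAnnotation(pos, pos + len(dna), "+", pid,
                                            int(c)))
                parts.append(dna)
                spacer = "".join("ACGT"[b] for b in
                                 rng.integers(4, size=spec.spacer_length))
                parts.append(spacer)
                pos += len(dna) + len(spacer)
                k = int(rng.integers(40, 121))
                query_hits.append(_tab_row(f"{gid}_{i}", f"P{c:03d}_0",
                                           10.0 ** -k,
                                           100.0 + float(rng.integers(0, 300)),
                                           spec.protein_length))
            genomes[gid] = "".join(parts)
            genome_genes[gid] = genes

    return SyntheticUniverse(spec, proteins, cluster_of, genomes,
                             genome_genes, labels, all_vs_all, query_hits)


class FragmentTokenizer:
    """Protein sentences for arbitrary fragments of synthetic genomes.

    Token assignment runs through the real best-hit path (query proteins
    vs. cluster representatives); a gene belongs to a fragment when the
    fragment covers at least half of the gene, emulating how a gene caller
    still recovers mostly-contained partial ORFs on fragment boundaries.
    """

    def __init__(self, universe: SyntheticUniverse,
                 vocab: ProteinVocabulary):
        self.universe = universe
        self.vocab = vocab
        hits_by_genome: dict[str, list[SimilarityEdge]] = {}
        for h in universe.query_hit_edges():
            hits_by_genome.setdefault(h.query_id.rpartition("_")[0],
                                      []).append(h)
        calls = universe.protein_calls()
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._tokens: dict[str, np.ndarray] = {}
        for gid, gene_calls in calls.items():
            tokens = assign_tokens(gene_calls, vocab,
                                   hits_by_genome.get(gid, []))
            self._starts[gid] = np.array([g.start for g in gene_calls])
            self._ends[gid] = np.array([g.end for g in gene_calls])
            self._tokens[gid] = np.array(tokens, dtype=np.int64)

    def tokens_for_window(self, genome_id: str, start: int,
                          end: int) -> list[int]:
        return window_tokens(self._starts[genome_id], self._ends[genome_id],
                             self._tokens[genome_id], start, end)

    def sentence(self, fragment: FragmentRecord) -> TokenSentence:
        return encode_sentence(self.tokens_for_window(
            fragment.source_id, fragment.start, fragment.end))

    def sentences(self, fragments: Sequence[FragmentRecord]
                  ) -> list[TokenSentence]:
        return [self.sentence(f) for f in fragments]


def make_bigram_corpus(n_sentences: int, sentence_tokens: int,
                       vocab_size: int, seed: int = 0
                       ) -> list[TokenSentence]:
    """Sentences with deterministic bigram structure: t is followed by t+1.

    Content tokens cycle through [5, vocab_size) starting at a random
    token, so every masked token is exactly determined by its neighbours.
    """
    rng = np.random.default_rng(seed)
    n_content_vocab = vocab_size - 5
    out = []
    for _ in range(n_sentences):
        t0 = int(rng.integers(n_content_vocab))
        tokens = [5 + (t0 + i) % n_content_vocab
                  for i in range(sentence_tokens)]
        out.append(encode_sentence(tokens))
    return out


def make_uniform_corpus(n_sentences: int, sentence_tokens: int,
                        vocab_size: int, seed: int = 0
                        ) -> list[TokenSentence]:
    """Structureless sentences: i.i.d. uniform content tokens (no signal)."""
    rng = np.random.default_rng(seed)
    return [encode_sentence(
        (5 + rng.integers(vocab_size - 5, size=sentence_tokens)).tolist())
        for _ in range(n_sentences)]


def random_genome_lengths(n: int, lo: int, hi: int, seed: int = 0,
                          prefix: str = "G") -> dict[str, int]:
    """Coordinate-only genome set (id -> length) for corpus bookkeeping."""
    rng = np.random.default_rng(seed)
    width = len(str(n - 1))
    return {f"{prefix}{i:0{width}d}": int(rng.integers(lo, hi, endpoint=True))
            for i in range(n)}
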