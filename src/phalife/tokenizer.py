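"""Contig -> protein-token sentence conversion.

A contig is read left to right as a sentence of protein tokens: genes are
called (or read from a precomputed protein table), each protein is assigned
the token of the cluster representative it aligns best to, and the ordered
token list is framed as [CLS] t1 .. tn [SEP] [PAD]... at a fixed length of
300. Contigs with more than 298 genes keep only the first 298 tokens.

Gene calling is a pluggable backend: tests and synthetic pipelines use the
precomputed-proteins reader; real contigs can go through the external
``prodigal -p meta`` binary when installed. Coordinates are 0-based
half-open throughout, and gene order along the contig (not strand) defines
sentence order.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Protocol, Sequence

import numpy as np
from Bio import SeqIO

from .vocabulary import CLS, PAD, SEP, UNK, ProteinVocabulary, SimilarityEdge

__all__ = [
    "ProteinCall",
    "TokenSentence",
    "SENTENCE_LENGTH",
    "MAX_CONTENT_TOKENS",
    "GeneCallError",
    "PrecomputedProteins",
    "ProdigalBackend",
    "call_genes",
    "assign_tokens",
    "encode_sentence",
    "decode_sentence",
    "tokenize_contigs",
    "read_sentences_tsv",
    "write_sentences_tsv",
]

SENTENCE_LENGTH = 300
MAX_CONTENT_TOKENS = SENTENCE_LENGTH - 2  # room for [CLS] and [SEP]


@dataclass(frozen=True)
class ProteinCall:
    """One called gene: where it sits on its contig and what it encodes."""

    contig_id: str
    ordinal: int           # 0-based gene order along the contig
    start: int             # 0-based half-open DNA coordinates
    end: int
    strand: str            # '+' or '-'
    aa_sequence: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"{self.contig_id} gene {self.ordinal}: bad coordinates "
                f"[{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def protein_id(self) -> str:
        return f"{self.contig_id}_{self.ordinal}"


@dataclass(frozen=True)
class TokenSentence:
    """Fixed-length (300) token-id vector with the [CLS]/[SEP]/[PAD] frame."""

    token_ids: np.ndarray          # shape (300,), int64
    attention_length: int          # count of non-[PAD] entries
    position_ids: np.ndarray = field(
        default_factory=lambda: np.arange(SENTENCE_LENGTH, dtype=np.int64))

    def __post_init__(self) -> None:
        ids = np.asarray(self.token_ids, dtype=np.int64)
        object.__setattr__(self, "token_ids", ids)
        if ids.shape != (SENTENCE_LENGTH,):
            raise ValueError(f"sentence must have length {SENTENCE_LENGTH}, "
                             f"got {ids.shape}")
        if ids[0] != CLS:
            raise ValueError("sentence must start with [CLS]")
        if self.attention_length < 2 or self.attention_length > SENTENCE_LENGTH:
            raise ValueError("attention_length out of range")
        if ids[self.attention_length - 1] != SEP:
            raise ValueError("[SEP] must close the content prefix")
        if np.any(ids[self.attention_length:] != PAD):
            raise ValueError("entries after [SEP] must be [PAD]")

    @property
    def content_ids(self) -> np.ndarray:
        """Tokens between [CLS] and [SEP] (may be empty)."""
        return self.token_ids[1:self.attention_length - 1]

    @property
    def n_content(self) -> int:
        return self.attention_length - 2


def encode_sentence(tokens: Sequence[int]) -> TokenSentence:
    """Frame an ordered token list as a fixed-length 300 sentence.

    Keeps the first 298 tokens when more are given; pads with [PAD] after
    the [SEP]. An empty list is allowed ([CLS][SEP] + 298 pads).
    """
    content = list(tokens)[:MAX_CONTENT_TOKENS]
    ids = np.full(SENTENCE_LENGTH, PAD, dtype=np.int64)
    ids[0] = CLS
    ids[1:1 + len(content)] = content
    ids[1 + len(content)] = SEP
    return TokenSentence(ids, attention_length=len(content) + 2)


def decode_sentence(sentence: TokenSentence) -> list[int]:
    """Content tokens of a sentence, specials and padding stripped."""
    return sentence.content_ids.tolist()


class GeneCallError(RuntimeError):
    """Gene-calling backend failure, naming the contig."""


class GeneCaller(Protocol):
    def __call__(self, contig_id: str, sequence: str) -> list[ProteinCall]: ...


class PrecomputedProteins:
    """Gene 'caller' that serves precomputed protein calls per contig.

    Construct from an in-memory mapping or from a protein FASTA whose
    headers follow ``{contig_id}_{ordinal} # start # end # strand`` with
    0-based half-open coordinates (the ``#`` fields are optional; without
    them, ordinal-scaled placeholder coordinates are synthesised so that
    sentence order is still well defined).
    """

    def __init__(self, calls: Mapping[str, Sequence[ProteinCall]]):
        self._calls = {cid: sorted(cs, key=lambda c: c.start)
                       for cid, cs in calls.items()}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "PrecomputedProteins":
        per_contig: dict[str, list[ProteinCall]] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            header = rec.description
            name = header.split(" # ")[0].split()[0]
            contig_id, _, ordinal = name.rpartition("_")
            if not contig_id or not ordinal.isdigit():
                raise GeneCallError(
                    f"protein header {name!r} does not follow "
                    "'{{contig_id}}_{{ordinal}}'")
            ordinal = int(ordinal)
            parts = header.split(" # ")
            if len(parts) >= 4:
                start, end, strand = int(parts[1]), int(parts[2]), parts[3]
            else:
                start, end, strand = ordinal * 1000, ordinal * 1000 + 3, "+"
            per_contig.setdefault(contig_id, []).append(ProteinCall(
                contig_id, ordinal, start, end, strand, str(rec.seq)))
        return cls(per_contig)

    def __call__(self, contig_id: str, sequence: str) -> list[ProteinCall]:
        return list(self._calls.get(contig_id, []))


class ProdigalBackend:
    """Gene calling via the external ``prodigal`` binary (meta mode)."""

    def __init__(self, executable: str = "prodigal", meta: bool = True):
        if shutil.which(executable) is None:
            raise GeneCallError(f"gene caller {executable!r} not found on PATH")
        self.executable = executable
        self.meta = meta

    def __call__(self, contig_id: str, sequence: str) -> list[ProteinCall]:
        with tempfile.TemporaryDirectory() as tmp:
            fasta = Path(tmp) / "contig.fa"
            faa = Path(tmp) / "contig.faa"
            fasta.write_text(f">{contig_id}\n{sequence}\n")
            cmd = [self.executable, "-i", str(fasta), "-a", str(faa), "-q"]
            if self.meta:
                cmd += ["-p", "meta"]
            proc = subprocess.run(cmd, capture_output=True, text=True)
            if proc.returncode != 0:
                raise GeneCallError(
                    f"prodigal failed on contig {contig_id}: {proc.stderr}")
            calls = []
            for i, rec in enumerate(SeqIO.parse(str(faa), "fasta")):
                # prodigal headers: id # start(1-based) # end # strand(1/-1) # ...
                parts = rec.description.split(" # ")
                start1, end1, strand_num = (int(parts[1]), int(parts[2]),
                                            int(parts[3]))
                calls.append(ProteinCall(
                    contig_id, i, start1 - 1, end1,
                    "+" if strand_num > 0 else "-",
                    str(rec.seq).rstrip("*")))
            return calls


def call_genes(contig_id: str, sequence: str,
               backend: GeneCaller) -> list[ProteinCall]:
    """Run a gene-calling backend on one contig; calls sorted by start."""
    try:
        calls = backend(contig_id, sequence)
    except GeneCallError:
        raise
    except Exception as exc:  # wrap backend failure with the contig name
        raise GeneCallError(f"gene calling failed on contig "
                            f"{contig_id}: {exc}") from exc
    return sorted(calls, key=lambda c: c.start)


def assign_tokens(
    calls: Sequence[ProteinCall],
    vocab: ProteinVocabulary,
    hits: Iterable[SimilarityEdge],
) -> list[int]:
    """Best-alignment token per called protein, preserving gene order.

    ``hits`` are alignments of the query proteins against the cluster
    representatives. Per protein the best hit has the lowest e-value, ties
    broken by highest bit score, then smallest token id. Proteins with no
    hit get [UNK]. A hit naming an unknown representative raises KeyError.
    """
    best: dict[str, tuple[float, float, int]] = {}
    for hit in hits:
        token = vocab.token_for_representative(hit.subject_id)
        key = (hit.evalue, -hit.bitscore, token)
        if hit.query_id not in best or key < best[hit.query_id]:
            best[hit.query_id] = key
    return [best[c.protein_id][2] if c.protein_id in best else UNK
            for c in calls]


def tokenize_contigs(
    contigs: Mapping[str, str],
    vocab: ProteinVocabulary,
    backend: GeneCaller,
    hits: Iterable[SimilarityEdge],
) -> dict[str, TokenSentence]:
    """Full contig -> sentence pipeline over a set of contigs.

    Deterministic: the same contigs, vocabulary and hits table always yield
    byte-identical sentences.
    """
    hits = list(hits)
    sentences: dict[str, TokenSentence] = {}
    for contig_id in contigs:
        calls = call_genes(contig_id, contigs[contig_id], backend)
        tokens = assign_tokens(calls, vocab, hits)
        sentences[contig_id] = encode_sentence(tokens)
    return sentences


def window_tokens(starts: np.ndarray, ends: np.ndarray, tokens: np.ndarray,
                  start: int, end: int) -> list[int]:
    """Tokens of the genes a [start, end) window covers, in gene order.

    A gene counts as covered when the window overlaps at least half of it,
    emulating a gene caller recovering mostly-contained partial ORFs at
    fragment boundaries.
    """
    overlap = np.minimum(ends, end) - np.maximum(starts, start)
    keep = overlap >= (ends - starts + 1) // 2
    return np.asarray(tokens)[keep].tolist()


def stack_sentences(
    sentences: Sequence[TokenSentence],
) -> tuple[np.ndarray, np.ndarray]:
    """Stack sentences into (ids, attention_lengths) arrays for batching."""
    ids = np.stack([s.token_ids for s in sentences])
    attn = np.array([s.attention_length for s in sentences], dtype=np.int64)
    return ids, attn


def write_sentences_tsv(path: str | Path,
                        sentences: Mapping[str, TokenSentence]) -> None:
    """TSV with one row per contig: contig_id, 300 space-separated token ids."""
    with open(path, "w") as fh:
        fh.write("contig_id\ttoken_ids\n")
        for cid, s in sentences.items():
            fh.write(f"{cid}\t{' '.join(map(str, s.token_ids.tolist()))}\n")


def read_sentences_tsv(path: str | Path) -> dict[str, TokenSentence]:
    sentences: dict[str, TokenSentence] = {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            cid, ids = line.rstrip("\n").split("\t")
            token_ids = np.array(ids.split(), dtype=np.int64)
            # [PAD] is never assigned as a content token, so the non-pad
            # count recovers attention_length exactly
            attention_length = int((token_ids != PAD).sum())
            sentences[cid] = TokenSentence(token_ids, attention_length)
    return sentences
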