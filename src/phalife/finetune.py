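"""Supervised fine-tuning for lifestyle classification.

The labeled genome universe is length-augmented: for every length of an
8-point grid spanning 100 bp to 20 kbp, 10,000 random fragments are drawn
per class (temperate / virulent), giving an exactly class-balanced corpus
of 160,000 fragments by default. The pretrained encoder is fine-tuned on
the cross-entropy of softmax(Y_0 W_p + b_p) with 10-fold cross-validation,
and the parameters of the fold with the best validation AUCROC are kept.
Training from scratch (no masked-LM pretraining) is supported as an
ablation arm.

A short-fragment benchmark builder mirrors the evaluation design: four
length bins (100-400, 400-800, 800-1200, 1200-1800 bp), 80,000 fragments
per bin balanced per class, with near-duplicate removal at sketch
similarity > 0.8 using an in-repo k-mer MinHash sketch.

Cross-validation splits are at genome level, not fragment level: fragments
of one genome never appear on both sides of a split, which would otherwise
leak sequence identity and inflate scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.model_selection import KFold, StratifiedGroupKFold

from .evaluate import roc_auc
from .model import (CLASS_NAMES, TEMPERATE, AdamOptimizer, ModelConfig,
                    ProteinBert)
from .pretrain import FragmentRecord, sample_fragment
from .tokenizer import TokenSentence, stack_sentences

__all__ = [
    "LabeledFragment",
    "PredictionRecord",
    "BenchmarkBin",
    "DEFAULT_LENGTH_GRID",
    "BENCHMARK_BINS",
    "build_finetune_corpus",
    "build_length_bin_benchmark",
    "sketch_similarity",
    "finetune",
    "FinetuneResult",
    "predict_sentences",
    "write_predictions_tsv",
]

#: augmentation lengths (bp): the four benchmark-bin boundary lengths plus
#: the four pretraining lengths, spanning the stated 100 bp - 20 kbp range
DEFAULT_LENGTH_GRID = (100, 400, 800, 1200, 1800, 5000, 10000, 20000)
#: fragments per class per length
N_PER_CLASS_PER_LENGTH = 10_000
#: benchmark length bins (bp, inclusive bounds)
BENCHMARK_BINS = ((100, 400), (400, 800), (800, 1200), (1200, 1800))
#: sketch-similarity threshold above which a fragment is a near-duplicate
DEDUP_THRESHOLD = 0.8


@dataclass(frozen=True)
class LabeledFragment(FragmentRecord):
    """A genome fragment carrying its source genome's lifestyle label."""

    label: str = ""

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.label not in CLASS_NAMES:
            raise ValueError(f"label must be one of {CLASS_NAMES}, "
                             f"got {self.label!r}")


def _class_genomes(genomes: Mapping, labels: Mapping[str, str]
                   ) -> dict[str, list[str]]:
    by_class: dict[str, list[str]] = {c: [] for c in CLASS_NAMES}
    for gid in sorted(genomes):
        label = labels[gid]
        if label not in CLASS_NAMES:
            raise ValueError(f"genome {gid}: unknown label {label!r}")
        by_class[label].append(gid)
    for c, gids in by_class.items():
        if not gids:
            raise ValueError(f"no genomes labeled {c!r}")
    return by_class


def _seq_len(seq) -> int:
    return seq if isinstance(seq, int) else len(seq)


def _cut(genomes: Mapping, gid: str, start: int, end: int,
         length_class: str, label: str) -> LabeledFragment:
    seq = genomes[gid]
    dna = None if isinstance(seq, int) else seq[start:end]
    return LabeledFragment(gid, start, end, length_class, dna, label)


def build_finetune_corpus(
    genomes: Mapping[str, str] | Mapping[str, int],
    labels: Mapping[str, str],
    length_grid: Sequence[int] = DEFAULT_LENGTH_GRID,
    n_per_class_per_length: int = N_PER_CLASS_PER_LENGTH,
    seed: int = 0,
) -> list[LabeledFragment]:
    """Length-augmented labeled fragment corpus with exact class balance.

    For each length and each class, exactly ``n_per_class_per_length``
    fragments are sampled uniformly over (genome, start) pairs of that
    class; total = 2 x len(length_grid) x n_per_class_per_length. Genomes
    shorter than the nominal length contribute their whole sequence
    (short-genome rule shared with the masked-LM corpus builder).
    """
    by_class = _class_genomes(genomes, labels)
    rng = np.random.default_rng(seed)
    fragments: list[LabeledFragment] = []
    for L in length_grid:
        for label in CLASS_NAMES:
            gids = by_class[label]
            picks = rng.integers(0, len(gids), size=n_per_class_per_length)
            for gi in picks:
                gid = gids[gi]
                start, end = sample_fragment(_seq_len(genomes[gid]), L, rng)
                fragments.append(_cut(genomes, gid, start, end, str(L), label))
    return fragments


# --------------------------------------------------------------------------
# k-mer MinHash sketch and near-duplicate removal
# --------------------------------------------------------------------------

_SKETCH_K = 21
_SKETCH_HASHES = 64
_LSH_BANDS = 8                       # 8 bands x 8 rows over 64 hashes
# Mersenne prime 2^31-1: (a*x + b) stays within int64 for a, x < 2^31
_HASH_P = (1 << 31) - 1
_hash_rng = np.random.default_rng(918273645)
_HASH_A = _hash_rng.integers(1, _HASH_P, size=_SKETCH_HASHES, dtype=np.int64)
_HASH_B = _hash_rng.integers(0, _HASH_P, size=_SKETCH_HASHES, dtype=np.int64)
_BASE_CODE = np.full(128, -1, dtype=np.int64)
for _i, _c in enumerate("ACGT"):
    _BASE_CODE[ord(_c)] = _i
    _BASE_CODE[ord(_c.lower())] = _i


def _kmer_codes(seq: str, k: int = _SKETCH_K) -> np.ndarray:
    vals = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if len(vals) < k:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(vals, k)
    ok = (win >= 0).all(axis=1)
    powers = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    return (win[ok] * powers).sum(axis=1)


def minhash_signature(seq: str) -> np.ndarray:
    """64-slot MinHash signature over 21-mers (deterministic hashing)."""
    codes = _kmer_codes(seq) % _HASH_P
    if len(codes) == 0:
        return np.full(_SKETCH_HASHES, _HASH_P, dtype=np.int64)
    h = (codes[None, :] * _HASH_A[:, None] + _HASH_B[:, None]) % _HASH_P
    return h.min(axis=1)


def sketch_similarity(seq_a: str, seq_b: str) -> float:
    """MinHash estimate of the k-mer Jaccard similarity of two sequences."""
    return float((minhash_signature(seq_a) == minhash_signature(seq_b)).mean())


def _dedup_first_seen(fragments: Sequence[LabeledFragment],
                      threshold: float) -> tuple[list[LabeledFragment], int]:
    """Greedy keep-first near-duplicate removal via LSH-bucketed MinHash.

    A fragment is removed when its sketch similarity with any earlier kept
    fragment exceeds ``threshold``. Candidate pairs come from shared LSH
    bands, which recalls essentially all pairs above 0.8 similarity.
    """
    kept: list[LabeledFragment] = []
    signatures: list[np.ndarray] = []
    buckets: dict[tuple[int, bytes], list[int]] = {}
    rows = _SKETCH_HASHES // _LSH_BANDS
    removed = 0
    for frag in fragments:
        if frag.dna is None:
            raise ValueError("dedup requires materialised fragment sequences")
        sig = minhash_signature(frag.dna)
        keys = [(b, sig[b * rows:(b + 1) * rows].tobytes())
                for b in range(_LSH_BANDS)]
        candidates: set[int] = set()
        for key in keys:
            candidates.update(buckets.get(key, ()))
        dup = any(float((signatures[j] == sig).mean()) > threshold
                  for j in candidates)
        if dup:
            removed += 1
            continue
        idx = len(kept)
        kept.append(frag)
        signatures.append(sig)
        for key in keys:
            buckets.setdefault(key, []).append(idx)
    return kept, removed


@dataclass
class BenchmarkBin:
    """One length-bin evaluation set, before and after dedup."""

    length_range: tuple[int, int]
    fragments: list[LabeledFragment]
    n_pre_dedup: int
    n_per_class_pre_dedup: int
    n_removed: int


def build_length_bin_benchmark(
    genomes: Mapping[str, str] | Mapping[str, int],
    labels: Mapping[str, str],
    bins: Sequence[tuple[int, int]] = BENCHMARK_BINS,
    n_per_bin: int = 80_000,
    per_class: int | None = None,
    dedup_threshold: float | None = DEDUP_THRESHOLD,
    seed: int = 0,
) -> list[BenchmarkBin]:
    """Short-fragment evaluation sets for each length bin.

    Per bin, ``n_per_bin`` fragments balanced per class are sampled with
    lengths uniform within the bin, then near-duplicates (sketch
    similarity > ``dedup_threshold``) are removed keeping the first-seen
    fragment. ``dedup_threshold=None`` skips dedup (e.g. for bookkeeping
    on coordinate-only genomes).
    """
    per_class = n_per_bin // 2 if per_class is None else per_class
    by_class = _class_genomes(genomes, labels)
    rng = np.random.default_rng(seed)
    out: list[BenchmarkBin] = []
    for lo, hi in bins:
        fragments: list[LabeledFragment] = []
        for label in CLASS_NAMES:
            gids = by_class[label]
            picks = rng.integers(0, len(gids), size=per_class)
            lengths = rng.integers(lo, hi, size=per_class, endpoint=True)
            for gi, L in zip(picks, lengths):
                gid = gids[gi]
                start, end = sample_fragment(_seq_len(genomes[gid]), int(L),
                                             rng)
                fragments.append(
                    _cut(genomes, gid, start, end, f"{lo}-{hi}", label))
        n_pre = len(fragments)
        if dedup_threshold is None:
            survivors, removed = fragments, 0
        else:
            survivors, removed = _dedup_first_seen(fragments, dedup_threshold)
        out.append(BenchmarkBin((lo, hi), survivors, n_pre, per_class,
                                removed))
    return out


# --------------------------------------------------------------------------
# fine-tuning
# --------------------------------------------------------------------------

@dataclass
class FinetuneResult:
    model: ProteinBert
    fold_aucs: list[float]
    best_fold: int
    #: pooled out-of-fold temperate probabilities and their labels, aligned;
    #: one entry per record that appeared in some validation fold
    val_probs: np.ndarray = field(default_factory=lambda: np.empty(0))
    val_labels: np.ndarray = field(default_factory=lambda: np.empty(0, int))


def finetune(
    sentences: Sequence[TokenSentence],
    labels: Sequence[int],
    groups: Sequence[str] | None = None,
    pretrained: ProteinBert | None = None,
    config: ModelConfig | None = None,
    folds: int = 10,
    lr: float = 1e-3,
    epochs: int = 10,
    batch_size: int = 32,
    seed: int = 0,
) -> FinetuneResult:
    """Fine-tune (or train from scratch) the lifestyle classifier.

    ``labels`` are class indices (0 = temperate, 1 = virulent). ``groups``
    are source-genome ids for genome-level cross-validation; when omitted
    the split is a seeded record-level k-fold. Pass ``pretrained`` to start
    from masked-LM parameters, or ``config`` alone for the from-scratch
    arm. Returns the fold model with the best validation AUCROC.
    """
    if pretrained is None and config is None:
        raise ValueError("supply a pretrained model or a config")
    ids, attn = stack_sentences(sentences)
    y = np.asarray(labels, dtype=np.int64)
    n = len(sentences)
    if groups is not None:
        # genome-level, class-stratified: fragments of one genome never
        # straddle a split, and each training fold keeps the class balance
        # (an imbalanced fold would bias the 0.5-cutoff calibration)
        splitter = StratifiedGroupKFold(n_splits=folds, shuffle=True,
                                        random_state=seed)
        split_iter = splitter.split(ids, y, groups=np.asarray(groups))
    else:
        splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
        split_iter = splitter.split(ids, y)

    fold_aucs: list[float] = []
    models: list[ProteinBert] = []
    oof_probs: list[np.ndarray] = []
    oof_labels: list[np.ndarray] = []
    for fold, (train_idx, val_idx) in enumerate(split_iter):
        if len(np.unique(y[train_idx])) < 2:
            raise ValueError(f"fold {fold}: training split has one class")
        if pretrained is not None:
            model = pretrained.copy()
        else:
            model = ProteinBert(config, seed=seed * 1000 + fold)
        opt = AdamOptimizer(model.params, lr=lr)
        fold_rng = np.random.default_rng(seed * 1000 + fold + 7)
        for _ in range(epochs):
            order = fold_rng.permutation(train_idx)
            for lo in range(0, len(order), batch_size):
                batch = order[lo:lo + batch_size]
                loss, grads = model.cls_loss_and_grads(ids[batch],
                                                       attn[batch], y[batch])
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"classification loss diverged in fold {fold}")
                opt.step(model.params, grads)
        probs = model.predict_proba(ids[val_idx], attn[val_idx])
        oof_probs.append(probs[:, TEMPERATE])
        oof_labels.append(y[val_idx])
        if len(np.unique(y[val_idx])) < 2:
            auc = float("nan")      # degenerate fold; cannot rank it
        else:
            auc = roc_auc(probs[:, TEMPERATE],
                          (y[val_idx] == TEMPERATE).astype(int)).auc
        fold_aucs.append(auc)
        models.append(model)
    best = int(np.nanargmax(fold_aucs))
    return FinetuneResult(models[best], fold_aucs, best,
                          np.concatenate(oof_probs),
                          np.concatenate(oof_labels))


# --------------------------------------------------------------------------
# prediction
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PredictionRecord:
    """Per-contig lifestyle call at a probability cutoff."""

    contig_id: str
    length_bp: int
    n_genes: int
    p_temperate: float
    p_virulent: float
    call: str


def predict_sentences(
    sentences: Mapping[str, TokenSentence],
    model: ProteinBert,
    cutoff: float = 0.5,
    contig_lengths: Mapping[str, int] | None = None,
) -> list[PredictionRecord]:
    """Lifestyle calls for tokenized contigs.

    call = temperate iff p_temperate >= cutoff (the boundary goes to
    temperate). Contigs with zero called genes are reported as
    "unclassified" with NaN probabilities. One output row per input contig.
    """
    records: list[PredictionRecord] = []
    items = list(sentences.items())
    classifiable = [(cid, s) for cid, s in items if s.n_content > 0]
    probs_by_cid: dict[str, np.ndarray] = {}
    if classifiable:
        ids, attn = stack_sentences([s for _, s in classifiable])
        probs = model.predict_proba(ids, attn)
        probs_by_cid = {cid: probs[i] for i, (cid, _) in enumerate(classifiable)}
    for cid, s in items:
        length = contig_lengths.get(cid, 0) if contig_lengths else 0
        if s.n_content == 0:
            records.append(PredictionRecord(cid, length, 0, float("nan"),
                                            float("nan"), "unclassified"))
            continue
        p = probs_by_cid[cid]
        call = "temperate" if p[TEMPERATE] >= cutoff else "virulent"
        records.append(PredictionRecord(cid, length, s.n_content,
                                        float(p[0]), float(p[1]), call))
    return records


def read_labels_tsv(path: str | Path) -> dict[str, str]:
    """Labels file: genome_id <tab> lifestyle (header optional)."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            gid, label = line.rstrip("\n").split("\t")
            if gid == "genome_id":
                continue
            if label not in CLASS_NAMES:
                raise ValueError(f"genome {gid}: unknown label {label!r}")
            labels[gid] = label
    return labels


def write_predictions_tsv(path: str | Path,
                          records: Sequence[PredictionRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("contig_id\tlength_bp\tn_genes\tp_temperate\tp_virulent\tcall\n")
        for r in records:
            fh.write(f"{r.contig_id}\t{r.length_bp}\t{r.n_genes}\t"
                     f"{r.p_temperate:.6f}\t{r.p_virulent:.6f}\t{r.call}\n")
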