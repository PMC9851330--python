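"""Self-supervised masked-LM training over phage genomes.

Complete genomes are cut into fragments of several nominal lengths (5, 10,
15 and 20 kbp by default, 10 random substrings per length, plus the full
genome), every fragment is tokenized into a protein sentence, and the
encoder is trained to recover randomly masked tokens: 5% of the content
tokens of each sentence are replaced by [MASK] (always [MASK]; no BERT-style
80/10/10 corruption) and the cross-entropy of softmax(Y_i W_d) against the
original token is minimised with Adam at learning rate 0.001.

Model selection follows the cross-validation protocol: the corpus is split
into k train/validation folds, one model is trained per fold, and the
parameters with the lowest validation masked-LM loss are returned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .model import AdamOptimizer, ModelConfig, ProteinBert
from .tokenizer import TokenSentence, stack_sentences
from .vocabulary import MASK

__all__ = [
    "FragmentRecord",
    "MaskedExample",
    "MLM_LENGTHS",
    "build_mlm_corpus",
    "mask_sentence",
    "mask_batch",
    "pretrain",
    "PretrainResult",
    "write_fragment_manifest",
]

#: nominal fragment lengths (bp) for masked-LM corpus construction
MLM_LENGTHS = (5000, 10000, 15000, 20000)
#: substrings sampled per genome per length
MLM_N_PER_LENGTH = 10
#: fraction of content tokens masked per sentence
MASK_RATE = 0.05


@dataclass(frozen=True)
class FragmentRecord:
    """A sampled genome substring.

    ``length_class`` is the nominal sampling length as a string, or
    ``"full"`` for the whole genome. When the source is shorter than the
    nominal length the fragment is the entire source. ``dna`` may be None
    when only coordinates are needed (bookkeeping, manifests).
    """

    source_id: str
    start: int
    end: int
    length_class: str
    dna: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad fragment interval [{self.start}, {self.end})")
        if self.dna is not None and len(self.dna) != self.end - self.start:
            raise ValueError("dna length does not match coordinates")

    @property
    def length(self) -> int:
        return self.end - self.start


def sample_fragment(sequence_length: int, nominal_length: int,
                    rng: np.random.Generator) -> tuple[int, int]:
    """Uniform-random substring coordinates; whole source when too short.

    The start is uniform on [0, len - L] inclusive. This short-genome rule
    is shared by the fine-tuning corpus builder.
    """
    if sequence_length <= nominal_length:
        return 0, sequence_length
    start = int(rng.integers(0, sequence_length - nominal_length,
                             endpoint=True))
    return start, start + nominal_length


def build_mlm_corpus(
    genomes: Mapping[str, str] | Mapping[str, int],
    lengths: Sequence[int] = MLM_LENGTHS,
    n_per_length: int = MLM_N_PER_LENGTH,
    include_full: bool = True,
    seed: int = 0,
) -> list[FragmentRecord]:
    """Fragment corpus for masked-LM training.

    Per genome: the full sequence (when ``include_full``) plus
    ``n_per_length`` random substrings for each length, sampled with
    replacement. Total count = G x (len(lengths) x n_per_length + 1).
    ``genomes`` maps id -> sequence; a mapping id -> length is also
    accepted, in which case fragments carry coordinates only.
    Reproducible: genomes are visited in sorted-id order under one seeded
    generator.
    """
    if not genomes:
        raise ValueError("no genomes supplied")
    rng = np.random.default_rng(seed)
    fragments: list[FragmentRecord] = []
    for gid in sorted(genomes):
        seq = genomes[gid]
        seq_len = seq if isinstance(seq, int) else len(seq)

        def cut(start: int, end: int, length_class: str) -> FragmentRecord:
            dna = None if isinstance(seq, int) else seq[start:end]
            return FragmentRecord(gid, start, end, length_class, dna)

        if include_full:
            fragments.append(cut(0, seq_len, "full"))
        for L in lengths:
            for _ in range(n_per_length):
                start, end = sample_fragment(seq_len, L, rng)
                fragments.append(cut(start, end, str(L)))
    return fragments


def write_fragment_manifest(path: str | Path,
                            fragments: Sequence[FragmentRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("source_id\tstart\tend\tlength_class\n")
        for f in fragments:
            fh.write(f"{f.source_id}\t{f.start}\t{f.end}\t{f.length_class}\n")


@dataclass(frozen=True)
class MaskedExample:
    """A sentence with [MASK] substitutions and the recovery targets."""

    input_ids: TokenSentence
    target_positions: np.ndarray
    target_ids: np.ndarray

    def __post_init__(self) -> None:
        if len(self.target_positions) < 1:
            raise ValueError("a masked example needs at least one target")


class EmptySentenceWarning(UserWarning):
    pass


def mask_sentence(sentence: TokenSentence, rate: float = MASK_RATE,
                  rng: np.random.Generator | None = None
                  ) -> MaskedExample | None:
    """Independently mask each content token with probability ``rate``.

    If no token is selected, one content position is forced uniformly at
    random, so every example has at least one target. [CLS], [SEP] and
    [PAD] are never masked. A sentence with zero content tokens is skipped
    (returns None with a warning).
    """
    rng = np.random.default_rng() if rng is None else rng
    n = sentence.n_content
    if n == 0:
        warnings.warn("sentence has no content tokens; skipping",
                      EmptySentenceWarning)
        return None
    content_pos = np.arange(1, 1 + n)
    chosen = content_pos[rng.random(n) < rate]
    if len(chosen) == 0:
        chosen = np.array([rng.choice(content_pos)])
    ids = sentence.token_ids.copy()
    targets = ids[chosen].copy()
    ids[chosen] = MASK
    return MaskedExample(
        TokenSentence(ids, sentence.attention_length), chosen, targets)


def mask_batch(ids: np.ndarray, attn_len: np.ndarray, rate: float,
               rng: np.random.Generator
               ) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Batched equivalent of :func:`mask_sentence` on stacked id arrays.

    Returns (masked_ids, (sample_idx, position, original_token)).
    Rows with no content tokens get no targets.
    """
    masked = ids.copy()
    sample_idx, positions, targets = [], [], []
    for i in range(ids.shape[0]):
        n = int(attn_len[i]) - 2
        if n == 0:
            continue
        content_pos = np.arange(1, 1 + n)
        chosen = content_pos[rng.random(n) < rate]
        if len(chosen) == 0:
            chosen = np.array([rng.choice(content_pos)])
        sample_idx.extend([i] * len(chosen))
        positions.extend(chosen.tolist())
        targets.extend(ids[i, chosen].tolist())
        masked[i, chosen] = MASK
    return masked, (np.array(sample_idx, dtype=np.int64),
                    np.array(positions, dtype=np.int64),
                    np.array(targets, dtype=np.int64))


@dataclass
class PretrainResult:
    model: ProteinBert
    fold_val_losses: list[float]
    best_fold: int


def _fold_indices(n: int, folds: int, rng: np.random.Generator
                  ) -> list[np.ndarray]:
    perm = rng.permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(perm, folds)]


def pretrain(
    sentences: Sequence[TokenSentence],
    config: ModelConfig,
    folds: int = 10,
    lr: float = 1e-3,
    epochs: int = 20,
    batch_size: int = 32,
    mask_rate: float = MASK_RATE,
    seed: int = 0,
) -> PretrainResult:
    """Masked-LM training with k-fold model selection.

    One model is trained per train/validation split; fresh masks are drawn
    every epoch, validation masks are fixed per fold. The model from the
    fold with the lowest validation loss is returned. All randomness is
    derived from ``seed``. A non-finite loss aborts with a diagnostic.
    """
    ids, attn = stack_sentences(sentences)
    if (attn < 3).any():
        raise ValueError("pretraining corpus contains sentences without "
                         "content tokens")
    n = len(sentences)
    rng = np.random.default_rng(seed)
    val_sets = _fold_indices(n, folds, rng)
    fold_losses: list[float] = []
    models: list[ProteinBert] = []
    for fold, val_idx in enumerate(val_sets):
        train_idx = np.setdiff1d(np.arange(n), val_idx)
        model = ProteinBert(config, seed=seed * 1000 + fold)
        opt = AdamOptimizer(model.params, lr=lr)
        fold_rng = np.random.default_rng(seed * 1000 + fold + 7)
        for _ in range(epochs):
            order = fold_rng.permutation(train_idx)
            for lo in range(0, len(order), batch_size):
                batch = order[lo:lo + batch_size]
                m_ids, triple = mask_batch(ids[batch], attn[batch],
                                           mask_rate, fold_rng)
                loss, grads = model.mlm_loss_and_grads(m_ids, attn[batch],
                                                       triple)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"masked-LM loss diverged in fold {fold}")
                opt.step(model.params, grads)
        val_rng = np.random.default_rng(seed * 1000 + fold + 13)
        vm_ids, vtriple = mask_batch(ids[val_idx], attn[val_idx],
                                     mask_rate, val_rng)
        fold_losses.append(model.mlm_eval_loss(vm_ids, attn[val_idx], vtriple))
        models.append(model)
    best = int(np.argmin(fold_losses))
    return PretrainResult(models[best], fold_losses, best)


def masked_token_accuracy(model: ProteinBert,
                          sentences: Sequence[TokenSentence],
                          mask_rate: float = MASK_RATE,
                          seed: int = 0) -> float:
    """Fraction of masked tokens recovered exactly (argmax prediction)."""
    ids, attn = stack_sentences(sentences)
    rng = np.random.default_rng(seed)
    m_ids, (sample_idx, pos, tgt) = mask_batch(ids, attn, mask_rate, rng)
    pred = model.mlm_predict(m_ids, attn, sample_idx, pos)
    return float((pred == tgt).mean())
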