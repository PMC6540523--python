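"""Amino-acid token embeddings: n-gram tokenization and skip-gram pre-training.

A protein or peptide is treated as a sentence whose words are either single
residues (1-gram) or non-overlapping residue triplets (3-gram, the ProtVec
convention). For 3-grams, each sequence is read in three frames offset by
0, 1 and 2 residues from the N-terminus, each frame yielding one sentence;
a trailing remainder shorter than the gram size is dropped.

Embeddings are trained with the skip-gram objective and negative sampling
(SGNS): for each (center, context) pair within the window, the center vector
is pushed toward its context's output vector and away from `negative`
sampled noise tokens drawn from the unigram^0.75 distribution. Training is
plain SGD with a linearly decayed learning rate and is deterministic for a
fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from sklearn.base import BaseEstimator

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP_TOKEN = "-"
UNK_TOKEN = "<unk>"


@dataclass
class TokenizationScheme:
    n: int = 1

    def __post_init__(self):
        if self.n not in (1, 3):
            raise ValueError("gram size must be 1 or 3")

    @property
    def offsets(self) -> tuple[int, ...]:
        return tuple(range(self.n))

    def base_vocabulary(self) -> list[str]:
        """Residue-level specials + all single residues; 3-gram vocabularies
        are completed from the corpus at training time."""
        return [GAP_TOKEN, UNK_TOKEN] + list(AMINO_ACIDS)


def tokenize(seq: str, scheme: TokenizationScheme, offset: int = 0) -> list[str]:
    """Non-overlapping n-grams starting at `offset`; remainder dropped.

    Letters outside the 20-residue alphabet (other than the gap character)
    become the unknown token for 1-grams; a 3-gram containing such a letter
    becomes the unknown token wholesale.
    """
    if offset not in scheme.offsets:
        raise ValueError(f"offset {offset} invalid for n={scheme.n}")
    seq = seq.upper()
    n = scheme.n
    tokens = []
    for i in range(offset, len(seq) - n + 1, n):
        tok = seq[i:i + n]
        if any(ch not in AMINO_ACIDS and ch != GAP_TOKEN for ch in tok):
            tok = UNK_TOKEN
        tokens.append(tok)
    return tokens


def read_peptide_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip().upper() for line in fh if line.strip()]


def build_corpus(fasta_paths=(), peptide_list_paths=(),
                 scheme: TokenizationScheme | None = None) -> list[list[str]]:
    """Token sentences from FASTA protein files and plain peptide lists.

    Each sequence contributes one sentence per offset (1 for 1-grams, 3 for
    3-grams), so sentence counts concatenate across sources.
    """
    scheme = scheme or TokenizationScheme()
    if not fasta_paths and not peptide_list_paths:
        raise ValueError("at least one corpus source is required")
    sequences: list[str] = []
    for path in fasta_paths:
        n_before = len(sequences)
        sequences.extend(str(rec.seq) for rec in SeqIO.parse(str(path), "fasta"))
        if len(sequences) == n_before:
            raise ValueError(f"no sequences read from {path}")
    for path in peptide_list_paths:
        peptides = read_peptide_list(path)
        if not peptides:
            raise ValueError(f"no peptides read from {path}")
        sequences.extend(peptides)
    sentences = []
    for seq in sequences:
        for off in scheme.offsets:
            toks = tokenize(seq, scheme, off)
            if toks:
                sentences.append(toks)
    return sentences


@dataclass
class EmbeddingTable:
    vectors: dict[str, np.ndarray]
    metadata: dict = field(default_factory=dict)

    @property
    def dim(self) -> int:
        return len(next(iter(self.vectors.values())))

    def matrix(self, vocabulary: list[str],
               rng: np.random.Generator | None = None) -> np.ndarray:
        """Rows for `vocabulary`, in order; tokens absent from the table get
        small random vectors (rng required if any are absent)."""
        out = np.empty((len(vocabulary), self.dim))
        for i, tok in enumerate(vocabulary):
            if tok in self.vectors:
                out[i] = self.vectors[tok]
            elif rng is not None:
                out[i] = rng.normal(0.0, 0.1, self.dim)
            else:
                raise KeyError(f"token {tok!r} missing from embedding table")
        return out

    def save(self, path) -> None:
        rows = [[tok, *vec] for tok, vec in self.vectors.items()]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)
        with open(str(path) + ".meta.json", "w") as fh:
            json.dump(self.metadata, fh, indent=1)

    @classmethod
    def load(cls, path) -> "EmbeddingTable":
        df = pd.read_csv(path, sep="\t", header=None)
        vectors = {str(row[0]): np.asarray(row[1:], dtype=float)
                   for row in df.itertuples(index=False)}
        try:
            with open(str(path) + ".meta.json") as fh:
                metadata = json.load(fh)
        except FileNotFoundError:
            metadata = {}
        return cls(vectors, metadata)


def one_hot_table(scheme: TokenizationScheme | None = None,
                  vocabulary: list[str] | None = None) -> EmbeddingTable:
    """Identity-matrix embedding: dim equals vocabulary size."""
    vocab = vocabulary if vocabulary is not None else (
        (scheme or TokenizationScheme()).base_vocabulary())
    eye = np.eye(len(vocab))
    return EmbeddingTable({tok: eye[i] for i, tok in enumerate(vocab)},
                          {"kind": "one_hot"})


class SkipGramEmbedder(BaseEstimator):
    """Skip-gram-with-negative-sampling trainer, scikit-learn style.

    Parameters
    ----------
    window : context radius; the tested grid for 1-grams was {3, 5, 7}.
    dim : embedding dimension; {4, 5, 6} for 1-grams, 100 for 3-grams.
    epochs, learning_rate : SGD schedule (lr decays linearly to lr/100).
    negative : noise samples per positive pair.
    min_count : tokens rarer than this are dropped from the vocabulary.
    random_state : seed; fixed seed gives identical tables.
    """

    def __init__(self, window: int = 5, dim: int = 5, epochs: int = 5,
                 learning_rate: float = 0.025, negative: int = 5,
                 min_count: int = 1, scheme_n: int = 1,
                 random_state: int | None = None):
        self.window = window
        self.dim = dim
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.negative = negative
        self.min_count = min_count
        self.scheme_n = scheme_n
        self.random_state = random_state

    def fit(self, sentences: list[list[str]], y=None) -> "SkipGramEmbedder":
        rng = np.random.default_rng(self.random_state)
        scheme = TokenizationScheme(self.scheme_n)
        counts: dict[str, int] = {}
        for sent in sentences:
            for tok in sent:
                counts[tok] = counts.get(tok, 0) + 1
        specials = [GAP_TOKEN, UNK_TOKEN]
        vocab = specials + sorted(t for t, c in counts.items()
                                  if c >= self.min_count and t not in specials)
        if len([t for t in vocab if counts.get(t, 0) > 0]) < 2:
            raise ValueError("corpus vocabulary must contain at least 2 tokens")
        index = {t: i for i, t in enumerate(vocab)}
        V = len(vocab)

        # noise distribution: unigram^0.75 (specials get one pseudo-count)
        freq = np.array([max(counts.get(t, 0), 1) for t in vocab], float) ** 0.75
        noise = freq / freq.sum()

        W_in = rng.uniform(-0.5, 0.5, size=(V, self.dim)) / self.dim
        W_out = np.zeros((V, self.dim))

        pairs = self._pairs(sentences, index)
        n_steps = self.epochs * len(pairs)
        losses = []
        step = 0
        noise_cdf = np.cumsum(noise)
        for epoch in range(self.epochs):
            order = rng.permutation(len(pairs))
            # presample this epoch's negatives in one vectorized draw
            neg_all = np.searchsorted(
                noise_cdf, rng.random((len(pairs), self.negative)))
            epoch_loss = 0.0
            for row, k in enumerate(order):
                c, ctx = pairs[k]
                lr = self.learning_rate * max(1 - step / max(n_steps, 1), 0.01)
                step += 1
                neg = neg_all[row]
                targets = np.concatenate(([ctx], neg))
                labels = np.zeros(len(targets))
                labels[0] = 1.0
                vin = W_in[c]
                vout = W_out[targets]
                score = 1.0 / (1.0 + np.exp(-np.clip(vout @ vin, -30, 30)))
                err = score - labels
                epoch_loss += -np.log(np.clip(score[0], 1e-12, None)) \
                    - np.log(np.clip(1 - score[1:], 1e-12, None)).sum()
                W_in[c] = vin - lr * (err @ vout)
                W_out[targets] -= lr * np.outer(err, vin)
            losses.append(epoch_loss / max(len(pairs), 1))
        self.vocabulary_ = vocab
        self.loss_history_ = losses
        self.table_ = EmbeddingTable(
            {t: W_in[i].copy() for t, i in index.items()},
            {"kind": "skipgram", "n": scheme.n, "window": self.window,
             "dim": self.dim, "epochs": self.epochs,
             "negative": self.negative, "seed": self.random_state,
             "corpus_sentences": len(sentences)})
        return self

    def _pairs(self, sentences, index) -> list[tuple[int, int]]:
        pairs = []
        for sent in sentences:
            ids = [index[t] for t in sent if t in index]
            for i, c in enumerate(ids):
                lo = max(0, i - self.window)
                hi = min(len(ids), i + self.window + 1)
                for j in range(lo, hi):
                    if j != i:
                        pairs.append((c, ids[j]))
        return pairs

    def transform(self, tokens: list[str]) -> np.ndarray:
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "table_")
        unk = self.table_.vectors[UNK_TOKEN]
        return np.stack([self.table_.vectors.get(t, unk) for t in tokens])


def train_skipgram(corpus: list[list[str]], *, window: int = 5, dim: int = 5,
                   epochs: int = 5, learning_rate: float = 0.025,
                   negative: int = 5, scheme_n: int = 1,
                   seed: int | None = None) -> EmbeddingTable:
    """Functional wrapper over :class:`SkipGramEmbedder`."""
    return SkipGramEmbedder(window=window, dim=dim, epochs=epochs,
                            learning_rate=learning_rate, negative=negative,
                            scheme_n=scheme_n, random_state=seed
                            ).fit(corpus).table_
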