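"""The dual-branch recurrent binding model.

A (peptide, MHC allele) pair is mapped to a binding probability by three
cooperating parts:

* a peptide branch — token embedding (single residues or offset residue
  triplets) feeding a recurrent layer: a bi-directional GRU for 1-grams and
  one-hot residues, or three parallel GRUs (one per reading frame) whose
  final states are concatenated for 3-grams;
* an MHC branch — either a learned per-allele identity embedding (one-hot
  mode, which cannot score alleles outside its registry) or a randomly
  initialized token embedding over the allele's fixed-length groove
  pseudo-sequence followed by a fully connected or GRU entry layer
  (sequence mode, which scores any allele with a known pseudo-sequence);
* a head — two ReLU fully connected layers and a single sigmoid unit.

Weights are shared across all alleles. Training uses Adam, binary
cross-entropy, a peptide-grouped validation split and early stopping with
best-weight restoration. Dropout: 0.4 on fully connected outputs and GRU
inputs, 0.3 recurrent (variational masks, one per example per minibatch).

Minibatches are bucketed by peptide length so the recurrent layers consume
genuinely variable-length sequences without padding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from ._tensor import Tensor, bce_with_logits, concat, gather_rows
from .nn import Adam, BiGRU, Dense, Embedding, GRU, Module
from .embedding import (AMINO_ACIDS, GAP_TOKEN, UNK_TOKEN, EmbeddingTable,
                        TokenizationScheme, tokenize)

PEPTIDE_REPRS = ("one_hot", "gram1", "gram3")
MHC_REPRS = ("one_hot_allele", "sequence")
MHC_ENTRIES = ("fully_connected", "gru")
GRAM3_DIM = 100
MIN_PEPTIDE_LEN = 8


@dataclass
class FinetuneSchedule:
    """Freeze -> unfreeze -> freeze adaptation of the peptide embedding:
    train with the embedding frozen until validation loss plateaus, enable
    adaptation for `unfreeze_epochs` (1-3) epochs, then freeze again until
    early stopping."""
    unfreeze_epochs: int = 2

    def __post_init__(self):
        if self.unfreeze_epochs not in (1, 2, 3):
            raise ValueError("unfreeze_epochs must be 1, 2 or 3")


def _validate_peptide(pep: str) -> str:
    pep = pep.upper()
    bad = set(pep) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"peptide {pep!r} contains invalid letters "
                         f"{sorted(bad)}")
    if len(pep) < MIN_PEPTIDE_LEN:
        raise ValueError(f"peptide {pep!r} shorter than {MIN_PEPTIDE_LEN}")
    return pep


class _BindingNet(Module):
    """Parameter container + forward pass. Token/allele indexing is done by
    the estimator; the net sees integer index arrays only."""

    def __init__(self, rng, *, peptide_repr, pep_vocab_size, pep_dim,
                 pep_pretrained, gru_units, mhc_repr, mhc_entry,
                 n_alleles, pseudo_len, mhc_vocab_size, mhc_token_dim,
                 mhc_fc_units, mhc_gru_units, head_fc_units):
        self.peptide_repr = peptide_repr
        self.mhc_repr = mhc_repr
        self.mhc_entry = mhc_entry
        self.pep_embedding = Embedding(rng, pep_vocab_size, pep_dim,
                                       pretrained=pep_pretrained)
        if peptide_repr == "gram3":
            # one GRU per reading frame; final states concatenated
            self.pep_rnns = [GRU(rng, pep_dim, gru_units) for _ in range(3)]
            pep_out = 3 * gru_units
        else:
            self.pep_rnn = BiGRU(rng, pep_dim, gru_units)
            pep_out = 2 * gru_units
        if mhc_repr == "one_hot_allele":
            self.allele_embedding = Embedding(rng, n_alleles, mhc_fc_units)
            mhc_out = mhc_fc_units
        else:
            # always randomly initialized: gap tokens have no pre-trained vector
            self.mhc_embedding = Embedding(rng, mhc_vocab_size, mhc_token_dim)
            if mhc_entry == "fully_connected":
                self.mhc_fc = Dense(rng, pseudo_len * mhc_token_dim, mhc_fc_units)
                mhc_out = mhc_fc_units
            else:
                self.mhc_rnn = GRU(rng, mhc_token_dim, mhc_gru_units)
                mhc_out = mhc_gru_units
        self.head1 = Dense(rng, pep_out + mhc_out, head_fc_units)
        self.head2 = Dense(rng, head_fc_units, head_fc_units)
        self.out = Dense(rng, head_fc_units, 1)


class BindingClassifier(BaseEstimator, ClassifierMixin):
    """Peptide–MHC binding probability estimator.

    X is an (n, 2) array-like of ``(peptide, allele)`` string pairs (or a
    DataFrame with ``peptide`` and ``allele`` columns); y is 0/1.

    Parameters mirror the architecture described in the module docstring.
    ``pretrained_embeddings`` takes an :class:`EmbeddingTable` whose
    dimension must match ``pep_dim`` (100 for 3-grams). ``pseudo_sequences``
    (sequence mode) maps allele name -> fixed-length groove string.
    ``finetune`` enables the freeze–unfreeze–freeze adaptation schedule.
    """

    def __init__(self, *, peptide_repr: str = "gram1",
                 mhc_repr: str = "sequence",
                 mhc_entry: str = "fully_connected",
                 gru_units: int = 64, mhc_fc_units: int = 256,
                 mhc_gru_units: int = 32, head_fc_units: int = 256,
                 pep_dim: int = 5, mhc_token_dim: int = 8,
                 dropout_fc_out: float = 0.4, dropout_gru_in: float = 0.4,
                 dropout_gru_recurrent: float = 0.3,
                 learning_rate: float = 1e-3, batch_size: int = 128,
                 max_epochs: int = 50, patience: int = 5,
                 val_fraction: float = 0.2,
                 pretrained_embeddings: EmbeddingTable | None = None,
                 embedding_trainable: bool = True,
                 finetune: FinetuneSchedule | None = None,
                 pseudo_sequences: dict | None = None,
                 known_alleles: list | None = None,
                 class_weight: str | None = None,
                 random_state: int | None = None):
        self.peptide_repr = peptide_repr
        self.mhc_repr = mhc_repr
        self.mhc_entry = mhc_entry
        self.gru_units = gru_units
        self.mhc_fc_units = mhc_fc_units
        self.mhc_gru_units = mhc_gru_units
        self.head_fc_units = head_fc_units
        self.pep_dim = pep_dim
        self.mhc_token_dim = mhc_token_dim
        self.dropout_fc_out = dropout_fc_out
        self.dropout_gru_in = dropout_gru_in
        self.dropout_gru_recurrent = dropout_gru_recurrent
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.pretrained_embeddings = pretrained_embeddings
        self.embedding_trainable = embedding_trainable
        self.finetune = finetune
        self.pseudo_sequences = pseudo_sequences
        self.known_alleles = known_alleles
        self.class_weight = class_weight
        self.random_state = random_state

    # -- input plumbing ----------------------------------------------------
    @staticmethod
    def _unpack(X) -> tuple[list[str], list[str]]:
        if isinstance(X, pd.DataFrame):
            peptides = X["peptide"].tolist()
            alleles = X["allele"].tolist()
        else:
            arr = np.asarray(X, dtype=object)
            if arr.ndim != 2 or arr.shape[1] != 2:
                raise ValueError("X must be (n, 2): (peptide, allele) pairs")
            peptides, alleles = arr[:, 0].tolist(), arr[:, 1].tolist()
        return [_validate_peptide(p) for p in peptides], [str(a) for a in alleles]

    def _check_config(self):
        if self.peptide_repr not in PEPTIDE_REPRS:
            raise ValueError(f"peptide_repr must be one of {PEPTIDE_REPRS}")
        if self.mhc_repr not in MHC_REPRS:
            raise ValueError(f"mhc_repr must be one of {MHC_REPRS}")
        if self.mhc_entry not in MHC_ENTRIES:
            raise ValueError(f"mhc_entry must be one of {MHC_ENTRIES}")
        if self.mhc_repr == "sequence" and not self.pseudo_sequences:
            raise ValueError("sequence mode requires pseudo_sequences "
                             "(allele -> groove string)")
        for rate in (self.dropout_fc_out, self.dropout_gru_in,
                     self.dropout_gru_recurrent):
            if not (0.0 <= rate < 1.0):
                raise ValueError("dropout rates must be in [0, 1)")

    def _resolve_pep_dim(self) -> tuple[int, np.ndarray | None]:
        """Embedding dimension and optional pre-trained matrix for the
        peptide vocabulary."""
        base_vocab = self._pep_vocab
        if self.peptide_repr == "one_hot":
            table = np.eye(len(base_vocab))
            return len(base_vocab), table
        dim = GRAM3_DIM if self.peptide_repr == "gram3" else self.pep_dim
        if self.pretrained_embeddings is None:
            return dim, None
        tab = self.pretrained_embeddings
        if tab.dim != dim:
            raise ValueError(
                f"pre-trained embedding dimension {tab.dim} does not match "
                f"the configured peptide dimension {dim}")
        rng = np.random.default_rng(self._seed(3))
        return dim, tab.matrix(base_vocab, rng=rng)

    def _seed(self, k: int) -> int:
        base = 0 if self.random_state is None else int(self.random_state)
        return (base * 7919 + k) % (2 ** 31)

    # -- tokenization ------------------------------------------------------
    def _build_vocab(self, peptides: list[str]) -> None:
        scheme_n = 3 if self.peptide_repr == "gram3" else 1
        self._scheme = TokenizationScheme(scheme_n)
        if scheme_n == 1:
            vocab = [GAP_TOKEN, UNK_TOKEN] + list(AMINO_ACIDS)
        else:
            toks = sorted({t for p in peptides for off in (0, 1, 2)
                           for t in tokenize(p, self._scheme, off)})
            if self.pretrained_embeddings is not None:
                toks = sorted(set(toks) | set(self.pretrained_embeddings.vectors))
            vocab = [GAP_TOKEN, UNK_TOKEN] + [t for t in toks
                                              if t not in (GAP_TOKEN, UNK_TOKEN)]
        self._pep_vocab = vocab
        self._pep_index = {t: i for i, t in enumerate(vocab)}

    def _pep_tokens(self, pep: str, offset: int = 0) -> list[int]:
        unk = self._pep_index[UNK_TOKEN]
        return [self._pep_index.get(t, unk)
                for t in tokenize(pep, self._scheme, offset)]

    def _allele_row(self, allele: str) -> np.ndarray | int:
        if self.mhc_repr == "one_hot_allele":
            if allele not in self._allele_index:
                raise KeyError(
                    f"allele {allele!r} is not in the training registry; the "
                    "one-hot model cannot score unseen alleles (use sequence "
                    "mode)")
            return self._allele_index[allele]
        if allele not in self.pseudo_sequences:
            raise KeyError(f"no groove pseudo-sequence known for {allele!r}")
        seq = self.pseudo_sequences[allele].upper()
        unk = self._mhc_index[UNK_TOKEN]
        return np.array([self._mhc_index.get(ch, unk) for ch in seq])

    # -- forward -----------------------------------------------------------
    def _masks(self, rng, n: int, dim: int, rate: float) -> Tensor | None:
        if rate <= 0:
            return None
        keep = rng.random((n, dim)) >= rate
        return Tensor(keep / (1.0 - rate))

    def _peptide_branch(self, net, peptides_tok, train: bool, rng) -> Tensor:
        pep_dim = net.pep_embedding.table.shape[1]
        if self.peptide_repr == "gram3":
            branch_outs = []
            for off in range(3):
                branch_outs.append(self._run_gru_bucketed(
                    net, net.pep_rnns[off],
                    [toks[off] for toks in peptides_tok], train, rng, pep_dim))
            return concat(branch_outs, axis=1)
        return self._run_gru_bucketed(net, net.pep_rnn,
                                      [toks[0] for toks in peptides_tok],
                                      train, rng, pep_dim)

    def _run_gru_bucketed(self, net, rnn, token_lists, train, rng, pep_dim):
        buckets: dict[int, list[int]] = {}
        for i, toks in enumerate(token_lists):
            buckets.setdefault(len(toks), []).append(i)
        outs, order = [], []
        units = rnn.fwd.units if isinstance(rnn, BiGRU) else rnn.units
        for length in sorted(buckets):
            idxs = buckets[length]
            arr = np.array([token_lists[i] for i in idxs])
            xs = [net.pep_embedding(arr[:, t]) for t in range(length)]
            im = rm = None
            if train:
                im = self._masks(rng, len(idxs), pep_dim, self.dropout_gru_in)
                rm = self._masks(rng, len(idxs), units,
                                 self.dropout_gru_recurrent)
            outs.append(rnn(xs, im, rm))
            order.extend(idxs)
        merged = outs[0] if len(outs) == 1 else concat(outs, axis=0)
        inv = np.empty(len(token_lists), dtype=int)
        inv[order] = np.arange(len(order))
        return gather_rows(merged, inv)

    def _mhc_branch(self, net, allele_rows, train: bool, rng) -> Tensor:
        if self.mhc_repr == "one_hot_allele":
            idx = np.asarray(allele_rows, dtype=int)
            return net.allele_embedding(idx).relu()
        mat = np.asarray(allele_rows)          # (batch, pseudo_len)
        n, plen = mat.shape
        if self.mhc_entry == "fully_connected":
            emb = net.mhc_embedding(mat)       # (batch, plen, dim)
            flat = emb.reshape(n, plen * self.mhc_token_dim)
            h = net.mhc_fc(flat).relu()
            if train:
                mask = self._masks(rng, n, h.shape[1], self.dropout_fc_out)
                if mask is not None:
                    h = h * mask
            return h
        xs = [net.mhc_embedding(mat[:, t]) for t in range(plen)]
        im = rm = None
        if train:
            im = self._masks(rng, n, self.mhc_token_dim, self.dropout_gru_in)
            rm = self._masks(rng, n, net.mhc_rnn.units,
                             self.dropout_gru_recurrent)
        return net.mhc_rnn(xs, im, rm)

    def _forward(self, net, peptides_tok, allele_rows, train: bool, rng
                 ) -> Tensor:
        pep = self._peptide_branch(net, peptides_tok, train, rng)
        mhc = self._mhc_branch(net, allele_rows, train, rng)
        h = concat([pep, mhc], axis=1)
        for layer in (net.head1, net.head2):
            h = layer(h).relu()
            if train:
                mask = self._masks(rng, h.shape[0], h.shape[1],
                                   self.dropout_fc_out)
                if mask is not None:
                    h = h * mask
        return net.out(h)                      # logits (batch, 1)

    def _construct_net(self, use_pretrained: bool) -> _BindingNet:
        """Build the network from the fitted vocab/registry attributes."""
        pseudo_len = (len(next(iter(self.pseudo_sequences.values())))
                      if self.mhc_repr == "sequence" else 0)
        if use_pretrained:
            pep_dim, pretrained = self._resolve_pep_dim()
        else:
            pep_dim = (len(self._pep_vocab) if self.peptide_repr == "one_hot"
                       else GRAM3_DIM if self.peptide_repr == "gram3"
                       else self.pep_dim)
            pretrained = None
        net = _BindingNet(
            np.random.default_rng(self._seed(1)),
            peptide_repr=self.peptide_repr,
            pep_vocab_size=len(self._pep_vocab), pep_dim=pep_dim,
            pep_pretrained=pretrained, gru_units=self.gru_units,
            mhc_repr=self.mhc_repr, mhc_entry=self.mhc_entry,
            n_alleles=len(self.allele_registry_), pseudo_len=pseudo_len,
            mhc_vocab_size=len(self._mhc_index),
            mhc_token_dim=self.mhc_token_dim,
            mhc_fc_units=self.mhc_fc_units, mhc_gru_units=self.mhc_gru_units,
            head_fc_units=self.head_fc_units)
        if self.peptide_repr == "one_hot":
            net.pep_embedding.trainable = False
        return net

    # -- training ----------------------------------------------------------
    def fit(self, X, y, validation=None) -> "BindingClassifier":
        self._check_config()
        peptides, alleles = self._unpack(X)
        y = np.asarray(y, dtype=int)
        if len(y) != len(peptides):
            raise ValueError("X and y length mismatch")
        if len(y) == 0:
            raise ValueError("empty training set")
        if len(np.unique(y)) < 2:
            raise ValueError("training set contains a single class; the "
                             "cross-entropy loss is degenerate")
        self.classes_ = np.array([0, 1])
        self._build_vocab(peptides)
        self._mhc_index = {t: i for i, t in
                           enumerate([GAP_TOKEN, UNK_TOKEN] + list(AMINO_ACIDS))}
        # known_alleles lets one-hot mode register alleles that carry no
        # training data (their identity embeddings stay at initialization)
        self.allele_registry_ = sorted(set(alleles) |
                                       set(self.known_alleles or ()))
        self._allele_index = {a: i for i, a in enumerate(self.allele_registry_)}
        net = self._construct_net(use_pretrained=True)
        if self.mhc_repr == "one_hot_allele":
            # alleles registered without training data get a neutral (zero)
            # identity embedding: an unseen allele carries no information,
            # and a random row could accidentally mimic a trained allele
            trained = set(alleles)
            for a, i in self._allele_index.items():
                if a not in trained:
                    net.allele_embedding.table.data[i] = 0.0

        # encode once
        def encode(peps, als):
            offs = range(3) if self.peptide_repr == "gram3" else (0,)
            toks = [[self._pep_tokens(p, o) for o in offs] for p in peps]
            rows = [self._allele_row(a) for a in als]
            return toks, rows

        if validation is not None:
            Xv, yv = validation
            vp, va = self._unpack(Xv)
            train_idx = np.arange(len(peptides))
        else:
            train_idx, val_idx = self._group_val_split(peptides, y)
            vp = [peptides[i] for i in val_idx]
            va = [alleles[i] for i in val_idx]
            yv = y[val_idx]
        tp = [peptides[i] for i in train_idx]
        ta = [alleles[i] for i in train_idx]
        yt = y[train_idx]
        if set(tp) & set(vp):
            raise ValueError("train and validation sets share peptides")
        toks_t, rows_t = encode(tp, ta)
        toks_v, rows_v = encode(vp, va)

        weights_t = None
        if self.class_weight == "balanced":
            freq = np.bincount(yt, minlength=2) / len(yt)
            weights_t = np.where(yt == 1, 0.5 / max(freq[1], 1e-9),
                                 0.5 / max(freq[0], 1e-9))

        rng_train = np.random.default_rng(self._seed(2))
        self.history_ = {"train_loss": [], "val_loss": [], "phase": []}
        if self.finetune is not None:
            phases = [("frozen", None), ("adapt", self.finetune.unfreeze_epochs),
                      ("frozen", None)]
        else:
            phases = [("adapt" if self.embedding_trainable else "frozen", None)]
        if self.peptide_repr == "one_hot":
            phases = [("frozen", None)]

        best_loss, best_weights, stale = np.inf, None, 0
        epoch_total = 0
        for phase_name, phase_epochs in phases:
            net.pep_embedding.trainable = (phase_name == "adapt"
                                           and self.peptide_repr != "one_hot")
            opt = Adam(net.parameters(), lr=self.learning_rate)
            stale = 0
            phase_done = 0
            while epoch_total < self.max_epochs:
                if phase_epochs is not None and phase_done >= phase_epochs:
                    break
                tl = self._run_epoch(net, opt, toks_t, rows_t, yt, weights_t,
                                     rng_train)
                vl = self._eval_loss(net, toks_v, rows_v, yv)
                self.history_["train_loss"].append(tl)
                self.history_["val_loss"].append(vl)
                self.history_["phase"].append(phase_name)
                epoch_total += 1
                phase_done += 1
                if vl < best_loss - 1e-6:
                    best_loss, best_weights, stale = vl, net.get_weights(), 0
                else:
                    stale += 1
                    if phase_epochs is None and stale >= self.patience:
                        break
        if best_weights is not None:
            net.set_weights(best_weights)
        self.best_val_loss_ = best_loss
        self.n_epochs_ = epoch_total
        self._net = net
        return self

    def _group_val_split(self, peptides, y) -> tuple[np.ndarray, np.ndarray]:
        """Peptide-grouped validation split: ~val_fraction of records, whole
        peptide groups, deterministic under random_state."""
        rng = np.random.default_rng(self._seed(4))
        uniq = sorted(set(peptides))
        order = rng.permutation(len(uniq))
        sizes = pd.Series(peptides).value_counts()
        target = self.val_fraction * len(peptides)
        val_peps, acc = set(), 0
        for i in order:
            if acc >= target:
                break
            val_peps.add(uniq[i])
            acc += sizes[uniq[i]]
        idx = np.arange(len(peptides))
        is_val = np.array([p in val_peps for p in peptides])
        if is_val.all() or not is_val.any():
            raise ValueError("validation split failed: too few peptide groups")
        return idx[~is_val], idx[is_val]

    def _length_key(self, toks) -> tuple:
        return tuple(len(t) for t in toks)

    def _run_epoch(self, net, opt, toks, rows, y, weights, rng) -> float:
        # bucket records by token-length signature, then form same-length
        # minibatches in shuffled order
        buckets: dict[tuple, list[int]] = {}
        for i, t in enumerate(toks):
            buckets.setdefault(self._length_key(t), []).append(i)
        batches = []
        for idxs in buckets.values():
            idxs = np.array(idxs)
            rng.shuffle(idxs)
            for k in range(0, len(idxs), self.batch_size):
                batches.append(idxs[k:k + self.batch_size])
        batches = [batches[i] for i in rng.permutation(len(batches))]
        total, count = 0.0, 0
        for batch in batches:
            btoks = [toks[i] for i in batch]
            brows = [rows[i] for i in batch]
            logits = self._forward(net, btoks, brows, True, rng)
            loss = bce_with_logits(
                logits, y[batch],
                None if weights is None else weights[batch])
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += float(loss.data) * len(batch)
            count += len(batch)
        return total / max(count, 1)

    def _eval_loss(self, net, toks, rows, y) -> float:
        logits = self._predict_logits(net, toks, rows)
        return float(bce_with_logits(Tensor(logits), y).data)

    def _predict_logits(self, net, toks, rows) -> np.ndarray:
        out = np.empty((len(toks), 1))
        buckets: dict[tuple, list[int]] = {}
        for i, t in enumerate(toks):
            buckets.setdefault(self._length_key(t), []).append(i)
        for idxs in buckets.values():
            for k in range(0, len(idxs), 1024):
                chunk = idxs[k:k + 1024]
                logits = self._forward(net, [toks[i] for i in chunk],
                                       [rows[i] for i in chunk], False, None)
                out[chunk] = logits.data
        return out

    # -- inference ---------------------------------------------------------
    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "_net")
        peptides, alleles = self._unpack(X)
        offs = range(3) if self.peptide_repr == "gram3" else (0,)
        toks = [[self._pep_tokens(p, o) for o in offs] for p in peptides]
        rows = [self._allele_row(a) for a in alleles]
        logits = self._predict_logits(self._net, toks, rows).ravel()
        p1 = 1.0 / (1.0 + np.exp(-np.clip(logits, -60, 60)))
        # keep the output strictly inside (0, 1)
        p1 = np.clip(p1, 1e-12, 1 - 1e-12)
        return np.column_stack([1 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def predict_pair(self, peptide: str, allele: str) -> float:
        return float(self.predict_proba([[peptide, allele]])[0, 1])


@dataclass
class EnsembleModel:
    """Median-of-five ensemble: one member per cross-validation fold."""

    members: list

    def __post_init__(self):
        if len(self.members) != 5:
            raise ValueError("the ensemble takes exactly 5 fold models")

    def predict_proba_pairs(self, peptides: list[str], alleles: list[str]
                            ) -> np.ndarray:
        X = np.column_stack([peptides, alleles])
        all_scores = np.stack([m.predict_proba(X)[:, 1] for m in self.members])
        return np.median(all_scores, axis=0)

    def predict_pair(self, peptide: str, allele: str) -> float:
        return float(self.predict_proba_pairs([peptide], [allele])[0])


def ensemble_predict(e: EnsembleModel, peptide: str, allele: str) -> float:
    return e.predict_pair(peptide, allele)


def grouped_folds(peptides: list[str], n_folds: int = 5,
                  seed: int | None = None) -> np.ndarray:
    """Peptide-grouped partition into `n_folds` folds balanced by record
    count: groups are assigned, largest first, to the currently smallest
    fold (ties broken by fold index; equal-size groups in seeded random
    order). Returns the fold id of every record."""
    sizes = pd.Series(peptides).value_counts()
    if len(sizes) < n_folds:
        raise ValueError(f"need at least {n_folds} distinct peptides, "
                         f"got {len(sizes)}")
    rng = np.random.default_rng(seed)
    groups = list(sizes.items())
    rng.shuffle(groups)
    groups.sort(key=lambda kv: -kv[1])  # stable: seeded order within sizes
    totals = np.zeros(n_folds)
    assignment: dict[str, int] = {}
    for pep, size in groups:
        fold = int(np.argmin(totals))
        assignment[pep] = fold
        totals[fold] += size
    return np.array([assignment[p] for p in peptides])


def cross_validate(ds, *, estimator_params: dict | None = None,
                   n_folds: int = 5, seed: int = 0
                   ) -> tuple[EnsembleModel, pd.DataFrame]:
    """Peptide-grouped k-fold cross-validation.

    For each fold, the other folds form the training set (from which the
    estimator splits off its peptide-grouped validation share) and the fold
    itself is scored out-of-sample. Returns the ensemble of fold models and
    a frame with one out-of-fold prediction per input record.
    """
    df = ds.to_frame() if hasattr(ds, "to_frame") else pd.DataFrame(ds)
    folds = grouped_folds(df["peptide"].tolist(), n_folds, seed)
    params = dict(estimator_params or {})
    oof = pd.DataFrame({"allele": df["allele"], "peptide": df["peptide"],
                        "label": df["label"],
                        "fold": folds, "score": np.nan})
    members = []
    for fold in range(n_folds):
        test_mask = folds == fold
        train_df = df[~test_mask]
        base_seed = params.get("random_state")
        base_seed = seed if base_seed is None else base_seed
        clf = BindingClassifier(**{**params, "random_state": base_seed + fold})
        clf.fit(train_df[["peptide", "allele"]].to_numpy(),
                train_df["label"].to_numpy())
        scores = clf.predict_proba(
            df[test_mask][["peptide", "allele"]].to_numpy())[:, 1]
        oof.loc[test_mask, "score"] = scores
        members.append(clf)
    return EnsembleModel(members), oof
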