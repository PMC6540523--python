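"""Model checkpoints: a directory holding estimator parameters, vocabulary,
allele registry, pseudo-sequence table and weight arrays, plus a format
version so stale checkpoints fail loudly."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .model import BindingClassifier, EnsembleModel

FORMAT_VERSION = 1


def save_model(clf: BindingClassifier, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    params = clf.get_params()
    params.pop("pretrained_embeddings")  # baked into the weights
    pseudo = params.pop("pseudo_sequences")
    finetune = params.pop("finetune")
    meta = {
        "format_version": FORMAT_VERSION,
        "params": params,
        "finetune_epochs": finetune.unfreeze_epochs if finetune else None,
        "pep_vocab": clf._pep_vocab,
        "allele_registry": clf.allele_registry_,
        "pseudo_sequences": pseudo,
    }
    with open(directory / "model.json", "w") as fh:
        json.dump(meta, fh)
    weights = clf._net.get_weights()
    np.savez(directory / "weights.npz",
             **{f"w{i}": w for i, w in enumerate(weights)})


def load_model(directory) -> BindingClassifier:
    directory = Path(directory)
    with open(directory / "model.json") as fh:
        meta = json.load(fh)
    if meta.get("format_version") != FORMAT_VERSION:
        raise ValueError(
            f"checkpoint format {meta.get('format_version')!r} is not "
            f"supported (expected {FORMAT_VERSION})")
    from .model import FinetuneSchedule
    finetune = (FinetuneSchedule(meta["finetune_epochs"])
                if meta["finetune_epochs"] else None)
    clf = BindingClassifier(**meta["params"], finetune=finetune,
                            pseudo_sequences=meta["pseudo_sequences"])
    clf.classes_ = np.array([0, 1])
    clf._pep_vocab = meta["pep_vocab"]
    clf._pep_index = {t: i for i, t in enumerate(clf._pep_vocab)}
    from .embedding import AMINO_ACIDS, GAP_TOKEN, UNK_TOKEN
    from .embedding import TokenizationScheme
    clf._scheme = TokenizationScheme(3 if clf.peptide_repr == "gram3" else 1)
    clf._mhc_index = {t: i for i, t in
                      enumerate([GAP_TOKEN, UNK_TOKEN] + list(AMINO_ACIDS))}
    clf.allele_registry_ = meta["allele_registry"]
    clf._allele_index = {a: i for i, a in enumerate(clf.allele_registry_)}
    net = clf._construct_net(use_pretrained=False)
    with np.load(directory / "weights.npz") as npz:
        net.set_weights([npz[f"w{i}"] for i in range(len(npz.files))])
    clf._net = net
    return clf


def save_ensemble(e: EnsembleModel, directory) -> None:
    directory = Path(directory)
    for i, member in enumerate(e.members):
        save_model(member, directory / f"fold{i}")


def load_ensemble(directory) -> EnsembleModel:
    directory = Path(directory)
    return EnsembleModel([load_model(directory / f"fold{i}")
                          for i in range(5)])
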