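"""Synthetic alleles, peptides, binding data, corpora and peptidome samples.

The generator emulates the anchor-residue logic of class I binding at desk
scale so that every pipeline stage is testable without external downloads.
Each synthetic allele carries a 75-residue groove pseudo-sequence; two fixed
pseudo-sequence positions (RULE_POSITIONS) determine, through a fixed
residue -> preferred-residue-set map, which peptide residues the allele
accepts at its two anchors (peptide position 2 and the C-terminus). A
peptide binds an allele iff both anchor residues lie in the allele's
preference sets. The map from groove residues to preferences is therefore a
deterministic, learnable function: alleles sharing groove residues at the
rule positions have identical binding rules, which is what makes
sequence-based generalization to held-out alleles possible.

Labels are the rule's output, optionally flipped independently with
probability epsilon; the flip mask is returned so noise checks are exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


from .curation import BindingRecord, CleanedDataset
from .embedding import AMINO_ACIDS

#: 0-based positions in the groove pseudo-sequence that carry the binding rule
RULE_POSITIONS = (10, 60)
#: additional polymorphic groove positions (class I polymorphism concentrates
#: at a handful of sites; everything else is consensus)
N_EXTRA_POLYMORPHIC = 10
#: residues each anchor preference set contains
PREFERENCE_SET_SIZE = 4


def _preference_set(groove_residue: str) -> frozenset:
    """Deterministic residue -> preferred anchor residues map (alphabet
    rotation; no randomness, so shared groove residues imply shared rules)."""
    i = AMINO_ACIDS.index(groove_residue)
    return frozenset(AMINO_ACIDS[(4 * i + j) % 20]
                     for j in range(PREFERENCE_SET_SIZE))


@dataclass
class SyntheticAlleleSpec:
    n_alleles: int = 8
    pseudo_length: int = 75
    seed: int = 0
    #: pairs of alleles forced to share their rule-carrying groove residues
    #: (index pairs); used to construct learnable leave-one-allele-out setups
    shared_rule_pairs: tuple = ()

    def __post_init__(self):
        if self.pseudo_length <= max(RULE_POSITIONS):
            raise ValueError("pseudo_length must cover the rule positions")


@dataclass
class SyntheticBindingRule:
    """Pure function (peptide, allele) -> 0/1 via per-allele anchor sets."""

    preferences: dict[str, tuple[frozenset, frozenset]]

    def __call__(self, peptide: str, allele: str) -> int:
        p2_set, ct_set = self.preferences[allele]
        return int(peptide[1] in p2_set and peptide[-1] in ct_set)


@dataclass
class SyntheticDatasetSpec:
    n_records: int = 5000
    length_range: tuple = (8, 15)
    positive_fraction: float = 0.5
    noise: float = 0.05
    #: share of negatives built as decoys: peptides anchored for a *different*
    #: allele (but failing the assigned allele's rule). Without decoys a
    #: model could separate classes by "looks anchored at all" without ever
    #: consulting the allele, which real binding panels do not permit.
    decoy_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.noise < 0.5):
            raise ValueError("label-noise rate must be in [0, 0.5)")
        lo, hi = self.length_range
        if lo < 8 or hi > 15 or lo > hi:
            raise ValueError("peptide lengths must lie within [8, 15]")


def generate_alleles(spec: SyntheticAlleleSpec
                     ) -> tuple[list[str], dict[str, str], SyntheticBindingRule]:
    """Returns (allele registry, pseudo-sequence table, ground-truth rule).

    Alleles are variants of a common consensus groove, polymorphic only at
    the rule positions plus a fixed handful of neutral sites — mirroring how
    class I alleles differ at few positions, which is what makes an unseen
    allele's groove in-distribution for a sequence-based model. Residues at
    the first rule position are drawn without replacement, so preference
    profiles are distinct across alleles unless a `shared_rule_pairs` entry
    explicitly copies them.
    """
    if spec.n_alleles > len(AMINO_ACIDS):
        raise ValueError("at most 20 alleles with distinct rule residues")
    rng = np.random.default_rng(spec.seed)
    aa = np.array(list(AMINO_ACIDS))
    names = [f"SYN-A*{i + 1:02d}:01" for i in range(spec.n_alleles)]
    consensus = rng.choice(aa, size=spec.pseudo_length)
    extra_sites = rng.choice(
        [i for i in range(spec.pseudo_length) if i not in RULE_POSITIONS],
        size=N_EXTRA_POLYMORPHIC, replace=False)
    rule1 = rng.choice(aa, size=spec.n_alleles, replace=False)
    rule2 = rng.choice(aa, size=spec.n_alleles, replace=True)
    pseudo: dict[str, str] = {}
    for k, name in enumerate(names):
        seq = consensus.copy()
        seq[RULE_POSITIONS[0]] = rule1[k]
        seq[RULE_POSITIONS[1]] = rule2[k]
        seq[extra_sites] = rng.choice(aa, size=len(extra_sites))
        pseudo[name] = "".join(seq)
    for a, b in spec.shared_rule_pairs:
        seq_a, seq_b = pseudo[names[a]], list(pseudo[names[b]])
        for pos in RULE_POSITIONS:
            seq_b[pos] = seq_a[pos]
        pseudo[names[b]] = "".join(seq_b)
    prefs = {name: (_preference_set(seq[RULE_POSITIONS[0]]),
                    _preference_set(seq[RULE_POSITIONS[1]]))
             for name, seq in pseudo.items()}
    return names, pseudo, SyntheticBindingRule(prefs)


def _draw_peptide(rng, length, p2_set, ct_set, positive: bool, aa) -> str:
    """Sample a peptide that satisfies (positive) or violates the anchor rule."""
    for _ in range(1000):
        pep = list(rng.choice(aa, size=length))
        if positive:
            pep[1] = rng.choice(sorted(p2_set))
            pep[-1] = rng.choice(sorted(ct_set))
            return "".join(pep)
        if not (pep[1] in p2_set and pep[-1] in ct_set):
            return "".join(pep)
    raise RuntimeError("could not sample a rule-violating peptide")


def generate_binding_data(alleles: list[str], pseudo: dict[str, str],
                          rule: SyntheticBindingRule,
                          dspec: SyntheticDatasetSpec,
                          decoy_donors: list[str] | None = None
                          ) -> tuple[CleanedDataset, np.ndarray]:
    """Binding records with rule-derived labels; returns (dataset, flip_mask).

    Peptide lengths are uniform on the length range; a `positive_fraction`
    share of peptides is constructed to satisfy its allele's rule. Labels
    equal the rule output, then are flipped independently with probability
    `noise`. (peptide, allele) pairs are unique. `decoy_donors` optionally
    names the allele panel decoy negatives borrow their anchors from
    (defaults to `alleles`); passing a disjoint panel builds evaluation
    sets whose negatives are all plausible binders of other alleles.
    """
    if not alleles:
        raise ValueError("allele registry is empty")
    rng = np.random.default_rng(dspec.seed)
    aa = np.array(list(AMINO_ACIDS))
    lo, hi = dspec.length_range
    seen: set[tuple[str, str]] = set()
    records: list[BindingRecord] = []
    true_labels: list[int] = []
    attempts = 0
    while len(records) < dspec.n_records:
        attempts += 1
        if attempts > 50 * dspec.n_records:
            raise RuntimeError(
                "positive fraction infeasible at this dataset size")
        allele = alleles[rng.integers(len(alleles))]
        positive = rng.random() < dspec.positive_fraction
        length = int(rng.integers(lo, hi + 1))
        p2_set, ct_set = rule.preferences[allele]
        donors = decoy_donors if decoy_donors is not None else alleles
        decoys_possible = (len(donors) > 1 if decoy_donors is None
                           else len(donors) > 0)
        if positive:
            pep = _draw_peptide(rng, length, p2_set, ct_set, True, aa)
        elif decoys_possible and rng.random() < dspec.decoy_fraction:
            # decoy negative: anchored for another allele, not for this one
            donor = donors[rng.integers(len(donors))]
            d2, dct = rule.preferences[donor]
            pep = _draw_peptide(rng, length, d2, dct, True, aa)
            if rule(pep, allele):
                continue
        else:
            pep = _draw_peptide(rng, length, p2_set, ct_set, False, aa)
        if (pep, allele) in seen:
            continue
        seen.add((pep, allele))
        y = rule(pep, allele)
        records.append(BindingRecord(pep, allele, "", "synthetic", y))
        true_labels.append(y)
    flip_mask = rng.random(len(records)) < dspec.noise
    for r, flip in zip(records, flip_mask):
        if flip:
            r.binary_label = 1 - r.binary_label
    ds = CleanedDataset(records, {"synthetic_noise_flips": int(flip_mask.sum())})
    return ds, flip_mask


def generate_corpus(n_proteins: int = 50, length_range: tuple = (50, 100),
                    n_ninemers: int = 200, seed: int = 0
                    ) -> tuple[list[tuple[str, str]], list[str]]:
    """Random protein FASTA records plus 9-mers cut from them at random
    offsets (a stand-in for a proteome and proteasome-cleaved fragments)."""
    if n_proteins < 1:
        raise ValueError("need at least one protein")
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    proteins = []
    for i in range(n_proteins):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        proteins.append((f"synprot{i + 1}", "".join(rng.choice(aa, size=length))))
    ninemers = []
    for _ in range(n_ninemers):
        _, seq = proteins[rng.integers(n_proteins)]
        start = int(rng.integers(0, len(seq) - 9 + 1))
        ninemers.append(seq[start:start + 9])
    return proteins, ninemers


@dataclass
class PeptidomeSample:
    sample_id: str
    alleles: list[str]
    positives: list[str]
    negatives: list[str]


def generate_peptidome(alleles: list[str], rule: SyntheticBindingRule,
                       n_pos: int = 100, n_neg: int = 100, seed: int = 0,
                       sample_id: str = "SYN-IND-1") -> PeptidomeSample:
    """An individual's detected-ligand set: positives bind >= 1 of the
    individual's alleles, negatives bind none of them."""
    if not alleles:
        raise ValueError("peptidome sample needs at least one allele")
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    positives: set[str] = set()
    negatives: set[str] = set()
    while len(positives) < n_pos:
        allele = alleles[rng.integers(len(alleles))]
        p2_set, ct_set = rule.preferences[allele]
        pep = _draw_peptide(rng, int(rng.integers(8, 16)), p2_set, ct_set,
                            True, aa)
        positives.add(pep)
    while len(negatives) < n_neg:
        pep = "".join(rng.choice(aa, size=int(rng.integers(8, 16))))
        if pep not in positives and not any(rule(pep, a) for a in alleles):
            negatives.add(pep)
    return PeptidomeSample(sample_id, list(alleles), sorted(positives),
                           sorted(negatives))


def write_fasta(records: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


def write_peptide_list(peptides: list[str], path) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(peptides) + "\n")
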