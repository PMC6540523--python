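"""Curation of qualitative peptide–MHC binding records.

Raw exports (IEDB-style TSV) carry one row per experimental observation with
a five-level qualitative call: Positive-High, Positive, Positive-Intermediate,
Positive-Low, Negative. Curation applies, in order:

1. a source blacklist (wholesale exclusion of conflict-heavy publications),
2. record-level filters (allele specificity, optional allele-sequence
   availability, peptide length 8–15, ambiguous letters B/X/J/Z),
3. a label policy mapping qualitative calls to binary targets (the default
   drops the low-confidence Positive-Intermediate / Positive-Low levels),
4. conflict resolution per (peptide, allele): identical duplicates collapse,
   mixed groups take the majority label, exact ties are excluded entirely.

Every stage records how many records it dropped, so the pipeline satisfies
records_in == records_out + sum(dropped).
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

QUALITATIVE_LABELS = (
    "Positive-High", "Positive", "Positive-Intermediate", "Positive-Low",
    "Negative",
)

#: strict = the default policy: drop the two low-confidence positive levels.
LABEL_POLICIES: dict[str, dict[str, int | None]] = {
    "strict": {
        "Positive-High": 1, "Positive": 1, "Positive-Intermediate": None,
        "Positive-Low": None, "Negative": 0,
    },
    "lenient": {
        "Positive-High": 1, "Positive": 1, "Positive-Intermediate": 1,
        "Positive-Low": 1, "Negative": 0,
    },
}

AMBIGUOUS_AA = set("BXJZ")
STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
MIN_PEPTIDE_LEN = 8
MAX_PEPTIDE_LEN = 15

# fully specified class I allele: gene*group:protein, e.g. HLA-A*02:01
_ALLELE_RE = re.compile(r"^(?P<gene>[A-Z0-9]+(?:-[A-Z0-9]+)*)\*\d+:\d+$")

DEFAULT_COLUMNS = {
    "allele": "allele", "peptide": "peptide", "label": "label",
    "source": "source",
}


@dataclass
class BindingRecord:
    peptide: str
    allele_name: str
    qualitative_label: str
    source_id: str = ""
    binary_label: int | None = None


@dataclass
class CleanedDataset:
    """Conflict-free binary-labelled records plus a per-rule drop audit."""

    records: list[BindingRecord]
    audit: dict[str, int] = field(default_factory=dict)
    source_blacklist: frozenset = frozenset()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"allele": [r.allele_name for r in self.records],
             "peptide": [r.peptide for r in self.records],
             "label": [r.binary_label for r in self.records]})

    def __len__(self) -> int:
        return len(self.records)


def normalize_allele(name: str) -> str:
    name = re.sub(r"\s+", "", str(name))
    m = _ALLELE_RE.match(name.upper())
    return m.group(0) if m else name.upper() if name else name


def parse_binding_table(path, columns: dict | None = None
                        ) -> tuple[list[BindingRecord], list[dict]]:
    """Read a TSV of raw binding records.

    `columns` maps the roles {peptide, allele, label, source} to the file's
    column names; the shipped default expects those literal names. Returns
    (records, rejects): rows whose qualitative label is not one of the five
    defined levels go to the rejects list rather than being silently dropped.
    """
    cols = {**DEFAULT_COLUMNS, **(columns or {})}
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty and df.columns.size == 0:
        logger.warning("empty binding table: %s", path)
        return [], []
    missing = [c for role, c in cols.items()
               if c not in df.columns and role != "source"]
    if missing:
        raise ValueError(
            f"binding table {path} is missing required column(s): "
            f"{', '.join(sorted(missing))}")
    has_source = cols["source"] in df.columns
    records, rejects = [], []
    for row in df.itertuples(index=False):
        row = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        label = str(row[cols["label"]]).strip()
        entry = BindingRecord(
            peptide=str(row[cols["peptide"]]).strip().upper(),
            allele_name=normalize_allele(row[cols["allele"]]),
            qualitative_label=label,
            source_id=str(row[cols["source"]]).strip() if has_source else "")
        if label in QUALITATIVE_LABELS:
            records.append(entry)
        else:
            rejects.append({**row, "_reason": f"unparseable label {label!r}"})
    if rejects:
        logger.warning("%d row(s) with unparseable labels rejected", len(rejects))
    if not records and not rejects:
        logger.warning("binding table %s contained no data rows", path)
    return records, rejects


def filter_record(r: BindingRecord,
                  known_allele_sequences: set[str] | None = None) -> str | None:
    """Return None to keep, or the first failing rule's reason code.

    Rules are checked in a fixed order: nonspecific_allele ->
    unknown_allele_sequence (only when a known-sequence set is supplied) ->
    length -> ambiguous_aa. The order affects only audit attribution.
    """
    if not _ALLELE_RE.match(r.allele_name):
        return "nonspecific_allele"
    if known_allele_sequences is not None and r.allele_name not in known_allele_sequences:
        return "unknown_allele_sequence"
    if not (MIN_PEPTIDE_LEN <= len(r.peptide) <= MAX_PEPTIDE_LEN):
        return "length"
    if set(r.peptide) - STANDARD_AA:
        return "ambiguous_aa"
    return None


def map_label(q: str, policy: str | dict = "strict") -> int | None:
    """Map a qualitative call to 1/0, or None meaning 'drop this record'."""
    table = LABEL_POLICIES[policy] if isinstance(policy, str) else policy
    if q not in table:
        raise ValueError(f"unknown qualitative label: {q!r}")
    return table[q]


def resolve_conflicts(records: list[BindingRecord],
                      blacklist: set[str] = frozenset()) -> CleanedDataset:
    """Blacklist -> de-duplicate -> majority vote -> drop exact ties.

    All records must already carry a binary label. The vote counts distinct
    records (not distinct sources). Output order is canonical
    (allele, peptide)-sorted, so the result is independent of input order.
    """
    blacklist = frozenset(blacklist)
    audit: dict[str, int] = {}
    kept = [r for r in records if r.source_id not in blacklist]
    audit["blacklisted_source"] = len(records) - len(kept)

    groups: dict[tuple[str, str], list[int]] = {}
    for r in kept:
        if r.binary_label is None:
            raise ValueError("resolve_conflicts requires binary labels on all records")
        groups.setdefault((r.peptide, r.allele_name), []).append(r.binary_label)

    out: list[BindingRecord] = []
    n_dup = n_majority = n_tie = 0
    for (pep, allele), labels in sorted(groups.items()):
        votes = Counter(labels)
        if len(votes) == 1:
            n_dup += len(labels) - 1
            label = labels[0]
        elif votes[0] == votes[1]:
            n_tie += len(labels)
            continue
        else:
            label = votes.most_common(1)[0][0]
            n_majority += len(labels) - 1
        out.append(BindingRecord(pep, allele, "", "", label))
    audit["duplicate_collapsed"] = n_dup
    audit["conflict_majority_collapsed"] = n_majority
    audit["conflict_tie_excluded"] = n_tie
    return CleanedDataset(out, audit, blacklist)


def clean(records: list[BindingRecord], *,
          label_policy: str | dict = "strict",
          blacklist: set[str] = frozenset(),
          known_allele_sequences: set[str] | None = None) -> CleanedDataset:
    """Full curation cascade: filters -> label mapping -> conflict resolution."""
    audit: dict[str, int] = Counter()
    surviving: list[BindingRecord] = []
    for r in records:
        reason = filter_record(r, known_allele_sequences)
        if reason is not None:
            audit[f"filter:{reason}"] += 1
            continue
        label = map_label(r.qualitative_label, label_policy)
        if label is None:
            audit["label_policy_dropped"] += 1
            continue
        surviving.append(BindingRecord(
            r.peptide, r.allele_name, r.qualitative_label, r.source_id, label))
    ds = resolve_conflicts(surviving, blacklist)
    ds.audit = {**dict(audit), **ds.audit}
    policy_name = label_policy if isinstance(label_policy, str) else "custom"
    logger.info("curation used label policy %r", policy_name)
    return ds


def dataset_summary(ds: CleanedDataset, ndigits: int = 1) -> dict:
    """Counts over the cleaned set: totals, per-gene allele counts and entry
    fractions, per-allele entry ranges. Because 'ligands per allele' can be
    read as all entries or positives only, both tallies are reported."""
    df = ds.to_frame()
    if df.empty:
        logger.warning("dataset_summary called on an empty dataset")
        return {"total_entries": 0, "alleles_per_gene": {}, "gene_fractions": {},
                "entries_per_allele_min": 0, "entries_per_allele_max": 0,
                "positives_per_allele_min": 0, "positives_per_allele_max": 0}
    gene = df["allele"].str.split("*").str[0]
    per_allele = df.groupby("allele").size()
    per_allele_pos = df[df["label"] == 1].groupby("allele").size()
    return {
        "total_entries": int(len(df)),
        "alleles_per_gene": df.assign(gene=gene).groupby("gene")["allele"]
                              .nunique().to_dict(),
        "gene_fractions": {g: round(100.0 * n / len(df), ndigits)
                           for g, n in gene.value_counts().items()},
        "entries_per_allele_min": int(per_allele.min()),
        "entries_per_allele_max": int(per_allele.max()),
        "positives_per_allele_min": int(per_allele_pos.min()) if len(per_allele_pos) else 0,
        "positives_per_allele_max": int(per_allele_pos.max()) if len(per_allele_pos) else 0,
    }


def write_cleaned(ds: CleanedDataset, path, audit_path=None) -> None:
    ds.to_frame().to_csv(path, sep="\t", index=False)
    if audit_path is not None:
        with open(audit_path, "w") as fh:
            for rule, n in ds.audit.items():
                fh.write(f"{rule}\t{n}\n")


def read_cleaned(path) -> CleanedDataset:
    df = pd.read_csv(path, sep="\t", dtype={"allele": str, "peptide": str,
                                            "label": int})
    recs = [BindingRecord(p, a, "", "", int(l))
            for a, p, l in zip(df["allele"], df["peptide"], df["label"])]
    return CleanedDataset(recs, {})
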