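"""MHC binding-groove pseudo-sequences from a multiple-sequence alignment.

Each class I allele is represented by the residues of the two alpha helices
that line the peptide-binding groove. The helix residue positions are given
on a reference allele (HLA-B*35:01, positions 50–84 and 140–179 of the chain
as numbered in its crystal structure) and transferred to every other allele
by locating those reference residues' columns in an MSA of all alleles.
Columns where another allele has a deletion keep the alignment gap character,
which downstream models treat as an ordinary vocabulary token.

Residue numbering is 1-based on the *ungapped* reference sequence exactly as
supplied. The reference FASTA must therefore be the chain matching the
intended numbering (mature protein vs precursor differ by the signal
peptide); this module performs no renumbering of its own.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO

GAP = "-"
DEFAULT_REFERENCE = "HLA-B*35:01"
#: the two alpha-helix windows (1-based, inclusive) on the reference chain
ALPHA_HELIX_WINDOWS = ((50, 84), (140, 179))
#: alternative beta-sheet windows; supported but off by default because
#: including the sheet residues degrades prediction performance
BETA_SHEET_WINDOWS = ((3, 37), (94, 126))


@dataclass
class AlignedAlleleSet:
    entries: dict[str, str]
    column_count: int


@dataclass
class ReferenceWindows:
    reference_allele: str = DEFAULT_REFERENCE
    windows: tuple = ALPHA_HELIX_WINDOWS

    def __post_init__(self):
        prev_end = 0
        for start, end in self.windows:
            if start < 1 or end < start:
                raise ValueError(f"invalid window {start}-{end}")
            if start <= prev_end:
                raise ValueError("windows must be ascending and non-overlapping")
            prev_end = end

    @property
    def n_positions(self) -> int:
        return sum(end - start + 1 for start, end in self.windows)


@dataclass
class AllelePseudoSequence:
    allele_name: str
    groove_sequence: str

    def __len__(self) -> int:
        return len(self.groove_sequence)


def read_aligned_fasta(path) -> AlignedAlleleSet:
    """Parse an aligned FASTA; enforce equal lengths and unique headers."""
    entries: dict[str, str] = {}
    ragged: list[str] = []
    length = None
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.description.strip() or rec.id
        if name in entries:
            raise ValueError(f"duplicate allele name in alignment: {name!r}")
        seq = str(rec.seq).upper()
        if length is None:
            length = len(seq)
        elif len(seq) != length:
            ragged.append(name)
        entries[name] = seq
    if ragged:
        raise ValueError(
            "ragged alignment (records differ in length): " + ", ".join(ragged))
    if length is None:
        raise ValueError(f"no sequences found in {path}")
    return AlignedAlleleSet(entries, length)


def reference_positions_to_columns(aln: AlignedAlleleSet,
                                   rw: ReferenceWindows | None = None
                                   ) -> list[int]:
    """Map 1-based ungapped reference residue positions to 0-based MSA columns.

    Gaps in the reference row do not count as residues, so an insertion in
    another allele shifts the returned columns without changing which
    reference residues they point at.
    """
    rw = rw or ReferenceWindows()
    if rw.reference_allele not in aln.entries:
        raise KeyError(
            f"reference allele {rw.reference_allele!r} not in alignment")
    row = aln.entries[rw.reference_allele]
    residue_to_column: list[int] = [
        col for col, ch in enumerate(row) if ch != GAP]
    columns: list[int] = []
    for start, end in rw.windows:
        if end > len(residue_to_column):
            raise ValueError(
                f"window position {end} exceeds ungapped reference length "
                f"{len(residue_to_column)}")
        columns.extend(residue_to_column[start - 1:end])
    return columns


def extract_pseudosequences(aln: AlignedAlleleSet, columns: list[int]
                            ) -> list[AllelePseudoSequence]:
    if columns and max(columns) >= aln.column_count:
        raise ValueError("column index beyond alignment width")
    return [AllelePseudoSequence(name, "".join(seq[c] for c in columns))
            for name, seq in aln.entries.items()]


def pseudosequence_table(aln: AlignedAlleleSet,
                         rw: ReferenceWindows | None = None) -> dict[str, str]:
    """allele -> groove sequence, using the default alpha-helix windows."""
    cols = reference_positions_to_columns(aln, rw)
    return {p.allele_name: p.groove_sequence
            for p in extract_pseudosequences(aln, cols)}


def run_alignment(fasta_path, tool: str | None = None) -> AlignedAlleleSet:
    """Align allele sequences with an external MSA tool (e.g. mafft, muscle).

    Without `tool` this refuses and directs the user to supply a pre-aligned
    FASTA to `read_aligned_fasta` — alignment is deliberately not bundled.
    """
    if tool is None:
        raise RuntimeError(
            "no multiple-sequence aligner configured; either pass "
            "tool='mafft' (or a path to an installed aligner) or supply a "
            "pre-aligned FASTA via read_aligned_fasta()")
    exe = shutil.which(tool)
    if exe is None:
        raise RuntimeError(f"aligner {tool!r} not found on PATH")
    proc = subprocess.run([exe, "--auto", str(fasta_path)]
                          if "mafft" in tool else [exe, "-in", str(fasta_path)],
                          capture_output=True, text=True)
    if proc.returncode != 0:
        raise RuntimeError(f"aligner failed (exit {proc.returncode}):\n"
                           f"{proc.stderr.strip()}")
    import io
    entries: dict[str, str] = {}
    length = None
    for rec in SeqIO.parse(io.StringIO(proc.stdout), "fasta"):
        entries[rec.description.strip() or rec.id] = str(rec.seq).upper()
        length = len(rec.seq)
    if not entries:
        raise RuntimeError("aligner produced no output")
    return AlignedAlleleSet(entries, length)


def write_pseudo_tsv(table: dict[str, str], path) -> None:
    pd.DataFrame({"allele": list(table), "groove_sequence": list(table.values())}
                 ).to_csv(path, sep="\t", index=False)


def read_pseudo_tsv(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    lengths = df["groove_sequence"].str.len().unique()
    if len(lengths) > 1:
        raise ValueError("pseudo-sequences differ in length")
    return dict(zip(df["allele"], df["groove_sequence"]))
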