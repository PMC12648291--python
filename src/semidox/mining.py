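"""Sequence mining for [4Fe-4S] cluster-binding peptides.

Bacterial ferredoxins coordinate one or two cubane [4Fe-4S] clusters through
four conserved cysteine thiolates per cluster.  The canonical binding motif is
a fixed-spacing cysteine template, ``C-x-x-C-x-x-C-x-x-x-C-P``, that appears
once per beta-alpha-beta half-domain.  This module reads protein FASTA, scans
for the motif, and classifies sequences into size/motif-count categories:

* ``semidoxin_like`` — a half-ferredoxin-sized peptide (default <= 40 aa) with
  exactly one cluster motif; such peptides can homodimerize to bind two
  clusters.
* ``short_ferredoxin`` — under 60 aa but already carrying two motifs.
* ``ferredoxin`` — a full-length (>= 60 aa) protein with two or more motifs.
* ``other`` — anything else.

Oxygen-requirement metadata (aerobe / anaerobe / facultative) can ride along
on FASTA headers as ``key=value`` tokens and is carried through to the
classification report, where it feeds the anaerobe-enrichment analysis in
:mod:`semidox.charge`.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

__all__ = [
    "AMINO_ACIDS",
    "OXYGEN_CLASSES",
    "DEFAULT_MOTIF",
    "DESIGN_PEPTIDES",
    "SEMIDOXIN_DESIGNS",
    "SYMDOXIN_DESIGNS",
    "SequenceRecord",
    "MotifHit",
    "FerredoxinClass",
    "ClassifyConfig",
    "read_fasta",
    "write_fasta",
    "find_cluster_motifs",
    "classify_sequence",
    "classify_all",
    "filter_short",
    "classification_report",
]

#: The 20 standard amino acids, one-letter codes.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Recognised oxygen-requirement labels (JGI-GOLD-style annotation).
OXYGEN_CLASSES = frozenset({"aerobe", "anaerobe", "facultative", "unknown"})

#: Default cluster-binding motif template: 'C' and 'P' are literal, '.' is any
#: residue.  Spacing C-x-x-C-x-x-C-x-x-x-C-P, 12 positions, 4 ligand Cys.
DEFAULT_MOTIF = "C..C..C...CP"

#: Designed semidoxins (28 aa), the natural Thermoanaerobacter semidoxin PD1
#: (30 aa), and the cognate single-chain symdoxins.
DESIGN_PEPTIDES: dict[str, str] = {
    "AN": "AYIITEKCIGCGKCARVCPVDAISGEWG",
    "AC": "HVIDQDKCIKCGACIEACPVDAIIKAWG",
    "SN": "AYVINDACIACGACVEECPVDAISEGWG",
    "SC": "YVIDPDTCIDCGACADVCPVDAIVVEWG",
    "PD1": "KLKNGIAYIDPKKCRDCGRCIDICPVGAIS",
    "ANN": "AYIITEKCIGCGKCARVCPVDAISGEVKKAYIITEKCIGCGKCARVCPVDAISG",
    "ACC": "HVIDQDKCIKCGACIEACPVDAIIKAEVKKHVIDQDKCIKCGACIEACPVDAIIKA",
    "SNN": "AYVINDACIACGACVEECPVDAISEGDKAAYVINDACIACGACVEECPVDAISEG",
    "SCC": "YVIDPDTCIDCGACADVCPVDAIVVEDKAYVIDPDTCIDCGACADVCPVDAIVVE",
}

SEMIDOXIN_DESIGNS = ("AN", "AC", "SN", "SC")
SYMDOXIN_DESIGNS = ("ANN", "ACC", "SNN", "SCC")


@dataclass
class SequenceRecord:
    """One protein sequence with optional taxon / oxygen-requirement metadata."""

    id: str
    residues: str
    description: str = ""
    oxygen_class: str = "unknown"
    taxon: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be nonempty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r}: residues must be nonempty")
        for i, ch in enumerate(self.residues):
            if ch not in AMINO_ACIDS:
                raise ValueError(
                    f"sequence {self.id!r}: non-standard residue {ch!r} "
                    f"at position {i}"
                )
        if self.oxygen_class not in OXYGEN_CLASSES:
            raise ValueError(
                f"sequence {self.id!r}: unknown oxygen_class "
                f"{self.oxygen_class!r} (expected one of {sorted(OXYGEN_CLASSES)})"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class MotifHit:
    """A single cluster-motif match within a sequence.

    ``start``/``end`` follow Python slice conventions (0-based, end
    exclusive); ``ligand_positions`` are the 0-based indices of the four
    first-shell cysteine ligands.
    """

    seq_id: str
    start: int
    end: int
    ligand_positions: list[int] = field(default_factory=list)


@dataclass(frozen=True)
class ClassifyConfig:
    """Size thresholds for the ferredoxin classification rules."""

    semidoxin_max_len: int = 40  # "~30 aa" with slack; inclusive
    short_max_len: int = 60  # strict upper bound for "short"


@dataclass
class FerredoxinClass:
    seq_id: str
    n_motifs: int
    length: int
    label: str


def _parse_header_metadata(description: str) -> tuple[str, str | None]:
    """Extract oxygen=/taxon= key=value tokens from a FASTA description."""
    oxygen = "unknown"
    taxon: str | None = None
    for token in description.split():
        if "=" not in token:
            continue
        key, _, value = token.partition("=")
        if key.lower() in {"oxygen", "oxygen_class"}:
            oxygen = value.lower()
        elif key.lower() == "taxon":
            taxon = value.replace("_", " ")
    return oxygen, taxon


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a protein FASTA file into :class:`SequenceRecord` objects.

    Residues are uppercased and trailing ``*`` stop characters stripped.
    Header tokens of the form ``oxygen=anaerobe`` or ``taxon=...`` populate
    the metadata fields.  Duplicate ids and non-amino-acid characters raise
    ``ValueError``; an empty file returns an empty list with a warning.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        residues = str(rec.seq).upper().rstrip("*")
        oxygen, taxon = _parse_header_metadata(rec.description)
        records.append(
            SequenceRecord(
                id=rec.id,
                residues=residues,
                description=rec.description,
                oxygen_class=oxygen,
                taxon=taxon,
            )
        )
    if not records:
        warnings.warn(f"no sequences found in {path}", stacklevel=2)
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path, width: int = 80) -> None:
    """Write records as FASTA with lines wrapped at ``width`` characters."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            header = rec.id
            extra = []
            if rec.oxygen_class != "unknown":
                extra.append(f"oxygen={rec.oxygen_class}")
            if rec.taxon:
                extra.append(f"taxon={rec.taxon.replace(' ', '_')}")
            if extra:
                header += " " + " ".join(extra)
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def _compile_motif(pattern: str) -> tuple[re.Pattern[str], list[int]]:
    """Turn a fixed-gap template ('C'/'P' literal, '.' wildcard) into a regex
    plus the offsets of the cysteine ligands within the template."""
    if not pattern or any(ch not in "CP." for ch in pattern):
        raise ValueError(
            f"motif template {pattern!r} may contain only 'C', 'P' and '.'"
        )
    regex = re.compile(pattern.replace(".", "[A-Z]"))
    ligand_offsets = [i for i, ch in enumerate(pattern) if ch == "C"]
    return regex, ligand_offsets


def find_cluster_motifs(
    record: SequenceRecord, pattern: str = DEFAULT_MOTIF
) -> list[MotifHit]:
    """Scan a sequence for cluster-binding motifs.

    Matches are taken left-to-right without overlap: the leftmost match wins
    and scanning resumes after its end.
    """
    regex, offsets = _compile_motif(pattern)
    hits: list[MotifHit] = []
    for m in regex.finditer(record.residues):
        hits.append(
            MotifHit(
                seq_id=record.id,
                start=m.start(),
                end=m.end(),
                ligand_positions=[m.start() + off for off in offsets],
            )
        )
    return hits


def classify_sequence(
    record: SequenceRecord,
    hits: list[MotifHit],
    cfg: ClassifyConfig = ClassifyConfig(),
) -> FerredoxinClass:
    """Assign a size/motif-count category to one sequence.

    Rules: ``semidoxin_like`` if length <= ``semidoxin_max_len`` and exactly
    one motif; ``short_ferredoxin`` if length < ``short_max_len`` and two
    motifs; ``ferredoxin`` if length >= ``short_max_len`` and >= 2 motifs;
    ``other`` otherwise.
    """
    n = len(hits)
    length = len(record)
    if length <= cfg.semidoxin_max_len and n == 1:
        label = "semidoxin_like"
    elif length < cfg.short_max_len and n == 2:
        label = "short_ferredoxin"
    elif length >= cfg.short_max_len and n >= 2:
        label = "ferredoxin"
    else:
        label = "other"
    return FerredoxinClass(seq_id=record.id, n_motifs=n, length=length, label=label)


def classify_all(
    records: list[SequenceRecord],
    pattern: str = DEFAULT_MOTIF,
    cfg: ClassifyConfig = ClassifyConfig(),
) -> list[FerredoxinClass]:
    return [classify_sequence(r, find_cluster_motifs(r, pattern), cfg) for r in records]


def filter_short(records: list[SequenceRecord], max_len: int = 60) -> list[SequenceRecord]:
    """Keep sequences strictly shorter than ``max_len`` residues."""
    return [r for r in records if len(r) < max_len]


def classification_report(
    records: list[SequenceRecord],
    pattern: str = DEFAULT_MOTIF,
    cfg: ClassifyConfig = ClassifyConfig(),
) -> pd.DataFrame:
    """Tabulate classification results (seq_id, length, n_motifs, label,
    oxygen_class), suitable for TSV export."""
    classes = classify_all(records, pattern, cfg)
    by_id = {r.id: r for r in records}
    return pd.DataFrame(
        {
            "seq_id": [c.seq_id for c in classes],
            "length": [c.length for c in classes],
            "n_motifs": [c.n_motifs for c in classes],
            "label": [c.label for c in classes],
            "oxygen_class": [by_id[c.seq_id].oxygen_class for c in classes],
        }
    )
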