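"""Sequence records and genotype collapsing.

A *genotype* is a class of identical (aligned) sequences; its abundance is
the number of reads collapsed into it.  Abundance can be annotated directly
in FASTA headers with an ``id@count`` suffix — the convention used by
several BCR-repertoire pipelines — or supplied in a sidecar TSV that
overrides the header annotation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from Bio import SeqIO

from .errors import ParseError, ValidationError

#: Alphabet accepted for nucleotide sequences.  ``N`` is kept as a fifth
#: symbol; ``-`` only appears after alignment.
ALPHABET = frozenset("ACGTN-")

_ABUNDANCE_RE = re.compile(r"^(?P<id>.+)@(?P<count>\d+)$")


@dataclass(frozen=True)
class SequenceRecord:
    """One input sequence with a positive integer abundance.

    Parameters
    ----------
    id:
        Unique identifier within one input set.
    seq:
        Nucleotide string over ``{A, C, G, T, N}`` (plus ``-`` once
        aligned).  Case-folded to upper on construction.
    abundance:
        Number of reads this record represents (default 1).
    """

    id: str
    seq: str
    abundance: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())
        if not self.id:
            raise ValidationError("sequence record has an empty id")
        if not self.seq:
            raise ValidationError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq) - ALPHABET
        if bad:
            raise ValidationError(
                f"record {self.id!r}: invalid symbols {sorted(bad)}; "
                f"allowed alphabet is {{A,C,G,T,N,-}}"
            )
        if self.abundance < 1:
            raise ValidationError(
                f"record {self.id!r}: abundance must be >= 1, got {self.abundance}"
            )

    def degapped(self) -> str:
        return self.seq.replace("-", "")


def _parse_header(header: str) -> tuple[str, int]:
    """Split an ``id@count`` header into (id, count); count defaults to 1."""
    m = _ABUNDANCE_RE.match(header)
    if m:
        return m.group("id"), int(m.group("count"))
    return header, 1


def read_abundance_table(path: str | Path) -> dict[str, int]:
    """Read a headerless two-column (id TAB count) abundance TSV."""
    table: dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise ParseError(f"{path}:{lineno}: expected two tab-separated columns")
        sid, count = parts
        try:
            n = int(count)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: count {count!r} is not an integer") from exc
        if n < 1:
            raise ValidationError(f"{path}:{lineno}: non-positive count for {sid!r}")
        table[sid] = n
    return table


def read_fasta_with_abundance(
    path: str | Path,
    abundance_table: Optional[str | Path] = None,
) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects, in file order.

    Headers may carry an ``@<int>`` abundance suffix; unannotated records
    default to abundance 1.  A sidecar TSV (id TAB count) overrides the
    header annotation — the TSV keys match the id *after* stripping any
    header suffix.
    """
    overrides = read_abundance_table(abundance_table) if abundance_table else {}
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except (ValueError, AssertionError) as exc:  # biopython parse failures
        raise ParseError(f"{path}: malformed FASTA: {exc}") from exc
    for rec in parsed:
        if not rec.id:
            raise ParseError(f"{path}: record with empty header")
        sid, count = _parse_header(rec.id)
        if sid in overrides:
            count = overrides[sid]
        if sid in seen:
            raise ValidationError(f"{path}: duplicate record id {sid!r}")
        seen.add(sid)
        if count < 1:
            raise ValidationError(f"{path}: record {sid!r}: non-positive abundance")
        records.append(SequenceRecord(id=sid, seq=str(rec.seq), abundance=count))
    if not records:
        raise ParseError(f"{path}: no records")
    unknown = set(overrides) - seen
    if unknown:
        raise ValidationError(
            f"abundance table lists ids absent from the FASTA: {sorted(unknown)}"
        )
    return records


@dataclass(frozen=True)
class Genotype:
    label: str
    seq: str
    abundance: int


@dataclass
class GenotypeTable:
    """Deduplicated aligned genotypes with abundances and a designated root.

    Invariants (checked by :meth:`validate`): labels unique, exactly one
    equals ``root_label``; all sequences share ``alignment_length``; no two
    genotypes carry the same sequence; abundance is conserved from the
    collapsed input.
    """

    genotypes: list[Genotype]
    root_label: str
    alignment_length: int = field(default=0)

    def __post_init__(self) -> None:
        if self.genotypes and not self.alignment_length:
            self.alignment_length = len(self.genotypes[0].seq)
        self.validate()

    # -- mapping-style accessors -------------------------------------------
    @property
    def labels(self) -> list[str]:
        return [g.label for g in self.genotypes]

    def sequences(self) -> dict[str, str]:
        return {g.label: g.seq for g in self.genotypes}

    def abundances(self) -> dict[str, int]:
        return {g.label: g.abundance for g in self.genotypes}

    def __len__(self) -> int:
        return len(self.genotypes)

    def __getitem__(self, label: str) -> Genotype:
        for g in self.genotypes:
            if g.label == label:
                return g
        raise KeyError(label)

    def total_abundance(self) -> int:
        return sum(g.abundance for g in self.genotypes)

    def validate(self) -> None:
        labels = self.labels
        if len(set(labels)) != len(labels):
            raise ValidationError("genotype labels are not unique")
        if labels.count(self.root_label) != 1:
            raise ValidationError(f"root label {self.root_label!r} not in table")
        seqs = [g.seq for g in self.genotypes]
        if len(set(seqs)) != len(seqs):
            raise ValidationError("two genotypes share an identical sequence")
        for g in self.genotypes:
            if len(g.seq) != self.alignment_length:
                raise ValidationError(
                    f"genotype {g.label!r}: length {len(g.seq)} != "
                    f"alignment length {self.alignment_length}"
                )


def collapse_genotypes(
    records: Sequence[SequenceRecord],
    root_id: str,
    aligned: bool = True,
) -> GenotypeTable:
    """Merge identical aligned sequences into genotypes.

    The genotype label is the id of its first member in input order and its
    abundance is the sum of member abundances, so the total abundance of
    the table equals the total over the input records.

    Parameters
    ----------
    records:
        Aligned (equal-length) sequence records.
    root_id:
        Id of the record holding the inferred unmutated ancestor; the
        genotype that record collapses into becomes the root genotype.
    aligned:
        Assert that all records have equal length (raise otherwise).
    """
    if not records:
        raise ValidationError("no records to collapse")
    ids = [r.id for r in records]
    if root_id not in ids:
        raise ValidationError(f"root id {root_id!r} not found among records")
    lengths = {len(r.seq) for r in records}
    if aligned and len(lengths) != 1:
        raise ValidationError(
            f"records have unequal lengths {sorted(lengths)}; align them first"
        )

    by_seq: dict[str, list[SequenceRecord]] = {}
    order: list[str] = []
    for rec in records:
        if rec.seq not in by_seq:
            by_seq[rec.seq] = []
            order.append(rec.seq)
        by_seq[rec.seq].append(rec)

    genotypes = [
        Genotype(
            label=members[0].id,
            seq=seq,
            abundance=sum(m.abundance for m in members),
        )
        for seq, members in ((s, by_seq[s]) for s in order)
    ]
    root_seq = next(r.seq for r in records if r.id == root_id)
    root_label = by_seq[root_seq][0].id
    return GenotypeTable(genotypes=genotypes, root_label=root_label)
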