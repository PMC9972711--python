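"""Multiple sequence alignment front-end.

Clonally related BCR sequences are near-identical, so a deterministic
center-star progressive alignment (pairwise Needleman–Wunsch against the
first record, gaps merged with the usual "once a gap, always a gap" rule)
is adequate; an external aligner such as MAFFT can be used instead for
data with complex indel structure.  ``mode="none"`` asserts the input is
already aligned.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import LineageError, ValidationError
from .records import SequenceRecord

# NW scoring for near-identical nucleotide sequences: favour substitutions
# over gaps so indel-free inputs align gap-free.
MATCH, MISMATCH, GAP = 0, -1, -2


def nw_pair(a: str, b: str) -> tuple[str, str]:
    """Global Needleman–Wunsch alignment of two ungapped sequences.

    Deterministic tie-break: diagonal, then gap in ``b``, then gap in ``a``.
    """
    n, m = len(a), len(b)
    score = np.zeros((n + 1, m + 1), dtype=np.int64)
    score[:, 0] = GAP * np.arange(n + 1)
    score[0, :] = GAP * np.arange(m + 1)
    aa = np.frombuffer(a.encode(), dtype=np.uint8)
    bb = np.frombuffer(b.encode(), dtype=np.uint8)
    for i in range(1, n + 1):
        sub = np.where(aa[i - 1] == bb, MATCH, MISMATCH)
        row = score[i]
        prev = score[i - 1]
        # vectorised over j is awkward because of the left-dependency; the
        # row loop is fine at clonal-family sizes.
        for j in range(1, m + 1):
            row[j] = max(prev[j - 1] + sub[j - 1], prev[j] + GAP, row[j - 1] + GAP)
    # traceback
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and score[i, j] == score[i - 1, j - 1] + (
            MATCH if a[i - 1] == b[j - 1] else MISMATCH
        ):
            out_a.append(a[i - 1]); out_b.append(b[j - 1]); i -= 1; j -= 1
        elif i > 0 and score[i, j] == score[i - 1, j] + GAP:
            out_a.append(a[i - 1]); out_b.append("-"); i -= 1
        else:
            out_a.append("-"); out_b.append(b[j - 1]); j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b))


def _merge_center_star(center: str, pairs: list[tuple[str, str]]) -> list[str]:
    """Merge pairwise (center, other) alignments into one MSA.

    Returns the aligned center followed by the aligned others, all of equal
    length.  Gap columns demanded by any pairwise alignment are inserted
    into all rows.
    """
    k = len(center)
    # gaps[i] = gaps inserted before center residue i; gaps[k] = trailing
    gaps = [0] * (k + 1)
    per_aln_gaps: list[list[int]] = []
    for ac, _ in pairs:
        g = [0] * (k + 1)
        pos = 0
        for ch in ac:
            if ch == "-":
                g[pos] += 1
            else:
                pos += 1
        per_aln_gaps.append(g)
        for i in range(k + 1):
            gaps[i] = max(gaps[i], g[i])

    def expand(row: str, own_gaps: list[int]) -> str:
        out: list[str] = []
        pos = 0      # center residue index
        idx = 0      # position in row
        for i in range(k + 1):
            have = own_gaps[i]
            out.append(row[idx:idx + have])
            out.append("-" * (gaps[i] - have))
            idx += have
            if i < k:
                out.append(row[idx])
                idx += 1
        return "".join(out)

    center_row = expand(center, [0] * (k + 1))
    rows = [center_row]
    for (ac, ao), g in zip(pairs, per_aln_gaps):
        rows.append(expand(ao, g))
    return rows


def align_sequences(
    records: Sequence[SequenceRecord],
    mode: str = "none",
    binary: str = "mafft",
) -> list[SequenceRecord]:
    """Return records with equal-length (gapped) sequences.

    Removing the gaps from any output sequence restores the input.
    ``mode`` is one of ``none`` (already aligned), ``builtin``
    (center-star NW), or ``external`` (run ``binary`` as a MAFFT-style
    aligner: FASTA in, aligned FASTA on stdout).
    """
    if not records:
        raise ValidationError("no records to align")
    if mode == "none":
        lengths = {len(r.seq) for r in records}
        if len(lengths) != 1:
            raise ValidationError(
                f"mode='none' requires equal lengths; saw {sorted(lengths)}"
            )
        return list(records)
    if mode == "builtin":
        ungapped = [r.degapped() for r in records]
        center = ungapped[0]
        pairs = [nw_pair(center, s) for s in ungapped[1:]]
        rows = _merge_center_star(center, pairs)
        return [
            SequenceRecord(id=r.id, seq=row, abundance=r.abundance)
            for r, row in zip(records, rows)
        ]
    if mode == "external":
        if shutil.which(binary) is None:
            raise LineageError(
                f"external aligner {binary!r} not found on PATH; install it "
                f"or use mode='builtin'"
            )
        with tempfile.TemporaryDirectory() as tmp:
            fasta = Path(tmp) / "in.fasta"
            fasta.write_text(
                "".join(f">{r.id}\n{r.degapped()}\n" for r in records)
            )
            proc = subprocess.run(
                [binary, "--quiet", "--auto", str(fasta)],
                capture_output=True, text=True,
            )
            if proc.returncode != 0:
                raise LineageError(
                    f"{binary} failed (exit {proc.returncode}): {proc.stderr.strip()}"
                )
        aligned: dict[str, str] = {}
        current = None
        for line in proc.stdout.splitlines():
            if line.startswith(">"):
                current = line[1:].split()[0]
                aligned[current] = ""
            elif current is not None:
                aligned[current] += line.strip()
        out = []
        for r in records:
            sid = r.id.split()[0]
            if sid not in aligned:
                raise LineageError(f"{binary} output lacks record {r.id!r}")
            out.append(SequenceRecord(id=r.id, seq=aligned[sid].upper(),
                                      abundance=r.abundance))
        return out
    raise ValidationError(f"unknown alignment mode {mode!r}")
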