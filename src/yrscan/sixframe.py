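"""Six-frame conceptual translation with invertible coordinate maps.

Every peptide position maps back to an exact 3-nt genomic interval, so
protein-level domain hits can be reported as genomic features. Stop codons
are retained as ``*`` (domains are routinely found in decayed copies whose
reading frames are interrupted) and codons containing N translate to ``X``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .seqio import GenomeRecord, Interval, revcomp

log = logging.getLogger("yrscan")

FRAMES = (1, 2, 3, -1, -2, -3)

_BASE_CODE = np.full(256, 4, dtype=np.int8)  # N and anything else -> 4
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i

# Standard genetic code (translation table 1) from Biopython, indexed in
# base-5 codon space so that any codon containing an N yields 'X'.
from Bio.Data.CodonTable import unambiguous_dna_by_id as _tables

_CODE5 = np.full(125, ord("X"), dtype=np.uint8)
_t1 = _tables[1]
for _b1 in "ACGT":
    for _b2 in "ACGT":
        for _b3 in "ACGT":
            _codon = _b1 + _b2 + _b3
            _aa = "*" if _codon in _t1.stop_codons else _t1.forward_table[_codon]
            _idx = 25 * "ACGT".index(_b1) + 5 * "ACGT".index(_b2) + "ACGT".index(_b3)
            _CODE5[_idx] = ord(_aa)


def translate(nt: str) -> str:
    """Translate a nucleotide string (table 1); trailing partial codon dropped."""
    codes = _BASE_CODE[np.frombuffer(nt.encode(), dtype=np.uint8)]
    n = len(codes) // 3
    if n == 0:
        return ""
    c = codes[: 3 * n].reshape(n, 3).astype(np.int32)
    idx = 25 * c[:, 0] + 5 * c[:, 1] + c[:, 2]
    return _CODE5[idx].tobytes().decode()


@dataclass(frozen=True)
class FrameTranslation:
    """One of the six conceptual translations of a genome record."""

    seq_id: str
    frame: int  # +1,+2,+3,-1,-2,-3
    peptide: str
    offset: int  # 0-based nt start of the first full codon, on the reading strand
    source_length: int

    @property
    def strand(self) -> str:
        return "+" if self.frame > 0 else "-"


def translate_six_frames(record: GenomeRecord) -> list[FrameTranslation]:
    """All six conceptual translations of ``record``.

    Frames -1..-3 translate the reverse complement; a record shorter than
    3 nt yields empty translations with a warning.
    """
    L = record.length
    if L < 3:
        log.warning("record %s shorter than 3 nt; empty translations", record.id)
    out = []
    rc = revcomp(record.residues)
    for frame in FRAMES:
        offset = abs(frame) - 1
        src = record.residues if frame > 0 else rc
        pep = translate(src[offset:])
        out.append(
            FrameTranslation(seq_id=record.id, frame=frame, peptide=pep,
                             offset=offset, source_length=L)
        )
    return out


def map_to_genome(t: FrameTranslation, pep_start: int, pep_end: int) -> Interval:
    """Genomic interval (forward coordinates) of peptide window [pep_start, pep_end)."""
    if not (0 <= pep_start < pep_end <= len(t.peptide)):
        raise ValueError(
            f"peptide window [{pep_start}, {pep_end}) out of range for frame {t.frame}"
        )
    lo = t.offset + 3 * pep_start
    hi = t.offset + 3 * pep_end
    if t.frame > 0:
        return Interval(t.seq_id, lo, hi, "+")
    L = t.source_length
    return Interval(t.seq_id, L - hi, L - lo, "-")


def map_from_genome(t: FrameTranslation, interval: Interval) -> tuple[int, int]:
    """Inverse of :func:`map_to_genome` (interval must be codon-aligned in frame)."""
    L = t.source_length
    if t.frame > 0:
        lo, hi = interval.start, interval.end
    else:
        lo, hi = L - interval.end, L - interval.start
    if (lo - t.offset) % 3 or (hi - lo) % 3:
        raise ValueError("interval is not codon-aligned in this frame")
    return (lo - t.offset) // 3, (hi - t.offset) // 3
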