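"""Readers/writers for the external formats the annotator touches.

All genomic coordinates are handled internally as 0-based half-open
intervals on the forward strand; every file written for interchange
(GFF3, TSV reports) uses 1-based inclusive coordinates, the GFF3 norm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO as _BioSeqIO

log = logging.getLogger("yrscan")

# IUPAC nucleotide one-letter codes; everything outside ACGTN collapses to N.
_IUPAC_NT = set("ACGTNRYSWKMBDHV")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SeqIOError(ValueError):
    """Raised for malformed sequence input."""


@dataclass(frozen=True)
class GenomeRecord:
    """A named nucleotide sequence over the {A,C,G,T,N} alphabet.

    ``soft_masked_fraction`` records how much of the input was lowercase
    before normalization (draft assemblies mark repeats by soft-masking).
    """

    id: str
    residues: str
    soft_masked_fraction: float = 0.0

    @property
    def length(self) -> int:
        return len(self.residues)

    def __post_init__(self) -> None:
        bad = set(self.residues) - set("ACGTN")
        if bad:
            raise SeqIOError(
                f"record {self.id!r}: illegal residues {sorted(bad)!r} after normalization"
            )


@dataclass(frozen=True)
class Interval:
    """0-based half-open genomic interval with strand."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return self.seq_id == other.seq_id and self.start < other.end and other.start < self.end

    def overlap_length(self, other: "Interval") -> int:
        if self.seq_id != other.seq_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_residues(raw: str, record_id: str = "?") -> tuple[str, float]:
    """Uppercase, collapse ambiguity codes to N; return (residues, soft-masked fraction)."""
    n_lower = sum(1 for c in raw if c.islower())
    up = raw.upper()
    bad = set(up) - _IUPAC_NT
    if bad:
        raise SeqIOError(f"record {record_id!r}: non-IUPAC characters {sorted(bad)!r}")
    n_ambig = sum(1 for c in up if c not in "ACGTN")
    if n_ambig:
        log.info("record %s: %d ambiguity codes converted to N", record_id, n_ambig)
        up = "".join(c if c in "ACGTN" else "N" for c in up)
    frac = n_lower / len(raw) if raw else 0.0
    return up, frac


def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read a (multi-record) nucleotide FASTA into GenomeRecords.

    Headers are split at the first whitespace for the id; duplicate ids are
    rejected; lowercase (soft-masked) input is uppercased and the masked
    fraction recorded on the returned records.
    """
    path = Path(path)
    text = path.read_text()
    if text.strip() and not text.lstrip().startswith(">"):
        raise SeqIOError(f"{path}: not FASTA (no '>' header)")
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        rid = rec.id
        if rid in seen:
            raise SeqIOError(f"{path}: duplicate record id {rid!r}")
        seen.add(rid)
        raw = str(rec.seq)
        if not raw:
            raise SeqIOError(f"{path}: record {rid!r} has an empty sequence")
        residues, frac = normalize_residues(raw, rid)
        records.append(GenomeRecord(id=rid, residues=residues, soft_masked_fraction=frac))
    if not records:
        raise SeqIOError(f"{path}: no FASTA records")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    """Write (id, sequence) pairs as wrapped FASTA."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3

def _gff_escape(value: str) -> str:
    return (
        str(value)
        .replace("%", "%25")
        .replace(";", "%3B")
        .replace("=", "%3D")
        .replace(",", "%2C")
        .replace("\t", "%09")
    )


def _gff_line(seq_id, source, ftype, start0, end0, score, strand, attrs: dict) -> str:
    """One GFF3 feature line; converts [start0, end0) to 1-based inclusive."""
    attr_s = ";".join(f"{k}={_gff_escape(v)}" for k, v in attrs.items())
    score_s = "." if score is None else f"{score:.1f}"
    return f"{seq_id}\t{source}\t{ftype}\t{start0 + 1}\t{end0}\t{score_s}\t{strand}\t.\t{attr_s}"


def write_gff3(elements: Sequence, path: str | Path, source: str = "yrscan") -> None:
    """Write annotated elements as GFF3.

    Each element becomes a ``mobile_genetic_element`` feature with
    ``polypeptide_domain`` children for domain hits and ``repeat_region``
    children for each terminal-repeat copy (plus the ICR when present).
    """
    lines = ["##gff-version 3"]
    for i, el in enumerate(elements, start=1):
        eid = f"YR{i:05d}"
        iv = el.outer_interval
        attrs = {
            "ID": eid,
            "superfamily": el.superfamily,
            "completeness": el.completeness,
            "clade": el.clade,
        }
        if getattr(el, "family", None) is not None:
            attrs["family"] = el.family
        if el.repeats is not None and el.repeats.kind != "none":
            attrs["repeat_structure"] = el.repeats.kind
        lines.append(
            _gff_line(iv.seq_id, source, "mobile_genetic_element", iv.start, iv.end, None, iv.strand, attrs)
        )
        for j, hit in enumerate(sorted(el.core.hits, key=lambda h: h.interval.start), start=1):
            h_attrs = {
                "ID": f"{eid}.d{j}",
                "Parent": eid,
                "domain_class": hit.domain_class,
                "profile": hit.profile_name,
                "coverage": f"{hit.profile_coverage:.3f}",
                "empirical_p": f"{hit.empirical_p:.3g}",
            }
            lines.append(
                _gff_line(
                    iv.seq_id, source, "polypeptide_domain",
                    hit.interval.start, hit.interval.end, hit.score, hit.interval.strand, h_attrs,
                )
            )
        if el.repeats is not None and el.repeats.kind != "none":
            names = ("left", "right") if el.repeats.kind == "ITR" else ("A1", "B1", "A2", "B2")
            for name, copy in zip(names, el.repeats.copies):
                r_attrs = {"ID": f"{eid}.{name}", "Parent": eid, "repeat_name": name}
                lines.append(
                    _gff_line(iv.seq_id, source, "repeat_region",
                              copy.interval.start, copy.interval.end, None, iv.strand, r_attrs)
                )
            if el.repeats.icr is not None:
                r_attrs = {"ID": f"{eid}.ICR", "Parent": eid, "repeat_name": "ICR"}
                lines.append(
                    _gff_line(iv.seq_id, source, "repeat_region",
                              el.repeats.icr.interval.start, el.repeats.icr.interval.end, None,
                              iv.strand, r_attrs)
                )
    Path(path).write_text("\n".join(lines) + "\n")


def write_element_table(elements: Sequence, path: str | Path) -> None:
    """TSV report, one row per element (1-based inclusive coordinates)."""
    import pandas as pd

    rows = []
    for el in elements:
        iv = el.outer_interval
        domains = ",".join(
            f"{h.domain_class}:{h.interval.start + 1}-{h.interval.end}"
            for h in sorted(el.core.hits, key=lambda h: h.interval.start)
        )
        rep = el.repeats.kind if el.repeats is not None else "none"
        rows.append(
            dict(
                seq_id=iv.seq_id, start=iv.start + 1, end=iv.end, strand=iv.strand,
                superfamily=el.superfamily, completeness=el.completeness, clade=el.clade,
                family=getattr(el, "family", None), domains=domains, repeat_structure=rep,
            )
        )
    pd.DataFrame(
        rows,
        columns=["seq_id", "start", "end", "strand", "superfamily", "completeness",
                 "clade", "family", "domains", "repeat_structure"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# HMMER3 ASCII profiles

#: profile name -> diagnostic domain class, mirroring the Pfam/CDD families
#: conventionally used for YR retrotransposons.
PROFILE_NAME_CLASS_MAP = {
    "RVT_1": "RT", "RVT_2": "RT", "RT_LTR": "RT", "RT_DIRS1": "RT",
    "RNase_H": "RH", "Rnase_H": "RH",
    "RNase_HI_RT_DIRS1": "RH", "RNase_HI_RT_Ty1": "RH", "RNase_HI_RT_Ty3": "RH",
    "Phage_integrase": "YR", "INT_Cre": "YR",
    "Dam": "MT",
}


def read_hmmer3_profile(path: str | Path, domain_class: str | None = None,
                        gap_open: float = -11.0, gap_extend: float = -1.0):
    """Load a HMMER3 ASCII profile as a position score matrix.

    Match-state emission probabilities are converted to log-odds against a
    uniform amino-acid background. Insert/transition structure is reduced to
    the two per-profile affine gap constants; this is a scanning profile, not
    a full plan7 model.
    """
    import pyhmmer

    from .domain_scan import DomainProfile

    path = Path(path)
    head = path.read_text(errors="replace").lstrip().splitlines()[0] if path.exists() else ""
    if not head.startswith("HMMER3"):
        raise SeqIOError(f"{path}: unsupported leader line {head!r} (expected HMMER3 ASCII)")
    with pyhmmer.plan7.HMMFile(str(path)) as hf:
        hmm = hf.read()
    if hmm.alphabet.type != "amino":
        raise SeqIOError(f"{path}: profile alphabet is {hmm.alphabet.type}, expected amino")
    import numpy as np

    emis = np.asarray(hmm.match_emissions, dtype=float)[1:, :20]  # row 0 is the begin state
    emis = np.clip(emis, 1e-9, None)
    columns = np.round(np.log(emis / (1.0 / 20.0)), 4)
    name = hmm.name.decode() if isinstance(hmm.name, bytes) else str(hmm.name)
    dclass = domain_class or PROFILE_NAME_CLASS_MAP.get(name)
    if dclass is None:
        raise SeqIOError(f"{path}: unknown domain class for profile {name!r}; pass domain_class=")
    return DomainProfile(
        name=name, domain_class=dclass, affinity="generic",
        columns=columns, gap_open=gap_open, gap_extend=gap_extend,
        score_threshold=0.25 * float(columns.max(axis=1).sum()),
    )


# ---------------------------------------------------------------------------
# Alignments and trees

@dataclass
class Alignment:
    """Equal-length gapped amino-acid rows with optional column partitions."""

    ids: list[str]
    rows: list[str]
    partitions: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids/rows length mismatch")
        if self.rows:
            n = len(self.rows[0])
            if any(len(r) != n for r in self.rows):
                raise SeqIOError("ragged alignment rows")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0


def read_aligned_fasta(path: str | Path) -> Alignment:
    ids, rows = [], []
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper())
    if not ids:
        raise SeqIOError(f"{path}: no records")
    return Alignment(ids=ids, rows=rows)


def write_aligned_fasta(a: Alignment, path: str | Path) -> None:
    write_fasta(zip(a.ids, a.rows), path)


def write_newick(tree, path: str | Path) -> None:
    """Serialize a tree (dendropy Tree) as Newick with 6-decimal branch lengths."""
    from .phylo import tree_to_newick

    Path(path).write_text(tree_to_newick(tree, decimals=6) + "\n")


def read_newick(path: str | Path):
    import dendropy

    return dendropy.Tree.get(path=str(path), schema="newick")
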