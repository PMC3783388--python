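"""Synthetic genomes with planted DIRS/Ngaro elements and truth records.

The generator emulates the two diagnostic architectures:

* DIRS:  ITR - gag stuffer - RT - RH - MT - YR - (ICR) - revcomp(ITR)
* Ngaro: A1 - gag stuffer - RT - RH - [+1 frameshift] - YR - B1 - A2 - B2

Domain peptides come from the packaged per-clade seed consensi and are
reverse-translated with seeded codon choice, so the scanning profiles have
a known relationship to the planted proteins. Decay is applied as
substitutions (uniform per-base rate), then truncation from a chosen end,
then whole-domain deletions, with truth coordinates updated at each step.
Every stage of the annotator is therefore testable offline against exact
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .profiles import DIRS_LINEAGES, NGARO_CLADES, element_domain_seeds
from .seqio import GenomeRecord, Interval, revcomp
from .sixframe import translate

_NT = np.array(list("ACGT"))

# codon choices per amino acid (standard code), built from the translation
# table used by the six-frame module
_CODONS_BY_AA: dict[str, list[str]] = {}
for _b1 in "ACGT":
    for _b2 in "ACGT":
        for _b3 in "ACGT":
            _c = _b1 + _b2 + _b3
            _CODONS_BY_AA.setdefault(translate(_c), []).append(_c)


class SpecError(ValueError):
    """Raised for contradictory element specifications."""


@dataclass(frozen=True)
class ElementSpec:
    """Parameters for one planted element.

    ``mu`` is the per-base substitution rate, ``truncation`` the fraction
    of the element removed from one end (``truncate_end`` forces which),
    ``lost_domains`` are deleted wholesale. DIRS specs must include MT and
    an ITR; Ngaro specs must include A/B repeats and exclude MT.
    """

    superfamily: str
    clade: str
    seed: int = 0
    frameshift_yr: bool = False
    itr_len: int = 150
    repeat_a_len: int = 60
    repeat_b_len: int = 60
    icr_len: int = 60
    stuffer_len: int = 300
    spacer_len: int = 30
    mu: float = 0.0
    truncation: float = 0.0
    truncate_end: Optional[str] = None  # "5p" | "3p" | None (random)
    lost_domains: tuple[str, ...] = ()
    strand: str = "+"
    domain_classes: Optional[tuple[str, ...]] = None

    def expected_domains(self) -> tuple[str, ...]:
        if self.domain_classes is not None:
            return self.domain_classes
        return ("RT", "RH", "MT", "YR") if self.superfamily == "DIRS" else ("RT", "RH", "YR")

    def validate(self) -> None:
        if self.superfamily not in ("DIRS", "Ngaro"):
            raise SpecError(f"unknown superfamily {self.superfamily!r}")
        if self.superfamily == "DIRS" and self.clade not in DIRS_LINEAGES:
            raise SpecError(f"DIRS clade must be in {DIRS_LINEAGES}")
        if self.superfamily == "Ngaro" and self.clade not in NGARO_CLADES:
            raise SpecError(f"Ngaro clade must be in {NGARO_CLADES}")
        doms = self.expected_domains()
        if self.superfamily == "Ngaro" and "MT" in doms:
            raise SpecError("Ngaro elements never carry an MT domain")
        if self.superfamily == "DIRS" and "MT" not in doms:
            raise SpecError("DIRS elements require the MT domain")
        if not (0.0 <= self.mu < 1.0):
            raise SpecError("mu must be in [0, 1)")
        if not (0.0 <= self.truncation < 1.0):
            raise SpecError("truncation must be in [0, 1)")
        if self.truncate_end not in (None, "5p", "3p"):
            raise SpecError("truncate_end must be '5p', '3p' or None")
        if self.frameshift_yr and self.superfamily != "Ngaro":
            raise SpecError("the frameshifted-YR option models Ngaro elements")


@dataclass
class TruthRecord:
    """Ground truth for one planted element (absolute genome coordinates)."""

    interval: Interval
    superfamily: str
    clade: str
    completeness: str
    strand: str
    has_frameshift: bool
    domains: dict[str, Interval] = field(default_factory=dict)
    domain_peptides: dict[str, str] = field(default_factory=dict)  # fully surviving only
    repeats: dict[str, Interval] = field(default_factory=dict)
    retained_domains: set[str] = field(default_factory=set)


@dataclass
class _Part:
    label: str  # e.g. "domain:RT", "repeat:ITR_L", "stuffer", "spacer", "frameshift"
    seq: str
    original_len: int


def _rand_nt(rng: np.random.Generator, n: int, gc: float = 0.45) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_NT[rng.choice(4, size=n, p=p)])


def _reverse_translate(pep: str, rng: np.random.Generator) -> str:
    return "".join(
        _CODONS_BY_AA[aa][rng.integers(0, len(_CODONS_BY_AA[aa]))] for aa in pep
    )


def _mutate(seq: str, mu: float, rng: np.random.Generator) -> str:
    if mu <= 0.0 or not seq:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < mu
    for i in np.flatnonzero(hit):
        options = [b for b in "ACGT" if b != arr[i]]
        arr[i] = options[rng.integers(0, 3)]
    return "".join(arr)


def synthesize_element(spec: ElementSpec) -> tuple[str, TruthRecord]:
    """Build one element sequence plus its truth record (element coordinates).

    Deterministic for a given spec (including its seed). The returned truth
    uses coordinates relative to the element start on the emitted strand's
    forward representation.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    seeds = element_domain_seeds(spec.superfamily, spec.clade)
    parts: list[_Part] = []

    def add(label: str, seq: str) -> None:
        parts.append(_Part(label=label, seq=seq, original_len=len(seq)))

    if spec.superfamily == "DIRS":
        itr = _rand_nt(rng, spec.itr_len)
        add("repeat:ITR_L", itr)
        add("stuffer", _rand_nt(rng, spec.stuffer_len))
        for d in ("RT", "RH", "MT", "YR"):
            add(f"domain:{d}", _reverse_translate(seeds[d], rng))
        add("spacer", _rand_nt(rng, spec.spacer_len))
        if spec.icr_len:
            add("repeat:ICR", revcomp(itr[: spec.icr_len]))
            add("spacer2", _rand_nt(rng, spec.spacer_len))
        add("repeat:ITR_R", revcomp(itr))
    else:
        rep_a = _rand_nt(rng, spec.repeat_a_len)
        rep_b = _rand_nt(rng, spec.repeat_b_len)
        add("repeat:A1", rep_a)
        add("stuffer", _rand_nt(rng, spec.stuffer_len))
        add("domain:RT", _reverse_translate(seeds["RT"], rng))
        add("domain:RH", _reverse_translate(seeds["RH"], rng))
        if spec.frameshift_yr:
            add("frameshift", _rand_nt(rng, 1))
        add("domain:YR", _reverse_translate(seeds["YR"], rng))
        add("spacer", _rand_nt(rng, spec.spacer_len))
        add("repeat:B1", rep_b)
        add("spacer2", _rand_nt(rng, spec.spacer_len))
        add("repeat:A2", rep_a)
        add("spacer3", _rand_nt(rng, spec.spacer_len))
        add("repeat:B2", rep_b)

    # decay step 1: substitutions
    for part in parts:
        part.seq = _mutate(part.seq, spec.mu, rng)

    # decay step 2: truncation from one end
    total = sum(len(p.seq) for p in parts)
    n_cut = int(round(spec.truncation * total))
    if n_cut:
        end = spec.truncate_end or ("5p" if rng.random() < 0.5 else "3p")
        remaining = n_cut
        seq_parts = parts if end == "3p" else list(reversed(parts))
        for part in reversed(seq_parts):
            if remaining <= 0:
                break
            cut = min(remaining, len(part.seq))
            part.seq = part.seq[:-cut] if end == "3p" else part.seq[cut:]
            remaining -= cut
        parts = [p for p in parts if p.seq]

    # decay step 3: whole-domain deletion
    lost = {f"domain:{d}" for d in spec.lost_domains}
    parts = [p for p in parts if p.label not in lost]

    seq = "".join(p.seq for p in parts)
    offsets: dict[str, tuple[int, int, int]] = {}
    pos = 0
    for p in parts:
        offsets[p.label] = (pos, pos + len(p.seq), p.original_len)
        pos += len(p.seq)

    domains: dict[str, Interval] = {}
    peptides: dict[str, str] = {}
    retained: set[str] = set()
    for d in spec.expected_domains():
        key = f"domain:{d}"
        if key not in offsets:
            continue
        s, e, orig = offsets[key]
        if e == s:
            continue
        domains[d] = Interval("element", s, e, "+")
        if e - s >= 0.6 * orig:
            retained.add(d)
        if e - s == orig:
            peptides[d] = translate(seq[s:e])
    repeats = {
        lab.split(":", 1)[1]: Interval("element", s, e, "+")
        for lab, (s, e, orig) in offsets.items()
        if lab.startswith("repeat:") and e > s
    }

    full_domains = {
        d for d in spec.expected_domains()
        if f"domain:{d}" in offsets
        and offsets[f"domain:{d}"][1] - offsets[f"domain:{d}"][0] == offsets[f"domain:{d}"][2]
    }
    expected_repeats = (
        {"ITR_L", "ITR_R"} if spec.superfamily == "DIRS" else {"A1", "B1", "A2", "B2"}
    )
    full_repeats = all(
        r in repeats and repeats[r].length == next(
            p.original_len for p in parts if p.label == f"repeat:{r}"
        )
        for r in expected_repeats
    ) if all(f"repeat:{r}" in offsets for r in expected_repeats) else False
    if full_domains == set(spec.expected_domains()) and full_repeats:
        completeness = "complete"
    elif len(domains) <= 1:
        completeness = "remnant"
    else:
        completeness = "truncated"

    truth = TruthRecord(
        interval=Interval("element", 0, len(seq), spec.strand),
        superfamily=spec.superfamily, clade=spec.clade, completeness=completeness,
        strand=spec.strand, has_frameshift=spec.frameshift_yr,
        domains=domains, domain_peptides=peptides, repeats=repeats,
        retained_domains=retained,
    )
    if spec.strand == "-":
        seq, truth = _flip(seq, truth)
    return seq, truth


def _flip(seq: str, truth: TruthRecord) -> tuple[str, TruthRecord]:
    L = len(seq)

    def f(iv: Interval) -> Interval:
        return Interval(iv.seq_id, L - iv.end, L - iv.start, "-")

    flipped = replace(
        truth,
        interval=f(truth.interval),
        domains={d: f(iv) for d, iv in truth.domains.items()},
        repeats={r: f(iv) for r, iv in truth.repeats.items()},
    )
    return revcomp(seq), flipped


def _shift(truth: TruthRecord, delta: int, seq_id: str) -> TruthRecord:
    def s(iv: Interval) -> Interval:
        return Interval(seq_id, iv.start + delta, iv.end + delta, iv.strand)

    return replace(
        truth,
        interval=s(truth.interval),
        domains={d: s(iv) for d, iv in truth.domains.items()},
        repeats={r: s(iv) for r, iv in truth.repeats.items()},
    )


class PlacementError(RuntimeError):
    pass


def synthesize_genome(specs: Sequence[ElementSpec], background_length: int,
                      gc: float = 0.45, nesting_probability: float = 0.0,
                      seed: int = 0, min_separation: int = 4000,
                      seq_id: str = "synth1") -> tuple[GenomeRecord, list[TruthRecord]]:
    """Place elements into i.i.d. background at the stated GC.

    Elements are placed without overlap with at least ``min_separation`` nt
    of background between insertions (so separate insertions stay separate
    under downstream hit chaining), or nested inside an earlier element
    with probability ``nesting_probability`` — nested copies insert into a
    host's interior avoiding its domain and repeat intervals, echoing
    elements found within clusters of mobile elements.
    """
    rng = np.random.default_rng(seed)
    blocks: list[tuple[str, list[TruthRecord]]] = []
    for i, spec in enumerate(specs):
        seq, truth = synthesize_element(spec)
        if blocks and rng.random() < nesting_probability:
            host_i = int(rng.integers(0, len(blocks)))
            host_seq, host_truths = blocks[host_i]
            q = _nesting_point(host_seq, host_truths, rng)
            if q is None:
                raise PlacementError("no nesting position available in host element")
            new_seq = host_seq[:q] + seq + host_seq[q:]
            delta = len(seq)
            updated: list[TruthRecord] = []
            for ht in host_truths:
                updated.append(_stretch(ht, q, delta))
            updated.append(_shift(truth, q, "element"))
            blocks[host_i] = (new_seq, updated)
        else:
            blocks.append((seq, [truth]))

    total_el = sum(len(b[0]) for b in blocks)
    k = len(blocks)
    if background_length < (k + 1) * min_separation and k > 0:
        raise PlacementError(
            f"background of {background_length} nt cannot hold {k} insertions "
            f"{min_separation} nt apart"
        )
    # constructive placement: the background slack beyond the mandatory
    # separations is split randomly over the k+1 gaps
    slack = background_length - (k + 1) * min_separation
    if slack < 0:
        raise PlacementError("could not place all elements; increase background length")
    extra = rng.multinomial(slack, np.full(k + 1, 1.0 / (k + 1))) if k else []
    positions = np.cumsum([min_separation + int(e) for e in extra[:k]]) if k else np.array([])

    background = _rand_nt(rng, background_length, gc)
    pieces = []
    truths: list[TruthRecord] = []
    prev = 0
    shift_acc = 0
    for (block_seq, block_truths), p in zip(blocks, positions if k else []):
        pieces.append(background[prev : int(p)])
        abs_start = int(p) + shift_acc
        for t in block_truths:
            truths.append(_shift(t, abs_start, seq_id))
        pieces.append(block_seq)
        shift_acc += len(block_seq)
        prev = int(p)
    pieces.append(background[prev:])
    genome = "".join(pieces)
    record = GenomeRecord(id=seq_id, residues=genome)
    truths.sort(key=lambda t: t.interval.start)
    return record, truths


def _stretch(truth: TruthRecord, q: int, delta: int) -> TruthRecord:
    """Update a host truth for an insertion of ``delta`` nt at point ``q``."""

    def s(iv: Interval) -> Interval:
        if iv.end <= q:
            return iv
        if iv.start >= q:
            return Interval(iv.seq_id, iv.start + delta, iv.end + delta, iv.strand)
        return Interval(iv.seq_id, iv.start, iv.end + delta, iv.strand)

    return replace(
        truth,
        interval=s(truth.interval),
        domains={d: s(iv) for d, iv in truth.domains.items()},
        repeats={r: s(iv) for r, iv in truth.repeats.items()},
    )


def _nesting_point(host_seq: str, host_truths: list[TruthRecord],
                   rng: np.random.Generator) -> int | None:
    """Interior insertion point avoiding all annotated feature intervals."""
    forbidden: list[tuple[int, int]] = []
    for t in host_truths:
        for iv in list(t.domains.values()) + list(t.repeats.values()):
            forbidden.append((iv.start, iv.end))
    outer = host_truths[0].interval
    candidates = [
        q for q in range(outer.start + 1, outer.end - 1)
        if not any(s < q < e for s, e in forbidden)
    ]
    if not candidates:
        return None
    return int(candidates[rng.integers(0, len(candidates))])


def truth_to_gff3(truths: Sequence[TruthRecord], path: str | Path, seq_id: str | None = None) -> None:
    """Write truth records as GFF3 (1-based inclusive)."""
    lines = ["##gff-version 3"]
    for i, t in enumerate(truths, start=1):
        eid = f"TRUTH{i:05d}"
        iv = t.interval
        lines.append(
            f"{iv.seq_id}\ttruth\tmobile_genetic_element\t{iv.start + 1}\t{iv.end}\t.\t"
            f"{t.strand}\t.\tID={eid};superfamily={t.superfamily};clade={t.clade};"
            f"completeness={t.completeness};frameshift={str(t.has_frameshift).lower()}"
        )
        for d, div in sorted(t.domains.items(), key=lambda kv: kv[1].start):
            lines.append(
                f"{div.seq_id}\ttruth\tpolypeptide_domain\t{div.start + 1}\t{div.end}\t.\t"
                f"{t.strand}\t.\tID={eid}.{d};Parent={eid};domain_class={d}"
            )
        for r, riv in sorted(t.repeats.items(), key=lambda kv: kv[1].start):
            lines.append(
                f"{riv.seq_id}\ttruth\trepeat_region\t{riv.start + 1}\t{riv.end}\t.\t"
                f"{t.strand}\t.\tID={eid}.{r};Parent={eid};repeat_name={r}"
            )
    Path(path).write_text("\n".join(lines) + "\n")
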