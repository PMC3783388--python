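"""Detection of the four diagnostic protein domains (RT, RH, YR, MT).

Six-frame peptides are scanned with position score matrices by exact local
dynamic programming; frame-split, strand-consistent hits are then chained
into element cores. Significance is assessed with empirical shuffle
p-values rather than closed-form E-value statistics, so the scanner is
self-contained: the null is the max score of the profile against
composition-preserving shuffles of the scanned peptide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import _align
from .seqio import Interval
from .sixframe import FrameTranslation, map_to_genome

DOMAIN_CLASSES = ("RT", "RH", "YR", "MT")
AFFINITIES = ("DIRS-specific", "Ngaro-like", "generic")


@dataclass(frozen=True)
class DomainProfile:
    """Scoring model for one diagnostic domain.

    ``columns`` holds one 20-long score vector per profile position (amino
    acids in :data:`yrscan._align.AA_ORDER`). Stops score -8 and X scores 0
    against every column; gaps use the two per-profile affine constants.
    """

    name: str
    domain_class: str
    affinity: str
    columns: np.ndarray
    gap_open: float = -11.0
    gap_extend: float = -1.0
    score_threshold: float = 1.0

    def __post_init__(self) -> None:
        cols = np.asarray(self.columns, dtype=np.float64)
        object.__setattr__(self, "columns", cols)
        if cols.ndim != 2 or cols.shape[1] != 20 or cols.shape[0] < 3:
            raise ValueError(f"profile {self.name!r}: need >= 3 columns of 20 scores")
        if not np.isfinite(cols).all():
            raise ValueError(f"profile {self.name!r}: non-finite scores")
        if self.domain_class not in DOMAIN_CLASSES:
            raise ValueError(f"profile {self.name!r}: unknown domain class {self.domain_class!r}")
        if self.affinity not in AFFINITIES:
            raise ValueError(f"profile {self.name!r}: unknown affinity {self.affinity!r}")
        if not (self.gap_open <= self.gap_extend < 0):
            raise ValueError("require gap_open <= gap_extend < 0")

    @property
    def length(self) -> int:
        return int(self.columns.shape[0])

    @property
    def consensus_self_score(self) -> float:
        return float(self.columns.max(axis=1).sum())


@dataclass(frozen=True)
class DomainHit:
    """A located, scored profile match on the genome."""

    interval: Interval
    frame: int
    domain_class: str
    profile_name: str
    score: float
    empirical_p: float = 1.0
    profile_coverage: float = 1.0
    peptide: str = ""
    affinity: str = "generic"

    def __post_init__(self) -> None:
        if not (0.0 < self.empirical_p <= 1.0):
            raise ValueError("empirical_p must be in (0, 1]")
        if not (0.0 < self.profile_coverage <= 1.0):
            raise ValueError("profile_coverage must be in (0, 1]")


@dataclass
class ElementCore:
    """Envelope of merged, strand-consistent domain hits."""

    interval: Interval
    strand: str
    hits: list[DomainHit]
    has_frameshift: bool

    @property
    def domain_classes(self) -> set[str]:
        return {h.domain_class for h in self.hits}

    def best_hit(self, domain_class: str) -> DomainHit | None:
        cand = [h for h in self.hits if h.domain_class == domain_class]
        return max(cand, key=lambda h: h.score) if cand else None


# ---------------------------------------------------------------------------
# scanning

def scan_profile(t: FrameTranslation, p: DomainProfile,
                 score_threshold: float | None = None) -> list[DomainHit]:
    """All non-overlapping local optima of ``p`` in one frame translation.

    Hits are extracted greedily from the best score with aligned-region
    masking; coordinates are genomic (forward strand) via the frame map.
    """
    if not t.peptide:
        return []
    thr = p.score_threshold if score_threshold is None else score_threshold
    codes = _align.encode_peptide(t.peptide)
    raw = _align.scan_local(p.columns, codes, p.gap_open, p.gap_extend, thr)
    hits = []
    for h in raw:
        hits.append(
            DomainHit(
                interval=map_to_genome(t, h.pep_start, h.pep_end),
                frame=t.frame,
                domain_class=p.domain_class,
                profile_name=p.name,
                score=h.score,
                profile_coverage=(h.prof_end - h.prof_start) / p.length,
                peptide=t.peptide[h.pep_start : h.pep_end],
                affinity=p.affinity,
            )
        )
    return hits


def null_max_scores(t: FrameTranslation, p: DomainProfile, n_shuffles: int,
                    seed: int, batched: bool = True) -> np.ndarray:
    """Max local score of ``p`` against ``n_shuffles`` shuffles of the peptide.

    With ``batched`` the shuffles are concatenated, separated by runs of
    forbidden-score positions longer than the profile (so no alignment can
    bridge two shuffles), and solved in one vectorized forward pass; the
    per-shuffle maxima are identical to scoring each shuffle separately.
    """
    rng = np.random.default_rng(seed)
    codes = _align.encode_peptide(t.peptide)
    if not batched:
        out = np.empty(n_shuffles, dtype=np.float64)
        for k in range(n_shuffles):
            out[k] = _align.max_local_score(p.columns, rng.permutation(codes),
                                            p.gap_open, p.gap_extend)
        return out
    # a gap long enough that bridging two shuffles always costs more than
    # any possible alignment gain
    sep = p.length + int(np.ceil(p.consensus_self_score / abs(p.gap_extend))) + 2
    n = codes.shape[0]
    block = n + sep
    cat = np.full(n_shuffles * block, _align.MASK_CODE, dtype=codes.dtype)
    starts = np.arange(n_shuffles) * block
    for k in range(n_shuffles):
        cat[starts[k] : starts[k] + n] = rng.permutation(codes)
    colmax = _align.forward_colmax(p.columns, cat, p.gap_open, p.gap_extend)
    seg_max = np.maximum.reduceat(colmax, starts)
    return np.maximum(seg_max, 0.0)


def empirical_pvalue(hit_score: float, t: FrameTranslation, p: DomainProfile,
                     n_shuffles: int = 199, seed: int = 0,
                     null_scores: np.ndarray | None = None) -> float:
    """p = (1 + #{shuffled max-scores >= hit_score}) / (n_shuffles + 1)."""
    if n_shuffles < 19:
        raise ValueError("n_shuffles must be >= 19")
    if null_scores is None:
        null_scores = null_max_scores(t, p, n_shuffles, seed)
    k = int(np.count_nonzero(null_scores >= hit_score))
    return (1 + k) / (n_shuffles + 1)


# ---------------------------------------------------------------------------
# merging

def _reciprocal_overlap(a: Interval, b: Interval) -> float:
    ov = a.overlap_length(b)
    if ov == 0:
        return 0.0
    return min(ov / a.length, ov / b.length)


def merge_hits(hits: Sequence[DomainHit], max_gap_nt: int = 3000) -> list[ElementCore]:
    """Chain same-strand hits within ``max_gap_nt`` into element cores.

    Single linkage on genomic gaps; within a core, same-class hits with
    > 50% reciprocal overlap are reduced to the best-scoring one (ties:
    longer alignment, then leftmost). ``has_frameshift`` is set when the
    retained hits of one core occupy more than one frame.
    """
    by_group: dict[tuple[str, str], list[DomainHit]] = {}
    for h in hits:
        by_group.setdefault((h.interval.seq_id, h.interval.strand), []).append(h)
    cores: list[ElementCore] = []
    for (seq_id, strand), group in sorted(by_group.items()):
        group.sort(key=lambda h: (h.interval.start, h.interval.end))
        chains: list[list[DomainHit]] = []
        chain_end = None
        for h in group:
            if chain_end is not None and h.interval.start - chain_end <= max_gap_nt:
                chains[-1].append(h)
                chain_end = max(chain_end, h.interval.end)
            else:
                chains.append([h])
                chain_end = h.interval.end
        for chain in chains:
            kept: list[DomainHit] = []
            order = sorted(
                chain,
                key=lambda h: (-h.score, -h.interval.length, h.interval.start),
            )
            for h in order:
                if any(
                    k.domain_class == h.domain_class
                    and _reciprocal_overlap(k.interval, h.interval) > 0.5
                    for k in kept
                ):
                    continue
                kept.append(h)
            kept.sort(key=lambda h: h.interval.start)
            env = Interval(
                seq_id, min(h.interval.start for h in kept),
                max(h.interval.end for h in kept), strand,
            )
            cores.append(
                ElementCore(
                    interval=env, strand=strand, hits=kept,
                    has_frameshift=len({h.frame for h in kept}) > 1,
                )
            )
    cores.sort(key=lambda c: (c.interval.seq_id, c.interval.start))
    return cores


@dataclass
class ParityReport:
    """RT/RH co-occurrence check: the two domains belong to one pol ORF."""

    n_rt_cores: int
    n_rh_cores: int
    flagged: list[int] = field(default_factory=list)  # indices of RH-only cores

    @property
    def ratio_rh_to_rt(self) -> float:
        if self.n_rt_cores == 0:
            return math.inf if self.n_rh_cores else math.nan
        return self.n_rh_cores / self.n_rt_cores


def qc_rt_rh_parity(cores: Sequence[ElementCore]) -> ParityReport:
    """Count RT- and RH-bearing cores; flag RH-without-RT cores.

    RH-only cores point at profile insensitivity for RT (the classic
    symptom that motivates rebuilding a lineage-specific RT profile); the
    check never deletes elements.
    """
    n_rt = sum(1 for c in cores if "RT" in c.domain_classes)
    n_rh = sum(1 for c in cores if "RH" in c.domain_classes)
    flagged = [
        i for i, c in enumerate(cores)
        if "RH" in c.domain_classes and "RT" not in c.domain_classes
    ]
    return ParityReport(n_rt_cores=n_rt, n_rh_cores=n_rh, flagged=flagged)


# ---------------------------------------------------------------------------
# building profiles from detected members

def build_profile_from_members(peptides: Sequence[str], domain_class: str,
                               name: str = "custom",
                               affinity: str = "generic",
                               background: float = 1.0 / 20.0,
                               max_gap_fraction: float = 0.5,
                               gap_open: float = -11.0,
                               gap_extend: float = -1.0) -> DomainProfile:
    """Build a position score matrix from member sequences.

    Members may be pre-aligned (equal-length, gapped rows) or unaligned, in
    which case the progressive aligner supplies the alignment. Per-column
    scores are ``ln((count_a + 1) / ((n + 1) * background))`` (+1
    pseudocount against a uniform background); columns more than half gaps
    are dropped.
    """
    if len(peptides) < 5:
        raise ValueError("need at least 5 member sequences")
    rows = [p.upper() for p in peptides]
    if len({len(r) for r in rows}) != 1:
        from .phylo import progressive_align

        rows = progressive_align(rows).rows
    n = len(rows)
    ncols = len(rows[0])
    cols = []
    for j in range(ncols):
        col = [r[j] for r in rows]
        if col.count("-") / n > max_gap_fraction:
            continue
        counts = np.zeros(20)
        for c in col:
            k = _align.AA_ORDER.find(c)
            if k >= 0:
                counts[k] += 1
        cols.append(np.log((counts + 1.0) / ((n + 1.0) * background)))
    if not cols:
        raise ValueError("all columns dropped")
    columns = np.round(np.vstack(cols), 4)
    thr = 0.25 * float(columns.max(axis=1).sum())
    return DomainProfile(
        name=name, domain_class=domain_class, affinity=affinity, columns=columns,
        gap_open=gap_open, gap_extend=gap_extend, score_threshold=thr,
    )


# ---------------------------------------------------------------------------
# packaged PSSM text format

def write_pssm(p: DomainProfile, path: str | Path) -> None:
    lines = [
        "# yrscan PSSM 1",
        f"name\t{p.name}",
        f"domain_class\t{p.domain_class}",
        f"affinity\t{p.affinity}",
        f"gap_open\t{p.gap_open:.6f}",
        f"gap_extend\t{p.gap_extend:.6f}",
        f"score_threshold\t{p.score_threshold:.6f}",
        "aa\t" + "\t".join(_align.AA_ORDER),
    ]
    for row in p.columns:
        lines.append("col\t" + "\t".join(f"{v:.6f}" for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_pssm(path: str | Path) -> DomainProfile:
    meta: dict[str, str] = {}
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        key, *rest = line.split("\t")
        if key == "col":
            rows.append([float(v) for v in rest])
        elif key != "aa":
            meta[key] = rest[0]
    return DomainProfile(
        name=meta["name"], domain_class=meta["domain_class"], affinity=meta["affinity"],
        columns=np.array(rows), gap_open=float(meta["gap_open"]),
        gap_extend=float(meta["gap_extend"]), score_threshold=float(meta["score_threshold"]),
    )
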