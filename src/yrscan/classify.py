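"""Superfamily, completeness and clade assignment.

The decision ladder for the superfamily follows the diagnostic value of
the evidence: the MT (DNA N-6-adenine-methyltransferase) domain occurs in
DIRS only, repeat architecture is the second axis (ITR = DIRS, split
direct repeats = Ngaro), and the affinity tags of the best-scoring
profiles act as a fallback vote. Contradictory evidence (an MT domain
together with a split-direct layout) yields ``undetermined`` with both
evidences recorded rather than a forced call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import _align, profiles as _profiles
from .domain_scan import DomainProfile, ElementCore
from .repeat_struct import NO_REPEATS, RepeatStructure
from .seqio import Interval

SUPERFAMILIES = ("DIRS", "Ngaro", "undetermined")
COMPLETENESS = ("complete", "truncated", "remnant")
EXPECTED_DOMAINS = {"DIRS": {"RT", "RH", "MT", "YR"}, "Ngaro": {"RT", "RH", "YR"}}

COMPLETE_COVERAGE = 0.8
REMNANT_COVERAGE = 0.5
CLADE_MARGIN = 0.05


@dataclass
class ElementModel:
    """A fully annotated YR retrotransposon."""

    core: ElementCore
    repeats: RepeatStructure
    outer_interval: Interval
    superfamily: str
    completeness: str
    clade: str
    evidence: list[str] = field(default_factory=list)
    family: str | None = None

    def __post_init__(self) -> None:
        if not self.core.hits:
            raise ValueError("an element must carry at least one domain hit")


def classify_superfamily(core: ElementCore, repeats: RepeatStructure) -> tuple[str, list[str]]:
    """Decision ladder: MT > repeat architecture > profile-affinity vote."""
    if not core.hits:
        raise ValueError("core has no domain hits")
    evidence: list[str] = []
    has_mt = "MT" in core.domain_classes
    kind = repeats.kind if repeats is not None else "none"
    if has_mt and kind == "SPLIT_DIRECT":
        evidence.append("conflict: MT domain (DIRS-diagnostic) with split direct repeats (Ngaro layout)")
        return "undetermined", evidence
    if has_mt:
        evidence.append("MT domain present (DIRS-diagnostic)")
        return "DIRS", evidence
    if kind == "ITR":
        evidence.append(f"inverted terminal repeats (identity {repeats.identity_a:.2f})")
        return "DIRS", evidence
    if kind == "SPLIT_DIRECT":
        evidence.append(
            f"split direct repeats A1-B1-A2-B2 (identity A {repeats.identity_a:.2f}, "
            f"B {repeats.identity_b:.2f})"
        )
        return "Ngaro", evidence
    votes = {"DIRS": 0, "Ngaro": 0}
    for dclass in sorted(core.domain_classes):
        best = core.best_hit(dclass)
        if best.affinity == "DIRS-specific":
            votes["DIRS"] += 1
            evidence.append(f"{dclass}: best profile {best.profile_name} is DIRS-specific")
        elif best.affinity == "Ngaro-like":
            votes["Ngaro"] += 1
            evidence.append(f"{dclass}: best profile {best.profile_name} is Ngaro-like")
        else:
            evidence.append(f"{dclass}: best profile {best.profile_name} is generic (abstains)")
    if votes["DIRS"] > votes["Ngaro"]:
        return "DIRS", evidence
    if votes["Ngaro"] > votes["DIRS"]:
        return "Ngaro", evidence
    evidence.append("affinity vote tied or all-generic")
    return "undetermined", evidence


def call_completeness(core: ElementCore, repeats: RepeatStructure, superfamily: str) -> str:
    """complete / truncated / remnant from domain set, coverage and repeats.

    ``complete`` needs the full expected domain set of the superfamily,
    every retained hit covering >= 80% of its profile, and the full repeat
    structure. ``remnant`` marks decay: every hit below 50% coverage, or a
    single surviving domain class. Everything else is ``truncated``; an
    undetermined element can never be complete (it has no architecture to
    complete).
    """
    classes = core.domain_classes
    coverages = [h.profile_coverage for h in core.hits]
    if all(c < REMNANT_COVERAGE for c in coverages) or len(classes) == 1:
        return "remnant"
    if superfamily in EXPECTED_DOMAINS:
        expected = EXPECTED_DOMAINS[superfamily]
        full_repeats = (repeats.kind == "ITR") if superfamily == "DIRS" else (
            repeats.kind == "SPLIT_DIRECT")
        if expected <= classes and all(c >= COMPLETE_COVERAGE for c in coverages) and full_repeats:
            return "complete"
    return "truncated"


def _motif_scores(core: ElementCore,
                  motif_sets: dict[str, dict[str, DomainProfile]]) -> dict[str, float]:
    peptides = {}
    for d in ("RT", "RH", "YR"):
        best = core.best_hit(d)
        if best is not None and best.peptide:
            peptides[d] = _align.encode_peptide(best.peptide)
    if not peptides:
        raise ValueError("no RT/RH/YR hit peptides available for motif scoring")
    scores = {}
    for group, per_domain in motif_sets.items():
        total = 0.0
        for d, codes in peptides.items():
            prof = per_domain[d]
            total += _align.max_local_score(prof.columns, codes, prof.gap_open, prof.gap_extend)
        scores[group] = total
    return scores


def _assign_by_motifs(core: ElementCore,
                      motif_sets: dict[str, dict[str, DomainProfile]],
                      margin_threshold: float = CLADE_MARGIN) -> tuple[str, float]:
    scores = _motif_scores(core, motif_sets)
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    best_name, best = ranked[0]
    second = ranked[1][1] if len(ranked) > 1 else float("-inf")
    if best <= 0:
        return "unassigned", 0.0
    margin = (best - second) / abs(best)
    if margin < margin_threshold:
        return "unassigned", margin
    return best_name, margin


def assign_ngaro_clade(core: ElementCore,
                       clade_motifs: dict[str, dict[str, DomainProfile]] | None = None,
                       margin_threshold: float = CLADE_MARGIN) -> tuple[str, float]:
    """Assign one of the four Ngaro clades from domain motif scores.

    Each clade scores the sum over available RT/RH/YR hit peptides of the
    best local motif-profile alignment; the winner needs a relative margin
    over the runner-up (default 5%), otherwise ``unassigned`` (clades can
    share motifs, so a narrow margin is not a call).
    """
    if clade_motifs is None:
        clade_motifs = _profiles.load_clade_motif_profiles()
    return _assign_by_motifs(core, clade_motifs, margin_threshold)


def assign_dirs_lineage(core: ElementCore,
                        lineage_motifs: dict[str, dict[str, DomainProfile]] | None = None,
                        margin_threshold: float = CLADE_MARGIN) -> tuple[str, float]:
    """Assign one of the two DIRS lineages; same scheme as the Ngaro clades."""
    if lineage_motifs is None:
        lineage_motifs = _profiles.load_lineage_motif_profiles()
    return _assign_by_motifs(core, lineage_motifs, margin_threshold)


def outer_interval(core: ElementCore, repeats: RepeatStructure) -> Interval:
    """Repeat-extended element envelope (core envelope when repeats absent)."""
    start, end = core.interval.start, core.interval.end
    if repeats is not None and repeats.kind != "none":
        start = min([start] + [c.interval.start for c in repeats.copies])
        end = max([end] + [c.interval.end for c in repeats.copies])
    return Interval(core.interval.seq_id, start, end, core.strand)


def annotate_element(core: ElementCore, repeats: RepeatStructure | None = None) -> ElementModel:
    """Full classification of one element core + repeat evidence."""
    repeats = repeats if repeats is not None else NO_REPEATS
    superfamily, evidence = classify_superfamily(core, repeats)
    completeness = call_completeness(core, repeats, superfamily)
    clade = "unassigned"
    margin = 0.0
    try:
        if superfamily == "Ngaro":
            clade, margin = assign_ngaro_clade(core)
        elif superfamily == "DIRS":
            clade, margin = assign_dirs_lineage(core)
    except ValueError:
        clade = "unassigned"
    if clade != "unassigned":
        evidence.append(f"clade {clade} (margin {margin:.3f})")
    return ElementModel(
        core=core, repeats=repeats, outer_interval=outer_interval(core, repeats),
        superfamily=superfamily, completeness=completeness, clade=clade,
        evidence=evidence,
    )
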