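"""End-to-end annotation pipeline: scan -> repeats -> classify -> cluster -> tree.

Every tunable lives in :class:`RunConfig`; a run writes its fully resolved
configuration next to its outputs so results are reproducible from the
output directory alone. All stochastic steps (shuffle nulls, graph
p-values, layout) derive their seeds from the configured master seed —
there is no wall-clock seeding anywhere.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import classify as _classify
from . import domain_scan as _ds
from . import family_cluster as _fc
from . import phylo as _phylo
from . import profiles as _profiles
from . import repeat_struct as _rs
from . import seqio as _seqio
from . import sixframe as _sf

log = logging.getLogger("yrscan")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """All pipeline tunables.

    Detection: hits must clear the per-profile score threshold and an
    empirical shuffle p-value (p <= domain_p, shuffle null of size
    null_shuffles drawn on a composition-preserving peptide subsample of
    null_peptide_len residues). Families: greedy clustering at
    identity_threshold with word filter word_len. Graph: edges at
    p <= graph_p_threshold from graph_shuffles shuffles per pair.
    """

    seed: int = 0
    # domain scanning
    domain_p: float = 0.01
    null_shuffles: int = 199
    null_peptide_len: int = 2000
    merge_gap_nt: int = 3000
    # repeat detection
    flank_nt: int = 2000
    repeat_k: int = 13
    repeat_min_len: int = 20
    repeat_min_identity: float = 0.80
    # family clustering
    identity_threshold: float = 0.60
    word_len: int = 4
    # similarity graph (on family representatives)
    graph_p_threshold: float = 1e-06
    graph_shuffles: int = 50
    run_graph: bool = True
    # tree stage
    trim_max_gap_fraction: float = 0.05
    distance_model: str = "poisson"
    run_tree: bool = True

    def validate(self) -> None:
        if not (0 < self.domain_p <= 1):
            raise ConfigError("domain_p must be in (0, 1]")
        if self.null_shuffles < 19:
            raise ConfigError("null_shuffles must be >= 19")
        if not (0 < self.identity_threshold <= 1):
            raise ConfigError("identity_threshold must be in (0, 1]")
        if self.distance_model not in ("p-distance", "poisson"):
            raise ConfigError(f"unknown distance model {self.distance_model!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must hold a key/value mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


@dataclass
class PipelineResult:
    elements: list[_classify.ElementModel]
    element_ids: list[str]
    families: list[_fc.FamilyCluster]
    graph: _fc.SimilarityGraph | None = None
    components: list[list[str]] | None = None
    tree: object | None = None
    parity: _ds.ParityReport | None = None


def element_id(el: _classify.ElementModel) -> str:
    iv = el.outer_interval
    return f"{iv.seq_id}:{iv.start + 1}-{iv.end}({iv.strand})"


# ---------------------------------------------------------------------------
# stages

def scan_genome(records: Sequence[_seqio.GenomeRecord], config: RunConfig,
                profiles: Sequence[_ds.DomainProfile] | None = None) -> list[_ds.DomainHit]:
    """Scan all six frames of all records with all profiles; filter hits.

    Hits need score >= the profile threshold and an empirical p <= domain_p
    against a per-(record, profile) shuffle null of the subsampled longest
    frame peptide.
    """
    if profiles is None:
        profiles = _profiles.load_packaged_profiles()
    out: list[_ds.DomainHit] = []
    for rec in records:
        translations = _sf.translate_six_frames(rec)
        longest = max(translations, key=lambda t: len(t.peptide))
        for p_i, prof in enumerate(profiles):
            raw = [h for t in translations for h in _ds.scan_profile(t, prof)]
            if not raw:
                continue
            null_t = _subsample_translation(longest, config.null_peptide_len,
                                            config.seed + 7919 * p_i)
            null = _ds.null_max_scores(null_t, prof, config.null_shuffles,
                                       seed=config.seed + 104729 * p_i)
            for h in raw:
                p = (1 + int(np.count_nonzero(null >= h.score))) / (config.null_shuffles + 1)
                if p <= config.domain_p:
                    out.append(replace(h, empirical_p=p))
        log.info("record %s: %d domain hits", rec.id, sum(1 for h in out if h.interval.seq_id == rec.id))
    return out


def _subsample_translation(t: _sf.FrameTranslation, max_len: int, seed: int) -> _sf.FrameTranslation:
    if len(t.peptide) <= max_len:
        return t
    rng = np.random.default_rng(seed)
    start = int(rng.integers(0, len(t.peptide) - max_len))
    return _sf.FrameTranslation(seq_id=t.seq_id, frame=t.frame,
                                peptide=t.peptide[start : start + max_len],
                                offset=t.offset, source_length=t.source_length)


def detect_repeats(record: _seqio.GenomeRecord, core: _ds.ElementCore,
                   config: RunConfig) -> _rs.RepeatStructure:
    """Best repeat architecture around a core (higher matched-bases score wins)."""
    kw = dict(flank_nt=config.flank_nt, k=config.repeat_k,
              min_len=config.repeat_min_len, min_identity=config.repeat_min_identity)
    itr = _rs.find_itr(record, core.interval, **kw)
    split = _rs.find_split_direct(record, core.interval, strand=core.strand, **kw)
    best = max((s for s in (itr, split) if s is not None),
               key=lambda s: s.score, default=None)
    if best is None:
        return _rs.NO_REPEATS
    if best.kind == "ITR":
        outer = _classify.outer_interval(core, best)
        icr = _rs.find_icr(record, outer, best, k=config.repeat_k,
                           min_identity=config.repeat_min_identity)
        best = best.with_icr(icr)
    return best


def annotate(records: Sequence[_seqio.GenomeRecord], config: RunConfig,
             profiles: Sequence[_ds.DomainProfile] | None = None,
             ) -> tuple[list[_classify.ElementModel], _ds.ParityReport]:
    """scan -> merge -> repeats -> classify."""
    config.validate()
    hits = scan_genome(records, config, profiles)
    cores = _ds.merge_hits(hits, max_gap_nt=config.merge_gap_nt)
    parity = _ds.qc_rt_rh_parity(cores)
    by_id = {r.id: r for r in records}
    elements = []
    for core in cores:
        repeats = detect_repeats(by_id[core.interval.seq_id], core, config)
        elements.append(_classify.annotate_element(core, repeats))
    counts = _tally(elements)
    log.info("%d elements (%s)", len(elements),
             ", ".join(f"{k}: {v}" for k, v in counts.items()) or "none")
    return elements, parity


def _tally(elements) -> dict[str, int]:
    counts: dict[str, int] = {}
    for el in elements:
        counts[el.superfamily] = counts.get(el.superfamily, 0) + 1
    return dict(sorted(counts.items()))


def run_pipeline(records: Sequence[_seqio.GenomeRecord], config: RunConfig,
                 outdir: str | Path | None = None,
                 profiles: Sequence[_ds.DomainProfile] | None = None) -> PipelineResult:
    """Full chain; writes GFF3/TSV/Newick outputs when ``outdir`` is given."""
    config.validate()
    elements, parity = annotate(records, config, profiles)
    ids = []
    concats = []
    for el in elements:
        eid = element_id(el)
        ids.append(eid)
        concats.append(_fc.concatenate_domains(el, eid))
    families = _fc.greedy_identity_cluster(concats, threshold=config.identity_threshold,
                                           word_len=config.word_len)
    fam_of = {}
    for k, fam in enumerate(families, start=1):
        for m in fam.member_ids:
            fam_of[m] = f"F{k:04d}"
    for el, eid in zip(elements, ids):
        el.family = fam_of.get(eid)
    log.info("%d families at %.0f%% identity", len(families), 100 * config.identity_threshold)

    graph = components = None
    rep_ids = [f.representative_id for f in families]
    rep_seqs = {c.element_id: c.peptide for c in concats if c.element_id in set(rep_ids)}
    if config.run_graph and len(rep_seqs) >= 2:
        graph = _fc.build_similarity_graph(rep_seqs, p_threshold=config.graph_p_threshold,
                                           n_shuffles=config.graph_shuffles,
                                           seed=config.seed + 12007)
        components = _fc.connected_components(graph)
        log.info("similarity graph: %d nodes, %d edges, %d components",
                 len(graph.nodes), len(graph.edges), len(components))

    tree = None
    if config.run_tree and len(rep_seqs) >= 3:
        tree = representative_tree(
            [el for el, eid in zip(elements, ids) if eid in rep_seqs],
            [eid for eid in ids if eid in rep_seqs],
            config,
        )

    result = PipelineResult(elements=elements, element_ids=ids, families=families,
                            graph=graph, components=components, parity=parity)
    result.tree = tree
    if outdir is not None:
        write_outputs(result, config, outdir)
    return result


def representative_tree(elements: Sequence[_classify.ElementModel], ids: Sequence[str],
                        config: RunConfig):
    """NJ tree over trimmed, concatenated RT/RH/YR alignments of representatives."""
    per_domain: dict[str, _seqio.Alignment] = {}
    for d in ("RT", "RH", "YR"):
        seqs, row_ids = [], []
        for el, eid in zip(elements, ids):
            hit = el.core.best_hit(d)
            if hit is not None and hit.peptide:
                seqs.append(hit.peptide.replace("*", "X"))
                row_ids.append(eid)
        if len(seqs) >= 2:
            aln = _phylo.progressive_align(seqs, ids=row_ids)
            try:
                aln = _phylo.trim_columns(aln, config.trim_max_gap_fraction)
            except ValueError:
                continue  # everything trimmed away; drop this partition
            per_domain[d] = aln
    if not per_domain:
        return None
    concat = _phylo.concat_partitions(per_domain)
    if len(concat.ids) < 3:
        return None
    try:
        dm = _phylo.distance_matrix(concat, model=config.distance_model)
    except ValueError as exc:
        log.warning("tree stage skipped: %s", exc)
        return None
    return _phylo.neighbor_joining(dm, concat.ids)


def write_outputs(result: PipelineResult, config: RunConfig, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _seqio.write_gff3(result.elements, outdir / "elements.gff3")
    _seqio.write_element_table(result.elements, outdir / "elements.tsv")
    with open(outdir / "families.tsv", "w") as fh:
        fh.write("element_id\tfamily_id\trepresentative\n")
        for k, fam in enumerate(result.families, start=1):
            for m in fam.member_ids:
                rep = "1" if m == fam.representative_id else "0"
                fh.write(f"{m}\tF{k:04d}\t{rep}\n")
    if result.graph is not None:
        with open(outdir / "graph_edges.tsv", "w") as fh:
            fh.write("node_a\tnode_b\tp_value\n")
            for u, v, p in result.graph.edges:
                fh.write(f"{u}\t{v}\t{p:.3e}\n")
    if result.tree is not None:
        _seqio.write_newick(result.tree, outdir / "representatives.nwk")
    config.to_yaml(outdir / "run_config.yaml")
    if not result.elements:
        log.info("0 elements detected")
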