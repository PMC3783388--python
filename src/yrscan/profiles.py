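"""Packaged scanning profiles, clade/lineage motif profiles and domain seeds.

The shipped seed peptides are synthetic stand-ins constructed to be
internally consistent with the scanner: a generic consensus per domain,
superfamily-specific variants (~70% identity to the generic consensus) and
clade/lineage variants carrying a 20-residue diagnostic motif. Real
annotation runs can substitute curated HMMER3 profiles via
:func:`yrscan.seqio.read_hmmer3_profile`; the synthetic set exists so that
every stage of the pipeline is exercisable offline with known truth.

Scanning profiles are BLOSUM62-row position score matrices: column ``i``
scores amino acid ``a`` as BLOSUM62(consensus_i, a). The per-profile
reporting threshold defaults to a quarter of the consensus self-score
(clamped at 40), which sits far above the shuffled-background maximum for
genome-scale scans yet keeps half-length decayed fragments detectable.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import numpy as np
from Bio.Align import substitution_matrices

from ._align import AA_ORDER
from .domain_scan import DomainProfile

NGARO_CLADES = ("Ngaro1", "Ngaro2", "Ngaro3", "Ngaro4")
DIRS_LINEAGES = ("DIRS_A", "DIRS_B")

_CLADE_KEY = {"Ngaro1": "CLADE1", "Ngaro2": "CLADE2", "Ngaro3": "CLADE3", "Ngaro4": "CLADE4",
              "DIRS_A": "LINA", "DIRS_B": "LINB"}
_SEED_KEY = {"Ngaro1": "NGARO1", "Ngaro2": "NGARO2", "Ngaro3": "NGARO3", "Ngaro4": "NGARO4",
             "DIRS_A": "DIRSA", "DIRS_B": "DIRSB"}


def _read_faa(name: str) -> dict[str, str]:
    out: dict[str, str] = {}
    text = resources.files("yrscan").joinpath("data", name).read_text()
    current = None
    for line in text.splitlines():
        if line.startswith(">"):
            current = line[1:].split()[0]
            out[current] = ""
        elif current is not None:
            out[current] += line.strip()
    return out


@lru_cache(maxsize=1)
def packaged_seeds() -> dict[str, str]:
    return _read_faa("synthetic_domain_seeds.faa")


@lru_cache(maxsize=1)
def packaged_motifs() -> dict[str, str]:
    return _read_faa("synthetic_clade_motifs.faa")


@lru_cache(maxsize=1)
def _blosum62() -> np.ndarray:
    m = substitution_matrices.load("BLOSUM62")
    out = np.zeros((20, 20))
    for i, a in enumerate(AA_ORDER):
        for j, b in enumerate(AA_ORDER):
            out[i, j] = m[a, b]
    return out


def profile_from_consensus(consensus: str, name: str, domain_class: str,
                           affinity: str = "generic",
                           threshold_fraction: float = 0.25,
                           min_threshold: float = 40.0) -> DomainProfile:
    """BLOSUM62-row position score matrix for a consensus peptide."""
    b62 = _blosum62()
    idx = [AA_ORDER.index(a) for a in consensus]
    columns = b62[idx, :]
    self_score = float(columns.max(axis=1).sum())
    return DomainProfile(
        name=name, domain_class=domain_class, affinity=affinity, columns=columns,
        gap_open=-11.0, gap_extend=-1.0,
        score_threshold=max(min_threshold, threshold_fraction * self_score),
    )


@lru_cache(maxsize=1)
def load_packaged_profiles() -> tuple[DomainProfile, ...]:
    """The default scanning profile set.

    Generic profiles per domain plus superfamily-specific RT/RH/YR variants
    (the affinity tags drive the classifier's fallback vote) and the
    DIRS-diagnostic MT profile.
    """
    s = packaged_seeds()
    specs = [
        ("RT_generic", "GEN_RT", "RT", "generic"),
        ("RT_DIRS", "DIRS_RT", "RT", "DIRS-specific"),
        ("RT_NGARO", "NGARO_RT", "RT", "Ngaro-like"),
        ("RH_generic", "GEN_RH", "RH", "generic"),
        ("RH_DIRS", "DIRS_RH", "RH", "DIRS-specific"),
        ("RH_NGARO", "NGARO_RH", "RH", "Ngaro-like"),
        ("YR_generic", "GEN_YR", "YR", "generic"),
        ("YR_DIRS", "DIRS_YR", "YR", "DIRS-specific"),
        ("YR_NGARO", "NGARO_YR", "YR", "Ngaro-like"),
        ("MT_DAM", "GEN_MT", "MT", "DIRS-specific"),
    ]
    return tuple(
        profile_from_consensus(s[seed], name, dclass, affinity)
        for name, seed, dclass, affinity in specs
    )


@lru_cache(maxsize=1)
def load_clade_motif_profiles() -> dict[str, dict[str, DomainProfile]]:
    """Per-clade (Ngaro1..4) motif profiles over RT/RH/YR."""
    m = packaged_motifs()
    out: dict[str, dict[str, DomainProfile]] = {}
    for clade in NGARO_CLADES:
        out[clade] = {
            d: profile_from_consensus(
                m[f"{_CLADE_KEY[clade]}_{d}"], f"{clade}_{d}_motif", d,
                "Ngaro-like", min_threshold=1.0,
            )
            for d in ("RT", "RH", "YR")
        }
    return out


@lru_cache(maxsize=1)
def load_lineage_motif_profiles() -> dict[str, dict[str, DomainProfile]]:
    """Per-lineage (DIRS_A / DIRS_B) motif profiles over RT/RH/YR."""
    m = packaged_motifs()
    out: dict[str, dict[str, DomainProfile]] = {}
    for lin in DIRS_LINEAGES:
        out[lin] = {
            d: profile_from_consensus(
                m[f"{_CLADE_KEY[lin]}_{d}"], f"{lin}_{d}_motif", d,
                "DIRS-specific", min_threshold=1.0,
            )
            for d in ("RT", "RH", "YR")
        }
    return out


def element_domain_seeds(superfamily: str, clade: str) -> dict[str, str]:
    """Domain peptides planted by the synthetic generator for one clade."""
    s = packaged_seeds()
    key = _SEED_KEY[clade]
    if superfamily == "DIRS":
        if clade not in DIRS_LINEAGES:
            raise ValueError(f"DIRS clade must be one of {DIRS_LINEAGES}, got {clade!r}")
        return {d: s[f"{key}_{d}"] for d in ("RT", "RH", "YR")} | {"MT": s["GEN_MT"]}
    if superfamily == "Ngaro":
        if clade not in NGARO_CLADES:
            raise ValueError(f"Ngaro clade must be one of {NGARO_CLADES}, got {clade!r}")
        return {d: s[f"{key}_{d}"] for d in ("RT", "RH", "YR")}
    raise ValueError(f"unknown superfamily {superfamily!r}")
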