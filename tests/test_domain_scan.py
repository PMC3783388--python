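"""Profile scanning, empirical significance, hit merging and profile building."""

import math

import numpy as np
import pytest

from conftest import mutate_peptide, naive_greedy_hits, random_peptide
from yrscan import _align
from yrscan.domain_scan import (DomainHit, DomainProfile, build_profile_from_members,
                                empirical_pvalue, merge_hits, null_max_scores,
                                qc_rt_rh_parity, read_pssm, scan_profile, write_pssm)
from yrscan.profiles import packaged_seeds, profile_from_consensus
from yrscan.seqio import Interval
from yrscan.sixframe import FrameTranslation


def make_translation(pep: str, frame: int = 1, seq_id: str = "s") -> FrameTranslation:
    L = 3 * len(pep) + abs(frame) - 1
    return FrameTranslation(seq_id=seq_id, frame=frame, peptide=pep,
                            offset=abs(frame) - 1, source_length=L)


@pytest.fixture(scope="module")
def rt_profile():
    return profile_from_consensus(packaged_seeds()["GEN_RT"], "RT_generic", "RT")


class TestScanProfile:
    def test_consensus_self_match(self, rt_profile):
        pep = packaged_seeds()["GEN_RT"]
        hits = scan_profile(make_translation(pep), rt_profile)
        assert len(hits) == 1
        h = hits[0]
        assert h.profile_coverage == 1.0
        # BLOSUM62 rows peak on the diagonal, so the self-score is the sum
        # of per-column maxima
        assert h.score == pytest.approx(rt_profile.consensus_self_score)
        assert (h.interval.start, h.interval.end) == (0, 3 * len(pep))

    def test_shuffled_consensus_rarely_hits(self, rt_profile, rng):
        pep = list(packaged_seeds()["GEN_RT"])
        n_hit = 0
        for _ in range(100):
            rng.shuffle(pep)
            n_hit += bool(scan_profile(make_translation("".join(pep)), rt_profile))
        assert n_hit <= 1

    def test_stop_codon_in_domain_tolerated(self, rt_profile):
        pep = packaged_seeds()["GEN_RT"]
        broken = pep[:60] + "*" + pep[60:]
        hits = scan_profile(make_translation(broken), rt_profile)
        assert len(hits) == 1
        assert hits[0].score < rt_profile.consensus_self_score

    def test_empty_peptide(self, rt_profile):
        assert scan_profile(make_translation(""), rt_profile) == []

    def test_scores_equal_full_matrix_oracle(self, rng):
        """Windowed greedy extraction == exhaustive DP + greedy masking."""
        for case in range(100):
            Lp = int(rng.integers(10, 25))
            cols = rng.integers(-4, 12, size=(Lp, 20)).astype(float)
            prof = DomainProfile(name="t", domain_class="RT", affinity="generic",
                                 columns=cols, score_threshold=1.0)
            n = int(rng.integers(20, 200))
            pep = random_peptide(rng, n)
            if case % 3 == 0:  # plant a strong match to exercise extraction
                cons = "".join(_align.AA_ORDER[int(c)] for c in cols.argmax(axis=1))
                at = int(rng.integers(0, n - Lp)) if n > Lp else 0
                pep = pep[:at] + cons + pep[at + Lp:]
            threshold = 0.5 * prof.consensus_self_score
            codes = _align.encode_peptide(pep)
            impl = sorted((h.score for h in _align.scan_local(
                cols, codes, prof.gap_open, prof.gap_extend, threshold)), reverse=True)
            oracle = naive_greedy_hits(cols, codes, prof.gap_open, prof.gap_extend, threshold)
            assert impl == pytest.approx(oracle), f"case {case}"

    def test_threshold_monotonicity(self, rt_profile, rng):
        pep = random_peptide(rng, 150) + packaged_seeds()["GEN_RT"] + random_peptide(rng, 150)
        t = make_translation(pep)
        counts = [len(scan_profile(t, rt_profile, score_threshold=thr))
                  for thr in (40.0, 100.0, 300.0, 800.0)]
        assert counts == sorted(counts, reverse=True)


class TestPlantedDomainRecovery:
    def test_exact_boundaries_at_zero_decay(self, rt_profile, rng):
        cons = packaged_seeds()["GEN_RT"]
        for _ in range(20):
            left = int(rng.integers(5, 120))
            pep = random_peptide(rng, left) + cons + random_peptide(rng, 80)
            hits = scan_profile(make_translation(pep), rt_profile)
            best = max(hits, key=lambda h: h.score)
            assert (best.interval.start, best.interval.end) == (3 * left, 3 * (left + len(cons)))

    def test_recovery_at_ten_percent_substitution(self, rt_profile, rng):
        cons = packaged_seeds()["GEN_RT"]
        found = 0
        for _ in range(100):
            decayed = mutate_peptide(rng, cons, 0.10)
            left = int(rng.integers(5, 120))
            pep = random_peptide(rng, left) + decayed + random_peptide(rng, 80)
            hits = scan_profile(make_translation(pep), rt_profile)
            found += any(
                h.interval.overlap_length(Interval("s", 3 * left, 3 * (left + len(cons)))) > 0
                for h in hits
            )
        assert found >= 90


class TestEmpiricalPvalue:
    def test_above_all_shuffles(self, rt_profile):
        t = make_translation(packaged_seeds()["GEN_RT"])
        null = np.zeros(99)
        assert empirical_pvalue(1000.0, t, rt_profile, n_shuffles=99, null_scores=null) == 0.01

    def test_below_all_shuffles(self, rt_profile):
        t = make_translation(packaged_seeds()["GEN_RT"])
        null = np.full(99, 1e9)
        assert empirical_pvalue(1.0, t, rt_profile, n_shuffles=99, null_scores=null) == 1.0

    def test_single_tie_among_19(self, rt_profile):
        t = make_translation(packaged_seeds()["GEN_RT"])
        null = np.concatenate([[50.0], np.zeros(18)])
        assert empirical_pvalue(50.0, t, rt_profile, n_shuffles=19,
                                null_scores=null) == pytest.approx(0.10)

    def test_too_few_shuffles_rejected(self, rt_profile):
        with pytest.raises(ValueError):
            empirical_pvalue(1.0, make_translation("MKL"), rt_profile, n_shuffles=5)

    def test_deterministic_given_seed(self, rt_profile, rng):
        t = make_translation(random_peptide(rng, 200))
        p1 = empirical_pvalue(60.0, t, rt_profile, n_shuffles=19, seed=42)
        p2 = empirical_pvalue(60.0, t, rt_profile, n_shuffles=19, seed=42)
        assert p1 == p2

    def test_batched_null_equals_per_shuffle_null(self, rt_profile, rng):
        t = make_translation(random_peptide(rng, 300))
        a = null_max_scores(t, rt_profile, 25, seed=7, batched=True)
        b = null_max_scores(t, rt_profile, 25, seed=7, batched=False)
        assert np.array_equal(a, b)


def _hit(start, end, dclass, frame=1, score=100.0, seq_id="s", strand="+"):
    return DomainHit(interval=Interval(seq_id, start, end, strand), frame=frame,
                     domain_class=dclass, profile_name=f"{dclass}_x", score=score,
                     peptide="A" * ((end - start) // 3))


class TestMergeHits:
    def test_frame_split_hits_merge_into_one_core(self):
        hits = [_hit(100, 400, "RT", frame=1), _hit(450, 700, "RH", frame=1),
                _hit(900, 1200, "YR", frame=2)]
        cores = merge_hits(hits, max_gap_nt=3000)
        assert len(cores) == 1
        assert cores[0].has_frameshift
        assert cores[0].interval.start == 100 and cores[0].interval.end == 1200

    def test_distant_hits_stay_separate(self):
        hits = [_hit(0, 300, "YR"), _hit(10300, 10600, "YR")]
        assert len(merge_hits(hits, max_gap_nt=3000)) == 2

    def test_overlapping_same_class_keeps_best(self):
        hits = [_hit(0, 300, "RT", score=50.0), _hit(30, 330, "RT", score=80.0)]
        cores = merge_hits(hits)
        assert len(cores) == 1
        assert [h.score for h in cores[0].hits] == [80.0]

    def test_opposite_strands_never_merge(self):
        hits = [_hit(0, 300, "RT", strand="+"), _hit(400, 700, "RH", strand="-")]
        assert len(merge_hits(hits)) == 2

    def test_gap_monotonicity(self, rng):
        starts = sorted(rng.integers(0, 50000, size=30))
        hits = [_hit(int(s), int(s) + 150, "RT") for s in starts]
        counts = [len(merge_hits(hits, max_gap_nt=g)) for g in (100, 1000, 5000, 50000)]
        assert counts == sorted(counts, reverse=True)


class TestRtRhParity:
    def test_balanced(self):
        cores = merge_hits([_hit(i * 10000, i * 10000 + 300, "RT") for i in range(10)]
                           + [_hit(i * 10000 + 400, i * 10000 + 700, "RH") for i in range(10)])
        rep = qc_rt_rh_parity(cores)
        assert rep.ratio_rh_to_rt == 1.0 and rep.flagged == []

    def test_rh_excess_flagged(self):
        cores = merge_hits(
            [_hit(i * 10000, i * 10000 + 300, "RH") for i in range(6)]
            + [_hit(100000 + i * 10000, 100000 + i * 10000 + 300, "RT") for i in range(6)]
            + [_hit(100000 + i * 10000 + 400, 100000 + i * 10000 + 700, "RH") for i in range(6)]
        )
        rep = qc_rt_rh_parity(cores)
        assert rep.ratio_rh_to_rt == 2.0
        assert len(rep.flagged) == 6

    def test_empty(self):
        rep = qc_rt_rh_parity([])
        assert rep.n_rt_cores == rep.n_rh_cores == 0 and rep.flagged == []


class TestBuildProfileFromMembers:
    def test_closed_form_self_score(self):
        # 5 identical length-30 members: every consensus column scores
        # ln((1+5)/(6*(1/20))) = ln(20) under the +1 pseudocount rule
        pep = "ACDEFGHIKLMNPQRSTVWYACDEFGHIKL"
        prof = build_profile_from_members([pep] * 5, "RT")
        assert prof.length == 30
        self_score = prof.consensus_self_score
        assert self_score == pytest.approx(30 * math.log(20), abs=0.02)

    def test_gappy_columns_dropped(self):
        rows = ["AC-DE", "AC-DE", "ACXDE", "AC-DE", "ACXDE"]
        prof = build_profile_from_members(rows, "RT", max_gap_fraction=0.5)
        assert prof.length == 4  # 60%-gap column removed

    def test_too_few_members(self):
        with pytest.raises(ValueError, match="5"):
            build_profile_from_members(["ACDEFGHIKLMN"] * 4, "RT")

    def test_write_read_round_trip_preserves_scores(self, tmp_path):
        prof = build_profile_from_members(["ACDEFGHIKLMNPQRSTVWY"] * 6, "YR", name="toy")
        p = tmp_path / "toy.pssm"
        write_pssm(prof, p)
        back = read_pssm(p)
        assert back.name == "toy" and back.domain_class == "YR"
        assert np.allclose(back.columns, prof.columns, atol=1e-6)
        assert back.score_threshold == pytest.approx(prof.score_threshold, abs=1e-6)

    def test_unaligned_members_are_aligned_first(self):
        base = "ACDEFGHIKLMNPQRSTVWY"
        members = [base, base, base[:10] + base[11:], base, base]
        prof = build_profile_from_members(members, "RH")
        assert prof.length >= 15
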