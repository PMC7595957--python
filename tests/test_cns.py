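"""Affine-gap alignment, identity profiles and CNS calling."""

from functools import lru_cache

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from grassreg.cns import (
    AlignScoring,
    PairwiseAlignment,
    align_windows,
    call_cns,
    conservation_scope,
    identity_profile,
)
from grassreg.core_io import GrassregError, RegulatoryRegionSet

from conftest import mutate_seq, random_seq

SCORING = AlignScoring()


def oracle_score(a, b, sc=SCORING):
    """Exhaustive-recursion optimal affine-gap global alignment score.

    States: last move M (substitution), X (gap in b), Y (gap in a).  A gap of
    length L costs open + (L-1)*extend, matching the implementation's
    convention but written as plain recursion over prefixes.
    """

    @lru_cache(maxsize=None)
    def best(i, j, state):
        if i == 0 and j == 0:
            return 0.0 if state == "M" else -np.inf
        cands = []
        if i > 0 and j > 0 and state == "M":
            s = sc.match if a[i - 1] == b[j - 1] else sc.mismatch
            cands.extend(best(i - 1, j - 1, p) + s for p in "MXY")
        if i > 0 and state == "X":
            cands.append(best(i - 1, j, "M") + sc.gap_open)
            cands.append(best(i - 1, j, "X") + sc.gap_extend)
            cands.append(best(i - 1, j, "Y") + sc.gap_open)
        if j > 0 and state == "Y":
            cands.append(best(i, j - 1, "M") + sc.gap_open)
            cands.append(best(i, j - 1, "X") + sc.gap_open)
            cands.append(best(i, j - 1, "Y") + sc.gap_extend)
        return max(cands) if cands else -np.inf

    return max(best(len(a), len(b), s) for s in "MXY")


class TestAlign:
    def test_identical_sequences_align_gapless(self):
        s = random_seq(np.random.default_rng(0), 60)
        aln = align_windows(s, s)
        assert aln.score == 60
        assert "-" not in aln.aligned_ref + aln.aligned_query
        assert np.all(identity_profile(aln, window_size=10).values == 1.0)

    def test_single_mismatch_worked_example(self):
        aln = align_windows("ACGT", "ACGA")
        assert aln.score == 2  # 3 matches - 1 mismatch
        assert aln.aligned_ref == "ACGT" and aln.aligned_query == "ACGA"

    def test_empty_sequence_is_fatal(self):
        with pytest.raises(GrassregError, match="empty"):
            align_windows("", "ACGT")

    def test_size_guard(self):
        with pytest.raises(GrassregError, match="cells"):
            align_windows("A" * 100, "C" * 100, max_cells=1000)

    def test_scores_match_exhaustive_recursion(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            a = random_seq(rng, int(rng.integers(1, 13)))
            b = random_seq(rng, int(rng.integers(1, 13)))
            aln = align_windows(a, b)
            assert aln.score == pytest.approx(oracle_score(a, b))

    def test_scores_match_biopython_pairwise_aligner(self):
        from Bio import Align

        pa = Align.PairwiseAligner()
        pa.mode = "global"
        pa.match_score = 1
        pa.mismatch_score = -1
        pa.open_gap_score = -4
        pa.extend_gap_score = -0.5
        rng = np.random.default_rng(7)
        for _ in range(20):
            a = random_seq(rng, int(rng.integers(5, 60)))
            b = mutate_seq(rng, a, 0.3)
            assert align_windows(a, b).score == pytest.approx(pa.score(a, b))

    def test_gap_removal_recovers_inputs(self):
        rng = np.random.default_rng(3)
        a, b = random_seq(rng, 80), random_seq(rng, 70)
        aln = align_windows(a, b)
        assert aln.aligned_ref.replace("-", "") == a
        assert aln.aligned_query.replace("-", "") == b
        refmap = aln.ref_col_map[aln.ref_col_map >= 0]
        assert np.array_equal(refmap, np.arange(80))


class TestIdentityProfile:
    def _aln(self, ref, query):
        colmap, pos = [], 0
        for c in ref:
            colmap.append(-1 if c == "-" else pos)
            pos += c != "-"
        return PairwiseAlignment(
            ref_gene_id="r",
            query_gene_id="q",
            aligned_ref=ref,
            aligned_query=query,
            score=0.0,
            ref_col_map=np.array(colmap),
        )

    def test_strict_seventy_percent_boundary(self):
        ref = "A" * 50
        # exactly 35/50 matches: 0.70 is NOT above the strict threshold
        q35 = "A" * 35 + "C" * 15
        v = identity_profile(self._aln(ref, q35), window_size=50).values
        assert v[0] == pytest.approx(0.70)
        assert not v[0] > 0.70
        q36 = "A" * 36 + "C" * 14
        v = identity_profile(self._aln(ref, q36), window_size=50).values
        assert v[0] == pytest.approx(0.72) and v[0] > 0.70

    def test_short_alignment_gives_empty_profile(self):
        aln = self._aln("A" * 49, "A" * 49)
        assert identity_profile(aln, window_size=50).values.size == 0

    def test_gap_columns_count_as_mismatch(self):
        aln = self._aln("AAAA-AAAAA", "AAAACAAAAA")
        v = identity_profile(aln, window_size=10).values
        assert v[0] == pytest.approx(0.9)

    def test_bad_window_size_fatal(self):
        with pytest.raises(GrassregError):
            identity_profile(self._aln("AA", "AA"), window_size=0)


def _plant_pair(rng, bg_len=6000, block_len=150, block_at=2500,
                block_identity=0.9, bg_identity=0.55):
    ref = random_seq(rng, bg_len)
    query = mutate_seq(rng, ref, 1 - bg_identity)
    block = ref[block_at : block_at + block_len]
    query = (
        query[:block_at]
        + mutate_seq(rng, block, 1 - block_identity)
        + query[block_at + block_len :]
    )
    return ref, query


def _full_noncoding(length):
    return RegulatoryRegionSet(
        gene_id="g", regions=[((0, length), "upstream_intergenic")]
    )


class TestCallCNS:
    def test_all_below_threshold_yields_nothing(self):
        rng = np.random.default_rng(0)
        a = random_seq(rng, 300)
        b = mutate_seq(rng, a, 0.45)
        aln = align_windows(a, b)
        prof = identity_profile(aln)
        assert call_cns(prof, aln, _full_noncoding(300)) == []

    def test_planted_block_recovered_with_high_jaccard(self):
        rng = np.random.default_rng(11)
        ref, query = _plant_pair(rng)
        aln = align_windows(ref, query, max_cells=40e6)
        prof = identity_profile(aln)
        calls = call_cns(prof, aln, _full_noncoding(6000))
        assert len(calls) == 1
        s, e = calls[0].interval
        inter = max(0, min(e, 2650) - max(s, 2500))
        union = max(e, 2650) - min(s, 2500)
        assert inter / union >= 0.8
        assert calls[0].mean_identity > 0.70
        assert e - s >= 50

    def test_cds_overlap_drops_short_remnant(self):
        # a 150-bp conserved run of which 120 bp overlap CDS: the 30-bp
        # non-coding remnant is below the minimum length and is dropped
        ref = "ACGT" * 100  # 400 bp, fully self-conserved
        aln = align_windows(ref, ref)
        prof = identity_profile(aln)
        regions = RegulatoryRegionSet(
            gene_id="g", regions=[((0, 30), "upstream_intergenic")]
        )  # the rest of the window is coding
        assert call_cns(prof, aln, regions) == []

    def test_remnant_of_window_size_survives(self):
        ref = "ACGT" * 100
        aln = align_windows(ref, ref)
        prof = identity_profile(aln)
        regions = RegulatoryRegionSet(
            gene_id="g", regions=[((0, 80), "upstream_intergenic")]
        )
        calls = call_cns(prof, aln, regions)
        assert len(calls) == 1
        assert calls[0].interval[1] - calls[0].interval[0] >= 50
        assert calls[0].feature_class == "upstream_intergenic"


class TestSymmetry:
    def test_swapped_arguments_give_same_qualifying_columns(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            a = random_seq(rng, 400)
            b = mutate_seq(rng, a, 0.25)
            pab = identity_profile(align_windows(a, b))
            pba = identity_profile(align_windows(b, a))
            qa = set(np.nonzero(pab.values > 0.7)[0])
            qb = set(np.nonzero(pba.values > 0.7)[0])
            assert qa == qb


class TestConservationScope:
    CLADES = {
        "bop1": "BOP", "bop2": "BOP", "bop3": "BOP",
        "pacC3": "PACMAD", "pac1": "PACMAD", "pac2": "PACMAD",
        "pac3": "PACMAD", "pac4": "PACMAD",
    }

    def _cns(self):
        from grassreg.cns import CNSInterval

        return CNSInterval(
            ref_gene_id="g", interval=(0, 60), mean_identity=0.9,
            feature_class="intron",
        )

    def test_present_everywhere_is_all_species(self):
        cns = conservation_scope(
            self._cns(), {sp: True for sp in self.CLADES}, self.CLADES
        )
        assert cns.scope == "all_species"

    def test_pacmad_only_including_c3_pacmad(self):
        presence = {sp: cl == "PACMAD" for sp, cl in self.CLADES.items()}
        cns = conservation_scope(self._cns(), presence, self.CLADES)
        assert cns.scope == "clade_restricted:PACMAD"
        assert cns.supporting_species == {
            "pacC3", "pac1", "pac2", "pac3", "pac4"
        }

    def test_mixed_partial(self):
        presence = {sp: False for sp in self.CLADES}
        presence.update(bop1=True, pac1=True, pac2=True)
        cns = conservation_scope(self._cns(), presence, self.CLADES)
        assert cns.scope == "partial"

    def test_empty_flags_fatal(self):
        with pytest.raises(GrassregError):
            conservation_scope(self._cns(), {}, {})
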