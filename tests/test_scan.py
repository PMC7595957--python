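"""PWM scanning: log-odds, exact null p-values, BH filtering."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from grassreg.core_io import GrassregError, RegulatoryRegionSet
from grassreg.motifs import PWM, revcomp
from grassreg.scan import (
    MotifHit,
    bh_filter,
    bh_qvalues,
    build_log_odds,
    null_distribution,
    scan_window,
)

from conftest import make_window, random_seq

UNIFORM = np.full(4, 0.25)


def random_pwm(rng, w, sharp=3.0):
    return PWM(motif_id="m", probs=rng.dirichlet(np.full(4, 1.0 / sharp), size=w).T)


def enumerate_tail(lom, background):
    """Brute-force null tail probabilities over all 4^w words (discretized
    exactly like the DP, so the two routes are comparable bin by bin)."""
    iscores = lom.int_scores
    w = lom.width
    tail = {}
    for word in itertools.product(range(4), repeat=w):
        s = int(sum(iscores[b, k] for k, b in enumerate(word)))
        p = float(np.prod([background[b] for b in word]))
        tail[s] = tail.get(s, 0.0) + p
    scores = sorted(tail)
    acc = 0.0
    out = {}
    for s in reversed(scores):
        acc += tail[s]
        out[s] = acc
    return out


class TestLogOdds:
    def test_background_pwm_scores_zero(self):
        pwm = PWM(motif_id="flat", probs=np.full((4, 5), 0.25))
        lom = build_log_odds(pwm, UNIFORM, pseudocount=0.0)
        assert np.allclose(lom.scores, 0.0)

    def test_deterministic_column_arithmetic(self):
        pwm = PWM(motif_id="sharp", probs=np.array([[1.0], [0.0], [0.0], [0.0]]))
        lom = build_log_odds(pwm, UNIFORM, pseudocount=0.01)
        pc = 0.01 / 1.04
        assert lom.scores[0, 0] == pytest.approx(
            np.log2((1 * (1 - 4 * pc) + pc) / 0.25)
        )
        assert lom.scores[0, 0] == pytest.approx(1.96, abs=0.01)
        assert lom.scores[1, 0] == pytest.approx(np.log2(pc / 0.25))

    def test_larger_pseudocount_shrinks_scores(self):
        rng = np.random.default_rng(0)
        pwm = random_pwm(rng, 6)
        a = build_log_odds(pwm, UNIFORM, pseudocount=0.01)
        b = build_log_odds(pwm, UNIFORM, pseudocount=0.02)
        assert np.all(np.abs(b.scores) <= np.abs(a.scores) + 1e-12)

    def test_zero_background_fatal(self):
        pwm = PWM(motif_id="x", probs=np.full((4, 3), 0.25))
        with pytest.raises(GrassregError):
            build_log_odds(pwm, np.array([0.5, 0.5, 0.0, 0.0]))


class TestNullDistribution:
    def test_dp_matches_enumeration(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            w = int(rng.integers(3, 7))
            pwm = random_pwm(rng, w)
            bg = rng.dirichlet(np.ones(4) * 5)
            lom = build_log_odds(pwm, bg)
            dist = null_distribution(lom, bg)
            brute = enumerate_tail(lom, bg)
            for s, p in brute.items():
                assert dist.pvalue_int(s) == pytest.approx(p, abs=1e-12)

    def test_max_score_pvalue_is_argmax_word_mass(self):
        rng = np.random.default_rng(2)
        pwm = random_pwm(rng, 4)
        bg = np.full(4, 0.25)
        lom = build_log_odds(pwm, bg)
        dist = null_distribution(lom, bg)
        iscores = lom.int_scores
        smax = int(iscores.max(axis=0).sum())
        n_argmax = int(np.prod((iscores == iscores.max(axis=0)).sum(axis=0)))
        assert dist.pvalue_int(smax) == pytest.approx(n_argmax * 0.25**4)

    def test_minimum_support_pvalue_is_one(self):
        rng = np.random.default_rng(3)
        lom = build_log_odds(random_pwm(rng, 5), UNIFORM)
        dist = null_distribution(lom, UNIFORM)
        assert dist.tail_p[0] == pytest.approx(1.0)
        assert np.all(np.diff(dist.tail_p) <= 1e-15)


def _regions(length, cls="upstream_intergenic"):
    return RegulatoryRegionSet(gene_id="g", regions=[((0, length), cls)])


class TestScanWindow:
    def test_planted_consensus_has_minimal_pvalue(self):
        rng = np.random.default_rng(4)
        pwm = random_pwm(rng, 8, sharp=20)
        cons = pwm.consensus()
        seq = random_seq(rng, 1000)
        seq = seq[:137] + cons + seq[137 + 8 :]
        win = make_window(seq)
        lom = build_log_odds(pwm, UNIFORM)
        dist = null_distribution(lom, UNIFORM)
        hits = scan_window(win, _regions(1000), lom, dist)
        at = [h for h in hits if h.start == 137 and h.strand == "+"]
        pmin = min(h.p_value for h in hits)
        assert at and at[0].p_value == pytest.approx(pmin)

    def test_reverse_complement_symmetry(self):
        rng = np.random.default_rng(5)
        pwm = random_pwm(rng, 6)
        seq = random_seq(rng, 200)
        win = make_window(seq)
        win_rc = make_window(revcomp(seq))
        lom = build_log_odds(pwm, UNIFORM)
        dist = null_distribution(lom, UNIFORM)
        fwd = scan_window(win, _regions(200), lom, dist)
        rev = scan_window(win_rc, _regions(200), lom, dist)
        key_f = sorted((h.start, h.strand, round(h.score, 9)) for h in fwd)
        flip = {"+": "-", "-": "+"}
        key_r = sorted(
            (200 - h.end, flip[h.strand], round(h.score, 9)) for h in rev
        )
        assert key_f == key_r

    def test_region_shorter_than_motif_yields_nothing(self):
        rng = np.random.default_rng(6)
        pwm = random_pwm(rng, 10)
        win = make_window(random_seq(rng, 50))
        lom = build_log_odds(pwm, UNIFORM)
        dist = null_distribution(lom, UNIFORM)
        assert scan_window(win, _regions(8), lom, dist) == []

    def test_n_bases_score_zero_but_positions_scanned(self):
        pwm = PWM(motif_id="flat", probs=np.full((4, 4), 0.25))
        win = make_window("ACGTNNNNACGT")
        lom = build_log_odds(pwm, UNIFORM, pseudocount=0.0)
        dist = null_distribution(lom, UNIFORM)
        hits = scan_window(win, _regions(12), lom, dist)
        assert len(hits) == 2 * (12 - 4 + 1)
        assert all(h.score == 0.0 for h in hits)


def test_bed6_export_shape():
    from grassreg.scan import hits_to_bed6

    hits = [MotifHit("m", "g", "s", "intron", 5, 13, "-", 1.0, 1e-4, 1e-3)]
    line = hits_to_bed6(hits).strip().split("\t")
    assert line == ["s|g", "5", "13", "m", "30", "-"]


def test_identity_profile_tsv_dump():
    from grassreg.cns import align_windows, identity_profile

    aln = align_windows("ACGTACGTAC", "ACGTACGTAC")
    text = identity_profile(aln, window_size=5).to_tsv()
    lines = text.strip().split("\n")
    assert lines[0] == "start_column\tidentity"
    assert lines[1] == "0\t1.0000"


def oracle_bh(pvals):
    """Independent O(n^2) step-up: q_(i) = min_{j>=i} p_(j) * m / j."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    for rank_idx, i in enumerate(order):
        best = min(
            pvals[order[j]] * m / (j + 1) for j in range(rank_idx, m)
        )
        q[i] = min(1.0, best)
    return q


class TestBH:
    def test_worked_example(self):
        q = bh_qvalues(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, 0.04)

    def test_all_ones(self):
        q = bh_qvalues(np.ones(5))
        assert np.all(q == 1.0)

    def test_single_test_strict_boundary(self):
        hits = [
            MotifHit("m", "g", "s", "intron", 0, 5, "+", 1.0, p) for p in (0.049,)
        ]
        kept = bh_filter(hits, alpha=0.05)
        assert len(kept) == 1 and kept[0].q_value == pytest.approx(0.049)
        hits = [MotifHit("m", "g", "s", "intron", 0, 5, "+", 1.0, 0.05)]
        assert bh_filter(hits, alpha=0.05) == []

    def test_matches_independent_oracle_exactly(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            p = rng.random(int(rng.integers(1, 40)))
            assert list(bh_qvalues(p)) == oracle_bh(list(p))

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(8)
        p = rng.random(500)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(bh_qvalues(p), q_sm, atol=1e-12)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    def test_qvalues_monotone_in_pvalue_rank(self, pvals):
        p = np.array(pvals)
        q = bh_qvalues(p)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-15)
        # retained set shrinks as alpha decreases
        assert np.sum(q < 0.01) <= np.sum(q < 0.05)

    def test_false_positive_batches_near_alpha_under_null(self):
        """Fraction of pure-background batches with any retained hit ~ alpha."""
        rng = np.random.default_rng(9)
        pwm = random_pwm(rng, 8, sharp=10)
        lom = build_log_odds(pwm, UNIFORM)
        dist = null_distribution(lom, UNIFORM)
        false_batches = 0
        n_sims = 50
        for _ in range(n_sims):
            win = make_window(random_seq(rng, 500))
            hits = scan_window(win, _regions(500), lom, dist)
            kept = bh_filter(hits, alpha=0.05)
            false_batches += bool(kept)
        assert false_batches / n_sims <= 0.05 + 0.05
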