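"""Presence bookkeeping, intersection categories, clade-specific calls."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from grassreg.core_io import GrassregError
from grassreg.scan import MotifHit
from grassreg.sets import (
    StudyDesign,
    build_presence,
    clade_specific,
    cluster_positions,
    shared_motifs,
    upset_partition,
)

GENE_SETS = ["SBPase", "FBPase", "PRK", "GAPDHB"]
SPECIES = ["bop1", "bop2", "bop3", "pacC3", "pac1", "pac2", "pac3", "pac4"]
PHOTO = {sp: ("C4" if sp.startswith("pac") and sp != "pacC3" else "C3") for sp in SPECIES}


def design():
    gene_to_set = {f"{g}_{s}": g for g in GENE_SETS for s in SPECIES}
    return StudyDesign(
        gene_sets=GENE_SETS,
        species=SPECIES,
        gene_to_set=gene_to_set,
        gene_to_species={f"{g}_{s}": s for g in GENE_SETS for s in SPECIES},
    )


def hit(motif, gene_set, sp, start=0):
    return MotifHit(
        motif_id=motif,
        gene_id=f"{gene_set}_{sp}",
        species_id=sp,
        feature_class="upstream_intergenic",
        start=start,
        end=start + 10,
        strand="+",
        score=1.0,
        p_value=1e-6,
        q_value=1e-3,
    )


def matrix_from_presence(present, motifs=("mA",)):
    """present: {(motif, gene_set, species): bool}"""
    hits = [
        hit(m, g, s)
        for (m, g, s), v in present.items()
        if v
    ]
    return build_presence(hits, design(), list(motifs))


class TestBuildPresence:
    def test_single_hit_sets_single_cell(self):
        m = build_presence([hit("mA", "SBPase", "bop1")], design(), ["mA"])
        assert m.is_present("mA", "SBPase", "bop1")
        assert m.present.sum() == 1

    def test_duplicate_hits_idempotent(self):
        hits = [hit("mA", "SBPase", "bop1", start=i) for i in range(5)]
        m = build_presence(hits, design(), ["mA"])
        assert m.present.sum() == 1

    def test_unknown_gene_fatal(self):
        bad = hit("mA", "SBPase", "bop1")
        bad.gene_id = "nonexistent"
        with pytest.raises(GrassregError):
            build_presence([bad], design(), ["mA"])

    def test_matches_bruteforce_existence_check(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            hits = [
                hit(
                    f"m{rng.integers(0, 4)}",
                    GENE_SETS[rng.integers(0, 4)],
                    SPECIES[rng.integers(0, 8)],
                )
                for _ in range(int(rng.integers(0, 30)))
            ]
            motifs = [f"m{i}" for i in range(4)]
            m = build_presence(hits, design(), motifs)
            for mo in motifs:
                for g in GENE_SETS:
                    for s in SPECIES:
                        expected = any(
                            h.motif_id == mo
                            and h.gene_id == f"{g}_{s}"
                            for h in hits
                        )
                        assert m.is_present(mo, g, s) == expected


class TestShared:
    def test_all_species_shared(self):
        m = build_presence(
            [hit("mA", "PRK", s) for s in SPECIES], design(), ["mA"]
        )
        assert shared_motifs(m, "PRK") == {"mA"}

    def test_seven_of_eight_not_shared(self):
        m = build_presence(
            [hit("mA", "PRK", s) for s in SPECIES[:-1]], design(), ["mA"]
        )
        assert shared_motifs(m, "PRK") == set()

    def test_missing_ortholog_excluded_from_quantifier(self):
        d = design()
        d.missing.add(("PRK", "pac4"))
        m = build_presence(
            [hit("mA", "PRK", s) for s in SPECIES[:-1]], d, ["mA"]
        )
        assert shared_motifs(m, "PRK") == {"mA"}

    def test_matches_bruteforce_forall(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            present = {
                ("mA", g, s): bool(rng.random() < 0.7)
                for g in GENE_SETS
                for s in SPECIES
            }
            m = matrix_from_presence(present)
            for g in GENE_SETS:
                expected = all(present[("mA", g, s)] for s in SPECIES)
                assert ("mA" in shared_motifs(m, g)) == expected


class TestUpset:
    def test_full_subset_labelled_common_cbb(self):
        shared = {g: {"VRN1_like"} for g in GENE_SETS}
        cats = upset_partition(shared, gene_set_order=GENE_SETS)
        assert len(cats) == 1
        assert cats[0].label == "common_CBB"
        assert cats[0].member_motifs == {"VRN1_like"}

    def test_sfg_label(self):
        shared = {
            "SBPase": {"mX"},
            "FBPase": {"mX"},
            "GAPDHB": {"mX"},
            "PRK": set(),
        }
        cats = upset_partition(shared, gene_set_order=GENE_SETS)
        assert cats[0].label == "common_SFG"

    def test_singleton_label(self):
        shared = {g: set() for g in GENE_SETS}
        shared["PRK"] = {"m1", "m2"}
        cats = upset_partition(shared, gene_set_order=GENE_SETS)
        assert cats[0].label == "common_PRK"
        assert cats[0].member_motifs == {"m1", "m2"}

    def test_partition_law_against_bruteforce(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            motifs = [f"m{i}" for i in range(int(rng.integers(1, 12)))]
            shared = {
                g: {m for m in motifs if rng.random() < 0.5} for g in GENE_SETS
            }
            cats = upset_partition(shared, gene_set_order=GENE_SETS)
            # disjoint + coverage
            union = set().union(*(c.member_motifs for c in cats)) if cats else set()
            assert union == set().union(*shared.values())
            total = sum(len(c.member_motifs) for c in cats)
            assert total == len(union)
            # each motif's category is its exact membership subset
            for c in cats:
                for m in c.member_motifs:
                    assert c.gene_subset == frozenset(
                        g for g in GENE_SETS if m in shared[g]
                    )


class TestCladeSpecific:
    def test_c4_specific_call(self):
        hits = [hit("mA", "SBPase", "pac1"), hit("mA", "SBPase", "pac3")]
        m = build_presence(hits, design(), ["mA"])
        calls = clade_specific(m, "SBPase", PHOTO)
        assert len(calls) == 1
        c = calls[0]
        assert c.direction == "C4_specific"
        assert c.supporting_species == {"pac1", "pac3"}

    def test_single_c3_hit_blocks_call(self):
        hits = [hit("mA", "SBPase", "pac1"), hit("mA", "SBPase", "bop2")]
        m = build_presence(hits, design(), ["mA"])
        assert clade_specific(m, "SBPase", PHOTO) == []

    def test_c3_specific_direction(self):
        hits = [hit("mA", "PRK", s) for s in SPECIES if PHOTO[s] == "C3"]
        m = build_presence(hits, design(), ["mA"])
        calls = clade_specific(m, "PRK", PHOTO)
        assert [c.direction for c in calls] == ["C3_specific"]

    def test_single_clade_study_fatal(self):
        m = build_presence([hit("mA", "PRK", "bop1")], design(), ["mA"])
        with pytest.raises(GrassregError):
            clade_specific(m, "PRK", {sp: "C3" for sp in SPECIES})

    def test_direction_exclusivity_and_antimonotonicity(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            present = {
                ("mA", g, s): bool(rng.random() < 0.4)
                for g in GENE_SETS
                for s in SPECIES
            }
            m = matrix_from_presence(present)
            for g in GENE_SETS:
                dirs = [c.direction for c in clade_specific(m, g, PHOTO)]
                assert len(dirs) == len(set(dirs))  # never both directions
            # adding a hit never creates a C4 call blocked by a C3 species
            g = "SBPase"
            before = {
                c.motif_id
                for c in clade_specific(m, g, PHOTO)
                if c.direction == "C4_specific"
            }
            present2 = dict(present)
            present2[("mA", g, "bop1")] = True
            m2 = matrix_from_presence(present2)
            after = {
                c.motif_id
                for c in clade_specific(m2, g, PHOTO)
                if c.direction == "C4_specific"
            }
            assert after <= before


class TestClusters:
    def test_worked_example(self):
        hits = [
            MotifHit("m", "g", "s", "u", s, e, "+", 0, 1e-3)
            for s, e in ((100, 110), (120, 130), (500, 510))
        ]
        clusters = cluster_positions(hits, max_gap=50)
        assert [c.interval for c in clusters] == [(100, 130), (500, 510)]
        assert len(clusters[0].member_hits) == 2

    def test_single_hit_single_cluster(self):
        hits = [MotifHit("m", "g", "s", "u", 7, 17, "+", 0, 1e-3)]
        assert [c.interval for c in cluster_positions(hits)] == [(7, 17)]

    def test_no_hits(self):
        assert cluster_positions([]) == []

    @given(
        st.lists(
            st.tuples(st.integers(0, 500), st.integers(1, 20)), max_size=20
        )
    )
    def test_gap_invariant(self, spans):
        hits = [
            MotifHit("m", "g", "s", "u", s, s + w, "+", 0, 1e-3)
            for s, w in spans
        ]
        clusters = cluster_positions(hits, max_gap=30)
        covered = sum(len(c.member_hits) for c in clusters)
        assert covered == len(hits)
        for c in clusters:
            hs = sorted(c.member_hits, key=lambda h: h.start)
            ends = np.maximum.accumulate([h.end for h in hs])
            for k in range(1, len(hs)):
                assert hs[k].start - ends[k - 1] <= 30
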