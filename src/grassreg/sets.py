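"""Presence/absence bookkeeping of retained motif hits across the study.

A motif is *present* for a (motif, gene set, species) triple when at least one
q-filtered hit exists in that species' ortholog of the gene set; orthologs
that were never scanned are *missing*, which is distinct from absent and is
excluded from every universal quantifier.  On top of presence we compute:

- shared motifs: present in every (non-missing) species of a gene set;
- UpSet-style intersection categories: each shared motif is assigned to the
  exact subset of gene sets sharing it (disjoint partition);
- clade-specific calls: C4-specific = absent from every C3 ortholog and
  present in at least one C4 species (symmetrically C3-specific) — the
  absence-based rule accommodates the independent origins of C4;
- positional clusters of hits along a window (single-linkage chaining).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .core_io import GrassregError, Interval
from .scan import MotifHit


@dataclass
class StudyDesign:
    """Gene sets x species grid plus the gene -> gene-set mapping."""

    gene_sets: list[str]
    species: list[str]
    gene_to_set: dict[str, str]  # gene_id -> gene_set_id
    gene_to_species: dict[str, str] = field(default_factory=dict)
    missing: set[tuple[str, str]] = field(default_factory=set)  # (gene_set, sp)


@dataclass
class PresenceMatrix:
    motifs: list[str]
    gene_sets: list[str]
    species: list[str]
    present: np.ndarray  # bool (n_motifs, n_gene_sets, n_species)
    missing: np.ndarray  # bool (n_gene_sets, n_species)
    provenance: str = ""

    def _mi(self, motif: str) -> int:
        return self.motifs.index(motif)

    def is_present(self, motif: str, gene_set: str, species: str) -> bool:
        return bool(
            self.present[
                self._mi(motif),
                self.gene_sets.index(gene_set),
                self.species.index(species),
            ]
        )


@dataclass
class IntersectionCategory:
    gene_subset: frozenset
    member_motifs: set
    label: str


@dataclass
class CladeSpecificCall:
    motif_id: str
    gene_set_id: str
    direction: str  # "C4_specific" | "C3_specific"
    supporting_species: set


@dataclass
class PositionCluster:
    gene_id: str
    species_id: str
    interval: Interval
    member_hits: list


def build_presence(
    hits: Sequence[MotifHit],
    design: StudyDesign,
    motif_ids: Iterable[str],
    provenance: str = "",
) -> PresenceMatrix:
    """Boolean presence per (motif, gene set, species) from retained hits."""
    motifs = list(motif_ids)
    gi = {g: k for k, g in enumerate(design.gene_sets)}
    si = {s: k for k, s in enumerate(design.species)}
    mi = {m: k for k, m in enumerate(motifs)}
    present = np.zeros((len(motifs), len(gi), len(si)), dtype=bool)
    missing = np.zeros((len(gi), len(si)), dtype=bool)
    for gs, sp in design.missing:
        missing[gi[gs], si[sp]] = True
    for h in hits:
        if h.gene_id not in design.gene_to_set:
            raise GrassregError(f"hit references unknown gene {h.gene_id!r}")
        gs = design.gene_to_set[h.gene_id]
        if gs not in gi:
            raise GrassregError(f"hit references unknown gene set {gs!r}")
        if h.species_id not in si:
            raise GrassregError(f"hit references unknown species {h.species_id!r}")
        if h.motif_id in mi:
            present[mi[h.motif_id], gi[gs], si[h.species_id]] = True
    return PresenceMatrix(
        motifs=motifs,
        gene_sets=list(design.gene_sets),
        species=list(design.species),
        present=present,
        missing=missing,
        provenance=provenance,
    )


def shared_motifs(
    m: PresenceMatrix, gene_set: str, quorum: float = 1.0
) -> set[str]:
    """Motifs present in every non-missing species ortholog of ``gene_set``.

    ``quorum`` relaxes the universal quantifier to a fraction of the
    non-missing species (1.0 = all, the default reading).
    """
    g = m.gene_sets.index(gene_set)
    scanned = ~m.missing[g]
    n = int(scanned.sum())
    if n == 0:
        raise GrassregError(f"gene set {gene_set!r} has no scanned species")
    counts = m.present[:, g, scanned].sum(axis=1)
    return {mo for mo, c in zip(m.motifs, counts) if c >= quorum * n}


def upset_partition(
    shared: dict[str, set[str]],
    gene_set_order: Sequence[str] | None = None,
    full_label: str = "CBB",
) -> list[IntersectionCategory]:
    """Disjoint intersection categories of the shared-motif sets.

    Every motif shared in at least one gene set is assigned to exactly one
    category: the exact subset of gene sets sharing it.  Labels follow the
    study's convention: the full subset is ``common_<full_label>``, singletons
    ``common_<gene set>``, other subsets ``common_`` plus the gene sets'
    initials in canonical order.
    """
    order = list(gene_set_order) if gene_set_order else sorted(shared)
    by_subset: dict[frozenset, set] = {}
    for motif in set().union(*shared.values()) if shared else set():
        subset = frozenset(g for g in order if motif in shared.get(g, set()))
        by_subset.setdefault(subset, set()).add(motif)
    cats = []
    for subset, members in by_subset.items():
        ordered = [g for g in order if g in subset]
        if len(subset) == len(order):
            label = f"common_{full_label}"
        elif len(subset) == 1:
            label = f"common_{ordered[0]}"
        else:
            label = "common_" + "".join(g[0].upper() for g in ordered)
        cats.append(
            IntersectionCategory(gene_subset=subset, member_motifs=members, label=label)
        )
    cats.sort(key=lambda c: (-len(c.gene_subset), c.label))
    return cats


def clade_specific(
    m: PresenceMatrix,
    gene_set: str,
    photo_of: dict[str, str],
    presence_quorum: int = 1,
) -> list[CladeSpecificCall]:
    """C4-specific (absent from all C3 orthologs, present in >= quorum C4
    species) and C3-specific calls for one gene set."""
    types = {photo_of.get(sp) for sp in m.species}
    if not {"C3", "C4"} <= types:
        raise GrassregError("study set must contain both C3 and C4 species")
    g = m.gene_sets.index(gene_set)
    scanned = ~m.missing[g]
    calls = []
    for direction, focal, other in (("C4_specific", "C4", "C3"), ("C3_specific", "C3", "C4")):
        focal_idx = [
            k for k, sp in enumerate(m.species) if photo_of[sp] == focal and scanned[k]
        ]
        other_idx = [
            k for k, sp in enumerate(m.species) if photo_of[sp] == other and scanned[k]
        ]
        if not focal_idx or not other_idx:
            continue
        for mk, motif in enumerate(m.motifs):
            if m.present[mk, g, other_idx].any():
                continue
            supp = [m.species[k] for k in focal_idx if m.present[mk, g, k]]
            if len(supp) >= presence_quorum:
                calls.append(
                    CladeSpecificCall(
                        motif_id=motif,
                        gene_set_id=gene_set,
                        direction=direction,
                        supporting_species=set(supp),
                    )
                )
    calls.sort(key=lambda c: (c.direction, c.motif_id))
    return calls


def cluster_positions(
    hits: Sequence[MotifHit], max_gap: int = 50
) -> list[PositionCluster]:
    """Single-linkage chaining of hits along one gene window.

    Consecutive hits (sorted by start) whose gap is at most ``max_gap`` join
    the same cluster.  Exploratory output; the clustering distance is a
    package convention, not a study-fixed parameter.
    """
    hs = sorted(hits, key=lambda h: (h.start, h.end))
    clusters: list[PositionCluster] = []
    for h in hs:
        if clusters and h.start - clusters[-1].interval[1] <= max_gap:
            cur = clusters[-1]
            cur.member_hits.append(h)
            cur.interval = (cur.interval[0], max(cur.interval[1], h.end))
        else:
            clusters.append(
                PositionCluster(
                    gene_id=h.gene_id,
                    species_id=h.species_id,
                    interval=(h.start, h.end),
                    member_hits=[h],
                )
            )
    return clusters


def presence_to_tsv(m: PresenceMatrix) -> str:
    rows = ["motif_id\tgene_set\tspecies\tstatus"]
    for mk, motif in enumerate(m.motifs):
        for g, gs in enumerate(m.gene_sets):
            for s, sp in enumerate(m.species):
                status = (
                    "missing"
                    if m.missing[g, s]
                    else ("present" if m.present[mk, g, s] else "absent")
                )
                rows.append(f"{motif}\t{gs}\t{sp}\t{status}")
    return "\n".join(rows) + "\n"


def membership_table(
    shared: dict[str, set[str]], gene_set_order: Sequence[str]
) -> str:
    """UpSet-ready boolean membership table (motif x gene set)."""
    motifs = sorted(set().union(*shared.values())) if shared else []
    rows = ["motif_id\t" + "\t".join(gene_set_order)]
    for mo in motifs:
        flags = "\t".join(
            "1" if mo in shared.get(g, set()) else "0" for g in gene_set_order
        )
        rows.append(f"{mo}\t{flags}")
    return "\n".join(rows) + "\n"
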