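"""Pairwise alignment of orthologous gene windows and CNS calling.

A conserved non-coding sequence (CNS) is a non-coding stretch of the reference
window whose windowed alignment identity exceeds 70% over 50 bp.  Windows of
orthologous genes are globally aligned (affine gaps, exact DP), a sliding
50-column identity profile is computed (gap columns count as mismatches), and
qualifying stretches are projected onto reference coordinates, merged, and
intersected with the non-coding regulatory regions.

Each CNS is then assigned a conservation scope from per-species presence
flags: present in every species (``all_species``), in exactly one clade
(``clade_restricted:BOP`` / ``clade_restricted:PACMAD``), or ``partial``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _align
from .core_io import GeneWindow, GrassregError, Interval, RegulatoryRegionSet

GAP = "-"

#: paper-derived CNS criterion
CNS_WINDOW = 50
CNS_IDENTITY = 0.70


@dataclass(frozen=True)
class AlignScoring:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -4.0
    gap_extend: float = -0.5


@dataclass
class PairwiseAlignment:
    ref_gene_id: str
    query_gene_id: str
    aligned_ref: str
    aligned_query: str
    score: float
    ref_col_map: np.ndarray  # per column: ref window coordinate, or -1 at gaps

    def __post_init__(self) -> None:
        if len(self.aligned_ref) != len(self.aligned_query):
            raise GrassregError("aligned strings differ in length")

    @property
    def ncols(self) -> int:
        return len(self.aligned_ref)

    def match_columns(self) -> np.ndarray:
        """Boolean per column: both bases present, equal, and unambiguous."""
        r = np.frombuffer(self.aligned_ref.encode(), dtype=np.uint8)
        q = np.frombuffer(self.aligned_query.encode(), dtype=np.uint8)
        ok = (r == q) & (r != ord(GAP)) & (r != ord("N"))
        return ok


@dataclass
class IdentityProfile:
    window_size: int
    step: int
    values: np.ndarray  # identity fraction per starting alignment column

    def to_tsv(self) -> str:
        """Plain dump: starting alignment column and identity fraction."""
        rows = ["start_column\tidentity"]
        for k, v in enumerate(self.values):
            rows.append(f"{k * self.step}\t{v:.4f}")
        return "\n".join(rows) + "\n"


@dataclass
class CNSInterval:
    ref_gene_id: str
    interval: Interval  # ref window coordinates
    mean_identity: float
    feature_class: str
    supporting_species: set[str] = field(default_factory=set)
    scope: str | None = None


def _encode(seq: str) -> np.ndarray:
    table = np.full(256, 4, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        table[ord(b)] = i
    return table[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]


def align_windows(
    ref: GeneWindow | str,
    query: GeneWindow | str,
    scoring: AlignScoring = AlignScoring(),
    max_cells: float = 25e6,
) -> PairwiseAlignment:
    """Optimal global alignment of two windows under affine-gap scoring.

    Deterministic tie-breaking: diagonal, then up (gap in query), then left.
    Refuses sequence pairs whose DP matrix would exceed ``max_cells`` cells.
    """
    ref_id = ref.gene_id if isinstance(ref, GeneWindow) else "ref"
    query_id = query.gene_id if isinstance(query, GeneWindow) else "query"
    a = ref.sequence if isinstance(ref, GeneWindow) else ref
    b = query.sequence if isinstance(query, GeneWindow) else query
    if not a or not b:
        raise GrassregError("cannot align an empty sequence")
    if len(a) * len(b) > max_cells:
        raise GrassregError(
            f"alignment of {len(a)} x {len(b)} exceeds {max_cells:g} DP cells; "
            "raise max_cells or use a banded aligner"
        )
    ac, bc = _encode(a), _encode(b)
    score, end_state, pM, pX, pY = _align.gotoh_fill(
        ac, bc, scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend
    )
    moves = _align.traceback(len(a), len(b), end_state, pM, pX, pY)
    ar, aq, colmap = [], [], []
    i = j = 0
    for mv in moves:
        if mv == _align.M_STATE:
            ar.append(a[i])
            aq.append(b[j])
            colmap.append(i)
            i += 1
            j += 1
        elif mv == _align.X_STATE:
            ar.append(a[i])
            aq.append(GAP)
            colmap.append(i)
            i += 1
        else:
            ar.append(GAP)
            aq.append(b[j])
            colmap.append(-1)
            j += 1
    return PairwiseAlignment(
        ref_gene_id=ref_id,
        query_gene_id=query_id,
        aligned_ref="".join(ar),
        aligned_query="".join(aq),
        score=float(score),
        ref_col_map=np.asarray(colmap, dtype=np.int64),
    )


def identity_profile(
    aln: PairwiseAlignment, window_size: int = CNS_WINDOW, step: int = 1
) -> IdentityProfile:
    """Sliding-window identity over alignment columns (gaps = mismatch)."""
    if window_size < 1:
        raise GrassregError("window_size must be >= 1")
    if step < 1:
        raise GrassregError("step must be >= 1")
    match = aln.match_columns().astype(np.float64)
    if match.size < window_size:
        values = np.empty(0)
    else:
        csum = np.concatenate(([0.0], np.cumsum(match)))
        values = (csum[window_size:] - csum[:-window_size]) / window_size
        values = values[::step]
    return IdentityProfile(window_size=window_size, step=step, values=values)


def _merge_positions(positions: np.ndarray) -> list[Interval]:
    """Merge sorted integer positions into maximal runs of consecutive ints."""
    if positions.size == 0:
        return []
    breaks = np.nonzero(np.diff(positions) > 1)[0]
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [positions.size - 1]))
    return [(int(positions[s]), int(positions[e]) + 1) for s, e in zip(starts, ends)]


def call_cns(
    profile: IdentityProfile,
    aln: PairwiseAlignment,
    regions: RegulatoryRegionSet,
    threshold: float = CNS_IDENTITY,
    project: str = "center",
) -> list[CNSInterval]:
    """Call CNS intervals on the reference window from one pairwise alignment.

    ``project`` controls how qualifying identity windows mark alignment
    columns as conserved: ``"center"`` marks the central column of each
    qualifying window (the conservation-curve reading of the VISTA-style
    criterion; default) while ``"span"`` marks all columns of each qualifying
    window.  Marked columns are projected through ``ref_col_map``, merged,
    intersected with the non-coding regulatory regions, and segments of at
    least ``window_size`` bases with mean identity above the threshold are
    emitted.
    """
    if project not in ("center", "span"):
        raise GrassregError(f"unknown projection mode {project!r}")
    w = profile.window_size
    ncols = aln.ncols
    conserved = np.zeros(ncols, dtype=bool)
    qualifying = np.nonzero(profile.values > threshold)[0] * profile.step
    if qualifying.size:
        if project == "center":
            conserved[qualifying + w // 2] = True
        else:
            for c in qualifying:
                conserved[c : c + w] = True

    refpos = aln.ref_col_map[conserved]
    refpos = np.unique(refpos[refpos >= 0])
    merged = _merge_positions(refpos)

    match = aln.match_columns()
    # first/last alignment column per ref coordinate, for identity recompute
    out: list[CNSInterval] = []
    ref_cols = np.nonzero(aln.ref_col_map >= 0)[0]
    ref_of_col = aln.ref_col_map[ref_cols]
    for run in merged:
        for (rs, re_), fclass in regions.regions:
            s, e = max(run[0], rs), min(run[1], re_)
            if e - s < w:
                continue
            inside = ref_cols[(ref_of_col >= s) & (ref_of_col < e)]
            c0, c1 = int(inside[0]), int(inside[-1]) + 1
            ident = float(match[c0:c1].mean())
            if ident > threshold:
                out.append(
                    CNSInterval(
                        ref_gene_id=aln.ref_gene_id,
                        interval=(s, e),
                        mean_identity=ident,
                        feature_class=fclass,
                    )
                )
    out.sort(key=lambda c: c.interval)
    return out


def conservation_scope(
    cns: CNSInterval,
    presence: dict[str, bool],
    clade_of: dict[str, str],
) -> CNSInterval:
    """Set the conservation scope of a CNS from per-species presence flags.

    ``presence`` must cover every species of the study set (the reference
    included); ``clade_of`` maps species to "BOP"/"PACMAD".
    """
    if not presence:
        raise GrassregError("empty presence flag set")
    missing = set(presence) - set(clade_of)
    if missing:
        raise GrassregError(f"species without clade label: {sorted(missing)}")
    cns.supporting_species = {sp for sp, p in presence.items() if p}
    clades = sorted(set(clade_of[sp] for sp in presence))
    if all(presence.values()):
        cns.scope = "all_species"
        return cns
    for clade in clades:
        members = [sp for sp in presence if clade_of[sp] == clade]
        others = [sp for sp in presence if clade_of[sp] != clade]
        if members and others and all(presence[sp] for sp in members) and not any(
            presence[sp] for sp in others
        ):
            cns.scope = f"clade_restricted:{clade}"
            return cns
    cns.scope = "partial"
    return cns


def cns_to_gff3(cns_list: list[CNSInterval], contig_id: str = ".") -> str:
    """CNS intervals as GFF3 ``conserved_region`` features (window coords)."""
    lines = ["##gff-version 3"]
    for k, c in enumerate(cns_list, 1):
        attrs = f"ID=cns{k};mean_identity={c.mean_identity:.4f}"
        if c.scope:
            attrs += f";scope={c.scope}"
        lines.append(
            "\t".join(
                [
                    contig_id if contig_id != "." else c.ref_gene_id,
                    "grassreg",
                    "conserved_region",
                    str(c.interval[0] + 1),
                    str(c.interval[1]),
                    f"{c.mean_identity:.4f}",
                    "+",
                    ".",
                    attrs,
                ]
            )
        )
    return "\n".join(lines) + "\n"
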