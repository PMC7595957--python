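"""Genome/annotation ingestion and per-gene regulatory window extraction.

The comparative analysis operates on fixed gene-relative windows: 2 kb of
sequence upstream of the transcription start site (or the start codon when no
5'UTR is annotated) through the gene body to 1 kb downstream of the end of the
3'UTR (or the stop codon).  Everything downstream of this module works in
window coordinates: 0-based, half-open, strand-normalized so the window always
reads 5'->3' of the gene.

Putative regulatory sequence is the non-coding portion of the window:
upstream/downstream intergenic flanks, UTRs, and introns.  Coding bases are
excluded everywhere.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

Interval = tuple[int, int]

FEATURE_CLASSES = (
    "upstream_intergenic",
    "utr5",
    "intron",
    "utr3",
    "downstream_intergenic",
)

#: default window geometry (bases)
DEFAULT_UPSTREAM = 2000
DEFAULT_DOWNSTREAM = 1000


class GrassregError(ValueError):
    """Fatal input or contract violation."""


def _check_sorted_disjoint(ivs: Sequence[Interval], what: str) -> None:
    for a, b in zip(ivs, ivs[1:]):
        if a[1] > b[0]:
            raise GrassregError(f"{what} intervals overlap: {a} vs {b}")


def _contained(inner: Interval, outers: Sequence[Interval]) -> bool:
    return any(o[0] <= inner[0] and inner[1] <= o[1] for o in outers)


@dataclass
class GeneModel:
    """One representative transcript of a gene, in genomic coordinates."""

    gene_id: str
    species_id: str
    photo_type: str  # "C3" | "C4"
    clade: str  # "BOP" | "PACMAD"
    contig_id: str
    strand: str  # "+" | "-"
    tss: int | None  # genomic position of the TSS (None if no 5'UTR annotated)
    cds_intervals: list[Interval]
    exon_intervals: list[Interval]
    utr5_intervals: list[Interval] = field(default_factory=list)
    utr3_intervals: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise GrassregError(f"bad strand {self.strand!r} for {self.gene_id}")
        self.cds_intervals = sorted(self.cds_intervals)
        self.exon_intervals = sorted(self.exon_intervals)
        self.utr5_intervals = sorted(self.utr5_intervals)
        self.utr3_intervals = sorted(self.utr3_intervals)
        _check_sorted_disjoint(self.cds_intervals, f"{self.gene_id} CDS")
        for c in self.cds_intervals:
            if not _contained(c, self.exon_intervals):
                raise GrassregError(
                    f"{self.gene_id}: CDS {c} not contained in any exon"
                )
        for u in self.utr5_intervals + self.utr3_intervals:
            for c in self.cds_intervals:
                if u[0] < c[1] and c[0] < u[1]:
                    raise GrassregError(
                        f"{self.gene_id}: UTR {u} overlaps CDS {c}"
                    )


@dataclass
class GeneWindow:
    """A strand-normalized analysis window around one gene.

    ``sequence[anchor_offset]`` is the anchor base (TSS or start codon).  All
    feature intervals are in window coordinates.  ``genome_span`` records the
    genomic slice the window was cut from, so coordinates can be mapped back.
    """

    gene_id: str
    species_id: str
    sequence: str
    anchor_offset: int
    upstream_len: int
    downstream_len: int
    cds: list[Interval]
    exons: list[Interval]
    utr5: list[Interval]
    utr3: list[Interval]
    contig_id: str = ""
    strand: str = "+"
    genome_span: Interval = (0, 0)

    def __post_init__(self) -> None:
        L = len(self.sequence)
        for iv in self.cds + self.exons + self.utr5 + self.utr3:
            if not (0 <= iv[0] <= iv[1] <= L):
                raise GrassregError(
                    f"{self.gene_id}: window feature {iv} outside [0,{L})"
                )

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.sequence)

    def to_genome(self, iv: Interval) -> Interval:
        """Map a window interval back to genomic coordinates."""
        g0, g1 = self.genome_span
        if self.strand == "+":
            return (g0 + iv[0], g0 + iv[1])
        return (g1 - iv[1], g1 - iv[0])


@dataclass
class RegulatoryRegionSet:
    """The non-coding feature intervals of one window, labelled by class."""

    gene_id: str
    regions: list[tuple[Interval, str]]

    def of_class(self, feature_class: str) -> list[Interval]:
        return [iv for iv, c in self.regions if c == feature_class]

    def class_at(self, pos: int) -> str | None:
        for (s, e), c in self.regions:
            if s <= pos < e:
                return c
        return None


def read_clade_table(stream) -> dict[str, tuple[str, str]]:
    """Read the 3-column species table: species_id, photo_type, clade."""
    table = {}
    for line in stream:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise GrassregError(f"clade table row needs 3 columns: {line!r}")
        sp, photo, clade = parts
        if photo not in ("C3", "C4") or clade not in ("BOP", "PACMAD"):
            raise GrassregError(f"bad clade table row: {line!r}")
        table[sp] = (photo, clade)
    return table


def _validate_gff3_lines(text: str) -> None:
    for i, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        if len(line.split("\t")) != 9:
            raise GrassregError(f"malformed GFF3 line {i}: {line!r}")


def read_fasta(stream) -> dict[str, str]:
    """Multi-record FASTA -> {contig_id: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(stream, "fasta")}


def read_annotation(
    gff3,
    fasta,
    clade_table: dict[str, tuple[str, str]],
    species_id: str,
    gene_ids: Iterable[str] | None = None,
) -> list[GeneModel]:
    """Build one :class:`GeneModel` per gene from GFF3 + FASTA.

    One representative transcript per gene is used: the longest mRNA.  Genes
    without an annotated five_prime_UTR get ``tss=None`` (the window anchor
    later falls back to the start codon).  GFF3 coordinates (1-based closed)
    are converted to the internal 0-based half-open convention.
    """
    if species_id not in clade_table:
        raise GrassregError(f"species {species_id!r} not in clade table")
    photo, clade = clade_table[species_id]

    gff_text = gff3.read() if hasattr(gff3, "read") else str(gff3)
    _validate_gff3_lines(gff_text)
    try:
        db = gffutils.create_db(
            gff_text,
            dbfn=":memory:",
            from_string=True,
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # pragma: no cover - gffutils internals
        raise GrassregError(f"failed to parse GFF3: {exc}") from exc

    contigs = read_fasta(fasta) if not isinstance(fasta, dict) else fasta

    wanted = list(gene_ids) if gene_ids is not None else [
        g.id for g in db.features_of_type("gene")
    ]
    models = []
    for gid in wanted:
        try:
            gene = db[gid]
        except gffutils.FeatureNotFoundError:
            raise GrassregError(f"gene {gid!r} absent from GFF3") from None
        if gene.seqid not in contigs:
            raise GrassregError(
                f"contig {gene.seqid!r} (gene {gid}) missing from FASTA"
            )
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if not mrnas:
            raise GrassregError(f"gene {gid!r} has no mRNA feature")
        rep = max(mrnas, key=lambda m: (m.end - m.start, m.id))

        def ivs(ftype: str) -> list[Interval]:
            return sorted(
                (f.start - 1, f.end) for f in db.children(rep, featuretype=ftype)
            )

        exons = ivs("exon")
        cds = ivs("CDS")
        utr5 = ivs("five_prime_UTR")
        utr3 = ivs("three_prime_UTR")
        if not exons:
            exons = sorted(cds + utr5 + utr3)
        tss: int | None = None
        if utr5:
            tss = rep.start - 1 if gene.strand == "+" else rep.end - 1
        models.append(
            GeneModel(
                gene_id=gid,
                species_id=species_id,
                photo_type=photo,
                clade=clade,
                contig_id=gene.seqid,
                strand=gene.strand,
                tss=tss,
                cds_intervals=cds,
                exon_intervals=exons,
                utr5_intervals=utr5,
                utr3_intervals=utr3,
            )
        )
    return models


def _anchor_genomic(model: GeneModel) -> int:
    """Genomic coordinate of the window anchor (first transcribed/coding base).

    Plus strand: the 0-based position itself.  Minus strand: the 0-based
    position of the biological first base (the highest coordinate).
    """
    if model.tss is not None:
        return model.tss
    if not model.cds_intervals:
        raise GrassregError(
            f"{model.gene_id}: no TSS and no CDS; window anchor undeterminable"
        )
    if model.strand == "+":
        return model.cds_intervals[0][0]
    return model.cds_intervals[-1][1] - 1


def _downstream_anchor_genomic(model: GeneModel) -> int:
    """Genomic coordinate one past the biological 3' end (strand-aware)."""
    feats = model.utr3_intervals or model.cds_intervals
    if not feats:
        raise GrassregError(f"{model.gene_id}: no 3'UTR and no CDS")
    if model.strand == "+":
        return max(e for _, e in feats)
    return min(s for s, _ in feats)  # exclusive in minus-strand sense


def extract_gene_window(
    model: GeneModel,
    genome: dict[str, str] | str,
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
) -> GeneWindow:
    """Cut the gene-relative analysis window out of the genome.

    The window is truncated (never padded) at contig edges; the realized
    ``upstream_len``/``downstream_len`` are recorded.  Minus-strand windows are
    reverse-complemented so they read 5'->3' of the gene.
    """
    seq = genome[model.contig_id] if isinstance(genome, dict) else genome
    n = len(seq)
    anchor = _anchor_genomic(model)
    down = _downstream_anchor_genomic(model)

    if model.strand == "+":
        g0 = max(0, anchor - upstream)
        g1 = min(n, down + downstream)
        upstream_len = anchor - g0
        downstream_len = g1 - down
        window_seq = seq[g0:g1]

        def remap(iv: Interval) -> Interval:
            return (iv[0] - g0, iv[1] - g0)

    else:
        g1 = min(n, anchor + 1 + upstream)
        g0 = max(0, down - downstream)
        upstream_len = g1 - (anchor + 1)
        downstream_len = down - g0
        window_seq = str(Seq(seq[g0:g1]).reverse_complement())

        def remap(iv: Interval) -> Interval:
            return (g1 - iv[1], g1 - iv[0])

    return GeneWindow(
        gene_id=model.gene_id,
        species_id=model.species_id,
        sequence=window_seq,
        anchor_offset=upstream_len,
        upstream_len=upstream_len,
        downstream_len=downstream_len,
        cds=sorted(remap(iv) for iv in model.cds_intervals),
        exons=sorted(remap(iv) for iv in model.exon_intervals),
        utr5=sorted(remap(iv) for iv in model.utr5_intervals),
        utr3=sorted(remap(iv) for iv in model.utr3_intervals),
        contig_id=model.contig_id,
        strand=model.strand,
        genome_span=(g0, g1),
    )


def partition_regulatory_regions(window: GeneWindow) -> RegulatoryRegionSet:
    """Partition the window into labelled putative regulatory regions.

    Emits upstream/downstream intergenic flanks, UTR intervals, and introns
    (exon gaps within the gene body).  CDS bases and exonic bases that are
    neither CDS nor UTR are excluded.  Overlapping exon annotations are fatal
    (introns would be ambiguous).
    """
    L = len(window.sequence)
    body = (window.anchor_offset, L - window.downstream_len)
    if body[1] < body[0]:
        raise GrassregError(f"{window.gene_id}: inconsistent window geometry")
    exons = sorted(window.exons)
    _check_sorted_disjoint(exons, f"{window.gene_id} exon")

    regions: list[tuple[Interval, str]] = []
    if window.anchor_offset > 0:
        regions.append(((0, window.anchor_offset), "upstream_intergenic"))
    for iv in window.utr5:
        regions.append((iv, "utr5"))
    # introns: bases of the gene body not covered by any exon
    cursor = body[0]
    for s, e in exons:
        s, e = max(s, body[0]), min(e, body[1])
        if s > cursor:
            regions.append(((cursor, s), "intron"))
        cursor = max(cursor, e)
    if cursor < body[1]:
        regions.append(((body[1] - (body[1] - cursor), body[1]), "intron"))
    for iv in window.utr3:
        regions.append((iv, "utr3"))
    if window.downstream_len > 0:
        regions.append(((body[1], L), "downstream_intergenic"))

    regions = [(iv, c) for iv, c in regions if iv[1] > iv[0]]
    regions.sort()
    _check_sorted_disjoint([iv for iv, _ in regions], f"{window.gene_id} region")
    for iv, c in regions:
        for cds in window.cds:
            if iv[0] < cds[1] and cds[0] < iv[1]:
                raise GrassregError(
                    f"{window.gene_id}: region {iv} ({c}) overlaps CDS {cds}"
                )
    return RegulatoryRegionSet(gene_id=window.gene_id, regions=regions)


def regions_to_bed6(window: GeneWindow, regions: RegulatoryRegionSet) -> str:
    """Regulatory regions as BED6 (window-relative, name = feature class)."""
    lines = []
    for (s, e), c in regions.regions:
        lines.append(
            f"{window.gene_id}\t{s}\t{e}\t{c}\t0\t+"
        )
    return "\n".join(lines) + ("\n" if lines else "")
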