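import io

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from grassreg.core_io import (  # noqa: E402
    GeneWindow,
    read_annotation,
    read_clade_table,
)

CLADE_TSV = (
    "rice\tC3\tBOP\n"
    "sorghum\tC4\tPACMAD\n"
)


def make_gff3(
    contig="chr1",
    gene_id="g1",
    strand="+",
    exons=((1001, 1300), (1601, 1900)),
    cds=((1101, 1300), (1601, 1800)),
    utr5=((1001, 1100),),
    utr3=((1801, 1900),),
):
    """Build a 1-gene GFF3 (1-based closed coordinates, as in the format)."""
    span = (
        min(x[0] for x in exons),
        max(x[1] for x in exons),
    )
    if strand == "-":
        # biological 5'UTR lies at the high-coordinate end of a minus gene
        utr5, utr3 = utr3, utr5
    lines = ["##gff-version 3"]

    def row(ftype, s, e, attrs, phase="."):
        lines.append(
            f"{contig}\tt\t{ftype}\t{s}\t{e}\t.\t{strand}\t{phase}\t{attrs}"
        )

    row("gene", span[0], span[1], f"ID={gene_id}")
    row("mRNA", span[0], span[1], f"ID={gene_id}.1;Parent={gene_id}")
    for s, e in exons:
        row("exon", s, e, f"Parent={gene_id}.1")
    for s, e in cds:
        row("CDS", s, e, f"Parent={gene_id}.1", phase="0")
    for s, e in utr5:
        row("five_prime_UTR", s, e, f"Parent={gene_id}.1")
    for s, e in utr3:
        row("three_prime_UTR", s, e, f"Parent={gene_id}.1")
    return "\n".join(lines) + "\n"


def make_genome(contig="chr1", length=4000, seed=0):
    rng = np.random.default_rng(seed)
    return {contig: "".join("ACGT"[i] for i in rng.integers(0, 4, length))}


@pytest.fixture
def clade_table():
    return read_clade_table(io.StringIO(CLADE_TSV))


@pytest.fixture
def simple_model(clade_table):
    genome = make_genome()
    models = read_annotation(
        io.StringIO(make_gff3()), genome, clade_table, "rice"
    )
    return models[0], genome


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def mutate_seq(rng, seq, rate):
    """Substitute bases at the given per-site rate (always to another base)."""
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = "ACGT"[("ACGT".index(out[i]) + int(rng.integers(1, 4))) % 4]
    return "".join(out)


def make_window(seq, gene_id="g", species_id="sp", **kw):
    defaults = dict(
        anchor_offset=0,
        upstream_len=0,
        downstream_len=0,
        cds=[],
        exons=[],
        utr5=[],
        utr3=[],
    )
    defaults.update(kw)
    return GeneWindow(gene_id=gene_id, species_id=species_id, sequence=seq, **defaults)
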