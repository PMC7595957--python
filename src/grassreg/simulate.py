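"""Seeded simulation of a miniature comparative-regulatory study.

The generator emits, for a configurable set of grass-like species split into
BOP and PACMAD clades (C3 and C4 photosynthetic types), one annotated gene
per species per gene set: a two-exon gene with UTRs embedded in a contig that
spans the standard analysis window (2 kb upstream of the TSS, gene body, 1 kb
downstream).  Sequences descend from a common ancestor with clade-scaled
substitution rates; coding sequence evolves slowly, background quickly.
Planted features with machine-readable ground truth:

- conserved non-coding blocks at a controlled pairwise identity, shared by
  all species or restricted to one clade (no indels inside blocks);
- motif instances sampled from library PWMs, placed at orthologous offsets
  within a chosen feature class, shared by all species or by one
  photosynthetic type only;
- negative-binomial M/BS count tables with planted activator / repressor /
  broad / null trans-factor patterns.

Outside planted blocks, short indels scramble local alignment while block
lengths are re-stabilized (trim/pad at block ends), so window coordinates are
identical across species and the truth table needs no per-species lift-over.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import GrassregError, Interval
from .motifs import PWM, revcomp, write_meme

ALPHABET = "ACGT"


# ---------------------------------------------------------------------------
# configuration


@dataclass
class SpeciesSpec:
    species_id: str
    photo_type: str  # "C3" | "C4"
    clade: str  # "BOP" | "PACMAD"
    strand: str = "+"  # strand the simulated genes are placed on


@dataclass
class PlantedCNSSpec:
    cns_id: str
    gene_set: str
    feature_class: str  # "upstream_intergenic" | "intron"
    length: int
    identity: float  # target pairwise identity among carriers
    scope: str  # "all_species" | "PACMAD" | "BOP"


@dataclass
class PlantedMotifSpec:
    motif_id: str
    gene_sets: list[str]
    feature_class: str
    sharing: str  # "all_species" | "C4_only" | "C3_only"
    n_instances: int = 3
    width: int = 14
    ic_per_column: float = 1.95


@dataclass
class ExpressionSpec:
    n_replicates: int = 3
    base_mean: float = 300.0
    dispersion: float = 0.1
    effect: float = 4.0
    n_filler: int = 50
    n_activators: int = 3
    n_repressors: int = 3
    n_broad: int = 3
    n_null: int = 3


def _default_species() -> list[SpeciesSpec]:
    return [
        SpeciesSpec("bop1", "C3", "BOP"),
        SpeciesSpec("bop2", "C3", "BOP", strand="-"),
        SpeciesSpec("bop3", "C3", "BOP"),
        SpeciesSpec("pacC3", "C3", "PACMAD"),  # C3 species inside PACMAD
        SpeciesSpec("pac1", "C4", "PACMAD"),
        SpeciesSpec("pac2", "C4", "PACMAD", strand="-"),
        SpeciesSpec("pac3", "C4", "PACMAD"),
        SpeciesSpec("pac4", "C4", "PACMAD"),
    ]


def _default_cns() -> list[PlantedCNSSpec]:
    return [
        PlantedCNSSpec("cns_SBP_intron", "SBPase", "intron", 150, 0.90, "all_species"),
        PlantedCNSSpec("cns_SBP_up1", "SBPase", "upstream_intergenic", 120, 0.90, "PACMAD"),
        PlantedCNSSpec("cns_SBP_up2", "SBPase", "upstream_intergenic", 100, 0.90, "PACMAD"),
        PlantedCNSSpec("cns_PRK_up", "PRK", "upstream_intergenic", 113, 0.92, "all_species"),
        PlantedCNSSpec("cns_FBP_up1", "FBPase", "upstream_intergenic", 120, 0.90, "PACMAD"),
        PlantedCNSSpec("cns_FBP_up2", "FBPase", "upstream_intergenic", 100, 0.90, "PACMAD"),
    ]


def _default_motifs(gene_sets: list[str]) -> list[PlantedMotifSpec]:
    return [
        PlantedMotifSpec("m_shared_all", list(gene_sets), "upstream_intergenic", "all_species"),
        PlantedMotifSpec("m_shared_G", ["GAPDHB"], "upstream_intergenic", "all_species"),
        PlantedMotifSpec("m_c4_SBP", ["SBPase"], "upstream_intergenic", "C4_only"),
        PlantedMotifSpec("m_c4_FBP", ["FBPase"], "upstream_intergenic", "C4_only"),
        PlantedMotifSpec("m_c3_PRK", ["PRK"], "upstream_intergenic", "C3_only"),
    ]


@dataclass
class SimulationConfig:
    """Study conditions of a simulated run (defaults mirror the real design)."""

    seed: int = 0
    species: list[SpeciesSpec] = field(default_factory=_default_species)
    gene_sets: list[str] = field(
        default_factory=lambda: ["SBPase", "FBPase", "PRK", "GAPDHB"]
    )
    upstream: int = 2000
    downstream: int = 1000
    utr5_len: int = 60
    cds_lens: tuple[int, int] = (240, 240)
    intron_len: int = 300
    utr3_len: int = 60
    gc: float = 0.44
    # substitution rates (clade branch, species branch) per feature class
    rates_background: tuple[float, float] = (0.15, 0.25)
    rates_utr: tuple[float, float] = (0.08, 0.12)
    rates_cds: tuple[float, float] = (0.02, 0.03)
    indel_rate: float = 0.01
    planted_cns: list[PlantedCNSSpec] = field(default_factory=_default_cns)
    planted_motifs: list[PlantedMotifSpec] | None = None
    n_library_motifs: int = 40
    library_width_range: tuple[int, int] = (8, 15)
    library_ic_range: tuple[float, float] = (1.0, 1.6)
    expression: ExpressionSpec = field(default_factory=ExpressionSpec)

    def __post_init__(self) -> None:
        if self.planted_motifs is None:
            self.planted_motifs = _default_motifs(self.gene_sets)
        for c in self.planted_cns:
            if not 0.5 < c.identity <= 1.0:
                raise GrassregError(f"{c.cns_id}: identity must be in (0.5, 1]")

    @property
    def clade_of(self) -> dict[str, str]:
        return {s.species_id: s.clade for s in self.species}

    @property
    def photo_of(self) -> dict[str, str]:
        return {s.species_id: s.photo_type for s in self.species}

    def sharing_species(self, sharing: str) -> list[str]:
        if sharing == "all_species":
            return [s.species_id for s in self.species]
        if sharing == "C4_only":
            return [s.species_id for s in self.species if s.photo_type == "C4"]
        if sharing == "C3_only":
            return [s.species_id for s in self.species if s.photo_type == "C3"]
        if sharing in ("PACMAD", "BOP"):
            return [s.species_id for s in self.species if s.clade == sharing]
        raise GrassregError(f"unknown sharing pattern {sharing!r}")


# ---------------------------------------------------------------------------
# truth bookkeeping


@dataclass
class PlantedMotifOccurrence:
    motif_id: str
    gene_set: str
    species_id: str
    gene_id: str
    start: int  # window coordinates
    end: int
    strand: str
    instance: str
    sharing: str


@dataclass
class PlantedCNSTruth:
    cns_id: str
    gene_set: str
    species_id: str
    start: int
    end: int
    feature_class: str
    scope: str


@dataclass
class TruthTable:
    cns: list[PlantedCNSTruth] = field(default_factory=list)
    motifs: list[PlantedMotifOccurrence] = field(default_factory=list)
    tf_labels: dict[str, str] = field(default_factory=dict)

    def motifs_tsv(self) -> str:
        rows = ["motif_id\tgene_set\tspecies_id\tgene_id\tstart\tend\tstrand\tinstance\tsharing"]
        for o in self.motifs:
            rows.append(
                f"{o.motif_id}\t{o.gene_set}\t{o.species_id}\t{o.gene_id}\t"
                f"{o.start}\t{o.end}\t{o.strand}\t{o.instance}\t{o.sharing}"
            )
        return "\n".join(rows) + "\n"

    def cns_tsv(self) -> str:
        rows = ["cns_id\tgene_set\tspecies_id\tstart\tend\tfeature_class\tscope"]
        for c in self.cns:
            rows.append(
                f"{c.cns_id}\t{c.gene_set}\t{c.species_id}\t{c.start}\t{c.end}\t"
                f"{c.feature_class}\t{c.scope}"
            )
        return "\n".join(rows) + "\n"

    def labels_tsv(self) -> str:
        rows = ["tf_id\texpected_label"]
        for tf, lab in sorted(self.tf_labels.items()):
            rows.append(f"{tf}\t{lab}")
        return "\n".join(rows) + "\n"

    @staticmethod
    def motifs_from_tsv(text: str) -> list[PlantedMotifOccurrence]:
        lines = text.strip().split("\n")[1:]
        out = []
        for ln in lines:
            m, gs, sp, gid, s, e, st, inst, sh = ln.split("\t")
            out.append(
                PlantedMotifOccurrence(m, gs, sp, gid, int(s), int(e), st, inst, sh)
            )
        return out


# ---------------------------------------------------------------------------
# sequence helpers


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p)


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each base with probability ``rate`` to a different base."""
    out = seq.copy()
    hit = rng.random(seq.size) < rate
    if hit.any():
        shift = rng.integers(1, 4, size=int(hit.sum()))
        out[hit] = (out[hit] + shift) % 4
    return out


def _pair_rate(identity: float) -> float:
    """Per-lineage substitution rate so two carriers match at ``identity``.

    Both carriers mutate independently from the ancestral block; matches occur
    when neither mutated or both mutated to the same base:
    (1-r)^2 + r^2/3 = identity.
    """
    disc = 4.0 - (16.0 / 3.0) * (1.0 - identity)
    return float((2.0 - np.sqrt(disc)) / (8.0 / 3.0))


def _stable_indels(
    seq: np.ndarray, rate: float, gc: float, rng: np.random.Generator
) -> np.ndarray:
    """Apply short indels, then trim/pad so the block length is unchanged."""
    if rate <= 0 or seq.size == 0:
        return seq
    parts = []
    i = 0
    n = seq.size
    events = np.nonzero(rng.random(n) < rate)[0]
    prev = 0
    for pos in events:
        parts.append(seq[prev:pos])
        length = int(rng.geometric(0.5))
        if rng.random() < 0.5:  # deletion
            prev = min(n, pos + length)
        else:  # insertion
            parts.append(_random_seq(rng, length, gc))
            prev = pos
    parts.append(seq[prev:])
    out = np.concatenate(parts) if parts else seq
    if out.size >= n:
        return out[:n]
    return np.concatenate([out, _random_seq(rng, n - out.size, gc)])


def _decode(codes: np.ndarray) -> str:
    return "".join(ALPHABET[int(c)] for c in codes)


_COMP_ARR = np.array([3, 2, 1, 0])


# ---------------------------------------------------------------------------
# motif library


def _temper_to_ic(raw: np.ndarray, target_ic: float) -> np.ndarray:
    """Exponent-temper a probability column so its information content hits
    the target (2 + sum p log2 p, uniform background)."""
    if not 0.0 <= target_ic <= 2.0 - 1e-9:
        if abs(target_ic - 2.0) < 1e-9:
            col = np.zeros(4)
            col[int(np.argmax(raw))] = 1.0
            return col
        raise GrassregError(f"unattainable information content {target_ic}")

    logr = np.log(np.maximum(raw, 1e-300))

    def temper(t: float) -> np.ndarray:
        z = t * logr
        p = np.exp(z - z.max())
        return p / p.sum()

    def ic(t: float) -> float:
        p = temper(t)
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log2(p), 0.0)
        return 2.0 + plogp.sum()

    lo, hi = 0.0, 400.0
    if ic(hi) < target_ic:
        hi = 4000.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if ic(mid) < target_ic:
            lo = mid
        else:
            hi = mid
    return temper(hi)


def _draw_pwm(
    rng: np.random.Generator, motif_id: str, width: int, ic_per_col: float
) -> PWM:
    cols = []
    for _ in range(width):
        raw = rng.dirichlet(np.ones(4))
        cols.append(_temper_to_ic(raw, ic_per_col))
    return PWM(motif_id=motif_id, probs=np.array(cols).T, nsites=20.0, source="library")


def simulate_motif_library(
    n_motifs: int,
    width_range: tuple[int, int] = (8, 15),
    ic_range: tuple[float, float] = (1.0, 1.6),
    seed: int | np.random.Generator = 0,
    prefix: str = "lib",
) -> list[PWM]:
    """Random PWM library: widths uniform in range, per-column IC tempered to
    a per-motif target drawn uniformly from ``ic_range``."""
    if n_motifs < 1:
        raise GrassregError("need at least one motif")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pwms = []
    for k in range(n_motifs):
        w = int(rng.integers(width_range[0], width_range[1] + 1))
        ic = float(rng.uniform(*ic_range))
        pwms.append(_draw_pwm(rng, f"{prefix}_{k:03d}", w, ic))
    return pwms


def _sample_instance(pwm: PWM, rng: np.random.Generator) -> str:
    return "".join(
        ALPHABET[rng.choice(4, p=pwm.probs[:, i])] for i in range(pwm.width)
    )


# ---------------------------------------------------------------------------
# genome simulation


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    fastas: dict[str, str]  # species -> FASTA text
    gffs: dict[str, str]  # species -> GFF3 text
    library: list[PWM]
    meme_text: str
    truth: TruthTable
    counts: dict[str, pd.DataFrame]  # species -> counts table
    sample_sheets: dict[str, pd.DataFrame]
    ortholog_map: pd.DataFrame  # tf_id, species_id, transcript_id

    def clade_table_tsv(self) -> str:
        rows = [
            f"{s.species_id}\t{s.photo_type}\t{s.clade}"
            for s in self.config.species
        ]
        return "\n".join(rows) + "\n"


def _allocate_blocks(
    feature_len: int,
    blocks: list[tuple[str, int]],
    rng: np.random.Generator,
    margin: int = 5,
) -> dict[str, int]:
    """Place named blocks at non-overlapping offsets inside a feature."""
    for _ in range(100):
        placed: list[tuple[int, int, str]] = []
        ok = True
        for name, length in blocks:
            if length + 2 * margin > feature_len:
                raise GrassregError(f"block {name} ({length} bp) exceeds feature")
            off = int(rng.integers(margin, feature_len - length - margin + 1))
            if any(off < e + margin and s < off + length + margin for s, e, _ in placed):
                ok = False
                break
            placed.append((off, off + length, name))
        if ok:
            return {name: s for s, _, name in placed}
    raise GrassregError("could not place planted blocks without collision")


def simulate_regulatory_genomes(
    cfg: SimulationConfig,
    library: list[PWM] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, str], dict[str, str], TruthTable, list[PWM]]:
    """Emit per-species FASTA/GFF3 plus the planted-feature truth table.

    Returns ``(fastas, gffs, truth, planted_pwms)``; the planted PWMs are
    generated here (one per planted motif spec) unless a library containing
    them is supplied.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    up, down = cfg.upstream, cfg.downstream
    u5, (c1, c2), intr, u3 = cfg.utr5_len, cfg.cds_lens, cfg.intron_len, cfg.utr3_len
    body = u5 + c1 + intr + c2 + u3
    L = up + body + down

    # fixed window-coordinate geometry, shared by every species
    geom = {
        "upstream": (0, up),
        "utr5": (up, up + u5),
        "cds1": (up + u5, up + u5 + c1),
        "intron": (up + u5 + c1, up + u5 + c1 + intr),
        "cds2": (up + u5 + c1 + intr, up + u5 + c1 + intr + c2),
        "utr3": (up + body - u3, up + body),
        "downstream": (up + body, L),
    }

    planted_pwms: dict[str, PWM] = {}
    if library is not None:
        planted_pwms = {p.motif_id: p for p in library}
    for spec in cfg.planted_motifs:
        if spec.motif_id not in planted_pwms:
            planted_pwms[spec.motif_id] = _draw_pwm(
                rng, spec.motif_id, spec.width, spec.ic_per_column
            )

    truth = TruthTable()
    fastas: dict[str, list[str]] = {s.species_id: [] for s in cfg.species}
    gffs: dict[str, list[str]] = {
        s.species_id: ["##gff-version 3"] for s in cfg.species
    }

    for gene_set in cfg.gene_sets:
        # ---- per-gene-set layout: allocate planted blocks per feature
        feature_blocks: dict[str, list[tuple[str, int]]] = {
            "upstream": [],
            "intron": [],
        }
        for c in cfg.planted_cns:
            if c.gene_set != gene_set:
                continue
            key = "upstream" if c.feature_class == "upstream_intergenic" else "intron"
            feature_blocks[key].append((f"cns:{c.cns_id}", c.length))
        occ_specs: list[tuple[str, PlantedMotifSpec, int]] = []
        for spec in cfg.planted_motifs:
            if gene_set not in spec.gene_sets:
                continue
            key = (
                "upstream"
                if spec.feature_class == "upstream_intergenic"
                else "intron"
            )
            w = planted_pwms[spec.motif_id].width
            for k in range(spec.n_instances):
                feature_blocks[key].append((f"motif:{spec.motif_id}:{k}", w))
        offsets = {
            feat: _allocate_blocks(
                geom[feat][1] - geom[feat][0], blocks, rng
            )
            for feat, blocks in feature_blocks.items()
        }

        # ---- ancestral sequences
        anc = {name: _random_seq(rng, e - s, cfg.gc) for name, (s, e) in geom.items()}
        anc_cns = {
            c.cns_id: _random_seq(rng, c.length, cfg.gc)
            for c in cfg.planted_cns
            if c.gene_set == gene_set
        }
        clades = sorted({s.clade for s in cfg.species})
        rates = {
            "upstream": cfg.rates_background,
            "downstream": cfg.rates_background,
            "intron": cfg.rates_background,
            "utr5": cfg.rates_utr,
            "utr3": cfg.rates_utr,
            "cds1": cfg.rates_cds,
            "cds2": cfg.rates_cds,
        }
        clade_seqs = {
            cl: {name: _mutate(anc[name], rates[name][0], rng) for name in anc}
            for cl in clades
        }

        for sp in cfg.species:
            segs = {
                name: _mutate(clade_seqs[sp.clade][name], rates[name][1], rng)
                for name in anc
            }
            # indel scrambling in non-coding background only
            for name in ("upstream", "intron", "downstream"):
                segs[name] = _stable_indels(segs[name], cfg.indel_rate, cfg.gc, rng)

            gene_id = f"{gene_set}_{sp.species_id}"
            # ---- overlay planted CNS blocks
            for c in cfg.planted_cns:
                if c.gene_set != gene_set:
                    continue
                feat = "upstream" if c.feature_class == "upstream_intergenic" else "intron"
                off = offsets[feat][f"cns:{c.cns_id}"]
                carriers = cfg.sharing_species(
                    "all_species" if c.scope == "all_species" else c.scope
                )
                if sp.species_id in carriers:
                    block = _mutate(anc_cns[c.cns_id], _pair_rate(c.identity), rng)
                    segs[feat][off : off + c.length] = block
                    truth.cns.append(
                        PlantedCNSTruth(
                            cns_id=c.cns_id,
                            gene_set=gene_set,
                            species_id=sp.species_id,
                            start=geom[feat][0] + off,
                            end=geom[feat][0] + off + c.length,
                            feature_class=c.feature_class,
                            scope=c.scope,
                        )
                    )
            # ---- overlay planted motif instances
            for spec in cfg.planted_motifs:
                if gene_set not in spec.gene_sets:
                    continue
                feat = (
                    "upstream"
                    if spec.feature_class == "upstream_intergenic"
                    else "intron"
                )
                pwm = planted_pwms[spec.motif_id]
                carriers = cfg.sharing_species(spec.sharing)
                for k in range(spec.n_instances):
                    off = offsets[feat][f"motif:{spec.motif_id}:{k}"]
                    if sp.species_id not in carriers:
                        continue
                    inst = _sample_instance(pwm, rng)
                    strand = "+" if rng.random() < 0.5 else "-"
                    placed = inst if strand == "+" else revcomp(inst)
                    codes = np.array([ALPHABET.index(b) for b in placed])
                    segs[feat][off : off + pwm.width] = codes
                    truth.motifs.append(
                        PlantedMotifOccurrence(
                            motif_id=spec.motif_id,
                            gene_set=gene_set,
                            species_id=sp.species_id,
                            gene_id=gene_id,
                            start=geom[feat][0] + off,
                            end=geom[feat][0] + off + pwm.width,
                            strand=strand,
                            instance=placed,
                            sharing=spec.sharing,
                        )
                    )

            window = np.concatenate(
                [segs[n] for n in ("upstream", "utr5", "cds1", "intron", "cds2", "utr3", "downstream")]
            )
            contig_id = f"{sp.species_id}_{gene_set}"
            if sp.strand == "+":
                contig = window
            else:
                contig = _COMP_ARR[window[::-1]]
            fastas[sp.species_id].append(f">{contig_id}\n{_decode(contig)}")

            def g(iv: Interval) -> tuple[int, int]:
                # window -> GFF3 1-based closed contig coordinates
                if sp.strand == "+":
                    return iv[0] + 1, iv[1]
                return L - iv[1] + 1, L - iv[0]

            mrna = (geom["utr5"][0], geom["utr3"][1])
            exon1 = (geom["utr5"][0], geom["cds1"][1])
            exon2 = (geom["cds2"][0], geom["utr3"][1])
            rows = []
            gs, ge = g(mrna)
            rows.append((gs, ge, "gene", f"ID={gene_id}"))
            rows.append((gs, ge, "mRNA", f"ID={gene_id}.1;Parent={gene_id}"))
            for ftype, iv in (
                ("exon", exon1),
                ("exon", exon2),
                ("five_prime_UTR", geom["utr5"]),
                ("CDS", geom["cds1"]),
                ("CDS", geom["cds2"]),
                ("three_prime_UTR", geom["utr3"]),
            ):
                s1, e1 = g(iv)
                rows.append((s1, e1, ftype, f"Parent={gene_id}.1"))
            rows.sort(key=lambda r: (r[0], r[1]))
            for s1, e1, ftype, attrs in rows:
                phase = "0" if ftype == "CDS" else "."
                gffs[sp.species_id].append(
                    f"{contig_id}\tgrassreg_sim\t{ftype}\t{s1}\t{e1}\t.\t{sp.strand}\t{phase}\t{attrs}"
                )

    fasta_text = {sp: "\n".join(parts) + "\n" for sp, parts in fastas.items()}
    gff_text = {sp: "\n".join(parts) + "\n" for sp, parts in gffs.items()}
    return fasta_text, gff_text, truth, list(planted_pwms.values())


# ---------------------------------------------------------------------------
# expression simulation


def simulate_expression(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, pd.DataFrame], dict[str, pd.DataFrame], pd.DataFrame, dict[str, str]]:
    """Negative-binomial M/BS count tables with planted TF classes.

    Returns ``(counts, sample_sheets, ortholog_map, truth_labels)``; counts
    are per C4 species (the cell-type-resolved data exist only for C4 taxa in
    the emulated design).  Activators put every ortholog's BS mean at
    ``effect`` times the M mean, repressors the inverse, broad factors
    alternate direction between orthologs within a species, null factors are
    flat.
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    ex = cfg.expression
    if ex.effect <= 0:
        raise GrassregError("expression effect must be > 0")
    if ex.n_replicates < 2:
        raise GrassregError("need >= 2 replicates per cell type")
    c4 = [s.species_id for s in cfg.species if s.photo_type == "C4"]
    if len(c4) < 2:
        raise GrassregError("need >= 2 C4 species for the expression design")

    tf_specs: list[tuple[str, str]] = []
    for i in range(ex.n_activators):
        tf_specs.append((f"TF_act{i+1}", "activator"))
    for i in range(ex.n_repressors):
        tf_specs.append((f"TF_rep{i+1}", "repressor"))
    for i in range(ex.n_broad):
        tf_specs.append((f"TF_broad{i+1}", "broad"))
    for i in range(ex.n_null):
        tf_specs.append((f"TF_null{i+1}", "null"))

    truth_labels = {
        tf: {
            "activator": "putative_activator",
            "repressor": "putative_repressor",
            "broad": "broad_regulator",
            "null": "not_classified",
        }[kind]
        for tf, kind in tf_specs
    }

    map_rows = []
    per_species_tx: dict[str, list[tuple[str, str, int]]] = {sp: [] for sp in c4}
    for tf, kind in tf_specs:
        n_sp = int(rng.integers(2, len(c4) + 1))
        chosen = list(rng.choice(c4, size=n_sp, replace=False))
        for sp in chosen:
            n_tx = 2 if kind == "broad" else int(rng.integers(1, 3))
            for t in range(n_tx):
                tx = f"{sp}.{tf}.{t+1}"
                map_rows.append({"tf_id": tf, "species_id": sp, "transcript_id": tx})
                per_species_tx[sp].append((tx, kind, t))

    counts: dict[str, pd.DataFrame] = {}
    sheets: dict[str, pd.DataFrame] = {}
    n_nb = 1.0 / ex.dispersion
    for sp in c4:
        tx_rows = per_species_tx[sp] + [
            (f"{sp}.filler.{i+1}", "null", 0) for i in range(ex.n_filler)
        ]
        samples = [f"{sp}_M_r{i+1}" for i in range(ex.n_replicates)] + [
            f"{sp}_BS_r{i+1}" for i in range(ex.n_replicates)
        ]
        data = np.zeros((len(tx_rows), len(samples)), dtype=np.int64)
        for r, (tx, kind, t) in enumerate(tx_rows):
            mu_m = float(rng.lognormal(np.log(ex.base_mean), 0.7))
            if kind == "activator":
                mu_bs = mu_m * ex.effect
            elif kind == "repressor":
                mu_bs = mu_m / ex.effect
            elif kind == "broad":
                mu_bs = mu_m * ex.effect if t % 2 == 0 else mu_m / ex.effect
            else:
                mu_bs = mu_m
            mus = [mu_m] * ex.n_replicates + [mu_bs] * ex.n_replicates
            for cidx, mu in enumerate(mus):
                p = n_nb / (n_nb + mu)
                data[r, cidx] = rng.negative_binomial(n_nb, p)
        counts[sp] = pd.DataFrame(
            data, index=[t[0] for t in tx_rows], columns=samples
        )
        sheets[sp] = pd.DataFrame(
            {
                "sample": samples,
                "species_id": sp,
                "cell_type": ["M"] * ex.n_replicates + ["BS"] * ex.n_replicates,
                "replicate": list(range(1, ex.n_replicates + 1)) * 2,
            }
        )
    ortho = pd.DataFrame(map_rows)
    return counts, sheets, ortho, truth_labels


# ---------------------------------------------------------------------------
# whole-study orchestration


def simulate_study(cfg: SimulationConfig) -> SimulatedStudy:
    """Generate the complete miniature study from one seed."""
    rng = np.random.default_rng(cfg.seed)
    planted_ids = {m.motif_id for m in cfg.planted_motifs}
    n_filler = max(0, cfg.n_library_motifs - len(planted_ids))
    fillers = simulate_motif_library(
        n_filler, cfg.library_width_range, cfg.library_ic_range, rng
    ) if n_filler else []
    fastas, gffs, truth, planted = simulate_regulatory_genomes(cfg, rng=rng)
    library = planted + fillers
    meme_text = write_meme(library)
    counts, sheets, ortho, labels = simulate_expression(cfg, rng=rng)
    truth.tf_labels = labels
    return SimulatedStudy(
        config=cfg,
        fastas=fastas,
        gffs=gffs,
        library=library,
        meme_text=meme_text,
        truth=truth,
        counts=counts,
        sample_sheets=sheets,
        ortholog_map=ortho,
    )
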