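"""File-based pipeline orchestration: stages, run directory, manifest.

Every stage reads and writes plain-text files in a run directory (no hidden
state between stages), so any stage can be rerun or inspected in isolation:

- ``simulate``    seeded miniature study (FASTA/GFF3/MEME/counts/truth)
- ``extract``     gene windows + regulatory-region partition
- ``cns``         pairwise window alignments + CNS calls per reference
- ``discover``    per-CNS-locus ZOOPS motifs, ortholog rescan, scope
- ``scan``        motif-library scan with exact p-values + BH filter
- ``setanalysis`` presence matrix, shared/intersection/clade-specific calls
- ``classify``    M/BS enrichment classification of trans-acting factors
- ``run-all``     all of the above, with one manifest
"""

from __future__ import annotations

import hashlib
import io
import json
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cns import (
    AlignScoring,
    CNSInterval,
    align_windows,
    call_cns,
    cns_to_gff3,
    conservation_scope,
    identity_profile,
)
from .core_io import (
    GeneWindow,
    GrassregError,
    RegulatoryRegionSet,
    extract_gene_window,
    partition_regulatory_regions,
    read_annotation,
    read_clade_table,
    read_fasta,
)
from .expression import (
    classification_table,
    classify_tf,
    normalize_log2fc,
    read_de_table,
    read_ortholog_map,
)
from .motifs import PWM, read_meme_motifs, select_motif, write_meme
from .scan import (
    MotifHit,
    bh_qvalues,
    build_log_odds,
    hits_to_tsv,
    null_distribution,
    scan_window_arrays,
)
from .sets import (
    StudyDesign,
    build_presence,
    clade_specific,
    cluster_positions,
    membership_table,
    presence_to_tsv,
    shared_motifs,
    upset_partition,
)
from .simulate import SimulationConfig, simulate_study


@dataclass
class PipelineConfig:
    """All tunable thresholds of a run; serialized into the manifest."""

    upstream_bp: int = 2000
    downstream_bp: int = 1000
    cns_window: int = 50
    cns_identity: float = 0.70
    cns_project: str = "center"
    align_match: float = 1.0
    align_mismatch: float = -1.0
    align_gap_open: float = -4.0
    align_gap_extend: float = -0.5
    align_max_cells: float = 25e6
    scan_alpha: float = 0.05
    scan_pseudocount: float = 0.01
    # optional FIMO-style p-value pre-threshold on reported hits (0 = off);
    # BH is always computed over all scored positions
    scan_p_prethreshold: float = 0.0
    inclusion_log2fc: float = 1.0
    inclusion_min_species: int = 2
    shared_quorum: float = 1.0
    clade_presence_quorum: int = 1
    cluster_max_gap: int = 50
    cns_motif_widths: tuple = (8, 12, 16, 20)
    cns_seeds_per_width: int = 3
    em_max_iter: int = 100
    em_tol: float = 1e-4
    ref_species: tuple = ()  # empty = first C3 and first C4 of the clade table
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.cns_identity < 1:
            raise GrassregError("cns_identity must be in (0,1)")
        if not 0 < self.scan_alpha < 1:
            raise GrassregError("scan_alpha must be in (0,1)")
        if self.cns_window < 1:
            raise GrassregError("cns_window must be >= 1")
        if self.shared_quorum <= 0 or self.shared_quorum > 1:
            raise GrassregError("shared_quorum must be in (0,1]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise GrassregError(f"invalid config keys: {sorted(unknown)}")
        for key in ("cns_motif_widths", "ref_species"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def scoring(self) -> AlignScoring:
        return AlignScoring(
            match=self.align_match,
            mismatch=self.align_mismatch,
            gap_open=self.align_gap_open,
            gap_extend=self.align_gap_extend,
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _text(path: Path) -> io.StringIO:
    return io.StringIO(Path(path).read_text())


#: required header columns of the tabular stage outputs; every output file is
#: schema-checked before its stage is recorded as successful
_SCHEMAS = {
    "windows_meta.tsv": [
        "species_id", "gene_id", "gene_set", "anchor_offset",
        "upstream_len", "downstream_len", "strand", "contig_id", "length",
    ],
    "regions.tsv": ["species_id", "gene_id", "start", "end", "feature_class"],
    "cns_pairs.tsv": [
        "ref_species", "query_species", "gene_set", "ref_gene_id",
        "start", "end", "mean_identity", "feature_class",
    ],
    "cns_loci.tsv": [
        "ref_species", "gene_set", "locus_id", "start", "end",
        "feature_class", "scope", "supporting_species", "motif_width",
    ],
    "hits.tsv": [
        "motif_id", "gene_id", "species_id", "feature_class", "start",
        "end", "strand", "score", "p_value", "q_value",
    ],
    "presence.tsv": ["motif_id", "gene_set", "species", "status"],
    "categories.tsv": ["label", "gene_subset", "n_motifs", "motifs"],
    "clade_calls.tsv": ["motif_id", "gene_set", "direction", "supporting_species"],
    "tf_classification.tsv": [
        "tf_id", "label", "n_species", "n_transcripts",
        "min_log2fc", "max_log2fc",
    ],
}


def _validate_schema(path: Path) -> None:
    expected = _SCHEMAS.get(path.name)
    if expected is None:
        return
    header = path.read_text().split("\n", 1)[0].split("\t")
    if header != expected:
        raise GrassregError(
            f"{path.name}: schema mismatch; got columns {header}"
        )


class Run:
    """A run directory with stage helpers and a manifest."""

    def __init__(self, outdir, config: PipelineConfig | None = None):
        self.dir = Path(outdir)
        self.dir.mkdir(parents=True, exist_ok=True)
        self.config = config or PipelineConfig()
        self.config.validate()
        self.manifest: dict = {
            "package": "grassreg",
            "version": __version__,
            "seed": self.config.seed,
            "config": asdict(self.config),
            "stages": {},
            "inputs": {},
            "outputs": {},
        }

    # -- manifest -----------------------------------------------------------
    def _record(self, stage: str, t0: float, outputs: list[Path]) -> None:
        self.manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3)}
        for p in outputs:
            _validate_schema(p)
            self.manifest["outputs"][str(p.relative_to(self.dir))] = _sha256(p)
        cfg_json = json.dumps(self.manifest["config"], sort_keys=True)
        self.manifest["config_sha256"] = hashlib.sha256(
            cfg_json.encode()
        ).hexdigest()
        (self.dir / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True) + "\n"
        )

    def _input(self, path: Path) -> Path:
        self.manifest["inputs"][str(path)] = _sha256(path)
        return path

    # -- simulate -----------------------------------------------------------
    def stage_simulate(self, sim_config: SimulationConfig | None = None):
        t0 = time.time()
        cfg = sim_config or SimulationConfig(seed=self.config.seed)
        study = simulate_study(cfg)
        out = []

        def w(name: str, text: str) -> Path:
            p = self.dir / name
            p.parent.mkdir(parents=True, exist_ok=True)
            p.write_text(text)
            out.append(p)
            return p

        for sp in study.fastas:
            w(f"genomes/{sp}.fasta", study.fastas[sp])
            w(f"genomes/{sp}.gff3", study.gffs[sp])
        w("clade_table.tsv", study.clade_table_tsv())
        w("library.meme", study.meme_text)
        w("truth/planted_motifs.tsv", study.truth.motifs_tsv())
        w("truth/planted_cns.tsv", study.truth.cns_tsv())
        w("truth/tf_labels.tsv", study.truth.labels_tsv())
        for sp, df in study.counts.items():
            w(f"expression/{sp}.counts.tsv", df.to_csv(sep="\t", index_label="transcript_id"))
            w(
                f"expression/{sp}.samples.tsv",
                study.sample_sheets[sp].to_csv(sep="\t", index=False),
            )
        w("ortholog_map.tsv", study.ortholog_map.to_csv(sep="\t", index=False))
        gene_sets = "\n".join(cfg.gene_sets) + "\n"
        w("gene_sets.txt", gene_sets)
        self._record("simulate", t0, out)
        return study

    # -- extract ------------------------------------------------------------
    def stage_extract(self) -> tuple[dict, dict]:
        """Windows + regions for every (species, gene set) in the run dir."""
        t0 = time.time()
        clade_table = read_clade_table(
            _text(self._input(self.dir / "clade_table.tsv"))
        )
        gene_sets = (self.dir / "gene_sets.txt").read_text().split()
        windows: dict[tuple[str, str], GeneWindow] = {}
        regions: dict[tuple[str, str], RegulatoryRegionSet] = {}
        meta_rows = []
        region_rows = []
        fasta_parts = []
        for sp in sorted(clade_table):
            fa = self._input(self.dir / "genomes" / f"{sp}.fasta")
            gff = self._input(self.dir / "genomes" / f"{sp}.gff3")
            genome = read_fasta(_text(fa))
            models = read_annotation(_text(gff), genome, clade_table, sp)
            for model in models:
                win = extract_gene_window(
                    model,
                    genome,
                    upstream=self.config.upstream_bp,
                    downstream=self.config.downstream_bp,
                )
                reg = partition_regulatory_regions(win)
                gene_set = next(
                    (g for g in gene_sets if model.gene_id.startswith(g)), ""
                )
                windows[(sp, model.gene_id)] = win
                regions[(sp, model.gene_id)] = reg
                meta_rows.append(
                    {
                        "species_id": sp,
                        "gene_id": model.gene_id,
                        "gene_set": gene_set,
                        "anchor_offset": win.anchor_offset,
                        "upstream_len": win.upstream_len,
                        "downstream_len": win.downstream_len,
                        "strand": win.strand,
                        "contig_id": win.contig_id,
                        "length": len(win.sequence),
                    }
                )
                fasta_parts.append(f">{sp}|{model.gene_id}\n{win.sequence}")
                for (s, e), c in reg.regions:
                    region_rows.append(
                        {
                            "species_id": sp,
                            "gene_id": model.gene_id,
                            "start": s,
                            "end": e,
                            "feature_class": c,
                        }
                    )
        out = []
        p = self.dir / "windows" / "windows.fasta"
        p.parent.mkdir(exist_ok=True)
        p.write_text("\n".join(fasta_parts) + "\n")
        out.append(p)
        p = self.dir / "windows" / "windows_meta.tsv"
        p.write_text(pd.DataFrame(meta_rows).to_csv(sep="\t", index=False))
        out.append(p)
        p = self.dir / "windows" / "regions.tsv"
        p.write_text(pd.DataFrame(region_rows).to_csv(sep="\t", index=False))
        out.append(p)
        self._record("extract", t0, out)
        return windows, regions

    def load_windows(self) -> tuple[dict, dict, pd.DataFrame]:
        meta = pd.read_csv(self.dir / "windows" / "windows_meta.tsv", sep="\t")
        seqs = read_fasta(_text(self.dir / "windows" / "windows.fasta"))
        reg_df = pd.read_csv(self.dir / "windows" / "regions.tsv", sep="\t")
        windows: dict[tuple[str, str], GeneWindow] = {}
        regions: dict[tuple[str, str], RegulatoryRegionSet] = {}
        for row in meta.itertuples(index=False):
            key = (row.species_id, row.gene_id)
            windows[key] = GeneWindow(
                gene_id=row.gene_id,
                species_id=row.species_id,
                sequence=seqs[f"{row.species_id}|{row.gene_id}"],
                anchor_offset=int(row.anchor_offset),
                upstream_len=int(row.upstream_len),
                downstream_len=int(row.downstream_len),
                cds=[],
                exons=[],
                utr5=[],
                utr3=[],
                contig_id=str(row.contig_id),
                strand=str(row.strand),
            )
        for (sp, gid), grp in reg_df.groupby(["species_id", "gene_id"], sort=True):
            regions[(sp, gid)] = RegulatoryRegionSet(
                gene_id=gid,
                regions=[
                    ((int(r.start), int(r.end)), str(r.feature_class))
                    for r in grp.sort_values("start").itertuples(index=False)
                ],
            )
        return windows, regions, meta

    def _design(self, meta: pd.DataFrame, clade_table: dict) -> StudyDesign:
        gene_sets = (self.dir / "gene_sets.txt").read_text().split()
        species = sorted(clade_table)
        gene_to_set = {
            r.gene_id: r.gene_set for r in meta.itertuples(index=False) if r.gene_set
        }
        have = {(r.gene_set, r.species_id) for r in meta.itertuples(index=False)}
        missing = {
            (g, s) for g in gene_sets for s in species if (g, s) not in have
        }
        return StudyDesign(
            gene_sets=gene_sets,
            species=species,
            gene_to_set=gene_to_set,
            gene_to_species={r.gene_id: r.species_id for r in meta.itertuples(index=False)},
            missing=missing,
        )

    def _refs(self, clade_table: dict) -> list[str]:
        if self.config.ref_species:
            return list(self.config.ref_species)
        refs = []
        for photo in ("C3", "C4"):
            cands = sorted(sp for sp, (p, _) in clade_table.items() if p == photo)
            if cands:
                refs.append(cands[0])
        return refs

    # -- cns ----------------------------------------------------------------
    def stage_cns(self) -> pd.DataFrame:
        """Pairwise CNS calls of every ortholog against each reference."""
        t0 = time.time()
        clade_table = read_clade_table(_text(self.dir / "clade_table.tsv"))
        windows, regions, meta = self.load_windows()
        cfg = self.config
        refs = self._refs(clade_table)
        aln_dir = self.dir / "alignments"
        aln_dir.mkdir(exist_ok=True)
        rows = []
        out = []
        by_set: dict[str, dict[str, str]] = {}
        for r in meta.itertuples(index=False):
            if r.gene_set:
                by_set.setdefault(r.gene_set, {})[r.species_id] = r.gene_id
        for ref_sp in refs:
            for gene_set in sorted(by_set):
                sp_to_gene = by_set[gene_set]
                if ref_sp not in sp_to_gene:
                    continue
                ref_win = windows[(ref_sp, sp_to_gene[ref_sp])]
                ref_reg = regions[(ref_sp, sp_to_gene[ref_sp])]
                for q_sp in sorted(sp_to_gene):
                    if q_sp == ref_sp:
                        continue
                    q_win = windows[(q_sp, sp_to_gene[q_sp])]
                    aln = align_windows(
                        ref_win, q_win, cfg.scoring(), max_cells=cfg.align_max_cells
                    )
                    prof = identity_profile(aln, window_size=cfg.cns_window)
                    calls = call_cns(
                        prof,
                        aln,
                        ref_reg,
                        threshold=cfg.cns_identity,
                        project=cfg.cns_project,
                    )
                    p = aln_dir / f"{gene_set}__{ref_sp}__{q_sp}.afa"
                    p.write_text(
                        f">{ref_sp}|{aln.ref_gene_id}\n{aln.aligned_ref}\n"
                        f">{q_sp}|{aln.query_gene_id}\n{aln.aligned_query}\n"
                    )
                    out.append(p)
                    for c in calls:
                        rows.append(
                            {
                                "ref_species": ref_sp,
                                "query_species": q_sp,
                                "gene_set": gene_set,
                                "ref_gene_id": c.ref_gene_id,
                                "start": c.interval[0],
                                "end": c.interval[1],
                                "mean_identity": round(c.mean_identity, 4),
                                "feature_class": c.feature_class,
                            }
                        )
        df = pd.DataFrame(
            rows,
            columns=[
                "ref_species",
                "query_species",
                "gene_set",
                "ref_gene_id",
                "start",
                "end",
                "mean_identity",
                "feature_class",
            ],
        )
        p = self.dir / "cns_pairs.tsv"
        p.write_text(df.to_csv(sep="\t", index=False))
        out.append(p)
        self._record("cns", t0, out)
        return df

    # -- discover -----------------------------------------------------------
    def stage_discover(self) -> pd.DataFrame:
        """Merge pairwise CNS calls into loci, discover a ZOOPS motif per
        locus, rescan every species, and set the conservation scope."""
        t0 = time.time()
        clade_table = read_clade_table(_text(self.dir / "clade_table.tsv"))
        clade_of = {sp: c for sp, (_, c) in clade_table.items()}
        windows, regions, meta = self.load_windows()
        cfg = self.config
        pairs = pd.read_csv(self.dir / "cns_pairs.tsv", sep="\t")
        by_set: dict[str, dict[str, str]] = {}
        for r in meta.itertuples(index=False):
            if r.gene_set:
                by_set.setdefault(r.gene_set, {})[r.species_id] = r.gene_id

        rows = []
        motif_pwms: list[PWM] = []
        loci_gff: list[CNSInterval] = []
        for (ref_sp, gene_set), grp in (
            pairs.groupby(["ref_species", "gene_set"], sort=True)
            if len(pairs)
            else []
        ):
            # merge overlapping pairwise intervals into loci
            ivs = sorted(
                (int(r.start), int(r.end), str(r.query_species), str(r.feature_class))
                for r in grp.itertuples(index=False)
            )
            loci: list[dict] = []
            for s, e, q_sp, fclass in ivs:
                if loci and s < loci[-1]["end"]:
                    loci[-1]["end"] = max(loci[-1]["end"], e)
                    loci[-1]["support"].add(q_sp)
                else:
                    loci.append(
                        {"start": s, "end": e, "support": {q_sp}, "class": fclass}
                    )
            sp_to_gene = by_set[gene_set]
            ref_win = windows[(ref_sp, sp_to_gene[ref_sp])]
            for li, locus in enumerate(loci):
                s, e = locus["start"], locus["end"]
                seqs = [ref_win.sequence[s:e]]
                for q_sp in sorted(locus["support"]):
                    seg = self._aligned_segment(gene_set, ref_sp, q_sp, s, e)
                    if seg and len(seg) >= cfg.cns_window // 2:
                        seqs.append(seg)
                if len(seqs) < 2:
                    continue
                w_cap = min(24, min(len(q) for q in seqs))
                widths = [w for w in cfg.cns_motif_widths if w <= w_cap] or [w_cap]
                pwm = select_motif(
                    seqs,
                    w_min=min(widths),
                    w_max=w_cap,
                    widths=widths,
                    seeds_per_width=cfg.cns_seeds_per_width,
                    max_iter=cfg.em_max_iter,
                    tol=cfg.em_tol,
                )
                pwm.motif_id = f"cnsmotif_{gene_set}_{ref_sp}_{li}"
                motif_pwms.append(pwm)
                presence = {ref_sp: True}
                for sp in sorted(clade_table):
                    if sp == ref_sp or sp not in sp_to_gene:
                        continue
                    presence[sp] = self._motif_present(
                        pwm, windows[(sp, sp_to_gene[sp])], regions[(sp, sp_to_gene[sp])]
                    )
                cns = CNSInterval(
                    ref_gene_id=sp_to_gene[ref_sp],
                    interval=(s, e),
                    mean_identity=float(grp["mean_identity"].max()),
                    feature_class=locus["class"],
                )
                conservation_scope(cns, presence, clade_of)
                loci_gff.append(cns)
                rows.append(
                    {
                        "ref_species": ref_sp,
                        "gene_set": gene_set,
                        "locus_id": pwm.motif_id,
                        "start": s,
                        "end": e,
                        "feature_class": locus["class"],
                        "scope": cns.scope,
                        "supporting_species": ",".join(
                            sorted(cns.supporting_species)
                        ),
                        "motif_width": pwm.width,
                    }
                )
        out = []
        p = self.dir / "cns_loci.tsv"
        df = pd.DataFrame(
            rows,
            columns=[
                "ref_species",
                "gene_set",
                "locus_id",
                "start",
                "end",
                "feature_class",
                "scope",
                "supporting_species",
                "motif_width",
            ],
        )
        p.write_text(df.to_csv(sep="\t", index=False))
        out.append(p)
        p = self.dir / "cns_loci.gff3"
        p.write_text(cns_to_gff3(loci_gff))
        out.append(p)
        p = self.dir / "cns_motifs.meme"
        p.write_text(write_meme(motif_pwms))
        out.append(p)
        self._record("discover", t0, out)
        return df

    def _aligned_segment(
        self, gene_set: str, ref_sp: str, q_sp: str, s: int, e: int
    ) -> str:
        """Gapless query subsequence aligned to ref window interval [s, e)."""
        p = self.dir / "alignments" / f"{gene_set}__{ref_sp}__{q_sp}.afa"
        if not p.exists():
            return ""
        lines = p.read_text().splitlines()
        aref, aq = lines[1], lines[3]
        refpos = -1
        out = []
        for cr, cq in zip(aref, aq):
            if cr != "-":
                refpos += 1
            if s <= refpos < e and cq != "-":
                out.append(cq)
            if refpos >= e:
                break
        return "".join(out)

    def _motif_present(self, pwm: PWM, window: GeneWindow, regions) -> bool:
        lom = build_log_odds(pwm, pseudocount=self.config.scan_pseudocount)
        dist = null_distribution(lom, pwm.background)
        _, _, _, pvals, _ = scan_window_arrays(window, regions, lom, dist)
        if pvals.size == 0:
            return False
        q = bh_qvalues(pvals)
        return bool((q < self.config.scan_alpha).any())

    # -- scan ---------------------------------------------------------------
    def stage_scan(self, motif_file: str | Path | None = None) -> list[MotifHit]:
        """Scan all regulatory regions with the motif library; BH per
        (library x gene set x species) batch; keep q < alpha."""
        t0 = time.time()
        motif_path = Path(motif_file) if motif_file else self.dir / "library.meme"
        if not motif_path.exists():
            raise GrassregError(
                f"motif file {motif_path} not found; run 'simulate' or pass "
                "an existing MEME minimal file"
            )
        pwms = read_meme_motifs(_text(self._input(motif_path)))
        windows, regions, meta = self.load_windows()
        cfg = self.config
        loms = [build_log_odds(p, pseudocount=cfg.scan_pseudocount) for p in pwms]
        dists = [null_distribution(l, p.background) for l, p in zip(loms, pwms)]
        retained: list[MotifHit] = []
        for r in meta.sort_values(["gene_set", "species_id"]).itertuples(index=False):
            key = (r.species_id, r.gene_id)
            win, reg = windows[key], regions[key]
            cand = []
            for pwm, lom, dist in zip(pwms, loms, dists):
                starts, strands, scores, pvals, classes = scan_window_arrays(
                    win, reg, lom, dist
                )
                cand.append((pwm, lom, starts, strands, scores, pvals, classes))
            allp = np.concatenate([c[5] for c in cand]) if cand else np.empty(0)
            if allp.size == 0:
                continue
            q = bh_qvalues(allp)
            off = 0
            for pwm, lom, starts, strands, scores, pvals, classes in cand:
                qs = q[off : off + pvals.size]
                keep_mask = qs < cfg.scan_alpha
                if cfg.scan_p_prethreshold > 0:
                    keep_mask &= pvals < cfg.scan_p_prethreshold
                keep = np.nonzero(keep_mask)[0]
                for k in keep:
                    retained.append(
                        MotifHit(
                            motif_id=pwm.motif_id,
                            gene_id=win.gene_id,
                            species_id=win.species_id,
                            feature_class=classes[k],
                            start=int(starts[k]),
                            end=int(starts[k]) + lom.width,
                            strand="+" if strands[k] == 0 else "-",
                            score=float(scores[k] * lom.granularity),
                            p_value=float(pvals[k]),
                            q_value=float(qs[k]),
                        )
                    )
                off += pvals.size
        retained.sort(
            key=lambda h: (h.species_id, h.gene_id, h.motif_id, h.start, h.strand)
        )
        p = self.dir / "hits.tsv"
        p.write_text(hits_to_tsv(retained))
        self._record("scan", t0, [p])
        return retained

    # -- setanalysis --------------------------------------------------------
    def stage_setanalysis(self) -> dict:
        t0 = time.time()
        clade_table = read_clade_table(_text(self.dir / "clade_table.tsv"))
        photo_of = {sp: p for sp, (p, _) in clade_table.items()}
        _, regions, meta = self.load_windows()
        hits_df = pd.read_csv(self.dir / "hits.tsv", sep="\t")
        hits = [
            MotifHit(
                motif_id=str(r.motif_id),
                gene_id=str(r.gene_id),
                species_id=str(r.species_id),
                feature_class=str(r.feature_class),
                start=int(r.start),
                end=int(r.end),
                strand=str(r.strand),
                score=float(r.score),
                p_value=float(r.p_value),
                q_value=float(r.q_value),
            )
            for r in hits_df.itertuples(index=False)
        ]
        motif_ids = sorted(
            {p.motif_id for p in read_meme_motifs(_text(self.dir / "library.meme"))}
        )
        design = self._design(meta, clade_table)
        matrix = build_presence(hits, design, motif_ids, provenance="library scan")
        shared = {
            g: shared_motifs(matrix, g, quorum=self.config.shared_quorum)
            for g in design.gene_sets
        }
        cats = upset_partition(shared, gene_set_order=design.gene_sets)
        calls = []
        for g in design.gene_sets:
            calls.extend(
                clade_specific(
                    matrix,
                    g,
                    photo_of,
                    presence_quorum=self.config.clade_presence_quorum,
                )
            )
        out = []
        p = self.dir / "presence.tsv"
        p.write_text(presence_to_tsv(matrix))
        out.append(p)
        p = self.dir / "membership.tsv"
        p.write_text(membership_table(shared, design.gene_sets))
        out.append(p)
        cat_rows = [
            {
                "label": c.label,
                "gene_subset": ",".join(g for g in design.gene_sets if g in c.gene_subset),
                "n_motifs": len(c.member_motifs),
                "motifs": ",".join(sorted(c.member_motifs)),
            }
            for c in cats
        ]
        p = self.dir / "categories.tsv"
        p.write_text(
            pd.DataFrame(
                cat_rows, columns=["label", "gene_subset", "n_motifs", "motifs"]
            ).to_csv(sep="\t", index=False)
        )
        out.append(p)
        call_rows = [
            {
                "motif_id": c.motif_id,
                "gene_set": c.gene_set_id,
                "direction": c.direction,
                "supporting_species": ",".join(sorted(c.supporting_species)),
            }
            for c in calls
        ]
        p = self.dir / "clade_calls.tsv"
        p.write_text(
            pd.DataFrame(
                call_rows,
                columns=["motif_id", "gene_set", "direction", "supporting_species"],
            ).to_csv(sep="\t", index=False)
        )
        out.append(p)
        # positional clusters, per gene window
        bed_lines = []
        for (sp, gid), grp in hits_df.groupby(["species_id", "gene_id"], sort=True):
            win_hits = [h for h in hits if h.species_id == sp and h.gene_id == gid]
            for k, cl in enumerate(
                cluster_positions(win_hits, max_gap=self.config.cluster_max_gap)
            ):
                bed_lines.append(
                    f"{sp}|{gid}\t{cl.interval[0]}\t{cl.interval[1]}\t"
                    f"cluster_{k}\t{len(cl.member_hits)}\t+"
                )
        p = self.dir / "clusters.bed"
        p.write_text("\n".join(bed_lines) + ("\n" if bed_lines else ""))
        out.append(p)
        self._record("setanalysis", t0, out)
        return {"matrix": matrix, "shared": shared, "categories": cats, "calls": calls}

    # -- classify -----------------------------------------------------------
    def stage_classify(self, de_table: str | Path | None = None) -> pd.DataFrame:
        t0 = time.time()
        ortho = read_ortholog_map(_text(self.dir / "ortholog_map.tsv"))
        records = []
        if de_table is not None:
            records = read_de_table(_text(Path(de_table)))
        else:
            exp_dir = self.dir / "expression"
            for counts_path in sorted(exp_dir.glob("*.counts.tsv")):
                sp = counts_path.name.replace(".counts.tsv", "")
                counts = pd.read_csv(counts_path, sep="\t", index_col="transcript_id")
                sheet = pd.read_csv(exp_dir / f"{sp}.samples.tsv", sep="\t")
                groups = dict(zip(sheet["sample"], sheet["cell_type"]))
                records.extend(normalize_log2fc(counts, groups, species_id=sp))
        results = [
            classify_tf(
                tf,
                records,
                min_abs_log2fc=self.config.inclusion_log2fc,
                min_species=self.config.inclusion_min_species,
            )
            for tf in ortho
        ]
        df = classification_table(results)
        p = self.dir / "tf_classification.tsv"
        p.write_text(df.to_csv(sep="\t", index=False))
        self._record("classify", t0, [p])
        return df

    # -- run-all ------------------------------------------------------------
    def run_all(self, sim_config: SimulationConfig | None = None) -> dict:
        study = self.stage_simulate(sim_config)
        self.stage_extract()
        self.stage_cns()
        self.stage_discover()
        self.stage_scan()
        sets_out = self.stage_setanalysis()
        classify_df = self.stage_classify()
        return {"study": study, "sets": sets_out, "classification": classify_df}
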