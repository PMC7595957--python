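"""Mesophyll/bundle-sheath enrichment of trans-acting factors.

For each reference transcription factor (A. thaliana identifier) the grass
orthologs' log2 fold-changes of bundle-sheath over mesophyll expression
(log2FC > 0 = BS-enriched) are collected and the factor is classified:

- putative activator: every ortholog consistently BS-enriched;
- putative repressor: every ortholog consistently M-enriched;
- broad regulator: mixed directions;
- not classified: the inclusion rules fail (no |log2FC| >= 1, or evidence
  from fewer than two species).

Evidence comes either from precomputed differential-expression tables or
from raw count tables via a lightweight median-of-ratios normalization (the
full negative-binomial GLM machinery of DESeq2/edgeR is intentionally out of
scope; classification only consumes fold-changes and significance flags).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core_io import GrassregError

LABELS = (
    "putative_activator",
    "putative_repressor",
    "broad_regulator",
    "not_classified",
)

#: inclusion thresholds
MIN_ABS_LOG2FC = 1.0
MIN_SPECIES = 2
ADJ_P_CUTOFF = 0.05


@dataclass
class OrthologRecord:
    tf_id: str
    orthologs: list[tuple[str, str]]  # (species_id, transcript_id)

    def __post_init__(self) -> None:
        if not self.orthologs:
            raise GrassregError(f"{self.tf_id}: ortholog list is empty")
        seen: dict[str, set] = {}
        for sp, tx in self.orthologs:
            if tx in seen.setdefault(sp, set()):
                raise GrassregError(f"{self.tf_id}: duplicate transcript {tx} in {sp}")
            seen[sp].add(tx)


@dataclass
class EnrichmentRecord:
    transcript_id: str
    species_id: str
    log2fc: float  # log2(BS/M); positive = bundle-sheath-enriched
    significant: bool | None = None  # adjusted p < 0.05

    def __post_init__(self) -> None:
        if not np.isfinite(self.log2fc):
            raise GrassregError(f"{self.transcript_id}: non-finite log2fc")


@dataclass
class TFClassification:
    tf_id: str
    label: str
    evidence: list[EnrichmentRecord] = field(default_factory=list)


def normalize_log2fc(
    counts: pd.DataFrame, groups: dict[str, str], species_id: str = ""
) -> list[EnrichmentRecord]:
    """Median-of-ratios normalization and per-transcript log2(BS/M).

    ``counts`` is transcripts x samples (nonnegative integers); ``groups``
    maps sample name to "M" or "BS".  Size factors use the DESeq convention:
    per-transcript geometric mean across samples as reference, transcripts
    containing zeros excluded; ``log2fc = log2((mean BS + 0.5)/(mean M + 0.5))``
    on normalized counts.  Significance is left unset.
    """
    if counts.lt(0).any().any():
        raise GrassregError("counts must be nonnegative")
    m_samples = [s for s in counts.columns if groups.get(s) == "M"]
    bs_samples = [s for s in counts.columns if groups.get(s) == "BS"]
    if not m_samples or not bs_samples:
        raise GrassregError("need at least one sample per group (M and BS)")
    mat = counts[m_samples + bs_samples].to_numpy(dtype=np.float64)
    if np.any(mat.sum(axis=0) == 0):
        raise GrassregError("a sample has all-zero counts")
    with np.errstate(divide="ignore"):
        logmat = np.log(mat)
    usable = np.all(np.isfinite(logmat), axis=1)
    if not usable.any():
        raise GrassregError("no transcript is nonzero in every sample")
    ref = np.exp(logmat[usable].mean(axis=1))
    size_factors = np.median(mat[usable] / ref[:, None], axis=0)
    norm = mat / size_factors
    n_m = len(m_samples)
    mean_m = norm[:, :n_m].mean(axis=1)
    mean_bs = norm[:, n_m:].mean(axis=1)
    lfc = np.log2((mean_bs + 0.5) / (mean_m + 0.5))
    return [
        EnrichmentRecord(transcript_id=t, species_id=species_id, log2fc=float(v))
        for t, v in zip(counts.index, lfc)
    ]


def read_de_table(stream) -> list[EnrichmentRecord]:
    """Read a precomputed DE table (transcript_id, species_id, log2fc, adj_p).

    ``significant`` is strict: adjusted p < 0.05.  Rows whose log2fc is not
    numeric are dropped with a warning; missing columns are fatal.
    """
    df = pd.read_csv(stream, sep="\t", dtype=str, comment="#")
    required = {"transcript_id", "species_id", "log2fc", "adj_p"}
    if not required <= set(df.columns):
        raise GrassregError(
            f"DE table missing columns: {sorted(required - set(df.columns))}"
        )
    records = []
    for row in df.itertuples(index=False):
        try:
            lfc = float(row.log2fc)
            if not np.isfinite(lfc):
                raise ValueError
        except (TypeError, ValueError):
            warnings.warn(
                f"dropping DE row with non-numeric log2fc: {row.transcript_id}",
                stacklevel=2,
            )
            continue
        records.append(
            EnrichmentRecord(
                transcript_id=str(row.transcript_id),
                species_id=str(row.species_id),
                log2fc=lfc,
                significant=float(row.adj_p) < ADJ_P_CUTOFF,
            )
        )
    return records


def _records_for(tf: OrthologRecord, records: Sequence[EnrichmentRecord]):
    keys = {(sp, tx) for sp, tx in tf.orthologs}
    return [r for r in records if (r.species_id, r.transcript_id) in keys]


def apply_inclusion(
    tf: OrthologRecord,
    records: Sequence[EnrichmentRecord],
    min_abs_log2fc: float = MIN_ABS_LOG2FC,
    min_species: int = MIN_SPECIES,
) -> bool:
    """Inclusion rule: |log2FC| >= 1 somewhere and evidence from >= 2 species."""
    evid = _records_for(tf, records)
    if not evid:
        return False
    species = {r.species_id for r in evid}
    return (
        max(abs(r.log2fc) for r in evid) >= min_abs_log2fc
        and len(species) >= min_species
    )


def classify_tf(
    tf: OrthologRecord,
    records: Sequence[EnrichmentRecord],
    min_abs_log2fc: float = MIN_ABS_LOG2FC,
    min_species: int = MIN_SPECIES,
) -> TFClassification:
    """Classify one reference TF from its orthologs' enrichment evidence.

    Zero fold-changes are sign-neutral: they count as evidence rows but do not
    enter the all-positive/all-negative quantifiers.  A TF with no nonzero
    evidence stays unclassified.
    """
    evid = sorted(
        _records_for(tf, records), key=lambda r: (r.species_id, r.transcript_id)
    )
    if not apply_inclusion(tf, records, min_abs_log2fc, min_species):
        return TFClassification(tf_id=tf.tf_id, label="not_classified", evidence=evid)
    signs = {np.sign(r.log2fc) for r in evid} - {0.0}
    if signs == {1.0}:
        label = "putative_activator"
    elif signs == {-1.0}:
        label = "putative_repressor"
    elif signs == {1.0, -1.0}:
        label = "broad_regulator"
    else:
        label = "not_classified"
    return TFClassification(tf_id=tf.tf_id, label=label, evidence=evid)


def read_ortholog_map(stream) -> list[OrthologRecord]:
    """Ortholog map TSV (tf_id, species_id, transcript_id) -> records."""
    df = pd.read_csv(stream, sep="\t", dtype=str)
    required = {"tf_id", "species_id", "transcript_id"}
    if not required <= set(df.columns):
        raise GrassregError(
            f"ortholog map missing columns: {sorted(required - set(df.columns))}"
        )
    out = []
    for tf_id, grp in df.groupby("tf_id", sort=True):
        out.append(
            OrthologRecord(
                tf_id=str(tf_id),
                orthologs=[
                    (str(r.species_id), str(r.transcript_id))
                    for r in grp.itertuples(index=False)
                ],
            )
        )
    return out


def classification_table(
    classifications: Iterable[TFClassification],
) -> pd.DataFrame:
    rows = []
    for c in classifications:
        lfcs = [r.log2fc for r in c.evidence]
        rows.append(
            {
                "tf_id": c.tf_id,
                "label": c.label,
                "n_species": len({r.species_id for r in c.evidence}),
                "n_transcripts": len(c.evidence),
                "min_log2fc": min(lfcs) if lfcs else np.nan,
                "max_log2fc": max(lfcs) if lfcs else np.nan,
            }
        )
    return pd.DataFrame(rows)


def load_curated_enrichment() -> tuple[list[OrthologRecord], list[EnrichmentRecord]]:
    """Load the packaged curated BS/M enrichment table for grass orthologs of
    A. thaliana trans-acting factors, plus its ortholog map."""
    data = resources.files("grassreg.data")
    with (data / "tf_enrichment_c4_grasses.tsv").open() as fh:
        records = read_de_table(fh)
    with (data / "tf_ortholog_map.tsv").open() as fh:
        orthologs = read_ortholog_map(fh)
    return orthologs, records
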