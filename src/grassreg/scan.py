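"""PWM scanning of regulatory regions with exact p-values and FDR control.

Log-odds matrices are discretized on a uniform score grid; the null score
distribution under the 0-order background is obtained by exact dynamic-
programming convolution over motif columns, so every candidate position gets
an exact tail p-value on that grid.  Candidates are then filtered per batch by
Benjamini-Hochberg at q < 0.05 (strict), which is how scanned motif
occurrences become reportable TFBS.

The step-up q-values are computed here directly (q_(i) = min_{j>=i} p_(j)*m/j)
rather than through a stats library so the arithmetic is bit-reproducible
against an independent implementation of the same formula.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

from .core_io import GeneWindow, GrassregError, RegulatoryRegionSet
from .motifs import PWM

DEFAULT_ALPHA = 0.05


@dataclass
class LogOddsMatrix:
    motif_id: str
    scores: np.ndarray  # (4, w) log2 odds
    granularity: float  # discretization unit

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if not np.all(np.isfinite(self.scores)):
            raise GrassregError(f"{self.motif_id}: non-finite log-odds")
        if self.granularity <= 0:
            raise GrassregError(f"{self.motif_id}: granularity must be > 0")

    @property
    def width(self) -> int:
        return self.scores.shape[1]

    @property
    def int_scores(self) -> np.ndarray:
        """Per-column scores rounded to integer multiples of the granularity."""
        return np.rint(self.scores / self.granularity).astype(np.int64)


@dataclass
class ScoreDistribution:
    motif_id: str
    support: np.ndarray  # ascending discretized scores (score units)
    tail_p: np.ndarray  # P(null score >= support[k])
    _min_int: int = 0
    _granularity: float = 1.0

    def pvalue_int(self, s: int) -> float:
        idx = s - self._min_int
        if idx < 0:
            return 1.0
        if idx >= self.tail_p.size:
            return float(self.tail_p[-1])
        return float(self.tail_p[idx])

    def pvalues_int(self, s: np.ndarray) -> np.ndarray:
        idx = np.clip(s - self._min_int, 0, self.tail_p.size - 1)
        p = self.tail_p[idx]
        return np.where(s - self._min_int < 0, 1.0, p)


@dataclass
class MotifHit:
    motif_id: str
    gene_id: str
    species_id: str
    feature_class: str
    start: int
    end: int
    strand: str
    score: float
    p_value: float
    q_value: float | None = None


def build_log_odds(
    pwm: PWM,
    background: np.ndarray | None = None,
    pseudocount: float = 0.01,
    granularity: float | None = None,
) -> LogOddsMatrix:
    """Pseudocount-regularized log2-odds matrix of a PWM vs the background.

    ``score[b,i] = log2((p[b,i]*(1-4*pc') + pc') / bg[b])`` with
    ``pc' = pseudocount/(1+4*pseudocount)``; a PWM identical to the background
    maps to the all-zero matrix when pseudocount is 0.
    """
    bg = pwm.background if background is None else np.asarray(background, float)
    if np.any(bg <= 0):
        raise GrassregError(f"{pwm.motif_id}: zero background frequency")
    pc = pseudocount / (1.0 + 4.0 * pseudocount)
    reg = pwm.probs * (1.0 - 4.0 * pc) + pc
    scores = np.log2(reg / bg[:, None])
    if granularity is None:
        rng = scores.max(axis=0).sum() - scores.min(axis=0).sum()
        granularity = max(rng, 1e-9) / 1000.0
    return LogOddsMatrix(motif_id=pwm.motif_id, scores=scores, granularity=granularity)


def null_distribution(
    lom: LogOddsMatrix, background: np.ndarray
) -> ScoreDistribution:
    """Exact null score distribution by DP convolution over motif columns."""
    bg = np.asarray(background, dtype=np.float64)
    if bg.shape != (4,) or np.any(bg < 0):
        raise GrassregError("background must be 4 nonnegative frequencies")
    bg = bg / bg.sum()
    iscores = lom.int_scores
    lo = int(iscores.min(axis=0).sum())
    hi = int(iscores.max(axis=0).sum())
    probs = np.zeros(hi - lo + 1)
    # DP over columns: probs[k] = P(sum of first i columns == lo_i + k)
    cur = np.array([1.0])
    cur_lo = 0
    for i in range(lom.width):
        col = iscores[:, i]
        clo, chi = int(col.min()), int(col.max())
        nxt = np.zeros(cur.size + (chi - clo))
        for b in range(4):
            off = int(col[b]) - clo
            nxt[off : off + cur.size] += bg[b] * cur
        cur = nxt
        cur_lo += clo
    probs[cur_lo - lo : cur_lo - lo + cur.size] = cur
    tail = np.minimum(1.0, np.maximum(0.0, np.cumsum(probs[::-1])[::-1]))
    support = (np.arange(lo, hi + 1)) * lom.granularity
    return ScoreDistribution(
        motif_id=lom.motif_id,
        support=support,
        tail_p=tail,
        _min_int=lo,
        _granularity=lom.granularity,
    )


_ENC_TABLE = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _ENC_TABLE[ord(_b)] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENC_TABLE[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]


def scan_window(
    window: GeneWindow,
    regions: RegulatoryRegionSet,
    lom: LogOddsMatrix,
    dist: ScoreDistribution,
) -> list[MotifHit]:
    """Score every offset of every regulatory region on both strands.

    N bases contribute zero log-odds but positions containing them are still
    scanned.  Hits never cross a region boundary; regions shorter than the
    motif yield no candidates.
    """
    w = lom.width
    iscores = lom.int_scores
    # 5th row: N scores 0 on both strands
    fwd = np.vstack([iscores, np.zeros((1, w), dtype=np.int64)])
    rc = np.vstack([iscores[::-1, ::-1], np.zeros((1, w), dtype=np.int64)])
    kidx = np.arange(w)
    hits: list[MotifHit] = []
    for (rs, re_), fclass in regions.regions:
        if re_ - rs < w:
            continue
        codes = _encode(window.sequence[rs:re_])
        wins = np.lib.stride_tricks.sliding_window_view(codes, w)
        for strand, mat in (("+", fwd), ("-", rc)):
            s_int = mat[wins, kidx].sum(axis=1)
            pvals = dist.pvalues_int(s_int)
            for off in range(s_int.size):
                hits.append(
                    MotifHit(
                        motif_id=lom.motif_id,
                        gene_id=window.gene_id,
                        species_id=window.species_id,
                        feature_class=fclass,
                        start=rs + off,
                        end=rs + off + w,
                        strand=strand,
                        score=float(s_int[off] * lom.granularity),
                        p_value=float(pvals[off]),
                    )
                )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def scan_window_arrays(
    window: GeneWindow,
    regions: RegulatoryRegionSet,
    lom: LogOddsMatrix,
    dist: ScoreDistribution,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Array-valued version of :func:`scan_window` for large batch scans.

    Returns ``(starts, strands, scores, pvals, classes)`` where ``strands`` is
    0 for '+' / 1 for '-' and ``classes`` maps positions to feature classes by
    parallel index.  Semantics match :func:`scan_window` exactly.
    """
    w = lom.width
    iscores = lom.int_scores
    fwd = np.vstack([iscores, np.zeros((1, w), dtype=np.int64)])
    rc = np.vstack([iscores[::-1, ::-1], np.zeros((1, w), dtype=np.int64)])
    kidx = np.arange(w)
    starts_l, strands_l, scores_l, classes = [], [], [], []
    for (rs, re_), fclass in regions.regions:
        if re_ - rs < w:
            continue
        codes = _encode(window.sequence[rs:re_])
        wins = np.lib.stride_tricks.sliding_window_view(codes, w)
        n = wins.shape[0]
        for scode, mat in ((0, fwd), (1, rc)):
            s_int = mat[wins, kidx].sum(axis=1)
            starts_l.append(np.arange(rs, rs + n))
            strands_l.append(np.full(n, scode, dtype=np.int8))
            scores_l.append(s_int)
            classes.extend([fclass] * n)
    if not starts_l:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty.astype(np.int8), empty, np.empty(0), []
    starts = np.concatenate(starts_l)
    strands = np.concatenate(strands_l)
    scores = np.concatenate(scores_l)
    pvals = dist.pvalues_int(scores)
    return starts, strands, scores, pvals, classes


def bh_qvalues(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values: q_(i) = min_{j>=i} p_(j)*m/j."""
    p = np.asarray(pvals, dtype=np.float64)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, m + 1, dtype=np.float64)
    scaled = p[order] * m / ranks
    q_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def bh_filter(
    candidates: Sequence[MotifHit],
    alpha: float = DEFAULT_ALPHA,
    batch_key: Callable[[MotifHit], tuple] | None = None,
    return_all: bool = False,
) -> list[MotifHit]:
    """Attach BH q-values per batch; retain hits with q < alpha (strict).

    The default batch is the whole candidate list: one scan run of one motif
    library over one orthologous gene set in one species.  A ``batch_key``
    callable may split candidates into finer batches.
    """
    if not candidates:
        return []
    batches: dict[tuple, list[MotifHit]] = {}
    for h in candidates:
        batches.setdefault(batch_key(h) if batch_key else (), []).append(h)
    out: list[MotifHit] = []
    for hs in batches.values():
        q = bh_qvalues(np.array([h.p_value for h in hs]))
        for h, qv in zip(hs, q):
            h.q_value = float(qv)
            if return_all or qv < alpha:
                out.append(h)
    out.sort(key=lambda h: (h.motif_id, h.gene_id, h.species_id, h.start, h.strand))
    return out


def hits_to_bed6(hits: Iterable[MotifHit]) -> str:
    """Hits as BED6 (window-relative; score column = -10*log10 q)."""
    lines = []
    for h in hits:
        q = h.q_value if h.q_value else 1e-300
        score = int(min(1000, round(-10 * np.log10(q))))
        lines.append(
            f"{h.species_id}|{h.gene_id}\t{h.start}\t{h.end}\t"
            f"{h.motif_id}\t{score}\t{h.strand}"
        )
    return "\n".join(lines) + ("\n" if lines else "")


def hits_to_tsv(hits: Iterable[MotifHit]) -> str:
    """Hit table as TSV (one row per retained occurrence)."""
    header = (
        "motif_id\tgene_id\tspecies_id\tfeature_class\tstart\tend\t"
        "strand\tscore\tp_value\tq_value"
    )
    rows = [header]
    for h in hits:
        q = "" if h.q_value is None else f"{h.q_value:.6g}"
        rows.append(
            f"{h.motif_id}\t{h.gene_id}\t{h.species_id}\t{h.feature_class}\t"
            f"{h.start}\t{h.end}\t{h.strand}\t{h.score:.4f}\t"
            f"{h.p_value:.6g}\t{q}"
        )
    return "\n".join(rows) + "\n"
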