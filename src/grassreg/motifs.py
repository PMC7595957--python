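"""Position weight matrices and ZOOPS motif discovery.

One ungapped motif is discovered per CNS set with a zero-or-one-occurrence-
per-sequence (ZOOPS) finite mixture fitted by expectation-maximization: each
sequence either contains no site (probability ``1-gamma``) or exactly one
site, uniformly placed on either strand.  Model selection over a width grid
uses a BIC-penalized log-likelihood; MEME's E-value machinery is deliberately
not reproduced.

The ``loglik`` tracked by the fitted model is the penalized log-likelihood
(data log-likelihood plus the Dirichlet smoothing term implied by the M-step
pseudocount); this is the quantity EM is guaranteed to never decrease.  The
plain data log-likelihood is kept alongside as ``data_loglik``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core_io import GrassregError

ALPHABET = "ACGT"
_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _encode(seq: str) -> np.ndarray:
    table = np.full(256, 4, dtype=np.int64)
    for i, b in enumerate(ALPHABET):
        table[ord(b)] = i
    return table[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]


@dataclass
class PWM:
    """Column-stochastic 4 x w nucleotide probability matrix."""

    motif_id: str
    probs: np.ndarray  # shape (4, w), rows in A,C,G,T order
    nsites: float = 20.0
    source: str = "discovered"  # "discovered" | "library"
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        self.background = np.asarray(self.background, dtype=np.float64)
        if self.probs.ndim != 2 or self.probs.shape[0] != 4:
            raise GrassregError(f"PWM {self.motif_id}: probs must be 4 x w")
        if np.any(self.probs < 0) or np.any(self.background < 0):
            raise GrassregError(f"PWM {self.motif_id}: negative probabilities")
        colsums = self.probs.sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > 1e-6):
            raise GrassregError(f"PWM {self.motif_id}: columns do not sum to 1")
        self.probs = self.probs / colsums
        if abs(self.background.sum() - 1.0) > 1e-6:
            raise GrassregError(f"PWM {self.motif_id}: background does not sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.probs.argmax(axis=0))

    def reverse_complement(self) -> "PWM":
        return PWM(
            motif_id=self.motif_id,
            probs=self.probs[::-1, ::-1].copy(),
            nsites=self.nsites,
            source=self.source,
            background=self.background.copy(),
        )


@dataclass
class ZoopsModel:
    pwm: PWM
    gamma: float
    background: np.ndarray
    loglik: float  # penalized log-likelihood (see module docstring)
    data_loglik: float = float("nan")
    n_iter: int = 0
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))


def information_content(pwm: PWM) -> tuple[np.ndarray, float]:
    """Bits per column (2 + sum p log2 p, uniform background) and their total."""
    p = pwm.probs
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    per_col = 2.0 + plogp.sum(axis=0)
    return per_col, float(per_col.sum())


def estimate_background(seqs: list[str]) -> np.ndarray:
    """0-order base frequencies of a sequence set (ambiguous bases ignored).

    Complementary bases are averaged (A=T, C=G) so that the background — and
    hence the whole two-strand ZOOPS likelihood — is strand-symmetric.
    """
    counts = np.ones(4)  # +1 to avoid zero frequencies
    for s in seqs:
        codes = _encode(s)
        counts += np.bincount(codes[codes < 4], minlength=4)[:4]
    counts = 0.5 * (counts + counts[::-1])
    return counts / counts.sum()


def seed_candidates(seqs: list[str], w: int, top_k: int = 10) -> list[PWM]:
    """Top-k most frequent w-mers (reverse complements collapsed) as soft PWMs.

    Each seed's matched base gets probability 0.5, the others 1/6.  Order is
    deterministic: count descending, then canonical w-mer lexicographically.
    """
    if not seqs:
        raise GrassregError("no sequences to seed from")
    if w > min(len(s) for s in seqs):
        raise GrassregError(f"seed width {w} exceeds shortest sequence")
    counts: dict[str, int] = {}
    for s in seqs:
        s = s.upper()
        for i in range(len(s) - w + 1):
            kmer = s[i : i + w]
            if any(b not in ALPHABET for b in kmer):
                continue
            canon = min(kmer, revcomp(kmer))
            counts[canon] = counts.get(canon, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top_k]
    seeds = []
    for kmer, cnt in ranked:
        probs = np.full((4, w), 1.0 / 6.0)
        for i, b in enumerate(kmer):
            probs[:, i] = 1.0 / 6.0
            probs[ALPHABET.index(b), i] = 0.5
        seeds.append(PWM(motif_id=f"seed_{kmer}", probs=probs, nsites=float(cnt)))
    return seeds


def _site_log_odds(codes: np.ndarray, log_ratio: np.ndarray, w: int) -> np.ndarray:
    """Sum of per-position log odds for every offset; shape (n_offsets,)."""
    m = codes.shape[0] - w + 1
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)
    return log_ratio[windows, np.arange(w)].sum(axis=1)


def em_zoops(
    seqs: list[str],
    seed: PWM,
    max_iter: int = 200,
    tol: float = 1e-6,
    pseudocount: float = 0.01,
    background: np.ndarray | None = None,
    gamma0: float = 0.5,
) -> ZoopsModel:
    """Fit the two-strand ZOOPS mixture by EM starting from ``seed``.

    Ambiguous (N) bases are probability-neutral under both motif and
    background.  Sequences shorter than the seed width are fatal.
    """
    if not seqs:
        raise GrassregError("empty sequence set")
    w = seed.width
    if w > min(len(s) for s in seqs):
        raise GrassregError(f"motif width {w} exceeds shortest sequence")
    bg = estimate_background(seqs) if background is None else np.asarray(background)
    codes = [_encode(s) for s in seqs]
    fwd = [np.lib.stride_tricks.sliding_window_view(c, w) for c in codes]
    rc_codes = [_encode(revcomp(s)) for s in seqs]
    rev = [np.lib.stride_tricks.sliding_window_view(c, w) for c in rc_codes]

    probs = seed.probs.copy()
    gamma = gamma0
    trace = []
    prev = -np.inf
    log_bg = np.log(bg)
    kidx = np.arange(w)
    for it in range(max_iter):
        # E-step: per-sequence posterior over {no site} u {offset x strand}
        with np.errstate(divide="ignore"):
            lp = np.vstack([np.log(probs), np.zeros((1, w))])  # N row neutral
            lb = np.concatenate([log_bg, [0.0]])
        log_ratio = lp - lb[:, None]
        data_ll = 0.0
        new_counts = np.zeros((5, w))  # row 4 collects (discarded) N weight
        gamma_num = 0.0
        for si in range(len(seqs)):
            lof = log_ratio[fwd[si], kidx].sum(axis=1)
            lor = log_ratio[rev[si], kidx].sum(axis=1)
            lo = np.concatenate([lof, lor])
            m_i = lof.shape[0]
            site_log = np.log(gamma) - np.log(2.0 * m_i) + lo if gamma > 0 else np.full(lo.shape, -np.inf)
            none_log = np.log1p(-gamma) if gamma < 1 else -np.inf
            allv = np.concatenate(([none_log], site_log))
            mx = allv.max()
            z = np.exp(allv - mx)
            zsum = z.sum()
            z /= zsum
            seq_ll = mx + np.log(zsum)  # log-lik relative to pure background
            cb = codes[si]
            bgl = log_bg[cb[cb < 4]].sum()
            data_ll += seq_ll + bgl
            gamma_num += 1.0 - z[0]
            zf = z[1 : 1 + m_i]
            zr = z[1 + m_i :]
            np.add.at(new_counts, (fwd[si], kidx), zf[:, None])
            np.add.at(new_counts, (rev[si], kidx), zr[:, None])
        if not np.isfinite(data_ll):
            raise GrassregError(f"non-finite likelihood at EM iteration {it}")
        penalized = data_ll + pseudocount * np.log(probs).sum()
        trace.append(penalized)
        if penalized - prev < tol and it > 0:
            prev = penalized
            break
        prev = penalized
        # M-step (N-weighted mass in row 4 is dropped)
        acgt = new_counts[:4] + pseudocount
        probs = acgt / acgt.sum(axis=0)
        gamma = min(1.0 - 1e-12, max(1e-12, gamma_num / len(seqs)))

    pwm = PWM(
        motif_id=seed.motif_id.replace("seed_", "zoops_"),
        probs=probs,
        nsites=max(1.0, gamma * len(seqs)),
        source="discovered",
        background=bg,
    )
    return ZoopsModel(
        pwm=pwm,
        gamma=float(gamma),
        background=bg,
        loglik=float(prev),
        data_loglik=float(data_ll),
        n_iter=len(trace),
        loglik_trace=np.asarray(trace),
    )


def select_motif(
    seqs: list[str],
    w_min: int = 6,
    w_max: int | None = None,
    seeds_per_width: int = 5,
    widths: list[int] | None = None,
    low_ic_bits: float = 4.0,
    **em_kwargs,
) -> PWM:
    """Discover one motif: EM over a width grid, BIC-penalized selection.

    The maximum width defaults to the shortest sequence length (the motif can
    be at most as wide as the shortest CNS).  Returns the PWM of the model
    maximizing ``loglik - 0.5*(3w+1)*log(total sequence length)``; ties go to
    the earlier (width, seed) in the deterministic grid order.  Motifs with
    total information content below ``low_ic_bits`` are flagged
    ``low_confidence`` in ``PWM.notes``.
    """
    if len(seqs) < 2:
        raise GrassregError("motif discovery needs at least 2 sequences")
    shortest = min(len(s) for s in seqs)
    if w_max is None:
        w_max = shortest
    w_max = min(w_max, shortest)
    if w_min > w_max:
        raise GrassregError(f"w_min {w_min} > w_max {w_max}")
    grid = widths if widths is not None else list(range(w_min, w_max + 1))
    grid = [w for w in grid if w_min <= w <= w_max]
    if not grid:
        raise GrassregError("empty width grid")
    total_len = sum(len(s) for s in seqs)
    best: tuple[float, ZoopsModel] | None = None
    for w in grid:
        for seed in seed_candidates(seqs, w, top_k=seeds_per_width):
            model = em_zoops(seqs, seed, **em_kwargs)
            bic = model.loglik - 0.5 * (3 * w + 1) * np.log(total_len)
            if best is None or bic > best[0]:
                best = (bic, model)
    assert best is not None
    model = best[1]
    pwm = model.pwm
    _, total_ic = information_content(pwm)
    pwm.notes.update(
        loglik=model.loglik,
        gamma=model.gamma,
        bic=best[0],
        low_confidence=bool(total_ic < low_ic_bits),
        total_ic=total_ic,
    )
    return pwm


# ---------------------------------------------------------------------------
# MEME minimal motif format


def write_meme(pwms: list[PWM], background: np.ndarray | None = None) -> str:
    """Serialize PWMs in MEME minimal motif format."""
    bg = np.full(4, 0.25) if background is None else np.asarray(background)
    out = [
        "MEME version 4",
        "",
        "ALPHABET= ACGT",
        "",
        "strands: + -",
        "",
        "Background letter frequencies",
        " ".join(f"{b} {f:.6f}" for b, f in zip(ALPHABET, bg)),
        "",
    ]
    for pwm in pwms:
        out.append(f"MOTIF {pwm.motif_id}")
        out.append(
            f"letter-probability matrix: alength= 4 w= {pwm.width} "
            f"nsites= {pwm.nsites:g} E= 0"
        )
        for col in pwm.probs.T:
            out.append(" ".join(f"{p:.6f}" for p in col))
        out.append("")
    return "\n".join(out) + "\n"


def read_meme_motifs(stream) -> list[PWM]:
    """Read a MEME minimal motif file into PWMs.

    The file-level background line is attached to every motif (uniform when
    absent).  Columns off by more than 1e-3 from stochasticity are
    renormalized with a warning; truncated motif blocks are fatal.

    The matrix lines are parsed directly (full float precision is kept, so a
    write/read round trip preserves probabilities to 1e-6 or better).
    """
    text = stream.read() if hasattr(stream, "read") else str(stream)
    lines = text.splitlines()
    if not any(ln.strip().startswith("MEME version") for ln in lines[:5]):
        raise GrassregError("malformed MEME minimal file: missing version line")
    bg = np.full(4, 0.25)
    out: list[PWM] = []
    i = 0
    while i < len(lines):
        ln = lines[i].strip()
        if ln.startswith("Background letter frequencies"):
            i += 1
            toks = lines[i].split()
            vals = {toks[k]: float(toks[k + 1]) for k in range(0, len(toks) - 1, 2)}
            bg = np.array([vals.get(b, 0.25) for b in ALPHABET])
            bg = bg / bg.sum()
        elif ln.startswith("MOTIF"):
            parts = ln.split()
            if len(parts) < 2:
                raise GrassregError(f"MOTIF line without identifier: {ln!r}")
            name = parts[1]
            i += 1
            while i < len(lines) and not lines[i].strip().startswith(
                "letter-probability matrix"
            ):
                if lines[i].strip().startswith("MOTIF"):
                    raise GrassregError(f"motif {name}: missing probability matrix")
                i += 1
            if i >= len(lines):
                raise GrassregError(f"motif {name}: truncated block")
            toks = lines[i].split()
            w = int(toks[toks.index("w=") + 1]) if "w=" in toks else None
            nsites = (
                float(toks[toks.index("nsites=") + 1]) if "nsites=" in toks else 20.0
            )
            rows = []
            i += 1
            while i < len(lines):
                vals = lines[i].split()
                if len(vals) == 4:
                    try:
                        rows.append([float(v) for v in vals])
                    except ValueError:
                        break
                    i += 1
                else:
                    break
            if w is None:
                w = len(rows)
            if len(rows) < w:
                raise GrassregError(
                    f"motif {name}: truncated block ({len(rows)}/{w} rows)"
                )
            mat = np.array(rows[:w]).T  # (4, w)
            colsums = mat.sum(axis=0)
            if np.any(colsums <= 0):
                raise GrassregError(f"motif {name}: empty probability column")
            if np.any(np.abs(colsums - 1.0) > 1e-3):
                warnings.warn(
                    f"motif {name}: columns renormalized (sums deviate > 1e-3)",
                    stacklevel=2,
                )
            out.append(
                PWM(
                    motif_id=name,
                    probs=mat / colsums,
                    nsites=nsites,
                    source="library",
                    background=bg.copy(),
                )
            )
            continue
        i += 1
    return out
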