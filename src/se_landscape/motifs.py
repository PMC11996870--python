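"""Position-weight-matrix construction and motif scanning.

Count matrices (JASPAR-style PFMs) are converted to log2-odds PWMs with a
background-split pseudocount; sequences are scanned on both strands and
hits reported above a fraction of the maximum attainable score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Pwm:
    """Log2-odds position weight matrix.

    ``matrix`` has shape (L, 4) with columns A, C, G, T; ``max_score`` is
    the sum over positions of the per-position maximum.
    """

    matrix: np.ndarray
    background: np.ndarray
    max_score: float = field(init=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must have shape (L, 4)")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("PWM entries must be finite (pseudocounted)")
        self.max_score = float(self.matrix.max(axis=1).sum())

    @property
    def length(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class MotifHit:
    """A motif occurrence at forward-strand coordinates."""

    sequence_id: str
    position: int
    strand: str
    score: float
    score_fraction: float


def pwm_from_counts(
    pfm: np.ndarray,
    pseudocount: float = 0.8,
    background: np.ndarray | None = None,
) -> Pwm:
    """Build a log2-odds PWM from an (L, 4) count matrix.

    prob(b, i) = (count(b, i) + pseudocount * background_b)
                 / (column_total_i + pseudocount);
    log-odds = log2(prob / background_b).  The pseudocount is split across
    bases by the background composition (the common JASPAR convention).
    """
    pfm = np.asarray(pfm, dtype=float)
    if pfm.ndim != 2 or pfm.shape[1] != 4:
        raise ValueError("PFM must have shape (L, 4) in A,C,G,T order")
    if np.any(pfm < 0):
        raise ValueError("PFM counts must be non-negative")
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    if not np.isclose(bg.sum(), 1.0) or np.any(bg <= 0):
        raise ValueError("background must be positive and sum to 1")
    totals = pfm.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        raise ValueError("every PFM column must have positive total")
    prob = (pfm + pseudocount * bg[None, :]) / (totals + pseudocount)
    return Pwm(matrix=np.log2(prob / bg[None, :]), background=bg)


def pfm_from_consensus(consensus: str, count: int = 100) -> np.ndarray:
    """A degenerate (L, 4) count matrix putting all mass on a consensus."""
    pfm = np.zeros((len(consensus), 4))
    for i, base in enumerate(consensus.upper()):
        pfm[i, _BASE_INDEX[base]] = count
    return pfm


def _window_scores(pwm: Pwm, seq: str) -> np.ndarray:
    """Score every forward-strand window; windows containing N get -inf."""
    L = pwm.length
    codes = np.array([_BASE_INDEX.get(b, -1) for b in seq], dtype=int)
    n_windows = len(seq) - L + 1
    scores = np.zeros(n_windows)
    valid = np.ones(n_windows, dtype=bool)
    for j in range(L):
        col = codes[j : j + n_windows]
        bad = col < 0
        valid &= ~bad
        scores += pwm.matrix[j, np.where(bad, 0, col)]
    scores[~valid] = -np.inf
    return scores


def scan_motif(
    pwm: Pwm,
    sequence: str,
    min_fraction: float = 0.8,
    sequence_id: str = "",
) -> list[MotifHit]:
    """Scan a DNA sequence on both strands for PWM matches.

    Every window is scored on the forward strand and on the reverse
    complement; reverse-strand hits are reported at forward coordinates
    with strand '-'.  Hits with score >= min_fraction * max_score are
    returned sorted by position, '+' before '-'.  Windows containing N
    never match.
    """
    seq = sequence.upper()
    if not seq:
        raise ValueError("empty sequence")
    L = pwm.length
    if L > len(seq):
        return []
    if pwm.max_score <= 0:
        raise ValueError("uninformative PWM (max_score <= 0) cannot be scanned")
    threshold = min_fraction * pwm.max_score
    hits: list[MotifHit] = []
    fwd = _window_scores(pwm, seq)
    rc_scores = _window_scores(pwm, reverse_complement(seq))
    n_windows = len(seq) - L + 1
    for pos in range(n_windows):
        if fwd[pos] >= threshold:
            hits.append(
                MotifHit(sequence_id, pos, "+", float(fwd[pos]),
                         float(fwd[pos] / pwm.max_score))
            )
        # window starting at pos on the forward strand corresponds to the
        # reverse-complement window starting at len(seq) - L - pos
        rc = rc_scores[len(seq) - L - pos]
        if rc >= threshold:
            hits.append(
                MotifHit(sequence_id, pos, "-", float(rc),
                         float(rc / pwm.max_score))
            )
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits
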