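"""Ankyrin-repeat detection by consensus similarity, and A-F class labels.

The ankyrin repeat (ANK) is a 33-residue helix-turn-helix motif that
occurs in tandem arrays.  Detection slides a 33-column window along the
protein and scores each window column-by-column against the packaged
33-residue ANK consensus with BLOSUM62; windows at or above the score
threshold are kept, overlaps resolved greedily by descending score.

Family members carry 2-7 repeats; the repeat count maps onto the
six classes A..F (A=2 ... F=7).  Other counts are "unclassified".
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
from Bio.Align import substitution_matrices

from .seqio import ProteinRecord

ANK_REPEAT_LENGTH = 33

#: repeat-count -> class label; 2..7 map to A..F
ANK_CLASSES = {2: "A", 3: "B", 4: "C", 5: "D", 6: "E", 7: "F"}


def _load_consensus() -> str:
    text = resources.files("xb3scan.data").joinpath("ank_consensus.txt").read_text()
    lines = [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    consensus = "".join(lines)
    assert len(consensus) == ANK_REPEAT_LENGTH
    return consensus


ANK_CONSENSUS: str = _load_consensus()

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

#: default acceptance threshold in BLOSUM62 score units.  The consensus
#: self-score is 168; repeats carrying up to 4 point mutations still score
#: >= ~130, while the maximum window score over 1000 random length-400
#: sequences is ~30 (calibrate_threshold at target_fpr=0 returns 30).
#: 80 sits midway, leaving a wide margin on both sides.
DEFAULT_ANK_THRESHOLD = 80.0


@dataclass(frozen=True)
class AnkRepeat:
    """One detected repeat: 1-based inclusive interval of length 33 + score."""

    start: int
    end: int
    score: float

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != ANK_REPEAT_LENGTH:
            raise ValueError("ANK repeat interval must span exactly 33 residues")


@dataclass(frozen=True)
class AnkAnnotation:
    """Ordered non-overlapping repeats, their count, and the A-F class."""

    repeats: tuple[AnkRepeat, ...]
    count: int
    ank_class: str

    def __post_init__(self) -> None:
        starts = [r.start for r in self.repeats]
        if starts != sorted(starts):
            raise ValueError("repeats must be sorted by start")
        for a, b in zip(self.repeats, self.repeats[1:]):
            if b.start <= a.end:
                raise ValueError("repeats must not overlap")


def score_window(window: str) -> float:
    """BLOSUM62 similarity of a 33-mer against the packaged consensus."""
    if len(window) != ANK_REPEAT_LENGTH:
        raise ValueError("window must have length 33")
    return float(sum(_BLOSUM62[c, w] for c, w in zip(ANK_CONSENSUS, window)))


def consensus_self_score() -> float:
    """Global maximum achievable window score (consensus vs itself)."""
    return score_window(ANK_CONSENSUS)


def _window_scores(seq: str) -> np.ndarray:
    """Scores of every 33-residue window, vectorised over positions."""
    n = len(seq) - ANK_REPEAT_LENGTH + 1
    if n <= 0:
        return np.empty(0)
    alphabet = _BLOSUM62.alphabet
    index = {ch: i for i, ch in enumerate(alphabet)}
    mat = np.asarray(_BLOSUM62)
    cons_idx = np.array([index[c] for c in ANK_CONSENSUS])
    seq_idx = np.array([index[c] for c in seq])
    windows = np.lib.stride_tricks.sliding_window_view(seq_idx, ANK_REPEAT_LENGTH)
    return mat[cons_idx[None, :], windows].sum(axis=1)


def scan_ank(record: ProteinRecord, threshold: float = DEFAULT_ANK_THRESHOLD) -> AnkAnnotation:
    """Detect tandem ANK repeats and assign the repeat-count class.

    Candidate windows with score >= threshold are accepted greedily in
    order of descending score (ties to the leftmost window), discarding
    any window overlapping an already accepted one.  Sequences shorter
    than 33 residues trivially carry no repeat.
    """
    scores = _window_scores(record.seq)
    order = np.lexsort((np.arange(len(scores)), -scores))
    taken: list[tuple[int, float]] = []
    for idx in order:
        s = scores[idx]
        if s < threshold:
            break
        if any(not (idx + ANK_REPEAT_LENGTH <= t or idx >= t + ANK_REPEAT_LENGTH) for t, _ in taken):
            continue
        taken.append((int(idx), float(s)))
    taken.sort()
    repeats = tuple(
        AnkRepeat(start=i + 1, end=i + ANK_REPEAT_LENGTH, score=s) for i, s in taken
    )
    count = len(repeats)
    return AnkAnnotation(
        repeats=repeats, count=count, ank_class=ANK_CLASSES.get(count, "unclassified")
    )


@dataclass(frozen=True)
class CalibrationResult:
    """Threshold chosen at the requested false-positive rate, with its
    empirical sensitivity on the positive set and the score landscape."""

    threshold: float
    sensitivity: float
    fpr: float
    max_negative_score: float


def calibrate_threshold(
    positives: list[str],
    negatives: list[str],
    target_fpr: float = 0.0,
) -> CalibrationResult:
    """Smallest score threshold with empirical FPR <= target on negatives.

    Positives are individual 33-residue repeat instances scored directly;
    negatives are full-length sequences scored by their maximum window
    score (a negative counts as a false positive when any window reaches
    the threshold).  Raising ``target_fpr`` never raises the returned
    threshold.
    """
    if not positives or not negatives:
        raise ValueError("both positive and negative sets must be non-empty")
    pos_scores = np.array([score_window(p) for p in positives])
    neg_scores = np.array(
        [
            _window_scores(n).max() if len(n) >= ANK_REPEAT_LENGTH else -np.inf
            for n in negatives
        ]
    )
    # candidate thresholds: every observed score plus one unit above the top
    candidates = np.unique(np.concatenate([pos_scores, neg_scores[np.isfinite(neg_scores)],
                                           [neg_scores.max() + 1.0]]))
    for thr in candidates:
        fpr = float(np.mean(neg_scores >= thr))
        if fpr <= target_fpr:
            return CalibrationResult(
                threshold=float(thr),
                sensitivity=float(np.mean(pos_scores >= thr)),
                fpr=fpr,
                max_negative_score=float(neg_scores.max()),
            )
    raise ValueError(
        f"target_fpr={target_fpr} unattainable; achievable minimum is "
        f"{float(np.mean(neg_scores >= neg_scores.max() + 1.0))}"
    )
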