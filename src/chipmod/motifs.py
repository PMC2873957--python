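"""OCT4 motif reconstruction, PWM scanning and motif quality filters.

The octamer ATGCAAAT is the OCT4 consensus. Its position weight matrix
is rebuilt from the data itself: every word within Levenshtein distance
2 of the octamer is harvested from peak-region sequences, adjacent
matches separated by at most 1 nt are fused into the longest match, and
the aligned words are stacked into a PWM whose columns are
pseudocounted base probabilities. Scanning scores a window as the
summed log2 odds of the window's bases against a background model
("bits"); a perfect octamer under its own zero-pseudocount PWM scores
8 * log2(4) = 16 bits. The operational score threshold is not a
constant but is calibrated as the median best score over regions with
high consensus peak scores.

Fixed dual-OCT4 elements — the PORE (ATTTGAAATGCAAAT) and the
palindromic MORE (ATGCATATGCAT) — are matched exactly. Two quality
filters prune reconstructed motif sets: near-duplicate PWMs (alignment
difference < 0.2) are collapsed onto the highest-information member,
and low-complexity words (overlapping-dinucleotide entropy < 1 bit) are
discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import MOTIF_WORDS, reverse_complement

__all__ = [
    "Pwm",
    "MotifHit",
    "MotifThreshold",
    "levenshtein",
    "levenshtein_neighborhood",
    "harvest_neighborhood",
    "merge_adjacent",
    "build_pwm",
    "scan_pwm",
    "best_hit",
    "calibrate_threshold",
    "match_fixed_motif",
    "pwm_align_distance",
    "dedup_motifs",
    "dimer_entropy",
    "filter_complexity",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

FIXED_MOTIFS = {"PORE": MOTIF_WORDS["PORE"], "MORE": MOTIF_WORDS["MORE"]}

OCT4_CONSENSUS = MOTIF_WORDS["OCT4"]


def _check_word(word: str, what: str = "word") -> str:
    word = word.upper()
    if not word:
        raise ValueError(f"{what} must be non-empty")
    if set(word) - set(BASES):
        raise ValueError(f"{what} contains non-ACGT symbols: {word!r}")
    return word


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (insertions, deletions, substitutions)."""
    a, b = _check_word(a), _check_word(b)
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def levenshtein_neighborhood(consensus: str = OCT4_CONSENSUS, max_dist: int = 2) -> dict[str, int]:
    """All ACGT words within ``max_dist`` edits of ``consensus``.

    Returned as word -> exact edit distance. Breadth-first expansion of
    single edits; the BFS level at which a word first appears is its
    Levenshtein distance to the consensus.
    """
    consensus = _check_word(consensus, "consensus")
    dist = {consensus: 0}
    frontier = {consensus}
    for d in range(1, max_dist + 1):
        new: set[str] = set()
        for w in frontier:
            for i in range(len(w)):
                new.add(w[:i] + w[i + 1 :])  # deletion
                for b in BASES:
                    new.add(w[:i] + b + w[i + 1 :])  # substitution / identity
            for i in range(len(w) + 1):
                for b in BASES:
                    new.add(w[:i] + b + w[i:])  # insertion
        frontier = {w for w in new if w and w not in dist}
        for w in frontier:
            dist[w] = d
    return dist


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence in one sequence (0-based leftmost offset)."""

    sequence_id: str
    offset: int
    strand: str
    motif: str
    word: str | None = None
    length: int | None = None
    score: float | None = None
    distance: int | None = None

    @property
    def end(self) -> int:
        return self.offset + (self.length if self.length is not None else len(self.word))


def harvest_neighborhood(
    sequences: dict[str, str],
    consensus: str = OCT4_CONSENSUS,
    max_dist: int = 2,
) -> list[MotifHit]:
    """Collect every neighbourhood word occurrence from peak regions.

    Windows of every length from len(consensus)-max_dist to
    len(consensus)+max_dist are tested on both strands; a window whose
    word (or reverse complement, for '-') lies within ``max_dist``
    edits of the consensus is reported once at its leftmost coordinate.
    """
    nb = levenshtein_neighborhood(consensus, max_dist)
    lengths = sorted({len(w) for w in nb})
    hits: list[MotifHit] = []
    for sid, seq in sequences.items():
        seq = seq.upper()
        for L in lengths:
            for off in range(0, len(seq) - L + 1):
                word = seq[off : off + L]
                d = nb.get(word)
                if d is not None:
                    hits.append(
                        MotifHit(sid, off, "+", consensus, word=word, length=L, distance=d)
                    )
                rc = reverse_complement(word)
                d = nb.get(rc)
                if d is not None:
                    hits.append(
                        MotifHit(sid, off, "-", consensus, word=word, length=L, distance=d)
                    )
    hits.sort(key=lambda h: (h.sequence_id, h.offset, h.length, h.strand))
    return hits


def merge_adjacent(
    hits: list[MotifHit],
    sequences: dict[str, str],
    max_gap: int = 1,
) -> list[MotifHit]:
    """Fuse same-strand matches separated by at most ``max_gap`` nt.

    Overlapping or near-adjacent neighbourhood words on one strand of
    one sequence are replaced by the single longest match spanning them
    (transitively); isolated hits pass through unchanged.
    """
    out: list[MotifHit] = []
    bykey: dict[tuple[str, str], list[MotifHit]] = {}
    for h in hits:
        bykey.setdefault((h.sequence_id, h.strand), []).append(h)
    for (sid, strand), group in sorted(bykey.items()):
        group = sorted(group, key=lambda h: (h.offset, h.end))
        first = group[0]
        cur_start, cur_end, n_parts = first.offset, first.end, 1

        def emit() -> None:
            word = sequences[sid][cur_start:cur_end].upper()
            out.append(
                MotifHit(
                    sid,
                    cur_start,
                    strand,
                    first.motif,
                    word=word,
                    length=cur_end - cur_start,
                    distance=None if n_parts > 1 else first.distance,
                )
            )

        for h in group[1:]:
            if h.offset - cur_end <= max_gap:
                cur_end = max(cur_end, h.end)
                n_parts += 1
            else:
                emit()
                first = h
                cur_start, cur_end, n_parts = h.offset, h.end, 1
        emit()
    out.sort(key=lambda h: (h.sequence_id, h.offset, h.strand))
    return out


class Pwm:
    """Position weight matrix over ACGT with a background model.

    probs is a 4 x L matrix (rows A, C, G, T) of per-position base
    probabilities; every column sums to 1. The information-content
    ("bits") form scales each column by its IC = 2 + sum_b p log2 p, the
    quantity drawn in sequence logos and bounded by 2 bits per column.
    Window scores are summed log2(p/background) values.
    """

    def __init__(
        self,
        probs: np.ndarray,
        name: str = "motif",
        background: np.ndarray | None = None,
    ) -> None:
        probs = np.asarray(probs, dtype=float)
        if probs.ndim != 2 or probs.shape[0] != 4:
            raise ValueError("probs must be a 4 x L matrix (rows A, C, G, T)")
        if probs.shape[1] < 4:
            raise ValueError("PWM length must be >= 4")
        if not np.allclose(probs.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("each PWM column must sum to 1")
        self.probs = probs
        self.name = name
        self.background = (
            np.full(4, 0.25) if background is None else np.asarray(background, float)
        )
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must sum to 1")

    @property
    def length(self) -> int:
        return self.probs.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=0))

    @property
    def bits(self) -> np.ndarray:
        p = self.probs
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log2(p), 0.0)
        ic = 2.0 + plogp.sum(axis=0)  # 2 - H(column)
        return p * ic

    @property
    def total_bits(self) -> float:
        return float(self.bits.sum())

    @property
    def score_matrix(self) -> np.ndarray:
        """log2(p / background) per (base, position); -inf where p = 0."""
        with np.errstate(divide="ignore"):
            return np.log2(self.probs / self.background[:, None])

    @property
    def max_score(self) -> float:
        return float(self.score_matrix.max(axis=0).sum())

    def __repr__(self) -> str:  # pragma: no cover
        return f"Pwm({self.name!r}, L={self.length}, consensus={self.consensus})"


def _best_ungapped_offset(word: str, consensus: str) -> int:
    """Offset of ``word`` against the consensus frame maximizing identity.

    Offsets range over all placements with at least one overlapping
    column; ties prefer larger overlap, then the placement closest to
    frame-aligned (smallest |offset|, then leftmost).
    """
    L = len(consensus)
    best = None
    for o in range(-(len(word) - 1), L):
        lo, hi = max(0, o), min(L, o + len(word))
        if hi <= lo:
            continue
        matches = sum(consensus[i] == word[i - o] for i in range(lo, hi))
        key = (matches, hi - lo, -abs(o), -o)
        if best is None or key > best[0]:
            best = (key, o)
    return best[1]


def build_pwm(
    words: list[str] | list[MotifHit],
    pseudocount: float = 0.5,
    consensus: str = OCT4_CONSENSUS,
    name: str = "OCT4",
    background: np.ndarray | None = None,
) -> Pwm:
    """Stack harvested words into a PWM on the consensus frame.

    Each word is anchored by its best ungapped alignment to the
    consensus; overhanging bases are dropped and columns a short word
    does not reach receive only pseudocounts. Column probabilities are
    (count_b + pseudocount) / (n_covering + 4 * pseudocount).
    """
    strings = [w.word if isinstance(w, MotifHit) else w for w in words]
    strings = [_check_word(w) for w in strings]
    if len(strings) < 2:
        raise ValueError("need at least 2 words to build a PWM")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    consensus = _check_word(consensus, "consensus")
    L = len(consensus)
    counts = np.zeros((4, L))
    cover = np.zeros(L)
    for w in strings:
        o = _best_ungapped_offset(w, consensus)
        for i in range(max(0, o), min(L, o + len(w))):
            counts[_BASE_INDEX[w[i - o]], i] += 1
            cover[i] += 1
    denom = cover + 4 * pseudocount
    if (denom == 0).any():
        raise ValueError(
            "some consensus columns are covered by no word and pseudocount is 0"
        )
    probs = (counts + pseudocount) / denom
    return Pwm(probs, name=name, background=background)


_CODE = np.full(256, -1, dtype=np.int64)
for _b, _i in _BASE_INDEX.items():
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _strand_scores(code: np.ndarray, pwm: Pwm) -> np.ndarray:
    """Score of every window of the coded sequence on the given strand."""
    L = pwm.length
    n = code.size - L + 1
    if n <= 0:
        return np.empty(0)
    S = pwm.score_matrix
    windows = np.lib.stride_tricks.sliding_window_view(code, L)
    valid = (windows >= 0).all(axis=1)
    scores = np.full(n, -np.inf)
    if valid.any():
        w = windows[valid]
        scores[valid] = S[w, np.arange(L)].sum(axis=1)
    return scores


def scan_pwm(
    sequence: str,
    pwm: Pwm,
    sequence_id: str = "seq",
    threshold: float | None = None,
) -> list[MotifHit]:
    """Score every window of a sequence on both strands.

    A window scores sum_i log2(p_i(base) / background(base)); minus-
    strand windows are scored against the reverse complement and
    reported at their leftmost coordinate on the forward sequence. With
    ``threshold`` set, only hits at or above it are returned.
    """
    if len(sequence) < pwm.length:
        raise ValueError("sequence shorter than the PWM")
    code = _encode(sequence)
    n, L = code.size, pwm.length
    hits: list[MotifHit] = []
    fwd = _strand_scores(code, pwm)
    rc = _encode(reverse_complement(sequence))
    rev = _strand_scores(rc, pwm)
    for off in range(n - L + 1):
        s = float(fwd[off])
        if threshold is None or s >= threshold:
            hits.append(MotifHit(sequence_id, off, "+", pwm.name, length=L, score=s))
        s = float(rev[n - L - off])
        if threshold is None or s >= threshold:
            hits.append(MotifHit(sequence_id, off, "-", pwm.name, length=L, score=s))
    return hits


def best_hit(sequence: str, pwm: Pwm, sequence_id: str = "seq") -> MotifHit:
    """The highest-scoring window over both strands (ties: leftmost, '+')."""
    hits = scan_pwm(sequence, pwm, sequence_id=sequence_id)
    return max(hits, key=lambda h: (h.score, -h.offset, h.strand == "+"))


@dataclass(frozen=True)
class MotifThreshold:
    """A calibrated motif-score cutoff (median rule over strong peaks)."""

    value: float
    peak_score_min: float
    n_regions: int


def calibrate_threshold(
    regions: list[tuple[float, str]],
    pwm: Pwm,
    peak_score_min: float = 0.5,
) -> MotifThreshold:
    """Median best PWM score over regions with high consensus support.

    ``regions`` is a list of (peak_score, sequence). Only regions with
    peak_score >= peak_score_min enter the calibration; the threshold
    is the median of their per-region best window scores. This is how
    an operational cutoff is derived from the data when no external
    score scale exists.
    """
    best = [
        best_hit(seq, pwm).score
        for score, seq in regions
        if score >= peak_score_min
    ]
    if not best:
        raise ValueError(
            f"no region reaches peak_score >= {peak_score_min}; cannot calibrate"
        )
    return MotifThreshold(float(np.median(best)), peak_score_min, len(best))


def match_fixed_motif(
    sequence: str,
    motif: str,
    sequence_id: str = "seq",
    max_mismatches: int = 0,
) -> list[MotifHit]:
    """Exact (or mismatch-tolerant) matching of a fixed motif word.

    ``motif`` is a name from the fixed-motif table (PORE, MORE) or a
    literal ACGT word. Both strands are searched; for palindromic
    (self-reverse-complement) motifs the '+' and '-' matches at one
    offset are the same physical site and are reported once.
    """
    word = _check_word(FIXED_MOTIFS.get(motif.upper(), motif), "motif")
    name = motif.upper() if motif.upper() in FIXED_MOTIFS else word
    seq = sequence.upper()
    L = len(word)
    palindromic = reverse_complement(word) == word

    def find(target: str) -> list[int]:
        if max_mismatches == 0:
            offs, start = [], seq.find(target)
            while start != -1:
                offs.append(start)
                start = seq.find(target, start + 1)
            return offs
        return [
            off
            for off in range(len(seq) - L + 1)
            if sum(a != b for a, b in zip(seq[off : off + L], target)) <= max_mismatches
        ]

    hits = [MotifHit(sequence_id, off, "+", name, word=word, length=L) for off in find(word)]
    if not palindromic:
        hits += [
            MotifHit(sequence_id, off, "-", name, word=word, length=L)
            for off in find(reverse_complement(word))
        ]
    return sorted(hits, key=lambda h: (h.offset, h.strand))


def pwm_align_distance(a: Pwm, b: Pwm, min_overlap: int = 1) -> float:
    """Alignment difference between two PWMs.

    Minimum over ungapped relative offsets (with at least
    ``min_overlap`` overlapping columns) of the mean per-column
    Euclidean distance between probability columns.
    """
    pa, pb = a.probs, b.probs
    La, Lb = a.length, b.length
    best = np.inf
    for o in range(-(Lb - min_overlap), La - min_overlap + 1):
        lo, hi = max(0, o), min(La, o + Lb)
        if hi - lo < min_overlap:
            continue
        cols = np.linalg.norm(pa[:, lo:hi] - pb[:, lo - o : hi - o], axis=0)
        best = min(best, float(cols.mean()))
    if not np.isfinite(best):
        raise ValueError("no offset satisfies the overlap requirement")
    return best


def dedup_motifs(pwms: list[Pwm], cutoff: float = 0.2, min_overlap: int = 1) -> list[Pwm]:
    """Collapse near-duplicate PWMs (alignment difference < cutoff).

    Single-linkage clusters at distance < cutoff; only the member with
    the highest total information content (summed bits) of each cluster
    survives, in input order.
    """
    n = len(pwms)
    parent = list(range(n))

    def root(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if pwm_align_distance(pwms[i], pwms[j], min_overlap) < cutoff:
                parent[root(j)] = root(i)
    best: dict[int, int] = {}
    for i, p in enumerate(pwms):
        r = root(i)
        if r not in best or p.total_bits > pwms[best[r]].total_bits:
            best[r] = i
    return [pwms[i] for i in sorted(best.values())]


def dimer_entropy(motif: str | Pwm) -> float:
    """Shannon entropy (bits) of the overlapping-dinucleotide distribution.

    Dimers are counted circularly (the word wraps around) so that every
    position contributes one dimer and a perfect k-periodic word scores
    exactly log2(k): AAAAAAAA has a single dimer and entropy 0,
    ATATATAT two equiprobable dimers and 1 bit, ACGTACGT four and
    2 bits. PWMs are assessed through their consensus word.
    """
    word = motif.consensus if isinstance(motif, Pwm) else _check_word(motif)
    if len(word) < 2:
        raise ValueError("need at least 2 symbols for a dimer distribution")
    wrapped = word + word[0]
    dimers = [wrapped[i : i + 2] for i in range(len(word))]
    _, counts = np.unique(dimers, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def filter_complexity(
    motifs: list[str] | list[Pwm], min_entropy: float = 1.0
) -> list[str] | list[Pwm]:
    """Drop motifs whose dimer entropy is below ``min_entropy`` bits."""
    return [m for m in motifs if dimer_entropy(m) >= min_entropy]
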