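"""miRNA target scoring and binding-site conservation profiles.

Complementarity between a miRNA (5'->3') and a transcript window
(3'->5') is scored with the classical plant penalty scheme: matches 0,
G:U wobbles 0.5, mismatches 1, a single 1-nt bulge 2, with all penalties
doubled at miRNA positions 2-13; sites scoring at or below the 2.5
cutoff are reported.  The predicted cleavage position is the target base
opposite miRNA position 10.

For orthogroups of aligned target sequences, nucleotide variation
against the group consensus is profiled in sliding windows to expose the
conservation of binding sites relative to their flanks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._seq import is_pair, is_watson_crick, validate_rna

SCORE_CUTOFF = 2.5
SEED_RANGE = (2, 13)          # 1-based miRNA positions with doubled penalties
GAP_PENALTY = 2.0
GU_PENALTY = 0.5
MISMATCH_PENALTY = 1.0
GAP_FORBIDDEN = (10, 11)      # no bulge at the cleavage-flanking positions
VARIATION_WINDOW = 30


def _weight(pos_1based: int) -> float:
    lo, hi = SEED_RANGE
    return 2.0 if lo <= pos_1based <= hi else 1.0


def _pair_state(m: str, t: str) -> tuple[str, float]:
    if is_watson_crick(m, t):
        return "|", 0.0
    if is_pair(m, t):
        return "o", GU_PENALTY
    return "x", MISMATCH_PENALTY


@dataclass(frozen=True)
class TargetAlignment:
    """A scored miRNA/transcript site."""

    mirna: str
    transcript: str
    start: int               # 0-based half-open on the transcript
    end: int
    states: str              # per miRNA position: | match, o G:U, x mismatch, - gap
    score: float
    cleavage: int            # target position opposite miRNA position 10
    gap_position: int = 0    # 1-based miRNA position of the bulge, 0 = none


def _alignment_columns(mirna_len: int, window_len: int, gap: int) -> list[int]:
    """Column of the window paired to each miRNA index (-1 = gapped).

    ``gap`` is the 0-based miRNA index where a bulge sits: for a target
    bulge (window one longer) the skipped window column lies between
    miRNA indices gap-1 and gap; for a miRNA bulge (window one shorter)
    the miRNA base at ``gap`` is unpaired.
    """
    L = mirna_len
    if window_len == L:
        return [L - 1 - i for i in range(L)]
    if window_len == L + 1:
        return [L - i if i < gap else L - 1 - i for i in range(L)]
    if window_len == L - 1:
        cols = []
        for i in range(L):
            if i < gap:
                cols.append(L - 2 - i)
            elif i == gap:
                cols.append(-1)
            else:
                cols.append(L - 1 - i)
        return cols
    raise ValueError("window length must be within 1 nt of the miRNA length")


def _score_columns(mirna: str, window: str, cols: list[int],
                   gap_pos_1based: int, abort_above: float | None = None):
    score = 0.0
    states = []
    if gap_pos_1based:
        score += GAP_PENALTY * _weight(gap_pos_1based)
        if abort_above is not None and score > abort_above:
            return None
    for i, c in enumerate(cols):
        if c < 0:
            states.append("-")
            continue
        state, pen = _pair_state(mirna[i], window[c])
        states.append(state)
        score += pen * _weight(i + 1)
        if abort_above is not None and score > abort_above:
            return None
    return score, "".join(states)


def _valid_gaps(mirna_len: int, window_len: int) -> list[tuple[int, int]]:
    """(gap index, 1-based gap position) choices for a window length."""
    if window_len == mirna_len:
        return [(0, 0)]
    if window_len == mirna_len + 1:
        candidates = range(1, mirna_len)          # bulge between i-1 and i
    elif window_len == mirna_len - 1:
        candidates = range(1, mirna_len - 1)      # miRNA base i unpaired
    else:
        return []
    out = []
    for g in candidates:
        pos = g + 1
        if pos in GAP_FORBIDDEN:
            continue
        out.append((g, pos))
    return out


def score_site(mirna: str, window: str, transcript: str = "",
               start: int = 0) -> TargetAlignment:
    """Score one candidate site; the window length may differ from the
    miRNA length by at most one nucleotide (one bulge).

    Returns the minimum-score alignment; ties prefer the ungapped
    alignment and then the 5'-most bulge.
    """
    validate_rna(mirna, name="miRNA")
    validate_rna(window, name="target window")
    L = len(mirna)
    best: TargetAlignment | None = None
    for g, gap_pos in _valid_gaps(L, len(window)):
        cols = _alignment_columns(L, len(window), g)
        score, states = _score_columns(mirna, window, cols, gap_pos)
        cleav_col = cols[9] if cols[9] >= 0 else cols[10]
        aln = TargetAlignment(
            mirna="", transcript=transcript, start=start,
            end=start + len(window), states=states, score=score,
            cleavage=start + cleav_col, gap_position=gap_pos,
        )
        if best is None or aln.score < best.score:
            best = aln
    assert best is not None
    return best


def _score_at_most(mirna: str, window: str, cutoff: float) -> float | None:
    """Best score if <= cutoff, else None (early-abort fast path)."""
    L = len(mirna)
    best = None
    for g, gap_pos in _valid_gaps(L, len(window)):
        cols = _alignment_columns(L, len(window), g)
        res = _score_columns(mirna, window, cols, gap_pos, abort_above=cutoff)
        if res is not None and (best is None or res[0] < best):
            best = res[0]
    return best


def predict_targets(candidates: list[tuple[str, str]],
                    transcripts: list[tuple[str, str]],
                    cutoff: float = SCORE_CUTOFF) -> list[TargetAlignment]:
    """Slide every candidate over every transcript (sense strand only)
    and report all sites scoring at or below the cutoff.

    ``candidates`` and ``transcripts`` are (name, sequence) pairs.
    Output order: (transcript, start, miRNA name).
    """
    if not transcripts:
        raise ValueError("transcripts must be non-empty")
    hits: list[TargetAlignment] = []
    for tid, tseq in transcripts:
        for name, mseq in candidates:
            L = len(mseq)
            for wlen in (L, L + 1, L - 1):
                for s in range(len(tseq) - wlen + 1):
                    window = tseq[s:s + wlen]
                    if _score_at_most(mseq, window, cutoff) is None:
                        continue
                    aln = score_site(mseq, window, tid, s)
                    hits.append(TargetAlignment(
                        mirna=name, transcript=tid, start=s, end=s + wlen,
                        states=aln.states, score=aln.score,
                        cleavage=aln.cleavage, gap_position=aln.gap_position,
                    ))
    hits.sort(key=lambda a: (a.transcript, a.start, a.mirna, a.end))
    return hits


@dataclass
class WindowVariationProfile:
    """Per-window mean nucleotide variation across an orthogroup."""

    group_id: str
    window: int
    starts: list[int]
    mean: list[float]
    se: list[float]
    site_interval: tuple[int, int] | None = None


def group_consensus(seqs: list[str]) -> str:
    """Per-column majority consensus with an alphabetical tie-break."""
    length = len(seqs[0])
    cols = []
    for j in range(length):
        tally: dict[str, int] = {}
        for s in seqs:
            tally[s[j]] = tally.get(s[j], 0) + 1
        cols.append(max(sorted(tally), key=lambda c: tally[c]))
    return "".join(cols)


def sliding_window_variation(seqs: list[str], window: int = VARIATION_WINDOW,
                             site_interval: tuple[int, int] | None = None,
                             group_id: str = "") -> WindowVariationProfile:
    """Mean/SE of per-member substitution counts vs the group consensus,
    in sliding windows over an equal-length alignment."""
    if len(seqs) < 2:
        raise ValueError("need at least two aligned sequences")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("aligned sequences must have equal lengths")
    if length < window:
        raise ValueError("alignment shorter than the window")
    consensus = group_consensus(seqs)
    diffs = np.array([[c != k for c, k in zip(s, consensus)] for s in seqs],
                     dtype=float)
    kernel = np.ones(window)
    per_member = np.vstack([np.convolve(row, kernel, mode="valid") for row in diffs])
    n = len(seqs)
    mean = per_member.mean(axis=0)
    sd = per_member.std(axis=0, ddof=1)
    se = sd / math.sqrt(n)
    starts = list(range(length - window + 1))
    return WindowVariationProfile(group_id=group_id, window=window, starts=starts,
                                 mean=mean.tolist(), se=se.tolist(),
                                 site_interval=site_interval)
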