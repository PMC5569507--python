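"""Genome mapping and hairpin-structure validation of miRNA candidates.

Candidates are mapped to the genome exactly (both strands), windows with
200-nt flanks on each side are extracted, folded with a base-pair
maximization dynamic program (Watson-Crick plus G:U, hairpin loops of at
least three nucleotides, deterministic traceback), and a candidate locus
passes when fewer than four of the mature positions are unpaired and the
mature sequence lies entirely on one arm.

An external thermodynamic folder can be plugged in by passing any
callable with the :func:`fold_maxpair` signature to
:func:`validate_candidate`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seq import revcomp, validate_rna

DEFAULT_FLANK = 200           # "400-bp flanking sequences": 200 nt each side
MAX_ARM_MISMATCHES = 4        # pass iff mismatches < 4
HIGH_COPY_THRESHOLD = 20      # loci counts above this are flagged repeat-like
MIN_LOOP = 3

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "N": 4}
# Watson-Crick + G:U wobble, indexed by the codes above.
_PAIRABLE = np.zeros((5, 5), dtype=np.bool_)
for _a, _b in [(0, 3), (3, 0), (1, 2), (2, 1), (2, 3), (3, 2)]:
    _PAIRABLE[_a, _b] = True

try:  # numba speeds the O(n^3) fill up ~100x; pure python fallback below
    from numba import njit as _njit
except ImportError:  # pragma: no cover - numba present in the target env
    _njit = None


def _fill_dp_python(codes, pairable, min_loop):
    n = codes.shape[0]
    dp = np.zeros((n, n), dtype=np.int16)
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i, j - 1]
            for k in range(i, j - min_loop):
                if pairable[codes[k], codes[j]]:
                    left = dp[i, k - 1] if k > i else 0
                    cand = left + dp[k + 1, j - 1] + 1
                    if cand > best:
                        best = cand
            dp[i, j] = best
    return dp


if _njit is not None:
    _fill_dp_numba = _njit(cache=False)(_fill_dp_python)
else:  # pragma: no cover
    _fill_dp_numba = None


@dataclass(frozen=True)
class GenomeHit:
    genome_id: str
    start: int      # 0-based half-open on the forward strand
    end: int
    strand: str     # "+" or "-"


@dataclass
class HairpinLocus:
    """One candidate locus with its predicted pairing and pass/fail call."""

    genome_id: str
    strand: str
    window_start: int
    window_end: int
    candidate_offset: int     # offset of the candidate within the window
    structure: str            # dot-bracket over the window
    mature_arm_mismatches: int
    passed: bool
    intra_candidate_pairing: bool = False


def map_exact(candidate: str, genome: dict[str, str]) -> list[GenomeHit]:
    """All exact occurrences of the candidate on both strands.

    Coordinates are 0-based half-open on the forward strand, ordered by
    (genome id, start, strand).
    """
    validate_rna(candidate, name="candidate")
    hits: list[GenomeHit] = []
    rc = revcomp(candidate)
    for gid in sorted(genome):
        seq = genome[gid]
        for query, strand in ((candidate, "+"), (rc, "-")):
            if strand == "-" and rc == candidate:
                continue  # palindromic query: avoid double-reporting
            pos = seq.find(query)
            while pos != -1:
                hits.append(GenomeHit(gid, pos, pos + len(query), strand))
                pos = seq.find(query, pos + 1)
    hits.sort(key=lambda h: (h.genome_id, h.start, h.strand))
    return hits


def extract_window(hit: GenomeHit, genome: dict[str, str],
                   flank: int = DEFAULT_FLANK) -> tuple[str, int]:
    """Extract the hit plus ``flank`` nt on each side (truncated at the
    genome ends), reverse-complemented for minus-strand hits so the
    candidate reads 5'->3' within the returned window."""
    seq = genome[hit.genome_id]
    ws = max(0, hit.start - flank)
    we = min(len(seq), hit.end + flank)
    window = seq[ws:we]
    if hit.strand == "+":
        return window, hit.start - ws
    return revcomp(window), we - hit.end


def fold_maxpair(sequence: str, min_loop: int = MIN_LOOP) -> tuple[str, int]:
    """Maximize Watson-Crick + G:U pairs over non-crossing structures.

    Returns the dot-bracket string from a deterministic traceback
    (unpaired branch preferred on ties, then the smallest pairing
    partner) and the pair count.
    """
    validate_rna(sequence)
    n = len(sequence)
    if n < min_loop + 2:
        return "." * n, 0
    codes = np.array([_CODE[c] for c in sequence], dtype=np.uint8)
    fill = _fill_dp_numba if _fill_dp_numba is not None else _fill_dp_python
    dp = fill(codes, _PAIRABLE, min_loop)
    structure = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= min_loop:
            continue
        if dp[i, j] == dp[i, j - 1]:
            stack.append((i, j - 1))
            continue
        for k in range(i, j - min_loop):
            if not _PAIRABLE[codes[k], codes[j]]:
                continue
            left = dp[i, k - 1] if k > i else 0
            if left + dp[k + 1, j - 1] + 1 == dp[i, j]:
                structure[k] = "("
                structure[j] = ")"
                if k > i:
                    stack.append((i, k - 1))
                stack.append((k + 1, j - 1))
                break
    return "".join(structure), int(dp[0, n - 1])


def pair_table(structure: str) -> list[int]:
    """Dot-bracket -> partner index per position (-1 if unpaired)."""
    partner = [-1] * len(structure)
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket structure")
            j = stack.pop()
            partner[i], partner[j] = j, i
    if stack:
        raise ValueError("unbalanced dot-bracket structure")
    return partner


def validate_hairpin(candidate: str, window: str, structure: str,
                     candidate_offset: int, genome_id: str = "",
                     strand: str = "+", window_start: int = 0,
                     max_mismatches: int = MAX_ARM_MISMATCHES) -> HairpinLocus:
    """Score a folded window: mismatches = unpaired candidate positions.

    The locus passes when fewer than ``max_mismatches`` candidate
    positions are unpaired and no candidate base pairs with another
    candidate base (the mature sequence must sit on a single arm).
    """
    if len(structure) != len(window):
        raise ValueError("structure and window lengths disagree")
    lo, hi = candidate_offset, candidate_offset + len(candidate)
    if window[lo:hi] != candidate:
        raise ValueError("candidate does not occur at the recorded offset")
    partner = pair_table(structure)
    mismatches = sum(1 for p in range(lo, hi) if partner[p] == -1)
    intra = any(lo <= partner[p] < hi for p in range(lo, hi) if partner[p] != -1)
    passed = mismatches < max_mismatches and not intra
    return HairpinLocus(
        genome_id=genome_id, strand=strand,
        window_start=window_start, window_end=window_start + len(window),
        candidate_offset=candidate_offset, structure=structure,
        mature_arm_mismatches=mismatches, passed=passed,
        intra_candidate_pairing=intra,
    )


@dataclass
class CandidateValidation:
    loci: list[HairpinLocus]
    passed: bool
    high_copy: bool

    @property
    def n_loci(self) -> int:
        return len(self.loci)


def validate_candidate(candidate: str, genome: dict[str, str],
                       flank: int = DEFAULT_FLANK,
                       max_mismatches: int = MAX_ARM_MISMATCHES,
                       fold=fold_maxpair) -> CandidateValidation:
    """Map, fold, and validate every genomic locus of a candidate.

    The candidate passes if any locus passes; more than 20 loci flags the
    candidate as repeat-like.  ``fold`` may be replaced by an external
    structure predictor with the same signature.
    """
    hits = map_exact(candidate, genome)
    loci: list[HairpinLocus] = []
    for hit in hits:
        window, offset = extract_window(hit, genome, flank)
        structure, _ = fold(window)
        loci.append(validate_hairpin(
            candidate, window, structure, offset,
            genome_id=hit.genome_id, strand=hit.strand,
            window_start=max(0, hit.start - flank),
            max_mismatches=max_mismatches,
        ))
    return CandidateValidation(
        loci=loci,
        passed=any(l.passed for l in loci),
        high_copy=len(loci) > HIGH_COPY_THRESHOLD,
    )
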