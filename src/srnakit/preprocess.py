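"""Small-RNA read filtering and normalization.

Raw reads are length-filtered to the retention window (16-26 nt by
default), cleaned of structural-RNA fragments (rRNA/tRNA/snoRNA/snRNA,
matched with up to two substitutions on either strand), and 3' uridine
tails longer than one nucleotide are collapsed to a single U.  The count
of retained 18-26-nt reads is recorded as the reads-per-million
denominator for the library.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._seq import revcomp, validate_rna

RPM_DENOM_RANGE = (18, 26)


@dataclass
class ReadSet:
    """Unique small-RNA sequences with raw counts for one library.

    ``total_18_26`` is the RPM denominator: the number of retained reads
    in the 18-26-nt window, frozen when the length filter runs.
    """

    counts: dict[str, int] = field(default_factory=dict)
    library_id: str = ""
    total_raw: int = 0
    total_18_26: int = 0

    def __post_init__(self) -> None:
        for seq, count in self.counts.items():
            validate_rna(seq)
            if count < 1:
                raise ValueError(f"read {seq!r} has count {count} < 1")
        if self.total_raw == 0:
            self.total_raw = self.n_reads
        if self.total_18_26 > self.total_raw:
            raise ValueError("total_18_26 exceeds total_raw")

    @property
    def n_reads(self) -> int:
        return sum(self.counts.values())

    @property
    def n_unique(self) -> int:
        return len(self.counts)

    def items(self):
        """Deterministic iteration order: count desc, then sequence."""
        return sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))


def filter_by_length(reads: ReadSet, min_len: int = 16, max_len: int = 26) -> ReadSet:
    """Retain reads with min_len <= length <= max_len (inclusive).

    Also records the 18-26-nt retained-read total used as the RPM
    denominator downstream.
    """
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    kept = {s: c for s, c in reads.counts.items() if min_len <= len(s) <= max_len}
    lo, hi = RPM_DENOM_RANGE
    denom = sum(c for s, c in kept.items() if lo <= len(s) <= hi)
    return ReadSet(counts=kept, library_id=reads.library_id,
                   total_raw=reads.total_raw, total_18_26=denom)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def filter_structural(reads: ReadSet, structural_ref: list[str],
                      max_mismatch: int = 2) -> ReadSet:
    """Drop reads matching a structural-RNA reference substring.

    A read is removed when it matches a same-length substring of any
    reference sequence, on either strand, with at most ``max_mismatch``
    substitutions.  An empty reference is a no-op.
    """
    if not structural_ref:
        return replace(reads, counts=dict(reads.counts))
    ref_arrays = []
    for ref in structural_ref:
        validate_rna(ref, name="structural reference")
        ref_arrays.append(_encode(ref))
        ref_arrays.append(_encode(revcomp(ref)))
    kept: dict[str, int] = {}
    for seq, count in reads.counts.items():
        arr = _encode(seq)
        k = len(arr)
        hit = False
        for ref_arr in ref_arrays:
            if len(ref_arr) < k:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(ref_arr, k)
            mismatches = (windows != arr).sum(axis=1)
            if int(mismatches.min()) <= max_mismatch:
                hit = True
                break
        if not hit:
            kept[seq] = count
    return replace(reads, counts=kept)


def shorten_u_tail(sequence: str) -> str:
    """Collapse a 3' run of >=2 uridines to a single U.

    A trailing run of exactly one U, or none, is returned unchanged.  An
    all-U sequence collapses to ``"U"`` (and will fail any sensible
    length filter downstream).
    """
    stripped = sequence.rstrip("U")
    if len(sequence) - len(stripped) >= 2:
        return stripped + "U"
    return sequence


def shorten_u_tails(reads: ReadSet) -> ReadSet:
    """Apply :func:`shorten_u_tail` to every unique read, summing counts
    of sequences made identical by the shortening."""
    merged: dict[str, int] = {}
    for seq, count in reads.counts.items():
        short = shorten_u_tail(seq)
        merged[short] = merged.get(short, 0) + count
    return replace(reads, counts=merged)


def compute_rpm(count: int, total_18_26: int) -> float:
    """Reads per million 18-26-nt reads."""
    if total_18_26 < 1:
        raise ValueError("RPM denominator must be >= 1")
    return count * 1e6 / total_18_26


def preprocess_reads(raw_counts: dict[str, int], structural_ref: list[str] | None = None,
                     min_len: int = 16, max_len: int = 26,
                     max_mismatch: int = 2, library_id: str = "") -> ReadSet:
    """Full preprocessing: length filter -> structural filter -> U-tail
    shortening -> re-apply length filter to drop degenerate collapses."""
    rs = ReadSet(counts=dict(raw_counts), library_id=library_id)
    rs = filter_by_length(rs, min_len, max_len)
    denom = rs.total_18_26
    rs = filter_structural(rs, structural_ref or [], max_mismatch)
    rs = shorten_u_tails(rs)
    kept = {s: c for s, c in rs.counts.items() if min_len <= len(s) <= max_len}
    return ReadSet(counts=kept, library_id=library_id,
                   total_raw=rs.total_raw, total_18_26=denom)
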