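"""Degradome/PARE tag mapping, cleavage-peak calling, and miRNA linking.

Tags shorter than 19 nt are removed; retained tags are mapped exactly to
transcripts (sense strand) and the 5'-end position of every occurrence is
accumulated into a per-transcript profile.  A position is called a peak
when all four rules hold:

1. at least 12 unique tag sequences mapped to the transcript;
2. the position ranks among the top 12 positions by mapped reads
   (ties at the rank-12 boundary are all admitted);
3. the position's RPM exceeds 5;
4. the position's RPM exceeds the mean plus five times the standard
   error of the RPM of all positions with mapped reads on the transcript.

Peaks are linked to candidate miRNAs by scoring the transcript window
that places the peak opposite miRNA positions 10-11.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .targets import SCORE_CUTOFF, TargetAlignment, score_site

MIN_TAG_LEN = 19
MIN_UNIQUE_TAGS = 12
TOP_N_POSITIONS = 12
MIN_PEAK_RPM = 5.0
SE_MULTIPLIER = 5.0

RULE_UNIQUE, RULE_TOP, RULE_RPM, RULE_SE = 1, 2, 4, 8
ALL_RULES = RULE_UNIQUE | RULE_TOP | RULE_RPM | RULE_SE


@dataclass
class DegradomeProfile:
    """Per-position 5'-end tag counts on one transcript."""

    transcript_id: str
    length: int
    counts: dict[int, int] = field(default_factory=dict)  # 0-based position
    n_unique_tags: int = 0
    library_total: int = 0  # RPM denominator: all retained library tags

    def rpm(self, count: int) -> float:
        if self.library_total < 1:
            raise ValueError("library_total must be >= 1")
        return count * 1e6 / self.library_total


@dataclass(frozen=True)
class Peak:
    position: int          # 0-based on the transcript
    count: int
    rpm: float
    rank: int              # 1-based rank by count, ties toward 5'
    background_mean: float
    background_se: float
    rules: int             # bitmask of passed rules
    passed: bool


def map_tags(tags: dict[str, int], transcripts: list[tuple[str, str]],
             min_len: int = MIN_TAG_LEN) -> dict[str, DegradomeProfile]:
    """Map tags exactly to the sense strand of every transcript.

    Multi-mapping tags count fully at every occurrence.  The library
    total (RPM denominator) is the number of retained tags, mapped or
    not.
    """
    retained = {seq: c for seq, c in tags.items() if len(seq) >= min_len}
    library_total = sum(retained.values())
    profiles: dict[str, DegradomeProfile] = {}
    for tid, tseq in transcripts:
        profile = DegradomeProfile(transcript_id=tid, length=len(tseq),
                                   library_total=library_total)
        unique: set[str] = set()
        for seq, count in retained.items():
            pos = tseq.find(seq)
            mapped = False
            while pos != -1:
                profile.counts[pos] = profile.counts.get(pos, 0) + count
                mapped = True
                pos = tseq.find(seq, pos + 1)
            if mapped:
                unique.add(seq)
        profile.n_unique_tags = len(unique)
        profiles[tid] = profile
    return profiles


def call_peaks(profile: DegradomeProfile, min_unique: int = MIN_UNIQUE_TAGS,
               top_n: int = TOP_N_POSITIONS, min_rpm: float = MIN_PEAK_RPM,
               se_multiplier: float = SE_MULTIPLIER) -> list[Peak]:
    """Evaluate the four peak rules at every position with mapped reads
    and return the positions passing all of them, 5'-most first."""
    positions = sorted(profile.counts)
    if not positions:
        return []
    counts = [profile.counts[p] for p in positions]
    rpms = [profile.rpm(c) for c in counts]
    n = len(positions)
    mean = sum(rpms) / n
    if n > 1:
        var = sum((r - mean) ** 2 for r in rpms) / (n - 1)
        se = math.sqrt(var) / math.sqrt(n)
    else:
        se = 0.0
    # rank by count descending, ties toward the 5' end
    order = sorted(range(n), key=lambda i: (-counts[i], positions[i]))
    rank = [0] * n
    for r, i in enumerate(order, start=1):
        rank[i] = r
    # boundary ties all admitted to rule 2
    top_cutoff = counts[order[top_n - 1]] if n > top_n else 0
    rule1 = profile.n_unique_tags >= min_unique
    peaks: list[Peak] = []
    for i, pos in enumerate(positions):
        rules = 0
        if rule1:
            rules |= RULE_UNIQUE
        if n <= top_n or counts[i] >= top_cutoff:
            rules |= RULE_TOP
        if rpms[i] > min_rpm:
            rules |= RULE_RPM
        if rpms[i] > mean + se_multiplier * se:
            rules |= RULE_SE
        if rules == ALL_RULES:
            peaks.append(Peak(position=pos, count=counts[i], rpm=rpms[i],
                              rank=rank[i], background_mean=mean,
                              background_se=se, rules=rules, passed=True))
    return peaks


@dataclass(frozen=True)
class PeakLink:
    mirna: str
    transcript: str
    cleavage: int          # 0-based peak position on the transcript
    score: float
    alignment: TargetAlignment


def link_peak_to_mirna(peak: Peak, transcript_id: str, transcript_seq: str,
                       candidates: list[tuple[str, str]],
                       score_cutoff: float = SCORE_CUTOFF) -> list[PeakLink]:
    """Link a called peak to candidate miRNAs.

    For each candidate the transcript window placing the peak position
    opposite miRNA position 10 (slicing between positions 10 and 11) is
    scored ungapped; candidates scoring at or below the cutoff are
    linked.
    """
    links: list[PeakLink] = []
    for name, mseq in sorted(candidates):
        L = len(mseq)
        start = peak.position - L + 10
        end = peak.position + 10
        if start < 0 or end > len(transcript_seq):
            continue
        window = transcript_seq[start:end]
        aln = score_site(mseq, window, transcript_id, start)
        if aln.score <= score_cutoff:
            links.append(PeakLink(mirna=name, transcript=transcript_id,
                                  cleavage=peak.position, score=aln.score,
                                  alignment=aln))
    return links


def link_all_peaks(profiles: dict[str, DegradomeProfile],
                   transcripts: dict[str, str],
                   candidates: list[tuple[str, str]],
                   score_cutoff: float = SCORE_CUTOFF,
                   **peak_kwargs) -> tuple[dict[str, list[Peak]], list[PeakLink]]:
    """Call peaks on every profile and link them to candidates."""
    peaks_by_tid: dict[str, list[Peak]] = {}
    links: list[PeakLink] = []
    for tid in sorted(profiles):
        peaks = call_peaks(profiles[tid], **peak_kwargs)
        peaks_by_tid[tid] = peaks
        for peak in peaks:
            links.extend(link_peak_to_mirna(peak, tid, transcripts[tid],
                                            candidates, score_cutoff))
    return peaks_by_tid, links
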