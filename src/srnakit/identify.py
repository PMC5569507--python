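"""Conserved-miRNA candidate identification.

Reads are matched to a reference catalog of annotated mature miRNAs by a
5'-anchored homology rule (at most two substitutions over the overlap and
at most one nucleotide difference in length), near-identical reference
families are merged (e.g. miR156 + miR157 -> "miR156/7"), matching reads
are collapsed into clusters sharing 5' nucleotides 1-16 with the most
abundant member as representative, clusters are filtered by abundance
(more than ten raw reads and more than five RPM), and surviving clusters
are assigned serial names of the form ``Spc-miR170/1-3p.2380_3761``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .preprocess import ReadSet, compute_rpm

MAX_SUBSTITUTIONS = 2     # "less than 3-nt mismatches"
MAX_LENGTH_DIFF = 1       # "less than 2-nt differences in length"
PREFIX_LEN = 16           # "identical 5' nucleotides 1-16"
MIN_RAW_READS = 10        # "more than ten raw reads"
MIN_RPM = 5.0             # "or five in RPM (whichever is higher)"


@dataclass(frozen=True)
class CatalogEntry:
    """One annotated mature miRNA from the reference catalog."""

    family: str
    sequence: str
    arm: str | None = None  # "5p"/"3p" when the header carries it


@dataclass(frozen=True)
class MatchResult:
    family: str
    substitutions: int
    length_difference: int  # len(query) - len(reference)
    is_match: bool


@dataclass
class MiRNACandidate:
    """A 5'-prefix cluster of identified miRNA isoforms."""

    sequence: str                      # representative (most abundant member)
    family: str                        # merged family name
    arm: str | None
    members: list[tuple[str, int]]     # (sequence, count), deterministic order
    raw_count: int                     # representative count
    cluster_count: int                 # sum over members
    rpm: float = 0.0
    name: str = ""
    flagged_short: bool = False

    @property
    def n_members(self) -> int:
        return len(self.members)


def match_candidate(query: str, reference: str, family: str = "",
                    max_subs: int = MAX_SUBSTITUTIONS,
                    max_len_diff: int = MAX_LENGTH_DIFF) -> MatchResult:
    """5'-anchored homology comparison of a read against a reference.

    Both 5' ends are aligned; substitutions are counted over the overlap
    and the 3' overhang contributes only to the length difference.
    """
    overlap = min(len(query), len(reference))
    subs = sum(query[i] != reference[i] for i in range(overlap))
    length_diff = len(query) - len(reference)
    ok = subs <= max_subs and abs(length_diff) <= max_len_diff
    return MatchResult(family=family, substitutions=subs,
                       length_difference=length_diff, is_match=ok)


@dataclass(frozen=True)
class Assignment:
    sequence: str
    count: int
    entry: CatalogEntry
    match: MatchResult


def identify_candidates(readset: ReadSet, catalog: list[CatalogEntry],
                        max_subs: int = MAX_SUBSTITUTIONS,
                        max_len_diff: int = MAX_LENGTH_DIFF) -> list[Assignment]:
    """Assign each read to its best-matching catalog reference.

    Best = minimal (substitutions, |length difference|) among matching
    references, with a lexicographic tie-break on family name.  Reads with
    no matching reference are dropped.
    """
    if not catalog:
        raise ValueError("catalog must be non-empty")
    assignments: list[Assignment] = []
    for seq, count in readset.items():
        best: tuple | None = None
        for entry in catalog:
            if abs(len(seq) - len(entry.sequence)) > max_len_diff:
                continue
            m = match_candidate(seq, entry.sequence, entry.family,
                                max_subs, max_len_diff)
            if not m.is_match:
                continue
            key = (m.substitutions, abs(m.length_difference), entry.family,
                   entry.arm or "", entry.sequence)
            if best is None or key < best[0]:
                best = (key, entry, m)
        if best is not None:
            assignments.append(Assignment(seq, count, best[1], best[2]))
    return assignments


_FAMILY_RE = re.compile(r"^([A-Za-z-]*?)(\d+)([a-z]*)$")


def _merged_family_name(families: list[str]) -> str:
    """Join merged family names the compact way: miR156+miR157 -> miR156/7.

    Numeric suffixes are sorted and joined with "/", eliding the digits a
    number shares with its predecessor (156,157 -> "156/7"; 170,171 ->
    "170/1").  Names that do not end in a number are joined verbatim.
    """
    parsed = [_FAMILY_RE.match(f) for f in families]
    prefixes = {m.group(1) for m in parsed if m}
    if any(m is None for m in parsed) or len(prefixes) != 1:
        return "/".join(sorted(set(families)))
    prefix = prefixes.pop()
    numbers = sorted({m.group(2) for m in parsed}, key=lambda d: (int(d), d))
    parts = [numbers[0]]
    for prev, cur in zip(numbers, numbers[1:]):
        shared = 0
        while (shared < min(len(prev), len(cur)) - 1
               and prev[shared] == cur[shared]):
            shared += 1
        parts.append(cur[shared:])
    return prefix + "/".join(parts)


def merge_families(catalog: list[CatalogEntry]) -> dict[str, str]:
    """Union similar reference families into merged names.

    Two families merge when any pair of their reference sequences
    satisfies the candidate match rule; merging is closed transitively.
    Returns ``{original family: merged family name}``.
    """
    families = sorted({e.family for e in catalog})
    parent = {f: f for f in families}

    def find(f: str) -> str:
        while parent[f] != f:
            parent[f] = parent[parent[f]]
            f = parent[f]
        return f

    by_family: dict[str, list[CatalogEntry]] = {f: [] for f in families}
    for e in catalog:
        by_family[e.family].append(e)
    for i, fa in enumerate(families):
        for fb in families[i + 1:]:
            linked = any(
                match_candidate(ea.sequence, eb.sequence).is_match
                for ea in by_family[fa] for eb in by_family[fb]
            )
            if linked:
                ra, rb = find(fa), find(fb)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)
    groups: dict[str, list[str]] = {}
    for f in families:
        groups.setdefault(find(f), []).append(f)
    merge_map: dict[str, str] = {}
    for members in groups.values():
        name = _merged_family_name(members) if len(members) > 1 else members[0]
        for f in members:
            merge_map[f] = name
    return merge_map


def cluster_by_prefix(assignments: list[Assignment],
                      merge_map: dict[str, str] | None = None,
                      prefix_len: int = PREFIX_LEN) -> list[MiRNACandidate]:
    """Collapse identified reads into clusters with identical 5' 1-16 nt.

    The representative is the most abundant member; ties go to the
    shorter, then lexicographically smaller, sequence.  Reads shorter
    than the prefix cluster by their full sequence and are flagged.
    """
    merge_map = merge_map or {}
    buckets: dict[str, list[Assignment]] = {}
    for a in assignments:
        key = a.sequence[:prefix_len]
        buckets.setdefault(key, []).append(a)
    clusters: list[MiRNACandidate] = []
    for key in sorted(buckets):
        members = sorted(buckets[key],
                         key=lambda a: (-a.count, len(a.sequence), a.sequence))
        rep = members[0]
        family = merge_map.get(rep.entry.family, rep.entry.family)
        clusters.append(MiRNACandidate(
            sequence=rep.sequence,
            family=family,
            arm=rep.entry.arm,
            members=[(a.sequence, a.count) for a in members],
            raw_count=rep.count,
            cluster_count=sum(a.count for a in members),
            flagged_short=len(rep.sequence) < prefix_len,
        ))
    clusters.sort(key=lambda c: (-c.cluster_count, c.sequence))
    return clusters


def abundance_threshold(total_18_26: int, min_raw: int = MIN_RAW_READS,
                        min_rpm: float = MIN_RPM, rule: str = "max") -> float:
    """Effective raw-read threshold for the abundance filter.

    ``rule="max"`` keeps the more stringent of the two thresholds (the
    default reading of "whichever is higher"); ``rule="either"`` keeps a
    cluster passing either one.
    """
    rpm_as_reads = min_rpm * total_18_26 / 1e6
    if rule == "max":
        return max(float(min_raw), rpm_as_reads)
    if rule == "either":
        return min(float(min_raw), rpm_as_reads)
    raise ValueError(f"unknown abundance rule {rule!r}")


def apply_abundance_filter(clusters: list[MiRNACandidate], total_18_26: int,
                           min_raw: int = MIN_RAW_READS, min_rpm: float = MIN_RPM,
                           rule: str = "max") -> list[MiRNACandidate]:
    """Retain clusters whose representative count strictly exceeds the
    effective threshold, and fill in representative RPM."""
    if total_18_26 < 1:
        raise ValueError("total_18_26 must be >= 1")
    threshold = abundance_threshold(total_18_26, min_raw, min_rpm, rule)
    retained = [c for c in clusters if c.raw_count > threshold]
    for c in retained:
        c.rpm = compute_rpm(c.raw_count, total_18_26)
    return retained


def name_candidate(species_code: str, family: str, serial: int, raw_count: int) -> str:
    """``{Species}-{family}.{serial}_{raw_count}``."""
    if serial < 1:
        raise ValueError("serial must be >= 1")
    return f"{species_code}-{family}.{serial}_{raw_count}"


def assign_names(clusters: list[MiRNACandidate], species_code: str) -> None:
    """Assign serial names in descending cluster_count order (in place)."""
    ordered = sorted(clusters, key=lambda c: (-c.cluster_count, c.sequence))
    for serial, c in enumerate(ordered, start=1):
        family = f"{c.family}-{c.arm}" if c.arm else c.family
        c.name = name_candidate(species_code, family, serial, c.raw_count)


def identify_pipeline(readset: ReadSet, catalog: list[CatalogEntry],
                      species_code: str = "Sim", prefix_len: int = PREFIX_LEN,
                      max_subs: int = MAX_SUBSTITUTIONS,
                      max_len_diff: int = MAX_LENGTH_DIFF,
                      min_raw: int = MIN_RAW_READS, min_rpm: float = MIN_RPM,
                      rule: str = "max") -> list[MiRNACandidate]:
    """Match -> merge families -> cluster -> abundance filter -> name."""
    assignments = identify_candidates(readset, catalog, max_subs, max_len_diff)
    merge_map = merge_families(catalog)
    clusters = cluster_by_prefix(assignments, merge_map, prefix_len)
    retained = apply_abundance_filter(clusters, readset.total_18_26,
                                      min_raw, min_rpm, rule)
    assign_names(retained, species_code)
    return retained
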