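"""Ground-truthed synthetic data for end-to-end pipeline verification.

Generates reference miRNA catalogs, genomes with planted hairpin
precursors, small-RNA libraries with realistic isoform noise
(substitutions, 3' truncation, nontemplated U-tails) over a 24-nt
genomic-siRNA background, and degradome tag sets concentrated at planted
cleavage positions.  Every generated read or tag is attributable to a
ground-truth record, so downstream stages are testable by parameter
recovery.  All randomness flows from explicit seeds; the same
configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from ._seq import revcomp
from .identify import CatalogEntry, match_candidate
from .preprocess import ReadSet

NUCLEOTIDES = np.array(list("ACGU"))
DEFAULT_LENGTH_WEIGHTS = {20: 0.15, 21: 0.6, 22: 0.2, 23: 0.05}
BACKGROUND_LEN = 24


@dataclass
class SimulationConfig:
    seed: int = 0
    n_families: int = 20
    mature_length_weights: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_WEIGHTS))
    substitution_rate: float = 0.02
    truncation_max: int = 2
    utail_max: int = 3
    depth: int = 100_000
    background_fraction: float = 0.3
    abundance_dispersion: float = 1.0
    similar_pairs: int = 0  # extra families planted 1 substitution apart

    def __post_init__(self) -> None:
        for name in ("substitution_rate", "background_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if self.truncation_max < 0 or self.utail_max < 0:
            raise ValueError("truncation_max and utail_max must be >= 0")
        if not self.mature_length_weights:
            raise ValueError("mature_length_weights must be non-empty")
        for length, w in self.mature_length_weights.items():
            if not 18 <= length <= 24:
                raise ValueError(f"mature length {length} outside 18-24")
            if w < 0:
                raise ValueError("length weights must be >= 0")


@dataclass
class FamilyTruth:
    family: str
    sequence: str
    arm: str
    true_count: int = 0                       # reads drawn for this family
    emitted: Counter = field(default_factory=Counter)  # final read -> count

    @property
    def top_read_count(self) -> int:
        """Count of the family's most abundant emitted unique read."""
        return max(self.emitted.values()) if self.emitted else 0

    @property
    def top_matchable_count(self) -> int:
        """Count of the most abundant emitted read that still satisfies
        the homology match rule against the family reference after
        U-tail shortening — the strongest single piece of evidence the
        abundance filter can act on."""
        from .preprocess import shorten_u_tail
        merged: Counter = Counter()
        for read, count in self.emitted.items():
            merged[shorten_u_tail(read)] += count
        matchable = [c for read, c in merged.items()
                     if match_candidate(read, self.sequence).is_match]
        return max(matchable) if matchable else 0


@dataclass(frozen=True)
class PlantedHairpin:
    genome_id: str
    mature: str
    star_mismatches: int
    mature_start: int    # 0-based half-open, forward strand
    mature_end: int
    insert_start: int
    insert_end: int
    strand: str = "+"


@dataclass(frozen=True)
class PlantedCleavage:
    transcript_id: str
    position: int        # 0-based 5'-end position of the cleavage fragment
    mirna: str           # guiding miRNA family name


@dataclass
class GroundTruth:
    families: dict[str, FamilyTruth] = field(default_factory=dict)
    hairpins: list[PlantedHairpin] = field(default_factory=list)
    cleavage_sites: list[PlantedCleavage] = field(default_factory=list)
    n_background: int = 0


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(NUCLEOTIDES, size=length))


def random_genome(length: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return _random_seq(rng, length)


_MIN_FAMILY_SEPARATION = 5  # substitutions; keeps 1-sub isoforms unambiguous


def generate_reference_catalog(config: SimulationConfig) -> list[CatalogEntry]:
    """Draw ``n_families`` mature sequences with lengths from the
    configured weights, pairwise separated well beyond the homology
    match rule, plus ``similar_pairs`` deliberate near-duplicate
    families (one substitution apart) for family-merge testing.
    """
    rng = np.random.default_rng(config.seed)
    lengths = sorted(config.mature_length_weights)
    weights = np.array([config.mature_length_weights[l] for l in lengths],
                       dtype=float)
    weights = weights / weights.sum()
    catalog: list[CatalogEntry] = []
    attempts = 0
    max_attempts = 500 * (config.n_families + config.similar_pairs)
    number = 101
    while len(catalog) < config.n_families:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                "cannot generate the requested family diversity under the "
                "configured length weights")
        length = int(rng.choice(lengths, p=weights))
        seq = _random_seq(rng, length)
        too_close = any(
            match_candidate(seq, e.sequence, max_subs=_MIN_FAMILY_SEPARATION,
                            max_len_diff=1).is_match
            for e in catalog)
        if too_close:
            continue
        arm = "5p" if rng.random() < 0.5 else "3p"
        catalog.append(CatalogEntry(family=f"miR{number}", sequence=seq, arm=arm))
        number += 1
    for _ in range(config.similar_pairs):
        parent = catalog[int(rng.integers(len(catalog)))]
        pos = int(rng.integers(len(parent.sequence)))
        alternatives = [n for n in "ACGU" if n != parent.sequence[pos]]
        base = alternatives[int(rng.integers(3))]
        seq = parent.sequence[:pos] + base + parent.sequence[pos + 1:]
        catalog.append(CatalogEntry(family=f"miR{number}", sequence=seq,
                                    arm=parent.arm))
        number += 1
    return catalog


def plant_hairpin(genome: str, mature: str, star_mismatches: int,
                  loop_len: int = 8, flank_len: int = 20,
                  seed: int = 0, genome_id: str = "chr1",
                  pad: str = "N") -> tuple[str, PlantedHairpin]:
    """Insert mature + loop + mismatched star (plus flanks) into the
    genome at a seeded random position.

    The loop, the flanks, and the mutated star positions are filled with
    the inert base N by default: N pairs nothing, so the planted duplex
    is the unique maximum-pairing structure of the insert and the
    number of unpaired mature positions equals ``star_mismatches``
    exactly.  Pass ``pad="ACGU"`` (or any alphabet) for random pairable
    padding instead; mutated star positions stay N either way.
    """
    if loop_len < 3:
        raise ValueError("loop_len must be >= 3")
    L = len(mature)
    # interior positions only: terminal mismatches could pair into flanks/loop
    interior = list(range(2, L - 2)) if L > 4 else list(range(L))
    if star_mismatches > len(interior):
        raise ValueError("too many star mismatches for this mature length")
    rng = np.random.default_rng(seed)
    star = list(revcomp(mature))
    chosen = rng.choice(interior, size=star_mismatches, replace=False)
    for j in sorted(int(x) for x in chosen):
        star[j] = "N"
    if pad == "N":
        left = right = "N" * flank_len
        loop = "N" * loop_len
    else:
        alphabet = np.array(list(pad))
        left = "".join(rng.choice(alphabet, size=flank_len))
        loop = "".join(rng.choice(alphabet, size=loop_len))
        right = "".join(rng.choice(alphabet, size=flank_len))
    insert = left + mature + loop + "".join(star) + right
    if len(genome) < len(insert):
        raise ValueError("genome shorter than the hairpin insert")
    pos = int(rng.integers(0, len(genome) - len(insert) + 1))
    new_genome = genome[:pos] + insert + genome[pos:]
    mature_start = pos + flank_len
    truth = PlantedHairpin(
        genome_id=genome_id, mature=mature, star_mismatches=star_mismatches,
        mature_start=mature_start, mature_end=mature_start + L,
        insert_start=pos, insert_end=pos + len(insert),
    )
    return new_genome, truth


def simulate_library(catalog: list[CatalogEntry], genome: str,
                     config: SimulationConfig) -> tuple[ReadSet, GroundTruth]:
    """Emit ``depth`` reads: miRNA-derived isoforms plus a 24-nt genomic
    background.

    Isoform noise per read: with probability ``substitution_rate`` one
    random position is substituted; the 3' end is truncated by 0 to
    ``truncation_max`` nt and extended by a U-tail of 0 to ``utail_max``
    nt (both uniform).  Background reads are genome substrings.
    """
    if not catalog:
        raise ValueError("catalog must be non-empty")
    rng = np.random.default_rng(config.seed + 1)
    n_background = int(round(config.background_fraction * config.depth))
    n_mirna = config.depth - n_background
    truth = GroundTruth(n_background=n_background)
    for e in catalog:
        truth.families[e.family] = FamilyTruth(family=e.family,
                                               sequence=e.sequence, arm=e.arm)
    # lognormal per-family expression, normalized to a multinomial
    expr = rng.lognormal(mean=0.0, sigma=config.abundance_dispersion,
                         size=len(catalog))
    probs = expr / expr.sum()
    family_counts = rng.multinomial(n_mirna, probs)
    counts: Counter = Counter()
    for entry, n_reads in zip(catalog, family_counts):
        ft = truth.families[entry.family]
        ft.true_count = int(n_reads)
        if n_reads == 0:
            continue
        base = entry.sequence
        subs = rng.random(n_reads) < config.substitution_rate
        sub_pos = rng.integers(0, len(base), size=n_reads)
        sub_alt = rng.integers(0, 3, size=n_reads)
        trunc = rng.integers(0, config.truncation_max + 1, size=n_reads)
        utail = rng.integers(0, config.utail_max + 1, size=n_reads)
        for i in range(n_reads):
            read = base
            if subs[i]:
                p = int(sub_pos[i])
                alts = [n for n in "ACGU" if n != read[p]]
                read = read[:p] + alts[int(sub_alt[i])] + read[p + 1:]
            t = int(trunc[i])
            if t:
                read = read[:-t]
            read = read + "U" * int(utail[i])
            counts[read] += 1
            ft.emitted[read] += 1
    if n_background:
        if len(genome) < BACKGROUND_LEN:
            raise ValueError("genome too short for background reads")
        starts = rng.integers(0, len(genome) - BACKGROUND_LEN + 1,
                              size=n_background)
        strands = rng.random(n_background) < 0.5
        for s, minus in zip(starts, strands):
            frag = genome[int(s):int(s) + BACKGROUND_LEN]
            counts[revcomp(frag) if minus else frag] += 1
    readset = ReadSet(counts=dict(counts), library_id=f"sim{config.seed}")
    return readset, truth


def simulate_degradome(transcripts: list[tuple[str, str]],
                       planted_sites: list[PlantedCleavage], depth: int,
                       noise_fraction: float, seed: int,
                       tag_lengths: tuple[int, ...] = (20, 21)) -> tuple[dict[str, int], GroundTruth]:
    """Emit degradome tags whose 5' ends concentrate at planted cleavage
    positions, plus uniformly positioned noise tags.

    Returns ``({tag sequence: count}, ground truth)``.  Tags are exact
    sense-strand substrings of the transcripts, at least 19 nt long.
    """
    if not 0.0 <= noise_fraction <= 1.0:
        raise ValueError("noise_fraction must be in [0, 1]")
    seqs = dict(transcripts)
    for site in planted_sites:
        if site.transcript_id not in seqs:
            raise ValueError(f"unknown transcript {site.transcript_id!r}")
        if not 0 <= site.position <= len(seqs[site.transcript_id]) - min(tag_lengths):
            raise ValueError(
                f"site at {site.position} outside transcript "
                f"{site.transcript_id!r} (too close to the 3' end for a tag)")
    rng = np.random.default_rng(seed)
    n_noise = int(round(noise_fraction * depth))
    n_signal = depth - n_noise
    tags: Counter = Counter()
    if planted_sites and n_signal:
        site_idx = rng.integers(0, len(planted_sites), size=n_signal)
        lens = rng.choice(tag_lengths, size=n_signal)
        for i in range(n_signal):
            site = planted_sites[int(site_idx[i])]
            tseq = seqs[site.transcript_id]
            length = min(int(lens[i]), len(tseq) - site.position)
            tags[tseq[site.position:site.position + length]] += 1
    if n_noise:
        tids = sorted(seqs)
        tid_idx = rng.integers(0, len(tids), size=n_noise)
        lens = rng.choice(tag_lengths, size=n_noise)
        for i in range(n_noise):
            tseq = seqs[tids[int(tid_idx[i])]]
            length = min(int(lens[i]), len(tseq))
            pos = int(rng.integers(0, len(tseq) - length + 1))
            tags[tseq[pos:pos + length]] += 1
    truth = GroundTruth(cleavage_sites=list(planted_sites))
    return dict(tags), truth


def make_target_transcripts(catalog: list[CatalogEntry], n_sites: int,
                            transcript_len: int, seed: int,
                            prefix: str = "tx") -> tuple[list[tuple[str, str]], list[PlantedCleavage]]:
    """Random transcripts each carrying one perfect-complement site for a
    catalog miRNA, with the cleavage position recorded opposite miRNA
    positions 10-11."""
    rng = np.random.default_rng(seed)
    transcripts = []
    sites = []
    for i in range(n_sites):
        entry = catalog[i % len(catalog)]
        L = len(entry.sequence)
        body = _random_seq(rng, transcript_len)
        start = int(rng.integers(40, transcript_len - L - 40))
        site_seq = revcomp(entry.sequence)
        tseq = body[:start] + site_seq + body[start + L:]
        tid = f"{prefix}{i + 1}"
        # tag 5' end marks the base paired to miRNA position 10
        cleavage = start + L - 10
        transcripts.append((tid, tseq))
        sites.append(PlantedCleavage(transcript_id=tid, position=cleavage,
                                     mirna=entry.family))
    return transcripts, sites
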