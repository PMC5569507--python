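"""Stage orchestration: wire the analysis modules into an end-to-end run.

Each stage reads plain-text inputs, writes TSV/FASTA outputs into the
configured output directory, and appends structured lines (thresholds
applied, record counts before/after each filter) to a deterministic run
log.  Coordinates in all reports are 1-based inclusive; the in-memory
model is 0-based half-open.
"""

from __future__ import annotations

import os
from dataclasses import replace

from . import degradome as deg
from . import hairpin as hp
from . import identify as ident
from . import io
from . import preprocess as pre
from . import stats as st
from . import synth
from . import targets as tg
from .config import PipelineConfig

CANDIDATE_COLUMNS = ["name", "family", "arm", "sequence", "length", "raw_count",
                     "cluster_count", "rpm", "n_members", "five_prime"]


class RunLog:
    """Accumulates deterministic log lines (no timestamps)."""

    def __init__(self) -> None:
        self.lines: list[str] = []

    def add(self, message: str) -> None:
        self.lines.append(message)

    def write(self, path: str) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("\n".join(self.lines) + ("\n" if self.lines else ""))


def _outpath(cfg: PipelineConfig, name: str) -> str:
    os.makedirs(cfg.out_dir, exist_ok=True)
    return os.path.join(cfg.out_dir, name)


def _fmt(x: float) -> str:
    return f"{x:.6g}"


# ---------------------------------------------------------------- simulate

def plant_all_hairpins(genome: str, catalog, star_mismatches: int, seed: int,
                       loop_len: int = 8, flank_len: int = 20,
                       genome_id: str = "chr1"):
    """Plant one hairpin per catalog family, keeping earlier loci
    coordinates consistent as later inserts shift the sequence."""
    truths: list[synth.PlantedHairpin] = []
    for i, entry in enumerate(catalog):
        genome, truth = synth.plant_hairpin(
            genome, entry.sequence, star_mismatches, loop_len=loop_len,
            flank_len=flank_len, seed=seed + i, genome_id=genome_id)
        shift = truth.insert_end - truth.insert_start
        truths = [
            replace(t, mature_start=t.mature_start + shift,
                    mature_end=t.mature_end + shift,
                    insert_start=t.insert_start + shift,
                    insert_end=t.insert_end + shift)
            if t.insert_start >= truth.insert_start else t
            for t in truths
        ]
        truths.append(truth)
    return genome, truths


def stage_simulate(cfg: PipelineConfig, log: RunLog):
    sim = cfg.simulate
    sim_config = synth.SimulationConfig(
        seed=cfg.seed, n_families=sim.n_families,
        substitution_rate=sim.substitution_rate,
        truncation_max=sim.truncation_max, utail_max=sim.utail_max,
        depth=sim.depth, background_fraction=sim.background_fraction,
        abundance_dispersion=sim.abundance_dispersion,
        similar_pairs=sim.similar_pairs)
    catalog = synth.generate_reference_catalog(sim_config)
    log.add(f"simulate: catalog of {len(catalog)} families, seed {cfg.seed}")
    genome = synth.random_genome(sim.genome_length, cfg.seed + 10)
    # pad each insert as wide as the validation flank so the extracted
    # windows stay within the inert padding
    genome, hairpins = plant_all_hairpins(
        genome, catalog, sim.hairpin_star_mismatches, cfg.seed + 100,
        flank_len=cfg.flank)
    log.add(f"simulate: planted {len(hairpins)} hairpins "
            f"({sim.hairpin_star_mismatches} star mismatches each)")
    readset, truth = synth.simulate_library(catalog, genome, sim_config)
    truth.hairpins = hairpins
    log.add(f"simulate: library of {readset.n_reads} reads "
            f"({truth.n_background} background), {readset.n_unique} unique")
    transcripts, sites = synth.make_target_transcripts(
        catalog, sim.n_cleavage_sites, sim.transcript_length, cfg.seed + 3)
    tags, deg_truth = synth.simulate_degradome(
        transcripts, sites, sim.degradome_depth,
        sim.degradome_noise_fraction, cfg.seed + 4)
    truth.cleavage_sites = deg_truth.cleavage_sites
    log.add(f"simulate: {sum(tags.values())} degradome tags over "
            f"{len(sites)} planted cleavage sites")

    io.write_fasta([(f"{e.family}|{e.arm}", e.sequence) for e in catalog],
                   _outpath(cfg, "catalog.fasta"))
    io.write_fasta([("chr1", genome)], _outpath(cfg, "genome.fasta"))
    io.write_collapsed_fasta(readset.counts, _outpath(cfg, "reads.fasta"))
    io.write_fasta(transcripts, _outpath(cfg, "transcripts.fasta"))
    io.write_collapsed_fasta(tags, _outpath(cfg, "degradome_tags.fasta"),
                             prefix="t")
    io.write_tsv(_outpath(cfg, "truth_families.tsv"),
                 ["family", "sequence", "arm", "true_count", "top_read_count"],
                 [(f.family, f.sequence, f.arm, f.true_count, f.top_read_count)
                  for f in truth.families.values()])
    io.write_tsv(_outpath(cfg, "truth_hairpins.tsv"),
                 ["genome_id", "mature", "star_mismatches", "mature_start",
                  "mature_end", "strand"],
                 [(h.genome_id, h.mature, h.star_mismatches,
                   h.mature_start + 1, h.mature_end, h.strand)
                  for h in truth.hairpins])
    io.write_tsv(_outpath(cfg, "truth_cleavage.tsv"),
                 ["transcript_id", "position", "mirna"],
                 [(s.transcript_id, s.position + 1, s.mirna)
                  for s in truth.cleavage_sites])
    io.write_yaml(cfg.to_dict(), _outpath(cfg, "config_used.yaml"))
    return catalog, genome, readset, truth, transcripts, tags


# -------------------------------------------------------------- preprocess

def stage_preprocess(cfg: PipelineConfig, log: RunLog,
                     raw_counts: dict[str, int],
                     structural_ref: list[str]) -> pre.ReadSet:
    total_raw = sum(raw_counts.values())
    log.add(f"preprocess: {total_raw} raw reads, {len(raw_counts)} unique")
    readset = pre.preprocess_reads(
        raw_counts, structural_ref, min_len=cfg.min_len, max_len=cfg.max_len,
        max_mismatch=cfg.structural_max_mismatch,
        library_id=cfg.species_code)
    log.add(f"preprocess: length window {cfg.min_len}-{cfg.max_len}, "
            f"structural filter <= {cfg.structural_max_mismatch} mismatches, "
            f"U-tails shortened; kept {readset.n_reads} reads "
            f"({readset.n_unique} unique), RPM denominator "
            f"{readset.total_18_26}")
    io.write_collapsed_fasta(readset.counts, _outpath(cfg, "readset.fasta"))
    io.write_tsv(_outpath(cfg, "library_totals.tsv"),
                 ["library_id", "total_raw", "total_retained", "total_18_26",
                  "n_unique"],
                 [(readset.library_id, readset.total_raw, readset.n_reads,
                   readset.total_18_26, readset.n_unique)])
    return readset


def load_readset(cfg: PipelineConfig) -> pre.ReadSet:
    counts = io.read_collapsed_fasta(_outpath(cfg, "readset.fasta"))
    _, rows = io.read_tsv(_outpath(cfg, "library_totals.tsv"))
    lib, total_raw, _, total_18_26, _ = rows[0]
    return pre.ReadSet(counts=counts, library_id=lib,
                       total_raw=int(total_raw), total_18_26=int(total_18_26))


# ---------------------------------------------------------------- identify

def read_catalog(path: str) -> list[ident.CatalogEntry]:
    """Catalog FASTA with ``family|arm`` headers (arm optional)."""
    entries = []
    for rec_id, seq in io.read_fasta(path):
        family, _, arm = rec_id.partition("|")
        entries.append(ident.CatalogEntry(family=family, sequence=seq,
                                          arm=arm or None))
    return entries


def stage_identify(cfg: PipelineConfig, log: RunLog, readset: pre.ReadSet,
                   catalog: list[ident.CatalogEntry]) -> list[ident.MiRNACandidate]:
    candidates = ident.identify_pipeline(
        readset, catalog, species_code=cfg.species_code,
        prefix_len=cfg.prefix_len, max_subs=cfg.max_substitutions,
        max_len_diff=cfg.max_length_diff, min_raw=cfg.min_raw_reads,
        min_rpm=cfg.min_rpm, rule=cfg.abundance_rule)
    threshold = ident.abundance_threshold(
        readset.total_18_26, cfg.min_raw_reads, cfg.min_rpm, cfg.abundance_rule)
    log.add(f"identify: match rule <= {cfg.max_substitutions} substitutions / "
            f"<= {cfg.max_length_diff} nt, prefix {cfg.prefix_len}, abundance "
            f"threshold {_fmt(threshold)} reads; retained {len(candidates)} "
            f"candidates in {len({c.family for c in candidates})} families")
    io.write_tsv(_outpath(cfg, "candidates.tsv"), CANDIDATE_COLUMNS,
                 [(c.name, c.family, c.arm or "", c.sequence, len(c.sequence),
                   c.raw_count, c.cluster_count, _fmt(c.rpm), c.n_members,
                   c.sequence[0]) for c in candidates])
    return candidates


def load_candidates(cfg: PipelineConfig) -> list[ident.MiRNACandidate]:
    _, rows = io.read_tsv(_outpath(cfg, "candidates.tsv"))
    out = []
    for (name, family, arm, seq, _length, raw, cluster, rpm, _nm, _fp) in rows:
        out.append(ident.MiRNACandidate(
            sequence=seq, family=family, arm=arm or None,
            members=[(seq, int(raw))], raw_count=int(raw),
            cluster_count=int(cluster), rpm=float(rpm), name=name))
    return out


# ----------------------------------------------------------------- hairpin

def stage_hairpin(cfg: PipelineConfig, log: RunLog,
                  candidates: list[ident.MiRNACandidate],
                  genome: dict[str, str]) -> dict[str, hp.CandidateValidation]:
    results: dict[str, hp.CandidateValidation] = {}
    rows = []
    n_pass = 0
    for c in candidates:
        # nontemplated tails keep the representative off the genome; fall
        # back to the most abundant cluster member that maps exactly
        res = hp.CandidateValidation(loci=[], passed=False, high_copy=False)
        for member_seq, _count in c.members[:5]:
            res = hp.validate_candidate(
                member_seq, genome, flank=cfg.flank,
                max_mismatches=cfg.hairpin_max_mismatches)
            if res.loci:
                break
        results[c.name] = res
        n_pass += res.passed
        for locus in res.loci:
            rows.append((c.name, locus.genome_id, locus.window_start + 1,
                         locus.window_end, locus.strand,
                         locus.mature_arm_mismatches,
                         "yes" if locus.passed else "no",
                         "yes" if res.high_copy else "no", locus.structure))
    log.add(f"hairpin: flank {cfg.flank} nt each side, "
            f"< {cfg.hairpin_max_mismatches} mismatches; {n_pass}/"
            f"{len(candidates)} candidates validated")
    io.write_tsv(_outpath(cfg, "hairpin_loci.tsv"),
                 ["candidate", "genome_id", "window_start", "window_end",
                  "strand", "mature_arm_mismatches", "passed", "high_copy",
                  "structure"], rows)
    return results


# --------------------------------------------------------------- degradome

def stage_degradome(cfg: PipelineConfig, log: RunLog, tags: dict[str, int],
                    transcripts: list[tuple[str, str]],
                    candidates: list[ident.MiRNACandidate]):
    profiles = deg.map_tags(tags, transcripts, min_len=cfg.min_tag_len)
    mirnas = [(c.name, c.sequence) for c in candidates]
    peaks_by_tid, links = deg.link_all_peaks(
        profiles, dict(transcripts), mirnas, score_cutoff=cfg.target_cutoff,
        min_unique=cfg.peak_min_unique, top_n=cfg.peak_top_n,
        min_rpm=cfg.peak_min_rpm, se_multiplier=cfg.peak_se_multiplier)
    n_peaks = sum(len(p) for p in peaks_by_tid.values())
    log.add(f"degradome: tags >= {cfg.min_tag_len} nt, peak rules "
            f"{cfg.peak_min_unique}/{cfg.peak_top_n}/{_fmt(cfg.peak_min_rpm)}/"
            f"{_fmt(cfg.peak_se_multiplier)}; {n_peaks} peaks, "
            f"{len(links)} miRNA links")
    peak_rows = []
    for tid in sorted(peaks_by_tid):
        for p in peaks_by_tid[tid]:
            peak_rows.append((tid, p.position + 1, p.count, _fmt(p.rpm),
                              p.rank, _fmt(p.background_mean),
                              _fmt(p.background_se), p.rules))
    io.write_tsv(_outpath(cfg, "degradome_peaks.tsv"),
                 ["transcript", "position", "count", "rpm", "rank",
                  "background_mean", "background_se", "rules_passed"],
                 peak_rows)
    io.write_tsv(_outpath(cfg, "mirna_links.tsv"),
                 ["mirna", "transcript", "cleavage_position", "score"],
                 [(l.mirna, l.transcript, l.cleavage + 1, _fmt(l.score))
                  for l in links])
    return peaks_by_tid, links


# ----------------------------------------------------------------- targets

def stage_targets(cfg: PipelineConfig, log: RunLog,
                  candidates: list[ident.MiRNACandidate],
                  transcripts: list[tuple[str, str]]) -> list[tg.TargetAlignment]:
    mirnas = [(c.name, c.sequence) for c in candidates]
    hits = tg.predict_targets(mirnas, transcripts, cutoff=cfg.target_cutoff)
    with_targets = {h.mirna for h in hits}
    log.add(f"targets: cutoff {_fmt(cfg.target_cutoff)}; {len(hits)} sites; "
            f"{len(with_targets)}/{len(candidates)} candidates with targets; "
            f"{len({h.transcript for h in hits})} target transcripts")
    io.write_tsv(_outpath(cfg, "target_sites.tsv"),
                 ["mirna", "transcript", "start", "end", "score", "cleavage",
                  "states", "gap_position"],
                 [(h.mirna, h.transcript, h.start + 1, h.end, _fmt(h.score),
                   h.cleavage + 1, h.states, h.gap_position) for h in hits])
    return hits


# ------------------------------------------------------------------- stats

def stage_stats(cfg: PipelineConfig, log: RunLog, readset: pre.ReadSet,
                candidates: list[ident.MiRNACandidate]) -> None:
    dist = st.size_distribution(readset)
    io.write_tsv(_outpath(cfg, "size_distribution.tsv"),
                 ["library_id", "length", "count", "proportion"],
                 [(dist.library_id, length, dist.counts[length],
                   _fmt(dist.proportions[length]))
                  for length in sorted(dist.counts)])
    ratio = st.ratio_24_21(readset)
    io.write_tsv(_outpath(cfg, "ratio_24_21.tsv"),
                 ["library_id", "ratio_24_21"],
                 [(readset.library_id, "NA" if ratio is None else _fmt(ratio))])
    if candidates:
        comp = st.five_prime_composition([c.sequence for c in candidates])
        io.write_tsv(_outpath(cfg, "five_prime_composition.tsv"),
                     ["nucleotide", "fraction"],
                     [(nt, _fmt(comp[nt])) for nt in "ACGU"])
        per_species = {readset.library_id or cfg.species_code:
                       {c.family: c.rpm for c in candidates}}
        matrix = st.build_family_matrix(per_species)
        io.write_tsv(_outpath(cfg, "family_rpm.tsv"),
                     ["family"] + list(matrix.rpm.columns),
                     [[fam] + [_fmt(v) for v in matrix.rpm.loc[fam]]
                      for fam in matrix.rpm.index])
    log.add(f"stats: size distribution over {sum(dist.counts.values())} reads; "
            f"24/21 ratio {'NA' if ratio is None else _fmt(ratio)}")


# --------------------------------------------------------------------- all

def run_all(cfg: PipelineConfig) -> RunLog:
    """Simulate a ground-truthed dataset and run every analysis stage."""
    log = RunLog()
    catalog, genome, _raw, _truth, transcripts, tags = stage_simulate(cfg, log)
    raw_counts = io.read_collapsed_fasta(_outpath(cfg, "reads.fasta"))
    readset = stage_preprocess(cfg, log, raw_counts, structural_ref=[])
    candidates = stage_identify(cfg, log, readset, catalog)
    stage_hairpin(cfg, log, candidates, {"chr1": genome})
    stage_degradome(cfg, log, tags, transcripts, candidates)
    stage_targets(cfg, log, candidates, transcripts)
    stage_stats(cfg, log, readset, candidates)
    log.write(_outpath(cfg, "run.log"))
    return log
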