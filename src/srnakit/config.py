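"""Pipeline configuration with the published defaults.

Every numeric threshold of every stage lives here so a single YAML file
(plus CLI overrides) drives the whole workflow: 16-26-nt retention,
<=2-substitution / <=1-nt homology matching, 5' 1-16 clustering, the
>10-reads / >5-RPM abundance filter, 200-nt flanks (400 nt total),
<4 hairpin mismatches, the 12 / 12 / 5 / 5 peak rules, the 2.5 target
cutoff, and the 30-nt variation window.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

from . import io


@dataclass
class SimulateSection:
    n_families: int = 20
    depth: int = 100_000
    substitution_rate: float = 0.02
    truncation_max: int = 2
    utail_max: int = 3
    background_fraction: float = 0.3
    abundance_dispersion: float = 1.0
    similar_pairs: int = 0
    genome_length: int = 20_000
    hairpin_star_mismatches: int = 0
    n_cleavage_sites: int = 10
    transcript_length: int = 400
    degradome_depth: int = 2_000
    degradome_noise_fraction: float = 0.2


@dataclass
class PipelineConfig:
    # paths
    reads: str = ""
    catalog: str = ""
    structural_ref: str = ""
    genome: str = ""
    transcripts: str = ""
    degradome_tags: str = ""
    out_dir: str = "srnakit_out"
    # identity
    seed: int = 0
    species_code: str = "Sim"
    # preprocess
    min_len: int = 16
    max_len: int = 26
    structural_max_mismatch: int = 2
    # identification
    max_substitutions: int = 2
    max_length_diff: int = 1
    prefix_len: int = 16
    min_raw_reads: int = 10
    min_rpm: float = 5.0
    abundance_rule: str = "max"
    # hairpin validation
    flank: int = 200
    hairpin_max_mismatches: int = 4
    # degradome
    min_tag_len: int = 19
    peak_min_unique: int = 12
    peak_top_n: int = 12
    peak_min_rpm: float = 5.0
    peak_se_multiplier: float = 5.0
    # targets
    target_cutoff: float = 2.5
    variation_window: int = 30
    # simulation
    simulate: SimulateSection = field(default_factory=SimulateSection)

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Build a config from defaults, an optional YAML file, and CLI
    overrides (highest precedence).  Unknown keys are errors."""
    data: dict = {}
    if path:
        loaded = io.read_yaml(path) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a mapping")
        data.update(loaded)
    for key, value in (overrides or {}).items():
        if value is not None:
            data[key] = value
    sim_data = data.pop("simulate", {}) or {}
    known = {f.name for f in fields(PipelineConfig)} - {"simulate"}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    sim_known = {f.name for f in fields(SimulateSection)}
    sim_unknown = set(sim_data) - sim_known
    if sim_unknown:
        raise ValueError(f"unknown simulate config keys: {sorted(sim_unknown)}")
    return PipelineConfig(simulate=SimulateSection(**sim_data), **data)
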