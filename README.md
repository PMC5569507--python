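# srnakit

A small-RNA analysis toolkit for genomes-poor plant lineages:

- **preprocess** — 16–26-nt length filtering, structural-RNA removal
  (rRNA/tRNA/snoRNA/snRNA fragments, ≤2 mismatches on either strand),
  3′ U-tail shortening, and RPM normalization over 18–26-nt reads.
- **identify** — conserved-miRNA candidate discovery by 5′-anchored
  homology to a reference catalog (≤2 substitutions, ≤1-nt length
  difference), merging of near-identical families (`miR156/7`),
  isoform clustering on 5′ nucleotides 1–16, the >10-reads / >5-RPM
  abundance filter, and `Spc-miR170/1-3p.2380_3761`-style naming.
- **hairpin** — exact genome mapping (both strands), ±200-nt window
  extraction, base-pair-maximization folding (Watson–Crick + G:U,
  hairpin loops ≥3, deterministic traceback), and the <4-unpaired-
  position validation rule.  Any callable with the `fold_maxpair`
  signature (e.g. a thermodynamic folder) can be plugged in.
- **degradome** — PARE tag mapping (≥19 nt, exact, sense strand),
  the four-rule local peak caller (≥12 unique tags; top-12 position;
  RPM > 5; RPM > mean + 5×SE), and peak-to-miRNA linking through the
  position-10/11 cleavage geometry.
- **targets** — plant-style complementarity scoring (match 0, G:U 0.5,
  mismatch 1, single 1-nt bulge 2, penalties doubled at positions 2–13)
  at a 2.5 cutoff, plus 30-nt sliding-window nucleotide-variation
  profiles of aligned orthogroups around binding sites.
- **stats** — size distributions, 24/21-nt ratios with an exact
  Wilcoxon rank-sum test, 5′-nucleotide composition with a χ² test,
  per-family consensus/variation summaries, and conservation-class
  (I–V) clustering of the family × species expression matrix.
- **synth** — a seeded synthetic-data generator (catalogs, genomes with
  planted hairpins, isomiR-rich libraries, degradome tags) so every
  stage is verifiable by parameter recovery against ground truth.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: parameter
recovery, brute-force rule-fidelity oracles, exhaustive folding
enumeration, the planted-hairpin mismatch boundary, degradome
recovery, statistics cross-checks, and byte-identical pipeline reruns.

## CLI

Every stage is a subcommand; `--config` takes a YAML file and flags
override it. Reports use 1-based inclusive coordinates.

```sh
# simulate a ground-truthed dataset and run every stage end to end
srnakit all --out-dir run1 --seed 7

# or stage by stage
srnakit simulate   --out-dir run1 --seed 7
srnakit preprocess --out-dir run1 --reads run1/reads.fasta
srnakit identify   --out-dir run1 --catalog run1/catalog.fasta
srnakit hairpin    --out-dir run1 --genome run1/genome.fasta
srnakit degradome  --out-dir run1 --degradome-tags run1/degradome_tags.fasta \
                   --transcripts run1/transcripts.fasta
srnakit targets    --out-dir run1 --transcripts run1/transcripts.fasta
srnakit stats      --out-dir run1
```

Outputs are TSVs (`candidates.tsv`, `hairpin_loci.tsv`,
`degradome_peaks.tsv`, `mirna_links.tsv`, `target_sites.tsv`, …), a
deterministic `run.log` recording every threshold and record count, and
an echo of the effective configuration.

Input conventions: reads as FASTQ or collapsed FASTA (`>id_count`
headers); catalog FASTA headers `family|arm` (e.g. `miR166|3p`);
genome/transcripts as plain FASTA (T is converted to U on read).

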