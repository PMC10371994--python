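"""Synthetic MiSeq-style amplicon pool generation.

Everything downstream of the sequencer is testable without any external
data: this module fabricates (i) per-amplicon reference sequences, (ii) a
cohort of diploid/hemizygous truth genotypes drawn under Hardy-Weinberg
equilibrium, and (iii) dual-indexed pooled reads with Poisson depth and iid
per-base substitution error.

Simulated reads are full-length single-end amplicon copies: the analysis is
pileup-based and the sequenced fragment is the amplicon itself, so paired
2x150 reads would exercise nothing extra.  Each read is the 8-bp forward
index, the (error-perturbed) amplicon copy, then the reverse-complemented
8-bp reverse index — the same construct the demultiplexer expects.

Default parameters reproduce the study conditions of the Tanzanian severe
malaria cohort the built-in panel targets: 100 samples, site alternate-allele
frequencies matching the published cohort, ~1200x mean amplicon depth with
the Dantu amplicon down-weighted to 0.15x (its primers bind less well, and
the published run averaged 184x there), and a per-base substitution error
of 0.005.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .panel import Panel
from .demux import SampleSheet, reverse_complement

__all__ = [
    "SimConfig",
    "TruthRecord",
    "SimulatedRead",
    "DEFAULT_ALT_FREQS",
    "simulate_references",
    "simulate_cohort",
    "simulate_reads",
    "write_fastq",
    "truth_table",
]

_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Study-cohort alternate allele frequencies per site key, computed from the
#: published genotype counts (het + 2*hom_alt over 2n; rs334 uses the
#: text-reported 5 het / 4 hom split).  Sites never observed variant in the
#: cohort have frequency 0.
DEFAULT_ALT_FREQS: dict[str, float] = {
    "X:154532738": 18 / 198,    # rs2230036
    "X:154533025": 0.0,         # rs76723693 (968)
    "X:154533122": 0.0,         # rs137852327
    "X:154534125": 0.0,         # rs137852328 (680)
    "X:154534177": 1 / 198,     # rs5986875
    "X:154534440": 0.0,         # rs5030872 (542)
    "X:154534527": 1 / 174,
    "X:154535277": 62 / 174,    # rs1050829 (376)
    "X:154535443": 1 / 174,
    "X:154535468": 1 / 174,
    "X:154536002": 24 / 174,    # rs1050828 (202)
    "11:5226867": 1 / 198,
    "11:5226925": 0.0,          # rs33915217
    "11:5226932": 1 / 198,      # rs35578002
    "11:5226943": 0.0,          # rs33950507 (HbE)
    "11:5226963": 0.0,          # rs33972047
    "11:5226966": 2 / 196,      # rs35382661
    "11:5227002": 13 / 198,     # rs334 (HbS): 5 het + 4 hom alt
    "11:5227003": 0.0,          # rs33930165 (HbC)
    "11:5227013": 157 / 192,    # rs713040
    "11:5227072": 1 / 198,      # rs386134236
    "1:159204646": 19 / 190,
    "1:159204893": 1.0,         # rs2814778 (Duffy) — fixed in the cohort
    "4:143781321": 3 / 196,     # rs186873296 (Dantu)
    "4:143781342": 1 / 198,
}


@dataclass
class SimConfig:
    """Simulation parameters; defaults emulate the study sequencing run."""

    n_samples: int = 100
    sex_ratio: float = 0.5          # fraction of males
    alt_freqs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ALT_FREQS))
    mean_depth: float = 1200.0      # reads per sample x amplicon
    error_rate: float = 0.005       # iid per-base substitution probability
    depth_multipliers: dict[str, float] = field(
        default_factory=lambda: {"DANTU_1": 0.15})
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must be in [0, 1]")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        for k, f in self.alt_freqs.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"alt frequency for {k} outside [0, 1]")
        for k, m in self.depth_multipliers.items():
            if m < 0:
                raise ValueError(f"depth multiplier for {k} negative")


@dataclass(frozen=True)
class TruthRecord:
    """Ground-truth genotypes for one simulated sample.

    ``genotypes`` maps site key to a tuple of alleles: length 2 for
    autosomal and female X sites, length 1 (hemizygous) for male X sites.
    """

    sample_id: str
    sex: str  # "male" | "female"
    genotypes: dict[str, tuple[str, ...]]


@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    sequence: str
    quality: str
    # provenance (the assignment log):
    sample_id: str
    amplicon_id: str
    haplotype: int


def simulate_references(panel: Panel, seed: int) -> dict[str, str]:
    """Draw a random reference sequence per amplicon.

    Bases are uniform over A/C/G/T, then each variant site's offset is
    overwritten with its ref allele so that panel and sequences agree.
    Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    refs: dict[str, str] = {}
    for amp in panel.amplicons:
        arr = _ALPHABET[rng.integers(0, 4, size=amp.length)]
        seq = bytearray(arr.tobytes())
        for s in amp.sites:
            seq[amp.local_offset(s.pos)] = ord(s.ref_allele)
        refs[amp.amplicon_id] = seq.decode()
    return refs


def simulate_cohort(panel: Panel, config: SimConfig) -> list[TruthRecord]:
    """Draw per-sample truth genotypes under Hardy-Weinberg equilibrium.

    Autosomal and female X genotypes are two independent Bernoulli(alt
    frequency) allele draws; male X sites get a single draw (hemizygous).
    Sites absent from ``config.alt_freqs`` use frequency 0.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    width = max(3, len(str(config.n_samples - 1)))
    records = []
    for i in range(config.n_samples):
        sex = "male" if rng.random() < config.sex_ratio else "female"
        genotypes: dict[str, tuple[str, ...]] = {}
        for site in panel.sites:
            freq = config.alt_freqs.get(site.key, 0.0)
            ploidy = 1 if (site.x_linked and sex == "male") else 2
            draws = rng.random(ploidy) < freq
            genotypes[site.key] = tuple(
                site.alt_allele if d else site.ref_allele for d in draws
            )
        records.append(
            TruthRecord(sample_id=f"S{i:0{width}d}", sex=sex, genotypes=genotypes)
        )
    return records


def _haplotypes(truth: TruthRecord, amp, ref_seq: str) -> list[bytes]:
    """Per-amplicon haplotype sequences for one sample (1 for male X)."""
    ploidy = 1 if (amp.chrom == "X" and truth.sex == "male") else 2
    haps = []
    for h in range(ploidy):
        seq = bytearray(ref_seq, "ascii")
        for s in amp.sites:
            seq[amp.local_offset(s.pos)] = ord(truth.genotypes[s.key][h])
        haps.append(bytes(seq))
    return haps


def simulate_reads(
    truth: list[TruthRecord],
    refs: dict[str, str],
    panel: Panel,
    config: SimConfig,
    sample_sheet: SampleSheet,
    shuffle: bool = True,
) -> tuple[list[SimulatedRead], list[tuple[str, str, str]]]:
    """Generate the pooled dual-indexed read set.

    For every sample x amplicon the read count is Poisson(mean_depth x
    amplicon multiplier); each read copies one of the sample's haplotypes
    chosen uniformly (a heterozygote therefore has expected alt fraction
    0.5), receives iid per-base substitution errors (uniform over the three
    alternative bases) on the amplicon portion, and is flanked by the
    sample's indices.  Qualities are constant Q30.

    Returns the pooled reads and an assignment log of
    ``(read_id, sample_id, amplicon_id)`` — the demultiplexing ground truth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)  # decoupled from cohort draw
    for t in truth:
        if t.sample_id not in sample_sheet.samples:
            raise KeyError(f"sample {t.sample_id} missing from sample sheet")

    reads: list[SimulatedRead] = []
    log: list[tuple[str, str, str]] = []
    serial = 0
    for t in truth:
        fwd, rev = sample_sheet.samples[t.sample_id]
        rev_rc = reverse_complement(rev)
        for amp in panel.amplicons:
            ref_seq = refs[amp.amplicon_id]
            haps = _haplotypes(t, amp, ref_seq)
            mult = config.depth_multipliers.get(amp.amplicon_id, 1.0)
            n_reads = rng.poisson(config.mean_depth * mult)
            length = len(ref_seq)
            for _ in range(n_reads):
                h = int(rng.integers(0, len(haps)))
                insert = bytearray(haps[h])
                if config.error_rate > 0:
                    hits = np.flatnonzero(rng.random(length) < config.error_rate)
                    for p in hits:
                        # uniform over the 3 bases != current
                        cur = insert[p]
                        choices = [b for b in b"ACGT" if b != cur]
                        insert[p] = choices[int(rng.integers(0, 3))]
                read_id = f"sim_{serial:07d}"
                serial += 1
                seq = fwd + insert.decode() + rev_rc
                reads.append(
                    SimulatedRead(
                        read_id=read_id,
                        sequence=seq,
                        quality="?" * len(seq),  # Phred Q30
                        sample_id=t.sample_id,
                        amplicon_id=amp.amplicon_id,
                        haplotype=h,
                    )
                )
                log.append((read_id, t.sample_id, amp.amplicon_id))
    if shuffle:
        order = rng.permutation(len(reads))
        reads = [reads[i] for i in order]
        log = [log[i] for i in order]
    return reads, log


def write_fastq(reads: list[SimulatedRead], path) -> None:
    """Write the pool as plain 4-line FASTQ."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")


def truth_table(truth: list[TruthRecord]):
    """Long-format truth genotypes as a DataFrame
    (sample_id, sex, site_key, genotype) with genotype like "T/A" or "T"."""
    import pandas as pd

    rows = [
        {
            "sample_id": t.sample_id,
            "sex": t.sex,
            "site_key": key,
            "genotype": "/".join(alleles),
        }
        for t in truth
        for key, alleles in t.genotypes.items()
    ]
    return pd.DataFrame(rows)
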