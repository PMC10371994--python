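"""End-to-end orchestration: simulate -> demultiplex -> align -> call ->
phenotype -> report, plus truth-comparison utilities.

This is the glue the CLI ``pipeline`` subcommand and the test-suite
round-trips use; each stage remains independently usable from its own
module.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import align as _align
from .caller import CallConfig, call_sample, calls_to_table
from .demux import (IndexScheme, SampleSheet, build_index_scheme,
                    check_pool_size, demultiplex)
from .panel import Panel
from .phenotype import infer_phenotypes, phenotype_table
from .report import completeness, summarize_sites
from .simulate import SimConfig, TruthRecord, simulate_cohort, \
    simulate_reads, simulate_references

__all__ = [
    "PipelineResult",
    "run_simulated_pipeline",
    "genotype_reads",
    "expected_call",
    "truth_calls_table",
    "g6pd_truth_classes",
    "recovery_rate",
]


@dataclass
class PipelineResult:
    panel: Panel
    references: dict[str, str]
    truth: list[TruthRecord]
    sheet: SampleSheet
    demux_stats: pd.DataFrame
    n_rejected_reads: int
    calls: pd.DataFrame       # tidy genotype table
    phenotypes: pd.DataFrame
    site_summaries: pd.DataFrame
    completeness: dict


def genotype_reads(
    reads_by_sample: dict[str, list[tuple[str, str, str]]],
    references: dict[str, str],
    panel: Panel,
    sex_by_sample: dict[str, str],
    call_config: CallConfig = CallConfig(),
    method: str = "auto",
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Align demultiplexed reads, pile up and call every sample.

    Returns (genotype table, phenotype table, number of rejected reads).
    """
    all_calls = []
    phenos = []
    n_rejected = 0
    for sample_id, reads in sorted(reads_by_sample.items()):
        alns = []
        for read_id, seq, qual in reads:
            res = _align.align_read(
                seq, references, method=method, read_id=read_id,
                read_qual=qual or None,
            )
            if isinstance(res, _align.Rejection):
                n_rejected += 1
            else:
                alns.append(res)
        cols = _align.pileup(alns, panel)
        sex = sex_by_sample.get(sample_id, "female")
        calls = call_sample(cols, panel, sex, call_config, sample_id)
        all_calls.extend(calls)
        phenos.append(infer_phenotypes(calls, sex, sample_id))
    return (
        calls_to_table(all_calls, panel),
        phenotype_table(phenos),
        n_rejected,
    )


def run_simulated_pipeline(
    panel: Panel,
    config: SimConfig,
    scheme: IndexScheme | None = None,
    max_mismatch: int = 0,
    call_config: CallConfig = CallConfig(),
    method: str = "auto",
) -> PipelineResult:
    """Simulate a pooled run under ``config`` and genotype it end to end."""
    if scheme is None:
        # enough unique pairs for the cohort at the standard 8-bp/90-pair shape
        n = 10
        while (n * n - n) < config.n_samples:
            n += 1
        scheme = build_index_scheme(n, n, seed=config.seed)
    refs = simulate_references(panel, config.seed)
    truth = simulate_cohort(panel, config)
    sheet = SampleSheet.from_scheme(
        [t.sample_id for t in truth], scheme,
        sex={t.sample_id: t.sex for t in truth},
    )
    check_pool_size(config.n_samples, len(panel.amplicons))
    reads, _log = simulate_reads(truth, refs, panel, config, sheet)
    dres = demultiplex(
        ((r.read_id, r.sequence, r.quality) for r in reads),
        scheme, sheet, max_mismatch=max_mismatch,
    )
    calls, phenos, n_rejected = genotype_reads(
        dres.assigned, refs, panel,
        sex_by_sample=sheet.sex, call_config=call_config, method=method,
    )
    return PipelineResult(
        panel=panel,
        references=refs,
        truth=truth,
        sheet=sheet,
        demux_stats=dres.stats(),
        n_rejected_reads=n_rejected,
        calls=calls,
        phenotypes=phenos,
        site_summaries=summarize_sites(calls, panel),
        completeness=completeness(calls, panel),
    )


def expected_call(alleles: tuple[str, ...], alt_allele: str) -> str:
    """Truth alleles -> the genotype class an ideal caller would emit."""
    dose = sum(a == alt_allele for a in alleles)
    if len(alleles) == 1:
        return "hemi_alt" if dose else "hemi_ref"
    return ("hom_ref", "het", "hom_alt")[dose]


def truth_calls_table(truth: list[TruthRecord], panel: Panel) -> pd.DataFrame:
    """Expected genotype classes per sample x site, from the truth records."""
    sites = {s.key: s for s in panel.sites}
    rows = [
        {
            "sample_id": t.sample_id,
            "site_key": key,
            "genotype": expected_call(alleles, sites[key].alt_allele),
        }
        for t in truth
        for key, alleles in t.genotypes.items()
    ]
    return pd.DataFrame(rows)


def g6pd_truth_classes(truth: list[TruthRecord], panel: Panel) -> dict[str, str]:
    """G6PD class per sample computed directly from truth diplotypes.

    Runs the same classification rule the phenotype module applies to
    called genotypes, so truth and pipeline output are comparable even for
    non-canonical allele combinations (classified undetermined on both
    sides).
    """
    from .caller import GenotypeCall
    from .phenotype import RSID_202, RSID_376, infer_g6pd

    site_202 = panel.site_by_rsid(RSID_202)
    site_376 = panel.site_by_rsid(RSID_376)
    out = {}
    for t in truth:
        calls = []
        for site in (site_202, site_376):
            alleles = t.genotypes[site.key]
            cls = expected_call(alleles, site.alt_allele)
            calls.append(
                GenotypeCall(t.sample_id, site.key, site.rsid,
                             depth=9999, alt_fraction=None, call=cls)
            )
        g6pd, _flags = infer_g6pd(calls[0], calls[1], t.sex)
        out[t.sample_id] = str(g6pd) if g6pd else "undetermined"
    return out


def recovery_rate(calls: pd.DataFrame, truth: list[TruthRecord],
                  panel: Panel) -> float:
    """Fraction of truth genotypes recovered exactly (no_call counts as a
    failure)."""
    expected = truth_calls_table(truth, panel)
    merged = expected.merge(
        calls[["sample_id", "site_key", "call"]],
        on=["sample_id", "site_key"], how="left",
    )
    return float((merged["genotype"] == merged["call"]).mean())
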