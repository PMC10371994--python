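"""Cohort-level summaries: genotype distributions, carrier frequencies,
concordance against reference genotyping, and profiling completeness.

All operations work on the tidy per-sample genotype table produced by
:func:`amplitype.caller.calls_to_table` (or any DataFrame with the same
columns).  no_call rows are excluded from every denominator — no
imputation, so denominators legitimately differ between sites.
Hemizygous calls fold onto the homozygous classes for tabulation, the
convention genotype-distribution tables use.

Percentages are rounded half-up to the conventional printed precisions:
frequencies to 1 decimal, overall discordance to 2 decimals, discordance
per 1000 genotypes to 1 decimal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .caller import FOLDED
from .panel import Panel

__all__ = [
    "SiteSummary",
    "ConcordanceReport",
    "round_half_up",
    "site_summary",
    "summarize_sites",
    "carrier_frequency",
    "homozygote_frequency",
    "allele_count_frequency",
    "concordance",
    "completeness",
    "g6pd_distribution",
]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal rounding with ties away from zero (printed-table convention)."""
    factor = 10 ** ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class SiteSummary:
    site_key: str
    rsid: str
    n_genotyped: int
    n_hom_ref: int
    n_het: int
    n_hom_alt: int
    mean_depth: float
    carrier_pct: float | None      # % of samples with >= 1 variant allele
    hom_alt_pct: float | None


@dataclass(frozen=True)
class ConcordanceReport:
    per_site: pd.DataFrame  # site_key, n_compared, n_discordant, concordance_pct
    n_compared: int
    n_discordant: int
    discordance_pct: float
    discordance_per_1000: float

    @property
    def concordance_pct(self) -> float:
        return round_half_up(100.0 - 100.0 * self.n_discordant
                             / self.n_compared, 2)


def carrier_frequency(counts: tuple[int, int, int]) -> float:
    """Percent of genotyped samples carrying >= 1 variant allele,
    from (hom_ref, het, hom_alt) counts; 1 decimal."""
    hom_ref, het, hom_alt = counts
    total = hom_ref + het + hom_alt
    if total <= 0:
        raise ValueError("carrier frequency undefined for empty counts")
    return round_half_up(100.0 * (het + hom_alt) / total, 1)


def homozygote_frequency(counts: tuple[int, int, int]) -> float:
    """Percent of genotyped samples homozygous for the variant allele."""
    hom_ref, het, hom_alt = counts
    total = hom_ref + het + hom_alt
    if total <= 0:
        raise ValueError("homozygote frequency undefined for empty counts")
    return round_half_up(100.0 * hom_alt / total, 1)


def allele_count_frequency(counts: tuple[int, int, int]) -> float:
    """True allele-count frequency (variant alleles over 2n chromosomes), in
    percent.  Distinct from :func:`carrier_frequency`, which counts
    participants; cohort tables in this field usually print the latter."""
    hom_ref, het, hom_alt = counts
    total = hom_ref + het + hom_alt
    if total <= 0:
        raise ValueError("allele frequency undefined for empty counts")
    return round_half_up(100.0 * (het + 2 * hom_alt) / (2 * total), 1)


def site_summary(table: pd.DataFrame, site_key: str) -> SiteSummary:
    """Genotype-distribution row for one site, no_call excluded throughout."""
    sub = table[table["site_key"] == site_key]
    rsid = str(sub["rsid"].iloc[0]) if len(sub) else "NA"
    called = sub[sub["folded"] != "no_call"]
    n = len(called)
    counts = called["folded"].value_counts()
    hom_ref = int(counts.get("hom_ref", 0))
    het = int(counts.get("het", 0))
    hom_alt = int(counts.get("hom_alt", 0))
    return SiteSummary(
        site_key=site_key,
        rsid=rsid,
        n_genotyped=n,
        n_hom_ref=hom_ref,
        n_het=het,
        n_hom_alt=hom_alt,
        mean_depth=float(called["depth"].mean()) if n else float("nan"),
        carrier_pct=(carrier_frequency((hom_ref, het, hom_alt)) if n else None),
        hom_alt_pct=(homozygote_frequency((hom_ref, het, hom_alt)) if n else None),
    )


def summarize_sites(table: pd.DataFrame, panel: Panel) -> pd.DataFrame:
    """One genotype-distribution row per panel site."""
    rows = []
    for s in panel.sites:
        summ = site_summary(table, s.key)
        rows.append(
            {
                "site_key": s.key,
                "rsid": s.rsid,
                "gene": s.gene,
                "label": s.label,
                "n_genotyped": summ.n_genotyped,
                "hom_ref": summ.n_hom_ref,
                "het": summ.n_het,
                "hom_alt": summ.n_hom_alt,
                "mean_depth": summ.mean_depth,
                "carrier_pct": summ.carrier_pct,
                "hom_alt_pct": summ.hom_alt_pct,
            }
        )
    return pd.DataFrame(rows)


def _normalize_genotypes(df: pd.DataFrame, panel: Panel | None) -> pd.DataFrame:
    """Accept either folded class labels or allele-pair strings ("T/A")."""
    df = df.copy()
    if "genotype" not in df.columns and "folded" in df.columns:
        df["genotype"] = df["folded"]
    elif "genotype" not in df.columns and "call" in df.columns:
        df["genotype"] = df["call"].map(FOLDED)
    df["genotype"] = df["genotype"].map(lambda g: FOLDED.get(g, g))
    if df["genotype"].astype(str).str.contains("/").any():
        if panel is None:
            raise ValueError(
                "allele-style genotypes need a panel to classify against"
            )
        sites = {s.key: s for s in panel.sites}

        def classify(row):
            g = str(row["genotype"])
            if "/" not in g:
                return g
            site = sites[row["site_key"]]
            dose = sum(a == site.alt_allele for a in g.split("/"))
            return ("hom_ref", "het", "hom_alt")[dose]

        df["genotype"] = df.apply(classify, axis=1)
    return df[["sample_id", "site_key", "genotype"]]


def concordance(
    called: pd.DataFrame,
    reference: pd.DataFrame,
    panel: Panel | None = None,
) -> ConcordanceReport:
    """Genotype agreement between two tables keyed by (sample_id, site_key).

    Only pairs where both sides carry a determinate genotype are compared
    (no_call and absent entries drop out).  Hemizygous classes are compared
    on their folded homozygous equivalents.  Symmetric in its two
    arguments.  Raises ``ValueError`` when no pairs are comparable.
    """
    a = _normalize_genotypes(called, panel)
    b = _normalize_genotypes(reference, panel)
    merged = a.merge(b, on=["sample_id", "site_key"], suffixes=("_a", "_b"))
    determinate = {"hom_ref", "het", "hom_alt"}
    merged = merged[
        merged["genotype_a"].isin(determinate)
        & merged["genotype_b"].isin(determinate)
    ]
    n = len(merged)
    if n == 0:
        raise ValueError("no comparable genotype pairs")
    merged = merged.assign(
        discordant=(merged["genotype_a"] != merged["genotype_b"])
    )
    d = int(merged["discordant"].sum())
    per_site = (
        merged.groupby("site_key")["discordant"]
        .agg(n_compared="size", n_discordant="sum")
        .reset_index()
    )
    per_site["n_discordant"] = per_site["n_discordant"].astype(int)
    per_site["concordance_pct"] = [
        round_half_up(100.0 * (nc - nd) / nc, 1)
        for nc, nd in zip(per_site["n_compared"], per_site["n_discordant"])
    ]
    return ConcordanceReport(
        per_site=per_site,
        n_compared=n,
        n_discordant=d,
        discordance_pct=round_half_up(100.0 * d / n, 2),
        discordance_per_1000=round_half_up(1000.0 * d / n, 1),
    )


def completeness(table: pd.DataFrame, panel: Panel) -> dict:
    """Profiling-completeness accounting.

    Per sample, an amplicon counts as failed when any of its sites is
    no_call.  Returns per-sample failed-amplicon counts, the histogram of
    samples by number of failed amplicons, and the number fully profiled.
    """
    site_to_amp = {
        s.key: a.amplicon_id for a in panel.amplicons for s in a.sites
    }
    n_amplicons = len(panel.amplicons)
    df = table.assign(amplicon=table["site_key"].map(site_to_amp))
    failed_per_sample: dict[str, int] = {}
    for sample, grp in df.groupby("sample_id"):
        covered = set(grp["amplicon"])
        failed = n_amplicons - len(covered)  # amplicons with no rows at all
        for amp, sub in grp.groupby("amplicon"):
            if (sub["folded"] == "no_call").any():
                failed += 1
        failed_per_sample[str(sample)] = failed
    histogram: dict[int, int] = {}
    for f in failed_per_sample.values():
        histogram[f] = histogram.get(f, 0) + 1
    return {
        "n_samples": len(failed_per_sample),
        "n_amplicons": n_amplicons,
        "failed_per_sample": failed_per_sample,
        "histogram": dict(sorted(histogram.items())),
        "n_fully_profiled": histogram.get(0, 0),
    }


def g6pd_distribution(pheno: pd.DataFrame) -> dict:
    """Per-sex G6PD class counts with within-sex percentages (1 decimal)
    and the overall severe-deficiency percentage.

    ``pheno`` is the phenotype table (columns sample_id, sex, g6pd_class,
    g6pd_severe); undetermined samples drop out of the denominators.
    """
    classified = pheno[pheno["g6pd_class"] != "undetermined"]
    if len(classified) == 0:
        raise ValueError("no G6PD-classified samples")
    out: dict = {"by_sex": {}}
    for sex, grp in classified.groupby("sex"):
        counts = grp["g6pd_class"].value_counts().to_dict()
        n = len(grp)
        out["by_sex"][str(sex)] = {
            "n": n,
            "counts": {k: int(v) for k, v in counts.items()},
            "pct": {
                k: round_half_up(100.0 * v / n, 1) for k, v in counts.items()
            },
        }
    n_classified = len(classified)
    n_severe = int(classified["g6pd_severe"].sum())
    out["n_classified"] = n_classified
    out["n_severe"] = n_severe
    out["severe_pct"] = round_half_up(100.0 * n_severe / n_classified, 1)
    return out
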