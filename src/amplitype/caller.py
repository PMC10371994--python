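"""Threshold-based genotype calling from variant-site pileups.

The calling rule is the depth/allele-fraction filter used throughout
targeted amplicon genotyping: sites covered below 30x are discarded
(no_call); otherwise the alternate-allele fraction f — computed over
ref+alt reads so that sequencing-error third bases do not depress it —
classifies the genotype as

* ``hom_ref``  when f < 0.20 (fewer than 20% non-reference reads),
* ``hom_alt``  when f > 0.80 (more than 80% non-reference reads),
* ``het``      otherwise (the closed band [0.20, 0.80]).

Male X-chromosome sites are hemizygous: diploid-style classes collapse to
``hemi_ref``/``hemi_alt``, and an apparent male heterozygote is folded to
its majority allele and flagged ``male_het_anomaly`` — a het is never
emitted for a male X site.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .align import PileupColumn
from .panel import Panel, VariantSite

__all__ = [
    "GenotypeCall",
    "CallConfig",
    "allele_fraction",
    "call_genotype",
    "call_sample",
    "calls_to_table",
    "write_vcf",
    "DIPLOID_CALLS",
    "FOLDED",
]

DIPLOID_CALLS = ("hom_ref", "het", "hom_alt")

#: Hemizygous classes fold onto homozygous classes for tabulation.
FOLDED = {
    "hom_ref": "hom_ref", "het": "het", "hom_alt": "hom_alt",
    "hemi_ref": "hom_ref", "hemi_alt": "hom_alt", "no_call": "no_call",
}


@dataclass(frozen=True)
class CallConfig:
    """Calling thresholds (defaults are the published filtering rules)."""

    min_depth: int = 30
    lower: float = 0.20   # f < lower -> hom_ref
    upper: float = 0.80   # f > upper -> hom_alt
    third_allele_share: float = 0.10


@dataclass(frozen=True)
class GenotypeCall:
    sample_id: str
    site_key: str
    rsid: str
    depth: int
    alt_fraction: float | None  # None when undefined (depth 0 / no ref+alt)
    call: str
    flags: frozenset[str] = frozenset()

    @property
    def folded(self) -> str:
        return FOLDED[self.call]


class UndefinedFractionError(ValueError):
    """Allele fraction requested for a zero-depth column."""


def allele_fraction(column: PileupColumn, site: VariantSite) -> float:
    """Alternate-allele read fraction, alt / (ref + alt).

    Bases other than the site's ref and alt alleles are excluded from the
    denominator (they are almost always sequencing error); callers flag a
    ``third_allele`` condition separately when such bases exceed 10% of
    total depth.  Raises :class:`UndefinedFractionError` when no ref or alt
    reads are present.
    """
    ref_n = column.counts.get(site.ref_allele, 0)
    alt_n = column.counts.get(site.alt_allele, 0)
    if ref_n + alt_n == 0:
        raise UndefinedFractionError(
            f"no ref/alt bases at {site.key} (depth {column.depth})"
        )
    return alt_n / (ref_n + alt_n)


def call_genotype(
    column: PileupColumn,
    site: VariantSite,
    sex: str,
    config: CallConfig = CallConfig(),
    sample_id: str = "",
) -> GenotypeCall:
    """Classify one sample x site from its pileup column.

    Depth below ``config.min_depth`` (default 30x, with exactly 30 kept)
    yields ``no_call`` flagged ``low_depth``.  Otherwise the fraction rule
    above applies; for male X sites the result is collapsed to a
    hemizygous class.
    """
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    flags: set[str] = set()
    depth = column.depth
    if depth < config.min_depth:
        flags.add("low_depth")
        return GenotypeCall(sample_id, site.key, site.rsid, depth, None,
                            "no_call", frozenset(flags))
    other = depth - column.counts.get(site.ref_allele, 0) \
        - column.counts.get(site.alt_allele, 0)
    if other > config.third_allele_share * depth:
        flags.add("third_allele")
    try:
        f = allele_fraction(column, site)
    except UndefinedFractionError:
        # adequately covered but by neither ref nor alt bases: withhold
        flags.add("third_allele")
        return GenotypeCall(sample_id, site.key, site.rsid, depth, None,
                            "no_call", frozenset(flags))
    if f < config.lower:
        call = "hom_ref"
    elif f > config.upper:
        call = "hom_alt"
    else:
        call = "het"
    if site.x_linked and sex == "male":
        if call == "het":
            flags.add("male_het_anomaly")
            call = "hemi_ref" if f <= 0.5 else "hemi_alt"
        else:
            call = {"hom_ref": "hemi_ref", "hom_alt": "hemi_alt"}[call]
    return GenotypeCall(sample_id, site.key, site.rsid, depth, f, call,
                        frozenset(flags))


def call_sample(
    pileups: list[PileupColumn],
    panel: Panel,
    sex: str,
    config: CallConfig = CallConfig(),
    sample_id: str = "",
) -> list[GenotypeCall]:
    """One call per panel site; sites missing from the pileup become
    zero-depth no_calls."""
    by_key = {(c.amplicon_id, c.local_offset): c for c in pileups}
    calls = []
    for amp in panel.amplicons:
        for site in amp.sites:
            col = by_key.get((amp.amplicon_id, amp.local_offset(site.pos)))
            if col is None:
                col = PileupColumn(amplicon_id=amp.amplicon_id,
                                   local_offset=amp.local_offset(site.pos))
            calls.append(call_genotype(col, site, sex, config, sample_id))
    return calls


def calls_to_table(calls: list[GenotypeCall], panel: Panel) -> pd.DataFrame:
    """Genotype calls as a tidy DataFrame (one row per sample x site)."""
    sites = {s.key: s for s in panel.sites}
    rows = []
    for c in calls:
        s = sites[c.site_key]
        rows.append(
            {
                "sample_id": c.sample_id,
                "chrom": s.chrom,
                "pos": s.pos,
                "rsid": s.rsid,
                "ref": s.ref_allele,
                "alt": s.alt_allele,
                "site_key": c.site_key,
                "depth": c.depth,
                "alt_fraction": c.alt_fraction,
                "call": c.call,
                "folded": c.folded,
                "flags": ",".join(sorted(c.flags)),
            }
        )
    return pd.DataFrame(rows)


_GT = {
    "hom_ref": (0, 0), "het": (0, 1), "hom_alt": (1, 1),
    "hemi_ref": (0,), "hemi_alt": (1,), "no_call": (None,),
}


def write_vcf(table: pd.DataFrame, panel: Panel, path) -> None:
    """Emit a minimal multi-sample VCF 4.2 (GT, DP, FILTER=low_depth)."""
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##source=amplitype')
    header.add_line('##FILTER=<ID=low_depth,Description="coverage below 30x">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    for chrom in dict.fromkeys(a.chrom for a in panel.amplicons):
        header.add_line(f"##contig=<ID={chrom}>")
    samples = sorted(table["sample_id"].unique())
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for site in panel.sites:
            sub = table[table["site_key"] == site.key].set_index("sample_id")
            rec = out.new_record(
                contig=site.chrom,
                start=site.pos - 1,
                stop=site.pos,
                alleles=(site.ref_allele, site.alt_allele),
                id=site.rsid if site.rsid != "NA" else None,
            )
            any_low = False
            for s in samples:
                if s in sub.index:
                    row = sub.loc[s]
                    rec.samples[s]["GT"] = _GT[row["call"]]
                    rec.samples[s]["DP"] = int(row["depth"])
                    any_low = any_low or ("low_depth" in str(row["flags"]))
                else:
                    rec.samples[s]["GT"] = (None,)
            rec.filter.add("low_depth" if any_low else "PASS")
            out.write(rec)
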