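"""Clinical interpretation of genotype calls.

Maps per-site genotype calls onto the classes clinicians report:

* **G6PD** — the African-type deficiency system, built from the 202
  (rs1050828 C>T) and 376 (rs1050829 T>C) positions.  Allele classes:
  B = neither variant; A+ = 376 only (near-normal activity);
  A− = 376 plus 202 (deficient).  Males carry one X allele (B, A+ or A−);
  females a diplotype (BB, BA+, BA−, A+A+, A+A−, A−A−).  Severe deficiency
  means A− hemizygous (male) or A−A− homozygous (female).
* **Haemoglobin** — HbS (rs334), HbC (rs33930165), HbE (rs33950507)
  compose the familiar two-letter types (HbAA wild type, HbAS sickle
  trait, HbSS sickle-cell disease, HbSC, ...).
* **Duffy** — rs2814778; the alt/alt (CC) genotype abolishes the Duffy
  antigen (Fy(a-b-)), the P. vivax entry receptor.
* **Dantu** — rs186873296 carrier status.

A required site with no_call makes the corresponding label undetermined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .caller import GenotypeCall

__all__ = [
    "G6PDClass",
    "PhenotypeRecord",
    "infer_g6pd",
    "infer_hbb",
    "infer_duffy",
    "infer_dantu",
    "infer_phenotypes",
    "phenotype_table",
    "RSID_202",
    "RSID_376",
    "SEVERE_G6PD_CLASSES",
]

RSID_202 = "rs1050828"
RSID_376 = "rs1050829"
RSID_HBS = "rs334"
RSID_HBC = "rs33930165"
RSID_HBE = "rs33950507"
RSID_DUFFY = "rs2814778"
RSID_DANTU = "rs186873296"

MALE_G6PD_CLASSES = ("B", "A+", "A-")
FEMALE_G6PD_CLASSES = ("BB", "BA+", "BA-", "A+A+", "A+A-", "A-A-")
SEVERE_G6PD_CLASSES = frozenset({"A-", "A-A-"})


@dataclass(frozen=True)
class G6PDClass:
    """A G6PD genotype class; ``severe_deficiency`` iff A- (male) or A-A-."""

    cls: str

    def __post_init__(self):
        if self.cls not in MALE_G6PD_CLASSES + FEMALE_G6PD_CLASSES:
            raise ValueError(f"unknown G6PD class {self.cls!r}")

    @property
    def severe_deficiency(self) -> bool:
        return self.cls in SEVERE_G6PD_CLASSES

    def __str__(self) -> str:
        return self.cls


@dataclass(frozen=True)
class PhenotypeRecord:
    sample_id: str
    sex: str
    g6pd: G6PDClass | None          # None = undetermined
    hbb: str                        # HbAA/HbAS/... or "undetermined"
    duffy: str                      # Fy_negative/... or "undetermined"
    dantu: str                      # non_carrier/... or "undetermined"
    flags: frozenset[str] = field(default_factory=frozenset)


def _alt_dose(call: GenotypeCall) -> int | None:
    """Alt-allele count of a diploid call (0/1/2), or None for no_call."""
    return {"hom_ref": 0, "het": 1, "hom_alt": 2,
            "hemi_ref": 0, "hemi_alt": 1}.get(call.call)


def infer_g6pd(
    call_202: GenotypeCall, call_376: GenotypeCall, sex: str
) -> tuple[G6PDClass | None, frozenset[str]]:
    """G6PD class from the 202 and 376 calls.

    Allele rule: B = 202-ref & 376-ref; A+ = 202-ref & 376-alt;
    A− = 202-alt & 376-alt.  A 202 variant on a 376-reference background is
    not a class in this system and is reported undetermined with a
    ``non_canonical`` flag.  For double-heterozygous females the diplotype
    is resolved as B/A− — every 202-alt allele is assumed to sit on the
    376-alt background, the haplotype structure the class system itself
    presupposes (there is no "202-only" class).

    Returns ``(class or None, flags)``.
    """
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    d202, d376 = _alt_dose(call_202), _alt_dose(call_376)
    if d202 is None or d376 is None:
        return None, frozenset({"undetermined"})
    if sex == "male":
        if d202 > 1 or d376 > 1:  # diploid-style call at a male X site
            return None, frozenset({"non_canonical"})
        if d202 == 1 and d376 == 0:
            return None, frozenset({"non_canonical"})
        cls = {(0, 0): "B", (0, 1): "A+", (1, 1): "A-"}[(d202, d376)]
        return G6PDClass(cls), frozenset()
    # female: allele doses, phased under the canonical haplotype assumption
    if d202 > d376:
        return None, frozenset({"non_canonical"})
    n_aminus = d202
    n_aplus = d376 - d202
    n_b = 2 - d376
    alleles = ["A-"] * n_aminus + ["A+"] * n_aplus + ["B"] * n_b
    order = {"B": 0, "A+": 1, "A-": 2}
    a1, a2 = sorted(alleles, key=order.__getitem__)
    return G6PDClass(a1 + a2), frozenset()


def infer_hbb(
    call_rs334: GenotypeCall,
    call_rs33930165: GenotypeCall,
    call_rs33950507: GenotypeCall,
) -> tuple[str, frozenset[str]]:
    """Haemoglobin type from the HbS/HbC/HbE sites.

    The two beta-globin alleles are composed from the variant doses: zero
    variants is HbAA, one S allele HbAS, two S alleles HbSS, one S and one
    C HbSC, and so on.  More than two variant alleles across the three
    sites is biologically inconsistent (only two chromosomes exist) and is
    flagged; S+E and C+E compounds fall outside the supported label set
    and come back undetermined with an ``unsupported_combination`` flag.
    """
    doses = {
        "S": _alt_dose(call_rs334),
        "C": _alt_dose(call_rs33930165),
        "E": _alt_dose(call_rs33950507),
    }
    if any(d is None for d in doses.values()):
        return "undetermined", frozenset({"undetermined"})
    total = sum(doses.values())
    if total > 2:
        return "undetermined", frozenset({"inconsistent_alleles"})
    variants = "".join(letter * d for letter, d in doses.items())
    label = "Hb" + ("A" * (2 - total)) + variants
    supported = {"HbAA", "HbAS", "HbSS", "HbAC", "HbCC", "HbSC",
                 "HbAE", "HbEE"}
    if label not in supported:
        return "undetermined", frozenset({"unsupported_combination"})
    return label, frozenset()


def infer_duffy(call_rs2814778: GenotypeCall) -> str:
    """Duffy antigen status; alt/alt abolishes expression (Fy negative)."""
    return {
        "hom_alt": "Fy_negative",
        "het": "Fy_heterozygous",
        "hom_ref": "Fy_positive",
    }.get(call_rs2814778.folded, "undetermined")


def infer_dantu(call_rs186873296: GenotypeCall) -> str:
    """Dantu blood-group carrier status."""
    return {
        "hom_alt": "homozygous",
        "het": "heterozygous",
        "hom_ref": "non_carrier",
    }.get(call_rs186873296.folded, "undetermined")


def infer_phenotypes(
    calls: list[GenotypeCall], sex: str, sample_id: str = ""
) -> PhenotypeRecord:
    """Full phenotype record for one sample's panel calls."""
    by_rsid = {c.rsid: c for c in calls}

    def need(rsid):
        if rsid not in by_rsid:
            raise KeyError(f"panel call for {rsid} missing")
        return by_rsid[rsid]

    g6pd, g6pd_flags = infer_g6pd(need(RSID_202), need(RSID_376), sex)
    hbb, hbb_flags = infer_hbb(need(RSID_HBS), need(RSID_HBC), need(RSID_HBE))
    duffy = infer_duffy(need(RSID_DUFFY))
    dantu = infer_dantu(need(RSID_DANTU))
    return PhenotypeRecord(
        sample_id=sample_id or (calls[0].sample_id if calls else ""),
        sex=sex,
        g6pd=g6pd,
        hbb=hbb,
        duffy=duffy,
        dantu=dantu,
        flags=frozenset(
            f for f in g6pd_flags | hbb_flags if f != "undetermined"
        ),
    )


def phenotype_table(records: list[PhenotypeRecord]) -> pd.DataFrame:
    rows = [
        {
            "sample_id": r.sample_id,
            "sex": r.sex,
            "g6pd_class": str(r.g6pd) if r.g6pd else "undetermined",
            "g6pd_severe": bool(r.g6pd.severe_deficiency) if r.g6pd else False,
            "hbb": r.hbb,
            "duffy": r.duffy,
            "dantu": r.dantu,
            "flags": ",".join(sorted(r.flags)),
        }
        for r in records
    ]
    return pd.DataFrame(rows)
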