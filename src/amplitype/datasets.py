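"""Published cohort summaries for the built-in malaria host panel.

The study behind the built-in panel genotyped 100 children admitted with
severe malaria in Muheza, Northeast Tanzania.  The per-site genotype
counts, the G6PD class distribution and the validation totals from that
cohort are shipped here as worked-example inputs: they drive the README
example and the reproduction script without any sequence download.

Two rows of the published per-site table disagree with the running text on
the het/hom split of rs334 (HbS); the text-reported split (5 het HbAS,
4 hom HbSS) is the default, with the table's split available via
``variant="table"``.  Per-sample tables derived from these aggregates
(:func:`g6pd_phenotype_table`, :func:`concordance_tables`) are synthetic
reconstructions: they reproduce the published counts exactly but the
sample identities are fabricated.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "cohort_genotype_counts",
    "g6pd_class_counts",
    "g6pd_phenotype_table",
    "concordance_tables",
    "CONCORDANCE_TOTALS",
]

#: (genotypes compared against pre-existing genotyping, discordant among them)
CONCORDANCE_TOTALS = (962, 4)

# per-site cohort genotype counts: hom_ref / het / hom_alt (hemizygotes folded)
_COHORT_COUNTS = [
    # site_key, rsid, gene, label, hom_ref, het, hom_alt, mean_depth
    ("X:154532738", "rs2230036", "G6PD", "", 87, 6, 6, 803),
    ("X:154533025", "rs76723693", "G6PD", "968", 99, 0, 0, 798),
    ("X:154533122", "rs137852327", "G6PD", "", 99, 0, 0, 798),
    ("X:154534125", "rs137852328", "G6PD", "680", 99, 0, 0, 629),
    ("X:154534177", "rs5986875", "G6PD", "", 98, 1, 0, 629),
    ("X:154534440", "rs5030872", "G6PD", "542", 99, 0, 0, 622),
    ("X:154534527", "NA", "G6PD", "", 86, 1, 0, 622),
    ("X:154535277", "rs1050829", "G6PD", "376", 48, 16, 23, 956),
    ("X:154535443", "NA", "G6PD", "", 86, 1, 0, 622),
    ("X:154535468", "NA", "G6PD", "", 86, 1, 0, 622),
    ("X:154536002", "rs1050828", "G6PD", "202", 71, 8, 8, 530),
    ("11:5226867", "NA", "HBB", "", 98, 1, 0, 1020),
    ("11:5226925", "rs33915217", "HBB", "beta_thal", 99, 0, 0, 1020),
    ("11:5226932", "rs35578002", "HBB", "", 98, 1, 0, 1020),
    ("11:5226943", "rs33950507", "HBB", "HbE", 99, 0, 0, 1020),
    ("11:5226963", "rs33972047", "HBB", "beta_thal", 99, 0, 0, 1020),
    ("11:5226966", "rs35382661", "HBB", "", 97, 2, 0, 1118),
    ("11:5227002", "rs334", "HBB", "HbS", 90, 5, 4, 2003),
    ("11:5227003", "rs33930165", "HBB", "HbC", 99, 0, 0, 2003),
    ("11:5227013", "rs713040", "HBB", "beta_thal_HPFH", 4, 27, 65, 2002),
    ("11:5227072", "rs386134236", "HBB", "", 98, 1, 0, 984),
    ("1:159204646", "NA", "ACKR1", "", 76, 19, 0, 644),
    ("1:159204893", "rs2814778", "ACKR1", "Fy", 0, 0, 95, 623),
    ("4:143781321", "rs186873296", "Dantu_intergenic", "Dantu", 95, 3, 0, 132),
    ("4:143781342", "NA", "Dantu_intergenic", "", 98, 1, 0, 184),
]


def cohort_genotype_counts(variant: str = "text") -> pd.DataFrame:
    """Published per-site genotype counts of the Tanzanian cohort.

    ``variant="text"`` (default) uses the running-text het/hom split for
    rs334; ``variant="table"`` uses the per-site table's split (4 het,
    5 hom).  All other rows are identical between the two.
    """
    df = pd.DataFrame(
        _COHORT_COUNTS,
        columns=["site_key", "rsid", "gene", "label",
                 "hom_ref", "het", "hom_alt", "mean_depth"],
    )
    if variant == "table":
        i = df.index[df["rsid"] == "rs334"][0]
        df.loc[i, ["het", "hom_alt"]] = [4, 5]
    elif variant != "text":
        raise ValueError("variant must be 'text' or 'table'")
    df["n_genotyped"] = df[["hom_ref", "het", "hom_alt"]].sum(axis=1)
    return df


def g6pd_class_counts() -> pd.DataFrame:
    """Published G6PD class distribution (83 classified children)."""
    rows = [
        ("male", "B", 25), ("male", "A+", 13), ("male", "A-", 5),
        ("female", "BB", 21), ("female", "BA+", 6), ("female", "BA-", 2),
        ("female", "A+A+", 7), ("female", "A+A-", 1), ("female", "A-A-", 3),
    ]
    return pd.DataFrame(rows, columns=["sex", "g6pd_class", "n"])


def g6pd_phenotype_table() -> pd.DataFrame:
    """Synthetic per-sample phenotype table reconstructed from the published
    G6PD class counts (sample ids fabricated; counts exact)."""
    rows = []
    i = 0
    for sex, cls, n in g6pd_class_counts().itertuples(index=False):
        for _ in range(n):
            rows.append(
                {
                    "sample_id": f"P{i:03d}",
                    "sex": sex,
                    "g6pd_class": cls,
                    "g6pd_severe": cls in ("A-", "A-A-"),
                }
            )
            i += 1
    return pd.DataFrame(rows)


def concordance_tables(
    n_compared: int = CONCORDANCE_TOTALS[0],
    n_discordant: int = CONCORDANCE_TOTALS[1],
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic called/reference genotype-table pair with the published
    comparison totals: ``n_compared`` shared determinate genotypes of which
    exactly ``n_discordant`` disagree.  Which pairs disagree and what the
    genotypes are is randomised from ``seed``; the totals are exact."""
    if not 0 <= n_discordant <= n_compared:
        raise ValueError("need 0 <= n_discordant <= n_compared")
    rng = np.random.default_rng(seed)
    classes = np.array(["hom_ref", "het", "hom_alt"])
    n_sites = 10
    keys = [
        (f"V{i:04d}", f"site{j}")
        for i in range((n_compared + n_sites - 1) // n_sites)
        for j in range(n_sites)
    ][:n_compared]
    called_gt = classes[rng.integers(0, 3, size=n_compared)]
    ref_gt = called_gt.copy()
    flip = rng.choice(n_compared, size=n_discordant, replace=False)
    for i in flip:
        ref_gt[i] = rng.choice([c for c in classes if c != called_gt[i]])
    called = pd.DataFrame(
        {"sample_id": [k[0] for k in keys],
         "site_key": [k[1] for k in keys],
         "genotype": called_gt}
    )
    reference = called.assign(genotype=ref_gt)
    return called, reference
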