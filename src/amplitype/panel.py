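"""Amplicon panel model: targets, variant sites, validation and I/O.

A :class:`Panel` is a closed universe of PCR amplicons, each a 1-based
inclusive genomic interval on GRCh38 carrying one or more single-nucleotide
variant sites.  The built-in ``malaria_host_v1`` panel covers the four loci
with well-established associations to malaria disease severity: ``HBB``
(sickle cell HbS and other beta-globin variants), ``G6PD`` (X-linked
deficiency alleles, four amplicons), ``ACKR1`` (Duffy blood group) and the
intergenic Dantu blood-group variant — 7 amplicons, 25 sites in total.

Coordinates are genomic 1-based; amplicon-local offsets are 0-based
(``local_offset = pos - amplicon.start``).  Ref/alt alleles are plus-strand
genomic bases even for minus-strand genes (HBB, G6PD); cDNA-style labels
such as "202" or "376" are metadata only.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator

import pandas as pd

__all__ = [
    "VariantSite",
    "AmpliconTarget",
    "Panel",
    "PanelError",
    "PanelValidationError",
    "SiteNotCoveredError",
    "load_panel",
    "load_panel_tsv",
    "validate_panel",
    "locate_site",
    "BUILTIN_PANELS",
]

_BASES = frozenset("ACGT")

#: Built-in panel names shipped with the package.
BUILTIN_PANELS = ("malaria_host_v1",)


class PanelError(Exception):
    """Malformed or unreadable panel definition."""


class PanelValidationError(PanelError):
    """Panel parsed but violates one or more invariants."""

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__(
            "panel failed validation:\n  " + "\n  ".join(self.violations)
        )


class SiteNotCoveredError(KeyError):
    """Genomic position falls inside no amplicon of the panel."""


@dataclass(frozen=True)
class VariantSite:
    """A biallelic SNP target.

    Parameters
    ----------
    chrom : str
        Chromosome name ("1", "4", "11", "X").
    pos : int
        1-based GRCh38 genomic coordinate.
    rsid : str
        dbSNP identifier, or "NA" when none is assigned.
    ref_allele, alt_allele : str
        Single plus-strand bases.
    label : str
        Clinical tag ("HbS", "202", "Fy", "Dantu", ...); may be empty.
    gene : str
        Gene symbol or "Dantu_intergenic".
    """

    chrom: str
    pos: int
    rsid: str = "NA"
    ref_allele: str = "N"
    alt_allele: str = "N"
    label: str = ""
    gene: str = ""

    @property
    def x_linked(self) -> bool:
        return self.chrom == "X"

    @property
    def key(self) -> str:
        """Canonical site key ``chrom:pos`` used across the pipeline."""
        return f"{self.chrom}:{self.pos}"

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return f"{self.key} {self.ref_allele}>{self.alt_allele} ({self.rsid})"


@dataclass(frozen=True)
class AmpliconTarget:
    """One PCR amplicon: a genomic interval and the variant sites it carries."""

    amplicon_id: str
    gene: str
    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    sites: tuple[VariantSite, ...] = ()

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    def local_offset(self, pos: int) -> int:
        """0-based offset of a genomic position on this amplicon."""
        return pos - self.start


@dataclass
class Panel:
    """An amplicon panel, optionally carrying reference sequences."""

    name: str
    amplicons: tuple[AmpliconTarget, ...]
    reference_sequences: dict[str, str] = field(default_factory=dict)

    def __iter__(self) -> Iterator[AmpliconTarget]:
        return iter(self.amplicons)

    @property
    def sites(self) -> tuple[VariantSite, ...]:
        return tuple(s for a in self.amplicons for s in a.sites)

    def amplicon(self, amplicon_id: str) -> AmpliconTarget:
        for a in self.amplicons:
            if a.amplicon_id == amplicon_id:
                return a
        raise KeyError(amplicon_id)

    def site_by_rsid(self, rsid: str) -> VariantSite:
        for s in self.sites:
            if s.rsid == rsid:
                return s
        raise KeyError(rsid)

    def site_by_key(self, key: str) -> VariantSite:
        for s in self.sites:
            if s.key == key:
                return s
        raise KeyError(key)

    def attach_references(self, fasta_path: str | Path) -> None:
        """Attach amplicon reference sequences from a FASTA keyed by amplicon_id."""
        import pysam

        with pysam.FastxFile(str(fasta_path)) as fh:
            for entry in fh:
                self.reference_sequences[entry.name] = entry.sequence.upper()
        _check_references(self, raise_on_error=True)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "amplicons": [
                {
                    "amplicon_id": a.amplicon_id,
                    "gene": a.gene,
                    "chrom": a.chrom,
                    "start": a.start,
                    "end": a.end,
                    "sites": [
                        {
                            "chrom": s.chrom,
                            "pos": s.pos,
                            "rsid": s.rsid,
                            "ref": s.ref_allele,
                            "alt": s.alt_allele,
                            "label": s.label,
                        }
                        for s in a.sites
                    ],
                }
                for a in self.amplicons
            ],
        }

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def _panel_from_dict(doc: dict) -> Panel:
    try:
        amplicons = []
        for a in doc["amplicons"]:
            sites = tuple(
                sorted(
                    (
                        VariantSite(
                            chrom=str(s["chrom"]),
                            pos=int(s["pos"]),
                            rsid=str(s.get("rsid", "NA")),
                            ref_allele=str(s["ref"]).upper(),
                            alt_allele=str(s["alt"]).upper(),
                            label=str(s.get("label", "")),
                            gene=str(a.get("gene", "")),
                        )
                        for s in a.get("sites", [])
                    ),
                    key=lambda s: s.pos,
                )
            )
            amplicons.append(
                AmpliconTarget(
                    amplicon_id=str(a["amplicon_id"]),
                    gene=str(a.get("gene", "")),
                    chrom=str(a["chrom"]),
                    start=int(a["start"]),
                    end=int(a["end"]),
                    sites=sites,
                )
            )
    except (KeyError, TypeError, ValueError) as exc:
        raise PanelError(f"malformed panel definition: {exc!r}") from exc
    return Panel(name=str(doc.get("name", "unnamed")), amplicons=tuple(amplicons))


def load_panel(source: str | Path) -> Panel:
    """Load and validate a panel from a JSON file or a built-in name.

    ``load_panel("malaria_host_v1")`` returns the packaged panel of the four
    malaria-protective loci.  Any other string/path is read as a panel JSON
    file (see :meth:`Panel.to_dict` for the schema).

    Raises
    ------
    PanelError
        If the file cannot be parsed.
    PanelValidationError
        If the parsed panel violates an invariant; the exception lists every
        violation found.
    """
    if isinstance(source, str) and source in BUILTIN_PANELS:
        text = (
            resources.files("amplitype").joinpath(f"data/{source}.json").read_text()
        )
    else:
        path = Path(source)
        if not path.exists():
            raise PanelError(f"panel source not found: {source}")
        text = path.read_text()
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise PanelError(f"panel JSON parse error: {exc}") from exc
    panel = _panel_from_dict(doc)
    violations = validate_panel(panel)
    if violations:
        raise PanelValidationError(violations)
    return panel


def load_panel_tsv(path: str | Path, name: str = "custom",
                   window: int = 500) -> Panel:
    """Import a flat TSV site list and derive one amplicon per gene cluster.

    Expected columns: ``gene, chrom, pos, rsid, ref, alt, label``.  Sites of
    the same gene within ``window`` bases are grouped into one amplicon whose
    interval is a ``window``-bp span centred on the group.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene", "chrom", "pos", "rsid", "ref", "alt", "label"}
    missing = required - set(df.columns)
    if missing:
        raise PanelError(f"site TSV missing columns: {sorted(missing)}")
    df["pos"] = df["pos"].astype(int)
    amplicons = []
    for (gene, chrom), grp in df.groupby(["gene", "chrom"], sort=False):
        grp = grp.sort_values("pos")
        cluster: list[dict] = []
        clusters: list[list[dict]] = []
        for _, row in grp.iterrows():
            if cluster and row["pos"] - cluster[0]["pos"] >= window:
                clusters.append(cluster)
                cluster = []
            cluster.append(row.to_dict())
        if cluster:
            clusters.append(cluster)
        for i, cl in enumerate(clusters, start=1):
            lo, hi = cl[0]["pos"], cl[-1]["pos"]
            centre = (lo + hi) // 2
            start = max(1, centre - window // 2 + 1)
            amplicons.append(
                {
                    "amplicon_id": f"{gene}_{i}",
                    "gene": gene,
                    "chrom": chrom,
                    "start": start,
                    "end": start + window - 1,
                    "sites": cl,
                }
            )
    panel = _panel_from_dict({"name": name, "amplicons": amplicons})
    violations = validate_panel(panel)
    if violations:
        raise PanelValidationError(violations)
    return panel


def _check_references(panel: Panel, raise_on_error: bool = False) -> list[str]:
    problems = []
    for a in panel.amplicons:
        seq = panel.reference_sequences.get(a.amplicon_id)
        if seq is None:
            continue
        if len(seq) != a.length:
            problems.append(
                f"{a.amplicon_id}: reference length {len(seq)} != interval "
                f"length {a.length}"
            )
            continue
        for s in a.sites:
            off = a.local_offset(s.pos)
            if seq[off] != s.ref_allele:
                problems.append(
                    f"{a.amplicon_id}: reference base {seq[off]} at offset "
                    f"{off} != ref allele {s.ref_allele} of {s.key}"
                )
    if problems and raise_on_error:
        raise PanelValidationError(problems)
    return problems


def validate_panel(panel: Panel, builtin_size_rule: bool = False) -> list[str]:
    """Return a list of invariant violations (empty iff the panel is valid).

    Checked: unique amplicon ids; alleles in {A,C,G,T} and ref != alt;
    positive 1-based coordinates; every site inside exactly one amplicon
    interval; sites sorted by position; attached reference sequences
    consistent with intervals and ref alleles.  Amplicon lengths outside
    400-600 bp raise a warning for user panels (hard violation only when
    ``builtin_size_rule`` is set, as for the shipped panel).
    """
    v: list[str] = []
    ids = [a.amplicon_id for a in panel.amplicons]
    for dup in sorted({i for i in ids if ids.count(i) > 1}):
        v.append(f"duplicate amplicon_id {dup}")
    for a in panel.amplicons:
        if a.start < 1 or a.end < a.start:
            v.append(f"{a.amplicon_id}: bad interval [{a.start}, {a.end}]")
        if not 400 <= a.length <= 600:
            msg = f"{a.amplicon_id}: length {a.length} outside 400-600 bp"
            if builtin_size_rule:
                v.append(msg)
            else:
                warnings.warn(msg, stacklevel=2)
        if list(a.sites) != sorted(a.sites, key=lambda s: s.pos):
            v.append(f"{a.amplicon_id}: sites not sorted by position")
        for s in a.sites:
            if s.pos <= 0:
                v.append(f"{s.key}: non-positive position")
            if s.ref_allele not in _BASES or s.alt_allele not in _BASES:
                v.append(f"{s.key}: alleles must be A/C/G/T "
                         f"({s.ref_allele}>{s.alt_allele})")
            elif s.ref_allele == s.alt_allele:
                v.append(f"{s.key}: ref allele equals alt allele")
    for s in {s for a in panel.amplicons for s in a.sites}:
        owners = [a.amplicon_id for a in panel.amplicons
                  if a.contains(s.chrom, s.pos)]
        if len(owners) == 0:
            v.append(f"{s.key}: inside no amplicon interval")
        elif len(owners) > 1:
            v.append(f"{s.key}: inside multiple amplicons {owners}")
    v.extend(_check_references(panel))
    return v


def locate_site(panel: Panel, chrom: str, pos: int) -> tuple[AmpliconTarget, int]:
    """Map a genomic position to ``(amplicon, 0-based local offset)``.

    Raises :class:`SiteNotCoveredError` when the position falls inside no
    amplicon of the panel.
    """
    chrom = str(chrom)
    for a in panel.amplicons:
        if a.contains(chrom, pos):
            return a, a.local_offset(pos)
    raise SiteNotCoveredError(f"{chrom}:{pos} not covered by panel {panel.name}")
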