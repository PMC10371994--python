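"""Dual 8-bp index schemes and read-to-sample assignment.

Each sample is tagged with one (forward, reverse) index pair that is kept
constant across all of its amplicons, so a pooled run can be demultiplexed
back to samples by the read ends alone: the forward index is the literal
8-bp read prefix, the reverse index appears reverse-complemented as the
8-bp read suffix.

A 10x10 index set gives 100 ordered pairs; with same-rank pairs (i == j)
excluded as an anti-hopping safeguard, 90 usable combinations remain —
enough for 90 samples per pool while every pool stays under the 200
amplicon-product ceiling that guarantees adequate per-sample coverage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

__all__ = [
    "IndexScheme",
    "SampleSheet",
    "DemuxResult",
    "IndexGenerationError",
    "build_index_scheme",
    "demultiplex",
    "hamming",
    "reverse_complement",
    "check_pool_size",
    "MAX_AMPLICONS_PER_POOL",
]

_COMP = str.maketrans("ACGTN", "TGCAN")

#: Maximum amplicon products per sequencing pool before coverage suffers.
MAX_AMPLICONS_PER_POOL = 200


class IndexGenerationError(RuntimeError):
    """Could not satisfy the Hamming-distance constraint within the attempt budget."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class IndexScheme:
    forward_indices: tuple[str, ...]
    reverse_indices: tuple[str, ...]
    valid_pairs: frozenset[tuple[str, str]]
    min_pairwise_hamming: int

    def __post_init__(self):
        for lst in (self.forward_indices, self.reverse_indices):
            if any(len(i) != self.index_length for i in lst):
                raise ValueError("all indices must share one length")
            for i, a in enumerate(lst):
                for b in lst[i + 1:]:
                    d = hamming(a, b)
                    if d < self.min_pairwise_hamming:
                        raise ValueError(
                            f"indices {a}/{b} at Hamming {d} < "
                            f"{self.min_pairwise_hamming}"
                        )

    @property
    def index_length(self) -> int:
        return len(self.forward_indices[0])


@dataclass
class SampleSheet:
    """sample_id -> (forward index, reverse index), plus sex per sample."""

    samples: dict[str, tuple[str, str]]
    sex: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        pairs = list(self.samples.values())
        if len(set(pairs)) != len(pairs):
            raise ValueError("index pairs must be unique across samples")
        for s, sx in self.sex.items():
            if sx not in ("male", "female"):
                raise ValueError(f"sample {s}: sex must be male/female, got {sx}")

    @classmethod
    def from_scheme(cls, sample_ids: Iterable[str], scheme: IndexScheme,
                    sex: dict[str, str] | None = None) -> "SampleSheet":
        """Assign valid pairs to samples in deterministic scheme order."""
        pairs = sorted(scheme.valid_pairs)
        ids = list(sample_ids)
        if len(ids) > len(pairs):
            raise ValueError(
                f"{len(ids)} samples but only {len(pairs)} valid index pairs"
            )
        return cls(samples=dict(zip(ids, pairs)), sex=dict(sex or {}))

    @classmethod
    def read_tsv(cls, path) -> "SampleSheet":
        df = pd.read_csv(path, sep="\t", dtype=str)
        need = {"sample_id", "fwd_index", "rev_index"}
        if not need <= set(df.columns):
            raise ValueError(f"sample sheet needs columns {sorted(need)}")
        samples = {
            r.sample_id: (r.fwd_index, r.rev_index) for r in df.itertuples()
        }
        sex = (
            {r.sample_id: r.sex for r in df.itertuples()}
            if "sex" in df.columns else {}
        )
        return cls(samples=samples, sex=sex)

    def write_tsv(self, path) -> None:
        rows = [
            {
                "sample_id": s,
                "fwd_index": f,
                "rev_index": r,
                "sex": self.sex.get(s, "NA"),
            }
            for s, (f, r) in self.samples.items()
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def build_index_scheme(
    n_fwd: int,
    n_rev: int,
    length: int = 8,
    min_hamming: int = 3,
    exclude_same_rank: bool = True,
    seed: int = 0,
    max_attempts: int = 10_000,
) -> IndexScheme:
    """Randomised-greedy generation of a dual index scheme.

    Candidate ``length``-mers are drawn uniformly and kept when at Hamming
    distance >= ``min_hamming`` from every index already accepted in the
    same list.  With ``exclude_same_rank`` (the default) the i-th forward
    with the i-th reverse index is not a usable pair, so a 10x10 scheme
    yields 90 valid combinations.

    Deterministic given ``seed``; raises :class:`IndexGenerationError` when
    the constraint cannot be met within ``max_attempts`` draws per list.
    """
    if n_fwd < 1 or n_rev < 1:
        raise ValueError("need at least one index per list")
    if length < min_hamming:
        raise ValueError("index length must be >= min_hamming")
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)

    def greedy(n: int) -> tuple[str, ...]:
        chosen: list[str] = []
        attempts = 0
        while len(chosen) < n:
            if attempts >= max_attempts:
                raise IndexGenerationError(
                    f"could not place {n} indices of length {length} at "
                    f"min Hamming {min_hamming} within {max_attempts} draws"
                )
            attempts += 1
            cand = bases[rng.integers(0, 4, size=length)].tobytes().decode()
            if all(hamming(cand, c) >= min_hamming for c in chosen):
                chosen.append(cand)
        return tuple(chosen)

    fwd = greedy(n_fwd)
    rev = greedy(n_rev)
    pairs = frozenset(
        (f, r)
        for i, f in enumerate(fwd)
        for j, r in enumerate(rev)
        if not (exclude_same_rank and i == j)
    )
    return IndexScheme(
        forward_indices=fwd,
        reverse_indices=rev,
        valid_pairs=pairs,
        min_pairwise_hamming=min_hamming,
    )


@dataclass
class DemuxResult:
    """Outcome of assigning one pooled read set to samples.

    ``assigned`` maps sample_id to a list of index-trimmed reads
    ``(read_id, sequence, quality)``; ``unassigned`` keeps untrimmed reads
    with a reason tag.  Bins partition the input: every read lands in
    exactly one place.
    """

    assigned: dict[str, list[tuple[str, str, str]]]
    unassigned: list[tuple[str, str, str, str]]  # (+ reason)

    @property
    def n_assigned(self) -> int:
        return sum(len(v) for v in self.assigned.values())

    @property
    def n_total(self) -> int:
        return self.n_assigned + len(self.unassigned)

    @property
    def unassigned_fraction(self) -> float:
        return len(self.unassigned) / self.n_total if self.n_total else 0.0

    def stats(self) -> pd.DataFrame:
        rows = [
            {"sample_id": s, "n_reads": len(v)}
            for s, v in sorted(self.assigned.items())
        ]
        rows.append({"sample_id": "__unassigned__",
                     "n_reads": len(self.unassigned)})
        return pd.DataFrame(rows)


def _match_index(observed: str, candidates: dict[str, list[str]],
                 max_mismatch: int) -> list[str]:
    """Sample ids whose index is within max_mismatch of the observed 8-mer."""
    if max_mismatch == 0:
        return candidates.get(observed, [])
    hits: list[str] = []
    for idx, ids in candidates.items():
        if hamming(observed, idx) <= max_mismatch:
            hits.extend(ids)
    return hits


def demultiplex(
    reads: Iterable[tuple[str, str, str]],
    scheme: IndexScheme,
    sheet: SampleSheet,
    max_mismatch: int = 0,
) -> DemuxResult:
    """Assign pooled reads to samples by their dual index pair.

    ``reads`` yields ``(read_id, sequence, quality)``.  A read is assigned
    to sample *s* iff its observed forward index (first 8 bases) is within
    ``max_mismatch`` of *s*'s forward index AND its observed reverse index
    (reverse complement of the last 8 bases) is within ``max_mismatch`` of
    *s*'s reverse index, and *s* is the only such sample.  Ambiguous or
    unmatched reads go to the unassigned bin; indices are trimmed from
    assigned reads.

    With the scheme's ``min_pairwise_hamming >= 2*max_mismatch + 1``
    assignment is provably unambiguous for any single index list.
    """
    L = scheme.index_length
    for pair in sheet.samples.values():
        if pair not in scheme.valid_pairs:
            raise ValueError(f"sample sheet pair {pair} not in scheme valid_pairs")
    by_fwd: dict[str, list[str]] = {}
    by_rev: dict[str, list[str]] = {}
    for s, (f, r) in sheet.samples.items():
        by_fwd.setdefault(f, []).append(s)
        by_rev.setdefault(r, []).append(s)

    assigned: dict[str, list[tuple[str, str, str]]] = {
        s: [] for s in sheet.samples
    }
    unassigned: list[tuple[str, str, str, str]] = []
    for read_id, seq, qual in reads:
        if len(seq) < 2 * L:
            unassigned.append((read_id, seq, qual, "too_short"))
            continue
        obs_fwd = seq[:L]
        obs_rev = reverse_complement(seq[-L:])
        fwd_hits = _match_index(obs_fwd, by_fwd, max_mismatch)
        rev_hits = _match_index(obs_rev, by_rev, max_mismatch)
        hits = set(fwd_hits) & set(rev_hits)
        if len(hits) == 1:
            s = hits.pop()
            assigned[s].append((read_id, seq[L:-L], qual[L:-L]))
        elif len(hits) > 1:
            unassigned.append((read_id, seq, qual, "ambiguous"))
        else:
            unassigned.append((read_id, seq, qual, "no_match"))
    return DemuxResult(assigned=assigned, unassigned=unassigned)


def check_pool_size(n_samples: int, n_amplicons: int,
                    max_per_pool: int = MAX_AMPLICONS_PER_POOL) -> int:
    """Warn when a pooling plan exceeds the per-pool amplicon-product ceiling.

    Returns the number of amplicon products (samples x amplicons) in the
    plan and emits a ``UserWarning`` when it exceeds ``max_per_pool``.
    """
    n_products = n_samples * n_amplicons
    if n_products > max_per_pool:
        warnings.warn(
            f"pooling plan holds {n_products} amplicon products; "
            f"more than {max_per_pool} per pool risks inadequate coverage — "
            f"split across pools with disjoint index combinations",
            stacklevel=2,
        )
    return n_products


def iter_fastq(path) -> Iterator[tuple[str, str, str]]:
    """Stream (read_id, sequence, quality) triples from a FASTQ file."""
    import pysam

    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            yield entry.name, entry.sequence, entry.quality or ""
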