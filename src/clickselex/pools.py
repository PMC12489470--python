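"""Sequencing-pool handling: reading, primer anchoring and trimming,
dereplication, and family clustering.

A :class:`Pool` is the unit that flows through the pipeline: a multiset of
DNA sequences with read counts. Raw selection-round reads are anchored on
the two fixed primer-binding sites (PBS) that flank the doped region,
trimmed to the interior, dereplicated, and greedily clustered into sequence
families around abundance-ranked centroids, mirroring standard practice for
doped-reselection (SELEX) pools.

Coordinates are 0-based half-open internally; reports use 1-based reference
coordinates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Iterator

import edlib
import numpy as np
from Bio import SeqIO

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic import LibrarySpec

__all__ = [
    "Pool",
    "PoolRecord",
    "FamilyCluster",
    "read_pool",
    "write_pool_fasta",
    "anchor_and_trim",
    "dereplicate",
    "cluster_families",
    "sequence_matrix",
]

_VALID_SEQ = re.compile(r"[ACGTN]+\Z")
_COUNT_TAG = re.compile(r";count=(\d+)")


@dataclass(frozen=True)
class PoolRecord:
    """One pool entry: a sequence observed ``count`` times."""

    sequence: str
    count: int = 1
    id: str = ""

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError(f"record {self.id!r}: count must be >= 1, got {self.count}")
        if not _VALID_SEQ.match(self.sequence):
            raise ValueError(
                f"record {self.id!r}: sequence must be uppercase over ACGTN"
            )


@dataclass
class Pool:
    """Multiset of sequences with counts."""

    records: list[PoolRecord]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PoolRecord]:
        return iter(self.records)

    @property
    def total_reads(self) -> int:
        """Sum of record counts (reads), as opposed to ``len`` (records)."""
        return sum(r.count for r in self.records)

    @property
    def n_unique(self) -> int:
        """Number of distinct sequences."""
        return len({r.sequence for r in self.records})

    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    @classmethod
    def from_sequences(
        cls, sequences: Iterable[str], counts: Iterable[int] | None = None
    ) -> "Pool":
        seqs = list(sequences)
        cnts = list(counts) if counts is not None else [1] * len(seqs)
        return cls(
            [
                PoolRecord(s.upper(), c, f"seq{i + 1}")
                for i, (s, c) in enumerate(zip(seqs, cnts))
            ]
        )


@dataclass(frozen=True)
class FamilyCluster:
    """A sequence family: centroid plus all members within the edit radius.

    The centroid is the highest-count member (ties broken by lexicographic
    order); ``total_count`` sums the member counts.
    """

    centroid: str
    members: tuple[tuple[str, int], ...]
    total_count: int = field(default=0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "total_count", sum(c for _, c in self.members))

    @property
    def member_count(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# I/O


def _detect_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".fa", ".fasta", ".fna"}:
        return "fasta"
    if suffix in {".fq", ".fastq"}:
        return "fastq"
    with open(path, "rb") as fh:
        first = fh.read(1)
    if first == b">":
        return "fasta"
    if first == b"@":
        return "fastq"
    raise ValueError(f"{path}: cannot detect FASTA/FASTQ format")


def read_pool(path: str | Path) -> Pool:
    """Read a FASTA or FASTQ file into a :class:`Pool`.

    Format is auto-detected from the extension, falling back to the first
    byte. Headers carrying a ``;count=N`` annotation set the record count;
    sequences are uppercased. Raises on empty or malformed files, naming the
    offending record index.
    """
    path = Path(path)
    fmt = _detect_format(path)
    records: list[PoolRecord] = []
    parser = SeqIO.parse(path, fmt)
    index = 0
    while True:
        try:
            rec = next(parser)
        except StopIteration:
            break
        except ValueError as exc:
            raise ValueError(f"{path}: malformed record at index {index}: {exc}") from exc
        m = _COUNT_TAG.search(rec.description)
        count = int(m.group(1)) if m else 1
        try:
            records.append(PoolRecord(str(rec.seq).upper(), count, rec.id))
        except ValueError as exc:
            raise ValueError(f"{path}: record at index {index}: {exc}") from exc
        index += 1
    if not records:
        raise ValueError(f"{path}: no sequence records found")
    return Pool(records)


def write_pool_fasta(pool: Pool, path: str | Path) -> None:
    """Write unique-sequence FASTA with counts encoded as ``;count=N``."""
    with open(path, "w") as fh:
        for rec in pool:
            name = rec.id or "seq"
            fh.write(f">{name};count={rec.count}\n{rec.sequence}\n")


# ---------------------------------------------------------------------------
# Anchoring and trimming


def sequence_matrix(sequences: list[str]) -> np.ndarray:
    """Stack equal-length sequences into a (n, L) uint8 byte matrix."""
    if not sequences:
        return np.empty((0, 0), dtype=np.uint8)
    length = len(sequences[0])
    if any(len(s) != length for s in sequences):
        raise ValueError("sequences must have equal length")
    buf = "".join(sequences).encode("ascii")
    return np.frombuffer(buf, dtype=np.uint8).reshape(len(sequences), length)


def _find_anchor(
    read: np.ndarray, anchor: np.ndarray, max_mismatches: int, start: int = 0
) -> int:
    """Leftmost offset >= start where anchor matches with <= max mismatches."""
    n = read.size - anchor.size + 1
    if n <= start:
        return -1
    windows = np.lib.stride_tricks.sliding_window_view(read, anchor.size)[start:]
    mismatches = (windows != anchor).sum(axis=1)
    hits = np.nonzero(mismatches <= max_mismatches)[0]
    return start + int(hits[0]) if hits.size else -1


def anchor_and_trim(
    pool: Pool, spec: "LibrarySpec", max_pbs_mismatches: int = 2
) -> tuple[Pool, dict[str, int]]:
    """Locate both PBS anchors in each read and extract the doped interior.

    Anchoring is substitution-only (Hamming): the 5' PBS is placed at its
    leftmost position with at most ``max_pbs_mismatches`` mismatches, then
    the 3' PBS at its leftmost position downstream of it. The interior is
    kept only when its length equals the doped length, so indel-containing
    reads fall into the rejects. Rejects are tallied by reason
    (``no_anchor``, ``wrong_length``), not raised.
    """
    if not pool.records:
        raise ValueError("empty pool")
    ref = spec.reference_sequence
    pbs5 = np.frombuffer(ref[: spec.pbs5_length].encode(), dtype=np.uint8)
    pbs3 = np.frombuffer(ref[len(ref) - spec.pbs3_length :].encode(), dtype=np.uint8)
    kept: list[PoolRecord] = []
    rejects = {"no_anchor": 0, "wrong_length": 0}
    for rec in pool:
        arr = np.frombuffer(rec.sequence.encode(), dtype=np.uint8)
        i5 = _find_anchor(arr, pbs5, max_pbs_mismatches)
        if i5 < 0:
            rejects["no_anchor"] += rec.count
            continue
        i3 = _find_anchor(arr, pbs3, max_pbs_mismatches, start=i5 + pbs5.size)
        if i3 < 0:
            rejects["no_anchor"] += rec.count
            continue
        interior = rec.sequence[i5 + pbs5.size : i3]
        if len(interior) != spec.doped_length:
            rejects["wrong_length"] += rec.count
            continue
        kept.append(PoolRecord(interior, rec.count, rec.id))
    return Pool(kept), rejects


# ---------------------------------------------------------------------------
# Dereplication and clustering


def dereplicate(pool: Pool) -> Pool:
    """Merge identical sequences, summing counts.

    Output is sorted by descending count, then lexicographic sequence — the
    canonical order the family clustering relies on. Idempotent.
    """
    totals: dict[str, int] = {}
    first_id: dict[str, str] = {}
    for rec in pool:
        if rec.sequence not in totals:
            first_id[rec.sequence] = rec.id
        totals[rec.sequence] = totals.get(rec.sequence, 0) + rec.count
    ordered = sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))
    return Pool(
        [PoolRecord(seq, count, first_id[seq]) for seq, count in ordered]
    )


def _within(a: str, b: str, k: int) -> bool:
    """True when Levenshtein(a, b) <= k (banded alignment)."""
    return edlib.align(a, b, mode="NW", k=k)["editDistance"] != -1


def cluster_families(unique_pool: Pool, max_edit_distance: int = 7) -> list[FamilyCluster]:
    """Greedy abundance-ordered centroid clustering into sequence families.

    Repeatedly takes the highest-count unassigned sequence (ties broken
    lexicographically) as a new centroid and assigns every unassigned
    sequence within ``max_edit_distance`` Levenshtein edits of it. The
    partition is deterministic and invariant to input order because the
    abundance/lexicographic sort is canonical.
    """
    if max_edit_distance < 0:
        raise ValueError("max_edit_distance must be >= 0")
    seqs = unique_pool.sequences()
    if len(set(seqs)) != len(seqs):
        raise ValueError("pool must be dereplicated before clustering")
    ordered = sorted(unique_pool.records, key=lambda r: (-r.count, r.sequence))
    assigned = np.zeros(len(ordered), dtype=bool)
    clusters: list[FamilyCluster] = []
    for i, centroid_rec in enumerate(ordered):
        if assigned[i]:
            continue
        assigned[i] = True
        members = [(centroid_rec.sequence, centroid_rec.count)]
        for j in range(i + 1, len(ordered)):
            if assigned[j]:
                continue
            if _within(ordered[j].sequence, centroid_rec.sequence, max_edit_distance):
                assigned[j] = True
                members.append((ordered[j].sequence, ordered[j].count))
        clusters.append(FamilyCluster(centroid_rec.sequence, tuple(members)))
    return clusters
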