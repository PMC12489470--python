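"""Per-position Variation Index (VI) conservation profiling.

After a doped reselection, positions that matter for catalysis drift back
toward the reference base while neutral positions keep the doping-rate
mutation frequency. The VI statistic normalizes the observed per-position
mutation frequency by the doping rate:

    VI = (1 - N/Nt) / mutation_rate

where N counts sequences matching the reference base at the position and
Nt counts all evaluable sequences there. VI << 1 marks functionally
important (conserved) nucleotides, VI ~ 1 neutral drift, VI > 1
mutation-tolerant positions. Profiles are reported in 1-based reference
coordinates and can be summarized by secondary-structure element (paired
regions P, loops L, junctions J).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .pools import FamilyCluster, Pool, cluster_families, dereplicate, sequence_matrix
from .synthetic import LibrarySpec

__all__ = [
    "ConservationProfile",
    "StructureElementMap",
    "PLACEHOLDER_ELEMENT_MAP",
    "count_matches",
    "compute_vi",
    "classify_positions",
    "build_profile",
    "summarize_by_element",
    "filter_most_populated",
]

logger = logging.getLogger(__name__)

WEIGHTINGS = ("per-read", "per-unique", "per-family")


@dataclass
class ConservationProfile:
    """Per-position conservation table over the doped interval.

    ``table`` columns: position (1-based), ref_base, N, Nt, VI, class.
    """

    table: pd.DataFrame
    mutation_rate: float
    weighting: str = "per-read"

    @property
    def mean_vi(self) -> float:
        return float(self.table["VI"].mean())

    def vi_at(self, position_1based: int) -> float:
        row = self.table.loc[self.table["position"] == position_1based]
        if row.empty:
            raise KeyError(f"position {position_1based} not in profile")
        return float(row["VI"].iloc[0])

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass(frozen=True)
class StructureElementMap:
    """Named secondary-structure elements over 1-based reference positions.

    Paired regions have two strands, so an element's positions need not be
    contiguous.
    """

    elements: dict[str, tuple[int, ...]]

    def __post_init__(self) -> None:
        for name, positions in self.elements.items():
            if any(p < 1 for p in positions):
                raise ValueError(f"element {name}: positions must be >= 1")

    @classmethod
    def from_json(cls, path: str | Path) -> "StructureElementMap":
        payload = json.loads(Path(path).read_text())
        return cls({name: tuple(pos) for name, pos in payload.items()})

    @classmethod
    def from_tsv(cls, path: str | Path) -> "StructureElementMap":
        """Two-column TSV: element <tab> position (one row per position)."""
        elements: dict[str, list[int]] = {}
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:2] != ["element", "position"]:
                raise ValueError(f"{path}: expected header 'element\\tposition'")
            for lineno, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                try:
                    elements.setdefault(parts[0], []).append(int(parts[1]))
                except (IndexError, ValueError) as exc:
                    raise ValueError(f"{path}: malformed row at line {lineno}") from exc
        return cls({name: tuple(pos) for name, pos in elements.items()})

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({k: list(v) for k, v in self.elements.items()}, indent=1) + "\n"
        )


# Synthetic placeholder map for the default 82-nt fixture reference: a
# four-way-junction-like layout (paired regions P, loops L, junctions J).
# J1/2 and L2 sit in the 5' PBS and are therefore never doped.
PLACEHOLDER_ELEMENT_MAP = StructureElementMap(
    {
        "J1/2": tuple(range(5, 12)),
        "L2": tuple(range(16, 22)),
        "P2": tuple(range(22, 27)) + tuple(range(31, 36)),
        "L3": tuple(range(27, 31)),
        "P3": tuple(range(36, 41)) + tuple(range(45, 50)),
        "L4": tuple(range(41, 45)),
        "J1/4": tuple(range(54, 58)),
        "P4": tuple(range(50, 54)) + tuple(range(58, 62)),
    }
)


# ---------------------------------------------------------------------------
# Counting


def _counting_units(
    pool: Pool,
    weighting: str,
    families: list[FamilyCluster] | None,
    max_edit_distance: int,
) -> tuple[list[str], np.ndarray]:
    if weighting == "per-read":
        return pool.sequences(), np.array([r.count for r in pool.records], dtype=float)
    if weighting == "per-unique":
        unique = dereplicate(pool)
        return unique.sequences(), np.ones(len(unique), dtype=float)
    if weighting == "per-family":
        if families is None:
            families = cluster_families(dereplicate(pool), max_edit_distance)
        return (
            [f.centroid for f in families],
            np.array([f.total_count for f in families], dtype=float),
        )
    raise ValueError(f"unknown weighting {weighting!r}; expected one of {WEIGHTINGS}")


def count_matches(
    trimmed_pool: Pool,
    spec: LibrarySpec,
    weighting: str = "per-read",
    families: list[FamilyCluster] | None = None,
    max_edit_distance: int = 7,
) -> pd.DataFrame:
    """Per-position reference-match counts (N, Nt) over the doped interval.

    Sequences must already be trimmed to the doped length. ``weighting``
    chooses the counting unit: reads (record counts), unique sequences
    (weight 1 each), or family centroids weighted by family total counts
    (pass precomputed ``families`` to avoid re-clustering). Bases called N
    are excluded from both N and Nt at that position.
    """
    for idx, rec in enumerate(trimmed_pool):
        if len(rec.sequence) != spec.doped_length:
            raise ValueError(
                f"record {rec.id or idx!r}: length {len(rec.sequence)} != "
                f"doped length {spec.doped_length}"
            )
    sequences, weights = _counting_units(
        trimmed_pool, weighting, families, max_edit_distance
    )
    matrix = sequence_matrix(sequences)
    ref = np.frombuffer(spec.doped_reference.encode(), dtype=np.uint8)
    valid = matrix != ord("N")
    match = (matrix == ref) & valid
    nt = (valid * weights[:, None]).sum(axis=0)
    n = (match * weights[:, None]).sum(axis=0)
    start, _ = spec.doped_interval
    return pd.DataFrame(
        {
            "position": np.arange(start + 1, start + 1 + spec.doped_length),
            "ref_base": list(spec.doped_reference),
            "N": n,
            "Nt": nt,
        }
    )


def compute_vi(N, Nt, mutation_rate: float):
    """Variation Index: observed mutation frequency over the doping rate.

    ``VI = (1 - N/Nt) / mutation_rate``; 0 means perfect conservation and
    1/mutation_rate maximal variability. Scalar or array inputs; Nt = 0
    yields NaN (position not evaluable), never 0.
    """
    if not 0 < mutation_rate <= 1:
        raise ValueError("mutation_rate must be in (0, 1]")
    n = np.asarray(N, dtype=float)
    nt = np.asarray(Nt, dtype=float)
    if np.any(n < 0) or np.any(n > nt):
        raise ValueError("require 0 <= N <= Nt")
    with np.errstate(divide="ignore", invalid="ignore"):
        vi = np.where(nt > 0, (1.0 - n / nt) / mutation_rate, np.nan)
    return float(vi) if vi.ndim == 0 else vi


def classify_positions(profile: ConservationProfile, threshold: float = 1.0) -> ConservationProfile:
    """Assign conservation classes from VI against the neutrality threshold.

    ``important`` (VI < threshold), ``tolerant`` (VI > threshold),
    ``boundary`` (VI exactly equal — reported separately, never merged),
    ``not-evaluable`` (Nt = 0).
    """
    vi = profile.table["VI"].to_numpy()
    cls = np.select(
        [np.isnan(vi), vi < threshold, vi > threshold],
        ["not-evaluable", "important", "tolerant"],
        default="boundary",
    )
    table = profile.table.copy()
    table["class"] = cls
    return ConservationProfile(table, profile.mutation_rate, profile.weighting)


def build_profile(
    trimmed_pool: Pool,
    spec: LibrarySpec,
    weighting: str = "per-read",
    mutation_rate: float | None = None,
    vi_threshold: float = 1.0,
    families: list[FamilyCluster] | None = None,
    max_edit_distance: int = 7,
) -> ConservationProfile:
    """Count, compute VI, and classify in one step."""
    rate = spec.mutation_rate if mutation_rate is None else mutation_rate
    counts = count_matches(trimmed_pool, spec, weighting, families, max_edit_distance)
    counts["VI"] = compute_vi(counts["N"].to_numpy(), counts["Nt"].to_numpy(), rate)
    profile = ConservationProfile(counts, rate, weighting)
    return classify_positions(profile, vi_threshold)


# ---------------------------------------------------------------------------
# Filtering and element summaries


def filter_most_populated(
    pool: Pool,
    fraction: float = 0.95,
    unit: str = "family",
    max_edit_distance: int = 7,
    families: list[FamilyCluster] | None = None,
) -> Pool:
    """Keep the most populated sequences covering ``fraction`` of all reads.

    With ``unit="family"`` whole families (ranked by total count) are kept
    until the cumulative read coverage reaches the fraction; with
    ``unit="unique"`` individual unique sequences are ranked instead.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    unique = dereplicate(pool)
    total = unique.total_reads
    if unit == "unique":
        kept: list = []
        covered = 0
        for rec in unique:  # already sorted by descending count
            kept.append(rec)
            covered += rec.count
            if covered >= fraction * total:
                break
        return Pool(kept)
    if unit == "family":
        if families is None:
            families = cluster_families(unique, max_edit_distance)
        ranked = sorted(families, key=lambda f: (-f.total_count, f.centroid))
        kept_seqs: set[str] = set()
        covered = 0
        for fam in ranked:
            kept_seqs.update(s for s, _ in fam.members)
            covered += fam.total_count
            if covered >= fraction * total:
                break
        return Pool([r for r in unique if r.sequence in kept_seqs])
    raise ValueError(f"unknown unit {unit!r}; expected 'family' or 'unique'")


def summarize_by_element(
    profile: ConservationProfile, element_map: StructureElementMap
) -> pd.DataFrame:
    """Aggregate a conservation profile by secondary-structure element.

    Positions outside the doped interval (e.g. elements in a primer-binding
    site) are counted as ``not-doped`` and excluded from the VI statistics.
    """
    doped_positions = set(profile.table["position"].tolist())
    rows = []
    indexed = profile.table.set_index("position")
    for name, positions in element_map.elements.items():
        in_doped = [p for p in positions if p in doped_positions]
        n_not_doped = len(positions) - len(in_doped)
        if n_not_doped:
            logger.info(
                "element %s: %d position(s) outside the doped interval "
                "excluded from VI statistics",
                name,
                n_not_doped,
            )
        sub = indexed.loc[in_doped] if in_doped else None
        vi = sub["VI"].dropna() if sub is not None else pd.Series(dtype=float)
        rows.append(
            {
                "element": name,
                "n_positions": len(positions),
                "n_not_doped": n_not_doped,
                "n_important": int((sub["class"] == "important").sum()) if sub is not None else 0,
                "n_tolerant": int((sub["class"] == "tolerant").sum()) if sub is not None else 0,
                "n_boundary": int((sub["class"] == "boundary").sum()) if sub is not None else 0,
                "mean_VI": float(vi.mean()) if len(vi) else np.nan,
                "min_VI": float(vi.min()) if len(vi) else np.nan,
                "max_VI": float(vi.max()) if len(vi) else np.nan,
            }
        )
    return pd.DataFrame(rows)
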