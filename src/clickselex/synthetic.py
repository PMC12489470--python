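"""Seeded generators for every input the reselection pipeline consumes.

Emulates the statistical structure of a click-ligating DNAzyme doped
reselection: an 82-nt library (21-nt 5' primer-binding site, 40-nt doped
region, 21-nt 3' PBS), per-position doping at a 45% mutation rate,
round-by-round selection in which each molecule is ligated (survives) with
probability 1 - exp(-rate * t) under a decreasing-time stringency schedule,
single-exponential ligation time courses, and back-solved gel-band fixtures
for the yield/selectivity calculators.

The sequence→rate map of the real enzyme is unknown; :class:`ActivityModel`
is a synthetic stand-in (multiplicative penalty per violated base
constraint) that exists so conservation-profile recovery can be tested
against a known ground truth.

All randomness flows from one integer seed. Composite simulations split it
with ``numpy.random.SeedSequence.spawn``, one child stream per round, so a
run is reproducible bit-for-bit and rounds are independent streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np

from .pools import Pool, PoolRecord, sequence_matrix

__all__ = [
    "LibrarySpec",
    "ActivityModel",
    "SelectionSchedule",
    "SelectionRound",
    "SelectionResult",
    "TimeCourse",
    "DEFAULT_REFERENCE",
    "generate_doped_pool",
    "simulate_selection_round",
    "simulate_selection",
    "generate_time_course",
    "generate_gel_fixture",
    "original_schedule",
    "reselection_schedule",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# Synthetic placeholder for the real 82-nt clone (5' PBS + doped + 3' PBS);
# the actual selected sequence is published only in supplementary material,
# so fixtures ship this stand-in and configs accept a substitute.
DEFAULT_REFERENCE = (
    "ACGTACCGTTAGCACCTGATC"  # 21-nt 5' PBS
    "GGATCCATTGCAGTGCTAAGCTTCAGGACTTAACGGTCAC"  # 40-nt doped region
    "GATCAGGTGCTAACGGTACGT"  # 21-nt 3' PBS
)


def _rng(seed) -> np.random.Generator:
    """Accept an int, SeedSequence or Generator and return a Generator."""
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class LibrarySpec:
    """Doped-library layout: fixed flanks around a mutagenized interval.

    ``doped_interval`` is 0-based half-open within ``reference_sequence``;
    ``mutation_rate`` is the per-position doping probability (the fraction
    of molecules carrying a non-reference base at each doped position).
    """

    reference_sequence: str = DEFAULT_REFERENCE
    doped_interval: tuple[int, int] = (21, 61)
    mutation_rate: float = 0.45
    pbs5_length: int = 21
    pbs3_length: int = 21

    def __post_init__(self) -> None:
        start, end = self.doped_interval
        n = len(self.reference_sequence)
        if not set(self.reference_sequence) <= set("ACGT"):
            raise ValueError("reference_sequence must be over ACGT")
        if not (0 <= start < end <= n):
            raise ValueError(f"doped_interval {self.doped_interval} outside reference")
        if start < self.pbs5_length or end > n - self.pbs3_length:
            raise ValueError("doped_interval overlaps a primer-binding site")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")

    @property
    def doped_length(self) -> int:
        start, end = self.doped_interval
        return end - start

    @property
    def doped_reference(self) -> str:
        start, end = self.doped_interval
        return self.reference_sequence[start:end]

    @property
    def doped_positions_1based(self) -> list[int]:
        start, end = self.doped_interval
        return list(range(start + 1, end + 1))


@dataclass(frozen=True)
class ActivityModel:
    """Synthetic ground-truth sequence→rate rule for the simulator.

    A sequence matching the required base at every constrained position
    ligates at ``k_max`` (h^-1); each violated constraint multiplies the
    rate by ``mismatch_penalty``. Positions are 0-based coordinates into
    the full reference.
    """

    required_bases: dict[int, str]
    k_max: float = 0.5
    mismatch_penalty: float = 0.2

    def __post_init__(self) -> None:
        if self.k_max <= 0:
            raise ValueError("k_max must be > 0")
        if not 0 < self.mismatch_penalty <= 1:
            raise ValueError("mismatch_penalty must be in (0, 1]")
        for pos, base in self.required_bases.items():
            if base not in "ACGT":
                raise ValueError(f"position {pos}: required base {base!r} not in ACGT")

    @property
    def constrained_positions(self) -> list[int]:
        return sorted(self.required_bases)

    @classmethod
    def from_reference(
        cls,
        spec: "LibrarySpec",
        positions_1based: list[int],
        k_max: float = 0.5,
        mismatch_penalty: float = 0.2,
    ) -> "ActivityModel":
        """Model requiring the reference base at the given 1-based positions.

        This is the ground truth used for conservation-recovery checks:
        constrained positions should come back with VI < 1.
        """
        return cls(
            required_bases={
                p - 1: spec.reference_sequence[p - 1] for p in positions_1based
            },
            k_max=k_max,
            mismatch_penalty=mismatch_penalty,
        )

    def rate(self, sequence: str) -> float:
        """Ligation rate of one full-length sequence, in h^-1."""
        violations = sum(
            1 for pos, base in self.required_bases.items() if sequence[pos] != base
        )
        return self.k_max * self.mismatch_penalty**violations

    def rates(self, matrix: np.ndarray) -> np.ndarray:
        """Vectorized rates for a (n, L) sequence byte matrix."""
        if not self.required_bases:
            return np.full(matrix.shape[0], self.k_max)
        positions = np.array(self.constrained_positions)
        required = np.frombuffer(
            "".join(self.required_bases[p] for p in positions).encode(), dtype=np.uint8
        )
        violations = (matrix[:, positions] != required).sum(axis=1)
        return self.k_max * self.mismatch_penalty ** violations

    def to_json(self, path: str | Path) -> None:
        payload = {
            # user-facing coordinates are 1-based
            "required_bases": {str(p + 1): b for p, b in self.required_bases.items()},
            "k_max": self.k_max,
            "mismatch_penalty": self.mismatch_penalty,
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ActivityModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            required_bases={int(p) - 1: b for p, b in payload["required_bases"].items()},
            k_max=payload["k_max"],
            mismatch_penalty=payload["mismatch_penalty"],
        )


@dataclass(frozen=True)
class SelectionRound:
    round_index: int
    pool_size: int
    reaction_time: float  # hours

    def __post_init__(self) -> None:
        if self.pool_size <= 0:
            raise ValueError("pool_size must be > 0")
        if self.reaction_time <= 0:
            raise ValueError("reaction_time must be > 0")


@dataclass(frozen=True)
class SelectionSchedule:
    """Per-round stringency: molecule count and positive-selection time."""

    rounds: tuple[SelectionRound, ...]

    def __post_init__(self) -> None:
        if not self.rounds:
            raise ValueError("schedule must contain at least one round")
        indices = [r.round_index for r in self.rounds]
        if indices != list(range(1, len(indices) + 1)):
            raise ValueError("round_index must increase 1, 2, ... without gaps")

    def to_json(self, path: str | Path) -> None:
        payload = [
            {"round": r.round_index, "pool_size": r.pool_size, "time_h": r.reaction_time}
            for r in self.rounds
        ]
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SelectionSchedule":
        payload = json.loads(Path(path).read_text())
        return cls(
            tuple(
                SelectionRound(r["round"], r["pool_size"], r["time_h"]) for r in payload
            )
        )

    @classmethod
    def from_times(cls, times: list[float], pool_size: int = 20000) -> "SelectionSchedule":
        return cls(
            tuple(
                SelectionRound(i + 1, pool_size, t) for i, t in enumerate(times)
            )
        )


def original_schedule(pool_size: int = 20000) -> SelectionSchedule:
    """The 11-round de novo selection stringency: 8 h x6, 4 h x2, 2 h x3."""
    return SelectionSchedule.from_times([8.0] * 6 + [4.0] * 2 + [2.0] * 3, pool_size)


def reselection_schedule(pool_size: int = 20000) -> SelectionSchedule:
    """The 7-round doped reselection stringency: 8 h x4, then 6, 3, 1.5 h."""
    return SelectionSchedule.from_times([8.0, 8.0, 8.0, 8.0, 6.0, 3.0, 1.5], pool_size)


@dataclass(frozen=True)
class TimeCourse:
    """Ligation-percent observations over hours."""

    times: tuple[float, ...]
    ligation_percent: tuple[float, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.times) != len(self.ligation_percent):
            raise ValueError("times and ligation_percent lengths differ")
        if any(t2 <= t1 for t1, t2 in zip(self.times, self.times[1:])):
            raise ValueError("times must be strictly increasing")
        if self.times and self.times[0] < 0:
            raise ValueError("times must be >= 0")
        if any(not 0 <= y <= 100 for y in self.ligation_percent):
            raise ValueError("ligation_percent values must be in [0, 100]")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("time_h\tlig_percent\n")
            for t, y in zip(self.times, self.ligation_percent):
                fh.write(f"{t:g}\t{y:.6g}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, label: str = "") -> "TimeCourse":
        times: list[float] = []
        values: list[float] = []
        with open(path) as fh:
            header = fh.readline().strip().split("\t")
            if header[:2] != ["time_h", "lig_percent"]:
                raise ValueError(f"{path}: expected header 'time_h\\tlig_percent'")
            for lineno, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                try:
                    times.append(float(parts[0]))
                    values.append(float(parts[1]))
                except (IndexError, ValueError) as exc:
                    raise ValueError(f"{path}: malformed row at line {lineno}") from exc
        return cls(tuple(times), tuple(values), label or Path(path).stem)


@dataclass
class SelectionResult:
    """Trajectory of per-round ligation fractions plus the final pool."""

    trajectory: list[float]
    final_pool: Pool
    status: str = "completed"  # or "pool extinct"


# ---------------------------------------------------------------------------
# Generators


def generate_doped_pool(spec: LibrarySpec, n_sequences: int, seed) -> Pool:
    """Synthesize a doped pool around the reference sequence.

    Each doped position mutates independently with probability
    ``spec.mutation_rate``; the replacement is uniform over the three
    non-reference bases. Non-doped positions are identical to the
    reference.
    """
    if n_sequences < 1:
        raise ValueError("n_sequences must be >= 1")
    rng = _rng(seed)
    ref = np.frombuffer(spec.reference_sequence.encode(), dtype=np.uint8)
    start, end = spec.doped_interval
    n_doped = end - start
    matrix = np.tile(ref, (n_sequences, 1))
    # reference base index (0..3) at each doped position
    ref_idx = np.searchsorted(_BASES, ref[start:end])
    mutate = rng.random((n_sequences, n_doped)) < spec.mutation_rate
    # offset 1..3 from the reference index, mod 4: uniform over alternatives
    offsets = rng.integers(1, 4, size=(n_sequences, n_doped))
    alt_idx = (ref_idx[None, :] + offsets) % 4
    doped = np.where(mutate, _BASES[alt_idx], matrix[:, start:end])
    matrix[:, start:end] = doped
    sequences = matrix.tobytes().decode("ascii")
    length = ref.size
    return Pool(
        [
            PoolRecord(sequences[i * length : (i + 1) * length], 1, f"seq{i + 1}")
            for i in range(n_sequences)
        ]
    )


def simulate_selection_round(
    pool: Pool, model: ActivityModel, reaction_time: float, seed
) -> tuple[Pool, float]:
    """One positive-selection step: ligation as stochastic survival.

    Each molecule survives independently with probability
    ``1 - exp(-rate(sequence) * reaction_time)``. Returns the survivor pool
    (counts thinned binomially) and the realized ligation fraction.
    """
    if not pool.records:
        raise ValueError("empty pool")
    if reaction_time <= 0:
        raise ValueError("reaction_time must be > 0")
    rng = _rng(seed)
    matrix = sequence_matrix(pool.sequences())
    rates = model.rates(matrix)
    p_survive = 1.0 - np.exp(-rates * reaction_time)
    counts = np.array([r.count for r in pool.records])
    survivors = rng.binomial(counts, p_survive)
    total = counts.sum()
    lig_fraction = survivors.sum() / total
    kept = [
        PoolRecord(rec.sequence, int(k), rec.id)
        for rec, k in zip(pool.records, survivors)
        if k > 0
    ]
    return Pool(kept), float(lig_fraction)


def _resample(pool: Pool, size: int, rng: np.random.Generator) -> Pool:
    """Multinomial re-amplification to ``size`` molecules (error-free PCR)."""
    counts = np.array([r.count for r in pool.records], dtype=float)
    drawn = rng.multinomial(size, counts / counts.sum())
    return Pool(
        [
            PoolRecord(rec.sequence, int(k), rec.id)
            for rec, k in zip(pool.records, drawn)
            if k > 0
        ]
    )


def simulate_selection(
    spec: LibrarySpec, model: ActivityModel, schedule: SelectionSchedule, seed
) -> SelectionResult:
    """Run a full selection: doped pool, then per-round survive/re-amplify.

    Round 1 starts from :func:`generate_doped_pool`; each later round draws
    ``pool_size`` molecules by multinomial resampling from the previous
    survivors before applying the ligation step. If a round leaves no
    survivors the trajectory is truncated with status ``"pool extinct"``.
    The final pool is re-amplified to the last round's pool size.
    """
    seed_seq = (
        seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    )
    children = seed_seq.spawn(2 * len(schedule.rounds) + 1)
    pool = generate_doped_pool(spec, schedule.rounds[0].pool_size, children[0])
    trajectory: list[float] = []
    for i, rnd in enumerate(schedule.rounds):
        if i > 0:
            pool = _resample(pool, rnd.pool_size, _rng(children[2 * i - 1]))
        survivors, lig_fraction = simulate_selection_round(
            pool, model, rnd.reaction_time, children[2 * i]
        )
        trajectory.append(lig_fraction)
        if not survivors.records:
            return SelectionResult(trajectory, Pool([]), status="pool extinct")
        pool = survivors
    final_pool = _resample(pool, schedule.rounds[-1].pool_size, _rng(children[-1]))
    return SelectionResult(trajectory, final_pool)


def generate_time_course(
    k_obs: float,
    y_max: float,
    times: list[float],
    noise_sd: float,
    seed,
    label: str = "",
) -> TimeCourse:
    """Noisy single-exponential ligation time course.

    ``lig%(t) = y_max * (1 - exp(-k_obs t))`` plus Gaussian noise with the
    given standard deviation (percentage points), clipped to [0, 100].
    """
    if k_obs <= 0:
        raise ValueError("k_obs must be > 0")
    if not 0 < y_max <= 100:
        raise ValueError("y_max must be in (0, 100]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    t = np.asarray(times, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    rng = _rng(seed)
    clean = y_max * (1.0 - np.exp(-k_obs * t))
    noisy = clean + rng.normal(0.0, noise_sd, size=t.size) if noise_sd > 0 else clean
    noisy = np.clip(noisy, 0.0, 100.0)
    return TimeCourse(tuple(t.tolist()), tuple(noisy.tolist()), label)


def generate_gel_fixture(
    kind: str, true_values: dict[str, float], seed
) -> dict[str, float]:
    """Back-solve band intensities reproducing requested gel metrics.

    ``kind="two-band"`` takes ``{"lig_percent": ...}`` and returns
    ``{lig, unlig}``; ``kind="three-band"`` takes ``{"Y": ..., "S": ...}``
    and returns ``{unlig, CP, LLP}``. Intensities are scaled by a random
    positive factor (the metrics are scale-invariant) so fixtures do not
    all sum to 100.
    """
    rng = _rng(seed)
    scale = float(rng.uniform(0.5, 5.0))
    if kind == "two-band":
        target = float(true_values["lig_percent"])
        if not 0 <= target <= 100:
            raise ValueError("lig_percent target must be in [0, 100]")
        return {"lig": target * scale, "unlig": (100.0 - target) * scale}
    if kind == "three-band":
        y = float(true_values["Y"])
        s = float(true_values["S"])
        if not (0 <= y <= 100 and 0 <= s <= 100):
            raise ValueError("Y and S targets must be in [0, 100]")
        if s < y:
            raise ValueError(f"infeasible targets: S ({s}) < Y ({y})")
        if y > 0 and s == 0:
            raise ValueError("infeasible targets: Y > 0 requires S > 0")
        # total lane intensity 100: CP = Y; CP + LLP = 100*CP/S
        cp = y
        llp = cp * (100.0 / s - 1.0) if s > 0 else 0.0
        unlig = 100.0 - cp - llp
        if unlig < -1e-9:
            raise ValueError(f"infeasible targets: Y={y}, S={s} imply negative un-lig")
        return {
            "unlig": max(unlig, 0.0) * scale,
            "CP": cp * scale,
            "LLP": llp * scale,
        }
    raise ValueError(f"unknown fixture kind {kind!r}")
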