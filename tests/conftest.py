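import numpy as np
import pytest
from hypothesis import settings

from clickselex import LibrarySpec

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def spec() -> LibrarySpec:
    """Default 82-nt library: 21-nt PBS flanks around a 40-nt doped region."""
    return LibrarySpec()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


# --- independent oracles -----------------------------------------------------


def levenshtein(a: str, b: str) -> int:
    """Plain DP edit distance, independent of the aligner the package uses."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def greedy_cluster_oracle(records: list[tuple[str, int]], radius: int):
    """Exhaustive re-implementation of abundance-ordered greedy clustering."""
    ordered = sorted(records, key=lambda r: (-r[1], r[0]))
    assigned = [False] * len(ordered)
    clusters = []
    for i, (centroid, _) in enumerate(ordered):
        if assigned[i]:
            continue
        assigned[i] = True
        members = [ordered[i]]
        for j in range(i + 1, len(ordered)):
            if not assigned[j] and levenshtein(ordered[j][0], centroid) <= radius:
                assigned[j] = True
                members.append(ordered[j])
        clusters.append((centroid, members))
    return clusters
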