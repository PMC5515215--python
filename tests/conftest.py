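"""Shared fixtures and independent oracles.

The oracles deliberately use brute-force strategies (exhaustive primer
expansion, grid-search SSE minimisation, stepwise max-linkage
agglomeration) so they stay independent of the implementation paths
they check.
"""
from __future__ import annotations

import itertools

import numpy as np
import pytest

from quorumflow.tags import IUPAC_CODES


def expand_primer(iupac: str) -> list[str]:
    """All concrete DNA strings matching an IUPAC primer."""
    return ["".join(p) for p in itertools.product(*[sorted(IUPAC_CODES[c]) for c in iupac])]


def oracle_match_positions(iupac: str, sequence: str) -> list[int]:
    """Plain substring search over the exhaustive expansion of the primer.

    Mirrors the rule that an N in the read matches only primer code N:
    expansions are matched literally, and for primer-N positions the
    read may also carry N.
    """
    plen = len(iupac)
    hits = set()
    for concrete in expand_primer(iupac):
        for p in range(len(sequence) - plen + 1):
            window = sequence[p : p + plen]
            if all(
                w == c or (w == "N" and iupac[i] == "N")
                for i, (w, c) in enumerate(zip(window, concrete))
            ):
                hits.add(p)
    return sorted(hits)


def oracle_first_order_grid(t: np.ndarray, c: np.ndarray,
                            c0_range=(0.5, 20.0), k_range=(0.01, 5.0),
                            n_grid: int = 400) -> tuple[float, float]:
    """Brute-force SSE minimisation over (c0, k) on a refined grid."""
    best = (np.inf, None, None)
    c0s = np.linspace(*c0_range, n_grid)
    ks = np.linspace(*k_range, n_grid)
    for _ in range(2):
        for c0 in c0s:
            resid = c[None, :] - c0 * np.exp(-np.outer(ks, t))
            sse = (resid**2).sum(axis=1)
            i = int(np.argmin(sse))
            if sse[i] < best[0]:
                best = (float(sse[i]), float(c0), float(ks[i]))
        # refine around the current optimum
        _, c0_hat, k_hat = best
        c0s = np.linspace(max(c0_hat * 0.9, 1e-6), c0_hat * 1.1, n_grid)
        ks = np.linspace(max(k_hat * 0.9, 1e-6), k_hat * 1.1, n_grid)
    return best[1], best[2]


def oracle_complete_linkage(points: np.ndarray):
    """Stepwise agglomeration recomputing max-linkage distances at each merge.

    Returns the sequence of merge heights and the final partition as a
    list of frozensets of original indices, for comparison against the
    scipy-based implementation.
    """
    clusters = [frozenset([i]) for i in range(len(points))]
    heights = []
    d = lambda a, b: float(np.linalg.norm(points[a] - points[b]))
    while len(clusters) > 1:
        best = (np.inf, None, None)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                dist = max(d(a, b) for a in clusters[i] for b in clusters[j])
                if dist < best[0]:
                    best = (dist, i, j)
        dist, i, j = best
        heights.append(dist)
        merged = clusters[i] | clusters[j]
        clusters = [c for idx, c in enumerate(clusters) if idx not in (i, j)] + [merged]
    return heights


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
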