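"""Deterministic synthetic populations and matrices for tests and docs.

These generators build inputs with known structure — tag clusters that
force within-cluster cooperation, and count matrices with planted
reciprocity patterns — so that downstream statistics have hand-checkable
expected values.  Everything is generated at call time from an explicit
random stream; regeneration with the same seed is byte-stable.
"""

from __future__ import annotations

import numpy as np

from .model_core import Population, Strategy
from .single_gen import SociometricMatrix

__all__ = ["make_clustered_tag_population", "make_planted_matrix"]


def make_clustered_tag_population(
    n_clusters: int,
    spread: float,
    rng: np.random.Generator,
    n_agents: int = 20,
) -> tuple[Population, np.ndarray]:
    """Population whose tags sit in ``n_clusters`` well-separated groups.

    Cluster centers are evenly spaced at ``(i + 0.5) / n_clusters``; each
    agent's tag is uniform within ``center +/- spread``.  Returns the
    population and the per-agent cluster labels.  Raises ``ValueError``
    when clusters would overlap (``2 * spread >= 1 / n_clusters``).
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if spread <= 0:
        raise ValueError("spread must be > 0")
    if 2 * spread >= 1.0 / n_clusters:
        raise ValueError(
            f"clusters overlap: 2*spread={2 * spread} >= 1/n_clusters={1 / n_clusters}"
        )
    labels = np.arange(n_agents) % n_clusters
    centers = (labels + 0.5) / n_clusters
    pop = Population(n_agents)
    pop.strategy[:] = int(Strategy.CHOOSING_COOPERATIVE)
    pop.tag[:] = centers + (rng.random(n_agents) * 2 - 1) * spread
    return pop, labels


def make_planted_matrix(
    pattern: str, N: int, rng: np.random.Generator
) -> SociometricMatrix:
    """Count matrix with a planted reciprocity structure.

    ``symmetric``
        every dyad exchanges equal counts (per-agent given/received
        correlation is exactly 1);
    ``antisymmetric``
        complementary dyads — given + received is constant per dyad, so
        per-agent correlation is exactly -1 (the 3-agent directed ring is
        the N=3 special case);
    ``null``
        i.i.d. uniform integer counts (no reciprocity structure).
    """
    if N < 3:
        raise ValueError("N must be >= 3")
    counts = np.zeros((N, N), dtype=np.int64)
    if pattern == "symmetric":
        w = rng.integers(0, 21, size=(N, N))
        w = np.triu(w, k=1)
        counts = w + w.T
    elif pattern == "antisymmetric":
        total = 10
        # Redraw until every agent's given vector varies across partners
        # (degenerate draws are vanishingly rare but would undefine r).
        while True:
            g = rng.integers(0, total + 1, size=(N, N))
            g = np.triu(g, k=1)
            counts = g + (total - g.T) * (np.tril(np.ones((N, N), dtype=np.int64), -1))
            np.fill_diagonal(counts, 0)
            off = ~np.eye(N, dtype=bool)
            ok = all(
                counts[i, off[i]].std() > 0 for i in range(N)
            )
            if ok:
                break
    elif pattern == "null":
        counts = rng.integers(0, 21, size=(N, N))
        np.fill_diagonal(counts, 0)
    else:
        raise ValueError(f"unknown pattern: {pattern!r}")
    return SociometricMatrix(counts.astype(np.int64))
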