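"""Single-generation simulation engine and sociometric-matrix I/O.

In the single-generation models every agent is a choosing cooperator: at
each step all N agents act once, in random order, and each directs one
cooperative act at the candidate selected by the symmetry rule (tag
similarity or spatial proximity).  There are no fitness consequences; the
output of a run is the N x N sociometric matrix of cooperation given
(rows = actors, columns = recipients), whose every row sums to the number
of steps.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import _engine
from .model_core import ModelVariant, Population, SimConfig, make_population

__all__ = [
    "SociometricMatrix",
    "run_single_generation",
    "run_replicates",
    "write_run_metadata",
]


@dataclasses.dataclass
class SociometricMatrix:
    """N x N count matrix of cooperative acts given.

    ``counts[i, j]`` is the number of acts agent i directed at agent j over
    a run; the diagonal is structurally zero.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("counts must be a square matrix")

    @property
    def n(self) -> int:
        return self.counts.shape[0]

    def validate(self, n_steps: int | None = None) -> None:
        """Check the structural invariants; raise ``ValueError`` on failure."""
        if np.any(np.diagonal(self.counts) != 0):
            raise ValueError("diagonal must be zero (no self-directed acts)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if n_steps is not None and not np.all(self.counts.sum(axis=1) == n_steps):
            raise ValueError(f"every row must sum to n_steps={n_steps}")

    @property
    def given(self) -> np.ndarray:
        """Total acts given per agent (row sums)."""
        return self.counts.sum(axis=1)

    @property
    def received(self) -> np.ndarray:
        """Total acts received per agent (column sums)."""
        return self.counts.sum(axis=0)

    def symmetrized(self) -> np.ndarray:
        """Undirected dyad weights ``w_ij + w_ji``."""
        return self.counts + self.counts.T

    # ---------------------------------------------------------------- I/O
    def to_frame(self) -> pd.DataFrame:
        ids = np.arange(self.n)
        return pd.DataFrame(self.counts, index=ids, columns=ids)

    def to_csv(self, path: str | Path) -> None:
        """CSV with a header row and an index column of agent ids."""
        self.to_frame().to_csv(path, index_label="actor")

    @classmethod
    def from_csv(cls, path: str | Path) -> "SociometricMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=np.int64))

    def to_edge_list(self, path: str | Path) -> None:
        """Nonzero entries as ``actor,recipient,weight`` CSV rows."""
        rows, cols = np.nonzero(self.counts)
        pd.DataFrame(
            {"actor": rows, "recipient": cols, "weight": self.counts[rows, cols]}
        ).to_csv(path, index=False)

    def checksum(self) -> str:
        """sha256 of the canonical CSV serialization."""
        return hashlib.sha256(self.to_frame().to_csv(index_label="actor").encode()).hexdigest()


def run_single_generation(
    config: SimConfig,
    rng: np.random.Generator,
    population: Population | None = None,
) -> SociometricMatrix:
    """Run one single-generation simulation and return the count matrix.

    A fresh population is created from ``config`` unless an existing one is
    supplied (useful for engineered tag layouts).  Every agent acts once per
    step and always cooperates; the choice kernel follows
    ``config.model_variant``.
    """
    if population is None:
        population = make_population(config, rng)
    if config.model_variant is ModelVariant.TAG:
        counts = _engine.run_tag_phase(population, config, rng)
    else:
        counts = _engine.run_proximity_phase(population, config, rng)
    m = SociometricMatrix(counts)
    m.validate(n_steps=config.n_steps)
    return m


def run_replicates(config: SimConfig) -> list[SociometricMatrix]:
    """Independent replicates, replicate i seeded ``config.seed + i``.

    Each replicate re-draws its own tags/positions; the full set of outputs
    is a pure function of the configuration.
    """
    out = []
    for i in range(config.n_replicates):
        rng = np.random.default_rng(config.seed + i)
        out.append(run_single_generation(config, rng))
    return out


def write_run_metadata(
    path: str | Path, config: SimConfig, matrices: list[SociometricMatrix]
) -> None:
    """JSON sidecar: full configuration, seed, per-replicate checksums."""
    meta = {
        "config": config.to_dict(),
        "seed": config.seed,
        "n_replicates": len(matrices),
        "replicate_checksums": [m.checksum() for m in matrices],
    }
    Path(path).write_text(json.dumps(meta, indent=2))
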