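"""Symmetry-based partner-choice kernels and toroidal movement.

Two choice rules, both free of any bookkeeping of cooperation received:

* tag similarity — pick the candidate whose tag minimizes the absolute
  difference from the actor's own tag;
* spatial proximity — pick the candidate nearest under the toroidal
  (wrap-around) Euclidean metric, after the actor takes one unit-length
  random-walk step in a uniformly random direction.

Exact ties are broken uniformly at random in both kernels.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np

from .model_core import Agent

__all__ = [
    "TorusGeometry",
    "toroidal_distance",
    "choose_by_tag",
    "choose_by_proximity",
    "random_walk",
]

_TWO_PI = 2.0 * math.pi


@dataclasses.dataclass(frozen=True)
class TorusGeometry:
    """Square toroidal world of side ``world_size``; opposite edges wrap,
    so no point is farther than ``world_size * sqrt(2) / 2`` from another."""

    world_size: float

    def __post_init__(self) -> None:
        if self.world_size <= 0:
            raise ValueError("world_size must be > 0")

    def wrap(self, xy: Sequence[float]) -> tuple[float, float]:
        L = self.world_size
        return (xy[0] % L, xy[1] % L)


def toroidal_distance(
    p: Sequence[float], q: Sequence[float], geom: TorusGeometry
) -> float:
    """Euclidean distance with per-axis wrap-around.

    Each axis separation is ``min(|p_i - q_i|, L - |p_i - q_i|)``.
    """
    L = geom.world_size
    dx = abs(p[0] - q[0])
    if dx > L - dx:
        dx = L - dx
    dy = abs(p[1] - q[1])
    if dy > L - dy:
        dy = L - dy
    return math.hypot(dx, dy)


def _pick_min(keys: Sequence[float], ids: Sequence[int], rng: np.random.Generator) -> int:
    """Id attaining the minimal key; exact ties resolved uniformly."""
    best = min(keys)
    tied = [i for i, k in zip(ids, keys) if k == best]
    if len(tied) == 1:
        return tied[0]
    return int(tied[int(rng.integers(len(tied)))])


def choose_by_tag(
    actor_tag: float,
    candidates: Sequence[tuple[int, float]],
    rng: np.random.Generator,
) -> int:
    """Return the candidate id whose tag is most similar to the actor's.

    ``candidates`` is a non-empty sequence of ``(id, tag)`` pairs; the
    winner minimizes ``|actor_tag - tag|``, ties broken uniformly at random.
    """
    if len(candidates) == 0:
        raise ValueError("candidate list must be non-empty")
    ids = [c[0] for c in candidates]
    keys = [abs(actor_tag - c[1]) for c in candidates]
    return _pick_min(keys, ids, rng)


def choose_by_proximity(
    actor: Agent,
    candidates: Sequence[Agent],
    geom: TorusGeometry,
    rng: np.random.Generator,
) -> int:
    """Return the id of the toroidally nearest candidate to the actor.

    Ties (equally close candidates) are resolved uniformly at random, as
    the proximity rule prescribes.
    """
    if len(candidates) == 0:
        raise ValueError("candidate list must be non-empty")
    p = actor.position
    ids = [c.id for c in candidates]
    keys = [toroidal_distance(p, c.position, geom) for c in candidates]
    return _pick_min(keys, ids, rng)


def random_walk(
    position: Sequence[float], geom: TorusGeometry, rng: np.random.Generator
) -> tuple[float, float]:
    """One unit-length step in a uniformly random direction, wrapped.

    The heading is a continuous uniform angle on [0, 2*pi); the toroidal
    displacement magnitude is exactly 1 (provided L > 2).
    """
    theta = rng.random() * _TWO_PI
    L = geom.world_size
    return ((position[0] + math.cos(theta)) % L, (position[1] + math.sin(theta)) % L)
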