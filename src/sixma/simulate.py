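"""Synthetic labeled 6mA-window generator.

Emulates the structure of published 6mA benchmark sets: fixed-length windows
(default 41 nt) with the candidate adenine fixed at the center, a positive
class carrying position-specific composition biases around the center, and a
negative class drawn from a uniform background.

The positive-class signal is a per-position mixture: at each *informative*
position the base is drawn from ``(1 - bias) * Uniform(ACGT) + bias *
point-mass(preferred base)``, where the preferred base of each informative
position is itself drawn once, deterministically, from the seed. ``bias=0``
makes the two classes identically distributed (a null dataset); ``bias=1``
plants a deterministic motif.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import LabeledDataset, SequenceRecord, VALID_BASES
from .errors import ParameterError

BASES = np.array(list("ACGT"))


def default_informative_positions(length: int, halfwidth: int = 5) -> tuple[int, ...]:
    """1-based positions within ±halfwidth of the center, center excluded."""
    center = (length + 1) // 2
    return tuple(
        p for p in range(center - halfwidth, center + halfwidth + 1)
        if p != center and 1 <= p <= length
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Parameters
    ----------
    n_pos, n_neg
        Class sizes.
    bias
        Strength of the planted position-specific composition difference,
        in [0, 1].
    length
        Window length (odd when a center base is fixed); default 41.
    center_base
        Base fixed at the central position of every window (default A,
        the candidate methylation site).
    informative_positions
        1-based positions carrying the bias; default: within ±5 of the
        center, excluding the center itself.
    seed
        Seed for all randomness, including the per-position preferred bases.
    """

    n_pos: int
    n_neg: int
    bias: float
    length: int = 41
    center_base: str = "A"
    informative_positions: tuple[int, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.bias <= 1.0):
            raise ParameterError(f"bias must lie in [0, 1], got {self.bias}")
        if self.n_pos < 0 or self.n_neg < 0:
            raise ParameterError("n_pos and n_neg must be non-negative")
        if self.length < 3:
            raise ParameterError(f"length must be >= 3, got {self.length}")
        if self.center_base is not None:
            if self.center_base not in VALID_BASES:
                raise ParameterError(f"center_base must be one of A,C,G,T, got {self.center_base!r}")
            if self.length % 2 == 0:
                raise ParameterError(
                    f"length must be odd when a center base is fixed, got {self.length}"
                )
        pos = self.informative_positions
        if pos is None:
            pos = default_informative_positions(self.length)
        pos = tuple(sorted(set(int(p) for p in pos)))
        center = (self.length + 1) // 2
        for p in pos:
            if not (1 <= p <= self.length):
                raise ParameterError(f"informative position {p} outside 1..{self.length}")
            if self.center_base is not None and p == center:
                raise ParameterError(f"informative position {p} collides with the fixed center")
        object.__setattr__(self, "informative_positions", pos)

    @property
    def center(self) -> int:
        """1-based center position."""
        return (self.length + 1) // 2


def informative_phi_positions(cfg: SimulationConfig) -> tuple[int, ...]:
    """1-based trinucleotide start positions whose window overlaps an
    informative sequence position (the feature positions of the
    position-specific trinucleotide encoding that carry planted signal)."""
    info = set(cfg.informative_positions)
    return tuple(
        u for u in range(1, cfg.length - 1)
        if {u, u + 1, u + 2} & info
    )


def preferred_bases(cfg: SimulationConfig) -> dict[int, str]:
    """Per-informative-position preferred base, deterministic in the seed."""
    rng = np.random.default_rng(cfg.seed)
    draws = rng.integers(0, 4, size=len(cfg.informative_positions))
    return {p: str(BASES[d]) for p, d in zip(cfg.informative_positions, draws)}


def simulate_dataset(cfg: SimulationConfig) -> LabeledDataset:
    """Generate ``n_pos + n_neg`` windows (positives first) under *cfg*.

    Identical config (including seed) yields a bit-identical dataset.
    """
    rng = np.random.default_rng(cfg.seed)
    # Preferred-base draw consumes the first rng values so that
    # preferred_bases(cfg) matches what the generator actually used.
    pref_idx = rng.integers(0, 4, size=len(cfg.informative_positions))
    pref = dict(zip(cfg.informative_positions, pref_idx))

    n, L = cfg.n_pos + cfg.n_neg, cfg.length
    base_idx = rng.integers(0, 4, size=(n, L))

    if cfg.bias > 0 and cfg.informative_positions:
        take_pref = rng.random(size=(cfg.n_pos, len(cfg.informative_positions))) < cfg.bias
        for j, p in enumerate(cfg.informative_positions):
            col = base_idx[: cfg.n_pos, p - 1]
            col[take_pref[:, j]] = pref[p]

    if cfg.center_base is not None:
        base_idx[:, cfg.center - 1] = int(np.where(BASES == cfg.center_base)[0][0])

    seqs = ["".join(BASES[row]) for row in base_idx]
    records = [
        SequenceRecord(id=f"pos_{i + 1}", seq=seqs[i], label=1) for i in range(cfg.n_pos)
    ] + [
        SequenceRecord(id=f"neg_{i + 1}", seq=seqs[cfg.n_pos + i], label=0)
        for i in range(cfg.n_neg)
    ]
    return LabeledDataset(records)
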