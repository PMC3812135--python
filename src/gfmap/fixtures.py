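"""Deterministic sequence generators for tests, demos and benchmarks.

Everything here is a pure function of its arguments (seeds included): the
worked 40-bp artificial circle, i.i.d. random sequences with controlled
base composition, rotations (cutting-point changes) and linear slices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BASE_ORDER, NucleotideSequence

__all__ = [
    "ARTIFICIAL_40MER",
    "CompositionSpec",
    "artificial_sequence",
    "random_sequence",
    "rotate",
    "subsequence",
]

#: Worked example: four repeats of a 10-mer on a 40-base circle.  Base
#: composition c_A=12, c_C=16, c_G=8, c_T=4.
ARTIFICIAL_40MER = "ACACTGACGC" * 4


@dataclass(frozen=True)
class CompositionSpec:
    """I.i.d. base composition for a random sequence.

    fractions are (A, C, G, T) probabilities summing to one.
    """

    fractions: tuple[float, float, float, float]
    length: int
    seed: int

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if any(f < 0 for f in self.fractions):
            raise ValueError("fractions must be non-negative")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {sum(self.fractions)}, expected 1")


def artificial_sequence() -> NucleotideSequence:
    """The 40-bp worked-example circle (10 distinct fingerprint points)."""
    return NucleotideSequence(id="artificial-40mer", residues=ARTIFICIAL_40MER)


def random_sequence(spec: CompositionSpec, id: str | None = None) -> NucleotideSequence:
    """I.i.d. draw of `length` bases with the given composition; seeded."""
    rng = np.random.default_rng(spec.seed)
    draws = rng.choice(np.frombuffer(BASE_ORDER.encode(), dtype=np.uint8),
                       size=spec.length, p=list(spec.fractions))
    residues = draws.tobytes().decode("ascii")
    if id is None:
        id = f"random-n{spec.length}-seed{spec.seed}"
    return NucleotideSequence(id=id, residues=residues)


def rotate(seq: NucleotideSequence, k: int) -> NucleotideSequence:
    """Re-cut the circle to start at position k+1 of the original.

    The fingerprint coordinates of each physical base are invariant under
    this operation; the resulting track is the cyclic shift by k.
    """
    k %= seq.n_bases
    return NucleotideSequence(
        id=f"{seq.id}+rot{k}",
        residues=seq.residues[k:] + seq.residues[:k],
        topology=seq.topology,
    )


def subsequence(seq: NucleotideSequence, start: int, end: int) -> NucleotideSequence:
    """1-based inclusive slice, treated circularly thereafter like any sequence."""
    if not (1 <= start <= end <= seq.n_bases):
        raise ValueError(
            f"slice [{start}, {end}] out of range for length {seq.n_bases}"
        )
    return NucleotideSequence(
        id=f"{seq.id}[{start}:{end}]",
        residues=seq.residues[start - 1 : end],
        topology=seq.topology,
    )
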