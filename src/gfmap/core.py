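"""Per-base genome fingerprint coordinates from circular relative distances.

Every base ``n`` of a sequence of length ``N`` receives a coordinate triple
``(x_n, y_n, z_n)`` built from the *sum of weighted relative distances*
(SWRD): for each base class B in {A, C, G, T},

    SWRD_B(n) = sum over positions m with residue B of RD(n, m) / N,

where RD(n, m) = ((m - n) mod N), with N substituted when the modulus is
zero (the focusing base has travelled the full circle back to the target
base).  The triple combines the four class sums the way the Z-curve does:

    x = (SWRD_A + SWRD_G) - (SWRD_C + SWRD_T)   (purine - pyrimidine)
    y = (SWRD_A + SWRD_C) - (SWRD_G + SWRD_T)   (amino  - keto)
    z = (SWRD_A + SWRD_T) - (SWRD_G + SWRD_C)   (weak   - strong)

Because RD is circular, the coordinates assigned to each physical base are
invariant under any rotation of the sequence (choice of cutting point); the
classic cumulative-count Z-curve (:func:`zcurve_track`) is not, which is the
contrast the fingerprint exists to fix.

Two engines produce identical tracks: a literal double-loop O(N^2) oracle
(:func:`fingerprint_naive`) and an O(N) incremental recurrence
(:func:`fingerprint_incremental`).  Both accumulate *unscaled integer* RD
sums and divide by N only when emitting coordinates, so engine equality,
rotation invariance and the conservation law

    sum_B SWRD_B(n) = (N + 1) / 2        (unambiguous sequences)

all hold exactly, not merely to floating tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

__all__ = [
    "BASE_ORDER",
    "AMBIGUITY",
    "NucleotideSequence",
    "SWRDProfile",
    "FingerprintTrack",
    "ZCurveTrack",
    "relative_distance",
    "weighted_relative_distance",
    "swrd_profile",
    "fingerprint_naive",
    "fingerprint_incremental",
    "zcurve_track",
    "class_sums_naive",
    "class_sums_incremental",
    "composition_center",
]

#: Fixed column order for per-class accumulators.
BASE_ORDER = "ACGT"

#: Placeholder residue for any IUPAC ambiguity symbol.  It occupies a
#: position (contributing to N and to every relative distance) but belongs
#: to no base class, so it adds zero to every SWRD component.
AMBIGUITY = "N"

_ALLOWED = frozenset(BASE_ORDER + AMBIGUITY)

# int64 is safe while the largest accumulator N*(N+1)/2 fits; beyond this
# the engines fall back to Python integers.
_INT64_SAFE_N = 4_000_000_000


@dataclass(frozen=True)
class NucleotideSequence:
    """A normalized nucleotide sequence: uppercase A/C/G/T plus 'N'.

    The topology flag is recorded metadata only; the circular relative
    distance treats every sequence as circular, so no computation branches
    on it.
    """

    id: str
    residues: str
    topology: str = "circular"

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"unknown topology {self.topology!r}")
        bad = set(self.residues) - _ALLOWED
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-normalized symbols "
                f"{sorted(bad)}; normalize before constructing"
            )

    @property
    def n_bases(self) -> int:
        return len(self.residues)

    def base_counts(self) -> dict[str, int]:
        """Counts of A, C, G, T (ambiguity placeholders excluded)."""
        return {b: self.residues.count(b) for b in BASE_ORDER}

    def class_indicator(self) -> np.ndarray:
        """(N, 4) 0/1 matrix; column order A, C, G, T; 'N' rows all zero."""
        arr = np.frombuffer(self.residues.encode("ascii"), dtype=np.uint8)
        return np.stack(
            [(arr == ord(b)).astype(np.int64) for b in BASE_ORDER], axis=1
        )


@dataclass(frozen=True)
class SWRDProfile:
    """Per-class weighted circular-distance sums for one target base."""

    swrd_a: float
    swrd_c: float
    swrd_g: float
    swrd_t: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.swrd_a, self.swrd_c, self.swrd_g, self.swrd_t)

    @property
    def total(self) -> float:
        return self.swrd_a + self.swrd_c + self.swrd_g + self.swrd_t


@dataclass(frozen=True)
class FingerprintTrack:
    """Ordered per-base coordinate triples: the genome fingerprint.

    ``coords`` is an (N, 3) float array.  When produced by an engine (rather
    than read back from disk) ``numerators`` holds the exact integer values
    ``coords * N``, enabling bit-exact comparisons.
    """

    sequence_id: str
    bases: str
    coords: np.ndarray
    engine: str
    numerators: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if len(self.coords) == 0:
            raise ValueError("empty fingerprint track")
        if self.coords.shape != (len(self.bases), 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match "
                f"{len(self.bases)} bases"
            )

    @property
    def n_bases(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class ZCurveTrack:
    """Classic cumulative-count Z-curve coordinates (integer valued).

    Retained as the linear baseline: its track depends on where the
    deposited sequence was cut, unlike the fingerprint.
    """

    sequence_id: str
    bases: str
    coords: np.ndarray

    @property
    def n_bases(self) -> int:
        return len(self.bases)


def _check_position(name: str, value: int, n_bases: int) -> None:
    if not 1 <= value <= n_bases:
        raise ValueError(f"{name}={value} out of range 1..{n_bases}")


def relative_distance(n: int, m: int, n_bases: int) -> int:
    """Circular distance from target base n to focusing base m, in 1..N.

    ``(m - n) mod N``, except that m == n yields N (the focusing base has
    gone once around the circle), never zero.
    """
    _check_position("n", n, n_bases)
    _check_position("m", m, n_bases)
    rd = (m - n) % n_bases
    return n_bases if rd == 0 else rd


def weighted_relative_distance(n: int, m: int, n_bases: int) -> float:
    """Relative distance scaled into (0, 1] by the sequence length."""
    return relative_distance(n, m, n_bases) / n_bases


def _int_class_sums_at(seq: NucleotideSequence, n: int) -> np.ndarray:
    """Unscaled integer RD sums per class (A, C, G, T) for target base n."""
    nb = seq.n_bases
    rd = (np.arange(1, nb + 1, dtype=np.int64) - n) % nb
    rd[rd == 0] = nb
    return rd @ seq.class_indicator()


def swrd_profile(seq: NucleotideSequence, n: int) -> SWRDProfile:
    """SWRD components for target base ``n`` (1-based)."""
    _check_position("n", n, seq.n_bases)
    a, c, g, t = (_int_class_sums_at(seq, n) / seq.n_bases).tolist()
    return SWRDProfile(swrd_a=a, swrd_c=c, swrd_g=g, swrd_t=t)


def _coords_from_class_sums(sums: np.ndarray, n_bases: int) -> tuple[np.ndarray, np.ndarray]:
    """Combine integer class sums (N, 4) into numerators and float coords."""
    a, c, g, t = (sums[:, i] for i in range(4))
    numerators = np.stack(
        [(a + g) - (c + t), (a + c) - (g + t), (a + t) - (g + c)], axis=1
    )
    return numerators, numerators / n_bases


def class_sums_naive(seq: NucleotideSequence) -> np.ndarray:
    """(N, 4) integer RD sums by the literal double loop — the O(N^2) oracle.

    The inner loop over the focusing base is vectorized; the work is still
    quadratic in N.
    """
    nb = seq.n_bases
    if nb > _INT64_SAFE_N:  # pragma: no cover - guard only
        raise OverflowError("sequence too long for int64 accumulators")
    ind = seq.class_indicator()
    m_idx = np.arange(nb, dtype=np.int64)
    sums = np.empty((nb, 4), dtype=np.int64)
    for i in range(nb):  # target base n = i + 1
        rd = (m_idx - i) % nb
        rd[i] = nb
        sums[i] = rd @ ind
    return sums


def class_sums_incremental(seq: NucleotideSequence) -> np.ndarray:
    """(N, 4) integer RD sums in O(N) via the sliding-target recurrence.

    Moving the target base from n to n+1 decreases every relative distance
    by one, except the focusing base now coinciding with the target, whose
    distance jumps from 1 back to N.  In unscaled integer form:

        S_B(n+1) = S_B(n) - c_B + N * [residue(n+1) == B],

    with c_B the total count of class-B residues.  The whole profile track
    is therefore a cumulative sum over the indicator matrix.
    """
    nb = seq.n_bases
    if nb > _INT64_SAFE_N:  # pragma: no cover - guard only
        raise OverflowError("sequence too long for int64 accumulators")
    ind = seq.class_indicator()
    counts = ind.sum(axis=0)
    # Target base 1: RD(1, m) = m - 1 for m >= 2, and N for m = 1.
    rd1 = np.arange(nb, dtype=np.int64)
    rd1[0] = nb
    s1 = rd1 @ ind
    steps = np.arange(nb, dtype=np.int64)[:, None]
    return s1[None, :] - steps * counts[None, :] + nb * (
        np.cumsum(ind, axis=0) - ind[0][None, :]
    )


def _build_track(seq: NucleotideSequence, sums: np.ndarray, engine: str) -> FingerprintTrack:
    numerators, coords = _coords_from_class_sums(sums, seq.n_bases)
    return FingerprintTrack(
        sequence_id=seq.id,
        bases=seq.residues,
        coords=coords,
        engine=engine,
        numerators=numerators,
    )


def fingerprint_naive(seq: NucleotideSequence) -> FingerprintTrack:
    """Fingerprint by the double-loop definition; quadratic-time oracle."""
    return _build_track(seq, class_sums_naive(seq), "naive")


def fingerprint_incremental(seq: NucleotideSequence) -> FingerprintTrack:
    """Fingerprint by the O(N) recurrence; exactly equals the naive engine."""
    return _build_track(seq, class_sums_incremental(seq), "incremental")


def zcurve_track(seq: NucleotideSequence) -> ZCurveTrack:
    """Cumulative-count Z-curve baseline (cutting-point sensitive).

    A_n, C_n, G_n, T_n count each base class over positions 1..n; the same
    purine/amino/weak combination as the fingerprint turns them into integer
    coordinates.
    """
    cum = np.cumsum(seq.class_indicator(), axis=0)
    coords, _ = _coords_from_class_sums(cum, seq.n_bases)
    return ZCurveTrack(sequence_id=seq.id, bases=seq.residues, coords=coords)


def composition_center(seq: NucleotideSequence) -> tuple[float, float, float]:
    """Closed-form geometric center of the fingerprint track.

    Summing RD(n, m) over all targets n gives N(N+1)/2 for every focusing
    base m, so the mean of each coordinate depends only on base composition:

        mean(x) = ((c_A + c_G) - (c_C + c_T)) * (N + 1) / (2 N),

    and analogously for y (A,C vs G,T) and z (A,T vs G,C).  Components are
    returned as correctly rounded floats of the exact rationals.
    """
    c = seq.base_counts()
    nb = seq.n_bases
    factor = Fraction(nb + 1, 2 * nb)
    combos = (
        (c["A"] + c["G"]) - (c["C"] + c["T"]),
        (c["A"] + c["C"]) - (c["G"] + c["T"]),
        (c["A"] + c["T"]) - (c["G"] + c["C"]),
    )
    x, y, z = (float(k * factor) for k in combos)
    return (x, y, z)
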