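"""Summary statistics and pairwise comparison of genome fingerprints.

A fingerprint track is condensed to its geometric center (per-axis mean),
per-axis population standard deviation, and the *signed geometric mean* Gm
of the center — the side length of the cube with the same volume as the
cuboid spanned by the center, carrying the sign of the product of the
components.  Two genomes are then compared through

    Ed  = Euclidean distance between their centers,
    Dr  = 100 * |Gm_a - Gm_b| / |Gm_a + Gm_b|   (percent),
    WDr = Dr * Ed,

where Dr is undefined (flagged, never raised) when the geometric means
cancel exactly.  Chain comparison pairs each genome with the next one in a
given ordering, the convention used for multi-taxon report tables; the full
pairwise matrix is also available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .core import FingerprintTrack

__all__ = [
    "GeometricSummary",
    "PairComparison",
    "summarize_track",
    "geometric_mean_signed",
    "euclidean_distance",
    "differentiate_rate",
    "weighted_differentiate_rate",
    "compare_pair",
    "compare_chain",
    "compare_all_pairs",
]

Triple = tuple[float, float, float]


@dataclass(frozen=True)
class GeometricSummary:
    """Per-genome fingerprint statistics."""

    id: str
    n_bases: int
    center: Triple
    sd: Triple
    gm: float


@dataclass(frozen=True)
class PairComparison:
    """Ed / Dr / WDr for an ordered pair of genome summaries.

    ``dr`` and ``wdr`` are None when the differentiate rate is undefined
    (geometric means summing to zero).  A fully-None comparison (``ed`` also
    None, ``id_b`` None) marks the trailing empty row of a chain report.
    """

    id_a: str
    id_b: str | None
    ed: float | None
    dr: float | None
    wdr: float | None

    @property
    def dr_defined(self) -> bool:
        return self.dr is not None

    @property
    def is_empty(self) -> bool:
        return self.id_b is None


def geometric_mean_signed(center: Triple) -> float:
    """Signed cube root of the product of the center components.

    Zero whenever any component is zero; otherwise the magnitude is the
    cube root of |x*y*z| and the sign is the sign of the product.
    """
    x, y, z = center
    if x == 0.0 or y == 0.0 or z == 0.0:
        return 0.0
    return float(np.cbrt(x * y * z))


def summarize_track(track: FingerprintTrack, id: str | None = None) -> GeometricSummary:
    """Geometric center, per-axis population SD, and Gm of a track.

    When the track carries exact integer numerators the center components
    are computed as correctly rounded floats of the exact rational means,
    so they match :func:`gfmap.core.composition_center` bit for bit.
    """
    if len(track.coords) == 0:
        raise ValueError("cannot summarize an empty track")
    nb = track.n_bases
    if track.numerators is not None:
        sums = track.numerators.sum(axis=0, dtype=object)
        center = tuple(float(Fraction(int(s), nb * nb)) for s in sums)
    else:
        center = tuple(float(v) for v in track.coords.mean(axis=0))
    sd = tuple(float(v) for v in track.coords.std(axis=0))  # divisor N
    return GeometricSummary(
        id=id if id is not None else track.sequence_id,
        n_bases=nb,
        center=center,  # type: ignore[arg-type]
        sd=sd,  # type: ignore[arg-type]
        gm=geometric_mean_signed(center),  # type: ignore[arg-type]
    )


def euclidean_distance(center_a: Triple, center_b: Triple) -> float:
    return math.dist(center_a, center_b)


def differentiate_rate(gm_a: float, gm_b: float) -> float | None:
    """Percent difference of two signed geometric means.

    ``100 * |gm_a - gm_b| / |gm_a + gm_b|``; None (undefined) when the
    denominator vanishes, including the all-zero case.  Opposite signs that
    nearly cancel blow the rate up — by design, since genomes whose centers
    sit in different octants are geometrically far apart.
    """
    denom = gm_a + gm_b
    if denom == 0.0:
        return None
    return 100.0 * abs(gm_a - gm_b) / abs(denom)


def weighted_differentiate_rate(dr: float | None, ed: float) -> float | None:
    """Dr (percent, full precision) times Ed; undefined propagates."""
    if dr is None:
        return None
    return dr * ed


def compare_pair(a: GeometricSummary, b: GeometricSummary) -> PairComparison:
    ed = euclidean_distance(a.center, b.center)
    dr = differentiate_rate(a.gm, b.gm)
    return PairComparison(
        id_a=a.id, id_b=b.id, ed=ed, dr=dr, wdr=weighted_differentiate_rate(dr, ed)
    )


def compare_chain(summaries: list[GeometricSummary]) -> list[PairComparison]:
    """Adjacent-pair comparisons in listed order.

    Row i compares summary i with summary i+1 and is reported on summary
    i's row; the final summary gets an empty comparison (rendered "/" in
    report tables).
    """
    if len(summaries) < 2:
        raise ValueError("chain comparison needs at least 2 summaries")
    rows = [compare_pair(a, b) for a, b in zip(summaries, summaries[1:])]
    rows.append(
        PairComparison(id_a=summaries[-1].id, id_b=None, ed=None, dr=None, wdr=None)
    )
    return rows


def compare_all_pairs(summaries: list[GeometricSummary]) -> list[list[PairComparison]]:
    """Full comparison matrix; symmetric in Ed and Dr, zero on the diagonal."""
    if len(summaries) < 2:
        raise ValueError("pairwise comparison needs at least 2 summaries")
    return [[compare_pair(a, b) for b in summaries] for a in summaries]
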