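"""Genome fingerprint maps: 3D primary map, six 2D projections, overlays.

The primary map (P-GFM) plots the (x, y, z) trajectory of one track in 3D.
The secondary maps (S-GFM) are the six 2D projections x~y, x~z, y~z, x~n,
y~n, z~n, rendered as one fixed-order panel figure.  The universal map
(UGFM) overlays many tracks in a single 3D scene, colored and legended by a
TGCC manifest grouping (strain, component type or category), so replicons
of very different sizes can be compared in one sitting.

Tracks are decimated before plotting (default cap 1e5 points per track);
decimation always keeps the first and last point.  SVG output is
deterministic: repeated runs with the same style yield identical bytes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt

from .core import FingerprintTrack
from .io import ManifestWarning, TGCCManifest

__all__ = [
    "VIEWS",
    "MAX_POINTS_PER_TRACK",
    "ProjectionSpec",
    "decimate_track",
    "auto_stride",
    "plot_primary",
    "plot_secondary",
    "plot_ugfm",
]

VIEWS = ("xyz3d", "x~n", "y~n", "z~n", "x~y", "x~z", "y~z")

#: Cap on plotted points per track; larger tracks are strided down.
MAX_POINTS_PER_TRACK = 100_000

_SECONDARY_ORDER = ("x~y", "x~z", "y~z", "x~n", "y~n", "z~n")
_AXIS = {"x": 0, "y": 1, "z": 2}

# Deterministic SVG ids across runs; keep text as text so labels and
# legends stay searchable in the output.
matplotlib.rcParams["svg.hashsalt"] = "gfmap"
matplotlib.rcParams["svg.fonttype"] = "none"

_SAVEFIG_KW = {"metadata": {"Date": None}}


@dataclass(frozen=True)
class ProjectionSpec:
    """Which projection to draw, at what decimation, with what styling."""

    view: str = "xyz3d"
    stride: int = 1
    style: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.view not in VIEWS:
            raise ValueError(f"unknown view {self.view!r}; choose from {VIEWS}")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")


def auto_stride(n_points: int, cap: int = MAX_POINTS_PER_TRACK) -> int:
    return max(1, -(-n_points // cap))


def decimate_track(track: FingerprintTrack, stride: int) -> FingerprintTrack:
    """Every stride-th point, first and last always retained; input unchanged."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if stride == 1:
        return track
    nb = track.n_bases
    idx = list(range(0, nb, stride))
    if idx[-1] != nb - 1:
        idx.append(nb - 1)
    return FingerprintTrack(
        sequence_id=track.sequence_id,
        bases="".join(track.bases[i] for i in idx),
        coords=track.coords[idx].copy(),
        engine=track.engine,
        numerators=None if track.numerators is None else track.numerators[idx].copy(),
    )


def _check_track(track: FingerprintTrack) -> None:
    if track is None or len(track.coords) == 0:
        raise ValueError("cannot plot an empty track")


def _savefig(fig, path: str | Path) -> None:
    fig.savefig(path, **_SAVEFIG_KW)
    plt.close(fig)


def plot_primary(
    track: FingerprintTrack,
    spec: ProjectionSpec | None = None,
    path: str | Path = "pgfm.svg",
) -> Path:
    """Primary genome fingerprint map: one 3D trajectory plot."""
    _check_track(track)
    spec = spec or ProjectionSpec()
    if spec.view != "xyz3d":
        raise ValueError(f"primary map requires view 'xyz3d', got {spec.view!r}")
    dec = decimate_track(track, spec.stride)
    fig = plt.figure(figsize=(7, 6))
    ax = fig.add_subplot(projection="3d")
    x, y, z = dec.coords.T
    ax.plot(x, y, z, lw=0.5, **({"color": spec.style["color"]} if "color" in spec.style else {}))
    ax.scatter(x, y, z, s=4)
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    ax.set_zlabel("z")
    ax.set_title(f"{track.sequence_id} (N={track.n_bases})")
    _savefig(fig, path)
    return Path(path)


def plot_secondary(
    track: FingerprintTrack,
    path: str | Path = "sgfm.svg",
    stride: int = 1,
) -> Path:
    """Six-panel secondary maps in fixed order x~y, x~z, y~z, x~n, y~n, z~n."""
    _check_track(track)
    dec = decimate_track(track, stride)
    n_pos = [i + 1 for i in range(track.n_bases)]
    if stride > 1:
        idx = list(range(0, track.n_bases, stride))
        if idx[-1] != track.n_bases - 1:
            idx.append(track.n_bases - 1)
        n_pos = [i + 1 for i in idx]
    fig, axes = plt.subplots(2, 3, figsize=(12, 7))
    for ax, view in zip(axes.ravel(), _SECONDARY_ORDER):
        a, b = view.split("~")
        xs = dec.coords[:, _AXIS[a]]
        ys = n_pos if b == "n" else dec.coords[:, _AXIS[b]]
        if b == "n":
            ax.plot(ys, xs, lw=0.6)
            ax.set_xlabel("n")
            ax.set_ylabel(a)
        else:
            ax.plot(xs, ys, lw=0.6)
            ax.set_xlabel(a)
            ax.set_ylabel(b)
        ax.set_title(view)
    fig.suptitle(f"{track.sequence_id} (N={track.n_bases})")
    fig.tight_layout()
    _savefig(fig, path)
    return Path(path)


def plot_ugfm(
    tracks: list[FingerprintTrack],
    manifest: TGCCManifest | None = None,
    path: str | Path = "ugfm.svg",
    group_by: str = "strain",
) -> Path:
    """Universal map: all tracks overlaid in one 3D scene.

    With a manifest, tracks are colored and legended by the chosen grouping
    key; tracks the manifest does not cover fall back to per-track styling
    (with a warning).  Axes autoscale so tiny plasmid maps and multi-Mbp
    chromosome maps share the scene.
    """
    if not tracks:
        raise ValueError("need at least one track")
    for t in tracks:
        _check_track(t)
    groups: dict[str, str] = {}
    if manifest is not None:
        covered = True
        for t in tracks:
            g = manifest.group_of(t.sequence_id, key=group_by)
            if g is None:
                covered = False
            else:
                groups[t.sequence_id] = g
        if not covered:
            warnings.warn(
                "manifest does not cover all tracks; using default styling "
                "for uncovered tracks",
                ManifestWarning,
            )
    labels = [groups.get(t.sequence_id, t.sequence_id) for t in tracks]
    palette = plt.rcParams["axes.prop_cycle"].by_key()["color"]
    color_of = {lab: palette[i % len(palette)]
                for i, lab in enumerate(dict.fromkeys(labels))}
    fig = plt.figure(figsize=(8, 7))
    ax = fig.add_subplot(projection="3d")
    seen: set[str] = set()
    for t, lab in zip(tracks, labels):
        dec = decimate_track(t, auto_stride(t.n_bases))
        x, y, z = dec.coords.T
        ax.plot(x, y, z, lw=0.5, color=color_of[lab],
                label=None if lab in seen else lab)
        seen.add(lab)
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    ax.set_zlabel("z")
    ax.legend(loc="upper left", fontsize=7)
    ax.set_title(f"UGFM ({len(tracks)} tracks)")
    _savefig(fig, path)
    return Path(path)
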