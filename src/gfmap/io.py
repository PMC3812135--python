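"""FASTA input, sequence normalization, and the tabular interchange files.

All tables are TSV (UTF-8, '#' comment lines, ASCII minus signs):

* coordinate tables — one fingerprint track, columns ``n base x y z`` with
  1-based positions and full-precision coordinates, preceded by commented
  header lines recording the sequence id, length and engine;
* summary tables — one row per genome with full-precision center, SD and
  Gm columns plus 2-decimal display columns;
* comparison reports — the taxon/center/Gm/Dr/WDr/Ed layout with "/" for
  undefined or trailing-empty entries;
* TGCC manifests — sequence_id / source_file / strain / component_type /
  category rows assigning each replicon to a strain and grouping keys.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .core import AMBIGUITY, FingerprintTrack, NucleotideSequence
from .stats import GeometricSummary, PairComparison

__all__ = [
    "TGCCManifest",
    "ManifestWarning",
    "normalize_residues",
    "read_fasta",
    "write_fasta",
    "write_coordinate_table",
    "read_coordinate_table",
    "write_summary_table",
    "read_summary_table",
    "write_comparison_table",
    "read_manifest",
    "write_manifest",
]

COMPONENT_TYPES = frozenset({"chromosome", "plasmid", "phage"})
CATEGORIES = frozenset({"bacteria", "archaea", "virus"})
MANIFEST_COLUMNS = ["sequence_id", "source_file", "strain", "component_type", "category"]

# IUPAC nucleotide one-letter codes beyond A/C/G/T/U; all collapse to the
# single ambiguity placeholder.
_IUPAC_AMBIGUOUS = set("RYSWKMBDHVN")


class ManifestWarning(UserWarning):
    """Non-fatal manifest/FASTA mismatch (e.g. manifest id without a record)."""


@dataclass(frozen=True)
class TGCCManifest:
    """Total-genetic-component-configuration table.

    Maps each sequence record to a strain, a genetic-component type
    (chromosome / plasmid / phage) and a biological category (bacteria /
    archaea / virus), so that multi-replicon strains can be grouped,
    colored and compared as one systematic unit.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in MANIFEST_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"manifest missing column(s): {', '.join(missing)}")
        ids = self.table["sequence_id"]
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique())
            raise ValueError(f"duplicate sequence_id values in manifest: {dupes}")
        bad_ct = sorted(set(self.table["component_type"]) - COMPONENT_TYPES)
        if bad_ct:
            raise ValueError(
                f"unknown component_type value(s) {bad_ct}; "
                f"allowed: {sorted(COMPONENT_TYPES)}"
            )
        bad_cat = sorted(set(self.table["category"]) - CATEGORIES)
        if bad_cat:
            raise ValueError(
                f"unknown category value(s) {bad_cat}; allowed: {sorted(CATEGORIES)}"
            )

    def __len__(self) -> int:
        return len(self.table)

    @property
    def strains(self) -> list[str]:
        return list(dict.fromkeys(self.table["strain"]))

    def group_of(self, sequence_id: str, key: str = "strain") -> str | None:
        if key not in ("strain", "component_type", "category"):
            raise ValueError(f"unknown grouping key {key!r}")
        rows = self.table[self.table["sequence_id"] == sequence_id]
        return None if rows.empty else str(rows.iloc[0][key])

    def check_coverage(self, sequence_ids: list[str]) -> None:
        """Warn (do not fail) about ids present on one side only."""
        known = set(self.table["sequence_id"])
        for missing in sorted(set(sequence_ids) - known):
            warnings.warn(
                f"sequence {missing!r} has no manifest row", ManifestWarning
            )
        for orphan in sorted(known - set(sequence_ids)):
            warnings.warn(
                f"manifest row {orphan!r} matches no sequence", ManifestWarning
            )


def normalize_residues(raw: str, record_id: str = "?") -> str:
    """Uppercase, map U->T (RNA), collapse IUPAC ambiguity codes to 'N'.

    Rejects, with the 1-based offending position, any symbol outside the
    IUPAC nucleotide alphabet.
    """
    out = []
    for pos, ch in enumerate(raw.upper(), start=1):
        if ch in "ACGT":
            out.append(ch)
        elif ch == "U":
            out.append("T")
        elif ch in _IUPAC_AMBIGUOUS:
            out.append(AMBIGUITY)
        else:
            raise ValueError(
                f"record {record_id!r}: symbol {ch!r} at position {pos} "
                "is not an IUPAC nucleotide code"
            )
    return "".join(out)


def read_fasta(path: str | Path, topology: str = "circular") -> list[NucleotideSequence]:
    """Read a (multi-record) FASTA file into normalized sequences."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    seqs: list[NucleotideSequence] = []
    for record in SeqIO.parse(str(path), "fasta"):
        raw = str(record.seq)
        if not raw:
            raise ValueError(f"record {record.id!r} in {path} is empty")
        seqs.append(
            NucleotideSequence(
                id=record.id,
                residues=normalize_residues(raw, record.id),
                topology=topology,
            )
        )
    return seqs


def write_fasta(seqs: list[NucleotideSequence], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, s.n_bases, width):
                fh.write(s.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Coordinate tables


def write_coordinate_table(track: FingerprintTrack, path: str | Path) -> None:
    """Serialize one track with full-precision (repr) coordinates."""
    if len(track.coords) == 0:
        raise ValueError("refusing to write an empty track")
    with open(path, "w") as fh:
        fh.write(f"# sequence_id: {track.sequence_id}\n")
        fh.write(f"# N: {track.n_bases}\n")
        fh.write(f"# engine: {track.engine}\n")
        fh.write("n\tbase\tx\ty\tz\n")
        for i, (base, row) in enumerate(zip(track.bases, track.coords), start=1):
            x, y, z = (float(v) for v in row)
            fh.write(f"{i}\t{base}\t{x!r}\t{y!r}\t{z!r}\n")


def _recover_numerators(coords: np.ndarray, n_bases: int) -> np.ndarray | None:
    """Recover exact integer numerators from round-tripped coordinates."""
    cand = np.rint(coords * n_bases)
    if np.all(np.abs(cand) < 2**52) and np.array_equal(cand / n_bases, coords):
        return cand.astype(np.int64)
    return None


def read_coordinate_table(path: str | Path) -> FingerprintTrack:
    """Exact inverse of :func:`write_coordinate_table`."""
    path = Path(path)
    header: dict[str, str] = {}
    rows: list[tuple[int, str, float, float, float]] = []
    with open(path) as fh:
        saw_columns = False
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition(":")
                header[key.strip()] = value.strip()
                continue
            parts = line.split("\t")
            if not saw_columns:
                if parts != ["n", "base", "x", "y", "z"]:
                    raise ValueError(
                        f"{path}:{lineno}: malformed column header {parts}"
                    )
                saw_columns = True
                continue
            try:
                rows.append(
                    (int(parts[0]), parts[1], float(parts[2]), float(parts[3]), float(parts[4]))
                )
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed data row") from exc
    for key in ("sequence_id", "N", "engine"):
        if key not in header:
            raise ValueError(f"{path}: missing '# {key}:' header line")
    n_declared = int(header["N"])
    if [r[0] for r in rows] != list(range(1, len(rows) + 1)):
        raise ValueError(f"{path}: position column must run 1..N in order")
    if len(rows) != n_declared:
        raise ValueError(
            f"{path}: header declares N={n_declared} but {len(rows)} rows present"
        )
    coords = np.array([[r[2], r[3], r[4]] for r in rows], dtype=float)
    return FingerprintTrack(
        sequence_id=header["sequence_id"],
        bases="".join(r[1] for r in rows),
        coords=coords,
        engine=header["engine"],
        numerators=_recover_numerators(coords, n_declared),
    )


# ---------------------------------------------------------------------------
# Summary tables

_SUMMARY_COLUMNS = [
    "id", "N", "x_mean", "y_mean", "z_mean", "sd_x", "sd_y", "sd_z", "gm",
]


def write_summary_table(summaries: list[GeometricSummary], path: str | Path) -> None:
    """One row per genome: 9 full-precision columns + 2-decimal display columns."""
    if not summaries:
        raise ValueError("refusing to write an empty summary table")
    with open(path, "w") as fh:
        fh.write("# genome fingerprint summaries\n")
        display = ["x_mean_2dp", "y_mean_2dp", "z_mean_2dp", "gm_2dp"]
        fh.write("\t".join(_SUMMARY_COLUMNS + display) + "\n")
        for s in summaries:
            full = [
                s.id, str(s.n_bases),
                repr(s.center[0]), repr(s.center[1]), repr(s.center[2]),
                repr(s.sd[0]), repr(s.sd[1]), repr(s.sd[2]), repr(s.gm),
            ]
            disp = [f"{s.center[0]:.2f}", f"{s.center[1]:.2f}",
                    f"{s.center[2]:.2f}", f"{s.gm:.2f}"]
            fh.write("\t".join(full + disp) + "\n")


def read_summary_table(path: str | Path) -> list[GeometricSummary]:
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    missing = [c for c in _SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing summary column(s) {missing}")
    return [
        GeometricSummary(
            id=str(row["id"]),
            n_bases=int(row["N"]),
            center=(row["x_mean"], row["y_mean"], row["z_mean"]),
            sd=(row["sd_x"], row["sd_y"], row["sd_z"]),
            gm=float(row["gm"]),
        )
        for _, row in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# Comparison reports


def _fmt(value: float | None) -> str:
    return "/" if value is None else f"{value:.2f}"


def write_comparison_table(
    summaries: list[GeometricSummary],
    comparisons: list[PairComparison],
    path: str | Path,
) -> None:
    """Report table: per-genome center and Gm plus the comparison columns.

    For chain mode, comparison i sits on the row of its first genome and the
    last row carries "/" entries; for a matrix, pass flattened rows.
    """
    if len(summaries) != len(comparisons):
        raise ValueError("one comparison row per summary required")
    with open(path, "w") as fh:
        fh.write("# genome fingerprint comparison report\n")
        fh.write("taxon\tx_mean\ty_mean\tz_mean\tgm\tdr\twdr\ted\n")
        for s, cmp_row in zip(summaries, comparisons):
            fh.write(
                "\t".join(
                    [
                        s.id,
                        f"{s.center[0]:.2f}", f"{s.center[1]:.2f}", f"{s.center[2]:.2f}",
                        f"{s.gm:.2f}",
                        _fmt(cmp_row.dr), _fmt(cmp_row.wdr), _fmt(cmp_row.ed),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# TGCC manifests


def read_manifest(path: str | Path) -> TGCCManifest:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    return TGCCManifest(table=df)


def write_manifest(manifest: TGCCManifest, path: str | Path) -> None:
    manifest.table.to_csv(path, sep="\t", index=False)
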