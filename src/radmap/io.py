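"""Readers and writers for the pipeline's tab-delimited file formats.

All files are UTF-8, tab-delimited, with '#'-prefixed comment lines.
The vector file is the compact RH genotype exchange format: a header line
of clone identifiers, then one line per marker holding the marker id and
its call string over {0,1,2} (one character per clone). Malformed lines
raise ``ParseError`` naming the offending line. Writers emit rows in a
deterministic order so outputs are byte-stable.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError
from .matrix import RHCallMatrix
from .ordering import OrderedGroupMap

_CALL_CHARS = {"0": 0, "1": 1, "2": 2}


# ---------------------------------------------------------------------------
# vector files
# ---------------------------------------------------------------------------

def write_vectors(matrix: RHCallMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("# RH vector file: clones header, then "
                 "marker<TAB>calls({0,1,2})\n")
        fh.write("\t".join(matrix.clones) + "\n")
        for j, marker in enumerate(matrix.markers):
            calls = "".join(str(int(c)) for c in matrix.calls[:, j])
            fh.write(f"{marker}\t{calls}\n")


def read_vectors(path: str | Path) -> RHCallMatrix:
    path = Path(path)
    clones: list[str] | None = None
    markers: list[str] = []
    rows: list[list[int]] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if clones is None:
                clones = line.split("\t")
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError("expected 'marker<TAB>calls'",
                                 str(path), lineno)
            marker, calls = parts
            if len(calls) != len(clones):
                raise ParseError(
                    f"call string for {marker} has length {len(calls)}, "
                    f"expected {len(clones)} clones", str(path), lineno)
            try:
                rows.append([_CALL_CHARS[c] for c in calls])
            except KeyError as exc:
                raise ParseError(f"invalid call character {exc.args[0]!r}",
                                 str(path), lineno) from None
            markers.append(marker)
    if clones is None:
        raise ParseError("no clone header line", str(path))
    calls = (np.array(rows, dtype=np.int8).T if rows
             else np.empty((len(clones), 0), dtype=np.int8))
    return RHCallMatrix(clones, markers, calls)


# ---------------------------------------------------------------------------
# tabular formats (TSV with '#' comments)
# ---------------------------------------------------------------------------

def _write_tsv(df: pd.DataFrame, path: str | Path, comment: str) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=False)


def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:
        raise ParseError(f"cannot parse TSV: {exc}", str(path)) from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"missing columns {missing}", str(path))
    return df


def write_genetic_map(gmap: pd.DataFrame, path: str | Path) -> None:
    out = gmap[["lg", "marker", "cm"]].sort_values(
        ["lg", "cm", "marker"], kind="stable")
    _write_tsv(out, path, "genetic map: lg, marker, cm")


def read_genetic_map(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, ["lg", "marker", "cm"])


def write_hits(hits: pd.DataFrame, path: str | Path) -> None:
    cols = ["marker", "species", "chromosome", "start", "end", "score",
            "length", "strand"]
    out = hits[cols].sort_values(["species", "marker", "chromosome",
                                  "start"], kind="stable")
    _write_tsv(out, path, "ortholog hits: " + ", ".join(cols))


def read_hits(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, ["marker", "species", "chromosome", "start",
                            "end", "score", "length"])


def write_anchors(anchors: pd.DataFrame, path: str | Path) -> None:
    out = anchors[["marker", "species", "chromosome",
                   "position"]].sort_values(
        ["species", "chromosome", "position", "marker"], kind="stable")
    _write_tsv(out, path, "anchors: marker, species, chromosome, position")


def read_anchors(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, ["marker", "species", "chromosome", "position"])


def read_overrides(path: str | Path) -> tuple[dict[str, float],
                                              dict[str, str]]:
    """Per-marker scoring overrides: marker, axis, threshold.

    Returns (threshold overrides, axis overrides) for score_intensities.
    """
    df = _read_tsv(path, ["marker", "axis", "threshold"])
    return (dict(zip(df["marker"], df["threshold"].astype(float))),
            dict(zip(df["marker"], df["axis"].astype(str))))


def write_two_point(estimates, path: str | Path) -> None:
    df = pd.DataFrame(
        [(e.marker_a, e.marker_b, e.theta, e.retention, e.lod,
          e.n_informative, e.distance_cr) for e in estimates],
        columns=["marker_a", "marker_b", "theta", "retention", "lod", "n",
                 "cr"])
    _write_tsv(df.sort_values(["marker_a", "marker_b"], kind="stable"),
               path, "two-point estimates")


def read_two_point(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, ["marker_a", "marker_b", "theta", "retention",
                            "lod", "n", "cr"])


def write_groups(groups, unlinked: list[str], path: str | Path) -> None:
    rows = [(g.group_id, m, g.lod_threshold) for g in groups
            for m in g.markers]
    rows += [("unlinked", m, "") for m in unlinked]
    _write_tsv(pd.DataFrame(rows, columns=["group", "marker",
                                           "formation_lod"]),
               path, "RH groups: group, marker, formation lod")


def write_map(maps: list[OrderedGroupMap], path: str | Path) -> None:
    """Ordered group maps; coordinates reported to 0.1 cR, co-localized
    markers comma-joined at one position."""
    rows = []
    for ogm in maps:
        positions = ogm.positions or [(float(c), [m]) for c, m in
                                      zip(ogm.coords, ogm.markers)]
        for idx, (coord, ms) in enumerate(positions):
            rows.append((ogm.group_id, idx, round(coord, 1),
                         ",".join(ms)))
    _write_tsv(pd.DataFrame(rows, columns=["group", "position", "cr",
                                           "markers"]),
               path, "RH map: group, position index, cR, markers")


def read_map(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, ["group", "position", "cr", "markers"])
    df["markers"] = df["markers"].astype(str)
    return df


def read_map_objects(path: str | Path) -> list[OrderedGroupMap]:
    """Rebuild OrderedGroupMap objects from a map TSV.

    Coordinates carry the file's 0.1 cR precision; adjacent thetas are
    re-derived from the coordinate gaps. Likelihoods are not stored in the
    format and come back as NaN.
    """
    df = read_map(path)
    out = []
    for gid, grp in df.groupby("group", sort=True):
        grp = grp.sort_values("position")
        positions = [(float(c), str(ms).split(","))
                     for c, ms in zip(grp["cr"], grp["markers"])]
        markers, coords = [], []
        for c, ms in positions:
            for m in ms:
                markers.append(m)
                coords.append(c)
        coords = np.asarray(coords, dtype=float)
        thetas = 1.0 - np.exp(-np.diff(coords) / 100.0)
        out.append(OrderedGroupMap(str(gid), markers, thetas, coords,
                                   float("nan"), float("nan"), positions))
    return out


def write_fragments(fragments: pd.DataFrame, path: str | Path) -> None:
    out = fragments[["chrom", "start_kb", "end_kb", "clone"]].sort_values(
        ["clone", "chrom", "start_kb"], kind="stable")
    _write_tsv(out, path, "truth fragments (BED-like, kb)")


def read_fragments(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, ["chrom", "start_kb", "end_kb", "clone"])


# ---------------------------------------------------------------------------
# CMap export (GMOD tab-delimited map/feature layout)
# ---------------------------------------------------------------------------

def write_cmap(maps: list[OrderedGroupMap], path: str | Path,
               map_set: str = "RH") -> None:
    """One feature row per marker with cR start/stop positions, following
    the GMOD CMap tab-delimited import layout."""
    rows = []
    for ogm in maps:
        stop = round(ogm.length_cr, 1)
        for m, c in zip(ogm.markers, ogm.coords):
            pos = round(float(c), 1)
            rows.append((f"{map_set}_{ogm.group_id}", ogm.group_id, 0.0,
                         stop, m, m, pos, pos, "marker", 1))
    df = pd.DataFrame(rows, columns=[
        "map_acc", "map_name", "map_start", "map_stop", "feature_acc",
        "feature_name", "feature_start", "feature_stop",
        "feature_type_acc", "is_landmark"])
    _write_tsv(df, path, "GMOD CMap tab-delimited map/feature export")


def read_cmap(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, ["map_acc", "map_name", "feature_name",
                            "feature_start", "feature_stop"])
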