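"""Reading and writing unmerged reflection data and dendrograms.

The text dialect is modelled on XDS_ASCII: "!"-prefixed header lines with
``KEY= value`` pairs followed by whitespace-separated records
``h k l i_obs sigma frame``.  Intensities may be negative (they are
background-subtracted); sigma must be positive.  Dendrograms are serialized
as JSON node lists.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .cell import UnitCell, d_spacing, s_from_d
from .symmetry import POINT_GROUP_PRESETS, bijvoet_key, point_group
from .sim_core import WedgeDataset, WedgePlan

__all__ = [
    "write_unmerged",
    "read_unmerged",
    "serialize_dendrogram",
    "read_dendrogram",
    "MalformedFileError",
]

_MANDATORY = ("FORMAT", "UNIT_CELL_CONSTANTS", "POINT_GROUP", "WAVELENGTH", "WEDGE_ID")
_FORMAT_TAG = "SWSX_UNMERGED_1"


class MalformedFileError(ValueError):
    """Raised when an unmerged reflection file violates the dialect."""


def write_unmerged(wedge: WedgeDataset, path) -> None:
    """Write one wedge in the "!"-headed text dialect (6 significant digits)."""
    if wedge.n_obs < 1:
        raise ValueError("refusing to write a wedge with no observations")
    cell = wedge.cell.as_tuple()
    lines = [
        f"!FORMAT= {_FORMAT_TAG}",
        "!UNIT_CELL_CONSTANTS= " + " ".join(f"{x:.4f}" for x in cell),
        f"!POINT_GROUP= {wedge.pointgroup_name}",
        f"!WAVELENGTH= {wedge.plan.wavelength:.5f}",
        f"!WEDGE_ID= {wedge.wedge_id}",
        f"!DOSE_GY= {wedge.plan.dose_total:.6g}",
        f"!WEDGE_DEG= {wedge.plan.wedge_deg:.4f}",
        f"!FRAME_DEG= {wedge.plan.frame_deg:.4f}",
        "!ITEMS= h k l i_obs sigma frame",
    ]
    obs = wedge.observations
    for h, k, l, i, sig, fr in zip(
        obs["h"], obs["k"], obs["l"], obs["i_obs"], obs["sigma"], obs["frame"]
    ):
        lines.append(f"{int(h):5d} {int(k):5d} {int(l):5d} {i:.6g} {sig:.6g} {int(fr):4d}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_unmerged(path) -> WedgeDataset:
    """Parse an unmerged reflection file; hkl_asu is recomputed from the header.

    Malformed records raise :class:`MalformedFileError` naming the line
    number, so no row is ever dropped silently.
    """
    text = Path(path).read_text().splitlines()
    header: dict[str, str] = {}
    records = []
    for lineno, raw in enumerate(text, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("!"):
            if records:
                raise MalformedFileError(f"line {lineno}: header line after records")
            if "=" in line:
                key, _, val = line[1:].partition("=")
                header[key.strip()] = val.strip()
            continue
        fields = line.split()
        if len(fields) != 6:
            raise MalformedFileError(
                f"line {lineno}: expected 6 fields, got {len(fields)}"
            )
        try:
            h, k, l = (int(fields[i]) for i in range(3))
            i_obs, sigma = float(fields[3]), float(fields[4])
            frame = int(fields[5])
        except ValueError as exc:
            raise MalformedFileError(f"line {lineno}: non-numeric field ({exc})") from exc
        if sigma <= 0:
            raise MalformedFileError(f"line {lineno}: sigma must be positive")
        records.append((h, k, l, i_obs, sigma, frame))

    for key in _MANDATORY:
        if key not in header:
            raise MalformedFileError(f"missing mandatory header key {key}")
    pg_name = header["POINT_GROUP"]
    if pg_name not in POINT_GROUP_PRESETS:
        raise MalformedFileError(
            f"unknown point group {pg_name!r}; shipped presets: "
            + ", ".join(sorted(POINT_GROUP_PRESETS))
        )
    try:
        cell_vals = [float(x) for x in header["UNIT_CELL_CONSTANTS"].split()]
        if len(cell_vals) != 6:
            raise ValueError("expected 6 cell constants")
    except ValueError as exc:
        raise MalformedFileError(f"bad UNIT_CELL_CONSTANTS: {exc}") from exc
    cell = UnitCell(*cell_vals)
    plan = WedgePlan(
        wedge_deg=float(header.get("WEDGE_DEG", 5.0)),
        frame_deg=float(header.get("FRAME_DEG", 0.2)),
        dose_total=float(header.get("DOSE_GY", 0.0)),
        wavelength=float(header["WAVELENGTH"]),
    )
    pg = point_group(pg_name)
    df = pd.DataFrame(
        records, columns=["h", "k", "l", "i_obs", "sigma", "frame"]
    )
    if len(df):
        hkl = df[["h", "k", "l"]].values
        keys, signs = bijvoet_key(pg, hkl)
        d = d_spacing(cell, hkl)
        df["kh"], df["kk"], df["kl"] = keys[:, 0], keys[:, 1], keys[:, 2]
        df["sign"] = signs
        df["d"] = d
        df["s"] = s_from_d(d)
        df["phi"] = (df["frame"].values + 0.5) * plan.frame_deg
        df = df[
            ["h", "k", "l", "kh", "kk", "kl", "sign", "s", "d", "i_obs", "sigma", "frame", "phi"]
        ]
    d_min = float(df["d"].min()) if len(df) else None
    return WedgeDataset(
        wedge_id=header["WEDGE_ID"],
        cell=cell,
        pointgroup_name=pg_name,
        plan=plan,
        observations=df,
        d_min=d_min,
    )


def serialize_dendrogram(dendrogram, path) -> None:
    """Write a dendrogram as JSON: nodes {id, height, children, members}."""
    if len(dendrogram.leaf_ids) < 1:
        raise ValueError("dendrogram must have at least one leaf")
    nodes = dendrogram.node_list()
    # sanity: each child appears under exactly one parent and heights rise
    seen = set()
    for node in nodes:
        for ch in node["children"]:
            if ch in seen:
                raise ValueError("cyclic or shared child in dendrogram")
            seen.add(ch)
    payload = {
        "leaf_ids": list(dendrogram.leaf_ids),
        "threshold": dendrogram.threshold,
        "nodes": nodes,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_dendrogram(path):
    from .cluster import Dendrogram  # deferred: avoid import cycle

    payload = json.loads(Path(path).read_text())
    return Dendrogram.from_node_list(
        payload["leaf_ids"], payload["nodes"], threshold=payload.get("threshold")
    )


def write_merged_csv(merged, path) -> None:
    """Merged CSV with a one-line header: h,k,l,friedel,i,sigma,mult,d."""
    df = merged.table.rename(
        columns={"kh": "h", "kk": "k", "kl": "l", "sign": "friedel", "i_mean": "i",
                 "sigma_mean": "sigma", "n_obs": "mult"}
    )
    df[["h", "k", "l", "friedel", "i", "sigma", "mult", "d"]].to_csv(path, index=False)
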