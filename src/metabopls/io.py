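"""Plain-text readers/writers for spectra, manifests and bucket tables.

Formats are deliberately simple and interoperable:

* spectrum: tab-separated ``ppm<TAB>intensity`` with ``#``-prefixed header
  lines carrying ``sample_id``, ``fluid`` and ``group``;
* manifest: CSV with columns ``sample_id, group, fluid, path``;
* bucket table: TSV, one row per sample (``sample_id``, ``group``, then one
  column per retained bucket, ordered by descending ppm), with the bucket
  scheme embedded as a JSON comment so the table is self-describing.

A minimal JCAMP-DX reader (AFFN-encoded ``XYDATA`` blocks) is included for
importing externally processed spectra.
"""

from __future__ import annotations

import json
import os
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import Spectrum

__all__ = [
    "write_spectrum",
    "read_spectrum",
    "read_jcamp",
    "write_manifest",
    "read_manifest",
    "write_bucket_table",
    "read_bucket_table",
]

_FLOAT_FMT = "%.17e"  # full float64 round-trip


def write_spectrum(s: Spectrum, dest) -> None:
    """Write a spectrum as 2-column TSV with ``#`` metadata headers."""
    with open(dest, "w") as fh:
        fh.write(f"# sample_id: {s.sample_id}\n")
        fh.write(f"# fluid: {s.fluid}\n")
        fh.write(f"# group: {s.group}\n")
        for p, y in zip(s.ppm, s.intensity):
            fh.write(f"{p:.17e}\t{y:.17e}\n")


def read_spectrum(src) -> Spectrum:
    """Read a 2-column spectrum file; ascending axes are flipped to the
    canonical descending orientation."""
    meta = {"sample_id": "", "fluid": "serum", "group": "unknown"}
    ppm: list[float] = []
    intensity: list[float] = []
    with open(src) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    meta[key.strip()] = value.strip()
                continue
            fields = line.split()
            if len(fields) != 2:
                raise ValueError(
                    f"{src}: line {lineno}: expected 2 columns, got {len(fields)}"
                )
            try:
                p, y = float(fields[0]), float(fields[1])
            except ValueError:
                raise ValueError(f"{src}: line {lineno}: non-numeric field") from None
            ppm.append(p)
            intensity.append(y)
    if not ppm:
        raise ValueError(f"{src}: no data rows")
    axis = np.asarray(ppm)
    d = np.diff(axis)
    if d.size and not (np.all(d > 0) or np.all(d < 0)):
        bad = int(np.argmax(np.sign(d) != np.sign(d[0]))) + 2
        raise ValueError(f"{src}: line {bad}: ppm axis not strictly monotone")
    return Spectrum(
        axis,
        np.asarray(intensity),
        sample_id=meta["sample_id"],
        fluid=meta["fluid"],
        group=meta["group"],
    )


def read_jcamp(src) -> Spectrum:
    """Read a minimal JCAMP-DX file (AFFN ``XYDATA (X++(Y..Y))`` block).

    Supports the subset needed to import already-processed 1D spectra:
    ``FIRSTX/LASTX/NPOINTS`` with optional ``XFACTOR/YFACTOR``.  Compressed
    (SQZ/DIF/DUP) ordinate forms are not supported.
    """
    headers: dict[str, str] = {}
    y_values: list[float] = []
    in_data = False
    with open(src) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("##"):
                key, _, value = line[2:].partition("=")
                key = key.strip().upper().replace(" ", "")
                if key == "XYDATA":
                    in_data = True
                    continue
                if key == "END":
                    in_data = False
                headers[key] = value.strip()
                continue
            if in_data:
                fields = line.replace(",", " ").split()
                try:
                    vals = [float(v) for v in fields]
                except ValueError:
                    raise ValueError(f"{src}: non-AFFN data line: {line!r}") from None
                y_values.extend(vals[1:])  # first value on each line is X
    for req in ("FIRSTX", "LASTX", "NPOINTS"):
        if req not in headers:
            raise ValueError(f"{src}: missing ##{req}=")
    npoints = int(float(headers["NPOINTS"]))
    if len(y_values) != npoints:
        raise ValueError(
            f"{src}: NPOINTS={npoints} but {len(y_values)} ordinates found"
        )
    firstx, lastx = float(headers["FIRSTX"]), float(headers["LASTX"])
    xfactor = float(headers.get("XFACTOR", 1.0))
    yfactor = float(headers.get("YFACTOR", 1.0))
    ppm = np.linspace(firstx * xfactor, lastx * xfactor, npoints)
    intensity = np.asarray(y_values) * yfactor
    return Spectrum(ppm, intensity, sample_id=headers.get("TITLE", ""))


# ---------------------------------------------------------------------------
# manifest

_MANIFEST_COLUMNS = ["sample_id", "group", "fluid", "path"]


def write_manifest(manifest: pd.DataFrame, dest) -> None:
    missing = [c for c in _MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    manifest[_MANIFEST_COLUMNS].to_csv(dest, index=False)


def read_manifest(src) -> pd.DataFrame:
    df = pd.read_csv(src, dtype=str)
    missing = [c for c in _MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{src}: manifest missing columns: {missing}")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if len(dup):
        raise ValueError(f"{src}: duplicate sample_id(s): {sorted(set(dup))}")
    base = os.path.dirname(os.path.abspath(src))
    df["path"] = [
        p if os.path.isabs(p) else os.path.join(base, p) for p in df["path"]
    ]
    return df


# ---------------------------------------------------------------------------
# bucket table

def write_bucket_table(b, dest) -> None:
    """Write a BucketTable as self-describing TSV."""
    from .preprocess import BucketScheme  # local import to avoid cycle

    scheme = b.scheme
    meta = {
        "normalized": bool(b.normalized),
        "fluid": b.fluid,
        "scheme": {
            "region": list(scheme.region),
            "width": scheme.width,
            "exclusions": [list(e) for e in scheme.exclusions],
            "reference": list(scheme.reference),
        },
    }
    with open(dest, "w") as fh:
        fh.write("# bucket-table: " + json.dumps(meta, sort_keys=True) + "\n")
        header = ["sample_id", "group"] + [f"{c:.6f}" for c in b.bucket_centers]
        fh.write("\t".join(header) + "\n")
        for sid, grp, row in zip(b.sample_ids, b.groups, b.matrix):
            fh.write(sid + "\t" + grp + "\t" + "\t".join(_FLOAT_FMT % v for v in row) + "\n")


def read_bucket_table(src):
    from .preprocess import BucketScheme, BucketTable, bucket_grid

    meta = None
    rows = []
    header = None
    with open(src) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("bucket-table:"):
                    meta = json.loads(body.partition(":")[2])
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                continue
            if len(fields) != len(header):
                raise ValueError(
                    f"{src}: line {lineno}: {len(fields)} fields, header has {len(header)}"
                )
            rows.append(fields)
    if meta is None:
        raise ValueError(f"{src}: missing '# bucket-table:' metadata line")
    if header is None or not rows:
        raise ValueError(f"{src}: no samples")
    sample_ids = [r[0] for r in rows]
    if len(set(sample_ids)) != len(sample_ids):
        dups = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise ValueError(f"{src}: duplicate sample_id(s): {dups}")
    groups = [r[1] for r in rows]
    matrix = np.array([[float(v) for v in r[2:]] for r in rows])
    sch = meta["scheme"]
    scheme = BucketScheme(
        region=tuple(sch["region"]),
        width=sch["width"],
        exclusions=tuple(tuple(e) for e in sch["exclusions"]),
        reference=tuple(sch["reference"]),
    )
    centers_full, retained_mask = bucket_grid(scheme)
    centers = centers_full[retained_mask]
    if matrix.shape[1] != centers.size:
        raise ValueError(
            f"{src}: {matrix.shape[1]} bucket columns but scheme retains {centers.size}"
        )
    return BucketTable(
        matrix=matrix,
        bucket_centers=centers,
        retained_mask=retained_mask,
        normalized=bool(meta["normalized"]),
        scheme=scheme,
        sample_ids=sample_ids,
        groups=groups,
        fluid=meta.get("fluid", "serum"),
    )
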