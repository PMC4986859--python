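"""Plain-text I/O: curve files, batch manifests, anatomy tables, trees.

Curve files are two-column delimited text (displacement_mm, force_N), `#`
comment lines, optional header.  A batch manifest is a delimited table
mapping curve files to specimen geometry, test type, side, species and
replicate, so a whole study can be processed in one call.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .anatomy import AnatomyProfile
from .curves import ForceDisplacementCurve

__all__ = [
    "read_curve",
    "write_curve",
    "read_manifest",
    "read_anatomy_table",
    "write_study",
]

PathLike = Union[str, Path]

#: manifest columns: per-curve metadata
MANIFEST_COLUMNS = (
    "curve_file",
    "species",
    "replicate",
    "test",  # tensile | bending
    "side",  # adaxial | abaxial | '' for tensile
    "width_w",
    "thickness_d",
    "free_length_l0",  # tensile only
    "span_L",  # bending only
)

ANATOMY_COLUMNS = (
    "upper_cuticle",
    "upper_epidermis",
    "upper_outer_wall",
    "palisade",
    "spongy",
    "lower_epidermis",
    "lower_outer_wall",
    "lower_cuticle",
)


def read_curve(path: PathLike, delimiter: Optional[str] = None) -> ForceDisplacementCurve:
    """Read a force–displacement curve from 2-column delimited text.

    Accepts `#` comments and an optional non-numeric header line; the
    delimiter is sniffed (comma vs whitespace/tab) unless given.
    """
    path = Path(path)
    lines = [
        ln for ln in path.read_text().splitlines()
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not lines:
        raise ValueError(f"{path}: no data lines")
    if delimiter is None:
        delimiter = "," if "," in lines[0] or "," in lines[-1] else None
    start = 0
    try:
        first = lines[0].split(delimiter)
        float(first[0])
    except (ValueError, IndexError):
        start = 1  # header
    rows = [ln.split(delimiter) for ln in lines[start:]]
    try:
        arr = np.array([[float(r[0]), float(r[1])] for r in rows])
    except (ValueError, IndexError) as exc:
        raise ValueError(f"{path}: malformed curve data ({exc})") from exc
    return ForceDisplacementCurve(arr[:, 0], arr[:, 1], sampling_note=str(path.name))


def write_curve(curve: ForceDisplacementCurve, path: PathLike) -> None:
    """Write a curve as CSV with a header line."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("displacement_mm,force_N\n")
        for d, f in zip(curve.displacement, curve.force):
            fh.write(f"{d:.6g},{f:.8g}\n")


def read_manifest(path: PathLike) -> pd.DataFrame:
    """Read a batch manifest; curve_file paths are resolved relative to it."""
    path = Path(path)
    df = pd.read_csv(path, skipinitialspace=True)
    missing = [c for c in ("curve_file", "species", "test", "width_w", "thickness_d")
               if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    df["curve_file"] = [str((path.parent / p).resolve()) for p in df["curve_file"]]
    return df


def read_anatomy_table(path: PathLike) -> pd.DataFrame:
    """Read an anatomy table (one row per section, thickness columns in um).

    Extra columns (species, section id) pass through; per-species
    aggregation is the arithmetic mean over sections.
    """
    df = pd.read_csv(path, skipinitialspace=True)
    missing = [c for c in ANATOMY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"anatomy table missing columns: {missing}")
    return df


def profile_from_row(row) -> AnatomyProfile:
    """Build an AnatomyProfile from one anatomy-table row (or mean row)."""
    return AnatomyProfile(**{c: float(row[c]) for c in ANATOMY_COLUMNS})


def write_study(study, out_dir: PathLike) -> Path:
    """Export a synthetic study as curve files + manifest + tables.

    Layout: ``curves/<species>_r<k>_{tensile|bend_adaxial|bend_abaxial}.csv``
    with ``manifest.csv``, ``anatomy.csv`` and ``truth.csv`` at the root.
    Round-trips with :func:`read_manifest`/:func:`read_curve`.
    """
    out_dir = Path(out_dir)
    (out_dir / "curves").mkdir(parents=True, exist_ok=True)
    rows = []
    for leaf in study.leaves:
        for k, rep in enumerate(study.curves[leaf.species], start=1):
            items = [("tensile", None, rep["tensile"])] + [
                ("bending", side, crv) for side, crv in rep["bending"].items()
            ]
            for test, side, crv in items:
                tag = "tensile" if test == "tensile" else f"bend_{side.value}"
                fname = f"curves/{leaf.species}_r{k}_{tag}.csv"
                write_curve(crv, out_dir / fname)
                rows.append(
                    {
                        "curve_file": fname,
                        "species": leaf.species,
                        "replicate": k,
                        "test": test,
                        "side": "" if side is None else side.value,
                        "width_w": leaf.width,
                        "thickness_d": leaf.thickness,
                        "free_length_l0": leaf.free_length if test == "tensile" else "",
                        "span_L": leaf.span if test == "bending" else "",
                        "alpha": leaf.alpha,
                    }
                )
    pd.DataFrame(rows).to_csv(out_dir / "manifest.csv", index=False)
    anat = pd.DataFrame(
        [
            {"species": sp, **{c: getattr(prof, c) for c in ANATOMY_COLUMNS}}
            for sp, prof in study.anatomy.items()
        ]
    )
    anat.to_csv(out_dir / "anatomy.csv", index=False)
    study.truth.to_csv(out_dir / "truth.csv", index=False)
    return out_dir
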