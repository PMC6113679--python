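"""Import and export of reference libraries as spreadsheet tables.

Accepted layout (xlsx: two sheets; csv: two files):

* ``spectra`` sheet / main csv — first column the wavenumber axis (cm^-1),
  one further column per spectrum, headed by the spectrum id.
* ``clusters`` sheet / ``<stem>.clusters.csv`` — columns ``spectrum_id``,
  ``cluster_number``, ``cluster_name``.

Header-row variants are tolerated: the wavenumber column may be headed by
anything containing "wavenumber", "wn" or "cm"; otherwise the first column
is taken as the axis.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .spectra import (
    ClusterDefinition,
    ReferenceLibrary,
    Spectrum,
    SpectrumMetadata,
    WavenumberGrid,
)

__all__ = ["import_library_table", "export_library_table"]

_WN_HINTS = ("wavenumber", "wn", "cm")


def _clusters_csv_path(path: Path) -> Path:
    return path.with_suffix(".clusters.csv")


def _read_frames(path: Path, fmt: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    if fmt == "xlsx":
        sheets = pd.read_excel(path, sheet_name=None)
        names = {k.lower(): k for k in sheets}
        spectra = sheets[names.get("spectra", list(sheets)[0])]
        cl_key = names.get("clusters")
        if cl_key is None:
            non_first = [k for k in sheets if k != list(sheets)[0]]
            if not non_first:
                raise ValueError(f"{path}: no cluster-assignment sheet found")
            cl_key = non_first[0]
        clusters = sheets[cl_key]
    else:
        spectra = pd.read_csv(path)
        cpath = _clusters_csv_path(path)
        if not cpath.exists():
            raise ValueError(f"{path}: cluster assignment file {cpath} missing")
        clusters = pd.read_csv(cpath)
    return spectra, clusters


def import_library_table(
    path: str | Path, format: str | None = None
) -> ReferenceLibrary:
    """Read a reference library from an xlsx workbook or csv file pair."""
    path = Path(path)
    fmt = format or ("xlsx" if path.suffix.lower() in (".xlsx", ".xls") else "csv")
    if fmt not in ("xlsx", "csv"):
        raise ValueError(f"unknown library table format {fmt!r}")
    spectra_df, clusters_df = _read_frames(path, fmt)
    if spectra_df.empty or spectra_df.shape[1] < 2:
        raise ValueError(f"{path}: spectra table needs a wavenumber column and >=1 spectrum")

    cols = list(spectra_df.columns)
    wn_col = cols[0]
    for c in cols:
        if any(h in str(c).lower() for h in _WN_HINTS):
            wn_col = c
            break
    wn = np.asarray(spectra_df[wn_col], dtype=float)
    grid = WavenumberGrid(wn)
    order = np.argsort(wn)[::-1]

    entries: dict[str, Spectrum] = {}
    for c in cols:
        if c == wn_col:
            continue
        sid = str(c)
        y = np.asarray(spectra_df[c], dtype=float)[order]
        entries[sid] = Spectrum(
            grid=grid, intensities=y, metadata=SpectrumMetadata(sample_name=sid)
        )

    ccols = {str(c).strip().lower(): c for c in clusters_df.columns}
    try:
        sid_col = ccols["spectrum_id"]
        num_col = ccols["cluster_number"]
    except KeyError as exc:
        raise ValueError(
            f"{path}: cluster sheet must have spectrum_id and cluster_number columns"
        ) from exc
    name_col = ccols.get("cluster_name")

    groups: dict[int, ClusterDefinition] = {}
    for _, row in clusters_df.iterrows():
        num = int(row[num_col])
        sid = str(row[sid_col])
        if sid not in entries:
            raise ValueError(f"{path}: cluster table references unknown spectrum {sid!r}")
        name = str(row[name_col]) if name_col is not None else f"cluster {num}"
        if num in groups:
            if groups[num].cluster_name != name and name_col is not None:
                raise ValueError(
                    f"{path}: cluster number {num} used with two names "
                    f"({groups[num].cluster_name!r}, {name!r})"
                )
            groups[num].member_ids.add(sid)
        else:
            groups[num] = ClusterDefinition(num, name, {sid})

    assigned = {sid for g in groups.values() for sid in g.member_ids}
    orphans = set(entries) - assigned
    if orphans:
        warnings.warn(
            f"{len(orphans)} spectrum columns referenced by no cluster; "
            "placed in the unassigned pool",
            stacklevel=2,
        )
    lo, hi = grid.extent
    return ReferenceLibrary(
        grid=grid,
        entries=entries,
        clusters=[groups[k] for k in sorted(groups)],
        spectral_range=(lo, hi),
        unassigned=orphans,
    )


def export_library_table(library: ReferenceLibrary, path: str | Path) -> Path:
    """Write a library in the layout accepted by :func:`import_library_table`."""
    path = Path(path)
    fmt = "xlsx" if path.suffix.lower() in (".xlsx", ".xls") else "csv"
    ids = library.sorted_ids()
    spectra_df = pd.DataFrame(
        {"wavenumber": library.grid.values}
        | {sid: library.entries[sid].intensities for sid in ids}
    )
    rows = []
    for c in sorted(library.clusters, key=lambda c: c.cluster_number):
        for sid in sorted(c.member_ids):
            rows.append((sid, c.cluster_number, c.cluster_name))
    clusters_df = pd.DataFrame(
        rows, columns=["spectrum_id", "cluster_number", "cluster_name"]
    )
    if fmt == "xlsx":
        with pd.ExcelWriter(path) as xw:
            spectra_df.to_excel(xw, sheet_name="spectra", index=False)
            clusters_df.to_excel(xw, sheet_name="clusters", index=False)
    else:
        spectra_df.to_csv(path, index=False)
        clusters_df.to_csv(_clusters_csv_path(path), index=False)
    return path
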