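"""Spectrum and dataset I/O.

Reads and writes two-column spectrum tables, assembles dataset manifests
(cell id, class label, measurement site per spectrum file), and builds the
four per-cell analysis databases: site-averaged (I) and single-site
center/cytoplasm/membrane (II/III/IV).
"""
from __future__ import annotations

import csv
import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np

__all__ = [
    "CLASS_LABELS",
    "SITES",
    "DATABASE_SITE_RULES",
    "Spectrum",
    "CellRecord",
    "DatasetManifest",
    "DatabaseSpec",
    "DatabaseEntry",
    "SpectrumParseError",
    "ManifestError",
    "read_spectrum",
    "write_spectrum",
    "load_manifest",
    "build_manifest",
    "build_database",
    "save_dataset",
    "load_dataset",
]

CLASS_LABELS = ("NFC", "NIH/3T3", "MBM-T")
SITES = ("center", "cytoplasm", "membrane")

#: database id -> site rule ("average" = pointwise mean over available sites)
DATABASE_SITE_RULES = {
    "I": "average",
    "II": "center",
    "III": "cytoplasm",
    "IV": "membrane",
}


class SpectrumParseError(ValueError):
    """Malformed spectrum table (carries path and 1-based line number)."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f" [{path}"
            loc += f":{line}]" if line is not None else "]"
        elif line is not None:
            loc += f" [line {line}]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


class ManifestError(ValueError):
    """Invalid dataset manifest."""


@dataclass
class Spectrum:
    """A single spectrum on a strictly ascending wavenumber grid (cm^-1).

    Descending grids (common instrument export order) are reversed on
    construction so that range slicing has one sign convention throughout.
    ``meta`` accumulates free-form provenance tags (source path, processing
    steps applied).
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        w = np.asarray(self.wavenumbers, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if w.ndim != 1 or y.ndim != 1:
            raise ValueError("wavenumbers and intensities must be 1-D")
        if w.size != y.size:
            raise ValueError(
                f"length mismatch: {w.size} wavenumbers vs {y.size} intensities"
            )
        if w.size < 2:
            raise ValueError("a spectrum needs at least 2 points")
        dw = np.diff(w)
        if np.all(dw < 0):  # descending export -> canonical ascending order
            w = w[::-1].copy()
            y = y[::-1].copy()
        elif not np.all(dw > 0):
            raise ValueError("wavenumber grid is not strictly monotone")
        if not (np.all(np.isfinite(w)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite wavenumber or intensity value")
        self.wavenumbers = w
        self.intensities = y

    def __len__(self) -> int:
        return self.wavenumbers.size

    def copy(self) -> "Spectrum":
        return Spectrum(
            self.wavenumbers.copy(), self.intensities.copy(), dict(self.meta)
        )

    def with_intensities(self, intensities: np.ndarray, **meta) -> "Spectrum":
        """New Spectrum on the same grid with updated meta tags."""
        m = dict(self.meta)
        m.update(meta)
        return Spectrum(self.wavenumbers, np.asarray(intensities, float), m)


@dataclass
class CellRecord:
    """One cell's labelled site spectra (one or more sites may be absent)."""

    cell_id: str
    class_label: str
    site_spectra: dict  # site -> Spectrum

    def __post_init__(self):
        if self.class_label not in CLASS_LABELS:
            raise ManifestError(
                f"unknown class label {self.class_label!r} for cell "
                f"{self.cell_id!r}; expected one of {CLASS_LABELS}"
            )
        if not self.site_spectra:
            raise ManifestError(f"cell {self.cell_id!r} has no site spectra")
        for site in self.site_spectra:
            if site not in SITES:
                raise ManifestError(
                    f"unknown site {site!r} for cell {self.cell_id!r}; "
                    f"expected one of {SITES}"
                )

    @property
    def sites(self) -> tuple:
        return tuple(s for s in SITES if s in self.site_spectra)


@dataclass
class DatasetManifest:
    """Validated collection of CellRecords sharing one wavenumber grid."""

    records: list
    grid: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        ids = [r.cell_id for r in self.records]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ManifestError(f"duplicate cell_id(s): {dup[:5]}")
        for r in self.records:
            for site, sp in r.site_spectra.items():
                if len(sp) != self.grid.size or not np.array_equal(
                    sp.wavenumbers, self.grid
                ):
                    raise ManifestError(
                        f"spectrum for cell {r.cell_id!r} site {site!r} does "
                        "not conform to the manifest grid"
                    )

    @property
    def n_cells(self) -> int:
        return len(self.records)

    @property
    def n_spectra(self) -> int:
        return sum(len(r.site_spectra) for r in self.records)

    def class_counts(self) -> dict:
        out = {c: 0 for c in CLASS_LABELS}
        for r in self.records:
            out[r.class_label] += 1
        return out


@dataclass(frozen=True)
class DatabaseSpec:
    """One of the four analysis databases (id <-> site rule bijection)."""

    database_id: str

    def __post_init__(self):
        if self.database_id not in DATABASE_SITE_RULES:
            raise ValueError(
                f"unknown database id {self.database_id!r}; "
                f"expected one of {tuple(DATABASE_SITE_RULES)}"
            )

    @property
    def site_rule(self) -> str:
        return DATABASE_SITE_RULES[self.database_id]


class DatabaseEntry(NamedTuple):
    cell_id: str
    class_label: str
    spectrum: Spectrum


def _parse_row(raw: str):
    parts = raw.replace(",", " ").split()
    if len(parts) < 2:
        raise ValueError("expected two columns (wavenumber, intensity)")
    return float(parts[0]), float(parts[1])


def read_spectrum(path) -> Spectrum:
    """Read a two-column delimited text table into a validated Spectrum.

    Accepts whitespace- or comma-delimited rows; lines starting with ``#``
    (and blank lines) are skipped. The grid may be ascending or descending
    in the file; storage order is always ascending.
    """
    wav, inten = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            stripped = raw.strip()
            if not stripped or stripped.startswith("#"):
                continue
            try:
                w, y = _parse_row(stripped)
            except ValueError as exc:
                raise SpectrumParseError(
                    f"malformed row: {exc}", path=path, line=lineno
                ) from None
            wav.append(w)
            inten.append(y)
    if len(wav) < 2:
        raise SpectrumParseError(
            f"need at least 2 data rows, found {len(wav)}", path=path
        )
    try:
        return Spectrum(np.array(wav), np.array(inten), meta={"source": str(path)})
    except ValueError as exc:
        raise SpectrumParseError(str(exc), path=path) from None


def write_spectrum(spectrum: Spectrum, path) -> None:
    """Write a Spectrum as a two-column table; round-trips exactly.

    Values are printed with 17 significant digits so ``read_spectrum``
    reproduces every float bit-for-bit.
    """
    with open(path, "w") as fh:
        fh.write("# wavenumber_cm-1 intensity\n")
        for w, y in zip(spectrum.wavenumbers, spectrum.intensities):
            fh.write(f"{w:.17g} {y:.17g}\n")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def build_manifest(
    rows: Iterable[tuple],
    spectra: dict,
    grid_tolerance_factor: float = 0.25,
    provenance: dict | None = None,
) -> DatasetManifest:
    """Assemble a DatasetManifest from (cell_id, class, site) rows.

    ``rows`` yields ``(key, cell_id, class_label, site)`` and ``spectra``
    maps ``key`` to a Spectrum.  The first spectrum's grid becomes the
    manifest grid; other grids within ``grid_tolerance_factor`` times the
    median spacing (pointwise) are snapped to it, larger mismatches are
    linearly interpolated onto it and flagged in meta.
    """
    grid = None
    tol = None
    by_cell: dict = {}
    cell_class: dict = {}
    for key, cell_id, class_label, site in rows:
        if class_label not in CLASS_LABELS:
            raise ManifestError(f"unknown class {class_label!r} (entry {key!r})")
        if site not in SITES:
            raise ManifestError(f"unknown site {site!r} (entry {key!r})")
        sp = spectra[key]
        if grid is None:
            grid = sp.wavenumbers
            tol = grid_tolerance_factor * float(np.median(np.diff(grid)))
        sp = _conform_to_grid(sp, grid, tol)
        if cell_id in cell_class and cell_class[cell_id] != class_label:
            raise ManifestError(
                f"cell {cell_id!r} listed with conflicting classes "
                f"{cell_class[cell_id]!r} and {class_label!r}"
            )
        cell_class[cell_id] = class_label
        sites = by_cell.setdefault(cell_id, {})
        if site in sites:
            raise ManifestError(f"duplicate (cell_id, site) pair: ({cell_id!r}, {site!r})")
        sites[site] = sp
    if grid is None:
        raise ManifestError("manifest contains no rows")
    records = [
        CellRecord(cid, cell_class[cid], sites) for cid, sites in by_cell.items()
    ]
    return DatasetManifest(records, grid, provenance or {})


def _conform_to_grid(sp: Spectrum, grid: np.ndarray, tol: float) -> Spectrum:
    if sp.wavenumbers.size == grid.size and np.allclose(
        sp.wavenumbers, grid, rtol=0.0, atol=tol
    ):
        if np.array_equal(sp.wavenumbers, grid):
            return sp
        return Spectrum(grid, sp.intensities, dict(sp.meta, grid_snapped=True))
    # larger mismatch: interpolate onto the manifest grid
    lo, hi = sp.wavenumbers[0], sp.wavenumbers[-1]
    if grid[0] < lo - tol or grid[-1] > hi + tol:
        raise ManifestError(
            "spectrum grid does not cover the manifest grid "
            f"([{lo:g}, {hi:g}] vs [{grid[0]:g}, {grid[-1]:g}])"
        )
    y = np.interp(grid, sp.wavenumbers, sp.intensities)
    return Spectrum(grid, y, dict(sp.meta, grid_interpolated=True))


def load_manifest(path, grid_tolerance_factor: float = 0.25) -> DatasetManifest:
    """Load a manifest CSV (columns file,cell_id,class,site) and its spectra.

    Spectrum file paths are resolved relative to the manifest's directory.
    SHA-256 checksums of every input file are recorded in provenance.
    """
    base = os.path.dirname(os.path.abspath(path))
    rows = []
    checksums = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"file", "cell_id", "class", "site"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ManifestError(
                f"manifest must have columns {sorted(required)}, "
                f"got {reader.fieldnames}"
            )
        for row in reader:
            rows.append(
                (row["file"], row["cell_id"], row["class"], row["site"])
            )
    spectra = {}
    for key, *_ in rows:
        if key not in spectra:
            fpath = os.path.join(base, key)
            spectra[key] = read_spectrum(fpath)
            checksums[key] = _sha256(fpath)
    provenance = {"manifest_path": str(path), "checksums": checksums}
    return build_manifest(rows, spectra, grid_tolerance_factor, provenance)


def build_database(manifest: DatasetManifest, spec: DatabaseSpec) -> list:
    """Build one per-cell database: list of DatabaseEntry, one per cell.

    Database I averages the cell's available site spectra pointwise (1-3
    sites; cells never have zero sites).  Databases II/III/IV take the
    single named site spectrum and omit cells lacking that site.
    """
    rule = spec.site_rule
    entries = []
    for rec in manifest.records:
        if rule == "average":
            stack = np.stack(
                [rec.site_spectra[s].intensities for s in rec.sites]
            )
            sp = Spectrum(
                manifest.grid,
                stack.mean(axis=0),
                {"sites_averaged": list(rec.sites)},
            )
        else:
            if rule not in rec.site_spectra:
                continue
            sp = rec.site_spectra[rule]
        entries.append(DatabaseEntry(rec.cell_id, rec.class_label, sp))
    if not entries:
        raise ManifestError(
            f"database {spec.database_id} is empty (no cell has site {rule!r})"
        )
    return entries


# ---------------------------------------------------------------------------
# bundled dataset container (JSON) used by the CLI


def save_dataset(manifest: DatasetManifest, path) -> None:
    """Serialize a manifest to a single JSON container (grid + records)."""
    payload = {
        "format": "ramandx-dataset-v1",
        "grid": manifest.grid.tolist(),
        "provenance": _jsonable(manifest.provenance),
        "records": [
            {
                "cell_id": r.cell_id,
                "class": r.class_label,
                "sites": {
                    s: {
                        "intensities": sp.intensities.tolist(),
                        "meta": _jsonable(sp.meta),
                    }
                    for s, sp in r.site_spectra.items()
                },
            }
            for r in manifest.records
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_dataset(path) -> DatasetManifest:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "ramandx-dataset-v1":
        raise ManifestError(f"{path}: not a ramandx dataset container")
    grid = np.asarray(payload["grid"], dtype=float)
    records = []
    for rec in payload["records"]:
        sites = {
            s: Spectrum(grid, np.asarray(d["intensities"], float), d.get("meta", {}))
            for s, d in rec["sites"].items()
        }
        records.append(CellRecord(rec["cell_id"], rec["class"], sites))
    return DatasetManifest(records, grid, payload.get("provenance", {}))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
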