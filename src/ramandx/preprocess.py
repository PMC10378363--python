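"""Spectral preprocessing pipeline.

Order of operations: cut to the working range, Savitzky-Golay smoothing,
iterative anchored-minima baseline correction in two sub-regions, vector
normalization with a final minimum-to-zero shift.  Everything here is
deterministic — no randomness anywhere in this module.
"""
from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.signal import savgol_filter

from .spectra_io import Spectrum

__all__ = [
    "BaselineConfig",
    "PreprocessConfig",
    "BaselineError",
    "DegenerateSpectrumError",
    "cut_to_range",
    "smooth_savgol",
    "compute_baseline",
    "correct_baseline",
    "vector_normalize",
    "preprocess_pipeline",
    "preprocess_manifest",
]


class BaselineError(ValueError):
    """Baseline construction failed (too few resolvable anchor points)."""


class DegenerateSpectrumError(ValueError):
    """Operation undefined on a constant spectrum."""


@dataclass(frozen=True)
class BaselineConfig:
    """Two-sub-region anchored-minima baseline.

    The first sub-region (above ``region_split``) contributes the minimum
    intensity within ``anchor_window`` cm^-1 of each fixed anchor
    wavenumber; the second sub-region (at or below the split) is tiled into
    ``n_ranges`` equal-width ranges, each contributing its minimum.  The
    anchors are joined by straight lines (flat beyond the outermost anchor)
    and the construction is repeated ``n_iterations`` times on the evolving
    spectrum.
    """

    region_split: float = 1200.0
    fixed_anchors: tuple = (1800.0, 1750.0, 1720.0, 1560.0, 1530.0, 1490.0)
    n_ranges: int = 50
    n_iterations: int = 5
    anchor_window: float = 10.0

    def __post_init__(self):
        if self.n_ranges < 1 or self.n_iterations < 1:
            raise ValueError("n_ranges and n_iterations must be >= 1")
        for a in self.fixed_anchors:
            if a <= self.region_split:
                raise ValueError(
                    f"fixed anchor {a:g} not inside the first sub-region "
                    f"(> {self.region_split:g})"
                )


@dataclass(frozen=True)
class PreprocessConfig:
    cut_range: tuple = (600.0, 1800.0)
    sg_window: int = 5
    sg_polyorder: int = 2
    baseline: BaselineConfig = field(default_factory=BaselineConfig)

    def __post_init__(self):
        lo, hi = self.cut_range
        if not lo < hi:
            raise ValueError("cut_range low must be < high")
        if self.sg_window % 2 == 0:
            raise ValueError("sg_window must be odd")
        if not self.sg_polyorder < self.sg_window:
            raise ValueError("sg_polyorder must be < sg_window")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.md5(blob.encode()).hexdigest()[:12]


def cut_to_range(spectrum: Spectrum, low: float, high: float) -> Spectrum:
    """Keep points with low <= wavenumber <= high (closed interval)."""
    mask = (spectrum.wavenumbers >= low) & (spectrum.wavenumbers <= high)
    if not mask.any():
        raise ValueError(
            f"cut range [{low:g}, {high:g}] contains no grid points "
            f"(grid spans [{spectrum.wavenumbers[0]:g}, "
            f"{spectrum.wavenumbers[-1]:g}])"
        )
    return Spectrum(
        spectrum.wavenumbers[mask],
        spectrum.intensities[mask],
        dict(spectrum.meta, cut=(float(low), float(high))),
    )


def smooth_savgol(spectrum: Spectrum, window: int = 5, polyorder: int = 2) -> Spectrum:
    """Savitzky-Golay smoothing with mirror-padded edges (length-preserving)."""
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if polyorder >= window:
        raise ValueError("polyorder must be < window")
    if len(spectrum) < window:
        raise ValueError(
            f"spectrum shorter ({len(spectrum)}) than the window ({window})"
        )
    y = savgol_filter(spectrum.intensities, window, polyorder, mode="mirror")
    return spectrum.with_intensities(y, savgol=(int(window), int(polyorder)))


def _anchor_points(w, y, cfg: BaselineConfig):
    """(wavenumbers, intensities) of all resolvable baseline anchors.

    The two grid endpoints are always anchored so the piecewise-linear
    baseline spans the full grid (a pure linear ramp is removed exactly).
    """
    aw, ay = [float(w[0]), float(w[-1])], [float(y[0]), float(y[-1])]
    first = w > cfg.region_split
    for a in cfg.fixed_anchors:
        m = first & (np.abs(w - a) <= cfg.anchor_window)
        if not m.any():
            continue
        idx = np.flatnonzero(m)
        i = idx[np.argmin(y[idx])]
        aw.append(w[i])
        ay.append(y[i])
    second = np.flatnonzero(w <= cfg.region_split)
    if second.size:
        lo_edge = w[second[0]]
        edges = np.linspace(lo_edge, cfg.region_split, cfg.n_ranges + 1)
        ws = w[second]
        ys = y[second]
        starts = np.searchsorted(ws, edges[:-1], side="left")
        stops = np.searchsorted(ws, edges[1:], side="left")
        stops[-1] = ws.size  # last range is closed at the split
        empty = 0
        for s, t in zip(starts, stops):
            if t <= s:
                empty += 1
                continue
            i = s + int(np.argmin(ys[s:t]))
            aw.append(ws[i])
            ay.append(ys[i])
        if empty:
            warnings.warn(
                f"{empty} of {cfg.n_ranges} baseline ranges contain no grid "
                "point and were skipped",
                stacklevel=3,
            )
    if len(aw) < 2:
        raise BaselineError(
            f"only {len(aw)} baseline anchor point(s) resolvable; need >= 2"
        )
    order = np.argsort(aw, kind="stable")
    aw = np.asarray(aw)[order]
    ay = np.asarray(ay)[order]
    keep = np.concatenate([[True], np.diff(aw) > 0])  # drop duplicate wavenumbers
    return aw[keep], ay[keep]


def compute_baseline(spectrum: Spectrum, config: BaselineConfig | None = None) -> Spectrum:
    """Piecewise-linear baseline through the anchored minima.

    The grid endpoints are anchored, so the baseline is defined on the
    whole grid without extrapolation.
    """
    cfg = config or BaselineConfig()
    w = spectrum.wavenumbers
    aw, ay = _anchor_points(w, spectrum.intensities, cfg)
    base = np.interp(w, aw, ay)
    return spectrum.with_intensities(base, baseline_anchors=int(aw.size))


def correct_baseline(spectrum: Spectrum, config: BaselineConfig | None = None) -> Spectrum:
    """Iteratively subtract the anchored-minima baseline.

    Anchors are recomputed from the evolving spectrum at every iteration;
    negative values are not clipped (the normalization step handles them).
    """
    cfg = config or BaselineConfig()
    w = spectrum.wavenumbers
    y = spectrum.intensities.copy()
    for _ in range(cfg.n_iterations):
        aw, ay = _anchor_points(w, y, cfg)
        y -= np.interp(w, aw, ay)
    return spectrum.with_intensities(y, baseline_iterations=cfg.n_iterations)


def vector_normalize(spectrum: Spectrum) -> Spectrum:
    """Mean-subtract, scale to unit Euclidean norm, shift the minimum to 0.

    The pre-shift vector has unit norm; because it is mean-free, it can be
    recovered from the output as ``out - mean(out)``.  Output minimum is
    exactly zero.  Invariant to positive scaling and additive constants.
    """
    y = spectrum.intensities
    centered = y - y.mean()
    norm = float(np.linalg.norm(centered))
    if norm == 0.0 or np.ptp(y) == 0.0:
        raise DegenerateSpectrumError(
            "constant spectrum cannot be vector-normalized (zero norm)"
        )
    unit = centered / norm
    shifted = unit - unit.min()
    return spectrum.with_intensities(shifted, vector_normalized=True)


def preprocess_pipeline(spectrum: Spectrum, config: PreprocessConfig | None = None) -> Spectrum:
    """cut -> smooth -> correct_baseline -> vector_normalize."""
    cfg = config or PreprocessConfig()
    s = cut_to_range(spectrum, *cfg.cut_range)
    s = smooth_savgol(s, cfg.sg_window, cfg.sg_polyorder)
    s = correct_baseline(s, cfg.baseline)
    s = vector_normalize(s)
    s.meta["preprocess_config"] = cfg.config_hash()
    s.meta["preprocess_steps"] = ["cut", "savgol", "baseline", "normalize"]
    return s


def preprocess_manifest(manifest, config: PreprocessConfig | None = None):
    """Apply the full pipeline to every spectrum of a DatasetManifest."""
    from .spectra_io import CellRecord, DatasetManifest

    cfg = config or PreprocessConfig()
    records = []
    grid = None
    for rec in manifest.records:
        sites = {}
        for site, sp in rec.site_spectra.items():
            out = preprocess_pipeline(sp, cfg)
            if grid is None:
                grid = out.wavenumbers
            sites[site] = out
        records.append(CellRecord(rec.cell_id, rec.class_label, sites))
    prov = dict(manifest.provenance)
    prov["preprocess_config"] = cfg.config_hash()
    return DatasetManifest(records, grid, prov)
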