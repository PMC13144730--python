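"""Extraction of oriented 4C-like contact profiles from contact matrices.

A "4C-like" profile is one viewpoint's row of a balanced Hi-C matrix, read
along the chromosome in a chosen direction, averaged over the viewpoint
window, Savitzky-Golay smoothed and normalized to sum 1.  The ratio of such a
profile to the mean of matched control viewpoints estimates the stripe
enrichment ``P(s) / P0(s)`` that the extrusion model predicts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "ContactMatrix",
    "Viewpoint",
    "ContactProfile",
    "RatioProfile",
    "SMOOTHING_PRESETS",
    "RE_CONTROL_VIEWPOINTS",
    "RDNA_CONTROL_VIEWPOINTS",
    "load_matrix",
    "extract_profile",
    "average_controls",
    "ratio",
    "detrend",
]

# Smoothing presets: (kernel kb, polynomial order); None disables smoothing.
SMOOTHING_PRESETS: dict[str, tuple[int | None, int | None]] = {
    "whole_chromosome": (39, 2),
    "zoom": (9, 1),
    "unsmoothed": (None, None),
}

# Control viewpoints matched to the RE and to the left rDNA flank by
# centromere distance and arm length, as (chrom, coordinate bp, strand);
# strand W = profile toward increasing coordinates, C = toward decreasing.
RE_CONTROL_VIEWPOINTS = [
    ("V", 66000, "W"),
    ("VIII", 21000, "W"),
    ("XIV", 713000, "C"),
    ("II", 153000, "W"),
    ("XI", 525631, "C"),
    ("XIII", 182646, "W"),
]
RDNA_CONTROL_VIEWPOINTS = [
    ("IV", 747000, "C"),
    ("XIV", 332000, "W"),
    ("XIII", 565000, "C"),
    ("XV", 624000, "C"),
    ("XI", 143000, "W"),
    ("II", 536000, "C"),
]


@dataclass
class ContactMatrix:
    """Dense, balanced, symmetric intra-chromosomal contact matrix.

    ``start_bp`` is the genomic coordinate (0-based) of the first bin;
    filtered (unbalanced) bins may hold NaN.
    """

    chromosome: str
    bin_width: float  # kb
    matrix: np.ndarray
    start_bp: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("contact matrix must be square")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.matrix) < -1e-12:
                raise ValueError("contact matrix has negative entries")
        diff = self.matrix - self.matrix.T
        if np.nanmax(np.abs(diff), initial=0.0) > 1e-9:
            raise ValueError("contact matrix is not symmetric")

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def bin_index(self, coordinate_bp: float) -> int:
        idx = int((coordinate_bp - self.start_bp) // (self.bin_width * 1000))
        if not 0 <= idx < self.n_bins:
            raise ValueError(
                f"coordinate {coordinate_bp} outside matrix for {self.chromosome}"
            )
        return idx


@dataclass(frozen=True)
class Viewpoint:
    """A 4C-like viewpoint: window of bins whose contacts are profiled.

    ``orientation`` follows the W/C strand convention: ``toward-right`` (W)
    reads contacts toward increasing coordinates, ``toward-left`` (C) toward
    decreasing ones.
    """

    chromosome: str
    center_bp: int
    window_kb: float = 3.0
    orientation: str = "toward-right"

    def __post_init__(self) -> None:
        orient = {"W": "toward-right", "C": "toward-left"}.get(
            self.orientation, self.orientation
        )
        object.__setattr__(self, "orientation", orient)
        if orient not in ("toward-right", "toward-left"):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.window_kb <= 0:
            raise ValueError("window_kb must be > 0")


@dataclass
class ContactProfile:
    """1D contact-frequency profile by genomic distance from a viewpoint."""

    distances: np.ndarray  # kb, positive increasing
    values: np.ndarray
    sem: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.distances.shape != self.values.shape:
            raise ValueError("distances and values must have equal length")
        if self.sem is not None:
            self.sem = np.asarray(self.sem, dtype=float)

    @property
    def bin_width(self) -> float:
        if len(self.distances) > 1:
            return float(self.distances[1] - self.distances[0])
        return float(self.distances[0])

    def normalized(self) -> "ContactProfile":
        total = np.nansum(self.values)
        if total <= 0:
            raise ValueError("profile sums to zero; cannot normalize")
        sem = None if self.sem is None else self.sem / total
        return ContactProfile(self.distances, self.values / total, sem, dict(self.meta))

    def to_frame(self) -> pd.DataFrame:
        data = {"distance_kb": self.distances, "value": self.values}
        if self.sem is not None:
            data["sem"] = self.sem
        return pd.DataFrame(data)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ContactProfile":
        df = pd.read_csv(path, sep="\t")
        sem = df["sem"].to_numpy() if "sem" in df else None
        return cls(df["distance_kb"].to_numpy(), df["value"].to_numpy(), sem)


@dataclass
class RatioProfile:
    """Enrichment of a viewpoint profile over its control, by distance."""

    distances: np.ndarray
    values: np.ndarray
    sem: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.distances.shape != self.values.shape:
            raise ValueError("distances and values must have equal length")
        if self.sem is not None:
            self.sem = np.asarray(self.sem, dtype=float)

    @property
    def bin_width(self) -> float:
        if len(self.distances) > 1:
            return float(self.distances[1] - self.distances[0])
        return float(self.distances[0])

    def to_frame(self) -> pd.DataFrame:
        data = {"distance_kb": self.distances, "value": self.values}
        if self.sem is not None:
            data["sem"] = self.sem
        return pd.DataFrame(data)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RatioProfile":
        df = pd.read_csv(path, sep="\t")
        sem = df["sem"].to_numpy() if "sem" in df else None
        return cls(df["distance_kb"].to_numpy(), df["value"].to_numpy(), sem)


def load_matrix(
    path: str | Path,
    chromosome: str | None = None,
    apply_weights: bool = False,
    bin_width: float | None = None,
) -> ContactMatrix:
    """Load a dense contact matrix from a .cool file or a dense TSV.

    For cooler input, ``apply_weights`` multiplies raw counts by the outer
    product of the stored balancing weights; requesting weights from a file
    that has none is an error.  TSV input is taken as already balanced.
    """
    path = Path(path)
    if path.suffix in (".cool", ".mcool"):
        from . import minicool

        if chromosome is None:
            raise ValueError("chromosome is required for cooler input")
        dense, bw, start = minicool.read_dense(path, chromosome, balance=apply_weights)
        return ContactMatrix(chromosome, bw, dense, start)
    try:
        dense = pd.read_csv(path, sep="\t", header=None, comment="#").to_numpy(float)
    except Exception as exc:  # pragma: no cover - message wrapping only
        raise ValueError(f"could not parse dense matrix {path}: {exc}") from exc
    if apply_weights:
        raise ValueError("balancing weights are only available in cooler files")
    return ContactMatrix(chromosome or path.stem, bin_width or 1.0, dense)


def _interpolate_nan(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Linear interpolation over NaN runs; returns (dense, nan_mask)."""
    mask = ~np.isfinite(values)
    if mask.all():
        raise ValueError("profile is entirely NaN")
    if mask.any():
        x = np.arange(values.size)
        values = values.copy()
        values[mask] = np.interp(x[mask], x[~mask], values[~mask])
    return values, mask


def _kernel_bins(kernel_kb: float, bin_width: float, order: int, n: int) -> int:
    w = int(round(kernel_kb / bin_width))
    if w % 2 == 0:
        w += 1
    w = min(w, n if n % 2 == 1 else n - 1)
    if w <= order:
        raise ValueError(
            f"smoothing kernel ({w} bins) must exceed polynomial order {order}"
        )
    return w


def extract_profile(
    matrix: ContactMatrix,
    viewpoint: Viewpoint,
    smooth_kernel: float | None = 39.0,
    smooth_order: int | None = 2,
    normalize: bool = True,
) -> ContactProfile:
    """Extract the viewpoint's oriented contact profile from a matrix.

    Rows covering the viewpoint window are averaged; the profile runs from
    the first bin next to the window outward in the viewpoint orientation.
    NaN bins are interpolated for the Savitzky-Golay filter and masked back
    afterwards; the filter's ends are handled by polynomial fits on the
    shrunken window (no padding beyond the arm).  The profile is re-normalized
    to sum 1 after smoothing.
    """
    if viewpoint.chromosome != matrix.chromosome:
        raise ValueError(
            f"viewpoint chromosome {viewpoint.chromosome!r} does not match "
            f"matrix {matrix.chromosome!r}"
        )
    half = viewpoint.window_kb * 1000 / 2
    lo = matrix.bin_index(viewpoint.center_bp - half + 1)
    hi = matrix.bin_index(min(viewpoint.center_bp + half,
                              matrix.start_bp + matrix.n_bins * matrix.bin_width * 1000) - 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        row = np.nanmean(matrix.matrix[lo : hi + 1, :], axis=0)

    if viewpoint.orientation == "toward-right":
        values = row[hi + 1 :]
    else:
        values = row[:lo][::-1]
    if values.size == 0:
        raise ValueError("viewpoint window touches the matrix edge; empty profile")
    distances = matrix.bin_width * np.arange(1, values.size + 1)

    if smooth_kernel is not None and smooth_order is not None:
        dense, nan_mask = _interpolate_nan(values)
        w = _kernel_bins(smooth_kernel, matrix.bin_width, smooth_order, values.size)
        smoothed = savgol_filter(dense, w, smooth_order, mode="interp")
        smoothed = np.clip(smoothed, 0.0, None)
        smoothed[nan_mask] = np.nan
        values = smoothed
        descriptor = {"kernel_kb": smooth_kernel, "order": smooth_order}
    else:
        descriptor = {"kernel_kb": None, "order": None}

    profile = ContactProfile(
        distances,
        values,
        meta={
            "viewpoint": f"{viewpoint.chromosome}:{viewpoint.center_bp}",
            "orientation": viewpoint.orientation,
            "smoothing": descriptor,
        },
    )
    return profile.normalized() if normalize else profile


def average_controls(profiles: list[ContactProfile]) -> ContactProfile:
    """Pointwise mean of control-viewpoint profiles (truncated to the
    shortest grid), with the SEM across controls."""
    if not profiles:
        raise ValueError("no control profiles given")
    widths = {round(p.bin_width, 9) for p in profiles}
    if len(widths) > 1:
        raise ValueError(f"inconsistent bin widths among controls: {sorted(widths)}")
    n = min(len(p.values) for p in profiles)
    stack = np.vstack([p.values[:n] for p in profiles])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
        sem = (
            np.nanstd(stack, axis=0, ddof=1) / np.sqrt(stack.shape[0])
            if stack.shape[0] > 1
            else None
        )
    return ContactProfile(profiles[0].distances[:n], mean, sem, {"n_controls": len(profiles)})


def ratio(profile: ContactProfile, control: ContactProfile) -> RatioProfile:
    """Pointwise profile/control ratio — the experimental estimate of
    ``P(s) / P0(s)``.  Bins with a zero or NaN control become NaN."""
    n = min(len(profile.values), len(control.values))
    if not np.allclose(profile.distances[:n], control.distances[:n]):
        raise ValueError("profile and control distance grids do not match")
    num = profile.values[:n]
    den = control.values[:n]
    bad = ~np.isfinite(den) | (den == 0) | ~np.isfinite(num)
    if (np.isfinite(num) & (den == 0)).any():
        warnings.warn("control profile has zero bins; ratio set to NaN there")
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.where(bad, np.nan, num / np.where(den == 0, np.nan, den))
    return RatioProfile(profile.distances[:n], vals)


def detrend(ratio_profile: RatioProfile, lowess_fraction: float = 0.3) -> RatioProfile:
    """Divide a ratio profile by its LOWESS trend.

    Removes the slowly varying stripe envelope so that localized residual
    peaks (candidate roadblocks) stand out on a baseline of ~1.
    """
    finite = np.isfinite(ratio_profile.values)
    if finite.sum() < 20:
        raise ValueError("need at least 20 finite points to detrend")
    x = ratio_profile.distances[finite]
    y = ratio_profile.values[finite]
    trend = lowess(y, x, frac=lowess_fraction, return_sorted=False)
    out = np.full_like(ratio_profile.values, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        out[finite] = y / np.where(trend <= 0, np.nan, trend)
    return RatioProfile(ratio_profile.distances, out, meta={"lowess_fraction": lowess_fraction})
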