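"""Spectral processing: referencing, binning, exclusion masking, noise
detection and normalization of 1D NMR spectra.

The processing chain is reference -> bin -> fixed exclusions -> noise
detection -> normalization; each stage records itself in the
:class:`BinnedMatrix` provenance so order violations are detectable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "BinnedMatrix",
    "ExclusionPolicy",
    "ReferencingError",
    "default_exclusion_policy",
    "reference_spectrum",
    "bin_spectrum",
    "bin_cohort",
    "apply_exclusions",
    "detect_noise_bins",
    "normalize",
]

MATRICES = ("plasma", "brain")

#: exclusion reasons allowed on a bin (exactly one per excluded bin)
EXCLUSION_REASONS = (
    "water/noise-region",
    "below-0.7",
    "above-9.38",
    "EDTA",
    "RSD-noise",
)

# EDTA / Ca-EDTA / Mg-EDTA resonance windows (plasma contamination).
EDTA_REGIONS = (
    (2.52, 2.58),
    (2.68, 2.74),
    (3.08, 3.24),
    (3.58, 3.65),
)


class ReferencingError(ValueError):
    """No usable reference peak inside the requested search window."""


@dataclass
class Spectrum:
    """One sample's 1D spectrum on a ppm axis.

    The axis must be strictly monotonic (ascending or descending) and the
    intensity vector finite and of equal length.
    """

    ppm: np.ndarray
    intensity: np.ndarray
    sample_id: str
    matrix: str
    reference: str = "none"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("ppm and intensity must be 1-D vectors")
        if self.ppm.size != self.intensity.size:
            raise ValueError(
                f"length mismatch: {self.ppm.size} ppm values vs "
                f"{self.intensity.size} intensities"
            )
        d = np.diff(self.ppm)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("ppm axis must be strictly monotonic")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError(f"non-finite intensity in sample {self.sample_id!r}")
        if self.matrix not in MATRICES:
            raise ValueError(f"unknown matrix {self.matrix!r}; expected one of {MATRICES}")

    def ascending(self) -> "Spectrum":
        """Return a view-equivalent spectrum with ascending ppm axis."""
        if self.ppm[0] < self.ppm[-1]:
            return self
        return Spectrum(
            ppm=self.ppm[::-1].copy(),
            intensity=self.intensity[::-1].copy(),
            sample_id=self.sample_id,
            matrix=self.matrix,
            reference=self.reference,
            meta=dict(self.meta),
        )


@dataclass
class ExclusionPolicy:
    """Fixed ppm regions to mask plus the RSD noise-bin rule parameters.

    ``regions`` is a list of ``(lo, hi, label)`` half-open intervals; labels
    must come from :data:`EXCLUSION_REASONS`. Overlapping same-label regions
    are merged on construction.
    """

    regions: list[tuple[float, float, str]] = field(default_factory=list)
    rsd_threshold: float = 0.5
    noise_floor_quantile: float = 0.25

    def __post_init__(self) -> None:
        if self.rsd_threshold <= 0:
            raise ValueError("rsd_threshold must be > 0")
        if not (0 < self.noise_floor_quantile < 1):
            raise ValueError("noise_floor_quantile must lie in (0, 1)")
        for lo, hi, label in self.regions:
            if label not in EXCLUSION_REASONS:
                raise ValueError(f"unknown exclusion label {label!r}")
            if not lo < hi:
                raise ValueError(f"empty exclusion region ({lo}, {hi})")
        self.regions = _merge_regions(self.regions)


def _merge_regions(
    regions: Sequence[tuple[float, float, str]],
) -> list[tuple[float, float, str]]:
    by_label: dict[str, list[tuple[float, float]]] = {}
    order: list[str] = []
    for lo, hi, label in regions:
        if label not in by_label:
            by_label[label] = []
            order.append(label)
        by_label[label].append((lo, hi))
    merged: list[tuple[float, float, str]] = []
    for label in order:
        ivs = sorted(by_label[label])
        cur_lo, cur_hi = ivs[0]
        for lo, hi in ivs[1:]:
            if lo <= cur_hi:
                cur_hi = max(cur_hi, hi)
            else:
                merged.append((cur_lo, cur_hi, label))
                cur_lo, cur_hi = lo, hi
        merged.append((cur_lo, cur_hi, label))
    return merged


def default_exclusion_policy(
    matrix: str,
    water_region: tuple[float, float] = (4.5, 6.0),
    rsd_threshold: float = 0.5,
    noise_floor_quantile: float = 0.25,
) -> ExclusionPolicy:
    """Default fixed-region policy for a sample matrix.

    Masks everything below 0.7 ppm and above 9.38 ppm, a combined
    water/noise region (default 4.5-6.0 ppm, covering both residual water
    and the noisy 5.0-6.0 ppm stretch), and -- for plasma only -- the EDTA
    contamination windows.
    """
    if matrix not in MATRICES:
        raise ValueError(f"unknown matrix {matrix!r}; expected one of {MATRICES}")
    regions: list[tuple[float, float, str]] = [
        (-math.inf, 0.7, "below-0.7"),
        (9.38, math.inf, "above-9.38"),
        (water_region[0], water_region[1], "water/noise-region"),
    ]
    if matrix == "plasma":
        regions += [(lo, hi, "EDTA") for lo, hi in EDTA_REGIONS]
    return ExclusionPolicy(
        regions=regions,
        rsd_threshold=rsd_threshold,
        noise_floor_quantile=noise_floor_quantile,
    )


@dataclass
class BinnedMatrix:
    """Samples x bins feature table on a fixed-width ppm grid.

    ``values`` holds the raw (or normalized) bin integrals; exclusion flags
    are metadata only and never alter stored values. ``excluded_reason``
    holds one reason string per excluded bin and ``None`` elsewhere.
    """

    values: np.ndarray
    bin_edges: list[tuple[float, float]]
    sample_ids: list[str]
    groups: list[str]
    matrix: str
    excluded_reason: np.ndarray | None = None
    normalization: str = "raw"
    stages: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.bin_edges)):
            raise ValueError("values shape does not match sample_ids x bin_edges")
        widths = np.array([hi - lo for lo, hi in self.bin_edges])
        if widths.size and not np.allclose(widths, widths[0], atol=1e-9):
            raise ValueError("bin widths are not uniform")
        if self.excluded_reason is None:
            self.excluded_reason = np.full(len(self.bin_edges), None, dtype=object)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    @property
    def excluded(self) -> np.ndarray:
        return np.array([r is not None for r in self.excluded_reason], dtype=bool)

    @property
    def retained(self) -> np.ndarray:
        return ~self.excluded

    @property
    def bin_labels(self) -> list[str]:
        return [f"b{lo:.2f}_{hi:.2f}" for lo, hi in self.bin_edges]

    def retained_values(self) -> np.ndarray:
        """Values over retained (non-excluded) bins only."""
        return self.values[:, self.retained]

    def retained_labels(self) -> list[str]:
        keep = self.retained
        return [lab for lab, k in zip(self.bin_labels, keep) if k]

    def copy(self) -> "BinnedMatrix":
        return BinnedMatrix(
            values=self.values.copy(),
            bin_edges=list(self.bin_edges),
            sample_ids=list(self.sample_ids),
            groups=list(self.groups),
            matrix=self.matrix,
            excluded_reason=self.excluded_reason.copy(),
            normalization=self.normalization,
            stages=list(self.stages),
            meta=dict(self.meta),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.bin_labels)


# ---------------------------------------------------------------------------
# referencing


def _noise_floor(intensity: np.ndarray) -> float:
    med = float(np.median(intensity))
    mad = float(np.median(np.abs(intensity - med)))
    return med + 5.0 * 1.4826 * mad


def reference_spectrum(
    s: Spectrum, target: float, search_window: tuple[float, float]
) -> Spectrum:
    """Shift the ppm axis so the tallest peak in ``search_window`` sits at
    ``target``.

    Intensities are untouched; the applied shift is stored under
    ``meta["reference_shift"]``. Raises :class:`ReferencingError` when the
    window contains no point above the spectrum's noise floor.
    """
    lo, hi = min(search_window), max(search_window)
    asc = s.ascending()
    in_win = (asc.ppm >= lo) & (asc.ppm <= hi)
    if not in_win.any():
        raise ReferencingError(
            f"search window ({lo}, {hi}) does not overlap the ppm axis of "
            f"sample {s.sample_id!r}"
        )
    idx = np.flatnonzero(in_win)
    apex_local = idx[int(np.argmax(asc.intensity[idx]))]
    apex_height = asc.intensity[apex_local]
    if apex_height <= _noise_floor(asc.intensity):
        raise ReferencingError(
            f"no peak above noise floor in window ({lo}, {hi}) for sample "
            f"{s.sample_id!r}: window max {apex_height:.4g}"
        )
    shift = target - asc.ppm[apex_local]
    meta = dict(s.meta)
    meta["reference_shift"] = float(shift)
    meta["reference_target"] = float(target)
    return Spectrum(
        ppm=s.ppm + shift,
        intensity=s.intensity.copy(),
        sample_id=s.sample_id,
        matrix=s.matrix,
        reference=f"@{target:g}",
        meta=meta,
    )


# ---------------------------------------------------------------------------
# binning


def bin_spectrum(
    s: Spectrum, width: float = 0.02, grid_anchor: float = 0.0
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Sum-method binning on a fixed grid.

    Bins are half-open ``[anchor + k*width, anchor + (k+1)*width)``; the bin
    value is the plain sum of the intensity samples whose ppm falls inside.
    Returns the bin vector together with its edges (bins at the axis ends
    may cover the axis only partially).
    """
    if width <= 0:
        raise ValueError("bin width must be > 0")
    asc = s.ascending()
    k = np.floor((asc.ppm - grid_anchor) / width).astype(np.int64)
    k_min, k_max = int(k.min()), int(k.max())
    n_bins = k_max - k_min + 1
    values = np.zeros(n_bins)
    np.add.at(values, k - k_min, asc.intensity)
    edges = [
        (grid_anchor + i * width, grid_anchor + (i + 1) * width)
        for i in range(k_min, k_max + 1)
    ]
    return values, edges


def bin_cohort(
    spectra: Sequence[Spectrum],
    groups: Sequence[str],
    width: float = 0.02,
    grid_anchor: float = 0.0,
) -> BinnedMatrix:
    """Bin every spectrum and stack rows on the common bin range.

    Per-sample referencing can shift axis ends by a bin, so the stacked
    matrix keeps only bins present in every sample.
    """
    if len(spectra) != len(groups):
        raise ValueError("one group label per spectrum required")
    if not spectra:
        raise ValueError("empty cohort")
    matrix = spectra[0].matrix
    per_sample = []
    lo_k, hi_k = -(10**9), 10**9
    for s in spectra:
        if s.matrix != matrix:
            raise ValueError("mixed matrix types in one cohort")
        vals, edges = bin_spectrum(s, width=width, grid_anchor=grid_anchor)
        k0 = int(round((edges[0][0] - grid_anchor) / width))
        per_sample.append((vals, k0))
        lo_k = max(lo_k, k0)
        hi_k = min(hi_k, k0 + len(vals) - 1)
    if hi_k < lo_k:
        raise ValueError("spectra share no common ppm range")
    n_bins = hi_k - lo_k + 1
    mat = np.zeros((len(spectra), n_bins))
    for row, (vals, k0) in enumerate(per_sample):
        start = lo_k - k0
        mat[row] = vals[start : start + n_bins]
    edges = [
        (grid_anchor + i * width, grid_anchor + (i + 1) * width)
        for i in range(lo_k, hi_k + 1)
    ]
    return BinnedMatrix(
        values=mat,
        bin_edges=edges,
        sample_ids=[s.sample_id for s in spectra],
        groups=list(groups),
        matrix=matrix,
        stages=["bin"],
        meta={"bin_width": width, "grid_anchor": grid_anchor},
    )


# ---------------------------------------------------------------------------
# exclusions


def apply_exclusions(m: BinnedMatrix, policy: ExclusionPolicy) -> BinnedMatrix:
    """Flag bins intersecting the policy's fixed regions.

    Flags are additive metadata (values preserved); a bin already carrying
    a reason keeps its first one.
    """
    out = m.copy()
    for lo, hi, label in policy.regions:
        for j, (blo, bhi) in enumerate(out.bin_edges):
            if blo < hi and bhi > lo and out.excluded_reason[j] is None:
                out.excluded_reason[j] = label
    out.stages.append("exclude")
    out.meta["n_retained_after_fixed"] = int(out.retained.sum())
    return out


# ---------------------------------------------------------------------------
# RSD noise-bin detection


def detect_noise_bins(m: BinnedMatrix, policy: ExclusionPolicy) -> BinnedMatrix:
    """Flag weak, unstable retained bins as RSD-noise.

    For each retained bin the across-sample RSD (sd/|mean|; +inf at mean 0)
    and the score mean+sd are computed; a bin is flagged when RSD exceeds
    ``policy.rsd_threshold`` AND its mean+sd falls below the
    ``policy.noise_floor_quantile`` quantile of all retained bins' scores.
    Bins with mean exactly 0 (infinite RSD) are always flagged.
    The per-bin decision log is stored under ``meta["noise_log"]``.
    """
    if m.n_samples < 3:
        raise ValueError(
            f"noise-bin detection needs >=3 samples, got {m.n_samples}"
        )
    if "exclude" not in m.stages:
        raise ValueError("apply_exclusions must run before detect_noise_bins")
    out = m.copy()
    keep = out.retained
    idx = np.flatnonzero(keep)
    vals = out.values[:, idx]
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rsd = np.where(mean == 0.0, np.inf, sd / np.abs(mean))
    score = mean + sd
    floor = float(np.quantile(score, policy.noise_floor_quantile))
    flagged = ((rsd > policy.rsd_threshold) & (score < floor)) | (mean == 0.0)
    for j, f in zip(idx, flagged):
        if f:
            out.excluded_reason[j] = "RSD-noise"
    log = pd.DataFrame(
        {
            "bin": [out.bin_labels[j] for j in idx],
            "rsd": rsd,
            "mean_plus_sd": score,
            "flagged": flagged,
        }
    )
    out.meta["noise_log"] = log
    out.meta["noise_floor"] = floor
    out.stages.append("noise-detect")
    return out


# ---------------------------------------------------------------------------
# normalization


def normalize(m: BinnedMatrix, mode: str, total: float = 100.0) -> BinnedMatrix:
    """Row-wise normalization.

    ``total_area``: divide each row by its sum over retained bins and
    multiply by ``total`` (default 100). ``tsp``: divide each row by its
    value in the bin containing 0.0 ppm (brain only).
    """
    if mode not in ("total_area", "tsp"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    out = m.copy()
    if mode == "total_area":
        keep = out.retained
        if not keep.any():
            raise ValueError("no retained bins to normalize over")
        row_sums = out.values[:, keep].sum(axis=1)
        if np.any(row_sums == 0):
            raise ValueError("sample with zero total area over retained bins")
        out.values = out.values / row_sums[:, None] * total
    else:
        if out.matrix != "brain":
            raise ValueError("TSP normalization is only defined for brain samples")
        tsp_bin = None
        for j, (lo, hi) in enumerate(out.bin_edges):
            if lo <= 0.0 < hi:
                tsp_bin = j
                break
        if tsp_bin is None:
            raise ValueError("no bin containing 0.0 ppm; cannot TSP-normalize")
        ref = out.values[:, tsp_bin]
        if np.any(ref <= 0):
            raise ValueError("zero or negative TSP bin value")
        out.values = out.values / ref[:, None]
    out.normalization = (
        mode if out.normalization == "raw" else f"{out.normalization}+{mode}"
    )
    out.stages.append(f"normalize:{mode}")
    return out
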