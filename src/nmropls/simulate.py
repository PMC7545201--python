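"""Synthetic two-group 1D NMR cohort generator.

Every downstream stage of the pipeline is exercised against cohorts from
this module, whose group effects (signed log2 fold changes) are known by
construction and exported as a ground-truth table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .processing import Spectrum
from .templates import MetaboliteTemplate, default_metabolite_library

__all__ = [
    "CohortDesign",
    "GroundTruth",
    "simulate_spectrum",
    "simulate_cohort",
    "default_plasma_design",
    "default_brain_design",
]

_GROUP_CODE = {"A": 0, "B": 1}
# sub-stream tags keeping biological variation independent of the
# group-keyed noise stream (same sample_index => same multipliers in A and B)
_BIO_STREAM = 7
_NOISE_STREAM = 11


@dataclass
class CohortDesign:
    """Recipe for one simulated two-group cohort.

    ``effects`` maps metabolite names to signed log2 fold changes applied
    multiplicatively to group B (the treated-like group). ``library``
    defaults to the built-in panel for the chosen matrix.
    """

    n_group_a: int = 15
    n_group_b: int = 14
    matrix: str = "plasma"
    effects: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.05
    shift_jitter_sd: float = 0.002
    baseline_amplitude: float = 0.1
    biological_sd: float = 0.15
    ppm_grid: tuple[float, float, int] = (-0.5, 10.0, 14001)
    seed: int = 0
    library: list[MetaboliteTemplate] | None = None

    def __post_init__(self) -> None:
        if self.n_group_a < 2 or self.n_group_b < 2:
            raise ValueError("each group needs at least 2 samples")
        if self.matrix not in ("plasma", "brain"):
            raise ValueError(f"unknown matrix {self.matrix!r}")
        lo, hi, n = self.ppm_grid
        if n < 1000:
            raise ValueError("ppm grid needs >= 1000 points")
        if not lo < hi:
            raise ValueError("ppm grid bounds inverted")
        for name, value in (
            ("noise_sd", self.noise_sd),
            ("shift_jitter_sd", self.shift_jitter_sd),
            ("baseline_amplitude", self.baseline_amplitude),
            ("biological_sd", self.biological_sd),
        ):
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {value}")
        lib_names = {t.name for t in self.resolve_library()}
        for key, lfc in self.effects.items():
            if key not in lib_names:
                raise ValueError(
                    f"effect key {key!r} names no template valid for matrix "
                    f"{self.matrix!r}"
                )
            if not math.isfinite(lfc):
                raise ValueError(f"non-finite effect for {key!r}")

    def resolve_library(self) -> list[MetaboliteTemplate]:
        if self.library is not None:
            return list(self.library)
        return default_metabolite_library(self.matrix)

    def group_size(self, group: str) -> int:
        return {"A": self.n_group_a, "B": self.n_group_b}[group]


@dataclass
class GroundTruth:
    """Expected direction of change per perturbed metabolite, with the
    0.02-ppm bins overlapping that metabolite's peaks."""

    table: pd.DataFrame  # metabolite, log2_fc, direction, bins

    def directions(self) -> dict[str, str]:
        return dict(zip(self.table["metabolite"], self.table["direction"]))


def _peak_profile(ppm: np.ndarray, center: float, rel: float, hw: float, shape: str) -> np.ndarray:
    if shape == "lorentzian":
        return rel * hw**2 / ((ppm - center) ** 2 + hw**2)
    # gaussian with HWHM = hw
    sigma = hw / math.sqrt(2.0 * math.log(2.0))
    return rel * np.exp(-((ppm - center) ** 2) / (2.0 * sigma**2))


def _smooth_baseline(x: np.ndarray, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    if amplitude == 0:
        return np.zeros_like(x)
    coeffs = rng.uniform(-1.0, 1.0, size=4)
    t = (x - x[0]) / (x[-1] - x[0])
    base = coeffs[0] + coeffs[1] * t + coeffs[2] * t**2 + coeffs[3] * t**3
    # keep the drift one-sided (non-negative), as after baseline correction
    base = base - base.min()
    peak = base.max()
    scale = rng.uniform(0.0, 1.0) * amplitude / peak if peak > 0 else 0.0
    return base * scale


def simulate_spectrum(design: CohortDesign, group: str, sample_index: int) -> Spectrum:
    """Simulate one sample's spectrum.

    Deterministic in ``(design.seed, group, sample_index)``. Biological
    abundance multipliers are keyed by sample_index only, so group A and B
    samples with the same index share them (group differences then come
    only from the planted effects).
    """
    if group not in _GROUP_CODE:
        raise ValueError(f"group must be 'A' or 'B', got {group!r}")
    if not 0 <= sample_index < design.group_size(group):
        raise ValueError(
            f"sample_index {sample_index} out of range for group {group}"
        )
    lib = design.resolve_library()
    lo, hi, n = design.ppm_grid
    ppm = np.linspace(lo, hi, n)

    bio_rng = np.random.default_rng([design.seed, _BIO_STREAM, sample_index])
    noise_rng = np.random.default_rng(
        [design.seed, _NOISE_STREAM, _GROUP_CODE[group], sample_index]
    )

    intensity = np.zeros(n)
    for template in lib:
        multiplier = float(
            np.exp(bio_rng.normal(0.0, design.biological_sd))
            if design.biological_sd > 0
            else 1.0
        )
        # keep bio stream advancing identically regardless of sigma
        if design.biological_sd == 0:
            bio_rng.normal(0.0, 1.0)
        abundance = template.base_abundance * multiplier
        if group == "B" and template.name in design.effects:
            abundance *= 2.0 ** design.effects[template.name]
        jitter = (
            noise_rng.normal(0.0, design.shift_jitter_sd)
            if design.shift_jitter_sd > 0
            else 0.0
        )
        if design.shift_jitter_sd == 0:
            noise_rng.normal(0.0, 1.0)
        for peak in template.peaks:
            intensity += abundance * _peak_profile(
                ppm, peak.center + jitter, peak.rel_intensity, peak.half_width, peak.shape
            )

    intensity += _smooth_baseline(ppm, design.baseline_amplitude, noise_rng)
    if design.noise_sd > 0:
        intensity += noise_rng.normal(0.0, design.noise_sd, size=n)

    sample_id = f"{group}{sample_index + 1:02d}"
    return Spectrum(
        ppm=ppm,
        intensity=intensity,
        sample_id=sample_id,
        matrix=design.matrix,
        reference="none",
        meta={"group": group, "seed": design.seed, "sample_index": sample_index},
    )


def _effect_bins(
    template: MetaboliteTemplate, width: float = 0.02, anchor: float = 0.0
) -> list[str]:
    labels = []
    for lo, hi in template.support_intervals():
        k_lo = math.floor((lo - anchor) / width)
        k_hi = math.floor((hi - anchor) / width)
        for k in range(k_lo, k_hi + 1):
            blo, bhi = anchor + k * width, anchor + (k + 1) * width
            lab = f"b{blo:.2f}_{bhi:.2f}"
            if lab not in labels:
                labels.append(lab)
    return labels


def ground_truth(design: CohortDesign, bin_width: float = 0.02) -> GroundTruth:
    """Seed-free ground truth derived from the design's effect map."""
    lib = {t.name: t for t in design.resolve_library()}
    rows = []
    for name, lfc in design.effects.items():
        direction = "up" if lfc > 0 else ("down" if lfc < 0 else "none")
        rows.append(
            {
                "metabolite": name,
                "log2_fc": lfc,
                "direction": direction,
                "bins": ";".join(_effect_bins(lib[name], width=bin_width)),
            }
        )
    table = pd.DataFrame(rows, columns=["metabolite", "log2_fc", "direction", "bins"])
    return GroundTruth(table=table)


def simulate_cohort(
    design: CohortDesign,
) -> tuple[list[Spectrum], pd.DataFrame, GroundTruth]:
    """Simulate the full two-group cohort.

    Returns the spectra (group A first), a metadata table, and the
    seed-independent ground truth.
    """
    spectra = [
        simulate_spectrum(design, "A", i) for i in range(design.n_group_a)
    ] + [simulate_spectrum(design, "B", i) for i in range(design.n_group_b)]
    metadata = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in spectra],
            "group": [s.meta["group"] for s in spectra],
            "matrix": design.matrix,
        }
    )
    return spectra, metadata, ground_truth(design)


# ---------------------------------------------------------------------------
# stock designs mirroring the study's cohort shapes


def default_plasma_design(seed: int = 0, **overrides) -> CohortDesign:
    """15-vs-14 plasma cohort with strong planted effects (lipoproteins and
    glucose down, isoleucine and creatine up in group B)."""
    effects = {
        "HDL-CH3": -0.8,
        "VLDL-CH3": -0.6,
        "lipid-CH2": -0.7,
        "isoleucine": 0.8,
        "alpha-glucose": -0.9,
        "beta-glucose": -0.9,
        "creatine": 0.7,
    }
    params = dict(
        n_group_a=15,
        n_group_b=14,
        matrix="plasma",
        effects=effects,
        seed=seed,
    )
    params.update(overrides)
    return CohortDesign(**params)


def default_brain_design(strength: str = "strong", seed: int = 0, **overrides) -> CohortDesign:
    """15-vs-14 brain cohort; ``strength='strong'`` plants a broad
    cortex-like effect panel, ``'weak'`` only small glutamine/NAA shifts."""
    if strength == "strong":
        effects = {
            "alanine": -0.6,
            "glutamate": -0.5,
            "glutamine": 0.7,
            "N-acetylaspartate": 0.6,
            "glycerol": 0.5,
            "serine": -0.7,
            "histidine": -0.5,
            "phenylalanine": -0.5,
        }
    elif strength == "weak":
        effects = {"glutamine": 0.5, "N-acetylaspartate": 0.45}
    else:
        raise ValueError("strength must be 'strong' or 'weak'")
    params = dict(
        n_group_a=15,
        n_group_b=14,
        matrix="brain",
        effects=effects,
        seed=seed,
    )
    params.update(overrides)
    return CohortDesign(**params)
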