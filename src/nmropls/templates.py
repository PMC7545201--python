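"""Metabolite peak templates for the synthetic cohort generator.

Peak centers and half-widths are library constants taken from standard
1H chemical-shift references (HMDB-style values); they are deliberately
simple fixed multiplets, not coupling simulations. Broad lipoprotein
envelopes emulate what survives CPMG editing in plasma.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["Peak", "MetaboliteTemplate", "default_metabolite_library"]

PPM_MIN, PPM_MAX = -0.5, 10.0


@dataclass(frozen=True)
class Peak:
    center: float  # ppm
    rel_intensity: float  # unitless, >= 0
    half_width: float  # ppm (HWHM), > 0
    shape: str = "lorentzian"  # or "gaussian"

    def __post_init__(self) -> None:
        if not (PPM_MIN <= self.center <= PPM_MAX):
            raise ValueError(f"peak center {self.center} outside [{PPM_MIN}, {PPM_MAX}] ppm")
        if self.rel_intensity < 0:
            raise ValueError("rel_intensity must be >= 0")
        if self.half_width <= 0:
            raise ValueError("half_width must be > 0")
        if self.shape not in ("lorentzian", "gaussian"):
            raise ValueError(f"unknown peak shape {self.shape!r}")


@dataclass(frozen=True)
class MetaboliteTemplate:
    name: str
    matrix: str  # plasma | brain | both
    peaks: tuple[Peak, ...]
    base_abundance: float = 1.0

    def __post_init__(self) -> None:
        if self.matrix not in ("plasma", "brain", "both"):
            raise ValueError(f"invalid matrix {self.matrix!r}")
        if not self.peaks:
            raise ValueError(f"template {self.name!r} has no peaks")
        if sum(p.rel_intensity for p in self.peaks) <= 0:
            raise ValueError(f"template {self.name!r} has zero total intensity")
        if self.base_abundance <= 0:
            raise ValueError("base_abundance must be > 0")

    def support_intervals(self) -> list[tuple[float, float]]:
        """One (lo, hi) interval per peak: center +/- half_width."""
        return [(p.center - p.half_width, p.center + p.half_width) for p in self.peaks]


def _L(center: float, rel: float, hw: float = 0.0035) -> Peak:
    return Peak(center, rel, hw, "lorentzian")


def _broad(center: float, rel: float, hw: float) -> Peak:
    return Peak(center, rel, hw, "lorentzian")


# Sharp-line half-width default 0.0035 ppm (~2.5 Hz at 700 MHz); lipoprotein
# envelopes get large half-widths in lieu of simulating CPMG relaxation.

_PLASMA = [
    MetaboliteTemplate("HDL-CH3", "plasma", (_broad(0.84, 1.0, 0.040),), 6.0),
    MetaboliteTemplate("VLDL-CH3", "plasma", (_broad(0.88, 1.0, 0.035),), 4.0),
    MetaboliteTemplate("lipid-CH2", "plasma", (_broad(1.27, 1.0, 0.045),), 8.0),
    MetaboliteTemplate(
        "isoleucine",
        "plasma",
        (_L(0.94, 1.0), _L(1.01, 0.9), _L(1.98, 0.3), _L(3.67, 0.2)),
        1.2,
    ),
    # glucose ring-proton multiplets in the retained 3.2-3.9 ppm region;
    # the alpha/beta anomeric protons (5.23/4.64) fall in masked regions
    # and are omitted on purpose.
    MetaboliteTemplate(
        "alpha-glucose",
        "plasma",
        (_L(3.40, 0.6), _L(3.53, 0.8), _L(3.71, 0.9), _L(3.83, 0.7)),
        5.0,
    ),
    MetaboliteTemplate(
        "beta-glucose",
        "plasma",
        (_L(3.25, 0.8), _L(3.47, 0.9), _L(3.89, 0.6)),
        5.0,
    ),
    MetaboliteTemplate("creatine", "both", (_L(3.03, 1.0), _L(3.93, 0.7)), 1.5),
    # lactate: CH3 doublet at the 1.33 plasma reference + CH quartet; the
    # 1.33 line is kept slightly taller so referencing picks it stably
    MetaboliteTemplate(
        "lactate",
        "both",
        (_L(1.33, 1.0), _L(1.34, 0.95), _L(4.11, 0.3)),
        4.0,
    ),
]

_BRAIN = [
    MetaboliteTemplate("alanine", "brain", (_L(1.47, 1.0), _L(1.49, 1.0)), 1.5),
    MetaboliteTemplate(
        "glutamate", "brain", (_L(2.05, 0.8), _L(2.35, 1.0), _L(3.75, 0.4)), 3.0
    ),
    MetaboliteTemplate(
        "glutamine", "brain", (_L(2.14, 0.9), _L(2.45, 1.0), _L(3.77, 0.3)), 2.5
    ),
    MetaboliteTemplate(
        "N-acetylaspartate", "brain", (_L(2.01, 1.0), _L(2.49, 0.3), _L(2.68, 0.3)), 3.0
    ),
    MetaboliteTemplate(
        "glycerol", "brain", (_L(3.56, 0.9), _L(3.65, 0.9), _L(3.79, 0.5)), 1.5
    ),
    MetaboliteTemplate("serine", "brain", (_L(3.85, 0.8), _L(3.96, 1.0)), 1.5),
    MetaboliteTemplate(
        "histidine", "brain", (_L(7.09, 0.8), _L(7.80, 1.0)), 0.8
    ),
    MetaboliteTemplate(
        "phenylalanine", "brain", (_L(7.33, 0.8), _L(7.38, 1.0), _L(7.43, 0.8)), 0.8
    ),
    MetaboliteTemplate("creatine", "both", (_L(3.03, 1.0), _L(3.93, 0.7)), 2.0),
    MetaboliteTemplate(
        "lactate", "both", (_L(1.33, 1.0), _L(1.34, 0.95), _L(4.11, 0.3)), 2.0
    ),
    # TSP chemical-shift reference defining delta 0
    MetaboliteTemplate("TSP", "brain", (_L(0.0, 1.0),), 3.0),
]


def default_metabolite_library(matrix: str) -> list[MetaboliteTemplate]:
    """Built-in metabolite panel for the given sample matrix."""
    if matrix == "plasma":
        return list(_PLASMA)
    if matrix == "brain":
        return list(_BRAIN)
    raise ValueError(f"unknown matrix {matrix!r}; expected 'plasma' or 'brain'")
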