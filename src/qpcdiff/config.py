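"""Domain types and configuration containers.

Coordinate convention used throughout the package: pixels are centred on
integer coordinates, 0-based, row-major arrays; polygon vertices are given
as (x, y) = (column, row) pairs.

Lengths are expressed in nanometres unless stated otherwise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

PHENOTYPES = ("progenitor", "neuron", "astrocyte")


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass(frozen=True)
class OpticalConfig:
    """Optical parameters of the simulated two-mode microscope.

    Parameters
    ----------
    wavelength : float
        Illumination wavelength in nm. Both imaging arms share one LED
        source (default 660 nm, chosen in the instrument for low
        photo-toxicity).
    phase_step : float
        Reference-phase increment delta between successive phase-contrast
        frames, in radians (default pi/2).
    n_steps : int
        Number of phase-stepped frames acquired (>= 3; the four-step
        arctangent estimator needs exactly 4).
    n_medium, n_cell : float
        Refractive indices of the culture medium and of cytoplasm. The
        height conversion uses only the contrast ``n_cell - n_medium``.
    penetration_depth : float
        1/e decay length of the evanescent field in nm; sets the optical
        section thickness of the total-internal-reflection channel.
    background_intensity : float
        Intensity of the unobstructed background, arbitrary camera units.
    noise_sd : float
        Standard deviation of additive Gaussian intensity noise.
    pixel_size : float
        Physical size of one pixel in nm (lateral sampling).
    """

    wavelength: float = 660.0
    phase_step: float = np.pi / 2
    n_steps: int = 4
    n_medium: float = 1.33
    n_cell: float = 1.38
    penetration_depth: float = 150.0
    background_intensity: float = 1.0
    noise_sd: float = 0.0
    pixel_size: float = 200.0

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValidationError("wavelength must be positive")
        if self.n_steps < 3:
            raise ValidationError("n_steps must be >= 3")
        if self.n_cell <= self.n_medium:
            raise ValidationError("n_cell must exceed n_medium")
        if self.penetration_depth <= 0:
            raise ValidationError("penetration_depth must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")

    @property
    def delta_n(self) -> float:
        return self.n_cell - self.n_medium


@dataclass(frozen=True)
class PhenotypeParams:
    """Morphological parameter distributions for one phenotype class.

    Each ``*_dist`` field is a (mean, sd) pair; samples are drawn from a
    normal truncated at +/- 3 sd (and at physical lower bounds). Areas in
    px^2, aspect ratios dimensionless (>= 1), heights and substrate gaps
    in nm. Defaults encode the morphological orderings the discrimination
    protocol relies on: astrocytes are large, flat, round and adherent;
    neurons are small-bodied, elongated, tall and lifted off the substrate;
    progenitors are elongated and intermediate.
    """

    class_label: str
    area_dist: tuple[float, float]
    aspect_ratio_dist: tuple[float, float]
    height_dist: tuple[float, float]
    substrate_gap_dist: tuple[float, float]

    def __post_init__(self) -> None:
        if self.class_label not in PHENOTYPES:
            raise ValidationError(f"unknown phenotype {self.class_label!r}")
        for name in ("area_dist", "aspect_ratio_dist", "height_dist"):
            mean, _sd = getattr(self, name)
            if mean <= 0:
                raise ValidationError(f"{name} mean must be positive")
        if self.aspect_ratio_dist[0] < 1:
            raise ValidationError("aspect ratio mean must be >= 1")
        if self.substrate_gap_dist[0] < 0:
            raise ValidationError("substrate gap mean must be >= 0")


def default_phenotypes() -> dict[str, PhenotypeParams]:
    """Default phenotype parameter set for the simulated 15-day culture.

    The orderings matter more than the absolute values: astrocyte mean area
    exceeds neuron mean area and its aspect-ratio mean is closer to 1, and
    substrate gaps make astrocytes (adherent) visible to the evanescent
    channel while neuron cell bodies sit beyond its reach.
    """
    return {
        "progenitor": PhenotypeParams(
            "progenitor",
            area_dist=(800.0, 150.0),
            aspect_ratio_dist=(2.5, 0.4),
            height_dist=(1300.0, 150.0),
            substrate_gap_dist=(80.0, 30.0),
        ),
        "neuron": PhenotypeParams(
            "neuron",
            area_dist=(600.0, 120.0),
            aspect_ratio_dist=(2.8, 0.5),
            height_dist=(1500.0, 200.0),
            substrate_gap_dist=(500.0, 80.0),
        ),
        "astrocyte": PhenotypeParams(
            "astrocyte",
            area_dist=(2500.0, 400.0),
            aspect_ratio_dist=(1.3, 0.15),
            height_dist=(400.0, 80.0),
            substrate_gap_dist=(30.0, 15.0),
        ),
    }


@dataclass
class CellGroundTruth:
    """Ground truth for one simulated cell.

    ``outline`` is an (n, 2) array of (x, y) vertices forming a simple
    polygon. ``height_peak`` is the apex of the dome-shaped height profile;
    ``substrate_gap`` the (uniform) membrane-coverslip separation.
    ``area`` and ``aspect_ratio`` are the analytically requested values the
    outline was built from.
    """

    cell_id: str
    class_label: str
    outline: np.ndarray
    area: float
    aspect_ratio: float
    height_peak: float
    substrate_gap: float
    amplitude_transmittance: float = 1.0
    center: tuple[float, float] = (0.0, 0.0)
    semi_axes: tuple[float, float] = (0.0, 0.0)
    angle: float = 0.0
    # rows of (harmonic m, amplitude, phase) describing the smooth radial
    # boundary perturbation; empty for a pure ellipse
    radial_coeffs: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))

    def __post_init__(self) -> None:
        self.outline = np.asarray(self.outline, dtype=float)
        if self.height_peak < 0 or self.substrate_gap < 0:
            raise ValidationError("height and substrate gap must be >= 0")
        if not (0 < self.amplitude_transmittance <= 1):
            raise ValidationError("amplitude transmittance must be in (0, 1]")


@dataclass
class ScenePhantom:
    """Ground-truth synthetic scene for one culture day."""

    grid_shape: tuple[int, int]
    cells: list[CellGroundTruth]
    day: int = 0


@dataclass
class FocalStack:
    """Through-focus image stack with known best-focus plane."""

    images: list[np.ndarray]
    focus_positions: np.ndarray
    true_best_index: int

    def __post_init__(self) -> None:
        shapes = {im.shape for im in self.images}
        if len(shapes) > 1:
            raise ValidationError("all planes must share one shape")
        d = np.diff(np.asarray(self.focus_positions, dtype=float))
        if d.size and not (np.all(d > 0) or np.all(d < 0)):
            raise ValidationError("focus positions must be strictly monotone")

    def __len__(self) -> int:
        return len(self.images)


def field_of_view_area_ratio(achieved_um: float = 400.0,
                             designed_um: float = 250.0) -> float:
    """Ratio of achieved to designed field-of-view areas.

    The population-imaging arm achieves a 400 um field of view against a
    250 um design, a (400/250)^2 = 2.56-fold gain in image area.
    """
    if achieved_um <= 0 or designed_um <= 0:
        raise ValidationError("fields of view must be positive")
    return (achieved_um / designed_um) ** 2
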