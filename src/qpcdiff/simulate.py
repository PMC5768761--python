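"""Synthetic scene generation and forward models of the two imaging modes.

A :class:`~qpcdiff.config.ScenePhantom` holds ground-truth cells (outline,
phenotype, height profile, substrate gap). Two renderers turn a phantom into
what the instrument records:

* a phase-stepped intensity stack, via the two-beam interference law
  ``I_k = E0^2 + E1^2 + 2 E0 E1 cos(dphi + k*delta)`` where E0 is the
  unscattered zero order and E1 the sample-scattered field;
* an evanescent-illumination frame in which adherent material frustrates
  total internal reflection and appears dark on a bright background, with
  contrast decaying as ``exp(-gap / penetration_depth)``.

The scene is treated as a thin phase-amplitude object
``t(x, y) = a(x, y) * exp(i * theta(x, y))``; the zero order is the spatial
mean of ``t`` (the global phase is rotated so the zero order is real, which
is the freedom any interferometer has in choosing its phase origin). The
scattered field is ``t`` minus the zero order, pointwise. By construction
the reconstruction chain recovers the phase of ``t`` relative to the zero
order; re-referencing to the background level recovers ``theta`` itself.

The exponential gap-contrast law is a deliberate simplification of
frustrated total internal reflection: only the penetration-depth scale is
physical, so quantitative gap-contrast values are model-internal.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.draw import polygon as draw_polygon

from .config import (
    CellGroundTruth,
    FocalStack,
    OpticalConfig,
    PhenotypeParams,
    ScenePhantom,
    ValidationError,
    default_phenotypes,
)
from .reconstruct import PhaseStepStack


class PlacementError(RuntimeError):
    """Raised when cells cannot be placed without overlap."""


class ForwardModelError(RuntimeError):
    """Raised when a scene violates the |E1| < |E0| disambiguation bound."""


# ---------------------------------------------------------------------------
# sampling helpers

def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      low: float = 0.0) -> float:
    """Normal draw truncated at +/- 3 sd and at ``low`` (by resampling)."""
    if sd == 0:
        return max(mean, low)
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if abs(v - mean) <= 3 * sd and v >= low:
            return v
    return max(mean, low)  # pragma: no cover - pathological parameters


_N_VERTICES = 96
_HARMONICS = (3, 4, 5)
_MAX_EPS = 0.04  # per-harmonic bound keeps outlines simple and moments stable


def _sample_blob(rng: np.random.Generator, area: float, aspect_ratio: float,
                 center: tuple[float, float], angle: float) -> dict:
    """Build an ellipse-like blob outline with smooth radial perturbation.

    Harmonics m >= 3 leave the second central moments unchanged to first
    order, so the recorded aspect ratio stays the measured one; the radius
    is renormalised so the enclosed area equals ``area`` analytically.
    """
    a = np.sqrt(area * aspect_ratio / np.pi)
    b = np.sqrt(area / (np.pi * aspect_ratio))
    coeffs = np.array([
        [m, rng.uniform(0.0, _MAX_EPS), rng.uniform(0, 2 * np.pi)]
        for m in _HARMONICS
    ])
    phi = np.linspace(0, 2 * np.pi, _N_VERTICES, endpoint=False)
    r = 1.0 + sum(e * np.cos(m * phi + p) for m, e, p in coeffs)
    # mean of r^2 over phi is 1 + sum(eps^2)/2 for pure cosine harmonics
    r = r / np.sqrt(1.0 + np.sum(coeffs[:, 1] ** 2) / 2.0)
    x = a * r * np.cos(phi)
    y = b * r * np.sin(phi)
    ca, sa = np.cos(angle), np.sin(angle)
    outline = np.column_stack([
        center[0] + ca * x - sa * y,
        center[1] + sa * x + ca * y,
    ])
    return {
        "outline": outline,
        "semi_axes": (a, b),
        "radial_coeffs": coeffs,
        "bound_radius": max(a, b) * (1 + coeffs[:, 1].sum()),
    }


def make_phantom(day: int, mixture: dict[str, int],
                 params: dict[str, PhenotypeParams] | None = None,
                 grid_shape: tuple[int, int] = (512, 512),
                 seed: int = 0) -> ScenePhantom:
    """Generate a ground-truth scene with non-overlapping cells.

    Parameters
    ----------
    day : culture day recorded on the phantom.
    mixture : phenotype label -> number of cells to place.
    params : phenotype parameter set; defaults to :func:`default_phenotypes`.
    grid_shape : (rows, cols) of the pixel grid.
    seed : seed for all sampling; identical inputs give identical phantoms.

    Raises
    ------
    PlacementError
        If a class's cells cannot be placed without overlap, naming the class.
    """
    if params is None:
        params = default_phenotypes()
    rng = np.random.default_rng(seed)
    rows, cols = grid_shape
    cells: list[CellGroundTruth] = []
    placed: list[tuple[float, float, float]] = []  # (cx, cy, bound radius)

    for label in sorted(mixture):
        count = mixture[label]
        if count < 0:
            raise ValidationError("cell counts must be >= 0")
        if count == 0:
            continue
        p = params[label]
        for i in range(count):
            area = _truncated_normal(rng, *p.area_dist, low=9.0)
            ar = _truncated_normal(rng, *p.aspect_ratio_dist, low=1.0)
            height = _truncated_normal(rng, *p.height_dist)
            gap = _truncated_normal(rng, *p.substrate_gap_dist)
            angle = rng.uniform(0, np.pi)
            blob = _sample_blob(rng, area, ar, (0.0, 0.0), angle)
            rad = blob["bound_radius"] + 2.0
            if 2 * rad >= min(rows, cols):
                raise PlacementError(
                    f"grid {grid_shape} too small for a {label} cell")
            for attempt in range(400):
                cx = rng.uniform(rad, cols - 1 - rad)
                cy = rng.uniform(rad, rows - 1 - rad)
                if all((cx - ox) ** 2 + (cy - oy) ** 2 > (rad + orad) ** 2
                       for ox, oy, orad in placed):
                    break
            else:
                raise PlacementError(
                    f"could not place {label} cell {i + 1}/{count} "
                    f"without overlap on grid {grid_shape}")
            outline = blob["outline"] + [cx, cy]
            placed.append((cx, cy, rad))
            cells.append(CellGroundTruth(
                cell_id=f"d{day:02d}_{label}_{i:03d}",
                class_label=label,
                outline=outline,
                area=area,
                aspect_ratio=ar,
                height_peak=height,
                substrate_gap=gap,
                amplitude_transmittance=rng.uniform(0.93, 1.0),
                center=(cx, cy),
                semi_axes=blob["semi_axes"],
                angle=angle,
                radial_coeffs=blob["radial_coeffs"],
            ))
    return ScenePhantom(grid_shape=grid_shape, cells=cells, day=day)


# ---------------------------------------------------------------------------
# per-cell rasterised fields

def cell_mask(cell: CellGroundTruth, grid_shape: tuple[int, int]) -> np.ndarray:
    """Boolean filled mask of a cell's outline on the full grid."""
    rr, cc = draw_polygon(cell.outline[:, 1], cell.outline[:, 0],
                          shape=grid_shape)
    mask = np.zeros(grid_shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def _normalized_radius(cell: CellGroundTruth,
                       yy: np.ndarray, xx: np.ndarray) -> np.ndarray:
    """Elliptical radius of grid points, normalised to 1 on the outline."""
    a, b = cell.semi_axes
    ca, sa = np.cos(cell.angle), np.sin(cell.angle)
    dx = xx - cell.center[0]
    dy = yy - cell.center[1]
    u = (ca * dx + sa * dy) / a
    v = (-sa * dx + ca * dy) / b
    rho = np.hypot(u, v)
    phi = np.arctan2(v, u)
    r_edge = 1.0 + sum(e * np.cos(m * phi + p)
                       for m, e, p in cell.radial_coeffs)
    r_edge = r_edge / np.sqrt(
        1.0 + np.sum(cell.radial_coeffs[:, 1] ** 2) / 2.0)
    return rho / r_edge


def height_field(phantom: ScenePhantom) -> np.ndarray:
    """Ground-truth height map h(x, y) in nm; zero outside cells.

    Each cell carries a dome profile ``h_peak * sqrt(1 - rho^2)`` where rho
    is the boundary-normalised elliptical radius, mimicking a rounded
    adherent cell body.
    """
    h = np.zeros(phantom.grid_shape)
    yy, xx = np.mgrid[0:phantom.grid_shape[0], 0:phantom.grid_shape[1]]
    for cell in phantom.cells:
        mask = cell_mask(cell, phantom.grid_shape)
        rho = _normalized_radius(cell, yy, xx)
        dome = cell.height_peak * np.sqrt(np.clip(1 - rho ** 2, 0.0, None))
        h[mask] = dome[mask]
    return h


def phase_delay_field(phantom: ScenePhantom,
                      optics: OpticalConfig) -> np.ndarray:
    """Ground-truth sample phase delay theta(x, y) in radians.

    Inverts the height conversion: ``theta = 2 pi (n_cell - n_medium) h /
    lambda``, with heights and wavelength in the same units (nm).
    """
    return 2 * np.pi * optics.delta_n * height_field(phantom) / optics.wavelength


def substrate_gap_field(phantom: ScenePhantom) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel substrate gap z(x, y) in nm and the union cell mask."""
    z = np.zeros(phantom.grid_shape)
    covered = np.zeros(phantom.grid_shape, dtype=bool)
    for cell in phantom.cells:
        mask = cell_mask(cell, phantom.grid_shape)
        z[mask] = cell.substrate_gap
        covered |= mask
    return z, covered


def amplitude_field(phantom: ScenePhantom) -> np.ndarray:
    """Amplitude transmittance a(x, y); 1 outside cells."""
    a = np.ones(phantom.grid_shape)
    for cell in phantom.cells:
        a[cell_mask(cell, phantom.grid_shape)] = cell.amplitude_transmittance
    return a


# ---------------------------------------------------------------------------
# forward models

def scene_field(phantom: ScenePhantom, optics: OpticalConfig) -> dict:
    """Decompose the scene into zero-order / scattered-order fields.

    Returns a dict with scalar ``E0``, maps ``E1`` and ``delta_phi``, the
    ground-truth ``theta_true``, and ``phase_ref`` — the phase the zero
    order carried before the global rotation that makes it real. The
    reconstructed phase of any pixel equals ``theta_true - phase_ref``.

    Raises
    ------
    ForwardModelError
        If ``|E1| >= |E0|`` anywhere; the amplitude disambiguation in the
        reconstruction assumes a dominant zero order.
    """
    theta = phase_delay_field(phantom, optics)
    amp = amplitude_field(phantom)
    t = amp * np.exp(1j * theta)
    e0c = t.mean()
    phase_ref = float(np.angle(e0c))
    t = t * np.exp(-1j * phase_ref)
    e0 = float(np.abs(e0c))
    scattered = t - e0
    e1 = np.abs(scattered)
    if np.any(e1 >= e0):
        raise ForwardModelError(
            "scene phase/amplitude contrast too strong: |E1| >= |E0|; "
            "reduce cell heights or coverage")
    return {
        "E0": e0,
        "E1": e1,
        "delta_phi": np.angle(scattered),
        "theta_true": theta,
        "phase_ref": phase_ref,
    }


def render_qpc_stack(phantom: ScenePhantom, optics: OpticalConfig,
                     seed: int = 0) -> PhaseStepStack:
    """Render the phase-stepped intensity stack of a phantom.

    Frame k is ``bg * (E0^2 + E1^2 + 2 E0 E1 cos(dphi + k delta))`` plus
    additive Gaussian noise of sd ``optics.noise_sd``, clipped at zero.
    Deterministic given (phantom, optics, seed).
    """
    f = scene_field(phantom, optics)
    rng = np.random.default_rng(seed)
    frames = []
    for k in range(optics.n_steps):
        ideal = (f["E0"] ** 2 + f["E1"] ** 2
                 + 2 * f["E0"] * f["E1"]
                 * np.cos(f["delta_phi"] + k * optics.phase_step))
        ideal = optics.background_intensity * ideal
        if optics.noise_sd > 0:
            ideal = ideal + rng.normal(0.0, optics.noise_sd, ideal.shape)
        frames.append(np.clip(ideal, 0.0, None))
    return PhaseStepStack(frames=frames, step=optics.phase_step)


def render_tirm(phantom: ScenePhantom, optics: OpticalConfig,
                seed: int = 0, c_max: float = 0.9) -> np.ndarray:
    """Render the evanescent-illumination frame of a phantom.

    Background pixels sit at ``background_intensity``; cell pixels are
    darkened by ``c_max * exp(-gap / penetration_depth)``, so adherent
    cells (small gap) are darkest and intensity increases monotonically
    with gap. Additive Gaussian noise, clipped at zero.
    """
    if not (0 < c_max <= 1):
        raise ValidationError("c_max must be in (0, 1]")
    z, covered = substrate_gap_field(phantom)
    bg = optics.background_intensity
    img = np.full(phantom.grid_shape, float(bg))
    img[covered] = bg * (1 - c_max * np.exp(-z[covered]
                                            / optics.penetration_depth))
    if optics.noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, optics.noise_sd, img.shape)
    return np.clip(img, 0.0, None)


def render_focal_stack(base_image: np.ndarray, n_planes: int,
                       blur_scale: float, true_best_index: int,
                       seed: int = 0, noise_sd: float = 0.0,
                       plane_spacing: float = 1000.0) -> FocalStack:
    """Simulate a through-focus stack around a known best-focus plane.

    Plane i is the base image blurred by a Gaussian of width
    ``blur_scale * |i - true_best_index|`` pixels; the best plane itself is
    the unblurred base image (pixel-identical when ``noise_sd`` is 0).
    """
    if n_planes < 2:
        raise ValidationError("a focal stack needs at least 2 planes")
    if not (0 <= true_best_index < n_planes):
        raise ValidationError("true_best_index out of range")
    base = np.asarray(base_image, dtype=float)
    rng = np.random.default_rng(seed)
    images = []
    for i in range(n_planes):
        sigma = blur_scale * abs(i - true_best_index)
        img = base.copy() if sigma == 0 else ndimage.gaussian_filter(
            base, sigma, mode="nearest")
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, img.shape)
        images.append(img)
    positions = plane_spacing * (np.arange(n_planes) - true_best_index)
    return FocalStack(images=images, focus_positions=positions,
                      true_best_index=true_best_index)
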