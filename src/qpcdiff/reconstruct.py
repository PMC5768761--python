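"""Quantitative phase-contrast reconstruction from phase-stepped stacks.

Four frames acquired at reference-phase steps of pi/2 obey

    I_k = E0^2 + E1^2 + 2 E0 E1 cos(dphi + k pi/2),   k = 0..3,

where E0 is the unscattered zero-order amplitude, E1 the scattered
(diffracted-order) amplitude and dphi their phase difference. The stack
determines

    dphi        = atan2(I3 - I1, I0 - I2)
    S = E0^2+E1^2 = sum_k I_k / 4
    P = E0 E1     = sqrt((I3 - I1)^2 + (I0 - I2)^2) / 4

(the /4 is required for consistency with the intensity law: I0 - I2 =
4 E0 E1 cos dphi and I3 - I1 = 4 E0 E1 sin dphi, so the bare square root
evaluates to 4 E0 E1). E0^2 and E1^2 are then the two roots of
``u^2 - S u + P^2 = 0``, disambiguated by the physical assumption that the
zero order dominates, E0 > E1. The sample phase delay relative to the zero
order follows as

    theta = atan2(E1 sin dphi, E0 + E1 cos dphi),

and converts to physical height via ``h = theta * lambda / (2 pi dn)``.

Four-quadrant ``atan2`` is used throughout (single-quadrant arctangent
cannot represent the full (-pi, pi] phase range). No phase unwrapping is
performed; theta is reported wrapped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .config import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class PhaseStepStack:
    """Intensity frames I(x, y; k) acquired at reference phases k * step."""

    frames: list[np.ndarray]
    step: float = np.pi / 2

    def __post_init__(self) -> None:
        self.frames = [np.asarray(f, dtype=float) for f in self.frames]
        shapes = {f.shape for f in self.frames}
        if len(shapes) > 1:
            raise ValidationError("all frames must share one shape")
        if any(not np.all(np.isfinite(f)) for f in self.frames):
            raise ValidationError("frames contain non-finite intensities")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class ComplexFieldMap:
    """Per-pixel reconstructed field: amplitudes E0 >= E1 and phase dphi."""

    E0: np.ndarray
    E1: np.ndarray
    delta_phi: np.ndarray
    n_clipped: int = 0  # pixels where noise made the discriminant negative


@dataclass
class PhaseMap:
    """Sample phase delay theta (radians), optionally converted to height."""

    theta: np.ndarray
    height: np.ndarray | None = None


def reconstruct_field(stack: PhaseStepStack) -> ComplexFieldMap:
    """Recover (E0, E1, dphi) from a four-step stack.

    Negative discriminants ``S^2 - 4 P^2`` (a noise effect: the estimated
    product momentarily exceeds S/2) are clipped to zero, which assigns
    ``E0 = E1 = sqrt(S/2)``; the number of affected pixels is logged and
    recorded on the result.
    """
    if len(stack) != 4:
        raise ValidationError(
            f"the four-step estimator needs exactly 4 frames, got {len(stack)}")
    if not np.isclose(stack.step, np.pi / 2):
        raise ValidationError("the four-step estimator requires step = pi/2")
    i0, i1, i2, i3 = stack.frames
    num = i3 - i1
    den = i0 - i2
    delta_phi = np.arctan2(num, den)
    s = (i0 + i1 + i2 + i3) / 4.0
    p = np.sqrt(num ** 2 + den ** 2) / 4.0
    disc = s ** 2 - 4.0 * p ** 2
    n_clipped = int(np.count_nonzero(disc < 0))
    if n_clipped:
        logger.info("clipped negative discriminant at %d pixels", n_clipped)
    root = np.sqrt(np.clip(disc, 0.0, None))
    e0 = np.sqrt((s + root) / 2.0)
    e1_sq = np.clip((s - root) / 2.0, 0.0, None)
    e1 = np.sqrt(e1_sq)
    return ComplexFieldMap(E0=e0, E1=e1, delta_phi=delta_phi,
                           n_clipped=n_clipped)


def phase_delay(fieldmap: ComplexFieldMap,
                reference: str = "none") -> PhaseMap:
    """Compute the sample phase delay theta from a reconstructed field.

    ``theta = atan2(E1 sin dphi, E0 + E1 cos dphi)`` is the phase of the
    total field E0 + E1 e^{i dphi} relative to the zero order. Because an
    interferometer only measures phase relative to its reference, theta
    carries a global offset equal to the scene-mean phase; pass
    ``reference="background"`` to subtract the phase level of the
    weakest-scatter pixels (the lowest-|E1| decile), which restores
    theta = 0 on empty background.
    """
    if reference not in ("none", "background"):
        raise ValidationError(f"unknown reference {reference!r}")
    theta = np.arctan2(fieldmap.E1 * np.sin(fieldmap.delta_phi),
                       fieldmap.E0 + fieldmap.E1 * np.cos(fieldmap.delta_phi))
    if reference == "background":
        cut = np.quantile(fieldmap.E1, 0.10)
        theta = theta - np.median(theta[fieldmap.E1 <= cut])
    return PhaseMap(theta=theta)


def phase_to_height(phase: PhaseMap, wavelength: float,
                    n_cell: float, n_medium: float) -> PhaseMap:
    """Convert phase delay to physical height, in the wavelength's units.

    ``h = theta * lambda / (2 pi (n_cell - n_medium))``; negative theta
    yields negative height (interpretation is left to the caller — it
    normally indicates a region optically thinner than the reference).
    """
    if n_cell <= n_medium:
        raise ValidationError("n_cell must exceed n_medium")
    h = phase.theta * wavelength / (2 * np.pi * (n_cell - n_medium))
    return PhaseMap(theta=phase.theta, height=h)


_MODES = ("bright_field", "dark_field", "zernike_pc")


def synthesize_mode(fieldmap: ComplexFieldMap, mode: str,
                    pc_attenuation: float = 1.0,
                    pc_shift: float = np.pi / 2) -> np.ndarray:
    """Synthesise an imaging mode from the reconstructed complex field.

    Having amplitude and phase of both orders, any downstream image can be
    computed after the fact:

    * ``bright_field``: |E0 + E1 e^{i dphi}|^2 — plain transmission;
    * ``dark_field``:   E1^2 — scattered light only;
    * ``zernike_pc``:   |a E0 e^{i shift} + E1 e^{i dphi}|^2 — classic
      phase contrast, the zero order phase-shifted (default pi/2) and
      attenuated by ``a``; approximately linear in small phase delays,
      unlike bright field which is quadratic.
    """
    if mode not in _MODES:
        raise ValidationError(f"unknown mode {mode!r}; one of {_MODES}")
    if not (0 < pc_attenuation <= 1):
        raise ValidationError("pc_attenuation must be in (0, 1]")
    scattered = fieldmap.E1 * np.exp(1j * fieldmap.delta_phi)
    if mode == "bright_field":
        total = fieldmap.E0 + scattered
    elif mode == "dark_field":
        return np.asarray(fieldmap.E1, dtype=float) ** 2
    else:
        total = pc_attenuation * fieldmap.E0 * np.exp(1j * pc_shift) + scattered
    return np.abs(total) ** 2


def render_frames(fieldmap: ComplexFieldMap, step: float = np.pi / 2,
                  n_steps: int = 4) -> PhaseStepStack:
    """Re-render noiseless frames from a field via the intensity law.

    Inverse of :func:`reconstruct_field`; used for consistency checks.
    """
    frames = [
        fieldmap.E0 ** 2 + fieldmap.E1 ** 2
        + 2 * fieldmap.E0 * fieldmap.E1 * np.cos(fieldmap.delta_phi + k * step)
        for k in range(n_steps)
    ]
    return PhaseStepStack(frames=frames, step=step)
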