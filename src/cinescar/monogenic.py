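"""Monogenic-signal amplitude/phase maps and their ED-ES differences.

The monogenic signal is the 2-D generalisation of the analytic signal: an
image is band-passed with an isotropic, zero-DC log-Gabor filter H (the even
part), and the two odd quadrature components q1, q2 are produced by the
Riesz transform (frequency multipliers i*u/|u| and i*v/|u|).  Together they
form S_m = w + i*q1 + j*q2, whose spherical decomposition yields a local
amplitude A = sqrt(w^2 + q1^2 + q2^2) (local energy / structure strength)
and a local phase P (structure type: line vs. edge), both invariant to the
mean intensity level.

For wall-motion imaging, A and P are computed on the end-diastolic and
end-systolic frames only, and the parametric maps are the differences
MA = A_ED - A_ES and MP = P_ED - P_ES: regions that deform between ED and ES
change their local structure, giving large differences; a scarred, poorly
contracting sector changes little.

The local phase is evaluated as atan2(sqrt(q1^2+q2^2), w), giving the
standard [0, pi] range that stays continuous where w changes sign; a
``literal-arctan`` variant with the one-argument arctan (range
(-pi/2, pi/2]) is provided for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .fourier import ParametricImage

PhaseConvention = Literal["atan2", "literal-arctan"]


@dataclass(frozen=True)
class MonogenicFilters:
    """Frequency-domain log-Gabor and Riesz transfer functions.

    ``h_even`` is the radial log-Gabor magnitude (real, >= 0, zero at DC).
    ``r1`` and ``r2`` are the real-valued direction cosines u/|u| and v/|u|
    of the Riesz multipliers (the factor i is applied at evaluation time),
    zero at DC, satisfying r1^2 + r2^2 = 1 off DC and odd symmetry.
    """

    h_even: np.ndarray
    r1: np.ndarray
    r2: np.ndarray
    wavelength: float
    sigma_on_f: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.h_even.shape


@dataclass
class MonogenicComponents:
    """Even/odd filter responses with derived local amplitude and phase."""

    w: np.ndarray
    q1: np.ndarray
    q2: np.ndarray
    amplitude: np.ndarray
    phase: np.ndarray


@dataclass
class DiffImages:
    """ED-ES difference maps of monogenic amplitude (MA) and phase (MP)."""

    ma: ParametricImage
    mp: ParametricImage


def build_filters(
    shape: tuple[int, int], wavelength: float = 16.0, sigma_on_f: float = 0.5
) -> MonogenicFilters:
    """Construct the log-Gabor / Riesz filter bank for a frame shape.

    The radial transfer function is G(f) = exp(-ln^2(f/f0) / (2 ln^2(s)))
    with centre frequency f0 = 1/wavelength (cycles/pixel) and bandwidth
    ratio s = sigma_on_f; G peaks at 1 exactly at f0 and is forced to 0 at
    DC so constant offsets never pass.
    """
    if wavelength < 2:
        raise ValueError("wavelength must be >= 2 pixels (Nyquist)")
    if not 0.0 < sigma_on_f < 1.0:
        raise ValueError("sigma_on_f must lie in (0, 1)")
    H, W = shape
    v = np.fft.fftfreq(H)[:, None]  # row (y) frequency, cycles/pixel
    u = np.fft.fftfreq(W)[None, :]  # column (x) frequency
    radius = np.hypot(u, v)
    radius_safe = np.where(radius == 0, 1.0, radius)
    f0 = 1.0 / wavelength
    log_gabor = np.exp(-(np.log(radius_safe / f0) ** 2) / (2 * np.log(sigma_on_f) ** 2))
    log_gabor = np.where(radius == 0, 0.0, log_gabor)
    r1 = np.where(radius == 0, 0.0, u / radius_safe)
    r2 = np.where(radius == 0, 0.0, v / radius_safe)
    return MonogenicFilters(
        h_even=log_gabor,
        r1=np.broadcast_to(r1, (H, W)).copy(),
        r2=np.broadcast_to(r2, (H, W)).copy(),
        wavelength=float(wavelength),
        sigma_on_f=float(sigma_on_f),
    )


def monogenic(
    image: np.ndarray,
    filters: MonogenicFilters,
    phase_convention: PhaseConvention = "atan2",
) -> MonogenicComponents:
    """Monogenic decomposition of one frame into (w, q1, q2, A, P).

    The convolutions run in the frequency domain (periodic boundaries):
    w is the even log-Gabor response, q1/q2 the Riesz quadrature pair of w.
    """
    image = np.asarray(image, dtype=float)
    if image.shape != filters.shape:
        raise ValueError(
            f"image shape {image.shape} does not match filters {filters.shape}"
        )
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    spectrum = np.fft.fft2(image)
    even_spec = spectrum * filters.h_even
    w = np.real(np.fft.ifft2(even_spec))
    q1 = np.real(np.fft.ifft2(even_spec * (1j * filters.r1)))
    q2 = np.real(np.fft.ifft2(even_spec * (1j * filters.r2)))
    odd = np.hypot(q1, q2)
    amplitude = np.sqrt(w**2 + q1**2 + q2**2)
    if phase_convention == "atan2":
        phase = np.arctan2(odd, w)
    elif phase_convention == "literal-arctan":
        with np.errstate(divide="ignore", invalid="ignore"):
            phase = np.arctan(np.divide(odd, w, out=np.full_like(w, np.inf), where=w != 0))
        phase = np.where((odd == 0) & (w == 0), 0.0, phase)
        phase = np.where(np.isinf(phase), np.pi / 2, phase)
    else:
        raise ValueError(f"unknown phase convention: {phase_convention}")
    phase = np.where(amplitude == 0, 0.0, phase)
    return MonogenicComponents(w=w, q1=q1, q2=q2, amplitude=amplitude, phase=phase)


def monogenic_diff(
    ed_frame: np.ndarray,
    es_frame: np.ndarray,
    filters: MonogenicFilters,
    phase_convention: PhaseConvention = "atan2",
    patient_id: str = "",
    slice_index: int = 0,
) -> DiffImages:
    """ED-ES monogenic difference maps MA = A_ED - A_ES, MP = P_ED - P_ES.

    No phase unwrapping is applied: with the [0, pi] per-frame phase range
    the difference lives in [-pi, pi].
    """
    ed_frame = np.asarray(ed_frame, dtype=float)
    es_frame = np.asarray(es_frame, dtype=float)
    if ed_frame.shape != es_frame.shape:
        raise ValueError("ED and ES frames must share a shape")
    ed = monogenic(ed_frame, filters, phase_convention)
    es = monogenic(es_frame, filters, phase_convention)
    ma = ParametricImage(
        ed.amplitude - es.amplitude, "MA", patient_id=patient_id, slice_index=slice_index
    )
    mp = ParametricImage(
        ed.phase - es.phase, "MP", patient_id=patient_id, slice_index=slice_index
    )
    return DiffImages(ma=ma, mp=mp)
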