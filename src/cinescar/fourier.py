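"""Fourier first-harmonic parametric images of wall motion.

Each pixel of a cine loop traces a videointensity time series f(t) over the
cardiac cycle.  Assuming the series is periodic over the T acquired frames,
it is modelled by its mean level and first harmonic,

    f(t) ~= A0 + A1 * sin(w*t + P1),        w = 2*pi/T,

and the amplitude A1 and phase P1 of the best least-squares fit become the
pixel values of two parametric images: FA (amplitude, indexing how strongly
the pixel's intensity is modulated by wall motion) and FP (phase, indexing
when in the cycle the modulation occurs).  Over scarred, hypokinetic
myocardium the modulation — and hence FA — is reduced.

For uniformly sampled complete cycles the least-squares solution coincides
with the DFT bin-1 coefficient, which is what we compute: A1 = 2|X1|/T and
P1 = angle(X1) + pi/2 folded to (-pi, pi] (the +pi/2 converts the DFT's
cosine reference to the sine convention above).  The equivalence with an
explicit normal-equations solve is asserted in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .io import CineLoop

Kind = Literal["C", "FA", "FP", "MA", "MP"]

# relative-to-mean amplitude below which the phase is meaningless noise
_PHASE_EPS = 1e-12


@dataclass(frozen=True)
class HarmonicFit:
    """Mean level, first-harmonic amplitude and phase of one pixel series."""

    a0: float
    a1: float
    p1: float
    omega: float


@dataclass
class ParametricImage:
    """A single-channel 2-D map tagged with its kind (C, FA, FP, MA, MP)."""

    data: np.ndarray
    kind: Kind
    patient_id: str = ""
    slice_index: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("a parametric image must be 2-D")


def _wrap_phase(p: np.ndarray | float) -> np.ndarray | float:
    """Wrap to the half-open interval (-pi, pi]."""
    wrapped = -np.mod(-np.asarray(p) + math.pi, 2 * math.pi) + math.pi
    return wrapped


def fit_first_harmonic(series: np.ndarray) -> HarmonicFit:
    """Least-squares first-harmonic fit of a single intensity time series."""
    series = np.asarray(series, dtype=float)
    if series.ndim != 1 or series.size < 3:
        raise ValueError("series must be 1-D with at least 3 samples")
    if not np.all(np.isfinite(series)):
        raise ValueError("series contains non-finite values")
    a0, a1, p1 = _bin1_fit(series[:, None])
    return HarmonicFit(
        a0=float(a0[0]),
        a1=float(a1[0]),
        p1=float(p1[0]),
        omega=2 * math.pi / series.size,
    )


def _bin1_fit(stack: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised DFT bin-1 fit along axis 0 of a T x N stack."""
    T = stack.shape[0]
    a0 = stack.mean(axis=0)
    t = np.arange(T)
    x1 = np.tensordot(np.exp(-2j * math.pi * t / T), stack, axes=(0, 0))
    a1 = 2.0 * np.abs(x1) / T
    p1 = _wrap_phase(np.angle(x1) + math.pi / 2)
    # phase is defined as 0 where the harmonic vanishes
    degenerate = a1 <= _PHASE_EPS * np.maximum(np.abs(a0), 1.0)
    p1 = np.where(degenerate, 0.0, p1)
    a1 = np.where(degenerate, a1, a1)
    return a0, a1, p1


def fourier_images(loop: CineLoop) -> tuple[ParametricImage, ParametricImage]:
    """Per-pixel first-harmonic amplitude (FA) and phase (FP) maps.

    Computed on the full frame; cropping to the LV bounding box happens in
    the preprocessing stage.
    """
    T, H, W = loop.frames.shape
    flat = loop.frames.reshape(T, H * W)
    _, a1, p1 = _bin1_fit(flat)
    fa = ParametricImage(
        a1.reshape(H, W), "FA", patient_id=loop.patient_id, slice_index=loop.slice_index
    )
    fp = ParametricImage(
        p1.reshape(H, W), "FP", patient_id=loop.patient_id, slice_index=loop.slice_index
    )
    return fa, fp


def fit_first_harmonic_lstsq(series: np.ndarray) -> HarmonicFit:
    """Direct normal-equations least-squares fit (reference implementation).

    Solves for (A0, A1*sin(P1), A1*cos(P1)) in the linearised model
    A0 + A1*sin(P1)*cos(w t) + A1*cos(P1)*sin(w t) and converts back to
    amplitude/phase.  Kept as an independently-coded cross-check of the
    DFT route; the two must agree for uniformly sampled full cycles.
    """
    series = np.asarray(series, dtype=float)
    T = series.size
    w = 2 * math.pi / T
    t = np.arange(T)
    design = np.column_stack([np.ones(T), np.cos(w * t), np.sin(w * t)])
    coef, *_ = np.linalg.lstsq(design, series, rcond=None)
    a0, c, s = coef
    a1 = math.hypot(c, s)
    p1 = math.atan2(c, s) if a1 > _PHASE_EPS * max(abs(a0), 1.0) else 0.0
    return HarmonicFit(a0=float(a0), a1=float(a1), p1=float(_wrap_phase(p1)), omega=w)
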