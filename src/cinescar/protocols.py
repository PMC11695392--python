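"""Evaluation protocols: fixed channel combinations P1-P12.

Each protocol is an ordered subset of the five per-slice channels — the
myocardium-masked ED cine frame C, the Fourier amplitude/phase maps FA/FP,
and the monogenic ED-ES difference maps MA/MP — stacked into one n-channel
network input.  C always comes first.  This table is the single source of
truth: the CNN's input channel count is always derived from it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fourier import Kind, ParametricImage


@dataclass(frozen=True)
class ProtocolSpec:
    name: str
    channels: tuple[Kind, ...]

    @property
    def n_channels(self) -> int:
        return len(self.channels)


# P3 = [C, FP] completes the symmetric design (Fourier phase alone),
# pairing with P2 = [C, FA] the way P6 pairs with P5 on the monogenic side.
PROTOCOLS: dict[str, ProtocolSpec] = {
    name: ProtocolSpec(name, channels)
    for name, channels in {
        "P1": ("C",),
        "P2": ("C", "FA"),
        "P3": ("C", "FP"),
        "P4": ("C", "FA", "FP"),
        "P5": ("C", "MA"),
        "P6": ("C", "MP"),
        "P7": ("C", "MA", "MP"),
        "P8": ("C", "FA", "MA"),
        "P9": ("C", "FP", "MP"),
        "P10": ("C", "FA", "FP", "MA", "MP"),
        "P11": ("C", "FA", "MP"),
        "P12": ("C", "FP", "MA"),
    }.items()
}


@dataclass
class ProtocolSample:
    """One training/eval record: channel stack, binary label, provenance."""

    tensor: np.ndarray  # (n_channels, side, side)
    label: int  # SCAR = 1, NL = 0
    patient_id: str
    slice_index: int

    def __post_init__(self) -> None:
        self.tensor = np.asarray(self.tensor, dtype=float)
        if self.tensor.ndim != 3:
            raise ValueError("sample tensor must be (n_channels, side, side)")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 (NL) or 1 (SCAR)")


def get_protocol(name: str) -> ProtocolSpec:
    try:
        return PROTOCOLS[name]
    except KeyError:
        raise KeyError(
            f"unknown protocol {name!r}; expected one of {', '.join(PROTOCOLS)}"
        ) from None


def build_sample(
    protocol: ProtocolSpec,
    channel_map: dict[Kind, ParametricImage],
    label: int,
    patient_id: str = "",
    slice_index: int = 0,
) -> ProtocolSample:
    """Stack the protocol's channels (already preprocessed) into one sample."""
    layers = []
    shape = None
    for kind in protocol.channels:
        if kind not in channel_map:
            raise KeyError(f"missing channel {kind} for protocol {protocol.name}")
        data = channel_map[kind].data
        if shape is None:
            shape = data.shape
        elif data.shape != shape:
            raise ValueError(
                f"channel {kind} shape {data.shape} does not match {shape}"
            )
        layers.append(data)
    return ProtocolSample(
        tensor=np.stack(layers, axis=0),
        label=int(label),
        patient_id=patient_id,
        slice_index=slice_index,
    )
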