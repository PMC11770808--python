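"""Core containers for timestamped photon data.

Photons are stored as integer clock ticks together with two channel labels:
the excitation source (donor or acceptor laser pulse, known from
pulsed-interleaved excitation) and the detection channel (donor or acceptor
spectral window).  Conversions to seconds happen only at analysis boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: channel label values
DONOR = 0
ACCEPTOR = 1

#: default clock period in seconds (40 MHz sync clock)
DEFAULT_CLOCK_PERIOD = 25e-9


@dataclass
class PhotonStream:
    """A time-ordered stream of photons with channel labels.

    Parameters
    ----------
    timestamps : ndarray of int64
        Photon arrival times in clock ticks, sorted ascending (ties allowed).
    excitation : ndarray of uint8
        Excitation source per photon, ``DONOR`` (0) or ``ACCEPTOR`` (1).
    detection : ndarray of uint8
        Detection channel per photon, ``DONOR`` (0) or ``ACCEPTOR`` (1).
    clock_period : float
        Seconds per clock tick.
    """

    timestamps: np.ndarray
    excitation: np.ndarray
    detection: np.ndarray
    clock_period: float = DEFAULT_CLOCK_PERIOD

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=np.int64)
        self.excitation = np.asarray(self.excitation, dtype=np.uint8)
        self.detection = np.asarray(self.detection, dtype=np.uint8)
        if not (len(self.timestamps) == len(self.excitation) == len(self.detection)):
            raise ValueError("timestamps/excitation/detection lengths differ")
        if self.clock_period <= 0:
            raise ValueError("clock_period must be positive")

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def times_s(self) -> np.ndarray:
        """Arrival times in seconds."""
        return self.timestamps * self.clock_period

    def validate(self) -> None:
        """Raise ``ValueError`` if the stream violates its invariants."""
        if np.any(np.diff(self.timestamps) < 0):
            idx = int(np.argmax(np.diff(self.timestamps) < 0))
            raise ValueError(f"timestamps not sorted ascending at row {idx + 1}")
        for name, arr in (("excitation", self.excitation), ("detection", self.detection)):
            bad = ~np.isin(arr, (DONOR, ACCEPTOR))
            if np.any(bad):
                raise ValueError(f"unknown {name} label at row {int(np.argmax(bad))}")


@dataclass
class SimulationTruth:
    """Ground-truth bookkeeping attached to a simulated dataset.

    ``state`` holds the conformational state (0 open, 1 closed) of the
    emitter at each photon's arrival, or -1 for photons without a hidden
    state (acceptor-excited, background, single-labeled molecules).
    """

    burst_bounds: np.ndarray  # (n_bursts, 2) start/stop ticks (inclusive)
    label: list  # 'dual' | 'donor_only' | 'acceptor_only' per burst
    state: np.ndarray  # int8 per photon, aligned with the stream
    paths: list = field(default_factory=list)  # DwellPath per burst (dual only -> None otherwise)


@dataclass
class PhotonDataset:
    """A photon stream plus acquisition metadata (and simulation truth)."""

    stream: PhotonStream
    meta: dict = field(default_factory=dict)
    truth: SimulationTruth | None = None

    @property
    def clock_period(self) -> float:
        return self.stream.clock_period


@dataclass
class BurstPhotons:
    """Photons of a single burst used by the photon-by-photon HMM.

    Only donor-excitation photons enter the likelihood; ``color`` is the
    detection channel (0 donor, 1 acceptor).
    """

    ticks: np.ndarray  # int64
    color: np.ndarray  # uint8

    def __post_init__(self) -> None:
        self.ticks = np.asarray(self.ticks, dtype=np.int64)
        self.color = np.asarray(self.color, dtype=np.uint8)
        if len(self.ticks) != len(self.color):
            raise ValueError("ticks and color lengths differ")

    def __len__(self) -> int:
        return len(self.ticks)
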