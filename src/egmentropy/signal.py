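"""The universal input container: a finite, single-channel electrogram segment.

Every stage of the pipeline — entropy estimation, artifact injection,
Monte Carlo sweeps — consumes and produces :class:`Signal` objects.
Amplitudes are in arbitrary units (intracardiac recordings are only
defined up to amplifier gain); the sampling rate defaults to 1 kHz,
the rate of the study the cohort emulates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Recognised class labels: organised / mildly fractionated ("NC") vs
#: complex fractionated ("C") atrial electrograms.
CLASS_LABELS = ("NC", "C")


@dataclass(frozen=True)
class Signal:
    """A real-valued sample sequence with sampling rate and optional class label.

    Parameters
    ----------
    samples : array-like of float
        Amplitude sequence, length >= 1, all values finite.
    fs : float
        Sampling rate in Hz (> 0). Default 1000.
    label : str or None
        Class tag, one of ``"NC"``, ``"C"``, or None when unclassified.
    id : str
        Opaque identifier used in reports and file headers.
    """

    samples: np.ndarray
    fs: float = 1000.0
    label: str | None = None
    id: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must all be finite")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.label is not None and self.label not in CLASS_LABELS:
            raise ValueError(f"label must be one of {CLASS_LABELS} or None")
        samples.setflags(write=False)
        object.__setattr__(self, "samples", samples)

    @property
    def n(self) -> int:
        """Record length N."""
        return int(self.samples.size)

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.n / self.fs

    def sd(self) -> float:
        """Population (divide-by-N) standard deviation of the samples."""
        return float(self.samples.std())

    def with_samples(self, samples: np.ndarray, id_suffix: str = "") -> "Signal":
        """A copy carrying new samples but the same rate and label."""
        return Signal(samples, fs=self.fs, label=self.label, id=self.id + id_suffix)


def as_signal(x, fs: float = 1000.0) -> Signal:
    """Coerce an array-like into a :class:`Signal` (no-op when already one)."""
    if isinstance(x, Signal):
        return x
    return Signal(np.asarray(x, dtype=np.float64), fs=fs)
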