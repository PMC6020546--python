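"""Synthetic acquisition artifacts: spike trains and sample loss.

Three perturbation models, all pure functions of (input, parameters, seed):

* **Spikes** — each of the N sample positions independently hosts a
  one-sample impulse with probability p_s (a per-sample Bernoulli reading
  of a binomial occurrence process, so positions never collide); impulse
  amplitudes are i.i.d. uniform on (-3*lambda, 3*lambda) where lambda is
  the host signal's peak-to-peak amplitude. Spikes are superimposed
  additively onto the host samples.
* **Distributed sample loss** — round(eta*N) individual samples removed at
  uniformly random distinct positions; survivors keep their order.
* **Consecutive sample loss** — one contiguous block of round(eta*N)
  samples removed, its start uniform over every position where it fits.

Both loss modes shorten the record to N - round(eta*N).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .entropy import EntropyParams, sampen_value
from .signal import Signal, as_signal

__all__ = [
    "SpikeTrain",
    "LossSpec",
    "PerturbationLevel",
    "SPIKE_GRID",
    "LOSS_GRID",
    "PERTURBATION_KINDS",
    "peak_to_peak",
    "make_spike_train",
    "add_spikes",
    "spike_entropy_reference",
    "remove_samples_distributed",
    "remove_samples_consecutive",
    "DegenerateReferenceError",
]

#: The study's spike-probability and loss-fraction grids (level 0 is the
#: unperturbed baseline and is added by the sweep driver).
SPIKE_GRID = (0.01, 0.02, 0.03, 0.04, 0.05, 0.10, 0.15, 0.20, 0.30, 0.40, 0.50)
LOSS_GRID = (0.01, 0.02, 0.03, 0.04, 0.05, 0.10, 0.15, 0.20, 0.30, 0.40, 0.50)

PERTURBATION_KINDS = ("spikes", "loss_distributed", "loss_consecutive")


class DegenerateReferenceError(ValueError):
    """Every realisation of a spike-train reference had undefined SampEn."""


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class SpikeTrain:
    """A sparse set of one-sample impulses: s(t) = sum_i a_i * delta(t - t_i).

    ``locations`` are strictly increasing 0-based sample indices,
    ``amplitudes`` the matching impulse heights, bounded by three times
    the host's peak-to-peak amplitude ``lambda_pp``.
    """

    locations: np.ndarray
    amplitudes: np.ndarray
    p_s: float
    lambda_pp: float

    def __post_init__(self) -> None:
        loc = np.asarray(self.locations, dtype=np.int64)
        amp = np.asarray(self.amplitudes, dtype=np.float64)
        if loc.shape != amp.shape or loc.ndim != 1:
            raise ValueError("locations and amplitudes must be aligned 1-D arrays")
        if loc.size and np.any(np.diff(loc) <= 0):
            raise ValueError("locations must be strictly increasing")
        if not 0.0 <= self.p_s <= 1.0:
            raise ValueError("p_s must lie in [0, 1]")
        if self.lambda_pp < 0:
            raise ValueError("lambda_pp must be nonnegative")
        if amp.size and np.max(np.abs(amp)) > 3.0 * self.lambda_pp:
            raise ValueError("spike amplitudes must lie within +/-3*lambda_pp")
        loc.setflags(write=False)
        amp.setflags(write=False)
        object.__setattr__(self, "locations", loc)
        object.__setattr__(self, "amplitudes", amp)

    @property
    def n(self) -> int:
        return int(self.locations.size)


@dataclass(frozen=True)
class LossSpec:
    """A sample-loss setting: fraction ``eta`` and mode."""

    eta: float
    mode: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("eta must lie in [0, 1]")
        if self.mode not in ("distributed", "consecutive"):
            raise ValueError("mode must be 'distributed' or 'consecutive'")


@dataclass(frozen=True)
class PerturbationLevel:
    """One grid point of a sweep: perturbation kind, level, realisation count."""

    kind: str
    level: float
    n_realisations: int = 50

    def __post_init__(self) -> None:
        if self.kind not in PERTURBATION_KINDS:
            raise ValueError(f"kind must be one of {PERTURBATION_KINDS}")
        if not 0.0 <= self.level <= 1.0:
            raise ValueError("level must lie in [0, 1]")
        if self.n_realisations < 1:
            raise ValueError("n_realisations must be >= 1")


def peak_to_peak(x: Signal) -> float:
    """max(x) - min(x); the amplitude scale lambda of the spike model."""
    x = as_signal(x)
    return float(np.ptp(x.samples))


def make_spike_train(
    N: int,
    p_s: float,
    lambda_pp: float,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> SpikeTrain:
    """Random spike train over N positions (see module docstring for the model)."""
    if N < 1:
        raise ValueError("N must be >= 1")
    if not 0.0 <= p_s <= 1.0:
        raise ValueError("p_s must lie in [0, 1]")
    if lambda_pp < 0:
        raise ValueError("lambda_pp must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    occupied = rng.random(N) < p_s
    locations = np.flatnonzero(occupied)
    amplitudes = rng.uniform(-3.0 * lambda_pp, 3.0 * lambda_pp, locations.size)
    return SpikeTrain(locations, amplitudes, p_s=p_s, lambda_pp=lambda_pp)


def add_spikes(x: Signal, train: SpikeTrain) -> Signal:
    """Superimpose the train onto the signal (additive; length unchanged)."""
    x = as_signal(x)
    if train.n and (train.locations[0] < 0 or train.locations[-1] >= x.n):
        raise IndexError("spike locations fall outside the signal")
    y = x.samples.copy()
    y[train.locations] += train.amplitudes
    return x.with_samples(y)


def spike_entropy_reference(
    N: int,
    p_s: float,
    lambda_pp: float,
    entropy_params: EntropyParams = EntropyParams(),
    n_realisations: int = 50,
    seed: int = 0,
) -> tuple[float, int]:
    """Mean SampEn of pure spike trains on a zero host (the Fig-4-style
    dashed reference curve), with the count of skipped undefined realisations.

    Realisations whose SampEn is undefined — e.g. a constant (empty) train
    under SD-relative tolerance — are skipped; if every realisation is
    undefined a :class:`DegenerateReferenceError` is raised.
    """
    relative = entropy_params.r_mode == "relative_sd"
    vals = np.empty(n_realisations)
    for i in range(n_realisations):
        rng = np.random.default_rng(np.random.SeedSequence((seed, i)))
        train = make_spike_train(N, p_s, lambda_pp, rng)
        samples = np.zeros(N)
        samples[train.locations] = train.amplitudes
        vals[i] = sampen_value(samples, entropy_params.m, entropy_params.r, relative)
    n_undefined = int(np.isnan(vals).sum())
    if n_undefined == n_realisations:
        raise DegenerateReferenceError(
            f"all {n_realisations} spike-train realisations had undefined SampEn"
        )
    return float(np.nanmean(vals)), n_undefined


def remove_samples_distributed(
    x: Signal, eta: float, seed: int | np.random.SeedSequence | np.random.Generator = 0
) -> Signal:
    """Remove round(eta*N) scattered samples; survivors keep their order."""
    x = as_signal(x)
    if eta < 0:
        raise ValueError("eta must be nonnegative")
    k = _round_half_up(eta * x.n)
    if k >= x.n:
        raise ValueError(f"cannot remove {k} of {x.n} samples")
    if k == 0:
        return x
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    drop = rng.choice(x.n, size=k, replace=False)
    return x.with_samples(np.delete(x.samples, drop))


def remove_samples_consecutive(
    x: Signal, eta: float, seed: int | np.random.SeedSequence | np.random.Generator = 0
) -> Signal:
    """Remove one contiguous block of round(eta*N) samples at a random start."""
    x = as_signal(x)
    if eta < 0:
        raise ValueError("eta must be nonnegative")
    k = _round_half_up(eta * x.n)
    if k >= x.n:
        raise ValueError(f"cannot remove {k} of {x.n} samples")
    if k == 0:
        return x
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    start = int(rng.integers(0, x.n - k + 1))
    return x.with_samples(np.delete(x.samples, slice(start, start + k)))


def apply_perturbation(
    x: Signal, kind: str, level: float, rng: np.random.Generator
) -> Signal:
    """Dispatch one perturbation realisation; level 0 is an exact identity."""
    if kind == "spikes":
        if level == 0.0:
            return x
        train = make_spike_train(as_signal(x).n, level, peak_to_peak(x), rng)
        return add_spikes(x, train)
    if kind == "loss_distributed":
        return remove_samples_distributed(x, level, rng)
    if kind == "loss_consecutive":
        return remove_samples_consecutive(x, level, rng)
    raise ValueError(f"unknown perturbation kind {kind!r}")
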