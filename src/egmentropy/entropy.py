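"""Sample Entropy (SampEn) estimation.

SampEn(m, r, N) is the negative natural logarithm of the conditional
probability that two subsequences of a series that match within tolerance
r for m consecutive points (Chebyshev distance) remain within r for m+1
points, with template self-matches excluded::

    SampEn = -ln( A / B )

where B counts ordered template pairs (i, j), i != j, with d_ij(m) <= r,
and A counts the same pairs at length m+1. Both template lengths are drawn
from the same index range 1..N-m, so the per-template normalisations cancel
in the ratio. Larger values mean a less predictable (more complex) series.

Two implementations are provided: an optimized numba-compiled kernel used
throughout the pipeline, and a deliberately naive pure-Python reference
(:func:`sample_entropy_bruteforce`) kept as an independent oracle for
testing; the two must agree to machine precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .signal import Signal, as_signal

__all__ = [
    "EntropyParams",
    "MatchCounts",
    "EntropyResult",
    "EntropyError",
    "DegenerateToleranceError",
    "RecordTooShortError",
    "resolve_tolerance",
    "count_matches",
    "sample_entropy",
    "sample_entropy_bruteforce",
]


class EntropyError(ValueError):
    """Base class for SampEn precondition failures."""


class DegenerateToleranceError(EntropyError):
    """SD-relative tolerance requested on a constant signal."""


class RecordTooShortError(EntropyError):
    """Fewer than two templates of length m+1 available (N < m + 2)."""


@dataclass(frozen=True)
class EntropyParams:
    """SampEn parameters.

    ``m`` is the embedding (template) length, ``r`` the similarity
    tolerance. With ``r_mode="relative_sd"`` (the standard convention,
    and the default) the tolerance actually applied is ``r`` times the
    population SD of the analysed signal; with ``"absolute"`` it is ``r``
    in signal units. The study defaults are m=2, r=0.2.
    """

    m: int = 2
    r: float = 0.2
    r_mode: str = "relative_sd"

    def __post_init__(self) -> None:
        if not (isinstance(self.m, (int, np.integer)) and self.m >= 1):
            raise ValueError(f"m must be a positive integer, got {self.m}")
        if not self.r > 0:
            raise ValueError(f"r must be positive, got {self.r}")
        if self.r_mode not in ("relative_sd", "absolute"):
            raise ValueError("r_mode must be 'relative_sd' or 'absolute'")


@dataclass(frozen=True)
class MatchCounts:
    """Raw and normalised template-match counts (ordered-pair convention).

    ``B_total`` / ``A_total`` are sums over templates i of the number of
    j != i within tolerance at length m / m+1. ``B_mean`` / ``A_mean`` are
    the averaged per-template probabilities B^m(r), A^m(r); they carry the
    same ratio as the totals. ``n_templates`` is N - m.
    """

    B_total: int
    A_total: int
    B_mean: float
    A_mean: float
    n_templates: int

    def __post_init__(self) -> None:
        if self.A_total > self.B_total:
            raise ValueError("A_total cannot exceed B_total")


#: Sentinel meaning "SampEn undefined" (no matches at one of the lengths).
UNDEFINED = None


@dataclass(frozen=True)
class EntropyResult:
    """SampEn value with the evidence it was computed from.

    ``value`` is ``None`` (the UNDEFINED sentinel) when either match total
    is zero; infinities are never produced. ``r_absolute`` is the tolerance
    actually applied, after SD scaling.
    """

    value: float | None
    counts: MatchCounts
    r_absolute: float

    @property
    def is_defined(self) -> bool:
        return self.value is not None


def resolve_tolerance(x: Signal, params: EntropyParams) -> float:
    """Tolerance in signal units: r itself, or r x SD(x) in relative mode.

    Raises
    ------
    DegenerateToleranceError
        If ``r_mode="relative_sd"`` and the signal is constant (SD = 0).
    """
    x = as_signal(x)
    if params.r_mode == "absolute":
        return float(params.r)
    sd = x.sd()
    if sd == 0.0:
        raise DegenerateToleranceError(
            "SD-relative tolerance is undefined for a constant signal"
        )
    return float(params.r * sd)


@njit(cache=True)
def _count_kernel(x: np.ndarray, m: int, r: float):  # pragma: no cover - jitted
    n_templates = x.shape[0] - m
    b = 0
    a = 0
    for i in range(n_templates):
        for j in range(i + 1, n_templates):
            d = 0.0
            for k in range(m):
                dk = abs(x[i + k] - x[j + k])
                if dk > d:
                    d = dk
            if d <= r:
                b += 2  # ordered pairs: (i, j) and (j, i)
                dk = abs(x[i + m] - x[j + m])
                if dk > d:
                    d = dk
                if d <= r:
                    a += 2
    return b, a


def count_matches(x: Signal, m: int, r_abs: float) -> MatchCounts:
    """Ordered-pair template match counts at lengths m and m+1.

    Both lengths use templates starting at positions 1..N-m, so every
    length-m template has a length-(m+1) extension and an (m+1)-match
    always implies an m-match (hence ``A_total <= B_total``).

    Raises
    ------
    RecordTooShortError
        If N < m + 2 (fewer than two templates of length m+1).
    """
    x = as_signal(x)
    if not r_abs > 0:
        raise ValueError(f"r_abs must be positive, got {r_abs}")
    if x.n < m + 2:
        raise RecordTooShortError(
            f"record of length {x.n} too short for m={m} (need N >= {m + 2})"
        )
    b, a = _count_kernel(x.samples, m, float(r_abs))
    n_templates = x.n - m
    denom = n_templates * (n_templates - 1)
    return MatchCounts(
        B_total=int(b),
        A_total=int(a),
        B_mean=b / denom,
        A_mean=a / denom,
        n_templates=n_templates,
    )


def sample_entropy(x: Signal, params: EntropyParams = EntropyParams()) -> EntropyResult:
    """SampEn(m, r, N) of a signal; value is None when no matches exist.

    The estimate is invariant to adding a constant to the signal, and in
    SD-relative mode also to multiplying it by a positive constant.
    """
    x = as_signal(x)
    r_abs = resolve_tolerance(x, params)
    counts = count_matches(x, params.m, r_abs)
    if counts.A_total == 0 or counts.B_total == 0:
        value = None
    else:
        value = -math.log(counts.A_total / counts.B_total)
    return EntropyResult(value=value, counts=counts, r_absolute=r_abs)


def sampen_value(samples: np.ndarray, m: int, r: float, relative: bool) -> float:
    """Fast scalar path used by Monte Carlo sweeps: SampEn or NaN if undefined.

    Skips Signal validation; ``relative`` selects SD-relative tolerance.
    Returns NaN both when undefined and when the tolerance degenerates
    (constant input in relative mode), so sweep code can treat either as
    a skipped realisation.
    """
    n = samples.shape[0]
    if n < m + 2:
        return math.nan
    if relative:
        sd = samples.std()
        if sd == 0.0:
            return math.nan
        r = r * sd
    b, a = _count_kernel(samples, m, r)
    if a == 0 or b == 0:
        return math.nan
    return -math.log(a / b)


def sample_entropy_bruteforce(
    x: Signal, params: EntropyParams = EntropyParams()
) -> EntropyResult:
    """Independent nested-loop reference implementation (testing oracle).

    Follows the defining equations literally — per-template counts B_i, A_i
    over j != i, averaged into B^m(r), A^m(r) — with no shared code with the
    optimized kernel beyond tolerance resolution.
    """
    x = as_signal(x)
    r_abs = resolve_tolerance(x, params)
    m = params.m
    n = x.n
    if n < m + 2:
        raise RecordTooShortError(
            f"record of length {n} too short for m={m} (need N >= {m + 2})"
        )
    s = [float(v) for v in x.samples]
    n_templates = n - m
    b_i = [0] * n_templates
    a_i = [0] * n_templates
    for i in range(n_templates):
        for j in range(n_templates):
            if j == i:
                continue
            d_m = max(abs(s[i + k] - s[j + k]) for k in range(m))
            if d_m <= r_abs:
                b_i[i] += 1
                d_m1 = max(d_m, abs(s[i + m] - s[j + m]))
                if d_m1 <= r_abs:
                    a_i[i] += 1
    b_total = sum(b_i)
    a_total = sum(a_i)
    norm = n_templates - 1
    b_mean = sum(v / norm for v in b_i) / n_templates
    a_mean = sum(v / norm for v in a_i) / n_templates
    counts = MatchCounts(
        B_total=b_total,
        A_total=a_total,
        B_mean=b_mean,
        A_mean=a_mean,
        n_templates=n_templates,
    )
    if a_total == 0 or b_total == 0:
        value = None
    else:
        value = -math.log(a_total / b_total)
    return EntropyResult(value=value, counts=counts, r_absolute=r_abs)
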