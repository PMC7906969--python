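"""Quantitative EEG features computed on a single-channel epoch.

The canonical feature vector has 30 entries, in a fixed named order:

* six relative band powers (delta, theta, alpha, mu, beta, gamma),
* six absolute band powers (same bands, in uV^2),
* spectral entropy of the normalised periodogram (nats),
* Shannon entropy of the amplitude-normalised signal (nats),
* normalised Lempel-Ziv (LZ76) complexity of the mean-binarised signal,
* eight order statistics / moments (min, max, median, mean, sample variance,
  SD, skew, excess kurtosis),
* seven signal-shape descriptors (curve length, energy, nonlinear/Teager
  energy, sixth power, sum, Hjorth mobility, Hjorth complexity).

Spectral features come from the plain one-sided periodogram (rectangular
window, no detrending).  Band edges are the conventional clinical ranges,
delta 1-4, theta 4-8, alpha 8-12, mu 12-16, beta 16-25, gamma 25-40 Hz; band
integration uses half-open intervals [lo, hi).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal
from scipy import stats as sp_stats

__all__ = [
    "BandDefinition",
    "Spectrum",
    "DEFAULT_BANDS",
    "FEATURE_NAMES",
    "compute_periodogram",
    "band_powers",
    "spectral_entropy",
    "signal_entropy",
    "lempel_ziv_complexity",
    "binarize_at_mean",
    "lz76_phrase_count",
    "hjorth_parameters",
    "time_domain_features",
    "extract_feature_vector",
]


@dataclass(frozen=True)
class BandDefinition:
    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"band {self.name}: need lo < hi")


DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("mu", 12.0, 16.0),
    BandDefinition("beta", 16.0, 25.0),
    BandDefinition("gamma", 25.0, 40.0),
)

#: Canonical order of the 30-entry feature vector.
FEATURE_NAMES: tuple[str, ...] = (
    tuple(f"rel_{b.name}_power" for b in DEFAULT_BANDS)
    + tuple(f"abs_{b.name}_power" for b in DEFAULT_BANDS)
    + ("spectral_entropy", "entropy", "lzc")
    + ("minimum", "maximum", "median", "mean", "variance", "sd", "skew",
       "kurtosis")
    + ("curve_length", "energy", "nonlinear_energy", "sixth_power", "sum",
       "mobility", "complexity")
)
assert len(FEATURE_NAMES) == 30


@dataclass
class Spectrum:
    """One-sided power spectral density: frequencies 0..Nyquist, power >= 0."""

    frequencies: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.frequencies.shape != self.power.shape:
            raise ValueError("frequencies and power must have the same length")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")


def compute_periodogram(samples: np.ndarray, rate: float) -> Spectrum:
    """One-sided periodogram with a rectangular window and no detrending.

    With density scaling, ``sum(power) * df`` equals the mean squared
    amplitude of the signal (discrete Parseval identity).
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size < 2:
        raise ValueError("need at least 2 samples")
    freqs, pxx = sp_signal.periodogram(
        samples, fs=rate, window="boxcar", detrend=False, scaling="density"
    )
    return Spectrum(frequencies=freqs, power=pxx)


def band_powers(
    spec: Spectrum, bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
) -> tuple[dict[str, float], dict[str, float]]:
    """Absolute (uV^2) and relative per-band power from a spectrum.

    Absolute power integrates the density over the half-open band [lo, hi);
    relative power divides by the total over the full spectrum.
    """
    df = (
        spec.frequencies[1] - spec.frequencies[0]
        if spec.frequencies.size > 1
        else 1.0
    )
    total = float(np.sum(spec.power) * df)
    absolute: dict[str, float] = {}
    relative: dict[str, float] = {}
    nyquist = spec.frequencies[-1]
    for band in bands:
        if band.lo < 0 or band.hi > nyquist + 1e-9:
            raise ValueError(f"band {band.name} outside [0, Nyquist]")
        mask = (spec.frequencies >= band.lo) & (spec.frequencies < band.hi)
        absolute[band.name] = float(np.sum(spec.power[mask]) * df)
    if total <= 0:
        raise ValueError("zero total power: relative band power undefined")
    for band in bands:
        relative[band.name] = absolute[band.name] / total
    return absolute, relative


def spectral_entropy(spec: Spectrum) -> float:
    """Shannon entropy (nats) of the spectrum normalised to a distribution."""
    total = float(np.sum(spec.power))
    if total <= 0:
        raise ValueError("zero spectrum: spectral entropy undefined")
    p = spec.power / total
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def signal_entropy(samples: np.ndarray, n_bins: int = 100) -> float:
    """Shannon entropy (nats) of the z-normalised amplitude histogram.

    A constant signal occupies a single bin and returns 0 by definition.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size < 2:
        raise ValueError("need at least 2 samples")
    sd = samples.std()
    if sd == 0:
        return 0.0
    z = (samples - samples.mean()) / sd
    counts, _ = np.histogram(z, bins=n_bins)
    p = counts[counts > 0] / samples.size
    return float(-np.sum(p * np.log(p)))


def binarize_at_mean(samples: np.ndarray) -> str:
    """Binary string with '1' where the sample is >= the signal mean."""
    samples = np.asarray(samples, dtype=float)
    mean = samples.mean()
    return "".join("1" if v >= mean else "0" for v in samples)


def lz76_phrase_count(s: str) -> int:
    """Number of phrases in the LZ76 exhaustive-history parsing of ``s``.

    Kaspar-Schuster scan: the current component is extended while it can be
    copied from earlier in the sequence (self-overlap allowed); each time it
    cannot, a new phrase starts.
    """
    n = len(s)
    if n == 0:
        return 0
    if n == 1:
        return 1
    c = 1           # phrases found so far
    l = 1           # start of the current component
    i = 0           # candidate copy source
    k = 1           # length matched so far
    k_max = 1
    while True:
        if s[i + k - 1] == s[l + k - 1]:
            k += 1
            if l + k > n:
                c += 1
                break
        else:
            k_max = max(k, k_max)
            i += 1
            if i == l:
                c += 1
                l += k_max
                if l + 1 > n:
                    break
                i = 0
                k = 1
                k_max = 1
            else:
                k = 1
    return c


def lempel_ziv_complexity(samples: np.ndarray) -> float:
    """Normalised LZ76 complexity of the mean-binarised signal.

    The signal is binarised at its arithmetic mean (>= mean -> 1), the LZ76
    phrase count c(n) is computed, and the result is c(n) * log2(n) / n, so
    that random sequences score near 1 and regular ones near 0.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size < 2:
        raise ValueError("need at least 2 samples")
    s = binarize_at_mean(samples)
    n = len(s)
    return lz76_phrase_count(s) * np.log2(n) / n


def hjorth_parameters(samples: np.ndarray) -> tuple[float, float]:
    """Hjorth mobility and complexity.

    mobility = sqrt(var(dx)/var(x)); complexity = mobility(dx)/mobility(x),
    with dx the first difference.  Both are invariant under amplitude scaling
    and mean shifts.  Raises on a constant signal.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    var_x = np.var(x)
    if var_x == 0:
        raise ValueError("zero-variance signal: Hjorth parameters undefined")
    dx = np.diff(x)
    var_dx = np.var(dx)
    mobility = np.sqrt(var_dx / var_x)
    ddx = np.diff(dx)
    if var_dx == 0:
        raise ValueError("zero-variance first difference")
    mobility_dx = np.sqrt(np.var(ddx) / var_dx)
    return float(mobility), float(mobility_dx / mobility)


def time_domain_features(samples: np.ndarray) -> dict[str, float]:
    """Thirteen amplitude-domain statistics of an epoch.

    Sample variance and SD use the n-1 denominator; skewness is the adjusted
    (bias-corrected) sample coefficient; kurtosis is excess (Fisher).  The
    energy-family features (curve length, energy, Teager energy, sixth power,
    sum) are totals over the epoch, not means.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    var = float(np.var(x, ddof=1))
    return {
        "minimum": float(np.min(x)),
        "maximum": float(np.max(x)),
        "median": float(np.median(x)),
        "mean": float(np.mean(x)),
        "variance": var,
        "sd": float(np.sqrt(var)),
        "skew": float(sp_stats.skew(x, bias=False)) if var > 0 else 0.0,
        "kurtosis": float(sp_stats.kurtosis(x, bias=False)) if var > 0 else 0.0,
        "curve_length": float(np.sum(np.abs(np.diff(x)))),
        "energy": float(np.sum(x**2)),
        "nonlinear_energy": float(np.sum(x[1:-1] ** 2 - x[2:] * x[:-2])),
        "sixth_power": float(np.sum(x**6)),
        "sum": float(np.sum(x)),
    }


def extract_feature_vector(samples: np.ndarray, rate: float) -> dict[str, float]:
    """The canonical 30-entry feature vector of a single-channel epoch.

    Returns an ordered mapping keyed by :data:`FEATURE_NAMES`; deterministic
    for a given input.  Constant epochs raise (several features are undefined);
    callers building feature tables should skip such epochs.
    """
    x = np.asarray(samples, dtype=float)
    spec = compute_periodogram(x, rate)
    absolute, relative = band_powers(spec)
    mobility, complexity = hjorth_parameters(x)
    td = time_domain_features(x)
    out: dict[str, float] = {}
    for band in DEFAULT_BANDS:
        out[f"rel_{band.name}_power"] = relative[band.name]
    for band in DEFAULT_BANDS:
        out[f"abs_{band.name}_power"] = absolute[band.name]
    out["spectral_entropy"] = spectral_entropy(spec)
    out["entropy"] = signal_entropy(x)
    out["lzc"] = lempel_ziv_complexity(x)
    for name in ("minimum", "maximum", "median", "mean", "variance", "sd",
                 "skew", "kurtosis", "curve_length", "energy",
                 "nonlinear_energy", "sixth_power", "sum"):
        out[name] = td[name]
    out["mobility"] = mobility
    out["complexity"] = complexity
    assert tuple(out) == FEATURE_NAMES
    return out
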