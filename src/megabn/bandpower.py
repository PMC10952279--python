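"""Spectral band power from parcellated region time series.

Regional power spectral densities are estimated with Welch's method and
reduced to relative power in five canonical frequency bands (delta, theta,
alpha, beta, gamma).  Gamma excludes 47.5-52.5 Hz to avoid UK powerline
interference.  Relative power is a composition over the five bands, so each
region's values sum to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "Band",
    "BandScheme",
    "RegionTimeSeries",
    "RegionalPSD",
    "BandPowerTable",
    "default_band_scheme",
    "welch_psd",
    "band_power",
    "relative_band_power",
]


@dataclass(frozen=True)
class Band:
    """One frequency band: half-open range [low, high) in Hz, with optional
    half-open excluded sub-ranges (e.g. a powerline notch)."""

    name: str
    low: float
    high: float
    exclusions: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"band {self.name!r}: need low < high, got [{self.low}, {self.high})")
        for lo, hi in self.exclusions:
            if not (self.low <= lo < hi <= self.high):
                raise ValueError(
                    f"band {self.name!r}: exclusion [{lo}, {hi}) not inside [{self.low}, {self.high})"
                )

    def contains(self, freqs: np.ndarray) -> np.ndarray:
        """Boolean mask of frequencies inside the band minus its exclusions."""
        mask = (freqs >= self.low) & (freqs < self.high)
        for lo, hi in self.exclusions:
            mask &= ~((freqs >= lo) & (freqs < hi))
        return mask

    @property
    def effective_bandwidth(self) -> float:
        return (self.high - self.low) - sum(hi - lo for lo, hi in self.exclusions)


@dataclass(frozen=True)
class BandScheme:
    """Ordered, non-overlapping set of frequency bands."""

    bands: tuple[Band, ...]

    def __post_init__(self) -> None:
        names = [b.name for b in self.bands]
        if len(set(names)) != len(names):
            raise ValueError("duplicate band names")
        ordered = sorted(self.bands, key=lambda b: b.low)
        for a, b in zip(ordered, ordered[1:]):
            if b.low < a.high:
                raise ValueError(f"bands {a.name!r} and {b.name!r} overlap")

    @property
    def band_names(self) -> list[str]:
        return [b.name for b in self.bands]

    @property
    def min_low(self) -> float:
        return min(b.low for b in self.bands)

    @property
    def max_high(self) -> float:
        return max(b.high for b in self.bands)


def default_band_scheme() -> BandScheme:
    """Delta 1-4, theta 4-8, alpha 8-13, beta 13-30, gamma 30-80 Hz with a
    47.5-52.5 Hz gamma notch; all ranges half-open."""
    return BandScheme(
        bands=(
            Band("delta", 1.0, 4.0),
            Band("theta", 4.0, 8.0),
            Band("alpha", 8.0, 13.0),
            Band("beta", 13.0, 30.0),
            Band("gamma", 30.0, 80.0, exclusions=((47.5, 52.5),)),
        )
    )


def _check_unique(region_ids: list[str]) -> None:
    if len(set(region_ids)) != len(region_ids):
        seen, dup = set(), set()
        for r in region_ids:
            (dup if r in seen else seen).add(r)
        raise ValueError(f"duplicate region ids: {sorted(dup)}")


@dataclass
class RegionTimeSeries:
    """Source-level signals, one row per cortical region."""

    region_ids: list[str]
    data: np.ndarray  # (n_regions, n_samples), arbitrary amplitude units
    fs: float  # sampling rate, Hz

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (regions x samples) array")
        if len(self.region_ids) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.region_ids)} region ids but {self.data.shape[0]} data rows"
            )
        _check_unique(self.region_ids)
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class RegionalPSD:
    """Welch power spectral densities on a shared frequency grid."""

    region_ids: list[str]
    freqs: np.ndarray  # Hz, strictly increasing
    psd: np.ndarray  # (n_regions, n_freqs), power per Hz

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.psd = np.asarray(self.psd, dtype=float)
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if self.psd.shape != (len(self.region_ids), self.freqs.size):
            raise ValueError("psd shape inconsistent with region_ids and freqs")
        if np.any(self.psd < 0):
            raise ValueError("negative power spectral density")


@dataclass
class BandPowerTable:
    """One subject's region x band relative power; rows sum to 1."""

    subject_id: str
    region_ids: list[str]
    band_names: list[str]
    values: np.ndarray  # (n_regions, n_bands), fractions in [0, 1]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.region_ids)
        if self.values.shape != (len(self.region_ids), len(self.band_names)):
            raise ValueError("values shape inconsistent with region/band lists")
        finite = np.isfinite(self.values).all(axis=1)
        if not finite.all():
            bad = self.region_ids[int(np.flatnonzero(~finite)[0])]
            raise ValueError(
                f"subject {self.subject_id!r}: non-finite relative power for "
                f"region {bad!r}"
            )
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12):
            raise ValueError(f"relative power outside [0, 1] for subject {self.subject_id!r}")
        bad = np.abs(self.values.sum(axis=1) - 1.0) > 1e-9
        if np.any(bad):
            first = self.region_ids[int(np.flatnonzero(bad)[0])]
            raise ValueError(
                f"subject {self.subject_id!r}: relative band power does not sum to 1 "
                f"for region {first!r} (and {int(bad.sum()) - 1} others)"
            )


def welch_psd(
    ts: RegionTimeSeries, window_s: float = 2.0, overlap_frac: float = 0.5
) -> RegionalPSD:
    """Welch PSD per region: Hann-tapered, constant-detrended sliding windows.

    Frequency resolution is 1/window_s Hz.  A trailing segment shorter than
    one window is dropped, the standard Welch convention.

    Raises
    ------
    ValueError
        If any signal is shorter than one window, contains non-finite
        samples, or the parameters are out of range.
    """
    nperseg = int(round(window_s * ts.fs))
    if nperseg < 2:
        raise ValueError(f"window of {window_s} s at fs={ts.fs} Hz is under 2 samples")
    if not 0 <= overlap_frac < 1:
        raise ValueError(f"overlap fraction must be in [0, 1), got {overlap_frac}")
    if ts.n_samples < nperseg:
        raise ValueError(
            f"signal for region {ts.region_ids[0]!r} has {ts.n_samples} samples, "
            f"shorter than one {nperseg}-sample window"
        )
    finite = np.isfinite(ts.data).all(axis=1)
    if not finite.all():
        bad = ts.region_ids[int(np.flatnonzero(~finite)[0])]
        raise ValueError(f"non-finite samples in region {bad!r}")

    freqs, psd = signal.welch(
        ts.data,
        fs=ts.fs,
        window="hann",
        nperseg=nperseg,
        noverlap=int(round(overlap_frac * nperseg)),
        detrend="constant",
        axis=-1,
    )
    return RegionalPSD(region_ids=list(ts.region_ids), freqs=freqs, psd=psd)


def band_power(psd: RegionalPSD, scheme: BandScheme | None = None) -> np.ndarray:
    """Absolute power per band: sum of PSD bins whose centre frequency falls
    in the band (minus exclusions), times the bin width.

    Returns a (n_regions, n_bands) array ordered like ``scheme.bands``.
    """
    if scheme is None:
        scheme = default_band_scheme()
    fmin, fmax = psd.freqs[0], psd.freqs[-1]
    uncovered = [b.name for b in scheme.bands if b.low < fmin or b.high > fmax + 1e-12]
    if uncovered:
        raise ValueError(
            f"frequency grid [{fmin}, {fmax}] Hz does not cover bands: {uncovered}"
        )
    df = float(np.median(np.diff(psd.freqs)))
    out = np.empty((psd.psd.shape[0], len(scheme.bands)))
    for j, band in enumerate(scheme.bands):
        mask = band.contains(psd.freqs)
        out[:, j] = psd.psd[:, mask].sum(axis=1) * df
    return out


def relative_band_power(
    abs_powers: np.ndarray,
    subject_id: str = "",
    region_ids: list[str] | None = None,
    band_names: list[str] | None = None,
) -> BandPowerTable:
    """Normalise each region's band powers by their sum (total power taken as
    the sum over the scheme's bands, so the gamma notch is excluded from both
    numerator and denominator).
    """
    abs_powers = np.asarray(abs_powers, dtype=float)
    if np.any(abs_powers < 0):
        raise ValueError("absolute band powers must be non-negative")
    if region_ids is None:
        region_ids = [f"region_{i}" for i in range(abs_powers.shape[0])]
    if band_names is None:
        band_names = default_band_scheme().band_names
    totals = abs_powers.sum(axis=1)
    zero = totals <= 0
    if np.any(zero):
        bad = region_ids[int(np.flatnonzero(zero)[0])]
        raise ValueError(
            f"region {bad!r} has zero total band power; relative power undefined"
        )
    return BandPowerTable(
        subject_id=subject_id,
        region_ids=list(region_ids),
        band_names=list(band_names),
        values=abs_powers / totals[:, None],
    )
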