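"""Normative band-power maps and patient abnormality maps.

A normative map stores, for every region and frequency band, the mean and
standard deviation of relative band power over a healthy-control cohort.
Patient values are z-scored against it, |z| = |x - mu| / sigma, and each
region keeps the maximum |z| across bands together with the band that
attained it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bandpower import BandPowerTable

__all__ = ["NormativeMap", "AbnormalityMap", "build_normative_map", "abnormality_map"]


@dataclass
class NormativeMap:
    """Per region-band control mean (mu) and sample SD (sigma)."""

    region_ids: list[str]
    band_names: list[str]
    mu: np.ndarray  # (n_regions, n_bands)
    sigma: np.ndarray  # (n_regions, n_bands), >= 0
    n_controls: int

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        shape = (len(self.region_ids), len(self.band_names))
        if self.mu.shape != shape or self.sigma.shape != shape:
            raise ValueError("mu/sigma shapes inconsistent with region/band lists")
        if np.any(self.mu < -1e-12) or np.any(self.mu > 1 + 1e-12):
            raise ValueError("normative means must lie in [0, 1]")
        if np.any(self.sigma < 0):
            raise ValueError("normative standard deviations must be non-negative")
        if self.n_controls < 2:
            raise ValueError("a normative map needs at least 2 controls")


@dataclass
class AbnormalityMap:
    """Per-region maximum absolute z-score and the band attaining it."""

    subject_id: str
    region_ids: list[str]
    max_abs_z: np.ndarray  # (n_regions,), >= 0
    argmax_band: list[str]

    def __post_init__(self) -> None:
        self.max_abs_z = np.asarray(self.max_abs_z, dtype=float)
        n = len(self.region_ids)
        if self.max_abs_z.shape != (n,) or len(self.argmax_band) != n:
            raise ValueError("abnormality map fields have inconsistent lengths")
        if np.any(self.max_abs_z < 0):
            raise ValueError("max absolute z-scores must be non-negative")

    def scores(self) -> dict[str, float]:
        return dict(zip(self.region_ids, self.max_abs_z.tolist()))


def _require_aligned(tables: list[BandPowerTable]) -> None:
    ref = tables[0]
    for t in tables[1:]:
        if t.band_names != ref.band_names:
            raise ValueError(
                f"band sets differ: {ref.band_names} vs {t.band_names} "
                f"(subjects {ref.subject_id!r}, {t.subject_id!r})"
            )
        if t.region_ids != ref.region_ids:
            diff = set(t.region_ids) ^ set(ref.region_ids)
            if diff:
                raise ValueError(
                    f"region sets differ between subjects {ref.subject_id!r} and "
                    f"{t.subject_id!r}; symmetric difference: {sorted(diff)}"
                )
            raise ValueError(
                f"region order differs between subjects {ref.subject_id!r} and "
                f"{t.subject_id!r}"
            )


def build_normative_map(controls: list[BandPowerTable]) -> NormativeMap:
    """Cell-wise mean and sample standard deviation (ddof=1) over controls.

    All control tables must share the same region and band sets; mismatches
    raise with the offending symmetric difference.
    """
    if len(controls) < 2:
        raise ValueError(f"need at least 2 controls, got {len(controls)}")
    _require_aligned(controls)
    stack = np.stack([c.values for c in controls])  # (n_controls, regions, bands)
    mu = stack.mean(axis=0)
    sigma = stack.std(axis=0, ddof=1)
    # cells constant across controls are exactly degenerate: snap mu to the
    # common value and sigma to 0, so the sigma==0 contract is float-exact
    const = np.ptp(stack, axis=0) == 0
    mu[const] = stack[0][const]
    sigma[const] = 0.0
    return NormativeMap(
        region_ids=list(controls[0].region_ids),
        band_names=list(controls[0].band_names),
        mu=mu,
        sigma=sigma,
        n_controls=len(controls),
    )


def abnormality_map(patient: BandPowerTable, norm: NormativeMap) -> AbnormalityMap:
    """Z-score a patient table against a normative map and reduce each region
    to its maximum |z| across bands.

    Degenerate cells (sigma == 0) yield z = 0 when the patient matches the
    control mean exactly, and raise otherwise — an infinite z would silently
    poison every downstream rank statistic.  Argmax ties resolve to the
    lowest band index (delta first).
    """
    if patient.band_names != norm.band_names:
        raise ValueError(
            f"band mismatch: patient {patient.band_names} vs map {norm.band_names}"
        )
    if patient.region_ids != norm.region_ids:
        diff = set(patient.region_ids) ^ set(norm.region_ids)
        if diff:
            raise ValueError(
                f"region mismatch between patient {patient.subject_id!r} and the "
                f"normative map; symmetric difference: {sorted(diff)}"
            )
        raise ValueError("patient regions are ordered differently from the normative map")

    diff_xm = patient.values - norm.mu
    degenerate = norm.sigma == 0
    conflict = degenerate & (diff_xm != 0)
    if np.any(conflict):
        i, j = (int(a[0]) for a in np.nonzero(conflict))
        raise ValueError(
            f"sigma is 0 but patient differs from the control mean at region "
            f"{norm.region_ids[i]!r}, band {norm.band_names[j]!r}"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        absz = np.abs(diff_xm) / norm.sigma
    absz[degenerate] = 0.0

    arg = np.argmax(absz, axis=1)  # np.argmax takes the first (lowest) index on ties
    return AbnormalityMap(
        subject_id=patient.subject_id,
        region_ids=list(patient.region_ids),
        max_abs_z=absz[np.arange(absz.shape[0]), arg],
        argmax_band=[norm.band_names[j] for j in arg],
    )
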