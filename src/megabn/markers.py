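"""Resection labelling and the three markers of surgical failure.

Regions are labelled resected / spared / unknown from pre- and post-operative
volumes (>10% loss = resected, 1-10% = unknown and excluded from analysis).
From a patient's abnormality map and mask, three markers are computed:

* ``mar``  — MA_R, mean abnormality of the resected regions (z units).
  Low values suggest the abnormal tissue was not resected (mechanism 1).
* ``drs``  — D_RS, distinguishability of resected vs spared tissue, a
  Mann-Whitney AUC in [0, 1]; 0 means the most abnormal regions were
  resected, 1 that they were spared, 0.5 chance (mechanism 2).
* ``acr``  — AC_R, the percentage of the cortex-wide summed abnormality
  located in resected regions (mechanism 3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.stats import rankdata

from .normative import AbnormalityMap

__all__ = [
    "RESECTED",
    "SPARED",
    "UNKNOWN",
    "ResectionMask",
    "MarkerSet",
    "label_resection",
    "mar",
    "drs",
    "acr",
    "compute_markers",
]

RESECTED = "resected"
SPARED = "spared"
UNKNOWN = "unknown"
_STATUSES = (RESECTED, SPARED, UNKNOWN)


@dataclass
class ResectionMask:
    """Per-region surgical status."""

    region_ids: list[str]
    status: list[str]  # each in {resected, spared, unknown}

    def __post_init__(self) -> None:
        if len(self.region_ids) != len(self.status):
            raise ValueError("region_ids and status lengths differ")
        if len(set(self.region_ids)) != len(self.region_ids):
            raise ValueError("duplicate region ids in resection mask")
        bad = sorted({s for s in self.status if s not in _STATUSES})
        if bad:
            raise ValueError(f"invalid status labels {bad}; expected one of {_STATUSES}")

    def regions_with(self, label: str) -> list[str]:
        return [r for r, s in zip(self.region_ids, self.status) if s == label]


@dataclass
class MarkerSet:
    """One patient's (MA_R, D_RS, AC_R) triple."""

    subject_id: str
    ma_r: float  # z units, >= 0
    d_rs: float  # in [0, 1]
    ac_r: float  # percent, in [0, 100]

    def __post_init__(self) -> None:
        if self.ma_r < 0:
            raise ValueError("MA_R must be non-negative")
        if not 0.0 <= self.d_rs <= 1.0:
            raise ValueError("D_RS must lie in [0, 1]")
        if not 0.0 <= self.ac_r <= 100.0:
            raise ValueError("AC_R must lie in [0, 100]")


def label_resection(
    pre_vol: Mapping[str, float], post_vol: Mapping[str, float]
) -> ResectionMask:
    """Label regions from pre/post-operative volume change.

    Percent change is 100*(pre - post)/pre.  Change > 10% labels the region
    resected; change in (1, 10] is unknown; change <= 1% spared.  Volume
    increases (registration noise, not regrowth) are clamped to 0% with a
    warning.
    """
    if set(pre_vol) != set(post_vol):
        diff = set(pre_vol) ^ set(post_vol)
        raise ValueError(f"pre/post volume region sets differ: {sorted(diff)}")
    region_ids = list(pre_vol)
    status = []
    grew = []
    for r in region_ids:
        pre, post = float(pre_vol[r]), float(post_vol[r])
        if pre <= 0:
            raise ValueError(f"non-positive pre-operative volume for region {r!r}: {pre}")
        change = 100.0 * (pre - post) / pre
        if change < 0:
            grew.append(r)
            change = 0.0
        if change > 10.0:
            status.append(RESECTED)
        elif change > 1.0:
            status.append(UNKNOWN)
        else:
            status.append(SPARED)
    if grew:
        warnings.warn(
            f"{len(grew)} region(s) increased in volume (e.g. {grew[0]!r}); "
            "treated as 0% change",
            stacklevel=2,
        )
    return ResectionMask(region_ids=region_ids, status=status)


def _split_scores(abn: AbnormalityMap, mask: ResectionMask) -> tuple[np.ndarray, np.ndarray]:
    """Abnormality scores of resected and spared regions; unknowns dropped."""
    if set(abn.region_ids) != set(mask.region_ids):
        diff = set(abn.region_ids) ^ set(mask.region_ids)
        raise ValueError(f"abnormality map and mask region sets differ: {sorted(diff)}")
    lookup = dict(zip(mask.region_ids, mask.status))
    res, spa = [], []
    for r, z in zip(abn.region_ids, abn.max_abs_z):
        s = lookup[r]
        if s == RESECTED:
            res.append(z)
        elif s == SPARED:
            spa.append(z)
    return np.asarray(res, dtype=float), np.asarray(spa, dtype=float)


def mar(abn: AbnormalityMap, mask: ResectionMask) -> float:
    """MA_R: mean of max |z| over resected regions."""
    res, _ = _split_scores(abn, mask)
    if res.size == 0:
        raise ValueError(f"no resected regions for subject {abn.subject_id!r}")
    return float(res.mean())


def drs(abn: AbnormalityMap, mask: ResectionMask) -> float:
    """D_RS: fraction of (resected, spared) pairs where the spared region is
    more abnormal, ties counting one half — the Mann-Whitney AUC with spared
    as the positive class.
    """
    res, spa = _split_scores(abn, mask)
    if res.size == 0 or spa.size == 0:
        raise ValueError(
            f"subject {abn.subject_id!r}: D_RS needs at least one resected and one "
            f"spared region (got {res.size} resected, {spa.size} spared)"
        )
    # midrank identity: sum of spared ranks in the pooled sample gives the
    # tie-adjusted pair count without the O(nR*nS) loop
    ranks = rankdata(np.concatenate([spa, res]))
    u_spared = ranks[: spa.size].sum() - spa.size * (spa.size + 1) / 2.0
    return float(u_spared / (res.size * spa.size))


def acr(abn: AbnormalityMap, mask: ResectionMask) -> float:
    """AC_R: percent of total abnormality (summed over resected + spared
    regions) that lies in the resection."""
    res, spa = _split_scores(abn, mask)
    total = res.sum() + spa.sum()
    if total <= 0:
        raise ValueError(
            f"subject {abn.subject_id!r}: total abnormality is zero; AC_R undefined"
        )
    if res.size == 0:
        warnings.warn(
            f"subject {abn.subject_id!r} has no resected regions; AC_R = 0", stacklevel=2
        )
        return 0.0
    return float(100.0 * res.sum() / total)


def compute_markers(abn: AbnormalityMap, mask: ResectionMask) -> MarkerSet:
    """All three markers for one patient."""
    return MarkerSet(
        subject_id=abn.subject_id,
        ma_r=mar(abn, mask),
        d_rs=drs(abn, mask),
        ac_r=acr(abn, mask),
    )
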