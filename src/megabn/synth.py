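"""Synthetic cohorts with known ground truth.

The generator emulates the study design end to end: a healthy-control
cohort of region x band relative power compositions, patients with focal or
widespread injected abnormalities, resection masks whose overlap with the
abnormal set encodes a failure mechanism, pre/post-operative volumes
consistent with the masks, and binary surgical outcomes.

Band-power compositions are produced by a logistic-normal model: each
region has cohort-level latent mean log-fractions, each subject adds
Gaussian latent noise per cell, and a softmax maps latents to a valid
composition (rows sum to 1).  Abnormality is injected in latent space as a
multiple of the latent noise SD in a single band per abnormal region, so
patient rows remain valid compositions while the induced z-scores scale
approximately linearly with the requested effect size.

Four mechanism scenarios are supported:

* ``mislocalized`` — the resection misses the abnormal set entirely
  (low MA_R, mechanism 1).
* ``partial`` — widespread graded abnormality; the resection removes only
  the weakest abnormal regions, sparing the most abnormal tissue
  (high D_RS, mechanism 2).
* ``diffuse`` — widespread abnormality; the resection removes the most
  abnormal few regions but barely dents the global load
  (low AC_R, mechanism 3).
* ``clean`` — the resection covers the full (focal) abnormal set; the
  expected good-outcome archetype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bandpower import BandPowerTable, default_band_scheme
from .markers import RESECTED, SPARED, UNKNOWN, ResectionMask

__all__ = [
    "SCENARIOS",
    "SynthConfig",
    "GroundTruth",
    "PatientBundle",
    "SynthCohort",
    "generate_controls",
    "generate_patient",
    "generate_cohort",
    "volumes_from_mask",
]

SCENARIOS = ("mislocalized", "partial", "diffuse", "clean")
_BAD_SCENARIOS = ("mislocalized", "partial", "diffuse")


@dataclass
class SynthConfig:
    """Study-shaped generator settings.

    Cohort shape defaults mirror the study design: 114 cortical regions
    (mid-resolution Lausanne parcellation), 70 healthy controls, 32
    patients split 12 good / 20 bad outcome.  ``effect_size`` is expressed
    in units of the latent noise SD, so it reads directly as an approximate
    z-score of the injected abnormality.
    """

    n_regions: int = 114
    n_controls: int = 70
    n_good: int = 12
    n_bad: int = 20
    band_names: tuple[str, ...] = tuple(default_band_scheme().band_names)
    # typical resting-state relative power fractions per band
    base_fractions: tuple[float, ...] = (0.20, 0.15, 0.30, 0.25, 0.10)
    region_mean_sd: float = 0.15  # spread of regional latent means (log-fraction units)
    noise_sd: float = 0.10  # within-subject latent SD per cell
    effect_size: float = 6.0  # injected abnormality, in latent-SD (~z) units
    focal_abnormal_count: int = 10
    diffuse_abnormal_count: int = 60
    resection_size: int = 10
    label_noise: float = 0.1  # probability an outcome label flips
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_regions",
            "n_controls",
            "n_good",
            "n_bad",
            "focal_abnormal_count",
            "diffuse_abnormal_count",
            "resection_size",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if len(self.band_names) != len(self.base_fractions):
            raise ValueError("band_names and base_fractions lengths differ")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if not 0 <= self.label_noise <= 1:
            raise ValueError("label_noise must lie in [0, 1]")
        if self.noise_sd < 0 or self.region_mean_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.resection_size > self.n_regions:
            raise ValueError("resection_size exceeds the number of regions")
        if self.diffuse_abnormal_count + self.resection_size > self.n_regions:
            raise ValueError("diffuse abnormal set plus resection exceeds region count")

    @property
    def region_ids(self) -> list[str]:
        return [f"roi_{i:03d}" for i in range(self.n_regions)]


@dataclass
class GroundTruth:
    """What was injected for one synthetic patient."""

    subject_id: str
    scenario: str
    abnormal_regions: list[str]
    effects: dict  # region -> injected effect size (latent-SD units)
    abnormal_bands: dict  # region -> band carrying the abnormality
    outcome_true: str  # scenario-determined label, before label noise
    outcome_observed: str
    resection_overlap: float  # |resected ∩ abnormal| / |resected|

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if not 0 <= self.resection_overlap <= 1:
            raise ValueError("resection_overlap must lie in [0, 1]")


@dataclass
class PatientBundle:
    table: BandPowerTable
    mask: ResectionMask
    pre_vol: dict
    post_vol: dict
    outcome: str
    truth: GroundTruth


@dataclass
class SynthCohort:
    config: SynthConfig
    controls: list[BandPowerTable]
    patients: list[PatientBundle] = field(default_factory=list)


def _softmax(latents: np.ndarray) -> np.ndarray:
    shifted = latents - latents.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


def _cohort_latent_means(cfg: SynthConfig) -> np.ndarray:
    """Regional mean log-fractions, drawn once per cohort seed."""
    rng = np.random.default_rng([cfg.seed, 0])
    base = np.log(np.asarray(cfg.base_fractions))
    return base[None, :] + rng.normal(0.0, cfg.region_mean_sd, (cfg.n_regions, len(base)))


def _subject_table(
    cfg: SynthConfig, means: np.ndarray, rng: np.random.Generator, subject_id: str
) -> tuple[BandPowerTable, np.ndarray]:
    latents = means + rng.normal(0.0, cfg.noise_sd, means.shape)
    table = BandPowerTable(
        subject_id=subject_id,
        region_ids=cfg.region_ids,
        band_names=list(cfg.band_names),
        values=_softmax(latents),
    )
    return table, latents


def generate_controls(cfg: SynthConfig) -> list[BandPowerTable]:
    """Healthy-control band-power tables (deterministic in cfg.seed)."""
    means = _cohort_latent_means(cfg)
    rng = np.random.default_rng([cfg.seed, 1])
    return [
        _subject_table(cfg, means, rng, f"control_{k:03d}")[0]
        for k in range(cfg.n_controls)
    ]


def _scenario_design(
    cfg: SynthConfig, scenario: str, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Abnormal region indices, per-region effects, resected indices."""
    all_idx = np.arange(cfg.n_regions)
    if scenario in ("clean", "mislocalized"):
        abnormal = rng.choice(all_idx, cfg.focal_abnormal_count, replace=False)
        effects = np.full(abnormal.size, cfg.effect_size)
        if scenario == "clean":
            resected = abnormal.copy()
        else:
            complement = np.setdiff1d(all_idx, abnormal)
            resected = rng.choice(complement, cfg.resection_size, replace=False)
    elif scenario == "partial":
        abnormal = rng.choice(all_idx, cfg.diffuse_abnormal_count, replace=False)
        # graded severity; resect only the weakest tier, sparing the worst tissue
        effects = cfg.effect_size * np.linspace(0.15, 1.0, abnormal.size)
        resected = abnormal[np.argsort(effects)[: cfg.resection_size]]
    elif scenario == "diffuse":
        abnormal = rng.choice(all_idx, cfg.diffuse_abnormal_count, replace=False)
        effects = cfg.effect_size * np.linspace(0.5, 1.0, abnormal.size)
        # the most abnormal few are resected, but the global load remains
        resected = abnormal[np.argsort(effects)[-cfg.resection_size :]]
    else:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    return abnormal, effects, resected


def generate_patient(
    cfg: SynthConfig,
    scenario: str,
    subject_id: str = "patient",
    rng: np.random.Generator | None = None,
    latent_means: np.ndarray | None = None,
) -> tuple[BandPowerTable, ResectionMask, GroundTruth, str]:
    """One synthetic patient under a mechanism scenario.

    The patient is sampled from the control model, then each abnormal
    region gets ``effect * noise_sd`` added to one randomly chosen band's
    latent value.  The mask encodes the scenario's resection/abnormality
    overlap, and the outcome is good only for the clean scenario, subject
    to the configured label-noise flip.
    """
    if rng is None:
        rng = np.random.default_rng([cfg.seed, 2])
    if latent_means is None:
        latent_means = _cohort_latent_means(cfg)

    abnormal, effects, resected = _scenario_design(cfg, scenario, rng)
    _, latents = _subject_table(cfg, latent_means, rng, subject_id)

    n_bands = len(cfg.band_names)
    bands = rng.integers(0, n_bands, abnormal.size)
    for i, eff, j in zip(abnormal, effects, bands):
        latents[i, j] += eff * cfg.noise_sd

    table = BandPowerTable(
        subject_id=subject_id,
        region_ids=cfg.region_ids,
        band_names=list(cfg.band_names),
        values=_softmax(latents),
    )

    region_ids = cfg.region_ids
    resected_set = set(resected.tolist())
    mask = ResectionMask(
        region_ids=region_ids,
        status=[RESECTED if i in resected_set else SPARED for i in range(cfg.n_regions)],
    )

    outcome_true = "good" if scenario == "clean" else "bad"
    outcome = outcome_true
    if rng.random() < cfg.label_noise:
        outcome = "bad" if outcome_true == "good" else "good"

    abnormal_set = set(abnormal.tolist())
    truth = GroundTruth(
        subject_id=subject_id,
        scenario=scenario,
        abnormal_regions=[region_ids[i] for i in abnormal],
        effects={region_ids[i]: float(e) for i, e in zip(abnormal, effects)},
        abnormal_bands={region_ids[i]: cfg.band_names[j] for i, j in zip(abnormal, bands)},
        outcome_true=outcome_true,
        outcome_observed=outcome,
        resection_overlap=len(resected_set & abnormal_set) / len(resected_set),
    )
    return table, mask, truth, outcome


def volumes_from_mask(
    mask: ResectionMask, rng: np.random.Generator | None = None
) -> tuple[dict, dict]:
    """Pre/post-operative volumes (mm^3) that round-trip through the
    >10% / 1-10% / <=1% volume-change labelling rule."""
    if rng is None:
        rng = np.random.default_rng()
    change = {RESECTED: 0.30, UNKNOWN: 0.05, SPARED: 0.002}
    pre, post = {}, {}
    for r, s in zip(mask.region_ids, mask.status):
        v = float(rng.uniform(2000.0, 6000.0))
        pre[r] = v
        post[r] = v * (1.0 - change[s])
    return pre, post


def generate_cohort(cfg: SynthConfig) -> SynthCohort:
    """The full study bundle: controls plus a patient cohort whose bad
    outcomes are spread over the three failure scenarios."""
    means = _cohort_latent_means(cfg)
    controls = generate_controls(cfg)

    scenarios = ["clean"] * cfg.n_good
    for k in range(cfg.n_bad):
        scenarios.append(_BAD_SCENARIOS[k % len(_BAD_SCENARIOS)])

    patients = []
    for k, scenario in enumerate(scenarios):
        rng = np.random.default_rng([cfg.seed, 2, k])
        table, mask, truth, outcome = generate_patient(
            cfg, scenario, subject_id=f"patient_{k:03d}", rng=rng, latent_means=means
        )
        pre, post = volumes_from_mask(mask, rng)
        patients.append(
            PatientBundle(
                table=table, mask=mask, pre_vol=pre, post_vol=post,
                outcome=outcome, truth=truth,
            )
        )
    return SynthCohort(config=cfg, controls=controls, patients=patients)
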