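"""Synthetic cohort generator: spiral drawings, questionnaires, demographics.

The generator emulates the statistical structure the analysis assumes, so the
whole pipeline is exercisable without any recorded data.

Drawing model
-------------
A participant traces the template spiral with roughly constant pen speed —
the sweep angle follows θ(t) = θ_max·sqrt(t/T), the constant-linear-speed
parametrization of an Archimedean spiral — over a sampled duration T.  On top
of the template radius three disturbances act:

* a rest-tremor component A_side·sin(2πf t + φ), injected radially; the
  per-side amplitude splits the configured tremor power by the laterality
  parameter (0.5 = symmetric; the affected side gets the larger share),
* band-limited motion noise: Gaussian white noise smoothed with a ~25 ms
  kernel and rescaled to the configured sd — human motor noise is smooth, and
  white per-sample noise would reduce the direction-change counts (F5–F7) to
  pure noise counters,
* extra noise (×3) over the first/last 8% of samples, standing in for pen
  placement and lift wobble.

Timestamps tick at the nominal 240 Hz with ±3% jitter; force is the
participant's force level plus smoothed within-recording noise, clipped at 0.

Phenotype presets (CG / PD / DD) encode the study conditions: PD has a
4–6 Hz, strongly lateralized rest tremor, a slower draw (bradykinesia) and
elevated non-motor yes-probabilities; DD mixes faster 5–10 Hz, essentially
bilateral tremor (essential-tremor-like and related phenotypes) with the same
elevated non-motor profile, so the questionnaire separates disease from
control but not PD from DD; CG has no tremor beyond motion noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .errors import DomainError
from .io import (CohortDataset, DrawingRecording, ParticipantRecord,
                 QuestionnaireResponse)
from .spiral import SpiralTemplate

#: smoothing kernel of the motion noise, seconds (≈ 6 Hz low-pass)
NOISE_KERNEL_S = 0.025
#: fraction of samples at each end receiving extra pen-drop/lift noise
EDGE_FRACTION = 0.08
EDGE_NOISE_FACTOR = 3.0
TIMESTAMP_JITTER = 0.03

#: per-item yes-probabilities: controls answer few items yes, disease groups
#: share an elevated, item-varying profile (mean 0.10 vs 0.40)
NMS_PROB_CG = np.linspace(0.02, 0.18, 30)
NMS_PROB_MD = np.linspace(0.20, 0.60, 30)

#: Hoehn-Yahr stage frequencies used for the PD preset (stage -> count /24)
HOEHN_YAHR_WEIGHTS = {1.0: 3, 2.0: 4, 2.5: 5, 3.0: 7, 4.0: 3, 5.0: 2}


@dataclass(frozen=True)
class PhenotypeConfig:
    """Generative parameters of one diagnostic group."""

    group: str
    tremor_freq_range: tuple[float, float]  # Hz, uniform per participant
    tremor_amplitude: tuple[float, float]   # cm (mean, sd), truncated below
    tremor_amplitude_min: float             # cm, truncation floor
    laterality: float                       # share of tremor power on affected side
    draw_duration: tuple[float, float]      # s (mean, sd)
    force_level: tuple[float, float]        # (between-subject mean, sd); 1 = average
    force_noise_sd: float                   # within-recording force sd
    motion_noise_sd: float                  # cm, band-limited
    nms_yes_prob: np.ndarray                # 30 per-item yes probabilities
    age_dist: tuple[float, float]           # years (mean, sd)
    female_prob: float

    def __post_init__(self):
        if not 0 <= self.laterality <= 1:
            raise DomainError("laterality must be in [0, 1]")
        probs = np.asarray(self.nms_yes_prob, dtype=float)
        if probs.shape != (30,) or probs.min() < 0 or probs.max() > 1:
            raise DomainError("nms_yes_prob must be 30 probabilities in [0, 1]")
        object.__setattr__(self, "nms_yes_prob", probs)
        for name in ("tremor_amplitude", "draw_duration", "force_level"):
            mean, sd = getattr(self, name)
            if sd < 0:
                raise DomainError(f"{name} sd must be non-negative")


def default_presets() -> dict[str, PhenotypeConfig]:
    """The study-condition phenotypes for the three groups."""
    return {
        "CG": PhenotypeConfig(
            group="CG",
            tremor_freq_range=(4.0, 12.0),
            tremor_amplitude=(0.025, 0.015),
            tremor_amplitude_min=0.0,
            laterality=0.5,
            draw_duration=(25.0, 5.0),
            force_level=(1.0, 0.12),
            force_noise_sd=0.10,
            motion_noise_sd=0.05,
            nms_yes_prob=NMS_PROB_CG,
            age_dist=(58.0, 10.0),
            female_prob=0.37,
        ),
        "PD": PhenotypeConfig(
            group="PD",
            tremor_freq_range=(4.0, 6.0),
            tremor_amplitude=(0.10, 0.05),
            tremor_amplitude_min=0.03,
            laterality=0.8,
            draw_duration=(32.0, 7.0),
            force_level=(0.90, 0.20),
            force_noise_sd=0.12,
            motion_noise_sd=0.05,
            nms_yes_prob=NMS_PROB_MD,
            age_dist=(68.0, 8.0),
            female_prob=0.667,
        ),
        "DD": PhenotypeConfig(
            group="DD",
            tremor_freq_range=(5.0, 10.0),
            tremor_amplitude=(0.10, 0.05),
            tremor_amplitude_min=0.03,
            laterality=0.5,
            draw_duration=(28.0, 6.0),
            force_level=(0.95, 0.18),
            force_noise_sd=0.11,
            motion_noise_sd=0.05,
            nms_yes_prob=NMS_PROB_MD,
            age_dist=(58.0, 9.0),
            female_prob=0.541,
        ),
    }


@dataclass(frozen=True)
class CohortConfig:
    """Sizes, seed and acquisition settings of a generated cohort."""

    n_cg: int = 27
    n_pd: int = 24
    n_dd: int = 26
    seed: int = 0
    sampling_rate: float = 240.0
    template: SpiralTemplate = field(default_factory=SpiralTemplate)

    def __post_init__(self):
        if min(self.n_cg, self.n_pd, self.n_dd) < 1:
            raise DomainError("need >= 1 participant per group")
        if self.sampling_rate <= 0:
            raise DomainError("sampling_rate must be positive")


@dataclass(frozen=True)
class ParticipantTraits:
    """Per-participant latent draw shared across the four recordings."""

    tremor_freq: float
    tremor_amplitude: float
    affected_hand: str
    duration: float
    force_mean: float
    force_noise_sd: float
    motion_noise_sd: float


#: between-subject spread (lognormal sigma) of the individual noise levels;
#: without it the noise sds would be near-constant within a group and the
#: std-type features would degenerate into perfect group separators
NOISE_LEVEL_SPREAD = 0.3


def _band_limited_noise(n: int, sd: float, rate: float, rng) -> np.ndarray:
    """Gaussian noise low-passed with a ~25 ms kernel, rescaled to sd."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    raw = rng.normal(0.0, 1.0, n)
    smooth = gaussian_filter1d(raw, sigma=max(NOISE_KERNEL_S * rate, 1e-9))
    scale = smooth.std()
    return smooth * (sd / scale) if scale > 0 else np.zeros(n)


def sample_traits(ph: PhenotypeConfig, rng) -> ParticipantTraits:
    lo, hi = ph.tremor_freq_range
    amp = rng.normal(*ph.tremor_amplitude)
    amp = max(abs(amp), ph.tremor_amplitude_min)
    return ParticipantTraits(
        tremor_freq=float(rng.uniform(lo, hi)),
        tremor_amplitude=float(amp),
        affected_hand="left" if rng.random() < 0.5 else "right",
        duration=float(max(rng.normal(*ph.draw_duration), 8.0)),
        force_mean=float(max(rng.normal(*ph.force_level), 0.1)),
        force_noise_sd=float(ph.force_noise_sd
                             * rng.lognormal(0.0, NOISE_LEVEL_SPREAD)),
        motion_noise_sd=float(ph.motion_noise_sd
                              * rng.lognormal(0.0, NOISE_LEVEL_SPREAD)),
    )


def simulate_drawing(ph: PhenotypeConfig, cc: CohortConfig, hand: str,
                     repetition: int, rng,
                     traits: ParticipantTraits | None = None,
                     participant_id: str = "SYN") -> DrawingRecording:
    """One synthetic spiral recording for a hand x repetition."""
    if traits is None:
        traits = sample_traits(ph, rng)
    template = cc.template
    duration = traits.duration * float(rng.uniform(0.95, 1.05))
    n = int(round(duration * cc.sampling_rate))
    dt = (1.0 / cc.sampling_rate) * (
        1.0 + rng.uniform(-TIMESTAMP_JITTER, TIMESTAMP_JITTER, n - 1)
    )
    t = np.concatenate(([0.0], np.cumsum(dt)))
    theta = template.theta_max * np.sqrt(t / t[-1])

    # split tremor power between sides by the laterality share
    share = ph.laterality if hand == traits.affected_hand else 1.0 - ph.laterality
    amplitude = traits.tremor_amplitude * np.sqrt(2.0 * share)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    tremor = amplitude * np.sin(2.0 * np.pi * traits.tremor_freq * t + phase)

    noise = _band_limited_noise(n, traits.motion_noise_sd, cc.sampling_rate, rng)
    k_edge = max(1, int(EDGE_FRACTION * n))
    envelope = np.ones(n)
    envelope[:k_edge] = EDGE_NOISE_FACTOR
    envelope[-k_edge:] = EDGE_NOISE_FACTOR
    r = template.radius(theta) + tremor + noise * envelope
    r = np.maximum(r, 0.0)
    x = template.center[0] + r * np.cos(theta)
    y = template.center[1] + r * np.sin(theta)

    force = traits.force_mean + _band_limited_noise(
        n, traits.force_noise_sd, cc.sampling_rate, rng
    )
    return DrawingRecording(
        participant_id=participant_id,
        hand=hand,
        repetition=repetition,
        t=t,
        x=x,
        y=y,
        force=np.maximum(force, 0.0),
        nominal_rate=cc.sampling_rate,
    )


def simulate_questionnaire(ph: PhenotypeConfig, rng) -> QuestionnaireResponse:
    """30 independent Bernoulli answers per the phenotype's yes-probabilities."""
    return QuestionnaireResponse((rng.random(30) < ph.nms_yes_prob).astype(int))


def _sample_hoehn_yahr(rng) -> float:
    stages = np.array(list(HOEHN_YAHR_WEIGHTS))
    weights = np.array(list(HOEHN_YAHR_WEIGHTS.values()), dtype=float)
    return float(rng.choice(stages, p=weights / weights.sum()))


def simulate_participant(ph: PhenotypeConfig, cc: CohortConfig,
                         participant_id: str, rng) -> ParticipantRecord:
    traits = sample_traits(ph, rng)
    recordings = [
        simulate_drawing(ph, cc, hand, rep, rng, traits, participant_id)
        for hand in ("left", "right")
        for rep in (1, 2)
    ]
    return ParticipantRecord(
        participant_id=participant_id,
        group=ph.group,
        age=float(np.clip(rng.normal(*ph.age_dist), 30.0, 92.0)),
        gender="female" if rng.random() < ph.female_prob else "male",
        hoehn_yahr=_sample_hoehn_yahr(rng) if ph.group == "PD" else None,
        questionnaire=simulate_questionnaire(ph, rng),
        recordings=recordings,
    )


def generate_cohort(cc: CohortConfig = CohortConfig(),
                    presets: dict[str, PhenotypeConfig] | None = None) -> CohortDataset:
    """A full cohort (default 27 CG / 24 PD / 26 DD), deterministic per seed."""
    presets = default_presets() if presets is None else presets
    rng = np.random.default_rng(cc.seed)
    participants = []
    for group, n in (("CG", cc.n_cg), ("PD", cc.n_pd), ("DD", cc.n_dd)):
        ph = presets[group]
        for i in range(n):
            participants.append(
                simulate_participant(ph, cc, f"{group}{i + 1:03d}", rng)
            )
    return CohortDataset(participants)
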