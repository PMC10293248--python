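import numpy as np
import pytest

from spiraldx.io import DrawingRecording, ParticipantRecord, QuestionnaireResponse
from spiraldx.simulate import CohortConfig, generate_cohort
from spiraldx.spiral import SpiralTemplate


@pytest.fixture(scope="session")
def template() -> SpiralTemplate:
    return SpiralTemplate()


def make_ideal_recording(template: SpiralTemplate, n: int = 2000,
                         duration: float = 20.0, participant_id: str = "IDEAL",
                         hand: str = "right", repetition: int = 1,
                         force: float = 1.0) -> DrawingRecording:
    """Recording tracing the template exactly at constant angular speed."""
    theta = np.linspace(0.0, template.theta_max, n)
    x, y = template.point(theta)
    return DrawingRecording(
        participant_id=participant_id, hand=hand, repetition=repetition,
        t=np.linspace(0.0, duration, n), x=x, y=y,
        force=np.full(n, force),
    )


def make_perturbed_recording(template: SpiralTemplate, amplitude: float,
                             freq_hz: float, n: int = 4800,
                             duration: float = 20.0, phase: float = 0.0,
                             **kwargs) -> DrawingRecording:
    """Template trace plus a radial sinusoid A·sin(2πft + phase)."""
    t = np.linspace(0.0, duration, n)
    theta = template.theta_max * np.sqrt(t / duration)
    r = template.radius(theta) + amplitude * np.sin(2 * np.pi * freq_hz * t + phase)
    r = np.maximum(r, 0.0)  # the pen cannot cross the centre
    kwargs.setdefault("participant_id", "PERT")
    kwargs.setdefault("hand", "right")
    kwargs.setdefault("repetition", 1)
    return DrawingRecording(
        t=t, x=r * np.cos(theta), y=r * np.sin(theta),
        force=np.ones(n), **kwargs,
    )


@pytest.fixture(scope="session")
def ideal_recording(template) -> DrawingRecording:
    return make_ideal_recording(template)


@pytest.fixture(scope="session")
def small_cohort():
    """A small but CV-able synthetic cohort shared across tests."""
    return generate_cohort(CohortConfig(n_cg=9, n_pd=8, n_dd=8, seed=42))


@pytest.fixture(scope="session")
def small_features(small_cohort):
    from spiraldx.features import extract_feature_table

    return extract_feature_table(small_cohort)


@pytest.fixture(scope="session")
def default_cohort_features():
    """Feature table of one default-size cohort (27/24/26), shared."""
    from spiraldx.features import extract_feature_table

    return extract_feature_table(generate_cohort(CohortConfig(seed=7)))


def make_participant(pid: str = "P1", group: str = "CG", age: float = 60.0,
                     gender: str = "male", yes: int = 0,
                     recordings=None, hoehn_yahr=None,
                     template: SpiralTemplate = SpiralTemplate()) -> ParticipantRecord:
    if recordings is None:
        # constant-linear-speed, exact template trace: the ideal drawer
        recordings = [
            make_perturbed_recording(template, 0.0, 1.0, participant_id=pid,
                                     hand=h, repetition=rep)
            for h in ("left", "right") for rep in (1, 2)
        ]
    items = np.zeros(30, dtype=int)
    items[:yes] = 1
    return ParticipantRecord(
        participant_id=pid, group=group, age=age, gender=gender,
        hoehn_yahr=hoehn_yahr, questionnaire=QuestionnaireResponse(items),
        recordings=recordings,
    )
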