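"""QYes and the 13 motor features extracted from spiral drawings.

Feature groups
--------------
* non-motor: ``QYes`` — number of yes answers on the 30-item PDNMS.
* precision: ``F1c_DistanceFFT`` (between-arm laterality of the binned
  3–15 Hz distance spectrum), ``F2_MaxDistance``, ``F3_MeanDistance``,
  ``F4_StdDevDistance``, ``F5_ChangeOfRadiusDirection``,
  ``F6_ChangesOfDirectionX``, ``F7_ChangesOfDirectionY``.
* force: ``F8_MeanForce``, ``F9_StDevForce``, ``F10_MedianForce``.
* time: ``F11_TimeOfDrawing``, ``F12_MeanVelocity``, ``F13_StdDevVelocity``.

The velocity series is the discrete derivative of position,

    v_i = sqrt((x_i − x_{i−1})² + (y_i − y_{i−1})²) / (t_i − t_{i−1}),  v_0 = 0,

and every variance/std in this module is the population (divide-by-N) form.
All motor features except F1c come from the stronger affected arm after
repetition averaging; F1c is the absolute between-side difference and is the
only feature consuming both arms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, ValidationError
from .io import DrawingRecording, ParticipantRecord, QuestionnaireResponse
from .preprocess import (CLIP_FRACTION, TOP_FRACTION, clip_distance_series,
                         clip_recording, clip_time_series, combine_repetitions,
                         remove_top_values, select_affected_arm)
from .spiral import DistanceSeries, SpiralTemplate, ensure_outward, signed_distance_series

FEATURE_NAMES = (
    "QYes",
    "F1c_DistanceFFT",
    "F2_MaxDistance",
    "F3_MeanDistance",
    "F4_StdDevDistance",
    "F5_ChangeOfRadiusDirection",
    "F6_ChangesOfDirectionX",
    "F7_ChangesOfDirectionY",
    "F8_MeanForce",
    "F9_StDevForce",
    "F10_MedianForce",
    "F11_TimeOfDrawing",
    "F12_MeanVelocity",
    "F13_StdDevVelocity",
)

#: motor (drawing-task) features, i.e. everything except the questionnaire count
TABLET_FEATURES = FEATURE_NAMES[1:]


@dataclass(frozen=True)
class SpectralConfig:
    """Band and binning of the distance-series spectrum (defaults: 3–15 Hz, 20 bins)."""

    f_lo: float = 3.0
    f_hi: float = 15.0
    n_bins: int = 20
    resample_rate: float = 240.0

    def __post_init__(self):
        if not self.f_lo < self.f_hi:
            raise DomainError("f_lo must be < f_hi")
        if self.n_bins < 2:
            raise DomainError("need at least 2 bins")
        if self.resample_rate <= 0:
            raise DomainError("resample_rate must be positive")

    @property
    def bin_edges(self) -> np.ndarray:
        return np.linspace(self.f_lo, self.f_hi, self.n_bins + 1)

    @property
    def bin_centers(self) -> np.ndarray:
        edges = self.bin_edges
        return 0.5 * (edges[:-1] + edges[1:])

    @property
    def bin_width(self) -> float:
        return (self.f_hi - self.f_lo) / self.n_bins


@dataclass(frozen=True, eq=False)
class VelocitySeries:
    """Absolute pen speed (cm/s) over time; the first element is defined as 0."""

    t: np.ndarray
    v: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float))
        object.__setattr__(self, "v", np.asarray(self.v, dtype=float))
        if self.t.shape != self.v.shape:
            raise ValidationError("t and v must have the same shape")

    def __len__(self) -> int:
        return len(self.t)


def qyes(q: QuestionnaireResponse) -> int:
    """Count of positively answered PDNMS items, in [0, 30]."""
    return int(np.sum(q.items))


def velocity_series(rec: DrawingRecording) -> VelocitySeries:
    """Discrete speed series of a recording; duplicated timestamps with
    identical position are dropped with a warning, with distinct position they
    are an error."""
    t, x, y = rec.t, rec.x, rec.y
    dt = np.diff(t)
    zero = dt == 0
    if zero.any():
        moved = (np.diff(x) != 0) | (np.diff(y) != 0)
        if np.any(zero & moved):
            idx = int(np.flatnonzero(zero & moved)[0]) + 1
            raise ValidationError(
                f"repeated timestamp with distinct position at sample {idx}"
            )
        warnings.warn("dropping samples with repeated timestamps")
        keep = np.concatenate(([True], ~zero))
        t, x, y = t[keep], x[keep], y[keep]
        dt = np.diff(t)
    v = np.hypot(np.diff(x), np.diff(y)) / dt
    return VelocitySeries(t=t, v=np.concatenate(([0.0], v)))


def binned_spectrum(ds: DistanceSeries, cfg: SpectralConfig = SpectralConfig()) -> np.ndarray:
    """Mean FFT magnitude of the distance series in each frequency bin.

    The (already clipped) series is linearly resampled onto a uniform grid at
    ``cfg.resample_rate`` (FFT needs uniform sampling; real timestamps
    jitter), transformed with a real FFT, and the amplitude spectrum
    (2·|X_k|/n) restricted to [f_lo, f_hi] is averaged within
    ``n_bins`` equal-width bins.  Bins without any spectral line are 0.
    """
    if len(ds) < 64:
        raise ValidationError(f"need >= 64 samples for the spectrum, got {len(ds)}")
    duration = float(ds.t[-1] - ds.t[0])
    if duration < 1.0 / cfg.f_lo:
        raise ValidationError(
            f"recording shorter than one {cfg.f_lo:g} Hz period ({duration:.3g} s)"
        )
    n_u = int(np.floor(duration * cfg.resample_rate)) + 1
    t_u = ds.t[0] + np.arange(n_u) / cfg.resample_rate
    d_u = np.interp(t_u, ds.t, ds.d)
    mag = 2.0 * np.abs(np.fft.rfft(d_u)) / n_u  # amplitude units (cm)
    freqs = np.fft.rfftfreq(n_u, 1.0 / cfg.resample_rate)
    in_band = (freqs >= cfg.f_lo) & (freqs <= cfg.f_hi)
    edges = cfg.bin_edges
    which = np.digitize(freqs[in_band], edges[1:-1], right=False)
    values = np.zeros(cfg.n_bins)
    band_mag = mag[in_band]
    for b in range(cfg.n_bins):
        sel = which == b
        if sel.any():
            values[b] = band_mag[sel].mean()
    return values


def spectral_bin_std(ds: DistanceSeries, cfg: SpectralConfig = SpectralConfig()) -> float:
    """Population std over the 20 spectral bin values of one distance series."""
    return float(np.std(binned_spectrum(ds, cfg)))


def dominant_bin_frequency(ds: DistanceSeries, cfg: SpectralConfig = SpectralConfig()) -> float:
    """Centre frequency (Hz) of the bin with the largest mean magnitude."""
    return float(cfg.bin_centers[int(np.argmax(binned_spectrum(ds, cfg)))])


def f1c_distance_fft(left: DistanceSeries, right: DistanceSeries,
                     cfg: SpectralConfig = SpectralConfig()) -> float:
    """Laterality feature: |bin-std(left) − bin-std(right)|."""
    return abs(spectral_bin_std(left, cfg) - spectral_bin_std(right, cfg))


def precision_features(d: np.ndarray) -> tuple[float, float, float]:
    """(F2, F3, F4) = (max |d|, mean |d|, population std of d).

    ``d`` is the signed distance series after top-5% magnitude removal.
    """
    d = np.asarray(d, dtype=float)
    if d.size == 0:
        raise ValidationError("empty distance series after filtering")
    mag = np.abs(d)
    return float(mag.max()), float(mag.mean()), float(np.std(d))


def count_direction_changes(values) -> int:
    """Number of sign changes in consecutive nonzero differences."""
    dif = np.diff(np.asarray(values, dtype=float))
    dif = dif[dif != 0]
    if dif.size < 2:
        return 0
    s = np.sign(dif)
    return int(np.sum(s[1:] != s[:-1]))


def direction_change_features(rec: DrawingRecording,
                              template: SpiralTemplate) -> tuple[int, int, int]:
    """(F5, F6, F7): direction changes of the radius, x and y sequences.

    ``rec`` must already be clipped; a perfect spiral has steadily increasing
    radius, so F5 = 0 there.  Tremor raises all three counts, F5 roughly in
    proportion to tremor frequency × duration.
    """
    if len(rec) < 3:
        raise ValidationError("need >= 3 samples to count direction changes")
    r = np.hypot(rec.x - template.center[0], rec.y - template.center[1])
    return (count_direction_changes(r),
            count_direction_changes(rec.x),
            count_direction_changes(rec.y))


def force_features(force) -> tuple[float, float, float]:
    """(F8, F9, F10) = mean, population std, median of the clipped force series."""
    force = np.asarray(force, dtype=float)
    if force.size == 0:
        raise ValidationError("empty force series")
    return float(force.mean()), float(np.std(force)), float(np.median(force))


def time_velocity_features(rec: DrawingRecording,
                           clip_fraction: float = CLIP_FRACTION) -> tuple[float, float, float]:
    """(F11, F12, F13): drawing time, mean and population std of velocity.

    F11 is taken on the unclipped recording (total drawing time); the velocity
    series is computed on the full recording and then clipped 10% per end, so
    the defined v_0 = 0 never enters the summary statistics.
    """
    duration = rec.duration
    if duration <= 0:
        raise ValidationError("zero-duration recording")
    vs = velocity_series(rec)
    v = clip_time_series(vs.v, clip_fraction)
    return float(duration), float(v.mean()), float(np.std(v))


def log_transform_features(values, eps: float = 1e-9):
    """Natural log of (value + eps) for visualization of drawing-task features."""
    values = np.asarray(values, dtype=float)
    if np.any(values < 0):
        raise DomainError("log transform requires non-negative feature values")
    return np.log(values + eps)


# ---------------------------------------------------------------------------
# per-recording / per-participant composition
# ---------------------------------------------------------------------------

def recording_features(rec: DrawingRecording, template: SpiralTemplate,
                       cfg: SpectralConfig = SpectralConfig(),
                       clip_fraction: float = CLIP_FRACTION,
                       top_fraction: float = TOP_FRACTION) -> dict:
    """All single-recording quantities (F2..F13, spectral bin std, arm std)."""
    rec = ensure_outward(rec)
    ds = signed_distance_series(rec, template)
    ds_clipped = clip_distance_series(ds, clip_fraction)
    rec_clipped = clip_recording(rec, clip_fraction)
    d_filtered = remove_top_values(ds.d, top_fraction, key=np.abs)

    f2, f3, f4 = precision_features(d_filtered)
    f5, f6, f7 = direction_change_features(rec_clipped, template)
    f8, f9, f10 = force_features(rec_clipped.force)
    f11, f12, f13 = time_velocity_features(rec, clip_fraction)
    return {
        "F2_MaxDistance": f2,
        "F3_MeanDistance": f3,
        "F4_StdDevDistance": f4,
        "F5_ChangeOfRadiusDirection": float(f5),
        "F6_ChangesOfDirectionX": float(f6),
        "F7_ChangesOfDirectionY": float(f7),
        "F8_MeanForce": f8,
        "F9_StDevForce": f9,
        "F10_MedianForce": f10,
        "F11_TimeOfDrawing": f11,
        "F12_MeanVelocity": f12,
        "F13_StdDevVelocity": f13,
        "_bin_std": spectral_bin_std(ds_clipped, cfg),
        "_distance_series": ds,
    }


def _average_arm(rec_feats: list[dict]) -> dict:
    keys = [k for k in rec_feats[0] if k != "_distance_series"]
    if len(rec_feats) == 1:
        return {k: rec_feats[0][k] for k in keys}
    return {k: combine_repetitions(rec_feats[0][k], rec_feats[1][k]) for k in keys}


def extract_feature_vector(p: ParticipantRecord,
                           template: SpiralTemplate = SpiralTemplate(),
                           cfg: SpectralConfig = SpectralConfig(),
                           clip_fraction: float = CLIP_FRACTION,
                           top_fraction: float = TOP_FRACTION) -> dict:
    """QYes + F1c..F13 for one participant.

    Per-repetition features are averaged within each arm; motor features come
    from the arm with the larger clipped distance-series std, except F1c which
    is the absolute between-arm difference of the spectral bin-std.
    """
    per_side: dict[str, list[dict]] = {}
    for hand in ("left", "right"):
        per_side[hand] = [
            recording_features(r, template, cfg, clip_fraction, top_fraction)
            for r in p.recordings_for(hand)
        ]
        if not per_side[hand]:
            raise ValidationError(
                f"participant {p.participant_id}: no {hand}-hand recording"
            )
    selection = select_affected_arm(
        [f["_distance_series"] for f in per_side["left"]],
        [f["_distance_series"] for f in per_side["right"]],
        clip_fraction,
    )
    side_feats = {hand: _average_arm(feats) for hand, feats in per_side.items()}
    chosen = side_feats[selection.chosen]
    out = {"QYes": float(qyes(p.questionnaire))}
    out["F1c_DistanceFFT"] = abs(
        side_feats["left"]["_bin_std"] - side_feats["right"]["_bin_std"]
    )
    for name in TABLET_FEATURES[1:]:
        out[name] = chosen[name]
    out["_affected_arm"] = selection.chosen
    return out


def extract_feature_table(cohort, template: SpiralTemplate = SpiralTemplate(),
                          cfg: SpectralConfig = SpectralConfig(),
                          clip_fraction: float = CLIP_FRACTION,
                          top_fraction: float = TOP_FRACTION):
    """One row per participant: metadata + the 14 model inputs (a DataFrame)."""
    import pandas as pd

    rows = []
    for p in cohort:
        fv = extract_feature_vector(p, template, cfg, clip_fraction, top_fraction)
        row = {
            "participant_id": p.participant_id,
            "group": p.group,
            "age": p.age,
            "gender": p.gender,
            "hoehn_yahr": p.hoehn_yahr,
            "affected_arm": fv.pop("_affected_arm"),
        }
        row.update(fv)
        rows.append(row)
    df = pd.DataFrame(rows).set_index("participant_id")
    return df[["group", "age", "gender", "hoehn_yahr", "affected_arm", *FEATURE_NAMES]]
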