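"""Data model and on-disk formats for stylus recordings and cohorts.

A recording is the raw unit of acquisition: one hand, one repetition, an
ordered multivariate time series of (t, x, y, force) sampled at a nominal
240 Hz.  Coordinates are centimetres with the origin at the spiral centre and
y pointing up; timestamps are seconds from the first sample; force is the
dimensionless pen pressure with 1 equal to an average input.

On disk a recording is a plain CSV (columns ``t,x,y,force``, header row, "."
decimal) preceded by ``# key=value`` comment lines carrying the metadata.  A
cohort is a JSON manifest listing participants, their 30-item yes/no
questionnaire rows, demographics, and relative paths to the recording CSVs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

from .errors import CohortError, FormatError, ValidationError

HANDS = ("left", "right")
GROUPS = ("CG", "PD", "DD")
GENDERS = ("female", "male")
HOEHN_YAHR_LEVELS = (1.0, 2.0, 2.5, 3.0, 4.0, 5.0)
N_QUESTIONNAIRE_ITEMS = 30

RECORDING_COLUMNS = ("t", "x", "y", "force")


@dataclass(frozen=True, eq=False)
class DrawingRecording:
    """Ordered stylus samples for one hand x repetition.

    Invariants: >= 2 samples, all values finite, timestamps non-decreasing,
    force >= 0.
    """

    participant_id: str
    hand: str
    repetition: int
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    force: np.ndarray
    nominal_rate: float = 240.0

    def __post_init__(self):
        for name in ("t", "x", "y", "force"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
        n = len(self.t)
        if self.hand not in HANDS:
            raise ValidationError(f"hand must be one of {HANDS}, got {self.hand!r}")
        if self.repetition not in (1, 2):
            raise ValidationError(f"repetition must be 1 or 2, got {self.repetition!r}")
        if any(len(getattr(self, c)) != n for c in ("x", "y", "force")):
            raise ValidationError("t, x, y, force must have equal length")
        if n < 2:
            raise ValidationError(f"a recording needs >= 2 samples, got {n}")
        for name in ("t", "x", "y", "force"):
            arr = getattr(self, name)
            if not np.all(np.isfinite(arr)):
                idx = int(np.flatnonzero(~np.isfinite(arr))[0])
                raise ValidationError(f"non-finite value in column {name!r} at row {idx}")
        if np.any(np.diff(self.t) < 0):
            idx = int(np.flatnonzero(np.diff(self.t) < 0)[0]) + 1
            raise ValidationError(f"timestamps decrease at row {idx}")
        if np.any(self.force < 0):
            idx = int(np.flatnonzero(self.force < 0)[0])
            raise ValidationError(f"negative force at row {idx}")
        if self.nominal_rate <= 0:
            raise ValidationError("nominal_rate must be positive")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def __eq__(self, other) -> bool:
        if not isinstance(other, DrawingRecording):
            return NotImplemented
        return (
            self.participant_id == other.participant_id
            and self.hand == other.hand
            and self.repetition == other.repetition
            and self.nominal_rate == other.nominal_rate
            and all(
                np.array_equal(getattr(self, c), getattr(other, c))
                for c in ("t", "x", "y", "force")
            )
        )

    def replace_samples(self, t, x, y, force) -> "DrawingRecording":
        return DrawingRecording(
            participant_id=self.participant_id,
            hand=self.hand,
            repetition=self.repetition,
            t=t,
            x=x,
            y=y,
            force=force,
            nominal_rate=self.nominal_rate,
        )


@dataclass(frozen=True, eq=False)
class QuestionnaireResponse:
    """Exactly 30 binary yes(1)/no(0) answers of the PDNMS questionnaire."""

    items: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.items)
        if arr.shape != (N_QUESTIONNAIRE_ITEMS,):
            raise ValidationError(
                f"questionnaire needs exactly {N_QUESTIONNAIRE_ITEMS} items, got shape {arr.shape}"
            )
        as_float = arr.astype(float)
        if not np.all(np.isin(as_float, (0.0, 1.0))):
            idx = int(np.flatnonzero(~np.isin(as_float, (0.0, 1.0)))[0])
            raise ValidationError(f"non-binary questionnaire answer at item {idx}")
        object.__setattr__(self, "items", as_float.astype(int))

    def __eq__(self, other) -> bool:
        if not isinstance(other, QuestionnaireResponse):
            return NotImplemented
        return np.array_equal(self.items, other.items)


@dataclass(eq=False)
class ParticipantRecord:
    """One participant: group label, demographics, recordings, questionnaire."""

    participant_id: str
    group: str
    age: float
    gender: str
    questionnaire: QuestionnaireResponse
    recordings: list[DrawingRecording] = field(default_factory=list)
    hoehn_yahr: float | None = None

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValidationError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.gender not in GENDERS:
            raise ValidationError(f"gender must be one of {GENDERS}, got {self.gender!r}")
        if not math.isfinite(self.age) or self.age <= 0:
            raise ValidationError(f"age must be a positive finite number, got {self.age}")
        if self.hoehn_yahr is not None:
            if self.group != "PD":
                raise ValidationError(
                    f"participant {self.participant_id}: Hoehn-Yahr only valid for PD"
                )
            if float(self.hoehn_yahr) not in HOEHN_YAHR_LEVELS:
                raise ValidationError(
                    f"Hoehn-Yahr must be in {HOEHN_YAHR_LEVELS}, got {self.hoehn_yahr}"
                )
        seen = set()
        for rec in self.recordings:
            key = (rec.hand, rec.repetition)
            if key in seen:
                raise ValidationError(
                    f"participant {self.participant_id}: duplicate recording {key}"
                )
            if rec.participant_id != self.participant_id:
                raise ValidationError(
                    f"recording id {rec.participant_id!r} does not match participant "
                    f"{self.participant_id!r}"
                )
            seen.add(key)

    def recordings_for(self, hand: str) -> list[DrawingRecording]:
        return sorted(
            (r for r in self.recordings if r.hand == hand), key=lambda r: r.repetition
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, ParticipantRecord):
            return NotImplemented
        return (
            self.participant_id == other.participant_id
            and self.group == other.group
            and self.age == other.age
            and self.gender == other.gender
            and self.hoehn_yahr == other.hoehn_yahr
            and self.questionnaire == other.questionnaire
            and sorted(self.recordings, key=lambda r: (r.hand, r.repetition))
            == sorted(other.recordings, key=lambda r: (r.hand, r.repetition))
        )


@dataclass(eq=False)
class CohortDataset:
    """A validated set of participants with unique ids."""

    participants: list[ParticipantRecord]

    def __post_init__(self):
        ids = [p.participant_id for p in self.participants]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortError(f"duplicate participant ids: {dup}")
        for p in self.participants:
            for hand in HANDS:
                if not p.recordings_for(hand):
                    raise CohortError(
                        f"participant {p.participant_id} has no {hand}-hand recording"
                    )

    def __len__(self) -> int:
        return len(self.participants)

    def __iter__(self):
        return iter(self.participants)

    def get(self, participant_id: str) -> ParticipantRecord:
        for p in self.participants:
            if p.participant_id == participant_id:
                return p
        raise KeyError(participant_id)

    @property
    def groups(self) -> pd.Series:
        return pd.Series(
            [p.group for p in self.participants],
            index=[p.participant_id for p in self.participants],
            name="group",
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, CohortDataset):
            return NotImplemented
        return self.participants == other.participants


# ---------------------------------------------------------------------------
# recording CSV
# ---------------------------------------------------------------------------

def write_recording(rec: DrawingRecording, path) -> Path:
    """Serialize a recording to CSV; lossless round-trip with read_recording."""
    path = Path(path)
    header = (
        f"# participant_id={rec.participant_id}\n"
        f"# hand={rec.hand}\n"
        f"# repetition={rec.repetition}\n"
        f"# nominal_rate={rec.nominal_rate!r}\n"
    )
    df = pd.DataFrame({c: getattr(rec, c) for c in RECORDING_COLUMNS})
    with open(path, "w") as fh:
        fh.write(header)
        # str(float) round-trips exactly in Python 3
        df.to_csv(fh, index=False)
    return path


def read_recording(path, dialect: str = "csv") -> DrawingRecording:
    """Read one recording CSV written by :func:`write_recording`."""
    if dialect != "csv":
        raise FormatError(f"unknown dialect {dialect!r}")
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - defensive
        raise FormatError(f"{path}: unreadable CSV ({exc})") from exc
    missing = [c for c in RECORDING_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    for col in RECORDING_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            raise ValidationError(
                f"{path}: non-numeric or missing value in column {col!r} at row "
                f"{int(np.flatnonzero(bad.to_numpy())[0])}"
            )
        df[col] = vals
    return DrawingRecording(
        participant_id=meta.get("participant_id", path.stem),
        hand=meta.get("hand", "right"),
        repetition=int(meta.get("repetition", 1)),
        t=df["t"].to_numpy(),
        x=df["x"].to_numpy(),
        y=df["y"].to_numpy(),
        force=df["force"].to_numpy(),
        nominal_rate=float(meta.get("nominal_rate", 240.0)),
    )


# ---------------------------------------------------------------------------
# cohort manifest
# ---------------------------------------------------------------------------

def _participant_to_manifest(p: ParticipantRecord, rec_paths: dict) -> dict:
    return {
        "participant_id": p.participant_id,
        "group": p.group,
        "age": p.age,
        "gender": p.gender,
        "hoehn_yahr": p.hoehn_yahr,
        "questionnaire": [int(v) for v in p.questionnaire.items],
        "recordings": [
            {"hand": r.hand, "repetition": r.repetition, "path": rec_paths[(p.participant_id, r.hand, r.repetition)]}
            for r in sorted(p.recordings, key=lambda r: (r.hand, r.repetition))
        ],
    }


def save_cohort(cohort: CohortDataset, out_dir) -> Path:
    """Write a cohort as manifest.json + one CSV per recording; returns manifest path."""
    out_dir = Path(out_dir)
    rec_dir = out_dir / "recordings"
    rec_dir.mkdir(parents=True, exist_ok=True)
    rec_paths = {}
    for p in cohort:
        for rec in p.recordings:
            rel = f"recordings/{p.participant_id}_{rec.hand}_{rec.repetition}.csv"
            write_recording(rec, out_dir / rel)
            rec_paths[(p.participant_id, rec.hand, rec.repetition)] = rel
    manifest = {
        "format": "spiraldx-cohort-v1",
        "participants": [_participant_to_manifest(p, rec_paths) for p in cohort],
    }
    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest_path


def load_cohort(manifest_path) -> CohortDataset:
    """Load and fully validate a cohort from its JSON manifest."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    try:
        with open(manifest_path) as fh:
            manifest = json.load(fh)
    except FileNotFoundError:
        raise CohortError(f"manifest not found: {manifest_path}")
    except json.JSONDecodeError as exc:
        raise FormatError(f"{manifest_path}: invalid JSON ({exc})") from exc
    entries = manifest.get("participants")
    if not isinstance(entries, list):
        raise FormatError(f"{manifest_path}: missing 'participants' list")
    participants = []
    for entry in entries:
        pid = entry.get("participant_id")
        if pid is None:
            raise FormatError(f"{manifest_path}: participant without participant_id")
        recs = []
        for rec_entry in entry.get("recordings", []):
            rec_path = base / rec_entry["path"]
            if not rec_path.exists():
                raise CohortError(
                    f"participant {pid}: recording file not found: {rec_path}"
                )
            rec = read_recording(rec_path)
            if (rec.hand, rec.repetition) != (rec_entry["hand"], int(rec_entry["repetition"])):
                raise CohortError(
                    f"participant {pid}: manifest says ({rec_entry['hand']}, "
                    f"{rec_entry['repetition']}) but file {rec_path} carries "
                    f"({rec.hand}, {rec.repetition})"
                )
            recs.append(rec)
        hy = entry.get("hoehn_yahr")
        participants.append(
            ParticipantRecord(
                participant_id=pid,
                group=entry["group"],
                age=float(entry["age"]),
                gender=entry["gender"],
                hoehn_yahr=None if hy is None else float(hy),
                questionnaire=QuestionnaireResponse(np.asarray(entry["questionnaire"])),
                recordings=recs,
            )
        )
    return CohortDataset(participants)
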