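"""Landmark digitization and reconstruction.

Five bony landmarks define the elbow's anatomical frames: the greater
tubercle and the medial and lateral epicondyles of the humerus, and the
radial and ulnar styloid processes at the wrist. Each landmark is touched
with a tracked stylus while two bone-fixed sensors (humerus and forearm)
record their own poses; the landmark is stored in its host sensor's local
frame and can then be reconstructed in world coordinates at any time step.

The radial styloid is treated as rigid with the forearm sensor, which is
valid because trials lock the forearm in supination (no pro/supination).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np

from .rigid import (
    PoseStream,
    RigidPose,
    ValidationError,
    align_streams,
    as_vec3,
    transform_point,
)

__all__ = [
    "Landmark",
    "HUMERUS",
    "FOREARM",
    "HOST_SENSOR",
    "RegistryEntry",
    "LandmarkRegistry",
    "digitize_landmark",
    "reconstruct_landmarks",
]

HUMERUS = "humerus"
FOREARM = "forearm"


class Landmark(str, Enum):
    """The five bony landmarks used to build the anatomical frames."""

    GREATER_TUBERCLE = "greater_tubercle"
    MEDIAL_EPICONDYLE = "medial_epicondyle"
    LATERAL_EPICONDYLE = "lateral_epicondyle"
    RADIAL_STYLOID = "radial_styloid"
    ULNAR_STYLOID = "ulnar_styloid"


#: which bone-fixed sensor each landmark moves rigidly with
HOST_SENSOR: dict[Landmark, str] = {
    Landmark.GREATER_TUBERCLE: HUMERUS,
    Landmark.MEDIAL_EPICONDYLE: HUMERUS,
    Landmark.LATERAL_EPICONDYLE: HUMERUS,
    Landmark.RADIAL_STYLOID: FOREARM,
    Landmark.ULNAR_STYLOID: FOREARM,
}


@dataclass
class RegistryEntry:
    """One digitized landmark: host sensor and sensor-local position (mm)."""

    host_sensor: str
    local: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        if self.host_sensor not in (HUMERUS, FOREARM):
            raise ValidationError(f"unknown host sensor {self.host_sensor!r}")
        self.local = as_vec3(self.local)
        self.n_samples = int(self.n_samples)


@dataclass
class LandmarkRegistry:
    """Complete set of five digitized landmarks.

    Invariant: the three humeral landmarks are hosted by the humerus
    sensor and the two wrist landmarks by the forearm sensor.
    """

    entries: dict[Landmark, RegistryEntry]

    def __post_init__(self) -> None:
        self.entries = {Landmark(k): v for k, v in self.entries.items()}
        missing = [lm.value for lm in Landmark if lm not in self.entries]
        if missing:
            raise ValidationError(f"registry missing landmarks: {', '.join(missing)}")
        for lm, entry in self.entries.items():
            expected = HOST_SENSOR[lm]
            if entry.host_sensor != expected:
                raise ValidationError(
                    f"{lm.value} must be hosted by the {expected} sensor, "
                    f"got {entry.host_sensor!r}"
                )

    def __getitem__(self, lm: Landmark) -> RegistryEntry:
        return self.entries[Landmark(lm)]

    def to_json_dict(self) -> dict:
        return {
            lm.value: {
                "host": e.host_sensor,
                "local_mm": [float(c) for c in e.local],
                "n_samples": e.n_samples,
            }
            for lm, e in sorted(self.entries.items(), key=lambda kv: kv[0].value)
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "LandmarkRegistry":
        entries = {
            Landmark(k): RegistryEntry(
                host_sensor=v["host"], local=v["local_mm"], n_samples=v.get("n_samples", 1)
            )
            for k, v in d.items()
        }
        return cls(entries=entries)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def load(cls, path) -> "LandmarkRegistry":
        return cls.from_json_dict(json.loads(Path(path).read_text()))


def digitize_landmark(
    stylus: PoseStream,
    host: PoseStream,
    landmark: Landmark,
    tip_offset=(0.0, 0.0, 0.0),
) -> RegistryEntry:
    """Digitize one landmark from time-aligned stylus and host windows.

    For each aligned sample pair the stylus tip (sensor origin plus a
    fixed ``tip_offset`` in the stylus frame) is expressed in the host
    sensor's local frame; the entry stores the mean over the window,
    which averages down independent digitization noise.
    """
    landmark = Landmark(landmark)
    if len(stylus) == 0 or len(host) == 0:
        raise ValidationError("digitization window is empty")
    idx_s, idx_h = align_streams(stylus, host)
    tip_offset = as_vec3(tip_offset)
    tips = stylus.rotations().apply(np.tile(tip_offset, (len(stylus), 1))) + stylus.positions
    host_rot = host.rotations()
    locals_ = host_rot[idx_h].inv().apply(tips[idx_s] - host.positions[idx_h])
    return RegistryEntry(
        host_sensor=HOST_SENSOR[landmark],
        local=locals_.mean(axis=0),
        n_samples=len(idx_s),
    )


def reconstruct_landmarks(
    registry: LandmarkRegistry, humerus: RigidPose, forearm: RigidPose
) -> dict[Landmark, np.ndarray]:
    """World positions of all five landmarks at the given sensor poses."""
    host_pose = {HUMERUS: humerus, FOREARM: forearm}
    out: dict[Landmark, np.ndarray] = {}
    for lm in Landmark:
        try:
            entry = registry[lm]
        except KeyError as exc:
            raise ValidationError(f"registry missing landmark {lm.value}") from exc
        out[lm] = transform_point(host_pose[entry.host_sensor], entry.local)
    return out
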