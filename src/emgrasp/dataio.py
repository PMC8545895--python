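"""Trial containers and on-disk storage for multi-channel surface EMG.

One trial is a [samples x channels] matrix recorded at 1,000 Hz together
with its labels: grasp type (one of six prehensile patterns), object
weight (light/heavy), subject and repetition. Datasets are stored as one
CSV per trial (header row of muscle names, one sample per row) plus a
JSON manifest describing subject, sampling rate, channel set and the
per-trial label records. The manifest's channel order is authoritative
for all downstream channel indexing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

GRASPS: tuple[str, ...] = ("spherical", "tripod", "power", "lateral", "tip", "extension")
WEIGHTS: tuple[str, ...] = ("light", "heavy")
FS_HZ: int = 1000

#: canonical six-channel montage (upper arm + trunk) and the eight-channel
#: extension adding the forearm wrist flexor/extensor pair
CHANNELS_6: tuple[str, ...] = (
    "deltoid_middle",
    "biceps",
    "triceps",
    "latissimus_dorsi",
    "trapezius",
    "pectoralis",
)
CHANNELS_8: tuple[str, ...] = CHANNELS_6 + (
    "flexor_carpi_radialis",
    "extensor_carpi_radialis",
)


class ValidationError(ValueError):
    """A trial or manifest violates a structural invariant."""


@dataclass(frozen=True)
class ChannelSet:
    """Ordered muscle labels with the triceps position singled out.

    The triceps channel anchors movement-onset detection, so its index
    must always be resolvable.
    """

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        names = tuple(self.names)
        object.__setattr__(self, "names", names)
        if len(names) not in (6, 8):
            raise ValidationError(f"channel count must be 6 or 8, got {len(names)}")
        if len(set(names)) != len(names):
            raise ValidationError("channel names must be unique")
        if "triceps" not in names:
            raise ValidationError("channel set must contain a 'triceps' channel")

    @property
    def count(self) -> int:
        return len(self.names)

    @property
    def triceps_index(self) -> int:
        return self.names.index("triceps")

    @classmethod
    def default(cls, n_channels: int) -> "ChannelSet":
        if n_channels == 6:
            return cls(CHANNELS_6)
        if n_channels == 8:
            return cls(CHANNELS_8)
        raise ValidationError(f"no default channel set for {n_channels} channels")


@dataclass
class EmgTrial:
    """One recorded or simulated trial with its labels."""

    signal: np.ndarray  # [samples x channels], mV
    fs: int
    grasp: str
    weight: str
    subject: str
    repetition: int
    channels: ChannelSet

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.fs != FS_HZ:
            raise ValidationError(f"sampling rate must be {FS_HZ} Hz, got {self.fs}")
        if self.signal.ndim != 2:
            raise ValidationError("signal must be a 2-D [samples x channels] matrix")
        if self.signal.shape[0] < 400:
            raise ValidationError(
                f"trial must hold at least 400 samples, got {self.signal.shape[0]}"
            )
        if self.signal.shape[1] != self.channels.count:
            raise ValidationError(
                f"signal has {self.signal.shape[1]} channels, "
                f"channel set has {self.channels.count}"
            )
        if not np.all(np.isfinite(self.signal)):
            bad = np.argwhere(~np.isfinite(self.signal))[0]
            raise ValidationError(
                f"non-finite sample at row {bad[0]}, channel {bad[1]} "
                f"({self.channels.names[bad[1]]})"
            )
        if self.grasp not in GRASPS:
            raise ValidationError(f"unknown grasp label {self.grasp!r}")
        if self.weight not in WEIGHTS:
            raise ValidationError(f"unknown weight label {self.weight!r}")
        if self.repetition < 1:
            raise ValidationError("repetition must be >= 1")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]


def write_manifest(trials: list[EmgTrial], out_dir: str | Path) -> Path:
    """Write one CSV per trial plus a JSON manifest; return the manifest path.

    Samples are serialized with 17 significant digits so the write->read
    round trip reproduces float64 signals bit-exactly.
    """
    if not trials:
        raise ValidationError("cannot write an empty trial list")
    channels = trials[0].channels
    for t in trials:
        if t.channels != channels:
            raise ValidationError("all trials in a manifest must share one channel set")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    records = []
    header = ",".join(channels.names)
    for i, t in enumerate(trials):
        fname = f"trial_{i:04d}_{t.grasp}_{t.weight}_r{t.repetition:02d}.csv"
        np.savetxt(
            out_dir / fname,
            t.signal,
            fmt="%.17g",
            delimiter=",",
            header=header,
            comments="",
        )
        records.append(
            {
                "file": fname,
                "grasp": t.grasp,
                "weight": t.weight,
                "repetition": t.repetition,
                "subject": t.subject,
            }
        )
    manifest = {
        "subject": trials[0].subject,
        "fs": FS_HZ,
        "channels": list(channels.names),
        "trials": records,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path


def read_manifest(path: str | Path) -> list[EmgTrial]:
    """Load and validate every trial referenced by a manifest.

    All trials are validated before any are returned: a single bad file
    aborts the whole load with an error naming that file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    manifest = json.loads(path.read_text())
    for key in ("fs", "channels", "trials"):
        if key not in manifest:
            raise ValidationError(f"manifest missing key {key!r}")
    channels = ChannelSet(tuple(manifest["channels"]))
    fs = int(manifest["fs"])
    base = path.parent

    trials: list[EmgTrial] = []
    for rec in manifest["trials"]:
        fpath = base / rec["file"]
        if not fpath.exists():
            raise FileNotFoundError(f"trial file missing: {fpath}")
        try:
            signal = np.loadtxt(fpath, delimiter=",", skiprows=1, ndmin=2)
        except ValueError as exc:
            raise ValidationError(f"unparseable trial file {fpath}: {exc}") from exc
        try:
            trial = EmgTrial(
                signal=signal,
                fs=fs,
                grasp=rec["grasp"],
                weight=rec["weight"],
                subject=rec.get("subject", manifest.get("subject", "unknown")),
                repetition=int(rec["repetition"]),
                channels=channels,
            )
        except ValidationError as exc:
            raise ValidationError(f"invalid trial {fpath.name}: {exc}") from exc
        trials.append(trial)
    return trials
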