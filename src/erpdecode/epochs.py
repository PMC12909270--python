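"""Epoched EEG data model, preprocessing, and container I/O.

An :class:`EpochedDataset` holds one participant's stimulus-locked epochs as
a ``trials x channels x samples`` voltage array (μV) together with the time
axis, channel labels and per-trial metadata.  Preprocessing implemented here
is restricted to the two epoch-level steps of the analysis pipeline:
prestimulus baseline subtraction and ±threshold amplitude rejection; all
continuous-data cleaning (filtering, ICA, re-referencing, interpolation) is
assumed to have happened upstream.

Conventions
-----------
* sample 0 is the first sample at/after the epoch start; stimulus onset
  (t = 0) belongs to the post-stimulus side;
* millisecond intervals are closed on the left and open on the right when
  converted to sample indices;
* trial order is never permuted by any operation in this module.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DIMENSIONS = ("appealing", "curiosity", "wanting")

_MAGIC = "erpdecode-epochs-v1"


class CorruptContainerError(ValueError):
    """Raised when a container's header and binary payload disagree."""


@dataclass
class TrialInfo:
    """Metadata for one trial (one image x question presentation)."""

    image_id: str
    dimension: str  # appealing | curiosity | wanting
    response: str  # yes | no | none (no button press)
    rating: int | None  # 0-100 post-experimental rating, None if absent
    response_side: str = "left"  # side of the YES option on screen
    rejected: bool = False

    def __post_init__(self) -> None:
        if self.dimension not in DIMENSIONS:
            raise ValueError(f"unknown dimension {self.dimension!r}")
        if self.response not in ("yes", "no", "none"):
            raise ValueError(f"unknown response {self.response!r}")
        if self.rating is not None and not 0 <= self.rating <= 100:
            raise ValueError("rating must lie in [0, 100]")


@dataclass
class EpochedDataset:
    """One participant's epoched voltages plus axes and trial metadata."""

    participant_id: str
    voltages: np.ndarray  # (n_trials, n_channels, n_samples), μV
    times: np.ndarray  # ms relative to stimulus onset
    channel_labels: tuple[str, ...]
    sampling_rate: float  # Hz
    trials: list[TrialInfo] = field(default_factory=list)
    baseline_corrected: bool = False
    group: str | None = None  # vaping-status group, if simulated/known

    def __post_init__(self) -> None:
        v = np.asarray(self.voltages)
        if v.ndim != 3:
            raise ValueError("voltages must be trials x channels x samples")
        n_trials, n_channels, n_samples = v.shape
        if len(self.trials) != n_trials:
            raise ValueError("trials metadata length != voltage trials")
        if len(self.channel_labels) != n_channels:
            raise ValueError("channel_labels length != voltage channels")
        t = np.asarray(self.times, dtype=float)
        if t.shape != (n_samples,):
            raise ValueError("times length != voltage samples")
        dt = np.diff(t)
        if n_samples > 1 and not (
            np.all(dt > 0)
            and np.allclose(dt, 1000.0 / self.sampling_rate, rtol=1e-6)
        ):
            raise ValueError("times must increase uniformly at 1000/fs ms")
        self.times = t
        self.channel_labels = tuple(self.channel_labels)

    # -- axis helpers -------------------------------------------------

    @property
    def n_trials(self) -> int:
        return self.voltages.shape[0]

    @property
    def n_channels(self) -> int:
        return self.voltages.shape[1]

    @property
    def n_samples(self) -> int:
        return self.voltages.shape[2]

    def sample_slice(self, interval_ms: tuple[float, float]) -> slice:
        """Samples with ``interval_ms[0] <= t < interval_ms[1]``."""
        lo, hi = interval_ms
        if lo >= hi:
            raise ValueError("empty interval")
        if lo < self.times[0] - 1e-9 or hi > self.times[-1] + 1000.0 / self.sampling_rate + 1e-9:
            raise ValueError(
                f"interval [{lo}, {hi}) ms outside epoch span "
                f"[{self.times[0]}, {self.times[-1]}] ms"
            )
        mask = (self.times >= lo - 1e-9) & (self.times < hi - 1e-9)
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise ValueError(f"interval [{lo}, {hi}) ms contains no samples")
        return slice(int(idx[0]), int(idx[-1]) + 1)


def times_axis(epoch_span_ms: tuple[float, float], sampling_rate: float) -> np.ndarray:
    """Uniform time axis for an epoch: floor(span·fs/1000) samples from span start."""
    lo, hi = epoch_span_ms
    n = int(np.floor((hi - lo) * sampling_rate / 1000.0))
    return lo + np.arange(n) * (1000.0 / sampling_rate)


# ---------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------

def baseline_correct(
    ds: EpochedDataset, baseline: tuple[float, float] = (-100.0, 0.0)
) -> EpochedDataset:
    """Subtract each trial x channel's mean voltage over the baseline interval.

    The default interval is the 100-ms prestimulus period.  Raises if the
    dataset was already corrected (double correction silently re-zeroes a
    different interval, which is almost always a pipeline bug).
    """
    if ds.baseline_corrected:
        raise RuntimeError("dataset already baseline-corrected")
    sl = ds.sample_slice(baseline)
    means = ds.voltages[:, :, sl].mean(axis=2, keepdims=True)
    return dataclasses.replace(
        ds,
        voltages=ds.voltages - means,
        trials=[dataclasses.replace(t) for t in ds.trials],
        baseline_corrected=True,
    )


def reject_amplitude(
    ds: EpochedDataset, threshold: float = 150.0
) -> tuple[EpochedDataset, dict]:
    """Mark trials whose |voltage| exceeds ``threshold`` μV at any channel/sample.

    Returns the dataset with ``rejected`` flags set (previous flags are kept)
    and a report dict with per-participant counts.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    exceed = np.abs(ds.voltages).max(axis=(1, 2)) > threshold
    trials = [
        dataclasses.replace(t, rejected=bool(t.rejected or exceed[i]))
        for i, t in enumerate(ds.trials)
    ]
    out = dataclasses.replace(ds, trials=trials)
    report = {
        "participant_id": ds.participant_id,
        "threshold_uv": float(threshold),
        "n_trials": int(ds.n_trials),
        "n_rejected": int(exceed.sum()),
        "rejected_indices": [int(i) for i in np.flatnonzero(exceed)],
    }
    return out, report


def select_trials(
    ds: EpochedDataset, dimension: str, drop_rejected: bool = True,
    drop_missing_response: bool = True,
) -> EpochedDataset:
    """View of one question dimension's trials, in original order.

    Missing responses (no button press) are excluded from decoding along
    with rejected trials when the respective flags are set.
    """
    if dimension not in DIMENSIONS:
        raise ValueError(f"unknown dimension {dimension!r}")
    keep = [
        i
        for i, t in enumerate(ds.trials)
        if t.dimension == dimension
        and not (drop_rejected and t.rejected)
        and not (drop_missing_response and t.response == "none")
    ]
    return dataclasses.replace(
        ds,
        voltages=ds.voltages[keep],
        trials=[ds.trials[i] for i in keep],
    )


# ---------------------------------------------------------------------
# container I/O
# ---------------------------------------------------------------------
# A container is a directory with:
#   header.json  - all metadata incl. the time axis and trial table
#   voltages.f32 - little-endian float32, trials-major / channels / samples

def write_container(ds: EpochedDataset, path: str | Path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    header = {
        "format": _MAGIC,
        "participant_id": ds.participant_id,
        "group": ds.group,
        "sampling_rate": float(ds.sampling_rate),
        "baseline_corrected": bool(ds.baseline_corrected),
        "channel_labels": list(ds.channel_labels),
        "times_ms": [float(t) for t in ds.times],
        "shape": [int(s) for s in ds.voltages.shape],
        "trials": [dataclasses.asdict(t) for t in ds.trials],
    }
    (path / "header.json").write_text(json.dumps(header, indent=1))
    arr = np.ascontiguousarray(ds.voltages, dtype="<f4")
    (path / "voltages.f32").write_bytes(arr.tobytes())
    return path


def read_container(path: str | Path) -> EpochedDataset:
    path = Path(path)
    try:
        header = json.loads((path / "header.json").read_text())
    except FileNotFoundError as e:
        raise CorruptContainerError(f"missing header.json in {path}") from e
    if header.get("format") != _MAGIC:
        raise CorruptContainerError(f"unrecognised container format in {path}")
    shape = tuple(header["shape"])
    raw = (path / "voltages.f32").read_bytes()
    expected = int(np.prod(shape)) * 4
    if len(raw) != expected:
        raise CorruptContainerError(
            f"voltages.f32 holds {len(raw)} bytes, header implies {expected}"
        )
    voltages = np.frombuffer(raw, dtype="<f4").reshape(shape).copy()
    trials = [TrialInfo(**t) for t in header["trials"]]
    return EpochedDataset(
        participant_id=header["participant_id"],
        voltages=voltages,
        times=np.asarray(header["times_ms"], dtype=float),
        channel_labels=tuple(header["channel_labels"]),
        sampling_rate=header["sampling_rate"],
        trials=trials,
        baseline_corrected=header["baseline_corrected"],
        group=header.get("group"),
    )


def trial_table(datasets: list[EpochedDataset]) -> pd.DataFrame:
    """Long trial-metadata table (one row per trial) across participants."""
    rows = []
    for ds in datasets:
        for t in ds.trials:
            rows.append(
                {
                    "participant_id": ds.participant_id,
                    "group": ds.group,
                    "image_id": t.image_id,
                    "dimension": t.dimension,
                    "response": t.response,
                    "rating": t.rating,
                    "response_side": t.response_side,
                    "rejected": t.rejected,
                }
            )
    return pd.DataFrame(rows)
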