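"""In-memory multimodal consultation datasets and their on-disk container.

A dataset is a fixed-size collection of consultations, each carrying three
token-sequence feature arrays (text, audio, visual), a label (class index or
a real assessment score in [-3, 3]), per-modality binary synthetic/real
flags, and an environment context vector describing the virtual setting.

On disk a dataset is one HDF5 file plus a JSON manifest sidecar
(``<path>.json``) echoing shapes, task type and the generating recipe; load
validates the two against each other and round-trips bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import h5py
import numpy as np

__all__ = [
    "MODALITIES",
    "MultimodalSample",
    "MultimodalDataset",
    "save_dataset",
    "load_dataset",
    "DatasetFormatError",
]

MODALITIES = ("text", "audio", "visual")
CONTAINER_VERSION = 1


class DatasetFormatError(RuntimeError):
    """Raised when the HDF5 container and its manifest are absent/inconsistent."""


@dataclass
class MultimodalSample:
    """One consultation: three token-feature arrays, label, flags, environment."""

    text_tokens: np.ndarray
    audio_tokens: np.ndarray
    visual_tokens: np.ndarray
    label: float | int
    synthetic_flags: np.ndarray  # shape (3,), order text/audio/visual, values {0,1}
    environment: np.ndarray

    def tokens(self, modality: str) -> np.ndarray:
        return getattr(self, f"{modality}_tokens")

    def validate(self) -> None:
        for m in MODALITIES:
            arr = self.tokens(m)
            if arr.ndim != 2 or arr.shape[0] < 1:
                raise ValueError(f"{m} tokens must be a non-empty (length x width) array")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{m} tokens contain non-finite values")
        if not np.all(np.isin(self.synthetic_flags, (0, 1))):
            raise ValueError("synthetic flags must be binary")


@dataclass
class MultimodalDataset:
    """Column-oriented dataset: per-modality (n, l_m, F_m) arrays plus metadata.

    ``task`` is ``"classification"`` (integer labels in 0..C-1) or
    ``"regression"`` (real scores in [-3, 3]).
    """

    text: np.ndarray
    audio: np.ndarray
    visual: np.ndarray
    labels: np.ndarray
    synthetic_flags: np.ndarray  # (n, 3) in modality order
    environment: np.ndarray  # (n, d_e)
    task: str
    n_classes: int | None = None
    spec: dict | None = None  # generating recipe echo, if synthetic

    def __post_init__(self):
        if self.task not in ("classification", "regression"):
            raise ValueError(f"unknown task {self.task!r}")
        n = self.text.shape[0]
        for m in MODALITIES:
            arr = self.modality(m)
            if arr.ndim != 3 or arr.shape[0] != n:
                raise ValueError(f"{m} array must be (n, l, F) with n={n}, got {arr.shape}")
        if self.labels.shape != (n,):
            raise ValueError(f"labels must be ({n},), got {self.labels.shape}")
        if self.synthetic_flags.shape != (n, 3):
            raise ValueError(f"synthetic_flags must be ({n}, 3), got {self.synthetic_flags.shape}")
        if self.environment.ndim != 2 or self.environment.shape[0] != n:
            raise ValueError("environment must be (n, d_e)")
        if self.task == "classification" and n > 0:
            if self.n_classes is None:
                self.n_classes = int(self.labels.max()) + 1
            if self.labels.min() < 0 or self.labels.max() >= self.n_classes:
                raise ValueError("class labels out of range")

    def modality(self, m: str) -> np.ndarray:
        return getattr(self, m)

    def __len__(self) -> int:
        return self.text.shape[0]

    @property
    def dims(self) -> dict[str, tuple[int, int]]:
        """Per-modality (sequence length, feature width)."""
        return {m: self.modality(m).shape[1:] for m in MODALITIES}

    @property
    def d_environment(self) -> int:
        return self.environment.shape[1]

    def sample(self, i: int) -> MultimodalSample:
        return MultimodalSample(
            text_tokens=self.text[i],
            audio_tokens=self.audio[i],
            visual_tokens=self.visual[i],
            label=self.labels[i],
            synthetic_flags=self.synthetic_flags[i],
            environment=self.environment[i],
        )

    def subset(self, idx: Sequence[int] | np.ndarray) -> "MultimodalDataset":
        idx = np.asarray(idx, dtype=np.intp)
        return MultimodalDataset(
            text=self.text[idx],
            audio=self.audio[idx],
            visual=self.visual[idx],
            labels=self.labels[idx],
            synthetic_flags=self.synthetic_flags[idx],
            environment=self.environment[idx],
            task=self.task,
            n_classes=self.n_classes,
            spec=self.spec,
        )


def _manifest_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def save_dataset(dataset: MultimodalDataset, path: str | Path) -> None:
    """Write the HDF5 container and its JSON manifest sidecar."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["container_version"] = CONTAINER_VERSION
        for m in MODALITIES:
            f.create_dataset(m, data=dataset.modality(m))
        f.create_dataset("labels", data=dataset.labels)
        f.create_dataset("synthetic_flags", data=dataset.synthetic_flags.astype(np.uint8))
        f.create_dataset("environment", data=dataset.environment)
    manifest: dict[str, Any] = {
        "container_version": CONTAINER_VERSION,
        "n_samples": len(dataset),
        "task": dataset.task,
        "n_classes": dataset.n_classes,
        "dims": {m: list(dataset.modality(m).shape[1:]) for m in MODALITIES},
        "d_environment": dataset.d_environment,
        "spec": dataset.spec,
    }
    _manifest_path(path).write_text(json.dumps(manifest, indent=2))


def load_dataset(path: str | Path) -> MultimodalDataset:
    """Load and cross-validate the container and manifest; lossless round-trip."""
    path = Path(path)
    mpath = _manifest_path(path)
    if not path.exists():
        raise DatasetFormatError(f"container not found: {path}")
    if not mpath.exists():
        raise DatasetFormatError(f"manifest not found: {mpath}")
    manifest = json.loads(mpath.read_text())
    version = manifest.get("container_version")
    if version != CONTAINER_VERSION:
        raise DatasetFormatError(f"unsupported container version: {version!r}")
    arrays: dict[str, np.ndarray] = {}
    with h5py.File(path, "r") as f:
        if f.attrs.get("container_version") != CONTAINER_VERSION:
            raise DatasetFormatError(
                f"unsupported container version: {f.attrs.get('container_version')!r}"
            )
        for name in (*MODALITIES, "labels", "synthetic_flags", "environment"):
            if name not in f:
                raise DatasetFormatError(f"missing array {name!r} in {path}")
            arrays[name] = f[name][...]
    n = manifest["n_samples"]
    for m in MODALITIES:
        got = arrays[m].shape
        want = (n, *manifest["dims"][m])
        if got != want:
            raise DatasetFormatError(f"manifest/container mismatch for {m!r}: {got} vs {want}")
    if arrays["labels"].shape[0] != n:
        raise DatasetFormatError("manifest/container mismatch for labels")
    return MultimodalDataset(
        text=arrays["text"],
        audio=arrays["audio"],
        visual=arrays["visual"],
        labels=arrays["labels"],
        synthetic_flags=arrays["synthetic_flags"].astype(np.uint8),
        environment=arrays["environment"],
        task=manifest["task"],
        n_classes=manifest["n_classes"],
        spec=manifest.get("spec"),
    )
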