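"""Manifest-driven datasets and cached network inputs.

A dataset is a UTF-8 CSV manifest with columns ``clip_path,label`` and
an optional ``subject_id``; paths are resolved relative to the manifest.
Network input images (128x256 standardized spectrograms) can be cached
to a single portable ``.npz`` beside the manifest.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .audio import load_audio
from .spectrogram import NET_INPUT_SHAPE, clip_to_net_input


@dataclass
class Dataset:
    manifest_path: Path
    clip_paths: list[Path]
    labels: np.ndarray
    subjects: np.ndarray | None

    def __len__(self) -> int:
        return len(self.clip_paths)


def load_manifest(path: str | Path) -> Dataset:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    df = pd.read_csv(path)
    for col in ("clip_path", "label"):
        if col not in df.columns:
            raise ValueError(f"manifest {path} lacks required column {col!r}")
    labels = df["label"].to_numpy(dtype=int)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be 0 (control) or 1 (patient)")
    subjects = (df["subject_id"].to_numpy(dtype=str)
                if "subject_id" in df.columns else None)
    clip_paths = [path.parent / p for p in df["clip_path"]]
    return Dataset(manifest_path=path, clip_paths=clip_paths,
                   labels=labels, subjects=subjects)


def prepare_inputs(dataset: Dataset, target_rate: int = 44100,
                   cache_path: str | Path | None = None) -> np.ndarray:
    """(N, 128, 256) standardized spectrogram images for every clip.

    When ``cache_path`` is given, a valid cache is reused and a missing
    one is written after computation.
    """
    if cache_path is not None:
        cache_path = Path(cache_path)
        if cache_path.exists():
            with np.load(cache_path) as data:
                images = data["images"]
            if images.shape == (len(dataset), *NET_INPUT_SHAPE):
                return images
    images = np.empty((len(dataset), *NET_INPUT_SHAPE), dtype=np.float32)
    for i, p in enumerate(dataset.clip_paths):
        clip = load_audio(p, target_rate=target_rate)
        images[i] = clip_to_net_input(clip, provenance=str(p)).pixels
    if cache_path is not None:
        np.savez_compressed(cache_path, images=images)
    return images


def images_from_clips(clips, target_rate: int | None = None) -> np.ndarray:
    """Network inputs straight from in-memory clips (no file round-trip)."""
    images = np.empty((len(clips), *NET_INPUT_SHAPE), dtype=np.float32)
    for i, c in enumerate(clips):
        audio = c.clip if hasattr(c, "clip") else c
        images[i] = clip_to_net_input(audio).pixels
    return images
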