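"""The three study harnesses: detector training, ablation, heat-band study.

These functions bind the model, training loop, metrics and Grad-CAM
into the experiment shapes the command line exposes: a subject-disjoint
hold-out training run, a four-variant ablation table (one row per
variant, seven metrics with confidence-interval columns), and the
band-localization statistics of the class activation maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.model_selection import StratifiedGroupKFold, StratifiedShuffleSplit

from .augment import AugmentationPolicy, augment
from .gradcam import band_energy_share, grad_cam
from .metrics import METRIC_NAMES, MetricRecord, compute_metrics
from .model import VARIANTS, NetConfig, SkipAttentionNet, build_model
from .spectrogram import NetInputImage
from .training import TrainConfig, TrainResult, train_model


def make_augment_fn(policy: AugmentationPolicy):
    """Batch-wise augmentation hook for ``train_model`` (None if disabled)."""
    if not policy.enabled:
        return None

    def augment_batch(batch: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = np.empty_like(batch)
        squeeze = batch.ndim == 4
        for i in range(batch.shape[0]):
            img = NetInputImage(pixels=batch[i, ..., 0] if squeeze else batch[i])
            aug = augment(img, policy, rng=rng).pixels
            out[i] = aug[..., None] if squeeze else aug
        return out

    return augment_batch


def holdout_split(labels: np.ndarray, groups: np.ndarray | None,
                  test_fraction: float = 0.25, seed: int = 0
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Subject-disjoint (or stratified, if no subjects) train/test split."""
    labels = np.asarray(labels)
    if groups is not None:
        # stratified AND group-disjoint: take one fold of a k-fold carve-up
        groups = np.asarray(groups)
        n_groups = np.unique(groups).size
        if n_groups < 2:
            raise ValueError("subject-level split needs at least 2 subjects")
        n_splits = min(max(2, round(1.0 / test_fraction)), n_groups)
        splitter = StratifiedGroupKFold(n_splits=n_splits, shuffle=True,
                                        random_state=seed)
        tr, te = next(splitter.split(labels[:, None], labels, np.asarray(groups)))
    else:
        splitter = StratifiedShuffleSplit(n_splits=1, test_size=test_fraction,
                                          random_state=seed)
        tr, te = next(splitter.split(labels[:, None], labels))
    return tr, te


def fit_detector(images: np.ndarray, labels: np.ndarray, net_config: NetConfig,
                 tc: TrainConfig, policy: AugmentationPolicy | None = None
                 ) -> TrainResult:
    model = build_model(net_config)
    augment_fn = make_augment_fn(policy) if policy is not None else None
    return train_model(model, images, labels, tc, augment_fn=augment_fn)


def evaluate_detector(model: SkipAttentionNet, images: np.ndarray,
                      labels: np.ndarray) -> MetricRecord:
    scores = model.predict_proba(images)[:, 1]
    return compute_metrics(scores, labels)


@dataclass
class HoldoutRun:
    model: SkipAttentionNet
    train_result: TrainResult
    metrics: MetricRecord
    train_idx: np.ndarray
    test_idx: np.ndarray


def train_holdout(images: np.ndarray, labels: np.ndarray,
                  groups: np.ndarray | None, net_config: NetConfig,
                  tc: TrainConfig, test_fraction: float = 0.25,
                  policy: AugmentationPolicy | None = None) -> HoldoutRun:
    """Train on a subject-disjoint split; report held-out metrics."""
    tr, te = holdout_split(labels, groups, test_fraction, seed=tc.seed)
    result = fit_detector(images[tr], labels[tr], net_config, tc, policy)
    rec = evaluate_detector(result.model, images[te], labels[te])
    return HoldoutRun(model=result.model, train_result=result, metrics=rec,
                      train_idx=tr, test_idx=te)


def run_ablation(images: np.ndarray, labels: np.ndarray,
                 groups: np.ndarray | None, base_config: NetConfig,
                 tc: TrainConfig, variants: tuple[str, ...] = VARIANTS,
                 test_fraction: float = 0.25, n_iterations: int = 1,
                 policy: AugmentationPolicy | None = None) -> pd.DataFrame:
    """One row per model variant: seven metric means with CI columns.

    Every variant trains under the identical protocol and splits; with
    ``n_iterations`` > 1 the split is re-drawn and the confidence
    interval is over iterations (degenerate at n = 1).
    """
    rows = []
    for variant in variants:
        per_iter = {m: [] for m in METRIC_NAMES}
        for it in range(n_iterations):
            cfg = NetConfig(**{**base_config.to_dict(),
                               "variant": variant, "seed": base_config.seed + it})
            tc_it = TrainConfig(**{**tc.to_dict(), "seed": tc.seed + it})
            tr, te = holdout_split(labels, groups, test_fraction, seed=tc_it.seed)
            result = fit_detector(images[tr], labels[tr], cfg, tc_it, policy)
            rec = evaluate_detector(result.model, images[te], labels[te])
            for m in METRIC_NAMES:
                per_iter[m].append(getattr(rec, m))
        row = {"variant": variant}
        for m in METRIC_NAMES:
            vals = np.asarray(per_iter[m], dtype=float)
            mean = float(np.nanmean(vals))
            half = (0.0 if len(vals) < 2 else
                    float(1.96 * np.nanstd(vals, ddof=1) / np.sqrt(len(vals))))
            row[m] = mean
            row[f"{m}_ci_lo"] = mean - half
            row[f"{m}_ci_hi"] = mean + half
        rows.append(row)
    return pd.DataFrame(rows)


def band_share_study(model: SkipAttentionNet, images: np.ndarray,
                     labels: np.ndarray, cutoff_hz: float = 5000.0,
                     sample_rate: int = 44100, n_fft: int = 2048
                     ) -> tuple[pd.DataFrame, float]:
    """Per-clip above-cutoff heat share and the one-sided rank-test p.

    Tests whether control-class shares are stochastically greater than
    patient-class shares (the planted wide-band contrast).
    """
    shares = []
    for i in range(images.shape[0]):
        hm = grad_cam(model, images[i])
        shares.append(band_energy_share(hm, cutoff_hz, sample_rate, n_fft))
    df = pd.DataFrame({"clip_index": np.arange(images.shape[0]),
                       "label": np.asarray(labels, dtype=int),
                       "band_share_above_cutoff": shares})
    control = df.loc[df.label == 0, "band_share_above_cutoff"]
    patient = df.loc[df.label == 1, "band_share_above_cutoff"]
    if len(control) == 0 or len(patient) == 0:
        raise ValueError("band share study needs clips of both classes")
    p_value = float(mannwhitneyu(control, patient, alternative="greater").pvalue)
    return df, p_value
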