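"""First-layer weight interpretation.

Each first-layer filter of the connectome-convolutional network assigns
one weight per ROI (per channel): the weight multiplying that ROI's
entry in every connectivity fingerprint. Summing absolute weights over
the 64 filters gives a per-ROI importance score — ROIs whose
connectivity discriminates the classes attract large absolute weights —
and summing over ROIs instead scores each filter's overall influence.
On simulated data the top-ranked ROIs can be compared against the
ground-truth modified ROIs.

Deeper layers re-weight filter outputs, so a small first-layer sum does
not prove an ROI is irrelevant; this summary is a first-layer view
only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import TrainedModel

__all__ = ["ImportanceProfile", "roi_importance", "recovery_score",
           "train_interpretation_model"]


@dataclass
class ImportanceProfile:
    """Summed absolute first-layer weights, per channel.

    ``per_roi`` has shape (channels, N): entry [c, j] sums |weight| of
    ROI j over all filters. ``per_filter`` has shape (channels, f1):
    entry [c, f] sums |weight| of filter f over all ROIs. Both
    marginals of the same |W| tensor, so their totals agree per
    channel. ``roi_ranking`` lists ROI indices per channel in
    descending importance.
    """

    per_roi: np.ndarray
    per_filter: np.ndarray
    roi_ranking: np.ndarray
    channel_names: list


def train_interpretation_model(dataset, seed: int = 0, epochs: int = 600,
                               **config_overrides) -> TrainedModel:
    """Train a CCNN on the whole dataset for weight interpretation.

    Interpretation runs use no held-out fold — all instances feed the
    model, so the learned weights reflect every measurement — and train
    far past classification convergence (no early stopping): the
    summed-|weight| statistic only dominates the random initialization
    once the optimizer has pushed the informative fingerprint weights
    for long enough, even though the classification loss plateaus much
    earlier.
    """
    import numpy as np

    from . import models as _models

    cfg = _models.ModelConfig(
        kind="ccnn", n_rois=dataset.n_rois, n_channels=dataset.n_channels,
        seed=seed, epochs=epochs, early_stop_patience=epochs + 1,
        **config_overrides,
    )
    model = _models.build(cfg)
    return _models.train(model, dataset, np.arange(dataset.n_instances))


def roi_importance(model: TrainedModel) -> ImportanceProfile:
    """Summarize conv-layer-1 weights into ROI/filter importances."""
    if model.config.kind != "ccnn":
        raise ValueError(f"weight interpretation requires a ccnn model, got {model.config.kind!r}")
    if not model.trained:
        raise ValueError("model is not trained")
    w1 = np.abs(model.weights["conv1"])          # (f1, C, N)
    per_roi = w1.sum(axis=0).copy()              # (C, N)
    per_filter = w1.sum(axis=2).T.copy()         # (C, f1)
    ranking = np.argsort(-per_roi, axis=1, kind="stable")
    return ImportanceProfile(
        per_roi=per_roi,
        per_filter=per_filter,
        roi_ranking=ranking,
        channel_names=[f"channel{c}" for c in range(per_roi.shape[0])],
    )


def recovery_score(
    profile: ImportanceProfile,
    true_roi_ids,
    top_k: int,
    channel: int | None = None,
) -> int:
    """How many truly modified ROIs rank in the importance top-k.

    With ``channel=None`` importances are pooled by summing over
    channels before ranking; otherwise a single channel's ranking is
    used.
    """
    n = profile.per_roi.shape[1]
    if not 1 <= top_k <= n:
        raise ValueError(f"top_k must be in [1, {n}]")
    if channel is None:
        pooled = profile.per_roi.sum(axis=0)
        ranking = np.argsort(-pooled, kind="stable")
    else:
        ranking = profile.roi_ranking[channel]
    top = set(int(i) for i in ranking[:top_k])
    return len(top & set(int(i) for i in true_roi_ids))
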