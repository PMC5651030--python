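"""Core in-memory container for labelled multi-channel connectome datasets.

A connectome dataset holds, for every measurement instance, one or more
N x N connectivity matrices (one per metric "channel"), a binary class
label, and a group identifier used for subject-grouped cross-validation
(for simulated data each instance is its own group).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: maximum allowed |M - M.T| for a stored connectivity matrix
SYMMETRY_TOL = 1e-9


@dataclass
class ConnectomeDataset:
    """Labelled multi-channel connectivity matrices.

    Parameters
    ----------
    data
        Array of shape ``(n_instances, n_channels, n_rois, n_rois)``.
        Every ``n_rois x n_rois`` slice must be symmetric within
        :data:`SYMMETRY_TOL`.
    labels
        Integer class label per instance (binary: 0/1).
    group_ids
        One identifier per instance. Instances sharing a group id are
        never split across cross-validation folds (e.g. repeated
        measurements of one subject). For simulated data the instance
        index is used, which reduces grouped CV to plain k-fold.
    channel_names
        Name of the connectivity metric behind each channel.
    roi_names
        Optional ROI labels, length ``n_rois``.
    metadata
        Free-form provenance: generator parameters, seed, and — for
        simulated data — the ground-truth ``modified_roi_ids``.
    """

    data: np.ndarray
    labels: np.ndarray
    group_ids: list
    channel_names: list
    roi_names: list | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.group_ids = list(self.group_ids)
        self.channel_names = list(self.channel_names)
        self.validate()

    # -- basic geometry ------------------------------------------------
    @property
    def n_instances(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_rois(self) -> int:
        return self.data.shape[2]

    @property
    def n_classes(self) -> int:
        return len(np.unique(self.labels))

    def validate(self) -> None:
        """Check shapes, label/group alignment and matrix symmetry."""
        if self.data.ndim != 4:
            raise ValueError(
                f"data must be 4-d (instances, channels, N, N); got shape {self.data.shape}"
            )
        n_inst, n_chan, n_rois, n_cols = self.data.shape
        if n_rois != n_cols:
            raise ValueError(f"connectivity matrices must be square; got {n_rois}x{n_cols}")
        if len(self.labels) != n_inst:
            raise ValueError(
                f"{len(self.labels)} labels for {n_inst} instances"
            )
        if len(self.group_ids) != n_inst:
            raise ValueError(
                f"{len(self.group_ids)} group ids for {n_inst} instances"
            )
        if len(self.channel_names) != n_chan:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {n_chan} channels"
            )
        if self.roi_names is not None and len(self.roi_names) != n_rois:
            raise ValueError(
                f"{len(self.roi_names)} roi names for {n_rois} ROIs"
            )
        asym = np.abs(self.data - np.swapaxes(self.data, -1, -2)).max(initial=0.0)
        if asym > SYMMETRY_TOL:
            raise ValueError(
                f"asymmetric connectivity matrix: max |M - M^T| = {asym:.3g} "
                f"exceeds tolerance {SYMMETRY_TOL}"
            )

    def subset(self, indices) -> "ConnectomeDataset":
        """Return a new dataset restricted to the given instances."""
        indices = np.asarray(indices, dtype=int)
        return ConnectomeDataset(
            data=self.data[indices],
            labels=self.labels[indices],
            group_ids=[self.group_ids[i] for i in indices],
            channel_names=self.channel_names,
            roi_names=self.roi_names,
            metadata=dict(self.metadata),
        )
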