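"""Dataset and matrix readers/writers.

A connectome dataset on disk is one directory with a ``manifest.json``
(the single source of truth for instance count, channel order, labels,
group ids, ROI count and provenance) plus the matrices themselves,
either as delimited text files ``inst{i}_chan{c}.tsv`` or as one packed
``data.npy`` array ordered (instance, channel, row, column).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .datasets import ConnectomeDataset

__all__ = ["SchemaError", "read_dataset", "write_dataset", "merge_channels",
           "read_time_series", "write_matrix", "save_model", "load_model"]

MANIFEST_NAME = "manifest.json"


class SchemaError(ValueError):
    """A dataset directory violates the manifest schema."""


def write_dataset(dataset: ConnectomeDataset, path, fmt: str = "tsv") -> Path:
    """Write a dataset directory; ``fmt`` is 'tsv' (text) or 'npy' (packed)."""
    if fmt not in ("tsv", "npy"):
        raise ValueError("fmt must be 'tsv' or 'npy'")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "n_instances": dataset.n_instances,
        "n_channels": dataset.n_channels,
        "n_rois": dataset.n_rois,
        "channel_names": dataset.channel_names,
        "labels": dataset.labels.tolist(),
        "group_ids": list(dataset.group_ids),
        "roi_names": dataset.roi_names,
        "storage": fmt,
        "metadata": _jsonable(dataset.metadata),
    }
    (path / MANIFEST_NAME).write_text(json.dumps(manifest, indent=1))
    if fmt == "npy":
        np.save(path / "data.npy", dataset.data)
    else:
        for i in range(dataset.n_instances):
            for c in range(dataset.n_channels):
                np.savetxt(path / f"inst{i}_chan{c}.tsv", dataset.data[i, c],
                           delimiter="\t")
    return path


def read_dataset(path) -> ConnectomeDataset:
    """Read a dataset directory written by :func:`write_dataset`.

    Channels are ordered by the manifest's ``channel_names``, never by
    directory listing order. Raises :class:`SchemaError` naming the
    offending file on any inconsistency.
    """
    path = Path(path)
    manifest_path = path / MANIFEST_NAME
    if not manifest_path.exists():
        raise SchemaError(f"missing {manifest_path}")
    try:
        manifest = json.loads(manifest_path.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"unparseable {manifest_path}: {exc}") from exc
    for key in ("n_instances", "n_channels", "n_rois", "channel_names",
                "labels", "group_ids", "storage"):
        if key not in manifest:
            raise SchemaError(f"{manifest_path} missing key {key!r}")
    n_i, n_c, n_r = manifest["n_instances"], manifest["n_channels"], manifest["n_rois"]
    if len(manifest["labels"]) != n_i:
        raise SchemaError(f"{manifest_path}: {len(manifest['labels'])} labels "
                          f"for {n_i} instances")
    if len(manifest["group_ids"]) != n_i:
        raise SchemaError(f"{manifest_path}: group_ids count mismatch")
    if len(manifest["channel_names"]) != n_c:
        raise SchemaError(f"{manifest_path}: channel_names count mismatch")

    if manifest["storage"] == "npy":
        data_path = path / "data.npy"
        if not data_path.exists():
            raise SchemaError(f"missing {data_path}")
        data = np.load(data_path)
        if data.shape != (n_i, n_c, n_r, n_r):
            raise SchemaError(f"{data_path}: shape {data.shape} does not match manifest")
    else:
        data = np.empty((n_i, n_c, n_r, n_r))
        for i in range(n_i):
            for c in range(n_c):
                f = path / f"inst{i}_chan{c}.tsv"
                if not f.exists():
                    raise SchemaError(f"missing matrix file {f}")
                m = np.loadtxt(f, delimiter="\t")
                if m.shape != (n_r, n_r):
                    raise SchemaError(f"{f}: shape {m.shape}, expected ({n_r}, {n_r})")
                data[i, c] = m
    try:
        return ConnectomeDataset(
            data=data,
            labels=np.asarray(manifest["labels"], dtype=int),
            group_ids=manifest["group_ids"],
            channel_names=manifest["channel_names"],
            roi_names=manifest.get("roi_names"),
            metadata=manifest.get("metadata", {}),
        )
    except ValueError as exc:
        raise SchemaError(f"invalid dataset at {path}: {exc}") from exc


def merge_channels(*datasets: ConnectomeDataset) -> ConnectomeDataset:
    """Stack datasets of the same instances as extra metric channels.

    Instance counts, labels, group ids and ROI counts must match
    exactly; channel names concatenate in argument order.
    """
    if not datasets:
        raise ValueError("merge_channels needs at least one dataset")
    first = datasets[0]
    for d in datasets[1:]:
        if d.n_instances != first.n_instances:
            raise ValueError("instance count mismatch between datasets")
        if d.n_rois != first.n_rois:
            raise ValueError("ROI count mismatch between datasets")
        if not np.array_equal(d.labels, first.labels):
            raise ValueError("label mismatch between datasets")
        if list(d.group_ids) != list(first.group_ids):
            raise ValueError("group_id mismatch between datasets")
    if len(datasets) == 1:
        return first
    data = np.concatenate([d.data for d in datasets], axis=1)
    names = [name for d in datasets for name in d.channel_names]
    meta = dict(first.metadata)
    meta["merged_from"] = [d.channel_names for d in datasets]
    return ConnectomeDataset(
        data=data, labels=first.labels, group_ids=first.group_ids,
        channel_names=names, roi_names=first.roi_names, metadata=meta,
    )


def read_time_series(path, delimiter: str = "\t"):
    """Read a T x N delimited time-series table (optional header row).

    Returns ``(signals, roi_names)``; ``roi_names`` is None without a
    header. A header is detected by a non-numeric first row.
    """
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
    tokens = first.strip().split(delimiter)
    try:
        [float(t) for t in tokens]
        header = False
    except ValueError:
        header = True
    signals = np.loadtxt(path, delimiter=delimiter, skiprows=1 if header else 0)
    if signals.ndim == 1:
        signals = signals[:, None]
    return signals, (tokens if header else None)


def write_matrix(matrix: np.ndarray, path, delimiter: str = "\t") -> None:
    np.savetxt(path, np.asarray(matrix), delimiter=delimiter)


def save_model(model, path) -> Path:
    """Save a trained model: config.json plus per-layer weight arrays."""
    from dataclasses import asdict

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    payload = {
        "config": asdict(model.config),
        "weight_names": sorted(model.weights),
        "bias_names": sorted(model.biases),
        "trained": model.trained,
        "training_log": model.training_log,
        "channel_mean": _jsonable(model.channel_mean),
        "channel_std": _jsonable(model.channel_std),
    }
    (path / "config.json").write_text(json.dumps(payload, indent=1))
    arrays = {f"w_{k}": v for k, v in model.weights.items()}
    arrays.update({f"b_{k}": v for k, v in model.biases.items()})
    np.savez(path / "layers.npz", **arrays)
    return path


def load_model(path):
    """Load a model saved by :func:`save_model`."""
    from .models import ModelConfig, TrainedModel

    path = Path(path)
    payload = json.loads((path / "config.json").read_text())
    config = ModelConfig(**payload["config"])
    with np.load(path / "layers.npz") as arrays:
        weights = {k: arrays[f"w_{k}"].copy() for k in payload["weight_names"]}
        biases = {k: arrays[f"b_{k}"].copy() for k in payload["bias_names"]}
    mean = payload.get("channel_mean")
    std = payload.get("channel_std")
    return TrainedModel(
        config=config, weights=weights, biases=biases,
        channel_mean=None if mean is None else np.asarray(mean),
        channel_std=None if std is None else np.asarray(std),
        training_log=payload.get("training_log", []),
        trained=payload.get("trained", False),
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
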