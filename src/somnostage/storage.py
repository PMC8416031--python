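"""HDF5 persistence for feature nights and trained models."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .crf import CrfParams
from .estimator import SleepStageClassifier
from .features import FeatureMatrix, NormalizationParams
from .pipeline import NightFeatures

__all__ = [
    "save_night_features",
    "load_night_features",
    "save_model",
    "load_model",
]


def save_night_features(night: NightFeatures, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=night.features.values)
        f.create_dataset("stages", data=night.stages)
        f.create_dataset(
            "feature_names",
            data=np.array([n.encode() for n in night.features.feature_names]),
        )
        f.create_dataset(
            "channel_order",
            data=np.array([c.encode() for c in night.features.channel_order]),
        )
        f.attrs["subject_id"] = night.subject_id
        f.attrs["night_id"] = night.night_id


def load_night_features(path) -> NightFeatures:
    with h5py.File(path, "r") as f:
        fm = FeatureMatrix(
            values=f["values"][()],
            feature_names=[n.decode() for n in f["feature_names"][()]],
            channel_order=[c.decode() for c in f["channel_order"][()]],
        )
        return NightFeatures(
            subject_id=str(f.attrs["subject_id"]),
            night_id=str(f.attrs["night_id"]),
            features=fm,
            stages=f["stages"][()],
        )


def save_model(clf: SleepStageClassifier, path, extra_meta: dict | None = None) -> None:
    """Checkpoint: float64 arrays plus a JSON manifest of shapes and config."""
    manifest = {
        "params": clf.get_params(),
        "n_features_in": int(clf.n_features_in_),
        "shapes": {k: list(v.shape) for k, v in clf.encoder_params_.items()},
        **(extra_meta or {}),
    }
    with h5py.File(path, "w") as f:
        enc = f.create_group("encoder")
        for k, v in clf.encoder_params_.items():
            enc.create_dataset(k, data=v)
        crf = f.create_group("crf")
        crf.create_dataset("transitions", data=clf.crf_.transitions)
        crf.create_dataset("start", data=clf.crf_.start)
        crf.create_dataset("end", data=clf.crf_.end)
        if clf.norm_ is not None:
            norm = f.create_group("norm")
            norm.create_dataset("mean", data=clf.norm_.mean)
            norm.create_dataset("std", data=clf.norm_.std)
            norm.attrs["epsilon"] = clf.norm_.epsilon
        f.attrs["manifest"] = json.dumps(manifest, default=str)


def load_model(path) -> SleepStageClassifier:
    with h5py.File(path, "r") as f:
        manifest = json.loads(f.attrs["manifest"])
        params = manifest["params"]
        if isinstance(params.get("class_weights"), list):
            params["class_weights"] = tuple(params["class_weights"])
        clf = SleepStageClassifier(**params)
        clf.encoder_params_ = {k: f["encoder"][k][()] for k in f["encoder"]}
        clf.crf_ = CrfParams(
            transitions=f["crf"]["transitions"][()],
            start=f["crf"]["start"][()],
            end=f["crf"]["end"][()],
        )
        clf.norm_ = None
        if "norm" in f:
            clf.norm_ = NormalizationParams(
                mean=f["norm"]["mean"][()],
                std=f["norm"]["std"][()],
                epsilon=float(f["norm"].attrs["epsilon"]),
            )
        clf.n_features_in_ = manifest["n_features_in"]
        clf.classes_ = np.arange(5)
    return clf
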