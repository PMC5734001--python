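"""Readers and writers: the csv_dir trial container, model documents, run configs.

The package's canonical on-disk format is a plain-text directory:

* ``trials.csv`` - long format with columns trial_id, channel, sample_index,
  value (RFC-4180, '.' decimal separator; values round-trip bit-exactly via
  shortest-repr decimal serialization);
* ``events.csv`` - trial_id, label;
* ``meta.json`` - sampling_rate, cue_time, channel order.

EDF/GDF recordings are read through mne (imported lazily) and epoched
around their cue events. Model documents are versioned JSON embedding the
basis vectors, eigenvalues, segmentation scheme, Gaussian parameters and
thresholds; numeric fields round-trip bit-exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .epochs import CLASS_LABELS, EpochSet, SegmentationScheme
from .features import ProjectiveBasis
from .model import SegmentGaussianModel
from .sprt import StoppingThresholds

logger = logging.getLogger("sprtbci")

MODEL_FORMAT_VERSION = 1
CSV_DIR_FORMAT_VERSION = 1


def write_epochs(epochs: EpochSet, path, force: bool = False) -> Path:
    """Write an EpochSet as a csv_dir container; refuses to overwrite without force."""
    path = Path(path)
    if path.exists() and any(path.iterdir()) and not force:
        raise FileExistsError(f"{path} exists and is not empty; pass force=True to overwrite")
    path.mkdir(parents=True, exist_ok=True)
    n_t, n_c, n_s = epochs.data.shape
    trial_id = np.repeat(np.arange(n_t), n_c * n_s)
    channel = np.tile(np.repeat(np.asarray(epochs.channel_names, dtype=object), n_s), n_t)
    sample_index = np.tile(np.arange(n_s), n_t * n_c)
    df = pd.DataFrame(
        {
            "trial_id": trial_id,
            "channel": channel,
            "sample_index": sample_index,
            "value": epochs.data.ravel(),
        }
    )
    df.to_csv(path / "trials.csv", index=False, lineterminator="\r\n", float_format="%.17g")
    if epochs.labels is not None:
        ev = pd.DataFrame({"trial_id": np.arange(n_t), "label": epochs.labels})
        ev.to_csv(path / "events.csv", index=False, lineterminator="\r\n")
    meta = {
        "format_version": CSV_DIR_FORMAT_VERSION,
        "sampling_rate": epochs.sampling_rate,
        "cue_time": epochs.cue_time,
        "channel_names": list(epochs.channel_names),
        "n_trials": n_t,
        "n_samples": n_s,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=2))
    return path


def _read_csv_dir(path: Path, channels=None) -> EpochSet:
    meta = json.loads((path / "meta.json").read_text())
    df = pd.read_csv(path / "trials.csv", float_precision="round_trip")
    required = {"trial_id", "channel", "sample_index", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"trials.csv must have columns {sorted(required)}")
    channel_names = channels or meta["channel_names"]
    trial_ids = np.sort(df["trial_id"].unique())
    counts = df.groupby("trial_id").size()
    if counts.nunique() != 1:
        bad = counts[counts != counts.mode()[0]].index.tolist()
        raise ValueError(f"trials of unequal length: trial_id {bad}")
    n_s = int(df["sample_index"].max()) + 1
    data = np.empty((len(trial_ids), len(channel_names), n_s))
    pivot = df.set_index(["trial_id", "channel", "sample_index"])["value"]
    kept, dropped = [], []
    for ti, tid in enumerate(trial_ids):
        block = np.empty((len(channel_names), n_s))
        for ci, ch in enumerate(channel_names):
            vals = pivot.loc[(tid, ch)].sort_index().to_numpy()
            if len(vals) != n_s:
                raise ValueError(f"trial {tid} channel {ch} has {len(vals)} samples, expected {n_s}")
            block[ci] = vals
        if not np.all(np.isfinite(block)):
            logger.warning("rejecting trial %s: non-finite samples", tid)
            dropped.append(tid)
            continue
        data[len(kept)] = block
        kept.append(tid)
    data = data[: len(kept)]
    labels = None
    events_path = path / "events.csv"
    if events_path.exists():
        ev = pd.read_csv(events_path).set_index("trial_id")["label"]
        lab = ev.reindex(kept)
        bad = lab[~lab.isin(CLASS_LABELS) & lab.notna()]
        if len(bad):
            raise ValueError(
                f"unknown labels {sorted(set(bad))} for trial_id {bad.index.tolist()}"
            )
        if lab.notna().all():
            labels = lab.to_numpy(dtype=object)
    return EpochSet(
        data=data,
        sampling_rate=meta["sampling_rate"],
        cue_time=meta["cue_time"],
        labels=labels,
        channel_names=tuple(channel_names),
    )


def _read_raw_biosignal(path: Path, fmt: str, channels, pre_cue: float, post_cue: float) -> EpochSet:
    import mne  # lazy: only needed for EDF/GDF ingestion

    reader = mne.io.read_raw_edf if fmt == "edf" else mne.io.read_raw_gdf
    raw = reader(str(path), preload=True, verbose="error")
    fs = raw.info["sfreq"]
    picks = list(channels) if channels else raw.ch_names
    sidecar = path.parent / "events.csv"
    if sidecar.exists():
        ev = pd.read_csv(sidecar)
        cue_samples = ev["cue_sample"].to_numpy(int)
        labels = ev["label"].to_numpy(dtype=object)
    else:
        ann = mne.events_from_annotations(raw, verbose="error")[0]
        if len(ann) == 0:
            raise ValueError(f"{path}: no events found and no events.csv sidecar")
        cue_samples = ann[:, 0]
        labels = None
    bad = None if labels is None else [l for l in labels if l not in CLASS_LABELS]
    if bad:
        raise ValueError(f"unknown labels {sorted(set(bad))} in events.csv")
    sig = raw.get_data(picks=picks)
    pre = int(round(pre_cue * fs))
    post = int(round(post_cue * fs))
    trials, kept_labels = [], []
    for i, cs in enumerate(cue_samples):
        lo, hi = cs - pre, cs + post
        if lo < 0 or hi > sig.shape[1]:
            logger.warning("rejecting trial %d: window outside recording", i)
            continue
        block = sig[:, lo:hi]
        if not np.all(np.isfinite(block)):
            logger.warning("rejecting trial %d: non-finite samples", i)
            continue
        trials.append(block)
        if labels is not None:
            kept_labels.append(labels[i])
    if not trials:
        raise ValueError(f"{path}: no usable trials")
    return EpochSet(
        data=np.stack(trials),
        sampling_rate=fs,
        cue_time=pre_cue,
        labels=np.asarray(kept_labels, dtype=object) if labels is not None else None,
        channel_names=tuple(picks),
    )


def read_epochs(
    path,
    fmt: str = "csv_dir",
    channels=None,
    pre_cue: float = 3.0,
    post_cue: float = 6.0,
) -> EpochSet:
    """Load an EpochSet from a csv_dir container or an EDF/GDF recording.

    For continuous EDF/GDF files, trials are epoched over
    ``[cue - pre_cue, cue + post_cue)`` using the annotation events or an
    ``events.csv`` sidecar (columns trial_id, cue_sample, label).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if fmt == "csv_dir":
        return _read_csv_dir(path, channels)
    if fmt in ("edf", "gdf"):
        return _read_raw_biosignal(path, fmt, channels, pre_cue, post_cue)
    raise ValueError(f"unknown format {fmt!r}; expected csv_dir, edf or gdf")


def save_model(
    path,
    bases: dict[str, ProjectiveBasis],
    scheme: SegmentationScheme,
    model: SegmentGaussianModel | None = None,
    thresholds: StoppingThresholds | None = None,
    provenance: dict | None = None,
) -> Path:
    """Persist bases / Gaussian model / thresholds as a versioned JSON document."""
    doc = {
        "format_version": MODEL_FORMAT_VERSION,
        "scheme": {"window_length": scheme.window_length, "step": scheme.step},
        "bases": {
            ch: {
                "u": b.u.tolist(),
                "lambda_max": b.lambda_max,
                "lambda_min": b.lambda_min,
                "branch": b.branch,
            }
            for ch, b in bases.items()
        },
        "provenance": provenance or {},
    }
    if model is not None:
        doc["gaussian_model"] = {
            "means": model.means.tolist(),
            "covs": model.covs.tolist(),
            "shrinkage": model.shrinkage,
            "transform": model.transform,
            "eps": model.eps,
            "n_train": list(model.n_train),
            "timestamps": None if model.timestamps is None else model.timestamps.tolist(),
        }
    if thresholds is not None:
        doc["thresholds"] = {
            "xi_L": thresholds.xi_L,
            "xi_R": thresholds.xi_R,
            "q_E": thresholds.q_E,
        }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(doc, indent=1))
    return path


def load_model(path):
    """Load a model document; returns (bases, scheme, model, thresholds, provenance)."""
    doc = json.loads(Path(path).read_text())
    if doc.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format_version {doc.get('format_version')}")
    scheme = SegmentationScheme(**doc["scheme"])
    bases = {
        ch: ProjectiveBasis(
            u=np.asarray(b["u"]),
            lambda_max=b["lambda_max"],
            lambda_min=b["lambda_min"],
            branch=b["branch"],
            channel=ch,
        )
        for ch, b in doc["bases"].items()
    }
    model = None
    if "gaussian_model" in doc:
        g = doc["gaussian_model"]
        model = SegmentGaussianModel(
            means=np.asarray(g["means"]),
            covs=np.asarray(g["covs"]),
            shrinkage=g["shrinkage"],
            transform=g["transform"],
            eps=g["eps"],
            n_train=tuple(g["n_train"]),
            timestamps=None if g["timestamps"] is None else np.asarray(g["timestamps"]),
        )
    thresholds = None
    if "thresholds" in doc:
        t = doc["thresholds"]
        thresholds = StoppingThresholds(xi_L=t["xi_L"], xi_R=t["xi_R"], q_E=t["q_E"])
    return bases, scheme, model, thresholds, doc.get("provenance", {})


@dataclasses.dataclass
class RunConfig:
    """All pipeline tunables; unknown keys in a config file are rejected."""

    window_length: float = 1.0
    step: float = 0.25
    channels: tuple[str, str] = ("C3", "C4")
    ridge: float | None = None
    train_window: str = "post_cue"
    shrinkage: float = 0.05
    transform: str = "raw"
    q_e: int | None = None
    criterion: str | None = None
    tie_policy: str = "random"
    accuracy_floor: float = 0.7
    folds: int = 10
    seed: int = 0

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = dict(mapping)
        if "channels" in cfg:
            cfg["channels"] = tuple(cfg["channels"])
        return cls(**cfg)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        mapping = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_mapping(mapping)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["channels"] = list(d["channels"])
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]
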