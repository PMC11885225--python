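"""In-memory containers for continuous and epoched M/EEG data.

A :class:`Recording` holds a channels x samples matrix together with channel
metadata, a set of channels marked bad, and a list of time-interval
annotations (e.g. ``bad_segment``).  Continuous data enter the pipeline as a
Recording and every preprocessing step returns a new (or updated) Recording.

Persistence uses a deliberately simple on-disk pair — ``<name>.json`` header
plus ``<name>.npy`` payload — whose bytes are a pure function of the content
(no embedded timestamps), so that identical runs produce identical files.
FIF files written by MNE-Python can be imported via :func:`read_recording`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

CHANNEL_TYPES = ("meg", "eeg", "ecg", "eog", "stim")


@dataclass
class Annotation:
    """Half-open time interval [onset, onset + duration) with a label."""

    onset: float
    duration: float
    label: str = "bad_segment"

    @property
    def end(self) -> float:
        return self.onset + self.duration

    def overlaps(self, start: float, stop: float) -> bool:
        return self.onset < stop and start < self.end


@dataclass
class Recording:
    """Continuous multichannel recording.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in channel-native units (T for MEG, V for EEG, a.u. otherwise).
    sfreq : float
        Sampling frequency in Hz, strictly positive.
    channel_labels : list of str
        Unique channel names.
    channel_types : list of str
        One of ``meg, eeg, ecg, eog, stim`` per channel.
    bad_channels : set of str
        Labels flagged as artifact-dominated; always a subset of
        ``channel_labels``.
    annotations : list of Annotation
        Bad-segment (or other) intervals in seconds.
    """

    data: np.ndarray
    sfreq: float
    channel_labels: list[str]
    channel_types: list[str]
    bad_channels: set[str] = field(default_factory=set)
    annotations: list[Annotation] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.sfreq <= 0:
            raise ValueError("sfreq must be positive")
        n_ch = self.data.shape[0]
        if len(self.channel_labels) != n_ch or len(self.channel_types) != n_ch:
            raise ValueError("channel metadata length mismatch")
        unknown = set(self.channel_types) - set(CHANNEL_TYPES)
        if unknown:
            raise ValueError(f"unknown channel types: {sorted(unknown)}")
        bad = set(self.bad_channels) - set(self.channel_labels)
        if bad:
            raise ValueError(f"bad_channels not in channel_labels: {sorted(bad)}")

    # -- basic geometry -------------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sfreq

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sfreq

    def copy(self) -> "Recording":
        return replace(
            self,
            data=self.data.copy(),
            channel_labels=list(self.channel_labels),
            channel_types=list(self.channel_types),
            bad_channels=set(self.bad_channels),
            annotations=[replace(a) for a in self.annotations],
        )

    # -- selection helpers ----------------------------------------------
    def picks(self, kind: str | None = None, good_only: bool = False) -> np.ndarray:
        """Indices of channels of a given type, optionally excluding bads."""
        idx = []
        for i, (lab, typ) in enumerate(zip(self.channel_labels, self.channel_types)):
            if kind is not None and typ != kind:
                continue
            if good_only and lab in self.bad_channels:
                continue
            idx.append(i)
        return np.asarray(idx, dtype=int)

    def good_sample_mask(self, labels: tuple[str, ...] = ("bad",)) -> np.ndarray:
        """Boolean mask of samples outside annotations whose label starts with
        any of the given prefixes."""
        mask = np.ones(self.n_samples, dtype=bool)
        for ann in self.annotations:
            if any(ann.label.startswith(p) for p in labels):
                i0 = max(0, int(np.ceil(ann.onset * self.sfreq)))
                i1 = min(self.n_samples, int(np.ceil(ann.end * self.sfreq)))
                mask[i0:i1] = False
        return mask

    def crop(self, tmin: float = 0.0, tmax: float | None = None) -> "Recording":
        """Return the sub-recording covering [tmin, tmax); annotations are
        shifted and clipped accordingly."""
        if tmax is None:
            tmax = self.duration
        if not 0 <= tmin < tmax <= self.duration + 1e-12:
            raise ValueError("invalid crop window")
        i0 = int(round(tmin * self.sfreq))
        i1 = min(int(round(tmax * self.sfreq)), self.n_samples)
        out = self.copy()
        out.data = self.data[:, i0:i1].copy()
        new_anns = []
        for ann in self.annotations:
            onset = max(ann.onset, tmin) - tmin
            end = min(ann.end, tmax) - tmin
            if end > onset:
                new_anns.append(Annotation(onset, end - onset, ann.label))
        out.annotations = new_anns
        return out

    # -- persistence -----------------------------------------------------
    def save(self, stem: str | Path) -> None:
        """Write ``<stem>.json`` + ``<stem>.npy`` (deterministic bytes)."""
        stem = Path(stem)
        stem.parent.mkdir(parents=True, exist_ok=True)
        header = {
            "kind": "recording",
            "sfreq": self.sfreq,
            "channel_labels": self.channel_labels,
            "channel_types": self.channel_types,
            "bad_channels": sorted(self.bad_channels),
            "annotations": [
                {"onset": a.onset, "duration": a.duration, "label": a.label}
                for a in self.annotations
            ],
        }
        stem.with_suffix(".json").write_text(
            json.dumps(header, sort_keys=True, indent=1) + "\n"
        )
        np.save(stem.with_suffix(".npy"), self.data)

    @classmethod
    def load(cls, stem: str | Path) -> "Recording":
        stem = Path(stem)
        header = json.loads(stem.with_suffix(".json").read_text())
        data = np.load(stem.with_suffix(".npy"))
        return cls(
            data=data,
            sfreq=header["sfreq"],
            channel_labels=header["channel_labels"],
            channel_types=header["channel_types"],
            bad_channels=set(header["bad_channels"]),
            annotations=[Annotation(**a) for a in header["annotations"]],
        )

    # -- MNE interop ------------------------------------------------------
    def to_mne(self):
        import mne

        info = mne.create_info(
            self.channel_labels,
            self.sfreq,
            ch_types=["mag" if t == "meg" else t for t in self.channel_types],
        )
        raw = mne.io.RawArray(self.data, info, verbose="error")
        raw.info["bads"] = sorted(self.bad_channels)
        if self.annotations:
            raw.set_annotations(
                mne.Annotations(
                    onset=[a.onset for a in self.annotations],
                    duration=[a.duration for a in self.annotations],
                    description=[a.label for a in self.annotations],
                )
            )
        return raw

    @classmethod
    def from_mne(cls, raw) -> "Recording":
        types = raw.get_channel_types()
        mapped = ["meg" if t in ("mag", "grad") else t for t in types]
        mapped = [t if t in CHANNEL_TYPES else "stim" for t in mapped]
        anns = [
            Annotation(float(on), float(du), str(de))
            for on, du, de in zip(
                raw.annotations.onset, raw.annotations.duration,
                raw.annotations.description,
            )
        ]
        return cls(
            data=raw.get_data(),
            sfreq=float(raw.info["sfreq"]),
            channel_labels=list(raw.ch_names),
            channel_types=mapped,
            bad_channels=set(raw.info["bads"]),
            annotations=anns,
        )


def read_recording(path: str | Path) -> "Recording":
    """Read a recording from disk: ``.fif`` via MNE, otherwise the native
    json/npy pair (pass either the ``.json`` path or the bare stem)."""
    path = Path(path)
    if path.suffix == ".fif":
        import mne

        raw = mne.io.read_raw_fif(path, preload=True, verbose="error")
        return Recording.from_mne(raw)
    stem = path.with_suffix("") if path.suffix in (".json", ".npy") else path
    return Recording.load(stem)


@dataclass
class EventTable:
    """Event onsets as (sample index, integer code, name) rows.

    Sample indices are strictly increasing; names are typically drawn from
    the pipeline config's ``meta`` event-code map.
    """

    sample: np.ndarray
    code: np.ndarray
    name: list[str]

    def __post_init__(self):
        self.sample = np.asarray(self.sample, dtype=int)
        self.code = np.asarray(self.code, dtype=int)
        if not (len(self.sample) == len(self.code) == len(self.name)):
            raise ValueError("event columns must have equal length")
        if len(self.sample) > 1 and not np.all(np.diff(self.sample) > 0):
            raise ValueError("event sample indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.sample)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        lines = ["sample\tcode\tname"]
        lines += [
            f"{s}\t{c}\t{n}" for s, c, n in zip(self.sample, self.code, self.name)
        ]
        path.write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "EventTable":
        rows = Path(path).read_text().strip().splitlines()[1:]
        sample, code, name = [], [], []
        for row in rows:
            s, c, n = row.split("\t")
            sample.append(int(s))
            code.append(int(c))
            name.append(n)
        return cls(np.array(sample, dtype=int), np.array(code, dtype=int), name)


@dataclass
class Epochs:
    """Event-locked trials: data has shape (n_trials, n_channels, n_samples)
    with sample k at time tmin + k / sfreq relative to the event."""

    data: np.ndarray
    tmin: float
    tmax: float
    sfreq: float
    trial_names: list[str]
    channel_labels: list[str] = field(default_factory=list)
    n_dropped: int = 0
    drop_reasons: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("epochs data must be 3-D (trials x channels x samples)")
        expected = int(round((self.tmax - self.tmin) * self.sfreq))
        if self.data.shape[2] != expected:
            raise ValueError(
                f"window length {self.data.shape[2]} != round((tmax-tmin)*sfreq)={expected}"
            )
        if len(self.trial_names) != self.data.shape[0]:
            raise ValueError("trial_names length mismatch")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.data.shape[2]) / self.sfreq

    def save(self, stem: str | Path) -> None:
        stem = Path(stem)
        stem.parent.mkdir(parents=True, exist_ok=True)
        header = {
            "kind": "epochs",
            "tmin": self.tmin,
            "tmax": self.tmax,
            "sfreq": self.sfreq,
            "trial_names": self.trial_names,
            "channel_labels": self.channel_labels,
            "n_dropped": self.n_dropped,
            "drop_reasons": self.drop_reasons,
        }
        stem.with_suffix(".json").write_text(
            json.dumps(header, sort_keys=True, indent=1) + "\n"
        )
        np.save(stem.with_suffix(".npy"), self.data)

    @classmethod
    def load(cls, stem: str | Path) -> "Epochs":
        stem = Path(stem)
        header = json.loads(stem.with_suffix(".json").read_text())
        header.pop("kind")
        return cls(data=np.load(stem.with_suffix(".npy")), **header)


@dataclass
class ICADecomposition:
    """Result of an ICA unmixing plus per-component artifact labels.

    ``mixing @ sources`` reconstructs the modelled (zero-mean) subspace of
    the input.  ``labels[k]`` is one of ``none, ecg, eog, other-artifact``;
    ``rejected`` indexes components scheduled for subtraction.  When the
    estimator's ``unmixing`` (components x channels) and channel ``mean``
    are available, rejection recomputes sources from the data at hand,
    which makes repeated application idempotent.
    """

    mixing: np.ndarray
    sources: np.ndarray
    labels: list[str] = field(default_factory=list)
    rejected: set[int] = field(default_factory=set)
    unmixing: np.ndarray | None = None
    mean: np.ndarray | None = None

    def __post_init__(self):
        self.mixing = np.asarray(self.mixing, dtype=np.float64)
        self.sources = np.asarray(self.sources, dtype=np.float64)
        if self.mixing.shape[1] != self.sources.shape[0]:
            raise ValueError("mixing/sources component dimension mismatch")
        if not self.labels:
            self.labels = ["none"] * self.mixing.shape[1]
        if len(self.labels) != self.mixing.shape[1]:
            raise ValueError("labels length mismatch")
        if any(k < 0 or k >= self.mixing.shape[1] for k in self.rejected):
            raise ValueError("rejected index out of range")
        if self.unmixing is not None:
            self.unmixing = np.asarray(self.unmixing, dtype=np.float64)
            if self.unmixing.shape != self.mixing.shape[::-1]:
                raise ValueError("unmixing must be components x channels")
        if self.mean is not None:
            self.mean = np.asarray(self.mean, dtype=np.float64)

    @property
    def n_components(self) -> int:
        return self.mixing.shape[1]

    def label_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for lab in self.labels:
            out[lab] = out.get(lab, 0) + 1
        return out

    def save(self, stem: str | Path) -> None:
        stem = Path(stem)
        stem.parent.mkdir(parents=True, exist_ok=True)
        header = {
            "kind": "ica",
            "labels": self.labels,
            "rejected": sorted(self.rejected),
        }
        stem.with_suffix(".json").write_text(
            json.dumps(header, sort_keys=True, indent=1) + "\n"
        )
        arrays = {"mixing": self.mixing, "sources": self.sources}
        if self.unmixing is not None:
            arrays["unmixing"] = self.unmixing
        if self.mean is not None:
            arrays["mean"] = self.mean
        np.savez(stem.with_suffix(".npz"), **arrays)

    @classmethod
    def load(cls, stem: str | Path) -> "ICADecomposition":
        stem = Path(stem)
        header = json.loads(stem.with_suffix(".json").read_text())
        blob = np.load(stem.with_suffix(".npz"))
        return cls(
            mixing=blob["mixing"],
            sources=blob["sources"],
            labels=header["labels"],
            rejected=set(header["rejected"]),
            unmixing=blob["unmixing"] if "unmixing" in blob else None,
            mean=blob["mean"] if "mean" in blob else None,
        )
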