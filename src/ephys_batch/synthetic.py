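"""Synthetic multi-subject M/EEG fixtures with known ground truth.

Every stage of the pipeline is testable without downloading data: the
generators emulate the structure of a multi-subject, multi-session visual
MEG study (several subjects, several runs each, three stimulus conditions)
at desk scale.  Recordings are band-limited random brain sources mixed to
sensors, plus sensor noise, a quasi-periodic cardiac-like component, sparse
blink-like transients, and optionally planted bad channels and bad
segments.  All generators are pure functions of their spec (seeded
determinism).

What is emulated: per-channel amplitude statistics good enough for GESD
screening; artifact components with unambiguous ECG/EOG correlates;
event-locked condition effects in known parcels and windows; shared parcel
covariance across subjects with planted polarity flips.  What is *not*
emulated: realistic head geometry in the mixing (random mixing by default),
1/f spectra, inter-subject anatomical variability — so passing tests
demonstrate algorithmic correctness, not real-data performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sp_signal

from .containers import Annotation, Epochs, EventTable, Recording
from .parcellation import ParcelTimeCourses

__all__ = [
    "SimulationSpec",
    "simulate_recording",
    "simulate_evoked_effect",
    "simulate_multisubject_parcels",
    "simulate_dipole_recording",
]

CONDITIONS = ("famous", "unfamiliar", "scrambled")


@dataclass
class SimulationSpec:
    """Study-scale parameters for the synthetic generators.

    Defaults describe the desk-scale study used throughout the test-suite:
    5 subjects x 2 sessions, 32 sensors, 10 parcels, 100 s at 250 Hz,
    sensor SNR 5, ~60 bpm cardiac artifact and ~15 blinks/min.
    """

    n_subjects: int = 5
    n_sessions: int = 2
    n_sensors: int = 32
    n_parcels: int = 10
    n_grid_sources: int = 20
    sfreq: float = 250.0
    duration: float = 100.0
    snr: float = 5.0
    ecg_rate_bpm: float = 60.0
    blink_rate_per_min: float = 15.0
    bad_channel_gain: float = 20.0
    bad_segment_gain: float = 15.0
    bad_segment_duration: float = 5.0
    n_bad_channels: int = 0
    n_bad_segments: int = 0
    n_events: int = 60
    effect_size: float = 1.0
    effect_window: tuple[float, float] = (0.05, 0.3)
    seed: int = 0

    def __post_init__(self):
        for name in ("n_subjects", "n_sessions", "n_sensors", "n_parcels",
                     "n_grid_sources"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.seed is None:
            raise ValueError("seed is mandatory")


def _bandlimited_noise(rng, n_src, n_samp, sfreq, band=(1.0, 30.0)):
    # pad generously so filtfilt edge transients never reach the output
    pad = int(2 * sfreq)
    x = rng.standard_normal((n_src, n_samp + 2 * pad))
    sos = sp_signal.butter(4, band, btype="bandpass", fs=sfreq, output="sos")
    x = sp_signal.sosfiltfilt(sos, x, axis=1)[:, pad : pad + n_samp]
    return x / x.std(axis=1, keepdims=True)


def _ecg_trace(rng, n_samp, sfreq, rate_bpm):
    """Quasi-periodic sharp biphasic pulses with beat-to-beat jitter."""
    period = 60.0 / rate_bpm
    t = np.arange(n_samp) / sfreq
    trace = np.zeros(n_samp)
    width = 0.04
    beat = period * (0.5 + rng.random() * 0.2)
    while beat < t[-1]:
        tau = (t - beat) / width
        trace += np.exp(-(tau**2)) * tau * -2.0  # biphasic derivative shape
        beat += period * (1.0 + 0.05 * rng.standard_normal())
    if trace.std() > 0:
        trace /= trace.std()
    return trace


def _eog_trace(rng, n_samp, sfreq, rate_per_min):
    """Sparse ~300 ms half-sine blink transients."""
    trace = np.zeros(n_samp)
    n_blinks = max(1, int(round(rate_per_min * n_samp / sfreq / 60.0)))
    width = int(0.3 * sfreq)
    onsets = rng.choice(max(n_samp - width, 1), size=n_blinks, replace=False)
    pulse = np.sin(np.linspace(0, np.pi, width))
    for o in onsets:
        trace[o : o + width] += pulse[: n_samp - o]
    if trace.std() > 0:
        trace /= trace.std()
    return trace


def simulate_recording(
    spec: SimulationSpec, subject: int = 0, session: int = 0
) -> tuple[Recording, EventTable, dict]:
    """One synthetic continuous session with ground truth.

    Returns the Recording (MEG channels + one ECG + one EOG reference
    channel), the event table (three conditions at evenly spaced onsets),
    and a ground-truth dict with the planted bad channels, bad segments,
    artifact source time courses and their sensor mixing columns.
    """
    rng = np.random.default_rng(
        [spec.seed, subject, session]
    )
    n_samp = int(round(spec.duration * spec.sfreq))
    n_meg = spec.n_sensors
    min_spacing = int(0.25 * spec.sfreq)
    if spec.n_events > 0 and spec.n_events * min_spacing > n_samp - 2 * spec.sfreq:
        raise ValueError("duration too short for the requested event count")

    sources = _bandlimited_noise(rng, spec.n_grid_sources, n_samp, spec.sfreq)
    mixing = rng.standard_normal((n_meg, spec.n_grid_sources))
    mixing /= np.linalg.norm(mixing, axis=0, keepdims=True)
    brain = mixing @ sources
    brain /= brain.std()

    noise = rng.standard_normal((n_meg, n_samp))
    noise /= noise.std()
    data = spec.snr * brain + noise

    # rate 0 switches a physiological component off entirely
    ecg = (_ecg_trace(rng, n_samp, spec.sfreq, spec.ecg_rate_bpm)
           if spec.ecg_rate_bpm > 0 else np.zeros(n_samp))
    eog = (_eog_trace(rng, n_samp, spec.sfreq, spec.blink_rate_per_min)
           if spec.blink_rate_per_min > 0 else np.zeros(n_samp))
    ecg_mix = rng.standard_normal(n_meg)
    ecg_mix /= np.linalg.norm(ecg_mix)
    eog_mix = rng.standard_normal(n_meg)
    eog_mix /= np.linalg.norm(eog_mix)
    artifact_gain = 2.0 * spec.snr
    data += artifact_gain * np.outer(ecg_mix, ecg)
    data += artifact_gain * np.outer(eog_mix, eog)

    truth: dict = {
        "bad_channels": [],
        "bad_segments": [],
        "ecg_trace": ecg,
        "eog_trace": eog,
        "ecg_mixing": artifact_gain * ecg_mix,
        "eog_mixing": artifact_gain * eog_mix,
        "brain_mixing": mixing,
    }

    labels = [f"MEG{i:03d}" for i in range(n_meg)]
    bad_idx = rng.choice(n_meg, size=spec.n_bad_channels, replace=False)
    for i in bad_idx:
        data[i] *= spec.bad_channel_gain
        truth["bad_channels"].append(labels[i])

    for k in range(spec.n_bad_segments):
        seg_len = int(spec.bad_segment_duration * spec.sfreq)
        lo = int(0.2 * n_samp)
        onset = lo + k * 2 * seg_len + int(rng.integers(seg_len))
        onset = min(onset, n_samp - seg_len - 1)
        data[:, onset : onset + seg_len] *= spec.bad_segment_gain
        truth["bad_segments"].append(
            (onset / spec.sfreq, spec.bad_segment_duration)
        )

    all_data = np.vstack([data, ecg[None], eog[None]])
    rec = Recording(
        data=all_data,
        sfreq=spec.sfreq,
        channel_labels=labels + ["ECG001", "EOG001"],
        channel_types=["meg"] * n_meg + ["ecg", "eog"],
    )

    if spec.n_events > 0:
        start = int(spec.sfreq)  # leave 1 s margin at each end
        span = n_samp - 2 * start
        samples = start + (np.arange(spec.n_events) * span) // spec.n_events
        names = [CONDITIONS[i % 3] for i in range(spec.n_events)]
        codes = [CONDITIONS.index(n) + 1 for n in names]
        events = EventTable(samples, np.array(codes), names)
    else:
        events = EventTable(np.array([], int), np.array([], int), [])
    return rec, events, truth


def simulate_evoked_effect(
    spec: SimulationSpec, subject: int = 0, session: int = 0
) -> tuple[Epochs, np.ndarray]:
    """Event-locked parcel epochs with a planted condition effect.

    Trials are parcel-level noise epochs spanning [-0.1, 0.5) s; face trials
    (famous + unfamiliar) receive an extra response of ``spec.effect_size``
    in the first two parcels inside ``spec.effect_window``.  Returns the
    Epochs (trials x parcels x samples) and the boolean ground-truth effect
    mask (parcels x samples).  Trial labels are balanced within +-1.
    """
    if len(CONDITIONS) < 2:
        raise ValueError("need at least two conditions")
    rng = np.random.default_rng([spec.seed, 7, subject, session])
    tmin, tmax = -0.1, 0.5
    n_samp = int(round((tmax - tmin) * spec.sfreq))
    n_trials = spec.n_events
    names = [CONDITIONS[i % 3] for i in range(n_trials)]
    data = rng.standard_normal((n_trials, spec.n_parcels, n_samp))
    times = tmin + np.arange(n_samp) / spec.sfreq
    w0, w1 = spec.effect_window
    tmask = (times >= w0) & (times < w1)
    mask = np.zeros((spec.n_parcels, n_samp), dtype=bool)
    target_parcels = [0, 1] if spec.n_parcels > 1 else [0]
    mask[np.ix_(target_parcels, np.nonzero(tmask)[0])] = True
    # subject-level random effect keeps group-level variance realistic
    subj_amp = spec.effect_size * (1.0 + 0.2 * rng.standard_normal())
    bump = np.sin(np.pi * (times[tmask] - w0) / (w1 - w0))
    for i, name in enumerate(names):
        if name in ("famous", "unfamiliar"):
            data[np.ix_([i], target_parcels, np.nonzero(tmask)[0])] += (
                subj_amp * bump
            )
    epochs = Epochs(
        data=data,
        tmin=tmin,
        tmax=tmax,
        sfreq=spec.sfreq,
        trial_names=names,
        channel_labels=[f"parcel_{p}" for p in range(spec.n_parcels)],
    )
    return epochs, mask


def simulate_multisubject_parcels(
    spec: SimulationSpec, n_samples: int | None = None
) -> tuple[list[ParcelTimeCourses], list[np.ndarray]]:
    """Per-subject parcel time courses sharing one covariance, with known
    random polarity flips applied per subject.

    Returns the flipped time courses and the true flip vectors (recovery by
    sign alignment is defined up to a global sign per subject).
    """
    rng = np.random.default_rng([spec.seed, 13])
    P = spec.n_parcels
    if n_samples is None:
        n_samples = int(spec.duration * spec.sfreq)
    A = rng.standard_normal((P, P)) / np.sqrt(P)
    cov = A @ A.T + 0.5 * np.eye(P)
    chol = np.linalg.cholesky(cov)
    out, true_flips = [], []
    for s in range(spec.n_subjects):
        x = chol @ rng.standard_normal((P, n_samples))
        f = rng.choice([-1.0, 1.0], size=P)
        out.append(
            ParcelTimeCourses(f[:, None] * x, [f"parcel_{p}" for p in range(P)],
                              spec.sfreq, subject_id=f"sub{s:03d}")
        )
        true_flips.append(f)
    return out, true_flips


def simulate_dipole_recording(
    grid, leadfield, dipole_index: int, orientation, snr: float,
    duration: float, sfreq: float, seed: int = 0,
):
    """Sensor data from a single grid dipole plus white sensor noise.

    The dipole carries band-limited unit-variance activity with the given
    (unit) moment orientation; sensor noise is scaled so the ratio of
    signal to noise standard deviation at the sensors equals ``snr``.
    """
    rng = np.random.default_rng(seed)
    n_samp = int(round(duration * sfreq))
    src = _bandlimited_noise(rng, 1, n_samp, sfreq)[0]
    u = np.asarray(orientation, dtype=float)
    u = u / np.linalg.norm(u)
    l = leadfield.point(dipole_index) @ u
    clean = np.outer(l, src)
    noise = rng.standard_normal(clean.shape)
    noise *= clean.std() / (snr * noise.std())
    return clean + noise


def write_study(
    spec: SimulationSpec, outdir: str | Path
) -> list[tuple[str, Path]]:
    """Materialize the study on disk: one recording + events + ground truth
    per subject/session under sub-XXX/run-XX, for wildcard discovery and
    batch processing."""
    import json

    outdir = Path(outdir)
    sessions = []
    for s in range(spec.n_subjects):
        for r in range(spec.n_sessions):
            rec, events, truth = simulate_recording(spec, s, r)
            stem = outdir / f"sub-{s:03d}" / f"run-{r:02d}"
            rec.save(stem)
            events.save(stem.with_suffix(".events.tsv"))
            serializable = {
                "bad_channels": truth["bad_channels"],
                "bad_segments": truth["bad_segments"],
            }
            # ground truth lives outside the wildcard-discoverable tree
            truth_path = outdir / "truth" / f"sub-{s:03d}_run-{r:02d}.json"
            truth_path.parent.mkdir(parents=True, exist_ok=True)
            truth_path.write_text(
                json.dumps(serializable, sort_keys=True, indent=1) + "\n"
            )
            sessions.append((f"{s:03d}-{r:02d}", stem.with_suffix(".json")))
    return sessions
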