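"""Sensor-space cleaning.

Artifact screening is built on the generalized extreme studentized deviate
(GESD) test: an iterative outlier procedure that, for i = 1..r, removes the
point with the largest studentized deviation R_i = max|x - mean| / sd and
compares it against a Student-t critical value

    lambda_i = (n - i) * t_{p, n-i-1} / sqrt((n - i - 1 + t^2) (n - i + 1)),
    p = 1 - alpha / (2 (n - i + 1)),

declaring the first k points outliers where k is the *largest* i with
R_i > lambda_i.  Unlike a single Grubbs test this remains sensitive when
several outliers mask each other.

Bad channels are screened by applying GESD to a per-channel summary metric
(std/var/kurtosis over good samples); bad segments by applying it to a
per-window metric over good channels of one type.  IC artifact handling
labels components by absolute Pearson correlation with recorded ECG/EOG
channels and subtracts the rejected subspace.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal, stats

from .containers import Annotation, Epochs, EventTable, ICADecomposition, Recording

__all__ = [
    "GESDResult",
    "gesd",
    "detect_bad_channels",
    "detect_bad_segments",
    "fit_ica",
    "label_ics_by_correlation",
    "apply_ic_rejection",
    "epoch",
    "bandpass_filter",
    "resample",
]


@dataclass
class GESDResult:
    """Outcome of a generalized ESD test.

    candidate_order holds the indices in removal order (most extreme first);
    R and lam are the test statistics and critical values for each step, and
    n_outliers is the largest i with R_i > lam_i (0 if none).
    """

    candidate_order: np.ndarray
    R: np.ndarray
    lam: np.ndarray
    alpha: float
    n_outliers: int

    @property
    def outliers(self) -> np.ndarray:
        return self.candidate_order[: self.n_outliers]


def gesd_critical_values(n: int, alpha: float, max_outliers: int) -> np.ndarray:
    """Critical values lambda_i, i = 1..max_outliers, for sample size n."""
    i = np.arange(1, max_outliers + 1)
    p = 1.0 - alpha / (2.0 * (n - i + 1))
    df = n - i - 1
    t = stats.t.ppf(p, df)
    return (n - i) * t / np.sqrt((df + t**2) * (n - i + 1))


def gesd(values, alpha: float = 0.05, max_outliers: int | None = None) -> GESDResult:
    """Two-sided generalized ESD outlier test.

    Parameters
    ----------
    values : array-like of float
    alpha : float in (0, 1)
        Significance level of each step.
    max_outliers : int, optional
        Upper bound r on the number of outliers tested; defaults to
        ``ceil(0.1 * n)``.

    Notes
    -----
    If the remaining points become (numerically) constant while candidate
    slots remain, the remaining R_i are set to 0 — no further outliers —
    rather than raising.
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    n = x.size
    if max_outliers is None:
        max_outliers = int(np.ceil(0.1 * n))
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n <= max_outliers + 2:
        raise ValueError("need length(values) > max_outliers + 2")

    remaining = np.arange(n)
    order = np.empty(max_outliers, dtype=int)
    R = np.zeros(max_outliers)
    for i in range(max_outliers):
        xi = x[remaining]
        sd = xi.std(ddof=1)
        dev = np.abs(xi - xi.mean())
        j = int(np.argmax(dev))
        if sd <= 0 or not np.isfinite(sd):
            # degenerate remainder: nothing further can be studentized
            order[i:] = remaining[: max_outliers - i]
            R[i:] = 0.0
            break
        R[i] = dev[j] / sd
        order[i] = remaining[j]
        remaining = np.delete(remaining, j)

    lam = gesd_critical_values(n, alpha, max_outliers)
    exceed = np.nonzero(R > lam)[0]
    n_outliers = int(exceed[-1] + 1) if exceed.size else 0
    return GESDResult(order, R, lam, alpha, n_outliers)


_METRICS = {
    "std": lambda a, axis: a.std(axis=axis, ddof=1),
    "var": lambda a, axis: a.var(axis=axis, ddof=1),
    "kurtosis": lambda a, axis: stats.kurtosis(a, axis=axis),
}


def detect_bad_channels(
    rec: Recording,
    metric: str = "std",
    alpha: float = 0.05,
    max_frac: float = 0.1,
    channel_type: str = "meg",
) -> tuple[Recording, str]:
    """Flag outlier channels of one type via GESD on a per-channel metric.

    The metric is computed over good samples only (bad-segment annotations
    excluded).  At most ``max_frac * n_channels`` channels are flagged.
    Returns the updated recording and a one-line summary for the session log.
    """
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {sorted(_METRICS)}")
    picks = rec.picks(channel_type, good_only=True)
    if picks.size == 0:
        return rec, f"bad_channels ({channel_type}): no good channels, skipped"
    if picks.size < 8:
        raise ValueError("need >= 8 good channels of the targeted type")
    good = rec.good_sample_mask()
    vals = _METRICS[metric](rec.data[np.ix_(picks, np.nonzero(good)[0])], 1)
    res = gesd(vals, alpha=alpha)
    cap = int(np.floor(max_frac * picks.size))
    flagged = res.outliers[:cap]
    out = rec.copy()
    for idx in flagged:
        out.bad_channels.add(rec.channel_labels[picks[idx]])
    names = [rec.channel_labels[picks[i]] for i in flagged]
    summary = (
        f"bad_channels ({channel_type}, metric={metric}): "
        f"{len(flagged)} bad channels detected {names}"
    )
    return out, summary


def detect_bad_segments(
    rec: Recording,
    window_s: float = 1.0,
    metric: str = "std",
    alpha: float = 0.05,
    channel_type: str = "meg",
) -> tuple[Recording, str]:
    """Flag outlier time windows via GESD and annotate them ``bad_segment``.

    The recording is tiled into non-overlapping windows of ``window_s``
    seconds; the metric is aggregated over good channels of the given type;
    contiguous flagged windows merge into single annotations aligned to
    window boundaries.
    """
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {sorted(_METRICS)}")
    wlen = int(round(window_s * rec.sfreq))
    if wlen < 2:
        raise ValueError("window_s * sfreq must be >= 2")
    n_win = rec.n_samples // wlen
    if n_win < 10:
        raise ValueError("recording must span >= 10 windows")
    picks = rec.picks(channel_type, good_only=True)
    if picks.size == 0:
        return rec, f"bad_segments ({channel_type}): no good channels, skipped"
    x = rec.data[picks, : n_win * wlen].reshape(picks.size, n_win, wlen)
    vals = _METRICS[metric](x, 2).mean(axis=0)  # aggregate over channels
    res = gesd(vals, alpha=alpha)
    flagged = np.zeros(n_win, dtype=bool)
    flagged[res.outliers] = True
    out = rec.copy()
    n_flagged = int(flagged.sum())
    i = 0
    while i < n_win:
        if flagged[i]:
            j = i
            while j + 1 < n_win and flagged[j + 1]:
                j += 1
            out.annotations.append(
                Annotation(i * window_s, (j - i + 1) * window_s, "bad_segment")
            )
            i = j + 1
        else:
            i += 1
    summary = (
        f"bad_segments ({channel_type}, metric={metric}): "
        f"{n_flagged}/{n_win} windows flagged"
    )
    return out, summary


def fit_ica(
    rec: Recording,
    n_components: int = 20,
    channel_type: str = "meg",
    seed: int | None = 0,
) -> ICADecomposition:
    """Estimate an ICA unmixing of the good channels of one type.

    The unmixing itself is delegated to FastICA; this module owns the
    labelling, bookkeeping and rejection built on top of it.  The returned
    mixing matrix is channels x components over *all* channels (zero rows
    for channels not decomposed) so rejection applies directly.
    """
    import warnings

    from sklearn.decomposition import FastICA
    from sklearn.exceptions import ConvergenceWarning

    picks = rec.picks(channel_type, good_only=True)
    n_components = min(n_components, picks.size)
    ica = FastICA(
        n_components=n_components, random_state=seed, whiten="unit-variance",
        max_iter=1000, tol=1e-4,
    )
    # estimate on artifact-free samples so bad segments cannot dominate the
    # whitening, then unmix the full timeline for labelling/subtraction
    good = rec.good_sample_mask()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        ica.fit(rec.data[np.ix_(picks, np.nonzero(good)[0])].T)
    sources = ica.transform(rec.data[picks].T).T  # components x samples
    mixing = np.zeros((rec.n_channels, n_components))
    mixing[picks] = ica.mixing_
    unmixing = np.zeros((n_components, rec.n_channels))
    unmixing[:, picks] = ica.components_
    mean = np.zeros(rec.n_channels)
    mean[picks] = ica.mean_
    return ICADecomposition(
        mixing=mixing, sources=sources, unmixing=unmixing, mean=mean
    )


def label_ics_by_correlation(
    ica: ICADecomposition,
    rec: Recording,
    threshold: float = 0.8,
    reject: bool = True,
) -> tuple[ICADecomposition, str]:
    """Label components whose |Pearson r| with any ECG/EOG channel exceeds
    ``threshold``; ties between an ECG and an EOG match go to ``ecg``.

    With ``reject=True`` labelled components are added to the rejected set.
    Returns the updated decomposition and a log summary.  If the recording
    carries no ECG/EOG channels this is a no-op.
    """
    good = rec.good_sample_mask()
    refs = [
        (typ, rec.data[i, good])
        for typ in ("ecg", "eog")
        for i in rec.picks(typ)
    ]
    if not refs:
        return ica, "ic_label: no ECG/EOG channels present, skipped"
    labels = list(ica.labels)
    rejected = set(ica.rejected)
    for k in range(ica.n_components):
        s = ica.sources[k, good]
        best_r, best_typ = 0.0, "none"
        for typ, ref in refs:
            if s.std() == 0 or ref.std() == 0:
                continue
            r = abs(np.corrcoef(s, ref)[0, 1])
            # strict > keeps an earlier ecg match on an exact tie
            if r > best_r:
                best_r, best_typ = r, typ
        if best_r >= threshold:
            labels[k] = best_typ
            if reject:
                rejected.add(k)
    out = ICADecomposition(ica.mixing, ica.sources, labels, rejected)
    counts = out.label_counts()
    summary = (
        f"ic_label: {counts.get('ecg', 0)} ecg, {counts.get('eog', 0)} eog "
        f"components labelled (threshold |r|>={threshold})"
    )
    return out, summary


def apply_ic_rejection(rec: Recording, ica: ICADecomposition) -> Recording:
    """Subtract the rejected IC subspace: data - mixing[:, R] @ sources[R].

    With an empty rejected set this is the identity.  When the decomposition
    carries its unmixing, the rejected source time courses are recomputed
    from the data being cleaned (s_R = W_R (x - mean)); since W A = I the
    removed subspace of an already-cleaned recording is zero, so the
    operation is idempotent.  Hand-built decompositions without an unmixing
    fall back to the stored sources.
    """
    out = rec.copy()
    if not ica.rejected:
        return out
    idx = sorted(ica.rejected)
    if ica.unmixing is not None:
        x = rec.data - (ica.mean[:, None] if ica.mean is not None else 0.0)
        s = ica.unmixing[idx] @ x
    else:
        s = ica.sources[idx]
    out.data = rec.data - ica.mixing[:, idx] @ s
    return out


def epoch(
    rec: Recording, events: EventTable, tmin: float, tmax: float
) -> Epochs:
    """Cut event-locked trials covering [tmin, tmax) around each event.

    Trials whose window falls outside the recording or overlaps a
    ``bad``-labelled annotation are dropped; the Epochs object records how
    many and why, so kept + dropped always equals the event count.
    """
    if tmin >= tmax:
        raise ValueError("tmin must be < tmax")
    n_win = int(round((tmax - tmin) * rec.sfreq))
    offset = int(round(tmin * rec.sfreq))
    bads = [a for a in rec.annotations if a.label.startswith("bad")]
    trials, names, reasons = [], [], []
    for s, name in zip(events.sample, events.name):
        i0 = s + offset
        i1 = i0 + n_win
        if i0 < 0 or i1 > rec.n_samples:
            reasons.append(f"event@{s}: window outside recording")
            continue
        t0, t1 = i0 / rec.sfreq, i1 / rec.sfreq
        if any(a.overlaps(t0, t1) for a in bads):
            reasons.append(f"event@{s}: overlaps bad segment")
            continue
        trials.append(rec.data[:, i0:i1])
        names.append(name)
    if not trials:
        raise ValueError(
            f"no surviving trials out of {len(events)} events "
            f"({len(reasons)} dropped: edge/bad-segment overlap)"
        )
    return Epochs(
        data=np.stack(trials),
        tmin=tmin,
        tmax=tmax,
        sfreq=rec.sfreq,
        trial_names=names,
        channel_labels=list(rec.channel_labels),
        n_dropped=len(reasons),
        drop_reasons=reasons,
    )


def bandpass_filter(rec: Recording, l_freq: float, h_freq: float) -> Recording:
    """Zero-phase FIR band-pass on all signal channels (stim left intact)."""
    nyq = rec.sfreq / 2.0
    if not 0 <= l_freq < h_freq < nyq:
        raise ValueError(f"band [{l_freq}, {h_freq}] outside (0, Nyquist={nyq})")
    import mne

    out = rec.copy()
    picks = [i for i, t in enumerate(rec.channel_types) if t != "stim"]
    out.data[picks] = mne.filter.filter_data(
        rec.data[picks], rec.sfreq,
        l_freq if l_freq > 0 else None, h_freq, verbose="error",
    )
    return out


def resample(
    rec: Recording, new_sfreq: float, events: EventTable | None = None
) -> Recording | tuple[Recording, EventTable]:
    """Polyphase resampling with anti-alias filtering.

    Annotations are in seconds and carry over unchanged; if an event table
    is supplied its sample indices are rescaled to the new rate and the
    resampled table is returned alongside the recording.
    """
    if new_sfreq <= 0:
        raise ValueError("new_sfreq must be positive")
    frac = Fraction(new_sfreq / rec.sfreq).limit_denominator(1000)
    out = rec.copy()
    out.data = signal.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    out.sfreq = new_sfreq
    if events is None:
        return out
    ratio = new_sfreq / rec.sfreq
    new_samples = np.round(events.sample * ratio).astype(int)
    return out, EventTable(new_samples, events.code.copy(), list(events.name))
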