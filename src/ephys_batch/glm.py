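"""Mass-univariate general linear models with contrasts, max-statistic
permutation inference, and a GLM-spectrum.

The model is ordinary least squares fitted independently to every outcome
dimension (parcel x timepoint, frequency x channel, ...):

    Y = X beta + eps,    cope = c^T beta,
    varcope = sigma_hat^2 c^T (X^T X)^+ c,    t = cope / sqrt(varcope),

with sigma_hat^2 estimated from the residuals and dof = n - rank(X).
Family-wise inference uses the permutation distribution of the maximum |t|
over the tested dimensions: group-mean contrasts are permuted by per-subject
sign flipping of first-level copes (valid under a symmetric null), condition
contrasts by relabelling trials.  The GLM-spectrum treats short-time
periodogram windows as observations; with an intercept-only design the
fitted intercept is exactly the Welch-averaged periodogram, and extra
per-window covariates model spectral drift or confounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

__all__ = [
    "DesignMatrix",
    "build_first_level_design",
    "build_group_design",
    "GLM",
    "GLMResults",
    "fit_glm",
    "PermutationResult",
    "max_stat_permutation",
    "GLMSpectrumResult",
    "glm_spectrum",
]


@dataclass
class DesignMatrix:
    """Design X (observations x regressors) with named contrast vectors."""

    X: np.ndarray
    regressor_names: list[str]
    contrasts: list[tuple[str, np.ndarray]] = field(default_factory=list)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if len(self.regressor_names) != self.X.shape[1]:
            raise ValueError("regressor_names length mismatch")
        if np.any(np.all(self.X == 0, axis=0)):
            raise ValueError("design contains an all-zero column")
        self.contrasts = [
            (name, np.asarray(c, dtype=np.float64)) for name, c in self.contrasts
        ]
        for name, c in self.contrasts:
            if c.shape != (self.X.shape[1],):
                raise ValueError(f"contrast '{name}' length mismatch")

    @property
    def n_regressors(self) -> int:
        return self.X.shape[1]

    @property
    def n_observations(self) -> int:
        return self.X.shape[0]


def build_first_level_design(
    trial_names: list[str],
    condition_order: list[str],
    contrast_spec: dict[str, list[float]] | None = None,
) -> DesignMatrix:
    """One-hot condition design for a single session's trials.

    Default contrasts: ``mean`` = equal weights 1/k, and — when the three
    face-paradigm conditions famous/unfamiliar/scrambled are all present —
    ``faces_vs_scrambled`` = [0.5, 0.5, -1] over (famous, unfamiliar,
    scrambled).
    """
    unknown = sorted(set(trial_names) - set(condition_order))
    if unknown:
        raise ValueError(f"trial labels not in condition_order: {unknown}")
    k = len(condition_order)
    col = {name: j for j, name in enumerate(condition_order)}
    X = np.zeros((len(trial_names), k))
    for i, name in enumerate(trial_names):
        X[i, col[name]] = 1.0
    contrasts: list[tuple[str, np.ndarray]] = []
    if contrast_spec is not None:
        contrasts = [(n, np.asarray(w, float)) for n, w in contrast_spec.items()]
    else:
        contrasts.append(("mean", np.full(k, 1.0 / k)))
        if {"famous", "unfamiliar", "scrambled"} <= set(condition_order):
            w = np.zeros(k)
            w[col["famous"]] = 0.5
            w[col["unfamiliar"]] = 0.5
            w[col["scrambled"]] = -1.0
            contrasts.append(("faces_vs_scrambled", w))
    return DesignMatrix(X, list(condition_order), contrasts)


def build_group_design(subject_ids: list[str]) -> DesignMatrix:
    """Subject-indicator design over sessions with one group-mean contrast
    weighting every subject equally (1/n_subjects)."""
    subjects = sorted(set(subject_ids), key=lambda s: subject_ids.index(s))
    col = {s: j for j, s in enumerate(subjects)}
    X = np.zeros((len(subject_ids), len(subjects)))
    for i, s in enumerate(subject_ids):
        X[i, col[s]] = 1.0
    contrast = np.full(len(subjects), 1.0 / len(subjects))
    return DesignMatrix(X, subjects, [("group_mean", contrast)])


@dataclass
class GLMResults:
    """OLS estimates and contrast statistics for every outcome dimension.

    Attributes keep the fitted shapes: ``beta`` is regressors x dims,
    ``cope``/``varcope``/``tstat`` are contrasts x dims, ``dof`` is
    n - rank(X).
    """

    beta: np.ndarray
    cope: np.ndarray
    varcope: np.ndarray
    tstat: np.ndarray
    dof: int
    design: DesignMatrix
    sigma2: np.ndarray
    outcome_shape: tuple[int, ...]

    def summary(self) -> str:
        lines = [
            "GLM (ordinary least squares, massive univariate)",
            f"  observations: {self.design.n_observations}"
            f"   regressors: {self.design.n_regressors}   dof: {self.dof}",
            f"  outcome dims: {self.outcome_shape}",
            f"{'contrast':<24}{'max |t|':>10}{'mean cope':>12}",
        ]
        for i, (name, _) in enumerate(self.design.contrasts):
            lines.append(
                f"{name:<24}{np.abs(self.tstat[i]).max():>10.3f}"
                f"{self.cope[i].mean():>12.4g}"
            )
        return "\n".join(lines)


class GLM:
    """Statsmodels-style model object: ``GLM(Y, design).fit()``.

    Y is observations x outcome dims (extra trailing dims are flattened and
    restored on the results object via ``outcome_shape``).
    """

    def __init__(self, Y: np.ndarray, design: DesignMatrix):
        Y = np.asarray(Y, dtype=np.float64)
        if Y.ndim == 1:
            Y = Y[:, None]
        self.outcome_shape = Y.shape[1:]
        self.Y = Y.reshape(Y.shape[0], -1)
        self.design = design
        if self.Y.shape[0] != design.n_observations:
            raise ValueError("observation count mismatch between Y and design")

    def fit(self) -> GLMResults:
        X = self.design.X
        rank = np.linalg.matrix_rank(X)
        n = X.shape[0]
        if n < rank + 1:
            raise ValueError("need more observations than rank(X)")
        pinv = np.linalg.pinv(X)
        beta = pinv @ self.Y
        resid = self.Y - X @ beta
        dof = n - rank
        sigma2 = (resid**2).sum(axis=0) / dof
        XtX_inv = pinv @ pinv.T  # (X^T X)^+ for full-rank X
        copes, varcopes, tstats = [], [], []
        for _, c in self.design.contrasts:
            cope = c @ beta
            varcope = sigma2 * float(c @ XtX_inv @ c)
            with np.errstate(divide="ignore", invalid="ignore"):
                t = np.where(varcope > 0, cope / np.sqrt(varcope), 0.0)
            copes.append(cope)
            varcopes.append(varcope)
            tstats.append(t)
        return GLMResults(
            beta=beta,
            cope=np.array(copes),
            varcope=np.array(varcopes),
            tstat=np.array(tstats),
            dof=dof,
            design=self.design,
            sigma2=sigma2,
            outcome_shape=self.outcome_shape,
        )


def fit_glm(Y: np.ndarray, design: DesignMatrix) -> GLMResults:
    """Functional wrapper around ``GLM(Y, design).fit()``."""
    return GLM(Y, design).fit()


@dataclass
class PermutationResult:
    """Max-statistic permutation null and the resulting significance mask."""

    null_max: np.ndarray
    threshold: float
    sig_mask: np.ndarray
    tstat_observed: np.ndarray
    n_perms: int
    seed: int | None
    alpha: float
    pvalue: float

    def summary(self) -> str:
        return (
            f"max-|t| permutation test: n_perms={self.n_perms}, "
            f"alpha={self.alpha}, threshold={self.threshold:.3f}, "
            f"{int(self.sig_mask.sum())} significant dims, "
            f"min p={self.pvalue:.4g}"
        )


def _one_sample_sign_flip_t(Y: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Vectorized one-sample t for every sign-flip row of S (n_perms x n)."""
    n = Y.shape[0]
    M = S @ Y / n
    rss = (Y**2).sum(axis=0)[None, :] - n * M**2
    sigma2 = rss / (n - 1)
    varcope = sigma2 / n
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(varcope > 0, M / np.sqrt(varcope), 0.0)


def max_stat_permutation(
    Y: np.ndarray,
    design: DesignMatrix,
    contrast_idx: int = 0,
    n_perms: int = 1000,
    seed: int | None = 0,
    scope_mask: np.ndarray | None = None,
    scheme: str = "sign_flip",
    groups: list | None = None,
    alpha: float = 0.05,
) -> PermutationResult:
    """Family-wise max-|t| permutation test for one contrast.

    scheme='sign_flip' multiplies observations by random signs (whole
    groups flip together when ``groups`` assigns observations to subjects) —
    the exchangeability scheme for group-mean contrasts on copes.
    scheme='labels' permutes design rows (within ``groups`` when given) —
    the scheme for condition contrasts.  The identity permutation is always
    included, so the minimum attainable p-value is 1/n_perms.  The null is
    the distribution of max |t| restricted to ``scope_mask`` (e.g. a
    post-stimulus time window); threshold is its 100(1-alpha) percentile
    and sig_mask marks observed |t| above it.
    """
    if n_perms < 20:
        raise ValueError("n_perms < 20 gives too coarse a p-value resolution")
    if scheme not in ("sign_flip", "labels"):
        raise ValueError("scheme must be 'sign_flip' or 'labels'")
    Y = np.asarray(Y, dtype=np.float64)
    flat = Y.reshape(Y.shape[0], -1)
    n = flat.shape[0]
    if scope_mask is None:
        scope = np.ones(flat.shape[1], dtype=bool)
    else:
        scope = np.asarray(scope_mask, dtype=bool).ravel()
    rng = np.random.default_rng(seed)
    if groups is None:
        if scheme == "labels":
            # labels are exchangeable across all observations
            group_idx = [np.arange(n)]
        else:
            group_idx = [np.array([i]) for i in range(n)]
    else:
        uniq = list(dict.fromkeys(groups))
        group_idx = [np.nonzero([g == u for g in groups])[0] for u in uniq]

    c = design.contrasts[contrast_idx][1]
    X = design.X
    one_sample = (
        scheme == "sign_flip"
        and X.shape[1] == 1
        and np.allclose(X, X[0, 0])
        and groups is None
    )

    t_obs_full = fit_glm(flat, design).tstat[contrast_idx]
    if one_sample:
        S = np.ones((n_perms, n))
        S[1:] = rng.choice([-1.0, 1.0], size=(n_perms - 1, n))
        tstats = _one_sample_sign_flip_t(flat * X[0, 0], S)
        null_max = np.abs(tstats[:, scope]).max(axis=1)
    else:
        null_max = np.empty(n_perms)
        for p in range(n_perms):
            if p == 0:
                Yp, Xp = flat, X
            elif scheme == "sign_flip":
                signs = np.ones(n)
                for gi in group_idx:
                    signs[gi] = rng.choice([-1.0, 1.0])
                Yp, Xp = flat * signs[:, None], X
            else:
                perm = np.arange(n)
                for gi in group_idx:
                    perm[gi] = gi[rng.permutation(len(gi))]
                Yp, Xp = flat, X[perm]
            d = DesignMatrix(Xp, design.regressor_names, design.contrasts)
            null_max[p] = np.abs(
                fit_glm(Yp, d).tstat[contrast_idx][scope]
            ).max()
    threshold = float(np.percentile(null_max, 100 * (1 - alpha)))
    obs_max = np.abs(t_obs_full[scope]).max()
    pvalue = float((null_max >= obs_max).mean())
    pvalue = max(pvalue, 1.0 / n_perms)
    sig_mask = (np.abs(t_obs_full) > threshold) & scope
    return PermutationResult(
        null_max=null_max,
        threshold=threshold,
        sig_mask=sig_mask.reshape(Y.shape[1:]),
        tstat_observed=t_obs_full.reshape(Y.shape[1:]),
        n_perms=n_perms,
        seed=seed,
        alpha=alpha,
        pvalue=pvalue,
    )


@dataclass
class GLMSpectrumResult:
    """Regression coefficients per frequency bin and channel.

    beta has shape (regressors, n_freqs, n_channels); with an intercept-only
    design beta[0] is exactly the Welch average of the windowed
    periodograms.
    """

    freqs: np.ndarray
    beta: np.ndarray
    regressor_names: list[str]
    window_s: float
    overlap: float
    taper: str
    sfreq: float

    def summary(self) -> str:
        return (
            f"GLM-spectrum: {len(self.freqs)} bins up to "
            f"{self.freqs[-1]:.1f} Hz, window {self.window_s}s "
            f"({self.taper}, overlap {self.overlap}), "
            f"regressors {self.regressor_names}"
        )


def _windowed_periodograms(
    data: np.ndarray, sfreq: float, nperseg: int, noverlap: int, taper: str
):
    """Per-window one-sided power spectral densities, Welch conventions
    (constant detrend per window, density scaling)."""
    win = sp_signal.get_window(taper, nperseg)
    step = nperseg - noverlap
    n_windows = (data.shape[1] - noverlap) // step
    if n_windows < 1:
        raise ValueError("data shorter than one window")
    scale = 1.0 / (sfreq * (win**2).sum())
    freqs = np.fft.rfftfreq(nperseg, 1.0 / sfreq)
    out = np.empty((n_windows, len(freqs), data.shape[0]))
    for w in range(n_windows):
        seg = data[:, w * step : w * step + nperseg]
        seg = seg - seg.mean(axis=1, keepdims=True)
        spec = np.fft.rfft(seg * win, axis=1)
        psd = scale * np.abs(spec) ** 2
        psd[:, 1:] *= 2.0
        if nperseg % 2 == 0:
            psd[:, -1] /= 2.0
        out[w] = psd.T
    return freqs, out


def glm_spectrum(
    rec,
    window_s: float = 2.0,
    overlap: float = 0.5,
    covariates: dict[str, np.ndarray] | None = None,
    taper: str = "hann",
    sfreq: float | None = None,
) -> GLMSpectrumResult:
    """Regression across short-time spectral windows.

    ``rec`` is a Recording or a channels x samples array (then ``sfreq``
    must be given).  Each tapered, overlapping window's periodogram is one
    observation; the design is an intercept plus any supplied per-window
    covariates (values per window, demeaned internally so the intercept
    remains the mean spectrum).
    """
    if hasattr(rec, "sfreq"):
        data, fs = rec.data, rec.sfreq
    else:
        data, fs = np.asarray(rec, dtype=np.float64), sfreq
        if fs is None:
            raise ValueError("sfreq required for array input")
        if data.ndim == 1:
            data = data[None, :]
    nperseg = int(round(window_s * fs))
    if nperseg < 8:
        raise ValueError("window_s * sfreq must be >= 8")
    noverlap = int(round(nperseg * overlap))
    freqs, Y = _windowed_periodograms(data, fs, nperseg, noverlap, taper)
    n_windows = Y.shape[0]
    names = ["intercept"]
    cols = [np.ones(n_windows)]
    if covariates:
        for name, v in covariates.items():
            v = np.asarray(v, dtype=np.float64)
            if v.shape != (n_windows,):
                raise ValueError(
                    f"covariate '{name}' must have one value per window "
                    f"({n_windows}), got {v.shape}"
                )
            cols.append(v - v.mean())
            names.append(name)
    if n_windows < len(cols) + 1:
        raise ValueError("fewer windows than regressors + 1")
    design = DesignMatrix(np.column_stack(cols), names, [("mean", np.eye(len(cols))[0])])
    res = GLM(Y, design).fit()
    beta = res.beta.reshape(len(cols), *Y.shape[1:])
    return GLMSpectrumResult(
        freqs=freqs,
        beta=beta,
        regressor_names=names,
        window_s=window_s,
        overlap=overlap,
        taper=taper,
        sfreq=fs,
    )
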