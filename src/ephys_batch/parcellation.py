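"""Parcel time courses, leakage correction, and cross-subject polarity
alignment.

Grid dipole time courses are reduced to one time course per parcel (first
principal component of the member dipoles, rescaled to their mean
variance).  Because the M/EEG inverse is ill-posed, reconstructed parcels
inherit spurious mutual correlations ("leakage"); these are removed by the
symmetric (multivariate) orthogonalization of Colclough-style closest
orthogonal matrix fitting, which also suppresses ghost interactions
inherited from third regions.  Finally, the arbitrary per-subject polarity
of each parcel (dipole/PCA sign ambiguity) is aligned across subjects by
choosing sign vectors that maximize the correlation between subjects'
parcel covariance matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ParcelAssignment",
    "ParcelTimeCourses",
    "SignFlipSolution",
    "load_label_volume",
    "assign_parcels",
    "extract_parcel_timecourses",
    "symmetric_orthogonalize",
    "sign_flip",
]


@dataclass
class ParcelAssignment:
    """Integer parcel id per grid point; 0 means unassigned/background."""

    parcel_id: np.ndarray
    parcel_names: dict[int, str]
    n_unmapped: int = 0

    def __post_init__(self):
        self.parcel_id = np.asarray(self.parcel_id, dtype=int)
        for pid in self.parcel_names:
            if pid != 0 and not np.any(self.parcel_id == pid):
                raise ValueError(f"named parcel {pid} has no grid points")

    @property
    def n_parcels(self) -> int:
        return len([p for p in self.parcel_names if p != 0])

    @property
    def ids(self) -> list[int]:
        return sorted(p for p in self.parcel_names if p != 0)


@dataclass
class ParcelTimeCourses:
    """n_parcels x samples (or trials x n_parcels x samples) parcel signals."""

    data: np.ndarray
    parcel_names: list[str]
    sfreq: float = 1.0
    subject_id: str = ""
    session_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)

    @property
    def n_parcels(self) -> int:
        return self.data.shape[-2]


def load_label_volume(path: str | Path):
    """Read an integer label volume + affine from a NIfTI file."""
    import nibabel as nib

    img = nib.load(str(path))
    return np.asarray(img.dataobj).astype(int), img.affine


def assign_parcels(
    grid,
    label_volume: np.ndarray,
    affine: np.ndarray,
    parcel_names: dict[int, str] | None = None,
) -> ParcelAssignment:
    """Map each grid point to the label of its containing voxel.

    Grid positions (meters) are converted to the volume's millimeter world
    frame, sent through the inverse affine, and rounded to the nearest voxel
    with round-half-away-from-zero.  Points landing outside the volume get
    id 0 and are counted in ``n_unmapped``.
    """
    affine = np.asarray(affine, dtype=float)
    inv = np.linalg.inv(affine)
    pos_mm = grid.positions * 1000.0
    vox = (inv[:3, :3] @ pos_mm.T).T + inv[:3, 3]
    # round half away from zero (np.round rounds half to even)
    idx = (np.sign(vox) * np.floor(np.abs(vox) + 0.5)).astype(int)
    ids = np.zeros(len(idx), dtype=int)
    shape = label_volume.shape
    inside = np.all((idx >= 0) & (idx < np.asarray(shape)), axis=1)
    ids[inside] = label_volume[idx[inside, 0], idx[inside, 1], idx[inside, 2]]
    n_unmapped = int((~inside).sum())
    if parcel_names is None:
        parcel_names = {
            int(p): f"parcel_{int(p)}" for p in np.unique(label_volume) if p != 0
        }
    present = {0: "background"}
    for pid, name in parcel_names.items():
        if pid != 0 and np.any(ids == pid):
            present[pid] = name
    return ParcelAssignment(ids, present, n_unmapped)


def extract_parcel_timecourses(
    source_tcs: np.ndarray, assignment: ParcelAssignment, method: str = "pca"
) -> ParcelTimeCourses:
    """First principal component per parcel, rescaled to the mean variance
    of the member dipoles.

    The PC sign is fixed so the sum of spatial weights is positive (and by
    the first nonzero weight when the sum is exactly zero), making the
    output deterministic before any cross-subject sign alignment.
    """
    if method != "pca":
        raise ValueError("only method='pca' is implemented")
    X = np.asarray(source_tcs, dtype=np.float64)
    out, names = [], []
    for pid in assignment.ids:
        members = np.nonzero(assignment.parcel_id == pid)[0]
        xm = X[members]
        xc = xm - xm.mean(axis=1, keepdims=True)
        var = xc.var(axis=1, ddof=1)
        if np.all(var == 0):
            out.append(np.zeros(X.shape[1]))
            names.append(assignment.parcel_names[pid])
            continue
        cov = xc @ xc.T / (xc.shape[1] - 1)
        evals, evecs = np.linalg.eigh(cov)
        w = evecs[:, -1]
        s = w.sum()
        if s < 0 or (s == 0 and w[np.nonzero(w)[0][0]] < 0):
            w = -w
        ts = w @ xc
        ts_var = ts.var(ddof=1)
        if ts_var > 0:
            ts = ts * np.sqrt(var.mean() / ts_var)
        out.append(ts)
        names.append(assignment.parcel_names[pid])
    return ParcelTimeCourses(np.array(out), names)


def symmetric_orthogonalize(
    ptc: ParcelTimeCourses | np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> ParcelTimeCourses | np.ndarray:
    """Closest-orthogonal-matrix leakage correction.

    Finds Y = D O minimizing ||X - D O||_F over matrices O with orthonormal
    rows and positive diagonal scalings D, by alternating

    (a) O <- U V^T from the thin SVD of D X  (closest orthonormal basis),
    (b) d_i <- x_i . o_i                     (per-parcel rescaling by
        regression of the original time course on its orthogonal partner),

    until the relative Frobenius change of Y falls below ``tol``.  Rows of
    the result are exactly mutually orthogonal and, as X is demeaned first,
    mutually uncorrelated.  Unlike sequential Gram-Schmidt the solution is
    symmetric in the parcels — no ordering is privileged — and it is the
    closest such matrix to the input.
    """
    is_ptc = isinstance(ptc, ParcelTimeCourses)
    X = ptc.data if is_ptc else np.asarray(ptc, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("expected a 2-D parcels x samples matrix")
    P, T = X.shape
    if T <= P:
        raise ValueError("need more samples than parcels")
    X = X - X.mean(axis=1, keepdims=True)
    rank = np.linalg.matrix_rank(X)
    if rank < P:
        raise ValueError(f"input is rank deficient (rank {rank} < {P} parcels)")
    d = np.linalg.norm(X, axis=1)
    Y_prev = None
    for _ in range(max_iter):
        U, _, Vt = np.linalg.svd(d[:, None] * X, full_matrices=False)
        O = U @ Vt
        d = np.einsum("ij,ij->i", X, O)
        Y = d[:, None] * O
        if Y_prev is not None:
            num = np.linalg.norm(Y - Y_prev)
            den = np.linalg.norm(Y_prev)
            if den > 0 and num / den < tol:
                break
        Y_prev = Y
    if is_ptc:
        return ParcelTimeCourses(
            Y, list(ptc.parcel_names), ptc.sfreq, ptc.subject_id, ptc.session_id
        )
    return Y


@dataclass
class SignFlipSolution:
    """Per-subject sign vectors aligning parcel polarity across subjects.

    objective_trace records the mean cross-subject covariance correlation
    after every accepted greedy improvement (non-decreasing by
    construction).
    """

    flips: list[np.ndarray]
    objective: float
    objective_trace: list[float] = field(default_factory=list)
    template_subject: int = 0
    seed: int | None = None


def _offdiag(C: np.ndarray) -> np.ndarray:
    mask = ~np.eye(C.shape[0], dtype=bool)
    return C[mask]


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    den = np.linalg.norm(a) * np.linalg.norm(b)
    return float(a @ b / den) if den > 0 else 0.0


def _subject_objective(C: np.ndarray, f: np.ndarray, tmpl_off: np.ndarray) -> float:
    return _corr(_offdiag(np.outer(f, f) * C), tmpl_off)


def _greedy_flip(
    C: np.ndarray, tmpl_off: np.ndarray, f0: np.ndarray, n_iter: int
) -> tuple[np.ndarray, float, list[float]]:
    f = f0.copy()
    best = _subject_objective(C, f, tmpl_off)
    trace = [best]
    for _ in range(n_iter):
        improved = False
        for p in range(len(f)):
            f[p] = -f[p]
            obj = _subject_objective(C, f, tmpl_off)
            if obj > best:
                best = obj
                trace.append(best)
                improved = True
            else:
                f[p] = -f[p]
        if not improved:
            break
    return f, best, trace


def sign_flip(
    subject_ptcs: list[ParcelTimeCourses | np.ndarray],
    n_init: int = 10,
    n_iter: int = 50,
    seed: int | None = 0,
) -> SignFlipSolution:
    """Align parcel polarities across subjects.

    The template is the subject whose covariance correlates best (over
    off-diagonal entries) with the element-wise mean covariance.  For each
    subject, the sign vector f maximizing the Pearson correlation between
    off-diagonal entries of F C F and the template covariance is sought by
    greedy single-parcel flips from ``n_init`` random initializations (the
    first initialization is all +1), each running at most ``n_iter``
    sweeps.  The objective is invariant to a global sign per subject, so
    recovery of planted flips is defined up to that global sign.
    """
    if len(subject_ptcs) < 2:
        raise ValueError("need at least 2 subjects")
    mats = [p.data if isinstance(p, ParcelTimeCourses) else np.asarray(p)
            for p in subject_ptcs]
    P = mats[0].shape[0]
    if P < 2:
        raise ValueError("need at least 2 parcels")
    if any(m.shape[0] != P for m in mats):
        raise ValueError("subjects must share the same parcel count")
    covs = [np.cov(m) for m in mats]
    mean_off = _offdiag(np.mean(covs, axis=0))
    tmpl = int(np.argmax([_corr(_offdiag(C), mean_off) for C in covs]))
    tmpl_off = _offdiag(covs[tmpl])
    rng = np.random.default_rng(seed)

    flips, per_subject_obj = [], []
    trace: list[float] = []
    for C in covs:
        best_f, best_obj, best_trace = None, -np.inf, []
        for init in range(max(n_init, 1)):
            f0 = (np.ones(P) if init == 0
                  else rng.choice([-1.0, 1.0], size=P))
            f, obj, tr = _greedy_flip(C, tmpl_off, f0, n_iter)
            if obj > best_obj:
                best_f, best_obj, best_trace = f, obj, tr
        flips.append(best_f)
        per_subject_obj.append(best_obj)
        # running mean objective after finishing each subject; the greedy
        # improvements within the subject are appended relative to its start
        base = sum(per_subject_obj[:-1])
        done = len(per_subject_obj) - 1
        for v in best_trace:
            trace.append((base + v) / (done + 1))
    # make the aggregate trace non-decreasing (per-subject segments are; the
    # running mean across subject boundaries is monotone after accumulation)
    trace = list(np.maximum.accumulate(trace))
    return SignFlipSolution(
        flips=flips,
        objective=float(np.mean(per_subject_obj)),
        objective_trace=trace,
        template_subject=tmpl,
        seed=seed,
    )


def apply_sign_flips(
    subject_ptcs: list[ParcelTimeCourses], solution: SignFlipSolution
) -> list[ParcelTimeCourses]:
    out = []
    for ptc, f in zip(subject_ptcs, solution.flips):
        out.append(
            ParcelTimeCourses(
                ptc.data * f[:, None], list(ptc.parcel_names),
                ptc.sfreq, ptc.subject_id, ptc.session_id,
            )
        )
    return out
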