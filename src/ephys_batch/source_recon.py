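"""Volumetric source modelling: spherical-head forward model and LCMV
beamforming.

The forward model is the closed-form magnetic field of a current dipole in a
homogeneous conducting sphere (Sarvas solution).  For a dipole with moment Q
at position r0 (sphere-centered coordinates), the field at sensor position r
is

    B(r) = mu0 / (4 pi F^2) * (F (Q x r0) - ((Q x r0) . r) grad F),

    a = r - r0,   F = a (R a + R^2 - r0 . r),
    grad F = (a^2/R + (a.r)/a + 2a + 2R) r - (a + 2R + (a.r)/a) r0,

with a = |a|, R = |r|.  Radially oriented dipoles (Q parallel to r0) are
magnetically silent, so the lead field of a grid point effectively spans a
two-dimensional tangential space — the beamformer handles this by
rank-reducing each local lead field before choosing an orientation.

The inverse is a scalar LCMV (linearly constrained minimum variance)
beamformer: per grid point, the source orientation u maximizing output
power, i.e. minimizing l_u^T C^-1 l_u over the rank-retained orientation
space, then weights

    w = C^-1 l / (l^T C^-1 l)

which satisfy the unit-gain constraint w^T l = 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

MU0_OVER_4PI = 1e-7  # T m / A

__all__ = [
    "SensorArray",
    "SourceGrid",
    "LeadField",
    "CovEstimate",
    "BeamformerWeights",
    "radial_sensor_array",
    "make_sphere_grid",
    "forward_spherical",
    "estimate_covariance",
    "lcmv_weights",
    "apply_weights",
    "power_map",
    "localize",
]


@dataclass
class SensorArray:
    """Magnetometer geometry in head-centered coordinates (meters)."""

    positions: np.ndarray      # n_sensors x 3
    orientations: np.ndarray   # n_sensors x 3, unit norm
    labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.orientations = np.asarray(self.orientations, dtype=np.float64)
        norms = np.linalg.norm(self.orientations, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("sensor orientations must be unit-norm")
        if not self.labels:
            self.labels = [f"MEG{i:03d}" for i in range(len(self.positions))]

    @property
    def n_sensors(self) -> int:
        return self.positions.shape[0]


def radial_sensor_array(
    n_sensors: int = 32,
    radius: float = 0.11,
    center=(0.0, 0.0, 0.0),
    cap_fraction: float = 0.65,
) -> SensorArray:
    """Radially oriented magnetometers on the upper cap of a helmet sphere.

    Sensors are laid out on a deterministic Fibonacci spiral covering the
    top ``cap_fraction`` of the sphere (a crude helmet).
    """
    center = np.asarray(center, dtype=float)
    i = np.arange(n_sensors)
    # z from straight up down to the cap edge
    z = 1.0 - cap_fraction * (i + 0.5) / n_sensors
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    unit = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    return SensorArray(positions=center + radius * unit, orientations=unit)


@dataclass
class SourceGrid:
    """Axis-aligned dipole lattice strictly inside a sphere; ordering is
    x-fastest (x varies quickest as the flat index increases)."""

    positions: np.ndarray
    spacing: float
    sphere_center: np.ndarray
    sphere_radius: float

    @property
    def n_points(self) -> int:
        return self.positions.shape[0]


def make_sphere_grid(center, radius: float, spacing: float) -> SourceGrid:
    """Build the lattice of points p = center + spacing * (i, j, k) with
    |p - center| < radius, ordered x-fastest."""
    if not 0 < spacing < 2 * radius:
        raise ValueError("need 0 < spacing < 2*radius")
    center = np.asarray(center, dtype=float)
    m = int(np.floor(radius / spacing))
    ax = np.arange(-m, m + 1) * spacing
    # x-fastest: iterate z slowest
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = center + np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    keep = np.linalg.norm(pts - center, axis=1) < radius
    return SourceGrid(pts[keep], spacing, center, radius)


@dataclass
class LeadField:
    """Forward operator: sensors x (grid points * 3 moment components),
    columns grouped per grid point in x, y, z moment order, units
    T per (A m)."""

    matrix: np.ndarray
    grid: SourceGrid
    sensor_labels: list[str]

    def point(self, j: int) -> np.ndarray:
        """n_sensors x 3 lead field of grid point j."""
        return self.matrix[:, 3 * j : 3 * j + 3]

    def save(self, stem: str | Path) -> None:
        stem = Path(stem)
        stem.parent.mkdir(parents=True, exist_ok=True)
        sidecar = {
            "kind": "leadfield",
            "sensor_labels": self.sensor_labels,
            "grid_positions": self.grid.positions.tolist(),
            "spacing": self.grid.spacing,
            "sphere_center": self.grid.sphere_center.tolist(),
            "sphere_radius": self.grid.sphere_radius,
        }
        stem.with_suffix(".json").write_text(
            json.dumps(sidecar, sort_keys=True) + "\n"
        )
        np.save(stem.with_suffix(".npy"), self.matrix)

    @classmethod
    def load(cls, stem: str | Path) -> "LeadField":
        stem = Path(stem)
        sc = json.loads(stem.with_suffix(".json").read_text())
        grid = SourceGrid(
            np.asarray(sc["grid_positions"]), sc["spacing"],
            np.asarray(sc["sphere_center"]), sc["sphere_radius"],
        )
        return cls(np.load(stem.with_suffix(".npy")), grid, sc["sensor_labels"])


def sarvas_field(r0: np.ndarray, q: np.ndarray, sensors: SensorArray,
                 center=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Projected field of one dipole (moment q at r0) at every sensor."""
    center = np.asarray(center, dtype=float)
    r = sensors.positions - center
    r0 = np.asarray(r0, dtype=float) - center
    a_vec = r - r0
    a = np.linalg.norm(a_vec, axis=1)
    R = np.linalg.norm(r, axis=1)
    r0_dot_r = r @ r0
    a_dot_r = np.einsum("ij,ij->i", a_vec, r)
    F = a * (R * a + R**2 - r0_dot_r)
    gF_r = a**2 / R + a_dot_r / a + 2 * a + 2 * R
    gF_r0 = a + 2 * R + a_dot_r / a
    gradF = gF_r[:, None] * r - gF_r0[:, None] * r0[None, :]
    qxr0 = np.cross(q, r0)
    B = MU0_OVER_4PI / F[:, None] ** 2 * (
        F[:, None] * qxr0[None, :] - (r @ qxr0)[:, None] * gradF
    )
    return np.einsum("ij,ij->i", B, sensors.orientations)


def forward_spherical(grid: SourceGrid, sensors: SensorArray) -> LeadField:
    """Sarvas lead field for every grid point and unit x/y/z dipole moment."""
    rel = sensors.positions - grid.sphere_center
    if np.any(np.linalg.norm(rel, axis=1) <= grid.sphere_radius):
        raise ValueError("all sensors must lie outside the conductor sphere")
    eye = np.eye(3)
    L = np.empty((sensors.n_sensors, grid.n_points * 3))
    for j, pos in enumerate(grid.positions):
        if np.allclose(pos, grid.sphere_center):
            L[:, 3 * j : 3 * j + 3] = 0.0  # dipole at center is silent
            continue
        for k in range(3):
            L[:, 3 * j + k] = sarvas_field(pos, eye[k], sensors,
                                           center=grid.sphere_center)
    return LeadField(L, grid, list(sensors.labels))


@dataclass
class CovEstimate:
    """Regularized sensor covariance C + lam * I with the pre-regularization
    numerical rank."""

    C: np.ndarray
    rank: int
    lam: float


def estimate_covariance(data: np.ndarray, lam_frac: float = 0.05) -> CovEstimate:
    """Sample covariance regularized by lam_frac times the mean eigenvalue.

    ``data`` is channels x samples (or trials x channels x samples, pooled
    over trials after per-trial demeaning).
    """
    data = np.asarray(data, dtype=np.float64)
    if data.ndim == 3:
        data = np.concatenate(
            [d - d.mean(axis=1, keepdims=True) for d in data], axis=1
        )
    if data.ndim != 2 or data.shape[1] == 0:
        raise ValueError("need channels x samples data with > 0 samples")
    if lam_frac < 0:
        raise ValueError("lam_frac must be >= 0")
    x = data - data.mean(axis=1, keepdims=True)
    C = x @ x.T / max(data.shape[1] - 1, 1)
    ev = np.linalg.eigvalsh(C)
    tol = ev.max() * max(C.shape) * np.finfo(float).eps
    rank = int((ev > tol).sum())
    lam = lam_frac * ev.mean()
    return CovEstimate(C + lam * np.eye(C.shape[0]), rank, lam)


@dataclass
class BeamformerWeights:
    """Scalar LCMV weights (n_grid x n_sensors) and the chosen unit source
    orientation per grid point."""

    W: np.ndarray
    orientation: np.ndarray
    lam: float
    grid: SourceGrid


def lcmv_weights(
    L: LeadField, cov: CovEstimate, rank_tol: float = 1e-6
) -> BeamformerWeights:
    """Scalar LCMV beamformer over the whole grid.

    Per grid point the local lead field is rank-reduced (singular values
    below ``rank_tol`` of the largest are discarded — for a spherical
    conductor this removes the silent radial direction) and the orientation
    minimizing l_u^T C^-1 l_u within the retained space is selected, which
    maximizes the unit-gain output power 1 / (l_u^T C^-1 l_u).
    """
    C = cov.C
    try:
        Cinv = np.linalg.inv(C)
    except np.linalg.LinAlgError as err:
        raise ValueError(
            "covariance is singular; re-estimate with lam_frac > 0"
        ) from err
    cond = np.linalg.cond(C)
    if cond > 1e12:
        raise ValueError(
            f"covariance numerically singular (cond={cond:.2e}); "
            "re-estimate with a larger lam_frac"
        )
    n_grid = L.grid.n_points
    W = np.zeros((n_grid, C.shape[0]))
    ori = np.zeros((n_grid, 3))
    for j in range(n_grid):
        Lj = L.point(j)
        U, s, _ = np.linalg.svd(Lj, full_matrices=False)
        keep = s > rank_tol * s[0] if s[0] > 0 else np.zeros(3, bool)
        if not keep.any():
            continue  # silent point (e.g. sphere center): zero weights
        # orientation restricted to the span of non-silent moment directions
        Q, _ = np.linalg.qr(Lj.T @ U[:, keep])
        Mred = Q.T @ (Lj.T @ Cinv @ Lj) @ Q
        _, w_evec = np.linalg.eigh(Mred)
        u = Q @ w_evec[:, 0]
        u /= np.linalg.norm(u)
        # deterministic sign: largest-magnitude component positive
        k = int(np.argmax(np.abs(u)))
        if u[k] < 0:
            u = -u
        l = Lj @ u
        Cinv_l = Cinv @ l
        denom = l @ Cinv_l
        W[j] = Cinv_l / denom
        ori[j] = u
    return BeamformerWeights(W, ori, cov.lam, L.grid)


def apply_weights(W: BeamformerWeights, data) -> np.ndarray:
    """Project sensor data to source space.

    ``data`` may be channels x samples (returns n_grid x samples) or an
    Epochs-like trials x channels x samples array (returns
    trials x n_grid x samples).
    """
    arr = data.data if hasattr(data, "data") else np.asarray(data)
    if arr.ndim == 2:
        if arr.shape[0] != W.W.shape[1]:
            raise ValueError("channel count does not match weights")
        return W.W @ arr
    if arr.ndim == 3:
        if arr.shape[1] != W.W.shape[1]:
            raise ValueError("channel count does not match weights")
        return np.einsum("gc,tcs->tgs", W.W, arr)
    raise ValueError("data must be 2-D or 3-D")


def power_map(
    W: BeamformerWeights, cov: CovEstimate, kind: str = "nai"
) -> np.ndarray:
    """Per-grid-point output power.

    ``kind='variance'`` is the raw beamformer output variance w^T C w, which
    is depth-biased (it grows toward the sphere center where lead fields
    vanish).  ``kind='nai'`` is the neural activity index
    w^T C w / (sigma^2 w^T w) with sigma^2 the smallest covariance
    eigenvalue — the standard noise normalization used for localization.
    """
    var = np.einsum("gc,cd,gd->g", W.W, cov.C, W.W)
    if kind == "variance":
        return var
    if kind == "nai":
        sigma2 = np.linalg.eigvalsh(cov.C)[0]
        wnorm = np.einsum("gc,gc->g", W.W, W.W)
        out = np.zeros_like(var)
        nz = wnorm > 0
        out[nz] = var[nz] / (sigma2 * wnorm[nz])
        return out
    raise ValueError("kind must be 'variance' or 'nai'")


def localize(W: BeamformerWeights, cov: CovEstimate) -> int:
    """Index of the grid point with the largest noise-normalized power."""
    return int(np.argmax(power_map(W, cov, kind="nai")))
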