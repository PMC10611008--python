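"""Class-augmented constant-velocity Kalman filter for bounding-box tracks.

The dynamical state is the 7-vector (u, v, s, r, du, dv, ds): box center
(u, v), aspect ratio s = w/h, height r, and rates of change for the first
three.  The height r carries no rate term and is propagated as constant.
The class label rides along as an immutable categorical outside the
Gaussian — it has no noise and no dynamics, and it is used upstream to
gate data association.

An alternative "sort" convention is available in which s is the box area
(with a rate term) and r the constant aspect ratio.  The transition matrix
is identical in both conventions; only the box↔observation map and the
noise scaling differ.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import BoundingBox, Detection, from_observation, to_observation

_DIM = 7  # (u, v, s, r, du, dv, ds)


class CovarianceError(ValueError):
    """Raised when a covariance matrix is not symmetric PSD."""


@dataclass(frozen=True)
class NoiseConfig:
    """Noise magnitudes, scaled by the track's box height.

    The position-like components (u, v, r) get standard deviations
    proportional to the current height, the velocity components a smaller
    proportional share; the dimensionless aspect component uses fixed
    absolute magnitudes.  Proportional scaling keeps the filter behaving
    the same for a 40 px fruit and a 400 px one.
    """

    std_weight_position: float = 1.0 / 20.0
    std_weight_velocity: float = 1.0 / 160.0
    aspect_std_initial: float = 0.1
    aspect_std_process: float = 0.01
    aspect_rate_std_initial: float = 1e-2
    aspect_rate_std_process: float = 1e-4
    aspect_std_measurement: float = 0.1


@dataclass(frozen=True)
class KalmanState:
    """Gaussian belief over one track's motion, plus its fixed class."""

    mean: np.ndarray          # shape (7,)
    covariance: np.ndarray    # shape (7, 7), symmetric PSD
    class_label: str


def _check_psd(cov: np.ndarray, tol: float = 1e-8) -> None:
    if not np.allclose(cov, cov.T, atol=1e-6):
        raise CovarianceError("covariance not symmetric")
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals.min() < -tol * max(1.0, eigvals.max()):
        raise CovarianceError(f"covariance not PSD (min eigenvalue {eigvals.min():.3g})")


def _transition_matrix() -> np.ndarray:
    f = np.eye(_DIM)
    f[0, 4] = 1.0  # u += du
    f[1, 5] = 1.0  # v += dv
    f[2, 6] = 1.0  # s += ds; r (index 3) stays constant
    return f


_F = _transition_matrix()
_H = np.eye(4, _DIM)  # observe (u, v, s, r)


class KalmanBoxFilter:
    """Shared predict/correct machinery; states are immutable snapshots."""

    def __init__(self, noise: NoiseConfig | None = None,
                 state_convention: str = "paper") -> None:
        if state_convention not in ("paper", "sort"):
            raise ValueError(f"unknown state_convention: {state_convention!r}")
        self.noise = noise or NoiseConfig()
        self.state_convention = state_convention

    # -- box <-> observation -------------------------------------------------
    def observe(self, box: BoundingBox) -> np.ndarray:
        if self.state_convention == "paper":
            return np.asarray(to_observation(box))
        # sort: s = area (has a rate), r = aspect ratio (constant)
        u, v = box.center
        return np.array([u, v, box.area, box.width / box.height])

    def box_from_mean(self, mean: np.ndarray) -> BoundingBox:
        u, v, s, r = mean[:4]
        if self.state_convention == "paper":
            return from_observation(u, v, max(s, 1e-6), max(r, 1e-6))
        area, aspect = max(s, 1e-6), max(r, 1e-6)
        w = np.sqrt(area * aspect)
        return BoundingBox.from_center(u, v, w, area / w)

    def _scale(self, mean: np.ndarray) -> float:
        """Height-like length scale used to size the noise."""
        if self.state_convention == "paper":
            return max(float(mean[3]), 1.0)
        return max(float(np.sqrt(max(mean[2], 1.0) / max(mean[3], 1e-6))), 1.0)

    # -- filter steps --------------------------------------------------------
    def initiate(self, det: Detection) -> KalmanState:
        n = self.noise
        obs = self.observe(det.box)
        mean = np.zeros(_DIM)
        mean[:4] = obs
        h = self._scale(mean)
        std = np.array([
            2 * n.std_weight_position * h,
            2 * n.std_weight_position * h,
            n.aspect_std_initial if self.state_convention == "paper" else 2 * n.std_weight_position * h ** 2,
            2 * n.std_weight_position * h,
            10 * n.std_weight_velocity * h,
            10 * n.std_weight_velocity * h,
            n.aspect_rate_std_initial if self.state_convention == "paper" else 10 * n.std_weight_velocity * h ** 2,
        ])
        return KalmanState(mean=mean, covariance=np.diag(std ** 2),
                           class_label=det.class_label)

    def _process_noise(self, mean: np.ndarray) -> np.ndarray:
        n = self.noise
        h = self._scale(mean)
        std = np.array([
            n.std_weight_position * h,
            n.std_weight_position * h,
            n.aspect_std_process if self.state_convention == "paper" else n.std_weight_position * h ** 2,
            n.std_weight_position * h,
            n.std_weight_velocity * h,
            n.std_weight_velocity * h,
            n.aspect_rate_std_process if self.state_convention == "paper" else n.std_weight_velocity * h ** 2,
        ])
        return np.diag(std ** 2)

    def _measurement_noise(self, mean: np.ndarray) -> np.ndarray:
        n = self.noise
        h = self._scale(mean)
        std = np.array([
            n.std_weight_position * h,
            n.std_weight_position * h,
            n.aspect_std_measurement if self.state_convention == "paper" else n.std_weight_position * h ** 2,
            n.std_weight_position * h,
        ])
        return np.diag(std ** 2)

    def predict(self, state: KalmanState) -> KalmanState:
        _check_psd(state.covariance)
        mean = _F @ state.mean
        cov = _F @ state.covariance @ _F.T + self._process_noise(state.mean)
        cov = (cov + cov.T) / 2.0
        return replace(state, mean=mean, covariance=cov)

    def correct(self, state: KalmanState, det: Detection) -> KalmanState:
        if det.class_label != state.class_label:
            raise RuntimeError(
                f"class mismatch in Kalman correct: track is {state.class_label!r}, "
                f"detection is {det.class_label!r} (gating must happen upstream)"
            )
        z = self.observe(det.box)
        r_mat = self._measurement_noise(state.mean)
        s_mat = _H @ state.covariance @ _H.T + r_mat
        gain = np.linalg.solve(s_mat.T, (_H @ state.covariance.T)).T
        innovation = z - _H @ state.mean
        mean = state.mean + gain @ innovation
        # Joseph form keeps the posterior covariance symmetric PSD
        ikh = np.eye(_DIM) - gain @ _H
        cov = ikh @ state.covariance @ ikh.T + gain @ r_mat @ gain.T
        cov = (cov + cov.T) / 2.0
        # keep the shape components physical
        mean[2] = max(mean[2], 1e-6)
        mean[3] = max(mean[3], 1e-6)
        return replace(state, mean=mean, covariance=cov)


def init_state(det: Detection, kf: KalmanBoxFilter | None = None) -> KalmanState:
    """Initialize a track state from a detection (velocities zero)."""
    return (kf or KalmanBoxFilter()).initiate(det)
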