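"""Unit-gain (LCMV) beamformer source reconstruction.

The sensor data B(t) is modelled as B(t) = L * Q(t) + noise, with L the
leadfield and Q the dipole moments.  For each source n a spatial filter

    W_n = (L_n^T C^-1 L_n)^-1 L_n^T C^-1

is built from the sensor covariance C (computed on band-filtered
concatenated trials, diagonally loaded), giving the reconstructed moment
q_n(t) = W_n B(t).  The filter passes unit gain at the target location
(W_n L_n = 1) while minimizing output variance.

The three-orientation leadfield l_n is first reduced to a single optimal
orientation: beamformer output power along unit orientation u is
1 / (u^T l_n C^-1 l_n^T u), so the power-maximizing u is the eigenvector of
the smallest eigenvalue of the 3x3 matrix l_n C^-1 l_n^T (obtained by SVD /
eigendecomposition).  The reduced leadfield is L_n = u^T l_n with its sign
fixed deterministically (largest-magnitude channel entry positive) — the
sign is irrelevant after rectification but fixing it keeps runs bit
reproducible.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import linalg

from .synthetic import SensorDataset, SourceGrid

logger = logging.getLogger(__name__)

__all__ = [
    "ForwardModel",
    "SensorCovariance",
    "BeamformerWeights",
    "SourceTimeseries",
    "balance_channel_types",
    "compute_covariance",
    "reduce_orientation",
    "compute_weights",
    "apply_weights",
    "rectify",
    "reconstruct",
]


@dataclass
class ForwardModel:
    grid: SourceGrid
    leadfield3: np.ndarray              # (sources, 3, channels)
    leadfield1: np.ndarray | None = None  # (sources, channels) after reduction
    orientations: np.ndarray | None = None  # (sources, 3) retained u


@dataclass
class SensorCovariance:
    matrix: np.ndarray
    lam: float

    def inverse(self) -> np.ndarray:
        try:
            cho = linalg.cho_factor(self.matrix)
        except linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                "sensor covariance is not positive definite; "
                "use diagonal loading (lam > 0)"
            ) from err
        return linalg.cho_solve(cho, np.eye(self.matrix.shape[0]))


@dataclass
class BeamformerWeights:
    W: np.ndarray  # (sources, channels)


@dataclass
class SourceTimeseries:
    q: np.ndarray  # (sources, samples) or (sources, samples, trials)
    sfreq: float
    times: np.ndarray | None = None
    condition_labels: tuple[str, ...] = ()
    absolute_applied: bool = False


def balance_channel_types(
    ds: SensorDataset, leadfield3: np.ndarray
) -> tuple[SensorDataset, np.ndarray]:
    """Scale each channel type (magnetometers / gradiometers) to unit average
    variance; the leadfield is scaled identically so the generative model
    B = L Q stays consistent.  Lets both channel types contribute jointly
    despite different physical units."""
    roles = np.asarray(ds.ch_roles)
    var = ds.data.reshape(ds.n_channels, -1).var(axis=1)
    scale = np.ones(ds.n_channels)
    for role in np.unique(roles):
        sel = roles == role
        mv = var[sel].mean()
        if mv > 0:
            scale[sel] = 1.0 / np.sqrt(mv)
    if ds.is_epoched:
        data = ds.data * scale[:, None, None]
    else:
        data = ds.data * scale[:, None]
    return ds.copy_with(data=data), leadfield3 * scale[None, None, :]


def compute_covariance(ds: SensorDataset, lam: float = 0.05) -> SensorCovariance:
    """Sample covariance over time of the concatenated trials, plus diagonal
    loading ``lam * mean(diag) * I`` (default 5% of mean sensor variance)."""
    if not ds.is_epoched:
        raise ValueError("covariance is computed on epoched (trial) data")
    if ds.n_trials < 2:
        raise ValueError("need at least 2 trials")
    X = ds.data.reshape(ds.n_channels, -1)  # concatenate trials along time
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite sensor data")
    if X.shape[1] <= ds.n_channels:
        warnings.warn(
            "fewer time samples than channels: covariance is rank deficient",
            stacklevel=2,
        )
    C = np.cov(X)
    if lam > 0:
        C = C + lam * np.mean(np.diag(C)) * np.eye(C.shape[0])
    return SensorCovariance(matrix=C, lam=float(lam))


def reduce_orientation(fm: ForwardModel, cov: SensorCovariance) -> ForwardModel:
    """SVD orientation reduction: per source keep the orientation maximizing
    beamformer output power (smallest singular value of l^T C^-1 l)."""
    Cinv = cov.inverse()
    n_src = fm.leadfield3.shape[0]
    L1 = np.empty((n_src, fm.leadfield3.shape[2]))
    U = np.empty((n_src, 3))
    for s in range(n_src):
        l = fm.leadfield3[s]  # (3, channels)
        M = l @ Cinv @ l.T
        if not np.any(M):
            raise ValueError(f"source {s}: zero leadfield (rank 0)")
        # M is symmetric PSD: SVD and eigendecomposition coincide.
        # Restrict to numerically nonzero eigenvalues: a null-space
        # orientation has formally infinite output power but a zero
        # reduced leadfield, which is useless downstream.
        evals, evecs = np.linalg.eigh(M)
        tol = evals[-1] * 1e-12
        k = int(np.argmax(evals > tol))
        u = evecs[:, k]  # smallest nonzero eigenvalue -> maximal output power
        Ln = u @ l
        j = int(np.argmax(np.abs(Ln)))
        if Ln[j] < 0:
            Ln, u = -Ln, -u
        L1[s], U[s] = Ln, u
    return replace(fm, leadfield1=L1, orientations=U)


def compute_weights(fm: ForwardModel, cov: SensorCovariance) -> BeamformerWeights:
    """W_n = (L_n^T C^-1 L_n)^-1 L_n^T C^-1 for every source n."""
    if fm.leadfield1 is None:
        raise ValueError("run reduce_orientation first (leadfield1 missing)")
    Cinv = cov.inverse()
    L = fm.leadfield1  # (sources, channels)
    norms = np.linalg.norm(L, axis=1)
    if np.any(norms == 0):
        bad = int(np.flatnonzero(norms == 0)[0])
        raise ValueError(f"source {bad}: zero reduced leadfield")
    num = L @ Cinv                       # (sources, channels)
    denom = np.einsum("sc,sc->s", num, L)  # L_n^T C^-1 L_n
    W = num / denom[:, None]
    return BeamformerWeights(W=W)


def apply_weights(weights: BeamformerWeights, ds: SensorDataset
                  ) -> SourceTimeseries:
    """q(t) = W B(t), per trial for epoched data; linear in B."""
    W = weights.W
    if W.shape[1] != ds.n_channels:
        raise ValueError(
            f"weights expect {W.shape[1]} channels, data has {ds.n_channels}"
        )
    q = np.tensordot(W, ds.data, axes=([1], [0]))
    return SourceTimeseries(
        q=q, sfreq=ds.sfreq, times=None if ds.times is None else ds.times.copy(),
        condition_labels=ds.condition_labels, absolute_applied=False,
    )


def rectify(src: SourceTimeseries) -> SourceTimeseries:
    """Element-wise absolute value of the reconstructed timeseries (the
    analyses downstream use the absolute strength of the signal)."""
    if src.absolute_applied:
        raise ValueError("rectify already applied")
    return replace(src, q=np.abs(src.q), absolute_applied=True)


def reconstruct(
    ds: SensorDataset, fm: ForwardModel, lam: float = 0.05,
    balance: bool = True, do_rectify: bool = True,
) -> tuple[SourceTimeseries, BeamformerWeights]:
    """Full inverse chain on one epoched dataset: channel balancing ->
    covariance -> orientation reduction -> weights -> source timeseries
    (-> rectification)."""
    lf3 = fm.leadfield3
    if balance:
        ds, lf3 = balance_channel_types(ds, lf3)
    fm_b = ForwardModel(grid=fm.grid, leadfield3=lf3)
    cov = compute_covariance(ds, lam=lam)
    fm_b = reduce_orientation(fm_b, cov)
    w = compute_weights(fm_b, cov)
    src = apply_weights(w, ds)
    if do_rectify:
        src = rectify(src)
    return src, w
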