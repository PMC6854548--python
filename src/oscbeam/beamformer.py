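"""Vectorised LCMV beamforming and noise-normalised power maps.

The vectorised linearly-constrained minimum-variance (LCMV) beamformer
reconstructs activity at a source point with a 3 x channels weight
matrix ``W = (L' C^-1 L)^-1 L' C^-1``, one constrained minimum-variance
filter per orthogonal current direction.  Source power is the trace of
the projected covariance over the three orientations ("summed" over the
three filter outputs), and the Neural Activity Index (NAI) divides it by
the projected noise power so that deep points are not penalised by
noise amplification:

    NAI(p) = tr(W C_active W') / tr(W N W')

Covariance matrices are estimated per condition and/or analysis window
after zero-phase 4th-order Butterworth band-pass filtering, and are
regularised by diagonal loading scaled to the mean diagonal of the
noise covariance estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .forward import LeadField
from .simulate import EpochsSet


@dataclass
class CovarianceEstimate:
    matrix: np.ndarray                  # (ch, ch), tesla^2
    window_ms: tuple[float, float]
    band_hz: tuple[float, float] | None
    n_samples: int
    regularization: float = 0.0         # diagonal load applied, tesla^2

    def __post_init__(self) -> None:
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("covariance must be square")
        scale = np.max(np.abs(m)) or 1.0
        if np.max(np.abs(m - m.T)) > 1e-12 * scale:
            raise ValueError("covariance must be symmetric")


@dataclass
class SpatialFilterEntry:
    weights: np.ndarray                 # (3, ch)
    point: np.ndarray                   # (3,) m
    window_ms: tuple[float, float]
    band_hz: tuple[float, float] | None


@dataclass
class VirtualElectrode:
    """Reconstructed three-orientation source time courses at one point."""

    data: np.ndarray                    # (trials, 3, samples)
    point: np.ndarray
    times_ms: np.ndarray
    sampling_rate: float
    labels: np.ndarray | None = None


@dataclass
class NAIVolume:
    values: np.ndarray                  # (n_points,), dimensionless
    band_hz: tuple[float, float]
    window_ms: tuple[float, float]
    skipped: np.ndarray | None = None   # bool mask of degenerate points


def save_filters(entries: list[SpatialFilterEntry], path) -> None:
    """Serialise spatial-filter entries (weights + metadata) to HDF5."""
    import h5py
    with h5py.File(path, "w") as fh:
        for i, e in enumerate(entries):
            grp = fh.create_group(f"filter_{i:06d}")
            grp.create_dataset("weights", data=e.weights)
            grp.attrs["point_m"] = e.point
            grp.attrs["window_ms"] = e.window_ms
            grp.attrs["band_hz"] = e.band_hz if e.band_hz else (0.0, 0.0)


def load_filters(path) -> list[SpatialFilterEntry]:
    import h5py
    entries = []
    with h5py.File(path, "r") as fh:
        for name in sorted(fh):
            grp = fh[name]
            band = tuple(grp.attrs["band_hz"])
            entries.append(SpatialFilterEntry(
                weights=grp["weights"][()],
                point=np.asarray(grp.attrs["point_m"]),
                window_ms=tuple(grp.attrs["window_ms"]),
                band_hz=None if band == (0.0, 0.0) else band))
    return entries


def bandpass(data: np.ndarray, sampling_rate: float,
             band_hz: tuple[float, float], order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis."""
    lo, hi = band_hz
    nyq = sampling_rate / 2.0
    if not 0 < lo < hi < nyq:
        raise ValueError(f"band {band_hz} must satisfy 0 < lo < hi < {nyq:.1f}")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=sampling_rate,
                        output="sos")
    return signal.sosfiltfilt(sos, data, axis=-1)


def estimate_covariance(epochs: EpochsSet,
                        window_ms: tuple[float, float],
                        band_hz: tuple[float, float] | None = None
                        ) -> CovarianceEstimate:
    """Sample covariance pooled over trials within a time window.

    The whole epoch is band-pass filtered first (avoiding edge effects
    inside the window), then cropped.  No mean removal: the band-pass
    removes the DC component, and zero data must map to a zero matrix.
    """
    t0, t1 = window_ms
    dt = 1000.0 / epochs.sampling_rate
    if (t0 < epochs.times_ms[0] - 1e-9
            or t1 > epochs.times_ms[-1] + dt + 1e-9):  # window is half-open
        raise ValueError(f"window {window_ms} outside epoch "
                         f"[{epochs.times_ms[0]:.1f}, {epochs.times_ms[-1]:.1f}] ms")
    data = epochs.data
    if band_hz is not None:
        data = bandpass(data, epochs.sampling_rate, band_hz)
    mask = (epochs.times_ms >= t0) & (epochs.times_ms < t1)
    n_win = int(np.sum(mask))
    if n_win < 3:
        raise ValueError(f"window {window_ms} spans only {n_win} samples (< 3)")
    seg = data[:, :, mask]                              # (tr, ch, s)
    n_total = seg.shape[0] * n_win
    cov = np.einsum("tcs,tds->cd", seg, seg) / n_total
    cov = 0.5 * (cov + cov.T)
    return CovarianceEstimate(matrix=cov, window_ms=window_ms,
                              band_hz=band_hz, n_samples=n_total)


def identity_noise_covariance(cov: CovarianceEstimate) -> CovarianceEstimate:
    """Alternative noise estimator: identity scaled by the smallest eigenvalue."""
    lam = float(np.min(np.linalg.eigvalsh(cov.matrix)))
    lam = max(lam, 0.0)
    n = cov.matrix.shape[0]
    return CovarianceEstimate(matrix=lam * np.eye(n), window_ms=cov.window_ms,
                              band_hz=cov.band_hz, n_samples=cov.n_samples)


def pool_covariances(a: CovarianceEstimate, b: CovarianceEstimate
                     ) -> CovarianceEstimate:
    """Sample-size-weighted pooling of two covariance estimates."""
    if a.matrix.shape != b.matrix.shape:
        raise ValueError("covariances must have matching shapes")
    n = a.n_samples + b.n_samples
    pooled = (a.matrix * a.n_samples + b.matrix * b.n_samples) / n
    return CovarianceEstimate(matrix=pooled,
                              window_ms=(min(a.window_ms[0], b.window_ms[0]),
                                         max(a.window_ms[1], b.window_ms[1])),
                              band_hz=a.band_hz, n_samples=n)


def regularize(cov: CovarianceEstimate, noise_cov: CovarianceEstimate,
               lambda_rel: float = 0.05) -> CovarianceEstimate:
    """Diagonal loading: C + lambda_rel * mean(diag(N)) * I."""
    if lambda_rel < 0:
        raise ValueError("lambda_rel must be >= 0")
    load = lambda_rel * float(np.mean(np.diag(noise_cov.matrix)))
    n = cov.matrix.shape[0]
    return CovarianceEstimate(matrix=cov.matrix + load * np.eye(n),
                              window_ms=cov.window_ms, band_hz=cov.band_hz,
                              n_samples=cov.n_samples,
                              regularization=load)


def _truncated_inverse(M: np.ndarray, rcond: float) -> tuple[np.ndarray, int]:
    """Eigen-inverse of a symmetric PSD matrix, truncating tiny eigenvalues."""
    lam, V = np.linalg.eigh(M)
    keep = lam > rcond * np.max(lam)
    inv = np.zeros_like(lam)
    inv[keep] = 1.0 / lam[keep]
    return (V * inv) @ V.T, int(np.sum(keep))


def lcmv_weights(leadfield_point: np.ndarray, cov: CovarianceEstimate,
                 rcond: float = 1e-10) -> np.ndarray:
    """Constrained minimum-variance weights for one point; W is 3 x channels.

    W = (L' C^-1 L)^+ L' C^-1.  In a spherical conductor the radial
    source direction is externally silent, so the 3 x 3 Gram matrix
    L' C^-1 L has rank 2 at every point; the truncated eigen-inverse
    keeps the detectable source subspace (silent directions get zero
    weights) and reduces to the exact inverse for full-rank lead
    fields, where W L = I3 holds to machine precision.
    """
    L = np.asarray(leadfield_point, dtype=float)
    if L.ndim != 2 or L.shape[1] != 3:
        raise ValueError("lead field at a point must be channels x 3")
    Ci_L = np.linalg.solve(cov.matrix, L)               # C^-1 L
    M = L.T @ Ci_L                                      # (3, 3)
    M_inv, rank = _truncated_inverse(M, rcond)
    if rank < 2:
        lam = np.linalg.eigvalsh(M)
        raise np.linalg.LinAlgError(
            f"L' C^-1 L has effective rank {rank} < 2 "
            f"(eigenvalues {lam}, condition number "
            f"{np.max(lam) / max(np.min(np.abs(lam)), 1e-300):.3g})")
    return M_inv @ Ci_L.T                               # (3, ch)


def virtual_electrode(filter_entry: SpatialFilterEntry | np.ndarray,
                      epochs: EpochsSet) -> VirtualElectrode:
    """Apply a point's weights to every trial: (trials, 3, samples)."""
    W = (filter_entry.weights if isinstance(filter_entry, SpatialFilterEntry)
         else np.asarray(filter_entry))
    if W.shape != (3, epochs.n_channels):
        raise ValueError(
            f"weights shape {W.shape} does not match {epochs.n_channels} channels")
    data = np.einsum("oc,tcs->tos", W, epochs.data)
    point = (filter_entry.point if isinstance(filter_entry, SpatialFilterEntry)
             else np.full(3, np.nan))
    return VirtualElectrode(data=data, point=point, times_ms=epochs.times_ms,
                            sampling_rate=epochs.sampling_rate,
                            labels=epochs.labels)


def _batched_weights(L_all: np.ndarray, cov_matrix: np.ndarray,
                     rcond: float = 1e-10
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised lcmv_weights over points (same truncated eigen-inverse).

    Returns (weights (m, 3, ch), degenerate mask (m,)); points whose
    Gram matrix has effective rank < 2 get zero weights and are flagged.
    """
    m, ch, _ = L_all.shape
    Ci_L = np.linalg.solve(cov_matrix,
                           L_all.transpose(1, 0, 2).reshape(ch, -1))
    Ci_L = Ci_L.reshape(ch, m, 3).transpose(1, 0, 2)    # (m, ch, 3)
    M = np.einsum("mck,mcl->mkl", L_all, Ci_L)          # (m, 3, 3)
    lam, V = np.linalg.eigh(M)                          # (m, 3), (m, 3, 3)
    lam_max = lam[:, -1]
    degenerate = ~(lam_max > 0)
    keep = lam > rcond * np.where(lam_max > 0, lam_max, 1.0)[:, None]
    degenerate |= keep.sum(axis=1) < 2
    inv = np.zeros_like(lam)
    np.divide(1.0, lam, out=inv, where=keep)
    M_inv = np.einsum("mik,mk,mjk->mij", V, inv, V)
    W = np.einsum("mij,mcj->mic", M_inv, Ci_L)          # (m, 3, ch)
    W[degenerate] = 0.0
    return W, degenerate


def nai_volume(epochs: EpochsSet, leadfield: LeadField,
               band_hz: tuple[float, float],
               active_window_ms: tuple[float, float],
               noise_cov: CovarianceEstimate,
               lambda_rel: float = 0.05,
               data_cov: CovarianceEstimate | None = None,
               weights_cov: CovarianceEstimate | None = None) -> NAIVolume:
    """Noise-normalised total-power map over the lattice.

    Weights come from the regularised active-window covariance by
    default; ``weights_cov`` substitutes another covariance (e.g. one
    pooled over the two windows of a contrast, so both maps share
    weights).  The NAI numerator uses the unregularised window
    covariance so that data identical to noise gives exactly 1.
    ``data_cov`` short-circuits the estimation step when the caller has
    already computed it.
    """
    if data_cov is None:
        data_cov = estimate_covariance(epochs, active_window_ms, band_hz)
    reg = regularize(weights_cov if weights_cov is not None else data_cov,
                     noise_cov, lambda_rel)
    W, degenerate = _batched_weights(leadfield.matrices, reg.matrix)
    num = np.einsum("moc,cd,mod->m", W, data_cov.matrix, W)
    den = np.einsum("moc,cd,mod->m", W, noise_cov.matrix, W)
    values = np.zeros(leadfield.matrices.shape[0])
    ok = ~degenerate & (den > 0)
    values[ok] = num[ok] / den[ok]
    return NAIVolume(values=values, band_hz=band_hz,
                     window_ms=active_window_ms,
                     skipped=degenerate | (den <= 0))
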