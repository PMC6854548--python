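"""Stockwell-transform time-frequency analysis of virtual electrodes.

The S-transform is a time-frequency decomposition with a Gaussian
window whose width scales inversely with frequency (sigma_t = 1/f), so
low frequencies get good spectral resolution and high frequencies good
temporal resolution while absolute phase is preserved.  The discrete
transform is computed in the frequency domain:

    S[tau, n] = sum_m H[m + n] exp(-2 pi^2 m^2 / n^2) exp(2 pi i m tau / N)

with H the DFT of the signal normalised by 1/N, so the time average of
S(tau, f) over tau equals the Fourier coefficient H(f) exactly — the
identity the unit tests lean on.  A unit-amplitude cosine therefore has
|S| ~ 0.5 at its frequency.

Evoked power transforms the trial average (phase-locked content only);
total power averages single-trial power (evoked + induced).  Power is
summed over the three virtual-electrode orientations, normalised per
frequency bin to percent signal change against a pre-trial baseline,
and finally averaged into 25 ms x 2 Hz tiles for the tile statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_F_RANGE_HZ = (5.0, 50.0)
DEFAULT_BASELINE_MS = (-700.0, -500.0)
DEFAULT_TILE_MS = 25.0
DEFAULT_TILE_HZ = 2.0


@dataclass
class STransformMap:
    coeffs: np.ndarray          # (n_freqs, n_samples), complex
    freqs_hz: np.ndarray
    times_ms: np.ndarray
    sampling_rate: float


@dataclass
class TFPowerMap:
    power: np.ndarray           # (n_freqs, n_samples)
    freqs_hz: np.ndarray
    times_ms: np.ndarray
    mode: str                   # "evoked" | "total"
    baseline_ms: tuple[float, float] | None = None
    participant_id: str | None = None

    def __post_init__(self) -> None:
        if self.baseline_ms is None and np.any(self.power < 0):
            raise ValueError("raw power must be >= 0")


@dataclass
class TileGrid:
    """Values on the time x frequency tile lattice (half-open tiles)."""

    values: np.ndarray          # (n_time_tiles, n_freq_tiles)
    time_edges_ms: np.ndarray   # lower edges
    freq_edges_hz: np.ndarray   # lower edges
    tile_ms: float = DEFAULT_TILE_MS
    tile_hz: float = DEFAULT_TILE_HZ

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("tile grid contains non-finite values")


def tile_grid_to_tsv(grid: TileGrid, path, value_name: str = "value",
                     header_meta: dict | None = None) -> None:
    """Long-format TSV: time_ms (lower edge), freq_hz (lower edge), value."""
    with open(path, "w") as fh:
        for k, v in (header_meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        fh.write(f"time_ms\tfreq_hz\t{value_name}\n")
        for i, te in enumerate(grid.time_edges_ms):
            for j, fe in enumerate(grid.freq_edges_hz):
                fh.write(f"{te:g}\t{fe:g}\t{grid.values[i, j]:.10g}\n")


def tile_grid_to_hdf5(grid: TileGrid, path) -> None:
    import h5py
    with h5py.File(path, "w") as fh:
        fh.create_dataset("values", data=grid.values)
        fh.create_dataset("time_edges_ms", data=grid.time_edges_ms)
        fh.create_dataset("freq_edges_hz", data=grid.freq_edges_hz)
        fh.attrs["tile_ms"] = grid.tile_ms
        fh.attrs["tile_hz"] = grid.tile_hz


def tile_grid_from_hdf5(path) -> TileGrid:
    import h5py
    with h5py.File(path, "r") as fh:
        return TileGrid(values=fh["values"][()],
                        time_edges_ms=fh["time_edges_ms"][()],
                        freq_edges_hz=fh["freq_edges_hz"][()],
                        tile_ms=float(fh.attrs["tile_ms"]),
                        tile_hz=float(fh.attrs["tile_hz"]))


def stockwell(x: np.ndarray, sampling_rate: float,
              f_range_hz: tuple[float, float] = DEFAULT_F_RANGE_HZ,
              times_ms: np.ndarray | None = None) -> STransformMap:
    """Discrete S-transform of one time course (FFT formulation)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("stockwell expects a single time course")
    N = x.size
    if N < 8:
        raise ValueError("signal must have >= 8 samples")
    lo, hi = f_range_hz
    nyq = sampling_rate / 2.0
    if not 0 < lo <= hi < nyq:
        raise ValueError(f"f_range {f_range_hz} must lie in (0, {nyq:.1f}) Hz")

    H = np.fft.fft(x) / N
    df = sampling_rate / N
    n_lo = int(np.ceil(lo / df))
    n_hi = int(np.floor(hi / df))
    n_idx = np.arange(max(n_lo, 1), n_hi + 1)

    m = np.arange(N)
    m_signed = ((m + N // 2) % N) - N // 2
    coeffs = np.empty((n_idx.size, N), dtype=complex)
    for row, n in enumerate(n_idx):
        gauss = np.exp(-2.0 * np.pi ** 2 * m_signed ** 2 / n ** 2)
        coeffs[row] = np.fft.ifft(np.roll(H, -n) * gauss) * N
    if times_ms is None:
        times_ms = np.arange(N) * 1000.0 / sampling_rate
    return STransformMap(coeffs=coeffs, freqs_hz=n_idx * df,
                         times_ms=np.asarray(times_ms, dtype=float),
                         sampling_rate=sampling_rate)


def _ve_data(ve) -> tuple[np.ndarray, float, np.ndarray]:
    """Accept a VirtualElectrode or a raw (trials, 3, samples) array."""
    if hasattr(ve, "data"):
        return ve.data, ve.sampling_rate, ve.times_ms
    raise TypeError("expected a VirtualElectrode (with .data/.sampling_rate)")


def evoked_power(ve, f_range_hz: tuple[float, float] = DEFAULT_F_RANGE_HZ,
                 participant_id: str | None = None) -> TFPowerMap:
    """Power of the trial average: phase-locked (evoked) content only.

    Trials are averaged first, each orientation is transformed, and the
    squared magnitudes are summed over the three orientations.
    """
    data, fs, times = _ve_data(ve)
    if data.shape[0] < 1:
        raise ValueError("need >= 1 trial")
    avg = data.mean(axis=0)                             # (3, samples)
    power = None
    for o in range(avg.shape[0]):
        st = stockwell(avg[o], fs, f_range_hz, times)
        p = np.abs(st.coeffs) ** 2
        power = p if power is None else power + p
        freqs = st.freqs_hz
    return TFPowerMap(power=power, freqs_hz=freqs, times_ms=times,
                      mode="evoked", participant_id=participant_id)


def total_power(ve, f_range_hz: tuple[float, float] = DEFAULT_F_RANGE_HZ,
                participant_id: str | None = None) -> TFPowerMap:
    """Mean single-trial power: evoked plus induced (non-phase-locked)."""
    data, fs, times = _ve_data(ve)
    n_trials = data.shape[0]
    if n_trials < 1:
        raise ValueError("need >= 1 trial")
    power = None
    for tr in range(n_trials):
        for o in range(data.shape[1]):
            st = stockwell(data[tr, o], fs, f_range_hz, times)
            p = np.abs(st.coeffs) ** 2
            power = p if power is None else power + p
            freqs = st.freqs_hz
    return TFPowerMap(power=power / n_trials, freqs_hz=freqs, times_ms=times,
                      mode="total", participant_id=participant_id)


def baseline_vector(tf: TFPowerMap,
                    baseline_ms: tuple[float, float] = DEFAULT_BASELINE_MS
                    ) -> np.ndarray:
    """Mean power per frequency bin over the baseline window."""
    t0, t1 = baseline_ms
    mask = (tf.times_ms >= t0) & (tf.times_ms < t1)
    if not np.any(mask):
        raise ValueError(f"baseline {baseline_ms} ms outside the map's time axis")
    return tf.power[:, mask].mean(axis=1)


def baseline_normalize(tf: TFPowerMap,
                       baseline_ms: tuple[float, float] = DEFAULT_BASELINE_MS,
                       baseline_values: np.ndarray | None = None
                       ) -> TFPowerMap:
    """Percent signal change against the per-frequency baseline mean.

    ``baseline_values`` substitutes an externally pooled baseline (e.g.
    averaged across the conditions entering a contrast, so that baseline
    estimation error cancels in condition differences).
    """
    base = (baseline_vector(tf, baseline_ms) if baseline_values is None
            else np.asarray(baseline_values, dtype=float))
    if base.shape != (tf.power.shape[0],):
        raise ValueError("baseline_values must give one value per frequency bin")
    bad = base <= 0
    if np.any(bad):
        f = tf.freqs_hz[np.argmax(bad)]
        raise ValueError(f"zero baseline power at {f:.2f} Hz")
    change = 100.0 * (tf.power - base[:, None]) / base[:, None]
    return TFPowerMap(power=change, freqs_hz=tf.freqs_hz, times_ms=tf.times_ms,
                      mode=tf.mode, baseline_ms=baseline_ms,
                      participant_id=tf.participant_id)


def resample_tiles(tf: TFPowerMap,
                   t_range_ms: tuple[float, float] = (-800.0, 700.0),
                   f_range_hz: tuple[float, float] = DEFAULT_F_RANGE_HZ,
                   tile_ms: float = DEFAULT_TILE_MS,
                   tile_hz: float = DEFAULT_TILE_HZ) -> TileGrid:
    """Average the native-resolution map into half-open 25 ms x 2 Hz tiles.

    Under the defaults (-800..700 ms, 5..50 Hz) the grid is 60 x 23
    (time tiles x frequency tiles), lower-edge labelled.
    """
    t_edges = np.arange(t_range_ms[0], t_range_ms[1], tile_ms)
    f_edges = np.arange(f_range_hz[0], f_range_hz[1], tile_hz)
    t_masks, f_masks = [], []
    for te in t_edges:
        mask = (tf.times_ms >= te) & (tf.times_ms < te + tile_ms)
        if not np.any(mask):
            raise ValueError(f"no native samples in tile starting {te} ms")
        t_masks.append(mask)
    for fe in f_edges:
        mask = (tf.freqs_hz >= fe) & (tf.freqs_hz < fe + tile_hz)
        if not np.any(mask):
            raise ValueError(f"no native bins in tile starting {fe} Hz")
        f_masks.append(mask)
    values = np.empty((t_edges.size, f_edges.size))
    for j, f_mask in enumerate(f_masks):
        band_mean = tf.power[f_mask].mean(axis=0)
        for i, t_mask in enumerate(t_masks):
            values[i, j] = band_mean[t_mask].mean()
    return TileGrid(values=values, time_edges_ms=t_edges, freq_edges_hz=f_edges,
                    tile_ms=tile_ms, tile_hz=tile_hz)
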