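"""Whole-brain active-vs-passive contrasts with permutation FWER control.

Per lattice point, a paired t statistic compares active- and
passive-window NAI maps across participants.  Family-wise error is
controlled with the permutation maximum statistic: under the null the
active/passive labels are exchangeable within participant, so each
permutation flips the labels (equivalently the sign of each
participant's difference map) and records the maximum |t| over all
points; the observed map is thresholded at the top-alpha quantile of
those maxima.

Default windows and bands: active {0-200, 200-400, 400-600} ms against
passive -700..-500 ms, in bands {5-15, 15-25, 25-35, 35-50} Hz.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

DEFAULT_ACTIVE_WINDOWS_MS = ((0.0, 200.0), (200.0, 400.0), (400.0, 600.0))
DEFAULT_PASSIVE_WINDOW_MS = (-700.0, -500.0)
DEFAULT_BANDS_HZ = ((5.0, 15.0), (15.0, 25.0), (25.0, 35.0), (35.0, 50.0))


@dataclass
class TMap:
    t: np.ndarray                   # (n_points,)
    df: int
    labels: tuple[str, str]         # (active, passive) descriptions
    zero_variance: np.ndarray       # bool flag per point


@dataclass
class PermutationNull:
    max_abs_t: np.ndarray           # (n_permutations,)
    threshold: float
    quantile: float                 # tail mass, e.g. 0.05 for "top 5%"
    seed: int | None
    mode: str

    def __post_init__(self) -> None:
        if len(self.max_abs_t) < 1:
            raise ValueError("empty permutation distribution")


def _paired_t(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised paired t over axis 0; zero-variance points get t = 0."""
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    zero_var = sd == 0
    t = np.zeros_like(mean)
    np.divide(mean, sd / np.sqrt(n), out=t, where=~zero_var)
    return t, zero_var


def active_passive_tmap(active: np.ndarray, passive: np.ndarray,
                        labels: tuple[str, str] = ("active", "passive")
                        ) -> TMap:
    """Paired t per point across participants (rows are participants)."""
    active = np.asarray(active, dtype=float)
    passive = np.asarray(passive, dtype=float)
    if active.shape != passive.shape:
        raise ValueError("active and passive maps must share the lattice")
    if active.ndim != 2 or active.shape[0] < 2:
        raise ValueError("need >= 2 participants (rows)")
    t, zero_var = _paired_t(active - passive)
    return TMap(t=t, df=active.shape[0] - 1, labels=labels,
                zero_variance=zero_var)


def permutation_threshold(active: np.ndarray, passive: np.ndarray,
                          n_permutations: int = 10000,
                          quantile: float = 0.05,
                          seed: int | None = 0,
                          mode: str = "whole_map",
                          exhaustive: bool = False,
                          two_sided: bool = True,
                          ) -> tuple[PermutationNull, TMap, np.ndarray]:
    """Maximum-statistic threshold for the active-vs-passive contrast.

    mode="whole_map" flips each participant's entire difference map (the
    standard choice: it preserves spatial covariance); mode="per_point"
    flips independently at every point.  ``exhaustive=True`` enumerates
    all 2^n sign patterns instead of sampling (whole_map only).

    Returns (null, observed TMap, survivor mask with |t| >= threshold).
    """
    if mode not in ("whole_map", "per_point"):
        raise ValueError(f"unknown mode {mode!r}")
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must be in (0, 1)")
    active = np.asarray(active, dtype=float)
    passive = np.asarray(passive, dtype=float)
    if active.shape != passive.shape:
        raise ValueError("active and passive maps must share the lattice")
    n, m = active.shape
    if n < 2:
        raise ValueError("need >= 2 participants")
    if not exhaustive and n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")

    diffs = active - passive
    tmap = active_passive_tmap(active, passive)
    stat = np.abs if two_sided else (lambda x: x)

    if exhaustive:
        if mode != "whole_map":
            raise ValueError("exhaustive enumeration requires whole_map mode")
        signs = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
    else:
        rng = np.random.default_rng(seed)
        if mode == "whole_map":
            signs = rng.choice((1.0, -1.0), size=(n_permutations, n))
        else:
            signs = rng.choice((1.0, -1.0), size=(n_permutations, n, m))

    if mode == "whole_map":
        flipped = signs[:, :, None] * diffs[None, :, :]
    else:
        flipped = signs * diffs[None, :, :]
    # paired t for every permutation at once
    mean = flipped.mean(axis=1)
    sd = flipped.std(axis=1, ddof=1)
    t_perm = np.zeros_like(mean)
    np.divide(mean, sd / np.sqrt(n), out=t_perm, where=sd > 0)
    max_stat = stat(t_perm).max(axis=1)

    threshold = float(np.quantile(max_stat, 1.0 - quantile))
    # zero-variance points carry t = 0 by convention and never survive
    survivors = (stat(tmap.t) >= threshold) & ~tmap.zero_variance
    null = PermutationNull(max_abs_t=max_stat, threshold=threshold,
                           quantile=quantile,
                           seed=None if exhaustive else seed, mode=mode)
    return null, tmap, survivors
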