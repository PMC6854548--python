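"""Condition contrasts on time-frequency tiles with cluster-extent control.

A tile is declared significant under two simultaneous criteria: (a) the
paired condition difference reaches p < .05, and (b) at least one of the
two contributing conditions departs from baseline at p < .01.  Because
the per-site models are not corrected across points of interest and
contrasts, a cluster-size correction is added: under the null hypothesis
the significant tiles are assumed to be scattered uniformly over the
time-frequency grid, and a Monte-Carlo simulation of random fills at the
observed fill rate gives the distribution of the largest contiguous
cluster, from which the minimal reportable cluster size at a
Bonferroni-adjusted alpha (default .05 across 12 analyses: 4 sites x 3
contrasts) is read off.

All threshold comparisons are strict inequalities.  Contiguity defaults
to edge adjacency (4-connectivity); 8-connectivity is available and is
recorded in every result.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import ndimage, stats

CONTRASTS = (("taxonomic", "thematic_strong"),
             ("taxonomic", "thematic_weak"),
             ("thematic_strong", "thematic_weak"))


@dataclass
class TileTestResult:
    mean_diff: np.ndarray       # A - B participant mean per tile
    t_diff: np.ndarray
    p_diff: np.ndarray          # adjusted when adjust="maxstat"
    p_base_a: np.ndarray        # one-sample vs 0 %-change
    p_base_b: np.ndarray
    n_participants: int
    p_diff_raw: np.ndarray | None = None
    adjust: str = "none"

    @property
    def df(self) -> int:
        return self.n_participants - 1


@dataclass
class StatContourMask:
    retained: np.ndarray        # bool, tiles surviving all three criteria
    cluster_ids: np.ndarray     # int labels on retained tiles, 0 elsewhere
    dashed: np.ndarray          # bool, dual-criteria tiles in sub-size clusters
    alpha_diff: float
    alpha_base: float
    min_cluster_size: int
    connectivity: int


@dataclass
class ClusterNullDistribution:
    grid_shape: tuple[int, int]
    fill_rate: float
    connectivity: int
    n_simulations: int
    probabilities: np.ndarray   # P(max cluster size == k), k = 0..n_tiles
    seed: int | None
    exact: bool = False

    def tail_probability(self, k: int) -> float:
        """P(max cluster size >= k)."""
        if k <= 0:
            return 1.0
        if k >= self.probabilities.size:
            return 0.0
        return float(self.probabilities[k:].sum())


def _t_one_and_paired(a: np.ndarray, b: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Paired t and two-sided p over axis 0, zero-variance-safe (t=0, p=1)."""
    d = a - b
    n = d.shape[0]
    sd = d.std(axis=0, ddof=1)
    mean = d.mean(axis=0)
    t = np.zeros_like(mean)
    np.divide(mean, sd / np.sqrt(n), out=t, where=sd > 0)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    p[sd == 0] = 1.0
    return t, p


def _maxstat_adjusted_p(diffs: np.ndarray, t_obs: np.ndarray,
                        n_permutations: int, seed: int | None) -> np.ndarray:
    """Single-step sign-flip max-|t| adjusted p-values over all tiles."""
    n = diffs.shape[0]
    flat = diffs.reshape(n, -1)
    rng = np.random.default_rng(seed)
    signs = rng.choice((1.0, -1.0), size=(n_permutations, n))
    flipped = signs[:, :, None] * flat[None]
    mean = flipped.mean(axis=1)
    sd = flipped.std(axis=1, ddof=1)
    t_perm = np.zeros_like(mean)
    np.divide(mean, sd / np.sqrt(n), out=t_perm, where=sd > 0)
    max_abs = np.abs(t_perm).max(axis=1)
    exceed = (max_abs[:, None] >= np.abs(t_obs).ravel()[None, :]).sum(axis=0)
    return ((1.0 + exceed) / (n_permutations + 1.0)).reshape(t_obs.shape)


def tile_condition_test(grids_a: np.ndarray, grids_b: np.ndarray,
                        adjust: str = "none",
                        n_permutations: int = 1000,
                        seed: int | None = 0) -> TileTestResult:
    """Per-tile paired test A vs B plus one-sample baseline tests.

    ``grids_a``/``grids_b`` stack per-participant tile grids (percent
    signal change) as (n_participants, n_time_tiles, n_freq_tiles).

    ``adjust="maxstat"`` replaces the raw difference p-values with
    sign-flip maximum-statistic adjusted ones, controlling the
    experiment-wise error over tiles within this analysis while
    respecting the spatial correlation of the time-frequency field (the
    original per-site models carried their own multiplicity control;
    raw per-tile p's on a smooth field would not).
    """
    grids_a = np.asarray(grids_a, dtype=float)
    grids_b = np.asarray(grids_b, dtype=float)
    if grids_a.shape != grids_b.shape:
        raise ValueError("condition grids must have identical shapes")
    if grids_a.ndim != 3 or grids_a.shape[0] < 3:
        raise ValueError("need >= 3 participants of (time, freq) grids")
    if adjust not in ("none", "maxstat"):
        raise ValueError(f"unknown adjust mode {adjust!r}")
    t_diff, p_raw = _t_one_and_paired(grids_a, grids_b)
    _, p_base_a = _t_one_and_paired(grids_a, np.zeros_like(grids_a))
    _, p_base_b = _t_one_and_paired(grids_b, np.zeros_like(grids_b))
    if adjust == "maxstat":
        p_diff = _maxstat_adjusted_p(grids_a - grids_b, t_diff,
                                     n_permutations, seed)
    else:
        p_diff = p_raw
    return TileTestResult(mean_diff=(grids_a - grids_b).mean(axis=0),
                          t_diff=t_diff, p_diff=p_diff,
                          p_base_a=p_base_a, p_base_b=p_base_b,
                          n_participants=grids_a.shape[0],
                          p_diff_raw=p_raw, adjust=adjust)


def dual_criteria_mask(result: TileTestResult, alpha_diff: float = 0.05,
                       alpha_base: float = 0.01) -> np.ndarray:
    """Tiles with p_diff < alpha_diff AND a baseline departure < alpha_base."""
    if not (0 < alpha_diff < 1 and 0 < alpha_base < 1):
        raise ValueError("alpha thresholds must be in (0, 1)")
    return ((result.p_diff < alpha_diff)
            & ((result.p_base_a < alpha_base)
               | (result.p_base_b < alpha_base)))


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 4:
        return np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
    if connectivity == 8:
        return np.ones((3, 3), dtype=bool)
    raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")


def label_clusters(mask: np.ndarray, connectivity: int = 4
                   ) -> tuple[np.ndarray, dict[int, int]]:
    """Connected components of a boolean grid; ids in scan order.

    Returns (label grid with 0 for background, {id: size}).
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=_structure(connectivity))
    # scipy assigns labels in raster-scan order of first occurrence already;
    # normalise anyway so the contract is explicit
    order = []
    seen = set()
    for lab in labels.ravel():
        if lab and lab not in seen:
            seen.add(lab)
            order.append(lab)
    remap = {old: new + 1 for new, old in enumerate(order)}
    out = np.zeros_like(labels)
    for old, new in remap.items():
        out[labels == old] = new
    sizes = {new: int(np.sum(out == new)) for new in range(1, n + 1)}
    return out, sizes


def _max_cluster_size(flat_idx: np.ndarray, shape: tuple[int, int],
                      structure: np.ndarray) -> int:
    mask = np.zeros(shape, dtype=bool)
    mask.ravel()[flat_idx] = True
    labels, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return 0
    return int(np.bincount(labels.ravel())[1:].max())


def cluster_null(grid_shape: tuple[int, int], fill_rate: float,
                 connectivity: int = 4, n_simulations: int = 10000,
                 seed: int | None = 0, exact: bool = False,
                 exact_limit: int = 500_000) -> ClusterNullDistribution:
    """Null distribution of the largest cluster under uniform random fill.

    Each draw places round(fill_rate * n_tiles) significant tiles
    uniformly without replacement and records the maximal contiguous
    cluster size.  ``exact=True`` enumerates every placement instead
    (feasible for small grids; guarded by ``exact_limit``).
    """
    if not 0.0 <= fill_rate <= 1.0:
        raise ValueError("fill_rate must be in [0, 1]")
    n_tiles = int(np.prod(grid_shape))
    n_fill = int(round(fill_rate * n_tiles))
    structure = _structure(connectivity)
    counts = np.zeros(n_tiles + 1)

    if exact:
        total = comb(n_tiles, n_fill)
        if total > exact_limit:
            raise ValueError(
                f"exact enumeration would need {total} placements "
                f"(> {exact_limit}); use Monte Carlo")
        for combo in itertools.combinations(range(n_tiles), n_fill):
            counts[_max_cluster_size(np.array(combo, dtype=int),
                                     grid_shape, structure)] += 1
        probs = counts / total
        return ClusterNullDistribution(grid_shape=tuple(grid_shape),
                                       fill_rate=fill_rate,
                                       connectivity=connectivity,
                                       n_simulations=total,
                                       probabilities=probs, seed=None,
                                       exact=True)

    if n_simulations < 100:
        raise ValueError("n_simulations must be >= 100")
    rng = np.random.default_rng(seed)
    for _ in range(n_simulations):
        idx = rng.choice(n_tiles, size=n_fill, replace=False)
        counts[_max_cluster_size(idx, grid_shape, structure)] += 1
    return ClusterNullDistribution(grid_shape=tuple(grid_shape),
                                   fill_rate=fill_rate,
                                   connectivity=connectivity,
                                   n_simulations=n_simulations,
                                   probabilities=counts / n_simulations,
                                   seed=seed)


def min_cluster_size(null: ClusterNullDistribution, alpha: float = 0.05,
                     n_analyses: int = 12) -> int:
    """Smallest k with P(max cluster >= k) < alpha / n_analyses."""
    if not 0 < alpha < 1 or n_analyses < 1:
        raise ValueError("alpha in (0,1) and n_analyses >= 1 required")
    bound = alpha / n_analyses
    for k in range(null.probabilities.size + 1):
        if null.tail_probability(k) < bound:
            return k
    raise RuntimeError("no cluster size satisfies the bound")  # unreachable


def apply_cluster_threshold(mask: np.ndarray, cluster_ids: np.ndarray,
                            k_min: int, alpha_diff: float = 0.05,
                            alpha_base: float = 0.01,
                            connectivity: int = 4) -> StatContourMask:
    """Drop clusters smaller than ``k_min``; keep them as "dashed" regions."""
    mask = np.asarray(mask, dtype=bool)
    if cluster_ids.shape != mask.shape:
        raise ValueError("cluster_ids must match the mask shape")
    if np.any((cluster_ids > 0) != mask):
        raise ValueError("cluster labels inconsistent with the mask")
    retained = np.zeros_like(mask)
    out_ids = np.zeros_like(cluster_ids)
    dashed = np.zeros_like(mask)
    for cid in np.unique(cluster_ids):
        if cid == 0:
            continue
        cells = cluster_ids == cid
        if int(cells.sum()) >= k_min:
            retained |= cells
            out_ids[cells] = cid
        else:
            dashed |= cells
    return StatContourMask(retained=retained, cluster_ids=out_ids,
                           dashed=dashed, alpha_diff=alpha_diff,
                           alpha_base=alpha_base, min_cluster_size=k_min,
                           connectivity=connectivity)


def behavioural_tests(table: pd.DataFrame,
                      exclusion_threshold: float = 0.75,
                      contrasts: tuple = CONTRASTS) -> dict:
    """Catch-trial RT and accuracy contrasts with the accuracy exclusion rule.

    Participants whose overall catch accuracy (weighted by catch count)
    is below the threshold are excluded, then each contrast is tested
    with a paired two-tailed t test on per-participant condition means.
    Returns {"report": DataFrame(measure, contrast, t, df, p),
    "excluded": [...], "n_retained": int}.
    """
    required = {"participant", "condition", "rt_ms", "accuracy", "n_catch"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"behavioural table missing columns {sorted(missing)}")

    overall = (table.assign(correct=lambda d: d.accuracy * d.n_catch)
               .groupby("participant")[["correct", "n_catch"]].sum())
    overall_acc = overall.correct / overall.n_catch
    excluded = sorted(overall_acc.index[overall_acc < exclusion_threshold])
    kept = table[~table.participant.isin(excluded)]
    participants = sorted(kept.participant.unique())
    if len(participants) < 3:
        raise ValueError(
            f"only {len(participants)} participants retained after the "
            f"accuracy-{exclusion_threshold} exclusion rule")

    wide = {m: kept.pivot_table(index="participant", columns="condition",
                                values=m)
            for m in ("rt_ms", "accuracy")}
    rows = []
    for measure, label in (("rt_ms", "reaction_time"), ("accuracy", "accuracy")):
        for a, b in contrasts:
            xa = wide[measure][a].loc[participants].to_numpy()
            xb = wide[measure][b].loc[participants].to_numpy()
            d = xa - xb
            if np.all(d == d[0]) and d.std(ddof=1) == 0:
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_rel(xa, xb)
            rows.append({"measure": label, "contrast": f"{a}_vs_{b}",
                         "t": float(t), "df": len(participants) - 1,
                         "p": float(p)})
    return {"report": pd.DataFrame(rows), "excluded": excluded,
            "n_retained": len(participants)}
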