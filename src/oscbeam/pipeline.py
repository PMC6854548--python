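"""Two-phase analysis orchestration and file I/O.

Phase one (``run_wholebrain``): forward model -> per-participant NAI
total-power maps per band and window -> paired active-vs-passive t-maps
-> permutation maximum-statistic thresholding.  Phase two (``run_poi``):
virtual electrodes at named points of interest, with condition-specific
beamformer weights -> evoked power -> baseline normalisation -> 25 ms x
2 Hz tiles -> three pairwise condition contrasts under the dual
significance criteria and Monte-Carlo cluster-extent correction.

POI names mirror the standard semantic-network sites (aSTG, pMTG, AG,
IFG) but their coordinates here are head-frame positions chosen in the
configuration; no anatomical registration is performed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import h5py
import numpy as np
import pandas as pd
import yaml

from . import beamformer as bf
from . import tilestats as ts
from . import timefreq as tf
from . import wholebrain as wb
from .forward import (SourceLattice, build_source_lattice, dipole_field,
                      lead_field)
from .simulate import (DipoleEffectSpec, EpochsSet, SimulationConfig,
                       reject_epochs, simulate_epochs)

DEFAULT_POIS = {
    # head-frame metres; names follow the semantic-network sites they emulate
    "aSTG": (0.045, 0.035, -0.030),
    "pMTG": (-0.055, -0.030, 0.010),
    "AG": (-0.045, -0.055, 0.035),
    "IFG": (0.040, 0.050, 0.005),
}


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    effects: list[DipoleEffectSpec] = field(default_factory=list)
    active_windows_ms: tuple = wb.DEFAULT_ACTIVE_WINDOWS_MS
    passive_window_ms: tuple = wb.DEFAULT_PASSIVE_WINDOW_MS
    bands_hz: tuple = wb.DEFAULT_BANDS_HZ
    poi_coords: dict = field(default_factory=lambda: dict(DEFAULT_POIS))
    poi_band_hz: tuple = (5.0, 50.0)
    lattice_spacing: float = 0.005
    lambda_rel: float = 0.05
    rejection_threshold: float = 5e-12
    n_permutations: int = 10000
    permutation_quantile: float = 0.05
    alpha_diff: float = 0.05
    alpha_base: float = 0.01
    tile_adjust: str = "maxstat"          # per-analysis multiplicity control
    n_tile_permutations: int = 1000
    n_cluster_simulations: int = 10000
    cluster_alpha: float = 0.05
    n_analyses: int = 12
    connectivity: int = 4
    mode: str = "evoked"                  # POI power mode
    seed: int = 0

    def config_hash(self) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            return str(o)
        blob = json.dumps(asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML document."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    sim = SimulationConfig(**doc.pop("simulation", {}))
    effects = [DipoleEffectSpec(
        location=np.asarray(e["location"], float),
        frequency_hz=float(e["frequency_hz"]),
        window_ms=tuple(e["window_ms"]),
        amplitude={k: float(v) for k, v in e["amplitude"].items()},
        phase_locked_fraction=float(e.get("phase_locked_fraction", 1.0)),
        orientation=np.asarray(e.get("orientation", (1.0, 0.0, 0.0)), float),
    ) for e in doc.pop("effects", [])]
    for key in ("active_windows_ms", "bands_hz"):
        if key in doc:
            doc[key] = tuple(tuple(w) for w in doc[key])
    if "passive_window_ms" in doc:
        doc["passive_window_ms"] = tuple(doc["passive_window_ms"])
    return PipelineConfig(simulation=sim, effects=effects, **doc)


# ---------------------------------------------------------------------------
# epoch I/O
# ---------------------------------------------------------------------------

def write_epochs_hdf5(epochs: EpochsSet, path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("data", data=epochs.data)
        fh.create_dataset("times", data=epochs.times_ms)
        fh.create_dataset("labels",
                          data=[s.encode() for s in epochs.labels])
        fh.create_dataset("is_catch", data=epochs.is_catch)
        fh.create_dataset("sensor_positions", data=epochs.sensors.positions)
        fh.create_dataset("sensor_orientations",
                          data=epochs.sensors.orientations)
        fh.create_dataset("channel_ids",
                          data=[s.encode() for s in epochs.sensors.channel_ids])
        fh.attrs["sampling_rate"] = epochs.sampling_rate
        fh.attrs["participant_id"] = epochs.participant_id


def read_epochs_hdf5(path, drop_catch: bool = False) -> EpochsSet:
    from .forward import SensorArray
    with h5py.File(path, "r") as fh:
        for key in ("data", "times", "labels"):
            if key not in fh:
                raise ValueError(f"malformed epochs file: missing /{key}")
        sensors = SensorArray(
            channel_ids=[s.decode() for s in fh["channel_ids"][()]],
            positions=fh["sensor_positions"][()],
            orientations=fh["sensor_orientations"][()])
        epochs = EpochsSet(
            data=fh["data"][()], times_ms=fh["times"][()],
            labels=np.array([s.decode() for s in fh["labels"][()]]),
            participant_id=str(fh.attrs["participant_id"]),
            sensors=sensors, sampling_rate=float(fh.attrs["sampling_rate"]),
            is_catch=fh["is_catch"][()].astype(bool)
            if "is_catch" in fh else None)
    if drop_catch:
        epochs = epochs.select(~epochs.is_catch)
    return epochs


def write_epochs_fif(epochs: EpochsSet, path) -> None:
    """Write epochs to FIF via MNE so standard MEG tooling can read them."""
    import mne
    info = mne.create_info(list(epochs.sensors.channel_ids),
                           epochs.sampling_rate, ch_types="mag")
    with info._unlock():
        for i, ch in enumerate(info["chs"]):
            ch["loc"][:3] = epochs.sensors.positions[i]
            ch["loc"][3:6] = epochs.sensors.orientations[i]
    label_codes = {lab: i + 1 for i, lab in
                   enumerate(dict.fromkeys(epochs.labels))}
    events = np.column_stack([
        np.arange(epochs.n_trials) * epochs.data.shape[2],
        np.zeros(epochs.n_trials, dtype=int),
        [label_codes[lab] for lab in epochs.labels]])
    ep = mne.EpochsArray(epochs.data, info, events=events,
                         event_id=label_codes,
                         tmin=epochs.times_ms[0] / 1000.0, verbose="error")
    ep.save(path, overwrite=True, verbose="error")


def read_epochs_fif(path) -> "mne.Epochs":
    import mne
    return mne.read_epochs(path, verbose="error")


# ---------------------------------------------------------------------------
# volume export
# ---------------------------------------------------------------------------

def nai_to_nifti(values: np.ndarray, lattice: SourceLattice, path) -> None:
    """Rasterise per-point values onto the lattice grid as a NIfTI image."""
    import nibabel as nib
    vol = np.zeros(lattice.grid_shape, dtype=float)
    vol[tuple(lattice.indices.T)] = values
    affine = np.eye(4)
    affine[:3, :3] *= lattice.spacing * 1000.0   # mm voxels
    affine[:3, 3] = lattice.origin * 1000.0
    nib.save(nib.Nifti1Image(vol, affine), str(path))


def volume_to_tsv(values: np.ndarray, lattice: SourceLattice, path,
                  header_meta: dict | None = None,
                  value_name: str = "nai") -> None:
    df = pd.DataFrame({"x_m": lattice.points[:, 0],
                       "y_m": lattice.points[:, 1],
                       "z_m": lattice.points[:, 2],
                       value_name: values})
    with open(path, "w") as fh:
        for k, v in (header_meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# phase one: whole-brain localisation
# ---------------------------------------------------------------------------

def _prepare_cohort(config: PipelineConfig):
    sim = config.simulation
    head = sim.default_head()
    sensors = sim.default_sensors()
    cohort, truth = simulate_epochs(sim, config.effects, head, sensors)
    kept, reports = [], []
    for ep in cohort:
        ep = ep.select(~ep.is_catch)          # catch trials never enter MEG
        ep, rep = reject_epochs(ep, config.rejection_threshold)
        kept.append(ep)
        reports.append(rep)
    return head, sensors, kept, truth, reports


def run_wholebrain(config: PipelineConfig, out_dir=None,
                   related_conditions: tuple[str, ...] = (
                       "taxonomic", "thematic_strong", "thematic_weak"),
                   ) -> dict:
    """Whole-brain NAI contrasts for every band x active window.

    Related conditions are pooled (the whole-brain phase characterises
    the response to semantically related trials as a whole).  Returns a
    dict with the lattice, per-contrast t-maps, thresholds and survivor
    masks; writes TSV/NIfTI when ``out_dir`` is given.
    """
    head, sensors, cohort, truth, reports = _prepare_cohort(config)
    lattice = build_source_lattice(head, config.lattice_spacing)
    lf = lead_field(head, lattice, sensors)

    results = {"lattice": lattice, "contrasts": {}, "truth": truth,
               "rejection_reports": reports,
               "config_hash": config.config_hash(), "seed": config.seed}
    rel_mask = lambda ep: np.isin(ep.labels, related_conditions)

    for band in config.bands_hz:
        # per participant and active window: weights shared between the
        # two windows of a contrast (pooled covariance), so that under
        # the null the active and passive maps are exchangeable
        active_maps = {win: [] for win in config.active_windows_ms}
        passive_maps = {win: [] for win in config.active_windows_ms}
        for ep in cohort:
            ep_rel = ep.select(rel_mask(ep))
            noise_cov = bf.estimate_covariance(
                ep_rel, config.passive_window_ms, band)
            for win in config.active_windows_ms:
                act_cov = bf.estimate_covariance(ep_rel, win, band)
                shared = bf.pool_covariances(act_cov, noise_cov)
                vol_a = bf.nai_volume(ep_rel, lf, band, win, noise_cov,
                                      config.lambda_rel, data_cov=act_cov,
                                      weights_cov=shared)
                vol_p = bf.nai_volume(ep_rel, lf, band,
                                      config.passive_window_ms, noise_cov,
                                      config.lambda_rel, data_cov=noise_cov,
                                      weights_cov=shared)
                active_maps[win].append(vol_a.values)
                passive_maps[win].append(vol_p.values)
        for win in config.active_windows_ms:
            active_arr = np.vstack(active_maps[win])
            passive_arr = np.vstack(passive_maps[win])
            null, tmap, survivors = wb.permutation_threshold(
                active_arr, passive_arr,
                n_permutations=config.n_permutations,
                quantile=config.permutation_quantile, seed=config.seed)
            key = (band, win)
            results["contrasts"][key] = {
                "tmap": tmap, "null": null, "survivors": survivors,
                "active": active_arr, "passive": passive_arr}
            if out_dir is not None:
                tag = f"band{band[0]:g}-{band[1]:g}_win{win[0]:g}-{win[1]:g}"
                meta = {"config_hash": results["config_hash"],
                        "seed": config.seed, "threshold": null.threshold}
                volume_to_tsv(tmap.t, lattice, f"{out_dir}/tmap_{tag}.tsv",
                              meta, value_name="t")
                nai_to_nifti(tmap.t * survivors, lattice,
                             f"{out_dir}/tmap_thresh_{tag}.nii.gz")
                pd.DataFrame({"permutation": np.arange(len(null.max_abs_t)),
                              "max_abs_t": null.max_abs_t}).to_csv(
                    f"{out_dir}/null_{tag}.tsv", sep="\t", index=False)
    return results


# ---------------------------------------------------------------------------
# phase two: POI time-frequency contrasts
# ---------------------------------------------------------------------------

def poi_tile_grids(cohort: list[EpochsSet], head, poi: np.ndarray,
                   config: PipelineConfig,
                   conditions: tuple[str, ...],
                   ) -> dict[str, np.ndarray]:
    """Per-condition stacks of baseline-normalised tile grids.

    For each participant and condition: covariance (full epoch, POI
    band) -> LCMV weights at the POI -> virtual electrode -> evoked (or
    total) power -> percent signal change -> 25 ms x 2 Hz tiles.
    """
    poi = np.asarray(poi, float)
    sim = config.simulation
    power_fn = tf.evoked_power if config.mode == "evoked" else tf.total_power
    if np.linalg.norm(poi - head.center) >= head.radius:
        raise ValueError(f"POI {poi} lies outside the head sphere")
    grids = {c: [] for c in conditions}
    for ep in cohort:
        dt = 1000.0 / ep.sampling_rate
        epoch_win = (float(ep.times_ms[0]), float(ep.times_ms[-1]) + dt)
        L = np.column_stack([
            dipole_field(head, poi, e, ep.sensors)
            for e in np.eye(3)])
        # raw per-condition power first; normalisation uses one baseline
        # pooled across the conditions entering the analysis, so baseline
        # estimation error cancels in condition differences
        raw_maps = {}
        for cond in conditions:
            ep_c = ep.condition(cond)
            if ep_c.n_trials == 0:
                raise ValueError(
                    f"condition {cond!r} missing for {ep.participant_id}")
            cov = bf.estimate_covariance(ep_c, epoch_win, config.poi_band_hz)
            noise = bf.estimate_covariance(ep_c, config.passive_window_ms,
                                           config.poi_band_hz)
            reg = bf.regularize(cov, noise, config.lambda_rel)
            W = bf.lcmv_weights(L, reg)
            ve = bf.virtual_electrode(
                bf.SpatialFilterEntry(W, poi, epoch_win,
                                      config.poi_band_hz), ep_c)
            raw_maps[cond] = power_fn(ve, participant_id=ep.participant_id)
        shared_base = np.mean(
            [tf.baseline_vector(m, config.passive_window_ms)
             for m in raw_maps.values()], axis=0)
        for cond, raw in raw_maps.items():
            p = tf.baseline_normalize(raw, config.passive_window_ms,
                                      baseline_values=shared_base)
            grid = tf.resample_tiles(p, t_range_ms=epoch_win)
            grids[cond].append(grid.values)
    return {c: np.stack(v) for c, v in grids.items()}


def poi_contrast(grids_a: np.ndarray, grids_b: np.ndarray,
                 config: PipelineConfig, seed: int | None = None) -> dict:
    """Dual-criteria + cluster-extent decision for one condition contrast."""
    result = ts.tile_condition_test(
        grids_a, grids_b, adjust=config.tile_adjust,
        n_permutations=config.n_tile_permutations,
        seed=config.seed if seed is None else seed)
    mask = ts.dual_criteria_mask(result, config.alpha_diff, config.alpha_base)
    labels, sizes = ts.label_clusters(mask, config.connectivity)
    fill_rate = float(mask.mean())
    null = ts.cluster_null(mask.shape, fill_rate, config.connectivity,
                           config.n_cluster_simulations,
                           seed=config.seed if seed is None else seed)
    k_min = ts.min_cluster_size(null, config.cluster_alpha, config.n_analyses)
    contour = ts.apply_cluster_threshold(mask, labels, k_min,
                                         config.alpha_diff, config.alpha_base,
                                         config.connectivity)
    return {"result": result, "mask": mask, "labels": labels, "sizes": sizes,
            "fill_rate": fill_rate, "null": null, "k_min": k_min,
            "contour": contour}


def run_poi(config: PipelineConfig, poi_name: str, out_dir=None,
            conditions: tuple[str, ...] = ("taxonomic", "thematic_strong",
                                           "thematic_weak"),
            cohort: list[EpochsSet] | None = None) -> dict:
    """POI analysis: per-condition tile grids and the three contrasts."""
    if poi_name not in config.poi_coords:
        raise KeyError(f"unknown POI {poi_name!r}; have "
                       f"{sorted(config.poi_coords)}")
    head = config.simulation.default_head()
    if cohort is None:
        _, _, cohort, _, _ = _prepare_cohort(config)
    grids = poi_tile_grids(cohort, head, config.poi_coords[poi_name],
                           config, conditions)
    contrasts = {}
    for a, b in ts.CONTRASTS:
        if a in grids and b in grids:
            contrasts[(a, b)] = poi_contrast(grids[a], grids[b], config)
    out = {"poi": poi_name, "grids": grids, "contrasts": contrasts,
           "config_hash": config.config_hash(), "seed": config.seed}
    if out_dir is not None:
        _write_poi_outputs(out, config, out_dir)
    return out


def _write_poi_outputs(out: dict, config: PipelineConfig, out_dir) -> None:
    sim = config.simulation
    t_edges = np.arange(sim.epoch_window_ms[0], sim.epoch_window_ms[1], 25.0)
    f_edges = np.arange(5.0, 50.0, 2.0)
    tt, ff = np.meshgrid(t_edges, f_edges, indexing="ij")
    for (a, b), c in out["contrasts"].items():
        tag = f"{out['poi']}_{a}_vs_{b}"
        res, contour = c["result"], c["contour"]
        df = pd.DataFrame({
            "time_ms": tt.ravel(), "freq_hz": ff.ravel(),
            "t_diff": res.t_diff.ravel(), "p_diff": res.p_diff.ravel(),
            "p_baseA": res.p_base_a.ravel(), "p_baseB": res.p_base_b.ravel(),
            "retained": contour.retained.ravel().astype(int),
            "cluster_id": contour.cluster_ids.ravel()})
        with open(f"{out_dir}/tiles_{tag}.tsv", "w") as fh:
            fh.write(f"# config_hash: {out['config_hash']}\n")
            fh.write(f"# seed: {out['seed']}\n")
            fh.write(f"# k_min: {c['k_min']}  fill_rate: {c['fill_rate']:.4f}"
                     f"  connectivity: {contour.connectivity}\n")
            df.to_csv(fh, sep="\t", index=False)
        plot_contrast_figure(out["grids"][a], out["grids"][b], c,
                             t_edges, f_edges, (a, b),
                             f"{out_dir}/fig_{tag}.png")


def plot_contrast_figure(grids_a, grids_b, contrast, t_edges, f_edges,
                         names, path) -> None:
    """Difference / condition A / condition B panels with cluster contours."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.2), sharey=True)
    extent = [t_edges[0], t_edges[-1] + 25.0, f_edges[0], f_edges[-1] + 2.0]
    panels = [((grids_a - grids_b).mean(axis=0), f"{names[0]} - {names[1]}"),
              (grids_a.mean(axis=0), names[0]),
              (grids_b.mean(axis=0), names[1])]
    for ax, (vals, title) in zip(axes, panels):
        im = ax.imshow(vals.T, origin="lower", aspect="auto", extent=extent,
                       cmap="RdBu_r")
        ax.set_title(title)
        ax.set_xlabel("time (ms)")
        fig.colorbar(im, ax=ax, label="% signal change")
    retained = contrast["contour"].retained
    if retained.any():
        axes[0].contour(t_edges + 12.5, f_edges + 1.0,
                        retained.T.astype(float), levels=[0.5], colors="k")
    if contrast["contour"].dashed.any():
        axes[0].contour(t_edges + 12.5, f_edges + 1.0,
                        contrast["contour"].dashed.T.astype(float),
                        levels=[0.5], colors="k", linestyles="dashed")
    axes[0].set_ylabel("frequency (Hz)")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
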