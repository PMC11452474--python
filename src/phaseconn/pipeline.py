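"""End-to-end orchestration: simulate/load -> preprocess -> WPLI -> CST ->
cluster statistics -> post hoc contrasts -> ROI/FDR -> behavior GLM.

A single global seed is fanned out to per-stage child seeds by stable
derivation, so any stage re-run in isolation reproduces its output.
Every run writes its resolved configuration, a manifest (seed, config
hash, package versions) and fixed-layout TSV result tables into a fresh
versioned run directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clusterstats import (EdgeStatResult, PermutationScheme, paired_t_edges,
                           permutation_cluster_test, rm_anova_edges)
from .netthresh import BinaryMask, apply_cst_mask, mask_to_frame, masks_per_band, stack_masks
from .preprocess import (FilterSpec, epoch_and_baseline, filter_continuous,
                         ica_clean, preprocess_epochs, resample_epochs,
                         subtract_erp)
from .roiglm import (CONTRASTS, ROISet, glm_behavior_link,
                     pool_roi_connectivity, roi_rm_anova_fdr)
from .spectral import BandScheme, epochs_to_band_wpli
from .synth import (CONDITIONS, EpochSet, Montage, Recording, StudyBundle,
                    StudyConfig, render_recording, simulate_study)

logger = logging.getLogger(__name__)

_BV_LABELS = {"Stimulus/S  1": "rep1", "Stimulus/S  2": "rep2",
              "Stimulus/S  3": "rep3"}


@dataclass
class PipelineConfig:
    """Complete, YAML-serializable description of one analysis run."""

    study: StudyConfig = field(default_factory=StudyConfig)
    data_dir: str | None = None  # read recordings from disk instead of simulating
    filter: FilterSpec = field(default_factory=FilterSpec)
    epoch_window: tuple[float, float] = (0.0, 10.0)
    baseline_window: tuple[float, float] = (-0.200, -0.002)
    resample_to: float = 500.0
    perm: PermutationScheme = field(default_factory=PermutationScheme)
    glm_bands: tuple[str, ...] = ("theta", "alpha")
    out_dir: str = "runs"
    seed: int = 0
    simulate_continuous: bool = False  # render + filter a continuous recording
    run_posthoc: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["study"]["planted_edges"] = [dataclasses.asdict(e)
                                       for e in self.study.planted_edges]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        from .synth import PlantedEdge
        d = dict(d)
        if "study" in d:
            s = dict(d["study"])
            if "planted_edges" in s:
                s["planted_edges"] = tuple(
                    PlantedEdge(e["ch_a"], e["ch_b"], e["band"],
                                e["lag_degrees"], tuple(e["kappa"]))
                    for e in s["planted_edges"])
            if "channels" in s and isinstance(s["channels"], list):
                s["channels"] = tuple(s["channels"])
            d["study"] = StudyConfig(**s)
        if "filter" in d:
            d["filter"] = FilterSpec(**d["filter"])
        if "perm" in d:
            d["perm"] = PermutationScheme(**d["perm"])
        for key in ("epoch_window", "baseline_window", "glm_bands"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path: Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class RunResult:
    run_dir: Path
    band_wpli: np.ndarray  # subjects x conditions x ch x ch x bands
    masks: list[BinaryMask]
    anova: EdgeStatResult
    posthoc: dict[str, EdgeStatResult]
    pooled: pd.DataFrame
    roi_anova: pd.DataFrame
    glm: pd.DataFrame
    behavior: pd.DataFrame
    subjects: list[str]
    ch_names: tuple[str, ...]
    band_names: tuple[str, ...]


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2 ** 31))


def rois_present(ch_names, rois: ROISet = ROISet()) -> ROISet:
    """Restrict an ROI set to the groups fully covered by the montage."""
    keep = tuple((name, members) for name, members in rois.rois
                 if all(c in ch_names for c in members))
    return ROISet(keep)


def read_recording(path: Path) -> Recording:
    """Read a BrainVision (.vhdr) or EDF recording into a Recording."""
    import mne
    path = Path(path)
    if path.suffix.lower() == ".vhdr":
        for ext in (".eeg", ".vmrk"):
            if not path.with_suffix(ext).exists():
                raise FileNotFoundError(
                    f"BrainVision triplet incomplete: missing {path.with_suffix(ext).name}")
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    elif path.suffix.lower() == ".edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    else:
        raise ValueError(f"unsupported recording format: {path.suffix!r}")
    montage = Montage(tuple(raw.ch_names))
    data = raw.get_data() * 1e6  # Volts -> microvolts
    events = []
    for ann in raw.annotations:
        desc = ann["description"]
        if desc.startswith("New Segment"):
            continue
        label = _BV_LABELS.get(desc, desc)
        events.append((int(round(ann["onset"] * raw.info["sfreq"])), label))
    events.sort()
    return Recording(data, float(raw.info["sfreq"]), montage, events)


def collect_band_wpli(bundle_epochs: dict[str, dict[str, EpochSet]],
                      bands: BandScheme = BandScheme(),
                      ) -> tuple[np.ndarray, list[str], tuple[str, ...]]:
    """Band-averaged WPLI tensor (subjects x conditions x ch x ch x bands)
    from preprocessed epochs."""
    subjects = sorted(bundle_epochs)
    first = next(iter(next(iter(bundle_epochs.values())).values()))
    ch_names = first.ch_names
    n_ch = len(ch_names)
    out = np.full((len(subjects), len(CONDITIONS), n_ch, n_ch, len(bands.names)), np.nan)
    for si, sid in enumerate(subjects):
        for ci, cond in enumerate(CONDITIONS):
            conn = epochs_to_band_wpli(bundle_epochs[sid][cond], bands)
            out[si, ci] = conn.values
    return out, subjects, ch_names


def _preprocess_study(bundle: StudyBundle, config: PipelineConfig) -> dict[str, dict[str, EpochSet]]:
    """Filter/epoch (continuous path) or baseline/crop (epoch path), then
    resample and subtract the per-condition ERP."""
    processed: dict[str, dict[str, EpochSet]] = {}
    for sid, conds in bundle.epochs.items():
        if config.simulate_continuous:
            rec = render_recording(list(conds.values()))
            rec = ica_clean(filter_continuous(rec, config.filter))
            by_cond = epoch_and_baseline(rec, config.epoch_window,
                                         config.baseline_window, subject_id=sid)
            processed[sid] = {
                cond: subtract_erp(resample_epochs(ep, config.resample_to))
                for cond, ep in by_cond.items()
            }
        else:
            processed[sid] = {
                cond: preprocess_epochs(ep, config.baseline_window,
                                        config.epoch_window, config.resample_to)
                for cond, ep in conds.items()
            }
    return processed


def run_pipeline(config: PipelineConfig) -> RunResult:
    """Execute the full analysis and persist all artifacts.

    Re-running with the same configuration and seed reproduces every
    result table bit-exactly.
    """
    root = np.random.SeedSequence(config.seed)
    ss_sim, ss_anova, *ss_t = root.spawn(2 + len(CONTRASTS))
    bands = BandScheme()

    logger.info("stage 1/7: %s", "loading recordings" if config.data_dir else "simulating study")
    if config.data_dir:
        bundle = _load_study(Path(config.data_dir), config)
    else:
        study = dataclasses.replace(config.study, seed=_child_seed(ss_sim))
        bundle = simulate_study(study)

    logger.info("stage 2/7: preprocessing")
    processed = _preprocess_study(bundle, config)

    logger.info("stage 3/7: spectra and WPLI")
    band_wpli, subjects, ch_names = collect_band_wpli(processed, bands)

    logger.info("stage 4/7: CST masks")
    group_mean = band_wpli.mean(axis=(0, 1))
    masks = masks_per_band(group_mean)
    mask_stack = stack_masks(masks)

    logger.info("stage 5/7: RM-ANOVA + cluster permutation")
    anova = rm_anova_edges(band_wpli, ch_names, bands.names,
                           subjects, CONDITIONS)
    anova.stat = apply_cst_mask(anova.stat, mask_stack)
    scheme_a = dataclasses.replace(config.perm, seed=_child_seed(ss_anova))
    anova = permutation_cluster_test(band_wpli, anova, scheme_a, mask_stack)

    posthoc: dict[str, EdgeStatResult] = {}
    if config.run_posthoc:
        logger.info("stage 6/7: post hoc paired contrasts")
        for (name, (cb, ca)), ss in zip(CONTRASTS.items(), ss_t):
            ia, ib = CONDITIONS.index(ca), CONDITIONS.index(cb)
            res = paired_t_edges(band_wpli, ia, ib, ch_names, bands.names,
                                 subjects, CONDITIONS)
            res.stat = apply_cst_mask(res.stat, mask_stack)
            scheme_t = dataclasses.replace(config.perm, seed=_child_seed(ss))
            posthoc[name] = permutation_cluster_test(
                band_wpli, res, scheme_t, mask_stack, contrast=(ia, ib))

    logger.info("stage 7/7: ROI pooling, FDR and behavior GLM")
    rois = rois_present(ch_names)
    pooled = pool_roi_connectivity(band_wpli, ch_names, bands.names,
                                   subjects, CONDITIONS, rois)
    roi_anova = roi_rm_anova_fdr(pooled)
    glm_bands = tuple(b for b in config.glm_bands if b in bands.names)
    glm = glm_behavior_link(pooled, bundle.behavior, glm_bands, rois=rois)

    run_dir = write_results(config, masks, anova, posthoc, pooled, roi_anova,
                            glm, bundle.behavior, band_wpli, ch_names,
                            bands.names, subjects)
    return RunResult(run_dir, band_wpli, masks, anova, posthoc, pooled,
                     roi_anova, glm, bundle.behavior, subjects, ch_names,
                     bands.names)


def _load_study(data_dir: Path, config: PipelineConfig) -> StudyBundle:
    """Load a written study (BrainVision per subject + behavior table)."""
    behavior = pd.read_csv(data_dir / "behavior.tsv", sep="\t")
    epochs: dict[str, dict[str, EpochSet]] = {}
    for sub_dir in sorted(p for p in data_dir.iterdir() if p.is_dir()):
        vhdrs = sorted(sub_dir.glob("*.vhdr"))
        if not vhdrs:
            continue
        rec = read_recording(vhdrs[0])
        rec = filter_continuous(rec, config.filter)
        by_cond = epoch_and_baseline(rec, config.epoch_window,
                                     config.baseline_window,
                                     subject_id=sub_dir.name)
        epochs[sub_dir.name] = {
            cond: subtract_erp(resample_epochs(ep, config.resample_to))
            for cond, ep in by_cond.items()
        }
    if not epochs:
        raise FileNotFoundError(f"no subject recordings found under {data_dir}")
    # loaded studies are already preprocessed here; mark them as epoch-domain
    cfg = dataclasses.replace(config.study, n_subjects=len(epochs))
    return StudyBundle(epochs=epochs, behavior=behavior, ground_truth=(),
                       config=cfg)


# ---------------------------------------------------------------------------
# stage-wise entry points (mirrored by the CLI subcommands); each persists
# its output so any stage can be rerun in isolation

def save_band_wpli(path: Path, band_wpli: np.ndarray, ch_names, band_names,
                   subjects) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("wpli", data=band_wpli)
        f.attrs["ch_names"] = list(ch_names)
        f.attrs["band_names"] = list(band_names)
        f.attrs["subjects"] = list(subjects)
        f.attrs["conditions"] = list(CONDITIONS)


def load_band_wpli(path: Path):
    with h5py.File(path, "r") as f:
        return (f["wpli"][()], tuple(f.attrs["ch_names"]),
                tuple(f.attrs["band_names"]), list(f.attrs["subjects"]))


def stage_preprocess(data_dir: Path, out_dir: Path,
                     config: PipelineConfig) -> Path:
    """Read raw recordings, preprocess, and persist epochs as HDF5."""
    from .preprocess import save_epochs
    bundle = _load_study(Path(data_dir), config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for sid, conds in bundle.epochs.items():
        for cond, ep in conds.items():
            save_epochs(ep, out_dir / f"{sid}_{cond}.h5")
    return out_dir


def stage_connectivity(preproc_dir: Path, out_file: Path) -> Path:
    """Band-averaged WPLI from preprocessed epoch files."""
    from .preprocess import load_epochs
    epochs: dict[str, dict[str, EpochSet]] = {}
    for p in sorted(Path(preproc_dir).glob("*.h5")):
        ep = load_epochs(p)
        epochs.setdefault(ep.subject_id, {})[ep.condition] = ep
    if not epochs:
        raise FileNotFoundError(f"no epoch files under {preproc_dir}")
    band_wpli, subjects, ch_names = collect_band_wpli(epochs)
    save_band_wpli(Path(out_file), band_wpli, ch_names, BandScheme().names,
                   subjects)
    return Path(out_file)


def stage_stats(wpli_file: Path, out_dir: Path,
                config: PipelineConfig) -> Path:
    """CST masks + cluster-permutation ANOVA and post hoc contrasts."""
    band_wpli, ch_names, band_names, subjects = load_band_wpli(wpli_file)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    masks = masks_per_band(band_wpli.mean(axis=(0, 1)))
    mask_stack = stack_masks(masks)
    root = np.random.SeedSequence(config.seed)
    ss_anova, *ss_t = root.spawn(1 + len(CONTRASTS))
    res = rm_anova_edges(band_wpli, ch_names, band_names, subjects, CONDITIONS)
    res.stat = apply_cst_mask(res.stat, mask_stack)
    scheme = dataclasses.replace(config.perm, seed=_child_seed(ss_anova))
    res = permutation_cluster_test(band_wpli, res, scheme, mask_stack)
    _write_table(res.to_frame(), out_dir / "edges_anova.tsv")
    for (name, (cb, ca)), ss in zip(CONTRASTS.items(), ss_t):
        ia, ib = CONDITIONS.index(ca), CONDITIONS.index(cb)
        t_res = paired_t_edges(band_wpli, ia, ib, ch_names, band_names,
                               subjects, CONDITIONS)
        t_res.stat = apply_cst_mask(t_res.stat, mask_stack)
        scheme_t = dataclasses.replace(config.perm, seed=_child_seed(ss))
        t_res = permutation_cluster_test(band_wpli, t_res, scheme_t,
                                         mask_stack, contrast=(ia, ib))
        _write_table(t_res.to_frame(), out_dir / f"edges_t_{name}.tsv")
    return out_dir


def stage_roiglm(wpli_file: Path, behavior_file: Path, out_dir: Path,
                 config: PipelineConfig) -> Path:
    """ROI pooling + RM-ANOVA/FDR and the behavior GLM."""
    band_wpli, ch_names, band_names, subjects = load_band_wpli(wpli_file)
    behavior = pd.read_csv(behavior_file, sep="\t")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rois = rois_present(ch_names)
    pooled = pool_roi_connectivity(band_wpli, ch_names, band_names,
                                   subjects, CONDITIONS, rois)
    _write_table(pooled, out_dir / "roi_pooled.tsv")
    _write_table(roi_rm_anova_fdr(pooled), out_dir / "roi_anova_fdr.tsv")
    glm_bands = tuple(b for b in config.glm_bands if b in band_names)
    glm = glm_behavior_link(pooled, behavior, glm_bands, rois=rois)
    _write_table(glm, out_dir / "glm_behavior.tsv")
    return out_dir


def _next_run_dir(out_dir: Path) -> Path:
    out_dir.mkdir(parents=True, exist_ok=True)
    k = 1
    while (out_dir / f"run-{k:03d}").exists():
        k += 1
    run_dir = out_dir / f"run-{k:03d}"
    run_dir.mkdir()
    return run_dir


def _write_table(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.4f")


def write_results(config, masks, anova, posthoc, pooled, roi_anova, glm,
                  behavior, band_wpli, ch_names, band_names, subjects) -> Path:
    """Persist all result tables (4-decimal TSV) plus full-precision HDF5."""
    run_dir = _next_run_dir(Path(config.out_dir))
    config.to_yaml(run_dir / "config.yaml")
    cfg_text = (run_dir / "config.yaml").read_text()
    manifest = {
        "seed": config.seed,
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "phaseconn_version": __version__,
        "numpy_version": np.__version__,
        "n_perm": config.perm.n_perm,
        "cluster_alpha": config.perm.cluster_alpha,
        "cluster_forming_alpha": config.perm.cluster_forming_alpha,
    }
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    with h5py.File(run_dir / "band_wpli.h5", "w") as f:
        f.create_dataset("wpli", data=band_wpli)
        f.attrs["ch_names"] = list(ch_names)
        f.attrs["band_names"] = list(band_names)
        f.attrs["subjects"] = list(subjects)
        f.attrs["conditions"] = list(CONDITIONS)

    mask_frames = [mask_to_frame(m, ch_names, band)
                   for m, band in zip(masks, band_names)]
    _write_table(pd.concat(mask_frames, ignore_index=True), run_dir / "cst_masks.tsv")
    _write_table(anova.to_frame(), run_dir / "edges_anova.tsv")
    for name, res in posthoc.items():
        _write_table(res.to_frame(), run_dir / f"edges_t_{name}.tsv")
    _write_table(pooled, run_dir / "roi_pooled.tsv")
    _write_table(roi_anova, run_dir / "roi_anova_fdr.tsv")
    _write_table(glm, run_dir / "glm_behavior.tsv")
    _write_table(behavior, run_dir / "behavior.tsv")
    return run_dir
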