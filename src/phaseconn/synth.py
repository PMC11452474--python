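"""Synthetic multi-subject EEG studies with planted phase coupling.

Generates continuous-style epoched recordings that emulate a passive
listening study: three repetitions (conditions) of the same stimuli,
1/f background activity, an instantaneous broadband common source that
mimics volume conduction, and narrowband sources planted between
designated electrode pairs with a fixed nonzero phase lag whose coupling
strength grows across repetitions.  A behavior table of Likert-style
familiarity scores grows with repetition in proportion to the planted
coupling, so that downstream connectivity-behavior regressions have a
recoverable positive slope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

CONDITIONS = ("rep1", "rep2", "rep3")

# 51-channel 10-10 montage (ground/reference and EOG channels excluded).
MONTAGE_51 = (
    "Fp1", "Fp2", "AF3", "AF4",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT9", "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8", "FT10",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "Pz", "P4", "P6", "P8",
    "O1", "O2",
)

# Right-hemisphere subset used for fast test-scale studies: the full
# right frontal, right parietal and right temporal regions of interest.
MONTAGE_16 = (
    "F2", "F4", "F6", "FC2", "FC4", "FC6", "FT8", "FT10", "T8",
    "CP2", "CP4", "CP6", "TP8", "P4", "P6", "P8",
)


@dataclass(frozen=True)
class Montage:
    """Ordered scalp electrode labels following the 10-10 convention."""

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            dupes = sorted({n for n in self.names if list(self.names).count(n) > 1})
            raise ValueError(f"duplicate channel label(s): {', '.join(dupes)}")

    @property
    def n_channels(self) -> int:
        return len(self.names)

    def index(self, label: str) -> int:
        try:
            return self.names.index(label)
        except ValueError:
            raise KeyError(f"unknown channel label: {label!r}") from None


def build_montage(channels: int | Sequence[str] = 51) -> Montage:
    """Return a canonical 10-10 montage.

    ``channels`` may be 51 (full montage), 16 (right-hemisphere test
    subset), or an explicit label list.  Explicit labels must belong to
    the 51-label canonical set.
    """
    if isinstance(channels, int):
        if channels == 51:
            return Montage(MONTAGE_51)
        if channels == 16:
            return Montage(MONTAGE_16)
        raise ValueError("canonical montage sizes are 51 and 16; pass labels otherwise")
    unknown = [c for c in channels if c not in MONTAGE_51]
    if unknown:
        raise ValueError(f"unknown channel label(s): {', '.join(unknown)}")
    return Montage(tuple(channels))


@dataclass
class Recording:
    """Continuous multichannel recording with stimulus markers."""

    data: np.ndarray  # channels x samples, microvolts
    fs: float
    montage: Montage
    events: list[tuple[int, str]]

    def __post_init__(self) -> None:
        if self.data.shape[0] != self.montage.n_channels:
            raise ValueError(
                f"data has {self.data.shape[0]} rows but montage has "
                f"{self.montage.n_channels} channels"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        samples = [s for s, _ in self.events]
        if any(b <= a for a, b in zip(samples, samples[1:])):
            raise ValueError("event sample indices must be strictly increasing")
        if samples and (samples[0] < 0 or samples[-1] >= self.data.shape[1]):
            raise ValueError("event sample index out of bounds")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class EpochSet:
    """Trials x channels x samples tensor for one subject and condition."""

    data: np.ndarray
    fs: float
    t0: float  # time of first sample relative to stimulus onset (s)
    condition: str
    subject_id: str
    ch_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("epoch data must be trials x channels x samples")
        if self.data.shape[1] != len(self.ch_names):
            raise ValueError("channel axis does not match channel names")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def crop(self, tmin: float, tmax: float) -> "EpochSet":
        """Keep samples with tmin <= t < tmax (tmax exclusive)."""
        t = self.times
        keep = (t >= tmin - 1e-9) & (t < tmax - 1e-9)
        return replace(self, data=self.data[:, :, keep], t0=float(t[keep][0]))


# Default planted design: one theta and one alpha edge whose coupling
# strength grows over the three repetitions.
@dataclass(frozen=True)
class PlantedEdge:
    ch_a: str
    ch_b: str
    band: str
    lag_degrees: float
    kappa: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not (0.0 < self.lag_degrees < 180.0):
            raise ValueError(
                "planted lag must lie strictly inside (0, 180) degrees; a zero "
                "lag is undetectable by a lag-based synchronization index"
            )
        if any(k < 0 for k in self.kappa):
            raise ValueError("coupling strengths must be non-negative")


DEFAULT_PLANTED = (
    PlantedEdge("F4", "CP4", "theta", 90.0, (0.0, 0.4, 0.8)),
    PlantedEdge("FC6", "P6", "alpha", 90.0, (0.0, 0.4, 0.8)),
)

# Band centers used to convert a phase lag into a pure time delay.
BAND_CENTERS = {
    "theta": 6.5, "alpha": 10.5, "beta1": 15.0, "beta2": 19.5,
    "beta3": 25.5, "beta4": 30.5, "gamma1": 35.5, "gamma2": 41.5,
}
BAND_EDGES = {
    "theta": (5.0, 8.0), "alpha": (8.0, 13.0), "beta1": (13.0, 17.0),
    "beta2": (17.0, 22.0), "beta3": (23.0, 28.0), "beta4": (28.0, 33.0),
    "gamma1": (33.0, 38.0), "gamma2": (38.0, 45.0),
}


@dataclass
class StudyConfig:
    """Design of a synthetic familiarization study.

    Defaults are the fast test scale (10 subjects, 16 channels, 12
    trials per condition); :meth:`full_scale` matches the acquisition
    scale of a 20-subject, 51-channel study with ~28 trials.
    """

    n_subjects: int = 10
    n_trials_per_condition: int = 12
    channels: int | Sequence[str] = 16
    planted_edges: tuple[PlantedEdge, ...] = DEFAULT_PLANTED
    common_source_gain: float = 1.0
    behavior_slope: float = 1.5
    noise_exponent: float = 1.0
    seed: int = 0
    fs: float = 1000.0
    t_pre: float = 0.2   # pre-stimulus span (s)
    t_post: float = 10.0  # post-stimulus span (s)
    edge_source_gain: float = 1.0
    subject_factor_sd: float = 0.3
    behavior_noise_sd: float = 0.5

    @classmethod
    def full_scale(cls, **kw) -> "StudyConfig":
        kw.setdefault("n_subjects", 20)
        kw.setdefault("n_trials_per_condition", 28)
        kw.setdefault("channels", 51)
        return cls(**kw)

    def montage(self) -> Montage:
        return build_montage(self.channels)

    def validate(self) -> None:
        if self.n_subjects < 1 or self.n_trials_per_condition < 2:
            raise ValueError("need >= 1 subject and >= 2 trials per condition")
        m = self.montage()
        for e in self.planted_edges:
            m.index(e.ch_a), m.index(e.ch_b)
            if e.band not in BAND_CENTERS:
                raise ValueError(f"unknown band {e.band!r} in planted edge")
        if self.common_source_gain < 0:
            raise ValueError("common_source_gain must be >= 0")


@dataclass
class StudyBundle:
    """All subjects' epochs plus behavior and the ground-truth design."""

    epochs: dict[str, dict[str, EpochSet]]  # subject -> condition -> EpochSet
    behavior: pd.DataFrame  # columns: subject_id, condition, mean_score
    ground_truth: tuple[PlantedEdge, ...]
    config: StudyConfig

    @property
    def subjects(self) -> list[str]:
        return list(self.epochs)


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...],
                n_samples: int, fs: float, exponent: float) -> np.ndarray:
    """1/f^exponent noise, unit RMS, generated by spectral shaping.

    Synthesis runs on an FFT-friendly padded length and is cropped, so
    generation stays fast for awkward sample counts.
    """
    from scipy.fft import irfft, next_fast_len
    nfft = next_fast_len(n_samples, real=True)
    n_freq = nfft // 2 + 1
    spec = rng.standard_normal(shape + (n_freq,), dtype=np.float32) \
        + 1j * rng.standard_normal(shape + (n_freq,), dtype=np.float32)
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    scale = np.ones(n_freq, dtype=np.float32)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    scale[0] = 0.0
    x = irfft(spec * scale, n=nfft, axis=-1)[..., :n_samples]
    rms = np.sqrt(np.mean(x ** 2, axis=-1, keepdims=True))
    return x / rms


def _narrowband_sources(rng: np.random.Generator, n_trials: int, n_samples: int,
                        fs: float, band: tuple[float, float]) -> np.ndarray:
    """Unit-RMS band-limited noise per trial (zero-phase filtered white noise)."""
    pad = int(fs)  # 1 s padding absorbs filter transients
    w = rng.standard_normal((n_trials, n_samples + 2 * pad), dtype=np.float32)
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, w, axis=-1)[:, pad:-pad].astype(np.float32)
    return x / np.sqrt(np.mean(x ** 2, axis=-1, keepdims=True, dtype=np.float32))


def simulate_subject(config: StudyConfig, subject_id: str,
                     rng: np.random.Generator) -> tuple[dict[str, EpochSet], list[dict]]:
    """Simulate one subject: an EpochSet per condition plus behavior rows.

    Each epoch spans t = -t_pre .. t_post.  Channel composition:
    1/f noise + common zero-lag broadband source (per-subject fixed
    random channel gains) + planted narrowband pairs where channel ``a``
    carries a band-limited source s(t) and channel ``b`` carries
    kappa_condition * s delayed by lag/(360 * f_center) seconds.  The
    source is regenerated per trial; the lag sign never changes.
    """
    config.validate()
    montage = config.montage()
    fs, n_ch = config.fs, montage.n_channels
    n_samp = int(round((config.t_pre + config.t_post) * fs))
    n_tr = config.n_trials_per_condition

    # static per-subject quantities
    common_gains = config.common_source_gain * rng.uniform(0.5, 1.5, size=n_ch)
    subject_factor = max(0.2, rng.normal(1.0, config.subject_factor_sd))

    edge_idx = [(montage.index(e.ch_a), montage.index(e.ch_b)) for e in config.planted_edges]
    edge_shift = [
        int(round(e.lag_degrees / (360.0 * BAND_CENTERS[e.band]) * fs))
        for e in config.planted_edges
    ]

    epochs: dict[str, EpochSet] = {}
    behavior_rows: list[dict] = []
    for ci, cond in enumerate(CONDITIONS):
        data = _pink_noise(rng, (n_tr, n_ch), n_samp, fs, config.noise_exponent)
        if config.common_source_gain > 0:
            broadband = rng.standard_normal((n_tr, 1, n_samp), dtype=np.float32)
            data = data + common_gains[None, :, None] * broadband
        for e, (ia, ib), shift in zip(config.planted_edges, edge_idx, edge_shift):
            kappa = e.kappa[ci] * subject_factor
            s = _narrowband_sources(rng, n_tr, n_samp + shift, fs, BAND_EDGES[e.band])
            data[:, ia] += config.edge_source_gain * s[:, shift:]
            if kappa > 0:
                data[:, ib] += config.edge_source_gain * kappa * s[:, :n_samp]
        epochs[cond] = EpochSet(
            data=data, fs=fs, t0=-config.t_pre, condition=cond,
            subject_id=subject_id, ch_names=montage.names,
        )
        score = 2.0 + config.behavior_slope * subject_factor * ci \
            + rng.normal(0.0, config.behavior_noise_sd)
        behavior_rows.append({
            "subject_id": subject_id, "condition": cond,
            "mean_score": float(np.clip(score, 1.0, 7.0)),
        })
    return epochs, behavior_rows


def simulate_study(config: StudyConfig) -> StudyBundle:
    """Simulate a full study; bit-reproducible from ``config.seed``."""
    config.validate()
    # independent per-subject streams so the design (not the noise) is shared
    children = np.random.SeedSequence(config.seed).spawn(config.n_subjects)
    epochs: dict[str, dict[str, EpochSet]] = {}
    rows: list[dict] = []
    for i, ss in enumerate(children):
        sid = f"sub-{i + 1:02d}"
        ep, beh = simulate_subject(config, sid, np.random.default_rng(ss))
        epochs[sid] = ep
        rows.extend(beh)
    behavior = pd.DataFrame(rows, columns=["subject_id", "condition", "mean_score"])
    return StudyBundle(epochs=epochs, behavior=behavior,
                       ground_truth=config.planted_edges, config=config)


# ---------------------------------------------------------------------------
# continuous rendering and on-disk study layout

def render_recording(epochsets: Sequence[EpochSet], gap_s: float = 1.0) -> Recording:
    """Concatenate epochs into a continuous recording with stimulus markers.

    Trials are separated by ``gap_s`` of silence; each event marks the
    stimulus onset (t = 0 within its epoch) with the condition label.
    """
    first = epochsets[0]
    fs = first.fs
    montage = Montage(first.ch_names)
    gap = int(round(gap_s * fs))
    pre = int(round(-first.t0 * fs))
    chunks, events = [], []
    cursor = 0
    chunks.append(np.zeros((montage.n_channels, gap)))
    cursor += gap
    for ep in epochsets:
        for tr in range(ep.n_trials):
            events.append((cursor + pre, ep.condition))
            chunks.append(ep.data[tr])
            cursor += ep.n_samples
            chunks.append(np.zeros((montage.n_channels, gap)))
            cursor += gap
    return Recording(np.concatenate(chunks, axis=1), fs, montage, events)


_BV_CODES = {c: i + 1 for i, c in enumerate(CONDITIONS)}


def write_brainvision(rec: Recording, path: Path, basename: str) -> Path:
    """Write a minimal BrainVision triplet (.vhdr/.eeg/.vmrk).

    Data are stored multiplexed IEEE float32 in microvolts; markers are
    ``Stimulus`` events coding the condition (rep1 -> S  1, ...).
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    vhdr, eeg, vmrk = (path / f"{basename}{ext}" for ext in (".vhdr", ".eeg", ".vmrk"))
    n_ch = rec.montage.n_channels
    header = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        f"MarkerFile={vmrk.name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={n_ch}",
        f"SamplingInterval={1e6 / rec.fs:g}",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "[Channel Infos]",
    ]
    header += [f"Ch{i + 1}={name},,1,µV" for i, name in enumerate(rec.montage.names)]
    vhdr.write_text("\n".join(header) + "\n", encoding="utf-8")

    rec.data.astype("<f4").T.tofile(eeg)  # multiplexed: sample-major

    markers = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,0",
    ]
    for k, (sample, cond) in enumerate(rec.events, start=2):
        code = _BV_CODES.get(cond)
        desc = f"S{code:>3d}" if code else cond
        # BrainVision marker positions are 1-based
        markers.append(f"Mk{k}=Stimulus,{desc},{sample + 1},1,0")
    vmrk.write_text("\n".join(markers) + "\n", encoding="utf-8")
    return vhdr


def write_study(bundle: StudyBundle, out_dir: Path, fmt: str = "brainvision") -> Path:
    """Persist a study: one directory per subject plus behavior/ground truth."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for sid, conds in bundle.epochs.items():
        sub_dir = out_dir / sid
        if fmt == "brainvision":
            rec = render_recording(list(conds.values()))
            write_brainvision(rec, sub_dir, sid)
        elif fmt == "hdf5":
            from .preprocess import save_epochs
            sub_dir.mkdir(parents=True, exist_ok=True)
            for cond, ep in conds.items():
                save_epochs(ep, sub_dir / f"{sid}_{cond}.h5")
        else:
            raise ValueError(f"unknown study format {fmt!r}")
    bundle.behavior.to_csv(out_dir / "behavior.tsv", sep="\t", index=False)
    truth = [
        {"ch_a": e.ch_a, "ch_b": e.ch_b, "band": e.band,
         "lag_degrees": e.lag_degrees, "kappa": list(e.kappa)}
        for e in bundle.ground_truth
    ]
    (out_dir / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    return out_dir
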