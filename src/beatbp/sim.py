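"""Synthetic paired PPG/ABP waveform simulator with known per-beat SBP truth.

Generates subject records at 125 Hz whose systolic blood pressure trajectory
combines a bounded per-beat random walk (steady variability) with hill-shaped
surge events (raised-cosine bumps of 10-30 mmHg over tens of beats), the
regime in which beat-to-beat SBP trend estimators need to work. Each ABP beat
attains exactly its SBP at its maximum sample and its DBP at its minimum; the
PPG beat is a two-Gaussian pulse (systolic wave + dicrotic wave) whose
amplitude rises, and systolic-peak latency shrinks, monotonically with the
beat's SBP, so the PPG-to-SBP regression task is learnable by construction.
Ground-truth beat onsets and SBP labels are emitted so the preprocessing
pipeline can be validated end to end.

This is a morphological emulator, not a hemodynamic (Windkessel) model.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import h5py
import numpy as np

__all__ = [
    "SimConfig",
    "WaveformRecord",
    "generate_record",
    "generate_cohort",
    "sbp_from_abp_peaks",
    "save_records_hdf5",
    "load_records_hdf5",
    "save_record_csv",
    "load_record_csv",
]

SBP_FLOOR = 60.0   # mmHg, random-walk clip
SBP_CEIL = 220.0
PPG_REF_SBP = 120.0  # global reference anchoring the morphology-SBP coupling


@dataclass
class SimConfig:
    """Parameters of one simulated subject record.

    Defaults emulate an 8-minute resting adult record at 125 Hz with modest
    beat-to-beat variability and roughly one >=10 mmHg surge every two
    minutes, so the >=8 min length requirement and the "at least one sequence
    with ΔSBP over 10 mmHg" inclusion criterion are both satisfiable.
    """

    duration_s: float = 480.0
    fs: float = 125.0
    hr_mean_bpm: float = 75.0
    hr_jitter: float = 0.03          # fractional cycle-length noise
    sbp_base: float = 120.0          # mmHg
    dbp_base: float = 70.0           # mmHg
    steady_sigma: float = 0.6        # mmHg per beat (random-walk scale)
    surge_rate: float = 0.5          # events / min
    surge_magnitude_range: tuple[float, float] = (10.0, 30.0)
    surge_duration_beats: int = 40
    noise_sigma: float = 0.02        # additive PPG noise (a.u.)
    baseline_wander_amp: float = 0.1  # a.u.
    seed: int = 0

    def validate(self) -> None:
        if self.duration_s <= 0 or self.fs <= 0:
            raise ValueError("duration_s and fs must be positive")
        if self.surge_magnitude_range[0] < 0:
            raise ValueError("surge magnitudes must be non-negative")
        if self.dbp_base >= self.sbp_base:
            raise ValueError("dbp_base must be below sbp_base")
        if self.hr_mean_bpm <= 0:
            raise ValueError("hr_mean_bpm must be positive")


@dataclass
class WaveformRecord:
    """One subject's paired PPG/ABP record.

    ``beat_onsets_true`` holds K+1 onset sample indices for K labelled beats:
    the start of every complete beat plus the start of the trailing partial
    beat kept at the end of the signal. ``sbp_true``/``dbp_true`` are the K
    per-beat labels. Truth fields are simulator-only; real recordings carry
    only ``ppg``/``abp``.
    """

    subject_id: str
    fs: float
    ppg: np.ndarray
    abp: np.ndarray
    beat_onsets_true: np.ndarray | None = None
    sbp_true: np.ndarray | None = None
    dbp_true: np.ndarray | None = None

    def __post_init__(self):
        if len(self.ppg) != len(self.abp):
            raise ValueError("ppg and abp must have equal length")
        if self.beat_onsets_true is not None:
            d = np.diff(self.beat_onsets_true)
            if len(d) and d.min() <= 0:
                raise ValueError("beat_onsets_true must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return len(self.ppg)


# --------------------------------------------------------------------- beats

def _abp_pulse_shape(length: int) -> np.ndarray:
    """Unit pulse on ``length`` samples: fast systolic upstroke, slower decay
    with a small dicrotic shoulder; rescaled so min=0 and max=1 on the grid."""
    phi = np.arange(length) / length
    rise_frac = 0.3
    s = np.where(
        phi < rise_frac,
        np.sin(0.5 * np.pi * phi / rise_frac) ** 2,
        np.cos(0.5 * np.pi * (phi - rise_frac) / (1.0 - rise_frac)) ** 2,
    )
    s = s + 0.08 * np.exp(-0.5 * ((phi - 0.55) / 0.07) ** 2)
    s = s - s.min()
    return s / s.max()


def _ppg_pulse(length: int, sbp: float) -> np.ndarray:
    """Two-Gaussian PPG beat; amplitude linear in absolute SBP, systolic
    latency shrinking linearly with SBP (same coupling for every subject, so
    SBP level is decodable from morphology alone)."""
    phi = np.arange(length) / length
    amp = 1.0 + 0.02 * (sbp - PPG_REF_SBP)
    amp = max(amp, 0.05)
    mu_sys = np.clip(0.30 - 0.0012 * (sbp - PPG_REF_SBP), 0.12, 0.45)
    sys_wave = amp * np.exp(-0.5 * ((phi - mu_sys) / 0.09) ** 2)
    dic_wave = 0.35 * amp * np.exp(-0.5 * ((phi - 0.65) / 0.13) ** 2)
    return sys_wave + dic_wave


def _sbp_trajectory(n_beats: int, cfg: SimConfig, rng: np.random.Generator
                    ) -> np.ndarray:
    walk = np.cumsum(rng.normal(0.0, cfg.steady_sigma, size=n_beats))
    sbp = cfg.sbp_base + walk
    # deterministic surge count so surge_rate>0 guarantees surges
    n_surges = int(round(cfg.surge_rate * cfg.duration_s / 60.0))
    if cfg.surge_rate > 0:
        n_surges = max(n_surges, 1)
    lo, hi = cfg.surge_magnitude_range
    dur = max(int(cfg.surge_duration_beats), 2)
    for _ in range(n_surges):
        mag = rng.uniform(lo, hi)
        center = rng.integers(dur // 2, max(n_beats - dur // 2, dur // 2 + 1))
        start = max(center - dur // 2, 0)
        stop = min(start + dur, n_beats)
        t = np.arange(stop - start)
        bump = 0.5 * (1.0 - np.cos(2.0 * np.pi * (t + 0.5) / dur))
        if bump.max() > 0:
            bump = bump * (mag / bump.max())  # peak exactly at drawn magnitude
        sbp[start:stop] += bump
    return np.clip(sbp, SBP_FLOOR, SBP_CEIL)


def generate_record(config: SimConfig, subject_id: str = "sim000"
                    ) -> WaveformRecord:
    """Simulate one paired PPG/ABP record.

    Deterministic: the same config (including seed) yields bit-identical
    output arrays.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    fs = config.fs
    total = int(round(config.duration_s * fs))
    mean_len = 60.0 / config.hr_mean_bpm * fs

    # draw beat lengths until the record is covered plus one extra beat
    lengths = []
    acc = 0
    while acc <= total:
        eps = np.clip(rng.normal(0.0, config.hr_jitter), -0.4, 0.4)
        ln = max(int(round(mean_len * (1.0 + eps))), int(0.25 * fs))
        lengths.append(ln)
        acc += ln
    lengths = np.asarray(lengths, dtype=int)
    onsets_all = np.concatenate([[0], np.cumsum(lengths)])
    # complete beats are those fully inside the signal of length `acc`
    n_beats = len(lengths) - 1
    n_samples = acc

    sbp = _sbp_trajectory(n_beats, config, rng)
    pp = np.maximum(
        (config.sbp_base - config.dbp_base) + 0.25 * (sbp - config.sbp_base),
        12.0,
    )
    dbp = sbp - pp

    abp = np.empty(n_samples)
    ppg = np.empty(n_samples)
    for k in range(len(lengths)):
        lo = onsets_all[k]
        ln = lengths[k]
        kk = min(k, n_beats - 1)  # trailing partial beat reuses last label
        shape = _abp_pulse_shape(ln)
        abp[lo : lo + ln] = dbp[kk] + (sbp[kk] - dbp[kk]) * shape
        ppg[lo : lo + ln] = _ppg_pulse(ln, sbp[kk])

    t = np.arange(n_samples) / fs
    if config.baseline_wander_amp > 0:
        f1, f2 = rng.uniform(0.05, 0.15), rng.uniform(0.2, 0.35)
        ph1, ph2 = rng.uniform(0, 2 * np.pi, size=2)
        ppg = ppg + config.baseline_wander_amp * (
            np.sin(2 * np.pi * f1 * t + ph1) + 0.5 * np.sin(2 * np.pi * f2 * t + ph2)
        )
    if config.noise_sigma > 0:
        ppg = ppg + rng.normal(0.0, config.noise_sigma, size=n_samples)

    return WaveformRecord(
        subject_id=subject_id,
        fs=fs,
        ppg=ppg,
        abp=abp,
        beat_onsets_true=onsets_all[: n_beats + 1],
        sbp_true=sbp,
        dbp_true=dbp,
    )


def generate_cohort(n_subjects: int, seed: int = 0,
                    base_config: SimConfig | None = None) -> list[WaveformRecord]:
    """Simulate a cohort; per-subject resting SBP ~ N(base, 8 mmHg) and heart
    rate ~ N(base, 6 bpm), each record with its own derived seed."""
    base = base_config or SimConfig()
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_subjects):
        cfg = SimConfig(**{**asdict(base)})
        cfg.sbp_base = float(np.clip(base.sbp_base + rng.normal(0, 8.0), 90, 180))
        cfg.dbp_base = cfg.sbp_base - (base.sbp_base - base.dbp_base)
        cfg.hr_mean_bpm = float(np.clip(base.hr_mean_bpm + rng.normal(0, 6.0), 45, 110))
        cfg.seed = int(rng.integers(0, 2**31 - 1))
        records.append(generate_record(cfg, subject_id=f"sim{i:03d}"))
    return records


# -------------------------------------------------------------------- labels

def sbp_from_abp_peaks(record: WaveformRecord, onsets: np.ndarray,
                       mode: str = "sbp") -> np.ndarray:
    """Per-beat label from the ABP waveform: the maximum over each
    inter-onset interval (``mode='sbp'``) or the minimum (``mode='dbp'``).

    K onsets delimit K-1 half-open intervals [o_j, o_{j+1}).
    """
    onsets = np.asarray(onsets, dtype=int)
    if len(onsets) < 2:
        import warnings

        warnings.warn("fewer than 2 onsets: no complete beat", stacklevel=2)
        return np.empty(0)
    if onsets[0] < 0 or onsets[-1] > record.n_samples:
        raise ValueError("onsets outside record bounds")
    if np.any(np.diff(onsets) <= 0):
        raise ValueError("onsets must be strictly increasing")
    reduce = np.max if mode == "sbp" else np.min
    if mode not in ("sbp", "dbp"):
        raise ValueError(f"unknown mode {mode!r}")
    return np.array(
        [reduce(record.abp[a:b]) for a, b in zip(onsets[:-1], onsets[1:])]
    )


# ------------------------------------------------------------------------ IO

def save_records_hdf5(records: list[WaveformRecord], path) -> None:
    """One group per subject: /<id>/{ppg,abp,fs,truth/*}."""
    with h5py.File(path, "w") as f:
        for rec in records:
            g = f.create_group(rec.subject_id)
            g.create_dataset("ppg", data=rec.ppg)
            g.create_dataset("abp", data=rec.abp)
            g.attrs["fs"] = rec.fs
            if rec.beat_onsets_true is not None:
                tg = g.create_group("truth")
                tg.create_dataset("beat_onsets", data=rec.beat_onsets_true)
                tg.create_dataset("sbp", data=rec.sbp_true)
                if rec.dbp_true is not None:
                    tg.create_dataset("dbp", data=rec.dbp_true)


def load_records_hdf5(path) -> list[WaveformRecord]:
    records = []
    with h5py.File(path, "r") as f:
        for sid in sorted(f.keys()):
            g = f[sid]
            kw = {}
            if "truth" in g:
                kw["beat_onsets_true"] = g["truth/beat_onsets"][...]
                kw["sbp_true"] = g["truth/sbp"][...]
                if "dbp" in g["truth"]:
                    kw["dbp_true"] = g["truth/dbp"][...]
            records.append(
                WaveformRecord(
                    subject_id=sid,
                    fs=float(g.attrs["fs"]),
                    ppg=g["ppg"][...],
                    abp=g["abp"][...],
                    **kw,
                )
            )
    return records


def save_record_csv(record: WaveformRecord, path) -> None:
    """Two-column CSV (ppg,abp) with a JSON sidecar of metadata."""
    path = Path(path)
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["ppg", "abp"])
        for p, a in zip(record.ppg, record.abp):
            w.writerow([repr(float(p)), repr(float(a))])
    meta = {"subject_id": record.subject_id, "fs": record.fs}
    if record.beat_onsets_true is not None:
        meta["beat_onsets_true"] = [int(x) for x in record.beat_onsets_true]
        meta["sbp_true"] = [float(x) for x in record.sbp_true]
        if record.dbp_true is not None:
            meta["dbp_true"] = [float(x) for x in record.dbp_true]
    path.with_suffix(".meta.json").write_text(json.dumps(meta))


def load_record_csv(path) -> WaveformRecord:
    path = Path(path)
    data = np.genfromtxt(path, delimiter=",", skip_header=1)
    meta = json.loads(path.with_suffix(".meta.json").read_text())
    kw = {}
    if "beat_onsets_true" in meta:
        kw["beat_onsets_true"] = np.asarray(meta["beat_onsets_true"], dtype=int)
        kw["sbp_true"] = np.asarray(meta["sbp_true"])
        if "dbp_true" in meta:
            kw["dbp_true"] = np.asarray(meta["dbp_true"])
    return WaveformRecord(
        subject_id=meta["subject_id"],
        fs=float(meta["fs"]),
        ppg=data[:, 0],
        abp=data[:, 1],
        **kw,
    )
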