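"""Raw paired PPG/ABP records -> contextual-cycle dataset.

The pipeline follows the construction used for beat-to-beat SBP trend
estimation from single-channel PPG:

1. screen records (length >= 8 min, quality mask),
2. band-pass the PPG with a zero-phase 4th-order Chebyshev II filter,
3. detect pulse onsets with a slope-sum-function (SSF) detector,
4. slice into non-overlapping cardiac cycles, length-normalise each slice to
   125 samples (zero-pad short cycles, linearly resample long ones) and label
   it with the SBP read from the ABP peak of the same interval,
5. stack n=60 consecutive disjoint slices into contextual samples paired with
   the 60-value SBP sequence,
6. keep only subjects with at least one sequence whose SBP span exceeds
   10 mmHg,
7. split each subject's samples chronologically 7:1:2 into train/val/test so
   training data always precedes test data in time.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy import signal as sps

from .sim import WaveformRecord, sbp_from_abp_peaks

logger = logging.getLogger("beatbp.preprocess")

__all__ = [
    "CycleSlice",
    "ContextualSample",
    "DatasetSplit",
    "screen_record",
    "filter_ppg",
    "detect_onsets",
    "slice_and_normalize",
    "assemble_contextual",
    "apply_inclusion",
    "split_chronological",
    "build_dataset",
    "save_dataset_hdf5",
    "load_dataset_hdf5",
    "load_uci_mat",
]

SLICE_LEN = 125           # samples per length-normalised cycle
MIN_RECORD_S = 480.0      # 8 min
CONTEXT_N = 60            # cycles per contextual sample
DELTA_SBP_MMHG = 10.0     # subject-inclusion / steady-state threshold

# Chebyshev II band-pass design (the filter family is fixed; the band and
# attenuation bracket resting cardiac content while preserving the dicrotic
# wave)
CHEB_ORDER = 4
CHEB_BAND_HZ = (0.5, 10.0)
CHEB_STOP_DB = 20.0

# anomaly-screen parameters
FLATLINE_WIN_S = 2.0
FLATLINE_REL_STD = 1e-6
ABP_RANGE_MMHG = (30.0, 250.0)
MIN_PULSE_PRESSURE = 10.0

# plausible cardiac-cycle length (40-200 bpm)
BEAT_LEN_RANGE_S = (0.3, 1.5)

# SSF onset-detector parameters (published defaults scaled to 125 Hz)
SSF_WINDOW_S = 0.128
SSF_THRESH_FRAC = 0.6
SSF_DECAY_S = 3.0
SSF_REFRACTORY_S = 0.3


@dataclass
class CycleSlice:
    """One length-normalised PPG cardiac cycle and its SBP label."""

    samples: np.ndarray          # length SLICE_LEN
    sbp: float                   # mmHg
    onset_index: int             # sample position in the source record
    source_len: int              # original cycle length in samples

    def __post_init__(self):
        if len(self.samples) != SLICE_LEN:
            raise ValueError(f"slice must have {SLICE_LEN} samples")
        if not np.isfinite(self.sbp):
            raise ValueError("sbp label must be finite")


@dataclass
class ContextualSample:
    """n chronologically ordered, disjoint cycle slices + the SBP sequence."""

    cycles: list                 # n CycleSlice
    sbp_seq: np.ndarray          # n mmHg values
    subject_id: str
    start_time: int              # sample index of the first cycle's onset

    def __post_init__(self):
        if len(self.cycles) != len(self.sbp_seq):
            raise ValueError("cycles and sbp_seq must have equal length")

    @property
    def matrix(self) -> np.ndarray:
        """(n, 125) stacked cycle matrix."""
        return np.stack([c.samples for c in self.cycles])


@dataclass
class DatasetSplit:
    train: list = field(default_factory=list)
    val: list = field(default_factory=list)
    test: list = field(default_factory=list)

    def counts(self) -> dict:
        return {"train": len(self.train), "val": len(self.val), "test": len(self.test)}


# ------------------------------------------------------------------ screening

def screen_record(record: WaveformRecord, min_len_s: float = MIN_RECORD_S):
    """Accept/reject a record and build a per-sample quality mask.

    Returns ``(record, mask)`` or ``None`` when the record is shorter than
    ``min_len_s``. The mask flags flatlined PPG spans, out-of-range ABP, and
    non-finite samples; the per-beat pulse-pressure screen is applied later,
    at slicing time, once beat boundaries exist.
    """
    if len(record.ppg) != len(record.abp):
        raise ValueError("ppg and abp must have equal length")
    n = record.n_samples
    if n / record.fs < min_len_s:
        logger.info("record %s rejected: %.1f s < %.1f s",
                    record.subject_id, n / record.fs, min_len_s)
        return None
    mask = np.ones(n, dtype=bool)
    mask &= np.isfinite(record.ppg) & np.isfinite(record.abp)
    mask &= (record.abp >= ABP_RANGE_MMHG[0]) & (record.abp <= ABP_RANGE_MMHG[1])
    # flatline screen: 2 s PPG windows, half-window hop so a flat span is
    # masked up to its boundaries
    win = int(FLATLINE_WIN_S * record.fs)
    scale = np.std(record.ppg) if np.std(record.ppg) > 0 else 1.0
    for lo in range(0, n - win + 1, max(win // 2, 1)):
        if np.std(record.ppg[lo : lo + win]) < FLATLINE_REL_STD * scale:
            mask[lo : lo + win] = False
    logger.info("record %s accepted: %d/%d samples usable",
                record.subject_id, int(mask.sum()), n)
    return record, mask


# ------------------------------------------------------------------ filtering

def filter_ppg(ppg: np.ndarray, fs: float) -> np.ndarray:
    """Zero-phase 4th-order Chebyshev II band-pass (0.5-10 Hz, 20 dB stop)."""
    if fs <= 0:
        raise ValueError("fs must be positive")
    sos = sps.cheby2(CHEB_ORDER, CHEB_STOP_DB, CHEB_BAND_HZ, btype="bandpass",
                     fs=fs, output="sos")
    padlen = 3 * (2 * len(sos) + 1)
    if len(ppg) <= padlen:
        raise ValueError("signal shorter than filter warm-up")
    return sps.sosfiltfilt(sos, ppg)


# ------------------------------------------------------------ onset detection

def detect_onsets(ppg: np.ndarray, fs: float) -> np.ndarray:
    """Slope-sum-function pulse-onset detector.

    The SSF at time t is the windowed sum of positive first differences over
    the preceding 128 ms; onsets are declared where the SSF crosses an
    adaptive threshold (a fraction of a decaying running maximum), subject to
    a 300 ms refractory period, and refined back to the local waveform foot.
    """
    ppg = np.asarray(ppg, dtype=float)
    n = len(ppg)
    w = max(int(SSF_WINDOW_S * fs), 1)
    d = np.diff(ppg, prepend=ppg[:1])
    du = np.maximum(d, 0.0)
    ssf = np.convolve(du, np.ones(w), mode="full")[:n]

    refractory = int(SSF_REFRACTORY_S * fs)
    decay = np.exp(-1.0 / (SSF_DECAY_S * fs))
    run_max = float(np.max(ssf[: min(n, int(2 * fs))])) or 1e-12
    onsets = []
    last = -refractory
    t = 1
    while t < n:
        run_max = max(run_max * decay, ssf[t], 1e-12)
        thresh = SSF_THRESH_FRAC * run_max
        if ssf[t] >= thresh and ssf[t - 1] < thresh and t - last >= refractory:
            lo = max(t - w, 0)
            onset = lo + int(np.argmin(ppg[lo : t + 1]))
            # the zero-phase filter flattens the foot into a shallow valley;
            # walk back to the earliest sample of the non-increasing run
            while onset > 0 and ppg[onset - 1] <= ppg[onset]:
                onset -= 1
            if not onsets or onset - onsets[-1] >= refractory:
                onsets.append(onset)
                last = t
        t += 1
    if not onsets:
        warnings.warn("no pulse onsets detected", stacklevel=2)
    return np.asarray(onsets, dtype=int)


# --------------------------------------------------------------------- slices

def _resample_to(x: np.ndarray, target: int) -> np.ndarray:
    """Uniform linear-interpolation resampling to ``target`` points."""
    src = np.arange(len(x))
    pos = np.linspace(0, len(x) - 1, target)
    return np.interp(pos, src, x)


def slice_and_normalize(
    ppg: np.ndarray,
    abp: np.ndarray,
    onsets: np.ndarray,
    fs: float = 125.0,
    mask: np.ndarray | None = None,
    label_mode: str = "sbp",
) -> list:
    """Cut cycles at onsets, length-normalise to 125 samples, label from ABP.

    Cycles shorter than 125 samples are right zero-padded; longer ones are
    uniformly resampled by linear interpolation. Beats outside the plausible
    0.3-1.5 s length range, overlapping masked samples, or with pulse
    pressure below 10 mmHg are dropped.
    """
    onsets = np.asarray(onsets, dtype=int)
    if len(onsets) < 2:
        return []
    lo_len = int(BEAT_LEN_RANGE_S[0] * fs)
    hi_len = int(BEAT_LEN_RANGE_S[1] * fs)
    reduce = np.max if label_mode == "sbp" else np.min
    slices = []
    for a, b in zip(onsets[:-1], onsets[1:]):
        src_len = b - a
        if src_len < lo_len or src_len > hi_len:
            continue
        if mask is not None and not mask[a:b].all():
            continue
        seg_abp = abp[a:b]
        if seg_abp.max() - seg_abp.min() < MIN_PULSE_PRESSURE:
            continue
        seg = np.asarray(ppg[a:b], dtype=float)
        if src_len < SLICE_LEN:
            out = np.concatenate([seg, np.zeros(SLICE_LEN - src_len)])
        elif src_len > SLICE_LEN:
            out = _resample_to(seg, SLICE_LEN)
        else:
            out = seg.copy()
        slices.append(
            CycleSlice(samples=out, sbp=float(reduce(seg_abp)),
                       onset_index=int(a), source_len=int(src_len))
        )
    return slices


# ------------------------------------------------------------------- assembly

def assemble_contextual(slices: list, n: int = CONTEXT_N,
                        subject_id: str = "") -> list:
    """Greedy non-overlapping windows of ``n`` consecutive slices.

    Consecutive means contiguous beats in the source record (next onset ==
    previous onset + previous source length); runs broken by dropped beats
    are never bridged, and trailing remainders shorter than ``n`` are
    discarded. No beat appears in two samples.
    """
    if len(slices) < n:
        if slices:
            warnings.warn(f"fewer than {n} usable slices", stacklevel=2)
        return []
    samples = []
    run: list = []
    for s in slices:
        if run and s.onset_index != run[-1].onset_index + run[-1].source_len:
            run = []
        run.append(s)
        if len(run) == n:
            samples.append(
                ContextualSample(
                    cycles=list(run),
                    sbp_seq=np.array([c.sbp for c in run]),
                    subject_id=subject_id,
                    start_time=run[0].onset_index,
                )
            )
            run = []
    if not samples:
        warnings.warn(f"fewer than {n} consecutive usable slices", stacklevel=2)
    return samples


# ------------------------------------------------------- inclusion, splitting

def apply_inclusion(samples_by_subject: dict, delta_thresh: float = DELTA_SBP_MMHG
                    ) -> dict:
    """Keep a subject iff at least one sequence spans strictly more than
    ``delta_thresh`` mmHg (max - min of its SBP sequence)."""
    kept = {}
    for sid, samples in samples_by_subject.items():
        spans = [float(np.max(s.sbp_seq) - np.min(s.sbp_seq)) for s in samples]
        if any(sp > delta_thresh for sp in spans):
            kept[sid] = samples
        else:
            logger.info("subject %s excluded: max ΔSBP %.2f <= %.2f mmHg",
                        sid, max(spans, default=0.0), delta_thresh)
    return kept


def split_chronological(samples_by_subject: dict,
                        ratios: tuple = (7, 1, 2)) -> DatasetSplit:
    """Per-subject chronological 7:1:2 split.

    With k samples, the first floor(0.7 k) go to train, the next floor(0.1 k)
    to val, and the remainder to test, so training data always precedes test
    data in time. Subjects with k < 3 contribute to train only.
    """
    total = sum(ratios)
    split = DatasetSplit()
    for sid, samples in samples_by_subject.items():
        samples = sorted(samples, key=lambda s: s.start_time)
        k = len(samples)
        if k < 3:
            warnings.warn(f"subject {sid}: only {k} samples, all to train",
                          stacklevel=2)
            split.train.extend(samples)
            continue
        n_train = int(np.floor(ratios[0] / total * k))
        n_val = int(np.floor(ratios[1] / total * k))
        split.train.extend(samples[:n_train])
        split.val.extend(samples[n_train : n_train + n_val])
        split.test.extend(samples[n_train + n_val :])
    return split


# ------------------------------------------------------------------- pipeline

def build_dataset(
    records: list,
    n: int = CONTEXT_N,
    min_len_s: float = MIN_RECORD_S,
    delta_thresh: float = DELTA_SBP_MMHG,
    use_true_onsets: bool = False,
    label_mode: str = "sbp",
    ratios: tuple = (7, 1, 2),
) -> tuple[DatasetSplit, dict]:
    """Full pipeline: screen -> filter -> onsets -> slices -> contextual
    samples -> inclusion -> chronological split.

    ``use_true_onsets=True`` bypasses filtering and detection and uses the
    simulator's ground-truth beat boundaries (for validating the labelling
    path in isolation). Returns the split and a manifest of per-stage counts.
    """
    manifest = {
        "records_in": len(records),
        "records_rejected": 0,
        "excluded_subjects": [],
        "beats": 0,
        "samples": 0,
        "per_subject": {},
    }
    by_subject: dict = {}
    for rec in records:
        screened = screen_record(rec, min_len_s=min_len_s)
        if screened is None:
            manifest["records_rejected"] += 1
            continue
        rec, mask = screened
        if use_true_onsets:
            if rec.beat_onsets_true is None:
                raise ValueError("record has no ground-truth onsets")
            onsets = rec.beat_onsets_true
            ppg_f = rec.ppg
        else:
            ppg_f = filter_ppg(rec.ppg, rec.fs)
            onsets = detect_onsets(ppg_f, rec.fs)
        slices = slice_and_normalize(ppg_f, rec.abp, onsets, fs=rec.fs,
                                     mask=mask, label_mode=label_mode)
        samples = assemble_contextual(slices, n=n, subject_id=rec.subject_id)
        manifest["beats"] += len(slices)
        manifest["per_subject"][rec.subject_id] = {
            "beats": len(slices),
            "samples": len(samples),
        }
        if samples:
            by_subject.setdefault(rec.subject_id, []).extend(samples)

    kept = apply_inclusion(by_subject, delta_thresh=delta_thresh)
    manifest["excluded_subjects"] = sorted(set(by_subject) - set(kept))
    manifest["subjects_out"] = len(kept)
    manifest["samples"] = sum(len(v) for v in kept.values())
    split = split_chronological(kept, ratios=ratios)
    manifest["split"] = split.counts()
    return split, manifest


# ------------------------------------------------------------------------- IO

def _pack(samples: list):
    m = len(samples)
    if m == 0:
        return (np.empty((0, 0, SLICE_LEN)), np.empty((0, 0)), [], [])
    n = len(samples[0].cycles)
    cyc = np.stack([s.matrix for s in samples])           # (m, n, 125)
    sbp = np.stack([s.sbp_seq for s in samples])          # (m, n)
    sids = [s.subject_id for s in samples]
    starts = [s.start_time for s in samples]
    return cyc, sbp, sids, starts


def save_dataset_hdf5(split: DatasetSplit, path, manifest: dict | None = None
                      ) -> None:
    """Groups train/val/test with datasets cycles [m,n,125] and sbp [m,n]."""
    with h5py.File(path, "w") as f:
        for name in ("train", "val", "test"):
            cyc, sbp, sids, starts = _pack(getattr(split, name))
            g = f.create_group(name)
            g.create_dataset("cycles", data=cyc)
            g.create_dataset("sbp", data=sbp)
            g.create_dataset("subject_id",
                             data=np.array(sids, dtype=h5py.string_dtype()))
            g.create_dataset("start_time", data=np.asarray(starts, dtype=int))
        if manifest is not None:
            f.attrs["manifest"] = json.dumps(manifest)


def load_dataset_hdf5(path) -> tuple[DatasetSplit, dict | None]:
    split = DatasetSplit()
    with h5py.File(path, "r") as f:
        for name in ("train", "val", "test"):
            g = f[name]
            cyc = g["cycles"][...]
            sbp = g["sbp"][...]
            sids = [s.decode() for s in g["subject_id"][...]]
            starts = g["start_time"][...]
            for i in range(len(cyc)):
                cycles = [
                    CycleSlice(samples=cyc[i, j], sbp=float(sbp[i, j]),
                               onset_index=0, source_len=SLICE_LEN)
                    for j in range(cyc.shape[1])
                ]
                # onset bookkeeping is not persisted; keep ordering via start_time
                getattr(split, name).append(
                    ContextualSample(cycles=cycles, sbp_seq=sbp[i],
                                     subject_id=sids[i],
                                     start_time=int(starts[i]))
                )
        manifest = json.loads(f.attrs["manifest"]) if "manifest" in f.attrs else None
    return split, manifest


def load_uci_mat(path, fs: float = 125.0) -> list:
    """Optional reader for the UCI cuffless-BP MAT layout: a cell array of
    3xT matrices with PPG in row 0 and ABP in row 1 (ECG row 2 ignored)."""
    records = []
    try:
        with h5py.File(path, "r") as f:  # MATLAB v7.3
            key = next(k for k in f.keys() if not k.startswith("#"))
            refs = f[key]
            flat = np.asarray(refs).ravel()
            for i, ref in enumerate(flat):
                mat = np.asarray(f[ref])
                if mat.shape[0] != 3:
                    mat = mat.T
                records.append(
                    WaveformRecord(subject_id=f"uci{i:04d}", fs=fs,
                                   ppg=np.asarray(mat[0], dtype=float),
                                   abp=np.asarray(mat[1], dtype=float))
                )
    except OSError:
        from scipy.io import loadmat  # pre-v7.3 fallback

        raw = loadmat(path)
        key = next(k for k in raw.keys() if not k.startswith("__"))
        for i, mat in enumerate(np.asarray(raw[key]).ravel()):
            mat = np.asarray(mat)
            if mat.shape[0] != 3:
                mat = mat.T
            records.append(
                WaveformRecord(subject_id=f"uci{i:04d}", fs=fs,
                               ppg=np.asarray(mat[0], dtype=float),
                               abp=np.asarray(mat[1], dtype=float))
            )
    return records
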