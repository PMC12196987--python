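# beatbp

Beat-to-beat **systolic blood pressure (SBP) trend estimation from
single-channel photoplethysmography (PPG)**, posed as sequence regression
over *contextual cycles*.

Cuff-based monitors miss the continuous beat-to-beat fluctuations — and the
abrupt surges — that matter for blood pressure variability (BPV) assessment.
`beatbp` is for researchers in cuffless blood pressure estimation who want a
complete, testable reference pipeline: instead of mapping a PPG window to a
single SBP value, the input is a block of n consecutive, non-overlapping,
length-normalised PPG cardiac-cycle slices C = [c₁, …, cₙ] and the output is
the n-value SBP sequence S = [SBP₁, …, SBPₙ], labelled from the peaks of a
simultaneously recorded arterial blood pressure (ABP) waveform.

The model is two-stage:

1. **Intra-cycle feature extraction** — each cycle slice passes through a
   shared **ResU block** (1-D U-shaped conv encoder/decoder wrapped in
   residual structure): `f_j = f_cir(f_up^d(f_res^r(f_down^d(f_cir(c_j))))) + c_j`.
2. **Context-sensitive interaction** — the n feature tokens F ∈ R^{n×l} run
   through pre-norm Transformer layers whose attention scores carry a
   **signed sinusoidal relative-position bias**:
   `p_{a,b} = sign(a−b)·PE(|a−b|)`,
   `Attention = Softmax(QKᵀ/√d_k + W_pᵀ p) V`,
   followed by a per-token projection head to the SBP sequence.

Training is Adam + mean-absolute-error loss; evaluation covers sequence
metrics (MAE; Rseq, the mean within-sequence Pearson correlation; VE, the
variability error between first-order difference sequences), ME/SD,
10-beat-averaged variants, steady/unsteady detection (span > 10 mmHg),
Bland–Altman agreement, and AAMI / BHS device-validation verdicts.

Because the public ICU waveform data the method targets cannot ship with a
package, `beatbp` includes a **synthetic paired PPG/ABP simulator** with
known per-beat SBP ground truth (random-walk baseline + hill-shaped surges,
PPG morphology monotonically coupled to SBP) so the entire pipeline is
buildable and testable offline. The network runs on a small, fully tested
numpy autodiff engine — no GPU or deep-learning framework required.

## Worked example

```bash
# a 6-section YAML drives every stage; see beatbp.config.PipelineConfig
beatbp simulate   --config config.yaml --out records.h5 --seed 1
beatbp preprocess --in records.h5 --out dataset.h5 --config config.yaml
beatbp train      --dataset dataset.h5 --config config.yaml --out-dir run
beatbp evaluate   --checkpoint run/checkpoint.npz --dataset dataset.h5 \
                  --out report.json
```

With a small demo configuration (10 simulated subjects × 240 s, n = 15
cycles per sample, reduced model: 8 base channels / 1 Trans-RPE layer /
2 residual blocks, 30 epochs at lr 1e-3) this prints:

```
wrote 10 subject(s), 2959 beats -> records.h5
{ "records_in": 10, "records_rejected": 0, "subjects_out": 10,
  "beats": 2847, "samples": 165, "excluded_subjects": [],
  "split": { "train": 109, "val": 11, "test": 45 } }
trained 30 epoch(s) (total 30), best val MAE 1.9685 mmHg -> run
sequences: 45  subjects: 10
MAE    1.713 mmHg   Rseq  0.319   VE  0.742 mmHg
ME     0.298 mmHg   SD    2.335 mmHg
beat-avg MAE 1.474  ME 0.281  SD 1.947 mmHg
state detection: ACC 0.7778  Pre 0.0000  Rec 0.0000  F1 0.0000  (TP 0 FP 0 FN 10 TN 35)
BHS: 95.70% / 99.85% / 100.00%  grade A
AAMI: fail (ME 0.298, SD 2.335, n=10)
Bland-Altman: 0.298 [-4.279, 4.874] mmHg, 93.9% within
```

Reading the numbers: every test sequence's 15 beats are predicted with a
mean absolute error of 1.7 mmHg and the trend error VE of 0.74 mmHg; 95.7 %
of absolute errors fall within 5 mmHg, so the run grades BHS A, while AAMI
fails purely on the subject count (10 < 85). At this tiny demo scale the
predictions are still too smooth to cross the 10 mmHg surge threshold, so
unsteady-state recall is 0 — the 60-subject study below resolves this —
and Rseq is modest because within-sequence variation is small relative to
the residual error. `beatbp predict` applies a trained checkpoint to raw
PPG records without ABP labels.

## Layout

| module | role |
| --- | --- |
| `beatbp.sim` | synthetic paired PPG/ABP records with per-beat truth |
| `beatbp.preprocess` | screening, Chebyshev II filtering, slope-sum onset detection, cycle slicing/labelling, contextual assembly, inclusion, chronological 7:1:2 split |
| `beatbp.autodiff` | minimal tape-based reverse-mode autodiff on numpy |
| `beatbp.model` | ResU blocks, Trans-RPE layers, projection head, checkpoints |
| `beatbp.train` | Adam, L1 loss, seeded loop, validation-based selection |
| `beatbp.metrics` | MAE/Rseq/VE, ME/SD, beat averaging, state detection, AAMI/BHS, Bland–Altman |
| `beatbp.experiments` | the fixed desk-scale studies |
| `beatbp.cli` / `beatbp.config` | `beatbp` command-line front end, YAML config |

See `docs/methods.md` for the model, the simulator's assumptions and what
passing tests do and do not show about real recordings.
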