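# painsense

Objective pain assessment from EEG. Self-reported pain ratings are the
clinical standard, but they fail for sedated, non-verbal or cognitively
impaired patients; an EEG-based classifier offers an observer-independent
alternative. `painsense` implements a complete, tested pipeline from raw
multichannel EEG with pain-rating event markers to pain-level predictions:

1. **I/O & labelling** — BrainVision-style triplets (`.vhdr`/`.eeg`/`.vmrk`)
   with `Comment` markers encoding `10000 + rating` for 1–10 pain ratings;
   variable 8–12 s epochs cut per event. Ratings map to a binary scheme
   (rating ≤ 5 → *no pain*, > 5 → *pain*) and a ternary severity scheme
   (≤ 3 *low*, 4–6 *moderate*, > 6 *high*).
2. **Preprocessing** — zero-phase 1 Hz high-pass, 50 Hz notch, polyphase
   downsampling 1000 → 500 Hz, extended-Infomax ICA with automatic
   artifact-component rejection.
3. **Features** — per channel, a level-5 Daubechies-4 discrete wavelet
   transform giving bands A5, D5…D1; per band the statistics
   {zero-crossing rate, 5/25/75/95th percentiles, mean, median, SD,
   variance, RMS}, concatenated into one fixed-length vector per epoch
   (62 channels → 62 × 6 × 10 = 3720 features).
4. **Augmentation** (training partitions only) — per sample
   `x·(1 ± C_mult)` with `C_mult = 0.05`, bounded uniform noise with
   realised SD equal to 2 % of the training-data SD, and frequency shifts
   `Re[ F⁻¹(2U·F(x)) · e^(±2jπ·C_freq·t) ]` with `C_freq = 0.2 Hz` — six
   rows per input — followed by SMOTE balancing (k = 5 nearest-neighbour
   interpolation) to equal class counts.
5. **Classification & evaluation** — SVM (RBF, C = 1, γ = scale), k-NN
   (k = 3), random forest (100 trees, Gini), a 1-D CNN and a stacked-LSTM
   network (Adam, categorical cross-entropy), evaluated under an 80:20
   holdout and stratified 10-fold cross-validation with accuracy,
   precision, recall, F1 and probability RMSE, all leakage-guarded.

A synthetic-session generator (`painsense.synthetic`) emulates the assumed
data structure — ~1000 Hz sampling, tens of channels, rating-conditional
alpha/beta band power, 50 Hz line noise, slow drift — so every stage is
testable without any recordings.

## Worked example

```python
import numpy as np
import painsense as ps

# 1. simulate a session: 8 channels, 40 trials, strong alpha/beta effect
cfg = ps.SimulationConfig(n_channels=8, n_events=40,
                          band_effect={"alpha": 3.0, "beta": 1.5}, seed=7)
raw, events = ps.generate_recording(cfg)

# 2. clean and epoch
clean, ica = ps.preprocess(raw, ps.PreprocessConfig(ica_max_samples=20_000))
scale = clean.fs / raw.fs
events = ps.EventTable(np.round(events.sample_index * scale).astype(int),
                       events.event_id, events.rating)
epochs = ps.epoch(clean, events)

# 3-5. features + augmentation + 10-fold evaluation of two families
report = ps.run_experiment(
    specs=[ps.ModelSpec("svm"), ps.ModelSpec("knn")],
    plan=ps.SplitPlan("kfold", k=10, seed=7),
    aug_config=ps.AugmentationConfig(seed=7),
    epochs=epochs, scheme="binary", seed=7,
)
print(report.table().to_string(index=False))
```

Output (printed by the code above):

```
family scheme protocol  accuracy  precision  recall  f1     rmse
   knn binary    kfold       1.0        1.0     1.0 1.0 0.083333
   svm binary    kfold       1.0        1.0     1.0 1.0 0.171145
```

Each row is one classifier family: mean 10-fold accuracy, positive-class
precision/recall/F1 (binary scheme), and the RMSE between predicted class
probabilities and one-hot labels. With the simulated band-power effect this
strong, both families recover the pain/no-pain distinction almost
perfectly; `report.bookkeeping` records how the training partition grew
(6× transform variants, then SMOTE balancing) inside every fold, and
`report.leakage_audit` confirms no test index ever reached a
training-only stage.

The same stages are available as a CLI:

```bash
painsense simulate --config sim.yaml --out session/
painsense epoch --vhdr session/recording.vhdr --out epochs.h5
painsense features --in epochs.h5 --out features.csv
painsense evaluate --features features.csv --scheme binary --protocol kfold \
    --models svm,knn,rf --out report/
```

## Layout

```
src/painsense/
  synthetic.py    # session generator + BrainVision-style writer
  eeg_io.py       # triplet reader, event decoding, epoching, label schemes
  preprocess.py   # filters, downsampling, Infomax ICA
  features.py     # db4 level-5 DWT + band statistics
  augment.py      # transform operators + SMOTE
  models.py       # svm/knn/rf/cnn/rnn behind one train/predict contract
  _nn.py          # numpy CNN/LSTM layers, Adam, softmax cross-entropy
  evaluate.py     # split plans, metrics, leakage-guarded experiment runner
  cli.py          # `painsense` command
docs/methods.md   # model/assumption/parameter notes
```
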