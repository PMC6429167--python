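# moodquant

Quantify depressive mood status from portable forehead EEG.

`moodquant` is a research library for computational psychiatry: it links
resting-state forehead EEG (two frontal channels, Fp1/Fp2, 512 Hz, ~5 min,
recorded twice daily over two weeks) to a quantitative mood score derived
from an ecological momentary-assessment diary, and exports the fitted model
as human-readable inference rules for clinicians.

## The method

**Mood target.** At each EEG session the subject completes a 40-item
adjective diary (POMS-SF vocabulary, seven mood categories), each item
rated 1–100 on a visual-analog slider with five verbal anchors spaced 25
points apart. For one subject the entries form a sessions × 40 matrix
`X`; column-centering and projecting onto the top eigenvector `w` of its
covariance gives the **first-principal-component (FPC) mood curve**

    y = (X − X̄) w,   ‖w‖ = 1,

oriented so that the mean loading on depression–dejection items is ≥ 0
(higher FPC = more depressed; a declining curve = amelioration).

**EEG features.** Each recording is cut into 50 %-overlapping segments.
A segment is denoised by soft-thresholding the detail coefficients of an
8-level `db5` discrete wavelet transform (universal threshold
σ·√(2 ln N), σ = MAD(D1)/0.6745) and decomposed into five subbands by
single-branch reconstruction of detail layers D3–D7, which at 512 Hz line
up with gamma (32–64 Hz), beta (16–32), alpha (8–16), theta (4–8) and
delta (2–4). From the six series (denoised + five subbands) a
**176-dimensional feature vector** is extracted per channel: 54
time-domain statistics, 54 frequency-domain features (Welch modified
periodogram: absolute/relative band power, spectral moments, plus six
cross-band ratios such as beta/theta), 56 wavelet features (statistics of
coefficient layers CD3–CD7 plus the wavelet entropy
−Σ pⱼ ln pⱼ of the per-layer energies), and 12 nonlinear features
(C0 complexity and approximate entropy per series). Segment vectors are
averaged to session level so each session pairs with one FPC value.

**Model.** A random-forest regression maps EEG features (z-scored with
training-fold statistics) to FPC values. Validation is
**Leave-One-Participant-Out Cross-Validation** (LOPOCV): each fold holds
out all sessions of one subject and scores predictions by Pearson
correlation `r` with a two-sided p value from
t = r√(n−2)/√(1−r²). Hyper-parameters are selected on a grid —
ntree 1…491 step 10, mtry 1…96 step 5 — by maximum mean fold correlation.

**Knowledge export.** Every root-to-leaf path of every fitted tree is
serialized as a Jena-style inference rule (`greaterThan` /
`lessThanOrEqual` clauses over named features with `onElectrode`
bindings, terminated by an `AssignOne` of the leaf value); applying the
rules reproduces `predict` exactly, and a feature-annotation vocabulary
translates each of the 176 names for non-ML users.

Because no clinical recordings ship with the package, a first-class
synthetic cohort generator produces EEG + diary data coupled through a
latent mood trajectory (declining week 1, optional week-2 rebound,
morning-worse diurnal rhythm), so the whole pipeline is testable and its
parameter recovery measurable.

## Worked example

`examples/04_train_evaluate.py` simulates a 3-subject toy cohort, extracts
features, builds FPC curves and runs LOPOCV:

```
dataset: 18 session rows x 352 features
patient  TrS  TeS       CC  p_value
    S01   12    6 0.934666 0.006263
    S02   12    6 0.975797 0.000872
    S03   12    6 0.946133 0.004274
mean CC = 0.9522 +/- 0.0212
```

`TrS`/`TeS` are the training/testing sample sizes of each fold (their sum
is constant: every fold holds out one whole subject); `CC` is the Pearson
correlation between the forest's predictions and the held-out subject's
FPC values — close to 1 here because the synthetic cohort couples EEG
alpha power strongly to the latent mood. The other example scripts walk
through cohort simulation, single-segment feature extraction, FPC curves
with diurnal/trend summaries, and rule export.

A thin CLI mirrors the pipeline: `moodquant simulate | extract | fpc |
train | evaluate | grid | export-rules` (see `moodquant --help`); every
run writes a JSON manifest for replay.

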