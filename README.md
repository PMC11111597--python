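# speechscreen

A research toolkit for **voice-based screening of cognitive decline
equivalent to dementia**. The screen takes a ~20-second spoken answer to the
time-orientation question — *"what is today's date and day of the week?"* —
and classifies the speaker as *dementia* or *cognitively normal* from three
kinds of information:

1. the speaker's **age** (years, study range [20, 100));
2. the **time-orientation score** s ∈ {0,…,4}: one point each for a correct
   year, month, day-of-month and weekday in the transcribed answer;
3. **20 low-order modulation-spectrum components** of the audio: for each
   MFCC trajectory c_k(t) the modulation spectrum is the log power spectrum
   along time, M_k(f) = log |F_t{c_k(t) − c̄_k}|², and the feature vector is
   the coefficient-averaged log power at the 20 lowest non-DC modulation
   frequencies (≈0.2–3.9 Hz at a 10 ms hop), the band carrying syllable-rate
   and pausing dynamics.

A gradient-boosting classifier over the 22-vector (age, s, ms_01…ms_20)
produces P(dementia); the label is positive when P ≥ 0.5. An evaluation
layer reproduces the diagnostic-accuracy analysis used for such screens:
accuracy, sensitivity and specificity with explicit fractions per facility
and per age decade, 2×2 Fisher exact tests of the diagnosis-vs-prediction
association, and an exact conditional r×c test (probability-mass two-sided
rule, full enumeration) for between-facility heterogeneity.

The intended audience is researchers in clinical speech analytics and
digital cognitive assessment who need a transparent, testable reference
implementation of this pipeline. No clinical audio is distributed; a
synthetic-cohort generator emulates the study conditions (stratum sizes and
age moments, class-dependent orientation-error rates, and syllable-like
amplitude-modulated audio with class-dependent temporal modulation).

## Worked example

Evaluate the predictions table whose per-facility confusion counts match the
published screening study (1586 participants, three facilities):

```python
from speechscreen import evaluate, table2_fixture

report = evaluate(table2_fixture())
print(report.format_table())
print(f"between-facility accuracy:    p = {report.facility_accuracy_p:.3f}")
print(f"between-facility sensitivity: p = {report.facility_sensitivity_p:.3f}")
```

prints

```
                           Accuracy            Sensitivity            Specificity
Total             98.1% (1556/1586)        97.3% (476/489)      98.5% (1080/1097)
A                   97.8% (765/782)        98.2% (279/284)        97.6% (486/498)
B                   98.8% (735/744)        97.3% (182/187)        99.3% (553/557)
C                     93.3% (56/60)          83.3% (15/18)          97.6% (41/42)
between-facility accuracy:    p = 0.015
between-facility sensitivity: p = 0.010
```

Reading: overall, 1556 of 1586 participants are classified concordantly
with the clinical diagnosis (98.1%); 476 of 489 dementia cases are detected
(sensitivity 97.3%) and 1080 of 1097 cognitively normal participants are
correctly ruled out (specificity 98.5%). The exact conditional tests on the
3×2 correct/incorrect-by-facility tables show that accuracy (p = 0.015) and
sensitivity (p = 0.010) differ between facilities — driven by the small
facility C — while every per-facility association between diagnosis and
prediction is itself significant at p < 0.001.

The full pipeline is also scriptable from the shell:

```sh
speechscreen simulate --out cohort/ --cohort balanced --n-per-class 200 --seed 42 --with-audio
speechscreen extract  --cohort cohort/cohort.csv --audio-dir cohort/audio --out features.csv
speechscreen train    --features features.csv --out model.joblib --seed 42
speechscreen screen   cohort/audio/A-dem-0000.wav --model model.joblib \
    --age 78 --reference-date 2022-11-30 --transcriber sidecar
speechscreen evaluate predictions.csv
```

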