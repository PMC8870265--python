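# cvepkit

Offline analysis toolkit for **code-modulated visual evoked potential
(cVEP) brain–computer interfaces**, focused on one question: when a user
records training data on several days, **how should the training blocks
be composed** into a classifier model?

A cVEP speller flickers every target with the same 63-bit maximal-length
binary sequence (m-sequence), circularly shifted by 2 bits per target at
a 60 Hz update rate, so one stimulation cycle lasts 1.05 s. The evoked
EEG response identifies the attended target by its phase. Classification
is template matching: for each target class *i* the training trials
**T**ᵢ,ⱼ ∈ ℝ^(m×n) (m = 16 channels, n = 1260 samples = two cycles at
600 Hz) are averaged into a template **X̂**ᵢ, and a spatial filter
**w**ᵢ ∈ ℝ^m is obtained from the first canonical correlation (CCA)
between the concatenated trials **T̂**ᵢ = [**T**ᵢ,₁ … **T**ᵢ,ₙᵦ] and the
tiled template [**X̂**ᵢ … **X̂**ᵢ]. The per-class filters are
concatenated into an ensemble matrix **W**; a test trial **T** is scored
against class *i* by the weighted sub-band correlation

  λᵢ = Σₖ aₖ · corr(vec(**X̂**ᵢₖᵀ**W**ₖ), vec(**T**ₖᵀ**W**ₖ)),
  aₖ = (k^(−1.25) + 0.25) / Σ,

where k indexes a 5-band filter bank (zero-phase 4th-order Butterworth
band-passes, 6/14/22/30/38 → 60 Hz), and the predicted class is
argmaxᵢ λᵢ. Performance is reported as accuracy and information
transfer rate, ITR = (log₂N + P log₂P + (1−P) log₂((1−P)/(N−1))) · 60/T
bits/min with N = 32 and T = 3.1 s per selection.

Because the original multi-day recordings are not public, the package
ships a seeded synthetic-EEG generator that reproduces the study's
*structure* (10 subjects × 2 sessions × 6 blocks × 32 targets, with
day-to-day drift in evoked amplitude, latency, and kernel shape), so
every protocol is exercised end to end. The block-composition protocols
are:

* **cross-session** — train on one day, test on the same day
  (leave-one-block-out) or on the other day;
* **stepwise** — blocks of both days interleaved into the sequence
  seq = 1, 7, 2, 8, 3, 9, 4, 10, 5, 11, 6, 12 and added to the model
  one at a time;
* **variants V1–V5** — fixed minimal-training splits of seq;
* **cross-subject** — every subject's session model applied to every
  other subject.

## Worked example

```python
import numpy as np
import cvepkit as ck

cs = ck.make_code_set()                       # 63-bit m-sequence, 32 shifts
study = ck.simulate_study(2, cs, seed=7)      # 2 subjects x 2 sessions x 6 blocks
ev = ck.Evaluator(study)

intra, inter = ck.cross_session_plans()[:2]   # Ms1->Ds1 (LOO), Ms1->Ds2
for subj in study.subjects:
    a = 100 * ev.plan_accuracy(intra, subj)
    b = 100 * ev.plan_accuracy(inter, subj)
    print(f"subject {subj}: intra {a:5.2f}%  inter {b:5.2f}%  "
          f"ITR {ck.itr(a / 100):.2f} / {ck.itr(b / 100):.2f} bits/min")
```

Output of this exact snippet:

```
subject 1: intra 94.79%  inter 11.98%  ITR 86.07 / 2.14 bits/min
subject 2: intra 79.69%  inter 53.65%  ITR 63.20 / 33.05 bits/min
```

Intra-session accuracy is high (the generator's default SNR is
calibrated so it averages in the mid-90s), while transferring the day-1
model to day-2 data costs accuracy — sometimes drastically, as for
subject 1 here, whose session effects drew a large kernel drift. That
spread across subjects, and the recovery obtained by mixing blocks from
both days into the model, are exactly what the block-composition
protocols quantify. The same pipeline is available
from the shell: `cvepkit simulate | codes | train | classify | evaluate
| itr | report` (see `cvepkit --help`).

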