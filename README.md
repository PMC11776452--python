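# cardiosync

Cardiorespiratory synchrony analysis for audiences experiencing a shared
stimulus — typically a live or recorded music performance. The package
takes continuous ECG and respiration-belt recordings (or generates
synthetic concert audiences with known ground truth) and quantifies how
strongly heart and breathing dynamics lock to the music and to each
other, comparing audio-visual (AV, performer visible) against audio-only
(AO) presentation.

It is written for psychophysiologists and music-cognition researchers who
want a tested, reproducible implementation of the full chain: signal
preprocessing, peak extraction, rate/phase conversion, windowed synchrony,
circular-shift significance testing, and mixed-model condition contrasts.

## The measures

All series live on a common 20 Hz grid. With a participant's
instantaneous heart rate HR(t) (from inter-beat intervals, 60/IBI in BPM)
and the stimulus spectral flux F(t) (Euclidean distance between magnitude
spectra of successive 25 ms frames, 50% overlap), synchrony is computed in
10-s sliding windows with a 1-s hop:

- **SRC** (stimulus–response correlation): windowed Pearson
  r(F(t), HR(t + τ)), with a common group lag τ estimated as the mean of
  per-participant optima over the first 10 s of the piece (searched up to
  one mean cardiac/respiratory cycle).
- **ISC** (inter-subject correlation): windowed Pearson r for every
  participant pair within one concert, combined by Fisher-z averaging
  (tanh of the mean of atanh r).
- **SRPC / ISPC**: the phase-coherence counterparts, computed on wrapped
  cycle phase (0 at each R-peak / inspiration peak, ±π at mid-cycle)
  against band-limited flux phase, using the phase-clustering statistic
  |n⁻¹ Σᵣ exp(i θᵣ)| ∈ [0, 1]. The flux band is the interquartile range
  of the audience's own mean heart/respiration frequencies.

Significance is assessed against circular-shift surrogates: each
participant's peak train is rotated by a uniform random offset modulo the
piece length (1000 shifts by default; tests and examples scale this
down), the one-sample t statistic of the time-averaged observations forms
the null, and p-values are FDR-adjusted across measures. AV-vs-AO
contrasts use linear mixed models with random intercepts for concert,
piece and participant plus a participant modality slope, simplified in a
declared order when singular.

## Worked example

```python
from cardiosync.model import ConcertSynchrony
from cardiosync.synth import generate_study

study = generate_study(seed=1, n_concerts=2, n_per_concert=4,
                       piece_seconds=120.0, section_counts=(5, 5, 5))
model = ConcertSynchrony.from_study(study)
results = model.fit(measures=("SRC-HR", "ISC-HR", "ISC-RR"),
                    n_perm=50, seed=0)
print(results.permutation.to_string(index=False))
```

prints (seed 1):

```
measure  observed_t        p        q
 SRC-HR   29.372818 0.019608 0.029412
 ISC-HR   14.789129 0.019608 0.029412
 ISC-RR    2.759941 0.039216 0.039216
```

Each row is one synchrony measure: `observed_t` is the one-sample t
statistic of its time-averaged per-section observations against zero, `p`
the circular-shift permutation p-value (with 50 permutations the
resolution floor is 1/51 ≈ 0.0196 — the SRC-HR and ISC-HR statistics beat
every surrogate), and `q` the FDR-adjusted value. This synthetic audience
is stimulus-coupled by construction, so all three correlation measures
are detected as above chance. `results.summary()` additionally reports
the estimated group lag — 526 ms here, within two 50-ms grid steps of the
generator's true 600 ms stimulus→heart lag on this small audience —
the AV−AO mixed-model contrasts, and the boundary orienting-response
profile; `results.plot_epochs("ISC-HR")` draws synchrony around section
boundaries per condition.

The same pipeline runs from the shell:

```
cardiosync run --seed 1 --out results/run1 --measures SRC-HR,ISC-HR --n-perm 200
cardiosync simulate --seed 1 --out synthetic_study   # write CSV/WAV layout
```

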