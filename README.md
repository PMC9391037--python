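# fetalvoc

Analysis pipeline for the prenatal development of vocal-motor behavior in the
common marmoset. Fetal orofacial (mouth-opening) and head movements scored
from ultrasound at 30 Hz are coded into five co-occurrence states; the
developmental rise of "order" is quantified with Shannon entropy and
Kullback-Leibler divergence; orofacial-head decoupling is tested against a
duration/latency-preserving permutation null; and fetal mouth-movement
temporal profiles are matched to infant call signatures via dynamic time
warping (DTW) against barycenter-averaged (DBA) contact-call templates and
via duration x syllable-number criteria boxes. A synthetic-data module
generates cohorts with the study's structure, so the entire pipeline runs and
is tested without any recordings.

Intended for researchers in developmental neuroscience, computational
ethology, and bioacoustics who work with scored behavioral event streams and
movement/vocalization time series.

## The measures

With movements of one kind merged into units whenever gaps are ≤ 500 ms (15
frames), each occurrence is an isolated orofacial (S1) or head (S2) movement,
an orofacial-led (S3) or head-led (S4) overlap, or a synchronous onset (S5).
Per session with state frequencies P:

- entropy `H(X) = -Σᵢ P(X=i) log₂ P(X=i)` (0 log 0 := 0), ceiling log₂5 ≈ 2.32
  bits;
- divergence from the early-gestation (E93-99) baseline distribution,
  `KL = Σᵢ Qᵢ log₂(Qᵢ/Pᵢ)` with Q the session and P the baseline;
- percent overlap `(#S3 + #S4 + #S5) / (#orofacial + #head units)`, compared
  with a 1000-replicate shuffle that preserves each stream's duration and
  latency marginals;
- normalized DTW cost (local cost |aᵢ-bⱼ|, steps {(1,0),(0,1),(1,1)}) of each
  fetal profile to its best of seven DBA contact-call templates (1-7
  syllables), summarized as per-session medians;
- percent of complete units matching the contact (3.69-6.5 s × 5-9
  syllables), twitter (0.96-1.5 s × 2-3), and lick (0.33-3.77 s × 1-6 ∪
  6.67-14.29 s × 10-16) signature boxes.

Trends over gestational day use AIC-selected polynomial fits; significance
uses multiple linear regression controlling for pregnancy with a single-term
ANOVA nullity test (F = t²). See `docs/methods.md` for every modeling and
numerical choice.

## Worked example

The numbered drivers under `analysis/` run the full study on a synthetic
cohort and write tables under `results/`:

```sh
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_state_coding.py
python analysis/03_entropy_divergence.py
python analysis/04_rates_overlap.py --seed 1
python analysis/05_template_matching.py --seed 1
python analysis/06_call_signatures.py
```

Output of the seed-1 run:

```
cohort: 64 sessions across 4 pregnancies
movement units: 969 orofacial, 755 head
...
mean state distribution (S1..S5):
  early (<=E110): [0.129 0.408 0.15  0.27  0.043]
  late  (>=E130): [0.657 0.271 0.043 0.024 0.005]
entropy: AIC degree 4; slope -0.0177 bits/day, F[1,59]=34.45, p=2.1e-07
KL from E93-99 baseline: AIC degree 1; slope +0.0399 bits/day, F[1,59]=69.93, p=1.3e-11
orofacial rate: AIC degree 2 (inverse-U profile)
head rate: AIC degree 1 (linear profile)
overlap: AIC degree 1; slope -0.00617/day, F[1,59]=127.24, p=2.3e-16
permutation null (1000 reps): slope CI [-3.98e-04, 3.29e-04] covers 0 (flat);
  mean regression line p=0.231
session-median DTW (64 sessions): beta±SE = -0.0022±0.0002, t=-14.76,
  F[1,59]=217.99, p=1.8e-21
percent match contact: beta±SE = 0.775±0.081 %/day, F[1,59]=90.85, p=1.5e-13
```

Reading the numbers: early sessions spread across all five states (entropy
near 2 bits) while late sessions collapse onto isolated movements, so entropy
falls and divergence from the early repertoire grows. The orofacial rate is
an inverse-U (degree 2) and the head rate linear (degree 1). Observed overlap
declines steeply and sits above the flat permutation envelope early in
gestation — the decoupling is not a movement-rate artifact. Session-median
DTW cost to infant contact-call templates declines (profiles grow
contact-like), and the share of units matching the contact signature rises
~0.8 %/day while twitter- and lick-like shares fall.

The same computation is available in one call:

```python
from fetalvoc.pipeline import PipelineConfig, run_pipeline
result = run_pipeline(PipelineConfig(seed=1), outdir="results/run1")
print(result.rate_fits["orofacial"].degree)   # 2
print(result.overlap_regression.p)            # 2.3e-16
```

To analyze real scored data instead, write the event and session tables in
the documented CSV dialect (`fetalvoc.readwrite`) and pass the sessions to
`run_pipeline(config, sessions=...)`.

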