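# cvmstage

Objective cervical vertebral maturation (CVM) staging from 2D landmarks.

Orthodontic treatment timing hinges on whether a growing patient is
pre-pubertal, pubertal or post-pubertal. The conventional read-out —
visual CVM staging of cervical vertebrae C2–C4 on the lateral
cephalometric radiograph already taken for diagnosis — is notoriously
observer-dependent. `cvmstage` implements an *objective* alternative:
from 17 named landmarks traced on C2, C3 and C4 it computes three
measurements and classifies the subject against published per-stage
reference values.

The measurements, per vertebra:

- **SWIA** (Superior Wall Inclination Angle, C3/C4): the angle
  CS^CP between the superior border (Cua–Cup) and the posterior border
  (Cup–Clp), measured at their shared corner Cup. Rises from ~74° to
  ~83° across maturation.
- **CD** (Concavity Depth, C2/C3/C4): the perpendicular distance from
  the deepest point Cd of the inferior border to the lower-border line
  CL (Cla–Clp). Zero on the flat pre-pubertal border, ~2 mm
  post-pubertally.
- **BS** (Body Shape, C3/C4): the ratio BW/BH, where BW and BH are the
  perpendicular distances from the superior-border midpoint Cum to the
  posterior-border line CP and to CL. Falls from ~1.7 (wide trapezoid)
  to ~1.0 (square).

Because no classification rule accompanies the published reference
table, the package provides two transparent rules built from the summary
statistics alone — an equal-prior Gaussian (naive-Bayes-style) score and
a robust scaled-L1 centroid distance — plus the full statistical
pipeline used to characterise the stages (normality triage, one-way
ANOVA / Kruskal–Wallis with Bonferroni/Dunn post-hocs, eta², compact
letter display, ICC reliability) and a synthetic vertebra generator
that inverts the measurement geometry exactly, so every component is
testable without patient data.

## Worked example

```python
import numpy as np
import cvmstage as cvm

ref = cvm.load_reference()                      # published per-stage values
rng = np.random.default_rng(0)

# draw a pubertal subject, build its landmarks with 0.4 mm tracing noise
p = cvm.sample_profile("pubertal", ref, rng)
subj = cvm.profile_to_landmarks(p, rng, subject_id="demo",
                                jitter_sd=0.4, rigid_motion=True)

q = cvm.profile(subj)                           # measure the 11 outcomes
print({k: round(v, 2) for k, v in q.as_dict().items()})
call = cvm.classify(q, ref)
print(call.stage, {s: round(v, 2) for s, v in call.scores.items()})
```

prints

```
{'swia_c3': 80.44, 'swia_c4': 79.83, 'cd_c2': 2.26, 'cd_c3': 1.66,
 'cd_c4': 1.29, 'bw_c3': 14.17, 'bw_c4': 13.88, 'bh_c3': 9.6,
 'bh_c4': 11.55, 'bs_c3': 1.48, 'bs_c4': 1.2}
pubertal {'pre-pubertal': -64.44, 'pubertal': -12.27, 'post-pubertal': -31.08}
```

The measured SWIA (~80°), concavity depths (>0) and body-shape ratios
(~1.2–1.5) sit squarely in the pubertal reference column, and the
pubertal log-density score (−12.3) dominates the pre-pubertal (−64.4)
and post-pubertal (−31.1) scores, so the subject is called pubertal,
unambiguously — despite the injected tracing noise.

The same workflow is available from the shell:

```sh
cvm simulate --seed 1 --counts 59,220,115 --jitter 0.5 \
    --out-annotations ann.csv --out-truth truth.csv
cvm measure --in ann.csv --out profiles.csv        # add --scale 1.4 for film frames
cvm stage   --in profiles.csv --out calls.json
cvm compare --in cohort.csv --out report.json      # Table-style group comparison
cvm icc     --in ratings.csv --model icc2_1        # reliability
```

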