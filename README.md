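# trisscore

Trauma severity scoring, TRISS survival prediction and cohort outcome
audit, for trauma-registry and care-quality researchers.

Trauma units judge their performance by comparing observed deaths with
the number a reference model predicts for the same case mix. This package
implements the full TRISS (Trauma and Injury Severity Score) pipeline
behind that comparison:

* **ISS** — anatomical severity from per-region AIS grades: the three
  highest of the six regional grades are squared and summed (0–75; any
  unsurvivable AIS 6 injury forces 75).
* **RTS** — physiological severity from coded Glasgow Coma Scale,
  systolic blood pressure and respiratory rate:
  `RTS = 0.9368·GCSc + 0.7328·SBPc + 0.2908·RRc` (0–7.8416), plus the
  unweighted 0–12 triage code sum.
* **TRISS** — per-patient probability of survival
  `Ps = 1/(1 + e^−b)`, `b = b0 + b1·RTS + b2·ISS + b3·1(age ≥ 55)`,
  with published blunt/penetrating coefficient sets as loadable data and
  the blunt model applied to penetrating trauma under age 15.
* **Audit statistics** — expected deaths `Σ(1 − Ps)`, the standardized
  mortality ratio (SMR), excess survivors per 100 patients (W), Flora's
  standardized survivor excess (Z), the six-band case-mix match (M), and
  the expected × observed × trauma-type outcome table.
* **Synthetic registries** — a seedable generator whose defaults emulate
  a 1000-patient multiple-trauma cohort (71.4% male, 4.5% penetrating,
  ISS 15.50 ± 11.31, RTS 7.49 ± 0.79) with outcomes drawn from the TRISS
  model itself and an odds-scale excess-mortality knob, so calibration
  and miscalibration behaviour of the audit statistics can be verified
  end to end.

See `docs/methods.md` for the model details and design choices.

## Worked example

```python
from trisscore import (CohortSpec, generate_frame, score_frame,
                       predict_frame, benchmark_report)

frame = generate_frame(CohortSpec(n=1000, seed=1))       # synthetic registry
pred = predict_frame(score_frame(frame))                 # + scores, logit, Ps
report = benchmark_report(pred["ps"], pred["outcome"], pred["trauma_type"])
print(f"mean ISS  {pred['iss'].mean():.2f}   mean RTS {pred['rts'].mean():.2f}")
print(f"observed deaths {report.observed_deaths}   "
      f"expected deaths {report.expected_deaths:.1f}")
print(f"SMR {report.smr:.3f}   W {report.w:.2f}   Z {report.z:.2f}")
```

prints

```
mean ISS  16.16   mean RTS 7.51
observed deaths 42   expected deaths 35.9
SMR 1.170   W -0.61   Z -1.13
```

The cohort's sample score means sit near the generator's targets (15.50
and 7.49). Outcomes were drawn from the model itself, so the cohort is
calibrated in expectation; this particular seed happened to draw 42
deaths against 35.9 expected (SMR 1.17, Z −1.13 — about one standard
deviation of ordinary sampling noise, not a care-quality signal).
Averaged over many seeds the SMR is 1 and Z is standard normal, which is
exactly what the test suite checks.

The same pipeline runs from the shell:

```sh
triss simulate --n 1000 --seed 1 -o cohort.csv
triss score cohort.csv -o scored.csv
triss predict scored.csv --coeffs table2 -o predicted.csv
triss benchmark predicted.csv -o report.json
triss summarize scored.csv -o summary.json
```

or in one step from a JSON config: `triss run --config run.json`.

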