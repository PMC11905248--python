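# doseaccum

Automated daily **dose accumulation** for MR-guided online adaptive
radiotherapy (MRgART), aimed at physicists doing treatment QA on few-fraction
prostate SBRT (5 × 7.25 Gy = 36.25 Gy).

During an adaptive course the plan is re-optimized on each day's MRI, so the
dose the patient actually receives is spread over five different anatomies.
To judge the course as a whole, each delivered fraction dose must be mapped
back to the planning anatomy and summed. `doseaccum` implements that chain
end to end:

1. **Rigid registration** of the daily MR to the planning MR, restricted to a
   PTV-focused box (PTV_eval bounding box + 30 mm AP/RL, + 20 mm SI),
   maximizing normalized cross-correlation.
2. **Hybrid deformable registration** — a multiresolution cubic B-spline
   free-form deformation minimizing

   `C(u) = w_I · SSD(I_plan, I_daily∘(id+u)) + w_C · Σ_s SSD(φ_s^plan, φ_s^daily∘(id+u)) + λ · bending(u)`

   where `φ_s` are truncated signed distance maps of the contours — the
   "hybrid" of intensity and contour-surface agreement.
3. **Dose warping** of each per-fraction delivered dose to the planning frame
   (pull-back trilinear dose mapping).
4. **Progressive composite**: after k of N fractions,
   `composite = Σ_{i≤k} delivered_i + (N−k)/N · planned`, so delivered dose
   gradually replaces the plan fraction-by-fraction.
5. **DVH constraint evaluation** against an institutional template
   (D_x%, D_x cc, V_x Gy rows for PTV_eval, rectum, bladder, urethra PRV,
   femoral heads, penile bulb) with a replanning flag that trips when any
   constraint deviates strictly more than ±3%.
6. **Validation metrics**: DICE / Jaccard / Hausdorff (max and mean surface
   distance), global 3%/3 mm gamma analysis, and Welch t-tests for comparing
   two workflows.

A synthetic pelvis phantom with analytically known deformation fields makes
every stage testable without clinical data: daily cases are generated by
deforming the planning case through an invertibility-checked truth field and
re-planning the dose on the deformed anatomy.

## Worked example

Simulate a five-fraction synthetic patient on a 3 mm grid, run the full
pipeline, and compare the accumulated composite with the plan:

```python
from doseaccum import PhantomSpec, WorkflowConfig
from doseaccum.workflow import run_patient_case, simulate_patient

spec = PhantomSpec(seed=1).scaled((64, 64, 64))   # 3 mm demo grid
planning, dailies = simulate_patient(seed=1, spec=spec)
report = run_patient_case(planning, dailies, WorkflowConfig(), "demo")
```

This prints (via the fields of `report`):

```
PTV_eval planned    : {'D95%': 36.251, 'D0.03cc': 36.26, 'V34.4Gy': 100.0, 'V36.25Gy': 100.0}
PTV_eval accumulated: {'D95%': 35.244, 'D0.03cc': 36.26, 'V34.4Gy': 99.723, 'V36.25Gy': 50.968}
differences (acc-plan): {'D95%': -1.006, 'D0.03cc': -0.0, 'V34.4Gy': -0.277, 'V36.25Gy': -49.032}
percent discrepancies : {'V34.4Gy': -0.28, 'V36.25Gy': -49.03}
gamma pass rate (3%/3mm): 98.68
fraction 1: PTV DICE vs truth 0.994, flag=True
...
fraction 5: PTV DICE vs truth 0.992, flag=True
```

Reading this: the plan puts 36.25 Gy on 95% of PTV_eval by construction.
After five deformed fractions the accumulated D95% is ~1 Gy lower and
V36.25Gy drops sharply — the plan sits exactly *at* the prescription
isodose, so any inter-fractional motion plus interpolation pushes coverage
below the knife-edge threshold; V34.4Gy (a 5% margin below prescription)
barely moves. The per-fraction DICE ≥ 0.98 values compare the registration's
warped PTV against the ground-truth warp, and the flag shows the ±3% rule
would have requested replanning.

The same pipeline is scriptable from the shell:

```bash
doseaccum simulate --out case1 --seed 1
doseaccum run-patient --case case1 --out report.json
doseaccum evaluate --dose case1/plan_dose.nii.gz --structures case1/structures
```

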