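# ribmap

3D rib-fracture mapping and cohort statistics for high-energy chest trauma.

Multiple rib fractures are the signature injury of high-energy blunt chest
trauma, and where the fracture lines sit along the ribs — posterior near the
spine, lateral, or anterior near the sternum — drives both the surgical
approach and the expected complications. `ribmap` is for trauma researchers
who have reduced each fracture line to a position along its rib and want
population-level answers: where do fracture lines concentrate, and do
associated thoracic fractures (clavicle, scapula, thoracic vertebra, sternum)
shift that distribution?

## The model

Each fracture line on a rib is reduced to a single number, its **percentage
position** along the rib's arc length. With D1 the along-bone distance from
the costovertebral joint (where the rib meets the spine) to the fracture site
and D2 the distance from the fracture site to the costochondral junction (the
end of the bony rib),

```
position = D1 / (D1 + D2) × 100       (0 % posterior, 100 % anterior)
```

Because the position is a fraction, it is scale free and transfers between
patients: all fracture lines can be projected onto one **standard thorax
template** (24 arc-length-parameterized rib centerlines — a built-in
parametric model, or your own centerlines from CSV/PLY). The package then

- aggregates **frequency matrices** (rib × 10 %-position bin) and smoothed
  along-rib densities (boundary-reflected Gaussian kernel), and paints them
  onto the template as a **3D fracture-frequency heat map** (PLY with
  per-vertex color, blue = few fracture lines, red = many);
- classifies positions into the CWIS **anterior / lateral / posterior**
  sectors (boundaries configurable; the consensus leaves them open);
- compares positions between patients with and without each associated
  fracture using the **Mann–Whitney U** test (exact enumeration for small
  samples, tie-corrected normal approximation otherwise), and tests the
  association between clavicle fractures and upper-rib (1st–3rd) involvement
  with a **chi-square / Fisher** 2×2 test;
- **simulates** cohorts with the observed statistical structure (fracture
  counts 7 ± 3.87 per patient, the published per-rib frequency weights, a
  bimodal position mixture peaking in the 20–30 % and 60–70 % segments, flag
  prevalences, and known location shifts) so every estimator can be checked
  against ground truth.

## Worked example

Simulate a 102-patient cohort and run the statistics:

```
$ ribmap simulate --n-patients 102 --seed 7 --out sim
simulated 102 patients, 626 fracture lines -> sim

$ ribmap stats --patients sim/patients.csv --fractures sim/fractures.csv --out out
COHORT SUMMARY
  patients: 102   fracture lines: 626
  mean lines/patient: 6.14   mean position: 43.44%  (SD 24.01)
  ...
POSITION BY ASSOCIATED FRACTURE (Mann-Whitney, record level)
  clavicle           yes 44.84% (SD 24.8, n=167)  no 42.94% (SD 23.72, n=459)  U=39866.0  p=0.4417
  scapula            yes 39.29% (SD 24.55, n=119)  no 44.42% (SD 23.8, n=507)  U=26383.0  p=0.03309
  thoracic_vertebra  yes 43.71% (SD 24.96, n=39)  no 43.43% (SD 23.97, n=587)  U=11502.0  p=0.9595
  sternum            yes 49.32% (SD 22.49, n=20)  no 43.25% (SD 24.05, n=606)  U=6851.0  p=0.3202

UPPER-RIB (1-3) FRACTURE RATE BY CLAVICLE FLAG: yes 89.66%  no 76.71%  method=chi_square  p=0.1375
```

Reading it: the scapula group's fracture lines sit on average 5.1 percent
points more posterior (39.29 % vs 44.42 %, p = 0.033) — the generator planted
a −7.5-point posterior shift, and at this small sample size the test already
detects it. The sternum shift (+12 planted) is not significant here because
only 3 of 102 patients carry the flag; at realistic multi-center sizes
(n = 2000 in the test suite) both shifts are recovered within tolerance.
Clavicle-positive patients show a higher upper-rib involvement (89.7 % vs
76.7 %).

`ribmap report` runs everything at once, additionally writing `matrix.csv`,
`density.csv`, `histogram.png`, and the painted `heatmap.ply`. The same
functionality is available as a library:

```python
from ribmap import percent_position, SimulationParams, generate_cohort, position_comparison

percent_position(266.10, 36.80)        # -> 87.85 (% of rib length, anterior)
cohort, truth = generate_cohort(SimulationParams(n_patients=2000, seed=1))
position_comparison(cohort, "scapula") # mean/SD per group, U, p
```

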