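# restcm

EEG reference comparison — REST, average, linked mastoids, vertex — through
the dynamic scalp-potential **center of mass (CM)**.

## The problem

Every scalp EEG recording is measured against a reference whose own potential
is unknown and time-varying: the choice of reference shifts the entire scalp
topography up or down at each instant and can distort any topography-derived
measure. The **reference electrode standardization technique (REST)**
approximately re-expresses recordings against an idealized reference at
infinity, using a volume-conductor head model: from recordings `V_ref = G_ref S`
(lead field `G_ref`, sources `S`) a minimum-norm source estimate
`S̃ = G_ref⁺ V_ref` gives reconstructed infinity-referenced potentials

    V_ir ≈ G G_ref⁺ V_ref = U V_ref,

with `G` the infinity-referenced lead field and `⁺` the Moore–Penrose
pseudoinverse (truncated SVD).

The CM summarizes a topography in a single moving point — the electrode-
coordinate average weighted by the strictly positive instantaneous voltages:

    X(t) = Σᵢ aᵢ mᵢ(t) / Σᵢ mᵢ(t),   mᵢ(t) > 0

(similarly Y, Z), and its **traveling velocity** is the frame-to-frame CM
displacement scaled to a 10 cm head, in m/s. Because the CM weights are
voltages, it is exactly the kind of measure a bad reference distorts. This
package quantifies that distortion two ways:

1. **Simulation** — dipoles on a 1994-point grid inside a three-concentric-
   sphere head model (radii 0.87/0.92/1.0, conductivities 1.0/0.0125/1.0)
   drive damped-Gaussian bursts; the forward-projected (exact,
   infinity-referenced) scalp maps are re-referenced to REST/AR/LM/CZ and the
   relative CM error `Err = ‖CM_ref − CM_ir‖ / ‖CM_ir‖` is tabulated per
   dipole, orientation and reference, with Tukey HSD comparisons.
2. **ERP application** — a visual-oddball pipeline (6 Hz zero-phase low-pass,
   500→250 Hz, epochs −200..800 ms, baseline correction, ±75 µV rejection,
   averaging) yields per-reference CM trajectories over 200–800 ms, stage-
   resolved statistics (S1 210–350, S2 350–480, S3 480–740 ms; one-way
   repeated-measures ANOVA with Greenhouse–Geisser correction + Tukey HSD),
   and lagged cross-condition velocity correlations. A seedable synthetic
   12-subject oddball cohort generator (P200/P250/P300 equivalent dipoles +
   structured noise, recorded against FCz) stands in for human recordings.

Audience: EEG/ERP methodologists and anyone building topography-based
dynamic measures who needs to know what their reference choice costs.

## Worked example

```python
import restcm as rc

# three-shell head model, 61-channel scalp montage, 1994-dipole grid
model   = rc.HeadModel()
montage = rc.standard_cap63().drop(["VEOG", "HEOG"])
grid    = rc.build_dipole_grid()            # spacing 0.0905, r <= 0.86, z >= 0
print(len(grid))                            # 1994

lf  = rc.leadfield_infinity(model, montage, grid)
sim = rc.run_reference_comparison(model=model, montage=montage,
                                  grid=grid, lf=lf)
print(sim.summary.pivot(index="reference", columns="orientation",
                        values="mean").round(4))
```

prints the mean relative CM error per reference and dipole orientation:

```
orientation       x       y       z
reference
AR           0.0034  0.0306  0.2766
CZ           0.1304  0.1135  0.4758
LM           0.0921  0.1286  0.0786
REST         0.0253  0.0166  0.0407
```

Reading: a vertex-directed (z) dipole's CM moves by ~28% of its norm under
the average reference and ~48% under CZ, but only ~4% under REST; the linked
mastoids distort posterior sources most. For x-oriented dipoles the exactly
left-right-symmetric fixture montage makes the AR offset nearly cancel, so
AR edges out REST there — the one place the idealized geometry departs from
a digitized cap. All pairwise Tukey comparisons over the 1994 dipoles
separate at p ≪ 0.001.

The ERP side, end to end on the synthetic cohort:

```python
cohort = rc.generate_cohort()               # 12 subjects, 3 x 150 trials
res    = rc.run_oddball_analysis(cohort, references=("REST", "AR", "LM"))
m      = res["measures"]
print(m[m.reference == "REST"].groupby("condition").p300_amplitude.mean())
```

```
condition
standard    2.32
target      8.34        # µV — the oddball target evokes the P300
```

and the REST-referenced mean CM trajectory sweeps frontal → parietal →
frontal across S1/S2/S3 for 12/12 synthetic subjects.

There is also a thin CLI: `restcm leadfield`, `restcm reref`, `restcm cm`,
`restcm simulate`, `restcm synth`, `restcm erp` (see `--help`).

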