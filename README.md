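# sacao — sub-arc collimator angle optimization for multi-metastasis VMAT SRS

When several brain metastases are treated with a single-isocenter coplanar
VMAT arc, the multi-leaf collimator (MLC) must shape all lesion projections
at once. Whenever two lesions share the same leaf pair, the aperture is
forced to span the healthy tissue between them — the *island blocking*
problem — and the right collimator angle changes as the gantry rotates.
Conventional plans keep one static collimator angle per arc; this package
implements sub-arc collimator angle optimization (SACAO): it splits each
arc into a small number of contiguous sub-arcs and assigns each its own
optimal collimator angle, chosen from the geometry of the patient's own
targets. It is aimed at medical-physics researchers studying collimator
optimization; it is not a treatment planning system and computes no
deliverable dose.

## Method

For every control point (CP, one per 2° of a 358° arc) the targets are
projected from the source through the isocenter plane into the beam's eye
view (BEV), and a conformal MLC aperture is fitted at each collimator
angle θ ∈ [0°, 180°) in 1° steps. Conformity is scored by the MLC
conformity index

    MCI = A_TP / A_MLC ∈ (0, 1],

the ratio of the target-silhouette area A_TP to the fitted aperture area
A_MLC. This yields a 180 × 180 heatmap (CPs × collimator angles) per arc.
The arc is then partitioned into at most nine sub-arcs of at least 30°
each, maximizing the summed best-angle MCI per sub-arc

    max over segmentations  Σ_segments  max_θ  Σ_{cp ∈ segment} MCI[cp, θ]

by exact dynamic programming over segment boundaries; among segmentations
within 1% of the optimum, the one with the fewest sub-arcs is kept, and
each sub-arc receives its argmax collimator. Plan quality of a dose grid
is scored with the standard SRS indices

    CI = V_ref / V_T,   HI = (D2% − D98%) / Dp,   GI = V50% / V100%,

and the per-plan field size is the span-weighted mean over sub-arcs,
FS = Σ (φᵢ/Φ)·fsᵢ with Φ = 358° for a full arc. A synthetic-phantom module
generates cohort-style cases (2–5 spherical lesions, 2–18 cc, inside a
9 cm-radius head) and matching synthetic dose grids, so the whole pipeline
is testable without patient data; DICOM RT-STRUCT/RT-DOSE readers accept
real exports.

## Worked example

`examples/03_subarc_optimization.py` optimizes a seeded synthetic case
(lesions of 10 and 9.3 cc) for the conventional dual 358° arcs:

```
arc 1: 3 sub-arcs   179-13/178, 13-257/2, 257-181/178
     179 ->    13 deg (166.0 deg): collimator 178.0 deg, mean MCI 0.818
      13 ->   257 deg (116.0 deg): collimator   2.0 deg, mean MCI 0.822
     257 ->   181 deg ( 76.0 deg): collimator 178.0 deg, mean MCI 0.811
   span-weighted field size: 70.74 cm^2
arc 2: 3 sub-arcs   181-259/178, 259-15/2, 15-179/178
   ...
```

Each line is one sub-arc in "gantry start-end/collimator" notation: the
first arc runs from gantry 179° counter-clockwise to 181° in three
segments, switching the collimator between 178° and 2° where the heatmap
says the lesion projections would otherwise share leaf pairs. The mean MCI
≈ 0.82 per sub-arc means the fitted apertures expose only ~22% more area
than the target silhouettes themselves; the weighted field size (70.7 cm²)
is the jaw area a static-collimator plan would have to hold open on
average. The other examples build the phantom (01), render the MCI heatmap
(02), compute CI/HI/GI on a synthetic dose (04), and summarize the bundled
20-case cohort table (05), whose total-volume median is 19.6 cc (range
8.2–48.2 cc).

There is also a thin CLI over the same functions:

```sh
sacao phantom --lesions 10,9.3 --seed 1 --out case
sacao optimize case/structures.json --out plan      # heatmaps + plan files
sacao metrics case/dose.npz case/structures.json --out report
```

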