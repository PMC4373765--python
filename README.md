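# tractcompart

Compartment-wise diffusion tractometry of a single white-matter tract.

In multiple sclerosis, focal T2 lesions often transect only part of a fiber
bundle such as the optic radiation (OR). Splitting the tract into fibers
that traverse a lesion (*lesional*) and fibers that are lesion-free along
their entire length (*non-lesional*) turns the intact fibers into an
internal control: node-by-node comparison of the two compartments isolates
what the lesion itself does to tissue diffusivity from what degeneration
does downstream. `tractcompart` implements that analysis as a tested
library, with a synthetic bundle phantom standing in for patient data, for
researchers working on tract-specific DTI markers of demyelination and
axonal loss.

## The model

Given tensor eigenvalues λ1 ≥ λ2 ≥ λ3 (units 10⁻³ mm²/s):

    AD = λ1,   RD = (λ2 + λ3)/2,   MD = (λ1 + λ2 + λ3)/3,
    FA = √(3/2) · √( Σᵢ(λᵢ − MD)² / Σᵢλᵢ² )

Each streamline is oriented seed-end (LGN) first and resampled to 50 nodes
at equal arc-length fractions (k−1)/49. The per-node value of a scalar map
is the *fiber-core* weighted mean over fibers: with dᵢ the Mahalanobis
distance of fiber i's node point from the node's mean position under the
node's positional covariance, weights wᵢ ∝ exp(−dᵢ²/2). Nodes 46–50 are
computed but excluded from analysis (fiber fanning at the calcarine end).
The asymmetry profile between compartments is

    Δ_k = (lesional_k − non-lesional_k) / non-lesional_k .

Lesions are mapped onto the node template to build a lesion-frequency
histogram, and a cumulative Wallerian-degeneration (WD) load: a lesion
spanning nodes [a, b] contributes a linear ramp from 0 at a to 1 at b and
stays 1 distal to b — transected axons degenerate from the (unknown,
uniform) transection point all the way to the cortical end. The package
predicts, and the phantom encodes, the signature pattern: ΔRD confined to
the lesion (demyelination), ΔAD rising distal to it and tracking the
cumulative WD load, both compartments identical proximal to the lesion.

## Worked example

```sh
python analysis/02_subject_asymmetry.py
```

generates a noise-free phantom (300 fibers, one lesion covering half the
bundle cross-section, +30% RD inside the lesion, +10% AD along transected
fibers distal to it) and runs the full pipeline:

```
phantom-7: 155 lesional / 145 non-lesional fibers, lesion nodes 27-36
  peak dRD in lesion   0.286 (injected 0.30)
  |dRD| outside lesion 0.0004
  |dAD| proximal       0.0002
  dAD >= 3 nodes distal 0.094 (injected 0.10)
```

The recovered RD asymmetry peaks inside the injected lesion extent near the
injected +30% and is flat elsewhere; AD asymmetry is flat proximal to the
lesion and close to the injected +10% from the lesion's distal border
onward. `analysis/03_cohort_topography.py` runs a 20-subject cohort with
lesions concentrated in the third quarter of the tract and prints the
topographic correlations (lesion frequency vs mean ΔRD r² = 0.97, WD load
vs mean ΔAD r² = 0.89 at its default seed). `analysis/01_simulate_cohort.py`
writes the cohort to disk and `analysis/04_group_statistics.py` exercises
the group statistics (node-wise t profiles, ANOVA, paired t,
backward-elimination regression).

The same steps are available as a command-line tool:

```sh
tractcompart simulate --n-subjects 20 --seed 11 --out data/
tractcompart profile --bundle sub_bundle.trk --metric-ad ad.nii.gz \
    --metric-rd rd.nii.gz --lesions lesions.nii.gz --anchor "12,32,12" \
    --out out/
tractcompart cohort --manifest data/manifest.json --out out/
```

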