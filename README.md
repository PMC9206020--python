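# lesionmap

Voxel-based lesion-symptom mapping (VLSM) for stroke cohorts, conjunction
analysis of two lesion-behavior maps, and Tonic Stretch Reflex Threshold
(TSRT) estimation from passive-stretch recordings — plus a synthetic cohort
generator so the entire chain can be exercised and validated without any
patient data.

## Who this is for

Researchers asking *where* in the brain damage matters for a behavioral
deficit. The motivating use case is upper-limb motor impairment after
hemispheric stroke, where two deficits co-occur but may dissociate
anatomically:

- **hemiparesis** — impaired voluntary movement, measured by the Fugl-Meyer
  Assessment of the upper limb (FMA-UL, 0–66, lower = worse);
- **spasticity** — velocity-dependent hyperresistance to passive stretch,
  measured by the TSRT (degrees; smaller angle = more severe).

## The methods

**VLSM.** Given binary lesion masks on a shared template grid and one score
per subject, every voxel lesioned in at least 20% of the cohort (count
threshold ⌊0.20·n⌋; 8 of 41) is tested by comparing scores of
lesioned-here vs intact-here subjects with a Mann–Whitney rank test. The
statistic is the tie-corrected normal approximation of U,

    z = (n₁n₂/2 − U₁) / σ_U,   σ²_U = n₁n₂/12 · [(N+1) − Σ(t³−t)/N(N−1)],

signed so z > 0 when lesioned subjects score worse, with one-sided
p = 1 − Φ(z). Multiple comparisons are controlled by Benjamini–Hochberg FDR
(q = 0.05) over the tested voxels; an under-powered second analysis can
borrow a *lenient* per-voxel criterion — the minimum z that survived FDR in
the reference analysis (z ≥ 2.09 ↔ p ≤ 0.018 in the motivating cohort).
Significant voxels are reported as connected clusters of ≥ 10 voxels
(26-adjacency by default), each localized by the most superior, then
posterior, then left voxel attaining the cluster's maximum z, and tabulated
per atlas structure.

**Conjunction.** Two z maps thresholded at the shared lenient criterion
classify every tested voxel as significant for A only, B only, or both; the
selective fractions (A-only/A-total, B-only/B-total) quantify how distinct
the two lesion-behavior networks are.

**TSRT.** Each passive stretch yields a *dynamic* threshold: the elbow angle
and velocity at which the stretched muscle's EMG envelope rises and stays
3 SD above the pre-stretch background for 25 ms. Ordinary least squares of
threshold angle on stretch velocity, extrapolated to zero velocity, gives
the TSRT; an intercept above 180° (full extension) means the reflex is
outside the biomechanical range, i.e. the muscle can relax fully.

**Synthetic cohorts.** `lesionmap.synthetic` plants two partially
overlapping critical regions in a one-hemisphere territory, grows connected
lesions with lognormal volumes (≈ 32 ± 45 cc, range 0.4–182 cc), depresses
an FMA-like score by damage to region A and a TSRT-like angle by damage to
region B, and simulates stretch trials whose reflex burst fires on a planted
linear angle–velocity threshold. Ground truth is returned alongside, so
recovery (Dice against the planted regions, intercept error against the
planted TSRT) is measurable.

## Worked example

```bash
python examples/02_vlsm_mapping.py
```

```
tested voxels: 284 (lesioned in >= 8 of 41 subjects)
FDR q=0.05: 184 significant voxels (realized p* = 0.0320, z* = 1.85)
cluster 1: 183 voxels, max z = 4.24 at (-42, -2, -14) mm
...
Dice vs planted paresis region (within tested voxels): 0.60
```

284 voxels reach the 20% coverage floor; 184 survive FDR and form one
cluster whose peak z sits at left-hemisphere (negative x) world coordinates.
Dice 0.60 against the planted region means the map recovered the simulated
critical territory. The other examples cover the overlay/damage tables
(`01`), conjunction and selective fractions (`03`), TSRT estimation from
simulated stretches (`04`, recovering a planted 107.4° threshold to 108.7°),
and the one-call pipeline (`05`).

A thin CLI mirrors the library:

```bash
lesionmap synth --out cohort --seed 3
lesionmap vlsm --masks cohort/masks --scores cohort/scores.tsv \
    --score FMA_UL --out vlsm_out
lesionmap run --out full_run --seed 2
```

## Layout

- `src/lesionmap/lesion_io.py` — masks, atlases, cohorts, flipping, overlay,
  per-structure damage
- `src/lesionmap/vlsm.py` — inclusion mask, voxelwise rank test, FDR /
  lenient selection, clusters, structure tables
- `src/lesionmap/conjunction.py` — shared-vs-selective classification
- `src/lesionmap/tsrt.py` — EMG onset, dynamic thresholds, TSRT regression
- `src/lesionmap/synthetic.py` — cohort and stretch-trial generators
- `src/lesionmap/evaluation.py` — planted-truth recovery and calibration
- `src/lesionmap/pipeline.py`, `cli.py` — orchestration and shell interface

See `docs/methods.md` for the modeling choices, defaults and limitations.
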