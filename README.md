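# actnet

Quantification of force-modulated actin-binding-protein (ABP) engagement in
myosin-tensed actin bundle networks — together with a synthetic-scene
generator that produces the same kind of data with known ground truth.

## The problem

In reconstituted contractile assays, paired actin filaments become entangled
into networks of parallel bundles spanning the gaps between micropatterned
myosin stripes. Two-channel TIRF imaging records the F-actin intensity (a
proxy for the number of filaments `n` in a bundle segment) and the bound ABP
intensity. A force-sensitive crosslinker such as dimeric α-catenin binds
mechanically loaded filaments more strongly; because motors apply a total
tension to a segment that is independent of its size, filaments in *small*
bundles bear a *higher per-filament load* `F/n`, and the force-activated
binder becomes enriched on them. A force-insensitive binder instead scales
linearly with bundle size (mass action).

`actnet` implements the full analysis path from image stacks to per-segment
ratiometric statistics, and a generative model of the assay:

- **`netsim`** — stripe micropatterns, random Y/star bundle networks with
  ground truth, the force-activated occupancy law
  `rho(n) = k0 * (1 + beta * g(F/n))` (`beta = 0` encodes the
  force-sensing-deficient mutant), and TIRF-like rendering
  (PSF blur, Poisson + Gaussian noise, bleaching, 2 s frames).
- **`bundleseg`** — automated segmentation: threshold → skeletonize →
  3×3 branch-point filter → debranch → label → dilate to consistent
  5-pixel-wide segment masks.
- **`netquant`** — per-segment mean intensities and ABP:actin ratios, state
  time-averaging, cross-state segment tracking and fold changes, per-trial
  normalization, median-quadrant enrichment fractions, OLS fits, Welch's
  t-test, paired ±ATP comparisons, line-scan bundle counting, ROI boxes, and
  rupture-time census/survival summaries.
- **`stoich`** — filament stoichiometry (subunits from length at a 2.73 nm
  rise, barbed-end concentrations, per-filament load).
- **`io` / `pipeline` / `cli`** — TIFF/CSV/JSON formats, run configs, and
  the `actnet` command-line tool
  (`simulate segment quantify states compare census stoich run`).

## Worked example

```bash
actnet run --demo --outdir demo
```

simulates two conditions — a force-activated binder (`beta = 2`) and a
force-insensitive one (`beta = 0`) — on 2.5 µm stripes with 17.5 µm gaps,
segments and measures them, and prints a report (`demo/report.json`):

```json
{
  "conditions": {
    "force":   {"n_segments": 11, "quadrant_fraction": 0.091,
                "mean_ratio": 1.047},
    "noforce": {"n_segments": 14, "quadrant_fraction": 0.0,
                "linfit": {"slope": 0.968, "r": 0.991},
                "mean_ratio": 0.244}
  },
  "comparisons": {
    "force_vs_noforce": {"welch_t": 5.21, "welch_df": 10.0,
                         "welch_p": 0.00039}
  }
}
```

Reading the numbers: the force-insensitive condition is almost perfectly
linear (`r = 0.991` for ABP vs actin intensity) with a mean ABP:actin ratio
of `0.244 ≈ k0/a0 = 30/120` — pure mass action. The force-activated
condition has a four-fold higher mean ratio, populates the small-bundle
quadrant (above-median ABP *and* below-median actin), and differs highly
significantly by Welch's test. The stoichiometry verb prints the filament
bookkeeping used to choose assay concentrations:

```
$ actnet stoich
filament length        8.6 um
rise per subunit       2.73 nm
subunits per filament  3150 (~3000)
barbed-end conc        0.317 nM (from 1 uM actin)
```

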