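# roottrack

Spatiotemporal analysis of fluorescent cell-cycle reporter regions in
growing plant roots imaged by two-channel 3D time-lapse (light-sheet)
microscopy.

Long time courses of a mitosis reporter such as CYCB1;1:GFP in the
*Arabidopsis* root meristem produce, per replicate, a sequence of 3D
stacks in two channels: fluorescence (bright blobs where cells express
the reporter) and brightfield (the whole root, used for geometry and
registration). `roottrack` turns such a sequence into quantitative,
comparable condition profiles:

1. **Segmentation** — per-frame intensity threshold (absolute or Otsu)
   followed by a marker-controlled 3D watershed splits touching regions;
   all geometry respects the strongly anisotropic voxels (3.33 µm axial,
   0.23 µm lateral).
2. **Root coordinate system** — k-means on a smoothed
   gradient-magnitude feature of the brightfield channel yields the root
   mask; its principal axis is the longitudinal axis and the extremal
   mask voxel the tip. Each ROI gets a tip distance and a perpendicular
   axis ("center") distance in µm.
3. **Tracking and growth** — consecutive brightfield frames are
   registered by phase correlation; the translation both measures root
   growth per 20-min interval and drift-corrects ROI centroids for
   greedy one-to-one nearest-neighbour linking. A track's *persistency*
   is its observed extent in hours (a nine-sample track at 20-min
   sampling persists 3 h). Growth magnitudes `g(n)` accumulate into the
   cumulative growth curve `G(n) = Σ_{µ≤n} g(µ)`.
4. **Ten metric signals** per replicate and time stamp `n`, over the set
   of visible ROIs: persistency average X1, spread X2 and sum X3
   (= X1·X4); ROI count X4; new appearances X5; track ends X6; tip
   distance average X7 and spread X8; center distance average X9 and
   spread X10. Signals are smoothed with a 10-tap moving average of
   weight 1/10 (truncated and renormalized at edges and missing frames)
   and averaged across replicates into a condition profile `p_{i,k}(n)`.
5. **Condition comparison** — each metric is normalized by its maximum
   across all conditions, then for a pair of conditions
   `SS_{i,j}(n) = (1/10) Σ_k (P'_{i,k}(n) − P'_{j,k}(n))²`
   and `SST_{i,j} = Σ_n SS_{i,j}(n)`.

Since raw microscope data of this kind are rarely public, the package
includes a first-class synthetic phantom generator
(`roottrack.synthetic`) that renders both channels with full ground
truth (event onsets, lifetimes, positions, growth drift), so every stage
is validated against exact oracles.

## Worked example

`examples/02_segment_and_track.py` generates a 12-frame phantom with 5
reporter events and 5 voxels of growth drift per interval, segments and
tracks it, and checks the result against the programmed truth:

```
ROIs per frame: [3, 4, 5, 5, 5, 5, 5, 5, 5, 4, 4, 3]

recovered tracks (first frame, length, persistency h) vs programmed:
  recovered (0, 9, 3.0)   programmed (0, 9, 3.0)   match: True
  recovered (0, 11, 3.67)   programmed (0, 11, 3.67)   match: True
  recovered (0, 12, 4.0)   programmed (0, 12, 4.0)   match: True
  recovered (1, 11, 3.67)   programmed (1, 11, 3.67)   match: True
  recovered (2, 10, 3.33)   programmed (2, 10, 3.33)   match: True

per-interval displacement (voxels): [-0.  5. -0.] (programmed [0 5 0])
growth per interval: 1.150 µm (5 lateral voxels x 0.23 µm = 1.15 µm)
cumulative growth over 11 intervals: 12.65 µm
```

Every programmed event is recovered with its exact onset, lifetime and
persistency; the registration finds the programmed 5-voxel drift, which
converts to 1.15 µm of growth per 20-min interval. The other examples
cover phantom generation (`01`), metric computation and filtering
(`03`), condition comparison via SS/SST (`04`) and the root coordinate
system (`05`).

## Command line

The same stages are available as a thin CLI over a run directory:

```bash
roottrack simulate --run myrun --seed 1          # phantom inputs + truth
roottrack all --run myrun                        # segment → geometry →
                                                 # track → metrics →
                                                 # growth → compare
```

Each stage writes CSV artifacts under `<condition>/<replicate>/derived/`
and updates `manifest.json`; stages check for their upstream outputs and
re-running with the same seed and config reproduces identical CSVs.

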