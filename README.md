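# wormscreen

Analytics for a *C. elegans* α-synuclein drug-repurposing screen. The
package covers the three computational stages such a screen needs, each
usable on its own and each testable end-to-end against synthetic data
generated in-repo:

1. **Coiler phenotyping from video** — transgenic worms expressing
   α-synuclein in dopaminergic neurons show a subtle "coiler" motor
   phenotype: the body spends more time in a circular posture. Frames
   are segmented (dark worms on light agar, Otsu threshold), and each
   animal's silhouette is scored by the circularity shape descriptor

   `circularity = 4π · A / P²`

   with `A` the body area and `P` the perimeter (outer contour): 1 for a
   perfect circle, → 0 for elongated shapes. The normal sinusoidal crawl
   sits near 0.2, omega turns near 0.5, and coils from 0.6 up to almost
   1. The **coiler score** of a population recording is the percentage
   of tracked frames with circularity > 0.6; speed is the
   duration-weighted average of per-animal path length over tracked
   time; both can be normalised to a control group as fold-of-control.

2. **Literature diffusion ranking** — candidate drugs are ranked by
   semantic similarity to a known set of molecules that reduce
   α-synuclein oligomers. Documents become TF-IDF vectors over the most
   common terms, each drug is the centroid of its documents' vectors,
   pairwise cosine similarity defines a weighted graph, and a random
   walk with restart (restart mass uniform on the known set, α = 0.15)
   scores every candidate by proximity to the whole known set.
   Leave-one-out cross-validation re-ranks each known among the
   candidates and reports ROC/AUC, average precision and a one-tailed
   Wilcoxon rank-sum test.

3. **RT-QuIC positivity calling** — real-time quaking-induced
   conversion plates (thioflavin-T fluorescence kinetics, readings every
   45 min for 60 h, four replicate wells per sample) are thresholded at
   the mean background (diluent) fluorescence plus 5 standard
   deviations; a replicate is positive when its 60 h endpoint exceeds
   the threshold, a sample is positive when at least one replicate is,
   and group positivity counts are compared with a two-sided Fisher
   exact test.

A `simulate` subpackage generates all three kinds of input with known
ground truth: rendered multi-worm recordings with controlled posture
rates, topic-structured corpora with a tunable known/candidate
separation, and kinetic plates with background and seeded wells.

## Worked example

```python
from wormscreen.simulate import WormSimConfig, simulate_worm_recording
from wormscreen.imaging import SegmentationConfig, segment_stack
from wormscreen.tracking import link_tracks, coiler_score, average_speed

config = WormSimConfig(n_worms=10, n_frames=720, fps=2.0, arena=(360, 270),
                       worm_length=60, worm_width=6,
                       coil_prob=0.05, turn_prob=0.05, seed=3)
stack, truth = simulate_worm_recording(config)
dets = segment_stack(stack, SegmentationConfig(worm_length=60, worm_width=6))
tracks = link_tracks(dets, max_disp=6.0, max_gap=2, fps=config.fps)
print(f"coiler score {coiler_score(tracks):.2f}%  "
      f"(ground truth {100 * truth.true_coil_fraction:.2f}%)")
print(f"speed {average_speed(tracks):.2f} px/s")
```

prints

```
coiler score 5.12%  (ground truth 5.11%)
speed 3.02 px/s
```

— the pipeline recovers the simulated 5% per-frame coil probability to
within a hundredth of a percentage point on this recording, and the
3 px/s configured crawl speed to within 1%.

The same stages are exposed as a CLI (`wormscreen simulate-worms`,
`segment`, `track`, `score`, `simulate-corpus`, `rank`, `loo-validate`,
`simulate-rtquic`, `rtquic-call`, `report`); every stochastic
subcommand takes `--seed`, refuses to overwrite outputs without
`--force`, and writes a JSON run manifest beside its outputs.

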