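# tandemtrap

Quantitative analysis of leader–follower tandem running in paired animal
trajectories, and of what a sticky surface does to it — built for deciding
whether a preserved two-animal snapshot (for example a termite pair in
amber) records coordinated tandem behaviour or an artefact of entrapment.

Termite mating pairs run in tandem: a follower keeps contact with the tip
of the leader's abdomen while the pair searches for a nest site.  A pair
caught by tree resin is not fixed instantaneously — it keeps moving slowly
on the sticky surface and typically ends up side-by-side rather than in
single file.  To read behaviour out of such a frozen configuration you
need three things, which this package provides:

1. **Spatial-organization metrics** of living paired trajectories —
   speed in body lengths per second, inter-individual distance in body
   lengths, the relative direction of the partner in the focal animal's
   egocentric frame (θ ∈ [0, π], 0 = ahead, π = behind), heading
   difference, egocentric partner-density maps, and both-trapped counts
   over time.  Frames are analysed at 1 FPS, restricted to frames where
   the raw distance is below the sum of the two body lengths ("twice a
   body length", the conservative interaction reach).
2. **A randomized-pairing null**: males are re-paired across events by a
   derangement σ (no male meets his own female), each swapped
   trajectory is rigidly realigned to the original male's initial
   position and heading, and the metric distributions of real vs
   randomized pairs are compared (two-sample KS / rank-sum on pooled
   frames, plus a calibrated Monte-Carlo quantile of the real mean in
   the null distribution of replicate means).  If real pairs sit closer
   than randomized ones, their proximity reflects active interaction,
   not shared immobilization.
3. **Pose-based role inference**: each individual's head position is
   summarised by its distances to the partner's head, pronotum border,
   and abdomen tip (normalised by body length); an unregularised
   logistic regression on the three distances classifies leader vs
   follower, with a PCA of the same features for visualisation, and a
   single snapshot — each individual scored independently — yields
   leader/follower probabilities for a preserved pair.

A seeded synthetic generator (`tandemtrap.simulate`) stands in for video
data: correlated-random-walk leaders (~2 BL/s) with contact-keeping
followers, sticky-patch entrapment events (~0.06 BL/s, side-by-side
settling, exponential escape hazard), and collinear six-point skeleton
postures.  The exact inferential tests (`tandemtrap.stats`) include an
exact small-sample Wilcoxon rank-sum with the full enumeration
distribution.

## Worked example

Simulate ten trap-entry events, restrict each to its jointly-trapped
window, downsample to 1 FPS, and ask whether the pairs stay closer than
the randomized-pairing null predicts:

```python
import numpy as np
from tandemtrap import (SyntheticParams, simulate_ensemble, downsample,
                        pair_metrics, randomize_pairs, compare_real_null,
                        speed_bl_s)
from tandemtrap.pipeline import both_trapped_window

params = SyntheticParams(duration_s=300.0, fps=30.0, seed=7)
events = [downsample(both_trapped_window(e), 1.0)
          for e in simulate_ensemble(params, "trapped", 10, seed=7)]

speeds = np.concatenate([speed_bl_s(ind, 1.0)
                         for e in events for ind in (e.female, e.male)])
print(f"trapped speed: {speeds.mean():.3f} +/- {speeds.std():.3f} BL/s")

real = np.concatenate([pair_metrics(e)["distance_bl"].to_numpy() for e in events])
ens = randomize_pairs(events, n_replicates=200, seed=1)
cmp = compare_real_null(real, ens, "distance_bl", "ks")
print(f"real mean distance: {cmp.real_mean:.2f} BL; null mean: {cmp.null_mean:.2f} BL")
print(f"KS D = {cmp.test.statistic:.3f}; Monte-Carlo p = {cmp.p_mc:.4f}")
```

prints

```
trapped speed: 0.069 +/- 0.049 BL/s
real mean distance: 0.51 BL; null mean: 3.34 BL
KS D = 0.881; Monte-Carlo p = 0.0050
```

Trapped pairs crawl at ~0.07 body lengths per second and sit about half a
body length apart, while randomized pairs — same individual movement,
interaction broken — drift to more than three body lengths: the proximity
of trapped partners is behaviour, not immobilization.  The Monte-Carlo p
is the two-sided placement of the real mean among the 200 replicate
means (its floor at 200 replicates is 1/201 ≈ 0.005).

The same machinery is available from the shell:

```sh
tandemtrap simulate --condition trapped --n-events 10 --seed 7 --out data/
tandemtrap metrics --in data/ --out metrics.csv
tandemtrap nullcompare --in data/ --n 1000 --seed 1 --metric distance --test ks
tandemtrap run --config run.toml     # full pipeline with summary.json
```

## Layout

| module | contents |
| --- | --- |
| `tandemtrap.types` | `TrackedIndividual`, `PairEvent`, `PostureFrame` containers |
| `tandemtrap.io` | tidy/pose-estimation CSV readers and writers, likelihood cutoff, 1-FPS downsampling |
| `tandemtrap.simulate` | seeded synthetic tandems, entrapment events, skeleton postures |
| `tandemtrap.kinematics` | speeds, distances, relative directions, density maps, trapped counts |
| `tandemtrap.nullmodel` | rigid alignment, derangement re-pairing, real-vs-null comparison |
| `tandemtrap.posture` | tip–head asymmetry, three-distance features, PCA + logistic role model |
| `tandemtrap.stats` | exact rank-sum, two-sample KS, paired t |
| `tandemtrap.pipeline` / `tandemtrap.cli` | end-to-end orchestration and the `tandemtrap` command |

See `docs/methods.md` for the model assumptions, parameter choices, and
known limitations.
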