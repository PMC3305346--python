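# morphowave

Quantification of cell-shape dynamics from time-lapse movies of single
migrating cells — built for the amoeboid regime (*Dictyostelium*-like
cells, ~15 µm, pseudopods every ~20 s) but applicable to any closed,
simple cell outline imaged over time.

Amoeboid cells move by extending pseudopods at the front. Around the
cell boundary, each pseudopod leaves a localized bump of high curvature
that travels rearward along the side of the cell; migration can thus be
read off the boundary alone. This package turns a movie into that
reading:

1. **Boundary extraction** — an active contour (snake) on intensity
   images, or marching-squares tracing on binary masks, resampled to a
   fixed count of N = 400 equidistant points per frame.
2. **Point tracking** — the 1:1, order-preserving correspondence between
   the N points of successive frames that minimises the total squared
   displacement `Σᵢ ‖xᵢ(t) − x_{(i+s) mod N}(t+1)‖²` over the N cyclic
   shifts `s`; composing the shifts gives every material point a single
   index through the whole movie.
3. **Curvature kymographs** — signed curvature per point, κᵢ = ±1/Rᵢ
   with Rᵢ the circumradius of points (i−10, i, i+10) and sign positive
   when the flanking midpoint falls inside the cell; laid out as an
   N × T kymograph, traveling curvature waves appear as tilted lines.
4. **Local motion** — each point mapped to the closest point of the
   frame 12 s later, the mapping smoothed twice along the boundary
   (19- then 15-point windows); the signed distance to the smoothed
   target (outward positive) is the protrusion/retraction measure.
5. **Wave tracking** — per-frame curvature peaks outside the persistent
   front/back bands, linked over time; each ridge gets a speed relative
   to the cell (index slope × point spacing) and to the substrate.
6. **Events and boundary MSD** — protrusions/retractions as space-time
   extrema of the motion field; the circular-mean protrusion location
   per frame; and its arc-length mean squared displacement, whose
   log-log slope separates ballistic (slope 2) from caged (slope 0)
   protrusive motion.
7. **Synthetic cells** — a seeded generator producing boundary movies
   (and rendered TIFF stacks) with programmed wave speed, birth rate,
   side alternation and polarisation onset, logging exact ground truth
   for every bump so each stage above is testable end to end.

## Worked example

Simulate a migrating cell (10 min at 4-s frames, waves at 20 µm/min
born 3/min on alternating sides) and run the full analysis:

```python
import numpy as np
import morphowave as mw
from morphowave.waves import WaveTrackParams, detect_wave_tracks, wave_speed
from morphowave.events import extract_events, EventParams

spec = mw.SyntheticCellSpec(seed=11, duration=600, wave_speed=20.0,
                            wave_birth_rate=3.0, alternation_prob=1.0)
movie, truth = mw.generate_boundary_movie(spec)
series = mw.track_series(movie)

kymo = mw.curvature_kymograph(series, smooth=None)
tracks = detect_wave_tracks(kymo, WaveTrackParams(max_jump=30))
speeds = [wave_speed(tr, series)[0] for tr in tracks]
field = mw.local_motion(series)              # 12-s lag motion measure
events = extract_events(field, EventParams())

print(f"{len(tracks)} wave tracks, median speed "
      f"{np.median(speeds):.1f} µm/min (programmed {spec.wave_speed})")
print(f"protrusion rate {events.rate('protrusion'):.2f}/min "
      f"(programmed {spec.wave_birth_rate})")
```

prints

```
25 wave tracks, median speed 20.2 µm/min (programmed 20.0)
protrusion rate 3.06/min (programmed 3.0)
```

i.e. the detector finds the programmed curvature waves, recovers their
speed relative to the cell within ~1%, and counts one protrusion event
per programmed pseudopod birth. The same analysis runs from the shell
on TIFF stacks or boundary CSV tables:

```bash
morphowave simulate --output-dir sim --seed 11 --duration 600
morphowave run --mode mask --input sim/masks.tif \
    --pixel-size 0.2 --frame-interval 4 --output-dir out
```

`out/` then holds the boundary table, curvature and motion kymographs
(CSV + PNG), wave tracks and speeds, the event list, the MSD curve and
a `summary.json` with the headline numbers, all stamped with a config
hash for reproducibility.

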