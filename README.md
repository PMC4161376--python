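# thumbkey

Data-driven evaluation of soft-keyboard geometries for single-handed,
thumb-operated phones.

When a phone is held in one hand, the thumb's motor performance is not
uniform: empirical reciprocal-tapping studies show it is best for taps near
the top-right of the screen and for movements along the SW/NE diagonal
(right-handed users), and worst in the bottom-right corner and along the
NW/SE diagonal. Standard QWERTY keyboards sit at the bottom of the screen
and ignore this. `thumbkey` lets interaction designers and ergonomists
score large families of QWERTY keyboard geometries against those empirical
capabilities *before* building prototypes or running user studies.

## The model

A keyboard design is a triple **(R, O, L)**: the home row's radius of
curvature R in mm (`flat` = no curvature; positive R curves the keyboard
down, negative up), the orientation O in degrees about the home row's
middle key (the "G" key; counter-clockwise positive), and the vertical
location L of the G-key centre (bottom / middle / top = 1/4, 1/2, 3/4 of
the screen height). Key sizes never change.

For each design, typing a fixed text is simulated as a task analysis:
capitals cost an extra shift tap, characters on the numbers/symbols layers
cost one or two layer-switch taps, and the spacebar is modelled as 4
adjacent subkeys of which the one nearest the previous tap is used. Every
tap is binned into one of 12 screen regions (3 columns × 4 rows, numbered
row-major from the top-left) and every inter-tap movement into one of 8
compass directions. Each region and direction carries an empirical rank
`Rk(IPe)` of its effective index of performance (a Fitts'-law throughput,
bits/sec; 1 = worst). With tap distributions `D` and total tap count
`Tt`:

```
PI_TL,gross = Σ_regions    D(region)    · Rk(IPe_region)
PI_MD,gross = Σ_directions D(direction) · Rk(IPe_direction)
```

(consecutive taps on the same key contribute no movement event). Gross
indices are divided by `Tt`, then each design's two per-tap indices are
ranked in ascending order across all N designs and the ranks normalised by
N, giving `PI_TL, PI_MD ∈ (0, 1]` and the total

```
PI_TOT = PI_TL + PI_MD  ∈ (0, 2],   2.00 = best attainable.
```

Because PI is a normalised rank, it is defined only relative to a design
population — the default population is the full 17 × 13 × 3 = 663-design
grid (R = flat and ±20…90 mm; O = −60°…+60° in 10° steps; three
locations). Sensitivity of `PI_TOT` to each design variable is measured
with Kruskal–Wallis tests, and well/poorly performing designs are located
as local extrema of the `PI_TOT` surface over the R × O lattice at each
location.

The direction table ships with published IPe values; the 12-location table
ships as a clearly flagged synthetic transcription that respects the
published ordering (regions 3 and 6 best, region 12 worst) and can be
replaced by measured values via `--tables`.

## Worked example

```sh
thumbkey fixtures text --length 375 --seed 1 --out text.txt
thumbkey sweep --text text.txt --out results.csv
thumbkey evaluate --results results.csv --r flat --o 0 --l bottom
```

The last command scores the standard keyboard (flat, unrotated, bottom of
the screen) within the 663-design population:

```json
{
  "design": "R=flat, O=0, L=bottom",
  "rank_tl": 76,
  "rank_md": 394,
  "pi_tl": 0.11,
  "pi_md": 0.59,
  "pi_tot": 0.71,
  "pi_tot_rank_from_best": 494,
  "n_designs": 663
}
```

The standard design ranks 494th of 663: its tap-location component is very
poor (`pi_tl` 0.11 — taps concentrate in the weak bottom regions) while its
movement-direction component is middling. The best design for this text is
`R=flat, O=30°, L=top` with `PI_TOT = 1.92`; the worst is `R=−60, O=−10°,
L=bottom` at 0.06.

```sh
thumbkey stats --results results.csv
```

```
variable     H  df         p
       R 8.855  16    0.9193
       O 297.9  12   1.3e-56
       L 228.3   2 2.695e-50
```

Location and orientation stratify performance strongly (large
Kruskal–Wallis H, p < 0.01); curvature does not (p ≈ 0.92) — so a designer
should fix L first, then O, and treat R as fine-tuning. `thumbkey extrema`
lists the local maxima/minima of the PI_TOT surface, and `thumbkey report`
writes the ranked CSV, plot-ready per-location PI_TOT matrices, a
highlights file and a run log in one go.

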