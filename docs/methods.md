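# Methods

## Model

`thumbkey` predicts relative typing performance of QWERTY keyboard
geometries on a phone screen from pre-tabulated thumb motor-performance
data, using a task-analysis decomposition: typing = a sequence of taps,
each tap characterised by where it lands (one of 12 screen regions) and
how the thumb moved to reach it (one of 8 compass directions). The model
assumes that throughput measured in reciprocal tapping (an effective index
of performance, IPe, from a Fitts'-law paradigm) transfers to the
non-repetitive movements of typing, and that tap-location effects and
movement-direction effects contribute equally and additively to overall
performance. Cognitive load, visual access, typing errors, auto-correct
behaviour and timing are all outside the model.

Only the *ranks* of the IPe values enter the score. Scoring is therefore
invariant under any monotone recalibration of the underlying throughput
measurements, which is also why the cross-design index is itself a rank:
a design's `PI_TL`/`PI_MD` is its ascending rank among the N designs of the
sweep, divided by N. The price of rank scales is population relativity —
a PI value is meaningless without its reference sweep, and
`evaluate_single` deliberately requires one.

## Geometry

The base layout is a three-layer (letters / numbers / symbols) QWERTY
keyboard on a 51 × 76 mm portrait screen, a measured approximation of a
~2012 4-inch-class phone keyboard: 4.9 mm horizontal key pitch (a 10-key
row spans 49 mm), 8 mm row pitch, 4.6 × 7.0 mm keys. All dimensions live
in `data/default_layout.yaml` and can be overridden. The spacebar is four
adjacent subkeys sharing the logical id `space`; the subkey tapped is the
one nearest the previous tap (ties to the leftmost; the left-middle subkey
when there is no previous tap).

Design transforms are applied in the fixed order **curvature → rotation →
vertical translation**. The first two fix the G-key centre, so the
location level L keeps its exact meaning (G at 19/38/57 mm on the 76 mm
screen) for every (R, O). Curvature places home-row key centres on a
circle of radius `ρ = |R| · r_scale` at equal arc length, preserving their
original horizontal spacing; other rows follow concentric circles offset
by their row distance. Positive R puts the circle centre below the home
row (keyboard curved down), negative above. The mapping from the nominal
R parameter to a physical radius is deliberately configurable
(`r_scale`, default 1 mm : 1 mm): nominal curvature parameters quoted for
real keyboards are not consistently literal circle radii, and the default
layout's half-chord of 19.6 mm makes every default level (|R| ≥ 20 mm)
feasible at 1 : 1. Radii below `max(half chord, inner-row offset)` raise
`InfeasibleCurvatureError` naming the minimum.

Region classification divides the screen into equal 3 × 4 cells numbered
row-major from the top-left (so 3 and 6 are the top-right cells and 12 the
bottom-right). Cells are half-open — a point on an interior boundary
belongs to the upper/right cell — and points pushed off-screen by extreme
transforms are clamped to the nearest cell rather than dropped. Direction
classification bins the inter-tap displacement into eight 45° sectors
centred on the compass points (N = screen top); an angle exactly on a
sector boundary goes to the sector clockwise of it. Both tie-break
conventions are arbitrary but fixed, and matter only on measure-zero
inputs.

## Typing simulation

The layer state machine is lazy: a switch key (`123`, `#+=`, `ABC`) is
pressed only when the next character requires a different layer, and no
trailing switch is emitted. Shift affects exactly one following letter.
Space and return exist on every layer and never force a switch. The total
tap count Tt (including shift/switch overhead) therefore depends only on
the text, never on the geometry — a property the tests assert, and the
reason ranking per-tap indices is equivalent to ranking gross indices
within one sweep.

"No movement" is keyed on identical tap coordinates (the same physical
key, including the same spacebar subkey); such repeats contribute a
location count but no direction event. The broader reading — no region
change — is available as `zero_mode="region"`.

## Statistics

Variable sensitivity uses Kruskal–Wallis tests of PI_TOT against each
design variable (tie-corrected H, chi-square p on groups−1 degrees of
freedom, α = 0.05), computed with `scipy.stats.kruskal` and cross-checked
in the tests against an independently coded H formula. When every
observation is identical the tie correction degenerates and H is defined
as 0 (p = 1). PI_TOT values are heavily tied rank sums, hence the
nonparametric choice.

Local extrema of the PI_TOT surface are detected on the R × O lattice at
fixed L, with the R axis ordered by signed curvature 1/R (flat at 0,
between the negative and positive branches) so lattice adjacency matches
geometric similarity. The default test is non-strict against the
8-neighbourhood, restricted to interior cells (complete neighbourhoods);
strictness, a 4-neighbourhood and boundary inclusion are configurable.

## Synthetic texts

The bundled generator draws characters i.i.d. from a weighted charset:
75% lowercase letters at approximate English frequencies, 1.5% capitals,
18% space, 2% digits, 4% punctuation — enough to exercise shift and both
layer switches at realistic rates. It does not model n-gram structure,
word lengths or real punctuation placement, so digraph-sensitive effects
(e.g. the high frequency of specific letter pairs) are only matched in
expectation, not in sequence; conclusions about specific texts should use
those texts via `--text`. Generation uses numpy's PCG64 seeded per spec,
so fixtures are bit-reproducible.

The default text length is 375 characters. At that length the per-design
indices are stable across text contents: the per-tap index is a mean over
~400 i.i.d.-ish taps, so its dispersion across texts shrinks roughly as
1/√length, and the tests check that dispersion at length 375 is below
dispersion at length 50 (10 seeded texts each, on an 18-design grid).

## Problem sizes and determinism

The full default sweep (663 designs × a 375-character text) runs in under
a second; tests and the acceptance script use that full size plus smaller
grids (4–18 designs) where an independent brute-force oracle is feasible.
Everything is deterministic given the inputs: identical runs produce
byte-identical CSVs, reports are regenerable from the results CSV alone,
and the only randomness anywhere is the seeded text generator.

## Known limitations

* The 12-location performance table is a synthetic transcription
  constrained by the published ordering, not measured values; absolute
  PI_TOT values for concrete designs shift with the true table, although
  the scale anchors (rank arithmetic, bounds) and the qualitative
  variable-sensitivity pattern (L and O dominant, R negligible) do not.
* Equal weighting of the location and direction components is an
  assumption, not a fitted quantity.
* The empirical tables describe right-handed, single-handed thumb use;
  nothing here generalises to two-handed grips or index-finger typing.
* Scores are relative ranks: the tool compares designs, it does not
  predict words-per-minute.
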