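# Methods

## Model overview

The simulator treats one cerebellar microzone network as a feed-forward
cascade of *linear unit functions* — each unit outputs the mean of its
inputs — connected by independent random sampling inside anatomically
defined territories. Nothing is learned and no biophysics is modelled:
parameter values represent coded data (firing rates on a common linear
scale), and the simulation is a snapshot of a continuously refreshed state.
The scientific claim under test is statistical: iterated
sample-and-average steps narrow the firing-rate distribution at every layer
while conserving its mean (central-limit distillation), and therefore make
the network output a linear, phase- and topography-sensitive function of
its input.

All randomness flows from a single master seed through named substreams
(`_rng.substream(seed, stage, index…)`), so stages are reproducible in
isolation and results do not depend on execution order.

## Input synthesis (mossy fibres)

Each of the 41 ranks draws its mossy fibre rates i.i.d. from a configurable
distribution; rates are truncated at 0 (negligible mass for the default
distributions). Defaults follow the study conditions: uniform 0–250 Hz,
normal (mean 125, SD 40), discontinuous (bands 50–110 and 180–300 Hz,
chosen to span 50–300 Hz with a visible gap), and, for the locomotor
experiment, per-rank normals with SD 12.5 Hz whose means trace
`baseline + A·sin(2π·(rank/n_ranks)·w + φ)` with baseline 125 Hz and
A = 100 Hz (the source figure does not print these; they keep rates inside
the 0–250 Hz operating range while using most of it).

Terminal branching/clustering is emulated generatively: a fibre makes 2–8
clusters (uniform), cluster centres are placed continuously along the rank
with ≥ 2 field-widths between centres (the reported ≥ 200 µm edge-to-edge
cluster separation plus the ~200 µm cluster footprint), each cluster holds
4–12 terminals (uniform) split binomially between the two fields its
footprint straddles, and a fibre's contribution to any field is capped at
1% of the field's terminal target by pushing a straddling cluster's excess
to its other field. Centres extend one field beyond each rank end (parts
outside the strip are dropped) so edge fields carry the same expected load.
These choices reproduce the three facts that matter downstream — ≈ 700–780
terminals per field, < 1% single-fibre share, and field rates that are
statistically indistinguishable from a with-replacement sample of rank
rates — and all are configurable (`BranchingParams`).

The replacement-facsimile property is tested on a field's *unique-source*
rates (which are an i.i.d. subsample of rank rates, because fibres reach a
field independently of their rate); the full terminal multiset contains
copy clumps that would invalidate a naive two-sample test.

## Granular recoding and calibration

Per field: 10 Golgi units each average 4 random terminal rates; each of the
700 glomeruli receives `scale · mean(4 random Golgi rates) + offset`,
floored at 0. Each granule cell draws 4 dendritic (terminal rate,
glomerular inhibition) pairs, wins a dendrite when excitation strictly
exceeds inhibition (ties lose; a zero-measure event for continuous rates),
fires on ≥ 3 wins of 4, and fires at the mean of all 4 dendritic excitation
rates (a winners-only mode exists). The Golgi chain sizes are not published
for this network and are exposed as parameters.

**The calibrated constant is additive.** The inhibition level is adjusted
so a target fraction of granule cells fires (0.5% default; 30% as the dense
regime). We calibrate the *offset* (in Hz) with the multiplicative scale
fixed at 1, because an additive constant makes the win margin — and hence
the active fraction — invariant under a uniform shift of all input rates.
That invariance is what produces the slope-one linearity of every
downstream layer mean and the phase-sensitivity behaviour of the locomotor
network; a purely multiplicative constant greater than 1 would make the
active fraction fall as input rates rise and would suppress activity in
high-rate ranks altogether. A multiplicative calibration mode is still
available (`mode="scale"`).

Calibration bisects the constant against the mean active fraction of a
random 25% subsample of fields (2000 granule cells per field), evaluated
under *common random numbers* so the objective is a deterministic,
monotone function of the constant. Default tolerance is 2% relative: tight
enough that, when two input shapes are calibrated to the same target, the
residual difference in mean density is small compared with the file-to-file
density SD (so shape-invariance comparisons measure the architecture, not
calibration error). The achieved fraction over the full grid differs from
the subsample estimate by its sampling error (~1–2% relative at the default
sizes).

## Molecular and nuclear layers

Stellate sample sizes are drawn from Binomial(420, **0.0119**): the rounded
contact probability reproduces the published 13-entry probability table to
4 decimal places, whereas the exact ratio 1000/84 000 = 1/84 does not (it
gives 0.0065 at x = 0 against the printed 0.0066). The exact-ratio law is
available via `StellateSampleLaw.from_geometry` and is the one with mean
exactly 5. Zero draws are resampled (`truncate_zero`): the mean-of-inputs
unit function is undefined at x = 0, and truncation is the minimal
intervention; it raises the realized mean sample size to ≈ 5.03.

Stellate units sample only their own sector's file pool, without
replacement within a unit. Each Purkinje cell receives two disjoint
16-unit flanks from its own sector plus 0–8 inner-depth units (layers 3–5
of 5; the outer two layers' axons are too short) from each existing
neighbouring sector. Compartments draw 6 distinct units from their flank
network, independently across compartments (one unit may serve several);
compartment value = mean of its two flank values; soma = mean of its 16
compartments. Nuclear cells draw a uniform 30–50 Purkinje cells without
replacement and output the mean. Purkinje inhibition is not sign-inverted:
all values live on one shared linear scale, and every test concerns
distributional shape, means and ranges, which are invariant to affine
display conventions.

## The locomotor (swimming) experiment

The rank row spans a fraction *w* of one body wavelength; phases step 90°
(w = 1) or 45° (w < 1) so the phase grid always contains the extremes of
the averaged sinusoid. The inhibition constant is calibrated once at the
first phase and frozen (the biological constant does not track cycle
phase); the Purkinje afferent networks — anatomy — are built once per
sweep. Each phase regenerates the input layer and reruns
granular → molecular → nuclear with fresh substreams.

The closed-form oracle: a file pools all ranks uniformly and every
subsequent stage conserves the mean, so the output centre tracks the
row-average of the rank-mean drive. Averaging `A·sin` over L = 2πw radians
leaves amplitude `A·g(L)`, `g(L) = (2/L)|sin(L/2)|`; predicted peak-to-peak
output range is `2A·g(L)` (0 at w = 1; 0.6366·2A at w = 1/2;
0.9003·2A at w = 1/4; half/three-quarter ratio 2.12). Simulated ranges
match within a few percent at the default settings; the package's pass
threshold for oracle agreement is 25%, reflecting granular-layer
nonlinearity at the sparse code plus sampling noise.

## Numerical and statistical choices

- **Tie-breaking**: strict inequality for a dendritic win; inhibition
  floored at 0 (the floor never binds at the calibrated sparse regime).
- **Counts round to nearest** (84 000, 420) rather than floor.
- **Mean-conservation SE** is estimated by 50 bootstrap resamples of each
  layer, combined as if the two layers were independent — conservative,
  since no closed form exists under the compound sampling laws.
- **Determinism**: identical (config, seed) reproduces every CSV bit for
  bit; this is asserted in the test suite.
- **Degenerate inputs**: empty fields, empty file pools, undersized flank
  networks and unreachable calibration targets raise typed errors naming
  the offending unit; a target already satisfied at the search boundary
  returns the boundary with a warning.

## Problem sizes

Full scale (41 × 100 fields, 9000 granule cells/field, ≈ 3.7 × 10⁷ granule
cells) simulates in a few seconds on one CPU, and the package defaults to
it. The test suite uses two reduced geometries chosen to keep the whole
suite fast while preserving the statistics under test: a 41-rank × 20-file
grid with 500 granule cells/field for integration and swim tests (the sine
experiment needs all 41 ranks; the file count only sets how many replicate
sectors are observed), and the full 41 × 100 grid with 1800 granule
cells/field for the density-regulation and cascade checks. The
compartment-span measurement follows its stated recipe (truncated-normal
parallel-fibre pools, SD 10 within a 60-unit window, single-flank
compartments) and is averaged over 10 replicate seeds because a span
(max − min over 1600 values) is an extreme-value statistic with
seed-to-seed SD ≈ 1.

## What the generator does and does not emulate

The synthetic inputs reproduce the *statistical* structure the theory
rests on — i.i.d. rank rates, copy-multiplicity from branching/clustering,
narrow phase-offset sine drives — but not lobule-specific termination
patterns, 3-D cluster geometry, spike timing or burst structure (the model
is explicitly a rate snapshot), feedback via granule-cell ascending axons
or parallel fibres onto Golgi cells (absent from the simulated chain, and
expected to tighten regulation further), or basket-cell/ephaptic timing.
Passing tests therefore show that the anatomical sampling architecture has
the claimed distillation properties under these input statistics; they do
not validate the biological realism of the input statistics themselves.

## Known limitations

- The granular-layer internals (Golgi chain sizes, the granule rate
  transform) follow a published companion model only in outline; the
  absolute spread of the parallel-fibre code (and hence absolute ranges at
  downstream layers, e.g. the ~117 Hz pf range of the worked example)
  depends on these unpublished details. Distribution-shape claims, mean
  conservation, density regulation and all ratio/attenuation results are
  insensitive to them.
- The exact branching/cluster distributions of mossy fibre terminals are
  not published; the defaults here are the simplest distributions that
  reproduce the three published constraints (see above).
- Sectors are modelled as independent files; parallel-fibre sharing between
  *neighbouring* microzones (the coordination argument) is outside the
  simulated single-network scope.
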