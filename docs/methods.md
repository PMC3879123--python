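# Methods

## The model

`cryptsim` simulates a single human colon crypt as an on-lattice
agent-based model. The crypt cylinder is cut open into a roll-out grid of
`SetCellsPerRow` columns (default 36) with left/right wraparound; each
column is a top-anchored stack of cells, row 0 being the lumen edge. The
crypt starts `RowsAtStart` rows deep (default 68, 2448 cells, matching the
biopsy mean of 2427.8 cells per crypt).

Each cell carries two state variables — its current per-tick probability of
dividing and of dying — plus a founder (clone) label and optional mutant
modifiers. One tick represents 4.5 h. A tick has two phases:

1. **Randomized event pass.** Every cell alive at the start of the tick is
   visited exactly once in a fresh uniformly random order. A visited cell
   first draws chemotherapy death (if a dose is active), then normal death
   with its current die probability, then — if it survived — division with
   its current divide probability. A death removes the cell and pulls the
   cells below it up one row, so cells migrate up the crypt because of
   loss above them, not mitotic pressure. A division keeps one progeny in
   the parent position and inserts the other one column over (rightward
   under polar division) and one row down; the displaced occupant moves
   along the same diagonal, iterating until a displaced cell lands in the
   first empty slot at the bottom of its target column. Progeny are copies
   of the parent (label, modifiers, current divide probability) and are
   not visited in the tick of their birth.
2. **Synchronous feedback.** Every cell's divide probability moves a
   fraction *f* of the way toward its positional target, where *f* is the
   gradient feedback strength of the cell's pre-update type; die
   probabilities are updated the same way. *f* = 1 is an immediate
   response, *f* < 1 a delayed (plastic) response.

### Gradients

Positional targets come from two power-law gradients along the crypt axis.
With normalized depth `y` (0 at the lumen, 1 at the gradient bottom):

- divide target `p_div(y) = DivMin + (DivMax − DivMin) · y^n_div`,
- die target `p_die(y) = DieMin + (DieMax − DieMin) · (1 − y)^n_die`.

Calibrated shape parameters: `n_div = 11.5`, `n_die = 14`, maxima 0.2 and
minima 0. A divide maximum of 0.2 per 4.5 h tick puts the fastest cell
cycle at ≈ 22 h and makes the standard cytotoxicity doses meaningful
(lethality 5 × 0.2 = certain death for the fastest dividers; the tumor
phenotype's +0.16 divide offset is a near-maximal boost).

The gradient *length* follows the size of the crypt: by default both
gradients span the current mean column height (`n_total / columns`), so a
cell's target depends on its relative position in the tissue, and growth
or shrinkage of the crypt re-maps every cell. Alternative span modes
(per-column, deepest-column, fixed anatomical length) are configurable;
they were explored during development and produce either collapse (fixed
spans starve the crypt of deep, proliferative cells after any shrinkage)
or excessive stiffness, and are retained for sensitivity analysis only.

### The stem-cell niche as the size regulator

Cells at or below `niche_row = RowsAtStart − QuiesceDepth` (default 68 − 3
= row 65) sit in the stem-cell niche: their divide target is the quiescent
value 0 instead of the divide gradient, approached with the quiescent
feedback strength (0.1). Because the divide integral exceeds the die
integral at the calibrated powers (1/12.5 vs 1/15), an unregulated crypt
would grow by ≈ 0.27% per tick. The niche absorbs this surplus: when the
crypt deepens, more cells sink under the quiescence signal and stop
dividing; when it shrinks, dormant cells resurface into the proliferative
gradient and reactivate. The quiescent feedback strength is therefore the
*response time of the crypt's size controller* — at 1 the population is
clamped tightly, at the calibrated 0.1 the crypt fluctuates visibly about
its mean, which is how the model expresses the crypt-to-crypt variation
seen in biopsies.

Mutant cells are insensitive to the quiescence signal (the
constitutive-pathway reading of adenoma initiation): they read the divide
gradient even inside the niche. This is what allows a mutant lineage to
outrun the size controller and push the crypt to adenoma size, and it is
the only reading under which a "quiescent stem cell" mutant placed in the
niche can found an adenoma at all.

### Cell types

Cell types are plastic states read off a cell's position and current
divide probability, mirroring the Ki-67 readout used for the reference
measurements: a cell is **proliferating** if its current divide
probability is ≥ `DiffCellProbabilityThreshold` (0.008) — in the niche
such cells are active stem cells; a non-dividing cell is a **quiescent
stem cell** if it sits in the niche and **differentiated** otherwise. The
three labels partition the living cells each tick.

## Calibrated parameter values

| Parameter | Value | Origin |
| --- | --- | --- |
| SetCellsPerRow × RowsAtStart | 36 × 68 | initial total ≈ biopsy mean 2427.8 |
| CptDivPwr / CryptDiePwr | 11.5 / 14 | gradient-shape calibration |
| CryptDivideMax / CryptDieMax | 0.2 / 0.2 | cell-cycle ≈ 22 h; dose arithmetic |
| QuiesceDepth | 3 rows | niche calibration (row 65 = quiescent stem) |
| DiffCellProbabilityThreshold | 0.008 | proliferating-cell mean 623.9 |
| Feedback strengths (SCq, prolif, diff) | 0.1, 0.3, 0.5 | dispersion calibration |
| Time unit | 4.5 h | dose-duration scale |
| Unbounded-size factor | 4 × initial | reporter threshold (configurable) |

With these defaults, 49 crypts initiated at uniformly random sizes of
61–75 rows and run for 1000 ticks give type means statistically
indistinguishable from the biopsy reference (chi-squared over the three
cell-type means, p > 0.05).

## Experiments and their scales

- **Calibration** (`calibration_experiment`): 49 crypts × 1000 ticks,
  initial heights uniform on [61, 75]; end-of-run snapshot counts (one
  time point per crypt, like a biopsy section), summarized as mean/SD/CV
  per type and compared with the packaged reference table by chi-squared.
- **Monoclonal conversion** (`monoclonal_experiment`): every cell starts
  as its own founder; no cell has any advantage; a replicate converts when
  one founder label remains. Default 30 replicates, 15 000-tick cap. The
  conversion-time distribution is right-skewed (roughly lognormal), and
  the winning founder's column is uniform — neutral drift.
- **Adenoma initiation** (`adenoma_experiment`): 200-tick burn-in,
  baseline = mean total over the last 100 burn-in ticks, one mutant
  (×1.3 divide, ×1.1 die) placed at a given row in a uniformly random
  column; a replicate is an adenoma when the total reaches 140% of
  baseline within 5000 ticks. Runs end early on adenoma detection or
  extinction of the mutant lineage. Default 40 replicates per position.
- **Cytotoxic recovery**: a single 1-tick dose at lethality 5 or 320;
  kill probability per cell per tick is `min(1, lethality × divide
  probability at dose onset)` (cells born mid-dose use their birth-time
  probability), so fast dividers are the most sensitive. Totals dip,
  overshoot and return, dose-dependently.
- **Therapy scheduling** (`therapy_experiment`): a tumor clone (+0.16
  divide, +0.1 die) grows from one cell in the lower third (default row
  63, adjacent to the niche, where a single founding cell reliably
  establishes) until mutants are 50% of the crypt; fractionated
  chemotherapy (lethality 2, interval = 8 × duration) then runs to cure
  (no mutant left), with a 5×-resting-size cap flagging runaway tumors as
  uncured. Duration sweep
  {1, 2, 3, 4, 6, 8} × 20 replicates; reported per duration: mean time to
  cure, cumulative healthy-cell chemotherapy deaths, and the minimum
  healthy-cell count during therapy. The "optimal" duration is the
  smallest whose mean time-to-cure is within 15% of the best (plateau
  onset).

## Numerical and design choices

- Single-threaded numba kernels; one seeded random stream per run (a run
  seeded with the same integer reproduces its report sequence bit for
  bit). Replicates derive well-separated seeds via `SeedSequence` mixing.
- The randomized pass visits cells through an identity map maintained
  across removals and cascade displacements, so each tick is a uniform
  random permutation of the tick-start population.
- Feedback-strength selection uses the cell's pre-update state; report
  counts use post-update state (both documented, fixed orderings).
- Null interventions are exact no-ops: a lethality-0 dose and a neutral
  phenotype leave the random stream untouched, so seed-matched
  trajectories are equal.
- Normalized depth uses row midpoints `(r + 0.5) / span`, so neither end
  of the crypt sees a deterministic event; gradient endpoints are exact at
  `y = 0` and `y = 1`.
- The crypt-resizing controller (`ResizeCryptAdjust`) is a clipped
  proportional controller on all divide targets,
  `clip(1 + gain·(CellTarget − n)/CellTarget, 0, 2)` with gain 0.1; the
  interface names the feature, the mechanism is this package's choice.
- Degenerate inputs: an extinct crypt reports zero counts and is not
  monoclonal; a one-cell crypt is monoclonal; columns may empty without
  affecting neighbors.

## Known limitations

- The model reproduces the reference *means* of all cell types and the
  qualitative dispersion ordering (delayed feedback gives visibly larger
  crypt-to-crypt variation than immediate response, and the largest
  relative variation is in the quiescent pool), but the absolute
  coefficients of variation are smaller than the measured ones: the niche
  size controller, even at quiescent strength 0.1, clamps totals more
  tightly than real crypts vary.
- A single ×1.3/×1.1 mutant placed in the mid-proliferative region (row
  59) usually washes out: the death flux above it carries it upward ≈ 1
  row per tick, and at a ×1.3-boosted divide probability of ≈ 0.06 per
  tick its lineage rarely reaches the niche foothold before being shed.
  Mutants seeded in the niche itself (row 65) initiate adenomas at the
  reference rate; mid-crypt initiation is under-efficient relative to the
  reference, and upper-crypt (row 20) initiation is rare background, as
  reported. Positional efficiency *ordering* therefore differs from the
  reference for the row-59 position.
- Because the niche caps gradient-driven growth, lowering the divide
  power alone produces a larger (but still regulated) crypt rather than
  unbounded growth; unbounded behavior requires a niche-insensitive
  (mutant) clone.
- At a fixed dosing duty cycle (interval = 8 × duration) the per-time
  kill rate of the tumor is nearly duration-independent in this model, so
  the time-to-cure curve is flat-to-noisy with a plateau near duration 3,
  and *cumulative* healthy-cell chemotherapy deaths mildly decrease with
  duration (therapy simply lasts longer at short durations). Both
  candidate collateral metrics (cumulative healthy chemotherapy deaths
  and minimum healthy count during therapy) are reported per run.
- No mechanics (cell shape, adhesion), no molecular identity of the
  gradients, no angiogenesis/invasion, and no toxicity outside the crypt.
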