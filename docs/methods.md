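# Methods

## The model

`colicomp` simulates competition during range expansion between two
*Escherichia coli* strains spotted together on solid medium: a
colicin-producing strain **C** that divides labor between reproduction and
self-sacrificing toxin production, and a competitor **X** (sensitive by
default).  The model is a fixed-step, random-sequential kinetic Monte Carlo
process on a square lattice (default 250 x 250 sites) with five site
states: empty agar `A`, reproducing producer `C`, toxin-producing `C_on`,
viable competitor `X`, and growth-inhibited competitor `X_stop`.

Per update step of length `dt`, every active site is visited once in a
freshly randomized order:

- **Replication.** A `C` or `X` cell replicates with probability
  `r * dt * (n_orth + diag_factor * n_diag)`, where the counts are its empty
  orthogonal/diagonal Moore neighbors and `diag_factor = 1/2` down-weights
  diagonal growth.  The daughter's site is drawn uniformly among the empty
  Moore neighbors; daughters do not act until the next sweep.
- **Switching.** A `C` cell becomes `C_on` with probability `s_C * dt`.
  Producers never replicate and never revert.
- **Lysis and toxin release.** A `C_on` cell lyses with probability
  `d_Con * dt`; its site reverts to (recolonizable) agar and a static
  exponential colicin profile `n_tox * exp(-d / lambda_tox)` (`d` the
  physical distance to the lysis site) is added to the cumulative toxin
  field over the whole lattice.  The field neither diffuses nor decays.
- **Inhibition.** An `X` cell on local cumulative toxin `T` becomes
  `X_stop` with probability `1 - exp(-sigma_x * T * dt)`.  `X_stop` is
  permanent and keeps occupying its site; only living `X` is susceptible
  (the producer is immune, as its immunity protein implies).

At steady state the producer ratio obeys `Con/C = s_C/d_Con` (from
`dCon/dt = s_C C - d_Con Con` with quasi-constant `C`), which is the bridge
between the switching rate and the observable producer fraction
`s_C/(s_C + d_Con)`.

### Coarse-graining (zooming)

When the colony touches the lattice boundary, each 5 x 5 block collapses to
one site — agar if fewer than 13 of 25 sites are occupied, else the
plurality non-agar state with the fixed tie precedence
`C_on > C > X_stop > X` — and the 50 x 50 result is re-centred in a fresh
250 x 250 lattice.  The toxin field is block-averaged.  Replication rates
are divided by five so the physical front speed (um/h) is preserved;
per-cell rates (`s_C`, `d_Con`, `sigma_x`) are unchanged, and `dt` is
multiplied by five (re-capped) so per-step event probabilities stay
constant.  A unit test verifies the front speed changes by < 10% across a
zoom and the physical area by < 5% for a developed colony.

### Scenarios

- `STOCHASTIC` — the reference model above.
- `ALL_OFF` — switching disabled (`s_C = 0`): a toxin-deficient producer.
- `SYNC_I` / `SYNC_II` — deterministic synchronous programs: C grows
  without switching for 50 min then pauses 50 min (I), or grows 100 min
  (II); at 100 min every C cell releases its toxin simultaneously and
  lyses.
- `NON_LYSING_ALL_ON` — every C cell releases `n_tox/2` at each
  replication instead of lysing, with `r_C` halved.

## Parameters

| parameter | default | unit | origin |
|---|---|---|---|
| `r_C`, `r_X` | 5.4 | 1/h per orthogonal empty neighbor | calibrated so a single-strain colony reaches ~4.9 mm diameter at 48 h |
| `diag_factor` | 0.5 | — | stated diagonal-growth scaling |
| `s_C` | 0.015 (swept 0.001–0.155) | 1/h | the fixed rate used for competitor-variant comparisons |
| `d_Con` | 1.2 | 1/h | mean producing time ~50 min before lysis |
| `sigma_x` | 1500 | 1/(toxin unit · h) | standard toxin sensitivity; acts nearly as a threshold |
| `n_tox` | 1.0 | toxin units | standard toxin amount per lysis |
| `lambda_tox` | 150 | um | inside the reported effective toxin range of 100–400 um |
| `base_pixel_um` | 2 | um | one pixel ~ one cell; the 450 um spot spans 225 px |
| `dt` | auto (0.00926 at defaults) | h | largest step with every single-event probability <= 0.05 |
| `t_end` | 48 | h | experiment duration |

The replication-rate calibration is itself an exposed operation
(`calibrate_growth_rate`): it scans a bracket of rates, simulates
single-strain colonies, fits the linear-regime area slope of each, and
interpolates the rate matching a target curve.

## Inocula and designs

`generate_inoculum` places ~150 cells (times an optional 2/4/8 density
multiplier) uniformly without collisions in a centred 450 um disc; each
cell is C with probability 1/101 (approximate 1:100 C:X ratio), and the
label assignment is resampled until at least one C cell is present, as the
analyzed experiments required.  The coffee-stain inhomogeneity seen at high
experimental densities is deliberately not modelled.  `make_fixed_IC_design`
freezes `n_IC` inoculum layouts and pairs each with independent simulation
seeds for every switching rate (default 16 x 30 x 17 = 8,160 runs).  The
default 17-value `s_C` grid is log-spaced over 0.001–0.155; the exact
original grid is not recoverable, so it is exposed as configuration.

## Metrics

- `F_C` — C-lineage share of the colonized area at 48 h (inhibited
  `X_stop` still counts as competitor area: dead cells keep occupying and
  fluorescing).
- Outcome class — extinction if total colony area < 10^6 um^2 (checked
  first: a trapped, tiny all-C colony is extinct), else C domination
  (> 90%), S domination (< 10%), coexistence otherwise; boundaries are
  strict inequalities.
- `N_C,Edge` — viable C clusters at the colony edge after 12 h:
  8-connected components of `{C, C_on}` containing at least one reproducing
  `C` site (clusters of producers only are dying) and touching an occupied
  site adjacent to the colony's external background (agar connected to the
  lattice border, 8-connectivity throughout, consistent with the Moore
  dynamics).
- Spatial initial metrics — `R_C0` is the norm of the mean C-position
  vector about the occupied centroid (the centre-of-mass formula as
  printed); `D_C0` is the mean Euclidean distance of C cells from their own
  centre of mass.  The literal printed form of the spread,
  `|mean(x_i - x_bar)|`, is identically zero and is available only under a
  `literal_spread` audit flag.
- Transition time — first recorded time C exceeds half the colonized area
  and stays above it for the next two recorded points (a 3-point
  debounce; the sampling interval is not part of the definition).
- Expansion rate / OD growth rate — linear fit in an automatically detected
  regime: among windows covering >= 25% of the series with R^2 >= 0.98,
  the window maximizing R^2 (binned at 1e-3) and then length wins, so a
  noiseless linear regime is fitted over its full extent while lag or
  saturation contamination loses.  `GR = b/ln 2` converts the log-OD slope
  to doublings per hour.

## Statistics

Type-I (sequential) ANOVA is computed from nested-model residual sums of
squares — `SS_k = RSS(terms 1..k-1) - RSS(terms 1..k)` — with
`eta^2 = SS/SS_total`; it is cross-checked against
`statsmodels.stats.anova_lm(typ=1)` in the tests.  Term order follows the
experimental design: the externally tuned division-of-labor variable first
(MitC dose or `s_C`), `N_C,Edge` second, spatial details last.  Categorical
predictors use treatment contrasts with the lowest level as reference;
sequential SS are encoding-invariant, coefficients are not.  The
edge-cluster model standardizes all predictors (the dose on its numeric
scale); the experimental F_C model treats the dose as categorical with all
pairwise interactions; the simulation F_C model treats `s_C`, `N_C,Edge`
and `IC` all as categorical.  P-values are reported without
multiple-testing correction (none is applied in this analysis family).
The density-sweep variance statistic is the across-replicate population
variance (divide by n) of the colonized-area C fraction, averaged over the
recorded time course.

## What the synthetic world does and does not establish

The generators emulate the stated experimental conditions (spot geometry,
1:100 ratio, >= 1 C cell, density multipliers) but not imaging noise,
segmentation error, droplet-ejection physics, or the coffee-stain effect;
fixture curves and regression tables carry their generating truth so that
the fitting and ANOVA stages are tested for *recovery*, not for agreement
with any measured value.  A green recovery test therefore establishes the
correctness of the pipeline, not the biological fidelity of the model.

## Numerical choices

- Fixed-step random-sequential updating (not event-driven): tractable on
  250 x 250 lattices and convergent to the same rates, validated by the
  exponential-lifetime and steady-state-ratio checks.  The single-event
  probability cap (0.05) bounds the discretization error.
- Toxin deposition inside runs uses a precomputed displacement table of
  the exponential kernel; a test asserts bitwise agreement with the direct
  formula.
- Lysed producer sites are recolonizable agar; inhibited competitors block
  their sites forever.
- Replication targets are drawn uniformly among empty Moore neighbors
  after the rate draw (diagonals are down-weighted in the rate, not in the
  target choice).
- Runs freeze once no viable cell remains (C, C_on, X all zero): the
  remaining records are filled without stepping, which is exact because no
  reaction can fire.
- Well-mixed surrogate for the steady-state ratio: replication is disabled
  and the viable-C pool is clamped constant (switched cells replaced),
  the discrete analogue of the quasi-steady assumption; without the clamp
  the ratio `Con/C` diverges linearly when `s_C = d_Con`.  Standard errors
  by batch means.

## Known limitations

- **High-switching-rate regime.**  With replication calibrated to the
  physical colony size (front speed ~46 um/h at 2 um pixels) the per-cell
  division rate exceeds the scanned switching rates (<= 0.155/h) by one to
  two orders of magnitude at every zoom level.  Early stochastic
  extinction of C lineages through switching is therefore essentially
  impossible in this parameterization, and the C-domination frequency is
  monotonically *increasing* over the scanned switching rates — earlier
  toxin release frees the C cluster from spatial enclosure before the
  competitor seals it in — rather than peaking at an intermediate rate.
  Reproducing a unimodal response within this model class would require
  switching rates comparable to the division rate (or, equivalently,
  interpreting the scanned values as per-update-step probabilities), which
  conflicts with the per-hour rate convention and the physical-size
  calibration adopted here.  The corresponding acceptance test documents
  this as an expected failure of the stated direction.
- No toxin diffusion or decay; no nutrient field; no 3-D structure; no
  resistance evolution.
- The coarse-graining plurality rule erases trapped C clusters smaller
  than about half a block (13 of 25 sites), which contributes to
  S-domination classifications at low switching rates.
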