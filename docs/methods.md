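# Methods

## Scope and model

All analyses operate on a constraint-based metabolic model: stoichiometric
matrix **S**, flux vector **v** (mmol·gAFDW⁻¹·h⁻¹), steady-state mass
balance S·v = 0, and capacity/directionality bounds α ≤ v ≤ β.  The model
container is `cobra.Model`; SBML Level 2 (bounds in kinetic-law parameters)
and Level 3 + fbc are read, Level 3 + fbc is written.  Default bounds when a
file omits them are the conventional big-M box: [0, 1000] for irreversible
and [−1000, 1000] for reversible reactions, in the flux units above.
Gene–protein–reaction (GPR) rules are boolean expressions with AND binding
tighter than OR and parentheses honoured (cobra's grammar); AND encodes
complexes, OR isozymes.

Reaction deletion returns a true copy with the reactions removed; the inner
loops of the scans (deletions, scenarios, phase planes) instead fix bounds
to [0, 0] inside cobra contexts, which keeps the solver basis and matrix
indices stable and is an order of magnitude faster than rebuilding.

## Solvers and numerical choices

* LPs and the mixed-integer stage use GLPK through optlang/cobra, with
  deterministic behaviour (no randomized components, fixed variable order).
* The quadratic least-norm problem min Σvᵢ² s.t. S·v = 0, bounds, is
  assembled sparsely and solved with OSQP (eps_abs = eps_rel = 1e-9,
  polishing on).  An L1 mode (min Σ|vᵢ| via the forward/reverse variable
  split, an LP) is selectable wherever the quadratic norm is used.
* Zero tolerance for "carries no flux" is 1e-9 (solver-noise scale).  The
  *biological* activity threshold ε of the evidence integration is a
  separate, much larger constant (default 0.1 mmol·gAFDW⁻¹·h⁻¹) — the two
  must not be conflated.
* Measured rates (R_E) are imposed as equalities with a numerical
  half-width of 1e-6.  Rate measurements carry finite precision, and
  razor-edge equalities taken from a previous solve at machine precision
  can sit outside another solver's feasibility tolerance; the half-width
  makes the pipeline robust without changing any result at measurement
  scale.
* In the evidence MILP, GLPK's default MIP tolerances can accept ε-sized
  violations of big-M indicator rows; the module pins the feasibility and
  integrality tolerances to 1e-9 and additionally creates an indicator
  branch only when the reaction's bounds can actually reach ±ε (an
  irreversible reaction never gets an "active negative" binary).

## FVA, usage classes, flux spans

FVA minimizes and maximizes each flux individually under a fixed constraint
set.  The constraint set is taken literally: measured rates enter as
equalities and no fraction-of-optimum objective constraint is added — where
an analysis wants growth pinned (PhPP FVA), it pins it explicitly.
Classification: *required* if 0 lies outside [min, max], *inactive* if both
ends are 0, *optional* otherwise, all at the 1e-9 zero tolerance.  The
*flux span* max − min measures resolution; deletion scans report the mean
span over a configurable central-metabolism set (for the toy network:
carbon fixation, precursor oxidation, transhydrogenase, storage synthesis
and mobilization, by-product formation).

## Phenotypic phase planes

Growth is maximized on a grid of (PSII, PSI) photon uptakes.  Photon
constraints default to equalities (`fixed`), matching controlled-
illumination experiments where the culture absorbs what the lamps deliver;
an `upper_bound` mode is available, and only in that mode are monotonicity
and concavity of the growth surface along the axes guaranteed (parametric
LP), which the tests assert.  Regions follow the reduced costs of the two
photon constraints (tolerance 1e-6): positive marginal value of PSII only →
region 1, both → region 2, PSI only → region 3.  Where duals are degenerate
at a vertex the code falls back to finite differences of one grid step.
Cells with zero growth carry no region; cells adjacent to another region
are flagged as boundary, and ties at boundaries keep the lower-numbered
label.  Region-wide FVA samples up to `sample_density`² interior points
(default 5²), fixes growth to its point-wise maximum minus an absolute
slack of 1e-9, and aggregates with a zero tolerance of 1e-6 — safely above
the flux wiggle the growth slack admits: *active* means a sign-definite
nonzero range at every sampled point, *blocked* means [0, 0] everywhere.

Limitation diagnosis offers the model one artificial generator at a time —
ADP + Pi + H⁺ → ATP + H₂O, or NADP⁺ + H⁺ → NADPH — capped at
δ = 0.1 mmol·gAFDW⁻¹·h⁻¹, and labels by which addition raises optimal
growth by more than 1e-8 h⁻¹: `energy_limited`, `reductant_limited`,
`mixed` (both), `neither` (e.g. carbon-limited).  On the toy network the
dual-limited region reports `mixed`: the toy's transhydrogenase and
respiratory shortcuts interconvert NADPH and ATP, so at an interior optimum
both currencies carry marginal value.  In larger networks whose conversion
routes saturate, the same probe separates the two cleanly; the single-
photosystem regions are reductant-limited in either case.

## ATP requirements (GAR/NGAR)

For each batch observation (growth rate, photon uptake at 630 nm → PSII and
680 nm → PSI), all three rates are fixed and the ATP-maintenance hydrolysis
flux is maximized by LP on a model whose biomass equation carries only
polymerization costs.  Unweighted ordinary least squares of maximal ATP
hydrolysis against growth rate gives the slope GAR and intercept NGAR; a
negative fitted intercept is clamped to zero with a warning.  Internally
GAR is mmol ATP·gAFDW⁻¹ so that GAR·μ has flux units; installing parameters
adds GAR to the biomass ATP/ADP/Pi/H⁺/H₂O terms and sets NGAR as the
maintenance reaction's lower bound.  Single-wavelength batches constrain
only the summed photon uptake (`mode="total"`), since one lamp still drives
both photosystems.

## Dark N2 fixation

The dark snapshot closes both photon uptakes and ammonia uptake, fixes
growth to zero, supplies glycogen through a bounded source reaction
(→ glycogen), runs maintenance at NGAR, and maximizes cyanophycin
production (or nitrogenase flux).  Yields are reported per glycogen unit
from the norm-minimized optimum; N2 fixation is read from the nitrogenase
flux and, as a cross-check, from cyanophycin nitrogen content.  For the toy
stoichiometry the optimum is hand-derivable: one glycogen unit yields 12
NADH-equivalents; each N2 costs 8 ferredoxin electrons (4 NADH) plus
16 ATP, and its cyanophycin storage another 2 ATP; respiration through
NDH-1 → cyt b6f → cytochrome oxidase pumps 12 H⁺ per NADH = 3 ATP.
Balancing electrons and ATP gives cyanophycin = 2/3·glycogen − NGAR/54,
decreasing in maintenance, with one H2 exported per N2 when the
hydrogenases are removed and full H2 recycling (and a higher yield) when
they are present.  The tests assert this closed form and an independently
assembled LP oracle.

## Expression-evidence integration

Gene-level evidence (protein detected yes/no; log2 mRNA) lifts to reaction
sets through the GPRs: R_H if the rule evaluates true with undetected genes
knocked out; R_L if every gene is undetected *and* weakly transcribed —
below the log2 threshold (default 8), or in `data_driven` mode below the
lowest mRNA among detected proteins.  R_H takes precedence on conflict
(logged); measured reactions and gene-less reactions stay out of both.

The fit is lexicographic.  Stage 1 (MILP): binaries y/x force flux ≥ ε /
≤ −ε, x = y = 0 forces zero; z = 1 forces an R_L flux to zero; maximize
Σ_{R_H}(x+y) + Σ_{R_L} z under big-M indicator rows (M = 1000).  Among
alternate score-optimal binary assignments a tiebreak MILP pins the score
and minimizes Σ|v|, selecting a cycle-poor interpretation deterministically.
Stage 2: with the binaries fixed the disjunctions collapse to plain bounds,
and the quadratic norm Σv² is minimized (OSQP).  The returned binaries
(x°, y°, z°) then also constrain the TPD FVA, so evidence can only shrink
flux ranges.  A `weight` parameter switches to a single-stage weighted
trade-off (score − weight·Σ|v|, kept linear); the lexicographic mode is
the default because no canonical weight exists.  Because the usage-class
counts depend on ε, `epsilon_sensitivity` recomputes them over
ε ∈ {0.01, 0.1, 1} as a built-in report.

## Deletion scans

Candidates default to the reactions *optional* under the baseline FVA
(required deletions break the measured rates; inactive ones change
nothing).  Each deletion (bounds → [0,0]) is followed by FVA over the
central set; infeasible deletions are retained with `feasible=False`.
Results rank ascending by mean central span.  Double-deletion scans prune
pairs whose singles each reduce the mean span by less than 1 mmol·gAFDW⁻¹·h⁻¹
(logged, disableable), and the report lists only deletions above that same
reporting floor.

## The toy phototroph and the synthetic generators

The toy network (39 reactions, 27 metabolites, 32 genes) reproduces the
canonical cyanobacterial electron-transport topology: PSII → plastoquinone →
cyt b6f → plastocyanin → PSI → ferredoxin → FNR → NADPH; ferredoxin-
plastoquinone cycling; pumping NDH-1 and non-pumping NDH-2; cytochrome c
and quinol oxidases; NADPH- and ferredoxin-dependent Mehler reactions; ATP
synthase; lumped Calvin-cycle carbon fixation; glycogen and cyanophycin
storage; nitrogenase and three hydrogenases (two soluble bidirectional,
one ferredoxin-dependent uptake).  Proton stoichiometries are textbook-like
integers per two electrons — PSII 2, cyt b6f 4, NDH-1 4, cytochrome oxidase
4, quinol oxidase 2, ATP synthase 4 H⁺/ATP — chosen so the qualitative
orderings that drive the analyses hold: the cytochrome-oxidase chain
outpumps the quinol oxidase, NDH-1 outpumps NDH-2, and cyclic flow trades
reductant for ATP.  Electron bookkeeping rides on metabolite charges
(reduced carriers differ by −1 or by one H plus matching charge), so every
internal reaction passes an element *and* charge audit; photons are
massless species, and exchange/demand/biomass reactions are exempt.
Biomass demands 30 precursor, 5 NH3, 10 NADPH and 20 ATP (polymerization
only) per gram — GAR is installed separately.

What the toy does *not* emulate: quantitative agreement with any
genome-scale reconstruction (its absolute yields, spans, and counts are its
own), photoinhibition or state transitions, pigment-specific absorption
cross-sections, and metabolite dilution.  Passing tests therefore establish
the correctness and the qualitative physiology of the methods, not
numerical predictions for a real organism.

The expression generator marks a gene active if any reaction carrying flux
(|v| > 1e-6) cites it, draws detection Bernoulli(0.9 active / 0.05
inactive) and log2 mRNA from N(11, 1) / N(5, 1) — well-separated modes
around the threshold 8, emulating high-coverage proteomics with occasional
spurious hits.  The batch generator computes growth by FBA under the true
(GAR = 50, NGAR = 1) at equal PSII/PSI uptakes from 10 to 60 (inside the
dual-limited region, where photon supply translates tightly into ATP and
the requirement parameters are identifiable) and applies one multiplicative
error per batch to the whole observation vector — growth and both photon
uptakes — emulating the shared ash-free-dry-weight normalization that
dominates per-biomass rate errors.  All generators are bit-reproducible
under fixed seeds.

In the tests, chemostat-style "measurements" are produced the way real ones
behave: growth rounded down to four decimals, O2 evolution at the midpoint
of its feasible interval at that growth — mutually consistent numbers of
finite precision.

## Known limitations

* No thermodynamic (ΔG/loop-law) constraints; cycles are suppressed only by
  norm minimization, and zero-cost redox shuttles dominate FVA spans until
  deleted — which the deletion scan demonstrates deliberately.
* The evidence MILP fixes one optimal binary assignment (after the L1
  tiebreak); the quadratic norm is minimized given those binaries, not
  jointly over all score-optimal assignments (a mixed-integer QP).  On
  enumerable instances the tests confirm the tiebreak reaches the least
  norm among score-optimal assignments.
* Region detection relies on LP duals; heavily degenerate models may need
  the finite-difference fallback (automatic) or a finer grid.
* The problem sizes exercised by the test-suite and the analysis scripts
  (toy network, ≤ 60×60 phase-plane cells, 20 batches) are chosen so the
  whole stack runs in seconds; all routines accept genome-scale models and
  scale as (LP solves) × (grid points or reactions).
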