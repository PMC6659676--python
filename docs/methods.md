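# Methods

## Scope and modeling assumptions

`costimnet` models the intracellular response of an activated CD8 T cell
to agonism of the costimulatory receptors 4-1BB (*I*) and OX40 (*Ox*)
during the window in which both receptors are co-expressed. The model is
a stochastic multistate (ternary) logic network: qualitative literature
knowledge is encoded as transition tables rather than rate laws, which
keeps the parameter count near zero at the cost of ordinal rather than
quantitative predictions.

Standing assumptions:

- TCR triggering is optimal and implicit; receptor engagement is all-or-
  none (inputs clamped at 0 or 2), so graded agonist dosing is out of
  scope.
- Production and decay rates are of comparable magnitude across species
  and are not modeled.
- Perturbed species fluctuate much less than unperturbed ones, so
  knock-out and overexpression are constant clamps at 0 and 2.
- TRAF3 is not an explicit species: its competition with TRAF2 for OX40
  binding is folded into the OX40→TRAF2 coupling (see `stim_T` below).
- Known feedbacks deliberately omitted for lack of T-cell-specific
  evidence: NF-κB-driven transcription of TRAF1/TRAF2, and autocrine
  cytokine loops back onto TNFR signaling.

## The rule set

Species: `I, Ox | Tr1, Tr2, Tr5, Nk, PKB, ERK, JNK, Bim, S, C`. Levels
0/1/2 = low/medium/high; `clamp(x) = min(2, max(0, x))`. Tables are
stored fully enumerated; the closed forms below only generate them.

| Target | Parents | Closed form | Rationale |
|---|---|---|---|
| Tr1 | I | `I` | TRAF1 is recruited by 4-1BB |
| Tr5 | Ox | `Ox` | TRAF5 is recruited by OX40 |
| Tr2 | I, Ox, Tr1 | `clamp(stim_T + Tr1 − 1)`, `stim_T = min(2, I + ⌊Ox/2⌋)` | both receptors activate TRAF2, 4-1BB more strongly (TRAF3 dampens the OX40 arm); TRAF1 boosts, or mitigates when absent |
| Nk | Tr2, Tr5 | `⌊(2·Tr2 + Tr5 + 1)/3⌋` | canonical NF-κB activation, TRAF2 evidence stronger than TRAF5 |
| PKB | Tr2, Ox | `⌊(Tr2 + Ox)/2⌋` | PI3K/PKB axis engaged by OX40 and TRAF2 |
| ERK | Tr1 | `Tr1` | carries the TRAF1-dependent arm of Bim suppression |
| JNK | Tr2, Nk | `clamp(1 + Tr2 − Nk)` | MAPK-cascade activation by TRAF2 vs transcriptional inhibition by NF-κB |
| Bim | JNK, ERK, PKB | `clamp(1 + JNK − inh_B)`, `inh_B = max(ERK, PKB)` | JNK releases Bim; ERK- and PKB/FoxO-dependent arms suppress it |
| S | Nk, PKB, Bim, JNK | see below | balance of pro-survival and pro-apoptotic drives |
| C | Nk, JNK | `Nk=0: (0,0,1); Nk=1: (1,1,1); Nk=2: (2,2,2)` over JNK | NF-κB dominant; moderate JNK with low NF-κB is insufficient |

`stim_T` and `inh_B` are rule-construction intermediates evaluated inside
the Tr2 and Bim lookups, not state variables.

**Survival rule.** With `act = Nk + PKB` and `inh = Bim + JNK`:

```
S = 2  if max(Nk, PKB) = 2 and act − inh ≥ 0
S = 0  if act < 2 or act − inh ≤ −2
S = 1  otherwise
```

The saturation branch was the one genuinely open design choice. A
stricter variant (`S = 2` iff `max(Nk, PKB) = 2` and `inh ≤ 1`) produces
identical baseline and knockout behavior but caps survival at 1 in the
4-1BB-mono + PKB-overexpression state (Nk=1, PKB=2, JNK=2, Bim=1),
contradicting the screen-level prediction that constitutive PKB decouples
survival from treatment entirely. The margin form `act − inh ≥ 0` keeps
the same activator/inhibitor balance semantics, reproduces that
prediction, and changes no other tabulated outcome; it is the shipped
default.

**ERK placement.** The Bim-inhibition literature ties the TRAF1 arm to
ERK. Folding ERK into `inh_B = max(Tr1, PKB)` would make ERK
perturbations undefined, so ERK is an explicit node driven by Tr1 with
`inh_B = max(ERK, PKB)` — equivalent at steady state, and it gives ERK
knock-out/overexpression well-defined meaning.

## Update semantics

One time step is a sweep: a uniformly random permutation of the free
(unclamped, non-input) species is drawn; each visited species fires
independently with probability `p`; a firing species reads its rule
target from the *current*, partially updated state and moves one level
toward it. Consequences:

- **Continuity**: |Δlevel| ≤ 1 per species per step, always.
- **Asynchrony**: update order is random and effects propagate within a
  sweep, emulating unordered molecular events without a global clock.
- **Stochastic laziness** (`p < 1`): not every possible interaction
  occurs each step.

An alternative scheme (`scheme="single"`: one randomly chosen species
considered per step) is available for sensitivity checks; it converges to
the same fixed points, only more slowly. Steady state is detected with
the deterministic predicate *every free species sits at its rule target*,
not by observing an unchanged state vector — under `p < 1` a state can
persist by chance, so the predicate is the only seed-independent
criterion. Once it holds no realization of the update can leave the
state (absorption).

## Parameters

| Parameter | Default | Units | Why |
|---|---|---|---|
| `p` | 0.5 | probability/step | must be < 1 by construction; 0.5 is the symmetric choice and is exposed in every interface so an externally specified value can be substituted and re-validated |
| `max_steps` | 200 | steps | hard cap; ~10× the longest observed convergence |
| `horizon` | 30 | steps | reporting length; the time axis is unitless and the deepest cascade (I/Ox → TRAF → Nk/PKB → JNK → Bim → S/C, ≤ 2 level-moves per species) converges well inside 30 steps at p = 0.5 |
| `n_runs` | 100 | trajectories | ensemble size used for all reported means/sds |
| `seed` | required | — | replicate streams are spawned from the master seed via `numpy` `SeedSequence`; identical settings ⇒ bit-identical output |

Initial state: clamps at their levels, everything else 0 (resting
physiological baseline). The bundled network is acyclic, so the steady
state provably does not depend on the initial levels; the suite verifies
this empirically with random initial states.

## Steady-state oracles

Two independent routes to the fixed points: (1) exhaustive enumeration of
all `3^k` assignments of the `k` free species (vectorized; ground truth
for any model, cyclic or not); (2) a single evaluation pass in
topological order, valid only for acyclic constrained models, where it
yields the unique fixed point. The test suite requires the two oracles to
agree, and requires stochastic ensembles to reach the same state, across
all 4 treatments × 9 perturbation rows.

## Validation suite and known-gaps

Every qualitative steady-state outcome the model is meant to reproduce is
encoded as a constraint over the analytic steady-state table (seed-free
by construction). "Perturbation X abrogates the response to treatment T"
is formalized as `readout(T, X) == readout(none, X)` — treated versus
untreated cells of the same phenotype.

Three constraints are declared **known-gaps**: the suite stays green when
they fail on the bundled model, and a user-supplied model file that
satisfies them gets full credit.

1. *ERK-KO abrogates the OX40-mono survival response.* Structurally
   unreachable: ERK is driven only by TRAF1, which OX40 does not engage,
   so ERK is already 0 in every OX40-mono state and the clamp changes
   nothing.
2. *JNK-OE abrogates both mono survival responses.* In the 4-1BB-mono
   state (Nk = 1, PKB = 1, ERK = 2) the clamp cannot push `Bim + JNK`
   past 3, which leaves `act − inh = −1 > −2`, so S stays 1.
3. *JNK-OE raises cytokine output above wild type in stimulated
   treatments.* Jointly unattainable with (a) the ERK-KO 4-1BB-mono
   abrogation that the suite does require — that forces the JNK target at
   (Tr2 = 2, Nk = 1) to 2, so wild-type 4-1BB-mono already has JNK = 2 —
   and (b) the baseline moderate cytokine level, which pins the C table's
   Nk = 1 row. A JNK clamp at 2 therefore cannot change C in any
   stimulated treatment. The JNK-OE cytokine gain survives only in the
   unstimulated condition (C: 0 → 1).

## What the stochastic scheme does and does not emulate

The ensemble mean/sd bands reproduce the qualitative shape of noisy
signaling kinetics: sigmoid-like rises, transient heterogeneity, and
collapse of variance once all runs absorb at the fixed point. They do not
represent biological cell-to-cell variability calibrated to data — the
noise source is the update schedule only, the time axis is unitless, and
every cell in an ensemble is identical in parameters. Passing tests
therefore demonstrate internal consistency and agreement with reported
qualitative outcomes, not quantitative kinetics of real T cells.

## Numerical and procedural choices

- Levels are plain ints validated at the boundaries (rule construction,
  condition construction, file parsing); tables are dicts keyed by parent
  tuples, with an int8 array view for the vectorized enumerator.
- Trajectories that converge before the reporting horizon are padded with
  the fixed state so ensembles align; the sd bands then shrink to 0.
- Screen matrices are computed from the analytic oracle and confirmed
  entry-by-entry against the modal ensemble final state; a disagreement
  raises rather than warns, since it would mean the engine and the
  oracles describe different dynamics.
- Problem sizes in the shipped checks: 3^10 ≈ 59k states per exhaustive
  enumeration, 100-run ensembles, 10,000 single-step trials for the
  firing-fraction estimate, and ≥ 1,000 fuzzed trajectories for the
  continuity property. All chosen as the smallest sizes at which the
  binomial/sampling error is far below the ordinal effect sizes.

## Known limitations

- Ordinal outputs only: no synergy index is computed (none is defined for
  discrete models); comparisons between treatments stay qualitative.
- No graded TCR or agonist input, no TRAF3 node, no NF-κB→TRAF or
  cytokine autocrine feedback (by design, above).
- PKB knock-out abrogates *both* mono survival responses in this
  reconstruction; the screen-level expectation only pins the OX40 half,
  and the 4-1BB half is left unasserted rather than guessed.
- The bundled tables are one reconstruction consistent with the
  qualitative constraints; alternative tables can be loaded from a model
  file and scored against the same suite.
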