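# costimnet

Stochastic multistate logic model of CD8 T cell costimulation through the
TNFR-family receptors **4-1BB (CD137)** and **OX40 (CD134)**.

Agonists of 4-1BB and OX40 each boost activated CD8 T cell survival and
cytokine output moderately; given together ("dual costimulation") they
generate *supereffector* cells with maximal survival and cytokine
production. `costimnet` simulates the intracellular network thought to
produce this effect — the TRAF adaptors (TRAF1/2/5), NF-κB, PKB (AKT),
ERK, JNK and the pro-apoptotic protein Bim, feeding two phenotypic
readouts, survival (*S*) and cytokine release (*C*) — and lets you run
*in silico* knock-out and overexpression experiments against any
combination of the two costimulatory inputs. It is intended for
immunologists and modelers exploring costimulatory agonist combinations
(e.g. for cancer immunotherapy) and for anyone who wants a small,
fully-auditable example of a stochastic discrete-logic signaling model.

## The model

Twelve species, each with an ordinal activity level *x* ∈ {0, 1, 2}
(low / medium / high). The receptor inputs *I* (4-1BB) and *Ox* (OX40)
are clamped at 0 or 2; every other species has a total transition table
generated from closed forms such as

- TRAF1/TRAF5 track their receptors: `Tr1 = I`, `Tr5 = Ox`
- TRAF2 integrates both receptors with 4-1BB dominant, boosted by TRAF1:
  `Tr2 = clamp(min(2, I + ⌊Ox/2⌋) + Tr1 − 1)`
- NF-κB weighs TRAF2 twice as strongly as TRAF5:
  `Nk = ⌊(2·Tr2 + Tr5 + 1)/3⌋`
- JNK balances its TRAF2 drive against NF-κB inhibition:
  `JNK = clamp(1 + Tr2 − Nk)`
- Bim balances JNK activation against its strongest inhibitor:
  `Bim = clamp(1 + JNK − max(ERK, PKB))`
- Survival balances activators against inhibitors: with
  `act = Nk + PKB`, `inh = Bim + JNK`, survival is maximal (*S* = 2)
  when one activator is saturated and `act ≥ inh`, collapses (*S* = 0)
  when `act < 2` or `act − inh ≤ −2`, and is moderate otherwise.

Dynamics: at each time step the unclamped species are visited in a
uniformly random order; each fires independently with probability
*p* (< 1, default 0.5) and, when it fires, moves **one level** toward
its table target (the continuity constraint). A state where every
species already sits at its target is a steady state. Knock-out and
overexpression are clamps at 0 and 2 respectively. The bundled network
is acyclic, so each condition has a unique fixed point, computable both
by exhaustive enumeration of all 3¹⁰ free states and by one topological
evaluation — the two oracles cross-check each other and the stochastic
ensembles.

## Worked example

Dual costimulation drives the supereffector state (S = C = 2); all 100
replicate runs converge within the 30-step reporting horizon:

```text
$ costimnet ensemble --condition dual --seed 7 --out results/dual
condition=dual seed=7 runs=100 converged@30=1.00 steady S=2 C=2
```

The knock-out/overexpression screen over the four costimulation
treatments (columns) prints the steady-state survival matrix:

```text
$ costimnet screen --runs 50 --seed 7 --out results/screen
survival matrix:
        none  monoI  monoOx  dual
WT         0      1       1     2
ERK-KO     0      0       1     2
PKB-KO     0      0       0     2
JNK-KO     0      1       1     2
Nk-KO      0      0       0     1
ERK-OE     0      1       1     2
PKB-OE     2      2       2     2
JNK-OE     0      1       0     2
Nk-OE      2      2       2     2
```

Reading it: wild-type survival rises 0 → 1 → 2 from no costimulation
through mono- to dual-costimulation. Of the four pathway knockouts, only
NF-κB loss (`Nk-KO`) blunts the dual response (2 → 1): the other nodes
compensate for each other, but NF-κB both promotes survival and restrains
the JNK→Bim pro-apoptotic axis. PKB or NF-κB overexpression yields
maximal survival regardless of treatment. A matching cytokine matrix is
written alongside, and every entry is confirmed by the modal final state
of a stochastic ensemble.

`costimnet validate` scores the model against the built-in suite of
qualitative steady-state constraints (baseline levels, knockout results,
screen predictions) and exits 0 while the suite is green; three
predictions the bundled reconstruction cannot reach are tracked as
declared known-gaps (see `docs/methods.md`).

Other subcommands: `costimnet simulate` (one trajectory as tidy CSV),
`costimnet fixed-points` (exhaustive steady-state enumeration). All
commands accept `--ko`/`--oe` clamps, `--p`, `--seed`, a YAML `--config`,
and custom model files in the plain-text table format documented in
`costimnet/modelio.py`.

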