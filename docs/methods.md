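# Methods

This note records the models implemented in `traitflow`, their
assumptions, the defaults that matter, and the places where the design was
genuinely open and a choice had to be made.

## Detection-error model and the core cutoff

A gene family truly present in genome *i* is observed with probability
*c<sub>i</sub>*, the genome's estimated completeness (fraction in (0, 1]),
independently across genomes and families. A family truly absent from
genome *i* can be falsely observed with probability
ε<sub>i</sub> = contamination<sub>i</sub> × s; the scale *s* defaults to 0
(contamination off), because CheckM-style contamination measures redundant
marker genes rather than a per-family false-presence rate, and a defensible
mapping between the two does not exist. The observed occurrence count of a
family is therefore Poisson-binomial (computed with
`scipy.stats.poisson_binom`; an exhaustive 2^N enumeration serves as an
independent cross-check in the tests).

Subdividing at cutoff *n* (core: observed ≥ *n*; strain-specific: observed
= 1; dispensable: 2..*n*−1) has six model error rates. The error channels
are downward only when contamination is off — detection can only lose
presences — which induces the identity structure used throughout:

* **fn_core** = P(observed < *n* | truly present in all *N* genomes);
* **fp_disp** = fn_core — a missed core family lands in the dispensable bin;
* **fn_disp** = P(observed outside [2, *n*−1] | true occupancy *m*),
  averaged over an occupancy prior on *m* ∈ [2, *n*−1] (uniform by default;
  the empirical occurrence spectrum can be supplied as weights), with the
  *m* least-complete genomes as hosts (a conservative bound);
* **fp_spec** = fn_disp — a dispensable family collapsing to a single
  observation lands in the strain-specific bin;
* **fn_spec** = max<sub>i</sub> P(the single host genome misses the family)
  = max<sub>i</sub>(1 − c<sub>i</sub>) when contamination is off;
* **fp_core** = worst case over dispensable occupancies *m* ∈ [2, *n*−1] of
  P(observed ≥ *n*), non-zero only through contamination.

Note the model's dispensable support is [2, *n*−1]: the framework assumes
true dispensable occupancy lies below the cutoff. Families whose true
occupancy falls in [*n*, *N*−1] are indistinguishable from core by any
occurrence-threshold rule once detection noise is present; see
*Limitations*.

**Cutoff selection.** `select_cutoff` scans every *n* ∈ [2, *N*] (the
feasible set is computed by full scan, never assumed to be an interval) and
returns the largest feasible *n* (most stringent core; `prefer="smallest"`
overrides). Feasibility by default binds the *n*-controllable rates
{fn_core, fp_core, fp_disp} against the threshold (default 0.01). The
completeness-floor rates (fn_spec and the low-occupancy channel of
fn_disp) do not depend on *n*; including them (`rate_scope="all"`) makes
the criterion unsatisfiable whenever any genome is less than ~99%
complete, so the literal all-six-rates reading is available but not the
default. All six rates are always reported for every candidate *n*.
Infeasibility is an explicit error carrying the full rate table, never a
silent fallback.

## Sampling curves

Exhausted subsampling: for each subset size *n*, every genome combination
is evaluated when C(N, n) ≤ `max_subsets` (default 1000), otherwise
`max_subsets` distinct subsets are drawn without replacement (seeded,
default seed 42). All three statistics (strict intersection, subset-unique
counts, union) are order-invariant, so combinations replace permutations
and `subsets_used` records the effective count. The curve "core" is the
strict all-member intersection, deliberately *not* the FN/FP cutoff core:
the decay-to-asymptote model describes how the strict intersection shrinks
as genomes accumulate, which is the quantity the exponential models were
formulated for.

Fitting profiles the decay constant: for fixed τ the model is linear in
(K, asymptote) and solved in closed form; τ is minimised from eight
log-spaced starts in [0.3, 30], each polished by bounded scalar search
(xatol 1e−12). This is deterministic, needs no user initialisation, and
recovers noiseless model data to ~1e−8 relative. Asymptotic standard
errors come from the Gauss–Newton Jacobian at the optimum. The pan model
inherits (Ks, τs, tg θ) from the strain-specific fit and estimates only
the intercept D = P(1); the construction guarantees the increment identity
P(n) − P(n−1) = Fs(n).

## Pan-pathway and flow roles

Functions inherit the pan-genome cutoff: a function's occurrence is the
number of genomes carrying ≥ 1 gene annotated to it (union-based, since a
function may aggregate several families), and the same ≥ *n* / = 1 / in
between rule labels it. The bundled flow-role configuration encodes the
18-module anaerobic/aerobic role table of the polyphosphate-accumulating
organism model (acetate uptake, PHA, glycogen and PolyP as the AN-phase
primary carbon source/sink, electron source and energy source; PHA,
complete TCA and oxygen-driven ETP in the AE phase). Each (phase, flow)
has exactly one primary provider and one primary consumer. Two judgement
calls: the LCFA module both supplies and consumes AN-phase carbon in the
source material, and a module holds a single role per (phase, flow) here,
so it is recorded as *inter* (interconverting); and the module→KO
membership is not specified anywhere authoritative, so the bundled
function lists are clearly labelled placeholders (ids `K9MMNN`) that the
synthetic generator and tests use — real analyses must supply their own KO
sets.

## Transcript normalization

RPKM = reads × 10⁹ / (gene length bp × sample total). CRPKM divides each
sample's RPKM by the median RPKM over the population's genes in that
sample (mean available via a switch; the mean-scaled variant MRPKM is
always emitted), and LCRPKM = log2(CRPKM + 1). Dividing by a within-
population summary removes the population's abundance from its expression
signal, making values comparable across samples; it is exactly invariant
to library size and yields a per-sample population median of 1 by
construction. An optional per-sample DNA-coverage divisor hooks in matched
metagenome depth when available. Module activity is the mean LCRPKM over
the module's genes, averaged over the phase's samples (trimmed mean
optional); modules with no genes present are *absent*, never zero.

## Scenario diagnosis

Within each phase, module activities are z-scored against all modules of
that phase; high means z > +0.5, low means z < −0.5 (configurable). The
across-module standard deviation is floored at `min_sd` = 0.3 LCRPKM
units, chosen from the fold-change geometry: a 4× change shifts LCRPKM by
≈ 1.3, so the floor keeps pure-noise deviations (≲ 0.15 at the default
simulation sizes) below the threshold while genuine effects score |z| ≈ 2.
The floor also subsumes the zero-variance case (all-equal activities →
all baseline).

The carbon-vs-electron axis votes in the AN phase: B evidence {complete
TCA high, partial TCA high, oxidative split-TCA branch low}; C evidence
{LCFA, AA, glutamate, oxidative branch, denitrification, hydrogenases
high}. The electron-vs-energy axis: state-2 evidence {complete TCA, ETP,
PolyP, P transporters high in AE}; state-3 evidence {PolyP, P transporters
low in AE; glycogen and partial TCA high in AE; ETP high in AN}. A state
is called only when its score beats the opposing score by more than
`margin` (default 1 vote); ties resolve to the balanced state, the
conservative no-intervention call. The "secondary carbon sources not
recruited" condition that accompanies carbon-excess evidence is implied by
the differential scoring (recruitment votes count for C) rather than being
a positive B vote — a positive vote would misclassify an all-baseline
profile. PolyP and transporter levels are read in the AE phase, where
polyphosphate is recharged. The favourable set is exactly
{A1, A2, C1, C2}. The z-scoring makes the diagnosis invariant to any
affine rescaling of a phase's activities (provided the spread stays above
the floor); invariance under general monotone transforms is *not*
guaranteed.

## Synthetic data

`simulate_pangenome` plants 1800 core families (occupancy *N*), 3500
dispensable families (occupancy uniform on 2..*N*−1, hosts random) and 250
strain-specific families per genome across *N* = 13 genomes, then observes
each presence with probability c<sub>i</sub> ~ U(0.85, 0.98) — the typical
completeness range of good-quality metagenome-assembled genomes. Families
never observed are dropped from the matrix and reported. The generator
never creates a presence when contamination is off.

`simulate_expression` gives each of the 18 modules 8 genes (plus 40
background genes), lengths uniform on 500–2000 bp, and negative-binomial
counts (dispersion 0.2 — typical RNA-seq overdispersion; mean proportional
to gene length times a baseline of 200 counts/kb). The planted scenario
template applies 4×/0.25× fold-changes to the scenario's high/low module
sets in the stated phase, with 4 samples per phase. These defaults make
template recovery unambiguous at the default thresholds, and are
configurable to probe robustness.

What the generator does *not* emulate: strain mixtures within the
population, annotation errors and multi-function genes, compositional
coupling between modules, sample-to-sample library-preparation batch
effects, and occupancy spectra with realistic U-shapes. Passing the
closed-loop tests therefore shows the rule table and templates are
mutually consistent and robust to count noise — not that real reactors
are classified with the same fidelity.

## Problem sizes

Tests and the acceptance script use 50 replicates for curve-fit recovery,
20 planted-truth pan-genome replicates, 5 seeds per scenario for the
closed loop, and subset caps of 50–1000 per *n*; these sizes give
Monte-Carlo standard errors comfortably inside the tolerances being
checked while keeping a full run in seconds.

## Limitations

* Any occurrence-threshold rule misassigns true occupancies adjacent to
  the cutoff once genomes are incomplete: a family truly in *N*−1 genomes
  is observed ≥ *n* with near certainty and labelled core, and an
  occupancy-2 family is observed once with probability ≈ 2c(1−c). The
  model's 99%-style guarantees are statements about its own rate
  definitions (dispensable support below the cutoff); against a planted
  truth whose dispensable occupancy spans up to *N*−1, per-category
  precision is bounded far below 99% no matter the cutoff. The
  `score_partition` helper reports exactly this.
* fn_spec is a worst-case single-genome bound; a spectrum-weighted average
  would be smaller but needs per-genome family counts the model does not
  assume.
* The diagnosis rule table operationalises qualitative descriptions; the
  vote thresholds (z ± 0.5, margin 1) are design choices exposed in
  `DiagnosisConfig`, not measured constants.
* Chemical evidence (effluent P, residual acetate) can be attached as
  flags but does not currently enter the votes.
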