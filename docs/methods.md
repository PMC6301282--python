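# Methods

This note records the modelling assumptions, default parameters, numerical
choices, and known limitations of the `rlflux` pipeline. It is written so a
reader can audit every number the pipeline produces.

## 1. Constraint-based model and FBA

A metabolic model is a stoichiometric matrix `S` (m metabolites × n
reactions), flux bounds `V_min ≤ v ≤ V_max`, an objective vector `c`, and
per-reaction gene–protein–reaction (GPR) boolean rules. Flux balance
analysis (FBA) solves the LP

```
max c·v   s.t.   S·v = 0 on internal metabolites,   V_min ≤ v ≤ V_max.
```

Only boundary (exchange/demand) reactions may carry a steady-state
imbalance. Sign convention: uptake through an exchange is negative flux, so
an uptake rate `r` mmol/gDW/h maps to lower bound `−r`. Unconstrained
reactions use the conventional ±1000 sentinel.

The LP layer is a persistent optlang/GLPK model that is built once per
network and re-solved with updated bounds/objectives; this is what makes
per-sample condition-specific solving affordable (≈1 ms per re-solve on the
toy network). The test suite cross-checks every headline optimum against an
independent scipy/HiGHS formulation.

## 2. Geometric FBA

The FBA optimum is generally a face of the flux polytope, not a point, so
raw FBA fluxes are solver-dependent. Geometric FBA selects a unique,
central representative:

1. Solve the FBA LP; fix `c·v = z*` (within slack `1e-9·max(1,|z*|)`).
2. Iterate: flux variability analysis (FVA) over still-active reactions;
   take per-reaction range midpoints `m`; minimize `Σ_j |v_j − m_j|`
   (linearized with deviation variables) over the optimal face; shrink the
   bounding box halfway toward the midpoints, *keeping the projected point
   inside the new box* so the restricted polytope never becomes empty.
3. Stop when every range width is ≤ tolerance (default `1e-6`) or after
   `max_iterations` (default 200; the last iterate is returned flagged
   unconverged).

Properties relied on downstream: the result is deterministic (independent
of solver vertex choice) within tolerance; symmetric alternatives are split
evenly (two parallel transporters of joint demand 10 carry 5 each); and
isolated reversible cycles — whose FVA ranges are symmetric about zero —
are driven to zero flux. The centering distance is L1 so every step stays
an LP. We implement centering only; no additional total-flux minimization
is layered on top.

## 3. Pathway engineering

The rhamnolipid graft is five irreversible core reactions (RHLA, RHLB,
RHLC, 3H3H, PHAC), a mono-rhamnolipid transport step, and an exchange.
Stoichiometries are kept exactly as curated in the source reconstruction,
including its quirks (PHAC's product doubling, RHLB's spurious proton); the
mass-balance checker reports these honestly instead of rebalancing.
Di-rhamnolipid transport/exchange is added only behind a flag, so RHLC is
expected to appear blocked by default — the pipeline centres on the
mono-rhamnolipid product.

Curation checks: element/charge balance for every non-boundary reaction
whose metabolites all carry formulas (others are listed "unchecked";
grafted metabolites intentionally carry no formulas rather than guessed
ones), and an FVA-based flux-carrying screen with proton/water steps
excluded as ubiquitous.

## 4. Expression integration (condition-specific models)

Normalized expression `θ` (per-gene mean over all samples = 1, so θ is a
fold change against the cohort average) maps to a bound-scaling factor

```
φ(θ) = [1 + γ·|ln θ|]^sgn(θ−1),   sgn(0) = 0,   γ = 1 by default.
```

Natural log is used so the identities φ(e)=2, φ(1/e)=1/2, and
φ(θ)·φ(1/θ)=1 hold exactly. Gene-level θ propagates to reactions through
the GPR with AND = min (limiting subunit of a complex) and OR = max (best
isozyme); genes missing from the profile contribute θ = 1. Both bounds of
every GPR-bearing reaction are multiplied by φ(θ_reaction); GPR-less
reactions are untouched unless `scale_all` is set (then they take
φ(missing-gene θ)). One geometric FBA per sample yields the
condition-specific flux matrix; infeasible samples are recorded with a
status, never silently dropped.

Note that φ only moves *bounds*: it changes predictions only where a bound
is binding at the optimum. The synthetic generator therefore tightens the
planted reaction's upper bound to 80% of its unconstrained geometric flux —
without a binding bound the integration is phenotypically invisible and
untestable.

## 5. Downstream statistics

- **DARs.** Two-group comparison per reaction by two-sided Wilcoxon
  rank-sum (`scipy.stats.mannwhitneyu`) — LP-constrained fluxes are bounded
  and non-Gaussian — with Benjamini–Hochberg adjustment across all tested
  reactions and a 0.05 threshold. Reactions with identical flux in every
  sample are excluded from testing (rank tests are undefined on pure ties)
  and reported separately.
- **Elastic net.** For each DAR, its flux across samples is regressed on
  the (column-standardized) expression matrix with penalty
  `λ[(1−α)‖β‖₁ + α‖β‖₂²]`, α = 0.5, via sklearn `ElasticNetCV`
  (`l1_ratio = 1−α`; at α = 0.5 the published sign conventions coincide).
  λ is the CV-error minimizer on a 100-point log grid with a seeded,
  shuffled 10-fold split. Degenerate responses (zero variance) return an
  all-zero β with a warning. Genes are ranked by |β|, ties broken by gene
  id for determinism.
- **PCA.** SVD of the column-centred (and, by default, unit-scaled =
  correlation PCA) reactions × conditions flux matrix. Eigenvalues are
  `s²/n`; variable coordinates are correlations with components;
  contributions are percentage shares of a component's inertia (summing to
  100 per component for variables and for individuals); cos² measures
  quality of representation. Constant columns are dropped with a warning
  under scaling; under covariance PCA (`scale=False`) they are kept with
  zero loadings — the carbon-study pipeline falls back to covariance PCA
  when a source column is constant so every source remains a PCA variable.

## 6. Synthetic data

`toy_model()` builds a deterministic, mass-balanced network mirroring the
engineered topology: glucose transport → g6p; a rhamnose branch g6p → g1p
→ dTDP-sugar; a glycolysis-like branch g6p → 2 acetyl-CoA; fatty-acid
synthesis 5 acetyl-CoA → hydroxyacyl-ACP; dimerization to HAA;
condensation with the dTDP-sugar to rhamnolipid; export and exchange; a
biomass drain; and a CoA turnover sink (which carries zero flux in the
base network but is required for the grafted Table-style chain, whose
printed stoichiometry nets +1 CoA per unit). Options add an isolated
3-reaction reversible cycle, a direct fatty-acid feed into the acyl pool,
parallel glucose transporters, and a binding 80% bound. Closed-form
optima: glucose 10 → 10/6 rhamnolipid; FA alone → 0; glucose+FA at 10
each → 35/6.

`synth_expression()` draws θ = exp(N(0, σ²)) per gene and sample
(σ = 0.25), shifts planted genes by +δ (δ = ln 2) on the log scale in the
mutant group only, and wires the two planted genes onto the two parallel
glucose transporters (the first with the binding 80% bound, the second as
the unconstrained complement). Null genes are assigned to reactions whose
sentinel bounds never bind, so between-group flux differences are confined
to the planted wiring — making DAR/top-gene recovery an exact property.
All randomness flows from one integer seed through one
`numpy.random.default_rng` generator.

## 7. Defaults and why

| Parameter | Default | Rationale |
|---|---|---|
| Uptake rate (scan/mixed/omics) | 10 mmol/gDW/h | control-condition convention |
| Geometric tolerance / max iterations | 1e-6 / 200 | published formulation; LP-only steps |
| γ (φ rule) | 1 | reference parameterization |
| log base in φ | e | closed-form identities |
| GPR aggregation | AND=min, OR=max | limiting subunit / best isozyme |
| DAR test / adjustment / threshold | rank-sum / BH / 0.05 | non-Gaussian LP fluxes; field default |
| Elastic-net α / folds / grid | 0.5 / 10 / 100 log-spaced | balanced penalty; CV minimum |
| PCA scaling | correlation (with covariance fallback) | correlation-circle presentation |
| Binding bound in synthetic data | 80% of unconstrained flux | makes bound scaling phenotypically visible |
| Mixed-substrate rates | 10 each | control rate per source |

## 8. Limitations

- Flux predictions are steady-state LP optima: no kinetics, no regulation,
  no dynamic batch culture.
- φ-scaling affects only reactions whose bounds bind; on unconstrained
  genome-scale models most reactions are insensitive to expression.
- The curation checker reports imbalances and unchecked reactions; it does
  not gap-fill or rebalance.
- Cycle suppression is only the centering behaviour of geometric FBA, not
  loopless FBA.
- The synthetic generator emulates the two-group design and the binding
  mechanism, not genome-scale dimensionality (a paper-scale flag exists for
  stress tests) nor real co-expression structure.
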