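# Methods

`errophylo` implements Bayesian phylogenetic inference for single-cell
SNV data in which sequencing noise is part of the observation model
rather than something to be filtered away beforehand. This note records
the models, the numerical choices, and the design decisions that were
genuinely open, together with what the simulation studies do and do not
demonstrate.

## Substitution models

**Binary model.** Mutation presence/absence evolves on {0, 1} with
forward rate 1 (0→1) and back-mutation rate λ (1→0):

    Q = [[−1, 1], [λ, −λ]],   π = (λ/(λ+1), 1/(λ+1)).

Q is used exactly as written — the forward rate anchors the time scale,
so branch lengths are expected substitutions per site for data sampled
at one time point. No rate normalisation is applied.

**GT16 model.** Diploid genotypes are the 16 *ordered* allele pairs
AA, AC, …, TT (index = 4·first + second). The generator extends the
general time-reversible nucleotide model: only single-allele changes
have nonzero rate,

    Q[aa→ab] = r_ab π_ab,  Q[aa→ba] = r_ab π_ba,
    Q[ab→aa] = r_ab π_aa,  Q[ab→bb] = r_ab π_bb,

with six exchangeabilities r = (r_AC, r_AG, r_AT, r_CG, r_CT, r_GT) and
stationary genotype frequencies π. All other off-diagonal entries —
including heterozygote-to-heterozygote changes such as AC→GC — are zero,
so every substitution passes through a homozygous state. Both models are
reversible (detailed balance π_x Q_xy = π_y Q_yx holds exactly by
construction).

By default the GT16 generator is rescaled so that −Σ π_x Q_xx = 1,
making branch lengths expected substitutions per site; the flag
`normalize` on `build_gt16_q` (and `normalize_q` on `Gt16ModelSpec`)
exposes the unscaled reading, since the convention is not forced by the
model itself. Exchangeabilities live on the simplex (they carry a
Dirichlet prior and the overall rate is fixed by normalisation, so only
their ratios are identifiable).

Internally the exchangeabilities are named `r_AC … r_GT`; the Greek
letters conventionally attached to them clash with the error-model
parameters, so they are not used in code.

**Transition probabilities.** P(t) = exp(Qt) is computed from the
eigendecomposition of the symmetrised generator
S = diag(√π) Q diag(1/√π) (real symmetric for reversible Q; `eigh` is
stable and the decomposition is reused for every branch). Entries are
clipped at 0 against round-off (below 1e−12) and rows renormalised.
Equilibrium frequencies below 1e−8 are rejected when parameters are
constructed, keeping Q irreducible and the symmetrisation well
conditioned; the scaling-and-squaring `expm` fallback for degenerate π
is therefore unreachable in normal use.

## Error models

Errors act independently per cell and site on the tips: the true
genotype y is observed as x with probability E[x, y] = P(x | y). Each
column of E is a probability distribution.

**Binary** (false positive α, false negative β):

    P(0|0) = 1−α,  P(1|0) = α,  P(0|1) = β,  P(1|1) = 1−β.

**GT16** (allelic dropout δ, combined amplification/sequencing error ϵ):
for a true homozygote aa,

    P(aa|aa) = 1 − ϵ + δϵ/2
    P(ab|aa) = P(ba|aa) = (1−δ)ϵ/6        (b ≠ a)
    P(bb|aa) = δϵ/6                        (b ≠ a)

and for a true ordered heterozygote ab (c ∉ {a, b}),

    P(ab|ab) = (1−δ)(1−ϵ)
    P(aa|ab) = P(bb|ab) = δ/2 + ϵ/6 − δϵ/3
    P(ac|ab) = P(cb|ab) = (1−δ)ϵ/6
    P(cc|ab) = δϵ/6.

*Ordered-state convention.* The expressions above normalise only
under a definite reading of which ordered observations are possible. We
adopt the per-allele reading: the first observed allele derives from a
and the second from b, and a single error event never swaps the pair.
Hence for a true heterozygote ab the observations ba, ca and bc have
probability zero (they would need two simultaneous allele errors, a
second-order term the model drops), while a true homozygote aa emits
both orders ab and ba symmetrically. Under this convention each column
of the 16×16 table sums to **exactly** 1 — no renormalisation is applied,
and construction fails loudly if the invariant is ever violated — and
the table collapses to the identity at ϵ = δ = 0. This is the only
convention we found under which these expressions are complete,
normalised and identity-collapsing at zero error; the column-sum test
over a 10×10 (ϵ, δ) grid pins it.

**Tip partials.** Without an error model a tip observing x carries the
indicator vector; with one it carries (P(x|y) for all true y). An
unphased heterozygote ab* is the ambiguity {ab, ba} with
P(ab*|y) = P(ab|y) + P(ba|y); missing data (`?` in FASTA/Nexus, `./.` in
VCF) carries the all-ones vector, i.e. errors are not applied to missing
observations. Boundary parameter values 0 and 1 are valid.

## Likelihood

Sites are independent; per site the standard pruning recursion computes
partial likelihood vectors bottom-up, combining children through their
branch transition matrices, and closes with Σ_x π_x L_root(x). For MCMC
throughput the engine collapses identical site patterns (weights applied
on the log scale), computes all branch matrices in one batched product
from the cached eigensystem, and rescales partials every 8 internal
nodes with accumulated log scalers — rescaling never changes the
returned value and is verified against an exhaustive sum over internal
states on trees of ≤5 tips in both state spaces. Ambiguity and missing
codes are resolved at tips only.

## Tree priors and simulators

Trees are rooted, strictly binary, with contemporaneous tips at height
0. The two tree processes are defined generatively and the MCMC prior
density is the exact density of the same process, so simulation and
inference share one distribution — the premise of a well-calibrated
study:

- **Yule (pure birth), conditioned on m tips**: merging backward from
  the tips, with k lineages the waiting time is Exp(k·birthrate) and a
  uniform random pair merges. Density over (labelled topology, heights):
  log p = Σ log k + (m−1)·log b − b·L with L the tree length (the
  k-weighted interval sum telescopes to L for ultrametric trees).
  Conditioning on the tip count is a modelling choice; the calibration
  property is insensitive to it because simulator and prior share one
  construction.
- **Kingman coalescent (constant θ)**: waiting time Exp(k(k−1)/(2θ)),
  density log p = Σ log C(k,2) − (m−1)·log θ − Σ C(k,2) u_k / θ.

Hyper-priors: birthrate ~ Normal(7, 1) truncated at 0 (the simulator
redraws non-positive values; the truncation keeps the density proper),
θ ~ Lognormal(−2, 1). The λ prior is Lognormal with log-mean −1; its
log-sd is not pinned by the study description, and we use 1.0 — the
calibration property is invariant to this choice because the same prior
generates and fits the data.

Sequence simulation draws the root state from π and child states from
P(t) down each branch; tip errors are then drawn per cell/site from the
error-table column of the true state. `strip_phasing` maps every
heterozygote ab to the ambiguity ab* (idempotent). All simulators are
deterministic functions of the supplied numpy Generator.

## MCMC

Metropolis–Hastings over (tree topology, node heights, scalar and
simplex parameters). Operators:

- multiplicative scale moves for positive scalars (Hastings ratio s);
- reflected uniform walks for probability parameters;
- delta exchange on simplex parameters (π, r), preserving the sum
  exactly;
- node-height slide (uniform between highest child and parent),
  root-offset scale, whole-tree height scale;
- narrow (nephew–aunt) and wide subtree exchange, drawn uniformly from
  the eligible swap set with the count ratio as Hastings correction;
- Wilson–Balding prune–regraft with uniform reattachment height; the
  pruned node is drawn from the (constant-size) set of nodes with a
  grandparent, destinations are counted in both directions, and
  regrafting above the root is left to the exchange moves;
- joint "up–down" scalings of all heights with a correlated scalar
  (birthrate down, or θ up; and heights up with (α, β) down for the
  binary error model) to follow the strong height–rate and
  height–error posterior ridges.

Step sizes adapt toward ~30% acceptance during burn-in only (10% of the
chain by default); afterwards the kernel is fixed, preserving detailed
balance. Proposals that would leave the support return a rejection
rather than raising. Likelihood re-evaluation is skipped for moves that
only touch the tree-prior hyperparameter. Chains are bit-reproducible
given the seed.

Operator correctness is validated by prior sampling: with no data the
chain must reproduce the joint prior, and tests compare sampled tree
height/length moments and analytic prior means (Beta, Lognormal,
Dirichlet components) against direct simulation — this catches Hastings
ratio errors with high power.

Initialisation: scalars at prior medians, the tree drawn from the tree
prior at those medians; a non-finite starting posterior raises
immediately.

**Diagnostics.** `hpd_interval` returns the shortest contiguous interval
containing ⌈mass·N⌉ sorted samples. `ess` uses the integrated
autocorrelation time with the FFT autocovariance truncated at the first
negative autocorrelation (the estimator used by common trace
analysers); it is cross-checked against `arviz.ess` and the AR(1)
closed form N(1−ρ)/(1+ρ) in tests.

## Tree statistics and SPR distance

Tree length, height and treeness (internal-branch share of total
length) follow the standard definitions; the gamma statistic is the
Pybus–Harvey γ on the internode intervals of an ultrametric tree
(tolerance 1e−6 relative height deviation, else an error — posterior
trees here are ultrametric by construction).

Topology accuracy is the rooted SPR edit distance, ignoring branch
lengths. A breadth-first search over SPR neighbourhoods is intractable
beyond depth ~2 (the neighbourhood is Θ(n²)), so exact distances are
computed through the maximum-agreement-forest characterisation of
rooted SPR distance: augment both trees with a root pseudo-leaf ρ; the
distance is the number of components of a maximum agreement forest
minus one. The search deepens iteratively over k-subsets of edges of
the first tree to cut, encoding label sets as bitmasks and checking
each induced partition for identical rooted restricted topologies and
vertex-disjoint spanning subtrees. Distances are exact up to `d_max`
(default 6, above the range posterior trees exhibit here); beyond the
cap the certified bracket [d_max+1, m] is returned and flagged
approximate. Posterior summaries memoise distances per distinct
topology. The implementation is validated against a brute-force BFS
oracle on small trees. Rooted rather than unrooted distances are
used, matching the rooted trees being compared.

## Well-calibrated studies

Each replicate draws the true parameters from the priors, simulates
tree → sequences → tip errors, runs MCMC with the *same* priors, and
records whether each parameter's 95% HPD covers the truth, the
posterior-median bias, and the SPR distance of thinned posterior
topologies to the true tree. With a correct sampler and matched priors
every parameter's coverage is 95% by construction, so the aggregate
coverage table is a sharp end-to-end test of simulator, likelihood,
priors and operators together. The deliberately mis-specified variants
re-fit the same datasets without the error model and show the
characteristic failure: tree length and the substitution rate lose
coverage (the noise is absorbed into extra substitutions, inflating the
tree), while the birth rate and tree height degrade far less. The
robustness variants draw error rates from wide uniform ranges
(α ∈ [0.001, 0.1], β ∈ [0.1, 0.6] binary; ϵ ∈ [0.001, 0.1],
δ ∈ [0.1, 0.8] GT16) while inference keeps its Beta priors
(α ~ Beta(1,20), β ~ Beta(3,3) binary), so their guarantee is
approximate by design.

**Scales.** Presets ship at two scales. The full scale uses 100
replicates with 30-tip/400-site (binary) and 16-tip/200-site (GT16)
data. The desk scale — 20 replicates, 12 tips, 200 sites (binary);
10 replicates, 8 tips, 100 sites (GT16) — is the configuration the test
suite and the acceptance script run, sized for a single CPU. Desk-scale
coverage estimates carry binomial noise of ±5 percentage points per
step at n = 20, and the mis-specification effect is diluted relative to
the full scale (half the sites and fewer tips widen the
posteriors, so the no-error-model coverage collapse is less deep).
Assertions therefore use exact binomial tests at significance 0.01
rather than point comparisons.

**Convergence handling.** A replicate whose minimum ESS over the
monitored parameters falls below a threshold is rerun once with a
doubled chain and flagged (never silently dropped). Thresholds: 200 at
full scale; at desk scale 50 (binary) and 40 (GT16), chosen with the
desk chain lengths (50k/60k states) so that routine replicates pass and
reruns stay exceptional — the HPD interval of a 95% mass is already
stable at these ESS values, and doubling every chain would double the
study cost for no measurable change in coverage.

**What the simulations do not show.** Data are generated from the
inference model itself: real single-cell data have doublets, copy-number
changes, coverage-dependent and site-correlated errors, none of which
are modelled here. Passing calibration demonstrates internal correctness
of the Bayesian machinery, not adequacy of the error model for any
particular dataset. Tips are contemporaneous; time-calibrated or dated
analyses (relaxed clocks, skyline population models) are outside this
package.

## Input conventions

FASTA: binary sequences use one character per site (0/1/?); GT16 uses
two characters per site, uppercase for phased genotypes, lowercase
pairs for unphased heterozygote ambiguities, `??` for missing. Nexus
data blocks use one symbol per genotype (`0–9A–F` in canonical order)
with `{xy}` ambiguity sets. VCF conversion (read-only) maps diploid GT
fields per sample and record: `A|C` → AC, `A/C` → {AC, CA}, `./.` →
missing; non-SNV records are skipped with a logged count; haploid or
>2-allele calls are errors naming the record. Record coordinates are
kept as metadata only — the models treat sites as exchangeable and
independent.
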