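# Methods

## Scope and model

The package implements the model-based (KPG-style) QSAR workflow in
which a drug-receptor equilibrium constant is expanded, via a
Klopman–Hudson perturbation treatment of the interaction energy and a
classical treatment of the rotational partition function, into a linear
form containing only drug-side quantities: per-skeleton-atom reactivity
indices, substituent orientational parameters, and optionally the
molecular mass. The quantum-chemical calculation that produces the MO
data is out of scope — eigenvalues, occupancies, per-atom per-MO
electron populations, net charges and geometries arrive precomputed in
a JSON interchange document — as are receptor-side quantities, which
the expansion folds into the fitted coefficients.

## Electronic-structure records and normalization

Energies are stored in eV (hartree input is converted with
1 Ha = 27.2114 eV; the choice of unit only rescales fitted
coefficients, but one canonical unit keeps indices comparable across
levels of theory). Structures must have at least one occupied and one
empty MO, energy-ascending, with every occupied MO below every empty
one; occupancy is taken from the input document, not inferred from
electron counts, because the intended inputs include closed-shell
cations where inference conventions differ.

Raw per-MO populations may carry Mulliken artefacts. Normalization
applies, per MO: clamp negatives to zero; zero every population at or
below the threshold (default 0.01 e); rescale survivors to unit sum.
Zeroing and rescaling iterate to a fixed point — rescaling a
heavy-total MO downward can push a value through the threshold — which
makes the operation idempotent. Every correction is logged. The clamp
rule is the simplest correction preserving Σ F = 1; published
correction schemes for negative Mulliken populations are not specified
at the level of formulas, so the package states its own rule. An MO
whose populations all fall at or below the threshold cannot be
renormalized and is a hard error rather than a silent drop.

## Reactivity indices

Superdelocalizabilities divide each Fukui index by its MO eigenvalue
(S = Σ F/E). The division form is what makes eigenvalues near zero
pathological — the sum diverges for methods whose empty eigenvalues
straddle the Fermi level (HF, DFT, CNDO/2-like spectra) — and that
pathology is handled by refusing: any contributing MO with |E| < 1e−6
eV raises a dedicated error identifying the input method as unsuitable
for this index, rather than returning a huge number. No factor of 2
for double occupancy is applied; the fitted coefficient absorbs any
constant factor.

Local frontier indices derive from the *atom's* frontier: the highest
occupied and lowest empty eigenvalues with nonzero population on that
atom after thresholding. An atom missing either side has no frontier
and its derived descriptors are reported missing — never zero, since a
fabricated zero would read as a real index value downstream. By
construction the atom frontier sits at or inside the molecular
HOMO–LUMO pair, so local hardness always dominates global hardness;
this is enforced as a property test.

## Frontier compaction and matrix assembly

Per atom, MO-resolved descriptors (F and orbital S) are relabelled
onto relative levels counting only populated MOs: HOMO, HOMO−1, …
downward; LUMO, LUMO+1, … upward. Compaction moves labels, never
values. Depth defaults to 3 occupied + 3 empty levels, matching the
deepest levels that appear in published equations of this family
(HOMO−1, LUMO+2).

The matrix has one row per molecule and one column per
(skeleton-atom, descriptor) pair plus orientational-parameter columns
and an optional mass column. The skeleton correspondence is user
input: fixing which atom of each molecule plays which skeleton role is
a chemical judgement, not a computation. Columns undefined for any
molecule are dropped with a logged reason (imputation would fabricate
chemistry); all-constant columns are dropped as carrying no regression
information. Assembly is deterministic and order-independent up to row
order.

Orientational parameters are O_t = Σ m_i R_i² (amu·Å²) over the
substituent's member atoms, R_i the Euclidean distance to the
attachment atom. The symmetry number of the rotational term is fixed
at 1, appropriate for the low-symmetry drug molecules this workflow
targets; hydrogen substituents are computed like any other. A member
atom coincident with its attachment atom contributes zero with a
warning. Rigid-motion invariance, s² distance scaling, and additivity
over disjoint member sets are property-tested.

## Regression and model search

Fits are ordinary least squares with intercept (statsmodels under the
hood). The reported panel: multiple R (correlation of fitted with
observed), R², adjusted R², F with (k, n−k−1) dof,
SD = √(SS_res/(n−k−1)), standardized betas, per-coefficient t tests,
the squared pairwise predictor-correlation matrix, standardized
residuals (residual/SD) and the molecules beyond the 2σ limit. The
residual dof convention n−k−1 and the simple residual/SD standardized
residual were validated against all five published SD values
reproducible from the bundled observed/calculated tables.

Model search is best-subset: subsets of sizes 1 and 2 are enumerated
exhaustively by closed-form normal equations on centered data; the
best survivors are extended column-by-column (beam width 10) up to
k_max; and every subset of the ≤20-column visited pool is enumerated
as a refinement. A purely greedy forward path was rejected: because
Fukui indices within an MO sum to one, descriptor columns are
structurally inter-correlated, and greedy selection reliably locks
onto proxy columns that jointly fit well without containing the
generative ones.

Admissible models must satisfy a pairwise-collinearity cap (default
r² ≤ 0.5 among selected predictors, consistent with the
squared-correlation matrices this literature publishes alongside its
equations) and an all-coefficients significance screen. The screen is
selection-aware: in a k-variable model drawn from p candidates, each
coefficient must reach p-value < α/C(p,k) (α = 0.05), a Bonferroni
correction over the family of size-k subsets, in the spirit of the
risk-inflation criterion. A nominal per-coefficient 0.05 would be
vacuous here: with ~50+ candidates the best pure-noise column clears
it almost every time, and at n = 16 a jointly chosen subset can
interpolate the noise so well that *every* coefficient of an overfit
model looks significant. With the corrected screen, pure-noise
searches return empty at roughly level α. `bonferroni_screen=False`
restores the nominal screen. Admissible models are ranked by adjusted
R², ties broken lexicographically; an empty result carries a
diagnostic summary instead of raising.

The outlier protocol refits after removing, one molecule at a time,
the worst standardized residual beyond the σ limit (default 2),
tracing every step; it ends "clean", "no acceptable model" (budget
exhausted with flags outstanding) or "under-determined" (a removal
would leave n ≤ k+2). Note that at the default 2σ limit a flag
requires n−k−1 > 4, since |standardized residual| ≤ √(n−k−1); the
under-determination guard is therefore reachable only with tighter
limits, and is kept as a defensive contract.

## Synthetic data

The generator emulates the pipeline's inputs under the default study
conditions: 16 molecules, 10 skeleton atoms plus 2 substituents of 1–3
atoms, 6 occupied MOs in (−20, −5) eV and 6 empty in (1, 10) eV — the
ZINDO/1-like convention in which every empty eigenvalue is positive,
the regime where superdelocalizability sums are well-behaved — with
population sparsity 0.3 (a mid-range value giving each atom a
distinctive populated-MO pattern while keeping most depth-≤3 columns
derivable), activities from two planted descriptor columns with
effects of 0.5–1.5 log-K units per column SD, and Gaussian activity
noise of SD 0.1 log units (measurement-level noise on log IC₅₀-style
data). A `dft_like` mode draws empty eigenvalues straddling zero to
exercise the near-zero-eigenvalue error paths. All randomness flows
from one integer-seeded PCG64 generator; same spec + seed reproduces
the dataset bit-for-bit.

When the planted model is auto-chosen, the choice is constrained to
identifiable sets: mutual r² ≤ 0.5 between true columns (the search's
own admissibility cap — an inadmissible truth could never be returned)
and r² ≤ 0.8 against every other candidate (the descriptor family
contains near-deterministic transforms of the same frontier pair, such
as hardness and softness of one atom at r² ≈ 0.95, and exact recovery
of one member of such a twin is ill-posed for any method). The screen
is skipped below 8 molecules, where sample correlations of columns are
uninformative. An explicitly supplied true model bypasses it.

What passing tests on these data do and do not show: the generator's
populations are independent uniform draws, not quantum-chemically
consistent densities; its geometries are random points, not conformers;
its activities are exactly linear in the descriptors. Recovery results
therefore validate the pipeline's correctness and the search's
selection behaviour under the stated noise, not the chemical adequacy
of any particular descriptor set for real receptor data.

## Numerical choices and problem sizes

Population-sum and identity tolerances: 1e−8 for Σ F per MO, 1e−10 for
the ς·η, ω and Q^max identities, 1e−12 for oracle-agreement checks.
Near-zero eigenvalue tolerance: 1e−6 eV. Rank deficiency is detected
on the full design matrix and reported with the dependent columns
identified by pivoted QR. Search tie-breaks are lexicographic on
sorted column labels, making rankings deterministic. The bundled
affinity tables are checked at the precision they are published to
(±0.01 on R and SD; ±1.5 on F, covering rounding of the printed
columns). Simulation-based checks run 1000 structures for oracle
agreement and 100 replicates for parameter recovery — sizes at which
the binomial uncertainty on a ≥95% recovery criterion is well below
the margin observed (recovery is 100/100 at the default conditions).

## Known limitations

* Populations are partition-agnostic: the package does not know or
  check whether they came from Mulliken, Löwdin or any other scheme.
* No cross-validation, bootstrap, or regularized alternatives to
  best-subset OLS: the workflow reproduces the classical protocol of
  this model family, whose selection inference is handled by the
  screens above.
* Exact principal moments of inertia are deliberately replaced by the
  orientational-parameter approximation; the mass term is optional.
* The interchange converter for QM-log parsers is a stub mapping
  already-parsed attributes plus a user-supplied population array; it
  does not read log files itself.
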