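# Methods

## Lattice model and fold space

Proteins are chains of L = 27 residues occupying every site of the 3×3×3
cubic box (compact Hamiltonian self-avoiding walks); smaller boxes (2×2×2,
3×3×2) serve as exactly checkable test systems.  Two residues are in
contact when they occupy adjacent lattice sites and are not consecutive
along the chain.  Every compact 27-mer has exactly 28 contacts; bipartite
lattice parity makes contacts impossible between positions of equal parity,
so 169 even-separation pairs plus the 26 backbone bonds — 195 of the 351
pairs — can never touch.

Folds are enumerated by a depth-first search over site-occupancy bitmasks,
with starts restricted to one symmetry-irreducible wedge of the box; a walk
is kept only when it equals the lexicographic minimum of its orbit under
the 48 octahedral box symmetries (optionally combined with chain reversal),
so each symmetry class is emitted exactly once and in a deterministic
lexicographic order.  Correctness rests on oracles, not on the pruning
argument: brute-force enumeration with explicit symmetry application on the
2×2×2 and 3×3×2 boxes, and, for the full cube, the free-action identity —
the DFS visits 4,960,608 directed compact walks (confirmed by an
independent plain-Python counter), which is exactly 48 × 103,346.  The
census is therefore 103,346 symmetry-inequivalent directed conformations,
51,704 when chain reversal is also quotiented — matching the classical
enumerations of this lattice.  A count of 103,406 appears in parts of the
literature; it equals 2 × 51,704 − 2 and is reproduced by no symmetry
convention we can construct (we conjecture it arose from doubling the
undirected count and mishandling the 62 reversal-symmetric classes).  The
package default is the directed convention (`include_reversal=False`),
recorded in every library's provenance.

## Energetics and sampling

Contact energies default to the Miyazawa–Jernigan 1996 contact table
(e_ij, RT units, unit temperature), shipped as a text file with its
checksum recorded; any symmetric q×q table can be loaded, and reduced
HP-like alphabets (q = 2, 3) are provided for the toy systems.  Folding
probabilities are Boltzmann ratios over a structure library; all Boltzmann
sums run in log space (log-sum-exp), with per-structure energies updated
incrementally under single-site mutations (exact to round-off, verified
against full recomputation).

The default competitor library is a seeded uniform subsample of the full
enumeration (N configurable; reduced-scale default 50, full-scale 10,000).
Uniform subsampling is the only reproducible stand-in for the historical
"representative subset" pool, whose selection procedure is not available;
the subsample seed is part of every run's provenance.

Sequence families are sampled by Metropolis Monte Carlo: one proposed
single-site mutation per step (site uniform, replacement uniform among the
other q−1 letters — a symmetric proposal, so detailed balance holds),
accepted with min(1, e^{−βΔH}) where H = −log P_nat, optionally minus
b × (matches to a wild type) for biased families.  β defaults to 10³; the
chain burns in until P_nat ≥ 0.995 (configurable; the toy presets disable
the gate) and emits one sequence every 1,000 steps.  Exactness is verified
on the cube2 system, where the target P_nat^β/Z over all 256 sequences is
enumerable: the sampled distribution matches to total-variation distance
< 0.02 at 10⁶ thinned samples.  The equilibration diagnostic compares
P_nat traces of chains started from distinct sequences and reports the
first step from which they stay within tolerance, flagging frozen or
non-overlapping chains.

## Inference

Weighted frequencies follow the identity-cutoff reweighting scheme
(ω_τ = 1/#{σ : identity > L(1−w)}, strict inequality, self included;
w = 0 means no reweighting), with optional uniform pseudocount mixing that
keeps one- and two-point marginals exactly consistent.

* **IM** — fields h_i = log f_i, reported in zero-sum gauge.
* **Mean-field DCA** — J = −C⁻¹ on the (q−1)-state restriction of the
  connected correlations, fields from the mean-field closure; requires a
  pseudocount (default λ = 0.5, the standard mean-field choice; exposed as
  a parameter).
* **PLM** — site-wise L2-regularised multinomial regressions (analytic
  gradients, L-BFGS, gradient tolerance 1e−5), asymmetric coupling
  estimates symmetrised by averaging, output in zero-sum gauge.  The
  default penalty γ = 0.01 is deliberately strong: good for contact
  ranking, poor for generation (over-shrunk couplings).
* **ACE** — cluster expansion of the cross-entropy.  Single sites and pairs
  have closed-form fits; pair contributions carry a Miller–Madow correction
  for the plug-in entropy bias ((k_i−1)(k_j−1)/2M_eff, k = letters observed
  at the site), without which selection at q = 20 and moderate M is
  dominated by bias rather than signal.  A pair enters the expansion only
  if its corrected contribution exceeds both the current threshold and a
  significance floor of 3 standard deviations of the null noise
  (χ²-approximation, √(2·df)/2M_eff; 3σ balances power against the ~L²/2
  pairs tested).  The threshold is lowered geometrically (factor 2) until
  the model reproduces the data's one- and two-point statistics within 3σ
  or every significant cluster is included; clusters up to size 4 are grown
  from overlapping selected ones for small alphabets (q ≤ 5), and fit by
  convex maximum-entropy optimisation over the cluster's q^k states.
  Because the truncated expansion overcounts shared-site correlations on
  long chains, each level's model is refined *before* the reconstruction
  test: Boltzmann-machine steps on the marginal residuals, restricted to
  the retained parameter support — plain gradient descent against exact
  marginals when q^L is enumerable, RPROP-style sign updates against
  Monte-Carlo marginals (with annealed sampling depth) otherwise, both with
  the L2 penalty γ = 5/M.  The entropy estimate is the accumulated cluster
  contribution; refinement is not folded into it (noted in its provenance).
  On the L = 6, q = 3 oracle the entropy matches exhaustive enumeration to
  within 0.2% and coupling error falls monotonically with M.

Gauge transformations (zero-sum, consensus, least-probable) are exact and
invertible; energy differences and the Gibbs distribution are preserved to
1e−10, checked as a property.  ACE models are reported in the
least-probable gauge, DCA/PLM in zero-sum.

## Scoring, pressures and classes

Pair scores are the APC-corrected Frobenius norm of the coupling blocks,
APC-corrected mutual information, or the projection λ_ij of couplings on
the negated energy table.  APC uses the average-product convention
(products of row *means* over the overall mean), under which a constant
score matrix is corrected exactly to zero.  Backbone pairs (|j−i| ≤ 1) are
excluded from rankings; parity-forbidden pairs are ranked by default (they
act as an internal noise floor) and can be excluded by flag.  Ties are
broken by pair index, so rankings are reproducible.

For the projection, model and energy table are expressed in the consensus
gauge of the reference frequencies (the energy table is shifted per site
pair by the same gauge transformation applied to the couplings, keeping the
projection well defined), and sums run by default only over letters
observed at the two sites.  The theoretical pressure divides the
contact-map difference c_ij − c̄_ij by log(1 + 1/(β·N_S e^{−Δ})); the
denominator's functional form is isolated in `pressure_denominator` so it
can be revised in one place.  Only the aggregate competitor weight
N_S e^{−Δ} enters; the package also reports a participation-ratio split
into an effective competitor count and gap for inspection.

Pair classes are defined against the closest competitor S_F (smallest
MSA-averaged energy gap): UN (native only), SN (both), CC (competitor
only), NN (neither, geometrically allowed), forbidden.

## Generative evaluation

Fields-only models are sampled exactly (per-site softmax); Potts models by
the same Metropolis move set as the sequence sampler, thinned and seeded.
The Gaussian approximation to the Potts distribution draws one-hot vectors
from N(f_i, C) over the first q−1 states and maps each site to the most
compatible letter (argmax over the block, the dropped state scored by the
residual).  Generated sequences are evaluated for P_nat against the full
library, Hamming distance to the training consensus, and the relation
between model energy and −log P_nat; the folding-fraction summary reuses
the sampler's 0.995 design threshold.

## Reduced-scale behaviour and limitations

The test suite runs the full pipeline at a reduced scale: 50 competitor
folds, alignments of 2,000 sequences.  At that scale some full-scale
contrasts compress or vanish, and this is a property of the physics, not of
the inference: with only 49 competitors, site conservation alone is almost
sufficient to fold (independent-site-generated sequences reach median
P_nat ≈ 0.996, matching Potts-generated ones), the MI noise floor at
M = 2,000 caps the ACE cluster support, and the projection score loses its
edge over the Frobenius ranking.  Increasing the pool and alignment to
N = 500 / M = 10⁴ (about two minutes of CPU) restores every full-scale
ordering: PLM 0.82 > MI 0.75 at PPV(28), projection(ACE) 0.75 ≥
Frobenius(ACE) 0.57, class pressures UN 1.11 > SN 0.14 > 0 > CC −0.59, and
ACE-generated sequences folding (median P_nat 0.98) where IM-generated ones
fail (0.27) at equal diversity.  Benchmark conclusions should therefore be
read as functions of (N, M, β): the competitor pool is as much a part of
the system as the fold.

The synthetic families emulate equilibrium selection for stability at a
single algorithmic temperature against a fixed pool of competitors.  They
contain no phylogeny (the bias option mimics only its simplest effect:
inflated identity to an ancestor), no insertions/deletions, no functional
constraints beyond folding, and a contact energy that is exactly pairwise.
Passing tests therefore validate the inference machinery under the model's
own assumptions; they do not certify performance on real alignments, where
all of these idealisations break.

Other limitations: the mean-field DCA route is implemented for contact
scoring rather than generation; paper-scale runs (N = 10⁴ competitors,
M = 5·10⁴ sequences) are supported by the same code paths but take hours of
CPU and are not exercised by the default test run; and the ACE threshold
and refinement defaults above are package choices recorded in each model's
provenance — the historical implementations they follow leave these details
open.
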