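# lpbench — a lattice-protein benchmark for inverse statistical methods

Coevolution-based ("inverse Potts" / direct-coupling) analysis infers
residue–residue interactions from the covariation statistics of a multiple
sequence alignment.  On real proteins its assumptions are untestable: the
true energetics and the set of competing folds are unknown.  `lpbench`
builds the exactly solvable testbed on which those assumptions can be
checked: 27-mer lattice proteins on the 3×3×3 cube, where the fold space
can be enumerated exhaustively, sequence families can be sampled from a
known Hamiltonian, and every inferred quantity can be compared with ground
truth.  It is written for method developers in structural bioinformatics
and statistical physics who want a controlled benchmark for contact
prediction, fitness-landscape inference and sequence design.

## The model

A sequence **A** = (a₁,…,a₂₇) folded into structure *S* with contact map
c⁽ˢ⁾ has energy

    E(A|S) = Σ_{i<j} c_ij^(S) E(a_i, a_j)

with the Miyazawa–Jernigan 20×20 contact-energy table *E*.  Its folding
probability against a library of N compact folds is the Boltzmann ratio

    P_nat(S|A) = e^{−E(A|S)} / Σ_{S'} e^{−E(A|S')}.

Sequence families are sampled from P_nat^β by Metropolis Monte Carlo
(β = 10³ by default, so retained sequences fold with probability ≳ 0.995).
From the sampled alignment the package infers maximum-entropy models

    P(A) ∝ exp( Σ_i h_i(a_i) + Σ_{i<j} J_ij(a_i, a_j) )

by four routes — independent-site (IM), mean-field DCA, pseudo-likelihood
(PLM) and adaptive cluster expansion (ACE, which also returns the model
entropy, an estimate of the fold's designability).  Contacts are predicted
by ranking pair scores: APC-corrected mutual information, the APC-corrected
Frobenius norm F_ij = Σ_ab J_ij(a,b)², or the projection of each coupling
block on the energy table,

    λ_ij = − Σ_ab J_ij(a,b) E(a,b) / Σ_ab E(a,b)² ,

the *design pressure* on the pair.  λ_ij is positive where couplings
stabilise native contacts (positive design) and negative where they
penalise contacts of competing folds (negative design); its theoretical
counterpart (c_ij − c̄_ij) / log(1 + 1/(β N_S e^{−Δ})) is built from the
native contact map, the gap-weighted average competitor map c̄ and the
aggregate competitor weight.  Finally, sequences sampled from the inferred
models are scored for folding probability and diversity, testing whether
the models are generative.

## Worked example

```bash
python examples/design_pressures.py
```

samples 2,000 sequences for one fold against 50 competitors, fits an ACE
Potts model, and decomposes its couplings into pressure classes
(UN = contact in the native fold only, SN = shared with the closest
competitor S_F, CC = contact in S_F only, NN = in neither):

```
closest competitor: fold 3 (smallest energy gap to the native fold over the alignment)
aggregate competitor weight N_S e^-Delta = 9.188e-04

class  pairs  mean lambda   (inferred)    mean lambda (theory)
UN       20       +0.145        +1.137
SN        8       +0.086        +0.845
CC       20       -0.022        -0.410
NN      108       -0.004        -0.197
```

The sign structure UN > SN > 0 > CC is the coupling-level signature of
positive and negative design: the inferred couplings encode not only the
native contacts but also which contacts must be *avoided* to keep the
sequence out of the competitor fold.  Inferred magnitudes sit below the
theoretical ones because the inference is regularised and the alignment is
finite.  The other scripts in `examples/` demonstrate fold enumeration,
Monte-Carlo sampling with equilibration diagnostics, contact prediction
(MI vs PLM vs ACE), and generative sequence design; everything is also
reachable from the `lp` command line
(`lp enumerate / sample / infer / score / generate / evaluate / bench`).

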