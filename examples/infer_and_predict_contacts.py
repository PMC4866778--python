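"""Infer Potts models from a lattice-protein alignment and predict contacts.

The benchmark's central question: do couplings inferred from sequence
covariation recover the fold's contact map?  This script samples an
alignment for one 27-mer fold against 50 competitors, infers models by
mutual information, pseudo-likelihood (PLM) and adaptive cluster expansion
(ACE), and ranks site pairs by each score.  PPV(28) is the fraction of the
28 top-ranked pairs that are true contacts (a perfect predictor scores 1).
"""

from dataclasses import replace

from lpbench import (
    frobenius_apc_scores,
    infer_ace,
    infer_plm,
    metropolis_chain,
    mi_apc_scores,
    ppv_curve,
)
from lpbench.msa_statistics import frequencies, mutual_information_scores
from lpbench.workbench import make_toy_system

lib, E, config = make_toy_system("minipool", seed=0)  # enumerates 3x3x3 once
config = replace(config, n_samples=2000, seed=0)
native = 0
print(f"sampling M={config.n_samples} sequences for fold {native} "
      f"of a {lib.N}-fold library ...")
msa = metropolis_chain(native, lib, E, config)
stats = frequencies(msa)
truth = lib.contact_map(native)

scores = {"MI (APC)": mi_apc_scores(mutual_information_scores(stats))}
print("fitting PLM (site-wise pseudo-likelihood, L2 penalty 0.01) ...")
scores["PLM"] = frobenius_apc_scores(infer_plm(msa, gamma=0.01))
print("fitting ACE (cluster expansion + Boltzmann-machine refinement) ...")
ace_model, entropy = infer_ace(msa, seed=0)
scores["ACE"] = frobenius_apc_scores(ace_model)

print(f"\nACE entropy estimate: {entropy.entropy:.1f} nats "
      f"(designability: exp of this many nats of sequences fold here)")
print(f"\n{'method':10s} PPV(28)   (fraction of top-28 pairs that are contacts)")
for name, s in scores.items():
    ppv = ppv_curve(s, truth)
    print(f"{name:10s} {ppv[27]:.3f}")
print("\nCoupling-based rankings disentangle direct interactions from the")
print("transitive correlations that limit mutual information; the margin")
print("grows with the size of the competitor pool and the alignment depth.")
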