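"""Test whether inferred models can design new folding sequences.

A generative model should produce sequences that (i) fold into the target
structure with high probability and (ii) retain the diversity of the family
it was trained on.  This script fits an independent-site model (IM) and an
ACE Potts model to the same alignment, samples fresh sequences from each,
and scores their folding probability against the full competitor library.
"""

from dataclasses import replace

from lpbench import (
    evaluate_generated,
    infer_ace,
    infer_im,
    metropolis_chain,
    sample_from_model,
)
from lpbench.msa_statistics import consensus_and_identity, frequencies
from lpbench.workbench import make_toy_system

lib, E, config = make_toy_system("minipool", seed=2)
config = replace(config, n_samples=2000, seed=2)
native = 0
print(f"training alignment: M={config.n_samples} sequences for fold {native} "
      f"of {lib.N}")
msa = metropolis_chain(native, lib, E, config)
consensus, _ = consensus_and_identity(msa)

ace_model, _ = infer_ace(msa, seed=2)
im_model = infer_im(frequencies(msa, pseudocount=1e-3))
im_model.meta["alphabet"] = E.alphabet

for name, model in [("Potts-ACE", ace_model), ("IM", im_model)]:
    generated = sample_from_model(model, 500, seed=3)
    ev = evaluate_generated(generated, native, lib, E, consensus, model=model)
    print(f"\n{name}: median P_nat = {ev.median_pnat:.4f}, "
          f"fraction with P_nat >= 0.995: {ev.fraction_folding:.2f}")
    print(f"  mean Hamming distance to the training consensus: "
          f"{ev.mean_distance:.1f} of {msa.L}")

print("\nWith a small competitor pool, site conservation alone already folds;")
print("the pairwise model's advantage grows with the number of competing")
print("folds (at the full 10,000-fold scale, IM-generated sequences fail to")
print("fold while Potts-generated ones succeed).")
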