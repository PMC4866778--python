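"""Sampling sequences from inferred models and scoring their folding quality.

A model is *generative* when sequences drawn from it fold into the target
structure with high probability while retaining the diversity of the
alignment it was fit to.  Three samplers are provided: exact per-site
sampling for independent-site models, Metropolis Monte Carlo on the Potts
energy, and the Gaussian approximation to the Potts distribution built from
DCA-style correlations (drawn in the one-hot embedding, then projected back
to letters).  Generated sequences are then evaluated against the lattice
model itself: their folding probability P_nat, their Hamming distance to the
natural consensus, and the relation between model energy and -log P_nat.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit

from .energetics import ContactEnergyMatrix, EnergyEvaluator, SequenceLike, encode_sequence
from .lattice_conformations import StructureLibrary
from .msa_statistics import FrequencyStats
from .potts_inference import PottsModel, potts_energies
from .sequence_sampler import AlignmentSet

__all__ = [
    "FoldingEvaluation",
    "sample_from_model",
    "sample_gaussian_dca",
    "evaluate_generated",
]


@dataclass
class FoldingEvaluation:
    """Per-sequence folding metrics of a generated alignment plus summaries."""

    pnat: np.ndarray
    distance_to_consensus: np.ndarray
    model_energy: Optional[np.ndarray] = None
    pnat_threshold: float = 0.995
    provenance: dict = field(default_factory=dict)

    @property
    def median_pnat(self) -> float:
        return float(np.median(self.pnat))

    @property
    def fraction_folding(self) -> float:
        """Fraction of sequences at or above the folding threshold."""
        return float(np.mean(self.pnat >= self.pnat_threshold))

    @property
    def mean_distance(self) -> float:
        return float(np.mean(self.distance_to_consensus))

    def energy_vs_neglog_pnat(self) -> np.ndarray:
        """(n, 2) array of (H_model, -log P_nat) pairs."""
        if self.model_energy is None:
            raise ValueError("no model energies attached")
        return np.column_stack([self.model_energy, -np.log(self.pnat)])

    def to_frame(self):
        import pandas as pd

        data = {
            "pnat": self.pnat,
            "distance_to_consensus": self.distance_to_consensus,
        }
        if self.model_energy is not None:
            data["model_energy"] = self.model_energy
        return pd.DataFrame(data)


@njit(cache=True)
def _potts_mc_kernel(h, J, n_samples, interval, burn_in, seed):
    np.random.seed(seed)
    L, q = h.shape
    seq = np.empty(L, dtype=np.int8)
    for i in range(L):
        seq[i] = np.random.randint(0, q)
    samples = np.empty((n_samples, L), dtype=np.int8)
    emitted = 0
    step = 0
    total = burn_in + n_samples * interval
    while step < total:
        site = np.random.randint(0, L)
        old = seq[site]
        new = np.random.randint(0, q - 1)
        if new >= old:
            new += 1
        dh = -(h[site, new] - h[site, old])
        for j in range(L):
            if j != site:
                dh -= J[site, j, new, seq[j]] - J[site, j, old, seq[j]]
        if dh <= 0.0 or np.random.random() < np.exp(-dh):
            seq[site] = new
        step += 1
        if step > burn_in and (step - burn_in) % interval == 0:
            samples[emitted] = seq
            emitted += 1
    return samples


def sample_from_model(
    model: PottsModel,
    n: int,
    seed: int = 0,
    interval: Optional[int] = None,
    burn_in: Optional[int] = None,
) -> AlignmentSet:
    """Draw ``n`` sequences from exp(-H_Potts).

    Fields-only models are sampled exactly (independent per-site softmax);
    otherwise a thinned Metropolis chain on the Potts energy is used, the
    same move set as the sequence-space sampler.
    """
    alphabet = model.meta.get("alphabet") or "".join(
        chr(ord("A") + k) for k in range(model.q)
    )
    rng = np.random.default_rng(seed)
    if not np.any(model.J):
        # exact independent sampling from softmax(h_i)
        logits = model.h - model.h.max(axis=1, keepdims=True)
        p = np.exp(logits)
        p /= p.sum(axis=1, keepdims=True)
        X = np.empty((n, model.L), dtype=np.int8)
        for i in range(model.L):
            X[:, i] = rng.choice(model.q, size=n, p=p[i])
        return AlignmentSet(
            X, alphabet, provenance={"kind": "IM exact sampling", "seed": seed}
        )
    interval = interval or 3 * model.L
    burn_in = burn_in if burn_in is not None else 50 * model.L
    kernel_seed = int(rng.integers(0, 2**31 - 1))
    X = _potts_mc_kernel(
        np.ascontiguousarray(model.h),
        np.ascontiguousarray(model.J),
        int(n),
        int(interval),
        int(burn_in),
        kernel_seed,
    )
    return AlignmentSet(
        X,
        alphabet,
        provenance={
            "kind": "potts MC sampling",
            "method": model.method,
            "seed": seed,
            "interval": interval,
            "burn_in": burn_in,
        },
    )


def sample_gaussian_dca(
    stats: FrequencyStats, n: int, seed: int = 0
) -> AlignmentSet:
    """Draw from the multivariate-Gaussian approximation to the Potts
    distribution in the one-hot encoding (mean = site frequencies,
    covariance = pseudocount-regularised connected correlations over the
    first q-1 states), then map each site to the most compatible letter:
    argmax over the sampled one-hot block, with the dropped last state scored
    by the residual 1 - sum of the block."""
    L, q = stats.f_i.shape
    n_dim = L * (q - 1)
    C = stats.connected_correlations()
    cov = np.empty((n_dim, n_dim))
    for i in range(L):
        for j in range(L):
            cov[i * (q - 1):(i + 1) * (q - 1), j * (q - 1):(j + 1) * (q - 1)] = C[
                i, j, : q - 1, : q - 1
            ]
    mean = stats.f_i[:, : q - 1].ravel()
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as err:
        raise ValueError(
            "connected-correlation matrix is not positive definite; rebuild "
            "the statistics with a (larger) pseudocount"
        ) from err
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n, n_dim))
    X_onehot = mean + Z @ chol.T
    X = np.empty((n, L), dtype=np.int8)
    blocks = X_onehot.reshape(n, L, q - 1)
    last = 1.0 - blocks.sum(axis=2, keepdims=True)
    scores = np.concatenate([blocks, last], axis=2)
    X[:, :] = np.argmax(scores, axis=2)
    alphabet = stats.alphabet or "".join(chr(ord("A") + k) for k in range(q))
    return AlignmentSet(
        X, alphabet, provenance={"kind": "gaussian-dca sampling", "seed": seed}
    )


def evaluate_generated(
    msa_generated: AlignmentSet,
    native_index: int,
    lib: StructureLibrary,
    E: ContactEnergyMatrix,
    natural_consensus: SequenceLike,
    model: Optional[PottsModel] = None,
    pnat_threshold: float = 0.995,
) -> FoldingEvaluation:
    """P_nat, distance to the natural consensus, and (optionally) model
    energies for every generated sequence; the (H_model, -log P_nat) pairs
    underlie the energy-vs-folding scatter."""
    consensus = encode_sequence(natural_consensus, E)
    if consensus.shape[0] != msa_generated.L:
        raise ValueError("consensus length does not match generated sequences")
    ev = EnergyEvaluator(lib, E)
    from scipy.special import logsumexp

    X = msa_generated.sequences
    pnat = np.empty(X.shape[0])
    for t in range(X.shape[0]):
        e = ev.energies(X[t])
        pnat[t] = np.exp(-e[native_index] - logsumexp(-e))
    dist = (X != consensus).sum(axis=1).astype(np.float64)
    energy = potts_energies(X, model) if model is not None else None
    return FoldingEvaluation(
        pnat,
        dist,
        model_energy=energy,
        pnat_threshold=pnat_threshold,
        provenance={
            "native_index": int(native_index),
            "generator": msa_generated.provenance.get("kind", "unknown"),
        },
    )
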