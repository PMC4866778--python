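"""Weighted alignment statistics: frequencies, reweighting, mutual information.

Reweighting gives each sequence weight ``1 / n_tau`` where ``n_tau`` counts
the alignment members (itself included) whose identity with it exceeds
``L (1 - w)`` positions, a strict inequality; ``w = 0`` disables reweighting
(all weights one).  Frequencies are weighted counts normalised by
``M_eff = sum of weights``, optionally mixed toward uniform by a pseudocount
``lambda`` (used by mean-field DCA).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .sequence_sampler import AlignmentSet

__all__ = [
    "FrequencyStats",
    "sequence_weights",
    "frequencies",
    "mutual_information_scores",
    "consensus_and_identity",
]


@dataclass
class FrequencyStats:
    """One- and two-point amino-acid frequencies of a weighted alignment."""

    f_i: np.ndarray  # (L, q)
    f_ij: np.ndarray  # (L, L, q, q); diagonal blocks hold diag(f_i)
    M_eff: float
    q: int
    pseudocount: float = 0.0
    alphabet: Optional[str] = None

    @property
    def L(self) -> int:
        return self.f_i.shape[0]

    def connected_correlations(self) -> np.ndarray:
        """C_ij(a, b) = f_ij(a, b) - f_i(a) f_j(b), all pairs including i = j."""
        return self.f_ij - np.einsum("ia,jb->ijab", self.f_i, self.f_i)

    def save(self, path) -> None:
        """Binary container (npz) with shape metadata; lossless."""
        np.savez_compressed(
            path,
            f_i=self.f_i,
            f_ij=self.f_ij,
            M_eff=self.M_eff,
            q=self.q,
            pseudocount=self.pseudocount,
            alphabet=np.array(self.alphabet or ""),
        )

    @classmethod
    def load(cls, path) -> "FrequencyStats":
        with np.load(path, allow_pickle=False) as data:
            return cls(
                f_i=data["f_i"],
                f_ij=data["f_ij"],
                M_eff=float(data["M_eff"]),
                q=int(data["q"]),
                pseudocount=float(data["pseudocount"]),
                alphabet=str(data["alphabet"]) or None,
            )

    def site_frequencies_tsv(self, path) -> None:
        """Human-readable TSV of the site marginals (1-based sites)."""
        import pandas as pd

        letters = list(self.alphabet) if self.alphabet else list(range(self.q))
        frame = pd.DataFrame(self.f_i, columns=letters)
        frame.insert(0, "site", np.arange(1, self.L + 1))
        frame.to_csv(path, sep="\t", index=False)

    def validate(self, atol: float = 1e-10) -> None:
        L, q = self.f_i.shape
        assert np.allclose(self.f_i.sum(axis=1), 1.0, atol=atol)
        assert np.allclose(self.f_ij.sum(axis=(2, 3)), 1.0, atol=atol)
        assert np.allclose(self.f_ij, np.transpose(self.f_ij, (1, 0, 3, 2)), atol=atol)
        # marginal consistency, off-diagonal pairs
        marg = self.f_ij.sum(axis=3)
        for i in range(L):
            for j in range(L):
                if i != j:
                    assert np.allclose(marg[i, j], self.f_i[i], atol=atol)


def sequence_weights(msa: AlignmentSet, w: float) -> tuple[np.ndarray, float]:
    """Identity-based weights and M_eff.

    ``omega_tau = 1 / |{sigma : identity(tau, sigma) > L (1 - w)}|`` with the
    self-match included; ``w = 0`` means no reweighting (all weights 1).
    """
    if not 0 <= w < 1:
        raise ValueError("identity cutoff w must lie in [0, 1)")
    M, L = msa.sequences.shape
    if w == 0:
        return np.ones(M), float(M)
    threshold = L * (1.0 - w)
    counts = np.zeros(M, dtype=np.int64)
    X = msa.sequences
    block = max(1, int(2e7 // (M * L)) or 1)
    for lo in range(0, M, block):
        hi = min(M, lo + block)
        ident = (X[lo:hi, None, :] == X[None, :, :]).sum(axis=2)
        counts[lo:hi] = (ident > threshold).sum(axis=1)
    weights = 1.0 / counts
    return weights, float(weights.sum())


def frequencies(
    msa: AlignmentSet,
    weights: Optional[np.ndarray] = None,
    pseudocount: float = 0.0,
    q: Optional[int] = None,
) -> FrequencyStats:
    """Weighted 1- and 2-point frequencies with optional uniform pseudocount.

    With pseudocount ``lam`` the mixture is ``(1-lam) f + lam / q`` per site
    and ``(1-lam) f + lam / q^2`` per pair, which keeps single- and two-point
    marginals exactly consistent.
    """
    X = msa.sequences
    M, L = X.shape
    q = q if q is not None else len(msa.alphabet)
    if weights is None:
        weights = np.ones(M)
    weights = np.asarray(weights, dtype=np.float64)
    if weights.shape != (M,):
        raise ValueError("weights length must equal M")
    M_eff = float(weights.sum())
    if M_eff <= 0:
        raise ValueError("effective number of sequences is zero")
    # one-hot encoding, (L, M, q)
    onehot = np.zeros((L, M, q))
    for i in range(L):
        onehot[i, np.arange(M), X[:, i]] = 1.0
    wnorm = weights / M_eff
    f_i = np.einsum("imq,m->iq", onehot, wnorm)
    f_ij = np.einsum("ima,m,jmb->ijab", onehot, wnorm, onehot)
    # diagonal blocks: joint of a site with itself is diag(f_i)
    for i in range(L):
        f_ij[i, i] = np.diag(f_i[i])
    lam = float(pseudocount)
    if not 0 <= lam <= 1:
        raise ValueError("pseudocount must lie in [0, 1]")
    if lam > 0:
        f_i = (1 - lam) * f_i + lam / q
        f_ij = (1 - lam) * f_ij + lam / q**2
        for i in range(L):
            f_ij[i, i] = np.diag(f_i[i])
    stats = FrequencyStats(
        f_i=f_i, f_ij=f_ij, M_eff=M_eff, q=q, pseudocount=lam, alphabet=msa.alphabet
    )
    return stats


def mutual_information_scores(stats: FrequencyStats) -> np.ndarray:
    """MI_ij = sum_ab f_ij log[f_ij / (f_i f_j)], zero-count terms contribute
    zero (limit convention).  Symmetric, non-negative, zero diagonal."""
    L, q = stats.f_i.shape
    mi = np.zeros((L, L))
    for i in range(L):
        for j in range(i + 1, L):
            fij = stats.f_ij[i, j]
            prod = np.outer(stats.f_i[i], stats.f_i[j])
            mask = fij > 0
            val = float(np.sum(fij[mask] * np.log(fij[mask] / prod[mask])))
            mi[i, j] = mi[j, i] = max(val, 0.0)
    return mi


def consensus_and_identity(msa: AlignmentSet) -> tuple[np.ndarray, float]:
    """Per-site modal sequence (ties broken by alphabet order) and the mean
    percent identity of alignment members to it."""
    if msa.M == 0:
        raise ValueError("empty MSA")
    q = len(msa.alphabet)
    X = msa.sequences
    consensus = np.empty(msa.L, dtype=np.int8)
    for i in range(msa.L):
        counts = np.bincount(X[:, i], minlength=q)
        consensus[i] = int(np.argmax(counts))  # argmax takes the first (lowest) index on ties
    identity = float((X == consensus).mean() * 100.0)
    return consensus, identity
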