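"""Metropolis Monte-Carlo sampling of lattice-protein sequence space.

Sequences are sampled for one native fold from the distribution
``P_nat(S_nat|A)^beta / Z``: a proposed single-site mutation is always
accepted when it raises the folding probability, and otherwise with
probability ``[P_nat(A')/P_nat(A)]^beta``.  ``beta`` acts as an inverse
algorithmic temperature setting the stringency of selection (default 1e3,
under which retained sequences fold with probability ~0.995 or higher).

An optional bias ``b`` adds ``-b * (number of sites matching a wild-type
sequence)`` to the effective Hamiltonian ``H = -log P_nat``, which
concentrates the sample around the wild type and mimics phylogenetic bias;
the Metropolis rule on ``beta * H_biased`` reduces to the plain rule at
``b = 0``.

One Monte-Carlo "step" is one proposed mutation, accepted or not; the chain
is thinned by emitting one sequence every ``interval`` steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from numba import njit

from .energetics import (
    ContactEnergyMatrix,
    EnergyEvaluator,
    SequenceLike,
    decode_sequence,
    encode_sequence,
)
from .lattice_conformations import StructureLibrary

__all__ = [
    "SamplerConfig",
    "AlignmentSet",
    "effective_hamiltonian",
    "metropolis_chain",
    "pnat_trace",
    "equilibration_diagnostic",
    "EquilibrationEstimate",
]


@dataclass(frozen=True)
class SamplerConfig:
    """Parameters of one sampling run.

    ``beta``: inverse algorithmic temperature (> 0, finite).
    ``bias``: per-site log-weight ``b`` toward ``wild_type`` (>= 0).
    ``n_samples``: number of emitted (thinned) sequences M.
    ``interval``: steps between emissions.
    ``pnat_threshold``: burn-in runs until P_nat reaches this value (and at
    least one interval has elapsed); set to 0 to disable the gate.
    """

    n_samples: int
    beta: float = 1e3
    bias: float = 0.0
    wild_type: Optional[str] = None
    interval: int = 1000
    pnat_threshold: float = 0.995
    max_burnin: int = 2_000_000
    seed: int = 0
    start_from_wild_type: bool = True

    def __post_init__(self):
        if not (self.beta > 0 and np.isfinite(self.beta)):
            raise ValueError("beta must be positive and finite (beta=inf is non-ergodic)")
        if self.bias < 0:
            raise ValueError("bias must be >= 0")
        if self.bias > 0 and self.wild_type is None:
            raise ValueError("bias > 0 requires a wild_type sequence")
        if self.interval < 1:
            raise ValueError("interval must be >= 1")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")

    def as_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "beta": self.beta,
            "bias": self.bias,
            "wild_type": self.wild_type,
            "interval": self.interval,
            "pnat_threshold": self.pnat_threshold,
            "seed": self.seed,
        }


@dataclass
class AlignmentSet:
    """A fixed-length sequence sample with optional reweighting metadata."""

    sequences: np.ndarray  # (M, L) int8 alphabet indices
    alphabet: str
    weights: Optional[np.ndarray] = None
    identity_cutoff: float = 0.0
    pnat: Optional[np.ndarray] = None  # per-sequence P_nat at emission
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.sequences = np.asarray(self.sequences, dtype=np.int8)
        if self.sequences.ndim != 2:
            raise ValueError("sequences must be (M, L)")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=np.float64)
            if self.weights.shape != (self.M,):
                raise ValueError("weights length must equal M")
            if np.any(self.weights <= 0) or np.any(self.weights > 1):
                raise ValueError("weights must lie in (0, 1]")

    @property
    def M(self) -> int:
        return self.sequences.shape[0]

    @property
    def L(self) -> int:
        return self.sequences.shape[1]

    @property
    def M_eff(self) -> float:
        return float(self.weights.sum()) if self.weights is not None else float(self.M)

    def to_strings(self) -> list[str]:
        return ["".join(self.alphabet[a] for a in row) for row in self.sequences]

    def write_fasta(self, path) -> None:
        """FASTA output; headers carry the sample index, chain id and P_nat."""
        from Bio.Seq import Seq
        from Bio.SeqIO import write as seqio_write
        from Bio.SeqRecord import SeqRecord

        chain = self.provenance.get("chain_id", 0)
        records = []
        for tau, s in enumerate(self.to_strings()):
            desc = f"chain={chain}"
            if self.pnat is not None:
                desc += f" pnat={self.pnat[tau]:.6f}"
            records.append(SeqRecord(Seq(s), id=f"tau{tau}", description=desc))
        with open(path, "w") as fh:
            seqio_write(records, fh, "fasta")

    @classmethod
    def read_fasta(cls, path, alphabet: str) -> "AlignmentSet":
        from Bio.SeqIO import parse as seqio_parse

        seqs, pnats = [], []
        lut = {c: i for i, c in enumerate(alphabet)}
        for rec in seqio_parse(str(path), "fasta"):
            seqs.append([lut[c] for c in str(rec.seq)])
            for tokenised in rec.description.split():
                if tokenised.startswith("pnat="):
                    pnats.append(float(tokenised[5:]))
        pnat = np.array(pnats) if len(pnats) == len(seqs) else None
        return cls(
            np.array(seqs, dtype=np.int8),
            alphabet,
            pnat=pnat,
            provenance={"kind": "file", "path": str(path)},
        )


# ---------------------------------------------------------------------------
# effective Hamiltonian


def effective_hamiltonian(
    seq: SequenceLike,
    native_index: int,
    lib: StructureLibrary,
    E: ContactEnergyMatrix,
    config: SamplerConfig,
) -> float:
    """``-log P_nat`` of the sequence, minus ``b x (matches to wild type)``
    when the bias is active."""
    from scipy.special import logsumexp

    a = encode_sequence(seq, E)
    e = EnergyEvaluator(lib, E).energies(a)
    h = float(e[native_index] + logsumexp(-e))
    if config.bias > 0:
        wt = encode_sequence(config.wild_type, E)
        h -= config.bias * float(np.sum(a == wt))
    return h


# ---------------------------------------------------------------------------
# Metropolis kernel


@njit(cache=True)
def _logz(e):
    m = -e[0]
    for k in range(e.shape[0]):
        if -e[k] > m:
            m = -e[k]
    s = 0.0
    for k in range(e.shape[0]):
        s += np.exp(-e[k] - m)
    return m + np.log(s)


@njit(cache=True)
def _chain_kernel(
    seq,
    energies,
    Emat,
    site_ptr,
    entry_struct,
    entry_partner,
    native,
    beta,
    bias,
    wt,
    n_samples,
    interval,
    threshold,
    max_burnin,
    seed,
    trace_every,
    n_trace,
):
    """Runs burn-in then emits ``n_samples`` thinned sequences in place.

    Returns (samples, sample_pnat, step_trace, burnin_steps, reached) where
    ``step_trace`` holds P_nat every ``trace_every`` steps from step 0
    (before burn-in gating) when ``n_trace > 0``.
    """
    np.random.seed(seed)
    L = seq.shape[0]
    q = Emat.shape[0]
    N = energies.shape[0]
    samples = np.empty((n_samples, L), dtype=np.int8)
    sample_pnat = np.empty(n_samples)
    step_trace = np.empty(n_trace)
    logz = _logz(energies)
    h_nat = energies[native] + logz  # -log pnat
    match = 0
    if bias > 0.0:
        for i in range(L):
            if seq[i] == wt[i]:
                match += 1
    enew = np.empty(N)
    emitted = 0
    burnin_steps = -1
    reached = threshold <= np.exp(-h_nat)
    step = 0
    traced = 0
    since_emit = 0
    total_cap = max_burnin + n_samples * interval + interval
    while emitted < n_samples and step < total_cap:
        if n_trace > 0 and traced < n_trace and step % trace_every == 0:
            step_trace[traced] = np.exp(-h_nat)
            traced += 1
        # propose
        site = np.random.randint(0, L)
        old = seq[site]
        new = np.random.randint(0, q - 1)
        if new >= old:
            new += 1
        for k in range(N):
            enew[k] = energies[k]
        lo = site_ptr[site]
        hi = site_ptr[site + 1]
        for idx in range(lo, hi):
            p = seq[entry_partner[idx]]
            enew[entry_struct[idx]] += Emat[new, p] - Emat[old, p]
        logz_new = _logz(enew)
        h_new = enew[native] + logz_new
        dh = h_new - h_nat
        if bias > 0.0:
            dmatch = 0
            if new == wt[site]:
                dmatch += 1
            if old == wt[site]:
                dmatch -= 1
            dh -= bias * dmatch
        else:
            dmatch = 0
        if dh <= 0.0 or np.random.random() < np.exp(-beta * dh):
            seq[site] = new
            for k in range(N):
                energies[k] = enew[k]
            h_nat = h_new
            match += dmatch
        step += 1
        since_emit += 1
        if burnin_steps < 0:
            # burn-in gate: pnat above threshold and at least one interval
            if not reached and np.exp(-(energies[native] + _logz(energies))) >= threshold:
                reached = True
            if reached and step >= interval:
                burnin_steps = step
                since_emit = 0
            elif step >= max_burnin:
                break
        elif since_emit >= interval:
            samples[emitted] = seq
            sample_pnat[emitted] = np.exp(-(energies[native] + _logz(energies)))
            emitted += 1
            since_emit = 0
    return samples[:emitted], sample_pnat[:emitted], step_trace[:traced], burnin_steps, reached


def _initial_sequence(config, E, lib, rng) -> np.ndarray:
    if config.bias > 0 and config.start_from_wild_type and config.wild_type is not None:
        return encode_sequence(config.wild_type, E)
    return rng.integers(0, E.q, size=lib.L).astype(np.int8)


def metropolis_chain(
    native_index: int,
    lib: StructureLibrary,
    E: ContactEnergyMatrix,
    config: SamplerConfig,
    initial_sequence: SequenceLike | None = None,
    evaluator: EnergyEvaluator | None = None,
) -> AlignmentSet:
    """Sample an alignment for the native fold; reproducible given the seed.

    The initial sequence is drawn uniformly (or taken from the wild type for
    biased runs) and burned in until P_nat exceeds ``config.pnat_threshold``.
    Raises ``RuntimeError`` if the threshold is not reached within
    ``config.max_burnin`` steps.
    """
    if not 0 <= native_index < lib.N:
        raise IndexError("native_index outside library")
    ev = evaluator if evaluator is not None else EnergyEvaluator(lib, E)
    rng = np.random.default_rng(config.seed)
    if initial_sequence is not None:
        seq = encode_sequence(initial_sequence, E).copy()
    else:
        seq = _initial_sequence(config, E, lib, rng).copy()
    energies = ev.energies(seq).astype(np.float64)
    wt = (
        encode_sequence(config.wild_type, E)
        if config.wild_type is not None
        else np.zeros(lib.L, dtype=np.int8)
    )
    kernel_seed = int(rng.integers(0, 2**31 - 1))
    samples, sample_pnat, _, burnin_steps, reached = _chain_kernel(
        seq,
        energies,
        E.matrix,
        ev.site_ptr,
        ev.entry_struct,
        ev.entry_partner,
        int(native_index),
        float(config.beta),
        float(config.bias),
        wt,
        int(config.n_samples),
        int(config.interval),
        float(config.pnat_threshold),
        int(config.max_burnin),
        kernel_seed,
        1,
        0,
    )
    if not reached or samples.shape[0] < config.n_samples:
        raise RuntimeError(
            f"burn-in failed to reach pnat >= {config.pnat_threshold} within "
            f"{config.max_burnin} steps (got {samples.shape[0]} samples); "
            "lower the threshold or raise max_burnin"
        )
    return AlignmentSet(
        samples,
        E.alphabet,
        pnat=sample_pnat,
        provenance={
            "kind": "metropolis_chain",
            "native_index": int(native_index),
            "burnin_steps": int(burnin_steps),
            "library": lib.manifest_hash(),
            **config.as_dict(),
        },
    )


def pnat_trace(
    native_index: int,
    lib: StructureLibrary,
    E: ContactEnergyMatrix,
    config: SamplerConfig,
    n_steps: int,
    trace_every: int = 1,
    initial_sequence: SequenceLike | None = None,
) -> np.ndarray:
    """Raw per-step P_nat trace of a chain (no burn-in gate, no thinning);
    the input for ``equilibration_diagnostic``."""
    ev = EnergyEvaluator(lib, E)
    rng = np.random.default_rng(config.seed)
    if initial_sequence is not None:
        seq = encode_sequence(initial_sequence, E).copy()
    else:
        seq = _initial_sequence(config, E, lib, rng).copy()
    energies = ev.energies(seq).astype(np.float64)
    wt = (
        encode_sequence(config.wild_type, E)
        if config.wild_type is not None
        else np.zeros(lib.L, dtype=np.int8)
    )
    kernel_seed = int(rng.integers(0, 2**31 - 1))
    cfg = replace(config, pnat_threshold=0.0, n_samples=1, interval=max(1, n_steps))
    n_trace = n_steps // trace_every
    _, _, trace, _, _ = _chain_kernel(
        seq,
        energies,
        E.matrix,
        ev.site_ptr,
        ev.entry_struct,
        ev.entry_partner,
        int(native_index),
        float(cfg.beta),
        float(cfg.bias),
        wt,
        1,
        n_steps,
        0.0,
        0,
        kernel_seed,
        int(trace_every),
        int(n_trace),
    )
    return trace


@dataclass(frozen=True)
class EquilibrationEstimate:
    steps: Optional[int]  # first step at which all chains agree, in MC steps
    tolerance: float
    converged: bool


def equilibration_diagnostic(
    traces: Sequence[np.ndarray], tolerance: float = 0.02, trace_every: int = 1
) -> EquilibrationEstimate:
    """Conservative steps-to-equilibrium estimate from >= 2 P_nat traces of
    chains started at distinct sequences: the first step from which all
    chains stay within ``tolerance`` of each other.  Flags non-convergence
    (e.g. a frozen chain) when no such step exists."""
    traces = [np.asarray(t, dtype=np.float64) for t in traces]
    if len(traces) < 2:
        raise ValueError("need >= 2 chains to assess initialisation independence")
    n = min(len(t) for t in traces)
    stacked = np.stack([t[:n] for t in traces])
    spread = stacked.max(axis=0) - stacked.min(axis=0)
    within = spread <= tolerance
    # last index of disagreement + 1
    bad = np.nonzero(~within)[0]
    if bad.size == 0:
        return EquilibrationEstimate(0, tolerance, True)
    first = int(bad[-1]) + 1
    if first >= n:
        return EquilibrationEstimate(None, tolerance, False)
    return EquilibrationEstimate(first * trace_every, tolerance, True)
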