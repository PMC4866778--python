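"""Contact energetics, folding probability and competitor-fold statistics.

The energy of a sequence ``A`` folded into structure ``S`` is the sum of
pairwise contact energies over the contacts of ``S`` (Miyazawa-Jernigan
20 x 20 table by default, unit temperature).  The probability that ``A``
folds into ``S`` is the Boltzmann weight of ``S`` against every fold in the
structure library,

    P_nat(S|A) = exp(-E(A|S)) / sum_S' exp(-E(A|S')).

Competition between folds is summarised by the gap of each competitor,
``exp(-Delta(S|S_nat)) = < exp(-[E(A|S) - E(A|S_nat)]) >_MSA``, the aggregate
``N_S exp(-Delta)`` over all competitors, and their gap-weighted average
contact map ``cbar`` -- the quantities that drive negative design.

All Boltzmann sums run in log space (log-sum-exp).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence, Union

import numpy as np
from scipy.special import logsumexp

from .lattice_conformations import ContactMap, StructureLibrary, forbidden_pairs

__all__ = [
    "ContactEnergyMatrix",
    "CompetitorProfile",
    "EnergyEvaluator",
    "load_mj_matrix",
    "encode_sequence",
    "decode_sequence",
    "fold_energy",
    "all_fold_energies",
    "pnat",
    "competitor_profile",
]

SequenceLike = Union[str, Sequence[int], np.ndarray]


@dataclass(frozen=True)
class ContactEnergyMatrix:
    """Symmetric q x q pair-energy table over an ordered alphabet."""

    alphabet: str
    matrix: np.ndarray  # (q, q) float

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=np.float64)
        object.__setattr__(self, "matrix", m)
        q = len(self.alphabet)
        if m.shape != (q, q):
            raise ValueError(f"matrix shape {m.shape} does not match alphabet size {q}")
        if not np.all(np.isfinite(m)):
            raise ValueError("energy matrix must be finite")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("energy matrix must be symmetric")
        if len(set(self.alphabet)) != q:
            raise ValueError("alphabet letters must be unique")

    @property
    def q(self) -> int:
        return len(self.alphabet)

    def index(self, letter: str) -> int:
        pos = self.alphabet.find(letter)
        if pos < 0:
            raise KeyError(f"letter {letter!r} not in alphabet {self.alphabet!r}")
        return pos

    def checksum(self) -> str:
        h = hashlib.sha256()
        h.update(self.alphabet.encode())
        h.update(np.ascontiguousarray(self.matrix).tobytes())
        return h.hexdigest()[:16]

    @classmethod
    def from_file(cls, path) -> "ContactEnergyMatrix":
        """Whitespace-delimited table with a header row of one-letter codes;
        data rows may carry a leading row label."""
        letters = None
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if letters is None:
                    letters = parts
                    continue
                vals = parts[1:] if parts[0] == letters[len(rows)] else parts
                rows.append([float(v) for v in vals])
        if letters is None:
            raise ValueError(f"no header row found in {path}")
        return cls("".join(letters), np.array(rows))

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("  " + "  ".join(self.alphabet) + "\n")
            for a, row in zip(self.alphabet, self.matrix):
                fh.write(a + " " + " ".join(f"{v:.4f}" for v in row) + "\n")


def load_mj_matrix() -> ContactEnergyMatrix:
    """The packaged Miyazawa-Jernigan (1996, Table 5) contact-energy table."""
    ref = resources.files("lpbench.data").joinpath("mj1996_table5.txt")
    with resources.as_file(ref) as path:
        return ContactEnergyMatrix.from_file(path)


def encode_sequence(seq: SequenceLike, E: ContactEnergyMatrix) -> np.ndarray:
    """Letters -> alphabet indices (int8); integer input is validated."""
    if isinstance(seq, str):
        return np.array([E.index(c) for c in seq], dtype=np.int8)
    arr = np.asarray(seq, dtype=np.int64)
    if arr.ndim != 1:
        raise ValueError("sequence must be one-dimensional")
    if np.any(arr < 0) or np.any(arr >= E.q):
        raise ValueError("sequence index outside alphabet")
    return arr.astype(np.int8)


def decode_sequence(seq: np.ndarray, E: ContactEnergyMatrix) -> str:
    return "".join(E.alphabet[int(a)] for a in seq)


# ---------------------------------------------------------------------------
# energies


def fold_energy(seq: SequenceLike, cmap: ContactMap, E: ContactEnergyMatrix) -> float:
    """E(A|S) = sum over contacts (i, j) of E(a_i, a_j)."""
    a = encode_sequence(seq, E)
    if len(a) != cmap.L:
        raise ValueError(f"sequence length {len(a)} != contact map length {cmap.L}")
    total = 0.0
    for i, j in cmap.pairs:
        total += E.matrix[a[i], a[j]]
    return float(total)


class EnergyEvaluator:
    """Vectorized fold energies over a whole library, with O(contacts-of-site)
    incremental updates after a single-site mutation.

    Precomputes per-structure contact pairs and a site-indexed CSR layout
    (site -> list of (structure, partner-site)) shared with the Monte-Carlo
    sampler kernels.
    """

    def __init__(self, lib: StructureLibrary, E: ContactEnergyMatrix):
        self.lib = lib
        self.E = E
        pairs = lib.contact_pairs_array()  # (N, P, 2)
        self.pairs = pairs
        N, P, _ = pairs.shape
        L = lib.L
        # CSR over sites: entries (structure, partner) for each occurrence of a site
        occur: list[list[tuple[int, int]]] = [[] for _ in range(L)]
        for s in range(N):
            for i, j in pairs[s]:
                occur[int(i)].append((s, int(j)))
                occur[int(j)].append((s, int(i)))
        counts = [len(o) for o in occur]
        self.site_ptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
        self.entry_struct = np.empty(self.site_ptr[-1], dtype=np.int32)
        self.entry_partner = np.empty(self.site_ptr[-1], dtype=np.int8)
        pos = 0
        for i in range(L):
            for s, j in occur[i]:
                self.entry_struct[pos] = s
                self.entry_partner[pos] = j
                pos += 1

    def energies(self, seq: SequenceLike) -> np.ndarray:
        """E(A|S) for every structure S, as an N-vector."""
        a = encode_sequence(seq, self.E)
        if len(a) != self.lib.L:
            raise ValueError("sequence length does not match library")
        i = self.pairs[:, :, 0].astype(np.int64)
        j = self.pairs[:, :, 1].astype(np.int64)
        return self.E.matrix[a[i], a[j]].sum(axis=1)

    def delta_energies(self, seq: SequenceLike, site: int, new_letter: int) -> np.ndarray:
        """Energy change per structure when ``site`` mutates to ``new_letter``;
        agrees with full recomputation to round-off."""
        a = encode_sequence(seq, self.E)
        lo, hi = self.site_ptr[site], self.site_ptr[site + 1]
        delta = np.zeros(self.lib.N)
        structs = self.entry_struct[lo:hi]
        partners = a[self.entry_partner[lo:hi].astype(np.int64)]
        np.add.at(
            delta,
            structs,
            self.E.matrix[int(new_letter), partners] - self.E.matrix[int(a[site]), partners],
        )
        return delta


def all_fold_energies(
    seq: SequenceLike, lib: StructureLibrary, E: ContactEnergyMatrix
) -> np.ndarray:
    """N-vector of fold energies; see ``EnergyEvaluator`` for repeated use."""
    if lib.N < 1:
        raise ValueError("empty structure library")
    return EnergyEvaluator(lib, E).energies(seq)


def pnat(
    seq: SequenceLike,
    native_index: int,
    lib: StructureLibrary,
    E: ContactEnergyMatrix,
    energies: np.ndarray | None = None,
) -> float:
    """Boltzmann probability that ``seq`` folds into the native structure,
    computed with log-sum-exp stabilisation."""
    if not 0 <= native_index < lib.N:
        raise IndexError(f"native_index {native_index} outside library of {lib.N}")
    e = all_fold_energies(seq, lib, E) if energies is None else np.asarray(energies)
    return float(np.exp(-e[native_index] - logsumexp(-e)))


# ---------------------------------------------------------------------------
# competitors


@dataclass
class CompetitorProfile:
    """Per-fold gaps to the native structure and their aggregates."""

    native_index: int
    gaps: np.ndarray  # Delta(S|S_nat) per structure; 0 at the native slot
    aggregate: float  # N_S exp(-Delta) = sum over competitors of exp(-gap)
    cbar: np.ndarray  # gap-weighted average competitor contact map, (L, L)
    closest_competitor: int  # argmin over S != native of Delta(S|S_nat)
    effective_n_competitors: float = field(default=np.nan)
    effective_gap: float = field(default=np.nan)

    @property
    def weights(self) -> np.ndarray:
        """exp(-Delta(S|S_nat)); the native slot is zeroed."""
        w = np.exp(-self.gaps)
        w[self.native_index] = 0.0
        return w

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "structure": np.arange(len(self.gaps)),
                "gap": self.gaps,
                "weight": self.weights,
            }
        )

    def save_tsv(self, path) -> None:
        """Per-structure gaps followed by the dense average contact map."""
        with open(path, "w") as fh:
            fh.write(f"# native {self.native_index} closest {self.closest_competitor} "
                     f"aggregate {self.aggregate!r}\n")
            fh.write("structure\tgap\tweight\n")
            w = self.weights
            for s, (g, ws) in enumerate(zip(self.gaps, w)):
                fh.write(f"{s}\t{g!r}\t{ws!r}\n")
            fh.write("# cbar\n")
            for row in self.cbar:
                fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def competitor_profile(
    native_index: int,
    lib: StructureLibrary,
    msa_sequences: np.ndarray,
    E: ContactEnergyMatrix,
) -> CompetitorProfile:
    """Gap spectrum of every fold against the native one, averaged over an MSA.

    ``exp(-Delta(S|S_nat))`` is the MSA average of ``exp(-[E(A|S) -
    E(A|S_nat)])``; the aggregate ``N_S exp(-Delta)`` sums it over
    competitors, and ``cbar`` weighs each competitor's contact map by its
    relative Boltzmann weight.  The closest competitor ``S_F`` minimises the
    gap.  The effective competitor number reported alongside is the
    participation ratio of the weights, with the effective gap defined so the
    pair reproduces the aggregate exactly.
    """
    msa_sequences = np.atleast_2d(np.asarray(msa_sequences))
    if msa_sequences.shape[0] == 0:
        raise ValueError("empty MSA")
    ev = EnergyEvaluator(lib, E)
    M = msa_sequences.shape[0]
    # log mean_tau exp(-(E(A|S) - E(A|S_nat))) per structure, streamed over tau
    log_terms = np.empty((M, lib.N))
    for t in range(M):
        e = ev.energies(msa_sequences[t])
        log_terms[t] = -(e - e[native_index])
    log_w = logsumexp(log_terms, axis=0) - np.log(M)
    gaps = -log_w
    w = np.exp(log_w)
    w[native_index] = 0.0
    aggregate = float(w.sum())
    cbar = np.zeros((lib.L, lib.L))
    for s in range(lib.N):
        if s == native_index or w[s] == 0.0:
            continue
        cbar += w[s] * lib.contact_map(s).dense
    cbar /= aggregate
    comp_gaps = np.where(np.arange(lib.N) == native_index, np.inf, gaps)
    closest = int(np.argmin(comp_gaps))
    pr = float(w.sum() ** 2 / np.sum(w**2))  # participation ratio
    eff_gap = float(-np.log(aggregate / pr))
    for i, j in forbidden_pairs(lib.L):
        assert cbar[i, j] == 0.0, "average contact map touches a forbidden pair"
    return CompetitorProfile(
        native_index=native_index,
        gaps=gaps,
        aggregate=aggregate,
        cbar=cbar,
        closest_competitor=closest,
        effective_n_competitors=pr,
        effective_gap=eff_gap,
    )
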