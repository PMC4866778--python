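"""Maximum-entropy (Potts) models fit to alignment statistics.

The Potts energy of a sequence is

    H(A) = - sum_i h_i(a_i) - sum_{i<j} J_ij(a_i, a_j),

with fields ``h`` and pairwise couplings ``J`` chosen so the model's one- and
two-point marginals reproduce those of the alignment.  Because only energy
differences matter, ``(h, J)`` are defined up to a gauge; the conventions
used here are zero-sum (every row/column of each coupling block sums to
zero), consensus (entries of the most probable letter per site vanish) and
least-probable (entries of the rarest letter vanish).

Four inference routes are provided, in increasing order of fidelity:

* independent-site model (IM): fields only, ``h_i = log f_i``;
* mean-field DCA: couplings from minus the inverse of the pseudocount-
  regularised connected-correlation matrix;
* pseudo-likelihood maximisation (PLM): site-wise L2-regularised logistic
  regressions, symmetrised by averaging;
* adaptive cluster expansion (ACE): a cluster expansion of the cross-entropy
  that recursively adds clusters of strongly coupled sites while their
  entropy contribution exceeds a threshold, lowered until the model
  reproduces the data statistics; followed by Boltzmann-machine refinement.
  ACE also returns the model entropy, the package's designability estimate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .msa_statistics import FrequencyStats, frequencies
from .sequence_sampler import AlignmentSet

__all__ = [
    "PottsModel",
    "EntropyEstimate",
    "potts_energy",
    "infer_im",
    "infer_dca_meanfield",
    "infer_plm",
    "infer_ace",
    "gauge_transform",
    "enumerate_states",
    "exact_log_probabilities",
    "exact_entropy",
    "exact_marginals",
]

GAUGES = ("zero-sum", "consensus", "least-probable", "unspecified")


@dataclass
class PottsModel:
    """Fields and couplings of a Potts model, with provenance metadata."""

    h: np.ndarray  # (L, q)
    J: np.ndarray  # (L, L, q, q); J[i, j, a, b] == J[j, i, b, a]; zero diagonal
    gauge: str = "unspecified"
    method: str = "unspecified"
    gamma: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.h = np.asarray(self.h, dtype=np.float64)
        self.J = np.asarray(self.J, dtype=np.float64)
        L, q = self.h.shape
        if self.J.shape != (L, L, q, q):
            raise ValueError("J must be (L, L, q, q)")
        if self.gauge not in GAUGES:
            raise ValueError(f"unknown gauge {self.gauge!r}")
        if not np.allclose(self.J, np.transpose(self.J, (1, 0, 3, 2)), atol=1e-9):
            raise ValueError("J must satisfy J[i,j,a,b] == J[j,i,b,a]")
        for i in range(L):
            if not np.allclose(self.J[i, i], 0.0, atol=1e-12):
                raise ValueError("diagonal coupling blocks must vanish")

    @property
    def L(self) -> int:
        return self.h.shape[0]

    @property
    def q(self) -> int:
        return self.h.shape[1]

    def copy(self) -> "PottsModel":
        return PottsModel(
            self.h.copy(), self.J.copy(), self.gauge, self.method, self.gamma, dict(self.meta)
        )

    # -- text serialization (lossless round trip) ---------------------------

    def save(self, path, alphabet: Optional[str] = None) -> None:
        """Documented text format: header, then ``h i a value`` and
        ``J i j a b value`` records.  Site indices are 1-based on disk."""
        alphabet = alphabet or self.meta.get("alphabet") or "".join(
            chr(ord("A") + k) for k in range(self.q)
        )
        with open(path, "w") as fh:
            fh.write(f"# L {self.L} q {self.q} gauge {self.gauge} "
                     f"method {self.method} gamma {self.gamma!r}\n")
            fh.write(f"# alphabet {alphabet}\n")
            for i in range(self.L):
                for a in range(self.q):
                    fh.write(f"h {i + 1} {alphabet[a]} {float(self.h[i, a])!r}\n")
            for i in range(self.L):
                for j in range(i + 1, self.L):
                    for a in range(self.q):
                        for b in range(self.q):
                            v = self.J[i, j, a, b]
                            if v != 0.0:
                                fh.write(
                                    f"J {i + 1} {j + 1} {alphabet[a]} {alphabet[b]} {float(v)!r}\n"
                                )

    @classmethod
    def load(cls, path) -> "PottsModel":
        header: dict = {}
        alphabet = None
        records = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    parts = line[1:].split()
                    if parts[:1] == ["alphabet"]:
                        alphabet = parts[1]
                    else:
                        header.update(zip(parts[::2], parts[1::2]))
                    continue
                records.append(line.split())
        L, q = int(header["L"]), int(header["q"])
        if alphabet is None:
            alphabet = "".join(chr(ord("A") + k) for k in range(q))
        lut = {c: k for k, c in enumerate(alphabet)}
        h = np.zeros((L, q))
        J = np.zeros((L, L, q, q))
        for rec in records:
            if rec[0] == "h":
                h[int(rec[1]) - 1, lut[rec[2]]] = float(rec[3])
            elif rec[0] == "J":
                i, j = int(rec[1]) - 1, int(rec[2]) - 1
                a, b = lut[rec[3]], lut[rec[4]]
                J[i, j, a, b] = float(rec[5])
                J[j, i, b, a] = float(rec[5])
        return cls(
            h,
            J,
            gauge=header.get("gauge", "unspecified"),
            method=header.get("method", "unspecified"),
            gamma=float(header.get("gamma", 0.0)),
            meta={"alphabet": alphabet},
        )


@dataclass(frozen=True)
class EntropyEstimate:
    """Entropy (nats) from the cluster expansion, with provenance."""

    entropy: float
    method: str
    threshold: float
    converged: bool
    note: str = ""


def potts_energy(seq: Sequence[int], model: PottsModel) -> float:
    """H(A) = -sum h - sum_{i<j} J, literal evaluation."""
    a = np.asarray(seq, dtype=np.int64)
    if a.shape != (model.L,):
        raise ValueError("sequence length does not match model")
    e = -float(model.h[np.arange(model.L), a].sum())
    for i in range(model.L):
        for j in range(i + 1, model.L):
            e -= model.J[i, j, a[i], a[j]]
    return e


def potts_energies(seqs: np.ndarray, model: PottsModel) -> np.ndarray:
    """Vectorised ``potts_energy`` over the rows of ``seqs``."""
    X = np.asarray(seqs, dtype=np.int64)
    M, L = X.shape
    e = -model.h[np.arange(L), X].sum(axis=1)
    for i in range(L):
        for j in range(i + 1, L):
            e -= model.J[i, j, X[:, i], X[:, j]]
    return e


# ---------------------------------------------------------------------------
# gauges


def _reference_letters(reference, L: int, mode: str) -> np.ndarray:
    if reference is None:
        raise ValueError(f"{mode} gauge requires per-site frequencies or letters")
    if isinstance(reference, FrequencyStats):
        f = reference.f_i
    else:
        reference = np.asarray(reference)
        if reference.ndim == 1:  # explicit reference sequence
            return reference.astype(np.int64)
        f = reference
    if f.shape[0] != L:
        raise ValueError("reference length does not match model")
    return np.argmax(f, axis=1) if mode == "consensus" else np.argmin(f, axis=1)


def gauge_transform(
    model: PottsModel, target: str, reference=None
) -> PottsModel:
    """Re-express the model in ``target`` gauge; physically equivalent
    (energy differences preserved) and invertible."""
    if target not in ("zero-sum", "consensus", "least-probable"):
        raise ValueError(f"unsupported target gauge {target!r}")
    L, q = model.L, model.q
    h = model.h.copy()
    J = model.J.copy()
    if target == "zero-sum":
        for i in range(L):
            for j in range(i + 1, L):
                K = J[i, j].copy()
                row = K.mean(axis=1)
                col = K.mean(axis=0)
                blk = K.mean()
                J[i, j] = K - row[:, None] - col[None, :] + blk
                J[j, i] = J[i, j].T
                h[i] += row - blk
                h[j] += col - blk
        for i in range(L):
            h[i] -= h[i].mean()
    else:
        r = _reference_letters(reference, L, target)
        for i in range(L):
            for j in range(i + 1, L):
                K = J[i, j]
                newK = K - K[r[i], :][None, :] - K[:, r[j]][:, None] + K[r[i], r[j]]
                h[i] += K[:, r[j]] - K[r[i], r[j]]
                h[j] += K[r[i], :] - K[r[i], r[j]]
                J[i, j] = newK
                J[j, i] = newK.T
        for i in range(L):
            h[i] -= h[i][r[i]]
    out = model.copy()
    out.h, out.J, out.gauge = h, J, target
    return out


# ---------------------------------------------------------------------------
# exact small-system utilities (oracles and ACE refinement backend)

#: exact enumeration guard: q**L must not exceed this
MAX_EXACT_STATES = 400_000


def enumerate_states(L: int, q: int) -> np.ndarray:
    """(q**L, L) array of all sequences; guarded against blow-up."""
    if q**L > MAX_EXACT_STATES:
        raise ValueError(f"q**L = {q**L} exceeds exact-enumeration guard")
    grids = np.meshgrid(*[np.arange(q)] * L, indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=1).astype(np.int8)


def exact_log_probabilities(model: PottsModel) -> tuple[np.ndarray, np.ndarray]:
    """(states, log p) of the Gibbs distribution, by full enumeration."""
    states = enumerate_states(model.L, model.q)
    loge = -potts_energies(states, model)
    return states, loge - logsumexp(loge)


def exact_entropy(model: PottsModel) -> float:
    _, logp = exact_log_probabilities(model)
    p = np.exp(logp)
    return float(-np.sum(p * logp))


def exact_marginals(model: PottsModel) -> tuple[np.ndarray, np.ndarray]:
    """Exact (f_i, f_ij) of the model distribution, by enumeration."""
    states, logp = exact_log_probabilities(model)
    p = np.exp(logp)
    L, q = model.L, model.q
    f_i = np.zeros((L, q))
    f_ij = np.zeros((L, L, q, q))
    for i in range(L):
        for a in range(q):
            f_i[i, a] = p[states[:, i] == a].sum()
    for i in range(L):
        for j in range(L):
            if i == j:
                f_ij[i, i] = np.diag(f_i[i])
                continue
            idx = states[:, i].astype(np.int64) * q + states[:, j]
            f_ij[i, j] = np.bincount(idx, weights=p, minlength=q * q).reshape(q, q)
    return f_i, f_ij


# ---------------------------------------------------------------------------
# independent-site model


def infer_im(stats: FrequencyStats, pseudocount: float = 0.0) -> PottsModel:
    """Fields-only model, ``h_i(a) = log f_i(a)``, reported in zero-sum gauge."""
    f = stats.f_i
    if pseudocount > 0:
        f = (1 - pseudocount) * f + pseudocount / stats.q
    if np.any(f <= 0):
        raise ValueError("zero frequencies; rebuild stats (or call) with a pseudocount")
    h = np.log(f)
    h -= h.mean(axis=1, keepdims=True)
    L, q = f.shape
    return PottsModel(
        h,
        np.zeros((L, L, q, q)),
        gauge="zero-sum",
        method="IM",
        meta={"pseudocount": pseudocount, "alphabet": stats.alphabet},
    )


# ---------------------------------------------------------------------------
# mean-field DCA


def infer_dca_meanfield(stats: FrequencyStats) -> PottsModel:
    """Couplings = minus the inverse of the connected-correlation matrix
    restricted to q-1 states per site; fields from the mean-field closure.

    The statistics must carry a pseudocount (the mean-field inversion is
    singular on raw counts); build them with ``frequencies(...,
    pseudocount=0.5)`` for the standard large regularisation.
    """
    L, q = stats.f_i.shape
    C = stats.connected_correlations()
    n = L * (q - 1)
    Cmat = np.empty((n, n))
    for i in range(L):
        for j in range(L):
            Cmat[i * (q - 1) : (i + 1) * (q - 1), j * (q - 1) : (j + 1) * (q - 1)] = C[
                i, j, : q - 1, : q - 1
            ]
    try:
        cond = np.linalg.cond(Cmat)
        if cond > 1e12:
            raise np.linalg.LinAlgError(f"condition number {cond:.2e}")
        Jr = -np.linalg.inv(Cmat)
    except np.linalg.LinAlgError as err:
        raise ValueError(
            "connected-correlation matrix is singular; rebuild the statistics "
            "with a pseudocount (e.g. frequencies(msa, pseudocount=0.5))"
        ) from err
    J = np.zeros((L, L, q, q))
    for i in range(L):
        for j in range(L):
            if i != j:
                J[i, j, : q - 1, : q - 1] = Jr[
                    i * (q - 1) : (i + 1) * (q - 1), j * (q - 1) : (j + 1) * (q - 1)
                ]
    # symmetrise away round-off
    J = 0.5 * (J + np.transpose(J, (1, 0, 3, 2)))
    # mean-field closure for the fields, in the lattice-gas gauge (state q-1)
    f = stats.f_i
    h = np.log(f / f[:, -1:])
    for i in range(L):
        coupling_term = np.zeros(q)
        for j in range(L):
            if j != i:
                coupling_term += J[i, j] @ f[j]
        h[i] -= coupling_term
    model = PottsModel(
        h, J, gauge="unspecified", method="DCA",
        meta={"pseudocount": stats.pseudocount, "alphabet": stats.alphabet},
    )
    return gauge_transform(model, "zero-sum")


# ---------------------------------------------------------------------------
# pseudo-likelihood maximisation


def _plm_site(X, onehot, wnorm, r, q, gamma, tol, max_iter):
    """L2-regularised multinomial regression of column r on all others."""
    M, L = X.shape
    others = [j for j in range(L) if j != r]
    n_par = q + len(others) * q * q
    Y = onehot[r]  # (M, q)
    cols = [X[:, j] for j in others]
    trace: list[float] = []

    def objective(x):
        hloc = x[:q]
        Jloc = x[q:].reshape(len(others), q, q)
        e = np.tile(hloc, (M, 1))
        for k, j in enumerate(others):
            e += Jloc[k][:, cols[k]].T
        lz = logsumexp(e, axis=1)
        ll = np.sum(wnorm * (lz - e[np.arange(M), X[:, r]]))
        reg = gamma * (np.sum(hloc**2) + np.sum(Jloc**2))
        P = np.exp(e - lz[:, None])
        D = (P - Y) * wnorm[:, None]
        gh = D.sum(axis=0) + 2 * gamma * hloc
        gJ = np.empty_like(Jloc)
        for k in range(len(others)):
            gJ[k] = D.T @ onehot[others[k]]
        gJ += 2 * gamma * Jloc
        trace.append(ll + reg)
        return ll + reg, np.concatenate([gh, gJ.ravel()])

    res = minimize(
        objective,
        np.zeros(n_par),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": tol, "ftol": 1e-14},
    )
    gnorm = float(np.max(np.abs(res.jac)))
    if not res.success and gnorm > 10 * tol:
        raise RuntimeError(
            f"PLM failed to converge at site {r}: {res.message} (|grad|={gnorm:.2e})"
        )
    hloc = res.x[:q]
    Jloc = res.x[q:].reshape(len(others), q, q)
    return hloc, dict(zip(others, Jloc)), trace


def infer_plm(
    msa: AlignmentSet,
    weights: Optional[np.ndarray] = None,
    gamma: float = 0.01,
    tol: float = 1e-5,
    max_iter: int = 500,
) -> PottsModel:
    """Pseudo-likelihood inference (convex, deterministic given the data).

    Each site's conditional likelihood is maximised with an L2 penalty
    ``gamma`` on all parameters (default 0.01, a deliberately strong
    regularisation); the two asymmetric estimates of each coupling block are
    symmetrised by averaging and the result is reported in zero-sum gauge.
    """
    if msa.M == 0:
        raise ValueError("empty MSA")
    X = msa.sequences.astype(np.int64)
    M, L = X.shape
    q = len(msa.alphabet)
    if weights is None:
        weights = np.ones(M)
    wnorm = np.asarray(weights, dtype=np.float64)
    wnorm = wnorm / wnorm.sum()
    onehot = np.zeros((L, M, q))
    for i in range(L):
        onehot[i, np.arange(M), X[:, i]] = 1.0
    h = np.zeros((L, q))
    J = np.zeros((L, L, q, q))
    traces = []
    for r in range(L):
        hloc, Jmap, trace = _plm_site(X, onehot, wnorm, r, q, gamma, tol, max_iter)
        h[r] = hloc
        for j, block in Jmap.items():
            J[r, j] += 0.5 * block
            J[j, r] += 0.5 * block.T
        traces.append(trace)
    model = PottsModel(
        h, J, gauge="unspecified", method="PLM", gamma=gamma,
        meta={"alphabet": msa.alphabet, "objective_traces": traces},
    )
    return gauge_transform(model, "zero-sum")


# ---------------------------------------------------------------------------
# adaptive cluster expansion


def _cluster_fit(sites, f_i, f_ij, q, gamma):
    """Regularised max-ent fit of a pairwise Potts model on one cluster,
    matching the cluster's 1- and 2-point marginals.

    Returns (cross_entropy, h_parts, J_parts) with parameters in a fixed
    (log-frequency) gauge.  Sizes 1 and 2 have closed forms; larger clusters
    are fit by convex minimisation over the cluster's q**k states.
    """
    k = len(sites)
    if k == 1:
        (i,) = sites
        f = f_i[i]
        s = float(-np.sum(f * np.log(f)))
        return s, {i: np.log(f)}, {}
    if k == 2 and gamma == 0.0:
        i, j = sites
        fij = f_ij[i, j]
        s = float(-np.sum(fij * np.log(fij)))
        Jblock = np.log(fij) - np.log(f_i[i])[:, None] - np.log(f_i[j])[None, :]
        return s, {i: np.log(f_i[i]), j: np.log(f_i[j])}, {(i, j): Jblock}
    # general convex fit over q**k states
    states = enumerate_states(k, q)
    pairs = list(itertools.combinations(range(k), 2))
    targets_h = [f_i[s] for s in sites]
    targets_J = {(u, v): f_ij[sites[u], sites[v]] for u, v in pairs}
    n_par = k * q + len(pairs) * q * q

    def unpack(x):
        hs = x[: k * q].reshape(k, q)
        Js = x[k * q :].reshape(len(pairs), q, q)
        return hs, Js

    idx = states.astype(np.int64)

    def objective(x):
        hs, Js = unpack(x)
        loge = hs[np.arange(k), idx].sum(axis=1)
        for p, (u, v) in enumerate(pairs):
            loge = loge + Js[p][idx[:, u], idx[:, v]]
        lz = logsumexp(loge)
        p_state = np.exp(loge - lz)
        val = lz - sum(np.sum(hs[u] * targets_h[u]) for u in range(k))
        val -= sum(np.sum(Js[p] * targets_J[pr]) for p, pr in enumerate(pairs))
        val += gamma * np.sum(Js**2)
        gh = np.empty((k, q))
        for u in range(k):
            gh[u] = np.bincount(idx[:, u], weights=p_state, minlength=q) - targets_h[u]
        gJ = np.empty((len(pairs), q, q))
        for p, (u, v) in enumerate(pairs):
            flat = idx[:, u] * q + idx[:, v]
            gJ[p] = (
                np.bincount(flat, weights=p_state, minlength=q * q).reshape(q, q)
                - targets_J[(u, v)]
                + 2 * gamma * Js[p]
            )
        return val, np.concatenate([gh.ravel(), gJ.ravel()])

    x0 = np.zeros(n_par)
    for u in range(k):
        x0[u * q : (u + 1) * q] = np.log(targets_h[u])
    res = minimize(objective, x0, jac=True, method="L-BFGS-B",
                   options={"maxiter": 2000, "gtol": 1e-8, "ftol": 1e-15})
    hs, Js = unpack(res.x)
    h_parts = {sites[u]: hs[u].copy() for u in range(k)}
    J_parts = {(sites[u], sites[v]): Js[p].copy() for p, (u, v) in enumerate(pairs)}
    return float(res.fun - gamma * np.sum(Js**2)), h_parts, J_parts


class _ClusterExpansion:
    """Memoised cluster contributions Delta S and Delta(h, J)."""

    def __init__(self, f_i, f_ij, q, gamma):
        self.f_i, self.f_ij, self.q, self.gamma = f_i, f_ij, q, gamma
        self.cache: dict = {}

    def delta(self, sites: tuple):
        sites = tuple(sorted(sites))
        if sites in self.cache:
            return self.cache[sites]
        s, h_parts, J_parts = _cluster_fit(sites, self.f_i, self.f_ij, self.q, self.gamma)
        ds = s
        dh = {i: v.copy() for i, v in h_parts.items()}
        dJ = {pr: v.copy() for pr, v in J_parts.items()}
        for size in range(1, len(sites)):
            for sub in itertools.combinations(sites, size):
                sds, sdh, sdJ = self.delta(sub)
                ds -= sds
                for i, v in sdh.items():
                    dh[i] -= v
                for pr, v in sdJ.items():
                    dJ[pr] -= v
        self.cache[sites] = (ds, dh, dJ)
        return self.cache[sites]


def _counting_marginals(X: np.ndarray, q: int) -> tuple[np.ndarray, np.ndarray]:
    """Unweighted 1-/2-point frequencies of an integer alignment, by
    bincount (fast path for the refinement loop)."""
    X = np.asarray(X, dtype=np.int64)
    M, L = X.shape
    f_i = np.empty((L, q))
    for i in range(L):
        f_i[i] = np.bincount(X[:, i], minlength=q) / M
    f_ij = np.empty((L, L, q, q))
    for i in range(L):
        f_ij[i, i] = np.diag(f_i[i])
        for j in range(i + 1, L):
            flat = X[:, i] * q + X[:, j]
            blk = np.bincount(flat, weights=None, minlength=q * q).reshape(q, q) / M
            f_ij[i, j] = blk
            f_ij[j, i] = blk.T
    return f_i, f_ij


def _sample_model_marginals(model, n, seed, interval=None):
    """Model marginals, exact by enumeration when feasible, else from the
    package's own Potts Monte-Carlo sampler.  Returns (f_i, f_ij,
    n_effective) with ``n_effective = inf`` for the exact route."""
    if model.q**model.L <= MAX_EXACT_STATES:
        f_i, f_ij = exact_marginals(model)
        return f_i, f_ij, np.inf
    from .generative_eval import sample_from_model

    msa = sample_from_model(model, n, seed=seed, interval=interval or 3 * model.L)
    f_i, f_ij = _counting_marginals(msa.sequences, model.q)
    return f_i, f_ij, float(n)


def infer_ace(
    msa: AlignmentSet,
    weights: Optional[np.ndarray] = None,
    gamma: Optional[float] = None,
    max_cluster_size: Optional[int] = None,
    threshold_factor: float = 2.0,
    max_levels: int = 14,
    noise_sigma: float = 3.0,
    refine: bool = True,
    refine_iters: int = 60,
    refine_rate: float = 0.05,
    refine_samples: int = 1000,
    reconstruction_sigma: float = 3.0,
    seed: int = 0,
) -> tuple[PottsModel, EntropyEstimate]:
    """Adaptive cluster expansion of the cross-entropy.

    Clusters are retained while ``|Delta S|`` exceeds a threshold that is
    lowered geometrically (factor ``threshold_factor``) until the model's
    1- and 2-point statistics match the data within ``reconstruction_sigma``
    standard errors; a Boltzmann-machine refinement (gradient steps on the
    marginal residuals, exact for small systems, Monte-Carlo otherwise)
    follows.  ``gamma`` defaults to 5/M.  The output is expressed in the
    least-probable gauge; the entropy estimate is the accumulated cluster
    contribution at the final threshold.
    """
    if msa.M == 0:
        raise ValueError("empty MSA")
    M, L = msa.sequences.shape
    q = len(msa.alphabet)
    if gamma is None:
        gamma = 5.0 / M
    if max_cluster_size is None:
        max_cluster_size = 2 if q > 5 else min(L, 4)
    stats = frequencies(msa, weights)
    M_eff = stats.M_eff
    # smoothing keeps cluster entropies finite on unseen states
    lam = 1.0 / (1.0 + M_eff)
    f_i = (1 - lam) * stats.f_i + lam / q
    f_ij = (1 - lam) * stats.f_ij + lam / q**2
    for i in range(L):
        f_ij[i, i] = np.diag(f_i[i])
    expansion = _ClusterExpansion(f_i, f_ij, q, 0.0)

    pair_list = list(itertools.combinations(range(L), 2))
    # Miller-Madow correction: the plug-in pair entropy is biased low by
    # ~(k_i - 1)(k_j - 1)/(2 M_eff) (k = letters observed at the site), which
    # would otherwise swamp cluster selection at large q / moderate M
    n_obs = (stats.f_i > 0).sum(axis=1)
    pair_ds = {}
    pair_floor = {}
    for i, j in pair_list:
        df = (n_obs[i] - 1) * (n_obs[j] - 1)
        bias = df / (2.0 * M_eff)
        pair_ds[(i, j)] = min(expansion.delta((i, j))[0] + bias, 0.0)
        # null sd of the plug-in pair contribution (chi^2 approximation);
        # pairs below noise_sigma of it are never selected
        pair_floor[(i, j)] = noise_sigma * np.sqrt(2.0 * df) / (2.0 * M_eff)
    t0 = max(abs(v) for v in pair_ds.values())
    single_entropy = sum(expansion.delta((i,))[0] for i in range(L))

    se_1 = np.sqrt(np.maximum(f_i * (1 - f_i), 1e-12) / M_eff)
    se_2 = np.sqrt(np.maximum(f_ij * (1 - f_ij), 1e-12) / M_eff)

    def build(threshold):
        selected = [
            pr
            for pr in pair_list
            if abs(pair_ds[pr]) >= max(threshold, pair_floor[pr])
        ]
        clusters = [(i,) for i in range(L)] + [tuple(pr) for pr in selected]
        # grow clusters from overlapping selected ones
        level = [tuple(pr) for pr in selected]
        size = 2
        while size < max_cluster_size and level:
            cand = set()
            for c1, c2 in itertools.combinations(level, 2):
                u = tuple(sorted(set(c1) | set(c2)))
                if len(u) == size + 1:
                    cand.add(u)
            level = [c for c in sorted(cand) if abs(expansion.delta(c)[0]) >= threshold]
            clusters.extend(level)
            size += 1
        entropy = 0.0
        h = np.zeros((L, q))
        J = np.zeros((L, L, q, q))
        for c in clusters:
            ds, dh, dJ = expansion.delta(c)
            if len(c) == 2:
                ds = pair_ds[c]  # bias-corrected contribution
            entropy += ds
            for i, v in dh.items():
                h[i] += v
            for (i, j), v in dJ.items():
                J[i, j] += v
                J[j, i] += v.T
        return entropy, PottsModel(h, J, gauge="unspecified", method="ACE",
                                   gamma=gamma, meta={"alphabet": msa.alphabet}), len(clusters)

    def reconstruction_gap(model):
        """Largest marginal residual in units of its 3-sigma tolerance."""
        mf_i, mf_ij, n_model = _sample_model_marginals(
            model, refine_samples, seed=seed + 1, interval=3 * L
        )
        se_model_1 = np.sqrt(np.maximum(mf_i * (1 - mf_i), 1e-12) / n_model)
        se_model_2 = np.sqrt(np.maximum(mf_ij * (1 - mf_ij), 1e-12) / n_model)
        tol_1 = reconstruction_sigma * np.sqrt(se_1**2 + se_model_1**2)
        tol_2 = reconstruction_sigma * np.sqrt(se_2**2 + se_model_2**2)
        gap = max(
            float(np.max(np.abs(mf_i - stats.f_i) / tol_1)),
            float(np.max(np.abs(mf_ij - stats.f_ij) / tol_2)),
        )
        return gap

    # Each level: assemble the cluster model, refine its retained parameters
    # by Boltzmann-machine steps, then test whether it reproduces the data
    # statistics.  Refinement precedes the test because the raw truncated
    # expansion overcounts shared-site correlations on long chains.  The
    # schedule stops when the significant cluster set stabilises (the noise
    # floor keeps spurious pairs out) or the reconstruction test passes.
    # the limiting selection: every pair above its own significance floor
    limit_sel = frozenset(
        pr for pr in pair_list if abs(pair_ds[pr]) >= pair_floor[pr] and pair_ds[pr] != 0
    )
    threshold = t0
    converged = False
    model = None
    prev_selected = None
    entropy, n_clusters, gap = single_entropy, L, np.inf
    for _ in range(max_levels):
        selected_now = frozenset(
            pr for pr in pair_list if abs(pair_ds[pr]) >= max(threshold, pair_floor[pr])
        )
        if model is not None and selected_now == prev_selected and max_cluster_size == 2:
            # nothing new can enter at this level (larger clusters would)
            threshold /= threshold_factor
            continue
        prev_selected = selected_now
        entropy, candidate, n_clusters = build(threshold)
        support = np.abs(candidate.J).sum(axis=(2, 3)) > 0
        if refine:
            candidate = _boltzmann_refine(
                candidate, stats, gamma, refine_iters, refine_rate, refine_samples,
                seed, support=support,
            )
        model = candidate
        gap = reconstruction_gap(model)
        if gap <= 1.0:
            converged = True
            break
        selected = frozenset(
            pr for pr in pair_list if abs(pair_ds[pr]) >= max(threshold, pair_floor[pr])
        )
        if selected >= limit_sel:
            break  # every significant pair is already in the model
        threshold /= threshold_factor
    model = gauge_transform(model, "least-probable", reference=stats.f_i)
    model.meta.update(
        n_clusters=n_clusters, threshold=threshold, M_eff=M_eff, seed=seed
    )
    est = EntropyEstimate(
        entropy=float(entropy),
        method=f"cluster expansion, max size {max_cluster_size}, "
               f"threshold schedule /{threshold_factor}",
        threshold=float(threshold),
        converged=converged,
        note="entropy accumulated over retained clusters; "
             "Boltzmann-machine refinement not folded into the estimate",
    )
    return model, est


def _refine_exact(model, stats, gamma, iters, support=None, rate=0.5, tol=1e-6):
    """Deterministic Boltzmann-machine refinement against exact model
    marginals (small systems): plain gradient ascent on the regularised
    likelihood until the marginal residuals vanish."""
    L = model.L
    mask_J = np.ones((L, L), dtype=bool) if support is None else support
    best = None
    for _ in range(iters):
        mf_i, mf_ij = exact_marginals(model)
        g_h = stats.f_i - mf_i
        g_J = stats.f_ij - mf_ij - 2 * gamma * model.J
        dev = float(np.max(np.abs(g_h)))
        for i in range(L):
            for j in range(i + 1, L):
                if mask_J[i, j]:
                    dev = max(dev, float(np.max(np.abs(stats.f_ij[i, j] - mf_ij[i, j]))))
        if best is None or dev < best[0]:
            best = (dev, model.copy())
        if dev < tol:
            break
        model.h += rate * g_h
        for i in range(L):
            for j in range(i + 1, L):
                if not mask_J[i, j]:
                    continue
                model.J[i, j] += rate * g_J[i, j]
                model.J[j, i] = model.J[i, j].T
    refined = best[1]
    refined.meta["refine_residual"] = float(best[0])
    return refined


def _boltzmann_refine(model, stats, gamma, iters, rate, n_samples, seed, support=None):
    """Boltzmann-machine refinement with RPROP-style per-parameter steps.

    Ascends the regularised likelihood using only the sign of the marginal
    residuals (robust to Monte-Carlo noise in the model marginals): step
    sizes grow by 1.2 while the residual sign persists and halve when it
    flips.  The sampling depth is annealed upward across iterations.
    ``support`` restricts coupling updates to the retained pair set; fields
    are always refined.  Marginals are exact for small systems.
    """
    L, q = model.L, model.q
    model = model.copy()
    if q**L <= MAX_EXACT_STATES:
        return _refine_exact(model, stats, gamma, max(iters, 500), support)
    step_h = np.full((L, q), rate)
    step_J = np.full((L, L, q, q), rate)
    prev_h = np.zeros((L, q))
    prev_J = np.zeros((L, L, q, q))
    mask_J = np.ones((L, L), dtype=bool) if support is None else support
    best = None
    for it in range(iters):
        n_it = int(n_samples * (1 + 2 * it / max(iters - 1, 1)))
        mf_i, mf_ij, _ = _sample_model_marginals(
            model, n_it, seed=seed + 100 + it, interval=3 * L
        )
        g_h = stats.f_i - mf_i
        g_J = stats.f_ij - mf_ij - 2 * gamma * model.J
        dev = float(np.max(np.abs(g_h)))
        for i in range(L):
            for j in range(i + 1, L):
                if mask_J[i, j]:
                    dev = max(dev, float(np.max(np.abs(stats.f_ij[i, j] - mf_ij[i, j]))))
        if best is None or dev < best[0]:
            best = (dev, model.copy())
        if dev < 1e-4:
            break
        # RPROP updates
        agree = np.sign(g_h) * np.sign(prev_h)
        step_h = np.clip(step_h * np.where(agree > 0, 1.2, np.where(agree < 0, 0.5, 1.0)),
                         1e-4, 10 * rate)
        model.h += step_h * np.sign(g_h)
        prev_h = g_h
        for i in range(L):
            for j in range(i + 1, L):
                if not mask_J[i, j]:
                    continue
                agree = np.sign(g_J[i, j]) * np.sign(prev_J[i, j])
                step_J[i, j] = np.clip(
                    step_J[i, j] * np.where(agree > 0, 1.2, np.where(agree < 0, 0.5, 1.0)),
                    1e-4, 10 * rate,
                )
                upd = step_J[i, j] * np.sign(g_J[i, j])
                model.J[i, j] += upd
                model.J[j, i] += upd.T
                prev_J[i, j] = g_J[i, j]
    refined = best[1]
    refined.meta["refine_residual"] = float(best[0])
    return refined
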