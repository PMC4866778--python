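"""Contact prediction and design-pressure maps from couplings or correlations.

Pair scores are ranked to predict contacts: the Frobenius norm of each
coupling block with the average-product correction (APC),

    F_ij = sum_ab J_ij(a,b)^2,   F_ij^APC = F_ij - F_i. F_j. / F..,

mutual information (also APC-corrected before ranking), or the projection of
the couplings on the negated contact-energy matrix.  That projection slope,

    lambda_ij = - sum_ab J_ij(a,b) E(a,b) / sum_ab E(a,b)^2,

is the design pressure on the pair: positive where couplings stabilise
native-like contacts (positive design), negative where they penalise
contacts of competing folds (negative design).  Its theoretical counterpart
is (c_ij - cbar_ij) divided by a factor built from the sampling temperature
and the aggregate competitor weight.

Pairs are classified against the closest competitor fold S_F: Unique-Native
(contact in the native fold only), Shared-Native (in both), Closest-
Competitor (in S_F only), Non-Native (in neither, geometrically allowed),
and forbidden (lattice parity/backbone).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .energetics import CompetitorProfile, ContactEnergyMatrix
from .lattice_conformations import ContactMap, forbidden_pairs
from .msa_statistics import FrequencyStats
from .potts_inference import PottsModel, gauge_transform

__all__ = [
    "PairScoreMatrix",
    "PressureMap",
    "apc",
    "frobenius_apc_scores",
    "pressures",
    "theoretical_pressures",
    "pressure_denominator",
    "classify_pairs",
    "PairClasses",
    "ppv_curve",
    "contact_matrix_top_eigenvalue",
]

PAIR_CLASSES = ("UN", "SN", "CC", "NN", "forbidden")


@dataclass
class PairScoreMatrix:
    """Symmetric pair scores with a kind tag and provenance."""

    scores: np.ndarray  # (L, L), symmetric, zero diagonal
    kind: str  # MI | Frobenius | APC-corrected | projection
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        s = np.asarray(self.scores, dtype=np.float64)
        if s.ndim != 2 or s.shape[0] != s.shape[1]:
            raise ValueError("scores must be square")
        if not np.all(np.isfinite(s)):
            raise ValueError("scores must be finite")
        if not np.allclose(s, s.T, atol=1e-10):
            raise ValueError("scores must be symmetric")
        np.fill_diagonal(s, 0.0)
        self.scores = s

    @property
    def L(self) -> int:
        return self.scores.shape[0]

    def ranked_pairs(self, min_separation: int = 2) -> list[tuple[int, int]]:
        """Pairs sorted by descending score; ties broken by (i, j) index.
        Pairs closer than ``min_separation`` along the chain (backbone) are
        excluded from the ranking."""
        L = self.L
        items = [
            (-self.scores[i, j], i, j)
            for i in range(L)
            for j in range(i + min_separation, L)
        ]
        items.sort()
        return [(i, j) for _, i, j in items]

    def to_frame(self, classes: Optional[dict] = None):
        import pandas as pd

        rows = []
        for i, j in self.ranked_pairs():
            rows.append(
                {
                    "i": i + 1,
                    "j": j + 1,
                    "score_kind": self.kind,
                    "value": self.scores[i, j],
                    "class": classes.get((i, j), "") if classes else "",
                }
            )
        return pd.DataFrame(rows)


def apc(F: np.ndarray) -> np.ndarray:
    """Average-product correction F_ij - F_i. F_j. / F.. (zero diagonal).

    F_i. and F.. are the average score of site i and the overall average
    (the original average-product convention, under which a constant score
    matrix is corrected exactly to zero).
    """
    F = np.asarray(F, dtype=np.float64).copy()
    L = F.shape[0]
    np.fill_diagonal(F, 0.0)
    if L < 2:
        return F
    row_mean = F.sum(axis=1) / (L - 1)
    total_mean = F.sum() / (L * (L - 1))
    if total_mean == 0:
        return F
    corrected = F - np.outer(row_mean, row_mean) / total_mean
    np.fill_diagonal(corrected, 0.0)
    return corrected


def frobenius_apc_scores(model: PottsModel, apply_apc: bool = True) -> PairScoreMatrix:
    """F_ij = sum_ab J_ij(a,b)^2 with the average-product correction.

    The score is gauge-dependent; score DCA/PLM models in the zero-sum gauge
    (which minimises the Frobenius norm) and ACE models in the least-probable
    gauge, as each method's couplings are reported.
    """
    L = model.L
    F = np.einsum("ijab->ij", model.J**2)
    np.fill_diagonal(F, 0.0)
    scores = apc(F) if apply_apc else F
    kind = "APC-corrected" if apply_apc else "Frobenius"
    return PairScoreMatrix(
        scores, kind, provenance={"method": model.method, "gauge": model.gauge}
    )


def mi_apc_scores(mi: np.ndarray) -> PairScoreMatrix:
    """Mutual-information scores, APC-corrected before ranking."""
    return PairScoreMatrix(apc(mi), "MI", provenance={"method": "MI"})


@dataclass
class PressureMap:
    """Per-pair design pressures and (optionally) their class labels."""

    lam: np.ndarray  # (L, L) symmetric
    kind: str = "projection"
    delta_c: Optional[np.ndarray] = None  # c_ij - cbar_ij
    classes: Optional[dict] = None  # (i, j) -> class label
    provenance: dict = field(default_factory=dict)

    @property
    def L(self) -> int:
        return self.lam.shape[0]

    def score_matrix(self) -> PairScoreMatrix:
        return PairScoreMatrix(self.lam, "projection", provenance=dict(self.provenance))

    def class_mean(self, label: str) -> float:
        if self.classes is None:
            raise ValueError("no class labels attached")
        vals = [self.lam[i, j] for (i, j), c in self.classes.items() if c == label]
        return float(np.mean(vals))


def pressures(
    model: PottsModel,
    E: ContactEnergyMatrix,
    reference_frequencies: FrequencyStats | np.ndarray,
    restrict_to_observed: bool = True,
) -> PressureMap:
    """Projection of each coupling block on the (negated) contact energies.

    Couplings and energies are expressed in the consensus gauge of the
    reference frequencies before projecting; with ``restrict_to_observed``
    the sums run only over letters seen at least once at each site.
    """
    f = (
        reference_frequencies.f_i
        if isinstance(reference_frequencies, FrequencyStats)
        else np.asarray(reference_frequencies)
    )
    if f.shape != (model.L, model.q):
        raise ValueError("reference frequencies shape does not match model")
    if model.q != E.q:
        raise ValueError("energy matrix alphabet size does not match model")
    consensus = np.argmax(f, axis=1)
    model_c = (
        model if model.gauge == "consensus" else gauge_transform(model, "consensus", f)
    )
    L, q = model.L, model.q
    lam = np.zeros((L, L))
    for i in range(L):
        for j in range(i + 1, L):
            # energies shifted by the same per-pair gauge transformation
            Eg = (
                E.matrix
                - E.matrix[consensus[i], :][None, :]
                - E.matrix[:, consensus[j]][:, None]
                + E.matrix[consensus[i], consensus[j]]
            )
            Jg = model_c.J[i, j]
            if restrict_to_observed:
                mask = np.outer(f[i] > 0, f[j] > 0)
                num = -np.sum(Jg[mask] * Eg[mask])
                den = np.sum(Eg[mask] ** 2)
            else:
                num = -np.sum(Jg * Eg)
                den = np.sum(Eg**2)
            lam[i, j] = lam[j, i] = num / den if den > 0 else 0.0
    return PressureMap(
        lam,
        kind="projection",
        provenance={"method": model.method, "gauge": "consensus"},
    )


def pressure_denominator(beta: float, aggregate_competitor_weight: float) -> float:
    """The factor converting the contact-map difference into a pressure:
    ``log(1 + 1 / (beta * N_S exp(-Delta)))``.

    Isolated here so the functional form can be revised in one place.
    """
    return float(np.log1p(1.0 / (beta * aggregate_competitor_weight)))


def theoretical_pressures(
    profile: CompetitorProfile,
    native_cmap: ContactMap,
    beta: float,
) -> PressureMap:
    """lambda^TH_ij = (c_ij - cbar_ij) / log(1 + 1/(beta N_S e^-Delta));
    zero wherever the native and average competitor maps agree."""
    c = native_cmap.dense.astype(np.float64)
    delta_c = c - profile.cbar
    lam = delta_c / pressure_denominator(beta, profile.aggregate)
    return PressureMap(
        lam,
        kind="theoretical",
        delta_c=delta_c,
        provenance={"beta": beta, "aggregate": profile.aggregate},
    )


@dataclass
class PairClasses:
    """Partition of all site pairs into UN/SN/CC/NN/forbidden."""

    labels: dict  # (i, j) i<j -> label
    L: int

    def pairs(self, label: str) -> list[tuple[int, int]]:
        return sorted(p for p, c in self.labels.items() if c == label)

    def counts(self) -> dict:
        out = {c: 0 for c in PAIR_CLASSES}
        for c in self.labels.values():
            out[c] += 1
        return out


def classify_pairs(
    native_cmap: ContactMap, competitor_cmap: ContactMap, L: Optional[int] = None
) -> PairClasses:
    """Label every pair against the closest competitor's contact map."""
    L = L or native_cmap.L
    forbidden = forbidden_pairs(L)
    labels = {}
    for i in range(L):
        for j in range(i + 1, L):
            pair = (i, j)
            if pair in forbidden:
                labels[pair] = "forbidden"
            elif pair in native_cmap:
                labels[pair] = "SN" if pair in competitor_cmap else "UN"
            else:
                labels[pair] = "CC" if pair in competitor_cmap else "NN"
    return PairClasses(labels, L)


def ppv_curve(
    scores: PairScoreMatrix,
    truth: ContactMap,
    exclude_forbidden: bool = False,
) -> np.ndarray:
    """Positive predictive value at each rank k: the fraction of the top k
    scores that are true contacts.  Backbone pairs (|j - i| <= 1) never enter
    the ranking; even-separation (parity-forbidden) pairs are excluded only
    when ``exclude_forbidden`` is set."""
    ranked = scores.ranked_pairs(min_separation=2)
    if exclude_forbidden:
        bad = forbidden_pairs(truth.L)
        ranked = [p for p in ranked if p not in bad]
    hits = np.cumsum([1 if p in truth else 0 for p in ranked])
    return hits / np.arange(1, len(ranked) + 1)


def contact_matrix_top_eigenvalue(cmap: ContactMap) -> float:
    """Largest eigenvalue of the binary contact matrix (a designability
    proxy); 0 for an empty map, 1 for a single contact."""
    if len(cmap) == 0:
        return 0.0
    return float(np.linalg.eigvalsh(cmap.dense.astype(np.float64))[-1])
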