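"""Compact self-avoiding conformations of short chains on small cubic boxes.

A lattice protein of length ``L`` is a self-avoiding walk visiting every site
of a rectangular box exactly once (a compact Hamiltonian walk).  For the
27-mer on the 3x3x3 box every compact conformation carries exactly 28
contacts: unordered pairs of chain positions occupying nearest-neighbour
lattice sites without being consecutive along the backbone.  Cubic-lattice
parity forbids contacts between positions ``i < j`` with ``j - i`` even, so
169 even-separation pairs plus the 26 backbone bonds -- 195 pairs in total --
can never be in contact in any fold.

Conformations are counted up to the octahedral symmetries of the box (48
rotations/reflections for a cube) and, optionally, chain reversal.  For the
3x3x3 box the enumeration yields 4,960,608 directed compact walks, i.e.
103,346 symmetry classes (the group action is free: 4,960,608 = 48 x 103,346)
and 51,704 classes when chain reversal is also quotiented, in agreement with
classic enumerations of this lattice.

Chain positions are 0-based internally and 1-based in human-readable output.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from numba import njit

__all__ = [
    "LatticeWalk",
    "ContactMap",
    "StructureLibrary",
    "enumerate_compact_folds",
    "canonical_form",
    "contact_map",
    "contact_counts",
    "pair_occurrences",
    "forbidden_pairs",
    "box_symmetry_tables",
    "all_compact_walks",
]

#: hard guard against runaway enumeration
MAX_BOX_SITES = 27

_UNIT_STEPS = ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1))


# ---------------------------------------------------------------------------
# geometry helpers


def _site_index(c, dims) -> int:
    return (c[0] * dims[1] + c[1]) * dims[2] + c[2]


def _site_coords(dims) -> np.ndarray:
    """(L, 3) coordinates in site-index order (lexicographic in x, y, z)."""
    return np.array(
        [(x, y, z) for x in range(dims[0]) for y in range(dims[1]) for z in range(dims[2])],
        dtype=np.int8,
    )


def box_symmetry_tables(dims: Sequence[int]) -> np.ndarray:
    """Site-permutation tables of the box symmetry group.

    Returns an ``(n_ops, L)`` array; row ``g`` maps site index ``s`` to its
    image under the ``g``-th signed axis permutation preserving the box.  A
    cube has 48 such operations, a general box fewer.
    """
    dims = tuple(int(d) for d in dims)
    L = dims[0] * dims[1] * dims[2]
    tables = []
    for perm in itertools.permutations(range(3)):
        if tuple(dims[p] for p in perm) != dims:
            continue
        for signs in itertools.product((False, True), repeat=3):
            table = np.empty(L, dtype=np.int8)
            for idx, c in enumerate(_site_coords(dims)):
                nc = [0, 0, 0]
                for axis in range(3):
                    v = int(c[perm[axis]])
                    nc[axis] = dims[perm[axis]] - 1 - v if signs[axis] else v
                table[idx] = _site_index(nc, dims)
            tables.append(table)
    return np.array(tables, dtype=np.int8)


def _neighbor_tables(dims) -> tuple[np.ndarray, np.ndarray]:
    """Ascending neighbour lists per site; ascending order makes the DFS emit
    canonical walks in lexicographic order."""
    L = dims[0] * dims[1] * dims[2]
    neigh = np.full((L, 6), -1, dtype=np.int8)
    count = np.zeros(L, dtype=np.int8)
    for idx, (x, y, z) in enumerate(_site_coords(dims)):
        for dx, dy, dz in _UNIT_STEPS:
            nx, ny, nz = x + dx, y + dy, z + dz
            if 0 <= nx < dims[0] and 0 <= ny < dims[1] and 0 <= nz < dims[2]:
                neigh[idx, count[idx]] = _site_index((nx, ny, nz), dims)
                count[idx] += 1
    for idx in range(L):
        neigh[idx, : count[idx]] = np.sort(neigh[idx, : count[idx]])
    return neigh, count


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class LatticeWalk:
    """A self-avoiding walk on a rectangular box, one site per chain position."""

    coords: np.ndarray  # (L, 3) int
    box: tuple[int, int, int]

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=np.int8)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "box", tuple(int(d) for d in self.box))
        self._validate()

    def _validate(self) -> None:
        c = self.coords
        if c.ndim != 2 or c.shape[1] != 3:
            raise ValueError("coords must be an (L, 3) array")
        if np.any(c < 0) or np.any(c >= np.array(self.box)):
            raise ValueError("walk leaves the box")
        if len({tuple(p) for p in c.tolist()}) != len(c):
            raise ValueError("walk revisits a site")
        steps = np.abs(np.diff(c.astype(np.int16), axis=0)).sum(axis=1)
        if len(c) > 1 and not np.all(steps == 1):
            raise ValueError("consecutive positions must differ by one unit step")

    @property
    def L(self) -> int:
        return len(self.coords)

    @property
    def sites(self) -> np.ndarray:
        """Site indices along the chain (lexicographic site numbering)."""
        d = self.box
        c = self.coords.astype(np.int64)
        return ((c[:, 0] * d[1] + c[:, 1]) * d[2] + c[:, 2]).astype(np.int8)

    @property
    def is_compact(self) -> bool:
        return self.L == self.box[0] * self.box[1] * self.box[2]

    @classmethod
    def from_sites(cls, sites: Iterable[int], box: Sequence[int]) -> "LatticeWalk":
        box = tuple(int(d) for d in box)
        coords = _site_coords(box)[np.asarray(list(sites), dtype=np.int64)]
        return cls(coords, box)


@dataclass(frozen=True)
class ContactMap:
    """Unordered non-backbone nearest-neighbour pairs of one conformation."""

    pairs: frozenset  # of (i, j) with i < j
    L: int

    def __post_init__(self):
        pairs = frozenset((int(i), int(j)) for i, j in self.pairs)
        for i, j in pairs:
            if not 0 <= i < j < self.L:
                raise ValueError(f"pair {(i, j)} out of range for L={self.L}")
        object.__setattr__(self, "pairs", pairs)

    @property
    def dense(self) -> np.ndarray:
        """Symmetric binary L x L view (zero diagonal)."""
        c = np.zeros((self.L, self.L), dtype=np.int8)
        for i, j in self.pairs:
            c[i, j] = c[j, i] = 1
        return c

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair) -> bool:
        i, j = pair
        return (min(i, j), max(i, j)) in self.pairs


@dataclass
class StructureLibrary:
    """Ordered collection of conformations sharing one box.

    ``walks`` stores one site-index sequence per row; ``provenance`` records
    how the library was built (full enumeration, seeded subsample, file).
    """

    walks: np.ndarray  # (N, L) int8 site indices
    box: tuple[int, int, int]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.walks = np.asarray(self.walks, dtype=np.int8)
        self.box = tuple(int(d) for d in self.box)
        if self.walks.ndim != 2 or self.walks.shape[0] < 1:
            raise ValueError("library needs at least one structure")

    @property
    def N(self) -> int:
        return self.walks.shape[0]

    @property
    def L(self) -> int:
        return self.walks.shape[1]

    def walk(self, index: int) -> LatticeWalk:
        return LatticeWalk.from_sites(self.walks[index], self.box)

    def contact_map(self, index: int) -> ContactMap:
        return contact_map(self.walk(index))

    def contact_maps(self) -> list[ContactMap]:
        return [self.contact_map(i) for i in range(self.N)]

    def contact_pairs_array(self) -> np.ndarray:
        """(N, n_pairs, 2) pair array; only valid when all structures have the
        same number of contacts (always true for compact walks of one box)."""
        per = [sorted(self.contact_map(i).pairs) for i in range(self.N)]
        n = len(per[0])
        if any(len(p) != n for p in per):
            raise ValueError("structures differ in contact count")
        return np.array(per, dtype=np.int8)

    def subsample(self, n: int, seed: int) -> "StructureLibrary":
        """Seeded uniform subsample without replacement, order preserved."""
        if not 1 <= n <= self.N:
            raise ValueError(f"cannot subsample {n} of {self.N} structures")
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(self.N, size=n, replace=False))
        prov = dict(self.provenance)
        prov.update(kind="seeded subsample", n=n, seed=seed, parent_N=self.N)
        return StructureLibrary(self.walks[idx].copy(), self.box, prov)

    def manifest_hash(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.walks).tobytes())
        h.update(repr(self.box).encode())
        return h.hexdigest()[:16]

    # -- serialization ------------------------------------------------------

    def save(self, path) -> None:
        """Plain-text structure file: header, then one conformation per line
        as ``x,y,z;x,y,z;...`` triples."""
        coords = _site_coords(self.box)
        with open(path, "w") as fh:
            fh.write(f"# box {self.box[0]},{self.box[1]},{self.box[2]}\n")
            fh.write(f"# symmetry {self.provenance.get('symmetry', 'octahedral')}"
                     f" reversal={self.provenance.get('include_reversal', False)}\n")
            fh.write(f"# kind {self.provenance.get('kind', 'unspecified')}\n")
            for row in self.walks:
                fh.write(";".join(",".join(map(str, coords[s])) for s in row) + "\n")

    @classmethod
    def load(cls, path) -> "StructureLibrary":
        """Read a structure file.

        Accepts the package's ``x,y,z;...`` triple format and, as a fallback,
        lines of whitespace-separated site indices (``0 1 4 ...``), a common
        structure-list convention for this lattice.
        """
        path = Path(path)
        box = None
        prov: dict = {"kind": "external file", "path": str(path)}
        rows = []
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if parts and parts[0] == "box":
                    box = tuple(int(v) for v in parts[1].split(","))
                continue
            if ";" in line or "," in line:
                triples = [tuple(int(v) for v in t.split(",")) for t in line.split(";")]
                if box is None:
                    box = tuple(int(np.max([t[k] for t in triples])) + 1 for k in range(3))
                rows.append([_site_index(t, box) for t in triples])
            else:
                sites = [int(v) for v in line.split()]
                if box is None:
                    # cubic box inferred from the chain length
                    side = round(len(sites) ** (1 / 3))
                    if side**3 != len(sites):
                        raise ValueError("cannot infer box dims; add a '# box' header")
                    box = (side, side, side)
                rows.append(sites)
        if not rows:
            raise ValueError(f"no structures found in {path}")
        return cls(np.array(rows, dtype=np.int8), box, prov)

    def __iter__(self) -> Iterator[LatticeWalk]:
        return (self.walk(i) for i in range(self.N))


# ---------------------------------------------------------------------------
# operations


def canonical_form(walk: LatticeWalk, include_reversal: bool = False) -> LatticeWalk:
    """Lexicographically minimal image of ``walk`` under the box symmetries
    (and chain reversal when ``include_reversal``).  Idempotent."""
    tables = box_symmetry_tables(walk.box)
    sites = walk.sites.astype(np.int64)
    candidates = [sites] + ([sites[::-1]] if include_reversal else [])
    best = min(tuple(int(v) for v in t[c]) for t in tables for c in candidates)
    return LatticeWalk.from_sites(best, walk.box)


def contact_map(walk: LatticeWalk) -> ContactMap:
    """Pairs of chain positions at unit lattice distance, excluding backbone
    neighbours.  Compact 27-mers always have 28 such pairs, compact 2x2x2
    walks 5 (12 box edges minus 7 backbone bonds)."""
    c = walk.coords.astype(np.int16)
    pairs = set()
    for i in range(walk.L):
        d = np.abs(c[i + 2 :] - c[i]).sum(axis=1)
        for off in np.nonzero(d == 1)[0]:
            pairs.add((i, i + 2 + int(off)))
    return ContactMap(frozenset(pairs), walk.L)


def contact_counts(lib: StructureLibrary) -> np.ndarray:
    """Number of contacts of every structure in the library (vectorised;
    suitable for the full 3x3x3 enumeration)."""
    coords = _site_coords(lib.box)[lib.walks.astype(np.int64)].astype(np.int16)
    N, L, _ = coords.shape
    counts = np.zeros(N, dtype=np.int64)
    for i in range(L):
        for j in range(i + 2, L):
            d = np.abs(coords[:, i] - coords[:, j]).sum(axis=1)
            counts += d == 1
    return counts


def pair_occurrences(lib: StructureLibrary) -> np.ndarray:
    """(L, L) matrix counting in how many structures each site pair is in
    contact; zero exactly on the forbidden pairs for a full enumeration."""
    coords = _site_coords(lib.box)[lib.walks.astype(np.int64)].astype(np.int16)
    N, L, _ = coords.shape
    occ = np.zeros((L, L), dtype=np.int64)
    for i in range(L):
        for j in range(i + 2, L):
            n = int(np.sum(np.abs(coords[:, i] - coords[:, j]).sum(axis=1) == 1))
            occ[i, j] = occ[j, i] = n
    return occ


def forbidden_pairs(L: int) -> frozenset:
    """Pairs that can never be in contact: backbone neighbours (j - i = 1)
    and even chain separations (lattice parity).  195 pairs for L = 27."""
    if L < 2:
        raise ValueError("L must be >= 2")
    return frozenset(
        (i, j)
        for i in range(L)
        for j in range(i + 1, L)
        if (j - i) == 1 or (j - i) % 2 == 0
    )


# ---------------------------------------------------------------------------
# enumeration


@njit(cache=True)
def _enumerate_kernel(neigh, ncount, tables, starts, L, include_reversal):
    """DFS over all directed compact walks from symmetry-irreducible start
    sites, keeping each walk that equals its own canonical form.  Returns
    (walks array, number of leaves visited)."""
    cap = 1 << 14
    out = np.empty((cap, L), dtype=np.int8)
    n_out = 0
    leaves = 0
    walk = np.empty(L, dtype=np.int8)
    choice = np.empty(L, dtype=np.int8)
    n_ops = tables.shape[0]
    for si in range(starts.shape[0]):
        s = starts[si]
        walk[0] = s
        visited = np.int64(1) << np.int64(s)
        depth = 0
        choice[0] = 0
        while depth >= 0:
            if depth == L - 1:
                leaves += 1
                is_can = True
                for p in range(n_ops):
                    for k in range(L):
                        a = tables[p, walk[k]]
                        b = walk[k]
                        if a < b:
                            is_can = False
                            break
                        elif a > b:
                            break
                    if not is_can:
                        break
                    if include_reversal:
                        for k in range(L):
                            a = tables[p, walk[L - 1 - k]]
                            b = walk[k]
                            if a < b:
                                is_can = False
                                break
                            elif a > b:
                                break
                        if not is_can:
                            break
                if is_can:
                    if n_out == cap:
                        cap *= 2
                        grown = np.empty((cap, L), dtype=np.int8)
                        grown[:n_out] = out
                        out = grown
                    out[n_out] = walk
                    n_out += 1
                visited ^= np.int64(1) << np.int64(walk[depth])
                depth -= 1
                continue
            cur = walk[depth]
            advanced = False
            k = choice[depth]
            while k < ncount[cur]:
                nxt = neigh[cur, k]
                if not (visited >> np.int64(nxt)) & np.int64(1):
                    choice[depth] = k + 1
                    depth += 1
                    walk[depth] = nxt
                    choice[depth] = 0
                    visited |= np.int64(1) << np.int64(nxt)
                    advanced = True
                    break
                k += 1
            if not advanced:
                if depth > 0:
                    visited ^= np.int64(1) << np.int64(walk[depth])
                depth -= 1
    return out[:n_out], leaves


def enumerate_compact_folds(
    box_dims: Sequence[int], include_reversal: bool = False
) -> StructureLibrary:
    """Enumerate compact Hamiltonian walks up to box symmetry.

    One representative per symmetry class is returned, in canonical
    lexicographic order, so structure indices are stable across runs.
    ``include_reversal`` additionally identifies a chain with its reversal
    (default off: the directed-chain convention, which yields 103,346 classes
    for the 3x3x3 box; with reversal, 51,704).

    Raises ``ValueError`` for boxes with more than 27 sites.
    """
    dims = tuple(int(d) for d in box_dims)
    if len(dims) != 3 or any(d < 1 for d in dims):
        raise ValueError("box_dims must be three integers >= 1")
    L = dims[0] * dims[1] * dims[2]
    if L > MAX_BOX_SITES:
        raise ValueError(
            f"box {dims} has {L} sites; enumeration is guarded at {MAX_BOX_SITES}"
        )
    tables = box_symmetry_tables(dims)
    neigh, ncount = _neighbor_tables(dims)
    # canonical walks start at an orbit-minimal site
    starts = np.array(sorted({int(tables[:, s].min()) for s in range(L)}), dtype=np.int8)
    walks, leaves = _enumerate_kernel(neigh, ncount, tables, starts, L, include_reversal)
    order = np.lexsort(walks.T[::-1])  # canonical lexicographic order
    walks = walks[order]
    lib = StructureLibrary(
        walks,
        dims,
        provenance={
            "kind": "full enumeration",
            "symmetry": f"octahedral({tables.shape[0]})",
            "include_reversal": bool(include_reversal),
            "directed_walks_visited": int(leaves),
        },
    )
    return lib


def all_compact_walks(box_dims: Sequence[int]) -> list[tuple]:
    """Brute-force list of *all* directed compact walks (no symmetry
    reduction), as tuples of site indices.

    Pure-Python reference enumerator used as the oracle for the fast kernel
    on small boxes; do not call on boxes with more than ~18 sites.
    """
    dims = tuple(int(d) for d in box_dims)
    L = dims[0] * dims[1] * dims[2]
    if L > 18:
        raise ValueError("brute-force enumeration is limited to small boxes")
    neigh, ncount = _neighbor_tables(dims)
    walks = []

    def rec(prefix: list, visited: int) -> None:
        if len(prefix) == L:
            walks.append(tuple(prefix))
            return
        cur = prefix[-1]
        for k in range(ncount[cur]):
            nxt = int(neigh[cur, k])
            if not (visited >> nxt) & 1:
                prefix.append(nxt)
                rec(prefix, visited | (1 << nxt))
                prefix.pop()

    for s in range(L):
        rec([s], 1 << s)
    return walks
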