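"""TM-score structural alignment and the ``1 - TM-score`` structural distance.

The TM-score between two aligned CA traces is

    TM = max over superpositions of (1/L_norm) * sum_i 1 / (1 + (d_i/d0)^2)

where ``d_i`` is the CA-CA distance of aligned residue pair *i* under the
superposition and ``d0(L_norm) = max(1.24 (L_norm - 15)^{1/3} - 1.8, 0.5)``
is the length-dependent scale that makes the score size-independent.
Scores above ~0.5 generally indicate a shared fold; 0.4 is a common
similarity criterion.

Because the score is normalized by one chain length it is asymmetric; the
symmetric score used for clustering and fold statistics is the mean of the
two single-sided normalizations, and the structural distance is
``1 - tm_sym``.  Alignments are found by a fragment-seeded heuristic:
gapless threading seeds, a best-matching 8-residue fragment seed, and a
secondary-structure-string seed, each refined by iterating superposition
and sequential dynamic programming until the residue correspondence is
stable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit
from scipy.spatial.transform import Rotation
from scipy.spatial.distance import cdist

from foldspace.structures_io import DomainStructure

DEFAULT_GAP_PENALTY = -0.6
_MAX_REFINE_ITER = 30


class DegenerateGeometryError(ValueError):
    """Point set is too degenerate (collinear) for a unique superposition."""


@dataclass
class AlignmentResult:
    """Result of a structural alignment between domains A and B.

    ``pairs`` holds (index in A, index in B) correspondences, strictly
    increasing in both coordinates.  ``rotation`` / ``translation`` map B
    onto A (``B' = B @ rotation.T + translation``) via the least-squares
    superposition on all aligned pairs; ``per_pair_distance`` are the CA-CA
    distances under that superposition.  ``tm_norm_a`` / ``tm_norm_b`` are
    the TM-scores normalized by the two chain lengths, ``tm_sym`` their
    mean, and ``distance = 1 - tm_sym``.
    """

    pairs: list[tuple[int, int]]
    rotation: np.ndarray
    translation: np.ndarray
    per_pair_distance: np.ndarray
    tm_norm_a: float
    tm_norm_b: float
    tm_sym: float
    distance: float


def d0(L_norm: int) -> float:
    """Length-dependent TM-score distance scale, floored at 0.5 Angstrom."""
    if L_norm < 1:
        raise ValueError("L_norm must be >= 1")
    if L_norm <= 15:
        return 0.5
    return max(1.24 * (L_norm - 15) ** (1.0 / 3.0) - 1.8, 0.5)


def kabsch_superpose(
    points_a: np.ndarray, points_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of B onto A.

    Returns ``(rotation, translation, rmsd)`` with
    ``B' = points_b @ rotation.T + translation`` minimizing the RMSD to
    ``points_a``.  The rotation is proper (reflections corrected).
    """
    a = np.asarray(points_a, dtype=float)
    b = np.asarray(points_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"point sets differ in shape: {a.shape} vs {b.shape}")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 points for superposition")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    ac, bc = a - ca, b - cb
    if np.linalg.matrix_rank(ac, tol=1e-8) < 2 and np.linalg.matrix_rank(bc, tol=1e-8) < 2:
        raise DegenerateGeometryError("point sets are collinear; superposition not unique")
    rot, rssd = Rotation.align_vectors(ac, bc)
    R = rot.as_matrix()
    t = ca - R @ cb
    rmsd = float(rssd) / np.sqrt(a.shape[0])
    return R, t, rmsd


def _superpose_transform(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Kabsch without degeneracy checks, for use inside refinement loops.

    Near-collinear subsets (e.g. a few strand residues) are fine here: any
    of the equally good rotations serves as a refinement step.
    """
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        rot, _ = Rotation.align_vectors(a - ca, b - cb)
    R = rot.as_matrix()
    return R, ca - R @ cb


def tm_terms(distances: np.ndarray, L_norm: int) -> float:
    """Evaluate the TM-score sum for given pair distances (no Max search)."""
    d = np.asarray(distances, dtype=float)
    d0v = d0(L_norm)
    return float(np.sum(1.0 / (1.0 + (d / d0v) ** 2)) / L_norm)


def tm_score_given_alignment(
    coords_a: np.ndarray, coords_b: np.ndarray, L_norm: int
) -> float:
    """TM-score of a fixed residue correspondence, maximized over superpositions.

    ``coords_a[i]`` and ``coords_b[i]`` are the CA positions of aligned pair
    *i*.  Superpositions are seeded from contiguous aligned fragments of
    lengths L_ali, L_ali/2 and L_ali/4 (minimum 4) and refined by repeatedly
    superposing on the subset of pairs closer than an inclusion cutoff that
    grows until at least 3 pairs are included, stopping once the included
    subset is stable.  The best score over all visited superpositions is
    returned.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    n = a.shape[0]
    if n < 3 or b.shape[0] != n:
        raise ValueError("need at least 3 aligned pairs with matching coordinates")
    d0v = d0(L_norm)
    d_incl = max(d0v, 1.0)

    frag_lens: list[int] = []
    for fl in (n, max(n // 2, 4), max(n // 4, 4)):
        fl = min(fl, n)
        if fl >= 3 and fl not in frag_lens:
            frag_lens.append(fl)

    best = 0.0
    for fl in frag_lens:
        stride = max(1, fl // 2)
        for start in range(0, n - fl + 1, stride):
            subset = np.zeros(n, dtype=bool)
            subset[start : start + fl] = True
            for _ in range(20):
                R, t = _superpose_transform(a[subset], b[subset])
                d = np.linalg.norm(a - (b @ R.T + t), axis=1)
                score = np.sum(1.0 / (1.0 + (d / d0v) ** 2)) / L_norm
                if score > best:
                    best = float(score)
                cut = d_incl
                new = d < cut
                while new.sum() < 3:
                    cut += 0.5
                    new = d < cut
                if np.array_equal(new, subset):
                    break
                subset = new
    return best


@njit(cache=False)
def _semiglobal_dp(S, gap):  # pragma: no cover - exercised via wrappers
    """Sequential DP with constant gap penalty and free terminal gaps.

    Tie-break: diagonal, then up (gap in B), then left (gap in A).
    Returns (pairs_i, pairs_j, score).
    """
    n, m = S.shape
    H = np.zeros((n + 1, m + 1))
    P = np.zeros((n + 1, m + 1), dtype=np.int8)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = H[i - 1, j - 1] + S[i - 1, j - 1]
            ptr = 0
            up = H[i - 1, j] + gap
            if up > best:
                best = up
                ptr = 1
            left = H[i, j - 1] + gap
            if left > best:
                best = left
                ptr = 2
            H[i, j] = best
            P[i, j] = ptr
    bi, bj = n, m
    best_end = H[n, m]
    for i in range(1, n + 1):
        if H[i, m] > best_end:
            best_end = H[i, m]
            bi, bj = i, m
    for j in range(1, m + 1):
        if H[n, j] > best_end:
            best_end = H[n, j]
            bi, bj = n, j
    cap = n if n < m else m
    pi = np.empty(cap, dtype=np.int64)
    pj = np.empty(cap, dtype=np.int64)
    k = 0
    i, j = bi, bj
    while i > 0 and j > 0:
        p = P[i, j]
        if p == 0:
            k += 1
            pi[cap - k] = i - 1
            pj[cap - k] = j - 1
            i -= 1
            j -= 1
        elif p == 1:
            i -= 1
        else:
            j -= 1
    return pi[cap - k :], pj[cap - k :], best_end


def _pseudo_dihedrals(coords: np.ndarray) -> np.ndarray:
    """CA(i..i+3) pseudo-dihedral angle in degrees, length L-3."""
    b1 = coords[1:-2] - coords[:-3]
    b2 = coords[2:-1] - coords[1:-2]
    b3 = coords[3:] - coords[2:-1]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2, axis=1, keepdims=True))
    x = np.sum(n1 * n2, axis=1)
    y = np.sum(m1 * n2, axis=1)
    return np.degrees(np.arctan2(y, x))


def secondary_structure_states(coords: np.ndarray) -> str:
    """3-state secondary structure string from CA pseudo-dihedrals.

    'H' for helical twist, 'E' for extended, 'C' otherwise; terminal
    residues default to 'C'.  Used only to seed alignments.
    """
    L = coords.shape[0]
    states = np.full(L, "C")
    if L >= 4:
        tau = _pseudo_dihedrals(coords)
        helical = (tau > 20.0) & (tau < 100.0)
        extended = np.abs(tau) > 140.0
        states[1 : L - 2][helical] = "H"
        states[1 : L - 2][extended] = "E"
    return "".join(states)


def _threading_seeds(la: int, lb: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Gapless alignments of B against A at all offsets, subsampled by stride."""
    stride = int(np.ceil(max(la, lb) / 20))
    min_overlap = min(5, la, lb)
    seeds = []
    for off in range(-(lb - min_overlap), la - min_overlap + 1, stride):
        i0 = max(0, off)
        i1 = min(la, lb + off)
        if i1 - i0 < min_overlap:
            continue
        ai = np.arange(i0, i1)
        seeds.append((ai, ai - off))
    return seeds


def _best_fragment_seed(
    a: np.ndarray, b: np.ndarray, frag: int = 8
) -> tuple[np.ndarray, np.ndarray] | None:
    """Pair of contiguous ``frag``-mers (one per structure) with lowest RMSD.

    Fragment starts are subsampled for long chains; RMSDs are computed for
    all retained start pairs via batched Kabsch on 3x3 covariances.
    """
    la, lb = a.shape[0], b.shape[0]
    if la < frag or lb < frag:
        return None
    stride_a = max(1, la // 25)
    stride_b = max(1, lb // 25)
    starts_a = np.arange(0, la - frag + 1, stride_a)
    starts_b = np.arange(0, lb - frag + 1, stride_b)
    wa = np.stack([a[s : s + frag] for s in starts_a])
    wb = np.stack([b[s : s + frag] for s in starts_b])
    wa = wa - wa.mean(axis=1, keepdims=True)
    wb = wb - wb.mean(axis=1, keepdims=True)
    ssa = np.sum(wa**2, axis=(1, 2))
    ssb = np.sum(wb**2, axis=(1, 2))
    cov = np.einsum("aik,bil->abkl", wa, wb)
    s = np.linalg.svd(cov, compute_uv=False)
    det = np.linalg.det(cov)
    traced = s[..., 0] + s[..., 1] + np.where(det >= 0, s[..., 2], -s[..., 2])
    msd = (ssa[:, None] + ssb[None, :] - 2 * traced) / frag
    ia, ib = np.unravel_index(np.argmin(msd), msd.shape)
    sa, sb = int(starts_a[ia]), int(starts_b[ib])
    idx = np.arange(frag)
    return idx + sa, idx + sb


def align(
    A: DomainStructure,
    B: DomainStructure,
    gap_penalty: float = DEFAULT_GAP_PENALTY,
) -> AlignmentResult:
    """Structurally align two domains and score the best correspondence.

    Seeds (gapless threading offsets, the best-matching 8-residue fragment
    pair, and a secondary-structure-string alignment) are each refined by
    iterating superposition -> TM-score matrix -> sequential DP until the
    pair set repeats or 30 iterations; the candidate maximizing ``tm_sym``
    (evaluated by :func:`tm_score_given_alignment` under both
    normalizations) is reported.
    """
    a, b = A.ca_coords, B.ca_coords
    la, lb = a.shape[0], b.shape[0]
    if la < 5 or lb < 5:
        raise ValueError("structures must have at least 5 residues to align")

    d0_search = max(d0(min(la, lb)), 0.5)
    seeds = _threading_seeds(la, lb)
    frag_seed = _best_fragment_seed(a, b)
    if frag_seed is not None:
        seeds.append(frag_seed)
    ss_a = secondary_structure_states(a)
    ss_b = secondary_structure_states(b)
    S_ss = (np.array(list(ss_a))[:, None] == np.array(list(ss_b))[None, :]).astype(float)
    pi, pj, _ = _semiglobal_dp(S_ss, gap_penalty)
    if len(pi) >= 3:
        seeds.append((pi, pj))

    candidates: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}
    for ai, bi in seeds:
        if len(ai) < 3:
            continue
        pi, pj = np.asarray(ai), np.asarray(bi)
        seen: set[tuple] = set()
        for _ in range(_MAX_REFINE_ITER):
            key = (tuple(pi), tuple(pj))
            if key in seen:
                break
            seen.add(key)
            R, t = _superpose_transform(a[pi], b[pj])
            d2 = cdist(a, b @ R.T + t, metric="sqeuclidean")
            S = 1.0 / (1.0 + d2 / d0_search**2)
            pi, pj, _ = _semiglobal_dp(S, gap_penalty)
            if len(pi) < 3:
                break
        if len(pi) >= 3:
            candidates[(tuple(pi), tuple(pj))] = (pi, pj)

    best: tuple[float, float, float, np.ndarray, np.ndarray] | None = None
    for pi, pj in candidates.values():
        tm_a = tm_score_given_alignment(a[pi], b[pj], la)
        tm_b = tm_score_given_alignment(a[pi], b[pj], lb)
        tm_sym = 0.5 * (tm_a + tm_b)
        if best is None or tm_sym > best[0]:
            best = (tm_sym, tm_a, tm_b, pi, pj)
    if best is None:
        raise ValueError(f"no alignment with >= 3 pairs found for {A.id} vs {B.id}")

    tm_sym, tm_a, tm_b, pi, pj = best
    R, t, _ = kabsch_superpose(a[pi], b[pj])
    d = np.linalg.norm(a[pi] - (b[pj] @ R.T + t), axis=1)
    return AlignmentResult(
        pairs=list(zip(pi.tolist(), pj.tolist())),
        rotation=R,
        translation=t,
        per_pair_distance=d,
        tm_norm_a=tm_a,
        tm_norm_b=tm_b,
        tm_sym=tm_sym,
        distance=1.0 - tm_sym,
    )


def structural_distance(A: DomainStructure, B: DomainStructure) -> float:
    """``1 - tm_sym`` between two domains; symmetric by canonical ordering.

    Arguments are ordered lexicographically by id before aligning, so
    ``structural_distance(A, B) == structural_distance(B, A)`` exactly.
    """
    if B.id < A.id:
        A, B = B, A
    return align(A, B).distance


def distance_matrix(
    domains: Sequence[DomainStructure], parallel_workers: int | None = None
) -> np.ndarray:
    """All-against-all symmetric structural distance matrix.

    Result is identical to serial evaluation regardless of scheduling; the
    optional ``parallel_workers`` only parallelizes the upper-triangle
    pair list (requires joblib).
    """
    n = len(domains)
    if n < 2:
        raise ValueError("need at least 2 domains")
    idx_pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]

    def _one(i: int, j: int) -> float:
        try:
            return structural_distance(domains[i], domains[j])
        except Exception as exc:
            raise RuntimeError(
                f"distance computation failed for pair ({domains[i].id}, {domains[j].id})"
            ) from exc

    if parallel_workers and parallel_workers > 1:
        from joblib import Parallel, delayed

        values = Parallel(n_jobs=parallel_workers)(delayed(_one)(i, j) for i, j in idx_pairs)
    else:
        values = [_one(i, j) for i, j in idx_pairs]

    D = np.zeros((n, n))
    for (i, j), v in zip(idx_pairs, values):
        D[i, j] = D[j, i] = v
    return D


def distance_matrix_between(
    rows: Sequence[DomainStructure], cols: Sequence[DomainStructure]
) -> np.ndarray:
    """Rectangular structural distance matrix between two domain sets."""
    out = np.zeros((len(rows), len(cols)))
    for i, r in enumerate(rows):
        for j, c in enumerate(cols):
            out[i, j] = 0.0 if r.id == c.id else structural_distance(r, c)
    return out
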