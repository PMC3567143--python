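"""The shared-folds overlap statistic and its permutation-test null.

Given a "focus" set of structures (e.g. viral capsid representatives) and
the complementary set, each non-focus domain is summarized by the
structural distance to its nearest neighbor in the focus set.  Domains
closer than a cutoff (default 0.6) are the focus set's structural
"relatives", and the test statistic is the number of distinct SCOP folds
(class.fold) they cover.  Significance is assessed against a null built by
randomly re-partitioning the total set into a pseudo-focus set of the same
size and its complement; null counts exclude "self folds" (folds already
present in the pseudo-focus set) as a conservative lower bound on folds
shared with non-self proteins.  Small observed counts are the alternative
of interest, so the p-value is the left-tail fraction of null counts at or
below the observed value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np


@dataclass
class SharedFoldResult:
    """Relatives of a focus set and the distinct folds they cover."""

    cutoff: float
    retained_ids: list[str]
    nn_distance: dict[str, float]
    folds: set[str]
    excluded_self_folds: set[str] | None = None

    @property
    def n_relatives(self) -> int:
        return len(self.retained_ids)

    @property
    def n_folds(self) -> int:
        return len(self.folds)


@dataclass
class PermutationResult:
    """Observed shared-fold count against its permutation null.

    ``p_raw`` is the plain left-tail fraction ``#{null <= observed}/n_perm``;
    ``p_conservative`` is ``(b+1)/(n_perm+1)``, never exactly zero.  When no
    null count is as small as the observed value the honest report is the
    upper bound ``p < 1/n_perm``.
    """

    observed: int
    null_counts: np.ndarray
    n_perm: int
    seed: int
    p_raw: float = field(init=False)
    p_conservative: float = field(init=False)

    def __post_init__(self) -> None:
        b = int(np.sum(self.null_counts <= self.observed))
        self.p_raw = b / self.n_perm
        self.p_conservative = (b + 1) / (self.n_perm + 1)

    def report(self) -> str:
        if self.p_raw == 0.0:
            return f"p < {1.0 / self.n_perm:g}"
        return f"p = {self.p_raw:g}"


def nearest_focus_distance(
    focus_ids: Iterable[str],
    other_ids: Iterable[str],
    D: np.ndarray,
    ids: Sequence[str],
) -> dict[str, float]:
    """Map each non-focus id to its minimum distance to any focus id.

    ``ids`` gives the row/column order of ``D``; focus and other sets must
    be disjoint.
    """
    focus = list(focus_ids)
    others = list(other_ids)
    if not focus:
        raise ValueError("focus set must be non-empty")
    overlap = set(focus) & set(others)
    if overlap:
        raise ValueError(f"focus and other sets overlap: {sorted(overlap)[:5]}")
    index_of = {d: i for i, d in enumerate(ids)}
    frow = np.array([index_of[f] for f in focus])
    orow = np.array([index_of[o] for o in others])
    mins = np.asarray(D)[np.ix_(orow, frow)].min(axis=1)
    return {o: float(m) for o, m in zip(others, mins)}


def shared_folds(
    nn: Mapping[str, float],
    fold_labels: Mapping[str, str],
    cutoff: float = 0.6,
    exclude_self: bool = False,
    focus_folds: set[str] | None = None,
) -> SharedFoldResult:
    """Relatives below the cutoff and the distinct folds they cover.

    Ids missing from ``fold_labels`` still count as relatives but
    contribute no fold.  With ``exclude_self`` the folds already present
    in the focus set (``focus_folds``) are removed from the count.
    """
    retained = sorted(i for i, d in nn.items() if d < cutoff)
    folds = {fold_labels[i] for i in retained if i in fold_labels}
    excluded: set[str] | None = None
    if exclude_self:
        if focus_folds is None:
            raise ValueError("exclude_self requires focus_folds")
        excluded = folds & focus_folds
        folds -= focus_folds
    return SharedFoldResult(
        cutoff=cutoff,
        retained_ids=retained,
        nn_distance={i: float(nn[i]) for i in retained},
        folds=folds,
        excluded_self_folds=excluded,
    )


def nn_ecdf(nn: Mapping[str, float]) -> list[tuple[float, float]]:
    """Right-continuous ECDF of nearest-neighbor distances.

    Returns sorted (distance, cumulative fraction) pairs, one per distinct
    distance, ending at fraction 1.
    """
    if not nn:
        raise ValueError("empty nearest-neighbor map")
    values = np.sort(np.array(list(nn.values()), dtype=float))
    distinct, counts = np.unique(values, return_counts=True)
    cum = np.cumsum(counts) / len(values)
    return list(zip(distinct.tolist(), cum.tolist()))


def permutation_test(
    all_ids: Sequence[str],
    fold_labels: Mapping[str, str],
    D: np.ndarray,
    focus_size: int,
    observed: int,
    n_perm: int = 10_000,
    cutoff: float = 0.6,
    seed: int = 0,
) -> PermutationResult:
    """Left-tailed permutation null for the shared-fold count.

    Each of ``n_perm`` independent permutations draws a pseudo-focus set A
    of ``focus_size`` ids uniformly without replacement from ``all_ids``,
    computes the shared-fold count of the complement B against A at
    ``cutoff`` with self-fold exclusion, and compares the observed count
    against the resulting null with the "<=" (left-tail) convention.
    """
    n = len(all_ids)
    if focus_size >= n:
        raise ValueError("focus_size must be smaller than the population")
    D = np.asarray(D, dtype=float)
    if D.shape != (n, n):
        raise ValueError("D must cover all ids")

    # integer fold codes; -1 = unlabeled (contributes no fold)
    fold_names = sorted({fold_labels[i] for i in all_ids if i in fold_labels})
    code_of = {f: k for k, f in enumerate(fold_names)}
    codes = np.array([code_of.get(fold_labels.get(i, None), -1) for i in all_ids])

    rng = np.random.default_rng(seed)
    null_counts = np.empty(n_perm, dtype=np.int64)
    idx = np.arange(n)
    for p in range(n_perm):
        a_idx = rng.choice(idx, size=focus_size, replace=False)
        mask = np.zeros(n, dtype=bool)
        mask[a_idx] = True
        b_idx = idx[~mask]
        nn = D[np.ix_(b_idx, a_idx)].min(axis=1)
        retained_codes = codes[b_idx[nn < cutoff]]
        retained_codes = retained_codes[retained_codes >= 0]
        self_codes = np.unique(codes[a_idx])
        shared = np.setdiff1d(np.unique(retained_codes), self_codes, assume_unique=True)
        null_counts[p] = len(shared)

    return PermutationResult(
        observed=observed, null_counts=null_counts, n_perm=n_perm, seed=seed
    )
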