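"""Sequence-identity redundancy filtering.

Identity between two domain sequences is computed from a global
Needleman-Wunsch alignment (match +1, mismatch 0, linear gap -1, terminal
gaps free) and normalized by the shorter sequence length -- the
conservative convention for domain-level redundancy removal.  A greedy
longest-first pass then retains a subset in which every pair falls below
the identity threshold (default 40%).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from Bio import Align, SeqIO

from foldspace.structures_io import DomainStructure


def read_fasta(path) -> dict[str, str]:
    """Sequences from a FASTA file as ``{record id: sequence}``."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


@dataclass(frozen=True)
class IdentityResult:
    """Pairwise global sequence identity.

    ``identity = matches / min(len_a, len_b)``; ``aligned_length`` counts
    alignment columns with a residue on both sides.
    """

    identity: float
    aligned_length: int
    matches: int


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -1.0
    # terminal gaps free
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    return aligner


def global_identity(seq_a: str, seq_b: str) -> IdentityResult:
    """Global-alignment identity of two sequences, shorter-length denominator."""
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    aligner = _make_aligner()
    alignment = aligner.align(seq_a, seq_b)[0]
    matches = 0
    aligned_length = 0
    for (a0, a1), (b0, b1) in zip(*alignment.aligned):
        aligned_length += a1 - a0
        for x, y in zip(seq_a[a0:a1], seq_b[b0:b1]):
            if x == y:
                matches += 1
    return IdentityResult(
        identity=matches / min(len(seq_a), len(seq_b)),
        aligned_length=aligned_length,
        matches=matches,
    )


def nonredundant_set(
    domains: Sequence[DomainStructure], threshold: float = 0.40
) -> list[str]:
    """Greedy longest-first redundancy culling at an identity threshold.

    Domains are visited by decreasing length (ties: lexicographic id); a
    domain is retained iff its identity to every already-retained domain
    is below ``threshold``.  Returns retained ids in visiting order.
    """
    for d in domains:
        if not d.sequence:
            raise ValueError(f"domain {d.id} has no sequence")
    ordered = sorted(domains, key=lambda d: (-d.length, d.id))
    kept: list[DomainStructure] = []
    for cand in ordered:
        if all(global_identity(cand.sequence, k.sequence).identity < threshold for k in kept):
            kept.append(cand)
    return [d.id for d in kept]


def removal_decisions(
    domains: Sequence[DomainStructure], threshold: float = 0.40
) -> list[tuple[str, str, float]]:
    """(removed_id, culprit_id, identity) rows for the culling pass."""
    ordered = sorted(domains, key=lambda d: (-d.length, d.id))
    kept: list[DomainStructure] = []
    removed: list[tuple[str, str, float]] = []
    for cand in ordered:
        culprit = None
        for k in kept:
            ident = global_identity(cand.sequence, k.sequence).identity
            if ident >= threshold:
                culprit = (cand.id, k.id, ident)
                break
        if culprit is None:
            kept.append(cand)
        else:
            removed.append(culprit)
    return removed
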