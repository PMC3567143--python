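"""Reading and filtering of protein domain structures and fold classifications.

Structures are consumed as CA-only traces parsed from PDB-format text
(fixed-column ``ATOM`` records, first ``MODEL`` only).  Fold labels follow
the SCOP ``sccs`` convention -- a dot-separated string
``class.fold.superfamily.family`` such as ``b.121.1.1`` -- of which the
``class.fold`` prefix (``b.121``) identifies the topology-level fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from Bio.SeqUtils import seq1

logger = logging.getLogger(__name__)


class EmptyChainError(ValueError):
    """No CA atoms were found for the requested chain."""


class PDBFormatError(ValueError):
    """A coordinate field could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


class MalformedSccsError(ValueError):
    """An sccs string does not have at least class and fold fields."""


@dataclass
class DomainStructure:
    """A CA-only coordinate trace of one protein domain.

    Attributes
    ----------
    id : str
        Domain identifier (e.g. an ASTRAL sid such as ``d1tiua_``).
    chain_id : str
        Chain the trace was read from.
    ca_coords : (L, 3) float array
        One CA position per residue, in Angstrom, in file order.
    sequence : str
        One-letter amino-acid sequence of length L; unknown residues are 'X'.
    sccs : str or None
        Optional SCOP classification string.
    """

    id: str
    chain_id: str
    ca_coords: np.ndarray
    sequence: str
    sccs: str | None = None

    def __post_init__(self) -> None:
        self.ca_coords = np.asarray(self.ca_coords, dtype=float)
        if self.ca_coords.ndim != 2 or self.ca_coords.shape[1] != 3:
            raise ValueError("ca_coords must be an (L, 3) array")
        if len(self.sequence) != len(self.ca_coords):
            raise ValueError("sequence length must equal number of CA coordinates")
        if not np.all(np.isfinite(self.ca_coords)):
            raise ValueError("all coordinates must be finite")

    @property
    def length(self) -> int:
        """Number of residues L in the trace."""
        return len(self.sequence)

    def __len__(self) -> int:
        return self.length


@dataclass(frozen=True)
class FoldLabel:
    """A SCOP classification string and its topology-level fold prefix."""

    sccs: str
    fold_id: str = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "fold_id", fold_of(self.sccs))


def fold_of(sccs: str) -> str:
    """Return the ``class.fold`` prefix identifying the SCOP fold.

    >>> fold_of("b.121.1.1")
    'b.121'
    """
    parts = sccs.split(".")
    if len(parts) < 2 or not parts[0] or not parts[1]:
        raise MalformedSccsError(f"sccs {sccs!r} has fewer than 2 dot-separated fields")
    return f"{parts[0]}.{parts[1]}"


def _three_to_one(resname: str) -> str:
    code = seq1(resname.strip().capitalize(), undef_code="X")
    if len(code) != 1 or not code.isalpha():
        return "X"
    return code.upper()


def read_ca_trace(pdb_text: str, chain_id: str, id: str | None = None) -> DomainStructure:
    """Parse a CA trace for one chain from PDB-format text.

    Only the first MODEL is read; HETATM records are ignored; alternate
    locations other than blank or 'A' are dropped; residues lacking a CA
    atom are skipped.  Residues with insertion codes are kept as distinct
    residues.  Ordering follows the file order of ATOM records.
    """
    coords: list[tuple[float, float, float]] = []
    seq_chars: list[str] = []
    seen_res: set[tuple[str, str]] = set()
    in_first_model = True
    saw_model = False

    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        record = line[:6].strip()
        if record == "MODEL":
            if saw_model:
                in_first_model = False
            saw_model = True
            continue
        if record == "ENDMDL":
            in_first_model = False
            continue
        if not in_first_model or record != "ATOM":
            continue
        if len(line) < 54:
            continue
        atom_name = line[12:16].strip()
        if atom_name != "CA":
            continue
        altloc = line[16]
        if altloc not in (" ", "A", ""):
            continue
        if line[21] != chain_id:
            continue
        # resseq + insertion code identifies the residue; duplicates (e.g.
        # a second altloc 'A' CA) are ignored.
        res_key = (line[22:26], line[26:27])
        if res_key in seen_res:
            continue
        seen_res.add(res_key)
        try:
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
        except ValueError as exc:
            raise PDBFormatError(f"unparseable coordinate field: {exc}", lineno) from None
        coords.append((x, y, z))
        seq_chars.append(_three_to_one(line[17:20]))

    if not coords:
        raise EmptyChainError(f"no CA atoms found for chain {chain_id!r}")

    return DomainStructure(
        id=id if id is not None else f"chain_{chain_id}",
        chain_id=chain_id,
        ca_coords=np.array(coords, dtype=float),
        sequence="".join(seq_chars),
    )


def filter_min_length(
    domains: Iterable[DomainStructure], min_len: int = 80
) -> list[DomainStructure]:
    """Keep domains with at least ``min_len`` residues (boundary inclusive)."""
    return [d for d in domains if d.length >= min_len]


def filter_max_length(
    domains: Iterable[DomainStructure], max_len: int = 600
) -> list[DomainStructure]:
    """Drop domains longer than ``max_len`` residues (boundary kept)."""
    return [d for d in domains if d.length <= max_len]


def read_scop_classification(cla_text: str) -> dict[str, FoldLabel]:
    """Parse an ASTRAL ``dir.cla``-style table into ``{sid: FoldLabel}``.

    Expected columns (tab-separated): sid, PDB code, residue description,
    sccs, sunid [...].  Lines starting with '#' are comments.  Rows whose
    sccs is malformed are skipped with a warning; a duplicated sid keeps
    the first occurrence.
    """
    labels: dict[str, FoldLabel] = {}
    for lineno, line in enumerate(cla_text.splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            fields = line.split()
        if len(fields) < 4:
            logger.warning("classification line %d: fewer than 4 columns, skipped", lineno)
            continue
        sid, sccs = fields[0], fields[3]
        if sid in labels:
            logger.warning("classification line %d: duplicate sid %s, keeping first", lineno, sid)
            continue
        try:
            labels[sid] = FoldLabel(sccs=sccs)
        except MalformedSccsError:
            logger.warning("classification line %d: malformed sccs %r, row skipped", lineno, sccs)
    return labels
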