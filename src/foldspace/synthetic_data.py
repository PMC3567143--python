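"""Synthetic inputs with the statistical structure the analysis assumes.

Two levels of realism are provided:

* **Latent fold-family datasets** -- abstract points in a latent Euclidean
  space, grouped into families around random centers, with pairwise
  Euclidean distances squashed to [0, 1) by ``d = e / (e + c)``.  These
  emulate the family structure of a fold-classified domain set (each
  family is one fold) and support a displaced "focus" subset emulating a
  structurally segregated class.  They exercise clustering and the
  shared-folds statistic without the alignment engine.

* **Toy CA-trace structure sets** -- ideal-geometry backbones built from
  secondary-structure templates (helix bundle, beta meander, jelly-roll
  style beta sandwich, and a mixed alpha/beta plait), perturbed by
  coordinate noise and loop-length jitter.  These exercise the TM-score
  alignment engine end to end.

The generators are deterministic under their seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.spatial.distance import squareform, pdist

from foldspace.structures_io import DomainStructure

logger = logging.getLogger(__name__)

TEMPLATE_KINDS = (
    "helix_bundle",
    "beta_meander",
    "sandwich_jellyroll_like",
    "alpha_beta_plait",
)

_AA3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR", "X": "UNK",
}


@dataclass
class LatentConfig:
    """Configuration of a latent fold-family dataset.

    ``squash_scale`` (c) maps Euclidean distances e to ``e/(e+c)``; with
    the defaults, typical within-family distances fall below 0.4 and
    cross-family distances above 0.6, mirroring the empirical fold
    similarity thresholds.  ``focus_families`` (1-based indices) are
    displaced by ``focus_displacement`` along a fixed latent direction to
    emulate a structurally segregated class.
    """

    n_families: int
    members_per_family: int | Sequence[int] = 3
    latent_dim: int = 8
    within_sd: float = 0.1
    center_scale: float = 0.45
    squash_scale: float = 1.0
    focus_families: tuple[int, ...] = ()
    focus_displacement: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ValueError("need at least one family")
        for s in (self.center_scale, self.squash_scale):
            if s <= 0:
                raise ValueError("scales must be positive")
        if self.within_sd < 0 or self.focus_displacement < 0:
            raise ValueError("within_sd and focus_displacement must be non-negative")
        bad = [f for f in self.focus_families if not 1 <= f <= self.n_families]
        if bad:
            raise ValueError(f"focus_families out of range: {bad}")

    @property
    def member_counts(self) -> list[int]:
        if isinstance(self.members_per_family, int):
            return [self.members_per_family] * self.n_families
        counts = list(self.members_per_family)
        if len(counts) != self.n_families:
            raise ValueError("members_per_family list must match n_families")
        return counts


@dataclass
class StructureTemplateConfig:
    """Configuration of a toy CA-trace structure set."""

    template: str
    n_residues: int = 100
    coordinate_noise_sd: float = 0.0
    loop_length_jitter: int = 0
    n_copies: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.template not in TEMPLATE_KINDS:
            raise ValueError(f"template must be one of {TEMPLATE_KINDS}")
        if self.n_residues < 30:
            raise ValueError("n_residues must be >= 30")
        if self.coordinate_noise_sd < 0:
            raise ValueError("noise must be non-negative")


@dataclass
class LatentDataset:
    """A generated latent dataset: ids aligned with the distance matrix rows."""

    ids: list[str]
    D: np.ndarray
    fold_labels: dict[str, str]
    focus_ids: list[str]
    family_of: dict[str, int]
    config: LatentConfig = field(repr=False, default=None)


def generate_latent_dataset(config: LatentConfig) -> LatentDataset:
    """Draw a fold-family dataset and return its squashed distance matrix.

    Family centers are isotropic Gaussian at ``center_scale``; focus-family
    centers are additionally displaced by ``focus_displacement`` along the
    first latent axis; members are centers plus Gaussian(``within_sd``)
    noise.  Pairwise Euclidean distances e become ``d = e/(e+c)`` in
    [0, 1).  Fold label of every member is its family index.
    """
    rng = np.random.default_rng(config.seed)
    counts = config.member_counts
    centers = rng.normal(0.0, config.center_scale, (config.n_families, config.latent_dim))
    shift = np.zeros(config.latent_dim)
    shift[0] = config.focus_displacement
    for f in config.focus_families:
        centers[f - 1] += shift

    ids: list[str] = []
    fold_labels: dict[str, str] = {}
    family_of: dict[str, int] = {}
    focus_ids: list[str] = []
    points = []
    for fam in range(1, config.n_families + 1):
        member_noise = rng.normal(0.0, config.within_sd, (counts[fam - 1], config.latent_dim))
        for m in range(counts[fam - 1]):
            did = f"F{fam:03d}_{m:02d}"
            ids.append(did)
            fold_labels[did] = f"x.{fam}"
            family_of[did] = fam
            points.append(centers[fam - 1] + member_noise[m])
            if fam in config.focus_families:
                focus_ids.append(did)

    e = pdist(np.array(points))
    d = e / (e + config.squash_scale)
    D = squareform(d)
    return LatentDataset(
        ids=ids, D=D, fold_labels=fold_labels, focus_ids=focus_ids,
        family_of=family_of, config=config,
    )


# ---------------------------------------------------------------------------
# toy CA-trace templates


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _perp(u: np.ndarray) -> np.ndarray:
    """A deterministic unit vector perpendicular to u."""
    axis = np.zeros(3)
    axis[int(np.argmin(np.abs(u)))] = 1.0
    w = axis - np.dot(axis, u) * u
    return _unit(w)


def _bridge(p: np.ndarray, q: np.ndarray, n_loop: int) -> list[np.ndarray]:
    """``n_loop`` interior points joining p to q with CA steps in [2.8, 4.2].

    Points sit on a circular arc with equal chords; a straight placement is
    used when the uniform spacing already falls in the allowed band.  The
    loop is lengthened if even 4.0-Angstrom steps cannot span the gap.
    """
    g = float(np.linalg.norm(q - p))
    n_loop = max(n_loop, int(np.ceil(g / 4.0)) - 1)
    n_seg = n_loop + 1
    u = _unit(q - p)
    if 2.8 <= g / n_seg <= 4.2:
        return [p + u * g * k / n_seg for k in range(1, n_seg)]
    s_target = 3.5
    # equal chords s on an arc satisfy s/g = sin(theta/2n)/sin(theta/2)
    f = lambda th: np.sin(th / (2 * n_seg)) / np.sin(th / 2) - s_target / g
    theta = brentq(f, 1e-9, 2 * np.pi - 1e-9)
    R = g / (2 * np.sin(theta / 2))
    w = _perp(u)
    center = (p + q) / 2 - w * R * np.cos(theta / 2)
    angles = -theta / 2 + theta * np.arange(1, n_seg) / n_seg
    return [center + R * (np.cos(a) * w + np.sin(a) * u) for a in angles]


def _helix(start: np.ndarray, axis: np.ndarray, n: int) -> np.ndarray:
    """Ideal alpha-helical CA trace: 1.5 A rise, 100 deg twist, 2.3 A radius."""
    axis = _unit(axis)
    e1 = _perp(axis)
    e2 = np.cross(axis, e1)
    i = np.arange(n)
    ang = np.radians(100.0) * i
    return (
        start[None, :]
        + 1.5 * i[:, None] * axis[None, :]
        + 2.3 * (np.cos(ang)[:, None] * e1[None, :] + np.sin(ang)[:, None] * e2[None, :])
    )


def _strand(start: np.ndarray, axis: np.ndarray, n: int) -> np.ndarray:
    """Extended strand CA trace: 3.3 A rise."""
    axis = _unit(axis)
    return start[None, :] + 3.3 * np.arange(n)[:, None] * axis[None, :]


def _template_segments(kind: str) -> tuple[list[tuple[str, np.ndarray, np.ndarray]], int]:
    """Segment plan: list of (segment type, anchor start, axis) and loop length."""
    z = np.array([0.0, 0.0, 1.0])
    up, down = z, -z
    if kind == "helix_bundle":
        h = 1.5 * 20  # nominal bundle height for anchor placement
        segs = [
            ("H", np.array([0.0, 0.0, 0.0]), up),
            ("H", np.array([10.0, 0.0, h]), down),
            ("H", np.array([10.0, 10.0, 0.0]), up),
            ("H", np.array([0.0, 10.0, h]), down),
        ]
        return segs, 3
    if kind == "beta_meander":
        h = 3.3 * 15
        segs = []
        for k in range(5):
            start_z = 0.0 if k % 2 == 0 else h
            segs.append(("E", np.array([4.8 * k, 0.0, start_z]), up if k % 2 == 0 else down))
        return segs, 2
    if kind == "sandwich_jellyroll_like":
        h = 3.3 * 10
        segs = []
        for k in range(8):
            sheet_y = 0.0 if k % 2 == 0 else 9.5
            x = 4.8 * (k // 2)
            start_z = 0.0 if k % 2 == 0 else h
            segs.append(("E", np.array([x, sheet_y, start_z]), up if k % 2 == 0 else down))
        return segs, 3
    if kind == "alpha_beta_plait":
        h = 3.3 * 12
        segs = [
            ("E", np.array([0.0, 0.0, 0.0]), up),
            ("H", np.array([2.4, 8.0, h]), down),
            ("E", np.array([4.8, 0.0, 0.0]), up),
            ("H", np.array([7.2, 8.0, h]), down),
            ("E", np.array([9.6, 0.0, 0.0]), up),
        ]
        return segs, 3
    raise ValueError(f"unknown template kind {kind!r}")


def build_template(
    kind: str, n_residues: int, loop_lengths: Sequence[int] | None = None
) -> tuple[np.ndarray, str]:
    """Ideal-geometry CA trace and pseudo-sequence for one template.

    Residues are split evenly over the template's secondary-structure
    segments after reserving the loop residues; helices use 'A', strands
    'V' and loops 'G' in the pseudo-sequence.
    """
    segs, default_loop = _template_segments(kind)
    n_segs = len(segs)
    if loop_lengths is None:
        loop_lengths = [default_loop] * (n_segs - 1)
    n_loop_total = sum(loop_lengths)
    per_seg = max((n_residues - n_loop_total) // n_segs, 4)
    seg_sizes = [per_seg] * n_segs
    leftover = n_residues - n_loop_total - per_seg * n_segs
    for k in range(max(leftover, 0)):
        seg_sizes[k % n_segs] += 1

    def _assemble(sizes: list[int]) -> tuple[np.ndarray, str]:
        coords: list[np.ndarray] = []
        seq: list[str] = []
        prev_end: np.ndarray | None = None
        for k, (styp, start, axis) in enumerate(segs):
            n_seg_res = sizes[k]
            rise = 1.5 if styp == "H" else 3.3
            start = start.copy()
            if start[2] > 0:  # descending segment: start at its own top
                start[2] = rise * (n_seg_res - 1)
            pts = (
                _helix(start, axis, n_seg_res)
                if styp == "H"
                else _strand(start, axis, n_seg_res)
            )
            if prev_end is not None:
                loop_pts = _bridge(prev_end, pts[0], loop_lengths[k - 1])
                coords.extend(loop_pts)
                seq.extend("G" * len(loop_pts))
            coords.extend(pts)
            seq.extend(("A" if styp == "H" else "V") * n_seg_res)
            prev_end = pts[-1]
        return np.array(coords), "".join(seq)

    # bridges may lengthen loops that span wide gaps; rebalance segment
    # sizes until the assembled chain hits the requested residue count
    coords, seq = _assemble(seg_sizes)
    for _ in range(6):
        diff = len(coords) - n_residues
        if diff == 0 or all(s <= 4 for s in seg_sizes):
            break
        step = -1 if diff > 0 else 1
        for k in range(abs(diff)):
            idx = k % n_segs
            seg_sizes[idx] = max(seg_sizes[idx] + step, 4)
        coords, seq = _assemble(seg_sizes)
    return coords, seq


def generate_toy_structures(config: StructureTemplateConfig) -> list[DomainStructure]:
    """Noisy copies of one structural template.

    Each copy jitters the loop lengths by up to ``loop_length_jitter``
    residues (changing the total length accordingly) and perturbs every
    CA by isotropic Gaussian noise of ``coordinate_noise_sd`` Angstrom.
    """
    rng = np.random.default_rng(config.seed)
    _, default_loop = _template_segments(config.template)
    n_loops = len(_template_segments(config.template)[0]) - 1
    out: list[DomainStructure] = []
    for c in range(config.n_copies):
        if config.loop_length_jitter > 0:
            jit = rng.integers(
                -config.loop_length_jitter, config.loop_length_jitter + 1, n_loops
            )
            loops = [max(1, default_loop + int(j)) for j in jit]
        else:
            loops = None
        coords, seq = build_template(config.template, config.n_residues, loops)
        coords = coords + rng.normal(0.0, config.coordinate_noise_sd, coords.shape)
        out.append(
            DomainStructure(
                id=f"{config.template}_{c:02d}",
                chain_id="A",
                ca_coords=coords,
                sequence=seq,
            )
        )
    return out


def generate_template_dataset(
    kinds: Sequence[str] = TEMPLATE_KINDS,
    n_residues: int = 100,
    coordinate_noise_sd: float = 0.5,
    loop_length_jitter: int = 1,
    n_copies: int = 6,
    seed: int = 0,
) -> tuple[list[DomainStructure], dict[str, str]]:
    """Multi-family structure dataset: ``n_copies`` noisy copies per template.

    Returns the structures and a map id -> template kind (the planted
    family label).
    """
    structures: list[DomainStructure] = []
    labels: dict[str, str] = {}
    for k, kind in enumerate(kinds):
        cfg = StructureTemplateConfig(
            template=kind,
            n_residues=n_residues,
            coordinate_noise_sd=coordinate_noise_sd,
            loop_length_jitter=loop_length_jitter,
            n_copies=n_copies,
            seed=seed + k,
        )
        for s in generate_toy_structures(cfg):
            structures.append(s)
            labels[s.id] = kind
    return structures, labels


def write_pdb(structure: DomainStructure) -> str:
    """Render a DomainStructure as single-model PDB text (CA atoms only).

    The structure id goes into the HEADER idCode field (4 characters;
    longer ids are truncated with a warning).
    """
    id4 = structure.id[:4]
    if len(structure.id) > 4:
        logger.warning("id %r truncated to %r for the PDB HEADER field", structure.id, id4)
    chain = (structure.chain_id or "A")[0]
    lines = [
        f"HEADER    SYNTHETIC CA TRACE                      {id4:>4s}",
        "MODEL        1",
    ]
    for i, (xyz, aa) in enumerate(zip(structure.ca_coords, structure.sequence), start=1):
        res3 = _AA3.get(aa.upper(), "GLY")
        x, y, z = xyz
        lines.append(
            f"ATOM  {i:5d}  CA  {res3:>3s} {chain}{i:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_fold_labels_tsv(dataset: LatentDataset) -> str:
    """TSV text (id, family, is_focus) for a latent dataset."""
    focus = set(dataset.focus_ids)
    rows = ["id\tfamily\tis_focus"]
    for did in dataset.ids:
        rows.append(f"{did}\t{dataset.family_of[did]}\t{int(did in focus)}")
    return "\n".join(rows) + "\n"
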