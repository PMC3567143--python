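"""End-to-end fold-space overlap analysis.

The pipeline mirrors the study design for testing whether a focus class of
protein domains is structurally segregated:

1.  load domains (PDB directory, precomputed distance matrix, or the
    synthetic generator) and fold labels;
2.  length-filter (>= 80 residues; optionally <= 600);
3.  sequence-identity filter the focus set (40%);
4.  average-linkage cluster the focus set at the 0.6 distance criterion
    and keep the cluster medoids as representatives;
5.  compute nearest-focus distances for all non-focus domains and count
    shared folds at each cutoff (0.5 and 0.6 by default);
6.  estimate significance by a left-tailed permutation test with
    self-fold exclusion in the null.

Every stage logs its domain counts and writes its artifact to the output
directory; the JSON summary is byte-reproducible for a fixed config and
seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from foldspace import tm_align
from foldspace.clustering import (
    ClusterPartition,
    average_linkage_tree,
    medoids,
    optimal_partition,
    separation_stats,
    tree_to_newick,
)
from foldspace.fold_statistics import (
    PermutationResult,
    SharedFoldResult,
    nearest_focus_distance,
    nn_ecdf,
    permutation_test,
    shared_folds,
)
from foldspace.redundancy import nonredundant_set
from foldspace.structures_io import (
    DomainStructure,
    filter_max_length,
    filter_min_length,
    read_ca_trace,
    read_scop_classification,
)
from foldspace.synthetic_data import LatentConfig, LatentDataset, generate_latent_dataset

logger = logging.getLogger(__name__)

_STAGE_IDS = {"permutation": 1, "synthetic": 2}


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed derived from the config seed."""
    ss = np.random.SeedSequence((seed, _STAGE_IDS[stage]))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Configuration of a full analysis run.

    Exactly one input mode must be set: ``pdb_dir`` (+ ``classification_file``
    and ``focus_list_file``), ``distance_matrix_file`` (+ ``labels_file``),
    or ``synthetic``.  Thresholds default to the study constants: 80/600
    residue limits, 40% identity, 0.6 clustering criterion, relative
    cutoffs 0.5 and 0.6, 10,000 permutations.
    """

    output_dir: str | Path = "foldspace_run"
    seed: int = 0
    # input modes
    pdb_dir: str | Path | None = None
    classification_file: str | Path | None = None
    focus_list_file: str | Path | None = None
    chain_id: str = "A"
    distance_matrix_file: str | Path | None = None
    labels_file: str | Path | None = None
    synthetic: LatentConfig | None = None
    # analysis parameters
    min_len: int = 80
    max_len: int | None = 600
    identity_threshold: float = 0.40
    cluster_threshold: float = 0.6
    relative_cutoffs: tuple[float, ...] = (0.5, 0.6)
    permutation_cutoff: float = 0.6
    n_perm: int = 10_000
    observed_exclude_self: bool = False
    null_exclude_self: bool = True
    cluster_focus: bool = True

    def __post_init__(self) -> None:
        for t in (self.identity_threshold, self.cluster_threshold, *self.relative_cutoffs):
            if not 0 < t < 1:
                raise ValueError(f"threshold {t} outside (0, 1)")
        if tuple(sorted(self.relative_cutoffs)) != tuple(self.relative_cutoffs):
            raise ValueError("relative_cutoffs must be sorted")
        modes = sum(
            x is not None for x in (self.pdb_dir, self.distance_matrix_file, self.synthetic)
        )
        if modes != 1:
            raise ValueError(
                "exactly one input mode required: pdb_dir, distance_matrix_file or synthetic"
            )


@dataclass
class RunReport:
    """Artifacts and counts of one full analysis run."""

    config: RunConfig
    stage_counts: dict[str, int]
    partition: ClusterPartition | None
    representatives: list[str]
    shared: dict[float, SharedFoldResult]
    permutation: PermutationResult | None
    summary: dict = field(default_factory=dict)


@dataclass
class _Inputs:
    ids: list[str]
    D: np.ndarray
    fold_labels: dict[str, str]
    focus_ids: list[str]
    structures: list[DomainStructure] | None = None


def _load_matrix_inputs(config: RunConfig) -> _Inputs:
    df = pd.read_csv(config.distance_matrix_file, sep="\t", index_col=0)
    ids = [str(c) for c in df.columns]
    D = df.to_numpy(dtype=float)
    labels = pd.read_csv(config.labels_file, sep="\t", dtype=str)
    fold_labels = dict(zip(labels["id"], labels["fold_id"]))
    if "is_focus" in labels.columns:
        focus = labels.loc[labels["is_focus"].astype(int) == 1, "id"].tolist()
    else:
        focus = _read_id_list(config.focus_list_file)
    return _Inputs(ids=ids, D=D, fold_labels=fold_labels, focus_ids=focus)


def _read_id_list(path: str | Path | None) -> list[str]:
    if path is None:
        raise ValueError("a focus-set id list file is required for this input mode")
    text = Path(path).read_text()
    return [line.strip() for line in text.splitlines() if line.strip()]


def _load_pdb_inputs(config: RunConfig) -> tuple[list[DomainStructure], dict[str, str], list[str]]:
    pdb_dir = Path(config.pdb_dir)
    structures = []
    for f in sorted(pdb_dir.glob("*.pdb")):
        s = read_ca_trace(f.read_text(), config.chain_id, id=f.stem)
        structures.append(s)
    if config.classification_file is None:
        raise ValueError("classification_file is required with pdb_dir input")
    cla = read_scop_classification(Path(config.classification_file).read_text())
    fold_labels = {sid: lab.fold_id for sid, lab in cla.items()}
    focus = _read_id_list(config.focus_list_file)
    return structures, fold_labels, focus


def _check_labels(ids: Sequence[str], fold_labels: Mapping[str, str]) -> None:
    missing = [i for i in ids if i not in fold_labels]
    if missing:
        raise ValueError(f"missing fold labels for ids: {missing[:10]}" +
                         (" ..." if len(missing) > 10 else ""))


def run_full_analysis(config: RunConfig) -> RunReport:
    """Execute the complete analysis and write all artifacts.

    Returns a :class:`RunReport`; the JSON summary written to the output
    directory is byte-identical across reruns with the same config and
    seed.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    if config.synthetic is not None:
        dataset = generate_latent_dataset(config.synthetic)
        inputs = _Inputs(
            ids=dataset.ids, D=dataset.D, fold_labels=dataset.fold_labels,
            focus_ids=dataset.focus_ids,
        )
        logger.info("stage load: synthetic latent dataset with %d domains", len(dataset.ids))
    elif config.distance_matrix_file is not None:
        inputs = _load_matrix_inputs(config)
        logger.info("stage load: %d domains from precomputed matrix", len(inputs.ids))
    else:
        structures, fold_labels, focus = _load_pdb_inputs(config)
        counts["loaded"] = len(structures)
        logger.info("stage load: %d structures", len(structures))
        structures = filter_min_length(structures, config.min_len)
        counts["after_min_length"] = len(structures)
        logger.info("stage min-length (%d): %d remain", config.min_len, len(structures))
        if config.max_len is not None:
            structures = filter_max_length(structures, config.max_len)
            counts["after_max_length"] = len(structures)
            logger.info("stage max-length (%d): %d remain", config.max_len, len(structures))
        by_id = {s.id: s for s in structures}
        focus = [f for f in focus if f in by_id]
        focus_structs = [by_id[f] for f in focus]
        kept_focus = nonredundant_set(focus_structs, config.identity_threshold)
        counts["focus_after_identity"] = len(kept_focus)
        logger.info(
            "stage identity filter (%.0f%%): focus %d -> %d",
            100 * config.identity_threshold, len(focus), len(kept_focus),
        )
        focus = sorted(kept_focus)
        others = [s for s in structures if s.id not in set(focus)]
        ordered = [by_id[f] for f in focus] + others
        logger.info("stage distances: all-against-all over %d domains", len(ordered))
        D = tm_align.distance_matrix(ordered)
        inputs = _Inputs(
            ids=[s.id for s in ordered], D=D, fold_labels=fold_labels,
            focus_ids=focus, structures=ordered,
        )

    _check_labels([i for i in inputs.ids if i not in set(inputs.focus_ids)], inputs.fold_labels)
    counts["total"] = len(inputs.ids)
    counts["focus"] = len(inputs.focus_ids)
    if not inputs.focus_ids:
        raise ValueError("focus set is empty")

    index_of = {d: i for i, d in enumerate(inputs.ids)}

    # focus-set clustering and medoid reduction
    partition = None
    if config.cluster_focus and len(inputs.focus_ids) >= 2:
        focus_idx = np.array([index_of[f] for f in inputs.focus_ids])
        Df = inputs.D[np.ix_(focus_idx, focus_idx)]
        tree = average_linkage_tree(Df)
        partition = optimal_partition(tree, Df, config.cluster_threshold, inputs.focus_ids)
        representatives = partition.medoid_ids
        sep = separation_stats(partition, Df, inputs.focus_ids)
        logger.info(
            "stage clustering: %d focus domains -> %d clusters (max intra %.3f; "
            "%d inter-cluster pairs < 0.4, fraction %.4f)",
            len(inputs.focus_ids), partition.n_clusters, partition.max_intra,
            sep.count, sep.fraction,
        )
        _write_cluster_tsv(out / "clusters.tsv", partition)
        (out / "focus_tree.nwk").write_text(tree_to_newick(tree, inputs.focus_ids) + "\n")
    else:
        representatives = sorted(inputs.focus_ids)
        logger.info("stage clustering: skipped; %d focus domains used directly",
                    len(representatives))
    counts["representatives"] = len(representatives)

    # nearest-focus distances and shared folds per cutoff
    others = [i for i in inputs.ids if i not in set(inputs.focus_ids)]
    counts["non_focus"] = len(others)
    nn = nearest_focus_distance(representatives, others, inputs.D, inputs.ids)
    _write_ecdf_tsv(out / "nn_ecdf.tsv", nn)
    focus_folds = {
        inputs.fold_labels[f] for f in inputs.focus_ids if f in inputs.fold_labels
    }
    shared: dict[float, SharedFoldResult] = {}
    for cutoff in config.relative_cutoffs:
        res = shared_folds(
            nn, inputs.fold_labels, cutoff,
            exclude_self=config.observed_exclude_self, focus_folds=focus_folds,
        )
        shared[cutoff] = res
        logger.info(
            "stage shared-folds (cutoff %.2f): %d relatives covering %d folds",
            cutoff, res.n_relatives, res.n_folds,
        )
    _write_fold_report(out / "fold_report.tsv", shared[config.relative_cutoffs[-1]],
                       inputs.fold_labels, nn, focus_folds)

    # permutation null over representatives + non-focus domains
    perm = None
    if config.n_perm > 0:
        pop = representatives + others
        pop_idx = np.array([index_of[p] for p in pop])
        Dp = inputs.D[np.ix_(pop_idx, pop_idx)]
        obs_res = shared_folds(
            nn, inputs.fold_labels, config.permutation_cutoff,
            exclude_self=config.observed_exclude_self, focus_folds=focus_folds,
        )
        perm = permutation_test(
            pop, inputs.fold_labels, Dp,
            focus_size=len(representatives),
            observed=obs_res.n_folds,
            n_perm=config.n_perm,
            cutoff=config.permutation_cutoff,
            seed=stage_seed(config.seed, "permutation"),
        )
        logger.info(
            "stage permutation: observed %d shared folds, %d permutations, "
            "p_raw %.4g, p_conservative %.4g (%s)",
            perm.observed, perm.n_perm, perm.p_raw, perm.p_conservative, perm.report(),
        )
        _write_null_tsv(out / "null_distribution.tsv", perm)

    summary = _summarize(config, counts, partition, representatives, shared, perm)
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return RunReport(
        config=config, stage_counts=counts, partition=partition,
        representatives=representatives, shared=shared, permutation=perm,
        summary=summary,
    )


def run_functional_class(config: RunConfig, class_ids: Sequence[str]) -> RunReport:
    """Same analysis with a functional class as the focus set.

    Class members are used directly (no structural clustering step) unless
    ``config.cluster_focus`` is explicitly enabled.
    """
    if not class_ids:
        raise ValueError("class id list is empty")
    from dataclasses import replace

    cfg = replace(config, cluster_focus=False)
    if cfg.synthetic is not None:
        dataset = generate_latent_dataset(cfg.synthetic)
        missing = [c for c in class_ids if c not in set(dataset.ids)]
        if missing:
            raise ValueError(f"class ids not in dataset: {missing[:10]}")
        dataset.focus_ids = list(class_ids)
        return _run_on_dataset(cfg, dataset)
    cfg = replace(cfg, focus_list_file=None)
    inputs = _load_matrix_inputs(cfg) if cfg.distance_matrix_file else None
    if inputs is None:
        raise ValueError("class-test requires a matrix or synthetic input mode")
    missing = [c for c in class_ids if c not in set(inputs.ids)]
    if missing:
        raise ValueError(f"class ids not in dataset: {missing[:10]}")
    inputs.focus_ids = list(class_ids)
    dataset = LatentDataset(
        ids=inputs.ids, D=inputs.D, fold_labels=inputs.fold_labels,
        focus_ids=inputs.focus_ids, family_of={}, config=None,
    )
    return _run_on_dataset(cfg, dataset)


def _run_on_dataset(config: RunConfig, dataset: LatentDataset) -> RunReport:
    from dataclasses import replace

    # route through the matrix input mode by writing the dataset out
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix_path = out / "_input_matrix.tsv"
    labels_path = out / "_input_labels.tsv"
    write_distance_tsv(matrix_path, dataset.D, dataset.ids)
    focus = set(dataset.focus_ids)
    rows = ["id\tfold_id\tis_focus"]
    for i in dataset.ids:
        rows.append(f"{i}\t{dataset.fold_labels.get(i, '')}\t{int(i in focus)}")
    labels_path.write_text("\n".join(rows) + "\n")
    cfg = replace(
        config, synthetic=None, pdb_dir=None,
        distance_matrix_file=matrix_path, labels_file=labels_path,
    )
    return run_full_analysis(cfg)


# ---------------------------------------------------------------------------
# artifact writers


def write_distance_tsv(path: str | Path, D: np.ndarray, ids: Sequence[str]) -> None:
    """Square distance matrix as TSV with an id header row/column."""
    pd.DataFrame(np.asarray(D), index=list(ids), columns=list(ids)).to_csv(path, sep="\t")


def write_distance_long_tsv(
    path: str | Path, results: Mapping[tuple[str, str], "tm_align.AlignmentResult"]
) -> None:
    """Long-format pairwise TSV: id_a, id_b, tm_a, tm_b, tm_sym, distance."""
    rows = []
    for (a, b), r in sorted(results.items()):
        rows.append((a, b, r.tm_norm_a, r.tm_norm_b, r.tm_sym, r.distance))
    pd.DataFrame(
        rows, columns=["id_a", "id_b", "tm_a", "tm_b", "tm_sym", "distance"]
    ).to_csv(path, sep="\t", index=False)


def _write_cluster_tsv(path: Path, partition: ClusterPartition) -> None:
    med = set(partition.medoid_ids)
    rows = ["id\tcluster\tis_medoid"]
    for did in sorted(partition.labels):
        rows.append(f"{did}\t{partition.labels[did]}\t{int(did in med)}")
    path.write_text("\n".join(rows) + "\n")


def _write_ecdf_tsv(path: Path, nn: Mapping[str, float]) -> None:
    rows = ["distance\tcumulative_fraction"]
    for d, f in nn_ecdf(nn):
        rows.append(f"{d:.6f}\t{f:.6f}")
    path.write_text("\n".join(rows) + "\n")


def _write_null_tsv(path: Path, perm: PermutationResult) -> None:
    values, cnt = np.unique(perm.null_counts, return_counts=True)
    rows = ["shared_folds\tcount"]
    for v, c in zip(values, cnt):
        rows.append(f"{v}\t{c}")
    path.write_text("\n".join(rows) + "\n")


def _write_fold_report(
    path: Path,
    res: SharedFoldResult,
    fold_labels: Mapping[str, str],
    nn: Mapping[str, float],
    focus_folds: set[str],
) -> None:
    per_fold: dict[str, list[str]] = {}
    for rid in res.retained_ids:
        f = fold_labels.get(rid)
        if f is not None:
            per_fold.setdefault(f, []).append(rid)
    rows = ["fold_id\tn_relatives\tmin_distance\tcontains_focus"]
    for f in sorted(per_fold):
        dmin = min(nn[r] for r in per_fold[f])
        rows.append(f"{f}\t{len(per_fold[f])}\t{dmin:.6f}\t{int(f in focus_folds)}")
    path.write_text("\n".join(rows) + "\n")


def _summarize(
    config: RunConfig,
    counts: dict[str, int],
    partition: ClusterPartition | None,
    representatives: list[str],
    shared: dict[float, SharedFoldResult],
    perm: PermutationResult | None,
) -> dict:
    summary: dict = {
        "seed": config.seed,
        "stage_counts": counts,
        "n_representatives": len(representatives),
        "cluster_threshold": config.cluster_threshold,
        "shared_folds": {
            f"{cutoff:g}": {"n_relatives": r.n_relatives, "n_folds": r.n_folds}
            for cutoff, r in shared.items()
        },
    }
    if partition is not None:
        summary["n_clusters"] = partition.n_clusters
        summary["max_intra_cluster_distance"] = round(partition.max_intra, 6)
    if perm is not None:
        summary["permutation"] = {
            "observed": perm.observed,
            "n_perm": perm.n_perm,
            "cutoff": config.permutation_cutoff,
            "p_raw": perm.p_raw,
            "p_conservative": round(perm.p_conservative, 8),
            "report": perm.report(),
        }
    return summary
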