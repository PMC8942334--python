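"""End-to-end orchestration: pairwise matrix → distances → trees → consensus.

A run takes a labelled set of Cα traces, aligns every unordered pair once
per alignment method (rigid, flexible), mirrors the scores into symmetric
similarity matrices, transforms them to distances, infers trees by each
configured distance method, midpoint-roots them, and amalgamates all trees
into a majority-rule consensus.  A Fitch–Margoliash tree of the mean
similarity across alignment methods (the "radial" tree) is produced as
well.  Outputs are deterministic for a fixed config and seed.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import skbio

from . import distphylo
from .align3d import (
    AlignParams,
    NullCalibration,
    StructAlignment,
    flexible_align,
    rigid_align,
    score_pvalue,
)
from .distphylo import SimilarityMatrix, cap_scores, mean_similarity, sim_to_dist_matrix
from .structio import CaTrace

__all__ = ["RunConfig", "MatrixResult", "TreesResult", "run_matrix", "run_trees"]

ALIGNERS = {"rigid": rigid_align, "flexible": flexible_align}


@dataclass
class RunConfig:
    """Configuration of a full structure-phylogenetics run."""

    structures: dict[str, CaTrace]
    methods: tuple[str, ...] = ("rigid", "flexible")
    tree_methods: tuple[str, ...] = ("upgma", "nj", "fm")
    params: AlignParams = field(default_factory=AlignParams)
    cap: float = 1000.0
    consensus_threshold: float = 0.5
    calibration: NullCalibration | None = None
    outdir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.structures) < 2:
            raise ValueError("need at least 2 structures")
        bad = set(self.methods) - set(ALIGNERS)
        if bad or not self.methods:
            raise ValueError(f"unknown alignment methods {sorted(bad)}")
        if not self.tree_methods:
            raise ValueError("need at least one tree method")


@dataclass
class MatrixResult:
    matrices: dict[str, SimilarityMatrix]
    report: pd.DataFrame           # one row per (pair, method)


@dataclass
class TreesResult:
    trees: dict[tuple[str, str], skbio.TreeNode]   # (align method, tree method)
    consensus: skbio.TreeNode
    radial: skbio.TreeNode                          # FM on mean similarity
    newick: dict[str, str]


def run_matrix(cfg: RunConfig) -> MatrixResult:
    """Align every unordered structure pair once per method and mirror.

    The diagonal holds self-alignment scores.  A pair that fails to align
    is recorded with score 0 and P-value 1 (warning), and the run
    continues.
    """
    labels = list(cfg.structures)
    n = len(labels)
    matrices = {m: np.zeros((n, n)) for m in cfg.methods}
    rows = []
    for m in cfg.methods:
        align = ALIGNERS[m]
        for i in range(n):
            for j in range(i, n):
                A = cfg.structures[labels[i]]
                B = cfg.structures[labels[j]]
                try:
                    aln = align(A, B, cfg.params)
                except Exception as exc:  # noqa: BLE001 - degrade to a warning
                    warnings.warn(f"alignment failed for ({labels[i]}, {labels[j]}): {exc}")
                    aln = StructAlignment.empty()
                p = score_pvalue(aln.raw_score, cfg.calibration) if cfg.calibration else aln.p_value
                matrices[m][i, j] = matrices[m][j, i] = aln.raw_score
                rows.append({
                    "a": labels[i], "b": labels[j], "method": m,
                    "raw_score": aln.raw_score, "rmsd": aln.rmsd,
                    "n_equiv": aln.n_equiv, "n_twists": len(aln.twists),
                    "p_value": p, "seq_identity": aln.seq_identity,
                })
    result = MatrixResult(
        matrices={m: SimilarityMatrix(labels, v) for m, v in matrices.items()},
        report=pd.DataFrame(rows),
    )
    if cfg.outdir:
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        result.report.to_csv(out / "pair_report.tsv", sep="\t", index=False)
        for m, sm in result.matrices.items():
            (out / f"similarity_{m}.tsv").write_text(distphylo.write_matrix(sm))
    return result


TREE_BUILDERS = {
    "upgma": distphylo.upgma,
    "nj": distphylo.neighbor_joining,
    "fm": distphylo.fitch_margoliash,
}


def _infer(matrix: SimilarityMatrix, tree_method: str, cap: float) -> skbio.TreeNode:
    d = sim_to_dist_matrix(cap_scores(matrix, cap), cap)
    tree = TREE_BUILDERS[tree_method](d)
    if tree_method == "upgma":
        return tree  # already rooted and ultrametric
    return distphylo.midpoint_root(tree)


def run_trees(matrices: dict[str, SimilarityMatrix], cfg: RunConfig) -> TreesResult:
    """Infer, root, and amalgamate trees from per-method similarity matrices.

    For each (matrix, tree method) pair: cap → distance transform → infer →
    midpoint-root.  All resulting trees enter the majority-rule consensus;
    a Fitch–Margoliash tree of the mean similarity matrix is produced as
    the radial tree.  Newick text (and a run manifest) are written to
    ``cfg.outdir`` when set.
    """
    if not matrices:
        raise ValueError("need at least one similarity matrix")
    trees: dict[tuple[str, str], skbio.TreeNode] = {}
    for m, sm in matrices.items():
        for tm in cfg.tree_methods:
            trees[(m, tm)] = _infer(sm, tm, cfg.cap)
    all_trees = list(trees.values())
    if len(all_trees) >= 2:
        cons = distphylo.consensus(all_trees, cfg.consensus_threshold)
    else:
        cons = all_trees[0].copy()
    mean_sm = mean_similarity(list(matrices.values()))
    radial = distphylo.midpoint_root(
        distphylo.fitch_margoliash(sim_to_dist_matrix(cap_scores(mean_sm, cfg.cap), cfg.cap))
    )
    newick = {f"{m}_{tm}": distphylo.write_newick(t) for (m, tm), t in trees.items()}
    newick["consensus"] = distphylo.write_newick(cons)
    newick["radial_fm_mean"] = distphylo.write_newick(radial)
    result = TreesResult(trees=trees, consensus=cons, radial=radial, newick=newick)
    if cfg.outdir:
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name, text in newick.items():
            (out / f"tree_{name}.nwk").write_text(text + "\n")
        manifest = {
            "labels": list(next(iter(matrices.values())).labels),
            "methods": list(matrices),
            "tree_methods": list(cfg.tree_methods),
            "cap": cfg.cap,
            "consensus_threshold": cfg.consensus_threshold,
            "seed": cfg.seed,
            "config_hash": _config_hash(cfg),
        }
        (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return result


def _config_hash(cfg: RunConfig) -> str:
    payload = json.dumps({
        "labels": sorted(cfg.structures),
        "methods": cfg.methods,
        "tree_methods": cfg.tree_methods,
        "cap": cfg.cap,
        "threshold": cfg.consensus_threshold,
        "seed": cfg.seed,
        "params": vars(cfg.params),
    }, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
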