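"""The highway recovery sweep: how much horizontal transfer can each
reconstruction method absorb before losing the true topology?

Per grid point h and replicate: simulate the 7-taxon genome set, overwrite
the F ortholog with the Bp sequence in round(G*h) families, drop the donor
Bp, and reconstruct the remaining 6 taxa by (a) supermatrix neighbor
joining on the Kimura-corrected distances of the concatenated alignment and
(b) the embedded-quartet plurality supertree over per-family NJ gene trees.
A replicate "recovers" the true tree when the Robinson-Foulds distance to
the species tree restricted to the six reconstruction taxa is zero; the
diagnostic F-sister-to-B signal is the presence of a (B,F) cherry split.

Each (grid point, replicate) pair draws its own RNG substream from the
master seed, so reruns and parallel execution are byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from rnol.models import SubstitutionModel, jtt_model
from rnol.quartets import (
    embedded_quartet_tally,
    plurality_quartet_map,
    supertree_search,
)
from rnol.reconstruct import (
    concatenate_supermatrix,
    exhaustive_ml_tree,
    gene_tree_set,
    neighbor_joining,
    protein_distance_matrix,
)
from rnol.simulate import (
    ExperimentConfig,
    apply_highway,
    drop_taxon,
    simulate_genome_set,
    true_ingroup_tree,
)
from rnol.tree import Bipartition, PhyloTree, robinson_foulds

__all__ = [
    "METHODS",
    "reconstruct_replicate",
    "run_recovery_sweep",
    "summarize_recovery",
    "recovery_table_tsv",
]

logger = logging.getLogger("rnol.sweep")

METHODS = ("supermatrix-NJ", "quartet-supertree", "supermatrix-ML")
DEFAULT_H_GRID = tuple(round(0.05 * i, 2) for i in range(13))  # 0.00 .. 0.60


def _has_bf_cherry(tree: PhyloTree) -> bool:
    target = frozenset({"B", "F"})
    return any(bp.side_a == target or bp.side_b == target
               for bp in tree.bipartitions())


def reconstruct_replicate(config: ExperimentConfig, h: float,
                          rng: np.random.Generator,
                          methods: Sequence[str],
                          model: Optional[SubstitutionModel] = None,
                          ) -> Dict[str, PhyloTree]:
    """Simulate one replicate at transfer fraction ``h`` and reconstruct it
    with each requested method."""
    model = model or jtt_model()
    gs = simulate_genome_set(config, rng, model=model)
    gs = apply_highway(gs, config.donor, config.recipient, h, rng)
    gs = drop_taxon(gs, config.donor)
    out = {}
    gene_trees = None
    for method in methods:
        if method == "supermatrix-NJ":
            sm = concatenate_supermatrix(gs)
            out[method] = neighbor_joining(protein_distance_matrix(sm.alignment))
        elif method == "supermatrix-ML":
            sm = concatenate_supermatrix(gs)
            out[method] = exhaustive_ml_tree(sm.alignment, model)
        elif method == "quartet-supertree":
            if gene_trees is None:
                gene_trees = gene_tree_set(gs, method="NJ")
            tally = embedded_quartet_tally(gene_trees)
            pmap = plurality_quartet_map(tally)
            out[method] = supertree_search(pmap, mode="exhaustive",
                                           taxa=gs.taxa)
        else:
            raise ValueError("unknown method %r" % method)
    return out


def run_recovery_sweep(config: ExperimentConfig,
                       h_grid: Sequence[float] = DEFAULT_H_GRID,
                       methods: Sequence[str] = ("supermatrix-NJ",
                                                 "quartet-supertree"),
                       model: Optional[SubstitutionModel] = None,
                       ) -> pd.DataFrame:
    """Recovery table over the transfer-fraction grid.

    Returns one row per (h, method) with replicate counts, the count and
    frequency of exact topology recovery, and the count of replicates whose
    reconstruction shows the F-sister-to-B cherry.
    """
    for h in h_grid:
        if not (0.0 <= h <= 1.0):
            raise ValueError("grid value %r outside [0, 1]" % h)
    model = model or jtt_model()
    truth = true_ingroup_tree(config.internal_branch, config.other_branch)
    rows = []
    for gi, h in enumerate(h_grid):
        counts = {m: 0 for m in methods}
        bf = {m: 0 for m in methods}
        for rep in range(config.replicates):
            seed = np.random.SeedSequence(entropy=config.seed,
                                          spawn_key=(gi, rep))
            rng = np.random.default_rng(seed)
            try:
                trees = reconstruct_replicate(config, h, rng, methods, model)
            except Exception as exc:
                raise RuntimeError("replicate failed at h=%g rep=%d: %s"
                                   % (h, rep, exc)) from exc
            for m in methods:
                if robinson_foulds(trees[m], truth) == 0:
                    counts[m] += 1
                if _has_bf_cherry(trees[m]):
                    bf[m] += 1
        for m in methods:
            rows.append({
                "internal_branch": config.internal_branch,
                "h": h,
                "method": m,
                "replicates": config.replicates,
                "recovered": counts[m],
                "recovery_freq": counts[m] / config.replicates,
                "f_sister_b": bf[m],
                "f_sister_b_freq": bf[m] / config.replicates,
            })
        logger.info("h=%.2f done: %s", h,
                    ", ".join("%s %d/%d" % (m, counts[m], config.replicates)
                              for m in methods))
    return pd.DataFrame(rows)


def summarize_recovery(table: pd.DataFrame,
                       majority_cut: float = 0.5) -> pd.DataFrame:
    """Threshold summary per (internal branch, method).

    last_success: largest grid h with recovery frequency > majority_cut.
    first_failure: smallest grid h with recovery frequency <= majority_cut.
    f_sister_b_onset: smallest grid h where the F-B cherry appears in more
    than ``majority_cut`` of replicates.  Missing events report NaN and the
    status column says "none on grid".
    """
    if table.empty:
        raise ValueError("empty recovery table")
    out = []
    for (b, method), grp in table.groupby(["internal_branch", "method"]):
        grp = grp.sort_values("h")
        succ = grp[grp.recovery_freq > majority_cut]["h"]
        fail = grp[grp.recovery_freq <= majority_cut]["h"]
        bf = grp[grp.f_sister_b_freq > majority_cut]["h"]
        out.append({
            "internal_branch": b,
            "method": method,
            "last_success": succ.max() if len(succ) else np.nan,
            "first_failure": fail.min() if len(fail) else np.nan,
            "first_failure_status": "on grid" if len(fail) else "none on grid",
            "f_sister_b_onset": bf.min() if len(bf) else np.nan,
            "f_sister_b_status": "on grid" if len(bf) else "none on grid",
        })
    return pd.DataFrame(out)


def recovery_table_tsv(table: pd.DataFrame, config: ExperimentConfig) -> str:
    header = ("# rnol recovery sweep; seed=%d; b=%g; other_branch=%g; "
              "genes=%d; length=%d; replicates=%d\n"
              % (config.seed, config.internal_branch, config.other_branch,
                 config.gene_count, config.gene_length, config.replicates))
    return header + table.to_csv(sep="\t", index=False)
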