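"""End-to-end evaluation on the synthetic benchmark.

Splits the simulated clade families into reference and held-out query
sets, assigns each query against the reference alignment, and scores
clade accuracy plus agreement between assignment methods.  Used by the
CLI ``benchmark`` subcommand and the acceptance checks.
"""

from __future__ import annotations

import numpy as np

from .classify import assign_clade
from .phylo import Alignment, distance_matrix, load_jtt
from .synthetic_data import SyntheticConfig, make_clade_benchmark

__all__ = ["holdout_knn_accuracy"]


def holdout_knn_accuracy(
    seed: int = 7,
    k: int = 5,
    holdout: float = 0.2,
    config: SyntheticConfig | None = None,
    compare_placement: bool = True,
) -> dict:
    """Hold out a fraction of each clade family as queries; score knn.

    The held-out members (every round(1/holdout)-th leaf of each family,
    deterministic in the member order) are stripped from the alignment and
    re-assigned with knn (and optionally NJ placement) against the rest.
    Decoys are never part of reference or query sets.
    """
    cfg = config or SyntheticConfig()
    bench = make_clade_benchmark(cfg, seed=seed)
    member_ids = [sid for sid in bench.alignment.ids if bench.truth[sid] != "decoy"]

    stride = max(2, round(1.0 / holdout))
    query_ids = set()
    for clade in sorted({bench.truth[s] for s in member_ids}):
        fam = [s for s in member_ids if bench.truth[s] == clade]
        query_ids.update(fam[::stride])

    ref_ids = [s for s in member_ids if s not in query_ids]
    ref_aln = Alignment(
        ids=tuple(ref_ids),
        rows=tuple(bench.alignment.row(s) for s in ref_ids),
    )
    clade_of = {s: bench.truth[s] for s in ref_ids}
    model = load_jtt()
    ref_dm = distance_matrix(ref_aln, model) if compare_placement else None

    n_correct = 0
    n_agree = 0
    records = []
    for qid in sorted(query_ids):
        qrow = bench.alignment.row(qid)
        knn = assign_clade(
            (qid, qrow), ref_aln, clade_of, method="knn", k=k,
            model=model, prealigned=True,
        )
        correct = knn.clade == bench.truth[qid]
        n_correct += correct
        rec = {
            "query": qid,
            "truth": bench.truth[qid],
            "knn": knn.clade,
            "knn_confidence": round(knn.confidence, 6),
        }
        if compare_placement:
            placed = assign_clade(
                (qid, qrow), ref_aln, clade_of, method="placement",
                model=model, ref_dm=ref_dm, prealigned=True,
            )
            rec["placement"] = placed.clade
            n_agree += placed.clade == knn.clade
        records.append(rec)

    n = len(records)
    out = {
        "seed": seed,
        "k": k,
        "n_queries": n,
        "n_references": len(ref_ids),
        "knn_accuracy": n_correct / n if n else float("nan"),
        "queries": records,
    }
    if compare_placement:
        out["placement_knn_agreement"] = n_agree / n if n else float("nan")
    return out
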