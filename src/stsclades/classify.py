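"""Clade assignment, cyclization-mechanism annotation and product
prediction for query sesquiterpene synthases.

Mushroom STSs fall into four sequence clades, each tied to one initial
cyclization chemistry: clade I performs 1,10-cyclization of (2E,6E)-FPP via
the (E,E)-germacradienyl cation, clade II 1,10-cyclization of the FPP
isomer (3R)-NPP via the (Z,E)-germacradienyl cation, clade III
1,11-cyclization of (2E,6E)-FPP via the trans-humulyl cation, and clade IV
1,6-cyclization of (3R)-NPP via the (6R)-beta-bisabolol cation.  Placing an
uncharacterized sequence into a clade therefore predicts its cyclization
route, and its nearest characterized neighbors suggest a product profile.

Queries are mapped into the reference alignment's coordinate frame by
affine-gap pairwise alignment against the alignment's majority-rule
consensus (users may instead supply pre-aligned queries), distances are
computed with pairwise deletion, and clades are assigned by nearest
neighbor, k-nearest majority vote, or neighbor-joining placement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np

from .motif_scan import ProteinSequence
from .phylo import (
    Alignment,
    DistanceMatrix,
    ModelChoice,
    SubstitutionModel,
    bipartitions,
    distance_matrix,
    jtt_ml_distance,
    load_jtt,
    nj_tree,
    p_distance,
    pairwise_sites,
    poisson_distance,
)
from .reference_db import CLADES, ReferenceDB

__all__ = [
    "MechanismAnnotation",
    "CladeAssignment",
    "PredictionReport",
    "mechanism_for_clade",
    "MECHANISMS",
    "align_query_to_reference",
    "assign_clade",
    "predict_products",
]


@dataclass(frozen=True)
class MechanismAnnotation:
    """The (substrate, ring closure, carbocation intermediate) triple of a
    clade's initial cyclization reaction."""

    clade: str
    substrate: str
    ring_closure: str
    intermediate: str


MECHANISMS: dict[str, MechanismAnnotation] = {
    "I": MechanismAnnotation(
        "I", "(2E,6E)-FPP", "1,10", "(E,E)-germacradienyl cation"
    ),
    "II": MechanismAnnotation(
        "II", "(3R)-NPP", "1,10", "(Z,E)-germacradienyl cation"
    ),
    "III": MechanismAnnotation(
        "III", "(2E,6E)-FPP", "1,11", "trans-humulyl cation"
    ),
    "IV": MechanismAnnotation(
        "IV", "(3R)-NPP", "1,6", "(6R)-beta-bisabolol cation"
    ),
}


def mechanism_for_clade(clade: str) -> MechanismAnnotation:
    """Total constant map clade -> cyclization mechanism."""
    try:
        return MECHANISMS[clade]
    except KeyError:
        raise ValueError(f"unknown clade label {clade!r}") from None


@dataclass(frozen=True)
class CladeAssignment:
    query_id: str
    clade: str
    method: Literal["nn", "knn", "placement"]
    neighbors: tuple[tuple[str, float], ...]  # (reference gene, distance), ascending
    confidence: float

    def __post_init__(self) -> None:
        dists = [d for _, d in self.neighbors]
        if any(b < a - 1e-12 for a, b in zip(dists, dists[1:])):
            raise ValueError("neighbors must be sorted ascending by distance")

    @property
    def mechanism(self) -> MechanismAnnotation:
        return mechanism_for_clade(self.clade)


@dataclass(frozen=True)
class PredictionReport:
    query_id: str
    clade: str
    mechanism: MechanismAnnotation
    candidates: tuple[tuple[str, int], ...]  # (normalized product, neighbor count)
    no_product_data: bool = False


def consensus_sequence(aln: Alignment) -> str:
    """Majority-rule consensus over non-gap residues, column by column.

    Columns that are all-gap yield 'X'.  Ties go to the alphabetically
    smallest residue (deterministic).
    """
    cols = []
    for c in range(aln.length):
        column = [r[c] for r in aln.rows if r[c] not in "-X"]
        if not column:
            cols.append("X")
            continue
        counts: dict[str, int] = {}
        for ch in column:
            counts[ch] = counts.get(ch, 0) + 1
        best = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        cols.append(best)
    return "".join(cols)


def align_query_to_reference(query: ProteinSequence, ref_aln: Alignment) -> str:
    """Map a query into the reference alignment's columns.

    Affine-gap global alignment (BLOSUM62, open -10 / extend -0.5) of the
    query against the reference consensus; query residues land in the
    columns their consensus partners occupy, insertions relative to the
    consensus are dropped, unmatched columns become gaps.
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    consensus = consensus_sequence(ref_aln)
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aligner.mode = "global"
    best = aligner.align(consensus, query.residues)[0]
    row = ["-"] * ref_aln.length
    for (t0, t1), (q0, q1) in zip(*best.aligned):
        for off in range(t1 - t0):
            row[t0 + off] = query.residues[q0 + off]
    return "".join(row)


def _pairwise_dist(a: str, b: str, model) -> float:
    if isinstance(model, SubstitutionModel):
        return jtt_ml_distance(a, b, model)
    if model == "p":
        return p_distance(a, b)
    if model == "poisson":
        return poisson_distance(a, b)
    raise ValueError(f"unknown model {model!r}")


def assign_clade(
    query: ProteinSequence | tuple[str, str],
    ref_aln: Alignment,
    clade_of: Mapping[str, str],
    method: Literal["nn", "knn", "placement"] = "knn",
    k: int = 5,
    model: ModelChoice | SubstitutionModel = "jtt-ml",
    n_boot: int = 0,
    seed: int = 0,
    ref_dm: DistanceMatrix | None = None,
    prealigned: bool = False,
) -> CladeAssignment:
    """Assign a query sequence to one of clades I-IV.

    ``query`` is an ungapped :class:`ProteinSequence` (mapped onto the
    reference frame via the built-in profile alignment) or, with
    ``prealigned=True``, an ``(id, gapped_row)`` pair already in reference
    coordinates.  ``clade_of`` maps reference ids to clade labels.

    Methods: ``nn`` takes the single nearest reference (confidence
    1 - d1/d2, a separation heuristic); ``knn`` the majority of the k
    nearest (ties: smallest mean distance, then lexicographic clade;
    confidence = vote share); ``placement`` grafts the query into a
    neighbor-joining tree of references plus query and reads the majority
    clade of its sister group (confidence = share of ``n_boot`` bootstrap
    placements agreeing; 1.0 when ``n_boot`` is 0).

    ``ref_dm`` may carry precomputed reference-reference distances (used by
    ``placement``) to avoid recomputation across queries.
    """
    if isinstance(model, str) and model == "jtt-ml":
        model = load_jtt()
    if prealigned:
        qid, qrow = query  # type: ignore[misc]
        if len(qrow) != ref_aln.length:
            raise ValueError("prealigned query row length != alignment length")
    else:
        qid, qrow = query.id, align_query_to_reference(query, ref_aln)  # type: ignore[union-attr]

    unknown = [r for r in ref_aln.ids if r not in clade_of]
    if unknown:
        raise ValueError(f"references without clade labels: {unknown[:5]}")

    dists = []
    for rid, rrow in zip(ref_aln.ids, ref_aln.rows):
        d = _pairwise_dist(qrow, rrow, model)
        if not np.isnan(d):
            dists.append((rid, float(d)))
    if not dists:
        raise ValueError(f"{qid}: no comparable sites against any reference")
    neighbors = tuple(sorted(dists, key=lambda t: (t[1], t[0])))

    if method == "nn":
        clade = clade_of[neighbors[0][0]]
        if len(neighbors) > 1 and neighbors[1][1] > 0:
            confidence = max(0.0, min(1.0, 1.0 - neighbors[0][1] / neighbors[1][1]))
        else:
            confidence = 1.0
    elif method == "knn":
        top = neighbors[: max(1, k)]
        votes: dict[str, list[float]] = {}
        for rid, d in top:
            votes.setdefault(clade_of[rid], []).append(d)
        ranked = sorted(
            votes.items(), key=lambda kv: (-len(kv[1]), float(np.mean(kv[1])), kv[0])
        )
        clade = ranked[0][0]
        confidence = len(votes[clade]) / len(top)
    elif method == "placement":
        clade, confidence = _placement(
            qid, qrow, ref_aln, clade_of, model, n_boot, seed, ref_dm
        )
    else:
        raise ValueError(f"unknown method {method!r}")

    return CladeAssignment(
        query_id=qid,
        clade=clade,
        method=method,
        neighbors=neighbors,
        confidence=confidence,
    )


def _joint_matrix(
    qid: str,
    qrow: str,
    ref_aln: Alignment,
    model,
    ref_dm: DistanceMatrix | None,
    columns: Sequence[int] | None = None,
) -> DistanceMatrix:
    """Distance matrix of references plus the query row."""
    ids = ref_aln.ids + (qid,)
    rows = ref_aln.rows + (qrow,)
    aln = Alignment(ids=ids, rows=rows)
    if columns is not None:
        aln = aln.select_columns(columns)
        return distance_matrix(aln, model)
    if ref_dm is not None and columns is None:
        n = len(ids)
        values = np.zeros((n, n))
        counts = np.zeros((n, n), dtype=int)
        values[: n - 1, : n - 1] = ref_dm.values
        counts[: n - 1, : n - 1] = ref_dm.n_sites
        for i, rrow in enumerate(ref_aln.rows):
            values[i, -1] = values[-1, i] = _pairwise_dist(qrow, rrow, model)
            counts[i, -1] = counts[-1, i] = pairwise_sites(qrow, rrow).size
        return DistanceMatrix(labels=ids, values=values, n_sites=counts)
    return distance_matrix(aln, model)


def _sister_clade(tree, qid: str, clade_of: Mapping[str, str]) -> str:
    """Majority clade among the query's sister-group leaves.

    The NJ tree is unrooted (displayed with an arbitrary trifurcating
    root), so the query's attachment node has two directions besides the
    query edge: its other child subtree(s) and the rest of the tree through
    the parent edge.  The sister group is the direction holding fewer
    leaves — the query's local cluster rather than the tree remainder.
    Ties go to the lexicographically smaller leaf set, then majority ties
    to the lexicographically smallest clade label.
    """
    all_leaves = {t.name for t in tree.tips()}
    query_tip = next(t for t in tree.tips() if t.name == qid)
    attach = query_tip.parent
    directions: list[set[str]] = []
    for child in attach.children:
        if child is query_tip:
            continue
        directions.append(
            {t.name for t in child.tips()} if child.children else {child.name}
        )
    below = {t.name for t in attach.tips()}
    up = all_leaves - below
    if up:
        directions.append(up)
    directions = [d - {qid} for d in directions if d - {qid}]
    sister = min(directions, key=lambda d: (len(d), tuple(sorted(d))))
    counts: dict[str, int] = {}
    for n in sister:
        c = clade_of[n]
        counts[c] = counts.get(c, 0) + 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]


def _placement(
    qid: str,
    qrow: str,
    ref_aln: Alignment,
    clade_of: Mapping[str, str],
    model,
    n_boot: int,
    seed: int,
    ref_dm: DistanceMatrix | None,
) -> tuple[str, float]:
    dm = _joint_matrix(qid, qrow, ref_aln, model, ref_dm)
    clade = _sister_clade(nj_tree(dm), qid, clade_of)
    if n_boot <= 0:
        return clade, 1.0
    agree = 0
    completed = 0
    for r in range(n_boot):
        rng = np.random.default_rng([seed, r])
        cols = rng.integers(0, ref_aln.length, size=ref_aln.length)
        try:
            rep_dm = _joint_matrix(qid, qrow, ref_aln, model, None, columns=cols)
            rep_clade = _sister_clade(nj_tree(rep_dm), qid, clade_of)
        except Exception:
            continue
        completed += 1
        if rep_clade == clade:
            agree += 1
    return clade, (agree / completed if completed else float("nan"))


def predict_products(
    assignment: CladeAssignment,
    db: ReferenceDB,
    k: int = 5,
    include_minor: bool = False,
) -> PredictionReport:
    """Rank candidate products from the k nearest references' major products.

    References with no detected or only unidentified products are skipped.
    With ``include_minor`` the neighbors' side products are counted too.
    Candidates are ranked by supporting-neighbor count, then alphabetically.
    """
    if not assignment.neighbors:
        raise ValueError("assignment has no neighbors")
    counts: dict[str, int] = {}
    informative = 0
    for rid, _ in assignment.neighbors[: max(1, k)]:
        try:
            entry = db.get(rid)
        except KeyError:
            continue
        major = entry.major_product
        if major is None:  # ND, blank, or unidentified first product
            continue
        informative += 1
        names = (
            [major.name]
            if not include_minor
            else [p.name for p in entry.products if p.flag == "normal"]
        )
        for name in dict.fromkeys(names):
            counts[name] = counts.get(name, 0) + 1
    ranked = tuple(
        sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    )
    return PredictionReport(
        query_id=assignment.query_id,
        clade=assignment.clade,
        mechanism=assignment.mechanism,
        candidates=ranked,
        no_product_data=(informative == 0),
    )
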