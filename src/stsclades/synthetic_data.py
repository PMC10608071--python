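"""Synthetic four-clade benchmark generator.

The reference dataset cannot ship sequence data, so tests and benchmarks
run on simulated families with the same statistical structure the analysis
assumes: four deeply diverged clades (one per cyclization class), each
expanded on its own random tree under the packaged JTT substitution model,
with clade-appropriate aspartate-rich and NSE motif strings planted at
realistic offsets and held invariant during evolution.  Decoy proteins
drawn i.i.d. from the JTT stationary frequencies (rejection-sampled to be
motif-free, so truth labels are unambiguous for the candidate screen) and
a truth table accompany the families.

Everything is deterministic under (config, seed): one integer seed feeds
``numpy.random.default_rng`` substreams derived per component, so outputs
are byte-identical across runs and platforms.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from skbio import TreeNode

from .motif_scan import BUILTIN_PATTERNS, ProteinSequence, compile_pattern, scan
from .phylo import AA_ORDER, Alignment, SubstitutionModel, load_jtt, newick_write
from .reference_db import ReferenceDB, load_reference

__all__ = [
    "SyntheticConfig",
    "SyntheticBenchmark",
    "make_model_tree",
    "evolve_sequences",
    "make_clade_benchmark",
]

CLADES = ("I", "II", "III", "IV")


@dataclass(frozen=True)
class MotifPlan:
    """Where and what to plant: motif strings and their offset windows."""

    aspartate_variants: tuple[str, ...]
    nse_variants: tuple[str, ...]
    aspartate_window: tuple[int, int] = (90, 110)
    nse_window: tuple[int, int] = (215, 240)


@dataclass(frozen=True)
class SyntheticConfig:
    """Benchmark shape. Defaults mirror the reference dataset's scale:
    dozens of ~350-residue enzymes per clade, deep inter-clade divergence
    (1 expected substitution/site on the backbone) over shallow intra-clade
    radiation (mean branch 0.08)."""

    family_size: int = 12
    sequence_length: int = 350
    interclade_divergence: float = 1.0
    intraclade_branch_mean: float = 0.08
    n_decoys: int = 20
    with_indels: bool = False
    indel_columns_per_family: int = 12

    def __post_init__(self) -> None:
        if self.family_size < 0 or self.n_decoys < 0:
            raise ValueError("sizes must be >= 0")
        if self.interclade_divergence <= 0 or self.intraclade_branch_mean <= 0:
            raise ValueError("divergences must be > 0")


@dataclass
class SyntheticBenchmark:
    alignment: Alignment
    sequences: list[ProteinSequence]  # ungapped
    truth: dict[str, str]  # id -> clade label or "decoy"
    trees: dict[str, str]  # clade -> newick of the generating family tree
    config: SyntheticConfig
    seed: int

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "sequences.fasta", "w") as fh:
            for s in self.sequences:
                fh.write(f">{s.id}\n{s.residues}\n")
        self.alignment.to_fasta(out / "alignment.fasta")
        with open(out / "truth.tsv", "w") as fh:
            fh.write("id\tlabel\n")
            for sid in self.alignment.ids:
                fh.write(f"{sid}\t{self.truth[sid]}\n")
        for clade, nwk in self.trees.items():
            (out / f"tree_clade_{clade}.nwk").write_text(nwk)
        echo = asdict(self.config) | {"seed": self.seed}
        (out / "config.json").write_text(json.dumps(echo, indent=2) + "\n")


def make_model_tree(n_leaves: int, branch_mean: float, seed) -> TreeNode:
    """Random bifurcating tree with exponential branch lengths.

    Topology: repeated uniform-random joining of two active lineages
    (yields a uniform draw over labeled rooted topologies); every edge gets
    an independent Exp(branch_mean) length.  Leaves are named t1..tN.
    Deterministic per seed.
    """
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    rng = np.random.default_rng(seed)
    active = [TreeNode(name=f"t{i + 1}") for i in range(n_leaves)]
    for node in active:
        node.length = float(rng.exponential(branch_mean))
    while len(active) > 2:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        parent = TreeNode()
        parent.extend([active[i], active[j]])
        parent.length = float(rng.exponential(branch_mean))
        active = [a for k, a in enumerate(active) if k not in (i, j)] + [parent]
    root = TreeNode()
    root.extend(active)
    return root


def _sample_transitions(
    states: np.ndarray, P: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One categorical draw per site from the row of P its state selects."""
    cdf = np.cumsum(P, axis=1)
    u = rng.random(states.size)
    return (u[:, None] > cdf[states]).sum(axis=1).astype(states.dtype)


def evolve_sequences(
    tree: TreeNode,
    root_seq: str,
    model: SubstitutionModel,
    seed,
    invariant_sites: Iterable[int] = (),
) -> dict[str, str]:
    """Simulate a site-independent CTMC along the tree; returns leaf seqs.

    Sites in ``invariant_sites`` are copied unchanged down every branch
    (used to hold planted motifs fixed).
    """
    rng = np.random.default_rng(seed)
    aa = np.array(list(AA_ORDER))
    idx = {a: i for i, a in enumerate(AA_ORDER)}
    root_states = np.array([idx[c] for c in root_seq], dtype=np.int64)
    frozen = np.zeros(root_states.size, dtype=bool)
    frozen[list(invariant_sites)] = True

    leaves: dict[str, str] = {}

    def descend(node: TreeNode, states: np.ndarray) -> None:
        for child in node.children:
            t = child.length or 0.0
            if t > 0:
                P = model.transition_matrix(t)
                new = _sample_transitions(states, P, rng)
                new[frozen] = states[frozen]
            else:
                new = states.copy()
            if child.children:
                descend(child, new)
            else:
                leaves[child.name] = "".join(aa[new])

    descend(tree, root_states)
    return leaves


def _clade_motif_plans(db: ReferenceDB) -> dict[str, MotifPlan]:
    """Motif plans anchored to the reference motif strings of each clade.

    Clades I-III plant DExxD-family aspartate strings; clade IV plants its
    characteristic DD(N)xxD-family strings and TRI5-like NSE strings, as in
    the curated table.
    """
    from .motif_scan import classify_motif1

    plans = {}
    nse = BUILTIN_PATTERNS["NSE"]
    for clade in CLADES:
        members = [e for e in db.entries if e.clade == clade]
        wanted = "DD(N)xxD" if clade == "IV" else "DExxD"
        asp = sorted(
            {e.motif1 for e in members if e.motif1 and classify_motif1(e.motif1) == wanted}
        )
        nse_strings = sorted(
            {
                e.motif2
                for e in members
                if e.motif2 and len(e.motif2) == 9 and nse.matches_at(e.motif2, 0)
            }
        )
        plans[clade] = MotifPlan(
            aspartate_variants=tuple(asp), nse_variants=tuple(nse_strings)
        )
    return plans


def _stationary_seq(length: int, model: SubstitutionModel, rng) -> str:
    aa = np.array(list(AA_ORDER))
    states = rng.choice(20, size=length, p=model.freqs)
    return "".join(aa[states])


def _motif_free_decoy(length: int, model: SubstitutionModel, rng) -> str:
    """Stationary-frequency sequence rejected until no catalytic-motif hit."""
    asp = BUILTIN_PATTERNS["aspartate-rich"]
    nse = BUILTIN_PATTERNS["NSE"]
    for _ in range(1000):
        s = _stationary_seq(length, model, rng)
        seq = ProteinSequence(id="tmp", residues=s)
        if not scan(seq, asp) and not scan(seq, nse):
            return s
    raise RuntimeError("could not sample a motif-free decoy")  # pragma: no cover


def make_clade_benchmark(
    config: SyntheticConfig = SyntheticConfig(),
    seed: int = 7,
    db: ReferenceDB | None = None,
) -> SyntheticBenchmark:
    """Generate the four-clade benchmark.

    A stationary root sequence diverges into four clade ancestors, each a
    CTMC run of length ``interclade_divergence / 2`` from the root (any two
    ancestors are thus separated by the configured divergence); each
    ancestor is expanded on its own random family tree; clade motif strings
    (sampled per clade from the packaged reference table) are planted at an
    offset drawn once per clade inside the plan windows and held invariant.
    Decoys are motif-free stationary sequences.
    """
    model = load_jtt()
    if db is None:
        db = load_reference()
    plans = _clade_motif_plans(db)
    L = config.sequence_length

    # check planted windows fit and never overlap
    for clade, plan in plans.items():
        a_hi = plan.aspartate_window[1] + max(map(len, plan.aspartate_variants))
        n_hi = plan.nse_window[1] + max(map(len, plan.nse_variants))
        if a_hi >= plan.nse_window[0]:
            raise ValueError(f"clade {clade}: motif windows overlap")
        if n_hi > L:
            raise ValueError(f"clade {clade}: motif plan exceeds sequence length")

    root_rng = np.random.default_rng([seed, 0])
    root_seq = _stationary_seq(L, model, root_rng)

    ids: list[str] = []
    rows: list[str] = []
    truth: dict[str, str] = {}
    trees: dict[str, str] = {}
    sequences: list[ProteinSequence] = []

    for ci, clade in enumerate(CLADES):
        crng = np.random.default_rng([seed, 1 + ci])
        plan = plans[clade]
        asp = plan.aspartate_variants[crng.integers(len(plan.aspartate_variants))]
        nse = plan.nse_variants[crng.integers(len(plan.nse_variants))]
        asp_off = int(crng.integers(plan.aspartate_window[0], plan.aspartate_window[1] + 1))
        nse_off = int(crng.integers(plan.nse_window[0], plan.nse_window[1] + 1))
        motif_sites = list(range(asp_off, asp_off + len(asp))) + list(
            range(nse_off, nse_off + len(nse))
        )

        # clade ancestor: half the backbone divergence away from the root,
        # so any two ancestors are interclade_divergence apart in expectation
        arng = np.random.default_rng([seed, 10 + ci])
        idx = {a: i for i, a in enumerate(AA_ORDER)}
        anc_states = _sample_transitions(
            np.array([idx[c] for c in root_seq], dtype=np.int64),
            model.transition_matrix(config.interclade_divergence / 2),
            arng,
        )
        ancestor = "".join(np.array(list(AA_ORDER))[anc_states])
        ancestor = (
            ancestor[:asp_off]
            + asp
            + ancestor[asp_off + len(asp) : nse_off]
            + nse
            + ancestor[nse_off + len(nse) :]
        )

        if config.family_size == 0:
            continue
        if config.family_size == 1:
            family = {"t1": ancestor}
            trees[clade] = "(t1:0.0);"
        else:
            ftree = make_model_tree(
                config.family_size, config.intraclade_branch_mean, [seed, 20 + ci]
            )
            trees[clade] = newick_write(ftree).strip()
            family = evolve_sequences(
                ftree, ancestor, model, [seed, 30 + ci], invariant_sites=motif_sites
            )
        for leaf in sorted(family, key=lambda s: int(s[1:])):
            sid = f"clade{clade}_{leaf}"
            ids.append(sid)
            rows.append(family[leaf])
            truth[sid] = clade
            sequences.append(ProteinSequence(id=sid, residues=family[leaf]))

    drng = np.random.default_rng([seed, 99])
    for i in range(config.n_decoys):
        sid = f"decoy_{i + 1:02d}"
        s = _motif_free_decoy(L, model, drng)
        ids.append(sid)
        rows.append(s)
        truth[sid] = "decoy"
        sequences.append(ProteinSequence(id=sid, residues=s))

    aligned_rows = list(rows)
    if config.with_indels:
        # delete column blocks per family (never inside planted motifs) so
        # pairwise deletion has real work to do
        irng = np.random.default_rng([seed, 98])
        family_ids = [
            [i for i, sid in enumerate(ids) if truth[sid] == clade] for clade in CLADES
        ]
        for members in family_ids:
            if not members:
                continue
            protected = set()
            for plan in plans.values():
                protected |= set(range(plan.aspartate_window[0], plan.nse_window[1] + 12))
            candidates = [c for c in range(L) if c not in protected]
            drop = set(
                irng.choice(
                    candidates,
                    size=min(config.indel_columns_per_family, len(candidates)),
                    replace=False,
                ).tolist()
            )
            for i in members:
                aligned_rows[i] = "".join(
                    "-" if c in drop else ch for c, ch in enumerate(aligned_rows[i])
                )
                sequences[i] = ProteinSequence(
                    id=ids[i], residues="".join(ch for ch in aligned_rows[i] if ch != "-")
                )

    return SyntheticBenchmark(
        alignment=Alignment(ids=tuple(ids), rows=tuple(aligned_rows)),
        sequences=sequences,
        truth=truth,
        trees=trees,
        config=config,
        seed=seed,
    )
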