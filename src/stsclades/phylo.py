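"""Distance-based protein phylogenetics: pairwise-deletion distances under
p, Poisson-corrected and JTT maximum-likelihood models, Saitou-Nei neighbor
joining, and column-bootstrap bipartition supports.

The JTT (Jones-Taylor-Thornton 1992) empirical amino-acid model ships as a
packaged text file of exchangeability counts and stationary frequencies.
The instantaneous rate matrix is built as Q_ij = s_ij * pi_j, normalized so
the mean substitution rate at stationarity is 1 — distances are therefore
in expected substitutions per site.  The ML distance between two rows
maximizes the independent-sites likelihood sum_sites log(pi_a * P_ab(t))
via bracketed scalar optimization of t.

Pairwise deletion: each pair of rows is compared only on columns where
neither row carries a gap; the ambiguity character X is treated the same
way (it contributes no information).  Trees are scikit-bio ``TreeNode``
objects (Newick round-trip comes with them); the neighbor-joining
agglomeration itself, with Studier-Keppler Q selection, deterministic
lexicographic tie-breaking and non-negative branch-length clamping, is
implemented here.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from functools import cached_property
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from skbio import TreeNode

__all__ = [
    "AA_ORDER",
    "Alignment",
    "SubstitutionModel",
    "DistanceMatrix",
    "BootstrapResult",
    "load_jtt",
    "pairwise_sites",
    "p_distance",
    "poisson_distance",
    "jtt_ml_distance",
    "distance_matrix",
    "nj_tree",
    "bipartitions",
    "bootstrap_support",
    "newick_read",
    "newick_write",
]

logger = logging.getLogger(__name__)

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}
GAP = "-"

T_MAX = 10.0
T_TOL = 1e-8
MAX_ITER = 200


class DistanceError(ValueError):
    pass


class NewickError(ValueError):
    pass


@dataclass(frozen=True)
class Alignment:
    """A protein multiple alignment (rows of equal length, unique ids)."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids/rows length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("alignment ids must be unique")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def __len__(self) -> int:
        return len(self.ids)

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]

    def select_columns(self, columns: Sequence[int]) -> "Alignment":
        cols = list(columns)
        return Alignment(
            ids=self.ids,
            rows=tuple("".join(r[c] for c in cols) for r in self.rows),
        )

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Alignment":
        from Bio import SeqIO

        ids, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            rows.append(str(rec.seq).upper())
        if not ids:
            raise ValueError(f"{path}: no FASTA records")
        return cls(ids=tuple(ids), rows=tuple(rows))

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for sid, row in zip(self.ids, self.rows):
                fh.write(f">{sid}\n{row}\n")


@dataclass(frozen=True)
class SubstitutionModel:
    """A time-reversible empirical amino-acid substitution model.

    ``rates`` is the 20x20 instantaneous rate matrix Q (rows sum to zero)
    scaled to one expected substitution per site per unit time at
    stationarity; ``freqs`` are the stationary frequencies in ``AA_ORDER``.
    """

    name: str
    freqs: np.ndarray
    rates: np.ndarray | None = None

    def __post_init__(self) -> None:
        if abs(self.freqs.sum() - 1.0) > 1e-9:
            raise ValueError("stationary frequencies must sum to 1")
        if self.rates is not None:
            if np.abs(self.rates.sum(axis=1)).max() > 1e-9:
                raise ValueError("rate rows must sum to 0")
            flux = self.freqs[:, None] * self.rates
            if np.abs(flux - flux.T).max() > 1e-9:
                raise ValueError("model must satisfy detailed balance")

    @cached_property
    def _eig(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        # symmetrize: B = D^1/2 Q D^-1/2 shares eigenvalues with Q
        d = np.sqrt(self.freqs)
        B = (self.rates * d[:, None]) / d[None, :]
        w, V = np.linalg.eigh((B + B.T) / 2)
        left = V.T * d[None, :]  # V^T D^1/2
        right = V / d[:, None]  # D^-1/2 V
        return w, right, left

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt) via the eigendecomposition of Q."""
        if self.rates is None:
            raise ValueError(f"model {self.name!r} has no rate matrix")
        w, right, left = self._eig
        P = (right * np.exp(w * t)[None, :]) @ left
        return np.clip(P, 0.0, None)

    def expected_p(self, t: float) -> float:
        """Expected proportion of differing sites after time t."""
        P = self.transition_matrix(t)
        return float(1.0 - self.freqs @ np.diag(P))

    @property
    def stationary_identity(self) -> float:
        """Pairwise identity between two stationary draws, sum(pi_i^2)."""
        return float(np.sum(self.freqs**2))


def load_jtt() -> SubstitutionModel:
    """Load the packaged JTT model and build its normalized rate matrix."""
    path = resources.files("stsclades").joinpath("data/jtt_model.tsv")
    lines = [
        ln for ln in path.read_text().splitlines() if ln and not ln.startswith("#")
    ]
    header = lines[0].split("\t")
    assert header[1:21] == list(AA_ORDER)
    S = np.zeros((20, 20))
    freqs = np.zeros(20)
    for i, ln in enumerate(lines[1:]):
        parts = ln.split("\t")
        S[i] = [float(v) for v in parts[1:21]]
        freqs[i] = float(parts[21])
    freqs = freqs / freqs.sum()
    Q = S * freqs[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mean_rate = -float(freqs @ np.diag(Q))
    Q /= mean_rate
    return SubstitutionModel(name="jtt-ml", freqs=freqs, rates=Q)


# ---------------------------------------------------------------------------
# pairwise distances


def pairwise_sites(a: str, b: str) -> np.ndarray:
    """Strictly increasing column indices where neither row has '-' or 'X'."""
    if len(a) != len(b):
        raise DistanceError(f"row length mismatch: {len(a)} vs {len(b)}")
    aa = np.frombuffer(a.encode(), dtype="S1")
    bb = np.frombuffer(b.encode(), dtype="S1")
    bad = (aa == b"-") | (bb == b"-") | (aa == b"X") | (bb == b"X")
    return np.nonzero(~bad)[0]


def _site_pairs(a: str, b: str) -> tuple[np.ndarray, np.ndarray]:
    idx = pairwise_sites(a, b)
    ai = np.array([AA_INDEX[a[i]] for i in idx], dtype=np.intp)
    bi = np.array([AA_INDEX[b[i]] for i in idx], dtype=np.intp)
    return ai, bi


def p_distance(a: str, b: str) -> float:
    """Proportion of differing residues over pairwise-deleted sites.

    NaN when the pair shares no comparable site.
    """
    ai, bi = _site_pairs(a, b)
    if ai.size == 0:
        return float("nan")
    return float(np.mean(ai != bi))


def poisson_distance(a: str, b: str) -> float:
    """Poisson-corrected distance -ln(1 - p); NaN when p >= 1 or undefined."""
    p = p_distance(a, b)
    if np.isnan(p) or p >= 1.0:
        return float("nan")
    return float(-np.log1p(-p))


def jtt_ml_distance(a: str, b: str, model: SubstitutionModel) -> float:
    """Maximum-likelihood divergence time under the JTT model.

    Maximizes sum over pairwise-deleted sites of log(pi_i P_ij(t)) for
    t in [0, T_MAX] by bounded scalar optimization (tolerance 1e-6 on t).
    Identical rows return exactly 0; pairs with no comparable site NaN.
    """
    if model.rates is None:
        raise DistanceError("jtt_ml_distance requires a rate-matrix model")
    ai, bi = _site_pairs(a, b)
    if ai.size == 0:
        return float("nan")
    if np.all(ai == bi):
        return 0.0
    counts = np.zeros((20, 20))
    np.add.at(counts, (ai, bi), 1.0)

    def neg_loglik(t: float) -> float:
        P = np.clip(model.transition_matrix(t), 1e-300, None)
        return -float(np.sum(counts * np.log(P)))

    res = minimize_scalar(
        neg_loglik,
        bounds=(T_TOL, T_MAX),
        method="bounded",
        options={"xatol": 1e-6, "maxiter": MAX_ITER},
    )
    if not res.success:
        raise DistanceError(
            f"ML distance optimization did not converge: t={res.x:.6g}, "
            f"nit={res.nfev}, message={res.message!r}"
        )
    return float(res.x)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances with per-pair comparable-site counts.

    Undefined pairs (zero comparable sites) are NaN.
    """

    labels: tuple[str, ...]
    values: np.ndarray
    n_sites: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.labels),) * 2:
            raise ValueError("shape mismatch")
        if np.nanmax(np.abs(v - v.T), initial=0.0) > 1e-12:
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("diagonal must be zero")
        with np.errstate(invalid="ignore"):
            if np.any(v[~np.isnan(v)] < 0):
                raise ValueError("distances must be non-negative")

    def undefined_pairs(self) -> list[tuple[str, str]]:
        out = []
        n = len(self.labels)
        for i in range(n):
            for j in range(i + 1, n):
                if np.isnan(self.values[i, j]):
                    out.append((self.labels[i], self.labels[j]))
        return out

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for i, lab in enumerate(self.labels):
                row = "\t".join(f"{v:.6f}" for v in self.values[i])
                fh.write(f"{lab}\t{row}\n")


ModelChoice = Literal["p", "poisson", "jtt-ml"]


def distance_matrix(
    aln: Alignment,
    model: ModelChoice | SubstitutionModel = "jtt-ml",
) -> DistanceMatrix:
    """All pairwise distances under the chosen model, pairwise deletion."""
    if isinstance(model, SubstitutionModel):
        sub, name = model, model.name
    elif model == "jtt-ml":
        sub, name = load_jtt(), "jtt-ml"
    elif model in ("p", "poisson"):
        sub, name = None, model
    else:
        raise ValueError(f"unknown model {model!r}")

    n = len(aln)
    values = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = aln.rows[i], aln.rows[j]
            counts[i, j] = counts[j, i] = pairwise_sites(a, b).size
            if name == "p":
                d = p_distance(a, b)
            elif name == "poisson":
                d = poisson_distance(a, b)
            else:
                d = jtt_ml_distance(a, b, sub)
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels=aln.ids, values=values, n_sites=counts)


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining with Studier-Keppler pair selection.

    Deterministic: Q-matrix ties are broken by the lexicographically
    smallest (representative label) pair, where a cluster's representative
    is its smallest leaf label.  Negative branch-length estimates are
    clamped to zero.  Returns an unrooted tree displayed with a
    trifurcating root.
    """
    n = len(dm.labels)
    if n < 3:
        raise DistanceError("neighbor joining needs at least 3 taxa")
    undef = dm.undefined_pairs()
    if undef:
        raise DistanceError(f"undefined distance for pairs: {undef}")

    d = dm.values.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in dm.labels]
    reps: list[str] = list(dm.labels)  # tie-break representative per cluster
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for ii in range(m):
            for jj in range(ii + 1, m):
                q = (m - 2) * sub[ii, jj] - r[ii] - r[jj]
                pair_key = tuple(sorted((reps[active[ii]], reps[active[jj]])))
                key = (q, pair_key)
                if best is None or key < best[0]:
                    best = (key, ii, jj)
        (_, _), ii, jj = best
        i, j = active[ii], active[jj]
        dij = d[i, j]
        li = dij / 2 + (r[ii] - r[jj]) / (2 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)

        parent = TreeNode()
        ci, cj = nodes[i], nodes[j]
        ci.length, cj.length = float(li), float(lj)
        parent.extend([ci, cj])

        # distances from the new node to every other active cluster
        new_row = np.full(d.shape[0] + 1, np.nan)
        for kk in active:
            if kk in (i, j):
                continue
            new_row[kk] = (d[i, kk] + d[j, kk] - dij) / 2
        d = np.pad(d, ((0, 1), (0, 1)), constant_values=np.nan)
        d[-1, :] = new_row
        d[:, -1] = new_row
        d[-1, -1] = 0.0

        nodes.append(parent)
        reps.append(min(reps[i], reps[j]))
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    # resolve the final three clusters around a central node
    a, b, c = active
    la = (d[a, b] + d[a, c] - d[b, c]) / 2
    lb = d[a, b] - la
    lc = d[a, c] - la
    root = TreeNode()
    for idx, ln in ((a, la), (b, lb), (c, lc)):
        nodes[idx].length = float(max(ln, 0.0))
        root.append(nodes[idx])
    return root


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial unrooted splits, each as its canonical leaf-name side.

    The side not containing the lexicographically smallest leaf is used as
    the canonical representative, so splits compare equal across rootings.
    """
    leaves = sorted(t.name for t in tree.tips())
    ref = leaves[0]
    full = set(leaves)
    splits: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = {t.name for t in node.tips()}
        if ref in side:
            side = full - side
        if 2 <= len(side) <= len(full) - 2:
            splits.add(frozenset(side))
    return splits


@dataclass(frozen=True)
class BootstrapResult:
    n_replicates: int
    n_completed: int
    supports: dict[frozenset[str], float]


def bootstrap_support(
    aln: Alignment,
    n_reps: int,
    seed: int,
    model: ModelChoice | SubstitutionModel = "jtt-ml",
) -> tuple[TreeNode, BootstrapResult]:
    """Column bootstrap of the NJ tree.

    Replicate r resamples alignment columns with replacement using the
    derived stream ``default_rng([seed, r])`` (replicates are therefore
    order-independent), rebuilds the tree, and the full-data tree's splits
    are scored by the fraction of completed replicates containing them.
    Replicates producing an undefined pair are skipped and logged.
    Supports are attached to the returned tree's internal nodes.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if isinstance(model, str) and model == "jtt-ml":
        model = load_jtt()  # load once for all replicates
    full_tree = nj_tree(distance_matrix(aln, model))
    target = bipartitions(full_tree)
    counts = {s: 0 for s in target}
    completed = 0
    for r in range(n_reps):
        rng = np.random.default_rng([seed, r])
        cols = rng.integers(0, aln.length, size=aln.length)
        rep_aln = aln.select_columns(cols)
        try:
            rep_tree = nj_tree(distance_matrix(rep_aln, model))
        except DistanceError as exc:
            logger.warning("bootstrap replicate %d skipped: %s", r, exc)
            continue
        completed += 1
        rep_splits = bipartitions(rep_tree)
        for s in target:
            if s in rep_splits:
                counts[s] += 1
    supports = {
        s: (c / completed if completed else float("nan")) for s, c in counts.items()
    }
    _annotate_supports(full_tree, supports)
    return full_tree, BootstrapResult(
        n_replicates=n_reps, n_completed=completed, supports=supports
    )


def _annotate_supports(tree: TreeNode, supports: dict[frozenset[str], float]) -> None:
    leaves = sorted(t.name for t in tree.tips())
    full = set(leaves)
    ref = leaves[0]
    for node in tree.non_tips(include_self=False):
        side = {t.name for t in node.tips()}
        if ref in side:
            side = full - side
        key = frozenset(side)
        if key in supports:
            node.name = f"{supports[key]:.3f}"


# ---------------------------------------------------------------------------
# Newick IO (scikit-bio round trip, with uniform error reporting)


def newick_read(source: str | Path) -> TreeNode:
    """Parse Newick from a string or a file path."""
    try:
        if isinstance(source, Path) or (
            isinstance(source, str) and "\n" not in source and Path(source).exists()
        ):
            return TreeNode.read(str(source), format="newick")
        return TreeNode.read(io.StringIO(str(source)), format="newick")
    except Exception as exc:  # skbio raises format-specific errors
        raise NewickError(f"malformed Newick: {exc}") from exc


def newick_write(tree: TreeNode, path: str | Path | None = None) -> str:
    buf = io.StringIO()
    tree.write(buf, format="newick")
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text
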