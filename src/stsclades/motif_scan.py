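"""Catalytic-motif consensus scanning for sesquiterpene synthases.

Terpene synthases carry two metal-binding motifs that position the Mg2+
cluster ionizing FPP/NPP: an N-terminal-side aspartate-rich motif (canonical
forms DExxD and DD(N)xxD, generalized D(D/E/N)xx(D/E)) and the downstream
NSE motif (consensus NDxxSxxxE).  This module compiles the field's consensus
notation — uppercase letter = fixed residue, ``x`` = any residue,
``(A/B/C)`` = alternation — into position-set matchers, scans protein
sequences for all (overlapping) matches, pairs an aspartate-rich hit with a
downstream NSE hit at plausible spacing, classifies the aspartate-rich
variant, and screens candidate proteomes for STS-like sequences.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "ProteinSequence",
    "MotifPattern",
    "MotifHit",
    "CatalyticPair",
    "ScanConfig",
    "compile_pattern",
    "scan",
    "locate_catalytic_pair",
    "classify_motif1",
    "motif_table",
    "screen_candidates",
    "BUILTIN_PATTERNS",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
_VALID_RESIDUES = AMINO_ACIDS | {"X"}


class PatternError(ValueError):
    """Malformed motif consensus notation; carries the offending offset."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (offset {offset})")
        self.offset = offset


@dataclass(frozen=True)
class ProteinSequence:
    """An ungapped protein sequence over the 20 amino acids plus X."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.residues) - _VALID_RESIDUES
        if bad:
            raise ValueError(f"{self.id}: invalid residues {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class MotifPattern:
    """A compiled consensus pattern.

    ``positions`` holds one frozenset of allowed residues per motif
    position; ``None`` marks an "x" (any residue, including the ambiguity
    character X).
    """

    name: str
    consensus: str
    positions: tuple[frozenset[str] | None, ...]

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def length(self) -> int:
        return len(self.positions)

    def matches_at(self, residues: str, start: int) -> bool:
        if start < 0 or start + len(self) > len(residues):
            return False
        for off, allowed in enumerate(self.positions):
            if allowed is not None and residues[start + off] not in allowed:
                return False
        return True

    def search(self, residues: str) -> "MotifHit | None":
        """First match within a plain string (no sequence id attached)."""
        for i in range(len(residues) - len(self) + 1):
            if self.matches_at(residues, i):
                return MotifHit("", self.name, i, residues[i : i + len(self)])
        return None


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    pattern_name: str
    start: int
    matched: str

    @property
    def end(self) -> int:
        return self.start + len(self.matched)


@dataclass(frozen=True)
class CatalyticPair:
    """An aspartate-rich hit paired with a downstream NSE hit.

    Both components are absent when no ordering with the aspartate-rich
    motif upstream of the NSE motif exists within the spacing window.
    """

    aspartate_hit: MotifHit | None
    nse_hit: MotifHit | None

    @property
    def spacing(self) -> int | None:
        if self.aspartate_hit is None or self.nse_hit is None:
            return None
        return self.nse_hit.start - self.aspartate_hit.start


@dataclass(frozen=True)
class ScanConfig:
    """Knobs for catalytic-pair location and candidate screening.

    The spacing window brackets the aspartate-rich -> NSE offset observed in
    characterized STSs; the length window brackets plausible STS protein
    sizes (~300-600 aa enzymes).
    """

    spacing_min: int = 60
    spacing_max: int = 260
    min_length: int = 250
    max_length: int = 700


def compile_pattern(consensus: str, name: str | None = None) -> MotifPattern:
    """Compile consensus notation into a :class:`MotifPattern`.

    Grammar: an uppercase amino-acid letter fixes the position, ``x``
    matches any residue (including X), and ``(A/B/C)`` allows alternatives.
    """
    if not consensus:
        raise PatternError("empty consensus", 0)
    positions: list[frozenset[str] | None] = []
    i = 0
    while i < len(consensus):
        c = consensus[i]
        if c == "x":
            positions.append(None)
            i += 1
        elif c == "(":
            j = consensus.find(")", i)
            if j < 0:
                raise PatternError("unbalanced parenthesis", i)
            alts = consensus[i + 1 : j].split("/")
            if not alts or any(len(a) != 1 or a not in AMINO_ACIDS for a in alts):
                raise PatternError(f"bad alternation {consensus[i : j + 1]!r}", i)
            positions.append(frozenset(alts))
            i = j + 1
        elif c in AMINO_ACIDS:
            positions.append(frozenset(c))
            i += 1
        else:
            raise PatternError(f"illegal character {c!r}", i)
    return MotifPattern(
        name=name if name is not None else consensus,
        consensus=consensus,
        positions=tuple(positions),
    )


# The consensus forms reported for fungal STSs.  "DD(N)xxD" is the canonical
# name of the D(D/N)xxD variant; both metal-binding motifs are generalized
# by "D(D/E/N)xx(D/E)".
BUILTIN_PATTERNS: dict[str, MotifPattern] = {
    p.name: p
    for p in [
        compile_pattern("NDxxSxxxE", name="NSE"),
        compile_pattern("D(D/E/N)xx(D/E)", name="aspartate-rich"),
        compile_pattern("DExxD", name="DExxD"),
        compile_pattern("D(D/N)xxD", name="DD(N)xxD"),
        compile_pattern("DxDTT", name="DxDTT"),
        compile_pattern("DDxDTT", name="DDxDTT"),
        compile_pattern("QDxxDxxxD", name="QDxxDxxxD"),
    ]
}


def scan(seq: ProteinSequence, pattern: MotifPattern) -> list[MotifHit]:
    """All (possibly overlapping) pattern matches, ordered by start."""
    res = seq.residues
    return [
        MotifHit(seq.id, pattern.name, i, res[i : i + len(pattern)])
        for i in range(len(res) - len(pattern) + 1)
        if pattern.matches_at(res, i)
    ]


def locate_catalytic_pair(
    seq: ProteinSequence, config: ScanConfig = ScanConfig()
) -> CatalyticPair:
    """Pick the aspartate-rich/NSE hit pair with spacing inside the window.

    Among valid orderings (aspartate-rich strictly upstream, spacing within
    ``[spacing_min, spacing_max]``) the pair whose spacing is closest to the
    window midpoint wins; ties go to the earliest aspartate-rich hit.  When
    no valid pairing exists, whichever single motif was found is still
    reported — unless the only candidates are out of order, in which case
    both components are absent.
    """
    asp_hits = scan(seq, BUILTIN_PATTERNS["aspartate-rich"])
    nse_hits = scan(seq, BUILTIN_PATTERNS["NSE"])
    midpoint = (config.spacing_min + config.spacing_max) / 2

    best: tuple[float, int, MotifHit, MotifHit] | None = None
    for a in asp_hits:
        for n in nse_hits:
            spacing = n.start - a.start
            if spacing <= 0 or not (config.spacing_min <= spacing <= config.spacing_max):
                continue
            key = (abs(spacing - midpoint), a.start)
            if best is None or key < (best[0], best[1]):
                best = (key[0], key[1], a, n)
    if best is not None:
        return CatalyticPair(aspartate_hit=best[2], nse_hit=best[3])

    if asp_hits and nse_hits:
        # both motifs present but no valid upstream/downstream pairing
        return CatalyticPair(aspartate_hit=None, nse_hit=None)
    return CatalyticPair(
        aspartate_hit=asp_hits[0] if asp_hits else None,
        nse_hit=nse_hits[0] if nse_hits else None,
    )


_CLASS_ORDER = ("DExxD", "DD(N)xxD", "other-variant", "absent")


def classify_motif1(motif1: str | None) -> str:
    """Classify an aspartate-rich region string into exactly one label.

    Sub-patterns are tested in order DExxD, DD(N)xxD, then the generalized
    D(D/E/N)xx(D/E) form ("other-variant"); strings matching none — and
    absent fields — are "absent".
    """
    if not motif1:
        return "absent"
    for label, pat in (
        ("DExxD", BUILTIN_PATTERNS["DExxD"]),
        ("DD(N)xxD", BUILTIN_PATTERNS["DD(N)xxD"]),
        ("other-variant", BUILTIN_PATTERNS["aspartate-rich"]),
    ):
        if pat.search(motif1) is not None:
            return label
    return "absent"


def motif_table(
    seqs: Iterable[ProteinSequence], config: ScanConfig = ScanConfig()
) -> "pd.DataFrame":
    """Per-sequence motif report mirroring the reference motif table."""
    import pandas as pd

    rows = []
    for seq in seqs:
        pair = locate_catalytic_pair(seq, config)
        m1 = pair.aspartate_hit.matched if pair.aspartate_hit else ""
        m2 = pair.nse_hit.matched if pair.nse_hit else ""
        rows.append(
            {
                "id": seq.id,
                "motif1": m1,
                "motif2": m2,
                "classification": classify_motif1(m1 or None),
            }
        )
    return pd.DataFrame(rows, columns=["id", "motif1", "motif2", "classification"])


def screen_candidates(
    seqs: Sequence[ProteinSequence], config: ScanConfig = ScanConfig()
) -> list[str]:
    """Keep STS-like sequences: length in window and a catalytic motif hit.

    Returns ids in deterministic lexicographic order.
    """
    kept = []
    for seq in seqs:
        if not (config.min_length <= len(seq) <= config.max_length):
            continue
        if scan(seq, BUILTIN_PATTERNS["NSE"]) or scan(
            seq, BUILTIN_PATTERNS["aspartate-rich"]
        ):
            kept.append(seq.id)
    return sorted(kept)
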