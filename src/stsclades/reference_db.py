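"""Curated reference knowledge base of characterized mushroom sesquiterpene
synthases (STSs).

The package ships a transcription of the published reference tables: one TSV
with gene name, species, accession, ordered product list, clade (I-IV, or
unassigned for entries the source did not analyze) and literature citation,
and a second TSV with the printed aspartate-rich (Motif I) and NSE-region
(Motif II) strings plus Pfam domain labels.  This module loads and validates
the transcription and exposes the counting operations used to summarize the
dataset: clade composition, product-role counts (major / minor / sole
product), and motif-pattern counts over the printed motif strings.

Product names are normalized to plain ASCII (Greek letters spelled out,
superscripts inlined, whitespace collapsed to hyphens) so that, e.g., the
printed "*α*-muurolene" and "α-muurolene" compare equal as
``"alpha-muurolene"``.  The printed strings are always preserved alongside
the normalized form.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd

__all__ = [
    "ProductRecord",
    "ReferenceSTS",
    "ReferenceDB",
    "normalize_product",
    "parse_products",
    "load_reference",
    "summarize_clades",
    "count_product_role",
    "count_motif_matches",
]

CLADES = ("I", "II", "III", "IV")
UNASSIGNED = "unassigned"

TABLE1_COLUMNS = ["gene_name", "species", "accession", "products", "clade", "citation"]
TABLE2_COLUMNS = ["gene_name", "motif1", "motif2", "domains"]

_PFAM_RE = re.compile(r"PF\d{5}")

_GREEK = {
    "α": "alpha",
    "β": "beta",
    "γ": "gamma",
    "Δ": "delta",
    "δ": "delta",
    "Ʈ": "tau",
    "τ": "tau",
}

# printed spelling variants -> canonical normalized name
_ALIASES = {
    "virifloridol": "viridiflorol",
}


class ReferenceTableError(ValueError):
    """Malformed packaged/user reference table."""


@dataclass(frozen=True)
class ProductRecord:
    """One catalytic product as printed in the reference table.

    ``rank`` is the 1-based position in the printed list; the first-listed
    product is the enzyme's major product.  ``flag`` is ``"nd"`` when the
    source recorded no detected product, ``"unknown"`` for unidentified
    sesquiterpene(ol) peaks, and ``"normal"`` otherwise.
    """

    name: str
    raw: str
    rank: int
    flag: Literal["normal", "nd", "unknown"] = "normal"

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError("rank is 1-based")
        if self.flag == "nd" and self.name:
            raise ValueError("'nd' records carry no product name")


@dataclass(frozen=True)
class ReferenceSTS:
    """One curated STS record joining the dataset and motif tables."""

    gene_name: str
    species: str
    accession: str
    products: tuple[ProductRecord, ...]
    clade: str
    citation: str
    motif1: str | None = None
    motif2: str | None = None
    domains: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.gene_name:
            raise ValueError("gene_name must be non-empty")
        if self.clade not in CLADES + (UNASSIGNED,):
            raise ValueError(f"bad clade {self.clade!r} for {self.gene_name}")
        for acc in self.domains:
            if not _PFAM_RE.fullmatch(acc):
                raise ValueError(f"bad Pfam accession {acc!r} for {self.gene_name}")

    @property
    def major_product(self) -> ProductRecord | None:
        """First-listed identified product, or None."""
        for p in self.products:
            if p.flag == "normal":
                return p
            return None  # an unknown peak heads the list: no usable major
        return None


@dataclass
class ReferenceDB:
    entries: list[ReferenceSTS]
    provenance: str = "table-transcription-v1"
    unmatched_motif_rows: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def get(self, gene_name: str) -> ReferenceSTS:
        for e in self.entries:
            if e.gene_name == gene_name:
                return e
        raise KeyError(gene_name)

    @property
    def assigned(self) -> list[ReferenceSTS]:
        return [e for e in self.entries if e.clade in CLADES]


def normalize_product(raw: str) -> str:
    """Normalize a printed product string to a canonical ASCII name.

    Lowercases, spells out Greek letters, inlines ``^..^`` superscripts,
    collapses whitespace runs to single hyphens, and applies the alias table
    for known printed spelling variants.
    """
    s = raw.strip()
    s = re.sub(r"\^([^^]+)\^", r"\1", s)  # Δ^6^- -> Δ6-
    for greek, spelled in _GREEK.items():
        s = s.replace(greek, spelled)
    s = s.lower()
    s = re.sub(r"\s+", "-", s)
    s = re.sub(r"-{2,}", "-", s)
    return _ALIASES.get(s, s)


# Product lists are printed ";"-separated, but two rows of the source table
# use ", " instead.  Commas inside product names ("cadina-1,4-diene") are
# never followed by a space, so splitting on ";" and ", " is unambiguous.
_SPLIT_RE = re.compile(r";|,\s")


def parse_products(raw: str) -> list[ProductRecord]:
    """Parse a printed product field into ordered ``ProductRecord``s.

    Total function: "ND" and blank fields yield an empty list; a trailing
    "etc." is dropped; "unknown sesquiterpene(ol)" entries are flagged.
    """
    text = raw.strip()
    if not text or text == "ND":
        return []
    records: list[ProductRecord] = []
    rank = 1
    for part in _SPLIT_RE.split(text):
        part = part.strip()
        if not part or part in ("etc.", "etc"):
            continue
        name = normalize_product(part)
        flag = "unknown" if name.startswith("unknown-sesquiterpen") else "normal"
        records.append(ProductRecord(name=name, raw=part, rank=rank, flag=flag))
        rank += 1
    return records


def _read_table(path: Path, columns: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ReferenceTableError(f"{path}: no data rows") from None
    if list(df.columns) != columns:
        raise ReferenceTableError(
            f"{path}: expected header {columns}, found {list(df.columns)}"
        )
    if df.empty:
        raise ReferenceTableError(f"{path}: no data rows")
    for idx, row in df.iterrows():
        if not str(row.iloc[0]).strip():
            # +2: header line plus 1-based numbering
            raise ReferenceTableError(f"{path}: malformed row at line {idx + 2}")
    return df


def packaged_table_paths() -> tuple[Path, Path]:
    """Paths of the packaged reference-table transcriptions."""
    data = resources.files("stsclades").joinpath("data")
    return (
        Path(str(data.joinpath("table1_reference.tsv"))),
        Path(str(data.joinpath("table2_motifs.tsv"))),
    )


def _parse_domains(cell: str) -> tuple[str, ...]:
    cell = cell.strip().rstrip(";")
    if not cell or cell == "na":
        return ()
    return tuple(p.strip() for p in cell.split(";") if p.strip())


def load_reference(
    path_table1: str | Path | None = None,
    path_table2: str | Path | None = None,
) -> ReferenceDB:
    """Load and validate the reference dataset from its two TSVs.

    Defaults to the packaged transcription.  The motif table is joined onto
    the dataset table by exact gene name; motif rows without a dataset
    partner are retained in ``unmatched_motif_rows`` rather than silently
    dropped, and dataset rows without motif data carry absent motif fields.
    """
    default1, default2 = packaged_table_paths()
    p1 = Path(path_table1) if path_table1 is not None else default1
    p2 = Path(path_table2) if path_table2 is not None else default2

    t1 = _read_table(p1, TABLE1_COLUMNS)
    t2 = _read_table(p2, TABLE2_COLUMNS)

    dupes = t1["gene_name"][t1["gene_name"].duplicated()]
    if not dupes.empty:
        raise ReferenceTableError(f"{p1}: duplicate gene_name(s): {sorted(set(dupes))}")
    dupes2 = t2["gene_name"][t2["gene_name"].duplicated()]
    if not dupes2.empty:
        raise ReferenceTableError(f"{p2}: duplicate gene_name(s): {sorted(set(dupes2))}")

    motifs = {r.gene_name: r for r in t2.itertuples(index=False)}
    entries: list[ReferenceSTS] = []
    for i, row in enumerate(t1.itertuples(index=False)):
        clade = row.clade.strip()
        clade = UNASSIGNED if clade == "\\" else clade
        m = motifs.pop(row.gene_name, None)

        def _motif(v: str | None) -> str | None:
            if v is None:
                return None
            v = v.strip()
            return None if (not v or v == "na") else v

        try:
            entries.append(
                ReferenceSTS(
                    gene_name=row.gene_name.strip(),
                    species=row.species.strip(),
                    accession=row.accession.strip(),
                    products=tuple(parse_products(row.products)),
                    clade=clade,
                    citation=row.citation.strip(),
                    motif1=_motif(m.motif1 if m else None),
                    motif2=_motif(m.motif2 if m else None),
                    domains=_parse_domains(m.domains) if m else (),
                )
            )
        except ValueError as exc:
            raise ReferenceTableError(f"{p1}: malformed row at line {i + 2}: {exc}") from exc

    return ReferenceDB(entries=entries, unmatched_motif_rows=sorted(motifs))


def summarize_clades(db: ReferenceDB) -> pd.DataFrame:
    """Per-clade entry and distinct-species counts over assigned entries."""
    rows = []
    for clade in CLADES:
        members = [e for e in db.entries if e.clade == clade]
        rows.append(
            {
                "clade": clade,
                "n_entries": len(members),
                "n_species": len({e.species for e in members}),
            }
        )
    return pd.DataFrame(rows)


def count_product_role(
    db: ReferenceDB,
    product: str,
    clade: str,
    role: Literal["major", "minor", "sole"],
) -> int:
    """Count entries of ``clade`` bearing ``product`` in the given role.

    major: first-listed product; minor: present at rank >= 2; sole: the
    entry's only product.  ``product`` must be a normalized name.
    """
    if clade not in CLADES:
        raise ValueError(f"unknown clade label {clade!r}")
    if role not in ("major", "minor", "sole"):
        raise ValueError(f"unknown role {role!r}")
    n = 0
    for e in db.entries:
        if e.clade != clade or not e.products:
            continue
        names = [p.name for p in e.products]
        if role == "major" and names[0] == product:
            n += 1
        elif role == "minor" and product in names[1:]:
            n += 1
        elif role == "sole" and names == [product]:
            n += 1
    return n


def count_motif_matches(db: ReferenceDB, pattern, field_name: str = "motif1") -> int:
    """Count entries whose printed motif string contains a pattern match.

    ``pattern`` is a compiled :class:`~stsclades.motif_scan.MotifPattern`.
    Absent motif fields never match.
    """
    if field_name not in ("motif1", "motif2"):
        raise ValueError(f"field must be 'motif1' or 'motif2', got {field_name!r}")
    n = 0
    for e in db.entries:
        s = getattr(e, field_name)
        if s and pattern.search(s):
            n += 1
    return n
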