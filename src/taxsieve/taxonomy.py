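"""Taxonomy loading, lineage resolution, and accession→TaxID mapping.

Supports the NCBI dump dialect (nodes.dmp / names.dmp, ``\\t|\\t``-separated)
and a compact 4-column TSV (taxid, parent_taxid, rank, name).  Lineages are
projected onto the canonical rank ladder

    superkingdom, phylum, class, order, family, genus, species, strain

with "kingdom"/"domain" treated as aliases of superkingdom (the CAMI
convention); unranked internal nodes are traversed but never reported.

Assembly accessions (GCF_/GCA_ prefixed) are matched through their 9-digit
base so that version bumps (GCF_000169215.1 vs .2) and RefSeq/GenBank
prefix differences never break the reference→TaxID join.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "RANKS",
    "RANK_ALIASES",
    "TaxonomyNode",
    "Lineage",
    "Taxonomy",
    "AccessionMap",
    "load_taxonomy",
    "accession_base",
    "map_candidates",
]

RANKS: tuple[str, ...] = (
    "superkingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
    "strain",
)
RANK_ALIASES: dict[str, str] = {
    "kingdom": "superkingdom",
    "domain": "superkingdom",
    "no rank": "no-rank",
    "norank": "no-rank",
}
_RANK_DEPTH = {rank: i for i, rank in enumerate(RANKS)}

# Short prefixes used when rendering lineages as text.
_RANK_PREFIX = {
    "superkingdom": "sk",
    "phylum": "p",
    "class": "c",
    "order": "o",
    "family": "f",
    "genus": "g",
    "species": "s",
    "strain": "t",
}


def canonical_rank(rank: str) -> str:
    rank = rank.strip().lower()
    return RANK_ALIASES.get(rank, rank)


@dataclass(frozen=True)
class TaxonomyNode:
    taxid: int
    parent_taxid: int
    rank: str
    name: str


@dataclass
class Lineage:
    """Ordered (rank, taxid, name) entries from highest rank to most specific;
    only canonical named ranks appear, each at most once."""

    entries: list[tuple[str, int, str]] = field(default_factory=list)

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def ranks(self) -> list[str]:
        return [r for r, _, _ in self.entries]

    def taxid_at(self, rank: str) -> Optional[int]:
        rank = canonical_rank(rank)
        for r, taxid, _ in self.entries:
            if r == rank:
                return taxid
        return None

    def most_specific(self) -> Optional[tuple[str, int, str]]:
        return self.entries[-1] if self.entries else None

    def render(self) -> str:
        return ";".join(
            f"{_RANK_PREFIX.get(rank, rank)}__{name}" for rank, _, name in self.entries
        )


class TaxonomyError(ValueError):
    pass


class Taxonomy:
    """Validated rooted taxonomy with lineage and rank-projection queries."""

    def __init__(self, nodes: Iterable[TaxonomyNode]):
        self.nodes: dict[int, TaxonomyNode] = {}
        for node in nodes:
            if node.taxid in self.nodes:
                raise TaxonomyError(f"duplicate taxid {node.taxid}")
            self.nodes[node.taxid] = node
        roots = [n.taxid for n in self.nodes.values() if n.parent_taxid == n.taxid]
        if len(roots) != 1:
            raise TaxonomyError(
                f"taxonomy must have exactly one root (parent = self); found {roots}"
            )
        self.root = roots[0]
        self._validate_connected()
        self._lineage_cache: dict[int, Lineage] = {}

    def _validate_connected(self) -> None:
        for taxid, node in self.nodes.items():
            seen = set()
            cur = taxid
            while cur != self.root:
                if cur in seen:
                    raise TaxonomyError(f"cycle detected through taxid {taxid}")
                seen.add(cur)
                parent = self.nodes[cur].parent_taxid
                if parent not in self.nodes:
                    raise TaxonomyError(
                        f"node {cur} has parent {parent} absent from the taxonomy"
                    )
                cur = parent

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.nodes

    def name_of(self, taxid: int) -> str:
        return self.nodes[taxid].name

    def rank_of(self, taxid: int) -> str:
        return canonical_rank(self.nodes[taxid].rank)

    def lineage_of(self, taxid: int) -> Lineage:
        """Named-rank lineage of a taxon, root-ward first.  Unranked nodes are
        traversed but omitted from the result."""
        if taxid not in self.nodes:
            raise TaxonomyError(f"unknown taxid {taxid}")
        cached = self._lineage_cache.get(taxid)
        if cached is not None:
            return cached
        chain: list[tuple[str, int, str]] = []
        cur = taxid
        while True:
            node = self.nodes[cur]
            rank = canonical_rank(node.rank)
            if rank in _RANK_DEPTH:
                chain.append((rank, node.taxid, node.name))
            if cur == self.root:
                break
            cur = node.parent_taxid
        chain.reverse()
        lineage = Lineage(chain)
        self._lineage_cache[taxid] = lineage
        return lineage

    def project_to_rank(self, lineage: Lineage | int, rank: str) -> Optional[int]:
        """TaxID of a lineage at the given canonical rank, or None when the
        lineage does not reach that rank."""
        if isinstance(lineage, int):
            lineage = self.lineage_of(lineage)
        return lineage.taxid_at(rank)


def _parse_dmp_line(line: str) -> list[str]:
    return [f.strip() for f in line.rstrip("\n").rstrip("|").split("|")]


def load_taxonomy(
    nodes_source: str | Path,
    names_source: Optional[str | Path] = None,
) -> Taxonomy:
    """Load a taxonomy from NCBI nodes.dmp + names.dmp, or from a 4-column
    TSV (taxid, parent_taxid, rank, name) when only one source is given."""
    if names_source is None:
        return _load_tsv(nodes_source)
    return _load_ncbi(nodes_source, names_source)


def _load_tsv(path: str | Path) -> Taxonomy:
    nodes = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise TaxonomyError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
        try:
            taxid, parent = int(parts[0]), int(parts[1])
        except ValueError as exc:
            raise TaxonomyError(f"{path}:{lineno}: non-integer taxid") from exc
        nodes.append(TaxonomyNode(taxid, parent, parts[2], parts[3]))
    return Taxonomy(nodes)


def _load_ncbi(nodes_path: str | Path, names_path: str | Path) -> Taxonomy:
    names: dict[int, str] = {}
    for line in Path(names_path).read_text().splitlines():
        if not line.strip():
            continue
        fields = _parse_dmp_line(line)
        # names.dmp: taxid | name | unique name | name class
        if len(fields) >= 4 and fields[3] == "scientific name":
            names[int(fields[0])] = fields[1]
    nodes = []
    for line in Path(nodes_path).read_text().splitlines():
        if not line.strip():
            continue
        fields = _parse_dmp_line(line)
        taxid, parent, rank = int(fields[0]), int(fields[1]), fields[2]
        nodes.append(TaxonomyNode(taxid, parent, rank, names.get(taxid, str(taxid))))
    return Taxonomy(nodes)


# ---------------------------------------------------------------------------
# Accession handling

_ACCESSION_RE = re.compile(r"^GC[AF]_(\d{9})(?:\.\d+)?$")


def accession_base(accession: str) -> str:
    """9-digit core of an assembly accession; strips the GCF_/GCA_ prefix and
    any version suffix, so GCF_000169215.1 and GCA_000169215.2 both map to
    "000169215"."""
    m = _ACCESSION_RE.match(accession.strip())
    if m is None:
        # Idempotent on its own output: a bare 9-digit base passes through.
        if re.fullmatch(r"\d{9}", accession.strip()):
            return accession.strip()
        raise ValueError(f"malformed assembly accession: {accession!r}")
    return m.group(1)


@dataclass
class AccessionMap:
    """base accession → (full accession, taxid, species_taxid), plus the
    candidates that could not be resolved."""

    entries: dict[str, tuple[str, int, int]] = field(default_factory=dict)
    unresolved: list[str] = field(default_factory=list)

    def taxid_of(self, ref_id: str) -> Optional[int]:
        entry = self.entries.get(accession_base(ref_id))
        return entry[1] if entry else None

    def species_taxid_of(self, ref_id: str) -> Optional[int]:
        entry = self.entries.get(accession_base(ref_id))
        return entry[2] if entry else None

    def species_map(self, ref_ids: Iterable[str]) -> dict[str, int]:
        out = {}
        for rid in ref_ids:
            sp = self.species_taxid_of(rid)
            if sp is not None:
                out[rid] = sp
        return out


def _read_assembly_summary(path: str | Path) -> list[tuple[str, int, int]]:
    """Rows of (accession, taxid, species_taxid) from an assembly-summary-style
    TSV.  Accepts the NCBI header (named columns after '# assembly_accession')
    or a bare 3+-column TSV in that order."""
    rows: list[tuple[str, int, int]] = []
    col = {"assembly_accession": 0, "taxid": 1, "species_taxid": 2}
    try:
        text = Path(path).read_text()
    except OSError as exc:
        raise ValueError(f"cannot read assembly summary {path}: {exc}") from exc
    for line in text.splitlines():
        if not line.strip():
            continue
        if line.startswith("#"):
            header = line.lstrip("# ").rstrip().split("\t")
            if "assembly_accession" in header:
                col = {name: i for i, name in enumerate(header)}
            continue
        parts = line.split("\t")
        try:
            rows.append(
                (
                    parts[col["assembly_accession"]],
                    int(parts[col["taxid"]]),
                    int(parts[col["species_taxid"]]),
                )
            )
        except (KeyError, IndexError, ValueError) as exc:
            raise ValueError(f"malformed assembly summary line: {line!r}") from exc
    return rows


def map_candidates(
    ref_ids: Sequence[str], assembly_summary: str | Path
) -> AccessionMap:
    """Resolve candidate accessions against a local assembly-summary mirror.

    Matching is by accession base, so a candidate at one assembly version
    resolves against a summary listing another.  Candidates without a match
    are recorded as unresolved, not fatal.  When two summary rows share a
    base but disagree on TaxID, the row with the lexicographically smallest
    full accession wins and a warning is emitted.
    """
    rows = sorted(_read_assembly_summary(assembly_summary))
    by_base: dict[str, tuple[str, int, int]] = {}
    for acc, taxid, sp in rows:
        try:
            base = accession_base(acc)
        except ValueError:
            continue
        if base in by_base:
            if (by_base[base][1], by_base[base][2]) != (taxid, sp):
                warnings.warn(
                    f"accession base {base}: conflicting TaxIDs in summary; "
                    f"keeping {by_base[base][0]}"
                )
            continue
        by_base[base] = (acc, taxid, sp)

    amap = AccessionMap()
    for rid in ref_ids:
        try:
            base = accession_base(rid)
        except ValueError:
            amap.unresolved.append(rid)
            continue
        if base in by_base:
            amap.entries[base] = by_base[base]
        else:
            amap.unresolved.append(rid)
    return amap
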