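"""Coverage-weighted lowest-common-ancestor classification.

Each query is assigned a consensus lineage from its alignments.  Two paths:

* **Exact path** — if any alignment covers the whole query without a
  mismatch, that reference's full lineage is assigned directly with
  confidence 1.0 (ties among exact hits broken by higher coverage, then
  ref_id).

* **Weighted path** — otherwise every supporting reference contributes

      weight = coverage × abundance

  where coverage is the fraction of the query aligned to that reference
  and abundance is the reference's frequency among all alignment records
  in the dataset.  Walking the rank ladder from superkingdom downward, the
  weights are accumulated onto each reference lineage's taxon at that
  rank; the heaviest taxon consistent with the parent chosen at the
  previous rank wins, and its share of the total rank weight is the
  *consensus fraction*.  The descent stops at the last rank whose fraction
  reaches ``min_support``; confidence is the product of the recorded
  fractions, so disagreement at any reported rank lowers it.

The result is deterministic: ties in weight break toward the smaller
TaxID, and permuting the alignment records never changes a call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .paf import PafRecord, QueryRefCoverage, group_coverages
from .taxonomy import RANKS, Lineage, Taxonomy

__all__ = [
    "Classification",
    "reference_abundance",
    "classify_query",
    "classify_all",
    "write_classifications",
    "read_classifications",
    "UNCLASSIFIED",
]

UNCLASSIFIED = "unclassified"

# Consensus-fraction comparisons tolerate float noise so an exactly-split
# rank (fraction 0.5) passes a min_support of 0.5, per the >= stopping rule.
_EPS = 1e-12


@dataclass
class Classification:
    query_id: str
    lineage: Lineage
    taxonomic_level: str
    taxid: Optional[int]
    confidence: float
    rank_fractions: dict[str, float] = field(default_factory=dict)

    @property
    def classified(self) -> bool:
        return self.taxid is not None


def reference_abundance(records: Iterable[PafRecord]) -> dict[str, float]:
    """Frequency of each reference among all alignment records; sums to 1."""
    counts: dict[str, int] = {}
    total = 0
    for rec in records:
        counts[rec.target_id] = counts.get(rec.target_id, 0) + 1
        total += 1
    if total == 0:
        raise ValueError("cannot compute reference abundance on an empty alignment set")
    return {ref: n / total for ref, n in counts.items()}


def _unclassified(query_id: str) -> Classification:
    return Classification(
        query_id=query_id,
        lineage=Lineage([]),
        taxonomic_level=UNCLASSIFIED,
        taxid=None,
        confidence=0.0,
    )


def classify_query(
    coverages: Sequence[QueryRefCoverage],
    abundances: Mapping[str, float],
    ref_taxids: Mapping[str, int],
    taxonomy: Taxonomy,
    min_support: float = 0.5,
    query_id: str = "",
) -> Classification:
    """Classify one query from its per-reference coverages.

    A query with no alignments is reported unclassified, not an error.
    """
    if not coverages:
        return _unclassified(query_id)
    query_id = coverages[0].query_id

    exact_hits = [c for c in coverages if c.exact]
    if exact_hits:
        best = min(exact_hits, key=lambda c: (-c.coverage, c.ref_id))
        lineage = taxonomy.lineage_of(ref_taxids[best.ref_id])
        rank, taxid, _ = lineage.most_specific() or (UNCLASSIFIED, None, "")
        return Classification(
            query_id=query_id,
            lineage=lineage,
            taxonomic_level=rank,
            taxid=ref_taxids[best.ref_id],
            confidence=1.0,
            rank_fractions={r: 1.0 for r in lineage.ranks()},
        )

    # Weighted consensus descent.
    weights: list[tuple[Lineage, float]] = []
    for cov in coverages:
        w = cov.coverage * abundances.get(cov.ref_id, 0.0)
        if w <= 0.0:
            continue
        weights.append((taxonomy.lineage_of(ref_taxids[cov.ref_id]), w))
    if not weights:
        return _unclassified(query_id)

    chosen: list[tuple[str, int, float]] = []  # (rank, taxid, fraction)
    parent_path: dict[str, int] = {}
    for rank in RANKS:
        rank_total = 0.0
        per_taxon: dict[int, float] = {}
        for lineage, w in weights:
            taxid = lineage.taxid_at(rank)
            if taxid is None:
                continue
            rank_total += w
            # Only taxa descending from the already-chosen parent chain may win.
            if all(lineage.taxid_at(r) == t for r, t in parent_path.items()):
                per_taxon[taxid] = per_taxon.get(taxid, 0.0) + w
        if rank_total <= 0.0 or not per_taxon:
            break
        winner = min(per_taxon, key=lambda t: (-per_taxon[t], t))
        fraction = per_taxon[winner] / rank_total
        if fraction < min_support - _EPS:
            break
        chosen.append((rank, winner, fraction))
        parent_path[rank] = winner

    if not chosen:
        return _unclassified(query_id)

    stop_rank, stop_taxid, _ = chosen[-1]
    entries = [(rank, taxid, taxonomy.name_of(taxid)) for rank, taxid, _ in chosen]
    confidence = 1.0
    for _, _, fraction in chosen:
        confidence *= fraction
    return Classification(
        query_id=query_id,
        lineage=Lineage(entries),
        taxonomic_level=stop_rank,
        taxid=stop_taxid,
        confidence=confidence,
        rank_fractions={rank: fraction for rank, _, fraction in chosen},
    )


def classify_all(
    records: Sequence[PafRecord],
    ref_taxids: Mapping[str, int],
    taxonomy: Taxonomy,
    min_support: float = 0.5,
    all_query_ids: Optional[Sequence[str]] = None,
) -> list[Classification]:
    """Classify every query in an alignment set; queries listed in
    ``all_query_ids`` but absent from the alignments come back unclassified."""
    if records:
        abundances = reference_abundance(records)
        per_query = group_coverages(records)
    else:
        abundances, per_query = {}, {}
    out = []
    seen = set()
    for query_id in sorted(per_query):
        seen.add(query_id)
        out.append(
            classify_query(
                per_query[query_id], abundances, ref_taxids, taxonomy, min_support
            )
        )
    if all_query_ids is not None:
        for query_id in all_query_ids:
            if query_id not in seen:
                out.append(_unclassified(query_id))
        order = {q: i for i, q in enumerate(all_query_ids)}
        out.sort(key=lambda c: order.get(c.query_id, len(order)))
    return out


_HEADER = ["Query", "Lineage", "Taxonomic Level", "TaxID", "Confidence"]


def write_classifications(
    classifications: Iterable[Classification], sink: str | Path
) -> None:
    """classified_sequences.tsv: Query, Lineage, Taxonomic Level, TaxID,
    Confidence (4 decimals)."""
    lines = ["\t".join(_HEADER)]
    for cls in classifications:
        taxid = "NA" if cls.taxid is None else str(cls.taxid)
        lines.append(
            "\t".join(
                [
                    cls.query_id,
                    cls.lineage.render(),
                    cls.taxonomic_level,
                    taxid,
                    f"{cls.confidence:.4f}",
                ]
            )
        )
    Path(sink).write_text("\n".join(lines) + "\n")


def read_classifications(path: str | Path) -> list[Classification]:
    """Read a classified_sequences.tsv back; lineages are reconstructed with
    names only (TaxIDs other than the representative are not round-tripped)."""
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].split("\t") != _HEADER:
        raise ValueError(f"{path}: missing classified_sequences header")
    out = []
    for line in lines[1:]:
        query, lineage_str, level, taxid, conf = line.split("\t")
        entries = []
        if lineage_str:
            prefix_to_rank = {"sk": "superkingdom", "p": "phylum", "c": "class",
                              "o": "order", "f": "family", "g": "genus",
                              "s": "species", "t": "strain"}
            for part in lineage_str.split(";"):
                prefix, name = part.split("__", 1)
                entries.append((prefix_to_rank.get(prefix, prefix), -1, name))
        out.append(
            Classification(
                query_id=query,
                lineage=Lineage(entries),
                taxonomic_level=level,
                taxid=None if taxid == "NA" else int(taxid),
                confidence=float(conf),
            )
        )
    return out
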