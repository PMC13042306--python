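"""Abundance profiles and CAMI-style evaluation metrics.

A profile maps, per taxonomic rank, TaxID → relative abundance.  Per-rank
sums may fall below 1 because mass from queries not classified to that
depth stays unassigned.  The scoring suite mirrors the CAMI conventions:

* presence/absence precision, recall, F1 at a minimum-abundance threshold
  (0.1% by default), reported in percent;
* L1 total variation Σ|p − q| over the union of taxa (no ½ factor, so
  L1 = 2 × Bray–Curtis for normalized profiles) on an explicit scale,
  fractions by default or percentage points;
* Bray–Curtis dissimilarity Σ|p − q| / Σ(p + q) in [0, 1];
* Pearson correlation of abundance vectors over the taxon union;
* contig-level accuracy: the fraction of truth contigs whose predicted
  lineage, projected to a rank, matches the truth lineage at that rank
  (unclassified-at-rank counts as incorrect).

Every pairwise metric zero-fills taxa present in only one profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .lca import Classification
from .taxonomy import RANKS, Taxonomy, canonical_rank

__all__ = [
    "Profile",
    "PresenceMetrics",
    "profile_from_classifications",
    "presence_metrics",
    "l1_distance",
    "bray_curtis",
    "pearson_abundance",
    "contig_accuracy",
    "rank_share_summary",
    "percent",
    "diff_table",
    "evaluate_profiles",
    "write_cami_profile",
    "read_cami_profile",
    "PRESENCE_THRESHOLD",
]

# CAMI presence/absence threshold: 0.1% relative abundance.
PRESENCE_THRESHOLD = 0.001

TaxonVector = Mapping[object, float]


@dataclass
class Profile:
    """Rank-indexed relative-abundance profile (fractions)."""

    per_rank: dict[str, dict[int, float]] = field(default_factory=dict)
    sample_id: str = ""
    basis: str = "contig-count"

    def at_rank(self, rank: str) -> dict[int, float]:
        return self.per_rank.get(canonical_rank(rank), {})

    def ranks(self) -> list[str]:
        return [r for r in RANKS if r in self.per_rank]


def _vector(profile: Union[Profile, TaxonVector], rank: Optional[str]) -> dict:
    """Accept either a Profile (with a rank) or a bare taxon→abundance map, so
    printed tables can be scored directly."""
    if isinstance(profile, Profile):
        if rank is None:
            raise ValueError("a rank is required when scoring a Profile")
        return dict(profile.at_rank(rank))
    return dict(profile)


def profile_from_classifications(
    classifications: Sequence[Classification],
    taxonomy: Optional[Taxonomy] = None,
    basis: str = "contig-count",
    lengths: Optional[Mapping[str, int]] = None,
    sample_id: str = "",
) -> Profile:
    """Aggregate per-query classifications into a rank-wise profile.

    Each query carries mass 1/N (contig-count basis) or length/total-length
    (length-weighted basis); the mass lands on its lineage's taxon at every
    rank the lineage reaches.  Shallow classifications leave the deeper
    ranks' sums below 1 (unclassified mass).
    """
    n = len(classifications)
    if basis == "length-weighted":
        if lengths is None:
            raise ValueError("length-weighted basis requires a lengths map")
        total_len = sum(lengths[c.query_id] for c in classifications)
    elif basis != "contig-count":
        raise ValueError(f"unknown profile basis: {basis!r}")

    per_rank: dict[str, dict[int, float]] = {rank: {} for rank in RANKS}
    for cls in classifications:
        if basis == "contig-count":
            mass = 1.0 / n if n else 0.0
        else:
            mass = lengths[cls.query_id] / total_len if total_len else 0.0
        for rank, taxid, _ in cls.lineage:
            bucket = per_rank[rank]
            bucket[taxid] = bucket.get(taxid, 0.0) + mass
    per_rank = {rank: taxa for rank, taxa in per_rank.items() if taxa}
    return Profile(per_rank=per_rank, sample_id=sample_id, basis=basis)


@dataclass(frozen=True)
class PresenceMetrics:
    precision: float  # percent
    recall: float  # percent
    f1: float  # percent
    pred_empty: bool = False


def presence_metrics(
    pred: Union[Profile, TaxonVector],
    truth: Union[Profile, TaxonVector],
    rank: Optional[str] = None,
    threshold: float = PRESENCE_THRESHOLD,
) -> PresenceMetrics:
    """Presence/absence precision, recall, F1 (percent) at an abundance
    threshold.  An empty truth-positive set leaves recall undefined and is an
    error; an empty predicted-positive set yields precision 0 with a flag.
    """
    p = {t for t, a in _vector(pred, rank).items() if a >= threshold}
    t = {t for t, a in _vector(truth, rank).items() if a >= threshold}
    if not t:
        raise ValueError("truth profile has no taxa above the presence threshold")
    if not p:
        return PresenceMetrics(0.0, 0.0, 0.0, pred_empty=True)
    tp = len(p & t)
    precision = 100.0 * tp / len(p)
    recall = 100.0 * tp / len(t)
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return PresenceMetrics(precision, recall, f1)


def _union_vectors(
    pred: Union[Profile, TaxonVector],
    truth: Union[Profile, TaxonVector],
    rank: Optional[str],
) -> tuple[np.ndarray, np.ndarray]:
    pv, tv = _vector(pred, rank), _vector(truth, rank)
    taxa = sorted(set(pv) | set(tv), key=repr)
    p = np.array([pv.get(t, 0.0) for t in taxa])
    q = np.array([tv.get(t, 0.0) for t in taxa])
    return p, q


def l1_distance(
    pred: Union[Profile, TaxonVector],
    truth: Union[Profile, TaxonVector],
    rank: Optional[str] = None,
    scale: str = "fraction",
) -> float:
    """Σ|pred − truth| over the taxon union; 'fraction' or 'pct' scale."""
    p, q = _union_vectors(pred, truth, rank)
    l1 = float(np.abs(p - q).sum())
    if scale == "pct":
        return 100.0 * l1
    if scale != "fraction":
        raise ValueError(f"unknown L1 scale {scale!r}")
    return l1


def bray_curtis(
    pred: Union[Profile, TaxonVector],
    truth: Union[Profile, TaxonVector],
    rank: Optional[str] = None,
) -> float:
    """Σ|p − q| / Σ(p + q); 0 for identical profiles, 1 for disjoint ones."""
    p, q = _union_vectors(pred, truth, rank)
    denom = float((p + q).sum())
    if denom == 0.0:
        raise ValueError("Bray–Curtis undefined: both profiles are empty")
    return float(np.abs(p - q).sum()) / denom


def pearson_abundance(
    pred: Union[Profile, TaxonVector],
    truth: Union[Profile, TaxonVector],
    rank: Optional[str] = None,
) -> float:
    """Pearson r over union abundance vectors (absent taxon = 0)."""
    p, q = _union_vectors(pred, truth, rank)
    if p.size < 2:
        raise ValueError("Pearson correlation needs at least 2 taxa in the union")
    if np.std(p) == 0.0 or np.std(q) == 0.0:
        raise ValueError("Pearson correlation undefined for zero-variance vector")
    return float(np.corrcoef(p, q)[0, 1])


def contig_accuracy(
    classifications: Sequence[Classification],
    truth: Mapping[str, int],
    taxonomy: Taxonomy,
    rank: str,
) -> float:
    """Percent of truth contigs whose prediction matches truth at a rank.

    Both sides are projected to the rank through the taxonomy; a contig
    whose prediction does not reach the rank (or is missing entirely)
    counts as incorrect.
    """
    if not truth:
        raise ValueError("contig truth map is empty")
    rank = canonical_rank(rank)
    predicted = {c.query_id: c for c in classifications}
    correct = 0
    for contig_id, true_taxid in truth.items():
        true_at_rank = taxonomy.project_to_rank(true_taxid, rank)
        cls = predicted.get(contig_id)
        if cls is None or true_at_rank is None:
            continue
        if cls.lineage.taxid_at(rank) == true_at_rank:
            correct += 1
    return 100.0 * correct / len(truth)


def percent(a: float, b: float) -> float:
    """100·a/b with an explicit zero-denominator error."""
    if b == 0:
        raise ValueError("percent undefined for zero denominator")
    return 100.0 * a / b


_SPECIES_GROUP = {"species", "strain"}


def rank_share_summary(classifications: Sequence[Classification]) -> dict[str, float]:
    """Share (percent) of classified queries by reporting depth:
    species/strain, genus, family, higher/unknown."""
    classified = [c for c in classifications if c.classified]
    if not classified:
        raise ValueError("no classified queries to summarize")
    groups = {"species/strain": 0, "genus": 0, "family": 0, "higher/unknown": 0}
    for cls in classified:
        if cls.taxonomic_level in _SPECIES_GROUP:
            groups["species/strain"] += 1
        elif cls.taxonomic_level == "genus":
            groups["genus"] += 1
        elif cls.taxonomic_level == "family":
            groups["family"] += 1
        else:
            groups["higher/unknown"] += 1
    n = len(classified)
    return {group: percent(count, n) for group, count in groups.items()}


def diff_table(
    pred: Union[Profile, TaxonVector],
    truth: Union[Profile, TaxonVector],
    rank: Optional[str] = None,
) -> pd.DataFrame:
    """Per-taxon (truth %, predicted %, diff pp) rows over the taxon union,
    sorted by truth abundance descending.  Diff is predicted minus truth in
    percentage points; a taxon present on one side only is zero-filled."""
    pv, tv = _vector(pred, rank), _vector(truth, rank)
    taxa = sorted(set(pv) | set(tv), key=lambda t: (-tv.get(t, 0.0), repr(t)))
    rows = [
        {
            "taxon": t,
            "truth_pct": 100.0 * tv.get(t, 0.0),
            "pred_pct": 100.0 * pv.get(t, 0.0),
            "diff_pp": 100.0 * (pv.get(t, 0.0) - tv.get(t, 0.0)),
        }
        for t in taxa
    ]
    return pd.DataFrame(rows, columns=["taxon", "truth_pct", "pred_pct", "diff_pp"])


def evaluate_profiles(
    pred: Profile,
    truth: Profile,
    ranks: Optional[Sequence[str]] = None,
    threshold: float = PRESENCE_THRESHOLD,
) -> pd.DataFrame:
    """Per-rank metric table plus a mean row (ranks averaged with equal
    weight).  Ranks default to those present in the truth profile."""
    if ranks is None:
        ranks = truth.ranks()
    rows = []
    for rank in ranks:
        pm = presence_metrics(pred, truth, rank, threshold=threshold)
        row = {
            "rank": rank,
            "precision": pm.precision,
            "recall": pm.recall,
            "f1": pm.f1,
            "l1": l1_distance(pred, truth, rank),
            "bray_curtis": bray_curtis(pred, truth, rank),
        }
        rows.append(row)
    df = pd.DataFrame(rows)
    mean = df.drop(columns="rank").mean()
    mean["rank"] = "mean"
    return pd.concat([df, mean.to_frame().T], ignore_index=True)[
        ["rank", "precision", "recall", "f1", "l1", "bray_curtis"]
    ]


# ---------------------------------------------------------------------------
# CAMI profiling format I/O (header + TAXID/RANK/TAXPATH/TAXPATHSN/PERCENTAGE)


def write_cami_profile(
    profile: Profile, taxonomy: Taxonomy, path: str | Path
) -> None:
    lines = [
        f"@SampleID:{profile.sample_id}",
        "@Version:0.9.1",
        f"@Ranks:{'|'.join(profile.ranks())}",
        "@@TAXID\tRANK\tTAXPATH\tTAXPATHSN\tPERCENTAGE",
    ]
    for rank in profile.ranks():
        taxa = profile.at_rank(rank)
        for taxid in sorted(taxa, key=lambda t: (-taxa[t], t)):
            lineage = taxonomy.lineage_of(taxid)
            taxpath = "|".join(str(t) for _, t, _ in lineage)
            taxpathsn = "|".join(name for _, _, name in lineage)
            lines.append(
                f"{taxid}\t{rank}\t{taxpath}\t{taxpathsn}\t{100.0 * taxa[taxid]:.6f}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_cami_profile(path: str | Path) -> Profile:
    profile = Profile()
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        if line.startswith("@SampleID:"):
            profile.sample_id = line.split(":", 1)[1].strip()
            continue
        if line.startswith("@"):
            continue
        taxid, rank, _taxpath, _taxpathsn, pct = line.split("\t")
        rank = canonical_rank(rank)
        profile.per_rank.setdefault(rank, {})[int(taxid)] = float(pct) / 100.0
    return profile
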