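"""Sample-adaptive candidate selection over containment screen hits.

A fixed containment cut-off either floods the aligner with near-duplicate
references or starves it when the sample diverges from the database.  The
selection loop instead starts at a stringent threshold (0.90 containment by
default) and lowers it in 0.02 steps until the candidate count reaches a
sample-scaled target (~3.25 per input sequence, rounded, minimum 5), or
until it hits a hard floor of 0.70, below which hits are treated as noise
and never returned.

Optionally, candidates are deduplicated to one reference per species (the
highest-containment representative) before counting, so the target caps
species-unique candidates rather than redundant assemblies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

from .sketch import ScreenHit

__all__ = [
    "CandidateBudget",
    "Candidate",
    "CandidateSet",
    "candidate_target",
    "adaptive_select",
    "dedup_species",
    "write_candidate_manifest",
]

# Containment values carry float noise from shared/s division; thresholds
# are compared with a small slack so e.g. 0.79 passes a 0.79 threshold.
_EPS = 1e-9


@dataclass(frozen=True)
class CandidateBudget:
    per_sequence: float = 3.25
    minimum: int = 5
    start_threshold: float = 0.90
    step: float = 0.02
    floor_threshold: float = 0.70
    dedup_species: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.floor_threshold <= self.start_threshold <= 1:
            raise ValueError(
                "need 0 < floor_threshold <= start_threshold <= 1, got "
                f"floor={self.floor_threshold}, start={self.start_threshold}"
            )
        if self.step <= 0:
            raise ValueError(f"step must be > 0, got {self.step}")


@dataclass(frozen=True)
class Candidate:
    ref_id: str
    containment: float
    species_taxid: Optional[int] = None


@dataclass
class CandidateSet:
    candidates: list[Candidate]
    final_threshold: float
    target_count: int
    n_queries: int

    def __len__(self) -> int:
        return len(self.candidates)

    def ref_ids(self) -> list[str]:
        return [c.ref_id for c in self.candidates]


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


def candidate_target(n_queries: int, budget: CandidateBudget) -> int:
    """Number of candidates to aim for: per_sequence × n_queries, rounded half
    up, never below the budget minimum."""
    if n_queries < 1:
        raise ValueError("candidate target needs at least one query sequence")
    return max(_round_half_up(budget.per_sequence * n_queries), budget.minimum)


def dedup_species(
    candidates: Sequence[Candidate],
    species_map: Optional[Mapping[str, int]],
) -> list[Candidate]:
    """Keep one candidate per species TaxID: highest containment, ties broken
    by lexicographically smallest ref_id.  Candidates absent from the map pass
    through untouched.  Idempotent."""
    if species_map is None:
        return list(candidates)
    best: dict[int, Candidate] = {}
    passthrough: list[Candidate] = []
    for cand in candidates:
        sp = cand.species_taxid
        if sp is None:
            sp = species_map.get(cand.ref_id)
        if sp is None:
            passthrough.append(cand)
            continue
        cand = Candidate(cand.ref_id, cand.containment, sp)
        incumbent = best.get(sp)
        if (
            incumbent is None
            or cand.containment > incumbent.containment + _EPS
            or (
                abs(cand.containment - incumbent.containment) <= _EPS
                and cand.ref_id < incumbent.ref_id
            )
        ):
            best[sp] = cand
    return _sorted(passthrough + list(best.values()))


def _sorted(candidates: list[Candidate]) -> list[Candidate]:
    return sorted(candidates, key=lambda c: (-c.containment, c.ref_id))


def adaptive_select(
    hits: Sequence[ScreenHit],
    n_queries: int,
    budget: CandidateBudget = CandidateBudget(),
    species_map: Optional[Mapping[str, int]] = None,
) -> CandidateSet:
    """Lower the containment threshold step-wise until the target is met.

    Thresholds walk an exact decimal grid (integer hundredths) from
    start_threshold down to floor_threshold; at each step the qualifying
    hits are counted after optional species deduplication.  If the floor is
    reached without meeting the target, whatever qualifies at the floor is
    returned (possibly nothing).
    """
    target = candidate_target(n_queries, budget)
    start_h = round(budget.start_threshold * 100)
    floor_h = round(budget.floor_threshold * 100)
    step_h = max(round(budget.step * 100), 1)

    selected: list[Candidate] = []
    final = budget.floor_threshold
    thr_h = start_h
    while thr_h >= floor_h:
        thr = thr_h / 100.0
        pool = [
            Candidate(h.ref_id, h.containment)
            for h in hits
            if h.containment >= thr - _EPS
        ]
        if budget.dedup_species and species_map is not None:
            pool = dedup_species(pool, species_map)
        selected = _sorted(pool)
        final = thr
        if len(selected) >= target:
            break
        thr_h -= step_h
    return CandidateSet(
        candidates=selected,
        final_threshold=final,
        target_count=target,
        n_queries=n_queries,
    )


def write_candidate_manifest(cset: CandidateSet, path: str | Path) -> None:
    """TSV manifest: ref_id, containment, species_taxid, final_threshold."""
    lines = ["ref_id\tcontainment\tspecies_taxid\tfinal_threshold"]
    for c in cset.candidates:
        sp = "" if c.species_taxid is None else str(c.species_taxid)
        lines.append(f"{c.ref_id}\t{c.containment:.6f}\t{sp}\t{cset.final_threshold:.2f}")
    Path(path).write_text("\n".join(lines) + "\n")
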