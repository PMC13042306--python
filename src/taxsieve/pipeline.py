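"""End-to-end composition of the classification stages.

The canonical flow is: sketch references → screen the pooled query k-mer
set for per-reference containment → adaptively select candidate references
→ obtain query↔candidate alignments (PAF, produced externally, by the
optional minimap2 hook, or synthetically) → coverage-weighted LCA
classification → rank-wise abundance profile and metrics.

`run_community_pipeline` wires those stages over in-memory synthetic
communities and is what the simulation-backed experiments (parameter
recovery, mutation sweeps, reference ablation) drive; the file-based entry
points in :mod:`taxsieve.cli` wrap the same functions.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

from .candidates import CandidateBudget, CandidateSet, adaptive_select
from .lca import Classification, classify_all
from .metrics import (
    Profile,
    presence_metrics,
    profile_from_classifications,
)
from .paf import PafRecord
from .simulate import (
    MutationParams,
    NoiseModel,
    SyntheticCommunity,
    mutate,
    profile_from_truth,
    synth_paf,
)
from .sketch import ScreenHit, Sketch, SketchParams, build_sketch, query_kmer_hashes, screen_references

__all__ = [
    "PipelineResult",
    "screen_and_select",
    "run_community_pipeline",
    "mutation_sweep",
    "RunConfig",
]


@dataclass
class PipelineResult:
    classifications: list[Classification]
    profile: Profile
    candidate_set: CandidateSet
    hits: list[ScreenHit]
    paf_records: list[PafRecord]

    def by_query(self) -> dict[str, Classification]:
        return {c.query_id: c for c in self.classifications}


def screen_and_select(
    query_sequences: Sequence[str],
    sketches: Sequence[Sketch],
    params: SketchParams,
    budget: CandidateBudget = CandidateBudget(),
    species_map: Optional[Mapping[str, int]] = None,
) -> tuple[list[ScreenHit], CandidateSet]:
    """Containment-screen every reference against the pooled query k-mer set
    and apply the adaptive candidate budget."""
    query_hashes = query_kmer_hashes(query_sequences, params)
    hits = screen_references(query_hashes, sketches)
    cset = adaptive_select(hits, len(query_sequences), budget, species_map)
    return hits, cset


def run_community_pipeline(
    community: SyntheticCommunity,
    queries: Optional[Sequence[tuple[str, str]]] = None,
    query_truth: Optional[Mapping[str, int]] = None,
    references: Optional[Sequence[tuple[str, str, int]]] = None,
    noise_model: NoiseModel = NoiseModel(),
    sketch_params: SketchParams = SketchParams(k=15, s=200, seed=42),
    budget: CandidateBudget = CandidateBudget(),
    min_support: float = 0.5,
    seed: int = 0,
) -> PipelineResult:
    """Full pipeline over a synthetic community.

    ``queries`` defaults to the community's contigs, ``references`` to its
    genomes (pass an ablated or otherwise modified set to probe robustness),
    and alignments come from the synthetic-PAF noise model restricted to the
    selected candidate references.
    """
    queries = list(queries if queries is not None else community.contigs)
    query_truth = dict(
        query_truth if query_truth is not None else community.contig_truth
    )
    references = list(references if references is not None else community.genomes)

    sketches = [
        build_sketch(seq, sketch_params, ref_id=ref_id)
        for ref_id, seq, _ in sorted(references)
    ]
    species_map = {
        ref_id: community.taxonomy.project_to_rank(taxid, "species") or taxid
        for ref_id, _, taxid in references
    }
    hits, cset = screen_and_select(
        [seq for _, seq in queries], sketches, sketch_params, budget, species_map
    )
    selected = set(cset.ref_ids())
    candidate_refs = [r for r in references if r[0] in selected]

    records = synth_paf(
        queries,
        candidate_refs,
        query_truth,
        noise_model=noise_model,
        taxonomy=community.taxonomy,
        seed=seed,
    )
    ref_taxids = {ref_id: taxid for ref_id, _, taxid in references}
    classifications = classify_all(
        records,
        ref_taxids,
        community.taxonomy,
        min_support=min_support,
        all_query_ids=[qid for qid, _ in queries],
    )
    profile = profile_from_classifications(classifications, community.taxonomy)
    return PipelineResult(classifications, profile, cset, hits, records)


def mutation_sweep(
    community: SyntheticCommunity,
    rates: Sequence[float] = (0.0, 0.1, 0.2, 0.3),
    sketch_params: SketchParams = SketchParams(k=15, s=200, seed=42),
    budget: CandidateBudget = CandidateBudget(),
    min_support: float = 0.5,
    seed: int = 0,
) -> dict[float, float]:
    """Species-rank presence F1 (percent) as the query contigs diverge.

    Each rate mutates every contig under the point-mutation + short-indel
    model (fixed per-contig seeds derived from ``seed``) and re-runs the
    whole pipeline; the synthetic alignments carry the matching identity.
    """
    truth = community.truth_profile
    out: dict[float, float] = {}
    for rate in rates:
        mutated = [
            (cid, mutate(seq, MutationParams(rate=rate, seed=seed + 7919 * i)))
            for i, (cid, seq) in enumerate(community.contigs)
        ]
        noise = (
            NoiseModel(kind="perfect")
            if rate == 0.0
            else NoiseModel(kind="partial", identity=max(1.0 - rate, 0.5))
        )
        result = run_community_pipeline(
            community,
            queries=mutated,
            noise_model=noise,
            sketch_params=sketch_params,
            budget=budget,
            min_support=min_support,
            seed=seed,
        )
        try:
            f1 = presence_metrics(result.profile, truth, "species").f1
        except ValueError:
            f1 = 0.0
        out[rate] = f1
    return out


# ---------------------------------------------------------------------------
# Run configuration (file-based pipeline; serialized next to every run so a
# saved config re-executes identically on identical inputs).


@dataclass
class RunConfig:
    queries: str = ""
    references: str = ""
    taxonomy_nodes: str = ""
    taxonomy_names: str = ""
    assembly_summary: str = ""
    ref_taxids: str = ""
    paf: str = ""
    outdir: str = "taxsieve_out"
    k: int = 21
    s: int = 1000
    hash_seed: int = 42
    per_sequence: float = 3.25
    minimum: int = 5
    start_threshold: float = 0.90
    step: float = 0.02
    floor_threshold: float = 0.70
    dedup_species: bool = True
    min_support: float = 0.5
    basis: str = "contig-count"
    threads: int = 1
    seed: int = 0

    def sketch_params(self) -> SketchParams:
        return SketchParams(k=self.k, s=self.s, seed=self.hash_seed)

    def budget(self) -> CandidateBudget:
        return CandidateBudget(
            per_sequence=self.per_sequence,
            minimum=self.minimum,
            start_threshold=self.start_threshold,
            step=self.step,
            floor_threshold=self.floor_threshold,
            dedup_species=self.dedup_species,
        )

    def to_text(self) -> str:
        return "\n".join(f"{k}={v}" for k, v in sorted(asdict(self).items())) + "\n"

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_text())

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        cfg = cls()
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            current = getattr(cfg, key)
            if isinstance(current, bool):
                setattr(cfg, key, value.strip().lower() in ("1", "true", "yes"))
            elif isinstance(current, int):
                setattr(cfg, key, int(value))
            elif isinstance(current, float):
                setattr(cfg, key, float(value))
            else:
                setattr(cfg, key, value.strip())
        return cfg

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_text().encode()).hexdigest()[:16]


def write_provenance(path: str | Path, config: RunConfig, note: str = "") -> None:
    """Sidecar naming the config hash so every artifact is traceable to the
    exact parameters that produced it."""
    lines = [
        f"config_hash={config.config_hash()}",
        f"seed={config.seed}",
        f"written={time.strftime('%Y-%m-%dT%H:%M:%S')}",
    ]
    if note:
        lines.append(f"note={note}")
    Path(path).write_text("\n".join(lines) + "\n")
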