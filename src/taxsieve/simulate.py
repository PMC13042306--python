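"""Synthetic communities, contigs, reads, mutations, and alignments.

Everything the pipeline consumes can be generated here with explicit
integer seeds and no network access: multi-domain communities with
rank-complete lineages, contig fragmentation, point-mutation + short-indel
divergence, deterministic 250 bp read windowing, synthetic PAF alignments
under declared noise models, and progressive reference ablation.

Genomes are i.i.d. random nucleotide strings, so distinct species share no
k-mer signal; relatedness between congeneric species is emulated at the
alignment layer (the cross-species bleed noise model) rather than at the
sequence layer.  The default community shape includes one four-species
genus so that sister-species effects — the dominant failure mode of
species-level classification — are exercised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .metrics import Profile
from .paf import PafRecord, write_paf as write_paf_records
from .taxonomy import RANKS, Taxonomy, TaxonomyNode

__all__ = [
    "SyntheticCommunity",
    "MutationParams",
    "NoiseModel",
    "generate_community",
    "generate_taxonomy",
    "fragment_contigs",
    "window_reads",
    "read_truth_from_contigs",
    "mutate",
    "synth_paf",
    "ablate_references",
    "write_fasta",
    "write_paf_records",
    "write_taxonomy_tsv",
    "write_contig_truth",
    "write_assembly_summary",
    "profile_from_truth",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_SUPERKINGDOMS = ("Bacteria", "Archaea", "Eukaryota")


@dataclass(frozen=True)
class MutationParams:
    """Per-base divergence model: each base independently suffers an event
    with probability ``rate``; an event is a substitution with probability
    ``sub_fraction``, otherwise an insertion or deletion (equally likely)
    whose length is geometric with mean ``indel_mean_len``."""

    rate: float = 0.0
    sub_fraction: float = 0.9
    indel_mean_len: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate <= 0.5:
            raise ValueError(f"mutation rate must lie in [0, 0.5], got {self.rate}")
        if not 0.0 <= self.sub_fraction <= 1.0:
            raise ValueError("sub_fraction must lie in [0, 1]")
        if self.indel_mean_len < 1.0:
            raise ValueError("indel_mean_len must be >= 1")


@dataclass(frozen=True)
class NoiseModel:
    """Synthetic-alignment behaviour.

    kind="perfect": each contig gets one full-length, mismatch-free record
    to its source reference.  kind="partial": the record covers a random
    fraction of the contig at sub-unit identity, so the exact-match path
    never fires.  Independently, ``bleed_prob`` adds an off-target record to
    a same-genus reference, and contigs whose source reference is absent
    (e.g. after ablation) bleed to *all* remaining same-genus references.
    """

    kind: str = "perfect"
    partial_coverage: tuple[float, float] = (0.5, 0.9)
    identity: float = 0.95
    bleed_coverage: tuple[float, float] = (0.4, 0.6)
    bleed_identity: float = 0.92
    bleed_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("perfect", "partial"):
            raise ValueError(f"noise model kind must be perfect or partial: {self.kind!r}")


@dataclass
class SyntheticCommunity:
    """A community with every truth asset the evaluation layer needs."""

    genomes: list[tuple[str, str, int]]  # (ref_id, sequence, taxid)
    contigs: list[tuple[str, str]]  # (contig_id, sequence)
    taxonomy: Taxonomy
    truth_profile: Profile
    contig_truth: dict[str, int]
    seed: int

    def ref_taxids(self) -> dict[str, int]:
        return {ref_id: taxid for ref_id, _, taxid in self.genomes}

    def species_map(self) -> dict[str, int]:
        out = {}
        for ref_id, _, taxid in self.genomes:
            sp = self.taxonomy.project_to_rank(taxid, "species")
            if sp is not None:
                out[ref_id] = sp
        return out

    def contig_lengths(self) -> dict[str, int]:
        return {cid: len(seq) for cid, seq in self.contigs}


def _default_shape(n_taxa: int) -> tuple[int, ...]:
    """Species-per-genus layout: one 4-species genus when the community is
    big enough, then genera of 2, then singletons."""
    if n_taxa <= 3:
        return tuple([1] * n_taxa)
    shape = [4] if n_taxa >= 5 else [2]
    remaining = n_taxa - shape[0]
    while remaining >= 4:
        shape.append(2)
        remaining -= 2
    shape.extend([1] * remaining)
    return tuple(shape)


def generate_taxonomy(
    species_per_genus: Sequence[int], n_superkingdoms: int = 2
) -> tuple[Taxonomy, list[int]]:
    """Rank-complete taxonomy for the given genus layout.

    Genera are dealt round-robin across superkingdoms (up to three domains),
    then wrapped in per-superkingdom phylum/class/order chains with genera
    paired two-per-family.  Returns the taxonomy and the species TaxIDs in
    genus order.
    """
    if not species_per_genus:
        raise ValueError("need at least one genus")
    n_sk = min(max(n_superkingdoms, 1), len(_SUPERKINGDOMS), len(species_per_genus))
    nodes = [TaxonomyNode(1, 1, "no-rank", "root")]
    next_id = 2
    sk_chain: list[dict[str, int]] = []
    for i in range(n_sk):
        chain = {}
        parent = 1
        for rank, label in (
            ("superkingdom", _SUPERKINGDOMS[i]),
            ("phylum", f"{_SUPERKINGDOMS[i]}_phylum"),
            ("class", f"{_SUPERKINGDOMS[i]}_class"),
            ("order", f"{_SUPERKINGDOMS[i]}_order"),
        ):
            nodes.append(TaxonomyNode(next_id, parent, rank, label))
            chain[rank] = next_id
            parent = next_id
            next_id += 1
        sk_chain.append(chain)

    species_taxids: list[int] = []
    family_of_sk: dict[int, tuple[int, int]] = {}  # sk -> (family taxid, genera in it)
    for g, n_species in enumerate(species_per_genus):
        sk = g % n_sk
        fam, used = family_of_sk.get(sk, (0, 2))
        if used >= 2:  # start a new family under this superkingdom's order
            fam = next_id
            nodes.append(
                TaxonomyNode(next_id, sk_chain[sk]["order"], "family", f"Family_{next_id}")
            )
            next_id += 1
            used = 0
        family_of_sk[sk] = (fam, used + 1)
        genus = next_id
        nodes.append(TaxonomyNode(genus, fam, "genus", f"Genus_{genus}"))
        next_id += 1
        for s in range(n_species):
            nodes.append(
                TaxonomyNode(next_id, genus, "species", f"Species_{genus}_{s + 1}")
            )
            species_taxids.append(next_id)
            next_id += 1
    return Taxonomy(nodes), species_taxids


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def fragment_contigs(
    genome: str,
    taxid: int,
    n_fragments: Optional[int] = None,
    length_range: Optional[tuple[int, int]] = None,
    seed: int = 0,
    id_prefix: str = "CTG",
) -> tuple[list[tuple[str, str]], dict[str, int]]:
    """Tile a genome into contigs (substrings, no overlap, full coverage).

    Either a fragment count or a length range must be given.  Contig lengths
    under a length range are drawn uniformly; a short terminal remainder is
    merged into the last contig.  Deterministic under seed.
    """
    if not genome:
        raise ValueError("cannot fragment an empty genome")
    L = len(genome)
    bounds: list[int] = [0]
    if n_fragments is not None:
        if n_fragments < 1 or n_fragments > L:
            raise ValueError(f"cannot cut {L} bases into {n_fragments} fragments")
        for i in range(1, n_fragments):
            bounds.append(round(i * L / n_fragments))
    elif length_range is not None:
        lo, hi = length_range
        if lo < 1 or hi < lo:
            raise ValueError(f"bad contig length range {length_range}")
        if hi > L:
            raise ValueError(f"requested fragment length {hi} exceeds genome length {L}")
        rng = np.random.default_rng(seed)
        pos = 0
        while L - pos > hi:
            pos += int(rng.integers(lo, hi + 1))
            if L - pos < lo:  # merge the runt into the previous contig
                pos = L
            bounds.append(min(pos, L))
    else:
        raise ValueError("give either n_fragments or length_range")
    if bounds[-1] != L:
        bounds.append(L)
    contigs = []
    truth = {}
    for i in range(len(bounds) - 1):
        cid = f"{id_prefix}_{i:04d}"
        contigs.append((cid, genome[bounds[i] : bounds[i + 1]]))
        truth[cid] = taxid
    return contigs, truth


def window_reads(
    contigs: Sequence[tuple[str, str]], window: int = 250, min_tail: int = 125
) -> list[tuple[str, str]]:
    """Deterministic read simulation: consecutive non-overlapping windows of
    ``window`` bases per contig; the final partial window is kept iff its
    length is at least ``min_tail``."""
    if window <= 0:
        raise ValueError("window must be positive")
    if not 0 < min_tail <= window:
        raise ValueError("need 0 < min_tail <= window")
    reads = []
    for cid, seq in contigs:
        n_full = len(seq) // window
        for i in range(n_full):
            reads.append((f"{cid}:w{i}", seq[i * window : (i + 1) * window]))
        tail = len(seq) - n_full * window
        if tail >= min_tail:
            reads.append((f"{cid}:w{n_full}", seq[n_full * window :]))
    return reads


def read_truth_from_contigs(
    reads: Sequence[tuple[str, str]], contig_truth: Mapping[str, int]
) -> dict[str, int]:
    """Read-level truth map: each windowed read inherits its contig's TaxID."""
    return {rid: contig_truth[rid.rsplit(":w", 1)[0]] for rid, _ in reads}


def mutate(sequence: str, params: MutationParams) -> str:
    """Apply the point-mutation + short-indel model; identical output for
    identical (sequence, params)."""
    if params.rate == 0.0 or not sequence:
        return sequence
    rng = np.random.default_rng(params.seed)
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    L = arr.size
    hit = np.nonzero(rng.random(L) < params.rate)[0]
    if hit.size == 0:
        return sequence
    is_sub = rng.random(hit.size) < params.sub_fraction
    is_ins = rng.random(hit.size) < 0.5
    geom_p = 1.0 / params.indel_mean_len
    lengths = rng.geometric(geom_p, size=hit.size)
    # Substitution targets: uniformly one of the 3 other bases.
    offsets = rng.integers(1, 4, size=hit.size)

    pieces: list[np.ndarray] = []
    cursor = 0
    for j, pos in enumerate(hit):
        if pos < cursor:
            continue  # swallowed by an earlier deletion
        pieces.append(arr[cursor:pos])
        if is_sub[j]:
            code = int(np.where(_BASES == arr[pos])[0][0])
            pieces.append(_BASES[[(code + int(offsets[j])) % 4]])
            cursor = pos + 1
        elif is_ins[j]:
            ins = rng.choice(_BASES, size=int(lengths[j]))
            pieces.append(ins)
            pieces.append(arr[pos : pos + 1])
            cursor = pos + 1
        else:
            cursor = pos + int(lengths[j])
    pieces.append(arr[cursor:])
    return np.concatenate(pieces).tobytes().decode("ascii")


def profile_from_truth(
    contig_truth: Mapping[str, int], taxonomy: Taxonomy, sample_id: str = "truth"
) -> Profile:
    """Count-basis truth profile: each contig contributes 1/N at every rank
    its lineage reaches."""
    n = len(contig_truth)
    if n == 0:
        raise ValueError("empty contig truth map")
    per_rank: dict[str, dict[int, float]] = {}
    for taxid in contig_truth.values():
        for rank, rank_taxid, _ in taxonomy.lineage_of(taxid):
            bucket = per_rank.setdefault(rank, {})
            bucket[rank_taxid] = bucket.get(rank_taxid, 0.0) + 1.0 / n
    return Profile(per_rank=per_rank, sample_id=sample_id, basis="contig-count")


def generate_community(
    n_taxa: int = 10,
    genome_len_range: tuple[int, int] = (25_000, 35_000),
    taxonomy_shape: Optional[Sequence[int]] = None,
    seed: int = 0,
    contig_len_range: tuple[int, int] = (2_000, 5_000),
    n_fragments_per_genome: Optional[int] = None,
) -> SyntheticCommunity:
    """Random community with genomes, tiled contigs, and truth assets.

    One reference genome per species; contigs tile each genome completely so
    an unablated reference set fully explains every contig.  The truth
    profile is on the contig-count basis, consistent with the generated
    contigs.  ``n_fragments_per_genome`` forces an equal contig count per
    genome (a balanced design useful for ablation experiments); otherwise
    contig lengths are drawn from ``contig_len_range``.
    """
    if n_taxa < 1:
        raise ValueError("need at least one taxon")
    shape = tuple(taxonomy_shape) if taxonomy_shape is not None else _default_shape(n_taxa)
    if sum(shape) != n_taxa:
        raise ValueError(f"taxonomy shape {shape} does not sum to n_taxa={n_taxa}")
    taxonomy, species_taxids = generate_taxonomy(shape)
    rng = np.random.default_rng(seed)

    genomes: list[tuple[str, str, int]] = []
    contigs: list[tuple[str, str]] = []
    contig_truth: dict[str, int] = {}
    for i, taxid in enumerate(species_taxids):
        length = int(rng.integers(genome_len_range[0], genome_len_range[1] + 1))
        seq = _random_sequence(rng, length)
        ref_id = f"GCF_{taxid:09d}.1"
        genomes.append((ref_id, seq, taxid))
        ctgs, truth = fragment_contigs(
            seq,
            taxid,
            n_fragments=n_fragments_per_genome,
            length_range=None if n_fragments_per_genome else contig_len_range,
            seed=int(rng.integers(0, 2**31 - 1)),
            id_prefix=f"CTG{i:02d}",
        )
        contigs.extend(ctgs)
        contig_truth.update(truth)

    truth_profile = profile_from_truth(contig_truth, taxonomy)
    return SyntheticCommunity(
        genomes=genomes,
        contigs=contigs,
        taxonomy=taxonomy,
        truth_profile=truth_profile,
        contig_truth=contig_truth,
        seed=seed,
    )


def synth_paf(
    contigs: Sequence[tuple[str, str]],
    references: Sequence[tuple[str, str, int]],
    contig_truth: Mapping[str, int],
    noise_model: NoiseModel = NoiseModel(),
    taxonomy: Optional[Taxonomy] = None,
    seed: int = 0,
) -> list[PafRecord]:
    """Emit synthetic PAF records linking contigs to references.

    Each contig whose source species has a reference present gets a record
    per the noise model; contigs whose source reference is missing bleed to
    every remaining same-genus reference (requires a taxonomy), emulating an
    aligner falling back to near relatives.
    """
    rng = np.random.default_rng(seed)
    by_taxid: dict[int, list[tuple[str, str]]] = {}
    for ref_id, seq, taxid in references:
        by_taxid.setdefault(taxid, []).append((ref_id, seq))
    genus_of: dict[int, Optional[int]] = {}
    if taxonomy is not None:
        for taxid in set(contig_truth.values()) | set(by_taxid):
            genus_of[taxid] = taxonomy.project_to_rank(taxid, "genus")

    records: list[PafRecord] = []

    def emit(cid: str, clen: int, ref_id: str, rlen: int, coverage: float,
             identity: float) -> None:
        span = max(int(round(coverage * clen)), 1)
        span = min(span, clen, rlen)
        matches = max(int(round(identity * span)), 1)
        records.append(
            PafRecord(
                query_id=cid, query_len=clen, query_start=0, query_end=span,
                strand="+", target_id=ref_id, target_len=rlen,
                target_start=0, target_end=span,
                n_matches=min(matches, span), block_len=span, mapq=60,
            )
        )

    for cid, seq in contigs:
        clen = len(seq)
        true_taxid = contig_truth[cid]
        true_refs = sorted(by_taxid.get(true_taxid, []))
        if true_refs:
            ref_id, rseq = true_refs[0]
            if noise_model.kind == "perfect":
                emit(cid, clen, ref_id, len(rseq), 1.0, 1.0)
            else:
                cov = rng.uniform(*noise_model.partial_coverage)
                emit(cid, clen, ref_id, len(rseq), cov, noise_model.identity)
            if noise_model.bleed_prob > 0 and rng.random() < noise_model.bleed_prob:
                target = _bleed_targets(true_taxid, by_taxid, genus_of)
                if target:
                    pick = target[int(rng.integers(len(target)))]
                    cov = rng.uniform(*noise_model.bleed_coverage)
                    emit(cid, clen, pick[0], len(pick[1]), cov,
                         noise_model.bleed_identity)
        else:
            for ref_id, rseq in _bleed_targets(true_taxid, by_taxid, genus_of):
                cov = rng.uniform(*noise_model.bleed_coverage)
                emit(cid, clen, ref_id, len(rseq), cov, noise_model.bleed_identity)
    return records


def _bleed_targets(
    true_taxid: int,
    by_taxid: Mapping[int, list[tuple[str, str]]],
    genus_of: Mapping[int, Optional[int]],
) -> list[tuple[str, str]]:
    genus = genus_of.get(true_taxid)
    if genus is None:
        return []
    out = []
    for taxid, refs in sorted(by_taxid.items()):
        if taxid != true_taxid and genus_of.get(taxid) == genus:
            out.extend(sorted(refs))
    return out


def ablate_references(
    references: Sequence[tuple[str, str, int]],
    taxids_to_remove: Sequence[int],
    level: float,
    seed: int = 0,
) -> list[tuple[str, str, int]]:
    """Remove floor(level × n) of each listed taxon's reference sequences,
    chosen reproducibly under seed; emulates progressively incomplete
    reference databases."""
    if not 0.0 <= level <= 1.0:
        raise ValueError(f"ablation level must lie in [0, 1], got {level}")
    present = {taxid for _, _, taxid in references}
    for taxid in taxids_to_remove:
        if taxid not in present:
            raise KeyError(f"taxid {taxid} has no references to ablate")
    rng = np.random.default_rng(seed)
    drop: set[str] = set()
    for taxid in sorted(set(taxids_to_remove)):
        refs = sorted(r for r, _, t in references if t == taxid)
        k = math.floor(level * len(refs))
        if k:
            drop.update(rng.choice(refs, size=k, replace=False).tolist())
    return [(r, s, t) for r, s, t in references if r not in drop]


# ---------------------------------------------------------------------------
# Plain-text writers for the pipeline's file interfaces.


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_taxonomy_tsv(taxonomy: Taxonomy, path: str | Path) -> None:
    lines = [
        f"{n.taxid}\t{n.parent_taxid}\t{n.rank}\t{n.name}"
        for n in sorted(taxonomy.nodes.values(), key=lambda n: n.taxid)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def write_contig_truth(contig_truth: Mapping[str, int], path: str | Path) -> None:
    lines = [f"{cid}\t{taxid}" for cid, taxid in sorted(contig_truth.items())]
    Path(path).write_text("\n".join(lines) + "\n")


def write_assembly_summary(
    references: Sequence[tuple[str, str, int]], taxonomy: Taxonomy, path: str | Path
) -> None:
    """Assembly-summary-style TSV (accession, taxid, species_taxid)."""
    lines = ["# assembly_accession\ttaxid\tspecies_taxid"]
    for ref_id, _, taxid in references:
        sp = taxonomy.project_to_rank(taxid, "species") or taxid
        lines.append(f"{ref_id}\t{taxid}\t{sp}")
    Path(path).write_text("\n".join(lines) + "\n")
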