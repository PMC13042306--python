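"""Bottom-s MinHash sketching and containment screening.

The screening stage asks, for every reference genome, what fraction of the
reference is present in a query sequence set.  Following the Mash-screen
formulation, each reference is condensed to a *bottom-s sketch*: the s
smallest 64-bit hash values of its canonical k-mer set.  The containment
index of reference A in query B is then estimated as

    c_k(A, B) = |S(A) ∩ π(B)| / |S(A)|

where S(A) is the reference sketch and π(B) the full distinct k-mer hash
set of the query.  The estimate carries an error on the order of
sqrt(1/s), so larger sketches buy precision at the cost of memory.

k-mers are canonicalised (lexicographic minimum of a k-mer and its reverse
complement) before hashing, so sketches are strand-agnostic.  Hashing is a
seeded 64-bit MurmurHash3-style finalizer applied to the 2-bit packing of
the canonical k-mer; sketches built with different (k, seed) pairs are
incomparable and mixing them is an error.
"""

from __future__ import annotations

import gzip
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy.stats import binom

__all__ = [
    "SketchParams",
    "Sketch",
    "ScreenHit",
    "KmerSizeInputs",
    "build_sketch",
    "canonical_kmer_codes",
    "hash_kmer",
    "query_kmer_hashes",
    "screen_containment",
    "screen_references",
    "containment_pvalue",
    "optimal_kmer_size",
    "sketch_error",
    "save_sketches",
    "load_sketches",
    "read_fasta",
]

_U64 = np.uint64
_MASK64 = (1 << 64) - 1

# Base encoding: A=0, C=1, G=2, T=3 matches lexicographic order, so the
# numeric minimum of the packed forward/reverse-complement codes is the
# canonical (lexicographically smaller) k-mer.  255 marks invalid bases.
_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _BASE_CODE[_b] = _i

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

# MurmurHash3 x64 finalizer constants.
_FMIX_C1 = 0xFF51AFD7ED558CCD
_FMIX_C2 = 0xC4CEB9FE1A85EC53
_SEED_GOLDEN = 0x9E3779B97F4A7C15


@dataclass(frozen=True)
class SketchParams:
    """Sketching parameters; sketches are comparable only when (k, seed) match."""

    k: int = 21
    s: int = 1000
    seed: int = 42
    alphabet_size: int = 4

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.k > 31:
            raise ValueError(f"k must be <= 31 for 64-bit packing, got {self.k}")
        if self.s < 1:
            raise ValueError(f"sketch size must be >= 1, got {self.s}")
        if self.alphabet_size < 2:
            raise ValueError(f"alphabet_size must be >= 2, got {self.alphabet_size}")

    def compatible_with(self, other: "SketchParams") -> bool:
        return self.k == other.k and self.seed == other.seed

    def require_compatible(self, other: "SketchParams") -> None:
        if not self.compatible_with(other):
            raise ValueError(
                f"incompatible sketch params: (k={self.k}, seed={self.seed}) "
                f"vs (k={other.k}, seed={other.seed})"
            )


@dataclass
class Sketch:
    """Bottom-s sketch of one reference sequence.

    ``hashes`` holds the min(s, n_kmers) smallest distinct hash values in
    strictly increasing order; ``n_kmers`` counts distinct canonical k-mers
    observed in the source sequence.
    """

    ref_id: str
    params: SketchParams
    hashes: np.ndarray
    n_kmers: int

    def __post_init__(self) -> None:
        self.hashes = np.asarray(self.hashes, dtype=_U64)
        if self.hashes.size > 1 and not np.all(self.hashes[:-1] < self.hashes[1:]):
            raise ValueError("sketch hashes must be strictly increasing")
        if self.hashes.size != min(self.params.s, self.n_kmers):
            raise ValueError(
                f"sketch of {self.ref_id}: |hashes|={self.hashes.size} "
                f"!= min(s={self.params.s}, n_kmers={self.n_kmers})"
            )

    def __len__(self) -> int:
        return int(self.hashes.size)


@dataclass(frozen=True)
class ScreenHit:
    """Containment of one reference sketch in a query k-mer set."""

    ref_id: str
    containment: float
    shared: int
    sketch_size_used: int
    p_value: float


@dataclass(frozen=True)
class KmerSizeInputs:
    """Inputs to the optimal k-mer size rule: genome size n and the desired
    probability q of observing a random k-mer by chance."""

    n: int
    q: float
    alphabet_size: int = 4

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"genome size must be >= 1, got {self.n}")
        if not 0.0 < self.q < 1.0:
            raise ValueError(f"q must lie in (0, 1), got {self.q}")
        if self.alphabet_size < 2:
            raise ValueError("alphabet_size must be >= 2")


def _fmix64(h: np.ndarray) -> np.ndarray:
    """Vectorised MurmurHash3 64-bit finalizer (wraps modulo 2^64)."""
    h = h.astype(_U64, copy=True)
    h ^= h >> _U64(33)
    h *= _U64(_FMIX_C1)
    h ^= h >> _U64(33)
    h *= _U64(_FMIX_C2)
    h ^= h >> _U64(33)
    return h


def _hash_codes(codes: np.ndarray, seed: int) -> np.ndarray:
    seeded = codes.astype(_U64) ^ _U64((seed * _SEED_GOLDEN) & _MASK64)
    return _fmix64(seeded)


def hash_kmer(kmer: str, seed: int) -> int:
    """Hash a single k-mer string (canonicalising first); scalar reference path.

    Equivalent to the vectorised pipeline; exposed so small examples can be
    hashed k-mer by k-mer.
    """
    rc = kmer.translate(_COMPLEMENT)[::-1]
    canonical = min(kmer.upper(), rc.upper())
    code = 0
    for base in canonical:
        c = _BASE_CODE[ord(base)]
        if c == 255:
            raise ValueError(f"non-ACGT base in k-mer: {kmer!r}")
        code = (code << 2) | int(c)
    h = code ^ ((seed * _SEED_GOLDEN) & _MASK64)
    h ^= h >> 33
    h = (h * _FMIX_C1) & _MASK64
    h ^= h >> 33
    h = (h * _FMIX_C2) & _MASK64
    h ^= h >> 33
    return h


def canonical_kmer_codes(sequence: str, k: int) -> np.ndarray:
    """2-bit packed canonical k-mer codes of a sequence (non-unique).

    Windows containing any non-ACGT base are skipped.  Processes in chunks so
    memory stays at O(chunk * k).
    """
    seq_bytes = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    codes = _BASE_CODE[seq_bytes]
    n = codes.size
    if n < k:
        return np.empty(0, dtype=_U64)

    fwd_pow = (_U64(4) ** np.arange(k - 1, -1, -1, dtype=_U64))
    rev_pow = fwd_pow[::-1]
    out: list[np.ndarray] = []
    chunk = 1 << 20
    start = 0
    while start < n - k + 1:
        stop = min(start + chunk, n - k + 1)
        window = np.lib.stride_tricks.sliding_window_view(
            codes[start : stop + k - 1], k
        )
        valid = ~np.any(window == 255, axis=1)
        if not valid.any():
            start = stop
            continue
        win = window[valid].astype(_U64)
        fwd = win @ fwd_pow
        rc = (_U64(3) - win) @ rev_pow
        out.append(np.minimum(fwd, rc))
        start = stop
    if not out:
        return np.empty(0, dtype=_U64)
    return np.concatenate(out)


def build_sketch(sequence: str, params: SketchParams, ref_id: str = "") -> Sketch:
    """Bottom-s sketch of a nucleotide sequence; deterministic for fixed inputs.

    A sequence shorter than k yields an empty sketch (n_kmers = 0) rather
    than an error.
    """
    codes = canonical_kmer_codes(sequence, params.k)
    distinct = np.unique(codes)
    hashes = np.unique(_hash_codes(distinct, params.seed))
    if hashes.size > params.s:
        bottom = np.partition(hashes, params.s - 1)[: params.s]
        hashes = np.sort(bottom)
    return Sketch(ref_id=ref_id, params=params, hashes=hashes, n_kmers=int(distinct.size))


def query_kmer_hashes(sequences: Iterable[str], params: SketchParams) -> np.ndarray:
    """Sorted distinct hash values of the pooled canonical k-mers of the query
    set (the full π(B); the query side is never sketched)."""
    parts = [canonical_kmer_codes(seq, params.k) for seq in sequences]
    if not parts:
        return np.empty(0, dtype=_U64)
    codes = np.unique(np.concatenate(parts)) if parts else np.empty(0, dtype=_U64)
    return np.unique(_hash_codes(codes, params.seed))


def screen_containment(query_hashes: np.ndarray | set, ref_sketch: Sketch) -> ScreenHit:
    """Estimate containment of a reference in a query k-mer hash set.

    containment = |{h in sketch : h in query}| / |sketch|, with a binomial
    upper-tail p-value for observing at least that many shared hashes by
    chance given the query's distinct k-mer count.
    """
    if len(ref_sketch) == 0:
        raise ValueError(
            f"reference sketch {ref_sketch.ref_id!r} is empty; containment undefined"
        )
    qh = np.asarray(sorted(query_hashes) if isinstance(query_hashes, set) else query_hashes,
                    dtype=_U64)
    idx = np.searchsorted(qh, ref_sketch.hashes)
    idx = np.clip(idx, 0, max(qh.size - 1, 0))
    shared = int(np.count_nonzero(qh[idx] == ref_sketch.hashes)) if qh.size else 0
    size = len(ref_sketch)
    p = containment_pvalue(shared, size, int(qh.size), ref_sketch.params)
    return ScreenHit(
        ref_id=ref_sketch.ref_id,
        containment=shared / size,
        shared=shared,
        sketch_size_used=size,
        p_value=p,
    )


def screen_references(
    query_hashes: np.ndarray, sketches: Sequence[Sketch]
) -> list[ScreenHit]:
    """Screen every reference sketch against one pooled query hash set."""
    if sketches:
        base = sketches[0].params
        for sk in sketches[1:]:
            base.require_compatible(sk.params)
    return [screen_containment(query_hashes, sk) for sk in sketches]


def containment_pvalue(
    shared: int, sketch_size: int, query_distinct_kmers: int, params: SketchParams
) -> float:
    """Upper-tail P(X >= shared), X ~ Binomial(sketch_size, r), where r is the
    chance a random k-mer hash appears in a query of the given distinct size.

    Non-increasing in ``shared``; shared = 0 always gives 1.0.
    """
    if not 0 <= shared <= sketch_size:
        raise ValueError(f"shared={shared} outside [0, {sketch_size}]")
    if query_distinct_kmers < 0:
        raise ValueError("query_distinct_kmers must be >= 0")
    if shared == 0:
        return 1.0
    # r = 1 - (1 - |Σ|^-k)^m computed stably for large m.
    log_miss = math.log1p(-params.alphabet_size ** (-params.k))
    r = -math.expm1(query_distinct_kmers * log_miss)
    return float(binom.sf(shared - 1, sketch_size, r))


def optimal_kmer_size(inputs: KmerSizeInputs) -> int:
    """Smallest integer k with alphabet^k >= n(1-q)/q: the k-mer size at which
    a random match in a genome of size n has probability at most q."""
    arg = inputs.n * (1.0 - inputs.q) / inputs.q
    k = math.ceil(math.log(arg) / math.log(inputs.alphabet_size))
    return max(k, 1)


def sketch_error(s: int) -> float:
    """Containment-estimate error scale for sketch size s: sqrt(1/s)."""
    if s < 1:
        raise ValueError(f"sketch size must be >= 1, got {s}")
    return math.sqrt(1.0 / s)


# ---------------------------------------------------------------------------
# Persistence: a documented JSON container (deliberately not Mash .msh).

_STORE_FORMAT = "taxsieve-sketches-v1"


def save_sketches(sketches: Sequence[Sketch], path: str | Path) -> None:
    if sketches:
        base = sketches[0].params
        for sk in sketches[1:]:
            base.require_compatible(sk.params)
    params = sketches[0].params if sketches else SketchParams()
    doc = {
        "format": _STORE_FORMAT,
        "params": {
            "k": params.k,
            "s": params.s,
            "seed": params.seed,
            "alphabet_size": params.alphabet_size,
        },
        "sketches": [
            {
                "ref_id": sk.ref_id,
                "n_kmers": sk.n_kmers,
                "hashes": [int(h) for h in sk.hashes],
            }
            for sk in sketches
        ],
    }
    Path(path).write_text(json.dumps(doc))


def load_sketches(path: str | Path) -> list[Sketch]:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != _STORE_FORMAT:
        raise ValueError(f"{path}: not a {_STORE_FORMAT} container")
    params = SketchParams(**doc["params"])
    return [
        Sketch(
            ref_id=entry["ref_id"],
            params=params,
            hashes=np.asarray(entry["hashes"], dtype=_U64),
            n_kmers=entry["n_kmers"],
        )
        for entry in doc["sketches"]
    ]


def read_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (id, sequence) from a FASTA file, transparently un-gzipping."""
    from Bio import SeqIO

    path = Path(path)
    if path.suffix == ".gz":
        with gzip.open(path, "rt") as fh:
            for rec in SeqIO.parse(fh, "fasta"):
                yield rec.id, str(rec.seq)
    else:
        with open(path) as fh:
            for rec in SeqIO.parse(fh, "fasta"):
                yield rec.id, str(rec.seq)
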