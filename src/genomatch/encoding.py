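"""Genomic-to-algebraic encodings and database polynomial construction.

A variant record (chrom, pos, ref, alt) becomes an integer pair:

* the *tag* d = ch + 24*pos, where chromosomes 1..22 keep their number and
  X, Y map to 0 and 23;
* the *value* alpha, the concatenation of 2-bit allele codes (A=00, T=01,
  G=10, C=11) for REF and ALT, each prefixed with a 1 bit to mark the
  sequence start and zero-padded to length l_SNP = 2*n_SNP + 1; an unknown
  sequence '.' encodes as 0.  alpha = 2**l_SNP * enc(ref) + enc(alt).

Values wider than the plaintext modulus t are split into C base-t chunks,
C = ceil((4*n_SNP + 2) / log2 t), least significant first.

Two database layouts are built from (tag, value) pairs:

* ``direct``: one polynomial DB(X) per chunk with coefficient alpha_i at
  exponent d_i (requires every tag below the ring dimension N);
* ``hashed``: tags are compressed through SHA3-256 into a pair
  (d*, d+) of log2(N)-bit indices, and per chunk a pair of polynomials
  (DB*, DB+) is built so that DB*[d*_i] + DB+[d+_i] = chunk_i (mod t).
  Records are packed greedily into fixed-capacity blocks; within a block
  the sum constraints form a weighted bipartite graph that is solved with
  a union-find over coefficient differences, and a record whose
  constraints contradict a block's existing ones is pushed to a later
  block.  All unconstrained coefficients are uniform in Z_t, so a
  non-matching query decrypts to noise.

Hash convention (shared by client and server, recorded in manifests):
SHA3-256 over the 8-byte little-endian tag; interpreting the digest as a
little-endian integer, d* is its low log2(N) bits and d+ the next log2(N).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .ring import HEParams, ParameterError, RingElt, monomial, reduce_centered

__all__ = [
    "FormatError",
    "DataError",
    "CapacityError",
    "VariantRecord",
    "EncodedRecord",
    "HashPair",
    "QueryEncoding",
    "DbEncoding",
    "HASH_CONVENTION",
    "encode_tag",
    "encode_alleles",
    "decode_alleles",
    "encode_value",
    "decode_value",
    "chunk_value",
    "unchunk_value",
    "chunk_count",
    "encode_record",
    "hash_tag",
    "build_db_direct",
    "build_db_hashed",
    "encode_query",
]


class FormatError(ValueError):
    """Malformed genomic input (chromosome, position, or allele string)."""


class DataError(ValueError):
    """Inconsistent database contents (e.g. duplicate tags)."""


class CapacityError(ValueError):
    """Tags exceed the ring dimension; the hashed layout is required."""


HASH_CONVENTION = "sha3-256/le64-tag/low-bits"

_BASE_CODE = {"A": 0, "T": 1, "G": 2, "C": 3}
_CODE_BASE = "ATGC"


# ---------------------------------------------------------------------------
# Record-level encodings
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantRecord:
    """One VCF data row restricted to CHROM/POS/REF/ALT."""

    chrom: str
    pos: int
    ref: str
    alt: str


@dataclass(frozen=True)
class EncodedRecord:
    d: int
    alpha: int
    chunks: tuple


@dataclass(frozen=True)
class HashPair:
    d_star: int
    d_dagger: int


def _chrom_code(chrom) -> int:
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    c = c.upper()
    if c == "X":
        return 0
    if c == "Y":
        return 23
    if c.isdigit() and 1 <= int(c) <= 22:
        return int(c)
    raise FormatError(f"chromosome must be 1..22, X or Y; got {chrom!r}")


def encode_tag(chrom, pos: int) -> int:
    """Tag encoding d = ch + 24*pos (X -> 0, Y -> 23); positions are 1-based."""
    code = _chrom_code(chrom)
    pos = int(pos)
    if pos < 1:
        raise FormatError(f"position must be >= 1; got {pos}")
    return code + 24 * pos


def encode_alleles(seq: str, n_snp: int) -> int:
    """Integer encoding of an allele string of length <= n_SNP.

    Each base maps to two bits (A=00, T=01, G=10, C=11); the concatenation
    is prefixed with a 1 bit marking the start of the sequence.  An
    unknown sequence ('.' or empty) encodes as 0.  'GC' -> 1|10|11 = 27.
    """
    if seq is None or seq == "." or seq == "":
        return 0
    s = str(seq).upper()
    if len(s) > n_snp:
        raise FormatError(
            f"allele string longer than n_SNP={n_snp}: {seq!r}"
        )
    val = 1
    for base in s:
        if base not in _BASE_CODE:
            raise FormatError(f"invalid base {base!r} in {seq!r}")
        val = (val << 2) | _BASE_CODE[base]
    return val


def decode_alleles(val: int, n_snp: int) -> str:
    """Inverse of :func:`encode_alleles`."""
    if val == 0:
        return "."
    bits = val.bit_length() - 1
    if bits % 2 or bits // 2 > n_snp:
        raise FormatError(f"not a valid allele encoding: {val}")
    out = []
    for shift in range(bits - 2, -2, -2):
        out.append(_CODE_BASE[(val >> shift) & 3])
    return "".join(out)


def ell_snp(n_snp: int) -> int:
    """Bit length of one allele-string encoding: l_SNP = 2*n_SNP + 1."""
    return 2 * n_snp + 1


def encode_value(ref: str, alt: str, n_snp: int) -> int:
    """Concatenated value alpha = 2**l_SNP * enc(ref) + enc(alt)."""
    return (encode_alleles(ref, n_snp) << ell_snp(n_snp)) | encode_alleles(
        alt, n_snp
    )


def decode_value(alpha: int, n_snp: int) -> tuple[str, str]:
    """Split alpha back into the (ref, alt) allele strings."""
    l = ell_snp(n_snp)
    return decode_alleles(alpha >> l, n_snp), decode_alleles(
        alpha & ((1 << l) - 1), n_snp
    )


def chunk_count(n_snp: int, t: int) -> int:
    """C = ceil((4*n_SNP + 2) / log2 t) base-t chunks cover any value."""
    log2t = t.bit_length() - 1
    if 1 << log2t != t:
        raise ParameterError("plaintext modulus t must be a power of two")
    return -(-(4 * n_snp + 2) // log2t)


def chunk_value(alpha: int, n_snp: int, t: int) -> tuple:
    """Base-t digits of alpha, least significant first, zero-padded to C."""
    C = chunk_count(n_snp, t)
    out = []
    v = int(alpha)
    for _ in range(C):
        out.append(v % t)
        v //= t
    if v:
        raise FormatError(f"value {alpha} does not fit in {C} base-{t} chunks")
    return tuple(out)


def unchunk_value(chunks, t: int) -> int:
    val = 0
    for c in reversed(list(chunks)):
        val = val * t + int(c) % t
    return val


def encode_record(rec: VariantRecord, n_snp: int, t: int) -> EncodedRecord:
    d = encode_tag(rec.chrom, rec.pos)
    alpha = encode_value(rec.ref, rec.alt, n_snp)
    return EncodedRecord(d=d, alpha=alpha, chunks=chunk_value(alpha, n_snp, t))


def hash_tag(d: int, N: int) -> HashPair:
    """Compress a tag into a pair of indices below N via SHA3-256.

    The digest of the 8-byte little-endian tag, read as a little-endian
    integer, supplies log2(N) bits for d* and the next log2(N) for d+.
    """
    if N < 2 or N & (N - 1):
        raise ParameterError("N must be a power of two")
    log2n = N.bit_length() - 1
    digest = hashlib.sha3_256(int(d).to_bytes(8, "little")).digest()
    h = int.from_bytes(digest, "little")
    return HashPair(d_star=h & (N - 1), d_dagger=(h >> log2n) & (N - 1))


# ---------------------------------------------------------------------------
# Database polynomial construction
# ---------------------------------------------------------------------------


@dataclass
class DbEncoding:
    """Per-chunk, per-block plaintext polynomial pairs plus placement.

    ``polys[c][b]`` is the pair (DB*, DB+) of mod-t ring elements for
    chunk c and block b; in direct mode the second entry is ``None`` and
    there is a single block.  ``placement`` maps record index to block.
    """

    mode: str
    n_snp: int
    t: int
    N: int
    C: int
    polys: list  # [chunk][block] -> (RingElt, RingElt | None)
    placement: dict
    filler: str = "random"
    block_capacity: int | None = None
    seed: int | None = None

    @property
    def n_blocks(self) -> int:
        return len(self.polys[0])

    def manifest(self) -> dict:
        return {
            "mode": self.mode,
            "n_snp": self.n_snp,
            "t": self.t,
            "N": self.N,
            "chunks": self.C,
            "blocks": self.n_blocks,
            "filler": self.filler,
            "block_capacity": self.block_capacity,
            "hash": HASH_CONVENTION if self.mode == "hashed" else None,
            "seed": self.seed,
        }


def _as_rng(rng) -> tuple[np.random.Generator, int | None]:
    if isinstance(rng, np.random.Generator):
        return rng, None
    seed = int(rng)
    return np.random.default_rng(seed), seed


def build_db_direct(records, params: HEParams, rng, n_snp: int = 10,
                    filler: str = "random") -> DbEncoding:
    """Encode records as DB(X) = sum_i alpha_i X^(d_i), one poly per chunk.

    Every tag must be below N.  Coefficients not carrying a record value
    are uniform in Z_t (``filler='random'``) or zero (``filler='zero'``,
    in which case a non-match decrypts to 0).
    """
    rng, seed = _as_rng(rng)
    if filler not in ("random", "zero"):
        raise ParameterError("filler must be 'random' or 'zero'")
    encoded = [encode_record(r, n_snp, params.t) for r in records]
    tags = [e.d for e in encoded]
    if len(set(tags)) != len(tags):
        raise DataError("duplicate tags in database")
    for e in encoded:
        if e.d >= params.N:
            raise CapacityError(
                f"tag {e.d} >= N={params.N}; use the hashed layout"
            )
    C = chunk_count(n_snp, params.t)
    polys = []
    for c in range(C):
        if filler == "random":
            coeffs = rng.integers(0, params.t, size=params.N, dtype=np.int64)
        else:
            coeffs = np.zeros(params.N, dtype=np.int64)
        for e in encoded:
            coeffs[e.d] = e.chunks[c]
        polys.append([(RingElt(reduce_centered(coeffs, params.t), params.t),
                       None)])
    placement = {i: 0 for i in range(len(encoded))}
    return DbEncoding(mode="direct", n_snp=n_snp, t=params.t, N=params.N,
                      C=C, polys=polys, placement=placement, filler=filler,
                      seed=seed)


class _BlockBuilder:
    """Union-find over coefficient constraints of one block.

    Nodes are ('s', k) / ('d', k) coefficient slots of DB* / DB+.  A record
    with hash pair (u, v) and chunk vector w imposes x_u + x_v = w (mod t),
    i.e. y_u - y_v = w for y_u = x_u (star) and y_v = -x_v (dagger), which
    is a standard difference constraint solved with weighted union-find.
    """

    def __init__(self, C: int, t: int, capacity: int):
        self.C = C
        self.t = t
        self.capacity = capacity
        self.parent: dict = {}
        self.pot: dict = {}  # y_node - y_parent, length-C int array mod t
        self.count = 0

    def _ensure(self, node) -> None:
        if node not in self.parent:
            self.parent[node] = node
            self.pot[node] = np.zeros(self.C, dtype=np.int64)

    def find(self, node):
        """Return (root, offset y_node - y_root), with path compression."""
        self._ensure(node)
        chain = []
        n = node
        while self.parent[n] != n:
            chain.append(n)
            n = self.parent[n]
        root = n
        # chain[i]'s parent is chain[i+1]; rewrite offsets relative to the
        # root walking from the node nearest the root outwards
        off_parent = np.zeros(self.C, dtype=np.int64)
        for n in reversed(chain):
            off_parent = (self.pot[n] + off_parent) % self.t
            self.parent[n] = root
            self.pot[n] = off_parent
        if chain:
            return root, self.pot[node]
        return root, np.zeros(self.C, dtype=np.int64)

    def try_add(self, star: int, dagger: int, w: np.ndarray) -> bool:
        """Place one record's constraint; True on success, no-op on failure."""
        if self.count >= self.capacity:
            return False
        u, v = ("s", star), ("d", dagger)
        self._ensure(u)
        self._ensure(v)
        ru, du = self.find(u)
        rv, dv = self.find(v)
        if ru == rv:
            if not np.array_equal((du - dv) % self.t, w % self.t):
                return False
        else:
            # y_rv - y_ru = du - w - dv
            self.parent[rv] = ru
            self.pot[rv] = (du - w - dv) % self.t
        self.count += 1
        return True

    def solve(self, rng: np.random.Generator, N: int):
        """Fill DB*/DB+ coefficient arrays; free choices are uniform in Z_t."""
        star = rng.integers(0, self.t, size=(self.C, N), dtype=np.int64)
        dagger = rng.integers(0, self.t, size=(self.C, N), dtype=np.int64)
        root_val: dict = {}
        for node in list(self.parent):
            root, off = self.find(node)
            if root not in root_val:
                root_val[root] = rng.integers(0, self.t, size=self.C,
                                              dtype=np.int64)
            y = (root_val[root] + off) % self.t
            kind, idx = node
            if kind == "s":
                star[:, idx] = y
            else:
                dagger[:, idx] = (-y) % self.t
        return star, dagger


def build_db_hashed(records, params: HEParams, rng, n_snp: int = 10,
                    block_capacity: int = 100) -> DbEncoding:
    """Build the dual polynomials DB*, DB+ with hashed tag compression.

    Records are packed greedily (first fit) into blocks of at most
    ``block_capacity`` records; a record whose sum constraint contradicts
    every open block starts a new one.  For every placed record i and
    every chunk c, DB*_c[d*_i] + DB+_c[d+_i] = chunk_i[c] (mod t).
    """
    rng, seed = _as_rng(rng)
    encoded = [encode_record(r, n_snp, params.t) for r in records]
    tags = [e.d for e in encoded]
    if len(set(tags)) != len(tags):
        raise DataError("duplicate tags in database")
    C = chunk_count(n_snp, params.t)
    blocks: list[_BlockBuilder] = []
    placement: dict = {}
    for i, e in enumerate(encoded):
        hp = hash_tag(e.d, params.N)
        w = np.array(e.chunks, dtype=np.int64)
        for b, blk in enumerate(blocks):
            if blk.try_add(hp.d_star, hp.d_dagger, w):
                placement[i] = b
                break
        else:
            blk = _BlockBuilder(C, params.t, block_capacity)
            blocks.append(blk)
            if not blk.try_add(hp.d_star, hp.d_dagger, w):
                raise DataError("record rejected by an empty block")
            placement[i] = len(blocks) - 1
    polys = [[] for _ in range(C)]
    for blk in blocks:
        star, dagger = blk.solve(rng, params.N)
        for c in range(C):
            polys[c].append(
                (RingElt(reduce_centered(star[c], params.t), params.t),
                 RingElt(reduce_centered(dagger[c], params.t), params.t))
            )
    return DbEncoding(mode="hashed", n_snp=n_snp, t=params.t, N=params.N,
                      C=C, polys=polys, placement=placement,
                      block_capacity=block_capacity, seed=seed)


# ---------------------------------------------------------------------------
# Query encoding
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QueryEncoding:
    """A query biomarker reduced to its tag, value chunks and monomials."""

    d: int
    alpha: int
    chunks: tuple
    mode: str
    monomial_star: RingElt
    monomial_dagger: RingElt | None
    hash_pair: HashPair | None


def encode_query(chrom, pos: int, ref: str, alt: str, params: HEParams,
                 n_snp: int = 10, mode: str = "hashed") -> QueryEncoding:
    """Encode a query biomarker into the monomials the client encrypts.

    In hashed mode these are X^(-d*) and X^(-d+); in direct mode the
    single monomial X^(-d).  Negative exponents follow the negacyclic
    rule X^(-k) = -X^(N-k) for 0 < k < N (and X^0 = 1).
    """
    d = encode_tag(chrom, pos)
    alpha = encode_value(ref, alt, n_snp)
    chunks = chunk_value(alpha, n_snp, params.t)
    if mode == "hashed":
        hp = hash_tag(d, params.N)
        return QueryEncoding(
            d=d, alpha=alpha, chunks=chunks, mode=mode,
            monomial_star=monomial(params.N, -hp.d_star, params.t),
            monomial_dagger=monomial(params.N, -hp.d_dagger, params.t),
            hash_pair=hp,
        )
    if mode == "direct":
        if d >= params.N:
            raise CapacityError(
                f"tag {d} >= N={params.N}; direct queries need small tags"
            )
        return QueryEncoding(
            d=d, alpha=alpha, chunks=chunks, mode=mode,
            monomial_star=monomial(params.N, -d, params.t),
            monomial_dagger=None, hash_pair=None,
        )
    raise ParameterError(f"unknown mode {mode!r}")
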