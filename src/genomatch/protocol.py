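"""The end-to-end search-and-extract flow: encrypt, search, resolve.

Client side: one secret key serves both schemes.  The database plaintext
polynomials are encrypted with the RLWE public-key scheme; the query
monomials X^(-d*) and X^(-d+) are encrypted with the symmetric RGSW
scheme.

Server side, per chunk c and block b:

    ct = CT* [x] ct*_{c,b}  (+)  CT+ [x] ct+_{c,b}      (hybrid products)
    out[c][b] = mod_switch(to_lwe(ct), q_out)

so the server returns one small LWE ciphertext per cell, each encrypting
DB*[d*] + DB+[d+] for that block -- the record's chunk value if the query
tag is present in the block, uniform noise otherwise.  The server touches
no secret material.

Client resolve: decrypt every cell and report a match if some block
reproduces all C chunks of the query value.

Two server implementations are provided: a reference path composed from
the public ring operations, and an algebraically identical vectorized
path that caches the gadget digits of the (fixed) database ciphertexts in
the Fourier domain and batches all blocks of a chunk through one einsum.
Both are exact; they produce bit-identical results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .encoding import HASH_CONVENTION, DbEncoding, QueryEncoding, unchunk_value
from .rgsw import RgswCiphertext, hybrid_mult, rgsw_encrypt
from .ring import (
    HEParams,
    ParameterError,
    _nega_fft,
    _nega_ifft,
    gadget_decompose,
    reduce_centered,
    round_half_away,
)
from .rlwe import (
    LweCiphertext,
    PublicKey,
    SecretKey,
    add,
    encrypt,
    keygen,
    lwe_to_bytes,
    mod_switch,
    to_lwe,
)

__all__ = [
    "ProtocolError",
    "EncryptedDatabase",
    "EncryptedQuery",
    "SearchResult",
    "ResolvedMatch",
    "client_setup",
    "encrypt_database",
    "encrypt_query",
    "server_search",
    "client_resolve",
]

logger = logging.getLogger("genomatch")


class ProtocolError(RuntimeError):
    """Mismatched manifests or an otherwise invalid protocol state."""


@dataclass
class EncryptedDatabase:
    """RLWE ciphertexts of every database polynomial plus the manifest."""

    cts: list  # [chunk][block] -> (RlweCiphertext, RlweCiphertext | None)
    manifest: dict
    _digit_ffts: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def mode(self) -> str:
        return self.manifest["mode"]

    @property
    def n_blocks(self) -> int:
        return len(self.cts[0])

    @property
    def n_chunks(self) -> int:
        return len(self.cts)

    def ciphertext_count(self) -> int:
        per_block = 2 if self.mode == "hashed" else 1
        return self.n_chunks * self.n_blocks * per_block


@dataclass
class EncryptedQuery:
    """RGSW ciphertexts of the query monomials."""

    CT_star: RgswCiphertext
    CT_dagger: RgswCiphertext | None
    manifest: dict

    @property
    def mode(self) -> str:
        return self.manifest["mode"]


@dataclass
class ResolvedMatch:
    matched: bool
    block: int | None
    value: int
    max_noise_ratio: float


@dataclass
class SearchResult:
    """Per-chunk, per-block LWE outputs at the switched modulus."""

    cells: list  # [chunk][block] -> LweCiphertext
    manifest: dict
    resolved: ResolvedMatch | None = None

    @property
    def n_blocks(self) -> int:
        return len(self.cells[0])

    @property
    def n_chunks(self) -> int:
        return len(self.cells)

    def to_bytes(self) -> bytes:
        return b"".join(
            lwe_to_bytes(cell) for row in self.cells for cell in row
        )


# ---------------------------------------------------------------------------
# Client: keys, database encryption, query encryption
# ---------------------------------------------------------------------------


def client_setup(params: HEParams,
                 rng: np.random.Generator) -> tuple[SecretKey, PublicKey]:
    """Generate the single key pair shared by the RLWE and RGSW schemes."""
    return keygen(params, rng)


def encrypt_database(dbenc: DbEncoding, pk: PublicKey, params: HEParams,
                     rng: np.random.Generator) -> EncryptedDatabase:
    """Encrypt every plaintext polynomial of the encoded database."""
    if dbenc.N != params.N or dbenc.t != params.t:
        raise ProtocolError("database encoding does not match the parameters")
    cts = []
    for c in range(dbenc.C):
        row = []
        for star, dagger in dbenc.polys[c]:
            ct_star = encrypt(star, pk, params, rng)
            ct_dagger = encrypt(dagger, pk, params, rng) if dagger is not None else None
            row.append((ct_star, ct_dagger))
        cts.append(row)
    return EncryptedDatabase(cts=cts, manifest=dict(dbenc.manifest()))


def encrypt_query(qenc: QueryEncoding, sk: SecretKey, params: HEParams,
                  rng: np.random.Generator) -> EncryptedQuery:
    """RGSW-encrypt the query monomial(s) under the shared secret key."""
    CT_star = rgsw_encrypt(qenc.monomial_star, sk, params, rng)
    CT_dagger = (
        rgsw_encrypt(qenc.monomial_dagger, sk, params, rng)
        if qenc.monomial_dagger is not None
        else None
    )
    manifest = {
        "mode": qenc.mode,
        "N": params.N,
        "t": params.t,
        "hash": None if qenc.mode == "direct" else HASH_CONVENTION,
    }
    return EncryptedQuery(CT_star=CT_star, CT_dagger=CT_dagger,
                          manifest=manifest)


# ---------------------------------------------------------------------------
# Server
# ---------------------------------------------------------------------------


def _check_manifests(edb: EncryptedDatabase, eq: EncryptedQuery,
                     params: HEParams) -> None:
    dm, qm = edb.manifest, eq.manifest
    if dm["mode"] != qm["mode"]:
        raise ProtocolError("database and query modes differ")
    for key in ("N", "t"):
        if dm.get(key) != qm.get(key) or dm.get(key) != getattr(params, key):
            raise ProtocolError(f"manifest mismatch on {key!r}")
    if dm["mode"] == "hashed" and dm.get("hash") != qm.get("hash"):
        raise ProtocolError("hash conventions differ")


def server_search(edb: EncryptedDatabase, eq: EncryptedQuery,
                  params: HEParams, method: str = "fft") -> SearchResult:
    """Run the homomorphic search: hybrid products, add, convert, switch.

    Pure function of ciphertexts and public manifest fields; takes no key
    material.  ``method`` selects the reference composition or the
    batched Fourier-domain path (identical outputs).
    """
    _check_manifests(edb, eq, params)
    if method == "fft":
        cells = _search_fft(edb, eq, params)
    elif method == "reference":
        cells = _search_reference(edb, eq, params)
    else:
        raise ParameterError(f"unknown search method {method!r}")
    manifest = dict(edb.manifest)
    manifest["q_out"] = params.q_out
    return SearchResult(cells=cells, manifest=manifest)


def _search_reference(edb, eq, params):
    cells = []
    for c in range(edb.n_chunks):
        row = []
        for b in range(edb.n_blocks):
            ct_star, ct_dagger = edb.cts[c][b]
            ct = hybrid_mult(eq.CT_star, ct_star)
            if ct_dagger is not None:
                ct = add(ct, hybrid_mult(eq.CT_dagger, ct_dagger))
            row.append(mod_switch(to_lwe(ct), params.q_out, params))
        cells.append(row)
    return cells


def _db_digit_ffts(edb: EncryptedDatabase, params: HEParams):
    """Fourier transforms of the gadget digits of every DB ciphertext.

    The database ciphertexts are fixed across queries, so their gadget
    decompositions (2*d_g small polynomials per ciphertext) are computed
    once and cached on the EncryptedDatabase.
    """
    if edb._digit_ffts:
        return edb._digit_ffts
    N = params.N
    n_var = 2 if edb.mode == "hashed" else 1
    cache = {}
    for v in range(n_var):
        per_chunk = []
        for c in range(edb.n_chunks):
            digs = np.empty((edb.n_blocks, 2 * params.d_g, N), dtype=np.int64)
            for b in range(edb.n_blocks):
                ct = edb.cts[c][b][v]
                for r, u in enumerate(gadget_decompose((ct.c0, ct.c1), params)):
                    digs[b, r] = u.coeffs
            per_chunk.append(_nega_fft(digs.astype(np.float64), N))
        cache[v] = per_chunk
    edb._digit_ffts = cache
    return cache


def _query_limb_ffts(CT: RgswCiphertext, params: HEParams):
    """FFTs of the 16-bit limbs of each RGSW matrix entry.

    Returns an array of shape (2*d_g, 2 cols, 2 limbs, N).  Gadget digits
    are bounded by B_g/2 = 64, so digit x limb convolutions stay below
    2*d_g * N * 64 * 2**16 ~ 2**37: far inside the float64-exact window.
    """
    N = params.N
    rows = np.empty((2 * params.d_g, 2, N), dtype=np.int64)
    for r, (b_row, a_row) in enumerate(CT.rows):
        rows[r, 0] = b_row.lift_residues()
        rows[r, 1] = a_row.lift_residues()
    limbs = np.stack([rows & 0xFFFF, rows >> 16], axis=2)  # (rows, col, limb, N)
    return _nega_fft(limbs.astype(np.float64), N)


def _round_int64(vals: np.ndarray) -> np.ndarray:
    iv = np.rint(vals)
    dev = float(np.abs(vals - iv).max(initial=0.0))
    if dev > 0.25:
        raise ArithmeticError(
            f"FFT search path lost exactness (max deviation {dev:.3g})"
        )
    return iv.astype(np.int64)


def _search_fft(edb, eq, params):
    N, Q, q_out = params.N, params.Q, params.q_out
    mask = np.uint64(Q - 1)
    digit_ffts = _db_digit_ffts(edb, params)
    query_ffts = {0: _query_limb_ffts(eq.CT_star, params)}
    if eq.CT_dagger is not None:
        query_ffts[1] = _query_limb_ffts(eq.CT_dagger, params)
    cells = []
    for c in range(edb.n_chunks):
        B = edb.n_blocks
        acc = np.zeros((2, B, N), dtype=np.int64)  # (col, block, coeff)
        for v, qf in query_ffts.items():
            D = digit_ffts[v][c]  # (B, rows, N) complex
            for col in range(2):
                parts = []
                for limb in range(2):
                    spec = np.einsum("brk,rk->bk", D, qf[:, col, limb, :])
                    parts.append(_round_int64(np.real(_nega_ifft(spec, N))))
                comb = (
                    parts[0].view(np.uint64)
                    + (parts[1].view(np.uint64) << np.uint64(16))
                ) & mask
                acc[col] += _center(comb.astype(np.int64), Q)
        acc0 = reduce_centered(acc[0], Q)
        acc1 = reduce_centered(acc[1], Q)
        # batched RLWE->LWE extraction of the constant term
        vec = np.empty((B, N + 1), dtype=np.int64)
        vec[:, 0] = acc0[:, 0]
        vec[:, 1] = acc1[:, 0]
        vec[:, 2:] = -acc1[:, :0:-1]
        # batched modulus switch
        switched = reduce_centered(round_half_away(vec * (q_out / Q)), q_out)
        cells.append([LweCiphertext(switched[b], q_out) for b in range(B)])
    return cells


def _center(r: np.ndarray, m: int) -> np.ndarray:
    return np.where(2 * r > m, r - m, r)


# ---------------------------------------------------------------------------
# Client: resolve
# ---------------------------------------------------------------------------


def client_resolve(result: SearchResult, sk: SecretKey, query_chunks,
                   params: HEParams) -> ResolvedMatch:
    """Decrypt every cell and decide presence/absence of the biomarker.

    A block matches when all C of its decrypted chunks equal the query's
    value chunks; the reassembled value of the first matching block is
    returned.  ``max_noise_ratio`` is the largest observed |t*e'/q|; the
    decryption condition requires it below 1/2.
    """
    q = result.cells[0][0].modulus
    t = params.t
    C, B = result.n_chunks, result.n_blocks
    vecs = np.stack(
        [np.stack([cell.vec for cell in row]) for row in result.cells]
    )  # (C, B, N+1)
    ip = reduce_centered(vecs @ sk.lwe_key, q)  # (C, B)
    m = round_half_away(ip * (t / q))
    noise = ip - (q // t) * m
    max_ratio = float(np.abs(noise).max()) * t / q
    decoded = np.mod(m, t)  # (C, B)
    target = np.array([c % t for c in query_chunks], dtype=np.int64)
    hits = np.all(decoded == target[:, None], axis=0)
    matched = bool(hits.any())
    block = int(np.argmax(hits)) if matched else None
    value = unchunk_value(decoded[:, block], t) if matched else 0
    resolved = ResolvedMatch(matched=matched, block=block, value=value,
                             max_noise_ratio=max_ratio)
    result.resolved = resolved
    return resolved
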