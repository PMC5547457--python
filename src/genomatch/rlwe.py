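"""The basic RLWE public-key scheme and its two ciphertext conversions.

Encryption follows the textbook construction: a ciphertext (c0, c1)
satisfies c0 + c1*s = (Q/t)*m + e for a small error e, so decryption is a
rounded rescale.  Two conversions make the search protocol's output
compact: ``to_lwe`` extracts an LWE encryption of the *constant*
coefficient of the plaintext (halving the payload and hiding every other
coefficient), and ``mod_switch`` rescales an LWE ciphertext from Q down to
q_out.  Decryption of an LWE ciphertext at modulus q succeeds whenever the
error satisfies |t*e/q| < 1/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ring import (
    HEParams,
    ParameterError,
    RingElt,
    reduce_centered,
    ring_add,
    ring_from_bytes,
    ring_mult,
    ring_to_bytes,
    round_half_away,
    sample,
)

__all__ = [
    "SecretKey",
    "PublicKey",
    "RlweCiphertext",
    "LweCiphertext",
    "keygen",
    "encrypt",
    "decrypt",
    "add",
    "to_lwe",
    "mod_switch",
    "lwe_decrypt",
    "lift_plaintext",
    "decryption_noise",
    "lwe_to_bytes",
    "lwe_from_bytes",
]


@dataclass
class SecretKey:
    """Sparse ternary ring secret s plus the derived LWE key (1, s_0..s_{N-1})."""

    s: RingElt
    lwe_key: np.ndarray

    @classmethod
    def from_ring(cls, s: RingElt) -> "SecretKey":
        key = np.concatenate(([1], s.coeffs)).astype(np.int64)
        return cls(s=s, lwe_key=key)


@dataclass
class PublicKey:
    """An RLWE instance (a, b) with b = -a*s + e."""

    a: RingElt
    b: RingElt


@dataclass
class RlweCiphertext:
    c0: RingElt
    c1: RingElt

    @property
    def modulus(self) -> int:
        return self.c0.modulus

    def to_bytes(self) -> bytes:
        return ring_to_bytes(self.c0) + ring_to_bytes(self.c1)

    @classmethod
    def from_bytes(cls, buf: bytes, offset: int = 0):
        c0, offset = ring_from_bytes(buf, offset)
        c1, offset = ring_from_bytes(buf, offset)
        return cls(c0, c1), offset


@dataclass
class LweCiphertext:
    """A length-(N+1) vector ct with <ct, (1, s)> = (q/t)*m + e (mod q)."""

    vec: np.ndarray
    modulus: int


def keygen(params: HEParams, rng: np.random.Generator) -> tuple[SecretKey, PublicKey]:
    """Generate the shared secret key and an RLWE public key."""
    s = sample("secret", params, rng)
    a = sample("uniform", params, rng)
    e = sample("gaussian", params, rng)
    b = ring_add(ring_mult(a, s).__neg__(), e)
    return SecretKey.from_ring(s), PublicKey(a=a, b=b)


def lift_plaintext(m: RingElt, params: HEParams) -> RingElt:
    """Scale a plaintext in R_t up to R_Q by the factor Q/t."""
    if m.modulus != params.t:
        raise ParameterError("plaintext must be reduced modulo t")
    return RingElt((params.Q // params.t) * m.coeffs, params.Q)


def encrypt(m: RingElt, pk: PublicKey, params: HEParams,
            rng: np.random.Generator) -> RlweCiphertext:
    """Public-key encryption: ((Q/t)m, 0) + (bv + e0, av + e1).

    The encryption randomness v is ternary of weight h, matching the
    secret's distribution; e0, e1 are rounded Gaussians.
    """
    scaled = lift_plaintext(m, params)
    v = sample("secret", params, rng)
    e0 = sample("gaussian", params, rng)
    e1 = sample("gaussian", params, rng)
    c0 = ring_add(ring_add(scaled, ring_mult(pk.b, v)), e0)
    c1 = ring_add(ring_mult(pk.a, v), e1)
    return RlweCiphertext(c0, c1)


def decrypt(ct: RlweCiphertext, sk: SecretKey, params: HEParams) -> RingElt:
    """m = round((t/Q) * [c0 + s*c1]_Q), reduced mod t (centered)."""
    u = ring_add(ct.c0, ring_mult(ct.c1, sk.s))
    scaled = round_half_away(u.coeffs * (params.t / params.Q))
    return RingElt(reduce_centered(scaled, params.t), params.t)


def add(ct1: RlweCiphertext, ct2: RlweCiphertext) -> RlweCiphertext:
    return RlweCiphertext(ring_add(ct1.c0, ct2.c0), ring_add(ct1.c1, ct2.c1))


def decryption_noise(ct: RlweCiphertext, sk: SecretKey, m: RingElt,
                     params: HEParams) -> int:
    """Max-norm of c0 + c1*s - (Q/t)*m (mod Q); the decryptability margin."""
    u = ring_add(ct.c0, ring_mult(ct.c1, sk.s))
    e = reduce_centered(u.coeffs - lift_plaintext(m, params).coeffs, params.Q)
    return int(np.abs(e).max())


def to_lwe(ct: RlweCiphertext) -> LweCiphertext:
    """Extract an LWE encryption of the constant plaintext coefficient.

    The output (c_{0,0}, c_{1,0}, -c_{1,N-1}, ..., -c_{1,1}) satisfies
    <out, (1, s_0, ..., s_{N-1})> = constant term of c0 + c1*s (mod Q).
    """
    c0 = ct.c0.coeffs
    c1 = ct.c1.coeffs
    vec = np.concatenate(([c0[0], c1[0]], -c1[:0:-1]))
    return LweCiphertext(vec.astype(np.int64), ct.modulus)


def mod_switch(ct: LweCiphertext, q_out: int,
               params: HEParams) -> LweCiphertext:
    """Rescale an LWE ciphertext to modulus q_out: ct' = round((q/Q) * ct)."""
    if ct.modulus % q_out:
        raise ParameterError("q_out must divide the current modulus")
    if q_out % params.t:
        raise ParameterError("t must divide q_out")
    if q_out == ct.modulus:
        return LweCiphertext(ct.vec.copy(), q_out)
    scaled = round_half_away(ct.vec * (q_out / ct.modulus))
    return LweCiphertext(reduce_centered(scaled, q_out), q_out)


def lwe_decrypt(ct: LweCiphertext, sk: SecretKey, params: HEParams) -> int:
    """m = round((t/q) * [<ct, s>]_q) as a value in [0, t)."""
    ip = reduce_centered(int(ct.vec @ sk.lwe_key), ct.modulus)
    m = round_half_away(ip * (params.t / ct.modulus))
    return m % params.t


# ---------------------------------------------------------------------------
# LWE serialization: 16-byte header + N+1 fixed-width entries
# ---------------------------------------------------------------------------

import struct

_LWE_MAGIC = b"GML1"
_LWE_HEADER = struct.Struct("<4sII4x")


def lwe_to_bytes(ct: LweCiphertext) -> bytes:
    m = ct.modulus
    if m & (m - 1):
        raise ParameterError("serialization requires a power-of-two modulus")
    width = 4 if m > 2**16 else 2
    dtype = "<u4" if width == 4 else "<u2"
    payload = np.mod(ct.vec, m).astype(dtype).tobytes()
    return _LWE_HEADER.pack(_LWE_MAGIC, len(ct.vec), m.bit_length() - 1) + payload


def lwe_from_bytes(buf: bytes, offset: int = 0) -> tuple[LweCiphertext, int]:
    magic, n, log2m = _LWE_HEADER.unpack_from(buf, offset)
    if magic != _LWE_MAGIC:
        raise ParameterError("bad LWE ciphertext magic")
    m = 1 << log2m
    width = 4 if m > 2**16 else 2
    dtype = "<u4" if width == 4 else "<u2"
    start = offset + _LWE_HEADER.size
    end = start + n * width
    vec = np.frombuffer(buf[start:end], dtype=dtype).astype(np.int64)
    return LweCiphertext(reduce_centered(vec, m), m), end
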