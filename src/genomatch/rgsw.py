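"""RGSW symmetric encryption and the hybrid RGSW x RLWE multiplication.

An RGSW ciphertext is a 2*d_g x 2 matrix over R_Q: a stack of RLWE
instances shifted by m*G, where G is the gadget matrix
(I || B_g*I || ... || B_g^(d_g-1)*I)^T.  The message m (in this protocol a
signed monomial +-X^k) sits as an approximate eigenvalue:

    CT * (1, s) = m * (1, s, B_g, B_g*s, ..., B_g^(d_g-1), B_g^(d_g-1)*s) + e.

The hybrid multiplication CT^T * WD(ct) of an RGSW ciphertext with the
gadget decomposition of an RLWE ciphertext returns an RLWE encryption of
the product of the two plaintexts, with only gadget-bounded additive noise
growth.  This single operation is the whole homomorphic workload of the
search protocol.

Row ordering is digit-major with the (b, a) column pair interleaved:
row 2j carries the gadget term B_g^j in the b-column, row 2j+1 carries
B_g^j in the a-column, matching the interleaved digit order produced by
``gadget_decompose`` on a ciphertext pair.  The serialization header
records this layout.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from types import SimpleNamespace

import numpy as np

from .ring import (
    HEParams,
    ParameterError,
    RingElt,
    gadget_decompose,
    reduce_centered,
    ring_add,
    ring_from_bytes,
    ring_mult,
    ring_to_bytes,
    sample,
)
from .rlwe import RlweCiphertext, SecretKey

__all__ = ["RgswCiphertext", "rgsw_encrypt", "hybrid_mult", "rgsw_noise"]

_RGSW_MAGIC = b"GMGW"
_RGSW_HEADER = struct.Struct("<4sHHII4x")


@dataclass
class RgswCiphertext:
    """2*d_g rows of (b_row, a_row) pairs over R_Q, plus the gadget base."""

    rows: list  # list[tuple[RingElt, RingElt]], length 2*d_g
    B_g: int

    @property
    def d_g(self) -> int:
        return len(self.rows) // 2

    @property
    def modulus(self) -> int:
        return self.rows[0][0].modulus

    def to_bytes(self) -> bytes:
        body = b"".join(
            ring_to_bytes(b) + ring_to_bytes(a) for b, a in self.rows
        )
        header = _RGSW_HEADER.pack(
            _RGSW_MAGIC, len(self.rows), 2, self.B_g, 0
        )
        return header + body

    @classmethod
    def from_bytes(cls, buf: bytes, offset: int = 0):
        magic, nrows, ncols, B_g, _ = _RGSW_HEADER.unpack_from(buf, offset)
        if magic != _RGSW_MAGIC or ncols != 2:
            raise ParameterError("bad RGSW ciphertext header")
        offset += _RGSW_HEADER.size
        rows = []
        for _ in range(nrows):
            b, offset = ring_from_bytes(buf, offset)
            a, offset = ring_from_bytes(buf, offset)
            rows.append((b, a))
        return cls(rows, B_g), offset


def rgsw_encrypt(m: RingElt, sk: SecretKey, params: HEParams,
                 rng: np.random.Generator) -> RgswCiphertext:
    """Symmetric RGSW encryption: CT = [b, a] + m*G.

    The message lives in R_t (in the protocol, a signed monomial) and is
    lifted to R_Q by its centered representative.  Each row is a fresh
    RLWE instance b = -a*s + e under the shared secret key; the error
    uses the same Gaussian parameter sigma as the RLWE scheme.
    """
    if m.modulus != params.t:
        raise ParameterError("RGSW plaintext must be reduced modulo t")
    m_lift = m.coeffs  # centered lift of the message into Z
    rows = []
    for j in range(params.d_g):
        g = reduce_centered((params.B_g**j) * m_lift, params.Q)
        for col in (0, 1):
            a = sample("uniform", params, rng)
            e = sample("gaussian", params, rng)
            b = ring_add(-ring_mult(a, sk.s), e)
            if col == 0:
                rows.append((RingElt(b.coeffs + g, params.Q), a))
            else:
                rows.append((b, RingElt(a.coeffs + g, params.Q)))
    return RgswCiphertext(rows, params.B_g)


def hybrid_mult(CT: RgswCiphertext, ct: RlweCiphertext) -> RlweCiphertext:
    """The external product CT^T * WD(ct).

    If CT encrypts m and ct encrypts m', the result is a valid RLWE
    encryption of m*m' in R_t.
    """
    if CT.modulus != ct.modulus:
        raise ParameterError("RGSW/RLWE modulus mismatch")
    gadget = SimpleNamespace(B_g=CT.B_g, d_g=CT.d_g)
    digits = gadget_decompose((ct.c0, ct.c1), gadget)
    N, Q = ct.c0.N, ct.modulus
    acc0 = np.zeros(N, dtype=np.int64)
    acc1 = np.zeros(N, dtype=np.int64)
    for u, (b_row, a_row) in zip(digits, CT.rows):
        acc0 += ring_mult(u, b_row).coeffs
        acc1 += ring_mult(u, a_row).coeffs
    return RlweCiphertext(RingElt(acc0, Q), RingElt(acc1, Q))


def rgsw_noise(CT: RgswCiphertext, m: RingElt, sk: SecretKey,
               params: HEParams) -> int:
    """Max-norm of CT*(1,s) - m*(1, s, B_g, B_g*s, ...): the row errors."""
    m_lift = m.coeffs
    worst = 0
    for r, (b_row, a_row) in enumerate(CT.rows):
        j, col = divmod(r, 2)
        lhs = ring_add(b_row, ring_mult(a_row, sk.s))
        target = RingElt(reduce_centered((params.B_g**j) * m_lift, params.Q),
                         params.Q)
        if col == 1:
            target = ring_mult(target, sk.s)
        e = reduce_centered(lhs.coeffs - target.coeffs, params.Q)
        worst = max(worst, int(np.abs(e).max()))
    return worst
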