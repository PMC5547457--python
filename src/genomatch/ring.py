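"""Exact arithmetic in the negacyclic ring Z_m[X]/(X^N + 1).

Everything the encryption scheme touches lives in power-of-two cyclotomic
rings R_m = Z_m[X]/(X^N + 1) with centered coefficient representatives in
(-m/2, m/2].  This module provides the ring element container, centered
modular reduction, exact negacyclic multiplication, the base-B_g gadget
decomposition used by the RGSW scheme, and the three samplers (sparse
ternary secrets, rounded Gaussians, uniform residues).

Multiplication is bit-exact.  Internally it uses a twisted complex FFT on
small coefficient limbs; the limb widths are chosen so that every
convolution coefficient stays far below 2**53 and the accumulated floating
point error is provably below 1/4, so rounding back to integers is exact.
A runtime assertion guards the margin on every call.
"""

from __future__ import annotations

import math
import struct
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = [
    "ParameterError",
    "HEParams",
    "DEFAULT_PARAMS",
    "RingElt",
    "reduce_centered",
    "ring_add",
    "ring_sub",
    "ring_neg",
    "ring_mult",
    "ring_scalar_mult",
    "monomial",
    "gadget_decompose",
    "gadget_recompose",
    "sample",
    "round_half_away",
    "ring_to_bytes",
    "ring_from_bytes",
]


class ParameterError(ValueError):
    """Raised for invalid scheme parameters or mismatched operands."""


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HEParams:
    """All constants of the hybrid RLWE/RGSW scheme.

    Attributes
    ----------
    N : ring dimension, a power of two.  The cyclotomic index is M = 2N.
    Q : ciphertext modulus.
    t : plaintext modulus (divides Q).
    B_g, d_g : gadget base and length, with B_g**d_g >= Q.
    sigma : standard deviation of the discrete Gaussian error.
    h : Hamming weight of the sparse ternary secret.
    q_out : output modulus after switching (divides Q, multiple of t).
    lam : targeted security level in bits.
    """

    N: int = 2048
    Q: int = 2**32
    t: int = 2**11
    B_g: int = 128
    d_g: int = 5
    sigma: float = 1.4
    h: int = 64
    q_out: int = 2**16
    lam: int = 128

    def __post_init__(self) -> None:
        if self.N < 2 or self.N & (self.N - 1):
            raise ParameterError("ring dimension N must be a power of two >= 2")
        if self.t < 2 or self.Q % self.t:
            raise ParameterError("plaintext modulus t must divide Q")
        if self.B_g**self.d_g < self.Q:
            raise ParameterError("gadget must cover the modulus: B_g**d_g >= Q")
        if self.q_out < 2 or self.Q % self.q_out:
            raise ParameterError("output modulus q_out must divide Q")
        if self.q_out % self.t:
            raise ParameterError("t must divide q_out for modulus switching")
        if not 0 < self.h <= self.N:
            raise ParameterError("secret weight h must lie in [1, N]")
        if self.sigma <= 0:
            raise ParameterError("sigma must be positive")

    @property
    def M(self) -> int:
        """Cyclotomic index 2N (so Phi_M(X) = X^N + 1)."""
        return 2 * self.N

    def min_ring_dimension(self) -> int:
        """Smallest N admissible at `lam` bits: N >= (lam+110)/7.2 * log2 Q."""
        return math.ceil((self.lam + 110) / 7.2 * math.log2(self.Q))

    @property
    def meets_security_bound(self) -> bool:
        return self.N >= (self.lam + 110) / 7.2 * math.log2(self.Q)


DEFAULT_PARAMS = HEParams()


# ---------------------------------------------------------------------------
# Centered reduction and the ring element container
# ---------------------------------------------------------------------------


def _center_array(r: np.ndarray, m: int) -> np.ndarray:
    # r holds nonnegative residues in [0, m); map to (-m/2, m/2]
    r = np.where(2 * r > m, r - m, r)
    return r


def reduce_centered(x, m: int):
    """Reduce modulo ``m`` into the centered interval (-m/2, m/2].

    Accepts a Python integer, an integer array, or a :class:`RingElt`
    (reduced coefficient-wise, returning a new element at modulus ``m``).
    """
    if m < 2:
        raise ParameterError("modulus must be >= 2")
    if isinstance(x, RingElt):
        return RingElt(reduce_centered(x.coeffs, m), m)
    if isinstance(x, np.ndarray):
        r = np.mod(x, m)
        return _center_array(r.astype(np.int64, copy=False), m)
    r = int(x) % m
    if 2 * r > m:
        r -= m
    return r


@dataclass
class RingElt:
    """An element of Z_m[X]/(X^N + 1) with centered coefficients."""

    coeffs: np.ndarray
    modulus: int

    def __post_init__(self) -> None:
        if self.modulus < 2:
            raise ParameterError("modulus must be >= 2")
        c = np.asarray(self.coeffs, dtype=np.int64)
        half = self.modulus // 2
        if c.min(initial=0) <= -half - 1 or c.max(initial=0) > half:
            c = reduce_centered(c, self.modulus)
        self.coeffs = c

    # -- construction helpers ------------------------------------------------

    @classmethod
    def zeros(cls, N: int, modulus: int) -> "RingElt":
        return cls(np.zeros(N, dtype=np.int64), modulus)

    @classmethod
    def constant(cls, value: int, N: int, modulus: int) -> "RingElt":
        c = np.zeros(N, dtype=np.int64)
        c[0] = reduce_centered(value, modulus)
        return cls(c, modulus)

    # -- dunder sugar --------------------------------------------------------

    @property
    def N(self) -> int:
        return self.coeffs.shape[0]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, RingElt)
            and self.modulus == other.modulus
            and np.array_equal(self.coeffs, other.coeffs)
        )

    def __add__(self, other: "RingElt") -> "RingElt":
        return ring_add(self, other)

    def __sub__(self, other: "RingElt") -> "RingElt":
        return ring_sub(self, other)

    def __mul__(self, other: "RingElt") -> "RingElt":
        return ring_mult(self, other)

    def __neg__(self) -> "RingElt":
        return ring_neg(self)

    def lift_residues(self) -> np.ndarray:
        """Nonnegative residues in [0, m)."""
        return np.mod(self.coeffs, self.modulus)


def _check_compatible(a: RingElt, b: RingElt) -> None:
    if a.modulus != b.modulus:
        raise ParameterError(
            f"modulus mismatch: {a.modulus} vs {b.modulus}"
        )
    if a.N != b.N:
        raise ParameterError(f"dimension mismatch: {a.N} vs {b.N}")


def ring_add(a: RingElt, b: RingElt) -> RingElt:
    _check_compatible(a, b)
    return RingElt(a.coeffs + b.coeffs, a.modulus)


def ring_sub(a: RingElt, b: RingElt) -> RingElt:
    _check_compatible(a, b)
    return RingElt(a.coeffs - b.coeffs, a.modulus)


def ring_neg(a: RingElt) -> RingElt:
    return RingElt(-a.coeffs, a.modulus)


def ring_scalar_mult(k: int, a: RingElt) -> RingElt:
    k = reduce_centered(k, a.modulus)
    return RingElt(reduce_centered(k * a.coeffs.astype(object), a.modulus)
                   if abs(k) > 2**31 else k * a.coeffs, a.modulus)


def monomial(N: int, exponent: int, modulus: int) -> RingElt:
    """The signed monomial X^exponent in R_m, for any integer exponent.

    Uses X^N = -1, i.e. X^(k+N) = -X^k; negative exponents follow from
    X^(-d) = X^(2N-d).
    """
    e = exponent % (2 * N)
    c = np.zeros(N, dtype=np.int64)
    if e < N:
        c[e] = 1
    else:
        c[e - N] = -1
    return RingElt(c, modulus)


# ---------------------------------------------------------------------------
# Exact negacyclic multiplication
# ---------------------------------------------------------------------------
#
# Coefficients are split into limbs small enough that every convolution
# coefficient is bounded by 2**42; the FFT then computes them to within
# ~1e-3 of the true integers and rounding is exact.  Limb products are
# recombined modulo m (wrap-around uint64 arithmetic when m is a power of
# two, exact int64 otherwise).

_LIMB_BITS = 11
_SINGLE_LIMB_MAX = 2**15


@lru_cache(maxsize=None)
def _twist(N: int):
    k = np.arange(N)
    w = np.exp(1j * np.pi * k / N)
    return w, np.conj(w)


def _nega_fft(x: np.ndarray, N: int) -> np.ndarray:
    w, _ = _twist(N)
    return np.fft.fft(x * w, axis=-1)


def _nega_ifft(X: np.ndarray, N: int) -> np.ndarray:
    _, wc = _twist(N)
    return np.fft.ifft(X, axis=-1) * wc


def _limbify(c: np.ndarray, m: int):
    """Split centered coefficients into (float_array, scale, maxabs) limbs."""
    amax = int(np.abs(c).max(initial=0))
    if amax <= _SINGLE_LIMB_MAX:
        return [(c.astype(np.float64), 1, max(amax, 1))]
    r = np.mod(c, m)  # nonnegative residues < m <= 2**32
    nlimbs = -(-max(m - 1, 1).bit_length() // _LIMB_BITS)
    mask = (1 << _LIMB_BITS) - 1
    out = []
    for i in range(nlimbs):
        limb = (r >> (_LIMB_BITS * i)) & mask
        out.append((limb.astype(np.float64), 1 << (_LIMB_BITS * i), mask))
    return out


def _round_exact(vals: np.ndarray) -> np.ndarray:
    iv = np.rint(vals)
    dev = float(np.abs(vals - iv).max(initial=0.0))
    if dev > 0.25:
        raise ArithmeticError(
            f"FFT convolution lost exactness (max deviation {dev:.3g})"
        )
    return iv.astype(np.int64)


def _combine_buckets(buckets: dict, m: int, N: int) -> np.ndarray:
    """Sum bucket_k * scale_k modulo m, exactly."""
    if m & (m - 1) == 0:
        acc = np.zeros(N, dtype=np.uint64)
        for scale, iv in buckets.items():
            acc += iv.view(np.uint64) * np.uint64(scale % (1 << 64))
        res = (acc & np.uint64(m - 1)).astype(np.int64)
        return _center_array(res, m)
    if m < 2**29:
        acc = np.zeros(N, dtype=np.int64)
        for scale, iv in buckets.items():
            acc = (acc + np.mod(iv, m) * (scale % m)) % m
        return _center_array(acc, m)
    # arbitrary large modulus: exact arbitrary-precision fallback
    acc = np.zeros(N, dtype=object)
    for scale, iv in buckets.items():
        acc = acc + iv.astype(object) * int(scale)
    return reduce_centered(np.array([int(v) % m for v in acc]), m)


def ring_mult(a: RingElt, b: RingElt) -> RingElt:
    """Exact negacyclic product a*b mod (X^N + 1, m)."""
    _check_compatible(a, b)
    N, m = a.N, a.modulus
    la = _limbify(a.coeffs, m)
    lb = _limbify(b.coeffs, m)
    fa = [(_nega_fft(x, N), s, mx) for x, s, mx in la]
    fb = [(_nega_fft(x, N), s, mx) for x, s, mx in lb]
    spectra: dict[int, np.ndarray] = {}
    for Fa, sa, mxa in fa:
        for Fb, sb, mxb in fb:
            if mxa * mxb * N > 2**42:
                raise ArithmeticError("limb bound exceeded; cannot multiply exactly")
            key = sa * sb
            prod = Fa * Fb
            if key in spectra:
                spectra[key] += prod
            else:
                spectra[key] = prod
    buckets = {
        scale: _round_exact(np.real(_nega_ifft(spec, N)))
        for scale, spec in spectra.items()
    }
    return RingElt(_combine_buckets(buckets, m, N), m)


# ---------------------------------------------------------------------------
# Gadget decomposition
# ---------------------------------------------------------------------------


def _balanced_digits(x: np.ndarray, B_g: int, d_g: int) -> list[np.ndarray]:
    """Signed base-B_g digits in [-B_g/2, B_g/2), least significant first."""
    x = x.copy()
    digits = []
    half = B_g // 2
    for _ in range(d_g):
        d = np.mod(x, B_g)
        d = np.where(d >= half, d - B_g, d)
        digits.append(d.astype(np.int64))
        x = (x - d) // B_g
    if np.any(x):
        raise ArithmeticError("gadget decomposition did not terminate")
    return digits


def gadget_decompose(v, params: HEParams):
    """Decompose a ring element (or a pair of them) into gadget digits.

    A single element yields d_g digit polynomials; a pair (c0, c1) yields
    the 2*d_g interleaved digits (digit_j(c0), digit_j(c1)) matching the
    row order of the gadget matrix G.  Digits satisfy the recomposition
    identity sum_j B_g**j * digit_j == v (mod Q) with every coefficient
    of magnitude at most B_g/2.
    """
    if isinstance(v, (tuple, list)):
        c0, c1 = v
        _check_compatible(c0, c1)
        d0 = _balanced_digits(c0.coeffs, params.B_g, params.d_g)
        d1 = _balanced_digits(c1.coeffs, params.B_g, params.d_g)
        out = []
        for j in range(params.d_g):
            out.append(RingElt(d0[j], c0.modulus))
            out.append(RingElt(d1[j], c0.modulus))
        return out
    digits = _balanced_digits(v.coeffs, params.B_g, params.d_g)
    return [RingElt(d, v.modulus) for d in digits]


def gadget_recompose(digits, params: HEParams):
    """Inverse of :func:`gadget_decompose` (tests and sanity checks)."""
    if len(digits) == 2 * params.d_g:
        c0 = gadget_recompose(digits[0::2], params)
        c1 = gadget_recompose(digits[1::2], params)
        return c0, c1
    m = digits[0].modulus
    acc = np.zeros(digits[0].N, dtype=np.int64)
    for j, d in enumerate(digits):
        acc = acc + (params.B_g**j) * d.coeffs
    return RingElt(reduce_centered(acc, m), m)


# ---------------------------------------------------------------------------
# Samplers
# ---------------------------------------------------------------------------


def round_half_away(x):
    """Round to nearest integer, half away from zero (the global convention)."""
    if isinstance(x, np.ndarray):
        return (np.sign(x) * np.floor(np.abs(x) + 0.5)).astype(np.int64)
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def sample(kind: str, params: HEParams, rng: np.random.Generator,
           modulus: int | None = None) -> RingElt:
    """Draw a ring element from one of the scheme's three distributions.

    ``secret``   -- sparse ternary: exactly h coefficients are +-1 (signs
                    equiprobable), positions uniform without replacement.
    ``gaussian`` -- i.i.d. integer-rounded Gaussian of std-dev sigma.
    ``uniform``  -- i.i.d. uniform over the centered residues mod ``modulus``.
    """
    m = modulus if modulus is not None else params.Q
    N = params.N
    if kind == "secret":
        c = np.zeros(N, dtype=np.int64)
        pos = rng.choice(N, size=params.h, replace=False)
        c[pos] = rng.choice(np.array([-1, 1], dtype=np.int64), size=params.h)
        return RingElt(c, m)
    if kind == "gaussian":
        c = round_half_away(rng.normal(0.0, params.sigma, size=N))
        return RingElt(c, m)
    if kind == "uniform":
        c = rng.integers(0, m, size=N, dtype=np.int64)
        return RingElt(c, m)
    raise ParameterError(f"unknown sampler kind: {kind!r}")


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------
#
# A ring element is stored as a 16-byte header (magic, N, log2 modulus,
# padding) followed by N little-endian fixed-width residues: 4 bytes per
# entry for moduli above 2**16, 2 bytes otherwise.

_RING_MAGIC = b"GMR1"
_HEADER = struct.Struct("<4sII4x")


def _entry_width(modulus: int) -> int:
    return 4 if modulus > 2**16 else 2


def ring_to_bytes(elt: RingElt) -> bytes:
    m = elt.modulus
    if m & (m - 1):
        raise ParameterError("serialization requires a power-of-two modulus")
    log2m = m.bit_length() - 1
    width = _entry_width(m)
    dtype = "<u4" if width == 4 else "<u2"
    payload = elt.lift_residues().astype(dtype).tobytes()
    return _HEADER.pack(_RING_MAGIC, elt.N, log2m) + payload


def ring_from_bytes(buf: bytes, offset: int = 0) -> tuple[RingElt, int]:
    magic, N, log2m = _HEADER.unpack_from(buf, offset)
    if magic != _RING_MAGIC:
        raise ParameterError("bad ring element magic")
    m = 1 << log2m
    width = _entry_width(m)
    dtype = "<u4" if width == 4 else "<u2"
    start = offset + _HEADER.size
    end = start + N * width
    c = np.frombuffer(buf[start:end], dtype=dtype).astype(np.int64)
    return RingElt(reduce_centered(c, m), m), end
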