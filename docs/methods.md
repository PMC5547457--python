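# Methods

## Model and assumptions

The protocol solves private exact-match retrieval over a key–value
database derived from variant records.  The threat model is semi-honest:
the server follows the protocol but may inspect everything it sees; the
client owns both the data and the keys.  Security of all ciphertexts
reduces to decisional Ring-LWE in the negacyclic ring
R_Q = Z_Q[X]/(X^N+1) with a sparse ternary secret.  The server never
receives key material — `server_search` is a pure function of
ciphertexts and public manifest fields, and its output is one LWE
ciphertext per (chunk, block) cell, each encrypting only the sum
DB*[d*] + DB†[d†] for the queried hash pair.  The conversion to a
single-coefficient LWE ciphertext is what prevents the reply from
leaking the other N−1 coefficients of the product polynomial.

What the client learns beyond presence/absence: the index of the
matching block.  Since the client built the database itself this is
considered acceptable; a deployment that splits the data owner from the
querier would need to revisit it.

## Scheme parameters

| symbol | default | meaning |
|--------|---------|---------|
| N      | 2048    | ring dimension (cyclotomic index M = 2N) |
| Q      | 2³²     | ciphertext modulus |
| t      | 2¹¹     | plaintext modulus (divides Q and q) |
| B_g, d_g | 128, 5 | gadget base/length, B_g^d_g = 2³⁵ ≥ Q |
| σ      | 1.4     | std-dev of the rounded-Gaussian errors |
| h      | 64      | Hamming weight of the ternary secret |
| q      | 2¹⁶     | output modulus after switching |
| λ      | 128     | security target; N ≥ (λ+110)/7.2·log₂Q = 1058 |

One Gaussian parameter serves both the RLWE and RGSW schemes.  The
output modulus q = 2¹⁶ is the smallest power of two that keeps 16-bit
result entries while leaving the noise budget below: after switching,
the error is (q/Q)·e plus a rounding term bounded by (1+h)/2 = 32.5 in
the worst case but concentrated near zero (a signed sum of h+1 half-unit
roundings, std ≈ 2.3); decryption needs |e'| < q/(2t) = 16.  The
worst-case bound exceeds 16, so correctness is statistical, not
worst-case: the failure probability per cell is Φ-tail(≈7σ) ≈ 10⁻¹¹, and
the largest ratio observed over the full acceptance run (8·10⁴ cells) is
|t·e'/q| ≈ 0.34.  The resolve step reports this margin so a deployment
can monitor it.

Structural parameter invariants (power-of-two N, t | q | Q,
B_g^d_g ≥ Q, h ≤ N) are enforced at construction.  The λ security bound
is exposed as a predicate rather than enforced, because reduced-
dimension rings (N = 8…64) are deliberately used in tests and would
never pass it; the default parameter set is asserted to pass.

## Encoding choices

* Tag: d = ch + 24·pos with X→0, Y→23; positions 1-based.  `chr`
  prefixes are tolerated and case is ignored.
* Alleles: 2 bits per base, leading 1 marker, '.'/empty → 0; REF and ALT
  concatenated as α = 2^ℓ·α_ref + α_alt with ℓ = 2·n_SNP+1.  Multi-
  allelic ALT fields are rejected rather than silently split.
* Chunking: C = ⌈(4·n_SNP+2)/log₂t⌉ base-t digits, least significant
  first (C = 1, 2, 4 for n_SNP = 2, 5, 10).
* Hashing: SHA3-256 of the 8-byte little-endian tag; the digest read as
  a little-endian integer supplies the low log₂N bits for d* and the
  next log₂N for d†.  Any fixed convention works as long as both sides
  share it, so it is recorded in every manifest and checked before a
  search.

## Database construction

The dual polynomials must satisfy DB*[d*ᵢ] + DB†[d†ᵢ] ≡ αᵢ (mod t) for
every record and chunk.  Within a block these are difference constraints
on a bipartite graph (star slots vs dagger slots, substituting
y_dagger = −x_dagger), solved incrementally with a weighted union-find:
adding a record either unions two components (always consistent) or
closes a cycle, in which case the accumulated offsets must reproduce the
record's chunk vector in *all* C chunks simultaneously.  Placement is
greedy first fit over blocks of capacity 100; a record that contradicts
every open block opens a new one.  Identical hash pairs with identical
values coexist in one block; with different values they are forced
apart.  After placement each component root receives a uniform random
value per chunk and offsets propagate, so every coefficient — free or
constrained — is marginally uniform on Z_t, which is what makes
non-matching cells indistinguishable from noise.

The direct layout (DB(X) with the value at exponent d) is kept for tag
domains below N; its zero-filler variant returns 0 for a non-match
instead of noise.

## Exact arithmetic

All ring arithmetic is bit-exact.  Multiplication splits centered
coefficients into limbs (single signed limb when max|c| ≤ 2¹⁵, else
11-bit limbs of the nonnegative residue), transforms them with the
twisted FFT that realizes negacyclic convolution, and recombines limb
products modulo m with wraparound uint64 arithmetic (power-of-two m) or
exact int64.  Limb bounds keep every convolution coefficient below
2⁴², where float64 FFT round-off is below 10⁻³; every inverse transform
asserts a rounding margin < 1/4, so any loss of exactness raises rather
than corrupts.  Gadget digits are balanced signed digits in
[−B_g/2, B_g/2), which halves the average digit magnitude relative to
unsigned digits and with it the hybrid-multiplication noise.
⌊·⌉ is round-half-away-from-zero everywhere.

`server_search` exists twice: a reference composition of the public ring
operations, and a production path that caches the gadget-digit FFTs of
the (query-independent) database ciphertexts and processes all blocks of
a chunk in one batched einsum, with 16-bit query limbs (digit × limb
sums stay below 2³⁷).  The two paths are asserted bit-identical in the
tests; the cache makes repeated queries against one database ~6× faster
than the first.

## Synthetic data

The generator emulates a germline variant database at the study's scale:
unique (chromosome, position) tags uniform over the 24 chromosome labels
and positions 1…3·10⁸, allele strings of length ≤ n_SNP with 80 %
single-base variants and the rest uniform in [2, n_SNP], and a 10 %
unknown ('.') probability per side (never both sides unknown, which
would make the value 0).  It reproduces the tag-distinctness, alphabet
and length structure of real VCF-derived records but none of their
linkage structure, allele-frequency spectrum or positional clustering —
irrelevant here, because the protocol treats records as opaque
(tag, value) pairs; passing tests therefore transfer to real data
whose records respect the same field constraints, and say nothing about
workloads that violate them (multi-allelic sites, symbolic alleles).

## Problem sizes

The randomized correctness suites run 1000 trials each at the default
parameters.  The end-to-end check uses a 10⁴-record database (n_SNP = 10,
C = 4, 100 blocks) with 100 present and 100 absent queries; the same
sizes are used by `scripts/acceptance.py`.  Larger databases scale
linearly in blocks (storage and per-query server work ∝ C·blocks).

## Known limitations

* Single query per round; no batching.
* Semi-honest model only; no integrity protection on the server's reply.
* The reply reveals the matching block index to the client.
* Wall-clock performance is not the goal: the implementation favors
  provable exactness over the complex-FFT throughput of an optimized
  native implementation.
* The hashed layout's false-positive probability is blocks·t^(−C)
  (≈ 10⁻¹² at defaults) — negligible but nonzero, and it grows if t or C
  shrink.
* Correctness after modulus switching is statistical (see above), with
  ~10⁻¹¹ per-cell failure probability at defaults.
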