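# genomatch

Secure search-and-extract of genomic biomarkers over homomorphically
encrypted databases.

## The problem

A client holds a VCF file of germline variants — rows of
`(CHROM, POS, REF, ALT)` — and wants to outsource it to an untrusted
server, then later ask "is this biomarker present, and what are its
alleles?" without the server learning anything about the database *or*
the query, and without the answer leaking any record other than the one
queried.  This is the secure outsourcing-matching problem for genetic
testing: the server must compute the exact match entirely on ciphertexts.

## The method

Every record is reduced to an integer pair: a **tag**
d = ch + 24·pos (chromosomes 1–22 keep their number, X→0, Y→23) and a
**value** α that concatenates 2-bit allele codes (A=00, T=01, G=10, C=11)
for REF and ALT, each prefixed with a 1 bit and zero-padded to
ℓ_SNP = 2·n_SNP + 1 bits; an unknown side ('.') encodes as 0, so e.g.
`GC` → 1|10|11₂ = 27 and (G, A) → α = 2²¹·6 + 4 = 12582916 at n_SNP = 10.

The whole database becomes a *single polynomial* per value chunk,

    DB(X) = Σᵢ αᵢ · X^(dᵢ)   ∈  Z_t[X]/(X^N + 1),

encrypted under an RLWE scheme (N = 2048, Q = 2³², t = 2¹¹).  A query
for tag d is an RGSW encryption of the monomial X^(−d).  Because
X^N = −1 in this ring, one **hybrid multiplication**
ct' = CTᵀ · WD(ct) — the external product of the RGSW query with the
gadget decomposition (B_g = 128, d_g = 5) of the RLWE database
ciphertext — rotates the coefficient at position d into the constant
term.  The server then *extracts* only that constant coefficient as an
LWE ciphertext and modulus-switches it from Q to q = 2¹⁶, so the reply
is small and reveals nothing about the other coefficients.  Decryption
is correct whenever |t·e/q| < 1/2 for the accumulated noise e.

Real tags are ~32-bit, far above N, so tags are compressed through
SHA3-256 into a pair (d*, d†) of 11-bit indices and the database is
built as *dual polynomials* DB*, DB† satisfying

    DB*[d*ᵢ] + DB†[d†ᵢ] ≡ αᵢ  (mod t)

for every record, with all unconstrained coefficients uniform in Z_t.
Records are packed into blocks of ≤ 100; the client decides a match when
some block reproduces all C = ⌈(4·n_SNP+2)/log₂t⌉ chunks of its query
value.  Values wider than t are split into those C base-t chunks and the
procedure repeats per chunk.  The secret key is a sparse ternary
polynomial with 64 nonzero ±1 coefficients; errors are rounded Gaussians
with σ = 1.4; the parameters satisfy the security bound
N ≥ (λ+110)/7.2 · log₂Q at λ = 128.

## Worked example

```python
import numpy as np
import genomatch as gm
from genomatch.io_synth import SynthConfig, generate_synthetic

params = gm.DEFAULT_PARAMS
rng = np.random.default_rng(7)

records = generate_synthetic(SynthConfig(n_records=1000, seed=11))
dbenc = gm.build_db_hashed(records, params, rng, n_snp=10, block_capacity=100)
sk, pk = gm.client_setup(params, rng)
edb = gm.encrypt_database(dbenc, pk, params, rng)

r = records[123]
q = gm.encode_query(r.chrom, r.pos, r.ref, r.alt, params, n_snp=10)
eq = gm.encrypt_query(q, sk, params, rng)

res = gm.server_search(edb, eq, params)        # server: ciphertexts only
match = gm.client_resolve(res, sk, q.chunks, params)
```

This prints (via the surrounding `print` calls):

```
database: 1000 records -> 10 blocks x 4 chunks
encrypted database: 80 RLWE ciphertexts
query: chrom=X pos=259213851 ref=A alt=CATTGT
tag d = 6221132424, alpha = 8395865, chunks = (1113, 3, 2, 0)
matched = True, block = 1, value = 8395865, max |t*e'/q| = 0.1562
decoded alleles: ('A', 'CATTGT')
```

The 1000 records became 10 blocks × 4 chunks = 40 polynomial pairs (80
RLWE ciphertexts).  The query's value 8395865 splits into four base-2¹¹
chunks; block 1 reproduced all four, so the client reports a match and
reassembles exactly the stored α — here decoding back to the REF/ALT
pair (A, CATTGT).  The worst observed noise ratio 0.16 is well inside
the |t·e'/q| < 1/2 decryption condition.  A query for an absent tag
decrypts to uniform noise in every block and matches all four chunks of
a given value with probability ≤ blocks · t⁻⁴ ≈ 2⁻⁴⁰.

The same flow is scriptable from a shell:

```sh
genomatch keygen --seed 1 --out keys/
genomatch encode-db db.vcf --keys keys/ --seed 2 --out dbenc/
genomatch encrypt-db dbenc/ --keys keys/ --seed 3 --out edb/
genomatch query --chrom 1 --pos 161235340 --ref G --alt A \
    --keys keys/ --seed 4 --out query/
genomatch search edb/ query/ --out results/
genomatch resolve results/ --keys keys/ --query query/
```

## Layout

- `src/genomatch/ring.py` — negacyclic ring arithmetic (exact), gadget
  decomposition, samplers, parameters
- `src/genomatch/rlwe.py` — the RLWE scheme, LWE extraction, modulus
  switching
- `src/genomatch/rgsw.py` — RGSW encryption and the hybrid multiplication
- `src/genomatch/encoding.py` — genomic encodings, SHA-3 tag compression,
  database polynomial construction
- `src/genomatch/protocol.py` — the three-party flow
- `src/genomatch/io_synth.py` — VCF I/O, synthetic data, golden fixture
- `docs/methods.md` — model, assumptions, numerical choices, limitations
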