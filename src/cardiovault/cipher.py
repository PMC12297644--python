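"""Matrix-based RSA block cipher.

A hybrid of a Hill-style mixing step and textbook RSA: plaintext bytes are
chunked into integers modulo n, grouped into k-vectors, mixed by an
invertible k x k matrix A over Z_n, and each mixed component is then raised
to the public exponent e modulo n.  Decryption applies the private exponent
d componentwise and then the modular inverse matrix A_inv.  Because n is
squarefree (a product of two distinct primes) the RSA map is a bijection on
all of Z_n, so the round trip is exact even for residues sharing a factor
with n.

This is an educational / fidelity cipher for studying the secured-pipeline
design, NOT audited cryptography: no padding scheme, no constant-time
guarantees, and test-scale key sizes by default.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass
from typing import List, Sequence

import sympy
from sympy.matrices import Matrix

__all__ = [
    "PublicKey",
    "PrivateKey",
    "generate_keypair",
    "matrix_inverse_mod",
    "encode_record",
    "decode_record",
    "encrypt",
    "decrypt",
    "encrypt_record",
    "decrypt_record",
    "keypair_to_json",
    "keypair_from_json",
]

Block = List[int]


@dataclass
class PublicKey:
    n: int
    e: int
    matrix: List[List[int]]  # k x k mixing matrix over Z_n
    k: int

    @property
    def chunk_width(self) -> int:
        """Bytes per plaintext chunk so that every chunk integer is < n."""
        return (self.n.bit_length() - 1) // 8


@dataclass
class PrivateKey:
    n: int
    d: int
    matrix_inv: List[List[int]]
    k: int
    primes: tuple[int, int] | None = None  # retained for testing only


def _random_prime(bits: int, rand: random.Random) -> int:
    """Draw a random prime of exactly ``bits`` bits (seeded)."""
    if bits < 2:
        raise ValueError("need at least 2 bits")
    while True:
        cand = rand.getrandbits(bits) | (1 << (bits - 1)) | 1
        if sympy.isprime(cand):
            return cand


def matrix_inverse_mod(A: Sequence[Sequence[int]], n: int) -> List[List[int]]:
    """Inverse of a square integer matrix modulo n.

    Raises ValueError when det(A) shares a factor with n; the error message
    never discloses the factor (which would leak n's factorization).
    """
    M = Matrix([[int(v) for v in row] for row in A])
    if not M.is_square:
        raise ValueError("matrix must be square")
    try:
        inv = M.inv_mod(n)
    except Exception as exc:  # sympy raises ValueError/NonInvertibleMatrixError
        raise ValueError("matrix is not invertible modulo n") from exc
    return [[int(v) % n for v in inv.row(i)] for i in range(inv.rows)]


def generate_keypair(
    bit_length: int = 64, k: int = 2, seed: int = 0
) -> tuple[PublicKey, PrivateKey]:
    """Seeded key generation.

    Two distinct primes of ~bit_length/2 bits form n; e is 65537 when
    coprime to phi(n) (else the next odd coprime); the mixing matrix A is
    sampled uniformly over Z_n until invertible mod n (error after 1000
    failed draws).
    """
    if bit_length < 16:
        raise ValueError("bit_length must be >= 16")
    if k < 1:
        raise ValueError("k must be >= 1")
    rand = random.Random(seed)
    half = bit_length // 2
    x = _random_prime(half, rand)
    y = _random_prime(bit_length - half, rand)
    while y == x:
        y = _random_prime(bit_length - half, rand)
    n = x * y
    phi = (x - 1) * (y - 1)
    e = 65537
    if math.gcd(e, phi) != 1:
        e = 3
        while math.gcd(e, phi) != 1:
            e += 2
    d = pow(e, -1, phi)
    for _ in range(1000):
        A = [[rand.randrange(n) for _ in range(k)] for _ in range(k)]
        try:
            A_inv = matrix_inverse_mod(A, n)
            break
        except ValueError:
            continue
    else:
        raise RuntimeError("failed to draw an invertible mixing matrix")
    pub = PublicKey(n=n, e=e, matrix=A, k=k)
    priv = PrivateKey(n=n, d=d, matrix_inv=A_inv, k=k, primes=(x, y))
    return pub, priv


def encode_record(record: bytes, pub: PublicKey) -> List[Block]:
    """Byte codec: length prefix, big-endian chunks, zero-pad to k-blocks.

    The record's byte length is the first integer; the payload is split into
    chunk_width-byte big-endian integers (final chunk zero-padded on the
    right); the integer list is padded with zeros to a multiple of k.
    """
    if not record:
        raise ValueError("record must be non-empty")
    w = pub.chunk_width
    if w < 1:
        raise ValueError("modulus too small for the byte codec (need n > 2^8)")
    if len(record) >= pub.n:
        raise ValueError("record too long for the length prefix")
    ints = [len(record)]
    for i in range(0, len(record), w):
        chunk = record[i:i + w]
        chunk = chunk + b"\x00" * (w - len(chunk))
        ints.append(int.from_bytes(chunk, "big"))
    while len(ints) % pub.k != 0:
        ints.append(0)
    return [ints[i:i + pub.k] for i in range(0, len(ints), pub.k)]


def decode_record(blocks: Sequence[Block], pub: PublicKey) -> bytes:
    """Inverse of :func:`encode_record`."""
    ints: List[int] = [v for block in blocks for v in block]
    if not ints:
        raise ValueError("no blocks to decode")
    w = pub.chunk_width
    length = ints[0]
    n_chunks = -(-length // w)  # ceil
    if n_chunks > len(ints) - 1:
        raise ValueError("truncated block stream")
    payload = b"".join(v.to_bytes(w, "big") for v in ints[1:1 + n_chunks])
    return payload[:length]


def _matvec_mod(A: Sequence[Sequence[int]], v: Sequence[int], n: int) -> List[int]:
    return [sum(a * b for a, b in zip(row, v)) % n for row in A]


def encrypt(blocks: Sequence[Block], pub: PublicKey, chain: bool = False) -> List[Block]:
    """Per block M: mix C = A.M mod n, then c_i = C_i^e mod n.

    With ``chain`` enabled the previous cipher block is added (mod n) to the
    next plain block before mixing, so identical plaintext blocks encrypt
    differently after the first.
    """
    out: List[Block] = []
    prev = [0] * pub.k
    for block in blocks:
        if len(block) != pub.k:
            raise ValueError(f"block length {len(block)} != k={pub.k}")
        if any(not (0 <= v < pub.n) for v in block):
            raise ValueError("block entry out of range [0, n)")
        m = [(v + p) % pub.n for v, p in zip(block, prev)] if chain else list(block)
        mixed = _matvec_mod(pub.matrix, m, pub.n)
        c = [pow(v, pub.e, pub.n) for v in mixed]
        out.append(c)
        prev = c
    return out


def decrypt(cipher: Sequence[Block], priv: PrivateKey, chain: bool = False) -> List[Block]:
    """Per block: m_i' = c_i^d mod n componentwise, then M = A_inv.m' mod n."""
    out: List[Block] = []
    prev = [0] * priv.k
    for block in cipher:
        if len(block) != priv.k:
            raise ValueError(f"cipher block length {len(block)} != k={priv.k}")
        unexp = [pow(v, priv.d, priv.n) for v in block]
        m = _matvec_mod(priv.matrix_inv, unexp, priv.n)
        if chain:
            m = [(v - p) % priv.n for v, p in zip(m, prev)]
            prev = list(block)
        out.append(m)
    return out


def encrypt_record(record: bytes, pub: PublicKey, chain: bool = False) -> List[Block]:
    return encrypt(encode_record(record, pub), pub, chain=chain)


def decrypt_record(cipher: Sequence[Block], priv: PrivateKey,
                   pub: PublicKey, chain: bool = False) -> bytes:
    return decode_record(decrypt(cipher, priv, chain=chain), pub)


def keypair_to_json(pub: PublicKey, priv: PrivateKey | None = None) -> str:
    """Serialize keys as JSON with decimal strings for big integers."""
    obj: dict = {
        "format_version": 1,
        "public": {
            "n": str(pub.n),
            "e": str(pub.e),
            "k": pub.k,
            "matrix": [[str(v) for v in row] for row in pub.matrix],
        },
    }
    if priv is not None:
        obj["private"] = {
            "n": str(priv.n),
            "d": str(priv.d),
            "k": priv.k,
            "matrix_inv": [[str(v) for v in row] for row in priv.matrix_inv],
        }
    return json.dumps(obj, indent=2)


def keypair_from_json(text: str) -> tuple[PublicKey, PrivateKey | None]:
    obj = json.loads(text)
    p = obj["public"]
    pub = PublicKey(
        n=int(p["n"]), e=int(p["e"]), k=int(p["k"]),
        matrix=[[int(v) for v in row] for row in p["matrix"]],
    )
    priv = None
    if "private" in obj:
        q = obj["private"]
        priv = PrivateKey(
            n=int(q["n"]), d=int(q["d"]), k=int(q["k"]),
            matrix_inv=[[int(v) for v in row] for row in q["matrix_inv"]],
        )
    return pub, priv
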