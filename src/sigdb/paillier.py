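"""Paillier additive homomorphic cryptosystem.

A from-scratch implementation of the Paillier scheme with the standard
``g = n + 1`` simplification:

* key: modulus ``n = p q`` (two same-size primes), private ``lambda =
  lcm(p-1, q-1)`` and ``mu = lambda^{-1} mod n``;
* encryption of ``m`` in ``[0, n)``: ``c = (1 + m n) r^n mod n^2`` with ``r``
  drawn fresh and uniform from the units mod ``n``;
* homomorphic addition: ``c1 c2 mod n^2`` decrypts to ``m1 + m2 mod n``;
* decryption: ``m = L(c^lambda mod n^2) mu mod n`` with ``L(x) = (x-1)/n``.

Randomness for key generation and encryption comes from the operating
system's CSPRNG (:mod:`secrets`). A *deterministic mode* — passing a seeded
``random.Random`` as ``rng`` — exists solely for reproducible regression
fixtures and is NOT secure: never use it to protect real data.

The default key size of 3072 bits targets ~128-bit security; 512- and
1024-bit keys are accepted for fast tests only.
"""

from __future__ import annotations

import math
import random
import secrets
from dataclasses import dataclass, field
from typing import Optional, Tuple

from .errors import KeyMismatchError

#: Key sizes accepted by :func:`keygen`. 512/1024 are for tests only.
SUPPORTED_KEY_SIZES = (512, 1024, 2048, 3072, 4096)
DEFAULT_KEY_SIZE = 3072

_SMALL_PRIMES = (2, 3, 5, 7, 11, 13, 17, 19, 23, 29, 31, 37, 41, 43, 47)


def _is_probable_prime(n: int, rounds: int = 40, rng: Optional[random.Random] = None) -> bool:
    """Miller-Rabin primality test."""
    if n < 2:
        return False
    for p in _SMALL_PRIMES:
        if n % p == 0:
            return n == p
    d, s = n - 1, 0
    while d % 2 == 0:
        d //= 2
        s += 1
    randbelow = rng.randrange if rng is not None else (lambda b: secrets.randbelow(b))
    for _ in range(rounds):
        a = randbelow(n - 3) + 2
        x = pow(a, d, n)
        if x in (1, n - 1):
            continue
        for _ in range(s - 1):
            x = x * x % n
            if x == n - 1:
                break
        else:
            return False
    return True


def _gen_prime(bits: int, rng: Optional[random.Random] = None) -> int:
    getrandbits = rng.getrandbits if rng is not None else secrets.randbits
    while True:
        candidate = getrandbits(bits) | (1 << (bits - 1)) | 1
        if _is_probable_prime(candidate, rng=rng):
            return candidate


@dataclass(frozen=True)
class PublicKey:
    """Paillier public key: modulus ``n`` with generator ``g = n + 1``."""

    n: int
    key_size: int

    def __post_init__(self) -> None:
        if self.n.bit_length() != self.key_size:
            raise ValueError(
                f"modulus bit length {self.n.bit_length()} != key_size {self.key_size}"
            )
        if self.n % 2 == 0:
            raise ValueError("modulus must be odd")

    @property
    def nsquare(self) -> int:
        return self.n * self.n

    def encrypt(self, m: int, rng: Optional[random.Random] = None) -> "Ciphertext":
        """Encrypt ``m`` in ``[0, n)`` with fresh randomness.

        ``rng`` (a seeded ``random.Random``) switches to the deterministic
        fixture mode; leave it ``None`` for cryptographic randomness.
        """
        if not 0 <= m < self.n:
            raise ValueError(f"plaintext {m} outside message space [0, {self.n})")
        n, n2 = self.n, self.nsquare
        while True:
            r = (rng.randrange(n - 1) if rng is not None else secrets.randbelow(n - 1)) + 1
            if math.gcd(r, n) == 1:
                break
        # g^m = (1 + n)^m = 1 + m n  (mod n^2)
        c = (1 + m * n) % n2 * pow(r, n, n2) % n2
        return Ciphertext(value=c, public_key=self)


@dataclass(frozen=True)
class PrivateKey:
    """Paillier private key bound to its :class:`PublicKey`."""

    p: int
    q: int
    public_key: PublicKey
    lam: int = field(init=False, repr=False)
    mu: int = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.p * self.q != self.public_key.n:
            raise ValueError("p*q does not match the public modulus")
        lam = math.lcm(self.p - 1, self.q - 1)
        object.__setattr__(self, "lam", lam)
        object.__setattr__(self, "mu", pow(lam, -1, self.public_key.n))

    def decrypt(self, c: "Ciphertext") -> int:
        """Recover the plaintext in ``[0, n)``."""
        if c.public_key.n != self.public_key.n:
            raise KeyMismatchError("ciphertext was produced under a different key")
        n, n2 = self.public_key.n, self.public_key.nsquare
        if not 0 <= c.value < n2:
            raise ValueError("malformed ciphertext: value outside [0, n^2)")
        x = pow(c.value, self.lam, n2)
        return (x - 1) // n * self.mu % n


@dataclass(frozen=True)
class Ciphertext:
    """A Paillier ciphertext; ``+`` is homomorphic plaintext addition."""

    value: int
    public_key: PublicKey

    def __add__(self, other: "Ciphertext") -> "Ciphertext":
        return add(self, other)


def keygen(
    key_size: int = DEFAULT_KEY_SIZE, rng: Optional[random.Random] = None
) -> Tuple[PublicKey, PrivateKey]:
    """Generate a Paillier key pair.

    ``key_size`` is the bit length of the modulus and must be one of
    :data:`SUPPORTED_KEY_SIZES` (use 3072+ for real data; 512/1024 only in
    tests). ``rng`` enables the deterministic fixture mode.
    """
    if key_size not in SUPPORTED_KEY_SIZES:
        raise ValueError(
            f"unsupported key_size {key_size}; choose one of {SUPPORTED_KEY_SIZES} "
            f"(512/1024 for tests, >=2048 for real use)"
        )
    half = key_size // 2
    while True:
        p = _gen_prime(half, rng)
        q = _gen_prime(half, rng)
        if p != q and (p * q).bit_length() == key_size:
            break
    pk = PublicKey(n=p * q, key_size=key_size)
    return pk, PrivateKey(p=p, q=q, public_key=pk)


def encrypt(pk: PublicKey, m: int, rng: Optional[random.Random] = None) -> Ciphertext:
    """Encrypt ``m`` under ``pk`` (see :meth:`PublicKey.encrypt`)."""
    return pk.encrypt(m, rng=rng)


def add(c1: Ciphertext, c2: Ciphertext) -> Ciphertext:
    """Homomorphic addition: the product of ciphertexts mod ``n^2``."""
    if c1.public_key.n != c2.public_key.n:
        raise KeyMismatchError("cannot add ciphertexts under different keys")
    n2 = c1.public_key.nsquare
    return Ciphertext(value=c1.value * c2.value % n2, public_key=c1.public_key)


def decrypt(sk: PrivateKey, c: Ciphertext) -> int:
    """Decrypt ``c`` under ``sk`` (see :meth:`PrivateKey.decrypt`)."""
    return sk.decrypt(c)
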