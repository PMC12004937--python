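"""SMILES tokenization, masked-sequence preprocessing and fingerprints.

The tokenizer treats each chemically meaningful symbol of a SMILES
string as one token over a fixed 51-symbol vocabulary (atoms, aromatic
atoms, ring digits, bond and branch punctuation, two-character element
symbols, and five special markers).  Sequences are framed by begin/end
markers and padded to a fixed length (default 256); over-length input
raises rather than truncating so that downstream features stay
deterministic.

Masked-sequence corruption follows the standard masked-language-model
recipe used for self-supervised pretraining on SMILES corpora: 15% of
the eligible (non-special) symbols are selected, of which 80% are
masked, 10% kept and 10% replaced by a random vocabulary symbol.

Fingerprints are produced by *providers*.  The pretrained
transformer/autoencoder embedding networks that motivate the provider
contract are external artifacts; this module ships

* :class:`BaselineNgramProvider` — a deterministic hashed token-n-gram
  embedding (n = 1..3, signed feature hashing, L2-normalised), usable
  anywhere a fingerprint is needed and fast enough for simulation; and
* :class:`TableProvider` — vectors loaded from a CSV of precomputed
  embeddings keyed by compound id, for plugging in external models.
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Protocol, Sequence, runtime_checkable

import numpy as np

from .chem import CuratedDataset, canonical_smiles

# special markers
BOS = "<s>"
EOS = "</s>"
PAD = "<pad>"
MASK = "<mask>"
UNK = "<unk>"

SPECIAL_TOKENS = (BOS, EOS, PAD, MASK, UNK)

# Two-character symbols recognised as single tokens (longest match first).
TWO_CHAR_SYMBOLS = ("Cl", "Br", "Si", "Se", "Na", "se")

_SINGLE_CHAR_SYMBOLS = (
    # organic-subset and common atoms
    "B", "C", "N", "O", "P", "S", "F", "I", "H",
    # aromatic atoms
    "b", "c", "n", "o", "p", "s",
    # ring-closure digits
    "0", "1", "2", "3", "4", "5", "6", "7", "8", "9",
    # bonds, branches, charges, stereo, separators
    "(", ")", "[", "]", "=", "#", "-", "+", "/", "\\", "@", ".", "%", ":", "*",
)

#: full 51-symbol vocabulary
VOCABULARY: tuple[str, ...] = SPECIAL_TOKENS + TWO_CHAR_SYMBOLS + _SINGLE_CHAR_SYMBOLS
assert len(VOCABULARY) == 51

_VOCAB_SET = frozenset(VOCABULARY)
_NON_SPECIAL = tuple(t for t in VOCABULARY if t not in SPECIAL_TOKENS)

DEFAULT_MAX_LEN = 256


class LengthError(ValueError):
    """SMILES longer than the fixed sequence length."""


class InvalidSmilesError(ValueError):
    """SMILES string rejected by canonicalization."""


@dataclass(frozen=True)
class TokenSequence:
    """Fixed-length token frame: begin, symbols, end, padding."""

    tokens: tuple[str, ...]
    valid_length: int

    def __post_init__(self) -> None:
        if self.tokens[0] != BOS or self.tokens[self.valid_length - 1] != EOS:
            raise ValueError("sequence must be framed by begin/end markers")
        if any(t != PAD for t in self.tokens[self.valid_length:]):
            raise ValueError("positions past valid_length must be padding")

    @property
    def max_len(self) -> int:
        return len(self.tokens)

    def symbols(self) -> tuple[str, ...]:
        """Payload tokens between the begin and end markers."""
        return self.tokens[1 : self.valid_length - 1]


@dataclass(frozen=True)
class MaskedSequence:
    """A token sequence after masked-language-model corruption."""

    tokens: tuple[str, ...]
    valid_length: int
    selected_positions: tuple[int, ...]
    actions: Mapping[int, str]  # position -> masked | kept | replaced


@dataclass(frozen=True)
class MaskingPolicy:
    select: float = 0.15
    mask: float = 0.8
    keep: float = 0.1
    replace: float = 0.1

    def __post_init__(self) -> None:
        if not np.isclose(self.mask + self.keep + self.replace, 1.0):
            raise ValueError("mask+keep+replace fractions must sum to 1")
        if not 0 <= self.select <= 1:
            raise ValueError("selection fraction must lie in [0, 1]")


def split_symbols(smiles: str) -> list[str]:
    """Split a SMILES string into vocabulary symbols.

    Bracket atoms ``[...]`` and the two-character element symbols are
    kept as single units; any unit absent from the vocabulary maps to
    the unknown token.
    """
    out: list[str] = []
    i = 0
    n = len(smiles)
    while i < n:
        ch = smiles[i]
        if ch == "[":
            j = smiles.find("]", i)
            if j == -1:  # unterminated bracket: fall back to char tokens
                out.append("[")
                i += 1
                continue
            out.append(smiles[i : j + 1])
            i = j + 1
        elif smiles[i : i + 2] in TWO_CHAR_SYMBOLS:
            out.append(smiles[i : i + 2])
            i += 2
        else:
            out.append(ch)
            i += 1
    return out


def tokenize_smiles(smiles: str, max_len: int = DEFAULT_MAX_LEN) -> TokenSequence:
    """Tokenize a SMILES string into a fixed-length framed sequence."""
    units = split_symbols(smiles)
    if len(units) > max_len - 2:
        raise LengthError(f"SMILES yields {len(units)} symbols, exceeding max_len-2 = {max_len - 2}")
    body = [u if u in _VOCAB_SET else UNK for u in units]
    tokens = [BOS, *body, EOS]
    valid_length = len(tokens)
    tokens.extend([PAD] * (max_len - valid_length))
    return TokenSequence(tokens=tuple(tokens), valid_length=valid_length)


def detokenize(seq: TokenSequence) -> str:
    """Rebuild the SMILES string; refuses sequences containing unknowns."""
    if UNK in seq.symbols():
        raise ValueError("cannot detokenize a sequence containing unknown tokens")
    return "".join(seq.symbols())


def mask_tokens(
    seq: TokenSequence,
    rng_seed: int,
    policy: MaskingPolicy = MaskingPolicy(),
) -> MaskedSequence:
    """Apply masked-language-model corruption to a token sequence.

    Exactly ``round(select * n_eligible)`` positions (round half up) are
    drawn without replacement from the valid non-special symbols; each
    is masked, kept or replaced with the policy's probabilities.
    Replacements are drawn uniformly from the non-special vocabulary.
    Deterministic given ``rng_seed``.
    """
    rng = np.random.default_rng(rng_seed)
    eligible = [
        i
        for i in range(1, seq.valid_length - 1)
        if seq.tokens[i] not in SPECIAL_TOKENS
    ]
    n_select = int(np.floor(policy.select * len(eligible) + 0.5))
    if n_select == 0:
        return MaskedSequence(seq.tokens, seq.valid_length, (), {})
    selected = sorted(rng.choice(len(eligible), size=n_select, replace=False).tolist())
    positions = tuple(eligible[i] for i in selected)

    tokens = list(seq.tokens)
    actions: dict[int, str] = {}
    for pos in positions:
        u = rng.random()
        if u < policy.mask:
            tokens[pos] = MASK
            actions[pos] = "masked"
        elif u < policy.mask + policy.keep:
            actions[pos] = "kept"
        else:
            tokens[pos] = str(rng.choice(_NON_SPECIAL))
            actions[pos] = "replaced"
    return MaskedSequence(tuple(tokens), seq.valid_length, positions, actions)


# ---------------------------------------------------------------------------
# fingerprint providers


@runtime_checkable
class FingerprintProvider(Protocol):
    provider_id: str
    dimension: int
    deterministic: bool

    def embed(self, smiles: str) -> np.ndarray: ...

    def embed_record(self, compound_id: str, smiles: str) -> np.ndarray: ...


@dataclass
class BaselineNgramProvider:
    """Deterministic hashed token-n-gram fingerprint.

    The SMILES string is canonicalised, tokenized, and its token
    n-grams (n = 1..3) are hashed into ``dimension`` signed buckets
    (feature hashing keyed by ``hash_seed``); the count vector is then
    L2-normalised.  Same canonical structure, same vector.
    """

    dimension: int = 512
    hash_seed: int = 0
    max_len: int = DEFAULT_MAX_LEN
    provider_id: str = field(init=False)
    deterministic: bool = field(init=False, default=True)

    def __post_init__(self) -> None:
        if self.dimension < 8:
            raise ValueError("dimension must be >= 8")
        self.provider_id = f"baseline-ngram-d{self.dimension}-h{self.hash_seed}"
        self._key = int(self.hash_seed).to_bytes(8, "little", signed=False)
        self._cache: dict[str, np.ndarray] = {}

    def _bucket(self, gram: str) -> tuple[int, float]:
        digest = hashlib.blake2b(gram.encode("utf8"), digest_size=8, key=self._key).digest()
        value = int.from_bytes(digest, "little")
        return (value >> 1) % self.dimension, 1.0 if value & 1 else -1.0

    def embed(self, smiles: str) -> np.ndarray:
        cached = self._cache.get(smiles)
        if cached is not None:
            return cached
        canon = canonical_smiles(smiles)
        if canon is None:
            raise InvalidSmilesError(f"cannot canonicalize {smiles!r}")
        symbols = tokenize_smiles(canon, self.max_len).symbols()
        vec = np.zeros(self.dimension)
        for n in (1, 2, 3):
            for i in range(len(symbols) - n + 1):
                idx, sign = self._bucket("\x00".join(symbols[i : i + n]))
                vec[idx] += sign
        norm = np.linalg.norm(vec)
        if norm > 0:
            vec /= norm
        vec.setflags(write=False)
        if len(self._cache) < 200_000:
            self._cache[smiles] = vec
        return vec

    def embed_record(self, compound_id: str, smiles: str) -> np.ndarray:
        return self.embed(smiles)


@dataclass
class TableProvider:
    """Fingerprints looked up from a table of precomputed vectors.

    Intended for externally generated embeddings (e.g. pretrained
    transformer or autoencoder models) exported as CSV with header
    ``compound_id,v1,...,vd``.
    """

    vectors: dict[str, np.ndarray]
    provider_id: str = "external"
    deterministic: bool = True

    def __post_init__(self) -> None:
        dims = {v.shape for v in self.vectors.values()}
        if len(dims) > 1:
            raise ValueError(f"inconsistent vector dimensions: {dims}")
        self.dimension = next(iter(dims))[0] if dims else 0

    @classmethod
    def from_csv(cls, path: str | Path, provider_id: str = "external") -> "TableProvider":
        vectors: dict[str, np.ndarray] = {}
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader)
            if not header or header[0] != "compound_id":
                raise ValueError("embedding CSV must start with a compound_id column")
            for row in reader:
                vectors[row[0]] = np.array([float(x) for x in row[1:]])
        return cls(vectors=vectors, provider_id=provider_id)

    def embed(self, smiles: str) -> np.ndarray:
        raise KeyError("TableProvider is keyed by compound_id; use embed_record")

    def embed_record(self, compound_id: str, smiles: str) -> np.ndarray:
        return self.vectors[compound_id]


@dataclass
class EmbeddingResult:
    """Feature matrix over the embeddable records of a dataset."""

    matrix: np.ndarray  # (n_kept, dimension)
    kept_indices: list[int]
    exclusions: list[tuple[str, str]]  # (compound_id, reason)


def embed_dataset(provider: FingerprintProvider, dataset: CuratedDataset) -> EmbeddingResult:
    """Embed every record of a curated dataset, reporting failures.

    Row order follows dataset record order over the kept records; any
    compound the provider cannot embed is listed in ``exclusions``
    rather than silently dropped.
    """
    rows: list[np.ndarray] = []
    kept: list[int] = []
    exclusions: list[tuple[str, str]] = []
    for i, (cid, smi, _) in enumerate(dataset.records()):
        try:
            vec = np.asarray(provider.embed_record(cid, smi), dtype=float)
        except Exception as exc:  # provider-specific failure, recorded per compound
            exclusions.append((cid, str(exc)))
            continue
        if not np.all(np.isfinite(vec)):
            exclusions.append((cid, "non-finite embedding"))
            continue
        rows.append(vec)
        kept.append(i)
    dim = getattr(provider, "dimension", rows[0].shape[0] if rows else 0)
    matrix = np.vstack(rows) if rows else np.empty((0, dim))
    return EmbeddingResult(matrix=matrix, kept_indices=kept, exclusions=exclusions)
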