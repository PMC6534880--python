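"""SMILES tokenization, vocabulary construction and sequence encoding.

A SMILES string is split into tokens covering whole lexical units: organic
subset atoms (aliphatic and aromatic), two-letter halogens, full bracketed
atom expressions ``[...]``, bond symbols, branch parentheses, ring-closure
digits and ``%NN`` two-digit ring closures.  Tokenization is lossless:
concatenating the token symbols reproduces the input exactly.

The vocabulary pins the control tokens ``GO`` (start) and ``EOS`` (end) at
indices 0 and 1 and sorts the remaining symbols lexicographically, so
repeated builds over permuted corpora are identical.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

GO = "GO"
EOS = "EOS"

DEFAULT_MAX_STEPS = 100

# Longest-match-first lexical grammar.  Anything not matched by one of these
# alternatives cannot start a legal SMILES token and is rejected.
_TOKEN_RE = re.compile(
    r"""(\[[^\]]+\]     # bracketed atom expression, one token
        |Cl|Br          # two-letter halogens
        |%\d{2}         # two-digit ring closure
        |[BCNOPSFI]     # organic-subset aliphatic atoms
        |[bcnops]       # aromatic organic-subset atoms
        |[0-9]          # ring-closure digits
        |[()]           # branch controls
        |[-=\#/\\:.~+*$]  # bonds / disconnection / wildcard
        )""",
    re.VERBOSE,
)

_ATOM_RE = re.compile(r"\[[^\]]+\]|Cl|Br|[BCNOPSFI]|[bcnops]|\*")
_BOND_SYMBOLS = frozenset("-=#/\\:.~$")


@dataclass(frozen=True)
class Token:
    """A single SMILES lexical unit with a coarse category."""

    symbol: str
    category: str  # atom | bond | branch-or-ring-control | special

    def __post_init__(self) -> None:
        if not self.symbol or any(c.isspace() for c in self.symbol):
            raise ValueError(f"bad token symbol: {self.symbol!r}")
        if self.category == "special" and self.symbol not in (GO, EOS):
            raise ValueError(f"special tokens are only {GO!r}/{EOS!r}, got {self.symbol!r}")


def _categorize(symbol: str) -> str:
    if symbol in (GO, EOS):
        return "special"
    if _ATOM_RE.fullmatch(symbol):
        return "atom"
    if symbol in _BOND_SYMBOLS:
        return "bond"
    return "branch-or-ring-control"


def tokenize(smiles: str) -> list[Token]:
    """Split ``smiles`` into tokens; lossless by construction.

    Raises ``ValueError`` at the first character that cannot start any legal
    SMILES token (including an unterminated ``[`` expression).
    """
    if not smiles:
        raise ValueError("cannot tokenize an empty string")
    tokens: list[Token] = []
    pos = 0
    while pos < len(smiles):
        m = _TOKEN_RE.match(smiles, pos)
        if m is None:
            raise ValueError(
                f"illegal SMILES character {smiles[pos]!r} at position {pos} in {smiles!r}"
            )
        sym = m.group(0)
        tokens.append(Token(sym, _categorize(sym)))
        pos = m.end()
    return tokens


def tokenize_symbols(smiles: str) -> list[str]:
    """Token symbols only (convenience wrapper around :func:`tokenize`)."""
    return [t.symbol for t in tokenize(smiles)]


@dataclass(frozen=True)
class Vocabulary:
    """Ordered token alphabet with GO/EOS pinned at positions 0 and 1."""

    tokens: tuple[Token, ...]
    index: dict[str, int] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        symbols = [t.symbol for t in self.tokens]
        if len(set(symbols)) != len(symbols):
            raise ValueError("duplicate symbols in vocabulary")
        if GO not in symbols or EOS not in symbols:
            raise ValueError("vocabulary must contain GO and EOS")
        object.__setattr__(self, "index", {s: i for i, s in enumerate(symbols)})

    @property
    def size(self) -> int:
        return len(self.tokens)

    @property
    def go(self) -> int:
        return self.index[GO]

    @property
    def eos(self) -> int:
        return self.index[EOS]

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.index

    def __len__(self) -> int:
        return self.size

    def symbol(self, i: int) -> str:
        return self.tokens[i].symbol

    def to_lines(self) -> str:
        return "\n".join(t.symbol for t in self.tokens) + "\n"

    @classmethod
    def from_symbols(cls, symbols: Iterable[str]) -> "Vocabulary":
        return cls(tuple(Token(s, _categorize(s)) for s in symbols))

    @classmethod
    def from_lines(cls, text: str) -> "Vocabulary":
        return cls.from_symbols([ln for ln in text.splitlines() if ln.strip()])


@dataclass(frozen=True)
class TokenSequence:
    """Encoded token indices y_1:T, EOS-terminated or truncated at max_steps."""

    indices: tuple[int, ...]

    @property
    def length(self) -> int:
        return len(self.indices)


def build_vocabulary(corpus: Sequence[str]) -> Vocabulary:
    """Collect all tokens in ``corpus`` plus GO/EOS into a sorted vocabulary.

    Deterministic: GO, EOS first, then observed symbols in lexicographic
    order, so the result is independent of corpus ordering.
    """
    if not corpus:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    observed: set[str] = set()
    for smiles in corpus:
        observed.update(tokenize_symbols(smiles))
    return Vocabulary.from_symbols([GO, EOS] + sorted(observed))


def encode(smiles: str, vocab: Vocabulary, max_steps: int | None = None) -> TokenSequence:
    """Encode ``smiles`` as vocabulary indices terminated by EOS.

    Raises ``KeyError`` naming the first out-of-vocabulary token.
    """
    indices: list[int] = []
    for sym in tokenize_symbols(smiles):
        if sym not in vocab:
            raise KeyError(f"token {sym!r} not in vocabulary")
        indices.append(vocab.index[sym])
    indices.append(vocab.eos)
    if max_steps is not None and len(indices) > max_steps:
        indices = indices[:max_steps]
    return TokenSequence(tuple(indices))


def decode(seq: TokenSequence | Sequence[int], vocab: Vocabulary) -> str:
    """Decode indices to a SMILES string, dropping GO and stopping at EOS."""
    indices = seq.indices if isinstance(seq, TokenSequence) else seq
    out: list[str] = []
    for i in indices:
        if i == vocab.eos:
            break
        if i == vocab.go:
            continue
        out.append(vocab.symbol(int(i)))
    return "".join(out)


def is_valid_smiles(s: str) -> bool:
    """True iff RDKit parses ``s`` into a molecule (the validity criterion)."""
    if not isinstance(s, str) or not s:
        return False
    try:
        return Chem.MolFromSmiles(s) is not None
    except Exception:
        return False


def canonical_smiles(s: str) -> str | None:
    """Canonical form of ``s``, or None if unparseable."""
    mol = Chem.MolFromSmiles(s) if s else None
    return Chem.MolToSmiles(mol) if mol is not None else None
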