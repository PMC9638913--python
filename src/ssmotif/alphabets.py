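"""Annotation alphabets for RNA sequence and secondary-structure context.

Every probe is annotated under seven alphabets: the 4-letter nucleotide
alphabet, three purely structural alphabets of increasing granularity
(2, 4 and 7 letters), and the three sequence x structure product alphabets
(8, 16 and 28 letters). Product symbols are single characters assigned
deterministically in nucleotide-major order so annotation strings stay one
character per base.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

NUCLEOTIDES = "ACGU"

#: 7-letter structural contexts: E external/unpaired, B bulge loop, L left
#: paired base, R right paired base, T internal loop, M multiloop, H hairpin loop.
STRUCTURE7 = "EBLRTMH"

#: 4-letter contexts: P paired, L hairpin loop, U unpaired/external,
#: M multiloop/internal loop/bulge.
STRUCTURE4 = "PLUM"

#: 2-letter contexts: P paired, U unpaired.
STRUCTURE2 = "PU"

#: Letterwise projection from the 7-letter contexts to the coarser alphabets.
PROJECT_7_TO_4 = {"L": "P", "R": "P", "H": "L", "E": "U", "B": "M", "T": "M", "M": "M"}
PROJECT_7_TO_2 = {"L": "P", "R": "P", "H": "U", "E": "U", "B": "U", "T": "U", "M": "U"}

#: Structure letters denoting a paired base, per structural granularity.
PAIRED_LETTERS = {"structure2": {"P"}, "structure4": {"P"}, "structure7": {"L", "R"}}

SEQUENCE_KIND = "sequence"
STRUCTURE_KINDS = ("structure2", "structure4", "structure7")
PRODUCT_KINDS = ("seqstruct8", "seqstruct16", "seqstruct28")

#: Deterministic feature/column ordering used throughout the pipeline.
ALPHABET_ORDER = (
    "sequence",
    "structure2",
    "structure4",
    "structure7",
    "seqstruct8",
    "seqstruct16",
    "seqstruct28",
)

_STRUCT_BASE = {"seqstruct8": "structure2", "seqstruct16": "structure4", "seqstruct28": "structure7"}

_SYMBOL_POOL = string.ascii_uppercase + string.ascii_lowercase + string.digits


class AlphabetError(ValueError):
    """Unknown alphabet kind or symbol."""


@dataclass(frozen=True)
class Alphabet:
    """A named, ordered symbol set with optional product decomposition.

    For product (sequence x structure) alphabets ``components`` maps each
    single-character symbol back to its ``(nucleotide, structure letter)``
    pair; for plain alphabets it is empty.
    """

    name: str
    kind: str
    symbols: str
    components: dict = field(default_factory=dict, repr=False)

    def __len__(self) -> int:
        return len(self.symbols)

    @property
    def size(self) -> int:
        return len(self.symbols)

    def index(self, symbol: str) -> int:
        i = self.symbols.find(symbol)
        if i < 0:
            raise AlphabetError(f"symbol {symbol!r} not in alphabet {self.name}")
        return i

    def decompose(self, symbol: str) -> tuple[str, str]:
        """Split a product symbol into (nucleotide, structure letter)."""
        if not self.components:
            raise AlphabetError(f"alphabet {self.name} is not a product alphabet")
        try:
            return self.components[symbol]
        except KeyError:
            raise AlphabetError(f"symbol {symbol!r} not in alphabet {self.name}") from None

    def compose(self, nucleotide: str, struct_letter: str) -> str:
        if not self.components:
            raise AlphabetError(f"alphabet {self.name} is not a product alphabet")
        key = (nucleotide, struct_letter)
        sym = self._compose_map.get(key)
        if sym is None:
            raise AlphabetError(f"no symbol for {key} in alphabet {self.name}")
        return sym

    @property
    def _compose_map(self) -> dict:
        return {pair: sym for sym, pair in self.components.items()}

    @property
    def structure_base(self) -> str | None:
        """Structural granularity underlying this alphabet, if any."""
        if self.kind in STRUCTURE_KINDS:
            return self.kind
        return _STRUCT_BASE.get(self.kind)

    def paired_mask(self) -> list[bool]:
        """Per-symbol flag: does the symbol denote a paired base?

        Sequence-only symbols are never paired; structure and product symbols
        are paired when their structural letter is P (2/4-letter) or L/R
        (7-letter).
        """
        base = self.structure_base
        if base is None:
            return [False] * self.size
        paired = PAIRED_LETTERS[base]
        mask = []
        for sym in self.symbols:
            letter = self.components[sym][1] if self.components else sym
            mask.append(letter in paired)
        return mask


def _make_product(kind: str, struct_letters: str) -> Alphabet:
    symbols = _SYMBOL_POOL[: 4 * len(struct_letters)]
    components = {}
    i = 0
    for nt in NUCLEOTIDES:
        for sl in struct_letters:
            components[symbols[i]] = (nt, sl)
            i += 1
    return Alphabet(name=kind, kind=kind, symbols=symbols, components=components)


ALPHABETS: dict[str, Alphabet] = {
    "sequence": Alphabet("sequence", "sequence", NUCLEOTIDES),
    "structure2": Alphabet("structure2", "structure2", STRUCTURE2),
    "structure4": Alphabet("structure4", "structure4", STRUCTURE4),
    "structure7": Alphabet("structure7", "structure7", STRUCTURE7),
    "seqstruct8": _make_product("seqstruct8", STRUCTURE2),
    "seqstruct16": _make_product("seqstruct16", STRUCTURE4),
    "seqstruct28": _make_product("seqstruct28", STRUCTURE7),
}


def get_alphabet(kind: str) -> Alphabet:
    try:
        return ALPHABETS[kind]
    except KeyError:
        raise AlphabetError(
            f"unknown alphabet kind {kind!r}; expected one of {ALPHABET_ORDER}"
        ) from None


def write_meme_alphabet(alphabet: Alphabet, path) -> None:
    """Write a MEME-suite custom alphabet definition file.

    Needed when the external STREME backend is used for motif discovery on
    structure or product annotations.
    """
    lines = [f"ALPHABET \"{alphabet.name}\"", ""]
    for sym in alphabet.symbols:
        if alphabet.components:
            nt, sl = alphabet.components[sym]
            lines.append(f"{sym} \"{nt}:{sl}\"")
        else:
            lines.append(f"{sym} \"{sym}\"")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
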