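"""Dot-bracket parsing and per-base structural context annotation.

RNA probes are folded externally (centroid structure from ``RNAfold -p``);
here the resulting dot-bracket string is decomposed into loops and each base
is classified into one of seven structural contexts:

* ``L`` / ``R`` — left / right strand of a helix (paired bases),
* ``H`` — hairpin loop (loop with no enclosed helix),
* ``B`` — bulge loop (internal loop with unpaired bases on only one side),
* ``T`` — internal loop (unpaired bases on both sides of the enclosed helix),
* ``M`` — multiloop (two or more enclosed helices),
* ``E`` — external / not enclosed by any pair.

The 7-letter annotation projects onto 4- and 2-letter structural alphabets
and combines with the nucleotide sequence into 28/16/8-letter product
annotations, giving seven annotations per probe.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .alphabets import (
    ALPHABET_ORDER,
    PROJECT_7_TO_2,
    PROJECT_7_TO_4,
    STRUCTURE7,
    get_alphabet,
)


class StructureError(ValueError):
    """Malformed or unsupported dot-bracket input."""


_PSEUDOKNOT_CHARS = set("[]{}<>")


def parse_dotbracket(db: str) -> list[int | None]:
    """Return the pair table: ``partner[i]`` is the index paired with ``i``.

    Only the plain ``( ) .`` dialect is accepted; pseudoknot bracket layers
    are rejected because centroid structures never contain them.
    """
    partner: list[int | None] = [None] * len(db)
    stack: list[int] = []
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise StructureError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            partner[i], partner[j] = j, i
        elif c != ".":
            if c in _PSEUDOKNOT_CHARS:
                raise StructureError(
                    f"pseudoknot bracket {c!r} at position {i} is not supported"
                )
            raise StructureError(f"illegal dot-bracket character {c!r} at position {i}")
    if stack:
        raise StructureError(f"unbalanced '(' at position {stack[-1]}")
    return partner


def classify_contexts(db: str) -> str:
    """Label every base of ``db`` with its 7-letter structural context."""
    partner = parse_dotbracket(db)
    n = len(db)
    labels = [""] * n
    for i, p in enumerate(partner):
        if p is not None:
            labels[i] = "L" if i < p else "R"

    # Walk each loop: the region directly enclosed by pair (i, j) -- or the
    # exterior -- minus the interiors of its child pairs.
    def label_loop(lo: int, hi: int, closing: tuple[int, int] | None) -> None:
        children: list[tuple[int, int]] = []
        unpaired: list[int] = []
        k = lo
        while k < hi:
            p = partner[k]
            if p is None:
                unpaired.append(k)
                k += 1
            else:
                children.append((k, p))
                k = p + 1
        for a, b in children:
            label_loop(a + 1, b, (a, b))
        if closing is None:
            for k in unpaired:
                labels[k] = "E"
            return
        if not unpaired:
            return
        if not children:
            letter = "H"
        elif len(children) >= 2:
            letter = "M"
        else:
            a, b = children[0]
            left = any(k < a for k in unpaired)
            right = any(k > b for k in unpaired)
            letter = "T" if left and right else "B"
        for k in unpaired:
            labels[k] = letter

    label_loop(0, n, None)
    return "".join(labels)


def project_structure(s7: str, granularity: str) -> str:
    """Project a 7-letter context string to the 4- or 2-letter alphabet."""
    if granularity == "structure4":
        table = PROJECT_7_TO_4
    elif granularity == "structure2":
        table = PROJECT_7_TO_2
    else:
        raise StructureError(f"unknown projection target {granularity!r}")
    out = []
    for c in s7:
        if c not in STRUCTURE7:
            raise StructureError(f"unknown structural context letter {c!r}")
        out.append(table[c])
    return "".join(out)


def combine_annotation(seq: str, struct: str, kind: str) -> str:
    """Combine nucleotides with structure letters into a product annotation."""
    if len(seq) != len(struct):
        raise StructureError(
            f"sequence length {len(seq)} != structure length {len(struct)}"
        )
    alphabet = get_alphabet(kind)
    compose = alphabet._compose_map
    try:
        return "".join(compose[(a, b)] for a, b in zip(seq, struct))
    except KeyError as exc:
        raise StructureError(f"no product symbol for pair {exc.args[0]}") from None


def normalize_rna(seq: str) -> str:
    """Uppercase and convert T to U."""
    return seq.upper().replace("T", "U")


@dataclass
class AnnotatedProbe:
    """A probe with its structure and all seven alphabet annotations.

    Annotations are trimmed to the variable region (0-based, half-open);
    the full flanked sequence is what gets folded, but only the variable
    region enters downstream analysis.
    """

    sequence: str
    dotbracket: str
    variable_region: tuple[int, int]
    annotations: dict[str, str] = field(default_factory=dict)
    name: str = ""

    def annotation(self, kind: str) -> str:
        return self.annotations[kind]


def annotate_probe(
    seq: str,
    db: str,
    variable_region: tuple[int, int] | None = None,
    name: str = "",
) -> AnnotatedProbe:
    """Produce all seven annotations of a probe, trimmed to its variable region."""
    seq = normalize_rna(seq)
    if len(seq) != len(db):
        raise StructureError(
            f"sequence length {len(seq)} != dot-bracket length {len(db)}"
        )
    if variable_region is None:
        variable_region = (0, len(seq))
    lo, hi = variable_region
    if not (0 <= lo <= hi <= len(seq)):
        raise StructureError(
            f"variable region {variable_region} out of bounds for length {len(seq)}"
        )
    s7 = classify_contexts(db)
    s4 = project_structure(s7, "structure4")
    s2 = project_structure(s7, "structure2")
    full = {
        "sequence": seq,
        "structure2": s2,
        "structure4": s4,
        "structure7": s7,
        "seqstruct8": combine_annotation(seq, s2, "seqstruct8"),
        "seqstruct16": combine_annotation(seq, s4, "seqstruct16"),
        "seqstruct28": combine_annotation(seq, s7, "seqstruct28"),
    }
    annotations = {kind: full[kind][lo:hi] for kind in ALPHABET_ORDER}
    return AnnotatedProbe(
        sequence=seq,
        dotbracket=db,
        variable_region=(lo, hi),
        annotations=annotations,
        name=name,
    )


def annotate_probes(
    records: list[tuple[str, str, str]],
    variable_region: tuple[int, int] | None = None,
) -> list[AnnotatedProbe]:
    """Annotate ``(name, sequence, dotbracket)`` records with a shared region."""
    return [
        annotate_probe(seq, db, variable_region=variable_region, name=name)
        for name, seq, db in records
    ]
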