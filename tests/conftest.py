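"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from ssmotif.alphabets import get_alphabet
from ssmotif.discover import PFM


def make_pfm(alphabet_kind: str, rows, name="pfm", pvalue=1e-4, seed_str=""):
    """Build a PFM from unnormalized rows (one per position)."""
    m = np.asarray(rows, dtype=float)
    m = m / m.sum(axis=1, keepdims=True)
    return PFM(
        alphabet=alphabet_kind,
        matrix=m,
        pvalue=pvalue,
        corrected_pvalue=pvalue,
        name=name,
        seed=seed_str,
    )


def consensus_pfm(alphabet_kind: str, consensus: str, strength=0.997, name=None):
    """Near-one-hot PFM: consensus letter gets ``strength``, rest split evenly."""
    alphabet = get_alphabet(alphabet_kind)
    rows = []
    for c in consensus:
        row = np.full(alphabet.size, (1 - strength) / (alphabet.size - 1))
        row[alphabet.index(c)] = strength
        rows.append(row)
    return make_pfm(alphabet_kind, rows, name=name or f"{alphabet_kind}-{consensus}",
                    seed_str=consensus)


def random_pfm(rng, alphabet_kind: str, width: int, name="rpfm"):
    alphabet = get_alphabet(alphabet_kind)
    return make_pfm(
        alphabet_kind, rng.dirichlet(np.ones(alphabet.size), size=width), name=name
    )


# ---------------------------------------------------------------------------
# dot-bracket helpers


def enumerate_balanced(max_len: int):
    """Yield every balanced dot-bracket string of length <= max_len."""

    def rec(prefix, open_count, remaining):
        if remaining == 0:
            if open_count == 0:
                yield prefix
            return
        yield from rec(prefix + ".", open_count, remaining - 1)
        yield from rec(prefix + "(", open_count + 1, remaining - 1)
        if open_count > 0:
            yield from rec(prefix + ")", open_count - 1, remaining - 1)

    for n in range(max_len + 1):
        yield from rec("", 0, n)


def random_balanced(rng, length: int) -> str:
    """A random balanced dot-bracket string of the given length."""
    out = []
    open_count = 0
    for i in range(length):
        remaining = length - i
        choices = ["."]
        if remaining > open_count + 1:
            choices.append("(")
        if open_count > 0:
            choices.append(")")
        c = choices[rng.integers(len(choices))]
        out.append(c)
        if c == "(":
            open_count += 1
        elif c == ")":
            open_count -= 1
    # close any dangling opens by rewriting trailing dots
    s = out
    for i in range(length - 1, -1, -1):
        if open_count == 0:
            break
        if s[i] == ".":
            s[i] = ")"
            open_count -= 1
        elif s[i] == "(":
            s[i] = "."
            open_count -= 1
    return "".join(s)


def oracle_contexts(db: str) -> str:
    """Brute-force 7-context classifier working directly off the pair list.

    For every unpaired base it finds the innermost enclosing pair by direct
    search, then rebuilds that loop's direct children and unpaired members
    by quadratic scanning. Independent of the package's recursive
    loop-decomposition implementation.
    """
    partner = {}
    stack = []
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            j = stack.pop()
            partner[i] = j
            partner[j] = i
    pairs = [(a, partner[a]) for a in partner if a < partner[a]]
    labels = []
    for i, c in enumerate(db):
        if c == "(":
            labels.append("L")
            continue
        if c == ")":
            labels.append("R")
            continue
        enclosing = None
        for a, b in pairs:
            if a < i < b and (enclosing is None or a > enclosing[0]):
                enclosing = (a, b)
        if enclosing is None:
            labels.append("E")
            continue
        a, b = enclosing
        children = []
        for c1, c2 in pairs:
            if a < c1 and c2 < b:
                direct = not any(
                    a < d1 < c1 and c2 < d2 < b for d1, d2 in pairs if (d1, d2) != (c1, c2)
                )
                if direct:
                    children.append((c1, c2))
        unpaired = [
            k
            for k in range(a + 1, b)
            if k not in partner and not any(c1 <= k <= c2 for c1, c2 in children)
        ]
        if not children:
            labels.append("H")
        elif len(children) >= 2:
            labels.append("M")
        else:
            c1, c2 = children[0]
            left = any(k < c1 for k in unpaired)
            right = any(k > c2 for k in unpaired)
            labels.append("T" if left and right else "B")
    return "".join(labels)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
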