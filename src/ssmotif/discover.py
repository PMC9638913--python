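"""Enriched-motif (PFM) discovery on probe annotations.

For each alphabet the positive annotation set is compared against the
negative set and up to 40 position frequency matrices of width 4-6 with
Bonferroni-corrected enrichment p-value < 0.01 are returned.

Two backends share one output contract:

* the built-in discoverer (default): every k-mer (k = 4..6) observed in the
  data is tested for per-probe occurrence enrichment in positives over
  negatives with a one-sided Fisher exact (hypergeometric) test; p-values
  are Bonferroni-corrected over the number of distinct k-mers tested,
  significant seeds are selected greedily with a Hamming-distance redundancy
  filter, and each PFM is built from the positional letter frequencies of
  the seed's exact matches in the positive set (pseudocount 0.1);
* an external STREME run (`-pvt 0.01 -minw 4 -maxw 6` with a custom alphabet
  file), opt-in, for users with the MEME suite installed.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import hypergeom

from .alphabets import Alphabet, get_alphabet, write_meme_alphabet

MIN_WIDTH = 4
MAX_WIDTH = 6
PVALUE_THRESHOLD = 0.01
MAX_PFMS = 40
PSEUDOCOUNT = 0.1


class DiscoveryError(ValueError):
    """Invalid input to motif discovery."""


@dataclass
class PFM:
    """Position frequency matrix over one annotation alphabet.

    ``matrix`` has one row per motif position and one column per alphabet
    symbol; every row sums to 1.
    """

    alphabet: str
    matrix: np.ndarray
    pvalue: float
    corrected_pvalue: float
    name: str = ""
    seed: str = ""

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise DiscoveryError("PFM matrix must be 2-dimensional")
        if np.any(self.matrix < 0):
            raise DiscoveryError("PFM entries must be non-negative")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise DiscoveryError("PFM position distributions must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        symbols = get_alphabet(self.alphabet).symbols
        return "".join(symbols[i] for i in self.matrix.argmax(axis=1))

    def to_dict(self) -> dict:
        return {
            "alphabet": self.alphabet,
            "matrix": self.matrix.tolist(),
            "pvalue": self.pvalue,
            "corrected_pvalue": self.corrected_pvalue,
            "name": self.name,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PFM":
        return cls(
            alphabet=d["alphabet"],
            matrix=np.asarray(d["matrix"]),
            pvalue=d["pvalue"],
            corrected_pvalue=d["corrected_pvalue"],
            name=d.get("name", ""),
            seed=d.get("seed", ""),
        )


@dataclass
class DiscoveryConfig:
    min_width: int = MIN_WIDTH
    max_width: int = MAX_WIDTH
    pvalue_threshold: float = PVALUE_THRESHOLD
    max_pfms: int = MAX_PFMS
    pseudocount: float = PSEUDOCOUNT
    backend: str = "builtin"  # or "streme"
    streme_binary: str = "streme"
    redundancy_hamming: int = 1


def presence_counts(
    annotations: list[str], min_width: int, max_width: int
) -> Counter:
    """Count, for each k-mer, the number of probes containing it at least once."""
    counts: Counter = Counter()
    for ann in annotations:
        n = len(ann)
        seen = set()
        for k in range(min_width, max_width + 1):
            for i in range(n - k + 1):
                seen.add(ann[i : i + k])
        counts.update(seen)
    return counts


def enrichment_pvalues(
    pos_counts: Counter, neg_counts: Counter, n_pos: int, n_neg: int
) -> dict[str, float]:
    """One-sided per-probe enrichment p-value for every k-mer observed.

    Equivalent to a one-sided Fisher exact test on the 2x2 presence table:
    P(X >= a) for X ~ Hypergeom(N = n_pos + n_neg, K = a + b, n = n_pos),
    where a and b are the positive / negative presence counts.
    """
    kmers = sorted(set(pos_counts) | set(neg_counts))
    a = np.array([pos_counts.get(k, 0) for k in kmers])
    b = np.array([neg_counts.get(k, 0) for k in kmers])
    pvals = hypergeom.sf(a - 1, n_pos + n_neg, a + b, n_pos)
    return dict(zip(kmers, pvals.tolist()))


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def build_pfm(
    seed: str,
    positives: list[str],
    alphabet: Alphabet,
    pseudocount: float = PSEUDOCOUNT,
) -> np.ndarray:
    """Positional letter frequencies of the seed's exact matches in positives."""
    w = len(seed)
    counts = np.full((w, alphabet.size), pseudocount, dtype=float)
    index = {c: i for i, c in enumerate(alphabet.symbols)}
    for ann in positives:
        start = ann.find(seed)
        while start != -1:
            for j in range(w):
                counts[j, index[ann[start + j]]] += 1.0
            start = ann.find(seed, start + 1)
    return counts / counts.sum(axis=1, keepdims=True)


def bonferroni_cap(
    pfms: list[PFM],
    n_tests: int,
    threshold: float = PVALUE_THRESHOLD,
    max_pfms: int = MAX_PFMS,
) -> list[PFM]:
    """Bonferroni-correct discovery p-values, filter, sort, and cap at 40."""
    if n_tests < 1:
        raise DiscoveryError(f"n_tests must be >= 1, got {n_tests}")
    for pfm in pfms:
        pfm.corrected_pvalue = min(1.0, pfm.pvalue * n_tests)
    kept = [p for p in pfms if p.corrected_pvalue < threshold]
    kept.sort(key=lambda p: (p.corrected_pvalue, p.seed))
    return kept[:max_pfms]


def discover_motifs(
    pos: list[str],
    neg: list[str],
    alphabet: str | Alphabet,
    config: DiscoveryConfig | None = None,
) -> list[PFM]:
    """Find up to 40 enriched PFMs in positive over negative annotations."""
    config = config or DiscoveryConfig()
    if isinstance(alphabet, str):
        alphabet = get_alphabet(alphabet)
    if not pos or not neg:
        raise DiscoveryError("positive and negative sets must be non-empty")
    if config.backend == "streme":
        return _discover_streme(pos, neg, alphabet, config)
    if config.backend != "builtin":
        raise DiscoveryError(f"unknown discovery backend {config.backend!r}")
    return _discover_builtin(pos, neg, alphabet, config)


def _discover_builtin(
    pos: list[str], neg: list[str], alphabet: Alphabet, config: DiscoveryConfig
) -> list[PFM]:
    pos_counts = presence_counts(pos, config.min_width, config.max_width)
    neg_counts = presence_counts(neg, config.min_width, config.max_width)
    pvals = enrichment_pvalues(pos_counts, neg_counts, len(pos), len(neg))
    n_tests = len(pvals)
    if n_tests == 0:
        return []
    # Greedy non-redundant selection of significant seeds, most significant
    # first; a seed within Hamming distance <= 1 of an already-selected seed
    # of the same width is skipped (mimics motif erasure).
    threshold = config.pvalue_threshold / n_tests
    candidates = sorted(
        (p, kmer) for kmer, p in pvals.items() if p < threshold
    )
    selected: list[str] = []
    for _, kmer in candidates:
        if any(
            len(s) == len(kmer) and _hamming(s, kmer) <= config.redundancy_hamming
            for s in selected
        ):
            continue
        selected.append(kmer)
    pfms = []
    for rank, seed in enumerate(selected):
        matrix = build_pfm(seed, pos, alphabet, config.pseudocount)
        pfms.append(
            PFM(
                alphabet=alphabet.kind,
                matrix=matrix,
                pvalue=pvals[seed],
                corrected_pvalue=min(1.0, pvals[seed] * n_tests),
                name=f"{alphabet.kind}-{rank:02d}-{seed}",
                seed=seed,
            )
        )
    return bonferroni_cap(
        pfms, n_tests, threshold=config.pvalue_threshold, max_pfms=config.max_pfms
    )


def _discover_streme(
    pos: list[str], neg: list[str], alphabet: Alphabet, config: DiscoveryConfig
) -> list[PFM]:
    from .io import ConfigurationError, read_meme_motifs, write_fasta

    exe = shutil.which(config.streme_binary)
    if exe is None:
        raise ConfigurationError(
            f"STREME binary {config.streme_binary!r} not found; "
            "use the builtin backend instead"
        )
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        write_fasta([(f"p{i}", s) for i, s in enumerate(pos)], tmp / "pos.fa")
        write_fasta([(f"n{i}", s) for i, s in enumerate(neg)], tmp / "neg.fa")
        write_meme_alphabet(alphabet, tmp / "alphabet.txt")
        subprocess.run(
            [
                exe,
                "--p", str(tmp / "pos.fa"),
                "--n", str(tmp / "neg.fa"),
                "--alph", str(tmp / "alphabet.txt"),
                "--pvt", str(config.pvalue_threshold),
                "--minw", str(config.min_width),
                "--maxw", str(config.max_width),
                "--oc", str(tmp / "out"),
                "--text",
            ],
            check=True,
            capture_output=True,
        )
        pfms = read_meme_motifs(tmp / "out" / "streme.txt", alphabet.kind)
    # STREME reports the number of motifs it evaluated; its output p-values
    # are already selection-adjusted, so the family size here is the number
    # of reported motifs.
    return bonferroni_cap(
        pfms,
        max(1, len(pfms)),
        threshold=config.pvalue_threshold,
        max_pfms=config.max_pfms,
    )
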