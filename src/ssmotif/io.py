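"""File formats: FASTA, Vienna structure files, MEME minimal motifs, folding hook.

Structure files follow the RNAfold text convention: an optional ``>name``
header, the sequence line, and the dot-bracket line with an optional
trailing energy annotation (`` (-12.30)`` or `` { -1.20 d=2.10}``) which is
stripped on read.
"""

from __future__ import annotations

import re
import shutil
import subprocess
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .alphabets import Alphabet, get_alphabet
from .annotate import StructureError, normalize_rna


class ConfigurationError(RuntimeError):
    """An external tool or option is required but unavailable."""


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``(name, RNA sequence)`` pairs (T normalized to U)."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.id, normalize_rna(str(rec.seq))))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


_ENERGY_SUFFIX = re.compile(r"\s*[({\[][^(){}\[\]]*[)}\]]\s*$")
_DB_CHARS = set("().")


def _strip_energy(line: str) -> str:
    """Remove a trailing free-energy annotation from a dot-bracket line."""
    stripped = line.strip()
    m = re.match(r"^([().]+)", stripped)
    if m and m.end() < len(stripped):
        rest = stripped[m.end():].strip()
        # tolerate " (-3.40)" / " { -1.2 d=2.1}" style suffixes only
        if rest and (rest[0] in "({[" or rest[0].isdigit() or rest[0] == "-"):
            return m.group(1)
    return stripped


def read_vienna(path) -> list[tuple[str, str, str]]:
    """Read a Vienna-style structure file into ``(name, seq, dotbracket)``.

    Accepts alternating sequence / dot-bracket lines, with optional ``>name``
    headers and tolerated energy suffixes.
    """
    records: list[tuple[str, str, str]] = []
    name = None
    seq = None
    counter = 0
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0] if len(line) > 1 else ""
                seq = None
                continue
            if seq is None:
                seq = normalize_rna(line)
            else:
                db = _strip_energy(line)
                if set(db) - _DB_CHARS:
                    raise StructureError(f"bad dot-bracket line in {path}: {line!r}")
                if len(db) != len(seq):
                    raise StructureError(
                        f"structure length {len(db)} != sequence length {len(seq)} in {path}"
                    )
                records.append((name if name is not None else f"probe_{counter}", seq, db))
                counter += 1
                name = None
                seq = None
    if seq is not None:
        raise StructureError(f"dangling sequence line without structure in {path}")
    if not records:
        raise ValueError(f"no structure records in {path}")
    return records


def write_vienna(records: list[tuple[str, str, str]], path) -> None:
    with open(path, "w") as fh:
        for name, seq, db in records:
            fh.write(f">{name}\n{seq}\n{db}\n")


def fold_sequences(
    seqs: list[str], temperature: float = 37.0, rnafold: str = "RNAfold"
) -> list[str]:
    """Fold sequences with ``RNAfold -p`` and return centroid dot-brackets.

    Optional hook: annotation itself always takes dot-brackets as input, so
    the rest of the package runs without the folder installed.
    """
    exe = shutil.which(rnafold)
    if exe is None:
        raise ConfigurationError(
            f"{rnafold!r} not found on PATH; provide structures explicitly"
        )
    inp = "\n".join(seqs) + "\n"
    proc = subprocess.run(
        [exe, "-p", "--noPS", "--noDP", "-T", str(temperature)],
        input=inp,
        capture_output=True,
        text=True,
        check=True,
    )
    centroids = []
    lines = [ln for ln in proc.stdout.splitlines() if ln.strip()]
    # Per sequence RNAfold -p emits: sequence, MFE, ensemble, centroid,
    # frequency/diversity. The centroid line carries a "{ ... d=... }" suffix.
    i = 0
    while i < len(lines):
        if lines[i].startswith(">"):
            i += 1
            continue
        block = lines[i : i + 5]
        if len(block) < 5:
            break
        centroid = _strip_energy(block[3])
        if set(centroid) - _DB_CHARS:
            raise StructureError(f"unexpected RNAfold output line: {block[3]!r}")
        centroids.append(centroid)
        i += 5
    if len(centroids) != len(seqs):
        raise StructureError(
            f"RNAfold returned {len(centroids)} centroid structures for {len(seqs)} sequences"
        )
    return centroids


def write_meme_motifs(pfms, path, alphabet: Alphabet | None = None) -> None:
    """Write PFMs in MEME minimal motif format with a custom alphabet header."""
    if not pfms:
        raise ValueError("no PFMs to write")
    alphabet = alphabet or get_alphabet(pfms[0].alphabet)
    lines = ["MEME version 4", "", f"ALPHABET= {alphabet.symbols}", ""]
    for pfm in pfms:
        lines.append(f"MOTIF {pfm.name}")
        lines.append(
            f"letter-probability matrix: alength= {alphabet.size} "
            f"w= {pfm.width} nsites= 20 E= {pfm.corrected_pvalue:.3g}"
        )
        for row in pfm.matrix:
            lines.append(" ".join(f"{x:.6f}" for x in row))
        lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_meme_motifs(path, alphabet_kind: str):
    """Read MEME minimal motif format back into PFM objects."""
    from .discover import PFM

    alphabet = get_alphabet(alphabet_kind)
    pfms = []
    name = None
    matrix_rows: list[list[float]] = []
    expect = 0
    evalue = 1.0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("MOTIF"):
                name = line.split(maxsplit=1)[1]
            elif line.startswith("letter-probability matrix"):
                m = re.search(r"w=\s*(\d+)", line)
                expect = int(m.group(1)) if m else 0
                me = re.search(r"E=\s*(\S+)", line)
                evalue = float(me.group(1)) if me else 1.0
                matrix_rows = []
            elif name is not None and expect and line and (line[0].isdigit() or line[0] == "."):
                matrix_rows.append([float(x) for x in line.split()])
                if len(matrix_rows) == expect:
                    pfms.append(
                        PFM(
                            alphabet=alphabet.kind,
                            matrix=np.asarray(matrix_rows),
                            pvalue=evalue,
                            corrected_pvalue=evalue,
                            name=name,
                        )
                    )
                    name = None
                    expect = 0
    if not pfms:
        raise ValueError(f"no motifs parsed from {path}")
    return pfms
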