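"""SELEX-like synthetic probe sets with planted motifs and known structures.

The generator emulates an in vitro selection experiment on randomized
probes (N40 by default, optionally flanked by constant primer-derived
sequence): the positive set carries a consensus motif planted in a fraction
of probes, the negative set is the unselected background pool. Three
planting modes cover the main RBP binding archetypes:

* ``none`` — the motif sits in otherwise unstructured sequence (sequence
  binders); emitted dot-brackets are all dots;
* ``hairpin_loop`` — the motif is embedded in the loop of a constructed
  hairpin with a Watson-Crick complementary stem (hairpin-loop binders);
* ``bipartite`` — two sub-motifs are planted with a uniformly drawn gap
  (bipartite binders).

Structures are emitted directly by construction and are self-consistent
with the sequences, so the whole pipeline is testable without an external
folding tool; a truth table records every plant for oracle-based tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .annotate import normalize_rna

IUPAC = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "R": "AG", "Y": "CU", "S": "CG", "W": "AU",
    "K": "GU", "M": "AC", "B": "CGU", "D": "AGU",
    "H": "ACU", "V": "ACG", "N": "ACGU",
}

COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


class SimulationError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic selection experiment.

    Defaults emulate a typical selection assay: 2000 probes per set of 40
    random bases, a hexamer consensus planted in half of the bound probes,
    uniform base composition.
    """

    n_probes: int = 2000
    probe_length: int = 40
    flank_5: str = ""
    flank_3: str = ""
    plant_rate: float = 0.5
    motif_consensus: str = "UGCAUG"
    #: second sub-motif for bipartite mode (Quaking-like bipartite element)
    motif_consensus_2: str = "UAAC"
    structure_mode: str = "none"  # none | hairpin_loop | bipartite
    gap_range: tuple[int, int] = (1, 20)
    stem_length: int = 5
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0

    def __post_init__(self):
        comp = np.asarray(self.base_composition, dtype=float)
        if comp.shape != (4,) or np.any(comp < 0) or abs(comp.sum() - 1) > 1e-9:
            raise SimulationError("base_composition must be 4 probabilities summing to 1")
        if not 0.0 <= self.plant_rate <= 1.0:
            raise SimulationError("plant_rate must be in [0, 1]")
        if self.structure_mode not in ("none", "hairpin_loop", "bipartite"):
            raise SimulationError(f"unknown structure_mode {self.structure_mode!r}")
        if self.structure_mode == "hairpin_loop":
            if self.stem_length < 3:
                raise SimulationError("hairpin stems need length >= 3")
            if len(self.motif_consensus) < 1:
                raise SimulationError("hairpin loop needs a motif to hold")
        self.motif_consensus = normalize_rna(self.motif_consensus)
        self.motif_consensus_2 = normalize_rna(self.motif_consensus_2)
        self.flank_5 = normalize_rna(self.flank_5)
        self.flank_3 = normalize_rna(self.flank_3)


@dataclass
class SimProbe:
    name: str
    sequence: str  # full probe including flanks
    dotbracket: str

    @property
    def record(self) -> tuple[str, str, str]:
        return (self.name, self.sequence, self.dotbracket)


@dataclass
class SimDataset:
    positives: list[SimProbe]
    negatives: list[SimProbe]
    truth: pd.DataFrame
    variable_region: tuple[int, int]
    config: GeneratorConfig


def _random_sequences(rng, n, length, composition) -> list[str]:
    letters = np.array(list("ACGU"))
    draws = rng.choice(4, size=(n, length), p=np.asarray(composition))
    return ["".join(row) for row in letters[draws]]


def _sample_iupac(rng, consensus: str) -> str:
    out = []
    for c in consensus:
        try:
            choices = IUPAC[c]
        except KeyError:
            raise SimulationError(f"unknown IUPAC code {c!r}") from None
        out.append(choices[rng.integers(len(choices))])
    return "".join(out)


def generate_background(config: GeneratorConfig, prefix: str = "bg") -> list[SimProbe]:
    """I.i.d. probes from the base composition with all-dot structures."""
    rng = np.random.default_rng(config.seed)
    seqs = _random_sequences(rng, config.n_probes, config.probe_length, config.base_composition)
    lo = len(config.flank_5)
    probes = []
    for i, s in enumerate(seqs):
        full = config.flank_5 + s + config.flank_3
        probes.append(SimProbe(f"{prefix}_{i}", full, "." * len(full)))
    return probes


def plant_motif(
    probes: list[SimProbe],
    consensus: str,
    rate: float,
    seed: int,
    variable_region: tuple[int, int] | None = None,
) -> tuple[list[SimProbe], pd.DataFrame]:
    """Overwrite background letters with the consensus in a Bernoulli(rate)
    subset of probes, at uniform random valid offsets within the variable
    region. IUPAC codes are sampled uniformly over their nucleotide sets."""
    consensus = normalize_rna(consensus)
    rng = np.random.default_rng(seed)
    out = []
    rows = []
    for probe in probes:
        lo, hi = variable_region or (0, len(probe.sequence))
        if hi - lo < len(consensus):
            raise SimulationError(
                f"consensus {consensus!r} does not fit in variable region {lo, hi}"
            )
        planted = rng.random() < rate
        if not planted:
            out.append(probe)
            rows.append({"probe": probe.name, "planted": False, "offset": -1, "site": ""})
            continue
        offset = int(rng.integers(lo, hi - len(consensus) + 1))
        site = _sample_iupac(rng, consensus)
        seq = probe.sequence[:offset] + site + probe.sequence[offset + len(site):]
        out.append(SimProbe(probe.name, seq, probe.dotbracket))
        rows.append({"probe": probe.name, "planted": True, "offset": offset, "site": site})
    return out, pd.DataFrame(rows)


def generate_hairpin_probe(
    loop_motif: str,
    stem_length: int,
    config: GeneratorConfig,
    rng=None,
    name: str = "hp",
) -> SimProbe:
    """One probe containing a constructed hairpin whose loop holds the motif.

    The stem is random, closed by its reverse complement (Watson-Crick
    only); the remainder of the probe is unpaired background. The structure
    string is built alongside the sequence, so the loop positions classify
    as hairpin-loop contexts by construction.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if stem_length < 3:
        raise SimulationError("hairpin stems need length >= 3")
    loop = _sample_iupac(rng, loop_motif)
    hp_len = 2 * stem_length + len(loop)
    if hp_len > config.probe_length:
        raise SimulationError(
            f"hairpin of length {hp_len} exceeds probe length {config.probe_length}"
        )
    stem = _random_sequences(rng, 1, stem_length, config.base_composition)[0]
    closing = "".join(COMPLEMENT[c] for c in reversed(stem))
    hairpin = stem + loop + closing
    hp_db = "(" * stem_length + "." * len(loop) + ")" * stem_length
    pad_total = config.probe_length - hp_len
    left = int(rng.integers(0, pad_total + 1))
    bg = _random_sequences(rng, 1, pad_total, config.base_composition)[0]
    var_seq = bg[:left] + hairpin + bg[left:]
    var_db = "." * left + hp_db + "." * (pad_total - left)
    full_seq = config.flank_5 + var_seq + config.flank_3
    full_db = "." * len(config.flank_5) + var_db + "." * len(config.flank_3)
    return SimProbe(name, full_seq, full_db)


def generate_dataset(config: GeneratorConfig) -> SimDataset:
    """Positive + negative probe sets with a truth table of plant locations."""
    lo = len(config.flank_5)
    hi = lo + config.probe_length
    neg_config = replace(config, seed=config.seed + 1)
    negatives = generate_background(neg_config, prefix="neg")
    positives = generate_background(config, prefix="pos")

    rng = np.random.default_rng(config.seed + 2)
    if config.structure_mode == "none":
        positives, truth = plant_motif(
            positives, config.motif_consensus, config.plant_rate,
            seed=config.seed + 2, variable_region=(lo, hi),
        )
    elif config.structure_mode == "hairpin_loop":
        out, rows = [], []
        for probe in positives:
            if rng.random() < config.plant_rate:
                hp = generate_hairpin_probe(
                    config.motif_consensus, config.stem_length, config,
                    rng=rng, name=probe.name,
                )
                out.append(hp)
                loop_start = lo + hp.dotbracket[lo:hi].index("(") + config.stem_length
                rows.append(
                    {"probe": probe.name, "planted": True, "offset": loop_start,
                     "site": hp.sequence[loop_start : loop_start + len(config.motif_consensus)]}
                )
            else:
                out.append(probe)
                rows.append({"probe": probe.name, "planted": False, "offset": -1, "site": ""})
        positives, truth = out, pd.DataFrame(rows)
    else:  # bipartite
        m1, m2 = config.motif_consensus, config.motif_consensus_2
        g_lo, g_hi = config.gap_range
        if g_lo < 0 or g_hi < g_lo:
            raise SimulationError(f"bad gap_range {config.gap_range}")
        if len(m1) + g_hi + len(m2) > config.probe_length:
            raise SimulationError("bipartite plant cannot fit at maximum gap")
        out, rows = [], []
        for probe in positives:
            if rng.random() >= config.plant_rate:
                out.append(probe)
                rows.append(
                    {"probe": probe.name, "planted": False, "offset": -1,
                     "site": "", "gap": -1}
                )
                continue
            gap = int(rng.integers(g_lo, g_hi + 1))
            span = len(m1) + gap + len(m2)
            offset = int(rng.integers(lo, hi - span + 1))
            s1 = _sample_iupac(rng, m1)
            s2 = _sample_iupac(rng, m2)
            seq = probe.sequence
            seq = seq[:offset] + s1 + seq[offset + len(s1):]
            off2 = offset + len(s1) + gap
            seq = seq[:off2] + s2 + seq[off2 + len(s2):]
            out.append(SimProbe(probe.name, seq, probe.dotbracket))
            rows.append(
                {"probe": probe.name, "planted": True, "offset": offset,
                 "site": s1 + "-" + s2, "gap": gap}
            )
        positives, truth = out, pd.DataFrame(rows)

    return SimDataset(
        positives=positives,
        negatives=negatives,
        truth=truth,
        variable_region=(lo, hi),
        config=config,
    )


def write_dataset(dataset: SimDataset, outdir) -> dict:
    """Write FASTA + Vienna structure files + truth TSV; returns the paths."""
    from pathlib import Path

    from .io import write_fasta, write_vienna

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "pos_fasta": outdir / "positives.fa",
        "neg_fasta": outdir / "negatives.fa",
        "pos_struct": outdir / "positives.db",
        "neg_struct": outdir / "negatives.db",
        "truth": outdir / "truth.tsv",
    }
    write_fasta([(p.name, p.sequence) for p in dataset.positives], paths["pos_fasta"])
    write_fasta([(p.name, p.sequence) for p in dataset.negatives], paths["neg_fasta"])
    write_vienna([p.record for p in dataset.positives], paths["pos_struct"])
    write_vienna([p.record for p in dataset.negatives], paths["neg_struct"])
    dataset.truth.to_csv(paths["truth"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}
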