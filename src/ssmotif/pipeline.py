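"""Dataset preprocessing, splits, and the end-to-end training pipeline.

The canonical data flow: clean and subsample the positive/negative probe
sets, split each class 50/20/5/25 (motif discovery / LR training / LR
validation / held-out test), annotate under the seven alphabets, discover
up to 40 PFMs per alphabet on the discovery split, scan all PFMs over the
remaining probes, optimize the L1 strength, fit and iteratively simplify
the logistic-regression model, and report.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from .alphabets import ALPHABET_ORDER
from .annotate import AnnotatedProbe, annotate_probe
from .discover import DiscoveryConfig, discover_motifs
from .regress import MotifModel, auroc_from_labels, optimize_l1, simplify_model
from .scan import FeatureMatrix, build_feature_matrix, drop_duplicate_features

logger = logging.getLogger("ssmotif")

SPLIT_FRACTIONS = (0.50, 0.20, 0.05, 0.25)
SPLIT_NAMES = ("discovery", "train", "validation", "heldout")
SUBSAMPLE_CAP = 1_000_000
MIN_PROBES = 20

_VALID = set("ACGU")


class PipelineError(ValueError):
    pass


@dataclass
class DatasetConfig:
    """Declarative description of one training run."""

    positive_path: str = ""
    negative_path: str = ""
    positive_structure_path: str = ""
    negative_structure_path: str = ""
    flank_5: str = ""
    flank_3: str = ""
    temperature: float = 37.0
    subsample_cap: int = SUBSAMPLE_CAP
    split_fractions: tuple = SPLIT_FRACTIONS
    seed: int = 0
    discovery: DiscoveryConfig = field(default_factory=DiscoveryConfig)
    l1_grid: np.ndarray | None = None
    cv_folds: int = 3

    def __post_init__(self):
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise PipelineError("split fractions must sum to 1")


def preprocess(
    pos: list[tuple[str, str]],
    neg: list[tuple[str, str]],
    cap: int = SUBSAMPLE_CAP,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Clean and subsample the positive/negative sequence sets.

    Probes containing letters outside {A, C, G, U} (after T -> U
    normalization) are discarded. Then both sets are subsampled (seeded,
    without replacement): to ``cap`` each when both exceed the cap,
    otherwise to the size of the smaller set.
    """
    def clean(records):
        out = []
        for name, seq in records:
            seq = seq.upper().replace("T", "U")
            if seq and set(seq) <= _VALID:
                out.append((name, seq))
        return out

    pos, neg = clean(pos), clean(neg)
    if not pos or not neg:
        raise PipelineError("a probe set is empty after removing ambiguous probes")
    target = min(cap, min(len(pos), len(neg)))
    rng = np.random.default_rng(seed)

    def subsample(records, k):
        if len(records) <= k:
            return list(records)
        idx = rng.choice(len(records), size=k, replace=False)
        return [records[i] for i in np.sort(idx)]

    return subsample(pos, target), subsample(neg, target)


def split_indices(n: int, fractions, seed: int) -> list[np.ndarray]:
    """Partition ``range(n)`` by largest-remainder rounding of ``fractions``."""
    if n < MIN_PROBES:
        raise PipelineError(f"need at least {MIN_PROBES} probes, got {n}")
    quotas = np.array([f * n for f in fractions])
    counts = np.floor(quotas).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(quotas - counts), kind="stable")
    for i in order[:remainder]:
        counts[i] += 1
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    out = []
    start = 0
    for c in counts:
        out.append(np.sort(perm[start : start + c]))
        start += c
    return out


def split_dataset(items: list, labels, fractions=SPLIT_FRACTIONS, seed: int = 0) -> dict:
    """Stratified disjoint split into discovery/train/validation/heldout.

    Items of each class are partitioned independently (largest-remainder
    rounding) so the class balance is preserved in every part.
    """
    labels = np.asarray(labels)
    parts: dict[str, list] = {name: [] for name in SPLIT_NAMES}
    part_labels: dict[str, list] = {name: [] for name in SPLIT_NAMES}
    for offset, cls in enumerate(np.unique(labels)):
        idx = np.flatnonzero(labels == cls)
        for name, sub in zip(SPLIT_NAMES, split_indices(len(idx), fractions, seed + offset)):
            parts[name].extend(items[i] for i in idx[sub])
            part_labels[name].extend([cls] * len(sub))
    return {
        name: (parts[name], np.asarray(part_labels[name])) for name in SPLIT_NAMES
    }


@dataclass
class TrainResult:
    model: MotifModel
    pfms_per_alphabet: dict[str, int]
    heldout_auroc: float | None
    timings: dict[str, float]
    splits: dict


def train_pipeline(
    records: list[tuple[str, str, str]],
    labels,
    config: DatasetConfig | None = None,
    variable_region: tuple[int, int] | None = None,
) -> TrainResult:
    """Run discovery -> scanning -> LR optimization -> simplification.

    ``records`` are ``(name, sequence, dotbracket)`` triples for both
    classes; ``labels`` are 1 for bound probes, 0 for background.
    """
    config = config or DatasetConfig()
    labels = np.asarray(labels)
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    probes = [
        annotate_probe(seq, db, variable_region=variable_region, name=name)
        for name, seq, db in records
    ]
    timings["annotate"] = time.perf_counter() - t0
    logger.info("annotated %d probes (seed=%d)", len(probes), config.seed)

    splits = split_dataset(probes, labels, config.split_fractions, seed=config.seed)
    disc_probes, disc_labels = splits["discovery"]

    t0 = time.perf_counter()
    pfms = []
    pfms_per_alphabet = {}
    for kind in ALPHABET_ORDER:
        pos_ann = [p.annotations[kind] for p, y in zip(disc_probes, disc_labels) if y == 1]
        neg_ann = [p.annotations[kind] for p, y in zip(disc_probes, disc_labels) if y == 0]
        found = discover_motifs(pos_ann, neg_ann, kind, config.discovery)
        pfms_per_alphabet[kind] = len(found)
        pfms.extend(found)
        logger.info("discovery[%s]: %d PFMs", kind, len(found))
    timings["discovery"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    features = {
        name: build_feature_matrix(pfms, *splits[name])
        for name in ("train", "validation", "heldout")
    }
    timings["scanning"] = time.perf_counter() - t0

    # Collapse columns that are exact duplicates after standardization so the
    # L1 fit is deterministic; the first (canonical-order) column represents
    # each duplicate group.
    n_before = features["train"].values.shape[1]
    features["train"], features["validation"], features["heldout"] = (
        drop_duplicate_features(
            features["train"], features["validation"], features["heldout"]
        )
    )
    n_after = features["train"].values.shape[1]
    if n_after < n_before:
        logger.info("collapsed %d duplicate feature columns", n_before - n_after)

    t0 = time.perf_counter()
    if pfms:
        l1_star = optimize_l1(
            features["train"].X,
            features["train"].y,
            grid=config.l1_grid,
            cv=config.cv_folds,
            seed=config.seed,
        )
    else:
        l1_star = 1.0
    timings["optimize_l1"] = time.perf_counter() - t0
    logger.info("optimized l1 strength: %g", l1_star)

    t0 = time.perf_counter()
    model = simplify_model(
        features["train"], features["validation"], l1_star, seed=config.seed
    )
    timings["simplify"] = time.perf_counter() - t0
    ratios = [
        model.trace[i + 1]["l1_strength"] / model.trace[i]["l1_strength"]
        for i in range(len(model.trace) - 1)
    ]
    logger.info(
        "simplification trace: %d steps, strength ratios %s",
        len(model.trace),
        ", ".join(f"{r:.4g}" for r in ratios[:5]) + ("..." if len(ratios) > 5 else ""),
    )

    heldout_auroc = None
    ho, ho_labels = features["heldout"].X, features["heldout"].y
    if len(ho_labels) and np.unique(ho_labels).size == 2 and model.coefficients.size:
        heldout_auroc = auroc_from_labels(model.decision_function(ho), ho_labels)
    logger.info(
        "initial AUROC %.4f, final AUROC %.4f, heldout %s, retained %d PFMs",
        model.initial_auroc,
        model.final_auroc,
        f"{heldout_auroc:.4f}" if heldout_auroc is not None else "n/a",
        len(model.retained),
    )
    return TrainResult(
        model=model,
        pfms_per_alphabet=pfms_per_alphabet,
        heldout_auroc=heldout_auroc,
        timings=timings,
        splits=splits,
    )
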