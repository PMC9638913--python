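"""PFM scanning and top-4-sum feature construction.

Each PFM is slid along the probe annotation from its own alphabet; windows
are scored as log-odds in bits against a uniform background, with matrix
entries floored at 1e-3 before the log so mismatches stay finite. The
per-(probe, PFM) feature is the sum of the top four window scores (or of
all windows when fewer than four exist).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alphabets import ALPHABET_ORDER, get_alphabet
from .annotate import AnnotatedProbe
from .discover import PFM

PROB_FLOOR = 1e-3
TOP_K = 4


class ScanError(ValueError):
    pass


def log_odds(pfm: PFM) -> np.ndarray:
    """Floored log2-odds matrix of a PFM versus the uniform background."""
    size = pfm.matrix.shape[1]
    return np.log2(np.maximum(pfm.matrix, PROB_FLOOR) * size)


def floor_feature(pfm: PFM) -> float:
    """Hard-floor feature for probes shorter than the PFM width."""
    size = pfm.matrix.shape[1]
    return TOP_K * pfm.width * math.log2(PROB_FLOOR * size)


def encode(annotation: str, alphabet_kind: str) -> np.ndarray:
    symbols = get_alphabet(alphabet_kind).symbols
    index = {c: i for i, c in enumerate(symbols)}
    try:
        return np.fromiter((index[c] for c in annotation), dtype=np.intp, count=len(annotation))
    except KeyError as exc:
        raise ScanError(f"symbol {exc.args[0]!r} not in alphabet {alphabet_kind}") from None


def window_scores(pfm: PFM, annotation: str) -> np.ndarray:
    """Scores of every window of ``annotation`` under the PFM, in bits."""
    x = encode(annotation, pfm.alphabet)
    return _window_scores_encoded(log_odds(pfm), x)


def _window_scores_encoded(lod: np.ndarray, x: np.ndarray) -> np.ndarray:
    w = lod.shape[0]
    n_windows = len(x) - w + 1
    if n_windows <= 0:
        return np.empty(0)
    scores = np.zeros(n_windows)
    for j in range(w):
        scores += lod[j, x[j : j + n_windows]]
    return scores


def score_window(pfm: PFM, annotation: str, pos: int) -> float:
    """Score one window starting at ``pos``."""
    if pos < 0 or pos + pfm.width > len(annotation):
        raise ScanError(
            f"window [{pos}, {pos + pfm.width}) out of range for length {len(annotation)}"
        )
    x = encode(annotation[pos : pos + pfm.width], pfm.alphabet)
    return float(log_odds(pfm)[np.arange(pfm.width), x].sum())


def _top_k_sum(scores: np.ndarray, k: int = TOP_K) -> float:
    if len(scores) <= k:
        return float(scores.sum())
    return float(np.partition(scores, -k)[-k:].sum())


def probe_feature(pfm: PFM, annotation: str) -> float:
    """Top-4 window score sum for one probe annotation."""
    if len(annotation) < pfm.width:
        return floor_feature(pfm)
    return _top_k_sum(window_scores(pfm, annotation))


@dataclass
class FeatureMatrix:
    """Dense (probe x PFM) feature matrix with binary labels.

    Column order is deterministic: alphabets in canonical order, then PFM
    discovery rank within each alphabet.
    """

    values: pd.DataFrame
    labels: np.ndarray
    pfms: list[PFM]

    @property
    def X(self) -> np.ndarray:
        return self.values.to_numpy()

    @property
    def y(self) -> np.ndarray:
        return self.labels

    def to_tsv(self, path, label_path=None) -> None:
        self.values.to_csv(path, sep="\t", index=True)
        if label_path is not None:
            pd.Series(self.labels, index=self.values.index, name="label").to_csv(
                label_path, sep="\t"
            )


def drop_duplicate_features(fm: FeatureMatrix, *others: FeatureMatrix):
    """Collapse feature columns that are exact duplicates after z-scoring.

    Annotations under different alphabets can be relabelings of one another
    (e.g. on a probe set with no paired bases every product annotation
    mirrors the sequence), making standardized columns identical and the L1
    optimum non-unique. The first column in canonical order represents each
    duplicate group; ``others`` (validation/test matrices) are reduced to
    the same columns. Returns the reduced matrices.
    """
    X = fm.X
    if X.shape[1] == 0:
        return (fm, *others) if others else fm
    means = X.mean(axis=0)
    stds = X.std(axis=0)
    stds = np.where(stds > 0, stds, 1.0)
    Z = np.round((X - means) / stds, 9)
    seen = {}
    keep = []
    for j in range(Z.shape[1]):
        key = Z[:, j].tobytes()
        if key not in seen:
            seen[key] = j
            keep.append(j)
    if len(keep) == Z.shape[1]:
        return (fm, *others) if others else fm
    cols = [fm.values.columns[j] for j in keep]
    reduced = [
        FeatureMatrix(m.values[cols], m.labels, [m.pfms[j] for j in keep])
        for m in (fm, *others)
    ]
    return tuple(reduced) if others else reduced[0]


def sort_pfms(pfms: list[PFM]) -> list[PFM]:
    order = {kind: i for i, kind in enumerate(ALPHABET_ORDER)}
    # stable: preserves discovery rank within an alphabet
    return sorted(pfms, key=lambda p: order[p.alphabet])


def build_feature_matrix(
    pfms: list[PFM],
    probes: list[AnnotatedProbe],
    labels,
) -> FeatureMatrix:
    """Score every PFM on every probe's matching annotation."""
    labels = np.asarray(labels)
    if len(labels) != len(probes):
        raise ScanError(f"{len(labels)} labels for {len(probes)} probes")
    pfms = sort_pfms(pfms)
    index = [p.name or f"probe_{i}" for i, p in enumerate(probes)]
    if not pfms:
        return FeatureMatrix(pd.DataFrame(index=index), labels, [])

    # Encode each alphabet's annotations once; probes of equal length share a
    # vectorized scan, others fall back to per-probe scoring.
    columns: dict[str, np.ndarray] = {}
    by_alphabet: dict[str, list[PFM]] = {}
    for pfm in pfms:
        by_alphabet.setdefault(pfm.alphabet, []).append(pfm)
    n = len(probes)
    for kind, group in by_alphabet.items():
        anns = []
        for p in probes:
            if kind not in p.annotations:
                raise ScanError(f"probe {p.name!r} lacks a {kind} annotation")
            anns.append(p.annotations[kind])
        encoded = [encode(a, kind) for a in anns]
        lengths = {len(a) for a in anns}
        uniform = len(lengths) == 1
        if uniform:
            X = np.vstack(encoded) if n else np.empty((0, lengths.pop() if lengths else 0), dtype=np.intp)
        for pfm in group:
            lod = log_odds(pfm)
            w = pfm.width
            out = np.empty(n)
            if uniform and X.shape[1] >= w:
                n_windows = X.shape[1] - w + 1
                scores = np.zeros((n, n_windows))
                for j in range(w):
                    scores += lod[j, X[:, j : j + n_windows]]
                if n_windows <= TOP_K:
                    out = scores.sum(axis=1)
                else:
                    out = np.partition(scores, -TOP_K, axis=1)[:, -TOP_K:].sum(axis=1)
            else:
                for i, x in enumerate(encoded):
                    if len(x) < w:
                        out[i] = floor_feature(pfm)
                    else:
                        out[i] = _top_k_sum(_window_scores_encoded(lod, x))
            columns[pfm.name] = out
    frame = pd.DataFrame({p.name: columns[p.name] for p in pfms}, index=index)
    return FeatureMatrix(frame, labels, pfms)
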