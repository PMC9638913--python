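"""Structural-specificity metrics and motif reports for fitted models.

Two summary metrics describe how much of a model's weight reflects RNA
secondary structure:

* per-alphabet weight proportions — for each of the seven annotation
  alphabets, the sum of |coefficient| over its retained PFMs divided by the
  total |coefficient| mass; the sequence-alphabet entry measures how much of
  the specificity is explained by primary sequence alone;
* paired-weight fraction — within structure-inclusive PFMs, the information
  content of each column attributed to paired-context symbols (P in the 2-
  and 4-letter alphabets, L/R in the 7-letter alphabet), weighted by the
  model coefficient of the PFM.
"""

from __future__ import annotations

import json
import warnings

import numpy as np
import pandas as pd

from .alphabets import ALPHABET_ORDER, get_alphabet
from .discover import PFM
from .regress import MotifModel


class InterpretError(ValueError):
    pass


def _weights(model: MotifModel) -> np.ndarray:
    return np.abs(np.asarray(model.coefficients, dtype=float))


def alphabet_weight_proportions(model: MotifModel) -> dict[str, float]:
    """Fraction of total |coefficient| mass carried by each alphabet."""
    w = _weights(model)
    total = w.sum()
    if total == 0:
        raise InterpretError("model has no nonzero coefficients")
    out = {kind: 0.0 for kind in ALPHABET_ORDER}
    for pfm, wi in zip(model.pfms, w):
        out[pfm.alphabet] += float(wi)
    return {kind: v / total for kind, v in out.items()}


def sequence_weight_fraction(model: MotifModel) -> float:
    return alphabet_weight_proportions(model)["sequence"]


def column_information(matrix: np.ndarray) -> np.ndarray:
    """Per-position information content in bits: log2|A| - H(position)."""
    size = matrix.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(matrix > 0, matrix * np.log2(matrix), 0.0)
    return np.log2(size) + plogp.sum(axis=1)


def pfm_paired_share(pfm: PFM) -> float:
    """Fraction of a PFM's information content attributed to paired bases.

    Each position's IC is split by the probability mass its distribution
    places on paired-context symbols; sequence-only PFMs score 0, as does a
    PFM with zero total IC.
    """
    alphabet = get_alphabet(pfm.alphabet)
    mask = np.asarray(alphabet.paired_mask())
    if not mask.any():
        return 0.0
    ic = column_information(pfm.matrix)
    total = ic.sum()
    if total <= 0:
        return 0.0
    paired_mass = pfm.matrix[:, mask].sum(axis=1)
    return float((ic * paired_mass).sum() / total)


def pfm_unpaired_share(pfm: PFM) -> float:
    """IC fraction attributed to unpaired-context symbols of a structural PFM."""
    alphabet = get_alphabet(pfm.alphabet)
    mask = np.asarray(alphabet.paired_mask())
    if not mask.any():
        return 0.0
    ic = column_information(pfm.matrix)
    total = ic.sum()
    if total <= 0:
        return 0.0
    unpaired_mass = pfm.matrix[:, ~mask].sum(axis=1)
    return float((ic * unpaired_mass).sum() / total)


def paired_weight_fraction(model: MotifModel) -> float:
    """Coefficient-weighted paired-IC share over all retained PFMs."""
    w = _weights(model)
    total = w.sum()
    if total == 0:
        raise InterpretError("model has no nonzero coefficients")
    shares = np.array([pfm_paired_share(p) for p in model.pfms])
    return float((w * shares).sum() / total)


def weight_decomposition(model: MotifModel) -> dict[str, float]:
    """Split total model weight into sequence-PFM, unpaired and paired parts.

    The three fractions sum to 1: structure-inclusive PFMs contribute their
    IC-weighted paired and unpaired shares; any structural PFM with zero
    total IC counts as unpaired (it carries no structural information).
    """
    w = _weights(model)
    total = w.sum()
    if total == 0:
        raise InterpretError("model has no nonzero coefficients")
    seq = paired = unpaired = 0.0
    for pfm, wi in zip(model.pfms, w):
        if wi == 0:
            continue
        if pfm.alphabet == "sequence":
            seq += wi
            continue
        ps = pfm_paired_share(pfm)
        us = pfm_unpaired_share(pfm)
        if ps + us == 0.0:
            us = 1.0  # zero-IC structural PFM: treat as uninformative/unpaired
        paired += wi * ps
        unpaired += wi * us
    return {
        "sequence": seq / total,
        "unpaired": unpaired / total,
        "paired": paired / total,
    }


def structure_specificity_report(model: MotifModel) -> dict:
    """Machine-readable structural-specificity summary of a model."""
    per_alphabet = alphabet_weight_proportions(model)
    return {
        "per_alphabet_weight": per_alphabet,
        "sequence_weight_fraction": per_alphabet["sequence"],
        "paired_weight_fraction": paired_weight_fraction(model),
        "weight_decomposition": weight_decomposition(model),
    }


def motif_report(model: MotifModel) -> pd.DataFrame:
    """Retained motifs ranked by their share of the total model weight."""
    w = _weights(model)
    total = w.sum()
    rows = []
    for pfm, coef, wi in zip(model.pfms, model.coefficients, w):
        if wi == 0:
            continue
        rows.append(
            {
                "pfm": pfm.name,
                "alphabet": pfm.alphabet,
                "consensus": pfm.consensus,
                "coefficient": float(coef),
                "weight_proportion": round(float(wi / total), 3),
                "paired_ic_share": round(pfm_paired_share(pfm), 3),
                "matrix": json.dumps(np.round(pfm.matrix, 6).tolist()),
            }
        )
    if not rows:
        warnings.warn("model retains no motifs; report is empty", stacklevel=2)
        return pd.DataFrame(
            columns=[
                "pfm", "alphabet", "consensus", "coefficient",
                "weight_proportion", "paired_ic_share", "matrix",
            ]
        )
    frame = pd.DataFrame(rows)
    return frame.sort_values(
        "weight_proportion", ascending=False, kind="mergesort"
    ).reset_index(drop=True)


def write_report(model: MotifModel, tsv_path, json_path=None) -> None:
    report = motif_report(model)
    report.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        payload = {
            "summary": structure_specificity_report(model)
            if np.any(model.coefficients)
            else {},
            "motifs": report.drop(columns=["matrix"]).to_dict(orient="records"),
            "initial_auroc": model.initial_auroc,
            "final_auroc": model.final_auroc,
            "l1_strength": model.l1_strength,
        }
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=1)
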