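"""Gap-HMM over discovered PFMs: variable spacing between motifs.

The model is a hidden Markov chain whose match states are the individual
positions of up to 10 PFMs from one alphabet. A recursive *begin* state
emits background before the first motif; after a PFM completes it may chain
directly into any PFM (back-to-back motifs), enter a recursive *gap* state
specific to that ordered PFM pair (variable spacing), or enter the
recursive absorbing *end* state. Emissions of PFM states equal the PFM
columns and are frozen during training; all other states emit uniformly.
Baum-Welch therefore only learns the transition structure: which motifs
co-occur and how far apart.

Scores from the seven per-alphabet gap-HMMs (per-probe log-probabilities)
are combined with a random-forest classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from hmmlearn.hmm import CategoricalHMM
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV

from .alphabets import Alphabet, get_alphabet
from .discover import PFM
from .regress import auroc_from_labels
from .scan import encode

MAX_HMM_PFMS = 10
MAX_TRAINING_PROBES = 10_000
EM_MAX_ITER = 100
EM_REL_TOL = 1e-4


class HMMError(ValueError):
    pass


@dataclass
class GapHMM:
    """State graph + parameters of the gap-HMM for one alphabet."""

    alphabet: str
    pfms: list[PFM]
    state_names: list[str]
    startprob: np.ndarray
    transmat: np.ndarray
    emissions: np.ndarray
    #: boolean mask of transitions allowed by the topology
    allowed: np.ndarray = field(repr=False, default=None)

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    def to_hmmlearn(self) -> CategoricalHMM:
        hmm = CategoricalHMM(
            n_components=self.n_states,
            n_features=self.emissions.shape[1],
            init_params="",
            params="st",  # emissions stay frozen
        )
        hmm.startprob_ = self.startprob.copy()
        hmm.transmat_ = self.transmat.copy()
        hmm.emissionprob_ = self.emissions.copy()
        return hmm


def build_gap_hmm(pfms: list[PFM], alphabet: str | Alphabet) -> GapHMM:
    """Construct the gap-HMM topology with uniform allowed-transition weights.

    States: ``begin``, one state per PFM position, one gap state per ordered
    PFM pair (self-pairs included, so repeated occurrences of one motif are
    representable), and ``end``.
    """
    if isinstance(alphabet, str):
        alphabet = get_alphabet(alphabet)
    if not 1 <= len(pfms) <= MAX_HMM_PFMS:
        raise HMMError(f"need 1..{MAX_HMM_PFMS} PFMs, got {len(pfms)}")
    for pfm in pfms:
        if pfm.alphabet != alphabet.kind:
            raise HMMError(
                f"PFM {pfm.name!r} is over {pfm.alphabet}, expected {alphabet.kind}"
            )
    n_pfms = len(pfms)
    names = ["begin"]
    pfm_start: list[int] = []
    pfm_end: list[int] = []
    for i, pfm in enumerate(pfms):
        pfm_start.append(len(names))
        names.extend(f"pfm{i}_pos{j}" for j in range(pfm.width))
        pfm_end.append(len(names) - 1)
    gap_index: dict[tuple[int, int], int] = {}
    for i in range(n_pfms):
        for j in range(n_pfms):
            gap_index[(i, j)] = len(names)
            names.append(f"gap_{i}_to_{j}")
    end = len(names)
    names.append("end")
    S = len(names)

    allowed = np.zeros((S, S), dtype=bool)
    allowed[0, 0] = True  # begin is recursive
    for j in pfm_start:
        allowed[0, j] = True
    for i, pfm in enumerate(pfms):
        s = pfm_start[i]
        for j in range(pfm.width - 1):  # strict left-to-right within a PFM
            allowed[s + j, s + j + 1] = True
        e = pfm_end[i]
        for j in pfm_start:
            allowed[e, j] = True  # back-to-back motifs
        for k in range(n_pfms):
            allowed[e, gap_index[(i, k)]] = True
        allowed[e, end] = True
    for (i, j), g in gap_index.items():
        allowed[g, g] = True  # recursive gap
        allowed[g, pfm_start[j]] = True
    allowed[end, end] = True  # absorbing

    transmat = allowed / allowed.sum(axis=1, keepdims=True)
    startprob = np.zeros(S)
    startprob[0] = 1.0

    size = alphabet.size
    emissions = np.full((S, size), 1.0 / size)
    for i, pfm in enumerate(pfms):
        emissions[pfm_start[i] : pfm_end[i] + 1] = pfm.matrix

    return GapHMM(
        alphabet=alphabet.kind,
        pfms=list(pfms),
        state_names=names,
        startprob=startprob,
        transmat=transmat,
        emissions=emissions,
        allowed=allowed,
    )


def _concat(annotations: list[str], alphabet_kind: str):
    encoded = [encode(a, alphabet_kind) for a in annotations]
    X = np.concatenate(encoded).reshape(-1, 1)
    lengths = [len(e) for e in encoded]
    return X, lengths


def train_transitions(
    hmm: GapHMM,
    annotations: list[str],
    max_iter: int = EM_MAX_ITER,
    rel_tol: float = EM_REL_TOL,
) -> GapHMM:
    """Baum-Welch on start/transition probabilities with frozen emissions.

    Runs EM one step at a time so convergence can be judged on the relative
    log-likelihood improvement; stops after ``max_iter`` steps otherwise.
    Structural zeros of the topology are never resurrected.
    """
    if not annotations:
        raise HMMError("empty training set")
    if len(annotations) > MAX_TRAINING_PROBES:
        annotations = annotations[:MAX_TRAINING_PROBES]
    X, lengths = _concat(annotations, hmm.alphabet)
    model = hmm.to_hmmlearn()
    prev_ll = None
    history = []
    for _ in range(max_iter):
        model.n_iter = 1
        model.tol = -np.inf  # we manage convergence ourselves
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X, lengths)
        # guard against degenerate M-steps for states with no expected visits
        bad = ~np.isfinite(model.transmat_).all(axis=1)
        if bad.any():
            model.transmat_[bad] = hmm.transmat[bad]
        model.transmat_[~hmm.allowed] = 0.0
        model.transmat_ /= model.transmat_.sum(axis=1, keepdims=True)
        ll = float(model.score(X, lengths))
        history.append(ll)
        if prev_ll is not None:
            denom = max(abs(prev_ll), 1.0)
            if ll - prev_ll < rel_tol * denom:
                break
        prev_ll = ll
    trained = GapHMM(
        alphabet=hmm.alphabet,
        pfms=hmm.pfms,
        state_names=hmm.state_names,
        startprob=np.asarray(model.startprob_),
        transmat=np.asarray(model.transmat_),
        emissions=np.asarray(model.emissionprob_),
        allowed=hmm.allowed,
    )
    trained.loglik_history = history
    return trained


def log_probability(hmm: GapHMM, annotation: str) -> float:
    """Forward-algorithm log P(annotation | model), computed in log space."""
    if not annotation:
        raise HMMError("empty annotation")
    x = encode(annotation, hmm.alphabet).reshape(-1, 1)
    return float(hmm.to_hmmlearn().score(x))


def log_probabilities(hmm: GapHMM, annotations: list[str]) -> np.ndarray:
    model = hmm.to_hmmlearn()
    return np.array(
        [model.score(encode(a, hmm.alphabet).reshape(-1, 1)) for a in annotations]
    )


def training_subsample(n_available: int) -> int:
    """Number of probes used for HMM training.

    At most 10 000; when fewer than 20 000 are available, half of them.
    """
    if n_available < 2 * MAX_TRAINING_PROBES:
        return n_available // 2
    return MAX_TRAINING_PROBES


def combine_hmm_scores(
    logprob_features: np.ndarray,
    labels: np.ndarray,
    test_features: np.ndarray | None = None,
    test_labels: np.ndarray | None = None,
    seed: int = 0,
    n_estimators_grid=(50, 200),
    max_depth_grid=(3, None),
    cv: int = 3,
):
    """Random-forest combiner over the seven per-alphabet log-probabilities.

    Tree count and depth are tuned by cross-validated AUROC. Returns the
    fitted classifier and its AUROC on the held-out features (or on the
    training features when no held-out set is given).
    """
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise HMMError("need both classes to train the combiner")
    search = GridSearchCV(
        RandomForestClassifier(random_state=seed),
        {"n_estimators": list(n_estimators_grid), "max_depth": list(max_depth_grid)},
        scoring="roc_auc",
        cv=cv,
    )
    search.fit(logprob_features, labels)
    clf = search.best_estimator_
    if test_features is None:
        test_features, test_labels = logprob_features, labels
    scores = clf.predict_proba(test_features)[:, 1]
    return clf, auroc_from_labels(scores, test_labels)
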