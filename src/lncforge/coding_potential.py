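"""Coding-potential scoring for transcripts.

Implements the classic sequence-intrinsic features used to separate coding
from noncoding transcripts — the Fickett TESTCODE statistic, an in-frame
hexamer usage log-ratio, and longest-ORF statistics — combined by a
logistic model into a coding probability.  The classifier follows the
scikit-learn estimator protocol (``fit``/``predict``/``predict_proba``)
so it composes with sklearn model selection.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.utils.validation import check_is_fitted

from .genome import reverse_complement

_STOPS = ("TAA", "TAG", "TGA")
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
ALL_HEXAMERS = ["".join(p) for p in itertools.product("ACGT", repeat=6)]


# ---------------------------------------------------------------------------
# Longest ORF

def _longest_orf_one_strand(seq: str) -> int:
    """Longest ATG..stop ORF (nt, stop included) over the 3 forward frames."""
    n = len(seq)
    best = 0
    for frame in range(3):
        start_pending: int | None = None
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if start_pending is None:
                if codon == "ATG":
                    start_pending = i
            elif codon in _STOPS:
                length = i + 3 - start_pending
                if length > best:
                    best = length
                start_pending = None
    return best


def longest_orf(seq: str) -> int:
    """Length in nt of the longest ATG-initiated, in-frame stop-terminated
    ORF over all six frames (stop codon included); 0 if none.

    Codons containing ``N`` match neither ATG nor a stop, so ambiguity
    breaks starts/stops but does not terminate a running frame.
    """
    seq = seq.upper()
    return max(
        _longest_orf_one_strand(seq),
        _longest_orf_one_strand(reverse_complement(seq)),
    )


# ---------------------------------------------------------------------------
# Fickett TESTCODE
#
# Published lookup tables of the TESTCODE statistic: for each base, the
# position parameter (max/min asymmetry of base usage across the three
# codon positions) and the content parameter (base fraction) are binned
# through the threshold lists below and mapped to a probability that the
# window is coding; the score is the weighted sum of the eight
# probabilities.

_POSITION_PROB = {
    "A": [0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22],
    "C": [0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23],
    "G": [0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08],
    "T": [0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09],
}
_POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
_POSITION_EDGES = [1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0]

_CONTENT_PROB = {
    "A": [0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21],
    "C": [0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.43, 0.44, 0.39, 0.31],
    "G": [0.40, 0.54, 0.47, 0.64, 0.64, 0.73, 0.41, 0.41, 0.33, 0.29],
    "T": [0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58],
}
_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}
_CONTENT_EDGES = [0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0]


def _lookup(value: float, edges: list[float], probs: list[float]) -> float:
    for edge, prob in zip(edges, probs):
        if value >= edge:
            return prob
    return probs[-1]


def fickett_score(seq: str) -> float:
    """Fickett TESTCODE score of a nucleotide sequence.

    Position parameters use base counts at the three codon-phase offsets
    (``max/(min+1)``); content parameters are base fractions.  Bases other
    than A/C/G/T are ignored in the counts.
    """
    seq = seq.upper()
    phase_counts = {b: [0, 0, 0] for b in "ACGT"}
    totals = {b: 0 for b in "ACGT"}
    for i, base in enumerate(seq):
        if base in phase_counts:
            phase_counts[base][i % 3] += 1
            totals[base] += 1
    n_used = sum(totals.values())
    score = 0.0
    for base in "ACGT":
        counts = phase_counts[base]
        position = max(counts) / (min(counts) + 1)
        content = totals[base] / n_used if n_used else 0.0
        score += (
            _lookup(position, _POSITION_EDGES, _POSITION_PROB[base])
            * _POSITION_WEIGHT[base]
        )
        score += (
            _lookup(content, _CONTENT_EDGES, _CONTENT_PROB[base])
            * _CONTENT_WEIGHT[base]
        )
    return score


def fickett_score_bounds() -> tuple[float, float]:
    """(min, max) score attainable from the lookup tables."""
    lo = sum(min(_POSITION_PROB[b]) * _POSITION_WEIGHT[b] for b in "ACGT") + sum(
        min(_CONTENT_PROB[b]) * _CONTENT_WEIGHT[b] for b in "ACGT"
    )
    hi = sum(max(_POSITION_PROB[b]) * _POSITION_WEIGHT[b] for b in "ACGT") + sum(
        max(_CONTENT_PROB[b]) * _CONTENT_WEIGHT[b] for b in "ACGT"
    )
    return lo, hi


# ---------------------------------------------------------------------------
# Hexamer usage bias

def count_hexamers(seq: str, step: int = 3) -> dict[str, int]:
    """Count in-frame (frame 0, ``step``-strided) hexamers over A/C/G/T."""
    seq = seq.upper()
    counts: dict[str, int] = {}
    for i in range(0, len(seq) - 5, step):
        hexamer = seq[i : i + 6]
        if set(hexamer) <= set("ACGT"):
            counts[hexamer] = counts.get(hexamer, 0) + 1
    return counts


def build_hexamer_table(
    coding_seqs: list[str], noncoding_seqs: list[str], pseudocount: float = 1.0
) -> dict[str, float]:
    """Log-ratio table ``log(f_coding / f_noncoding)`` over all 4096 hexamers,
    pseudo-count smoothed so every entry is finite."""
    def freqs(seqs: list[str]) -> dict[str, float]:
        counts = {h: pseudocount for h in ALL_HEXAMERS}
        for s in seqs:
            for h, c in count_hexamers(s).items():
                counts[h] += c
        total = sum(counts.values())
        return {h: c / total for h, c in counts.items()}

    fc, fn = freqs(coding_seqs), freqs(noncoding_seqs)
    return {h: math.log(fc[h] / fn[h]) for h in ALL_HEXAMERS}


def hexamer_score(seq: str, table: dict[str, float]) -> float:
    """Mean log coding/noncoding frequency ratio over in-frame hexamers;
    0.0 for sequences with no scorable hexamer."""
    counts = count_hexamers(seq)
    n = sum(counts.values())
    if n == 0:
        return 0.0
    return sum(table[h] * c for h, c in counts.items()) / n


# ---------------------------------------------------------------------------
# Classifier

@dataclass
class CodingPotentialScore:
    transcript_id: str
    fickett: float
    hexamer: float
    orf_len: int
    orf_coverage: float
    coding_probability: float
    label: str  # "coding" | "noncoding"


class CodingPotentialClassifier(BaseEstimator, ClassifierMixin):
    """Logistic coding/noncoding classifier over sequence-intrinsic features.

    Features per sequence: Fickett TESTCODE score, mean in-frame hexamer
    log-ratio, longest-ORF length (nt) and ORF coverage (ORF length over
    transcript length).  The hexamer table is estimated from the training
    sequences themselves with +1 smoothing.

    Parameters
    ----------
    cutoff : float, default 0.5
        Coding-probability decision threshold: ``label = coding`` iff
        probability >= cutoff.
    random_state : int or None
        Seed recorded for reproducibility of the fit.
    """

    def __init__(self, cutoff: float = 0.5, random_state: int | None = None):
        self.cutoff = cutoff
        self.random_state = random_state

    # -- feature extraction -------------------------------------------------
    def _features(self, seqs: list[str]) -> np.ndarray:
        rows = []
        for s in seqs:
            orf = longest_orf(s)
            rows.append(
                [
                    fickett_score(s),
                    hexamer_score(s, self.hexamer_table_),
                    float(orf),
                    orf / len(s) if len(s) else 0.0,
                ]
            )
        return np.asarray(rows, dtype=float)

    # -- estimator protocol -------------------------------------------------
    def fit(self, X: list[str], y) -> "CodingPotentialClassifier":
        """Fit from sequences ``X`` and labels ``y`` (1 = coding, 0 = noncoding)."""
        y = np.asarray(y, dtype=int)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        coding = [s for s, lab in zip(X, y) if lab == 1]
        noncoding = [s for s, lab in zip(X, y) if lab == 0]
        if len(coding) < 2 or len(noncoding) < 2:
            raise ValueError("need >= 2 sequences per class to fit")
        self.hexamer_table_ = build_hexamer_table(coding, noncoding)
        feats = self._features(list(X))
        self.feature_means_ = feats.mean(axis=0)
        self.feature_scales_ = feats.std(axis=0)
        self.feature_scales_[self.feature_scales_ == 0] = 1.0
        z = (feats - self.feature_means_) / self.feature_scales_
        lr = LogisticRegression(  # unpenalized maximum likelihood
            C=np.inf, solver="lbfgs", max_iter=2000, random_state=self.random_state
        )
        lr.fit(z, y)
        self.coef_ = lr.coef_.ravel()
        self.intercept_ = float(lr.intercept_[0])
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X: list[str]) -> np.ndarray:
        check_is_fitted(self, "coef_")
        feats = self._features(list(X))
        z = (feats - self.feature_means_) / self.feature_scales_
        logits = z @ self.coef_ + self.intercept_
        p = 1.0 / (1.0 + np.exp(-np.clip(logits, -700, 700)))
        p = np.clip(p, 1e-12, 1.0 - 1e-12)  # keep cutoff=1.0 a no-op filter
        return np.column_stack([1.0 - p, p])

    def predict(self, X: list[str]) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= self.cutoff).astype(int)

    # -- domain-facing surface ----------------------------------------------
    def score_transcripts(
        self, ids: list[str], seqs: list[str]
    ) -> list[CodingPotentialScore]:
        probs = self.predict_proba(seqs)[:, 1]
        out = []
        for tid, s, p in zip(ids, seqs, probs):
            orf = longest_orf(s)
            out.append(
                CodingPotentialScore(
                    transcript_id=tid,
                    fickett=fickett_score(s),
                    hexamer=hexamer_score(s, self.hexamer_table_),
                    orf_len=orf,
                    orf_coverage=orf / len(s) if len(s) else 0.0,
                    coding_probability=float(p),
                    label="coding" if p >= self.cutoff else "noncoding",
                )
            )
        return out


def train_coding_model(
    coding_seqs: list[str],
    noncoding_seqs: list[str],
    seed: int | None = None,
    cutoff: float = 0.5,
) -> CodingPotentialClassifier:
    """Convenience wrapper: fit a :class:`CodingPotentialClassifier` from two
    sequence sets."""
    X = list(coding_seqs) + list(noncoding_seqs)
    y = [1] * len(coding_seqs) + [0] * len(noncoding_seqs)
    return CodingPotentialClassifier(cutoff=cutoff, random_state=seed).fit(X, y)
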