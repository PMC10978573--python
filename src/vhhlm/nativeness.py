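"""Zero-shot nativeness scoring from a masked language model.

Each position of the query is masked in turn; the final-layer logit of the
observed residue, z_i, contributes exp(-z_i) and the nativeness score is the
sum over positions. Lower scores mean the sequence sits closer to the
distribution the model was trained on: a residue the model finds likely gets
a large logit and a vanishing contribution, a surprising residue a large one.

The inverse-exponent-of-logits reading is one of two defensible
interpretations of scoring sequences by aggregate positional surprise; the
pseudo-log-likelihood alternative (sum of -log p of the observed residue,
``variant="pll"``) is also provided. Both are monotone-decreasing in the
observed residue's logit; neither is claimed to be byte-identical to any
published implementation.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io import AMINO_ACIDS, SequenceRecord
from .lm import MaskedLanguageModel

logger = logging.getLogger("vhhlm")

_AA_IDX = {a: i for i, a in enumerate(AMINO_ACIDS)}


@dataclasses.dataclass
class NativenessScore:
    id: str
    score: float
    per_position: list[float]
    length: int

    @property
    def per_residue(self) -> float:
        return self.score / self.length if self.length else float("nan")


def nativeness_score(model: MaskedLanguageModel, seq: SequenceRecord | str,
                     variant: str = "inverse_exponent",
                     normalize: bool = False) -> NativenessScore:
    """Score one sequence; lower = more native to the model's training corpus.

    ``variant="inverse_exponent"``: sum_i exp(-z_i) of observed-residue
    logits under per-position masking. ``variant="pll"``: sum_i -log p_i
    (negative pseudo-log-likelihood). Non-canonical residues are excluded
    from the sum with a warning. ``normalize`` divides by the number of
    scored positions.
    """
    rec = seq if isinstance(seq, SequenceRecord) else SequenceRecord("query", str(seq))
    s = rec.sequence
    scored = [i for i, ch in enumerate(s) if ch in _AA_IDX]
    if len(scored) < len(s):
        logger.warning("%s: %d non-canonical positions excluded from nativeness",
                       rec.id, len(s) - len(scored))
    logits = model.position_logits(s, scored)  # (n, vocab)
    contribs: list[float] = []
    for row, i in zip(logits, scored):
        z = row[_AA_IDX[s[i]]]
        if variant == "inverse_exponent":
            contribs.append(float(np.exp(-z)))
        elif variant == "pll":
            res = row[:20]
            res = res - res.max()
            p = np.exp(res)
            p /= p.sum()
            contribs.append(float(-np.log(p[_AA_IDX[s[i]]])))
        else:
            raise ValueError(f"unknown variant {variant!r}")
    total = float(sum(contribs))
    if normalize and contribs:
        total /= len(contribs)
    return NativenessScore(id=rec.id, score=total, per_position=contribs,
                           length=len(scored))


def ranking_auc(native_scores: np.ndarray, foreign_scores: np.ndarray) -> float:
    """P(random native scores LOWER than random foreign), ties count half."""
    native = np.asarray(native_scores, dtype=float)
    foreign = np.asarray(foreign_scores, dtype=float)
    less = (native[:, None] < foreign[None, :]).sum()
    ties = (native[:, None] == foreign[None, :]).sum()
    return float((less + 0.5 * ties) / (native.size * foreign.size))


@dataclasses.dataclass
class SeparationResult:
    native_scores: np.ndarray
    foreign_scores: dict[str, np.ndarray]
    auc: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"set": "native", "score": s} for s in self.native_scores]
        for name, scores in self.foreign_scores.items():
            rows += [{"set": name, "score": s} for s in scores]
        return pd.DataFrame(rows)


def separation_experiment(model: MaskedLanguageModel,
                          native_set: list[SequenceRecord | str],
                          foreign_sets: dict[str, list],
                          variant: str = "inverse_exponent",
                          normalize: bool = False) -> SeparationResult:
    """Score a native set against foreign sets and report ranking AUCs.

    AUC is the probability that a random native sequence scores lower than a
    random foreign one (1 = perfect separation, 0.5 = none).
    """
    if not native_set or any(not v for v in foreign_sets.values()):
        raise ValueError("all sequence sets must be non-empty")
    native = np.array([nativeness_score(model, s, variant, normalize).score
                       for s in native_set])
    foreign: dict[str, np.ndarray] = {}
    auc: dict[str, float] = {}
    for name, seqs in foreign_sets.items():
        foreign[name] = np.array([nativeness_score(model, s, variant, normalize).score
                                  for s in seqs])
        auc[name] = ranking_auc(native, foreign[name])
    return SeparationResult(native_scores=native, foreign_scores=foreign, auc=auc)


class NativenessScorer(BaseEstimator):
    """Estimator wrapper: ``fit`` trains (or adopts) an MLM, ``score_samples``
    returns nativeness scores (lower = more native, matching the convention
    of the underlying statistic; note sklearn outlier APIs use the opposite
    sign convention)."""

    def __init__(self, model: MaskedLanguageModel | None = None,
                 variant: str = "inverse_exponent", normalize: bool = False,
                 **mlm_params):
        self.model = model
        self.variant = variant
        self.normalize = normalize
        self.mlm_params = mlm_params

    def fit(self, X, y=None) -> "NativenessScorer":
        if self.model is not None:
            self.model_ = self.model
        else:
            self.model_ = MaskedLanguageModel(**self.mlm_params).fit(X)
        return self

    def score_samples(self, X) -> np.ndarray:
        return np.array([nativeness_score(self.model_, x, self.variant,
                                          self.normalize).score for x in X])
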