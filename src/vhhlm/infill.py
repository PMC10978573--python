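"""Positional infilling benchmark.

Every position of a test sequence is obscured one at a time; a predictor
returns a residue distribution and the top prediction is compared with the
true residue. Accuracies are aggregated per IMGT-defined region — each of
FW1-4 and CDR1-3, plus the composites V (all positions), FW (all frameworks)
and CDRs (all loops) — first per sequence (matches divided by the region's
length in that sequence), then averaged unweighted across sequences.

A context-free PSSM baseline predictor is provided: it looks up the residue
distribution for a position's IMGT label and ignores everything else in the
sequence, which is exactly the information a gene-based mutational map
offers. The contrast between it and the masked LM quantifies the value of
sequence context.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .io import AMINO_ACIDS, SequenceRecord
from .numbering import (CDR_REGIONS, FRAMEWORK_REGIONS, REGIONS,
                        GermlineScaffold, NumberedSequence, UnnumberableError,
                        number_sequence, parse_label)
from .pssm import Pssm

logger = logging.getLogger("vhhlm")

#: reporting order: composites first, then individual regions
REPORT_REGIONS: tuple[str, ...] = ("V", "FW", "CDRs", "CDR3") + REGIONS


@dataclasses.dataclass
class PositionPrediction:
    """Ranked residue prediction at one obscured position."""

    index: int
    true_residue: str
    ranked_residues: str  # 20 residues, most probable first; ties alphabetical
    probabilities: np.ndarray  # (20,), order = alphabetical residues, sums to 1

    @property
    def top(self) -> str:
        return self.ranked_residues[0]

    @property
    def is_match(self) -> bool:
        return self.top == self.true_residue

    @property
    def is_tie(self) -> bool:
        p = self.probabilities
        top = p.max()
        return int((p == top).sum()) > 1


def _rank(probabilities: np.ndarray) -> str:
    """Residues ordered by probability, alphabetical tie-break (stable sort)."""
    order = np.lexsort((np.arange(20), -probabilities))
    return "".join(AMINO_ACIDS[i] for i in order)


def infill_sequence(predictor, seq: SequenceRecord | str) -> list[PositionPrediction]:
    """Obscure each position in turn and record the predictor's distribution.

    ``predictor`` is either a callable ``(sequence, position) -> (20,)
    probability vector`` or an object with ``predict_all_positions(sequence)``
    returning an (L, 20) matrix (one batched pass — much faster for the
    transformer).
    """
    s = seq.sequence if isinstance(seq, SequenceRecord) else str(seq)
    if hasattr(predictor, "predict_all_positions"):
        matrix = np.asarray(predictor.predict_all_positions(s))
    else:
        rows = []
        for i in range(len(s)):
            try:
                rows.append(np.asarray(predictor(s, i)))
            except Exception as exc:
                raise RuntimeError(f"predictor failed at position {i} of "
                                   f"sequence {s[:12]}...: {exc}") from exc
        matrix = np.stack(rows)
    preds = []
    for i, res in enumerate(s):
        p = matrix[i]
        total = p.sum()
        if not np.isclose(total, 1.0, atol=1e-6):
            p = p / total
        preds.append(PositionPrediction(index=i, true_residue=res,
                                        ranked_residues=_rank(p),
                                        probabilities=p))
    return preds


def region_accuracy(preds: list[PositionPrediction], ns: NumberedSequence
                    ) -> dict[str, float]:
    """Top-prediction match rate per region for one sequence.

    Composites: V over all positions, FW over FW1-4, CDRs over CDR1-3.
    Regions with zero positions in this sequence are omitted.
    """
    if len(preds) != len(ns.sequence):
        raise ValueError(f"{len(preds)} predictions for a length-{len(ns.sequence)} "
                         "numbered sequence")
    matches = {r: 0 for r in REGIONS}
    lengths = {r: 0 for r in REGIONS}
    for region in REGIONS:
        for i in ns.region_indices(region):
            lengths[region] += 1
            if preds[i].is_match:
                matches[region] += 1
    out: dict[str, float] = {}
    groups = {"V": REGIONS, "FW": FRAMEWORK_REGIONS, "CDRs": CDR_REGIONS}
    for name, members in groups.items():
        n = sum(lengths[r] for r in members)
        if n:
            out[name] = sum(matches[r] for r in members) / n
    for region in REGIONS:
        if lengths[region]:
            out[region] = matches[region] / lengths[region]
    return out


@dataclasses.dataclass
class InfillReport:
    """Per-sequence and mean per-region infilling accuracies."""

    per_sequence: dict[str, dict[str, float]]
    mean_per_region: dict[str, float]
    n_sequences: int
    n_skipped: int = 0
    n_ties: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [{"region": r, "mean_accuracy": v,
                 "n_sequences": sum(1 for acc in self.per_sequence.values() if r in acc)}
                for r, v in self.mean_per_region.items()]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def benchmark(predictor, dataset: list[SequenceRecord],
              scaffolds: list[GermlineScaffold]) -> InfillReport:
    """Run the infilling benchmark over a test set.

    Unnumberable sequences are skipped and counted. Mean accuracies are
    unweighted means over sequences in which the region is non-empty.
    """
    if not dataset:
        raise ValueError("dataset is empty")
    per_sequence: dict[str, dict[str, float]] = {}
    n_skipped = n_ties = 0
    for rec in dataset:
        try:
            ns = number_sequence(rec, scaffolds)
        except UnnumberableError as exc:
            logger.warning("skipping %s: %s", rec.id, exc)
            n_skipped += 1
            continue
        preds = infill_sequence(predictor, rec)
        n_ties += sum(p.is_tie for p in preds)
        per_sequence[rec.id] = region_accuracy(preds, ns)
    if not per_sequence:
        raise ValueError("all sequences were unnumberable")
    mean_per_region: dict[str, float] = {}
    for region in REPORT_REGIONS:
        vals = [acc[region] for acc in per_sequence.values() if region in acc]
        if vals:
            mean_per_region[region] = float(np.mean(vals))
    return InfillReport(per_sequence=per_sequence, mean_per_region=mean_per_region,
                        n_sequences=len(per_sequence), n_skipped=n_skipped,
                        n_ties=n_ties)


class PssmPredictor:
    """Context-free baseline: the PSSM row for the position's IMGT label.

    The query is numbered once; positions whose label has no PSSM row fall
    back to a uniform distribution. PSSM position keys are matched on the
    full label first, then on the base position (so insertions share their
    anchor's row).
    """

    def __init__(self, pssm: Pssm, scaffolds: list[GermlineScaffold] | None = None):
        self.pssm = pssm
        self.scaffolds = scaffolds
        self._index = pssm.index

    def _labels(self, seq: str) -> list[str]:
        if self.scaffolds is None:
            # positions are plain 1-based indices (unaligned corpora)
            return [str(i + 1) for i in range(len(seq))]
        ns = number_sequence(seq, self.scaffolds)
        return ns.labels()

    def predict_all_positions(self, seq: str) -> np.ndarray:
        labels = self._labels(seq)
        out = np.full((len(seq), 20), 1.0 / 20.0)
        for i, lab in enumerate(labels):
            row = self._index.get(lab)
            if row is None:
                base, _ = parse_label(lab)
                row = self._index.get(str(base))
            if row is not None:
                out[i] = self.pssm.matrix[row]
        return out

    def __call__(self, seq: str, position: int) -> np.ndarray:
        return self.predict_all_positions(seq)[position]


def pssm_predictor(pssm: Pssm, scaffolds: list[GermlineScaffold] | None = None
                   ) -> PssmPredictor:
    """Functional alias for :class:`PssmPredictor`."""
    return PssmPredictor(pssm, scaffolds)
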