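"""Germline assignment diagnostics and PSSM construction.

Implements the analysis that motivates gene-agnostic language modeling:
assign each sequence to its closest germline by framework identity, tabulate
gene frequencies, and profile the FW2+FW3 clone landscape as a function of
edit distance to the modal (germline-proxy) clone. A clean, single-germline
repertoire yields a unimodal curve descending from the mode; density bumps
farther out indicate unassigned or missing germlines — the failure mode that
makes gene-based PSSMs unreliable for nanobodies.
"""

from __future__ import annotations

import dataclasses
import logging
from collections import Counter

import edlib
import numpy as np
import pandas as pd

from .io import AMINO_ACIDS, SequenceRecord
from .numbering import (FRAMEWORK_REGIONS, GermlineScaffold, NumberedSequence,
                        UnnumberableError, number_sequence, parse_label,
                        region_of)
from .pssm import AA_INDEX, Pssm

logger = logging.getLogger("vhhlm")


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (substitutions, insertions, deletions)."""
    if not a or not b:
        return max(len(a), len(b))
    return int(edlib.align(a, b, mode="NW", task="distance")["editDistance"])


@dataclasses.dataclass
class GeneAssignment:
    id: str
    gene_id: str
    framework_identity: float
    tie: bool = False


def assign_gene(ns: NumberedSequence, germlines: list[GermlineScaffold]
                ) -> GeneAssignment:
    """Closest germline by identity over the germline's framework positions.

    Sequences lacking FW2 or FW3 raise :class:`UnnumberableError` (callers
    count and skip them). Ties are broken by gene_id order and flagged.
    """
    if not ns.extract_region("FW2") or not ns.extract_region("FW3"):
        raise UnnumberableError(f"{ns.record.id}: missing FW2/FW3 data")
    residues = {lab: res for res, lab in ns.positions}
    best: tuple[float, str] | None = None
    tie = False
    for sc in sorted(germlines, key=lambda g: g.gene_id):
        matches = total = 0
        for res, pos in zip(sc.sequence, sc.imgt_numbers):
            if region_of(pos) not in FRAMEWORK_REGIONS:
                continue
            total += 1
            if residues.get(str(pos)) == res:
                matches += 1
        ident = matches / total if total else 0.0
        if best is None or ident > best[0]:
            best = (ident, sc.gene_id)
            tie = False
        elif ident == best[0]:
            tie = True
    return GeneAssignment(id=ns.record.id, gene_id=best[1],
                          framework_identity=best[0], tie=tie)


def gene_frequency_table(assignments: list[GeneAssignment]) -> dict[str, float]:
    """Gene usage as percentages (summing to 100)."""
    if not assignments:
        raise ValueError("no assignments")
    counts = Counter(a.gene_id for a in assignments)
    n = len(assignments)
    return {gene: 100.0 * c / n for gene, c in counts.most_common()}


@dataclasses.dataclass
class DistanceCurve:
    """Frequency-by-edit-distance profile of FW2+FW3 clones.

    ``points`` rows: (distance, total_frequency of all chains at that
    distance, frequency of the most frequent unique clone at that distance).
    Total frequencies sum to 1 over distances; the top-clone series is
    pointwise bounded by the total series.
    """

    gene_id: str
    modal_fw23: str
    points: list[tuple[int, float, float]]
    modal_tie: bool = False

    def distances(self) -> list[int]:
        return [d for d, _, _ in self.points]

    def total_frequencies(self) -> list[float]:
        return [t for _, t, _ in self.points]

    def top_clone_frequencies(self) -> list[float]:
        return [c for _, _, c in self.points]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points,
                            columns=["distance", "total_frequency",
                                     "top_clone_frequency"]).assign(gene=self.gene_id)


def fw23_clone(ns: NumberedSequence) -> str:
    """Concatenated FW2+FW3 sequence, the clone unit of the distance analysis."""
    return ns.extract_region("FW2") + ns.extract_region("FW3")


def distance_curve(numbered: list[NumberedSequence], gene_id: str = "all"
                   ) -> DistanceCurve:
    """Profile FW2+FW3 clones by edit distance to the modal clone.

    The modal clone stands in for the germline (the most abundant FW2+FW3
    sequence under correct assignment); ties for the mode are resolved to the
    lexicographically smallest clone and flagged.
    """
    clones = [fw23_clone(ns) for ns in numbered
              if ns.extract_region("FW2") and ns.extract_region("FW3")]
    if not clones:
        raise ValueError("no records with FW2 and FW3 data")
    counts = Counter(clones)
    top_count = max(counts.values())
    modal_candidates = sorted(c for c, k in counts.items() if k == top_count)
    modal = modal_candidates[0]
    n = len(clones)
    by_distance: dict[int, list[tuple[str, int]]] = {}
    for clone, k in counts.items():
        d = levenshtein(clone, modal)
        by_distance.setdefault(d, []).append((clone, k))
    points = []
    for d in sorted(by_distance):
        members = by_distance[d]
        total = sum(k for _, k in members) / n
        top = max(k for _, k in members) / n
        points.append((d, total, top))
    return DistanceCurve(gene_id=gene_id, modal_fw23=modal, points=points,
                         modal_tie=len(modal_candidates) > 1)


def build_pssm(numbered: list[NumberedSequence], label: str = "corpus",
               pseudocount: float = 0.0) -> Pssm:
    """Per-IMGT-position residue frequencies from numbered records.

    Positions observed in no record get no row. ``pseudocount`` adds
    add-``k`` smoothing (off by default).
    """
    if not numbered:
        raise ValueError("no numbered records")
    counts: dict[str, np.ndarray] = {}
    for ns in numbered:
        for res, lab in ns.positions:
            if res not in AA_INDEX:
                continue
            row = counts.setdefault(lab, np.zeros(20))
            row[AA_INDEX[res]] += 1

    def sort_key(lab: str):
        base, ins = parse_label(lab)
        return (base, ins)

    positions = sorted(counts, key=sort_key)
    matrix = np.stack([counts[p] + pseudocount for p in positions])
    support = np.array([int(counts[p].sum()) for p in positions])
    matrix = matrix / matrix.sum(axis=1, keepdims=True)
    return Pssm(label=label, positions=positions, matrix=matrix, support=support)


def closest_human_mismatches(ns: NumberedSequence,
                             human_germlines: list[GermlineScaffold]
                             ) -> list[tuple[int, str, str]]:
    """Framework mismatches against the closest (human) germline.

    CDRs are treated as grafted and excluded. Returns (IMGT position, query
    residue, germline residue) sorted by position; '-' marks a position
    absent from the query.
    """
    assignment = assign_gene(ns, human_germlines)
    scaffold = next(g for g in human_germlines if g.gene_id == assignment.gene_id)
    residues = {lab: res for res, lab in ns.positions}
    mismatches = []
    for res, pos in zip(scaffold.sequence, scaffold.imgt_numbers):
        if region_of(pos) not in FRAMEWORK_REGIONS:
            continue
        q = residues.get(str(pos), "-")
        if q != res:
            mismatches.append((pos, q, res))
    return mismatches


def number_all(records: list[SequenceRecord], scaffolds: list[GermlineScaffold]
               ) -> tuple[list[NumberedSequence], int]:
    """Number a repertoire, skipping (and counting) unnumberable sequences."""
    numbered, skipped = [], 0
    for rec in records:
        try:
            numbered.append(number_sequence(rec, scaffolds))
        except UnnumberableError as exc:
            logger.warning("skipping %s: %s", rec.id, exc)
            skipped += 1
    return numbered, skipped
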