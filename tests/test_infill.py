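"""Infilling harness: oracle bounds, hand-built fixtures, PSSM baseline."""

import numpy as np
import pytest

from vhhlm.infill import (PssmPredictor, benchmark, infill_sequence,
                          region_accuracy)
from vhhlm.io import AMINO_ACIDS, SequenceRecord
from vhhlm.numbering import number_sequence
from vhhlm.pssm import Pssm


def oracle_predictor(seq: str, pos: int) -> np.ndarray:
    """Peeks at the true residue: upper bound of the benchmark."""
    p = np.zeros(20)
    p[AMINO_ACIDS.index(seq[pos])] = 1.0
    return p


def adversarial_predictor(seq: str, pos: int) -> np.ndarray:
    """Uniform over the 19 wrong residues: lower bound (zero matches)."""
    p = np.full(20, 1 / 19)
    p[AMINO_ACIDS.index(seq[pos])] = 0.0
    return p


def test_oracle_predictor_matches_everywhere(scaffolds_a):
    seq = scaffolds_a[0].sequence
    preds = infill_sequence(oracle_predictor, seq)
    assert all(p.is_match for p in preds)
    ns = number_sequence(seq, scaffolds_a)
    acc = region_accuracy(preds, ns)
    assert all(v == 1.0 for v in acc.values())


def test_adversarial_predictor_never_matches(scaffolds_a):
    seq = scaffolds_a[0].sequence
    preds = infill_sequence(adversarial_predictor, seq)
    assert not any(p.is_match for p in preds)


def test_hand_built_mock_fixture():
    """Length-5 toy with hand-specified distributions; matches counted by hand."""
    seq = "ACDEF"
    table = {
        0: "A",  # match
        1: "D",  # miss (true C)
        2: "D",  # match
        3: "A",  # miss (true E)
        4: "F",  # match
    }

    def mock(s, i):
        p = np.full(20, 0.01)
        p[AMINO_ACIDS.index(table[i])] = 1 - 0.19
        return p / p.sum()

    preds = infill_sequence(mock, seq)
    assert [p.is_match for p in preds] == [True, False, True, False, True]
    assert [p.top for p in preds] == list("ADDAF")


def test_ranking_breaks_ties_alphabetically():
    p = np.zeros(20)
    ia, ig = AMINO_ACIDS.index("A"), AMINO_ACIDS.index("G")
    p[ia] = p[ig] = 0.5
    preds = infill_sequence(lambda s, i: p, "G")
    assert preds[0].ranked_residues[:2] == "AG"
    assert preds[0].is_tie and not preds[0].is_match  # A beats G on the tie


def test_region_accuracy_arithmetic(scaffolds_a):
    seq = scaffolds_a[0].sequence
    ns = number_sequence(seq, scaffolds_a)
    fw1 = ns.region_indices("FW1")

    def fw1_only(s, i):  # matches exactly inside FW1, misses elsewhere
        return oracle_predictor(s, i) if i in fw1 else adversarial_predictor(s, i)

    acc = region_accuracy(infill_sequence(fw1_only, seq), ns)
    assert acc["FW1"] == 1.0
    assert acc["CDRs"] == 0.0
    assert acc["V"] == pytest.approx(len(fw1) / len(seq))
    assert acc["FW"] == pytest.approx(len(fw1) / sum(
        len(ns.region_indices(r)) for r in ("FW1", "FW2", "FW3", "FW4")))


def test_benchmark_means_are_unweighted(scaffolds_a):
    recs = [SequenceRecord("full_match", scaffolds_a[0].sequence),
            SequenceRecord("no_match", scaffolds_a[1].sequence)]

    def half_oracle(s, i):
        if s == scaffolds_a[0].sequence:
            return oracle_predictor(s, i)
        return adversarial_predictor(s, i)

    report = benchmark(half_oracle, recs, scaffolds_a)
    assert report.mean_per_region["V"] == pytest.approx(0.5)
    assert report.n_sequences == 2 and report.n_skipped == 0


def test_benchmark_skips_unnumberable(scaffolds_a):
    recs = [SequenceRecord("ok", scaffolds_a[0].sequence),
            SequenceRecord("junk", "ACDEFGHIKLMNPQRSTVWY" * 5)]
    report = benchmark(oracle_predictor, recs, scaffolds_a)
    assert report.n_sequences == 1 and report.n_skipped == 1
    with pytest.raises(ValueError, match="unnumberable"):
        benchmark(oracle_predictor, [recs[1]], scaffolds_a)


def test_brute_force_oracle_equivalence(scaffolds_a):
    """The report equals an explicit position-by-position recount."""
    rng = np.random.default_rng(12)
    frozen = {}

    def frozen_mock(s, i):
        key = (s, i)
        if key not in frozen:
            v = rng.dirichlet(np.ones(20) * 0.3)
            frozen[key] = v
        return frozen[key]

    recs = [SequenceRecord(f"r{k}", sc.sequence)
            for k, sc in enumerate(scaffolds_a)]
    report = benchmark(frozen_mock, recs, scaffolds_a)

    for rec in recs:
        ns = number_sequence(rec, scaffolds_a)
        # independent recount
        for region, acc in report.per_sequence[rec.id].items():
            if region == "V":
                idx = range(len(rec.sequence))
            elif region == "FW":
                idx = [i for r in ("FW1", "FW2", "FW3", "FW4")
                       for i in ns.region_indices(r)]
            elif region == "CDRs":
                idx = [i for r in ("CDR1", "CDR2", "CDR3")
                       for i in ns.region_indices(r)]
            else:
                idx = ns.region_indices(region)
            matches = 0
            for i in idx:
                probs = frozen_mock(rec.sequence, i)
                order = np.lexsort((np.arange(20), -probs))
                matches += AMINO_ACIDS[order[0]] == rec.sequence[i]
            assert acc == pytest.approx(matches / len(list(idx)))


def test_pssm_predictor_is_context_free(scaffolds_a):
    sc = scaffolds_a[0]
    m = np.full((len(sc.sequence), 20), 1e-3)
    for i, res in enumerate(sc.sequence):
        m[i, AMINO_ACIDS.index(res)] = 1.0
    m /= m.sum(axis=1, keepdims=True)
    pssm = Pssm("g", [str(p) for p in sc.imgt_numbers], m)
    pred = PssmPredictor(pssm, scaffolds_a)
    other = scaffolds_a[3].sequence
    p1 = pred(sc.sequence, 2)
    p2 = pred(other, 2)
    np.testing.assert_array_equal(p1, p2)  # ignores sequence content


def test_pssm_predictor_uniform_fallback(scaffolds_a):
    pssm = Pssm("one", ["1"], np.full((1, 20), 0.05))
    pred = PssmPredictor(pssm, scaffolds_a)
    p = pred(scaffolds_a[0].sequence, 50)
    np.testing.assert_allclose(p, 0.05)
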