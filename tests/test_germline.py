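"""Germline assignment, edit distances, distance curves, PSSM construction."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vhhlm.germline import (assign_gene, build_pssm, closest_human_mismatches,
                            distance_curve, gene_frequency_table, levenshtein,
                            number_all)
from vhhlm.io import SequenceRecord
from vhhlm.numbering import HALLMARK_POSITIONS, number_sequence
from vhhlm.simulate import Cdr3Config, ShmConfig, simulate_repertoire


def dp_levenshtein(a: str, b: str) -> int:
    """Independent quadratic DP oracle."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def test_levenshtein_known_cases():
    assert levenshtein("KITTEN", "SITTING") == 3
    assert levenshtein("", "ABC") == 3
    assert levenshtein("ABC", "") == 3
    assert levenshtein("SAME", "SAME") == 0


def test_levenshtein_exhaustive_against_dp_oracle():
    words = ["".join(w) for k in range(4) for w in itertools.product("AG", repeat=k)]
    for a in words:
        for b in words:
            assert levenshtein(a, b) == dp_levenshtein(a, b)


@settings(deadline=None, derandomize=True, max_examples=80)
@given(st.text(alphabet="ACGT", max_size=10), st.text(alphabet="ACGT", max_size=10),
       st.text(alphabet="ACGT", max_size=10))
def test_levenshtein_is_a_metric(a, b, c):
    assert levenshtein(a, b) == levenshtein(b, a)
    assert (levenshtein(a, b) == 0) == (a == b)
    assert levenshtein(a, c) <= levenshtein(a, b) + levenshtein(b, c)


def test_assign_gene_identity_and_mutation(scaffolds_a):
    sc = scaffolds_a[2]
    ns = number_sequence(sc.sequence, scaffolds_a)
    a = assign_gene(ns, scaffolds_a)
    assert a.gene_id == sc.gene_id and a.framework_identity == 1.0
    # one framework substitution keeps the assignment, drops identity below 1
    i = sc.imgt_numbers.index(70)
    mutated = sc.sequence[:i] + ("W" if sc.sequence[i] != "W" else "Y") \
        + sc.sequence[i + 1:]
    a2 = assign_gene(number_sequence(mutated, scaffolds_a), scaffolds_a)
    assert a2.gene_id == sc.gene_id and a2.framework_identity < 1.0


def test_equidistant_chimera_tie_flagged(scaffolds_a):
    """A sequence exactly between two genes goes to the first id and is flagged."""
    g1, g2 = scaffolds_a[0], scaffolds_a[1]
    # the two genes differ at framework positions 1 and 84 (by construction);
    # take g1 at one, g2 at the other -> equidistant
    chars = list(g1.sequence)
    chars[g1.imgt_numbers.index(84)] = g2.residue_at(84)
    ns = number_sequence("".join(chars), scaffolds_a)
    a = assign_gene(ns, scaffolds_a)
    assert a.tie
    assert a.gene_id == min(g1.gene_id, g2.gene_id)


def test_gene_frequency_table(scaffolds_a):
    single = [assign_gene(number_sequence(scaffolds_a[0].sequence, scaffolds_a),
                          scaffolds_a)] * 4
    assert gene_frequency_table(single) == {"VHH-1": 100.0}
    with pytest.raises(ValueError):
        gene_frequency_table([])


def test_gene_frequencies_recover_mixing_weights(scaffolds_a):
    """Multinomial recovery of simulator weights within 3 sigma at n=1000."""
    weights = [0.7, 0.2, 0.1, 0.0, 0.0]
    recs = simulate_repertoire(scaffolds_a, ShmConfig(base_rate=0.01, seed=6),
                               Cdr3Config(seed=6), 1000, seed=8, weights=weights)
    numbered, _ = number_all(recs, scaffolds_a)
    freqs = gene_frequency_table([assign_gene(ns, scaffolds_a) for ns in numbered])
    for sc, w in zip(scaffolds_a, weights):
        got = freqs.get(sc.gene_id, 0.0) / 100.0
        sigma = np.sqrt(w * (1 - w) / 1000)
        assert abs(got - w) <= max(3 * sigma, 0.01)


def test_distance_curve_zero_rate_is_a_point_mass(scaffolds_a):
    recs = simulate_repertoire([scaffolds_a[0]], ShmConfig(base_rate=0.0, seed=0),
                               Cdr3Config(seed=0), 50, seed=1)
    numbered, _ = number_all(recs, scaffolds_a)
    curve = distance_curve(numbered)
    assert curve.points == [(0, 1.0, 1.0)]
    assert curve.modal_fw23 == scaffolds_a[0].region_string("FW2") \
        + scaffolds_a[0].region_string("FW3")


def test_distance_curve_mass_conservation(scaffolds_a, small_repertoire):
    numbered, _ = number_all(small_repertoire, scaffolds_a)
    curve = distance_curve(numbered)
    assert sum(curve.total_frequencies()) == pytest.approx(1.0)
    for _, total, top in curve.points:
        assert top <= total + 1e-12


def test_build_pssm_point_mass_and_row_omission(scaffolds_a):
    ns = number_sequence(scaffolds_a[0].sequence, scaffolds_a)
    pssm = build_pssm([ns, ns, ns])
    assert len(pssm.positions) == len(scaffolds_a[0].sequence)
    assert np.allclose(pssm.matrix.max(axis=1), 1.0)  # point masses
    assert "33" not in pssm.positions  # a CDR1 position absent from the scaffold


def test_build_pssm_recovers_generating_frequencies(scaffolds_a):
    recs = simulate_repertoire([scaffolds_a[0]], ShmConfig(base_rate=0.1, seed=9),
                               Cdr3Config(seed=9), 2000, seed=10)
    numbered, _ = number_all(recs, scaffolds_a)
    pssm = build_pssm(numbered)
    # germline residue remains modal at ~90% at framework positions
    sc = scaffolds_a[0]
    row = pssm.row("20")
    from vhhlm.io import AMINO_ACIDS
    top = AMINO_ACIDS[int(np.argmax(row))]
    assert top == sc.residue_at(20)
    assert 0.85 <= row.max() <= 0.95


def test_closest_human_mismatches(scaffolds_a, scaffolds_b):
    humans = scaffolds_b
    ns_self = number_sequence(humans[0].sequence, humans)
    assert closest_human_mismatches(ns_self, humans) == []
    # a VHH germline accumulates mismatches at the FW2 hallmarks
    ns_vhh = number_sequence(scaffolds_a[0].sequence, scaffolds_a)
    positions = {p for p, _, _ in closest_human_mismatches(ns_vhh, humans)}
    assert set(HALLMARK_POSITIONS) <= positions
    # single engineered FW3 substitution -> exactly one mismatch
    sc = humans[0]
    i = sc.imgt_numbers.index(80)
    engineered = sc.sequence[:i] + ("K" if sc.sequence[i] != "K" else "R") \
        + sc.sequence[i + 1:]
    ns_e = number_sequence(engineered, humans)
    mm = closest_human_mismatches(ns_e, humans)
    assert len(mm) == 1 and mm[0][0] == 80
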