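"""Repertoire simulator: SHM statistics, CDR3 resampling, property model."""

import numpy as np
import pytest

from vhhlm.numbering import REGION_BOUNDS, number_sequence
from vhhlm.simulate import (Cdr3Config, PropertyModel, ShmConfig,
                            default_property_model, make_species_pair,
                            simulate_property, simulate_repertoire,
                            uniform_substitution_matrix)

FIXED_CDR3 = Cdr3Config(length_distribution={9: 1.0},
                        composition={"G": 1.0}, seed=0)


def test_zero_rate_reproduces_germline_frameworks(scaffolds_a):
    recs = simulate_repertoire(scaffolds_a, ShmConfig(base_rate=0.0, seed=0),
                               FIXED_CDR3, 10, seed=1)
    for rec in recs:
        sc = next(s for s in scaffolds_a if s.gene_id == rec.germline_gene)
        lo, hi = REGION_BOUNDS["CDR3"]
        expected = "".join(r for r, p in zip(sc.sequence, sc.imgt_numbers)
                           if p < lo) + "G" * 9 \
            + "".join(r for r, p in zip(sc.sequence, sc.imgt_numbers) if p > hi)
        assert rec.sequence == expected
        assert rec.n_mutations == 0


def test_same_seed_gives_identical_repertoires(scaffolds_a):
    kw = dict(n=25, seed=7)
    r1 = simulate_repertoire(scaffolds_a, ShmConfig(seed=1), Cdr3Config(seed=1), **kw)
    r2 = simulate_repertoire(scaffolds_a, ShmConfig(seed=1), Cdr3Config(seed=1), **kw)
    assert [r.sequence for r in r1] == [r.sequence for r in r2]


def test_mean_mutation_count_matches_binomial(scaffolds_a):
    """Flat rate 0.02, no hotspots: mean mutations within 3 binomial SEs."""
    n, rate = 1000, 0.02
    shm = ShmConfig(base_rate=rate, hotspot_multipliers={}, seed=2)
    recs = simulate_repertoire(scaffolds_a, shm, FIXED_CDR3, n, seed=3)
    n_sites = 117 - 9  # non-CDR3 scaffold positions
    mean = np.mean([r.n_mutations for r in recs])
    expected = rate * n_sites
    se = np.sqrt(n_sites * rate * (1 - rate) / n)
    assert abs(mean - expected) <= 3 * se


def test_hotspot_multiplier_scales_region_rate(scaffolds_a):
    """CDR1 at 4x base rate: observed ratio within 20% at n=5000."""
    shm = ShmConfig(base_rate=0.02, hotspot_multipliers={"CDR1": 4.0}, seed=4)
    recs = simulate_repertoire(scaffolds_a, shm, FIXED_CDR3, 5000, seed=5)
    cdr1_mut = fw3_mut = 0
    lo1, hi1 = REGION_BOUNDS["CDR1"]
    lo3, hi3 = REGION_BOUNDS["FW3"]
    n_cdr1 = n_fw3 = 0
    scaffold_by_gene = {s.gene_id: s for s in scaffolds_a}
    for rec in recs:
        sc = scaffold_by_gene[rec.germline_gene]
        # fixed-length CDR3 keeps record and scaffold aligned residue-for-residue
        assert len(rec.sequence) == len(sc.sequence)
        for res, ref, p in zip(rec.sequence, sc.sequence, sc.imgt_numbers):
            if lo1 <= p <= hi1:
                n_cdr1 += 1
                cdr1_mut += res != ref
            elif lo3 <= p <= hi3:
                n_fw3 += 1
                fw3_mut += res != ref
    ratio = (cdr1_mut / n_cdr1) / (fw3_mut / n_fw3)
    assert 0.8 * 4.0 <= ratio <= 1.2 * 4.0


def test_invalid_configurations_rejected(scaffolds_a):
    with pytest.raises(ValueError, match="germline"):
        simulate_repertoire([], ShmConfig(), Cdr3Config(), 5, seed=0)
    with pytest.raises(ValueError, match="sum to 1"):
        bad = uniform_substitution_matrix()
        bad[0, 1] += 0.1
        ShmConfig(substitution_matrix=bad)
    with pytest.raises(ValueError, match="diagonal"):
        m = np.full((20, 20), 1 / 20)
        ShmConfig(substitution_matrix=m)
    with pytest.raises(ValueError, match="length_distribution"):
        Cdr3Config(length_distribution={9: 0.5})
    with pytest.raises(ValueError, match=r"\[3, 30\]"):
        Cdr3Config(length_distribution={2: 1.0})


def test_property_constant_when_no_effects(scaffolds_a, small_repertoire):
    model = PropertyModel(effect_weights={}, intercept=55.0, noise_sd=0.0)
    values = simulate_property(small_repertoire[:20], model, scaffolds_a)
    assert all(v == 55.0 for _, v in values)


def test_property_single_effect_is_additive(scaffolds_a):
    recs = simulate_repertoire(scaffolds_a, ShmConfig(base_rate=0.0, seed=0),
                               FIXED_CDR3, 5, seed=2)
    # R at IMGT 50 is the species-A hallmark: every record carries it
    model = PropertyModel(effect_weights={(50, "R"): 5.0}, intercept=60.0,
                          noise_sd=0.0)
    values = simulate_property(recs, model, scaffolds_a)
    assert all(v == 65.0 for _, v in values)


def test_property_noise_sd_recovered(scaffolds_a, small_repertoire):
    """Residual SD vs noiseless values within the chi-square band at n=200."""
    recs = small_repertoire
    noisy = PropertyModel(effect_weights={}, intercept=60.0, noise_sd=2.0, seed=9)
    clean_vals = 60.0
    values = simulate_property(recs, noisy, scaffolds_a)
    resid = np.array([v for _, v in values]) - clean_vals
    assert 1.6 <= resid.std(ddof=1) <= 2.4


def test_property_weights_recovered_by_regression(scaffolds_a):
    """OLS on the true indicator features recovers effect weights (2 SE)."""
    import statsmodels.api as sm
    recs = simulate_repertoire(scaffolds_a, ShmConfig(seed=3),
                               Cdr3Config(seed=3), 300, seed=6)
    keys = [(105, "G"), (105, "Y"), (107, "W")]
    truth = {k: w for k, w in zip(keys, (3.0, -2.0, 4.0))}
    model = PropertyModel(effect_weights=truth, intercept=60.0, noise_sd=0.5,
                          seed=7)
    simulate_property(recs, model, scaffolds_a)
    rows, ys = [], []
    for rec in recs:
        ns = number_sequence(rec, scaffolds_a)
        feats = [float(ns.residue_at(p) == aa) for p, aa in keys]
        rows.append(feats)
        ys.append(rec.measurement)
    fit = sm.OLS(ys, sm.add_constant(np.array(rows))).fit()
    for i, k in enumerate(keys):
        est, se = fit.params[i + 1], fit.bse[i + 1]
        assert abs(est - truth[k]) <= 2 * se


def test_species_pair_hallmarks(scaffolds_a, scaffolds_b):
    pair = make_species_pair(1, 2)
    for sc in pair.germlines_a:
        ns = number_sequence(sc.sequence, pair.germlines_a)
        assert ns.hallmark_motif() == "FERF"
    for sc in pair.germlines_b:
        ns = number_sequence(sc.sequence, pair.germlines_b)
        assert ns.hallmark_motif() == "VGLW"
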