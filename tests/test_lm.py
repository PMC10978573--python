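"""Tokenizer, masking policy, and masked-LM estimator behavior."""

import numpy as np
import pytest

from vhhlm.lm import (PRESETS, MaskedLanguageModel, MaskPolicy, Vocabulary,
                      apply_mask, detokenize, tokenize)


@pytest.fixture(scope="module")
def vocab():
    return Vocabulary()


def test_vocabulary_layout(vocab):
    assert len(vocab) == 25
    assert vocab.tokens[:20] == list("ACDEFGHIKLMNPQRSTVWY")
    assert vocab.tokens[20:] == ["[MASK]", "[PAD]", "[CLS]", "[SEP]", "[UNK]"]


def test_tokenize_wraps_with_cls_sep(vocab):
    ids = tokenize("ACD", vocab)
    assert ids == [vocab.cls_id, 0, 1, 2, vocab.sep_id]
    assert len(ids) == 3 + 2


def test_round_trip_and_unk(vocab, caplog):
    assert detokenize(tokenize("MKVLQW", vocab), vocab) == "MKVLQW"
    with caplog.at_level("WARNING", logger="vhhlm"):
        ids = tokenize("ACZ", vocab)
    assert ids[3] == vocab.unk_id
    assert "non-canonical" in caplog.text
    with pytest.raises(ValueError):
        tokenize("", vocab)


def test_mask_policy_validation():
    with pytest.raises(ValueError, match="sum to 1"):
        MaskPolicy(replace_with_mask=0.9, replace_with_random=0.2, keep_original=0.1)


def test_apply_mask_counts_and_determinism(vocab):
    seq100 = "ACDEFGHIKL" * 10
    batch = [vocab.encode(seq100)]
    toks, labels, pad = apply_mask(batch, MaskPolicy(seed=5), vocab)
    assert int((labels >= 0).sum()) == 15  # ceil(0.15 * 100)
    toks2, labels2, _ = apply_mask(batch, MaskPolicy(seed=5), vocab)
    np.testing.assert_array_equal(toks, toks2)
    np.testing.assert_array_equal(labels, labels2)
    # short sequence still gets one label
    _, labels3, _ = apply_mask([vocab.encode("ACD")], MaskPolicy(mask_fraction=0.01),
                               vocab)
    assert int((labels3 >= 0).sum()) == 1


def test_full_masking_replaces_every_residue(vocab):
    policy = MaskPolicy(mask_fraction=1.0, replace_with_mask=1.0,
                        replace_with_random=0.0, keep_original=0.0)
    toks, labels, _ = apply_mask([vocab.encode("ACDEF")], policy, vocab)
    assert (toks[0, 1:6] == vocab.mask_id).all()
    assert (labels[0, 1:6] >= 0).all()


def test_cls_sep_pad_never_masked(vocab):
    policy = MaskPolicy(mask_fraction=1.0)
    batch = [vocab.encode("ACDEFG"), vocab.encode("AC")]
    toks, labels, _ = apply_mask(batch, policy, vocab)
    assert labels[0, 0] == -1 and labels[0, 7] == -1
    assert labels[1, 0] == -1 and labels[1, 3] == -1  # CLS/SEP of short row
    assert (labels[1, 4:] == -1).all()  # PAD region


@pytest.mark.parametrize("preset,target", [("small", 14e6), ("big", 86e6)])
def test_published_scale_parameter_budgets(preset, target):
    """The named presets land within ±30% of their published parameter counts."""
    model = MaskedLanguageModel.from_preset(preset)
    model._build()
    assert 0.7 * target <= model.n_parameters_ <= 1.3 * target
    d = PRESETS[preset][2]
    assert d in (320, 768)


@pytest.fixture(scope="module")
def memorizer():
    """Tiny model trained on a single repeated sequence."""
    seq = "QVQLVESGGGLVQAGGSLRLSCAAS"
    model = MaskedLanguageModel(n_epochs=80, batch_size=16, learning_rate=2e-3,
                                random_state=0, validation_fraction=0.1)
    model.fit([seq] * 100)
    return model, seq


def test_memorization_drives_loss_to_zero(memorizer):
    model, _ = memorizer
    trace = model.loss_trace_
    assert trace[-1]["val_loss"] < 0.1
    assert trace[-1]["train_loss"] < trace[0]["train_loss"]


def test_memorized_sequence_reconstructed_exactly(memorizer):
    model, seq = memorizer
    probs = model.predict_all_positions(seq)
    rec = "".join("ACDEFGHIKLMNPQRSTVWY"[i] for i in probs.argmax(axis=1))
    assert rec == seq


def test_predict_position_contract(memorizer):
    model, seq = memorizer
    p = model.predict_position(seq, 3)
    assert p.shape == (20,)
    assert p.sum() == pytest.approx(1.0, abs=1e-6)
    with pytest.raises(ValueError, match="out of range"):
        model.predict_position(seq, len(seq))


def test_untrained_model_is_near_uniform():
    model = MaskedLanguageModel(n_epochs=0, random_state=1)
    model.fit(["ACDEFGHIKLMNPQRSTVWY"])
    p = model.predict_position("ACDEFGHIKLMNPQRSTVWY", 5)
    assert p.max() - p.min() < 0.05


def test_zero_epochs_leaves_parameters_at_init():
    m0 = MaskedLanguageModel(n_epochs=0, random_state=2)
    m0.fit(["ACDEFGHIKL"])
    fresh = MaskedLanguageModel(n_epochs=0, random_state=2)
    fresh._build()
    for a, b in zip(m0._params(), fresh._params()):
        np.testing.assert_array_equal(a.value, b.value)


def test_eval_determinism_and_checkpoint_round_trip(memorizer, tmp_path):
    model, seq = memorizer
    p1 = model.predict_all_positions(seq)
    p2 = model.predict_all_positions(seq)
    np.testing.assert_array_equal(p1, p2)
    model.save(tmp_path / "ckpt")
    back = MaskedLanguageModel.load(tmp_path / "ckpt")
    np.testing.assert_allclose(back.predict_all_positions(seq), p1, atol=1e-6)
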