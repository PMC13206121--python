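"""Aggregator architectures, selection rule and complexity accounting."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from slidemil.aggregators import (
    AGGREGATOR_NAMES,
    AggregatorSpec,
    DTPParams,
    attention_scores,
    build_aggregator,
    count_flops,
    count_parameters,
    k_eff,
    load_model,
    parameter_breakdown,
    save_model,
)

STAGE2 = dict(in_dim=1024, n_classes=4)


@pytest.mark.parametrize(
    "n,expected",
    [(400, 100), (8000, 2000), (228, 100), (4000, 1000), (50, 50), (1, 1),
     (401, 100), (404, 101), (100000, 2000)],
)
def test_k_eff_values(n, expected):
    assert k_eff(n) == expected


@given(st.integers(min_value=1, max_value=50000))
def test_k_eff_bounded_and_monotone(n):
    dtp = DTPParams()
    k = k_eff(n, dtp)
    assert min(n, dtp.k_min) <= k <= dtp.k_max
    assert k_eff(n + 1, dtp) >= k


def test_k_eff_rejects_empty_bag():
    with pytest.raises(ValueError):
        k_eff(0)


def test_parameter_count_derivation_meanpool_768():
    # (768*512+512) + (512*256+256) + (256*4+4), summed by hand
    expected = (768 * 512 + 512) + (512 * 256 + 256) + (256 * 4 + 4)
    assert expected == 526_084
    assert count_parameters(AggregatorSpec(name="meanpool", in_dim=768, n_classes=4)) == expected


def test_clam_exceeds_abmil_by_instance_heads_exactly():
    abmil = count_parameters(AggregatorSpec(name="abmil", **STAGE2))
    clam = count_parameters(AggregatorSpec(name="clam_sb", **STAGE2))
    assert clam - abmil == 4 * (512 * 2 + 2) == 4104


def test_parameter_shares_match_architecture_structure():
    pool = parameter_breakdown(AggregatorSpec(name="meanpool", **STAGE2))
    assert pool["fc1_share"] == pytest.approx(0.80, abs=0.005)
    ab = parameter_breakdown(AggregatorSpec(name="abmil", **STAGE2))
    assert ab["attention_share"] == pytest.approx(0.33, abs=0.005)
    dtp = parameter_breakdown(AggregatorSpec(name="dtp_transmil", **STAGE2))
    assert dtp["encoder_share"] == pytest.approx(0.84, abs=0.005)
    assert dtp["fc1_share"] == pytest.approx(0.105, abs=0.0005)


def test_model_parameter_count_matches_accounting():
    for name in AGGREGATOR_NAMES:
        spec = AggregatorSpec(name=name, in_dim=256, n_classes=5)
        assert build_aggregator(spec).n_parameters() == count_parameters(spec)


def test_flops_scale_linearly_in_bag_size_for_projection():
    spec = AggregatorSpec(name="meanpool", **STAGE2)
    f1, f2 = count_flops(spec, 1000), count_flops(spec, 2000)
    head = (2 * 512 * 256 + 256 + 2 * 256 * 4) / 1e9
    # doubling N doubles everything except the classifier head
    assert f2 - head == pytest.approx(2 * (f1 - head))
    # closed form at N=1
    expected1 = (2 * 1024 * 512 + 512 + 512 + 2 * 512 * 256 + 256 + 2 * 256 * 4) / 1e9
    assert count_flops(spec, 1) == pytest.approx(expected1)


def test_meanpool_constant_bag_reduces_to_classifier():
    """With all projected instances equal, pooling returns that vector."""
    spec = AggregatorSpec(name="meanpool", in_dim=8, n_classes=3, dropout_fc1=0.0,
                          dropout_cls=0.0)
    m = build_aggregator(spec, seed=0)
    row = np.random.default_rng(1).standard_normal(8)
    bag = np.tile(row, (20, 1))
    logits_bag, _ = m.forward(bag)
    logits_one, _ = m.forward(row[None, :])
    assert np.allclose(logits_bag.data, logits_one.data)


@pytest.mark.parametrize("name", AGGREGATOR_NAMES)
def test_permutation_invariance(name):
    spec = AggregatorSpec(name=name, in_dim=16, n_classes=4, dropout_fc1=0.0,
                          dropout_cls=0.0, dropout_enc=0.0)
    m = build_aggregator(spec, seed=3)
    rng = np.random.default_rng(4)
    bag = rng.standard_normal((31, 16))
    perm = rng.permutation(31)
    l1, _ = m.forward(bag)
    l2, _ = m.forward(bag[perm])
    assert np.allclose(l1.data, l2.data, atol=1e-10)


@pytest.mark.parametrize("name", AGGREGATOR_NAMES)
def test_forward_emits_finite_logits(name):
    rng = np.random.default_rng(7)
    spec = AggregatorSpec(name=name, in_dim=32, n_classes=5)
    m = build_aggregator(spec, seed=1)
    for n in (1, 5, 130):
        logits, _ = m.forward(rng.standard_normal((n, 32)) * 3)
        assert logits.shape == (5,)
        assert np.isfinite(logits.data).all()


def test_dtp_small_bag_keeps_all_instances():
    spec = AggregatorSpec(name="dtp_transmil", in_dim=16, n_classes=4)
    m = build_aggregator(spec, seed=0)
    bag = np.random.default_rng(0).standard_normal((80, 16))
    _, aux = m.forward(bag)
    assert len(aux["selected"]) == 80  # N < K_min: every instance enters


def test_attention_score_conventions():
    rng = np.random.default_rng(9)
    bag = rng.standard_normal((50, 16))
    # pooling: no attention
    for name in ("meanpool", "maxpool"):
        m = build_aggregator(AggregatorSpec(name=name, in_dim=16, n_classes=4))
        assert attention_scores(m, bag) is None
    # abmil/clam: softmax over instances sums to 1
    for name in ("abmil", "clam_sb"):
        m = build_aggregator(AggregatorSpec(name=name, in_dim=16, n_classes=4))
        a = attention_scores(m, bag)
        assert a.shape == (50,)
        assert a.sum() == pytest.approx(1.0, abs=1e-6)
    # dtp: sigmoid scorer outputs for every instance, each in (0, 1)
    m = build_aggregator(AggregatorSpec(name="dtp_transmil", in_dim=16, n_classes=4))
    a = attention_scores(m, bag)
    assert a.shape == (50,)
    assert ((a > 0) & (a < 1)).all()
    # zeroed scorer -> all scores exactly 0.5
    m.scorer_fc.weight.data[...] = 0
    m.scorer_fc.bias.data[...] = 0
    m.scorer_out.weight.data[...] = 0
    m.scorer_out.bias.data[...] = 0
    assert np.allclose(attention_scores(m, bag), 0.5)


def test_spec_validation():
    with pytest.raises(ValueError):
        AggregatorSpec(name="nope")
    with pytest.raises(ValueError):
        AggregatorSpec(name="abmil", in_dim=0)
    with pytest.raises(ValueError):
        DTPParams(ratio=0.0)
    with pytest.raises(ValueError):
        DTPParams(k_min=300, k_max=100)


def test_checkpoint_roundtrip(tmp_path):
    spec = AggregatorSpec(name="abmil", in_dim=24, n_classes=3)
    m = build_aggregator(spec, seed=5)
    bag = np.random.default_rng(2).standard_normal((12, 24))
    before, _ = m.forward(bag)
    save_model(tmp_path / "ckpt", m)
    back = load_model(tmp_path / "ckpt")
    after, _ = back.forward(bag)
    assert back.spec.name == "abmil"
    assert np.allclose(before.data, after.data)
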