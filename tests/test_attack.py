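"""Attack orchestration: labels, success rules, single attacks, campaigns."""

import numpy as np
import pytest

from pixelattack import (
    AttackConfig,
    apply_perturbation,
    attack_campaign,
    is_success,
    label_set_name,
    make_toy_classifier,
    predict_label,
    run_attack,
)


@pytest.mark.parametrize(
    "cl, expected",
    [((0.1, 0.7, 0.2), 1), ((0.5, 0.5), 0), ((0.2, 0.2, 0.6), 2)],
)
def test_predict_label_multiclass_argmax_lowest_tie(cl, expected):
    assert predict_label(np.array(cl), "multiclass") == expected


def test_predict_label_multilabel_threshold():
    assert tuple(predict_label(np.array([0.6, 0.2]), "multilabel", 0.5)) == (1, 0)


def test_untargeted_success_any_label_change():
    ori = np.array([1, 0, 0, 0, 0])
    adv = np.array([1, 0, 1, 0, 0])  # class added, original retained
    assert is_success(ori, adv, "untargeted")
    assert not is_success(ori, ori.copy(), "untargeted")
    assert not is_success(2, 2, "untargeted")
    assert is_success(2, 0, "untargeted")


def test_targeted_success_requires_exact_match():
    target = np.zeros(4, dtype=int)  # the "Normal" label
    assert is_success(np.array([0, 1, 0, 0]), np.zeros(4, dtype=int), "targeted", target)
    assert not is_success(np.array([0, 1, 0, 0]), np.array([1, 0, 0, 0]), "targeted", target)


def test_label_set_name_rendering():
    names = ("Atelectasis", "Cardiomegaly", "Effusion")
    assert label_set_name(np.array([1, 0, 1]), names) == "Atelectasis, Effusion"
    assert label_set_name(np.array([0, 0, 0]), names) == "Normal"
    assert label_set_name(1, names) == "Cardiomegaly"


def test_run_attack_fragile_model_returns_working_gene(fragile_model):
    img = np.zeros((6, 6, 1), dtype=np.uint8)
    result = run_attack(img, fragile_model, AttackConfig(seed=3))
    assert result.success
    assert result.original_label == 0 and result.adversarial_label == 1
    # the returned gene really flips the model when applied
    adv = apply_perturbation(img, result.gene)
    assert int(np.argmax(fragile_model(adv[None])[0])) == 1
    # and it edited at most one pixel past the threshold
    changed = (adv != img).any(axis=2).sum()
    assert changed <= 1


def test_run_attack_constant_model_fails_at_budget(constant_model):
    img = np.zeros((4, 4, 1), dtype=np.uint8)
    cfg = AttackConfig(population_size=8, max_iterations=4, seed=0)
    result = run_attack(img, constant_model, cfg)
    assert not result.success
    assert result.iterations_used == 4
    assert result.adversarial_label == result.original_label


def test_targeted_noop_rejected(fragile_model):
    img = np.zeros((4, 4, 1), dtype=np.uint8)  # clean prediction is class 0
    cfg = AttackConfig(mode="targeted", target=0, seed=0)
    with pytest.raises(ValueError, match="no-op"):
        run_attack(img, fragile_model, cfg)


def test_multilabel_untargeted_attack_changes_label_set():
    model = make_toy_classifier("multilabel_sigmoid", 2, scale=0.5)
    img = np.full((4, 4, 1), 110, dtype=np.uint8)  # both bands below midpoint
    cfg = AttackConfig(task="multilabel", population_size=30, max_iterations=30, seed=5)
    result = run_attack(img, model, cfg)
    assert result.success
    assert tuple(result.original_label) == (0, 0)
    assert tuple(result.adversarial_label) != (0, 0)


def _two_class_pool():
    # class 0: dark uniform images; class 1: same but with a hot pixel
    images, labels = [], []
    for k in range(3):
        img = np.full((4, 4, 1), 30 + k, dtype=np.uint8)
        images.append(img)
        labels.append(0)
        hot = img.copy()
        hot[0, 0, 0] = 255
        images.append(hot)
        labels.append(1)
    return images, labels


def test_campaign_matrix_consistent_with_records(fragile_model):
    images, labels = _two_class_pool()
    cfg = AttackConfig(population_size=50, max_iterations=50, seed=9)
    campaign = attack_campaign(
        images, labels, fragile_model, cfg, experiments_per_class=3,
        class_names=("clean", "hot"),
    )
    for i, name in enumerate(campaign.matrix.origin_classes):
        n_success = sum(
            1 for r in campaign.records if r.class_name == name and r.result.success
        )
        assert campaign.matrix.counts[i].sum() == n_success
        assert campaign.matrix.counts[i].sum() <= campaign.trials[name]
    assert (np.diag(campaign.matrix.counts) == 0).all()


def test_campaign_is_deterministic(fragile_model):
    images, labels = _two_class_pool()
    cfg = AttackConfig(population_size=30, max_iterations=20, seed=21)
    a = attack_campaign(images, labels, fragile_model, cfg, 2, class_names=("c", "h"))
    b = attack_campaign(images, labels, fragile_model, cfg, 2, class_names=("c", "h"))
    assert np.array_equal(a.matrix.counts, b.matrix.counts)
    assert [r.seed for r in a.records] == [r.seed for r in b.records]
    for ra, rb in zip(a.records, b.records):
        assert np.array_equal(ra.result.gene.vector, rb.result.gene.vector)


def test_campaign_excludes_misclassified_images(fragile_model):
    # a "hot" image labelled as class 0 is misclassified from the start
    images = [np.full((4, 4, 1), 30, dtype=np.uint8)]
    hot = images[0].copy()
    hot[0, 0, 0] = 255
    images.append(hot)
    labels = [0, 0]
    cfg = AttackConfig(population_size=20, max_iterations=5, seed=0)
    campaign = attack_campaign(
        images, labels, fragile_model, cfg, 2, class_names=("a", "b")
    )
    assert campaign.excluded == {"a": 1}
    assert campaign.trials["a"] == 1


def test_empty_success_campaign_gives_zero_matrix(constant_model):
    images = [np.zeros((4, 4, 1), dtype=np.uint8)] * 2
    labels = [0, 0]
    cfg = AttackConfig(population_size=8, max_iterations=2, seed=0)
    campaign = attack_campaign(
        images, labels, constant_model, cfg, 2, class_names=("x", "y", "z")
    )
    assert campaign.matrix.counts.sum() == 0
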