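"""Model contract: forward behavior, training protocol, persistence."""

import numpy as np
import pytest

from edgetic.errors import (
    CompatibilityError,
    ConfigError,
    DataError,
    DegenerateClassError,
    RoleError,
)
from edgetic.gat import (
    ModelConfig,
    PerturbationModel,
    TrainingExample,
    _backward,
    _forward,
    _init_params,
    _weighted_bce_loss_grad,
    compute_class_weights,
    finetune,
    load_model,
    predict_ensemble,
    pretrain_stability,
)
from edgetic.structure import ContactGraph

from conftest import TRAINING_SEEDS


def _toy_example(seed=0, n_nodes=10, n_interactor=6, dim=8, mut_node=1):
    rng = np.random.default_rng(seed)
    edges = set()
    for _ in range(18):
        i, j = rng.integers(0, n_nodes, size=2)
        if i != j:
            edges.add((min(i, j), max(i, j)))
    graph = ContactGraph(
        chain_role=["interactor"] * n_interactor
        + ["partner"] * (n_nodes - n_interactor),
        position=np.concatenate(
            [np.arange(1, n_interactor + 1),
             np.arange(1, n_nodes - n_interactor + 1)]
        ),
        amino_acid=["A"] * n_nodes,
        edges=edges,
        contact_threshold=4.5,
        n_interactor=n_interactor,
    )
    return TrainingExample(
        graph=graph,
        node_features=rng.standard_normal((n_nodes, dim)),
        raw_encoding=rng.standard_normal(dim),
        mutation_node=mut_node,
        label=1,
    )


@pytest.fixture
def toy_model():
    return PerturbationModel(ModelConfig(embed_dim=8, hidden_dim=16, heads=2, seed=4))


class TestForward:
    def test_output_in_open_unit_interval(self, toy_model):
        for seed in range(5):
            p = toy_model.forward(_toy_example(seed=seed))
            assert 0.0 < p < 1.0

    def test_inference_deterministic(self, toy_model):
        ex = _toy_example()
        assert toy_model.forward(ex) == toy_model.forward(ex)

    def test_permutation_equivariance(self, toy_model):
        ex = _toy_example(seed=2)
        n = ex.graph.n_nodes
        rng = np.random.default_rng(7)
        perm = rng.permutation(n)          # perm[old] = new index
        inv = np.argsort(perm)
        permuted_graph = ContactGraph(
            chain_role=[ex.graph.chain_role[inv[k]] for k in range(n)],
            position=np.array([ex.graph.position[inv[k]] for k in range(n)]),
            amino_acid=[ex.graph.amino_acid[inv[k]] for k in range(n)],
            edges={
                (min(perm[i], perm[j]), max(perm[i], perm[j]))
                for i, j in ex.graph.edges
            },
            contact_threshold=4.5,
            n_interactor=ex.graph.n_interactor,
        )
        permuted = TrainingExample(
            graph=permuted_graph,
            node_features=ex.node_features[inv],
            raw_encoding=ex.raw_encoding,
            mutation_node=int(perm[ex.mutation_node]),
            label=ex.label,
        )
        assert toy_model.forward(permuted) == pytest.approx(
            toy_model.forward(ex), abs=1e-10
        )

    def test_partner_chain_mutation_rejected(self, toy_model):
        ex = _toy_example(mut_node=8)  # partner-role node
        with pytest.raises(RoleError):
            toy_model.forward(ex)

    def test_dimension_mismatch_rejected(self):
        model = PerturbationModel(ModelConfig(embed_dim=16, hidden_dim=16, heads=2))
        with pytest.raises(ConfigError):
            model.forward(_toy_example(dim=8))


def test_gradients_match_finite_differences():
    config = ModelConfig(embed_dim=6, hidden_dim=8, heads=2, dropout=0.0, seed=1)
    params = _init_params(config)
    rng = np.random.default_rng(0)
    n = 7
    x = rng.standard_normal((n, config.input_dim))
    mask = rng.random((n, n)) < 0.4
    mask = mask | mask.T
    np.fill_diagonal(mask, True)
    enc = rng.standard_normal(config.embed_dim)

    def loss():
        logit, _ = _forward(params, config, x, mask, 2, enc)
        return _weighted_bce_loss_grad(logit, 1, 1.3)[0]

    logit, cache = _forward(params, config, x, mask, 2, enc)
    _, d_logit = _weighted_bce_loss_grad(logit, 1, 1.3)
    grads = {k: np.zeros_like(v) for k, v in params.items()}
    _backward(params, config, cache, d_logit, grads)
    eps = 1e-6
    for name in params:
        flat = params[name].ravel()
        for i in rng.choice(flat.size, size=min(4, flat.size), replace=False):
            old = flat[i]
            flat[i] = old + eps
            up = loss()
            flat[i] = old - eps
            down = loss()
            flat[i] = old
            numeric = (up - down) / (2 * eps)
            analytic = grads[name].ravel()[i]
            assert analytic == pytest.approx(numeric, rel=1e-4, abs=1e-8), name


class TestClassWeights:
    def test_balanced(self):
        assert compute_class_weights([0, 1] * 25) == {0: 1.0, 1: 1.0}

    def test_imbalanced_hand_arithmetic(self):
        weights = compute_class_weights([0] * 90 + [1] * 10)
        assert weights[0] == pytest.approx(100 / 180)
        assert weights[1] == pytest.approx(5.0)

    def test_published_corpus_counts(self):
        # 1,395 disruptive vs 4,499 non-disruptive triplets
        weights = compute_class_weights([1] * 1395 + [0] * 4499)
        assert weights[1] == pytest.approx(5894 / (2 * 1395))
        assert weights[0] == pytest.approx(5894 / (2 * 4499))

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateClassError):
            compute_class_weights([1, 1, 1])


class TestPersistence:
    def test_round_trip_reproduces_outputs(self, toy_model, tmp_path):
        ex = _toy_example()
        before = toy_model.forward(ex)
        path = tmp_path / "model.ckpt"
        toy_model.save(path)
        assert load_model(path).forward(ex) == before

    def test_checksum_stable(self, toy_model, tmp_path):
        p1, p2 = tmp_path / "a.ckpt", tmp_path / "b.ckpt"
        toy_model.save(p1)
        toy_model.save(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_wrong_dimension_rejected(self, toy_model, tmp_path):
        path = tmp_path / "model.ckpt"
        toy_model.save(path)
        with pytest.raises(CompatibilityError):
            load_model(path, expect_dim=1024)

    def test_not_a_checkpoint(self, tmp_path):
        path = tmp_path / "junk.ckpt"
        path.write_bytes(b"not a checkpoint")
        with pytest.raises(CompatibilityError):
            load_model(path)


class TestEnsemble:
    def test_single_member_identity(self, toy_model):
        ex = _toy_example()
        assert predict_ensemble([toy_model], ex) == toy_model.forward(ex)

    def test_mean_of_members(self):
        ex = _toy_example()
        models = [
            PerturbationModel(ModelConfig(embed_dim=8, hidden_dim=16, heads=2, seed=s))
            for s in range(10)
        ]
        expected = np.mean([m.forward(ex) for m in models])
        assert predict_ensemble(models, ex) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            predict_ensemble([], _toy_example())


class TestTraining:
    def test_seeded_reproducibility(self, small_ppi):
        examples = small_ppi["examples"][:40]
        config = ModelConfig(embed_dim=32, hidden_dim=16, heads=2, epochs=3,
                             patience=3, finetune_lr=1e-3)
        _, r1 = finetune(None, config, examples, seed=5, from_scratch=True)
        _, r2 = finetune(None, config, examples, seed=5, from_scratch=True)
        assert r1.losses == r2.losses
        assert all(np.isfinite(l) for pair in r1.losses for l in pair)

    def test_report_weights_match_training_labels(self, small_ppi):
        examples = small_ppi["examples"][:40]
        config = ModelConfig(embed_dim=32, hidden_dim=16, heads=2, epochs=2,
                             patience=2)
        _, report = finetune(None, config, examples, seed=0, from_scratch=True)
        assert report.class_weights == compute_class_weights(
            [ex.label for ex in examples]
        )

    def test_empty_dataset_rejected(self):
        config = ModelConfig(embed_dim=8, hidden_dim=16, heads=2)
        with pytest.raises(DataError):
            finetune(None, config, [], from_scratch=True)
        with pytest.raises(DataError):
            pretrain_stability(config, [])

    def test_finetune_requires_pretrained(self, small_ppi):
        config = ModelConfig(embed_dim=32, hidden_dim=16, heads=2, epochs=1)
        with pytest.raises(ConfigError):
            finetune(None, config, small_ppi["examples"][:20])


class TestPlantedSignal:
    """Checks on the session-scoped two-stage training run (400 triplets,
    ε = 0.05, class-1-style holdout)."""

    def test_stability_pretraining_learns_burial(self, planted_run):
        from edgetic.evaluation import roc_auc

        model = planted_run["pretrained"]
        examples = planted_run["stability_examples"]
        auc = roc_auc(model.predict_many(examples),
                      [e.label for e in examples])
        assert auc >= 0.9

    def test_interface_variants_score_higher(self, planted_run):
        """Locality: variants far from the interface get lower predicted
        loss probability than interface variants (direction, not size)."""
        model = planted_run["finetuned"]
        probs, is_interface = [], []
        for ex in planted_run["test"]:
            probs.append(model.forward(ex))
            is_interface.append(ex.record.source.endswith("interface"))
        probs = np.array(probs)
        is_interface = np.array(is_interface)
        assert probs[is_interface].mean() > probs[~is_interface].mean()

    def test_transfer_reaches_target_loss_no_slower(self, planted_run):
        """Warm-starting from the stability model reaches a working
        validation loss in no more epochs than training from scratch
        (median across seeds)."""
        target = 0.55  # weighted BCE well below the 0.693 chance level

        def epochs_to_target(report):
            for epoch, (_, monitor) in enumerate(report.losses, start=1):
                if monitor <= target:
                    return epoch
            return len(report.losses) + 1

        runs = planted_run["runs"]
        med_scratch = np.median(
            [epochs_to_target(runs["scratch"][s]["report"])
             for s in TRAINING_SEEDS]
        )
        med_warm = np.median(
            [epochs_to_target(runs["finetuned"][s]["report"])
             for s in TRAINING_SEEDS]
        )
        assert med_warm <= med_scratch
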