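"""Two-phase schedule: conservation, early stopping, restoration, learning."""

import numpy as np
import pytest

import xylotype.training as training_mod
from xylotype.arch import ArchitectureSpec, assemble
from xylotype.estimator import preprocess_patches
from xylotype.training import (
    TrainPhaseSpec,
    evaluate_epoch,
    train_two_phase,
)


def mini_net(n_classes=3, dims=(64, 24), seed=0, dropout=0.5):
    spec = ArchitectureSpec(backbone="mini", n_classes=n_classes, dropout_rate=dropout)
    return assemble(spec, dims, seed=seed)[0]


def tiny_xy(tiny_patches, subset=slice(None)):
    x = preprocess_patches(tiny_patches["x_train"][subset])
    labels = tiny_patches["y_train"][subset]
    classes = sorted(set(labels))
    y = np.array([classes.index(l) for l in labels])
    return x, y


def test_zero_epoch_schedule_is_a_no_op(tiny_patches):
    x, y = tiny_xy(tiny_patches)
    net = mini_net()
    before = net.get_weights()
    p1 = TrainPhaseSpec(max_epochs=0, freeze_backbone=True)
    p2 = TrainPhaseSpec(optimizer="adam", learning_rate=1e-3, max_epochs=0,
                        freeze_backbone=False)
    train_two_phase(net, x, y, monitor=None, phase1=p1, phase2=p2)
    after = net.get_weights()
    assert all(np.array_equal(before[k], after[k]) for k in before)


def test_phase1_conserves_backbone_bit_exactly(tiny_patches):
    x, y = tiny_xy(tiny_patches)
    net = mini_net()
    initial = {
        k: v for k, v in net.get_weights().items() if k.startswith("backbone")
    }
    p1 = TrainPhaseSpec(max_epochs=3, learning_rate=1e-2, freeze_backbone=True)
    p2 = TrainPhaseSpec(optimizer="adam", max_epochs=0, freeze_backbone=False)
    train_two_phase(net, x, y, monitor=None, phase1=p1, phase2=p2)
    final = net.get_weights()
    for k, v in initial.items():
        np.testing.assert_array_equal(v, final[k])
    # head moved: training happened
    assert not np.array_equal(
        final["head_dense.W"], assemble(
            ArchitectureSpec(backbone="mini", n_classes=3), (64, 24), 0
        )[0].get_weights()["head_dense.W"],
    )


def test_phase2_updates_backbone(tiny_patches):
    x, y = tiny_xy(tiny_patches)
    net = mini_net()
    initial = net.get_weights()
    p1 = TrainPhaseSpec(max_epochs=0)
    p2 = TrainPhaseSpec(optimizer="adam", learning_rate=1e-3, max_epochs=1,
                        freeze_backbone=False)
    train_two_phase(net, x, y, monitor=None, phase1=p1, phase2=p2)
    changed = [
        k for k in initial
        if k.startswith("backbone") and not np.array_equal(initial[k],
                                                           net.get_weights()[k])
    ]
    assert changed


def test_learning_on_two_separable_classes(tiny_patches):
    # Classes 0 and 2 of the toy preset are far apart in texture space.
    labels = tiny_patches["y_train"]
    keep = np.isin(labels, [sorted(set(labels))[0], sorted(set(labels))[2]])
    x, y = tiny_xy(tiny_patches, keep)
    y = (y > 0).astype(int)
    net = mini_net(n_classes=2)
    p1 = TrainPhaseSpec(max_epochs=5, learning_rate=1e-2, seed=1)
    p2 = TrainPhaseSpec(optimizer="adam", learning_rate=1e-3, max_epochs=5,
                        freeze_backbone=False, seed=2)
    history = train_two_phase(net, x, y, monitor=None, phase1=p1, phase2=p2)
    acc, loss = evaluate_epoch(net, x, y)
    assert acc >= 0.95
    assert len(history.phase_records(1)) == 5
    assert len(history.phase_records(2)) == 5


def test_patience_arithmetic_with_scripted_monitor(tiny_patches, monkeypatch):
    # Monitored accuracy strictly decreasing after epoch 0 with patience p
    # must stop at epoch p exactly and restore the epoch-0 weights.
    x, y = tiny_xy(tiny_patches)
    scripted = iter([0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1, 0.05])

    def fake_eval(network, xm, ym, batch_size=64):
        return next(scripted), 0.0

    monkeypatch.setattr(training_mod, "evaluate_epoch", fake_eval)
    net = mini_net()
    p1 = TrainPhaseSpec(max_epochs=0)
    p2 = TrainPhaseSpec(optimizer="adam", learning_rate=1e-3, max_epochs=20,
                        early_stop_patience=3, freeze_backbone=False, seed=0)
    history = train_two_phase(net, x, y, monitor=(x[:8], y[:8]),
                              phase1=p1, phase2=p2)
    records = history.phase_records(2)
    assert history.stopping_epoch[2] == 3  # best epoch 0 + patience 3
    assert len(records) == 4  # epochs 0..3 ran
    assert records["monitor_acc"].tolist() == [0.9, 0.8, 0.7, 0.6]


def test_best_weight_restoration(tiny_patches):
    x, y = tiny_xy(tiny_patches)
    net = mini_net(dropout=0.3)
    mon = (x[::3], y[::3])
    p1 = TrainPhaseSpec(max_epochs=3, learning_rate=1e-2, seed=3)
    p2 = TrainPhaseSpec(optimizer="adam", learning_rate=1e-3, max_epochs=6,
                        early_stop_patience=10, freeze_backbone=False, seed=4)
    history = train_two_phase(net, x, y, monitor=mon, phase1=p1, phase2=p2)
    best = history.phase_records(2)["monitor_acc"].max()
    acc, _ = evaluate_epoch(net, mon[0], mon[1])
    assert acc == pytest.approx(best, abs=1e-12)


def test_seed_reproducibility(tiny_patches):
    x, y = tiny_xy(tiny_patches)

    def run():
        net = mini_net(seed=5)
        p1 = TrainPhaseSpec(max_epochs=2, learning_rate=1e-2, seed=6)
        p2 = TrainPhaseSpec(optimizer="adam", learning_rate=1e-3, max_epochs=2,
                            freeze_backbone=False, seed=7)
        h = train_two_phase(net, x, y, monitor=(x[:12], y[:12]),
                            phase1=p1, phase2=p2)
        return net.get_weights(), h.to_frame()

    w1, h1 = run()
    w2, h2 = run()
    assert all(np.array_equal(w1[k], w2[k]) for k in w1)
    assert h1.equals(h2)


def test_missing_class_detected_before_training(tiny_patches):
    x, y = tiny_xy(tiny_patches)
    y = np.where(y == 2, 1, y)  # class index 2 never present
    net = mini_net(n_classes=3)
    with pytest.raises(ValueError, match=r"missing class indices \[2\]"):
        train_two_phase(net, x, y, monitor=None,
                        phase1=TrainPhaseSpec(max_epochs=1),
                        phase2=TrainPhaseSpec(optimizer="adam", max_epochs=0,
                                              freeze_backbone=False))


def test_non_finite_loss_aborts_with_diagnostic(tiny_patches):
    x, y = tiny_xy(tiny_patches)
    net = mini_net()
    net.layers[0][1].params["W"][:] = np.nan
    with pytest.raises(RuntimeError, match="non-finite loss"):
        train_two_phase(net, x, y, monitor=None,
                        phase1=TrainPhaseSpec(max_epochs=1),
                        phase2=TrainPhaseSpec(optimizer="adam", max_epochs=0,
                                              freeze_backbone=False))


class TestEvaluateEpoch:
    def test_constant_class_predictor(self, tiny_patches):
        x, y = tiny_xy(tiny_patches)
        net = mini_net()
        dense = dict(net.layers)["head_dense"]
        dense.params["W"][:] = 0.0
        dense.params["b"][:] = np.array([5.0, 0.0, 0.0], dtype=np.float32)
        acc, _ = evaluate_epoch(net, x, np.zeros(len(x), dtype=int))
        assert acc == 1.0

    def test_uniform_logits_break_ties_to_lowest_index(self, tiny_patches):
        x, y = tiny_xy(tiny_patches)
        net = mini_net()
        dense = dict(net.layers)["head_dense"]
        dense.params["W"][:] = 0.0
        dense.params["b"][:] = 0.0
        acc0, _ = evaluate_epoch(net, x[y == 0], y[y == 0])
        acc_rest, _ = evaluate_epoch(net, x[y != 0], y[y != 0])
        assert acc0 == 1.0 and acc_rest == 0.0

    def test_repeatable_to_machine_precision(self, tiny_patches):
        x, y = tiny_xy(tiny_patches)
        net = mini_net()
        a1 = evaluate_epoch(net, x, y)
        a2 = evaluate_epoch(net, x, y)
        assert a1 == a2

    def test_empty_set_rejected(self):
        net = mini_net()
        with pytest.raises(ValueError, match="empty"):
            evaluate_epoch(net, np.empty((0, 3, 64, 24), np.float32),
                           np.empty(0, int))
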