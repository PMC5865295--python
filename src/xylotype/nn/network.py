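"""Sequential network container with a backbone/head boundary.

The backbone is the convolutional feature extractor; the head is everything
from global pooling onward. The boundary matters twice: backbone weights can
be frozen (feature-extractor training), and frozen-phase training caches the
backbone's output feature maps so only the head is re-evaluated per epoch.
"""

from __future__ import annotations

import numpy as np

from xylotype.nn.layers import BatchNorm1D, Layer, softmax

__all__ = ["Network"]


class Network:
    """An ordered list of named layers split into backbone and head."""

    def __init__(self, layers: list[tuple[str, Layer]], n_backbone: int):
        names = [name for name, _ in layers]
        if len(set(names)) != len(names):
            raise ValueError("layer names must be unique")
        self.layers = layers
        self.n_backbone = n_backbone

    # ------------------------------------------------------------------ core
    def forward(
        self, x: np.ndarray, train: bool = False, rng=None, start: int = 0
    ) -> np.ndarray:
        out = x
        for _, layer in self.layers[start:]:
            out = layer.forward(out, train=train, rng=rng)
        return out

    def backward(self, dout: np.ndarray, stop: int = 0) -> np.ndarray:
        grad = dout
        for _, layer in reversed(self.layers[stop:]):
            grad = layer.backward(grad)
        return grad

    def backbone_forward(self, x: np.ndarray, train: bool = False, rng=None):
        out = x
        for _, layer in self.layers[: self.n_backbone]:
            out = layer.forward(out, train=train, rng=rng)
        return out

    def head_forward(self, features: np.ndarray, train: bool = False, rng=None):
        return self.forward(features, train=train, rng=rng, start=self.n_backbone)

    def head_backward(self, dout: np.ndarray) -> np.ndarray:
        return self.backward(dout, stop=self.n_backbone)

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Evaluation-mode class probabilities, batched over the input."""
        outs = []
        for i in range(0, x.shape[0], batch_size):
            logits = self.forward(x[i : i + batch_size], train=False)
            outs.append(softmax(logits))
        return np.concatenate(outs, axis=0)

    # ----------------------------------------------------------- parameters
    def parameters(self, trainable_only: bool = False):
        """Yield (qualified_name, layer, param_key) triples."""
        for name, layer in self.layers:
            if trainable_only and not layer.trainable:
                continue
            for key in layer.params:
                yield f"{name}.{key}", layer, key

    def set_backbone_trainable(self, trainable: bool) -> None:
        for _, layer in self.layers[: self.n_backbone]:
            layer.trainable = trainable

    @property
    def backbone_trainable(self) -> bool:
        return all(layer.trainable for _, layer in self.layers[: self.n_backbone])

    def parameter_counts(self) -> dict[str, int]:
        total = sum(layer.n_params for _, layer in self.layers)
        trainable = sum(
            layer.n_params for _, layer in self.layers if layer.trainable
        )
        return {"total": total, "trainable": trainable}

    def calibrate_batchnorm(
        self, x: np.ndarray, batch_size: int = 64, from_features: bool = False
    ) -> None:
        """Replace batch-norm running statistics by population statistics.

        Mini-batch training (batch size 8) leaves the exponential running
        averages noisy and lagging behind the current weights, which
        distorts evaluation-mode predictions. This recomputes the exact
        mean/variance of each BatchNorm input over ``x`` (patches, or
        backbone feature maps when ``from_features``) under the current
        weights.
        """
        for idx, (_, layer) in enumerate(self.layers):
            if isinstance(layer, BatchNorm1D):
                start = self.n_backbone if from_features else 0
                chunks = []
                for i in range(0, x.shape[0], batch_size):
                    out = x[i : i + batch_size]
                    for _, lyr in self.layers[start:idx]:
                        out = lyr.forward(out, train=False)
                    chunks.append(out)
                pooled = np.concatenate(chunks, axis=0)
                layer.set_state(
                    {
                        "running_mean": pooled.mean(axis=0),
                        "running_var": pooled.var(axis=0),
                    }
                )
                return
        raise ValueError("network has no BatchNorm1D layer")

    # ---------------------------------------------------------------- state
    def get_weights(self) -> dict[str, np.ndarray]:
        """Deep copy of all parameters and batch-norm running statistics."""
        state: dict[str, np.ndarray] = {}
        for name, layer in self.layers:
            for key, value in layer.params.items():
                state[f"{name}.{key}"] = value.copy()
            if isinstance(layer, BatchNorm1D):
                for key, value in layer.state().items():
                    state[f"{name}.{key}"] = value.copy()
        return state

    def set_weights(self, state: dict[str, np.ndarray]) -> None:
        for name, layer in self.layers:
            for key in layer.params:
                layer.params[key] = state[f"{name}.{key}"].copy()
            if isinstance(layer, BatchNorm1D):
                layer.set_state(
                    {
                        "running_mean": state[f"{name}.running_mean"],
                        "running_var": state[f"{name}.running_var"],
                    }
                )

    def save(self, path) -> None:
        np.savez(path, **self.get_weights())

    def load(self, path) -> None:
        with np.load(path) as data:
            self.set_weights({k: data[k] for k in data.files})
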