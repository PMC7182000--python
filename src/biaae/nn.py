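"""Neural-network layers and the Adam optimizer used by every model variant.

Layers follow the familiar Module convention: parameters are discoverable
through :meth:`Module.parameters`, ``train()``/``eval()`` toggle dropout and
batch-norm behaviour, and ``requires_grad_`` freezes a subtree so that an
objective evaluated through it routes no gradient into its weights (used to
alternate encoder/decoder and discriminator updates).
"""

from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor, concat

__all__ = [
    "Module", "Linear", "LeakyReLU", "ReLU", "Tanh", "Sigmoid", "Dropout",
    "BatchNorm1d", "Sequential", "Embedding", "GRU", "mlp", "Adam",
]


class Module:
    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for value in self.__dict__.values():
            candidates: list = []
            if isinstance(value, Parameter):
                candidates = [value]
            elif isinstance(value, Module):
                candidates = value.parameters()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        candidates.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        candidates.append(item)
            for p in candidates:
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def modules(self) -> list["Module"]:
        found = [self]
        for value in self.__dict__.values():
            if isinstance(value, Module):
                found.extend(value.modules())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        found.extend(item.modules())
        return found

    def train(self, mode: bool = True) -> "Module":
        for module in self.modules():
            module.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def requires_grad_(self, flag: bool) -> "Module":
        for param in self.parameters():
            param.requires_grad = flag
        return self

    def zero_grad(self) -> None:
        for param in self.parameters():
            param.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {str(i): p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError(f"state has {len(state)} arrays, model has {len(params)} parameters")
        for i, param in enumerate(params):
            incoming = np.asarray(state[str(i)])
            if incoming.shape != param.data.shape:
                raise ValueError(f"parameter {i}: shape {incoming.shape} != {param.data.shape}")
            param.data = incoming.astype(np.float64).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Parameter(Tensor):
    """Leaf tensor registered as trainable; stays discoverable when frozen."""

    __slots__ = ()


def parameter(array: np.ndarray) -> Parameter:
    return Parameter(array, requires_grad=True)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        bound = math.sqrt(2.0 / (in_features + out_features))
        self.weight = parameter(rng.normal(0.0, bound, size=(in_features, out_features)))
        self.bias = parameter(np.zeros(out_features))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return x.leaky_relu(self.slope)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Tanh(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.tanh()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class Dropout(Module):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class BatchNorm1d(Module):
    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = parameter(np.ones(num_features))
        self.beta = parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mean = x.mean(axis=0, keepdims=True)
            var = ((x - mean) ** 2).mean(axis=0, keepdims=True)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean.data.ravel()
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var.data.ravel()
            norm = (x - mean) / ((var + self.eps) ** 0.5)
        else:
            norm = (x - Tensor(self.running_mean)) / Tensor(np.sqrt(self.running_var + self.eps))
        return norm * self.gamma + self.beta


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


def mlp(
    in_dim: int,
    hidden: list[int] | tuple[int, ...],
    out_dim: int,
    rng: np.random.Generator,
    activation: str = "leaky_relu",
    batchnorm: bool = False,
    dropout: float = 0.0,
    final_activation: Module | None = None,
) -> Sequential:
    """Fully-connected stack: Linear (+BN) + activation per hidden width."""
    acts = {"leaky_relu": lambda: LeakyReLU(0.2), "relu": ReLU, "tanh": Tanh}
    layers: list[Module] = []
    prev = in_dim
    for width in hidden:
        layers.append(Linear(prev, width, rng))
        if batchnorm:
            layers.append(BatchNorm1d(width))
        layers.append(acts[activation]())
        if dropout > 0:
            layers.append(Dropout(dropout, rng))
        prev = width
    layers.append(Linear(prev, out_dim, rng))
    if final_activation is not None:
        layers.append(final_activation)
    return Sequential(*layers)


class Embedding(Module):
    def __init__(self, num_embeddings: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.weight = parameter(rng.normal(0.0, 0.1, size=(num_embeddings, dim)))

    def forward(self, token_ids: np.ndarray) -> Tensor:
        return self.weight[np.asarray(token_ids)]


class GRUCell(Module):
    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        super().__init__()
        bound = math.sqrt(1.0 / hidden_size)
        shape_w = (input_size, 3 * hidden_size)
        shape_u = (hidden_size, 3 * hidden_size)
        self.w = parameter(rng.uniform(-bound, bound, size=shape_w))
        self.u = parameter(rng.uniform(-bound, bound, size=shape_u))
        self.b = parameter(np.zeros(3 * hidden_size))
        self.hidden_size = hidden_size

    def forward(self, x: Tensor, h: Tensor) -> Tensor:
        n = self.hidden_size
        gates_x = x @ self.w + self.b
        gates_h = h @ self.u
        r = (gates_x[:, :n] + gates_h[:, :n]).sigmoid()
        z = (gates_x[:, n:2 * n] + gates_h[:, n:2 * n]).sigmoid()
        cand = (gates_x[:, 2 * n:] + r * gates_h[:, 2 * n:]).tanh()
        return (Tensor(1.0) - z) * h + z * cand


class GRU(Module):
    """Stacked GRU over a (time, batch, features) input sequence."""

    def __init__(self, input_size: int, hidden_size: int, num_layers: int, rng: np.random.Generator):
        super().__init__()
        self.cells = [
            GRUCell(input_size if i == 0 else hidden_size, hidden_size, rng)
            for i in range(num_layers)
        ]
        self.hidden_size = hidden_size
        self.num_layers = num_layers

    def forward(self, inputs: list[Tensor], h0: list[Tensor] | None = None):
        """Run the stack; `inputs` is a list of (batch, features) tensors.

        Returns (outputs, final_hiddens): top-layer output per step and the
        final hidden state of each layer.
        """
        batch = inputs[0].shape[0]
        hs = h0 if h0 is not None else [
            Tensor(np.zeros((batch, self.hidden_size))) for _ in self.cells
        ]
        hs = list(hs)
        outputs: list[Tensor] = []
        for x in inputs:
            for layer, cell in enumerate(self.cells):
                hs[layer] = cell(x, hs[layer])
                x = hs[layer]
            outputs.append(x)
        return outputs, hs


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 3e-4, betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            m_hat = self.m[i] / (1 - b1**self.t)
            v_hat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
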