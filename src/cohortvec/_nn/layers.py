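"""Neural building blocks (modules with named parameters) on the autograd core."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, embedding, layer_norm


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Lightweight container; submodules and Parameters are discovered by attribute."""

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for name, v in self.__dict__.items():
            if isinstance(v, Parameter):
                out[name] = v.data
            elif isinstance(v, Module):
                for k, arr in v.state_dict().items():
                    out[f"{name}.{k}"] = arr
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        for k, arr in item.state_dict().items():
                            out[f"{name}.{i}.{k}"] = arr
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, v in self.__dict__.items():
            if isinstance(v, Parameter):
                v.data = np.asarray(state[name], dtype=v.data.dtype)
            elif isinstance(v, Module):
                v.load_state_dict({k.split(".", 1)[1]: a for k, a in state.items()
                                   if k.startswith(name + ".")})
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        prefix = f"{name}.{i}."
                        item.load_state_dict({k[len(prefix):]: a for k, a in
                                              state.items() if k.startswith(prefix)})


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (n_in + n_out))
        self.weight = Parameter(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.bias = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Embedding(Module):
    def __init__(self, n_tokens: int, dim: int, rng: np.random.Generator,
                 init: np.ndarray | None = None):
        if init is not None:
            self.weight = Parameter(init)
        else:
            self.weight = Parameter(rng.normal(0.0, 0.02, size=(n_tokens, dim)))

    def __call__(self, ids: np.ndarray) -> Tensor:
        return embedding(self.weight, ids)


class LayerNorm(Module):
    def __init__(self, dim: int):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta)


class FeedForward(Module):
    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())


_NEG = -1e9  # additive attention mask value


class MultiHeadAttention(Module):
    """Scaled dot-product attention; no positional information anywhere."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        if dim % n_heads:
            raise ValueError(f"model dim {dim} not divisible by n_heads {n_heads}")
        self.n_heads = n_heads
        self.dim = dim
        self.q = Linear(dim, dim, rng)
        self.k = Linear(dim, dim, rng)
        self.v = Linear(dim, dim, rng)
        self.out = Linear(dim, dim, rng)

    def __call__(self, x_q: Tensor, x_kv: Tensor,
                 key_pad_mask: np.ndarray | None = None,
                 causal: bool = False) -> Tensor:
        B, Lq, D = x_q.shape
        Lk = x_kv.shape[1]
        H, hd = self.n_heads, D // self.n_heads

        def split(t: Tensor, L: int) -> Tensor:
            return t.reshape(B, L, H, hd).swapaxes(1, 2)  # (B,H,L,hd)

        q = split(self.q(x_q), Lq)
        k = split(self.k(x_kv), Lk)
        v = split(self.v(x_kv), Lk)
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(hd))  # (B,H,Lq,Lk)
        add = np.zeros((B, 1, Lq, Lk), dtype=np.float32)
        if key_pad_mask is not None:  # True marks PAD keys
            add = add + np.where(key_pad_mask[:, None, None, :], _NEG, 0.0)
        if causal:
            tri = np.triu(np.full((Lq, Lk), _NEG, dtype=np.float32), k=1)
            add = add + tri[None, None]
        attn = (scores + Tensor(add)).softmax(axis=-1)
        ctx = (attn @ v).swapaxes(1, 2).reshape(B, Lq, D)
        return self.out(ctx)


class EncoderLayer(Module):
    """Pre-norm transformer encoder layer."""

    def __init__(self, dim: int, n_heads: int, dff: int, rng: np.random.Generator):
        self.ln1 = LayerNorm(dim)
        self.attn = MultiHeadAttention(dim, n_heads, rng)
        self.ln2 = LayerNorm(dim)
        self.ffn = FeedForward(dim, dff, rng)

    def __call__(self, x: Tensor, key_pad_mask: np.ndarray | None) -> Tensor:
        h = self.ln1(x)
        x = x + self.attn(h, h, key_pad_mask=key_pad_mask)
        return x + self.ffn(self.ln2(x))


class DecoderLayer(Module):
    """Pre-norm decoder layer: causal self-attention then cross-attention."""

    def __init__(self, dim: int, n_heads: int, dff: int, rng: np.random.Generator):
        self.ln1 = LayerNorm(dim)
        self.self_attn = MultiHeadAttention(dim, n_heads, rng)
        self.ln2 = LayerNorm(dim)
        self.cross_attn = MultiHeadAttention(dim, n_heads, rng)
        self.ln3 = LayerNorm(dim)
        self.ffn = FeedForward(dim, dff, rng)

    def __call__(self, x: Tensor, memory: Tensor,
                 memory_pad_mask: np.ndarray | None) -> Tensor:
        h = self.ln1(x)
        x = x + self.self_attn(h, h, causal=True)
        x = x + self.cross_attn(self.ln2(x), memory, key_pad_mask=memory_pad_mask)
        return x + self.ffn(self.ln3(x))
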