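"""Two-stage network for beat-to-beat SBP sequence regression.

Stage 1 (intra-cycle feature extraction): every PPG cycle slice is passed
through a shared ResU block — a 1-D U-shaped convolutional encoder/decoder
wrapped in residual structure — producing one length-l feature vector per
cycle:

    f_j = f_cir( f_up^d( f_res^r( f_down^d( f_cir(c_j) ) ) ) ) + c_j

where f_cir is convolution + instance norm + ReLU, d is the U depth and r
the number of residual blocks at the bottleneck. The n feature vectors are
stacked chronologically into tokens F in R^{n x l}.

Stage 2 (context-sensitive interaction): L pre-norm Transformer layers whose
self-attention scores carry a signed sinusoidal relative-position bias,

    p_{a,b} = sign(a-b) * PE(|a-b|),
    Attention = Softmax(Q K^T / sqrt(d_k) + W_p^T p) V,

with one learnable projection vector W_p per head per layer. A per-token
projection head (l -> l/2 -> 1) maps tokens to the n-value SBP sequence.

Cycle slices are stored at 125 samples and right zero-padded to l0 = 128 at
model input so the outer residual addition is shape-consistent with l = 128.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace

import numpy as np

from .autodiff import Tensor, concatenate, gelu, relu, softmax

__all__ = ["ModelConfig", "ResUTransRPE", "signed_pe", "save_checkpoint",
           "load_checkpoint", "MODEL_INPUT_LEN"]

MODEL_INPUT_LEN = 128  # l0: cycle slices zero-padded from 125 at model input


@dataclass
class ModelConfig:
    n: int = 60                 # cycles per contextual sample
    l0: int = MODEL_INPUT_LEN   # model input length per cycle
    l: int = 128                # feature length (= D_vector)
    d: int = 2                  # U depth
    r: int = 8                  # residual blocks at the bottleneck
    heads: int = 8
    layers: int = 3             # Trans-RPE layers (L)
    base_channels: int = 16
    mlp_expansion: int = 4
    dropout: float = 0.1
    pe_mode: str = "rpe"        # rpe | ape | none
    kernel_size: int = 3

    def validate(self) -> None:
        if self.l % self.heads:
            raise ValueError("l must be divisible by heads")
        if self.l0 != self.l:
            raise ValueError("l0 must equal l (outer residual addition)")
        if self.d < 1 or self.r < 1 or self.layers < 1:
            raise ValueError("d, r and layers must be >= 1")
        if self.l0 % (2**self.d):
            raise ValueError("l0 must be divisible by 2^d")
        if self.pe_mode not in ("rpe", "ape", "none"):
            raise ValueError(f"unknown pe_mode {self.pe_mode!r}")


# ------------------------------------------------------------------ encoding

def sinusoidal_pe(j, d_vector: int) -> np.ndarray:
    """Sinusoidal position encoding of (possibly vector) position ``j``:
    PE_{2x} = sin(j / 10000^{2x/D}), PE_{2x+1} = cos(j / 10000^{2x/D})."""
    j = np.asarray(j, dtype=float)[..., None]
    x = np.arange(d_vector // 2, dtype=float)
    div = 10000.0 ** (2.0 * x / d_vector)
    pe = np.empty(j.shape[:-1] + (d_vector,))
    pe[..., 0::2] = np.sin(j / div)
    pe[..., 1::2] = np.cos(j / div)
    return pe


def signed_pe(a, b, d_vector: int) -> np.ndarray:
    """Signed relative encoding p_{a,b} = sign(a-b) * PE(|a-b|)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    diff = a - b
    return np.sign(diff)[..., None] * sinusoidal_pe(np.abs(diff), d_vector)


def rpe_tensor(n: int, d_vector: int) -> np.ndarray:
    """Full (n, n, D) signed relative-position tensor over 1-based positions."""
    pos = np.arange(1, n + 1)
    return signed_pe(pos[:, None], pos[None, :], d_vector)


# ---------------------------------------------------------------- layer algebra

def _conv1d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1,
            pad: int | None = None) -> Tensor:
    """1-D convolution, x (N, Cin, L), w (Cout, Cin, k) -> (N, Cout, Lout)."""
    cout, cin, k = w.shape
    if pad is None:
        pad = (k - 1) // 2
    if pad:
        x = x.pad_last(pad, pad)
    n, _, lpad = x.shape
    lout = (lpad - k) // stride + 1
    win = x.take_windows(k, stride)                       # (N, Cin, Lout, k)
    win = win.transpose((0, 2, 1, 3)).reshape(n, lout, cin * k)
    out = win @ w.reshape(cout, cin * k).swapaxes(0, 1)   # (N, Lout, Cout)
    out = out + b.reshape(1, 1, cout)
    return out.transpose((0, 2, 1))


def _instance_norm(x: Tensor, g: Tensor, b: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalise each (sample, channel) over the length axis; affine g, b."""
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    y = xc / (var + eps).sqrt()
    c = x.shape[1]
    return y * g.reshape(1, c, 1) + b.reshape(1, c, 1)


def _layer_norm(x: Tensor, g: Tensor, b: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return xc / (var + eps).sqrt() * g + b


def _linear_upsample_matrix(n_in: int, factor: int = 2) -> np.ndarray:
    """(n_out, n_in) linear-interpolation matrix, n_out = factor * n_in."""
    n_out = factor * n_in
    pos = np.linspace(0.0, n_in - 1.0, n_out)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = pos - lo
    m = np.zeros((n_out, n_in))
    m[np.arange(n_out), lo] += 1.0 - frac
    m[np.arange(n_out), hi] += frac
    return m


# --------------------------------------------------------------------- model

class ResUTransRPE:
    """The full two-stage model (ResU feature extractor + Trans-RPE stack).

    Parameters are held as named :class:`Tensor` leaves in ``self.params``;
    the forward pass builds the autodiff graph on the fly.
    """

    def __init__(self, config: ModelConfig, seed: int = 0):
        config.validate()
        self.config = config
        self.params: dict[str, Tensor] = {}
        # affine output transform (set from training targets, so the network
        # regresses in standardised units while predictions stay in mmHg)
        self.output_offset = 0.0
        self.output_scale = 1.0
        self._rng = np.random.default_rng(seed)
        self._dropout_rng = np.random.default_rng(
            np.random.SeedSequence([seed, 0xD0]))
        self._build()
        c = config
        self._p_rpe = rpe_tensor(c.n, c.l) if c.pe_mode == "rpe" else None
        self._ape = (sinusoidal_pe(np.arange(1, c.n + 1), c.l)
                     if c.pe_mode == "ape" else None)

    # ------------------------------------------------------------ parameters
    def _param(self, name: str, shape, fan_in: int | None = None,
               zero: bool = False) -> Tensor:
        if zero:
            data = np.zeros(shape)
        else:
            scale = np.sqrt(2.0 / fan_in) if fan_in else 0.02
            data = self._rng.normal(0.0, scale, size=shape)
        t = Tensor(data, requires_grad=True)
        self.params[name] = t
        return t

    def _conv_block(self, name: str, cin: int, cout: int) -> None:
        k = self.config.kernel_size
        self._param(f"{name}.w", (cout, cin, k), fan_in=cin * k)
        self._param(f"{name}.b", (cout,), zero=True)
        self._param(f"{name}.g", (cout,))
        self.params[f"{name}.g"].data = np.ones(cout)
        self._param(f"{name}.beta", (cout,), zero=True)

    def _build(self) -> None:
        c = self.config
        ch = c.base_channels
        self._conv_block("resu.stem", 1, ch)
        for i in range(c.d):
            self._conv_block(f"resu.down{i}", ch * 2**i, ch * 2**(i + 1))
        cw = ch * 2**c.d
        for i in range(c.r):
            self._conv_block(f"resu.res{i}.a", cw, cw)
            self._conv_block(f"resu.res{i}.b", cw, cw)
        for i in range(c.d):
            self._conv_block(f"resu.up{i}", ch * 2**(c.d - i), ch * 2**(c.d - i - 1))
        self._conv_block("resu.out", ch, 1)

        for t in range(c.layers):
            p = f"trans{t}"
            for nm in ("ln1", "ln2"):
                self._param(f"{p}.{nm}.g", (c.l,))
                self.params[f"{p}.{nm}.g"].data = np.ones(c.l)
                self._param(f"{p}.{nm}.b", (c.l,), zero=True)
            for nm in ("wq", "wk", "wv", "wo"):
                self._param(f"{p}.{nm}", (c.l, c.l), fan_in=c.l)
                self._param(f"{p}.{nm}_b", (c.l,), zero=True)
            hid = c.l * c.mlp_expansion
            self._param(f"{p}.mlp1", (c.l, hid), fan_in=c.l)
            self._param(f"{p}.mlp1_b", (hid,), zero=True)
            self._param(f"{p}.mlp2", (hid, c.l), fan_in=hid)
            self._param(f"{p}.mlp2_b", (c.l,), zero=True)
            if c.pe_mode == "rpe":
                self._param(f"{p}.wp", (c.heads, c.l), zero=True)

        half = c.l // 2
        self._param("proj.w1", (c.l, half), fan_in=c.l)
        self._param("proj.b1", (half,), zero=True)
        self._param("proj.w2", (half, 1), fan_in=half)
        self._param("proj.b2", (1,), zero=True)

        self._upsample_mats = [
            _linear_upsample_matrix(c.l0 // 2**(i + 1))
            for i in reversed(range(c.d))
        ]  # applied in decoder order: smallest scale first

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    # --------------------------------------------------------------- helpers
    def _dropout(self, x: Tensor, training: bool) -> Tensor:
        p = self.config.dropout
        if not training or p <= 0:
            return x
        mask = (self._dropout_rng.random(x.shape) >= p) / (1.0 - p)
        return x * Tensor(mask)

    def _cir(self, x: Tensor, name: str, stride: int = 1) -> Tensor:
        """f_cir: convolution + instance norm + ReLU."""
        y = _conv1d(x, self.params[f"{name}.w"], self.params[f"{name}.b"],
                    stride=stride)
        y = _instance_norm(y, self.params[f"{name}.g"], self.params[f"{name}.beta"])
        return relu(y)

    # ----------------------------------------------------------------- stage 1
    def resu_forward(self, cycles: Tensor | np.ndarray) -> Tensor:
        """ResU block on a batch of cycles: (M, l0) -> (M, l)."""
        c = self.config
        x = cycles if isinstance(cycles, Tensor) else Tensor(cycles)
        if x.shape[-1] != c.l0:
            raise ValueError(f"cycle length {x.shape[-1]} != l0 {c.l0}")
        m = x.shape[0]
        h = x.reshape(m, 1, c.l0)
        h = self._cir(h, "resu.stem")
        skips = [h]
        for i in range(c.d):
            h = self._cir(h, f"resu.down{i}", stride=2)
            skips.append(h)
        for i in range(c.r):
            y = self._cir(h, f"resu.res{i}.a")
            y = _conv1d(y, self.params[f"resu.res{i}.b.w"],
                        self.params[f"resu.res{i}.b.b"])
            y = _instance_norm(y, self.params[f"resu.res{i}.b.g"],
                               self.params[f"resu.res{i}.b.beta"])
            h = relu(y + h)
        for i in range(c.d):
            up = Tensor(self._upsample_mats[i])
            h = h @ up.swapaxes(0, 1)          # (M, C, L) -> (M, C, 2L)
            h = self._cir(h, f"resu.up{i}")
            h = h + skips[c.d - i - 1]          # additive encoder skip
        h = self._cir(h, "resu.out")            # (M, 1, l0)
        return h.reshape(m, c.l0) + x

    def build_tokens(self, cycles: Tensor | np.ndarray) -> Tensor:
        """(B, n, l0) cycle stack -> (B, n, l) feature tokens, shared weights."""
        c = self.config
        x = cycles if isinstance(cycles, Tensor) else Tensor(cycles)
        if x.shape[-2] != c.n:
            raise ValueError(f"expected {c.n} cycles, got {x.shape[-2]}")
        b = x.shape[0]
        feats = self.resu_forward(x.reshape(b * c.n, c.l0))
        return feats.reshape(b, c.n, c.l)

    # ----------------------------------------------------------------- stage 2
    def _rpe_bias(self, layer: int) -> Tensor | None:
        """(heads, n, n) attention-score bias W_p^T p for one layer."""
        if self.config.pe_mode != "rpe":
            return None
        c = self.config
        wp = self.params[f"trans{layer}.wp"]            # (H, D)
        p = Tensor(self._p_rpe.reshape(c.n * c.n, c.l))  # constant
        bias = p @ wp.swapaxes(0, 1)                     # (n*n, H)
        return bias.reshape(c.n, c.n, c.heads).transpose((2, 0, 1))

    def attention(self, x: Tensor, layer: int, training: bool = False) -> Tensor:
        """Multi-head self-attention with optional relative-position bias."""
        c = self.config
        b, n, l = x.shape
        dk = l // c.heads
        p = f"trans{layer}"

        def proj(nm):
            y = x @ self.params[f"{p}.{nm}"] + self.params[f"{p}.{nm}_b"]
            return y.reshape(b, n, c.heads, dk).transpose((0, 2, 1, 3))

        q, k, v = proj("wq"), proj("wk"), proj("wv")
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(dk))
        bias = self._rpe_bias(layer)
        if bias is not None:
            scores = scores + bias.reshape(1, c.heads, n, n)
        attn = softmax(scores, axis=-1)
        attn = self._dropout(attn, training)
        out = (attn @ v).transpose((0, 2, 1, 3)).reshape(b, n, l)
        out = out @ self.params[f"{p}.wo"] + self.params[f"{p}.wo_b"]
        return self._dropout(out, training)

    def trans_layer(self, x: Tensor, layer: int, training: bool = False) -> Tensor:
        """Pre-norm block: x' = MSA(LN(x)) + x ; out = MLP(LN(x')) + x'."""
        p = f"trans{layer}"
        h = _layer_norm(x, self.params[f"{p}.ln1.g"], self.params[f"{p}.ln1.b"])
        x = self.attention(h, layer, training) + x
        h = _layer_norm(x, self.params[f"{p}.ln2.g"], self.params[f"{p}.ln2.b"])
        h = gelu(h @ self.params[f"{p}.mlp1"] + self.params[f"{p}.mlp1_b"])
        h = self._dropout(h, training)
        h = h @ self.params[f"{p}.mlp2"] + self.params[f"{p}.mlp2_b"]
        return self._dropout(h, training) + x

    def project(self, tokens: Tensor) -> Tensor:
        """Per-token head: affine l -> l/2, ReLU, affine l/2 -> 1; (B,n,l)->(B,n)."""
        h = relu(tokens @ self.params["proj.w1"] + self.params["proj.b1"])
        h = h @ self.params["proj.w2"] + self.params["proj.b2"]
        b, n, _ = tokens.shape
        return h.reshape(b, n)

    # ------------------------------------------------------------------ full
    def forward(self, cycles: Tensor | np.ndarray, training: bool = False
                ) -> Tensor:
        """(B, n, l0) -> (B, n) predicted SBP sequence."""
        tokens = self.build_tokens(cycles)
        if self.config.pe_mode == "ape":
            tokens = tokens + Tensor(self._ape[None])
        for t in range(self.config.layers):
            tokens = self.trans_layer(tokens, t, training)
        out = self.project(tokens)
        if self.output_scale != 1.0 or self.output_offset != 0.0:
            out = out * self.output_scale + self.output_offset
        return out

    def set_output_transform(self, offset: float, scale: float) -> None:
        """Predictions become ``raw * scale + offset`` (mmHg)."""
        if scale <= 0:
            raise ValueError("scale must be positive")
        self.output_offset = float(offset)
        self.output_scale = float(scale)

    def predict(self, cycles: np.ndarray) -> np.ndarray:
        """Inference on raw 125-sample slices or l0-sample inputs."""
        cycles = np.asarray(cycles, dtype=float)
        if cycles.shape[-1] < self.config.l0:
            pad = self.config.l0 - cycles.shape[-1]
            cycles = np.pad(cycles, [(0, 0)] * (cycles.ndim - 1) + [(0, pad)])
        return self.forward(cycles, training=False).data

    # ------------------------------------------------------------ state dict
    def state_dict(self) -> dict:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict) -> None:
        for k, v in state.items():
            if k not in self.params:
                raise KeyError(f"unexpected parameter {k}")
            if self.params[k].data.shape != v.shape:
                raise ValueError(f"shape mismatch for {k}")
            self.params[k].data = np.asarray(v, dtype=float).copy()


# --------------------------------------------------------------- checkpoints

def save_checkpoint(model: ResUTransRPE, path, extra: dict | None = None) -> None:
    """Single-file checkpoint: all weights + embedded ModelConfig."""
    payload = {f"param/{k}": v for k, v in model.state_dict().items()}
    payload["config_json"] = np.frombuffer(
        json.dumps({"model": asdict(model.config),
                    "output": {"offset": model.output_offset,
                               "scale": model.output_scale},
                    "extra": extra or {}}).encode(), dtype=np.uint8)
    np.savez(path, **payload)


def load_checkpoint(path) -> tuple[ResUTransRPE, dict]:
    with np.load(path) as z:
        meta = json.loads(bytes(z["config_json"].tobytes()).decode())
        config = ModelConfig(**meta["model"])
        model = ResUTransRPE(config, seed=0)
        model.load_state_dict(
            {k[len("param/"):]: z[k] for k in z.files if k.startswith("param/")}
        )
        out = meta.get("output", {})
        model.output_offset = float(out.get("offset", 0.0))
        model.output_scale = float(out.get("scale", 1.0))
    return model, meta.get("extra", {})
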