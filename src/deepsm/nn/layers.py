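"""Network building blocks: residual U-Net and bidirectional ConvLSTM.

The denoiser applies a shared-weight four-level residual U-Net to every
frame to extract spatial features, runs a pair of ConvLSTMs over the
feature sequence in opposite temporal directions, fuses the two passes by
channel concatenation and a 1x1 convolution, and projects to a per-frame
intensity correction added to the input frame.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = ["Module", "Conv2d", "ResBlock", "ResUNet", "ConvLSTMCell",
           "BiConvLSTM", "DeepSM"]


class Module:
    """Parameter container with recursive collection."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for value in self.__dict__.values():
            items = value if isinstance(value, (list, tuple)) else [value]
            for item in items:
                if isinstance(item, Tensor) and item.requires_grad:
                    if id(item) not in seen:
                        seen.add(id(item))
                        params.append(item)
                elif isinstance(item, Module):
                    for p in item.parameters():
                        if id(p) not in seen:
                            seen.add(id(p))
                            params.append(p)
        return params

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("checkpoint does not match architecture")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("checkpoint does not match architecture")
            p.data = a.astype(np.float32).copy()


class Conv2d(Module):
    def __init__(self, c_in, c_out, kernel_size, rng, zero_init=False):
        k = kernel_size
        if zero_init:
            w = np.zeros((c_out, c_in, k, k))
        else:
            std = np.sqrt(2.0 / (c_in * k * k))
            w = rng.normal(0.0, std, size=(c_out, c_in, k, k))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.weight, self.bias)


class ResBlock(Module):
    """Double convolution whose input is added to its output.

    A 1x1 projection matches channels on the residual branch when the input
    and output widths differ.
    """

    def __init__(self, c_in, c_out, kernel_size, rng):
        self.conv1 = Conv2d(c_in, c_out, kernel_size, rng)
        self.conv2 = Conv2d(c_out, c_out, kernel_size, rng)
        self.proj = Conv2d(c_in, c_out, 1, rng) if c_in != c_out else None

    def __call__(self, x: Tensor) -> Tensor:
        y = self.conv2(ag.relu(self.conv1(x)))
        skip = self.proj(x) if self.proj is not None else x
        return ag.relu(ag.add(y, skip))


class ResUNet(Module):
    """Four-level encoder/decoder with residual blocks and skip connections.

    Each level halves the spatial resolution (2x2 max pool) on the way down
    and doubles it (nearest upsample) on the way up, so inputs must have
    spatial dims divisible by 16.  Output spatial shape equals input shape.
    """

    def __init__(self, c_in, base_channels, c_out, kernel_size, rng,
                 n_levels=4):
        if n_levels != 4:
            raise ValueError("the architecture is defined with four levels")
        c = base_channels
        widths = [c, 2 * c, 4 * c, 8 * c]
        self.enc = []
        prev = c_in
        for width in widths:
            self.enc.append(ResBlock(prev, width, kernel_size, rng))
            prev = width
        self.bottleneck = ResBlock(widths[-1], widths[-1], kernel_size, rng)
        self.dec = []
        prev = widths[-1]
        for width in reversed(widths):
            self.dec.append(ResBlock(prev + width, width, kernel_size, rng))
            prev = width
        self.head = Conv2d(widths[0], c_out, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        h, w = x.data.shape[2:]
        if h % 16 or w % 16:
            raise ValueError(f"spatial dims must be multiples of 16, got {h}x{w}")
        skips = []
        cur = x
        for block in self.enc:
            cur = block(cur)
            skips.append(cur)
            cur = ag.maxpool2x2(cur)
        cur = self.bottleneck(cur)
        for block, skip in zip(self.dec, reversed(skips)):
            cur = ag.upsample2x(cur)
            cur = block(ag.concat([cur, skip], axis=1))
        return self.head(cur)


class ConvLSTMCell(Module):
    """LSTM cell whose gate transforms are convolutions over feature maps."""

    def __init__(self, c_in, c_hidden, kernel_size, rng):
        self.c_hidden = c_hidden
        self.gates = Conv2d(c_in + c_hidden, 4 * c_hidden, kernel_size, rng)
        # positive forget-gate bias stabilizes early training
        bias = self.gates.bias.data
        bias[c_hidden:2 * c_hidden] = 1.0

    def __call__(self, x: Tensor, h: Tensor, c: Tensor):
        z = self.gates(ag.concat([x, h], axis=1))
        i_gate, f_gate, o_gate, g_gate = ag.split_channels(z, 4)
        i_gate = ag.sigmoid(i_gate)
        f_gate = ag.sigmoid(f_gate)
        o_gate = ag.sigmoid(o_gate)
        g_gate = ag.tanh(g_gate)
        c_next = ag.add(ag.mul(f_gate, c), ag.mul(i_gate, g_gate))
        h_next = ag.mul(o_gate, ag.tanh(c_next))
        return h_next, c_next

    def init_state(self, batch, h, w):
        zeros = np.zeros((batch, self.c_hidden, h, w), dtype=np.float32)
        return Tensor(zeros), Tensor(zeros.copy())


class BiConvLSTM(Module):
    """Forward and backward ConvLSTM passes fused per frame.

    The two hidden sequences are concatenated channel-wise and mixed by a
    1x1 convolution; sequence length is preserved.
    """

    def __init__(self, c_in, c_hidden, c_out, kernel_size, rng):
        self.forward_cell = ConvLSTMCell(c_in, c_hidden, kernel_size, rng)
        self.backward_cell = ConvLSTMCell(c_in, c_hidden, kernel_size, rng)
        self.fuse = Conv2d(2 * c_hidden, c_out, 1, rng)

    def _run(self, cell: ConvLSTMCell, frames: list[Tensor]) -> list[Tensor]:
        b, _, h, w = frames[0].data.shape
        hidden, cstate = cell.init_state(b, h, w)
        outputs = []
        for frame in frames:
            hidden, cstate = cell(frame, hidden, cstate)
            outputs.append(hidden)
        return outputs

    def __call__(self, frames: list[Tensor]) -> list[Tensor]:
        fwd = self._run(self.forward_cell, frames)
        bwd = self._run(self.backward_cell, frames[::-1])[::-1]
        # linear fusion: a rectifier here can die for whole feature maps and
        # freeze the downstream projection at zero
        return [
            self.fuse(ag.concat([f, b], axis=1)) for f, b in zip(fwd, bwd)
        ]


class DeepSM(Module):
    """Per-frame residual U-Net -> bidirectional ConvLSTM -> 1x1 projection.

    The projection is zero-initialized, so the freshly built model is the
    identity map; training learns the correction that removes the noise.
    ``n_blocks`` repeats the ResUNet/Bi-ConvLSTM pair.
    """

    def __init__(self, spec, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.spec = spec
        c, hid, k = spec.base_channels, spec.lstm_hidden_channels, spec.kernel_size
        self.blocks = []
        c_in = 1
        for _ in range(spec.n_blocks):
            self.blocks.append(ResUNet(c_in, c, c, k, rng, spec.n_levels))
            self.blocks.append(BiConvLSTM(c, hid, hid, k, rng))
            c_in = hid
        self.head = Conv2d(c_in, 1, 1, rng, zero_init=True)

    def forward(self, x: np.ndarray) -> Tensor:
        """Map a (B, T, H, W) array to the denoised Tensor of the same shape."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        b, t, h, w = x.shape
        frames_in = Tensor(x.reshape(b * t, 1, h, w))
        cur: list[Tensor] | None = None
        flat: Tensor = frames_in
        for i, block in enumerate(self.blocks):
            if isinstance(block, ResUNet):
                flat = block(flat if cur is None else _stack_frames(cur, b, t))
                cur = [
                    ag.take_rows(flat, np.arange(b) * t + ti) for ti in range(t)
                ]
            else:
                cur = block(cur)
        inputs = [ag.take_rows(frames_in, np.arange(b) * t + ti) for ti in range(t)]
        outs = [ag.add(self.head(f), xi) for f, xi in zip(cur, inputs)]
        return ag.concat(outs, axis=1)  # (B, T, H, W): channel axis carries time

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x).data


def _stack_frames(frames: list[Tensor], b: int, t: int) -> Tensor:
    """Interleave a T-list of (B, C, H, W) frames back into (B*T, C, H, W)."""
    stacked = ag.concat(frames, axis=0)  # t-major: (T*B, C, H, W)
    order = np.arange(t * b).reshape(t, b).T.ravel()  # -> b-major
    return ag.take_rows(stacked, order)
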