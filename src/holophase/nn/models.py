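"""U-Net generator and patch-wise discriminator built on the numpy engine.

The generator is an encoder-decoder with skip connections: the encoder
halves the spatial size at every level down to a 1 x 1 bottleneck, the
decoder mirrors it with transposed convolutions, concatenating the matching
encoder feature map at each level, and ends in a tanh. The discriminator is
a patch classifier: a stack of strided convolutions producing a score map in
(0, 1) whose every element judges one receptive-field patch of the
(hologram, phase) pair.
"""

from __future__ import annotations

import numpy as np

from .core import (
    Adam,
    BatchNorm2d,
    Conv2d,
    ConvTranspose2d,
    Dropout,
    LeakyReLU,
    Parameter,
    ReLU,
    Sigmoid,
    Tanh,
)

__all__ = ["UNetGenerator", "PatchDiscriminator", "receptive_field"]


def _channel_schedule(depth: int, base: int, maxf: int) -> list[int]:
    return [min(base * 2**i, maxf) for i in range(depth)]


class UNetGenerator:
    """Hologram -> phase translator with a 2^depth total downsampling."""

    def __init__(
        self,
        input_size: int = 256,
        depth: int = 8,
        base_filters: int = 64,
        max_filters: int = 512,
        in_channels: int = 3,
        out_channels: int = 3,
        dropout_layers: int = 4,
        dropout_rate: float = 0.5,
        seed: int = 0,
    ):
        if input_size % (2**depth) != 0:
            raise ValueError(
                f"input size {input_size} not divisible by 2^depth = {2**depth}"
            )
        self.input_size = input_size
        self.depth = depth
        self.in_channels = in_channels
        self.out_channels = out_channels
        rng = np.random.default_rng(seed)
        ch = _channel_schedule(depth, base_filters, max_filters)

        self.enc = []
        self.enc_bn: list[BatchNorm2d | None] = []
        prev = in_channels
        for i in range(depth):
            self.enc.append(Conv2d(prev, ch[i], 4, 2, 1, rng, name=f"enc{i}"))
            # no normalization on the first layer or the 1x1 bottleneck
            self.enc_bn.append(BatchNorm2d(ch[i], name=f"enc{i}.bn")
                               if 0 < i < depth - 1 else None)
            prev = ch[i]
        self.enc_act = [LeakyReLU(0.2) for _ in range(depth)]

        self.dec = []
        self.dec_bn: list[BatchNorm2d | None] = []
        self.dec_drop: list[Dropout | None] = []
        self.dec_act = [ReLU() for _ in range(depth)]
        for i in range(depth):
            in_ch = ch[depth - 1] if i == 0 else 2 * ch[depth - 1 - i]
            out_ch = out_channels if i == depth - 1 else ch[depth - 2 - i]
            self.dec.append(ConvTranspose2d(in_ch, out_ch, 4, 2, 1, rng, name=f"dec{i}"))
            self.dec_bn.append(BatchNorm2d(out_ch, name=f"dec{i}.bn")
                               if i < depth - 1 else None)
            self.dec_drop.append(Dropout(dropout_rate, rng)
                                 if i < dropout_layers and i < depth - 1 else None)
        self.tanh = Tanh()

    def params(self) -> list[Parameter]:
        ps: list[Parameter] = []
        for layer in (*self.enc, *self.dec):
            ps += layer.params()
        for bn in (*self.enc_bn, *self.dec_bn):
            if bn is not None:
                ps += bn.params()
        return ps

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        if x.shape[1] != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {x.shape[1]}")
        if x.shape[2] % (2**self.depth) or x.shape[3] % (2**self.depth):
            raise ValueError("spatial size must be divisible by 2^depth")
        skips = []
        h = x
        for i in range(self.depth):
            if i > 0:
                h = self.enc_act[i].forward(h, training)
            h = self.enc[i].forward(h, training)
            if self.enc_bn[i] is not None:
                h = self.enc_bn[i].forward(h, training)
            skips.append(h)
        self._bottleneck_hw = h.shape[2:]
        for i in range(self.depth):
            h = self.dec_act[i].forward(h, training)
            h = self.dec[i].forward(h, training)
            if self.dec_bn[i] is not None:
                h = self.dec_bn[i].forward(h, training)
            if self.dec_drop[i] is not None:
                h = self.dec_drop[i].forward(h, training)
            if i < self.depth - 1:
                h = np.concatenate([h, skips[self.depth - 2 - i]], axis=1)
        return self.tanh.forward(h, training)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.tanh.backward(dout)
        skip_grads: dict[int, np.ndarray] = {}
        for i in reversed(range(self.depth)):
            if i < self.depth - 1:
                own = self.dec[i].b.value.shape[0]  # channels produced by this level
                d, dskip = d[:, :own], d[:, own:]
                skip_grads[self.depth - 2 - i] = dskip
            if self.dec_drop[i] is not None:
                d = self.dec_drop[i].backward(d)
            if self.dec_bn[i] is not None:
                d = self.dec_bn[i].backward(d)
            d = self.dec[i].backward(d)
            d = self.dec_act[i].backward(d)
        for i in reversed(range(self.depth)):
            if i in skip_grads:
                d = d + skip_grads[i]
            if self.enc_bn[i] is not None:
                d = self.enc_bn[i].backward(d)
            d = self.enc[i].backward(d)
            if i > 0:
                d = self.enc_act[i].backward(d)
        return d

    # -- checkpointing -------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {p.name: p.value.copy() for p in self.params()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.params():
            p.value[...] = state[p.name]


class PatchDiscriminator:
    """Score map classifier over (hologram, phase) channel-concatenated pairs.

    Default geometry: six convolutions with strides [2, 2, 2, 2, 1, 1]
    (kernel 4 where the stride is 2, kernel 3 otherwise) so that a
    256 x 256 x 6 input yields a 16 x 16 score map in (0, 1).
    """

    def __init__(
        self,
        in_channels: int = 6,
        base_filters: int = 64,
        max_filters: int = 512,
        strides: tuple[int, ...] = (2, 2, 2, 2, 1, 1),
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        self.in_channels = in_channels
        n = len(strides)
        chans = [min(base_filters * 2**i, max_filters) for i in range(n - 1)] + [1]
        self.layers = []
        self.bns: list[BatchNorm2d | None] = []
        self.acts: list[LeakyReLU | None] = []
        prev = in_channels
        for i, (s, c) in enumerate(zip(strides, chans)):
            k = 4 if s == 2 else 3
            self.layers.append(Conv2d(prev, c, k, s, 1, rng, name=f"disc{i}"))
            self.bns.append(BatchNorm2d(c, name=f"disc{i}.bn") if 1 <= i <= n - 2 else None)
            self.acts.append(LeakyReLU(0.2) if i < n - 1 else None)
            prev = c
        self.sigmoid = Sigmoid()
        self.kernels = [4 if s == 2 else 3 for s in strides]
        self.strides = list(strides)

    def params(self) -> list[Parameter]:
        ps: list[Parameter] = []
        for layer in self.layers:
            ps += layer.params()
        for bn in self.bns:
            if bn is not None:
                ps += bn.params()
        return ps

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        if x.shape[1] != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {x.shape[1]}")
        h = x
        for conv, bn, act in zip(self.layers, self.bns, self.acts):
            h = conv.forward(h, training)
            if bn is not None:
                h = bn.forward(h, training)
            if act is not None:
                h = act.forward(h, training)
        return self.sigmoid.forward(h[:, 0], training)  # (B, Ho, Wo) scores

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.sigmoid.backward(dout)[:, None]
        for conv, bn, act in zip(reversed(self.layers), reversed(self.bns), reversed(self.acts)):
            if act is not None:
                d = act.backward(d)
            if bn is not None:
                d = bn.backward(d)
            d = conv.backward(d)
        return d

    def state_dict(self) -> dict[str, np.ndarray]:
        return {p.name: p.value.copy() for p in self.params()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.params():
            p.value[...] = state[p.name]


def receptive_field(kernels: list[int], strides: list[int]) -> int:
    """Receptive field of one output element of a conv stack, in input pixels."""
    rf, jump = 1, 1
    for k, s in zip(kernels, strides):
        rf += (k - 1) * jump
        jump *= s
    return rf
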