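"""Small configurable 3D U-Net built from the NumPy layers.

Encoder–decoder with skip connections: each level is a double conv block
(conv3–ReLU–conv3–ReLU); levels are joined by 2×2×2 max pooling on the way
down and nearest-neighbour upsampling + channel concatenation on the way up;
a pointwise convolution maps to class logits.  Channel width doubles per
level from ``base_channels``.
"""

from __future__ import annotations

import numpy as np

from .layers import Conv3d, MaxPool2, ReLU, Upsample2


class _DoubleConv:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.layers = [
            Conv3d(c_in, c_out, 3, rng),
            ReLU(),
            Conv3d(c_out, c_out, 3, rng),
            ReLU(),
        ]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def convs(self) -> list[Conv3d]:
        return [self.layers[0], self.layers[2]]


class UNet3D:
    """3D U-Net over ``n_classes`` with ``n_levels`` resolution levels.

    Input spatial dims must be divisible by ``2**(n_levels - 1)``.
    """

    def __init__(
        self,
        in_channels: int = 1,
        n_classes: int = 3,
        base_channels: int = 8,
        n_levels: int = 3,
        seed: int = 0,
    ):
        self.in_channels = in_channels
        self.n_classes = n_classes
        self.base_channels = base_channels
        self.n_levels = n_levels
        rng = np.random.default_rng(seed)
        widths = [base_channels * 2**l for l in range(n_levels)]
        self.enc = []
        c_prev = in_channels
        for w in widths:
            self.enc.append(_DoubleConv(c_prev, w, rng))
            c_prev = w
        self.pools = [MaxPool2() for _ in range(n_levels - 1)]
        self.ups = [Upsample2() for _ in range(n_levels - 1)]
        self.dec = []
        for l in range(n_levels - 2, -1, -1):
            self.dec.append(_DoubleConv(widths[l + 1] + widths[l], widths[l], rng))
        self.head = Conv3d(widths[0], n_classes, 1, rng)

    # -- parameter access -------------------------------------------------
    def _convs(self) -> list[Conv3d]:
        convs: list[Conv3d] = []
        for block in self.enc + self.dec:
            convs.extend(block.convs())
        convs.append(self.head)
        return convs

    def params(self) -> list[np.ndarray]:
        return [p for c in self._convs() for p in c.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for c in self._convs() for g in c.grads()]

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        own = self.params()
        if len(own) != len(weights):
            raise ValueError(
                f"expected {len(own)} weight arrays, got {len(weights)}"
            )
        for p, w in zip(own, weights):
            p[...] = w

    @property
    def arch(self) -> dict:
        return {
            "in_channels": self.in_channels,
            "n_classes": self.n_classes,
            "base_channels": self.base_channels,
            "n_levels": self.n_levels,
        }

    # -- forward / backward -----------------------------------------------
    # Activations flow channels-leading (C, B, D, H, W) between layers; the
    # public interface uses conventional (B, C, D, H, W) arrays.
    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(np.swapaxes(x, 0, 1), dtype=np.float32)
        skips = []
        for l, block in enumerate(self.enc):
            x = block.forward(x)
            if l < self.n_levels - 1:
                skips.append(x)
                x = self.pools[l].forward(x)
        self._skip_channels = [s.shape[0] for s in skips]
        for i, block in enumerate(self.dec):
            up = self.ups[i].forward(x)
            x = np.concatenate([up, skips[-(i + 1)]], axis=0)
            x = block.forward(x)
        return np.ascontiguousarray(np.swapaxes(self.head.forward(x), 0, 1))

    def backward(self, dlogits: np.ndarray) -> None:
        dlogits = np.ascontiguousarray(np.swapaxes(dlogits, 0, 1), dtype=np.float32)
        dy = self.head.backward(dlogits)
        dskips: list[np.ndarray] = []
        for i in range(len(self.dec) - 1, -1, -1):
            dcat = self.dec[i].backward(dy)
            c_skip = self._skip_channels[-(i + 1)]
            dup, dskip = dcat[:-c_skip], dcat[-c_skip:]
            dskips.append(dskip)  # i descends, so skip levels arrive 0, 1, ...
            dy = self.ups[i].backward(np.ascontiguousarray(dup))
        # mirror the encoder: deepest level has no pool/skip
        for l in range(self.n_levels - 1, -1, -1):
            if l < self.n_levels - 1:
                dy = self.pools[l].backward(dy)
                dy = dy + dskips[l]
            dy = self.enc[l].backward(dy)
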