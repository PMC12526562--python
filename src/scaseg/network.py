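"""The attention/inception 3D U-Net.

Encoder-decoder with five resolution levels (four 2x2x2 max-poolings and
four learned stride-2 upsamplings).  Every convolutional stage is a
simplified inception module with two branches: the main branch chains
1x1x1 -> 3x3x3 -> 3x3x3 convolutions and keeps all three intermediate maps,
while a side branch applies a shape-preserving 3x3x3 max pool followed by a
1x1x1 convolution; the four maps are concatenated and instance-normalized.
Each skip connection passes through a stack of convolutional block attention
modules (CBAM): channel attention (global max+average pooling through a
shared bottleneck perceptron, sigmoid-gated) followed by spatial attention
whose 7x7x7 receptive field is realized as three consecutive 3x3x3
convolutions.  The head is dropout -> 1x1x1 convolution -> softmax.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import List, Optional

import numpy as np
from scipy.special import expit

from . import nn
from .config import ModelConfig


def branch_widths(f_out: int, fractions) -> List[int]:
    ws = []
    for fr in fractions:
        w = f_out * fr
        if abs(w - round(w)) > 1e-9 or round(w) < 1:
            raise ValueError(f"branch width {w} is not a positive integer")
        ws.append(int(round(w)))
    if sum(ws) != f_out:
        raise ValueError("branch widths do not sum to f_out")
    return ws


class InceptionModule(nn.Module):
    """Two-branch multi-scale block producing ``f_out`` channels."""

    def __init__(self, c_in, f_out, fractions=(0.25, 0.25, 0.25, 0.25),
                 bias=True, affine=True, name="im"):
        w1, w2, w3, w4 = branch_widths(f_out, fractions)
        self.widths = (w1, w2, w3, w4)
        self.c_in, self.f_out = c_in, f_out
        self.conv1 = nn.Conv3d(c_in, w1, 1, bias, f"{name}.c1")
        self.conv2 = nn.Conv3d(w1, w2, 3, bias, f"{name}.c2")
        self.conv3 = nn.Conv3d(w2, w3, 3, bias, f"{name}.c3")
        self.pool = nn.MaxPool3dSame()
        self.conv4 = nn.Conv3d(c_in, w4, 1, bias, f"{name}.c4")
        self.relus = [nn.ReLU() for _ in range(4)]
        self.norm = nn.InstanceNorm(f_out, affine, name=f"{name}.n")

    def init(self, rng):
        for m in (self.conv1, self.conv2, self.conv3, self.conv4, self.norm):
            m.init(rng)

    def params(self):
        out = []
        for m in (self.conv1, self.conv2, self.conv3, self.conv4, self.norm):
            out.extend(m.params())
        return out

    def forward(self, x, training=False):
        a1 = self.relus[0].forward(self.conv1.forward(x, training), training)
        a2 = self.relus[1].forward(self.conv2.forward(a1, training), training)
        a3 = self.relus[2].forward(self.conv3.forward(a2, training), training)
        p = self.pool.forward(x, training)
        a4 = self.relus[3].forward(self.conv4.forward(p, training), training)
        cat = np.concatenate([a1, a2, a3, a4], axis=0)
        return self.norm.forward(cat, training)

    def backward(self, dy):
        d = self.norm.backward(dy)
        w1, w2, w3, w4 = self.widths
        d1, d2, d3, d4 = np.split(d, np.cumsum([w1, w2, w3])[:3], axis=0)
        dx = self.pool.backward(self.conv4.backward(self.relus[3].backward(d4)))
        da2 = self.conv3.backward(self.relus[2].backward(d3))
        da1 = self.conv2.backward(self.relus[1].backward(d2 + da2))
        dx += self.conv1.backward(self.relus[0].backward(d1 + da1))
        return dx


class ChannelAttention(nn.Module):
    """Global max+average pooled descriptors through a shared two-layer
    perceptron (reduction ``r``), summed and sigmoid-gated per channel."""

    def __init__(self, channels, reduction, bias=True, name="cam"):
        if channels // reduction < 1:
            raise ValueError("channels/reduction must be >= 1")
        hidden = channels // reduction
        self.channels = channels
        self.fc1 = nn.Dense(channels, hidden, bias, f"{name}.fc1")
        self.fc2 = nn.Dense(hidden, channels, bias, f"{name}.fc2")

    def init(self, rng):
        self.fc1.init(rng)
        self.fc2.init(rng)

    def params(self):
        return self.fc1.params() + self.fc2.params()

    def _mlp(self, s, training, cache):
        h = self.fc1.forward(s, training)
        hr = np.maximum(h, 0)
        o = self.fc2.forward(hr, training)
        if training:
            cache.append((self.fc1._cache, h > 0, self.fc2._cache))
        return o

    def forward(self, x, training=False):
        c = x.shape[0]
        xf = x.reshape(c, -1)
        s_avg = xf.mean(axis=1)
        amax = xf.argmax(axis=1)
        s_max = xf[np.arange(c), amax]
        mlp_caches = []
        o = self._mlp(s_avg, training, mlp_caches) + self._mlp(s_max, training, mlp_caches)
        gate = expit(o)
        y = x * gate[:, None, None, None]
        if training:
            self._cache = (x, gate, amax, mlp_caches, x.shape)
        return y.astype(nn.F32)

    def backward(self, dy):
        x, gate, amax, mlp_caches, shape = self._cache
        self._cache = None
        c = shape[0]
        n = int(np.prod(shape[1:]))
        dgate = (dy * x).sum(axis=(1, 2, 3))
        dx = dy * gate[:, None, None, None]
        do = dgate * gate * (1.0 - gate)
        ds = []
        for fc1_cache, relu_mask, fc2_cache in mlp_caches:
            self.fc2._cache = fc2_cache
            dh = self.fc2.backward(do) * relu_mask
            self.fc1._cache = fc1_cache
            ds.append(self.fc1.backward(dh))
        dxf = dx.reshape(c, n)
        dxf += ds[0][:, None] / n
        dxf[np.arange(c), amax] += ds[1]
        return dxf.reshape(shape).astype(nn.F32)


class SpatialAttention(nn.Module):
    """Channel-wise max/mean maps -> stacked 3x3x3 convolutions -> sigmoid
    gate.  Three stacked 3^3 kernels give the 7^3 receptive field of the
    original single-convolution design with far fewer parameters."""

    def __init__(self, plan=(2, 2, 1), bias=True, name="sam"):
        if plan[-1] != 1:
            raise ValueError("final spatial-attention map must be 1 channel")
        chans = (2,) + tuple(plan)
        self.convs = [nn.Conv3d(chans[i], chans[i + 1], 3, bias, f"{name}.c{i}")
                      for i in range(len(plan))]
        self.relus = [nn.ReLU() for _ in range(len(plan) - 1)]

    def init(self, rng):
        for c in self.convs:
            c.init(rng)

    def params(self):
        out = []
        for c in self.convs:
            out.extend(c.params())
        return out

    def attention_map(self, s, training=False):
        """Gate map from a 2-channel (max, mean) summary lattice."""
        h = s
        for i, conv in enumerate(self.convs):
            h = conv.forward(h, training)
            if i < len(self.convs) - 1:
                h = self.relus[i].forward(h, training)
        return expit(h)

    def forward(self, x, training=False):
        c = x.shape[0]
        amax = x.argmax(axis=0)
        cmax = np.take_along_axis(x, amax[None], axis=0)[0]
        cavg = x.mean(axis=0)
        s = np.stack([cmax, cavg]).astype(nn.F32)
        m = self.attention_map(s, training)
        y = x * m
        if training:
            self._cache = (x, m, amax)
        return y.astype(nn.F32)

    def backward(self, dy):
        x, m, amax = self._cache
        self._cache = None
        c = x.shape[0]
        dm = (dy * x).sum(axis=0, keepdims=True)
        dx = dy * m
        dh = dm * m * (1.0 - m)
        for i in range(len(self.convs) - 1, -1, -1):
            if i < len(self.convs) - 1:
                dh = self.relus[i].backward(dh)
            dh = self.convs[i].backward(dh)
        dcmax, dcavg = dh[0], dh[1]
        dx += dcavg[None] / c
        dxmax = np.zeros_like(x)
        np.put_along_axis(dxmax, amax[None], dcmax[None], axis=0)
        return (dx + dxmax).astype(nn.F32)


class CBAM(nn.Module):
    """Channel attention followed by spatial attention."""

    def __init__(self, channels, reduction=16, plan=(2, 2, 1), bias=True, name="cbam"):
        self.cam = ChannelAttention(channels, reduction, bias, f"{name}.cam")
        self.sam = SpatialAttention(plan, bias, f"{name}.sam")

    def init(self, rng):
        self.cam.init(rng)
        self.sam.init(rng)

    def params(self):
        return self.cam.params() + self.sam.params()

    def forward(self, x, training=False):
        return self.sam.forward(self.cam.forward(x, training), training)

    def backward(self, dy):
        return self.cam.backward(self.sam.backward(dy))


def build_inception_module(c_in, f_out, fractions=(0.25, 0.25, 0.25, 0.25),
                           bias=True, affine=True) -> InceptionModule:
    return InceptionModule(c_in, f_out, fractions, bias, affine)


def build_cbam(channels, reduction=16, plan=(2, 2, 1), bias=True) -> CBAM:
    return CBAM(channels, reduction, plan, bias)


class UNet(nn.Module):
    """Full encoder-decoder; see the module docstring for the topology."""

    def __init__(self, config: ModelConfig):
        config.validate()
        self.config = config
        W = config.encoder_widths
        fr = config.im_branch_fractions
        b, a = config.conv_bias, config.norm_affine
        self.encoders = []
        c = config.in_channels
        for i, f in enumerate(W):
            self.encoders.append(InceptionModule(c, f, fr, b, a, f"enc{i}"))
            c = f
        self.pools = [nn.MaxPool3dStride2() for _ in range(4)]
        # clamp the reduction at shallow levels so narrow variants stay valid
        self.skips = [
            [CBAM(W[i], min(config.cam_reduction, W[i]), config.sam_channel_plan,
                  b, f"skip{i}.{j}")
             for j in range(config.cbam_stack)]
            for i in range(4)
        ]
        self.ups = []
        self.decoders = []
        for i in range(3, -1, -1):
            self.ups.append(nn.ConvTranspose3d(W[i + 1], W[i], b, f"up{i}"))
            self.decoders.append(InceptionModule(2 * W[i], W[i], fr, b, a, f"dec{i}"))
        self.dropout = nn.Dropout(config.dropout_rate)
        self.head = nn.Conv3d(W[0], config.n_classes, 1, True, "head")
        self.softmax = nn.Softmax()

    def init(self, rng):
        for m in self.encoders + self.decoders:
            m.init(rng)
        for stack in self.skips:
            for m in stack:
                m.init(rng)
        for m in self.ups:
            m.init(rng)
        self.head.init(rng)

    def params(self):
        out = []
        for m in self.encoders:
            out.extend(m.params())
        for stack in self.skips:
            for m in stack:
                out.extend(m.params())
        for m in self.ups:
            out.extend(m.params())
        for m in self.decoders:
            out.extend(m.params())
        out.extend(self.head.params())
        return out

    def forward(self, x, training=False, rng=None):
        """Softmax class probabilities, shape (n_classes, *input_shape)."""
        x = np.ascontiguousarray(x, dtype=nn.F32)
        if x.ndim == 3:
            x = x[None]
        if x.shape[0] != self.config.in_channels:
            raise ValueError("channel mismatch")
        if any(s % 16 != 0 for s in x.shape[1:]):
            raise ValueError("input spatial dimensions must be divisible by 16")
        feats = []
        h = x
        for i in range(4):
            h = self.encoders[i].forward(h, training)
            s = h
            for m in self.skips[i]:
                s = m.forward(s, training)
            feats.append(s)
            h = self.pools[i].forward(h, training)
        h = self.encoders[4].forward(h, training)
        for j, i in enumerate(range(3, -1, -1)):
            u = self.ups[j].forward(h, training)
            h = np.concatenate([feats[i], u], axis=0)
            h = self.decoders[j].forward(h, training)
        h = self.dropout.forward(h, training, rng=rng)
        h = self.head.forward(h, training)
        return self.softmax.forward(h, training)

    def backward(self, dprob):
        d = self.softmax.backward(dprob)
        d = self.head.backward(d)
        d = self.dropout.backward(d)
        W = self.config.encoder_widths
        dskips = [None] * 4
        # decoder chain in reverse build order
        for j in range(3, -1, -1):
            i = 3 - j  # encoder level of decoders[j]
            d = self.decoders[j].backward(d)
            ds, du = d[:W[i]], d[W[i]:]
            dskips[i] = ds
            d = self.ups[j].backward(du)
        for i in range(4):
            # propagate skip gradient through the CBAM stack
            g = dskips[i]
            for m in reversed(self.skips[i]):
                g = m.backward(g)
            dskips[i] = g
        d = self.encoders[4].backward(d)
        for i in range(3, -1, -1):
            d = self.pools[i].backward(d)
            d = d + dskips[i]
            d = self.encoders[i].backward(d)
        return d


@dataclass
class NetworkHandle:
    """Opaque model object plus its config; parameter_count is a pure
    function of the config."""

    net: UNet
    config: ModelConfig

    @property
    def parameter_count(self) -> int:
        return self.net.num_params()


def build_network(config: Optional[ModelConfig] = None, seed: int = 0) -> NetworkHandle:
    config = config or ModelConfig()
    net = UNet(config)
    net.init(np.random.default_rng(seed))
    return NetworkHandle(net=net, config=config)


def count_parameters(handle: NetworkHandle) -> int:
    return handle.parameter_count


def bottleneck_shape(input_shape) -> tuple:
    if any(s % 16 != 0 for s in input_shape):
        raise ValueError("input spatial dimensions must be divisible by 16")
    return tuple(s // 16 for s in input_shape)


def save_checkpoint(handle: NetworkHandle, path) -> None:
    arrays = {f"p{i}": p.value for i, p in enumerate(handle.net.params())}
    arrays["__config__"] = np.frombuffer(
        json.dumps(handle.config.to_dict()).encode(), dtype=np.uint8)
    np.savez_compressed(str(path), **arrays)


def load_checkpoint(path) -> NetworkHandle:
    with np.load(str(path)) as data:
        cfg = ModelConfig.from_dict(json.loads(bytes(data["__config__"]).decode()))
        handle = build_network(cfg, seed=0)
        for i, p in enumerate(handle.net.params()):
            arr = data[f"p{i}"]
            if arr.shape != p.value.shape:
                raise ValueError("checkpoint does not match the config")
            p.value[...] = arr
    return handle
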