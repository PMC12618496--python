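"""Grouped 3D convolution as an autodiff primitive.

Implemented as a sum over kernel offsets of strided (B,C,Xo,Yo,Zo) x (O,C)
contractions — no im2col temporaries, so memory stays linear in the input.
Sized for toy volumes, not throughput.
"""
from __future__ import annotations

import numpy as np

from .autodiff import Tensor
from .layers import Module


def conv3d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1,
           padding: int = 1, groups: int = 1) -> Tensor:
    """x: (B, Cin, X, Y, Z); w: (Cout, Cin/groups, kx, ky, kz); b: (Cout,)."""
    B, Cin, X, Y, Z = x.shape
    Cout, Cg, kx, ky, kz = w.shape
    if Cin % groups or Cout % groups or Cg != Cin // groups:
        raise ValueError("channel counts incompatible with groups")
    og = Cout // groups
    pad = padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad), (pad, pad)))
    Xp, Yp, Zp = xp.shape[2:]
    Xo = (Xp - kx) // stride + 1
    Yo = (Yp - ky) // stride + 1
    Zo = (Zp - kz) // stride + 1

    def in_slice(i, j, k):
        return (
            slice(i, i + stride * Xo, stride),
            slice(j, j + stride * Yo, stride),
            slice(k, k + stride * Zo, stride),
        )

    out = np.zeros((B, Cout, Xo, Yo, Zo))
    for g in range(groups):
        cg = slice(g * Cg, (g + 1) * Cg)
        ogs = slice(g * og, (g + 1) * og)
        for i in range(kx):
            for j in range(ky):
                for k in range(kz):
                    xs = xp[(slice(None), cg, *in_slice(i, j, k))]
                    out[:, ogs] += np.einsum(
                        "bcxyz,oc->boxyz", xs, w.data[ogs, :, i, j, k],
                        optimize=True,
                    )
    out += b.data[None, :, None, None, None]

    def backward(grad):
        gw = np.zeros_like(w.data)
        gb = grad.sum(axis=(0, 2, 3, 4))
        gx_pad = np.zeros_like(xp)
        for g in range(groups):
            cg = slice(g * Cg, (g + 1) * Cg)
            ogs = slice(g * og, (g + 1) * og)
            gg = grad[:, ogs]
            for i in range(kx):
                for j in range(ky):
                    for k in range(kz):
                        sl = (slice(None), cg, *in_slice(i, j, k))
                        xs = xp[sl]
                        gw[ogs, :, i, j, k] = np.einsum(
                            "bcxyz,boxyz->oc", xs, gg, optimize=True
                        )
                        gx_pad[sl] += np.einsum(
                            "boxyz,oc->bcxyz", gg, w.data[ogs, :, i, j, k],
                            optimize=True,
                        )
        gx = gx_pad[:, :, pad:pad + X, pad:pad + Y, pad:pad + Z]
        return gx, gw, gb

    return Tensor._from_op(out, (x, w, b), backward)


class Conv3d(Module):
    def __init__(self, rng, in_ch: int, out_ch: int, kernel: int = 3,
                 stride: int = 1, groups: int = 1):
        fan_in = in_ch // groups * kernel**3
        self.weight = Tensor(
            rng.normal(0, 1.0 / np.sqrt(fan_in),
                       size=(out_ch, in_ch // groups, kernel, kernel, kernel)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True)
        self.stride, self.padding, self.groups = stride, kernel // 2, groups

    def __call__(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias, self.stride, self.padding,
                      self.groups)
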