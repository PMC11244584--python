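"""Lightweight FLOP profiler.

Operation counts follow the convention common to single-stage-detector
reporting: only convolution (and any dense) multiply-accumulates are
tallied, and FLOPs = 2 x MACs.  Normalisation layers, activations and
elementwise ops are excluded.  The convention is calibrated once against
the stock baseline model and then applied uniformly to every variant.
"""
from __future__ import annotations

import contextlib

_active: list["FlopTally"] = []


class FlopTally:
    def __init__(self):
        self.macs = 0

    @property
    def flops(self) -> int:
        return 2 * self.macs


@contextlib.contextmanager
def count_macs():
    tally = FlopTally()
    _active.append(tally)
    try:
        yield tally
    finally:
        _active.remove(tally)


def record_conv(conv, out_shape) -> None:
    if not _active:
        return
    n, cout, ho, wo = out_shape
    k = conv.kernel_size
    macs = n * k * k * (conv.in_channels // conv.groups) * cout * ho * wo
    for tally in _active:
        tally.macs += macs
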