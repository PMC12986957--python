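"""Parameter and multiply-accumulate accounting.

Counts follow the single-count MAC convention of the common FLOP counters:
convolutions, linear layers and attention matrix products are counted; batch
normalization, activations, pooling and resampling are not.  Both siamese
temporal streams are included (the encoder runs twice per forward pass).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .config import ModelConfig
from .dgmd import ChangeDetectionNet


@dataclass
class ComplexityReport:
    params: int          # trainable parameter count
    macs: int            # multiply-accumulates, one bi-temporal forward
    input_size: int      # evaluation resolution (square)

    @property
    def params_m(self) -> float:
        return self.params / 1e6

    @property
    def gflops(self) -> float:
        return self.macs / 1e9

    def to_dict(self) -> dict:
        return {"params": self.params, "params_M": round(self.params_m, 2),
                "macs": self.macs, "flops_G": round(self.gflops, 2),
                "input_size": self.input_size}


def complexity_report(cfg: ModelConfig | None = None, input_size: int = 256,
                      model: ChangeDetectionNet | None = None
                      ) -> ComplexityReport:
    """Measure model complexity with a real forward pass at ``input_size``.

    The MAC tally is collected during one bi-temporal forward (batch size 1,
    eval-mode normalization), so it reflects exactly the operations the
    deployed model executes, including both encoder streams.
    """
    if model is None:
        model = ChangeDetectionNet(cfg or ModelConfig(), seed=0)
    model.eval()
    x = np.zeros((1, model.cfg.in_channels, input_size, input_size),
                 np.float32)
    with nn.no_grad(), nn.count_macs() as counter:
        model(nn.Tensor(x), nn.Tensor(x.copy()))
    return ComplexityReport(params=model.n_parameters(), macs=counter[0],
                            input_size=input_size)
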