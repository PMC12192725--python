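"""Analytic parameter and multiply-accumulate accounting.

Parameters are counted exactly as the number of trainable scalars in the
built model.  MACs are summed from closed per-layer formulas over one
forward pass: a k x k convolution contributes Cout*Cin*k^2*Hout*Wout, a
depthwise convolution C*k^2*H*W, a token MLP tokens*in*out; upsampling,
normalisations, activations and pooling are excluded, the convention under
which lightweight segmentation networks report their "GFLOPs" (one
multiply-add counted once).  ``flops=True`` doubles the count for strict
floating-point-operation accounting.

Both counts are independent of weight values and of train/eval mode.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from .model import RMISNet

__all__ = ["ProfileReport", "count_parameters", "count_macs", "profile_model"]

DEFAULT_INPUT_HW = (256, 256)  # headline preprocessing size


@dataclass(frozen=True)
class ProfileReport:
    parameter_count: int
    macs: int
    input_size: tuple[int, int, int]  # (H, W, channels)

    @property
    def parameters_m(self) -> float:
        return round(self.parameter_count / 1e6, 2)

    @property
    def gflops(self) -> float:
        return round(self.macs / 1e9, 2)

    def as_dict(self) -> dict:
        return {
            "parameter_count": self.parameter_count,
            "parameters_m": self.parameters_m,
            "macs": self.macs,
            "gflops": self.gflops,
            "input_size": list(self.input_size),
        }

    def as_text(self) -> str:
        rows = [
            ("parameters", f"{self.parameter_count:,}"),
            ("parameters (M)", f"{self.parameters_m:.2f}"),
            ("MACs", f"{self.macs:,}"),
            ("GFLOPs (giga-MACs)", f"{self.gflops:.2f}"),
            ("input size", "x".join(map(str, self.input_size))),
        ]
        width = max(len(k) for k, _ in rows)
        return "\n".join(f"{k.ljust(width)}  {v}" for k, v in rows)

    def save_json(self, path):
        Path(path).write_text(json.dumps(self.as_dict(), indent=2))


def count_parameters(model) -> int:
    """Exact count of trainable scalars (weights, biases, norm affines)."""
    return model.param_count()


def count_macs(model: RMISNet, input_hw=DEFAULT_INPUT_HW, flops: bool = False) -> int:
    """Closed-form multiply-accumulate count of one forward pass."""
    macs = model.macs(tuple(input_hw))
    return 2 * macs if flops else macs


def profile_model(model: RMISNet, input_hw=DEFAULT_INPUT_HW) -> ProfileReport:
    h, w = input_hw
    return ProfileReport(
        parameter_count=count_parameters(model),
        macs=count_macs(model, input_hw),
        input_size=(h, w, model.config.in_channels),
    )
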