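"""Declarative layer-by-layer CNN architectures with parameter accounting.

Three compact models for 30x30x1 grayscale inputs:

* model 1 — 9 layers: 5x5 conv (16 filters), two 2x2 max-pools around a
  dropout, then dense 256/64/output; 217,954 parameters at 2 classes.
* model 2 — 10 layers: two 3x3 conv blocks (30 then 15 filters) with
  pooling, dense 128/50/output; 80,165 parameters at 2 classes.
* model 3 — 11 layers: three 3x3 conv blocks (30/60/30 filters), dense
  256/64/output; 241,624 parameters at 2 outputs (the published layout),
  241,754 at the 4 glioma classes.

Convolutions are valid-padded, stride 1; max-pooling is 2x2 stride 2 with
ceiling output on odd extents (pad right/bottom), the convention required
for the 13x13 -> 7x7 chain of model 1.  Parameter counts follow the closed
forms: conv = filters*(k*k*in_channels + 1); dense = units*(inputs + 1).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

__all__ = ["LayerSpec", "ArchitectureSpec", "build_architecture", "count_parameters"]


@dataclass(frozen=True)
class LayerSpec:
    name: str
    kind: str  # input | conv | maxpool | dropout | flatten | dense
    config: dict = field(default_factory=dict)
    output_shape: tuple = ()
    param_count: int = 0


@dataclass(frozen=True)
class ArchitectureSpec:
    model_id: int
    layers: tuple[LayerSpec, ...]
    num_classes: int

    @property
    def total_params(self) -> int:
        return sum(l.param_count for l in self.layers)

    def per_layer_params(self) -> dict[str, int]:
        return {l.name: l.param_count for l in self.layers}

    def to_json(self) -> str:
        return json.dumps(
            {
                "model_id": self.model_id,
                "num_classes": self.num_classes,
                "total_params": self.total_params,
                "layers": [
                    {
                        "name": l.name,
                        "kind": l.kind,
                        "config": l.config,
                        "output_shape": list(l.output_shape),
                        "param_count": l.param_count,
                    }
                    for l in self.layers
                ],
            },
            indent=2,
        )

    def table(self) -> str:
        """Aligned per-layer text table (name, kind, output shape, params)."""
        rows = [("Layer", "Kind", "Output shape", "Params")]
        for l in self.layers:
            shape = " x ".join(str(d) for d in l.output_shape)
            rows.append((l.name, l.kind, shape, f"{l.param_count:,}"))
        rows.append(("total", "", "", f"{self.total_params:,}"))
        widths = [max(len(r[i]) for r in rows) for i in range(4)]
        return "\n".join(
            "  ".join(c.ljust(w) for c, w in zip(r, widths)) for r in rows
        )


# layer templates per model: (kind, kwargs)
_TEMPLATES = {
    1: [
        ("input", {}),
        ("conv", {"filters": 16, "kernel": 5}),
        ("maxpool", {"pool": 2}),
        ("dropout", {"rate": 0.20}),
        ("maxpool", {"pool": 2}),
        ("flatten", {}),
        ("dense", {"units": 256, "activation": "relu"}),
        ("dense", {"units": 64, "activation": "relu"}),
        ("dense", {"units": None, "activation": "softmax"}),
    ],
    2: [
        ("input", {}),
        ("conv", {"filters": 30, "kernel": 3}),
        ("maxpool", {"pool": 2}),
        ("conv", {"filters": 15, "kernel": 3}),
        ("maxpool", {"pool": 2}),
        ("dropout", {"rate": 0.20}),
        ("flatten", {}),
        ("dense", {"units": 128, "activation": "relu"}),
        ("dense", {"units": 50, "activation": "relu"}),
        ("dense", {"units": None, "activation": "softmax"}),
    ],
    3: [
        ("input", {}),
        ("conv", {"filters": 30, "kernel": 3}),
        ("maxpool", {"pool": 2}),
        ("conv", {"filters": 60, "kernel": 3}),
        ("dropout", {"rate": 0.20}),
        ("conv", {"filters": 30, "kernel": 3}),
        ("maxpool", {"pool": 2}),
        ("flatten", {}),
        ("dense", {"units": 256, "activation": "relu"}),
        ("dense", {"units": 64, "activation": "relu"}),
        ("dense", {"units": None, "activation": "softmax"}),
    ],
}

INPUT_SHAPE = (30, 30, 1)


def build_architecture(model_id: int, num_classes: int = 2) -> ArchitectureSpec:
    """Construct one of the three model specs with chained shapes and counts."""
    if model_id not in _TEMPLATES:
        raise ValueError(f"unknown model_id {model_id}; expected 1, 2 or 3")
    if num_classes < 2:
        raise ValueError("need at least 2 output classes")
    layers: list[LayerSpec] = []
    shape: tuple = INPUT_SHAPE
    counters: dict[str, int] = {}
    for kind, cfg in _TEMPLATES[model_id]:
        cfg = dict(cfg)
        counters[kind] = counters.get(kind, 0) + 1
        name = "input" if kind == "input" else f"{kind}_{counters[kind]}"
        if kind == "input":
            out, params = INPUT_SHAPE, 0
        elif kind == "conv":
            h, w, cin = shape
            k, f = cfg["kernel"], cfg["filters"]
            if h < k or w < k:
                raise ValueError(f"{name}: input {shape} smaller than kernel {k}")
            out = (h - k + 1, w - k + 1, f)
            params = f * (k * k * cin + 1)
            cfg.setdefault("activation", "relu")
        elif kind == "maxpool":
            h, w, cin = shape
            p = cfg["pool"]
            out = (math.ceil(h / p), math.ceil(w / p), cin)
            params = 0
        elif kind == "dropout":
            out, params = shape, 0
        elif kind == "flatten":
            out = (int(math.prod(shape)),)
            params = 0
        elif kind == "dense":
            if len(shape) != 1:
                raise ValueError(f"{name}: dense requires a flat input, got {shape}")
            units = cfg["units"] if cfg["units"] is not None else num_classes
            cfg["units"] = units
            if shape[0] == 0 or units == 0:
                raise ValueError(f"{name}: degenerate dense layer ({shape[0]} -> {units})")
            out = (units,)
            params = units * (shape[0] + 1)
        else:  # pragma: no cover
            raise ValueError(f"unknown layer kind {kind}")
        layers.append(LayerSpec(name, kind, cfg, out, params))
        shape = out
    return ArchitectureSpec(model_id, tuple(layers), num_classes)


def count_parameters(spec: ArchitectureSpec) -> dict:
    """Re-derive per-layer parameter counts and validate the shape chain.

    Raises ``ValueError`` naming the first layer whose recorded output
    shape or count disagrees with the closed-form recomputation.
    """
    rebuilt = build_architecture(spec.model_id, spec.num_classes)
    for ours, theirs in zip(rebuilt.layers, spec.layers):
        if ours.output_shape != theirs.output_shape:
            raise ValueError(
                f"layer {theirs.name}: inconsistent output shape "
                f"{theirs.output_shape}, expected {ours.output_shape}"
            )
        if ours.param_count != theirs.param_count:
            raise ValueError(
                f"layer {theirs.name}: inconsistent parameter count "
                f"{theirs.param_count}, expected {ours.param_count}"
            )
    return {"per_layer": rebuilt.per_layer_params(), "total": rebuilt.total_params}
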