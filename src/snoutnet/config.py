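"""Model and run configuration.

The detector follows the compact "s"-scale convention of the YOLOv8
family: base channels (64, 128, 256, 512, 512) and base stage depths
(3, 6, 6, 3), scaled by ``width_mult`` and ``depth_mult``.  A variant
name selects which refined component replaces its baseline counterpart;
the three refinements are independent but may be composed through the
explicit ``blocks`` / ``head`` / ``attn`` flags.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Dict, Optional

BASE_CHANNELS = (64, 128, 256, 512, 512)
BASE_DEPTHS = (3, 6, 6, 3)

#: variant -> (blocks, head, attn)
VARIANTS: Dict[str, tuple] = {
    "baseline": ("c2f", "plain", "none"),
    "cspc": ("cspc", "plain", "none"),
    "fasff3": ("c2f", "fasff3", "none"),
    "fasff4": ("c2f", "fasff4", "none"),
    "iema": ("c2f", "plain", "iema"),
}


@dataclass
class ModelConfig:
    variant: str = "baseline"
    depth_mult: float = 0.33
    width_mult: float = 0.50
    num_classes: int = 4
    reg_max: int = 16
    input_size: int = 640
    seed: int = 0
    # component overrides; None means "use the variant's preset"
    blocks: Optional[str] = None   # c2f | cspc
    head: Optional[str] = None     # plain | fasff3 | fasff4
    attn: Optional[str] = None     # none | ema | irmb | iema

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(
                f"unknown variant {self.variant!r}; registered: {sorted(VARIANTS)}")
        if self.reg_max < 2:
            raise ValueError("reg_max must be >= 2")
        if self.input_size % 32 != 0:
            raise ValueError("input_size must be divisible by 32")

    def resolved(self) -> tuple:
        b, h, a = VARIANTS[self.variant]
        return (self.blocks or b, self.head or h, self.attn or a)

    def channels(self) -> tuple:
        return tuple(max(8, int(round(c * self.width_mult / 8)) * 8)
                     for c in BASE_CHANNELS)

    def depths(self) -> tuple:
        return tuple(max(1, round(d * self.depth_mult)) for d in BASE_DEPTHS)

    def to_dict(self) -> dict:
        return asdict(self)

    @staticmethod
    def from_dict(d: dict) -> "ModelConfig":
        return ModelConfig(**d)


# ---------------------------------------------------------------------------
# run configuration (YAML schema)
# ---------------------------------------------------------------------------

_SCHEMA = {
    "data": {"root": str, "dialect": str,
             "split": {"fractions": list, "seed": int},
             "on_the_fly_aug": bool},
    "aug": {"rotation_deg": (int, float), "flip_p": (int, float),
            "jitter": (int, float)},
    "model": {"variant": str, "depth_mult": (int, float),
              "width_mult": (int, float), "num_classes": int,
              "reg_max": int, "input_size": int, "seed": int,
              "blocks": str, "head": str, "attn": str},
    "schedule": {"epochs": int, "batch_size": int,
                 "lr_init": (int, float), "lr_final": (int, float),
                 "warmup_epochs": (int, float), "weight_decay": (int, float),
                 "grad_clip_norm": (int, float), "early_stop_patience": int,
                 "seed": int, "seeds": list, "val_interval": int},
    "eval": {"conf_threshold": (int, float), "iou_threshold": (int, float)},
}


def validate_run_config(cfg: dict, schema: dict = _SCHEMA, path: str = "") -> None:
    """Reject unknown keys and badly typed values before any work starts."""
    if not isinstance(cfg, dict):
        raise ValueError(f"config section {path or '<root>'} must be a mapping")
    for key, value in cfg.items():
        where = f"{path}.{key}" if path else key
        if key not in schema:
            raise ValueError(f"unknown config key: {where!r} "
                             f"(known: {sorted(schema)})")
        expected = schema[key]
        if isinstance(expected, dict):
            validate_run_config(value, expected, where)
        elif not isinstance(value, expected):
            raise ValueError(f"config key {where!r} has type "
                             f"{type(value).__name__}, expected {expected}")
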