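"""Run configuration and reproducibility plumbing.

A :class:`RunConfig` is fully serializable (YAML/JSON); a run's config
plus its master seed reproduce its outputs exactly.  The master seed is
expanded into per-component child seeds through a documented splitting
rule (``SeedSequence([master, crc32(label)])``), so each pipeline stage
is independently reproducible.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .models import Variant

VARIANT_ALIASES = {
    "elg": Variant.ELIGIBILITY,
    "eligibility": Variant.ELIGIBILITY,
    "tab": Variant.TABULAR,
    "tabular": Variant.TABULAR,
    "hybrid": Variant.HYBRID,
    "hybrid1l": Variant.HYBRID_1L,
    "hybrid_1l": Variant.HYBRID_1L,
    "hybrid1d": Variant.HYBRID_1D,
    "hybrid_1d": Variant.HYBRID_1D,
}


def parse_variant(name: str) -> Variant:
    try:
        return VARIANT_ALIASES[name.lower()]
    except KeyError:
        raise ValueError(
            f"unknown model {name!r}; choose from {sorted(VARIANT_ALIASES)}"
        ) from None


def parse_window(value) -> Optional[int]:
    """Normalization-window flag: an integer number of trials, 0 to
    disable scaling, or 'all' for a whole-task window."""
    if isinstance(value, str):
        if value.lower() == "all":
            return None
        value = int(value)
    if value is None:
        return None
    if value < 0:
        raise ValueError("normalization window must be >= 0 or 'all'")
    return int(value)


def split_seed(master: int, label: str) -> np.random.SeedSequence:
    """Deterministic per-component child seed: the master entropy is
    extended with the CRC-32 of the component label."""
    return np.random.SeedSequence([int(master), zlib.crc32(label.encode())])


@dataclass
class RunConfig:
    """Everything a pipeline run needs; defaults mirror the task's
    study conditions (8 stimuli x 12 repeats = 336 trials, walk step
    SD 0.5, 3 walks, 5-trial normalization window)."""

    seed: int = 0
    n_participants: int = 8
    n_repeats: int = 12
    step_scale: float = 0.5
    n_walks: int = 3
    model: str = "hybrid"
    zwindow: str = "5"
    skip_absent_components: bool = False
    beta_min: float = 0.0
    optimizer_popsize: int = 15
    optimizer_maxiter: int = 60
    optimizer_tol: float = 1e-6

    @property
    def variant(self) -> Variant:
        return parse_variant(self.model)

    @property
    def norm_window(self) -> Optional[int]:
        return parse_window(self.zwindow)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"invalid config fields: {sorted(unknown)}")
        return cls(**data)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
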