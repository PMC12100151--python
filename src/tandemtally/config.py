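"""Pipeline configuration: TOML file merged with CLI overrides.

Every run echoes its effective configuration (and a short hash of it) into
output headers so any result file can be traced to the exact parameters and
seed that produced it.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .count import UnitParams
from .plasmid import DEFAULT_ENZYMES, PlasmidMap, RestrictionEnzyme
from .select import AnchorParams
from .simulate import ClipModel, ErrorModel

__all__ = ["PipelineConfig", "load_config", "config_hash"]


@dataclass
class PipelineConfig:
    vector_fasta: str | None = None
    unit_fasta: str | None = None
    array_insert_pos: int = 0
    enzyme: str = "PmlI"
    enzymes: dict[str, RestrictionEnzyme] = field(
        default_factory=lambda: dict(DEFAULT_ENZYMES)
    )
    anchor: AnchorParams = field(default_factory=AnchorParams)
    unit: UnitParams = field(default_factory=UnitParams)
    error: ErrorModel = field(default_factory=ErrorModel)
    clip: ClipModel = field(default_factory=ClipModel)
    normalization: str = "mean"
    include_partial: bool = False
    seed: int = 1
    out_dir: str = "tandemtally_out"

    def plasmid_map(self) -> PlasmidMap:
        """Build the construct from configured FASTAs, or fall back to the
        packaged synthetic default construct."""
        if self.vector_fasta and self.unit_fasta:
            from .seqio import read_fasta

            vector = next(iter(read_fasta(self.vector_fasta).values()))
            unit = next(iter(read_fasta(self.unit_fasta).values()))
            return PlasmidMap(
                vector, self.array_insert_pos, unit, self.enzymes[self.enzyme]
            )
        from .constructs import default_plasmid_map

        return default_plasmid_map()

    def header_lines(self, extra: dict | None = None) -> list[str]:
        from . import __version__

        info = {"tool": f"tandemtally {__version__}",
                "config": config_hash(self), "seed": self.seed}
        info.update(extra or {})
        return [" ".join(f"{k}={v}" for k, v in info.items())]


def _as_dict(cfg: PipelineConfig) -> dict:
    d = {}
    for k, v in vars(cfg).items():
        if hasattr(v, "__dataclass_fields__"):
            d[k] = vars(v)
        elif isinstance(v, dict):
            d[k] = {
                kk: vars(vv) if hasattr(vv, "__dataclass_fields__") else vv
                for kk, vv in v.items()
            }
        else:
            d[k] = v
    return d


def config_hash(cfg: PipelineConfig) -> str:
    d = _as_dict(cfg)
    d.pop("out_dir", None)  # where output lands does not change what it is
    blob = json.dumps(d, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Read a TOML config; keyword overrides win over file values."""
    data: dict = {}
    if path is not None:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    cfg = PipelineConfig()
    enzymes = dict(DEFAULT_ENZYMES)
    for name, entry in data.pop("enzymes", {}).items():
        enzymes[name] = RestrictionEnzyme(
            name, entry["recognition"], entry.get("cut_offset")
        )
    cfg.enzymes = enzymes
    for section, cls in (
        ("anchor", AnchorParams), ("unit", UnitParams),
        ("error", ErrorModel), ("clip", ClipModel),
    ):
        if section in data:
            setattr(cfg, section, cls(**data.pop(section)))
    for key, val in {**data, **overrides}.items():
        if not hasattr(cfg, key):
            raise KeyError(f"unknown config key {key!r}")
        setattr(cfg, key, val)
    return cfg
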