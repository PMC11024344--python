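"""Pipeline configuration: one validated mapping for every stage.

Configs load from YAML (or plain dicts).  Unknown keys are rejected up
front — a typo must fail before any computation — and every run writes a
resolved copy of the config alongside its results for provenance.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

__all__ = ["PipelineConfig", "SimulationBlock", "SegmentationBlock",
           "NullBlock", "PunctaBlock", "StatsBlock"]


def _from_mapping(cls, data: dict, path: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in config section "
                         f"{path!r}; allowed: {sorted(allowed)}")
    return cls(**data)


@dataclass
class SimulationBlock:
    """Synthetic-cohort settings (see ``synthetic.NicheConfig`` for units)."""

    n_animals_per_group: dict = field(default_factory=lambda: {"WT": 8, "iKD": 8})
    distance_offset_um: dict = field(default_factory=dict)
    between_animal_sd_um: float = 0.8
    n_cells_per_type: dict | None = None
    image_size_px: list = field(default_factory=lambda: [384, 1600])
    n_sections: int = 4
    pixel_size_um: float = 0.5
    band_halfwidth_um: float = 10.0
    vessel_density_um_per_um2: float = 0.04
    vessel_radius_um: float = 2.5
    hoechst_density_per_100um: float = 30.0


@dataclass
class SegmentationBlock:
    channel: str = "CD31"
    threshold: str | float = "otsu"
    min_area_um2: float = 20.0
    min_elongation: float = 2.5


@dataclass
class NullBlock:
    spacing_um: float = 100.0


@dataclass
class PunctaBlock:
    channel: str = "Vegfa"
    threshold: str | float = "otsu"
    min_separation_px: int = 2


@dataclass
class StatsBlock:
    alpha: float = 0.05
    phenotypes: list = field(default_factory=lambda: ["RGL-NSC", "IPC"])
    rule_set: str = "reporter"


@dataclass
class PipelineConfig:
    """Top-level configuration: all stage blocks plus seed and output dir."""

    simulation: SimulationBlock = field(default_factory=SimulationBlock)
    segmentation: SegmentationBlock = field(default_factory=SegmentationBlock)
    null_sampling: NullBlock = field(default_factory=NullBlock)
    puncta: PunctaBlock = field(default_factory=PunctaBlock)
    stats: StatsBlock = field(default_factory=StatsBlock)
    seed: int = 0
    out_dir: str = "results"

    _BLOCKS = {"simulation": SimulationBlock, "segmentation": SegmentationBlock,
               "null_sampling": NullBlock, "puncta": PunctaBlock,
               "stats": StatsBlock}

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        allowed = set(cls._BLOCKS) | {"seed", "out_dir"}
        unknown = set(data) - allowed
        if unknown:
            raise ValueError(f"unknown top-level config key(s) {sorted(unknown)}; "
                             f"allowed: {sorted(allowed)}")
        kwargs = {}
        for name, blk_cls in cls._BLOCKS.items():
            if name in data:
                kwargs[name] = _from_mapping(blk_cls, data[name] or {}, name)
        for scalar in ("seed", "out_dir"):
            if scalar in data:
                kwargs[scalar] = data[scalar]
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("_BLOCKS", None)
        return d

    def write_resolved(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
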