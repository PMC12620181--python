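"""Study configuration: validated sections, YAML round trip, content hash."""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .io import config_hash

__all__ = ["StudyConfig", "default_study_config"]

_SECTION_KEYS = {
    "sequence": {
        "n_blocks", "block_duration", "prep_durations", "prep_angles", "td1",
        "prep_to_readout_gap", "shots_per_block", "profiles_per_shot", "tr",
        "te", "flip_deg", "n_repetitions",
    },
    "dictionary": {"t1_stride", "t2_stride", "b0_min", "b0_max", "b0_step",
                   "time_step", "k"},
    "trajectory": {"acceleration", "n_repetitions", "turns"},
    "phantom": {"matrix", "n_vials", "t1_range", "t2_range", "ff_values",
                "b0_profile", "b0_max", "n_coils", "voxel_size"},
    "motion": {"period", "amplitude", "drift", "noise_sd", "gain", "enabled"},
    "noise": {"fraction", "coil_correlation"},
    "recon": {"lam", "rho", "admm_iters", "cg_iters", "fgp_iters"},
    "waterfat": {"preset", "field_strength", "candidate_step", "smoothness"},
    "matching": {"b0_extension_steps"},
}


@dataclass
class StudyConfig:
    """Nested study configuration with strict key checking."""

    sections: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        for name, sec in self.sections.items():
            if name not in _SECTION_KEYS:
                raise ValueError(f"unknown config section {name!r}")
            unknown = set(sec) - _SECTION_KEYS[name]
            if unknown:
                raise ValueError(
                    f"unknown keys in section {name!r}: {sorted(unknown)}"
                )

    def get(self, section: str, key: str, default=None):
        return self.sections.get(section, {}).get(key, default)

    def to_dict(self) -> dict:
        return {"seed": self.seed, "sections": self.sections}

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        extra = set(d) - {"seed", "sections"}
        if extra:
            raise ValueError(f"unknown top-level config keys: {sorted(extra)}")
        return cls(sections=d.get("sections", {}), seed=int(d.get("seed", 0)))

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path_or_text) -> "StudyConfig":
        try:
            with open(path_or_text) as fh:
                d = yaml.safe_load(fh)
        except (OSError, TypeError):
            d = yaml.safe_load(path_or_text)
        return cls.from_dict(d or {})

    @property
    def hash(self) -> str:
        return config_hash(self.to_dict())


def default_study_config(seed: int = 0) -> StudyConfig:
    """Configuration of the standard synthetic study (48 x 48 x 12)."""
    return StudyConfig(seed=seed, sections={
        "phantom": {"matrix": [48, 48, 12], "n_vials": 8,
                    "t1_range": [300.0, 1500.0], "t2_range": [15.0, 100.0],
                    "ff_values": [0.0, 0.0, 0.05, 0.12, 0.25],
                    "b0_profile": "per_vial", "b0_max": 60.0,
                    "n_coils": 4, "voxel_size": 3.0},
        "dictionary": {"b0_min": -140.0, "b0_max": 140.0, "b0_step": 20.0,
                       "time_step": 0.01, "k": 5},
        "trajectory": {"acceleration": 7.5},
        "motion": {"period": 3.7, "amplitude": 1.0, "drift": 0.1,
                   "noise_sd": 0.02, "gain": 10.0, "enabled": True},
        "noise": {"fraction": 0.05},
        "recon": {"lam": 0.01, "rho": 0.01, "admm_iters": 12,
                  "cg_iters": 25, "fgp_iters": 30},
        "waterfat": {"preset": "in_vivo_9peak", "field_strength": 3.0,
                     "candidate_step": 2.0, "smoothness": 2e-4},
        "matching": {"b0_extension_steps": 2},
    })
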