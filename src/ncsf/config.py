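"""Shared constants and the serializable run configuration.

All magic numbers of the method live here: the fixed left-branch width of
the contrast sensitivity function, the standard reference CSF used for AUC
normalization, the AUC integration interval, and the default fitting /
simulation settings. Everything is overridable and round-trips through
YAML or JSON.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

#: Fixed fall-off rate of the left (low spatial frequency) branch.
WIDTH_L_DEFAULT = 0.68

#: Standard reference CSF of healthy controls: (cs_p, sf_p, width_l, width_r).
STANDARD_CSF = (166.0, 2.5, 0.68, 1.28)

#: Spatial-frequency interval (c/deg) over which the normalized AUC is taken.
AUC_INTERVAL = (0.5, 18.0)

#: Number of log-spaced quadrature points for the AUC integral.
AUC_GRID_POINTS = 200

#: Floor applied to CSF sensitivity before forming the semisaturation contrast.
SENSITIVITY_EPS = 1e-6

#: Spatial frequencies of the stimulus protocol (c/deg).
STIMULUS_SFS = (0.5, 1.0, 3.0, 6.0, 12.0, 18.0)

#: Michelson contrast range of the protocol (%).
CONTRAST_RANGE = (0.25, 80.0)


@dataclass
class RunConfig:
    """Bundle of tunable settings for a full design/simulate/fit run."""

    tr: float = 1.5
    block_duration: float = 18.0
    blank_duration: float = 15.0
    sfs: tuple[float, ...] = STIMULUS_SFS
    contrast_range: tuple[float, float] = CONTRAST_RANGE
    n_contrasts: int = 12
    order_seed: int = 2024
    width_l: float = WIDTH_L_DEFAULT
    standard_csf: tuple[float, float, float, float] = STANDARD_CSF
    auc_interval: tuple[float, float] = AUC_INTERVAL
    auc_grid_points: int = AUC_GRID_POINTS
    michelson_to_rms: bool = False
    r2_threshold: float = 30.0
    hrf_coefficients: tuple[float, float, float] = (1.0, 1.0, 0.0)
    extra: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        # tuples -> lists for clean YAML/JSON
        return json.loads(json.dumps(d))

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs = {k: v for k, v in d.items() if k in known}
        for key in ("sfs", "contrast_range", "standard_csf", "auc_interval",
                    "hrf_coefficients"):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (json.dumps(self.to_dict(), indent=2)
                if path.suffix == ".json"
                else yaml.safe_dump(self.to_dict(), sort_keys=False))
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        raw = path.read_text()
        data = json.loads(raw) if path.suffix == ".json" else yaml.safe_load(raw)
        return cls.from_dict(data)
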