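"""YAML configuration for processing and simulation runs.

Recognized keys (all optional):

``expansion_factor``      float >= 1, expansion applied to difference layer 2
``base_map``              "identity" or "linear"
``out_low_db``            scalar or ``[[freq_hz, db], ...]`` breakpoint list
``out_high_db``           scalar or breakpoint list
``calibration_dbspl_fs``  dB SPL of a full-scale sine (default 120)
``profile``               listener profile name such as "P-2000-14"
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .envelope import CALIBRATION_DBSPL_FS

__all__ = ["PlattConfig", "load_config"]


@dataclass
class PlattConfig:
    expansion_factor: float = 1.0
    base_map: str = "identity"
    out_low_db: object = None
    out_high_db: object = None
    calibration_dbspl_fs: float = CALIBRATION_DBSPL_FS
    profile: str | None = None
    extra: dict = field(default_factory=dict)

    def output_limits(self, channel_freqs_hz: np.ndarray):
        """Resolve scalar/breakpoint output limits to per-channel vectors."""
        def resolve(v):
            if v is None:
                return None
            if np.isscalar(v):
                return np.full(len(channel_freqs_hz), float(v))
            bp = np.asarray(v, dtype=float)
            return np.interp(
                np.log10(channel_freqs_hz), np.log10(bp[:, 0]), bp[:, 1]
            )

        return resolve(self.out_low_db), resolve(self.out_high_db)


def load_config(path) -> PlattConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in PlattConfig.__dataclass_fields__ if f != "extra"}
    kwargs = {k: v for k, v in raw.items() if k in known}
    extra = {k: v for k, v in raw.items() if k not in known}
    return PlattConfig(**kwargs, extra=extra)
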