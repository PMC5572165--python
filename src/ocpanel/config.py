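"""Pipeline configuration: defaults, YAML loading, validation.

The default profile encodes the study conventions used throughout the
package: calibration FPR alpha = 0.05, the CA125 35 U/ml referral cutoff
kept fixed, yearly tDx bins with a pooled >4y bin, pooled control
specificity, per-sample sensitivity, and the standard eight panels (CA125
alone as reference, each marker with CA125, the pairwise combinations with
CA125, and the full panel).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import yaml

from .errors import ConfigurationError
from .panels import MARKER_DIRECTIONS, PUBLISHED_THRESHOLDS

DEFAULT_PANEL_MARKERS: list[list[str]] = [
    ["ca125"],
    ["igfbp2", "ca125"],
    ["lcat", "ca125"],
    ["shbg", "ca125"],
    ["shbg", "igfbp2", "ca125"],
    ["lcat", "shbg", "ca125"],
    ["igfbp2", "lcat", "ca125"],
    ["igfbp2", "lcat", "shbg", "ca125"],
]

REFERENCE_PANEL_NAME = "CA125"
HEADLINE_PANEL_NAME = "IGFBP2:LCAT:CA125"


@dataclass
class PipelineConfig:
    input_path: Optional[str] = None      # cohort CSV/TSV; None -> simulate
    simulate: bool = False
    seed: int = 0
    alpha: float = 0.05
    panels: list[list[str]] = field(default_factory=lambda: [list(p) for p in DEFAULT_PANEL_MARKERS])
    fixed_thresholds: dict[str, float] = field(
        default_factory=lambda: {"ca125": PUBLISHED_THRESHOLDS["ca125"][1]}
    )
    use_published_thresholds: bool = False  # apply 78.5/8.831/16.1/35 verbatim
    bin_edges_days: Optional[list[float]] = None  # finite lower edges; last bin open
    month_days: float = 30.4375
    specificity_mode: str = "pooled"      # "pooled" | "binned"
    sensitivity_unit: str = "per_sample"  # "per_sample" | "per_subject"
    leadtime_mode: str = "model"          # "model" | "either"
    missing_policy: str = "negative"      # "negative" | "error"
    scaling_reference: str = "all_samples"
    output_dir: str = "ocpanel-report"
    make_plots: bool = True

    def validate(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ConfigurationError(f"alpha must be in (0, 1), got {self.alpha}")
        for panel in self.panels:
            if not panel:
                raise ConfigurationError("panel with no markers in config")
            for marker in panel:
                if marker not in MARKER_DIRECTIONS:
                    raise ConfigurationError(
                        f"panel references unknown marker {marker!r}"
                    )
        for mode, allowed in (
            (self.specificity_mode, ("pooled", "binned")),
            (self.sensitivity_unit, ("per_sample", "per_subject")),
            (self.leadtime_mode, ("model", "either")),
            (self.missing_policy, ("negative", "error")),
            (self.scaling_reference, ("all_samples", "controls_only")),
        ):
            if mode not in allowed:
                raise ConfigurationError(f"{mode!r} not one of {allowed}")
        if self.input_path is None and not self.simulate:
            raise ConfigurationError("either input_path or simulate must be set")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        config = cls(**raw)
        config.validate()
        return config


def bins_from_edges(edges: Sequence[float]):
    """Build half-open bins from finite lower edges; the last bin is open-ended."""
    import numpy as np

    from .preprocess import TimeBin

    edges = sorted(float(e) for e in edges)
    if not edges or edges[0] != 0.0:
        raise ConfigurationError("bin edges must start at 0")
    bins = []
    for lo, hi in zip(edges, edges[1:] + [np.inf]):
        label = f"{lo:g}-{hi:g}d" if np.isfinite(hi) else f">{lo:g}d"
        bins.append(TimeBin(label, lo, hi))
    return bins
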