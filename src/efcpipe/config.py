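"""Pipeline configuration: every stage parameter with validated defaults."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from ._validation import require


@dataclass
class PipelineConfig:
    """All stage parameters.

    Defaults follow the analysis conventions used throughout the package:
    discard 5 volumes, 70% cumulative PCA variance for nuisance selection,
    0.25 Hz low-pass, t > 2 with FDR q 0.05 and >= 2 contiguous voxels,
    dendrogram cut at 0.7, reporting threshold r > 0.3, Dice overlap
    criterion |dr| <= 0.15 and edge export at r > 0.5.
    """

    # preprocessing
    n_discard: int = 5
    cum_var: float = 0.70
    lowpass_cutoff: float = 0.25
    filter_order: int = 5
    stop_atten: float = 40.0
    # GLM / activation
    t_min: float = 2.0
    fdr_q: float = 0.05
    min_contig: int = 2
    connectivity: int = 6
    psc_baseline: str = "rest_tail"  # or "all_rest"
    cycle_window_s: float = 46.0
    # HRF
    hrf_peak_delay: float = 6.0
    hrf_undershoot_delay: float = 16.0
    hrf_peak_dispersion: float = 1.0
    hrf_undershoot_dispersion: float = 1.0
    hrf_undershoot_ratio: float = 1.0 / 6.0
    ppi_hrf: str = "fitted"  # "fitted" two-gamma from the seed, or "canonical"
    # clustering / comparison
    cut_height: float = 0.7
    corr_threshold: float = 0.3
    dice_delta_r: float = 0.15
    edge_r_min: float = 0.5
    power_edge_set: str = "first_suprathreshold"
    # seeds / synthesis
    seed: int = 0
    seed_roi: str | None = None

    def __post_init__(self) -> None:
        require(self.n_discard >= 0, "n_discard must be >= 0")
        require(0 < self.cum_var <= 1, "cum_var must be in (0, 1]")
        require(self.lowpass_cutoff > 0, "lowpass_cutoff must be > 0")
        require(self.filter_order >= 1, "filter_order must be >= 1")
        require(self.stop_atten > 0, "stop_atten must be > 0")
        require(0 < self.fdr_q < 1, "fdr_q must be in (0, 1)")
        require(self.min_contig >= 1, "min_contig must be >= 1")
        require(self.connectivity in (6, 18, 26), "connectivity must be 6, 18 or 26")
        require(self.psc_baseline in ("rest_tail", "all_rest"), "unknown psc_baseline")
        require(self.cut_height >= 0, "cut_height must be >= 0")
        require(self.dice_delta_r >= 0, "dice_delta_r must be >= 0")
        require(self.ppi_hrf in ("fitted", "canonical"), "ppi_hrf must be 'fitted' or 'canonical'")
        require(
            self.power_edge_set in ("first_suprathreshold", "all", "union"),
            "unknown power_edge_set",
        )

    def hrf_spec(self):
        from .hrf_glm import HRFSpec

        return HRFSpec(
            peak_delay=self.hrf_peak_delay,
            undershoot_delay=self.hrf_undershoot_delay,
            peak_dispersion=self.hrf_peak_dispersion,
            undershoot_dispersion=self.hrf_undershoot_dispersion,
            undershoot_ratio=self.hrf_undershoot_ratio,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
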