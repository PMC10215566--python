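"""Configuration objects for the simulators and the end-to-end pipeline.

All randomness in the package flows through integer seeds held on these
objects; the same configuration and seed always reproduce the same dataset.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import yaml

#: 11-plex TMT reporter channel names, in labeling order.
TMT11_CHANNELS = (
    "126", "127N", "127C", "128N", "128C",
    "129N", "129C", "130N", "130C", "131N", "131C",
)

#: Standard SIL response-curve spike levels (fmol), 0.01 fmol to 10 pmol.
RESPONSE_SPIKE_LEVELS_FMOL = (0.01, 0.1, 1.0, 10.0, 100.0, 1000.0, 10000.0)

#: Minimum SIL spike concentration (pmol/mL) added to cohort samples; when
#: the endogenous level is below this, this amount is spiked instead.
MIN_SPIKE_PMOL_PER_ML = 5.0


@dataclass(frozen=True)
class MissingModel:
    """Logistic, abundance-dependent dropout applied per protein per batch.

    The probability that a protein row is entirely missing from one TMT
    batch is ``max_rate / (1 + exp((log2_abundance - midpoint) / scale))``:
    low-abundance proteins drop out of individual batches, which is what
    produces the batch-overlap (Venn) structure downstream.
    """

    midpoint_log2: float = 13.0
    scale_log2: float = 1.5
    max_rate: float = 1.0

    def dropout_probability(self, baseline_log2):
        import numpy as np

        z = (np.asarray(baseline_log2, dtype=float) - self.midpoint_log2) / self.scale_log2
        return self.max_rate / (1.0 + np.exp(z))


@dataclass(frozen=True)
class SimulationConfig:
    """Design of a simulated two-phase discovery/validation study.

    Defaults mirror the study design the package models: a 40-sample
    discovery cohort (20 ALS / 20 HC) measured in 4 batches of 11-plex TMT
    with one master-pool (MP) channel per batch, a 61-sample validation
    cohort (30 ALS / 31 HC), and a within-group SD of 0.24 on the log2
    scale.
    """

    n_proteins: int = 3000
    n_per_group_discovery: tuple[int, int] = (20, 20)  # (ALS, HC)
    n_validation: tuple[int, int] = (30, 31)  # (ALS, HC)
    n_batches: int = 4
    channels_per_batch: int = 11  # one channel reserved for the MP
    sigma_log2: float = 0.24
    effect_table: Mapping[str, float] = field(default_factory=dict)
    missing_model: MissingModel = field(default_factory=MissingModel)
    batch_effect_sd: float = 0.3
    mp_noise_sd_log2: float = 0.05
    baseline_log2_range: tuple[float, float] = (10.0, 30.0)
    seed: int = 0

    def __post_init__(self):
        if self.sigma_log2 <= 0:
            raise ValueError("sigma_log2 must be positive")
        if self.n_batches * (self.channels_per_batch - 1) < sum(self.n_per_group_discovery):
            raise ValueError(
                f"capacity error: {self.n_batches} batches x "
                f"{self.channels_per_batch - 1} sample channels cannot hold "
                f"{sum(self.n_per_group_discovery)} discovery samples"
            )
        lo, hi = self.baseline_log2_range
        if not lo < hi:
            raise ValueError("baseline_log2_range must be increasing")

    @property
    def n_discovery(self) -> int:
        return sum(self.n_per_group_discovery)


@dataclass(frozen=True)
class PrmSimSpec:
    """Design of a simulated PRM experiment (cohort or response series).

    ``panel`` rows are (peptide sequence, protein/gene, y-ion ladder
    length); the ladder length is the number of monitored fragment y ions
    starting at y3. ``noise_cv`` is the multiplicative replicate-to-replicate
    coefficient of variation of the peak amplitude. ``noise_floor`` and
    ``saturation_ceiling`` bound the detector response (signal units), which
    is what creates finite linear ranges in response curves.
    """

    panel: Sequence[tuple[str, str, int]] = ()
    spike_levels_fmol: Sequence[float] = RESPONSE_SPIKE_LEVELS_FMOL
    rt_window_sec: float = 60.0
    rt_step_sec: float = 1.0
    peak_center_sec: float = 30.0
    peak_width_sec: float = 3.0
    response_factor: float = 1000.0  # signal units per fmol (or per pmol/mL)
    noise_cv: float = 0.10
    noise_floor: float = 0.0
    saturation_ceiling: float = float("inf")
    replicates: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for pep, _, ladder in self.panel:
            if ladder < 3:
                raise ValueError(
                    f"peptide {pep}: y-ion ladder length must be >= 3"
                )
        levels = list(self.spike_levels_fmol)
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise ValueError("spike levels must be strictly increasing")


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (serializable to/from YAML)."""

    seed: int = 0
    n_proteins: int = 3000
    sigma_log2: float = 0.24
    batch_effect_sd: float = 0.3
    effect_table: dict[str, float] = field(default_factory=dict)
    q_cutoff_tier1: float = 0.05
    q_cutoff_tier2: float = 0.1
    p_cutoff_validation: float = 0.05
    n_permutations: int = 1000
    sam_s0: float = 0.0
    merge_mode: str = "intersection"
    impute_scope: str = "protein"
    zscore_axis: str = "protein"
    detectability_min_log2: float = 18.0
    validation_biological_sd: float = 1.0
    ion_rule: str = "ladder"
    linear_slope_band: tuple[float, float] = (0.8, 1.2)
    linear_min_r2: float = 0.98
    prm_noise_cv: float = 0.10
    n_bootstrap: int = 500
    mccv_repeats: int = 100
    panel_sizes: tuple[int, ...] = (3, 5, 10, 15)
    output_dir: str = "csfmark_run"

    def to_yaml(self, path) -> None:
        data = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("linear_slope_band", "panel_sizes"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)
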