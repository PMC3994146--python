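"""Analysis configuration.

All thresholds that drive the classification pipeline live in one dataclass so
that a run is fully described by (probe table, tree, config, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import yaml

from .errors import ParameterError

#: Ordered treatment levels, highest substrate concentration first.
TREATMENTS = ("H", "M", "L")

#: Added amino-acid concentration per treatment, mol/L (5 uM, 500 nM, 50 nM).
TREATMENT_CONCENTRATIONS = {"H": 5e-6, "M": 5e-7, "L": 5e-8}

#: Natural-abundance 15N/14N isotope ratio, a plausible unhybridized-background
#: standard when raw ion counts are supplied without a measured standard.
NATURAL_ABUNDANCE_15N = 0.003677


@dataclass
class AnalysisConfig:
    """Tunable parameters of the trophic-strategy analysis.

    Parameters
    ----------
    alpha
        Significance level for the concentration-effect ANCOVA and the
        pairwise post-hoc tests.
    activity_cutoff_fraction
        Fraction of the maximum reference-treatment HCE above which a taxon
        is called highly active (0.5 = the 50%-of-maximum rule).
    n_reshuffles
        Number of tip-label permutations in the phylogenetic-signal null.
    rng_seed
        Master seed; every stochastic step derives its stream from it.
    r_standard
        15N/14N ratio of the unhybridized background, used when probe tables
        carry raw ion counts instead of delta values.
    min_spots
        Minimum probe spots per taxon/treatment regression (slope SE needs
        at least 3 points).
    enrichment_alpha
        Level of the one-sided slope>0 t-test in the enrichment flag.
    require_positive_mean
        Whether the enrichment flag additionally requires mean delta > 0.
    activity_reference
        Treatment whose HCE defines the activity ranking (default "H").
    posthoc_correction
        "none" (uncorrected pairwise tests) or "holm".
    ancova_model
        "interaction" tests slope and intercept shifts jointly;
        "intercept" tests only intercept shifts (common-slope ANCOVA).
    """

    alpha: float = 0.05
    activity_cutoff_fraction: float = 0.5
    n_reshuffles: int = 1000
    rng_seed: int = 0
    r_standard: float = NATURAL_ABUNDANCE_15N
    min_spots: int = 3
    enrichment_alpha: float = 0.05
    require_positive_mean: bool = True
    activity_reference: str = "H"
    posthoc_correction: str = "none"
    ancova_model: str = "interaction"
    treatment_concentrations: dict = field(
        default_factory=lambda: dict(TREATMENT_CONCENTRATIONS)
    )

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ParameterError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0.0 < self.activity_cutoff_fraction <= 1.0:
            raise ParameterError(
                "activity_cutoff_fraction must be in (0, 1], "
                f"got {self.activity_cutoff_fraction}"
            )
        if self.n_reshuffles < 1:
            raise ParameterError("n_reshuffles must be >= 1")
        if self.r_standard <= 0:
            raise ParameterError("r_standard must be positive")
        if self.min_spots < 3:
            raise ParameterError("min_spots must be >= 3 (slope SE needs df >= 1)")
        if self.activity_reference not in TREATMENTS:
            raise ParameterError(
                f"activity_reference must be one of {TREATMENTS}"
            )
        if self.posthoc_correction not in ("none", "holm"):
            raise ParameterError("posthoc_correction must be 'none' or 'holm'")
        if self.ancova_model not in ("interaction", "intercept"):
            raise ParameterError("ancova_model must be 'interaction' or 'intercept'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
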