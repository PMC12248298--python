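"""Sample designs, analysis configuration, and region presets.

All procedural thresholds of the differential analysis live on
:class:`AnalysisConfig` so that a run is fully described by (inputs, config,
seed).  The defaults reproduce the standard hippocampal-aging analysis:
peptides are significant at a >2-fold effect and per-protein BH-adjusted
p < 0.05; a protein is called when two or more of its peptides are
significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "SampleDesign",
    "AnalysisConfig",
    "REGION_PRESETS",
    "ConfigError",
    "DesignError",
]


class ConfigError(ValueError):
    """Raised when an AnalysisConfig is internally inconsistent."""


class DesignError(ValueError):
    """Raised when a sample design is malformed or mismatched to a table."""


@dataclass(frozen=True)
class SampleDesign:
    """Mapping of sample columns to experimental groups.

    Parameters
    ----------
    table:
        DataFrame with columns ``sample_id``, ``group`` and
        ``replicate_index``.  Sample ids must be unique; replicate indices
        are positive integers within each group.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "group", "replicate_index"}
        missing = required - set(self.table.columns)
        if missing:
            raise DesignError(f"design table missing columns: {sorted(missing)}")
        sids = self.table["sample_id"]
        if sids.duplicated().any():
            dupes = sorted(sids[sids.duplicated()].unique().tolist())
            raise DesignError(f"duplicate sample ids in design: {dupes}")
        if (self.table["replicate_index"] < 1).any():
            raise DesignError("replicate_index must be a positive integer")

    @classmethod
    def from_groups(cls, group_sizes: Mapping[str, int]) -> "SampleDesign":
        """Build a design with systematic sample names ``<group>_<i>``."""
        rows = [
            {"sample_id": f"{g}_{i}", "group": g, "replicate_index": i}
            for g, n in group_sizes.items()
            for i in range(1, n + 1)
        ]
        return cls(pd.DataFrame(rows))

    @property
    def groups(self) -> list[str]:
        """Group labels in first-appearance order."""
        return list(dict.fromkeys(self.table["group"]))

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    def samples_in(self, group: str) -> list[str]:
        sel = self.table["group"] == group
        if not sel.any():
            raise DesignError(f"group {group!r} not present in design")
        return self.table.loc[sel, "sample_id"].tolist()

    def group_size(self, group: str) -> int:
        return len(self.samples_in(group))

    def relabelled(self, new_groups: Sequence[str]) -> "SampleDesign":
        """Return a design with the same samples but permuted group labels."""
        if len(new_groups) != len(self.table):
            raise DesignError("relabelling must cover every sample")
        tab = self.table.copy()
        tab["group"] = list(new_groups)
        return SampleDesign(tab)

    def require_differential(self) -> None:
        if len(self.groups) < 2:
            raise DesignError("a differential run requires at least two groups")


#: Missing-value filter thresholds per hippocampal subfield: an ion is dropped
#: only when its missing count exceeds the threshold in *every* group.
REGION_PRESETS: dict[str, dict[str, int]] = {
    "CA1": {"AU": 5, "AI": 3},
    "CA3": {"AU": 4, "AI": 3},
    "DG": {"AU": 4, "AI": 3},
}


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds and policies for one differential structural analysis.

    Attributes
    ----------
    numerator, denominator:
        Group labels forming the reported ratio (numerator over denominator).
    max_missing_per_group:
        Per-group missing-count thresholds for the conjunctive ion filter.
        ``None`` disables the filter.
    imputation_policy:
        ``"none"`` (strict analysis), ``"general"`` (impute the high-missing
        group when >66% missing there and >55% present opposite), or
        ``"all_or_nothing"`` (impute only all-missing vs all-present ions).
    impute_mean, impute_sd:
        Gaussian used for imputed raw intensities (default 10,000 +/- 1,000),
        truncated below at 1 so log2 stays defined.
    fc_threshold_log2, alpha_adjusted:
        Peptide significance: |log2 ratio| > fc_threshold_log2 and
        per-protein BH-adjusted p < alpha_adjusted.
    normalization_fc_log2, normalization_alpha:
        Trigger for subtracting the control (trypsin-only) abundance ratio.
    control_mode:
        ``"protein"`` (default): normalize against the protein-level control
        ratio; ``"matched_peptide"``: against the same peptide in the control.
    min_significant_peptides_for_call, min_peptides_for_assessment:
        Protein-level calling rule (>=2 significant peptides; proteins with
        fewer than 2 valid peptides are "insufficient").
    min_obs_per_group:
        Minimum observed-or-imputed values per group for a per-ion test.
    require_unique_mapping:
        When True, only peptides mapping to a single proteome location count
        toward protein calls.
    rng_seed:
        Seed for imputation draws (and any other stochastic step).
    """

    numerator: str = "AU"
    denominator: str = "AI"
    max_missing_per_group: Mapping[str, int] | None = None
    imputation_policy: str = "none"
    impute_mean: float = 10_000.0
    impute_sd: float = 1_000.0
    fc_threshold_log2: float = 1.0
    alpha_adjusted: float = 0.05
    normalization_fc_log2: float = 1.0
    normalization_alpha: float = 0.01
    control_mode: str = "protein"
    min_significant_peptides_for_call: int = 2
    min_peptides_for_assessment: int = 2
    min_obs_per_group: int = 2
    require_unique_mapping: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.imputation_policy not in ("none", "general", "all_or_nothing"):
            raise ConfigError(
                f"unknown imputation_policy {self.imputation_policy!r}"
            )
        if self.control_mode not in ("protein", "matched_peptide"):
            raise ConfigError(f"unknown control_mode {self.control_mode!r}")
        for name in ("impute_mean", "impute_sd", "fc_threshold_log2",
                     "normalization_fc_log2"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("alpha_adjusted", "normalization_alpha"):
            a = getattr(self, name)
            if not 0 < a < 1:
                raise ConfigError(f"{name} must lie in (0, 1)")
        if self.numerator == self.denominator:
            raise ConfigError("numerator and denominator groups must differ")

    @classmethod
    def for_region(cls, region: str, **overrides) -> "AnalysisConfig":
        """Aging-cohort preset (AU vs AI) with the subfield's filter thresholds
        and the general imputation policy."""
        try:
            thresholds = REGION_PRESETS[region]
        except KeyError:
            raise ConfigError(
                f"unknown region {region!r}; expected one of {sorted(REGION_PRESETS)}"
            ) from None
        base = cls(
            numerator="AU",
            denominator="AI",
            max_missing_per_group=dict(thresholds),
            imputation_policy="general",
        )
        return replace(base, **overrides) if overrides else base

    @classmethod
    def refolding(cls, numerator: str = "refolded", denominator: str = "native",
                  **overrides) -> "AnalysisConfig":
        """Refoldability preset: all-or-nothing imputation, no missing filter
        (missing values are simply dropped from averages)."""
        base = cls(
            numerator=numerator,
            denominator=denominator,
            max_missing_per_group=None,
            imputation_policy="all_or_nothing",
        )
        return replace(base, **overrides) if overrides else base

    def with_(self, **overrides) -> "AnalysisConfig":
        return replace(self, **overrides)
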