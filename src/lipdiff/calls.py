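"""Protein-level classification and permutation-based FDR estimation.

A protein is *called* (CASC in the cognition comparison, nonrefoldable in
the refolding comparison) when two or more of its peptides change
significantly; proteins with fewer than two valid peptides carry too little
information and are marked insufficient.  The false-discovery rate of the
whole pipeline is estimated empirically by re-running it with group labels
randomly permuted across replicates (preserving group sizes) and counting
how many proteins are still called.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import AnalysisConfig, SampleDesign
from .io import IonTable
from . import diffstruct

__all__ = [
    "call_proteins",
    "intersect_strict_general",
    "PermutationSummary",
    "estimate_fdr_by_permutation",
    "protein_abundance_de",
]

CALLED = "called"
NOT_CALLED = "not_called"
INSUFFICIENT = "insufficient"


def call_proteins(
    peptide_results: pd.DataFrame,
    config: AnalysisConfig,
    analysis_tag: str = "general",
) -> pd.DataFrame:
    """Classify each protein from its peptide significance flags.

    Valid peptides are those with a computed p-value; when
    ``config.require_unique_mapping`` is set and a ``multi_match`` column is
    present, multi-mapping peptides do not count toward significance.
    """
    df = peptide_results.copy()
    df["_valid"] = df["p_value"].notna()
    sig = df["significant"].fillna(False).astype(bool) & df["_valid"]
    if config.require_unique_mapping and "multi_match" in df.columns:
        sig &= ~df["multi_match"].fillna(False).astype(bool)
    df["_sig"] = sig
    grouped = df.groupby("protein").agg(
        n_valid_peptides=("_valid", "sum"),
        n_significant_peptides=("_sig", "sum"),
    ).reset_index()
    n_valid = grouped["n_valid_peptides"]
    n_sig = grouped["n_significant_peptides"]
    call = np.where(
        n_valid < config.min_peptides_for_assessment,
        INSUFFICIENT,
        np.where(
            n_sig >= config.min_significant_peptides_for_call, CALLED, NOT_CALLED
        ),
    )
    grouped["call"] = call
    grouped["analysis_tag"] = analysis_tag
    return grouped


def intersect_strict_general(
    strict_calls: pd.DataFrame, general_calls: pd.DataFrame
) -> dict[str, object]:
    """Overlap between the strict (no-imputation) and general call sets."""
    strict = set(strict_calls.loc[strict_calls["call"] == CALLED, "protein"])
    general = set(general_calls.loc[general_calls["call"] == CALLED, "protein"])
    return {
        "strict_only": sorted(strict - general),
        "general_only": sorted(general - strict),
        "both": sorted(strict & general),
        "n_strict": len(strict),
        "n_general": len(general),
        "n_both": len(strict & general),
    }


@dataclass
class PermutationSummary:
    """Observed vs label-permuted call counts and the implied FDR estimate.

    ``fdr_estimate`` divides the mean null call count by the observed count;
    ``fdr_estimate_max`` uses the worst (max) null count instead.  Both are
    NaN when nothing was called in the observed data.
    """

    observed_called: int
    null_called_per_permutation: list[int]
    permutation_seeds: list[int]

    @property
    def fdr_estimate(self) -> float:
        if self.observed_called == 0:
            return float("nan")
        return float(np.mean(self.null_called_per_permutation)) / self.observed_called

    @property
    def fdr_estimate_max(self) -> float:
        if self.observed_called == 0:
            return float("nan")
        return float(np.max(self.null_called_per_permutation)) / self.observed_called


def _permute_design(design: SampleDesign, rng: np.random.Generator) -> SampleDesign:
    labels = design.table["group"].to_numpy()
    return design.relabelled(rng.permutation(labels))


def estimate_fdr_by_permutation(
    run_pipeline,
    lip_table: IonTable,
    design: SampleDesign,
    config: AnalysisConfig,
    n_permutations: int = 3,
    seed: int = 0,
) -> PermutationSummary:
    """Re-run the full pipeline under random group relabellings.

    ``run_pipeline(table, config) -> protein_calls DataFrame`` must execute
    every stage (impute, filter, test, merge, normalize, BH, call) so the
    null counts see the same procedure as the observed data.  Permutations
    shuffle labels across all samples, preserving group sizes; at small n
    duplicate permutations can occur.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    observed = run_pipeline(lip_table, config)
    n_obs = int((observed["call"] == CALLED).sum())
    master = np.random.default_rng(seed)
    perm_seeds = [int(s) for s in master.integers(0, 2**31 - 1, n_permutations)]
    null_counts = []
    for ps in perm_seeds:
        rng = np.random.default_rng(ps)
        permuted = lip_table.with_design(_permute_design(design, rng))
        calls = run_pipeline(permuted, config)
        null_counts.append(int((calls["call"] == CALLED).sum()))
    return PermutationSummary(n_obs, null_counts, perm_seeds)


def protein_abundance_de(
    control: IonTable, config: AnalysisConfig
) -> pd.DataFrame:
    """Differential protein abundance from the trypsin-only table.

    A protein is called differentially abundant at |log2 ratio| > 1 and
    Welch p < 0.01 with no multiplicity correction, matching the
    protein-level volcano convention.  Proteins with fewer than two
    observed values in either group are insufficient.
    """
    stats_ = diffstruct.control_protein_statistics(control, config)
    num = control.design.samples_in(config.numerator)
    den = control.design.samples_in(config.denominator)
    per_protein = control.data.groupby("protein")[num + den].sum(min_count=1)
    n1 = per_protein[num].notna().sum(axis=1).reindex(stats_["protein"]).to_numpy()
    n2 = per_protein[den].notna().sum(axis=1).reindex(stats_["protein"]).to_numpy()
    insufficient = (n1 < 2) | (n2 < 2)
    called = (
        (stats_["control_log2_ratio"].abs() > config.normalization_fc_log2)
        & (stats_["control_p"] < config.normalization_alpha)
        & ~insufficient
    )
    out = stats_.rename(
        columns={"control_log2_ratio": "log2_ratio", "control_p": "p_value"}
    )
    out["call"] = np.where(
        insufficient, INSUFFICIENT, np.where(called, CALLED, NOT_CALLED)
    )
    out["analysis_tag"] = "abundance"
    return out
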