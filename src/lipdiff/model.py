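"""Model/results interface to the differential structural analysis.

:class:`LipDifferentialModel` holds the inputs of one comparison — a LiP
ion table, an optional trypsin-only control, an optional proteome for
peptide localization, and an :class:`~lipdiff.config.AnalysisConfig` —
and ``fit()`` executes the pipeline (impute -> filter -> per-ion tests ->
ion->peptide merge -> control normalization -> per-protein BH -> protein
calls), returning a :class:`LipDifferentialResults` with the peptide-level
estimates, protein calls, QC metrics, a ``summary()`` table, and
permutation-based FDR estimation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import calls as calls_mod
from . import diffstruct
from .config import AnalysisConfig, SampleDesign
from .io import IonTable, write_results
from .peptides import locate_and_classify

__all__ = [
    "LipDifferentialModel",
    "LipDifferentialResults",
    "annotate_peptides",
    "qc_report",
    "run_differential_analysis",
]


def annotate_peptides(
    peptides: pd.DataFrame, proteome: dict[str, str] | None
) -> pd.DataFrame:
    """Attach trypticity, structural site, and multi-mapping flags.

    Without a proteome every peptide is marked unmapped and carries no
    site; protein-level calling still works, the site-level analyses do not.
    """
    out = peptides.copy()
    if proteome is None:
        out["trypticity"] = "unmapped"
        out["site"] = np.nan
        out["multi_match"] = False
        return out
    cache: dict[tuple[str, str], tuple[str, float, bool]] = {}
    tryps, sites, multi = [], [], []
    for prot, pep in out[["protein", "peptide"]].itertuples(index=False):
        key = (prot, pep)
        if key not in cache:
            loc = locate_and_classify(pep, prot, proteome)
            cache[key] = (
                loc.trypticity,
                float(loc.site) if loc.site is not None else np.nan,
                loc.multi_match,
            )
        t, s, m = cache[key]
        tryps.append(t)
        sites.append(s)
        multi.append(m)
    out["trypticity"] = tryps
    out["site"] = sites
    out["multi_match"] = multi
    return out


def qc_report(table: IonTable, proteome: dict[str, str] | None) -> dict:
    """Per-sample percent half-tryptic peptides and per-group median CV."""
    samples = table.samples
    report: dict = {"n_ions": len(table)}
    if proteome is not None and len(table):
        pep_info = annotate_peptides(
            table.data[["protein", "peptide"]].drop_duplicates(), proteome
        )
        trypt = table.data[["protein", "peptide"]].merge(
            pep_info, on=["protein", "peptide"], how="left"
        )["trypticity"].to_numpy()
        half = np.isin(trypt, ("half_nterm", "half_cterm"))
        classified = trypt != "unmapped"
        pct = {}
        for s in samples:
            present = table.data[s].notna().to_numpy()
            denom = int((present & classified).sum())
            pct[s] = (
                100.0 * int((present & half).sum()) / denom if denom else np.nan
            )
        report["percent_half_tryptic_by_sample"] = pct
    cvs = {}
    for g in table.design.groups:
        cols = table.design.samples_in(g)
        vals = table.data[cols].to_numpy(dtype=float)
        n, mean, var = diffstruct._nan_moments(vals)
        ok = n >= 2
        cvs[g] = (
            float(np.median(np.sqrt(var[ok]) / mean[ok])) if ok.any() else np.nan
        )
    report["median_cv_by_group"] = cvs
    return report


def run_differential_analysis(
    lip: IonTable,
    control: IonTable | None,
    config: AnalysisConfig,
    proteome: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Execute the full pipeline; returns (peptide results, protein calls,
    qc report).  Deterministic given ``config.rng_seed``."""
    imputed, imputed_flags = diffstruct.impute_missing(lip, config)
    filtered = diffstruct.filter_ions(imputed, config)
    ion_stats = diffstruct.ion_statistics(filtered, config)
    peptides = diffstruct.merge_ions_to_peptides(ion_stats)
    peptides = annotate_peptides(peptides, proteome)
    if control is not None and len(peptides):
        control = control.with_design(lip.design)
        if config.control_mode == "matched_peptide":
            cstats = diffstruct.control_peptide_statistics(control, config)
        else:
            cstats = diffstruct.control_protein_statistics(control, config)
        peptides = diffstruct.normalize_against_control(peptides, cstats, config)
    else:
        peptides["normalized"] = False
        peptides["no_control"] = True
    peptides = diffstruct.adjust_per_protein(peptides)
    peptides = diffstruct.flag_significant(peptides, config)
    protein_calls = calls_mod.call_proteins(peptides, config)
    qc = qc_report(filtered, proteome)
    qc["n_ions_input"] = len(lip)
    qc["n_ions_after_filter"] = len(filtered)
    qc["n_cells_imputed"] = int(imputed_flags.to_numpy().sum())
    qc["n_peptides"] = len(peptides)
    return peptides, protein_calls, qc


class LipDifferentialModel:
    """Differential proteolytic-susceptibility model for one comparison.

    Parameters
    ----------
    lip:
        Ion table from the limited-proteolysis samples.
    control:
        Optional trypsin-only ion table used for abundance normalization
        and protein-level differential abundance.
    proteome:
        Optional {accession: sequence} mapping for peptide localization.
    config:
        Analysis thresholds and policies.
    """

    def __init__(
        self,
        lip: IonTable,
        control: IonTable | None = None,
        proteome: dict[str, str] | None = None,
        config: AnalysisConfig | None = None,
    ) -> None:
        self.lip = lip
        self.control = control
        self.proteome = proteome
        self.config = config or AnalysisConfig()
        self.lip.design.require_differential()

    @classmethod
    def from_simulation(cls, sim, config: AnalysisConfig | None = None):
        """Build a model directly from a :class:`~lipdiff.synthetic.SimulationResult`."""
        groups = sim.design.groups
        cfg = config or AnalysisConfig(numerator=groups[0], denominator=groups[1])
        return cls(sim.lip, sim.control, sim.proteome, cfg)

    def fit(self) -> "LipDifferentialResults":
        peptides, protein_calls, qc = run_differential_analysis(
            self.lip, self.control, self.config, self.proteome
        )
        return LipDifferentialResults(self, peptides, protein_calls, qc)

    def _pipeline_for_permutation(self, table: IonTable, config: AnalysisConfig):
        _, protein_calls, _ = run_differential_analysis(
            table, self.control, config, self.proteome
        )
        return protein_calls


@dataclass
class LipDifferentialResults:
    """Fitted results: peptide-level statistics and protein-level calls."""

    model: LipDifferentialModel
    peptides: pd.DataFrame
    proteins: pd.DataFrame
    qc: dict

    @property
    def config(self) -> AnalysisConfig:
        return self.model.config

    @property
    def called_proteins(self) -> list[str]:
        sel = self.proteins["call"] == calls_mod.CALLED
        return sorted(self.proteins.loc[sel, "protein"])

    @property
    def n_called(self) -> int:
        return int((self.proteins["call"] == calls_mod.CALLED).sum())

    @property
    def n_assessed(self) -> int:
        return int(self.proteins["call"].isin(
            [calls_mod.CALLED, calls_mod.NOT_CALLED]
        ).sum())

    def significant_peptides(self) -> pd.DataFrame:
        return self.peptides.loc[self.peptides["significant"].astype(bool)]

    def sites(self) -> pd.DataFrame:
        """Site records (protein, residue_index, significant) for the
        proximity analyses, one row per peptide with a defined site."""
        s = self.peptides.dropna(subset=["site"])
        return pd.DataFrame({
            "protein": s["protein"].to_numpy(),
            "residue_index": s["site"].astype(int).to_numpy(),
            "significant": s["significant"].astype(bool).to_numpy(),
        })

    def estimate_fdr(self, n_permutations: int = 3, seed: int = 0):
        """Permutation FDR: re-run the whole pipeline under random group
        relabellings and compare null call counts to the observed one."""
        return calls_mod.estimate_fdr_by_permutation(
            self.model._pipeline_for_permutation,
            self.model.lip,
            self.model.lip.design,
            self.config,
            n_permutations=n_permutations,
            seed=seed,
        )

    def abundance_calls(self) -> pd.DataFrame:
        """Protein-level differential abundance from the control table."""
        if self.model.control is None:
            raise ValueError("no control table supplied")
        return calls_mod.protein_abundance_de(self.model.control, self.config)

    def write(self, peptide_path, protein_path) -> None:
        write_results(self.peptides, self.proteins, peptide_path, protein_path)

    def summary(self) -> str:
        cfg = self.config
        n_sig = int(self.peptides["significant"].astype(bool).sum())
        n_pep = len(self.peptides)
        counts = self.proteins["call"].value_counts()
        lines = [
            "Differential structural analysis (LiP-MS)",
            "=" * 48,
            f"comparison:          {cfg.numerator} / {cfg.denominator}",
            f"imputation policy:   {cfg.imputation_policy}",
            f"significance:        |log2FC| > {cfg.fc_threshold_log2:g}, "
            f"BH-adjusted p < {cfg.alpha_adjusted:g} (per protein)",
            f"ions in / kept:      {self.qc.get('n_ions_input', 'NA')} / "
            f"{self.qc.get('n_ions_after_filter', 'NA')}"
            f"  (cells imputed: {self.qc.get('n_cells_imputed', 0)})",
            f"peptides tested:     {n_pep}",
            f"significant:         {n_sig} "
            f"({100.0 * n_sig / n_pep:.1f}%)" if n_pep else
            "significant:         0",
            f"proteins assessed:   {self.n_assessed}",
            f"proteins called:     {self.n_called} "
            f"(insufficient: {int(counts.get(calls_mod.INSUFFICIENT, 0))})",
        ]
        med_cv = self.qc.get("median_cv_by_group", {})
        if med_cv:
            cvtxt = ", ".join(f"{g}: {v:.2f}" for g, v in med_cv.items())
            lines.append(f"median within-group CV: {cvtxt}")
        return "\n".join(lines)
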