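"""Statistical core of the differential structural analysis.

Stages, in pipeline order:

1. conditional imputation of missing intensities (``general`` or
   ``all_or_nothing`` policy, Gaussian draws around a low constant),
2. conjunctive missing-value filtering,
3. per-ion Welch t-tests on log2 intensities and log2 ratios of raw means,
4. ion -> peptide merging (median ratio; Fisher's method when directions
   agree, else p = 1),
5. normalization against the trypsin-only control when its abundance change
   triggers (>2-fold, p < 0.01),
6. Benjamini-Hochberg correction applied within each protein, since the
   null hypothesis is per protein ("this protein is not structurally
   different") and every peptide is one chance to reject it.

Design choices: tests run on log2-transformed intensities (variance
stabilization) while ratios are means of raw intensities; imputation
precedes filtering; the >66%/>55% fractions are strict inequalities on
exact fractions; direction agreement requires all ion log2 ratios to share
a strict sign (a zero ratio breaks agreement); p = 0 is clamped to 1e-300
before Fisher combination.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import AnalysisConfig, ConfigError, SampleDesign
from .io import IonTable

__all__ = [
    "impute_missing",
    "filter_ions",
    "welch_test",
    "welch_test_matrix",
    "ion_ratio",
    "ion_statistics",
    "merge_ions_to_peptides",
    "merge_single_peptide",
    "control_protein_statistics",
    "control_peptide_statistics",
    "normalize_against_control",
    "adjust_per_protein",
    "flag_significant",
]

P_CLAMP = 1e-300


def _nan_moments(m: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise count, mean and ddof-1 variance over finite entries,
    without the all-NaN-slice warnings of the nan* reductions."""
    finite = np.isfinite(m)
    n = finite.sum(axis=1)
    filled = np.where(finite, m, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n > 0, filled.sum(axis=1) / np.maximum(n, 1), np.nan)
        dev2 = np.where(finite, (m - mean[:, None]) ** 2, 0.0)
        var = np.where(n > 1, dev2.sum(axis=1) / np.maximum(n - 1, 1), np.nan)
    return n, mean, var

GENERAL_MISSING_FRAC = 0.66   # strict: imputed group has > 66% missing
GENERAL_PRESENT_FRAC = 0.55   # strict: opposite group has > 55% present


# ---------------------------------------------------------------------------
# imputation and filtering


def impute_missing(
    table: IonTable, config: AnalysisConfig
) -> tuple[IonTable, pd.DataFrame]:
    """Fill missing cells according to ``config.imputation_policy``.

    Returns the (possibly) imputed table and a boolean frame of the same
    sample-column shape marking imputed cells.  Observed cells are never
    modified; draws come from Normal(impute_mean, impute_sd^2) truncated
    below at 1, seeded by ``config.rng_seed``.
    """
    design = table.design
    samples = table.samples
    flags = pd.DataFrame(
        False, index=table.data.index, columns=samples, dtype=bool
    )
    if config.imputation_policy == "none" or len(table) == 0:
        return table, flags

    groups = [config.numerator, config.denominator]
    cols = {g: design.samples_in(g) for g in groups}
    mat = table.data[samples]
    miss = {g: mat[cols[g]].isna().sum(axis=1) for g in groups}
    n = {g: len(cols[g]) for g in groups}

    to_fill = pd.DataFrame(False, index=table.data.index, columns=samples)
    for g, other in ((groups[0], groups[1]), (groups[1], groups[0])):
        if config.imputation_policy == "general":
            high_missing = miss[g] / n[g] > GENERAL_MISSING_FRAC
            other_present = (n[other] - miss[other]) / n[other] > GENERAL_PRESENT_FRAC
            # if both groups are high-missing, neither qualifies: the rule
            # requires complementary presence on the other side
            eligible = high_missing & other_present
        else:  # all_or_nothing
            eligible = (miss[g] == n[g]) & (miss[other] == 0)
        if eligible.any():
            block = mat.loc[eligible, cols[g]]
            to_fill.loc[eligible, cols[g]] = block.isna()

    fill_mask = to_fill.to_numpy()
    if not fill_mask.any():
        return table, flags

    rng = np.random.default_rng(config.rng_seed)
    draws = rng.normal(config.impute_mean, config.impute_sd, int(fill_mask.sum()))
    draws = np.maximum(draws, 1.0)
    values = mat.to_numpy(dtype=float).copy()
    values[fill_mask] = draws
    data = table.data.copy()
    data[samples] = values
    flags.loc[:, :] = fill_mask
    return IonTable(data, design), flags


def filter_ions(table: IonTable, config: AnalysisConfig) -> IonTable:
    """Drop ions whose missing count exceeds the configured threshold in
    *every* group simultaneously (conjunctive rule); applied after
    imputation.  Surviving ions keep their missing cells, which are simply
    excluded from downstream means."""
    if config.max_missing_per_group is None:
        return table
    thresholds = dict(config.max_missing_per_group)
    groups = [config.numerator, config.denominator]
    for g in groups:
        if g not in thresholds:
            raise ConfigError(f"no missing-value threshold configured for group {g!r}")
    mat = table.data
    exceed = pd.Series(True, index=mat.index)
    for g in groups:
        cols = table.design.samples_in(g)
        exceed &= mat[cols].isna().sum(axis=1) > thresholds[g]
    return table.subset(~exceed)


# ---------------------------------------------------------------------------
# per-ion statistics


def welch_test(x, y) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test, two-sided.

    Returns (t, Welch-Satterthwaite df, p).  Requires >= 2 values per side.
    When both sample variances are zero the p-value degenerates to 1 if the
    means agree and 0 otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("welch_test requires at least 2 values per side")
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    if v1 == 0 and v2 == 0:
        equal = x.mean() == y.mean()
        return 0.0 if equal else np.inf, float(len(x) + len(y) - 2), \
            1.0 if equal else 0.0
    t, p = stats.ttest_ind(x, y, equal_var=False)
    se1, se2 = v1 / len(x), v2 / len(y)
    df = (se1 + se2) ** 2 / (
        se1**2 / (len(x) - 1) + se2**2 / (len(y) - 1)
    )
    return float(t), float(df), float(p)


def welch_test_matrix(
    x: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise nan-aware Welch test for two matrices of log2 intensities.

    Rows with fewer than 2 finite values on either side get p = NaN
    (insufficient data; the ion is excluded, not an error).
    """
    n1, m1, v1 = _nan_moments(x)
    n2, m2, v2 = _nan_moments(y)
    ok = (n1 >= 2) & (n2 >= 2)
    t = np.full(len(x), np.nan)
    df = np.full(len(x), np.nan)
    p = np.full(len(x), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        se1 = np.where(ok, v1 / n1, np.nan)
        se2 = np.where(ok, v2 / n2, np.nan)
        denom = np.sqrt(se1 + se2)
        t_ok = (m1 - m2) / denom
        df_ok = (se1 + se2) ** 2 / (
            se1**2 / (n1 - 1) + se2**2 / (n2 - 1)
        )
    degenerate = ok & (v1 == 0) & (v2 == 0)
    t[ok] = t_ok[ok]
    df[ok] = df_ok[ok]
    with np.errstate(invalid="ignore"):
        p[ok] = 2.0 * stats.t.sf(np.abs(t_ok[ok]), df_ok[ok])
    if degenerate.any():
        same = degenerate & (m1 == m2)
        diff = degenerate & (m1 != m2)
        t[same], p[same], df[same] = 0.0, 1.0, (n1 + n2 - 2)[same]
        t[diff], p[diff], df[diff] = np.inf, 0.0, (n1 + n2 - 2)[diff]
    return t, df, p


def ion_ratio(x, y) -> float:
    """log2 of the ratio of raw-intensity means (numerator over denominator),
    means taken over available (observed or imputed) cells."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("ion_ratio requires at least one value per side")
    return float(np.log2(x.mean() / y.mean()))


def ion_statistics(table: IonTable, config: AnalysisConfig) -> pd.DataFrame:
    """Per-ion log2 ratios and Welch p-values.

    Tests run on log2 intensities; ratios are log2 of raw-mean quotients.
    Ions with fewer than ``config.min_obs_per_group`` available values in
    either group carry p = NaN and are not merged downstream.
    """
    num_cols = table.design.samples_in(config.numerator)
    den_cols = table.design.samples_in(config.denominator)
    raw_x = table.data[num_cols].to_numpy(dtype=float)
    raw_y = table.data[den_cols].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_x = np.log2(raw_x)
        log_y = np.log2(raw_y)
    t, df, p = welch_test_matrix(log_x, log_y)
    n1, mean_x, _ = _nan_moments(raw_x)
    n2, mean_y, _ = _nan_moments(raw_y)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where((n1 > 0) & (n2 > 0), np.log2(mean_x / mean_y), np.nan)
    insufficient = (n1 < config.min_obs_per_group) | (n2 < config.min_obs_per_group)
    p = np.where(insufficient, np.nan, p)
    out = table.data[["protein", "peptide", "ion"]].copy()
    out["log2_ratio"] = ratio
    out["t"] = t
    out["df"] = df
    out["p_value"] = p
    out["n_num"] = n1
    out["n_den"] = n2
    return out


# ---------------------------------------------------------------------------
# ion -> peptide merging


def merge_single_peptide(ratios, pvalues) -> tuple[float, float]:
    """Merge one peptide's ion results: median log2 ratio; Fisher-combined
    p when all ion ratios strictly agree in sign, else p = 1.  A single ion
    passes through unchanged."""
    r = np.asarray(ratios, dtype=float)
    p = np.asarray(pvalues, dtype=float)
    if len(r) == 0:
        raise ValueError("merge requires at least one ion result")
    med = float(np.median(r))
    if len(r) == 1:
        return med, float(p[0])
    if np.all(r > 0) or np.all(r < 0):
        stat = -2.0 * np.sum(np.log(np.clip(p, P_CLAMP, 1.0)))
        return med, float(stats.chi2.sf(stat, 2 * len(p)))
    return med, 1.0


def merge_ions_to_peptides(ion_results: pd.DataFrame) -> pd.DataFrame:
    """Merge per-ion statistics to peptides keyed by (protein, peptide).

    Ions without a p-value (insufficient data) are dropped first; a peptide
    with no testable ion does not appear in the output.
    """
    usable = ion_results.dropna(subset=["p_value", "log2_ratio"])
    if len(usable) == 0:
        return pd.DataFrame(
            columns=["protein", "peptide", "log2_ratio", "p_value", "n_ions"]
        )
    rows = []
    for (prot, pep), grp in usable.groupby(["protein", "peptide"], sort=True):
        ratio, p = merge_single_peptide(
            grp["log2_ratio"].to_numpy(), grp["p_value"].to_numpy()
        )
        rows.append(
            {"protein": prot, "peptide": pep, "log2_ratio": ratio,
             "p_value": p, "n_ions": len(grp)}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# control normalization


def control_protein_statistics(
    control: IonTable, config: AnalysisConfig
) -> pd.DataFrame:
    """Protein-level abundance ratio and Welch p from the trypsin-only table.

    Per-sample protein intensity is the sum of the protein's ion
    intensities (missing cells contribute nothing); the test runs on log2
    of those sums.
    """
    num_cols = control.design.samples_in(config.numerator)
    den_cols = control.design.samples_in(config.denominator)
    per_protein = control.data.groupby("protein")[num_cols + den_cols].sum(
        min_count=1
    )
    raw_x = per_protein[num_cols].to_numpy(dtype=float)
    raw_y = per_protein[den_cols].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        _, _, p = welch_test_matrix(np.log2(raw_x), np.log2(raw_y))
        _, mean_x, _ = _nan_moments(raw_x)
        _, mean_y, _ = _nan_moments(raw_y)
        ratio = np.log2(mean_x / mean_y)
    return pd.DataFrame(
        {"protein": per_protein.index, "control_log2_ratio": ratio,
         "control_p": p}
    ).reset_index(drop=True)


def control_peptide_statistics(
    control: IonTable, config: AnalysisConfig
) -> pd.DataFrame:
    """Peptide-level control statistics (the literal 'corresponding peptide'
    reading), computed by the same ion -> peptide merge as the LiP table."""
    stats_ = ion_statistics(control, config)
    merged = merge_ions_to_peptides(stats_)
    return merged.rename(
        columns={"log2_ratio": "control_log2_ratio", "p_value": "control_p"}
    )[["protein", "peptide", "control_log2_ratio", "control_p"]]


def normalize_against_control(
    peptides: pd.DataFrame,
    control_stats: pd.DataFrame,
    config: AnalysisConfig,
) -> pd.DataFrame:
    """Subtract the control abundance ratio from peptides whose protein (or
    matched peptide) changed abundance: trigger is |control log2 ratio| >
    ``normalization_fc_log2`` and control p < ``normalization_alpha``.

    Peptides without a control entry are left untouched and flagged
    ``no_control``.  Normalization is additive in log space and idempotent:
    the ``normalized`` flag marks rows already corrected.
    """
    keys = ["protein", "peptide"] if config.control_mode == "matched_peptide" \
        else ["protein"]
    peptides = peptides.drop(
        columns=["control_log2_ratio", "control_p", "no_control"],
        errors="ignore",
    )
    out = peptides.merge(
        control_stats[keys + ["control_log2_ratio", "control_p"]],
        on=keys, how="left",
    )
    has_control = out["control_log2_ratio"].notna() & out["control_p"].notna()
    trigger = (
        has_control
        & (out["control_log2_ratio"].abs() > config.normalization_fc_log2)
        & (out["control_p"] < config.normalization_alpha)
    )
    already = out.get("normalized")
    if already is not None:
        trigger &= ~already.fillna(False).astype(bool)
    out["log2_ratio"] = np.where(
        trigger, out["log2_ratio"] - out["control_log2_ratio"], out["log2_ratio"]
    )
    out["normalized"] = trigger | (
        already.fillna(False).astype(bool) if already is not None else False
    )
    out["no_control"] = ~has_control
    return out


# ---------------------------------------------------------------------------
# per-protein multiple-testing correction and significance


def adjust_per_protein(peptides: pd.DataFrame) -> pd.DataFrame:
    """Benjamini-Hochberg step-up applied independently within each protein.

    High-coverage proteins offer more chances to reject the per-protein null
    ("this protein is not structurally different"); correcting within the
    protein keeps that from inflating calls.
    """
    out = peptides.copy()
    adjusted = np.full(len(out), np.nan)
    pvals = out["p_value"].to_numpy(dtype=float)
    for _, idx in out.groupby("protein").indices.items():
        p = pvals[idx]
        ok = np.isfinite(p)
        if ok.any():
            adj = multipletests(p[ok], method="fdr_bh")[1]
            tmp = np.full(len(idx), np.nan)
            tmp[ok] = adj
            adjusted[idx] = tmp
    out["adjusted_p"] = adjusted
    return out


def flag_significant(peptides: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    """Mark peptides exceeding both the fold-change and adjusted-p thresholds."""
    out = peptides.copy()
    out["significant"] = (
        out["log2_ratio"].abs() > config.fc_threshold_log2
    ) & (out["adjusted_p"] < config.alpha_adjusted)
    out["significant"] = out["significant"].fillna(False).astype(bool)
    return out
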