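"""Cross-experiment association analyses.

These operations relate the cognition comparison to the refoldability
comparison (and to protein covariates): 2x2 contingency of protein-level
calls with Fisher's exact test, residue-level proximity between structural
sites from the two experiments, proximity of sites to post-translational
modifications, and binned covariate enrichment with chi-square tests.

Site conventions: a "site" is the PK cut residue of a half-tryptic peptide
or the midpoint residue of a fully tryptic one; proximity means an absolute
residue distance of at most the window (5 residues for cross-experiment
colocalization, 15 for PTM proximity).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyTable",
    "fisher_exact_2x2",
    "protein_contingency",
    "label_site_proximity",
    "site_contingency",
    "ptm_proximity_fractions",
    "covariate_enrichment",
    "site_level_frequency",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table of counts [[a, b], [c, d]] with its exact-test summary."""

    a: int
    b: int
    c: int
    d: int
    row_labels: tuple[str, str]
    col_labels: tuple[str, str]
    odds_ratio: float
    p_two_sided: float

    @property
    def counts(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])

    def row_fractions(self, column: int = 0) -> tuple[float, float]:
        """Fraction of each row falling in the given column."""
        r1 = self.a + self.b
        r2 = self.c + self.d
        top = (self.a, self.c) if column == 0 else (self.b, self.d)
        return (
            top[0] / r1 if r1 else float("nan"),
            top[1] / r2 if r2 else float("nan"),
        )


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Sample odds ratio and two-sided Fisher exact p for [[a, b], [c, d]].

    The two-sided p sums hypergeometric probabilities no larger than that of
    the observed table.  The odds ratio is the sample (a*d)/(b*c), infinite
    when b*c == 0 and a*d > 0.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("counts must be nonnegative integers")
    if a + b + c + d == 0:
        raise ValueError("empty contingency table")
    if b * c == 0:
        odds = float("nan") if a * d == 0 else float("inf")
    else:
        odds = (a * d) / (b * c)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return odds, float(p)


def protein_contingency(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    labels: tuple[str, str] = ("a_called", "b_called"),
) -> tuple[ContingencyTable, dict[str, float]]:
    """Cross-tabulate two protein call sets over their common universe.

    Only proteins *assessed* in both experiments (call ``called`` or
    ``not_called``, not insufficient) enter the table.  Rows split on
    experiment B's call, columns on experiment A's, so the per-row marginal
    frequencies answer "how likely is an (un)called-in-B protein to be
    called in A", and their quotient is the fold ratio.
    """
    def assessed(calls):
        keep = calls["call"].isin(["called", "not_called"])
        return calls.loc[keep].set_index("protein")["call"] == "called"

    sa, sb = assessed(calls_a), assessed(calls_b)
    common = sa.index.intersection(sb.index)
    if len(common) == 0:
        raise ValueError("no proteins assessed in both experiments")
    a_called = sa.loc[common]
    b_called = sb.loc[common]
    a = int((a_called & b_called).sum())
    b = int((~a_called & b_called).sum())
    c = int((a_called & ~b_called).sum())
    d = int((~a_called & ~b_called).sum())
    odds, p = fisher_exact_2x2(a, b, c, d)
    table = ContingencyTable(
        a, b, c, d,
        row_labels=(labels[1], f"not_{labels[1]}"),
        col_labels=(labels[0], f"not_{labels[0]}"),
        odds_ratio=odds, p_two_sided=p,
    )
    freq_b = a / (a + b) if a + b else float("nan")
    freq_not_b = c / (c + d) if c + d else float("nan")
    fold = freq_b / freq_not_b if freq_not_b else float("inf")
    marginals = {
        f"frequency_{labels[0]}_given_{labels[1]}": freq_b,
        f"frequency_{labels[0]}_given_not_{labels[1]}": freq_not_b,
        "fold_ratio": fold,
        "n_common": len(common),
    }
    return table, marginals


def label_site_proximity(
    site: int,
    ref_sites_significant: Iterable[int],
    ref_sites_not: Iterable[int],
    window: int = 5,
) -> str:
    """Classify one site by which reference sites lie within the window.

    Returns ``uniquely_near_sig``, ``uniquely_near_nonsig``, ``both`` or
    ``neither``; the latter two are excluded from the downstream 2x2.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    near_sig = any(abs(site - r) <= window for r in ref_sites_significant)
    near_non = any(abs(site - r) <= window for r in ref_sites_not)
    if near_sig and near_non:
        return "both"
    if near_sig:
        return "uniquely_near_sig"
    if near_non:
        return "uniquely_near_nonsig"
    return "neither"


def site_contingency(
    query_sites: pd.DataFrame,
    ref_sites: pd.DataFrame,
    window: int = 5,
) -> tuple[ContingencyTable, pd.DataFrame]:
    """Residue-level colocalization between two experiments' sites.

    ``query_sites`` and ``ref_sites`` carry columns ``protein``,
    ``residue_index`` and boolean ``significant``.  Each query site is
    labelled by :func:`label_site_proximity` against the reference sites on
    its protein; sites near both kinds or near neither are excluded, and
    the remaining sites form a 2x2 of (query significant) x (uniquely near
    significant reference), tested with Fisher's exact test.

    Returns the table plus a per-row summary with the unique-proximity
    fractions computed over included sites and the raw label counts, so
    alternative denominators can be audited.
    """
    ref_by_protein: dict[str, tuple[list[int], list[int]]] = {}
    for prot, grp in ref_sites.groupby("protein"):
        sig = grp.loc[grp["significant"].astype(bool), "residue_index"].tolist()
        non = grp.loc[~grp["significant"].astype(bool), "residue_index"].tolist()
        ref_by_protein[prot] = (sig, non)

    labels = []
    for prot, res, qsig in query_sites[
        ["protein", "residue_index", "significant"]
    ].itertuples(index=False):
        sig_refs, non_refs = ref_by_protein.get(prot, ([], []))
        labels.append(
            (bool(qsig), label_site_proximity(res, sig_refs, non_refs, window))
        )
    lab = pd.DataFrame(labels, columns=["query_significant", "proximity"])
    counts = (
        lab.groupby(["query_significant", "proximity"]).size().unstack(fill_value=0)
    )
    counts = counts.reindex(
        index=[True, False],
        columns=["uniquely_near_sig", "uniquely_near_nonsig", "both", "neither"],
        fill_value=0,
    )

    a = int(counts.loc[True, "uniquely_near_sig"])
    b = int(counts.loc[True, "uniquely_near_nonsig"])
    c = int(counts.loc[False, "uniquely_near_sig"])
    d = int(counts.loc[False, "uniquely_near_nonsig"])
    if a + b + c + d == 0:
        # every site fell in `both`/`neither`: no testable table
        odds, p = float("nan"), 1.0
    else:
        odds, p = fisher_exact_2x2(a, b, c, d)
    table = ContingencyTable(
        a, b, c, d,
        row_labels=("query_significant", "query_not_significant"),
        col_labels=("uniquely_near_sig", "uniquely_near_nonsig"),
        odds_ratio=odds, p_two_sided=p,
    )
    summary = counts.reset_index().rename(columns={"query_significant": "row"})
    included = summary["uniquely_near_sig"] + summary["uniquely_near_nonsig"]
    with np.errstate(invalid="ignore", divide="ignore"):
        summary["fraction_uniquely_near_sig"] = np.where(
            included > 0, summary["uniquely_near_sig"] / included, np.nan
        )
    return table, summary


def ptm_proximity_fractions(
    sites: pd.DataFrame,
    ptm_sites: pd.DataFrame,
    window: int = 15,
) -> pd.DataFrame:
    """Fraction of significant and non-significant sites proximal to a PTM.

    One row per PTM kind with the proximal fraction and counts among
    significant and non-significant sites; proximity is |distance| <=
    window on the same protein.  With an empty PTM list both fractions
    are 0.
    """
    kinds = sorted(ptm_sites["kind"].unique()) if len(ptm_sites) else []
    rows = []
    for kind in kinds or [None]:
        if kind is None:
            sub = ptm_sites.iloc[0:0]
        else:
            sub = ptm_sites.loc[ptm_sites["kind"] == kind]
        ptm_by_protein = {
            prot: grp["residue_index"].to_numpy()
            for prot, grp in sub.groupby("accession")
        }
        near = []
        for prot, res in sites[["protein", "residue_index"]].itertuples(index=False):
            mods = ptm_by_protein.get(prot)
            near.append(
                bool(mods is not None and np.any(np.abs(mods - res) <= window))
            )
        frame = sites.assign(_near=near)
        sig = frame["significant"].astype(bool)
        n_sig, n_non = int(sig.sum()), int((~sig).sum())
        prox_sig = int(frame.loc[sig, "_near"].sum())
        prox_non = int(frame.loc[~sig, "_near"].sum())
        rows.append({
            "kind": kind if kind is not None else "none",
            "fraction_significant_proximal": prox_sig / n_sig if n_sig else 0.0,
            "fraction_nonsignificant_proximal": prox_non / n_non if n_non else 0.0,
            "n_significant": n_sig,
            "n_nonsignificant": n_non,
            "n_significant_proximal": prox_sig,
            "n_nonsignificant_proximal": prox_non,
        })
    return pd.DataFrame(rows)


DEFAULT_BINNINGS: dict[str, Sequence[float]] = {
    # deciles of percent disorder 0-100
    "percent_disorder": tuple(np.arange(0, 101, 10.0)),
    "mw_kda": (0.0, 20.0, 40.0, 60.0, 100.0, float("inf")),
}


def _bin_series(values: pd.Series, column: str, bins) -> pd.Series:
    if bins is None:
        bins = DEFAULT_BINNINGS.get(column)
    if bins is None:  # categorical / small-integer covariates
        if column == "n_domains":
            return values.map(lambda v: "3+" if v >= 3 else str(int(v)))
        return values.astype(str)
    edges = list(bins)
    # ordered categorical keeps bins in numeric order through the groupbys
    return pd.cut(values, bins=edges, include_lowest=True, right=True)


def covariate_enrichment(
    protein_calls: pd.DataFrame,
    annotation: pd.DataFrame,
    column: str,
    bins: Sequence[float] | None = None,
) -> tuple[pd.DataFrame, float]:
    """Per-bin call frequency and a chi-square test of independence.

    ``protein_calls`` provides call status; proteins marked insufficient are
    excluded.  Bins with zero proteins are dropped (with the per-bin frame
    reflecting that).  For overlapping memberships (domain topologies), call
    :func:`topology_enrichment` instead.
    """
    assessed = protein_calls.loc[
        protein_calls["call"].isin(["called", "not_called"])
    ]
    merged = assessed.merge(
        annotation[["accession", column]].rename(columns={"accession": "protein"}),
        on="protein", how="inner",
    ).dropna(subset=[column])
    if len(merged) == 0:
        raise ValueError("no annotated, assessed proteins to bin")
    merged["_bin"] = _bin_series(merged[column], column, bins)
    merged["_called"] = merged["call"] == "called"
    counts = merged.groupby("_bin", observed=False)["_called"].agg(["sum", "count"])
    counts = counts[counts["count"] > 0]
    per_bin = pd.DataFrame({
        "bin": counts.index.astype(str),
        "n_proteins": counts["count"].to_numpy(),
        "n_called": counts["sum"].to_numpy(),
        "fraction_called": (counts["sum"] / counts["count"]).to_numpy(),
    }).reset_index(drop=True)
    table = np.column_stack([
        per_bin["n_called"].to_numpy(),
        (per_bin["n_proteins"] - per_bin["n_called"]).to_numpy(),
    ])
    nonzero = table.sum(axis=1) > 0
    table = table[nonzero]
    if table.shape[0] < 2 or np.any(table.sum(axis=0) == 0):
        p = 1.0
    else:
        p = float(stats.chi2_contingency(table, correction=False)[1])
    return per_bin, p


def topology_enrichment(
    protein_calls: pd.DataFrame,
    annotation: pd.DataFrame,
) -> pd.DataFrame:
    """Per-topology call frequency with a 2x2 chi-square each.

    Domain-topology memberships overlap (a protein may contain several
    domains), so each topology is tested as members vs non-members.
    """
    assessed = protein_calls.loc[
        protein_calls["call"].isin(["called", "not_called"])
    ]
    merged = assessed.merge(
        annotation[["accession", "topologies"]].rename(
            columns={"accession": "protein"}
        ),
        on="protein", how="inner",
    )
    merged["_called"] = merged["call"] == "called"
    all_topologies = sorted({t for tup in merged["topologies"] for t in tup})
    rows = []
    for topo in all_topologies:
        member = merged["topologies"].map(lambda tup: topo in tup)
        a = int((member & merged["_called"]).sum())
        b = int((member & ~merged["_called"]).sum())
        c = int((~member & merged["_called"]).sum())
        d = int((~member & ~merged["_called"]).sum())
        tab = np.array([[a, b], [c, d]])
        if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
            p = 1.0
        else:
            p = float(stats.chi2_contingency(tab, correction=False)[1])
        rows.append({
            "topology": topo, "n_members": a + b, "n_members_called": a,
            "fraction_called": a / (a + b) if a + b else float("nan"),
            "chi2_p": p,
        })
    return pd.DataFrame(rows)


def site_level_frequency(
    peptide_results: pd.DataFrame,
    annotation: pd.DataFrame,
    column: str,
    bins: Sequence[float] | None = None,
    deduplicate: bool = True,
) -> pd.DataFrame:
    """Per-bin fraction of significant sites, without protein assignment.

    Assessing sites directly controls for coverage bias: a protein with
    more peptides gets more sites in the denominator too.  By default
    identical (protein, residue) sites from different peptides are counted
    once (a site is significant if any peptide at it is); both counts are
    reported via the ``n_sites`` / ``n_site_records`` columns.
    """
    sites = peptide_results.dropna(subset=["site"]).copy()
    sites["site"] = sites["site"].astype(int)
    sites["significant"] = sites["significant"].fillna(False).astype(bool)
    n_records = sites.groupby(["protein", "site"]).size()
    if deduplicate:
        sites = (
            sites.groupby(["protein", "site"])["significant"].any().reset_index()
        )
    merged = sites.merge(
        annotation[["accession", column]].rename(columns={"accession": "protein"}),
        on="protein", how="inner",
    ).dropna(subset=[column])
    merged["_bin"] = _bin_series(merged[column], column, bins)
    agg = merged.groupby("_bin", observed=False).agg(
        n_sites=("significant", "size"),
        n_significant=("significant", "sum"),
    )
    agg = agg[agg["n_sites"] > 0]
    record_counts = merged.merge(
        n_records.rename("n_rec"), left_on=["protein", "site"],
        right_index=True, how="left",
    ).groupby("_bin", observed=False)["n_rec"].sum()
    out = agg.reset_index().rename(columns={"_bin": "bin"})
    out["fraction_significant"] = out["n_significant"] / out["n_sites"]
    out["n_site_records"] = (
        out["bin"].map(record_counts).fillna(out["n_sites"]).astype(int)
    )
    out["bin"] = out["bin"].astype(str)
    return out
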