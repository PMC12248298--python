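"""Readers and writers for ion tables, proteomes, designs, and results.

The quantification entry point is a FragPipe-style ``combined_ion`` TSV with
one row per ion (peptide + modification + charge) and one intensity column
per sample.  Cells equal to 0, the empty string, or ``NA`` are treated as
missing, matching label-free-quantification conventions where 0 denotes an
unobserved ion.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from .config import DesignError, SampleDesign

__all__ = [
    "IonTable",
    "FormatError",
    "read_combined_ion_table",
    "read_fasta_proteome",
    "read_sample_design",
    "read_annotation_table",
    "read_ptm_sites",
    "write_results",
    "read_peptide_results",
    "read_protein_calls",
]

ID_COLUMNS = ("protein", "peptide", "ion")

#: Default combined_ion header dialect.  A caller may pass ``column_map`` to
#: adapt other FragPipe versions without touching the reader.
DEFAULT_COLUMN_MAP = {
    "Protein": "protein",
    "Peptide Sequence": "peptide",
    "Ion": "ion",
}

_VALID_AA = set("ACDEFGHIKLMNPQRSTVWY")


class FormatError(ValueError):
    """Raised for malformed input files."""


@dataclass
class IonTable:
    """Ion-level intensity matrix with identifiers and a sample design.

    ``data`` is a wide DataFrame with columns ``protein``, ``peptide``,
    ``ion`` followed by one float column per sample (NaN = missing).
    """

    data: pd.DataFrame
    design: SampleDesign

    def __post_init__(self) -> None:
        missing_id = [c for c in ID_COLUMNS if c not in self.data.columns]
        if missing_id:
            raise FormatError(f"ion table missing identifier columns: {missing_id}")
        absent = [s for s in self.design.sample_ids if s not in self.data.columns]
        if absent:
            raise DesignError(
                f"samples in design absent from ion table: {absent}"
            )
        ions = self.data["ion"]
        if ions.duplicated().any():
            dupes = sorted(ions[ions.duplicated()].unique().tolist())
            raise FormatError(f"duplicate ion ids: {dupes[:5]}")
        vals = self.data[self.design.sample_ids].to_numpy(dtype=float)
        if np.any(vals[np.isfinite(vals)] <= 0):
            raise FormatError("intensities must be strictly positive when present")

    @property
    def samples(self) -> list[str]:
        return self.design.sample_ids

    @property
    def intensities(self) -> pd.DataFrame:
        return self.data[self.samples]

    def matrix(self) -> np.ndarray:
        return self.data[self.samples].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, mask) -> "IonTable":
        return IonTable(self.data.loc[mask].reset_index(drop=True), self.design)

    def with_design(self, design: SampleDesign) -> "IonTable":
        return IonTable(self.data, design)


def _coerce_intensity(col: pd.Series) -> pd.Series:
    s = col.replace({"": np.nan, "NA": np.nan, "na": np.nan, "NaN": np.nan})
    s = pd.to_numeric(s, errors="raise").astype(float)
    return s.mask(s == 0, np.nan)


def read_combined_ion_table(
    path,
    design: SampleDesign,
    column_map: Mapping[str, str] | None = None,
) -> IonTable:
    """Read a combined_ion TSV into an :class:`IonTable`.

    Intensity columns are matched as ``<sample_id> Intensity`` or the bare
    ``<sample_id>``; 0/empty/NA cells become missing.
    """
    cmap = dict(DEFAULT_COLUMN_MAP if column_map is None else column_map)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    missing = [src for src in cmap if src not in raw.columns]
    if missing:
        raise FormatError(
            f"combined_ion table at {path} missing identifier columns: {missing}"
        )
    dup_cols = raw.columns[raw.columns.duplicated()].tolist()
    if dup_cols:
        raise FormatError(f"duplicated columns in {path}: {sorted(set(dup_cols))}")
    out = raw[list(cmap)].rename(columns=cmap).copy()
    out["peptide"] = out["peptide"].str.upper()
    for sid in design.sample_ids:
        if f"{sid} Intensity" in raw.columns:
            src = f"{sid} Intensity"
        elif sid in raw.columns:
            src = sid
        else:
            raise DesignError(f"sample {sid!r} from design absent from header of {path}")
        out[sid] = _coerce_intensity(raw[src])
    return IonTable(out.reset_index(drop=True), design)


def _accession_from_header(header: str) -> str:
    """UniProt-style ``sp|ACC|NAME`` -> middle token, else first token."""
    first = header.split()[0]
    parts = first.split("|")
    return parts[1] if len(parts) >= 3 else first


def read_fasta_proteome(path) -> dict[str, str]:
    """Read a FASTA proteome to {accession: uppercase sequence}."""
    proteome: dict[str, str] = {}
    n = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n += 1
        acc = _accession_from_header(rec.description or rec.id)
        seq = str(rec.seq).upper()
        bad = set(seq) - _VALID_AA
        if bad:
            raise FormatError(
                f"non-amino-acid characters {sorted(bad)} in record {acc!r}"
            )
        if acc in proteome:
            raise FormatError(f"duplicate accession in proteome: {acc!r}")
        proteome[acc] = seq
    if n == 0:
        raise FormatError(f"no FASTA records found in {path}")
    return proteome


def read_sample_design(path) -> SampleDesign:
    """Read a headered TSV with sample_id, group, replicate_index columns."""
    tab = pd.read_csv(path, sep="\t")
    return SampleDesign(tab)


def read_annotation_table(path) -> pd.DataFrame:
    """Per-protein covariates: accession, percent_disorder, mw_kda,
    n_domains, topologies (``;``-separated), lifetime_days."""
    tab = pd.read_csv(path, sep="\t")
    if "accession" not in tab.columns:
        raise FormatError("annotation table requires an 'accession' column")
    if "percent_disorder" in tab.columns:
        pd_vals = tab["percent_disorder"].dropna()
        if ((pd_vals < 0) | (pd_vals > 100)).any():
            raise FormatError("percent_disorder must lie within [0, 100]")
    if "topologies" in tab.columns:
        tab["topologies"] = (
            tab["topologies"].fillna("").map(
                lambda s: tuple(t for t in str(s).split(";") if t)
            )
        )
    return tab.set_index("accession", drop=False)


def read_ptm_sites(path, proteome: Mapping[str, str] | None = None) -> pd.DataFrame:
    """PTM site list: accession, residue_index (1-based), kind."""
    tab = pd.read_csv(path, sep="\t")
    required = {"accession", "residue_index", "kind"}
    missing = required - set(tab.columns)
    if missing:
        raise FormatError(f"PTM table missing columns: {sorted(missing)}")
    if (tab["residue_index"] < 1).any():
        raise FormatError("residue_index must be 1-based positive")
    if proteome is not None:
        for acc, grp in tab.groupby("accession"):
            if acc in proteome and (grp["residue_index"] > len(proteome[acc])).any():
                raise FormatError(f"PTM residue beyond protein length for {acc}")
    return tab


PEPTIDE_RESULT_COLUMNS = [
    "protein", "peptide", "trypticity", "site",
    "log2_ratio", "p_value", "adjusted_p", "significant",
]
PROTEIN_CALL_COLUMNS = [
    "protein", "n_valid_peptides", "n_significant_peptides", "call",
]


def _fmt_number(x) -> str:
    if pd.isna(x):
        return ""
    return f"{float(x):.6g}"


def _fmt_p(x) -> str:
    if pd.isna(x):
        return ""
    return f"{float(x):.6e}"


def write_results(peptide_results: pd.DataFrame, protein_calls: pd.DataFrame,
                  peptide_path, protein_path) -> None:
    """Write peptide- and protein-level result TSVs.

    Column orders are fixed (see ``PEPTIDE_RESULT_COLUMNS`` and
    ``PROTEIN_CALL_COLUMNS``); rows are sorted by (protein, site, peptide)
    and (protein) respectively; p-values use scientific notation, other
    numbers plain decimal with 6 significant digits.
    """
    pep = peptide_results.copy()
    for col in PEPTIDE_RESULT_COLUMNS:
        if col not in pep.columns:
            pep[col] = pd.NA
    pep = pep[PEPTIDE_RESULT_COLUMNS].sort_values(
        ["protein", "site", "peptide"], na_position="last"
    )
    out = pep.copy()
    out["log2_ratio"] = pep["log2_ratio"].map(_fmt_number)
    out["p_value"] = pep["p_value"].map(_fmt_p)
    out["adjusted_p"] = pep["adjusted_p"].map(_fmt_p)
    out["site"] = pep["site"].map(lambda x: "" if pd.isna(x) else str(int(x)))
    out["significant"] = pep["significant"].map(
        lambda x: "" if pd.isna(x) else str(bool(x))
    )
    out.to_csv(peptide_path, sep="\t", index=False)

    prot = protein_calls.copy()
    for col in PROTEIN_CALL_COLUMNS:
        if col not in prot.columns:
            prot[col] = pd.NA
    prot = prot[PROTEIN_CALL_COLUMNS].sort_values("protein")
    prot.to_csv(protein_path, sep="\t", index=False)


def read_peptide_results(path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t")
    for col in ("log2_ratio", "p_value", "adjusted_p", "site"):
        tab[col] = pd.to_numeric(tab[col], errors="coerce")
    if "significant" in tab.columns:
        tab["significant"] = tab["significant"].map(
            {True: True, False: False, "True": True, "False": False}
        )
    return tab


def read_protein_calls(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_combined_ion_table(table: IonTable, path) -> None:
    """Serialize an IonTable back to the combined_ion TSV dialect
    (missing cells written as 0, per LFQ convention)."""
    inv = {v: k for k, v in DEFAULT_COLUMN_MAP.items()}
    out = table.data.rename(columns=inv).copy()
    for sid in table.samples:
        col = out[sid].fillna(0.0)
        out[f"{sid} Intensity"] = col
        del out[sid]
    out.to_csv(path, sep="\t", index=False)
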