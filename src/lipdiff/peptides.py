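"""Peptide localization, trypticity classification, and site assignment.

In a limited-proteolysis experiment the protease of interest (proteinase K)
cuts native proteins at solvent-accessible positions; a subsequent complete
trypsin digest then reads those cuts out as *half-tryptic* peptides — one
terminus follows trypsin's rule (immediately preceded by K or R), the other
marks the PK cut.  Fully tryptic peptides conform at both ends.  The residue
position carried into all site-level analyses is the PK cut site for
half-tryptic peptides and the (floor) midpoint residue for fully tryptic
peptides.

Protein N- and C-termini are treated as trypsin-conforming boundaries, the
standard proteomics convention.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

__all__ = [
    "PeptideLocation",
    "locate_peptide",
    "classify_trypticity",
    "assign_site",
    "locate_and_classify",
    "percent_half_tryptic",
    "strip_modifications",
]

TRYPTIC_RESIDUES = frozenset("KR")
HALF_KINDS = ("half_nterm", "half_cterm")

def strip_modifications(ion_id: str) -> str:
    """Reduce a modified-sequence ion id (e.g. ``AAK[+42.0106]LR2`` or
    ``M(ox)PEPTIDEK3``) to its bare peptide sequence: bracketed annotations
    are removed first, then any remaining non-upper-case character (charge
    suffix digits, lowercase tags)."""
    bare = re.sub(r"\[[^\]]*\]|\([^\)]*\)", "", ion_id)
    return re.sub(r"[^A-Z]", "", bare)


@dataclass(frozen=True)
class PeptideLocation:
    """Position of a peptide within its parent protein (1-based, inclusive)."""

    protein_accession: str
    start: int
    end: int
    trypticity: str
    site: int | None
    multi_match: bool = False

    def __post_init__(self) -> None:
        if self.trypticity not in (
            "full", "half_nterm", "half_cterm", "non_tryptic", "unmapped"
        ):
            raise ValueError(f"unknown trypticity {self.trypticity!r}")


def locate_peptide(peptide: str, protein: str) -> tuple[int, int] | None:
    """Leftmost exact match of ``peptide`` in ``protein`` as 1-based
    (start, end) inclusive, or None if unmapped."""
    if not peptide:
        raise ValueError("empty peptide sequence")
    idx = protein.find(peptide)
    if idx < 0:
        return None
    return idx + 1, idx + len(peptide)


def classify_trypticity(start: int, end: int, protein: str) -> str:
    """Classify a located peptide by how its termini conform to trypsin.

    The N-terminal end conforms iff the peptide begins the protein or the
    preceding residue is K/R; the C-terminal end conforms iff the peptide
    ends the protein or its last residue is K/R.
    """
    if not (1 <= start <= end <= len(protein)):
        raise ValueError("peptide span outside protein")
    n_ok = start == 1 or protein[start - 2] in TRYPTIC_RESIDUES
    c_ok = end == len(protein) or protein[end - 1] in TRYPTIC_RESIDUES
    if n_ok and c_ok:
        return "full"
    if n_ok != c_ok:
        # exactly one end conforms; the *failing* end is the PK cut
        return "half_nterm" if not n_ok else "half_cterm"
    return "non_tryptic"


def assign_site(start: int, end: int, trypticity: str) -> int:
    """Structural site residue: the PK cut for half-tryptic peptides, the
    floor midpoint for fully tryptic ones."""
    if trypticity == "full":
        return (start + end) // 2
    if trypticity == "half_nterm":
        return start
    if trypticity == "half_cterm":
        return end
    raise ValueError(f"no site defined for trypticity {trypticity!r}")


def locate_and_classify(
    peptide: str,
    accession: str,
    proteome: Mapping[str, str],
) -> PeptideLocation:
    """Locate ``peptide`` in the protein named by the ion-table row and
    classify it.

    Multi-mapping is flagged when the peptide occurs more than once in that
    protein or matches additional proteins of the proteome; the leftmost
    occurrence in the named protein is used.
    """
    protein = proteome.get(accession)
    span = None if protein is None else locate_peptide(peptide, protein)
    if span is None:
        return PeptideLocation(accession, 0, 0, "unmapped", None)
    start, end = span
    trypt = classify_trypticity(start, end, protein)
    site = assign_site(start, end, trypt) if trypt != "non_tryptic" else None
    multi = protein.find(peptide, start) >= 0
    if not multi:
        for acc, seq in proteome.items():
            if acc != accession and peptide in seq:
                multi = True
                break
    return PeptideLocation(accession, start, end, trypt, site, multi_match=multi)


def percent_half_tryptic(trypticities: Sequence[str] | Iterable[str]) -> float:
    """Percentage of classified peptides that are half-tryptic.

    The denominator counts full, half and non-tryptic peptides; unmapped
    entries are excluded.
    """
    counted = [t for t in trypticities if t != "unmapped"]
    if not counted:
        raise ValueError("no classified peptides")
    n_half = sum(t in HALF_KINDS for t in counted)
    return 100.0 * n_half / len(counted)
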