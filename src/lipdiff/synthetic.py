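"""Synthetic LiP-MS study generator.

Emulates the data the differential pipeline consumes — a random proteome,
FragPipe-style ion tables for a LiP run and a trypsin-only control, a
sample design with cohort metadata, per-protein annotations — together
with a ground-truth manifest of everything planted, so that recovery,
calibration and false-discovery behaviour can be measured exactly.

The generative model: each protein is digested in silico with trypsin;
a subset of its peptides is observed, each as one or more ions (charge
states); in the LiP table a configurable fraction of peptides carries a
proteinase-K cut and is therefore half-tryptic; per-ion baseline
intensities are lognormal, replicate intensities scatter around the group
mean with a fixed within-group coefficient of variation; structurally
affected ("planted") proteins shift >=2 of their peptides by a fixed log2
effect in one group of the LiP table only, while the control table carries
protein-level abundance effects only.  Missingness is the union of a hard
detection threshold (missing-not-at-random: the drawn intensity fell below
it) and independent random dropout (missing completely at random).

Defaults mirror the aging-cohort study design: 10 vs 7 replicates,
within-group CV 0.20, ~47% half-tryptic peptides in LiP samples vs ~8% in
controls, and planted effects of |log2| = 2 on 2-4 peptides for 15% of
proteins.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .config import ConfigError, SampleDesign
from .io import IonTable

__all__ = [
    "SimulationParams",
    "TruthSet",
    "SimulationResult",
    "generate_proteome",
    "tryptic_digest",
    "simulate_lip_study",
    "assign_cohort",
    "LEARNING_INDEX_CUTOFF",
]

#: Morris-water-maze learning-index cutoff separating aged-unimpaired (below)
#: from aged-impaired (at or above); higher scores mean worse performance.
LEARNING_INDEX_CUTOFF = 240.0

AMINO_ACIDS = list("ACDEFGHILMNPQSTVWY")  # 18 non-K/R residues
KR_FREQUENCY = 0.11  # combined K+R frequency, realistic for tryptic digests


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions for :func:`simulate_lip_study`."""

    n_proteins: int = 200
    protein_length_log_mean: float = 6.0   # ln-scale; median ~400 residues
    protein_length_log_sd: float = 0.35
    min_protein_length: int = 60
    peptides_per_protein: int = 6
    ions_per_peptide_mean: float = 1.5     # geometric, support >= 1
    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"AU": 10, "AI": 7}
    )
    baseline_log2_mean: float = 17.0       # ~1.3e5 intensity units
    baseline_log2_sd: float = 2.5
    cv: float = 0.20                       # within-group coefficient of variation
    planted_fraction: float = 0.15
    planted_peptides_min: int = 2
    planted_peptides_max: int = 4
    planted_effect_log2: float = 2.0
    control_de_fraction: float = 0.05
    control_effect_log2: float = 1.5
    mnar_threshold: float = 10_000.0
    mcar_rate: float = 0.03
    pk_cut_probability: float = 0.47       # LiP half-tryptic mass
    pk_cut_probability_control: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("planted_fraction", "control_de_fraction", "mcar_rate",
                     "pk_cut_probability", "pk_cut_probability_control"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.planted_peptides_min < 2:
            raise ConfigError(
                "planted peptides per protein must be >= 2 so a planted "
                "protein can satisfy the calling rule"
            )
        if self.planted_peptides_max < self.planted_peptides_min:
            raise ConfigError("planted_peptides_max < planted_peptides_min")
        if self.cv <= 0 or self.ions_per_peptide_mean < 1:
            raise ConfigError("cv must be > 0 and ions_per_peptide_mean >= 1")

    def with_(self, **overrides) -> "SimulationParams":
        return replace(self, **overrides)


@dataclass
class TruthSet:
    """Ground truth for one simulated study."""

    planted_proteins: list[str]
    planted_peptides: pd.DataFrame   # protein, peptide, effect_log2
    control_de_proteins: pd.DataFrame  # protein, effect_log2
    missingness: pd.DataFrame        # table, ion, sample, cause
    learning_indexes: pd.DataFrame   # sample_id, group, learning_index
    peptide_meta: pd.DataFrame       # table, protein, peptide, trypticity
    seed: int


@dataclass
class SimulationResult:
    lip: IonTable
    control: IonTable
    design: SampleDesign
    annotation: pd.DataFrame
    ptm_sites: pd.DataFrame
    truth: TruthSet
    proteome: dict[str, str]


def generate_proteome(
    n_proteins: int,
    seed: int,
    length_log_mean: float = 6.0,
    length_log_sd: float = 0.35,
    min_length: int = 60,
) -> dict[str, str]:
    """Random protein sequences with ~11% combined K/R so tryptic peptides
    of realistic length exist.  Deterministic per seed."""
    rng = np.random.default_rng(seed)
    lengths = np.maximum(
        np.rint(rng.lognormal(length_log_mean, length_log_sd, n_proteins)),
        min_length,
    ).astype(int)
    alphabet = np.array(["K", "R"] + AMINO_ACIDS)
    probs = np.array(
        [KR_FREQUENCY / 2, KR_FREQUENCY / 2]
        + [(1 - KR_FREQUENCY) / len(AMINO_ACIDS)] * len(AMINO_ACIDS)
    )
    proteome = {}
    for i, L in enumerate(lengths):
        seq = "".join(rng.choice(alphabet, size=L, p=probs))
        proteome[f"SYN{i + 1:04d}"] = seq
    return proteome


def tryptic_digest(sequence: str) -> list[tuple[int, int]]:
    """Fully tryptic fragments as 1-based inclusive (start, end) spans,
    cutting after every K/R (no missed cleavages)."""
    spans = []
    start = 1
    for i, aa in enumerate(sequence, start=1):
        if aa in "KR" or i == len(sequence):
            spans.append((start, i))
            start = i + 1
    return [s for s in spans if s[1] >= s[0]]


def _half_tryptic_fragment(
    span: tuple[int, int], sequence: str, rng: np.random.Generator
) -> tuple[int, int] | None:
    """Cut a tryptic peptide at a uniform interior position, returning a
    genuinely half-tryptic fragment of length >= 5, or None."""
    start, end = span
    candidates = []
    for cut in range(start, end):  # cut after residue `cut`
        left = (start, cut)
        right = (cut + 1, end)
        # left keeps the conforming N-terminus; it is half-tryptic iff its
        # new C-terminal residue is not K/R (and not the protein terminus)
        if cut - start + 1 >= 5 and sequence[cut - 1] not in "KR" and cut != len(sequence):
            candidates.append(left)
        # right keeps the conforming C-terminus; half-tryptic iff preceded
        # by a non-K/R residue
        if end - cut >= 5 and sequence[cut - 1] not in "KR" and cut + 1 != 1:
            candidates.append(right)
    if not candidates:
        return None
    return candidates[rng.integers(len(candidates))]


def assign_cohort(learning_index: float) -> str:
    """Cohort from the water-maze learning index: at or above the cutoff is
    aged-impaired (worse performance), below is aged-unimpaired."""
    if learning_index <= 0:
        raise ValueError("learning index must be positive")
    return "AI" if learning_index >= LEARNING_INDEX_CUTOFF else "AU"


def _draw_learning_indexes(
    design: SampleDesign, rng: np.random.Generator
) -> pd.DataFrame:
    rows = []
    for sid, group in design.table[["sample_id", "group"]].itertuples(index=False):
        if group == "AI":
            li = float(rng.uniform(245.0, 330.0))
        else:  # AU, young, or refolding labels — all below cutoff
            li = float(rng.uniform(150.0, 235.0))
        rows.append({"sample_id": sid, "group": group, "learning_index": li})
    return pd.DataFrame(rows)


def _sigma_from_cv(cv: float) -> float:
    # lognormal multiplicative noise with unit mean and the requested CV
    return float(np.sqrt(np.log1p(cv**2)))


def simulate_lip_study(
    proteome: dict[str, str] | None = None,
    params: SimulationParams = SimulationParams(),
) -> SimulationResult:
    """Generate one synthetic study (LiP + control tables, design,
    annotations, PTM sites, truth manifest).  Bit-reproducible per seed."""
    rng = np.random.default_rng(params.seed)
    if proteome is None:
        proteome = generate_proteome(
            params.n_proteins, int(rng.integers(2**31 - 1)),
            params.protein_length_log_mean, params.protein_length_log_sd,
            params.min_protein_length,
        )
    accs = list(proteome)
    design = SampleDesign.from_groups(dict(params.group_sizes))
    groups = design.groups
    if len(groups) != 2:
        raise ConfigError("simulation requires exactly two groups")
    num_cols = design.samples_in(groups[0])
    den_cols = design.samples_in(groups[1])
    sigma = _sigma_from_cv(params.cv)

    n_planted = int(round(params.planted_fraction * len(accs)))
    planted = set(rng.choice(accs, size=n_planted, replace=False)) if n_planted else set()
    n_control_de = int(round(params.control_de_fraction * len(accs)))
    control_de = (
        {a: float(rng.choice([-1, 1]) * params.control_effect_log2)
         for a in rng.choice(accs, size=n_control_de, replace=False)}
        if n_control_de else {}
    )

    lip_rows, ctrl_rows = [], []
    planted_records, meta_records = [], []

    for acc in accs:
        seq = proteome[acc]
        spans = [s for s in tryptic_digest(seq) if 7 <= s[1] - s[0] + 1 <= 50]
        if not spans:
            continue
        k = min(params.peptides_per_protein, len(spans))
        chosen_idx = rng.choice(len(spans), size=k, replace=False)
        chosen = [spans[i] for i in chosen_idx]

        # which peptides (by index among chosen LiP peptides) carry effects
        if acc in planted:
            n_eff = int(rng.integers(params.planted_peptides_min,
                                     params.planted_peptides_max + 1))
            n_eff = min(n_eff, k)
            eff_idx = set(rng.choice(k, size=n_eff, replace=False).tolist())
        else:
            eff_idx = set()

        for table_name, rows, pk_prob in (
            ("lip", lip_rows, params.pk_cut_probability),
            ("control", ctrl_rows, params.pk_cut_probability_control),
        ):
            for j, span in enumerate(chosen):
                frag, trypt = span, "full"
                if rng.random() < pk_prob:
                    half = _half_tryptic_fragment(span, seq, rng)
                    if half is not None:
                        frag = half
                        trypt = "half"
                pep = seq[frag[0] - 1: frag[1]]
                meta_records.append(
                    {"table": table_name, "protein": acc, "peptide": pep,
                     "trypticity": trypt}
                )
                effect = 0.0
                if table_name == "lip" and j in eff_idx:
                    effect = float(rng.choice([-1, 1]) * params.planted_effect_log2)
                    planted_records.append(
                        {"protein": acc, "peptide": pep, "effect_log2": effect}
                    )
                if table_name == "control" and acc in control_de:
                    effect = control_de[acc]
                n_ions = int(rng.geometric(1.0 / params.ions_per_peptide_mean))
                for charge in range(2, 2 + n_ions):
                    baseline = 2.0 ** rng.normal(
                        params.baseline_log2_mean, params.baseline_log2_sd
                    )
                    mean_num = baseline * 2.0**effect
                    mean_den = baseline
                    noise = np.exp(
                        rng.normal(-sigma**2 / 2, sigma,
                                   len(num_cols) + len(den_cols))
                    )
                    vals = np.concatenate([
                        mean_num * noise[: len(num_cols)],
                        mean_den * noise[len(num_cols):],
                    ])
                    row = {"protein": acc, "peptide": pep,
                           "ion": f"{acc}/{j}/{pep}/{table_name}/{charge}"}
                    row.update(dict(zip(num_cols + den_cols, vals)))
                    rows.append(row)

    missing_records = []

    def apply_missingness(rows: list[dict], table_name: str) -> pd.DataFrame:
        df = pd.DataFrame(rows)
        samples = num_cols + den_cols
        vals = df[samples].to_numpy(dtype=float)
        mnar = vals < params.mnar_threshold
        mcar = rng.random(vals.shape) < params.mcar_rate
        ions = df["ion"].to_numpy()
        for mask, cause in ((mnar, "mnar"), (mcar & ~mnar, "mcar")):
            ii, jj = np.nonzero(mask)
            for i, j in zip(ii.tolist(), jj.tolist()):
                missing_records.append(
                    {"table": table_name, "ion": ions[i],
                     "sample": samples[j], "cause": cause}
                )
        vals[mnar | mcar] = np.nan
        df[samples] = vals
        # drop ions missing everywhere: they would never be quantified
        keep = ~np.all(np.isnan(df[samples].to_numpy(dtype=float)), axis=1)
        return df.loc[keep].reset_index(drop=True)

    lip_df = apply_missingness(lip_rows, "lip")
    ctrl_df = apply_missingness(ctrl_rows, "control")

    lip = IonTable(lip_df, design)
    control = IonTable(ctrl_df, design)

    annotation, ptm_sites = _annotate(proteome, rng)
    truth = TruthSet(
        planted_proteins=sorted(planted),
        planted_peptides=pd.DataFrame(
            planted_records, columns=["protein", "peptide", "effect_log2"]
        ),
        control_de_proteins=pd.DataFrame(
            [{"protein": a, "effect_log2": e} for a, e in sorted(control_de.items())],
            columns=["protein", "effect_log2"],
        ),
        missingness=pd.DataFrame(
            missing_records, columns=["table", "ion", "sample", "cause"]
        ),
        learning_indexes=_draw_learning_indexes(design, rng),
        peptide_meta=pd.DataFrame(meta_records),
        seed=params.seed,
    )
    return SimulationResult(lip, control, design, annotation, ptm_sites,
                            truth, proteome)


TOPOLOGIES = (
    "all-alpha", "all-beta", "alpha/beta", "alpha+beta",
    "TIM-barrel", "flavodoxin-like", "beta-grasp", "SH3",
)


def _annotate(
    proteome: dict[str, str], rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-protein covariates and PTM site lists with realistic marginals.

    Covariates are drawn independently of planted effects (the generator
    does not build covariate-call associations in; enrichment analyses on
    synthetic data therefore test the null path unless a caller plants
    associations explicitly).
    """
    rows, ptm_rows = [], []
    for acc, seq in proteome.items():
        length = len(seq)
        n_domains = int(rng.poisson(1.2))
        topo = tuple(
            sorted(rng.choice(TOPOLOGIES, size=min(n_domains, len(TOPOLOGIES)),
                              replace=False))
        ) if n_domains else ()
        rows.append({
            "accession": acc,
            "percent_disorder": float(np.clip(rng.beta(1.2, 2.5) * 100, 0, 100)),
            "mw_kda": length * 0.110,  # ~110 Da mean residue mass
            "n_domains": n_domains,
            "topologies": topo,
            "lifetime_days": float(rng.lognormal(2.0, 1.0)),
        })
        for kind, rate in (("phospho", 0.008), ("oxidation", 0.01)):
            n_mod = rng.binomial(length, rate)
            if n_mod:
                for res in rng.choice(length, size=n_mod, replace=False):
                    ptm_rows.append(
                        {"accession": acc, "residue_index": int(res) + 1,
                         "kind": kind}
                    )
    annotation = pd.DataFrame(rows).set_index("accession", drop=False)
    ptm = pd.DataFrame(ptm_rows, columns=["accession", "residue_index", "kind"])
    return annotation, ptm
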