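"""Global physicochemical peptide descriptors and screening statistics.

Computes the descriptor panel used to compare generated peptides against
their training set: net charge (Henderson–Hasselbalch at pH 7.4),
isoelectric point, Eisenberg hydrophobicity and hydrophobic moment,
aromaticity, charge density, aliphatic index, instability index and
hydrophobic ratio.  On top of the panel sit min-max scaling to a reference
corpus, Euclidean distances to the reference centroid in the scaled
descriptor space, Welch's t-tests, and the random / amphipathic-helical
baseline sequence generators.

The pKa set (Bjellqvist) and the Eisenberg consensus hydrophobicity scale
are shipped as editable YAML data files; the dipeptide instability weights
are the Guruprasad DIWV table as distributed with Biopython.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from Bio.SeqUtils import molecular_weight
from Bio.SeqUtils.ProtParamData import DIWV
from scipy import stats

from .corpus import CANONICAL, Corpus, Peptide


def _load_yaml(name: str) -> dict:
    with resources.files("pepgen.data").joinpath(name).open() as fh:
        return yaml.safe_load(fh)


EISENBERG: dict[str, float] = _load_yaml("eisenberg.yaml")
_PKA = _load_yaml("pka.yaml")

#: Residues counted as hydrophobic for the hydrophobic-ratio descriptor.
HYDROPHOBIC_SET = frozenset("ACFILMVWY")
#: Aromatic residues.
AROMATIC_SET = frozenset("FWY")

#: Stable column order of descriptor tables.
DESCRIPTOR_COLUMNS = [
    "charge",
    "eisenberg_hydrophobicity",
    "hydrophobic_moment",
    "length",
    "isoelectric_point",
    "aromaticity",
    "charge_density",
    "aliphatic_index",
    "instability_index",
    "hydrophobic_ratio",
]

#: The combined descriptor space used for centroid distances (the panel
#: reported side by side for training vs generated sets).
DISTANCE_FEATURES = [
    "charge",
    "eisenberg_hydrophobicity",
    "hydrophobic_moment",
    "length",
    "isoelectric_point",
    "aromaticity",
]


# ---------------------------------------------------------------------------
# Single-sequence descriptors


def net_charge(seq: str, pH: float = 7.4, include_termini: bool = True) -> float:
    """Net charge in elementary units from Henderson–Hasselbalch sums.

    Basic groups (K, R, H, N-terminus) contribute ``+1/(1+10^(pH-pKa))``;
    acidic groups (D, E, C, Y, C-terminus) contribute ``-1/(1+10^(pKa-pH))``.
    Monotone non-increasing in pH.
    """
    pos = 0.0
    neg = 0.0
    for aa, pka in _PKA["sidechain_basic"].items():
        n = seq.count(aa)
        if n:
            pos += n / (1.0 + 10.0 ** (pH - pka))
    for aa, pka in _PKA["sidechain_acidic"].items():
        n = seq.count(aa)
        if n:
            neg += n / (1.0 + 10.0 ** (pka - pH))
    if include_termini:
        pos += 1.0 / (1.0 + 10.0 ** (pH - _PKA["n_terminus"]))
        neg += 1.0 / (1.0 + 10.0 ** (_PKA["c_terminus"] - pH))
    return pos - neg


def isoelectric_point(seq: str, tol: float = 1e-4) -> float:
    """pH at which the net charge vanishes, by bisection on [0, 14]."""
    lo, hi = 0.0, 14.0
    c_lo = net_charge(seq, lo)
    c_hi = net_charge(seq, hi)
    if c_lo < 0 or c_hi > 0:
        raise ArithmeticError("net charge does not change sign on pH [0, 14]")
    while hi - lo > 1e-8:
        mid = 0.5 * (lo + hi)
        c = net_charge(seq, mid)
        if abs(c) < tol:
            return mid
        if c > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def eisenberg_mean(seq: str) -> float:
    """Arithmetic mean of Eisenberg consensus hydrophobicities."""
    return sum(EISENBERG[aa] for aa in seq) / len(seq)


def hydrophobic_moment(seq: str, angle: float = 100.0) -> float:
    """Eisenberg hydrophobic moment μH at a helical twist of *angle* degrees.

    μH = |Σ_i H_i e^{i·δ·i}| / N with H the Eisenberg values; the canonical
    measure of helical amphipathicity.
    """
    delta = math.radians(angle)
    s = sum(EISENBERG[aa] * math.sin(i * delta) for i, aa in enumerate(seq))
    c = sum(EISENBERG[aa] * math.cos(i * delta) for i, aa in enumerate(seq))
    return math.hypot(s, c) / len(seq)


def aromaticity(seq: str) -> float:
    """Fraction of residues that are F, W or Y."""
    return sum(aa in AROMATIC_SET for aa in seq) / len(seq)


def aliphatic_index(seq: str) -> float:
    """Ikai aliphatic index: X_A + 2.9 X_V + 3.9 (X_I + X_L), mole percent."""
    n = len(seq)
    x = {aa: 100.0 * seq.count(aa) / n for aa in "AVIL"}
    return x["A"] + 2.9 * x["V"] + 3.9 * (x["I"] + x["L"])


def instability_index(seq: str) -> float:
    """Guruprasad instability index: (10/L) Σ DIWV over adjacent dipeptides.

    Length-1 sequences return 0 by convention.
    """
    if len(seq) < 2:
        return 0.0
    total = sum(DIWV[a][b] for a, b in zip(seq, seq[1:]))
    return 10.0 / len(seq) * total


def hydrophobic_ratio(seq: str) -> float:
    """Fraction of residues in the configured hydrophobic set."""
    return sum(aa in HYDROPHOBIC_SET for aa in seq) / len(seq)


def charge_density(seq: str, pH: float = 7.4) -> float:
    """Net charge per Dalton of average molecular weight."""
    return net_charge(seq, pH) / molecular_weight(seq, "protein")


def describe(corpus: Corpus, pH: float = 7.4) -> pd.DataFrame:
    """Descriptor table, one row per peptide, indexed by peptide id."""
    if len(corpus) == 0:
        raise ValueError("cannot describe an empty corpus")
    rows = []
    for p in corpus:
        s = p.sequence
        rows.append({
            "charge": net_charge(s, pH),
            "eisenberg_hydrophobicity": eisenberg_mean(s),
            "hydrophobic_moment": hydrophobic_moment(s),
            "length": float(len(s)),
            "isoelectric_point": isoelectric_point(s),
            "aromaticity": aromaticity(s),
            "charge_density": charge_density(s, pH),
            "aliphatic_index": aliphatic_index(s),
            "instability_index": instability_index(s),
            "hydrophobic_ratio": hydrophobic_ratio(s),
        })
    return pd.DataFrame(rows, index=[p.id for p in corpus],
                        columns=DESCRIPTOR_COLUMNS)


# ---------------------------------------------------------------------------
# Scaling and distances


@dataclass
class ScalingParams:
    """Per-descriptor (min, max) reference ranges for min-max scaling."""

    minima: pd.Series
    maxima: pd.Series

    @property
    def columns(self) -> list[str]:
        return list(self.minima.index)


def fit_scaling(reference: pd.DataFrame) -> ScalingParams:
    """Learn min-max ranges from a reference table; constant columns dropped.

    A constant column cannot define a scale and is excluded from the scaled
    descriptor space (with a warning via pandas' natural NaN propagation
    avoided by dropping it here).
    """
    if len(reference) == 0:
        raise ValueError("reference table is empty")
    minima = reference.min()
    maxima = reference.max()
    keep = maxima > minima
    if not keep.all():
        import logging
        logging.getLogger(__name__).warning(
            "fit_scaling: dropping constant column(s) %s",
            list(reference.columns[~keep]),
        )
    return ScalingParams(minima=minima[keep], maxima=maxima[keep])


def apply_scaling(table: pd.DataFrame, params: ScalingParams) -> pd.DataFrame:
    """(x - min) / (max - min); reference range maps to [0, 1], not clipped."""
    missing = set(params.columns) - set(table.columns)
    if missing:
        raise KeyError(f"table lacks descriptor column(s) {sorted(missing)}")
    sub = table[params.columns]
    return (sub - params.minima) / (params.maxima - params.minima)


def unscale(table: pd.DataFrame, params: ScalingParams) -> pd.DataFrame:
    return table * (params.maxima - params.minima) + params.minima


def euclidean_to_centroid(
    scaled_query: pd.DataFrame, scaled_reference: pd.DataFrame
) -> tuple[pd.Series, float, float]:
    """Per-row L2 distance to the reference centroid, plus (mean, SD).

    Both tables must share descriptor columns (the scaled combined space).
    """
    if list(scaled_query.columns) != list(scaled_reference.columns):
        raise KeyError(
            "descriptor columns differ: "
            f"{list(scaled_query.columns)} vs {list(scaled_reference.columns)}"
        )
    centroid = scaled_reference.mean(axis=0)
    diff = scaled_query - centroid
    dist = pd.Series(np.sqrt((diff ** 2).sum(axis=1)), index=scaled_query.index,
                     name="distance")
    return dist, float(dist.mean()), float(dist.std(ddof=1)) if len(dist) > 1 else 0.0


# ---------------------------------------------------------------------------
# Welch's t-test


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float


def welch_ttest(sample_a, sample_b) -> WelchResult:
    """Two-sided Welch's t-test with Welch–Satterthwaite degrees of freedom."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            # degenerate null case: identical constant samples
            return WelchResult(t=0.0, df=float(len(a) + len(b) - 2), p=1.0)
        raise ValueError("zero variance in both samples with unequal means")
    na, nb = len(a), len(b)
    se2a, se2b = va / na, vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2a + se2b)
    df = (se2a + se2b) ** 2 / (
        se2a ** 2 / (na - 1) + se2b ** 2 / (nb - 1)
    )
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(t=float(t), df=float(df), p=float(min(p, 1.0)))


def compare_tables(
    table_a: pd.DataFrame, table_b: pd.DataFrame,
    features: list[str] | None = None,
) -> pd.DataFrame:
    """Per-feature mean ± SD of both tables plus Welch t/df/p.

    The side-by-side layout used to report generated vs training (or
    random) descriptor panels.
    """
    features = features or [c for c in table_a.columns if c in table_b.columns]
    rows = []
    for feat in features:
        res = welch_ttest(table_a[feat], table_b[feat])
        rows.append({
            "feature": feat,
            "mean_a": table_a[feat].mean(), "sd_a": table_a[feat].std(ddof=1),
            "mean_b": table_b[feat].mean(), "sd_b": table_b[feat].std(ddof=1),
            "t": res.t, "df": res.df, "p": res.p,
        })
    return pd.DataFrame(rows).set_index("feature")


# ---------------------------------------------------------------------------
# Baseline sequence generators


def _sample_lengths(n: int, length_sampler, rng: np.random.Generator) -> list[int]:
    if callable(length_sampler):
        return [int(length_sampler(rng)) for _ in range(n)]
    pool = list(length_sampler)
    return [int(x) for x in rng.choice(pool, size=n)] if n else []


def random_baseline(n: int, length_sampler, seed: int = 0) -> Corpus:
    """Uniform-composition random peptides; the null baseline.

    ``length_sampler`` is either a sequence of lengths to resample from
    (e.g. the empirical training lengths) or a callable ``rng -> int``.
    """
    rng = np.random.default_rng(seed)
    alphabet = list(CANONICAL)
    peptides = []
    for j, L in enumerate(_sample_lengths(n, length_sampler, rng)):
        seq = "".join(rng.choice(alphabet, size=L))
        peptides.append(Peptide(id=f"ran_{j:05d}", sequence=seq,
                                provenance="random"))
    return Corpus(peptides)


#: Residue pools for the amphipathic helical baseline.
HELICAL_HYDROPHOBIC_POOL = "AFILMVW"
HELICAL_POLAR_POOL = "DEHKNQRST"


def helical_baseline(n: int, length_sampler, seed: int = 0,
                     twist: float = 100.0) -> Corpus:
    """Idealised amphipathic helical peptides.

    Residues are placed on a helical wheel at *twist* degrees per residue;
    positions whose wheel angle falls in a 180° arc draw from a hydrophobic
    pool, the rest from a polar/charged pool.  By construction the resulting
    peptides have a large hydrophobic moment.
    """
    rng = np.random.default_rng(seed)
    hyd = list(HELICAL_HYDROPHOBIC_POOL)
    pol = list(HELICAL_POLAR_POOL)
    peptides = []
    for j, L in enumerate(_sample_lengths(n, length_sampler, rng)):
        seq = []
        for i in range(L):
            angle = (i * twist) % 360.0
            pool = hyd if angle < 180.0 else pol
            seq.append(str(rng.choice(pool)))
        peptides.append(Peptide(id=f"hel_{j:05d}", sequence="".join(seq),
                                provenance="helical"))
    return Corpus(peptides)
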