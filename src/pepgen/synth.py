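"""Synthetic fixtures for every pipeline stage.

Generates motif-bearing peptide corpora (learnable structure for the
language model), contact-count series with a planted number of low-variance
records, two-chain toy trajectories whose per-frame contact counts follow a
prescribed schedule, and smooth toy CD basis sets.  Everything is
reproducible from its seed and round-trips through the package's standard
file formats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cdspec import BasisSet
from .corpus import CANONICAL, Corpus, Peptide
from .mdscreen import AtomRecord, ContactSeries, Trajectory


@dataclass
class SynthSpec:
    """Recipe for a synthetic peptide corpus."""

    seed: int = 0
    n: int = 100
    length_range: tuple[int, int] = (9, 15)
    motif: str | None = None
    composition_bias: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        lo, hi = self.length_range
        if lo > hi or lo < 1:
            raise ValueError(f"invalid length range {self.length_range}")
        if self.motif and len(self.motif) > lo:
            raise ValueError("motif longer than the minimum sequence length")


def synth_corpus(spec: SynthSpec) -> Corpus:
    """Seeded corpus with uniform lengths and an optional implanted motif.

    The motif is placed at a random position in every sequence; non-motif
    positions draw from the (optionally biased) residue distribution.
    """
    rng = np.random.default_rng(spec.seed)
    alphabet = list(CANONICAL)
    if spec.composition_bias:
        w = np.array([spec.composition_bias.get(aa, 1.0) for aa in alphabet], float)
        p = w / w.sum()
    else:
        p = None
    lo, hi = spec.length_range
    peptides = []
    for j in range(spec.n):
        L = int(rng.integers(lo, hi + 1))
        seq = list(rng.choice(alphabet, size=L, p=p))
        if spec.motif:
            pos = int(rng.integers(0, L - len(spec.motif) + 1))
            seq[pos : pos + len(spec.motif)] = list(spec.motif)
        peptides.append(Peptide(id=f"syn_{j:05d}", sequence="".join(seq),
                                provenance="training"))
    return Corpus(peptides)


def synth_contact_records(
    seed: int,
    n_total: int = 127,
    n_low_variance: int = 57,
    cutoff: float = 3.0,
    n_frames: int = 100,
) -> list[tuple[str, ContactSeries, float]]:
    """Contact series with exactly ``n_low_variance`` below the variance cutoff.

    Low-variance series are Poisson-like counts squeezed around their mean;
    high-variance series mix two well-separated count levels.  Each series'
    sample variance is verified by direct recomputation at generation time
    and resampled until it falls on the intended side of the cutoff.
    Binding energies are drawn on both sides of the 17 kcal/mol magnitude
    threshold (negative, MMPBSA sign convention).
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    if not (0 <= n_low_variance <= n_total):
        raise ValueError("need 0 <= n_low_variance <= n_total")
    rng = np.random.default_rng(seed)
    records = []
    for j in range(n_total):
        want_low = j < n_low_variance
        while True:
            base = int(rng.integers(3, 10))
            if want_low:
                counts = base + rng.integers(-1, 2, size=n_frames)
            else:
                jumps = rng.integers(0, 2, size=n_frames)
                counts = base + jumps * int(rng.integers(5, 9)) \
                    + rng.integers(-1, 2, size=n_frames)
            var = np.asarray(counts, float).var(ddof=1)  # independent check
            if (var <= cutoff) == want_low:
                break
        energy = -float(rng.uniform(8.0, 26.0))
        records.append((f"pep_{j:03d}", ContactSeries(f"pep_{j:03d}", counts), energy))
    order = rng.permutation(n_total)  # interleave low/high variance records
    return [records[i] for i in order]


def synth_trajectory(
    seed: int,
    contact_schedule: list[int],
    n_residue_pairs: int = 10,
) -> Trajectory:
    """Two-chain toy trajectory realising a per-frame contact-count schedule.

    Chain A (the "peptide") and chain B each carry ``n_residue_pairs``
    single-CA residues.  In frame t the first ``schedule[t]`` opposing
    residue pairs sit 3.5 Å apart (inside a 4.0 Å threshold) and the rest
    8 Å apart; distinct pairs are spaced 50 Å along x so cross-pair contacts
    cannot occur.
    """
    schedule = list(contact_schedule)
    if not schedule:
        raise ValueError("contact schedule must have at least one frame")
    if max(schedule) > n_residue_pairs:
        raise ValueError(
            f"schedule requests {max(schedule)} contacts but only "
            f"{n_residue_pairs} residue pairs exist"
        )
    rng = np.random.default_rng(seed)
    atoms = []
    for i in range(n_residue_pairs):
        atoms.append(AtomRecord(name="CA", element="C", res_name="ALA",
                                res_index=i + 1, chain="A"))
    for i in range(n_residue_pairs):
        atoms.append(AtomRecord(name="CA", element="C", res_name="GLY",
                                res_index=i + 1, chain="B"))
    coords = np.zeros((len(schedule), 2 * n_residue_pairs, 3))
    for t, n_contacts in enumerate(schedule):
        for i in range(n_residue_pairs):
            x = 50.0 * i + float(rng.normal(0, 0.01))
            gap = 3.5 if i < n_contacts else 8.0
            coords[t, i] = (x, 0.0, 0.0)
            coords[t, n_residue_pairs + i] = (x, gap, 0.0)
    return Trajectory(atoms=atoms, coords=coords)


def synth_basis(
    seed: int = 0,
    n_classes: int = 3,
    grid: np.ndarray | None = None,
) -> BasisSet:
    """Smooth toy CD basis spectra on a 190–250 nm grid.

    The first class is helix-like (double negative band near 208/222 nm and
    a positive band near 193 nm), the second sheet-like (single negative
    band near 218 nm), the third coil-like (negative band near 198 nm);
    further classes are seeded random smooth curves.
    """
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    wl = np.arange(190.0, 251.0) if grid is None else np.asarray(grid, float)
    rng = np.random.default_rng(seed)

    def band(center: float, width: float, depth: float) -> np.ndarray:
        return depth * np.exp(-0.5 * ((wl - center) / width) ** 2)

    columns = []
    templates = [
        band(193, 6, 60000) + band(208, 6, -33000) + band(222, 7, -30000),
        band(196, 6, 25000) + band(218, 8, -18000),
        band(198, 7, -40000) + band(220, 10, 3000),
    ]
    names = ["helix", "sheet", "coil"]
    for j in range(n_classes):
        if j < 3:
            columns.append(templates[j])
        else:
            centers = rng.uniform(195, 235, size=2)
            depths = rng.uniform(-30000, 30000, size=2)
            columns.append(band(centers[0], 8, depths[0]) + band(centers[1], 8, depths[1]))
            names.append(f"class{j}")
    return BasisSet(wavelengths=wl, class_names=names[:n_classes],
                    basis=np.column_stack(columns))
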