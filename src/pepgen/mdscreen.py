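"""Peptide–receptor contact analysis and the contact-variance screen.

Consumes multi-model PDB trajectories (one MODEL per frame).  Interface
residue pairs are identified with a closed 4.0 Å heavy-atom distance
threshold; the screening statistic is the unbiased sample variance of the
per-frame contact count.  Candidates pass when that variance is <= 3 and
the magnitude of their (favorable) binding free energy is >= 17 kcal/mol,
and survivors are ranked by binding energy (ties: lower variance, then id).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

#: Positively charged residues (three-letter), used by the charged-residue
#: contact selection.
POSITIVE_RESIDUES = frozenset({"ARG", "LYS", "HIS"})
_ONE_TO_THREE = {"R": "ARG", "K": "LYS", "H": "HIS"}


class TrajectoryError(ValueError):
    """Malformed multi-model PDB input."""


@dataclass(frozen=True)
class AtomRecord:
    name: str
    element: str
    res_name: str
    res_index: int
    chain: str


@dataclass
class Trajectory:
    """Fixed atom roster plus per-frame coordinates in Å.

    ``coords`` has shape (n_frames, n_atoms, 3); the roster is shared by
    every frame (enforced at parse time).
    """

    atoms: list[AtomRecord]
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1] != len(self.atoms):
            raise TrajectoryError(
                f"coordinate array {self.coords.shape} inconsistent with "
                f"{len(self.atoms)} atoms"
            )
        if not np.isfinite(self.coords).all():
            raise TrajectoryError("non-finite coordinates")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def chains(self) -> list[str]:
        seen = dict.fromkeys(a.chain for a in self.atoms)
        return list(seen)


@dataclass
class ContactSeries:
    """Per-frame peptide–receptor residue-contact counts."""

    peptide_id: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if (self.counts < 0).any():
            raise ValueError("contact counts must be non-negative")


@dataclass
class ScreenRecord:
    peptide_id: str
    contact_variance: float
    binding_energy: float | None
    passes_variance: bool
    passes_energy: bool
    rank: int | None = None


# ---------------------------------------------------------------------------
# Multi-model PDB I/O


def read_trajectory(path: str | Path) -> Trajectory:
    """Parse a multi-model PDB into a :class:`Trajectory`.

    Every MODEL must carry the same atom roster (name, residue, chain, in
    the same order); a mismatch raises naming the model.  A file without
    MODEL records is read as a single frame.
    """
    path = Path(path)
    frames: list[list[tuple[AtomRecord, tuple[float, float, float]]]] = []
    current: list | None = None
    model_numbers: list[int] = []
    in_model = False
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            if in_model:
                raise TrajectoryError(f"{path}:{lineno}: nested MODEL record")
            in_model = True
            current = []
            model_numbers.append(int(line[6:].split()[0]) if line[6:].split() else len(frames) + 1)
        elif rec == "ENDMDL":
            if not in_model:
                raise TrajectoryError(f"{path}:{lineno}: ENDMDL without MODEL")
            frames.append(current)
            current = None
            in_model = False
        elif rec in ("ATOM", "HETATM"):
            try:
                atom = AtomRecord(
                    name=line[12:16].strip(),
                    element=(line[76:78].strip() or line[12:16].strip()[:1]).upper(),
                    res_name=line[17:20].strip(),
                    res_index=int(line[22:26]),
                    chain=line[21].strip() or "A",
                )
                xyz = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
            except ValueError as exc:
                raise TrajectoryError(f"{path}:{lineno}: malformed ATOM record") from exc
            if current is None:
                current = []
                model_numbers.append(1)
                in_model = False  # implicit single-model file
            current.append((atom, xyz))
    if in_model:
        raise TrajectoryError(f"{path}: unterminated MODEL block")
    if current:  # implicit single-model file without MODEL/ENDMDL
        frames.append(current)
    if not frames:
        raise TrajectoryError(f"{path}: no atoms found")
    roster = [a for a, _ in frames[0]]
    coords = np.empty((len(frames), len(roster), 3))
    for m, frame in enumerate(frames):
        names = [a for a, _ in frame]
        if names != roster:
            raise TrajectoryError(
                f"{path}: model {model_numbers[m]} atom roster differs from model "
                f"{model_numbers[0]} ({len(names)} vs {len(roster)} atoms)"
            )
        coords[m] = [xyz for _, xyz in frame]
    return Trajectory(atoms=roster, coords=coords)


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a multi-model PDB (MODEL/ENDMDL blocks)."""
    with open(path, "w") as fh:
        for m in range(traj.n_frames):
            fh.write(f"MODEL     {m + 1:4d}\n")
            for j, (atom, xyz) in enumerate(zip(traj.atoms, traj.coords[m]), start=1):
                fh.write(
                    f"ATOM  {j:5d} {atom.name:<4s}{atom.res_name:>4s} "
                    f"{atom.chain}{atom.res_index:4d}    "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                    f"  1.00  0.00          {atom.element:>2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Contacts


def _chain_atom_indices(traj: Trajectory, chain: str, heavy_only: bool) -> np.ndarray:
    idx = [
        j for j, a in enumerate(traj.atoms)
        if a.chain == chain and not (heavy_only and a.element == "H")
    ]
    if not idx:
        known = traj.chains
        raise KeyError(f"chain {chain!r} not found (chains: {known})")
    return np.array(idx)


def residue_contacts(
    traj: Trajectory,
    frame: int,
    chain_a: str,
    chain_b: str,
    cutoff: float = 4.0,
    heavy_only: bool = True,
) -> set[tuple[int, int]]:
    """Residue index pairs with any inter-atom distance <= cutoff (closed).

    Pair (i, j) has i from ``chain_a`` and j from ``chain_b``; hydrogens are
    excluded by default (heavy-atom convention for the 4.0 Å threshold).
    """
    ia = _chain_atom_indices(traj, chain_a, heavy_only)
    ib = _chain_atom_indices(traj, chain_b, heavy_only)
    d = cdist(traj.coords[frame, ia], traj.coords[frame, ib])
    pairs = set()
    for ai, bi in zip(*np.nonzero(d <= cutoff)):
        pairs.add((traj.atoms[ia[ai]].res_index, traj.atoms[ib[bi]].res_index))
    return pairs


def contact_series(
    traj: Trajectory,
    chain_a: str,
    chain_b: str,
    cutoff: float = 4.0,
    heavy_only: bool = True,
    positive_only: bool = False,
    peptide_id: str = "peptide",
) -> ContactSeries:
    """Per-frame contact counts between the peptide chain and the receptor.

    ``positive_only`` restricts the peptide-side residues to the positively
    charged set {R, K, H}; an empty selection is a configuration error.
    """
    selected: set[int] | None = None
    if positive_only:
        selected = {
            a.res_index for a in traj.atoms
            if a.chain == chain_a and a.res_name in POSITIVE_RESIDUES
        }
        if not selected:
            raise ValueError(
                f"positive-residue selection is empty for chain {chain_a!r}"
            )
    counts = []
    for m in range(traj.n_frames):
        pairs = residue_contacts(traj, m, chain_a, chain_b, cutoff, heavy_only)
        if selected is not None:
            pairs = {p for p in pairs if p[0] in selected}
        counts.append(len(pairs))
    return ContactSeries(peptide_id=peptide_id, counts=np.array(counts))


def contact_variance(series: ContactSeries, ddof: int = 1) -> float:
    """Unbiased sample variance of the per-frame contact counts."""
    counts = np.asarray(series.counts, dtype=float)
    if len(counts) < 2:
        raise ValueError("contact variance needs at least 2 frames")
    return float(counts.var(ddof=ddof))


def distance_stats(
    traj: Trajectory,
    residue_pair: tuple[tuple[str, int], tuple[str, int]],
    heavy_only: bool = True,
) -> tuple[float, float]:
    """Mean and SD over frames of the minimum inter-atom distance (Å).

    ``residue_pair`` is ((chain, res_index), (chain, res_index)).
    """
    (ch_a, res_a), (ch_b, res_b) = residue_pair
    ia = [j for j, a in enumerate(traj.atoms)
          if a.chain == ch_a and a.res_index == res_a
          and not (heavy_only and a.element == "H")]
    ib = [j for j, a in enumerate(traj.atoms)
          if a.chain == ch_b and a.res_index == res_b
          and not (heavy_only and a.element == "H")]
    if not ia or not ib:
        raise KeyError(f"residue pair {residue_pair} not resolvable")
    per_frame = [
        float(cdist(traj.coords[m, ia], traj.coords[m, ib]).min())
        for m in range(traj.n_frames)
    ]
    arr = np.array(per_frame)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return float(arr.mean()), sd


# ---------------------------------------------------------------------------
# Screening and ranking


def screen(
    records: list[tuple[str, ContactSeries | float, float | None]],
    variance_cutoff: float = 3.0,
    energy_cutoff_kcal: float = 17.0,
) -> list[ScreenRecord]:
    """Apply the contact-variance and binding-energy criteria.

    Each input is (peptide_id, contact series or precomputed variance,
    binding energy in kcal/mol or None).  A record passes the variance
    criterion when variance <= cutoff (closed) and the energy criterion when
    the magnitude of its favorable binding energy is >= the cutoff (i.e.
    ΔG <= -17 kcal/mol under the usual MMPBSA sign convention, but a
    positive magnitude is accepted equivalently).  Nothing is dropped: every
    input returns with its flags; records without an energy fail the energy
    criterion and are flagged by ``binding_energy=None``.
    """
    out = []
    for pid, series_or_var, energy in records:
        if isinstance(series_or_var, ContactSeries):
            var = contact_variance(series_or_var)
        else:
            var = float(series_or_var)
        passes_var = var <= variance_cutoff
        passes_en = energy is not None and abs(energy) >= energy_cutoff_kcal
        out.append(ScreenRecord(
            peptide_id=pid, contact_variance=var, binding_energy=energy,
            passes_variance=passes_var, passes_energy=passes_en,
        ))
    n_var = sum(r.passes_variance for r in out)
    n_both = sum(r.passes_variance and r.passes_energy for r in out)
    logger.info("screen: %d records, %d pass variance <= %g, %d pass both",
                len(out), n_var, variance_cutoff, n_both)
    return out


def rank_top_k(records: list[ScreenRecord], k: int = 20) -> list[ScreenRecord]:
    """Rank records passing both criteria; most favorable energy first.

    Order: larger |binding energy| first, ties by lower contact variance,
    then lexicographic peptide id.  Assigns ``rank`` (1-based) on the
    returned copies; at most ``k`` records are returned.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    passing = [r for r in records if r.passes_variance and r.passes_energy]
    ordered = sorted(
        passing,
        key=lambda r: (-abs(r.binding_energy), r.contact_variance, r.peptide_id),
    )[:k]
    for i, r in enumerate(ordered, start=1):
        r.rank = i
    return ordered


def screen_report(records: list[ScreenRecord]) -> pd.DataFrame:
    """Tabular screening report (CSV-ready), all records with flags and rank."""
    return pd.DataFrame(
        [{
            "peptide_id": r.peptide_id,
            "contact_variance": r.contact_variance,
            "binding_energy_kcal_mol": r.binding_energy,
            "passes_variance": r.passes_variance,
            "passes_energy": r.passes_energy,
            "rank": r.rank,
        } for r in records]
    )


# ---------------------------------------------------------------------------
# Cell-penetrating peptide fusion

PENETRATIN = "RQIKIWFQNRRMKWKK"


def fuse_cpp(seq: str, cpp: str = PENETRATIN) -> str:
    """N-terminal fusion of a cell-penetrating peptide: returns cpp + seq."""
    from .corpus import _CANONICAL_SET
    for s, label in ((cpp, "cpp"), (seq, "sequence")):
        bad = set(s) - _CANONICAL_SET
        if bad:
            raise ValueError(f"non-canonical residue(s) {sorted(bad)} in {label}")
    return cpp + seq
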