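"""Calculated circular-dichroism spectra from secondary-structure content.

A CD spectrum is modelled as a linear combination of per-class basis
spectra (helix, sheet, coil by default) weighted by the secondary-structure
fractions — the basis-set approach used by structure-based empirical
spectrum calculators.  The screening step keeps candidate peptides whose
helical band at 220 nm is at least as strong (as negative, in mean-residue
ellipticity) as a reference spectrum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

#: DSSP-style secondary-structure codes mapped to the 3-class scheme.
_HELIX_CODES = frozenset("HGI")
_SHEET_CODES = frozenset("EB")
_COIL_CODES = frozenset("TSC-")


class BasisError(ValueError):
    """Malformed basis-set file or class mismatch."""


@dataclass
class BasisSet:
    """Per-class CD basis spectra on a common wavelength grid.

    ``basis`` has shape (n_wavelengths, n_classes) in mean-residue
    ellipticity units (deg·cm²·dmol⁻¹); the grid is strictly ascending (nm).
    """

    wavelengths: np.ndarray
    class_names: list[str]
    basis: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.basis = np.asarray(self.basis, dtype=float)
        if self.basis.shape != (len(self.wavelengths), len(self.class_names)):
            raise BasisError(
                f"basis shape {self.basis.shape} inconsistent with "
                f"{len(self.wavelengths)} wavelengths x {len(self.class_names)} classes"
            )
        if np.any(np.diff(self.wavelengths) <= 0):
            raise BasisError("wavelength grid must be strictly ascending")
        if not np.isfinite(self.basis).all():
            raise BasisError("basis contains non-finite values")


@dataclass(frozen=True)
class SSComposition:
    """Secondary-structure fractions per class; must sum to 1."""

    fractions: dict[str, float]

    def __post_init__(self) -> None:
        vals = np.array(list(self.fractions.values()), dtype=float)
        if ((vals < -1e-9) | (vals > 1 + 1e-9)).any():
            raise ValueError("fractions must lie in [0, 1]")
        if abs(vals.sum() - 1.0) > 1e-6:
            raise ValueError(f"fractions sum to {vals.sum():.6f}, expected 1")


@dataclass
class CDSpectrum:
    """Mean-residue ellipticity on a wavelength grid (nm)."""

    wavelengths: np.ndarray
    ellipticity: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.ellipticity = np.asarray(self.ellipticity, dtype=float)
        if self.wavelengths.shape != self.ellipticity.shape:
            raise ValueError("wavelength and ellipticity grids differ in length")


# ---------------------------------------------------------------------------


def load_basis(path: str | Path) -> BasisSet:
    """Parse a whitespace-delimited basis file.

    Line 1: class names.  Each further line: wavelength followed by one
    value per class.  A descending grid is re-sorted ascending with a
    warning; ragged or non-numeric rows raise naming the line.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines()
             if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise BasisError(f"{path}: empty basis file")
    class_names = lines[0].split()
    rows = []
    for lineno, ln in enumerate(lines[1:], start=2):
        parts = ln.split()
        if len(parts) != len(class_names) + 1:
            raise BasisError(
                f"{path}:{lineno}: expected {len(class_names) + 1} columns, "
                f"got {len(parts)}"
            )
        try:
            rows.append([float(x) for x in parts])
        except ValueError as exc:
            raise BasisError(f"{path}:{lineno}: non-numeric value") from exc
    arr = np.array(rows)
    wl, basis = arr[:, 0], arr[:, 1:]
    order = np.argsort(wl)
    if not np.array_equal(order, np.arange(len(wl))):
        logger.warning("load_basis: %s grid not ascending; re-sorting", path)
        wl, basis = wl[order], basis[order]
    return BasisSet(wavelengths=wl, class_names=class_names, basis=basis)


def save_basis(b: BasisSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(" ".join(b.class_names) + "\n")
        for wl, row in zip(b.wavelengths, b.basis):
            fh.write(f"{wl:.1f} " + " ".join(f"{v:.6f}" for v in row) + "\n")


def save_spectrum(s: CDSpectrum, path: str | Path) -> None:
    np.savetxt(path, np.column_stack([s.wavelengths, s.ellipticity]),
               fmt="%.6f", header="wavelength_nm mean_residue_ellipticity")


def load_spectrum(path: str | Path) -> CDSpectrum:
    arr = np.loadtxt(path)
    return CDSpectrum(wavelengths=arr[:, 0], ellipticity=arr[:, 1])


def ss_from_string(dssp_like: str) -> SSComposition:
    """3-class composition from a DSSP-style string (H/G/I, E/B, rest coil)."""
    if not dssp_like:
        raise ValueError("empty secondary-structure string")
    unknown = set(dssp_like) - (_HELIX_CODES | _SHEET_CODES | _COIL_CODES)
    if unknown:
        raise ValueError(f"unknown secondary-structure code(s) {sorted(unknown)}")
    n = len(dssp_like)
    helix = sum(c in _HELIX_CODES for c in dssp_like) / n
    sheet = sum(c in _SHEET_CODES for c in dssp_like) / n
    return SSComposition({"helix": helix, "sheet": sheet,
                          "coil": 1.0 - helix - sheet})


def compute_spectrum(ss: SSComposition, b: BasisSet) -> CDSpectrum:
    """Linear combination: θ(λ) = Σ_j f_j B_j(λ)."""
    if set(ss.fractions) != set(b.class_names):
        raise BasisError(
            f"composition classes {sorted(ss.fractions)} do not match basis "
            f"classes {sorted(b.class_names)}"
        )
    f = np.array([ss.fractions[name] for name in b.class_names])
    return CDSpectrum(wavelengths=b.wavelengths.copy(),
                      ellipticity=b.basis @ f)


def ellipticity_at(s: CDSpectrum, lambda_nm: float) -> float:
    """Linear interpolation of the spectrum; exact at grid points."""
    if not (s.wavelengths[0] <= lambda_nm <= s.wavelengths[-1]):
        raise ValueError(
            f"wavelength {lambda_nm} nm outside grid "
            f"[{s.wavelengths[0]}, {s.wavelengths[-1]}]"
        )
    return float(np.interp(lambda_nm, s.wavelengths, s.ellipticity))


def filter_by_reference(
    candidates: list[tuple[str, CDSpectrum]],
    reference: CDSpectrum,
    lambda_nm: float = 220.0,
    invert: bool = False,
) -> list[str]:
    """Keep candidates whose band at ``lambda_nm`` is at least as helical.

    The default convention reads the 220 nm band as the helical marker:
    a candidate survives iff its ellipticity there is <= the reference's
    (more negative = stronger helical signal, boundary included).
    ``invert`` flips the comparison for the opposite reading of "lower
    ellipticity".  Order-preserving and deterministic.
    """
    ref_val = ellipticity_at(reference, lambda_nm)
    survivors = []
    for cid, spec in candidates:
        val = ellipticity_at(spec, lambda_nm)
        keep = val >= ref_val if invert else val <= ref_val
        if keep:
            survivors.append(cid)
    logger.info("filter_by_reference: %d / %d candidates retained at %.0f nm",
                len(survivors), len(candidates), lambda_nm)
    return survivors
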