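"""Conformer-ensemble bookkeeping.

Kabsch (minimal-RMSD) superposition, redundant-conformer elimination with
an energy window plus pairwise-RMSD sweep, and Boltzmann population
weights.  Energies are carried in kJ/mol relative to an arbitrary zero;
adapters for hartree and kcal/mol inputs convert at the I/O boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Conformer",
    "Ensemble",
    "R_GAS",
    "KJ_PER_HARTREE",
    "KJ_PER_KCAL_TH",
    "kabsch_rmsd",
    "eliminate_redundant",
    "boltzmann_weights",
    "read_xyz",
    "write_xyz",
    "read_shieldings_tsv",
    "write_shieldings_tsv",
]

#: gas constant, J mol^-1 K^-1 (CODATA)
R_GAS = 8.314462618
#: hartree → kJ/mol
KJ_PER_HARTREE = 2625.4996
#: thermochemical kcal → kJ
KJ_PER_KCAL_TH = 4.184


@dataclass(frozen=True)
class Conformer:
    """One geometry with a relative energy and optional per-atom shieldings.

    Parameters
    ----------
    id : str
        Frame identifier.
    elements : tuple of str
        Element symbols, fixed atom ordering.
    coords : ndarray, shape (n_atoms, 3)
        Cartesian coordinates in Å.
    energy : float
        Relative energy in kJ/mol.
    shieldings : dict, optional
        atom index → isotropic shielding σ in ppm.
    """

    id: str
    elements: tuple[str, ...]
    coords: np.ndarray
    energy: float
    shieldings: dict[int, float] | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_atoms, 3)")
        if coords.shape[0] != len(self.elements):
            raise ValueError("elements/coords length mismatch")
        if coords.shape[0] < 2:
            raise ValueError("a conformer needs at least 2 atoms")
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates")
        if not math.isfinite(self.energy):
            raise ValueError("non-finite energy")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "elements", tuple(self.elements))

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def heavy_atom_indices(self) -> tuple[int, ...]:
        return tuple(i for i, el in enumerate(self.elements) if el != "H")


@dataclass(frozen=True)
class Ensemble:
    """A labelled candidate (e.g. one diastereomer) and its conformers."""

    label: str
    conformers: tuple[Conformer, ...]
    temperature: float = 298.15

    def __post_init__(self) -> None:
        conformers = tuple(self.conformers)
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if conformers:
            ref = conformers[0].elements
            for c in conformers[1:]:
                if c.elements != ref:
                    raise ValueError(
                        f"conformer {c.id!r} has a different atom sequence"
                    )
        object.__setattr__(self, "conformers", conformers)

    def __len__(self) -> int:
        return len(self.conformers)

    @property
    def energies(self) -> np.ndarray:
        return np.array([c.energy for c in self.conformers])

    def weights(self) -> np.ndarray:
        """Boltzmann populations at the ensemble temperature."""
        return boltzmann_weights(self.energies, self.temperature)


def kabsch_rmsd(
    a: Conformer,
    b: Conformer,
    subset: tuple[int, ...] | list[int] | None = None,
    heavy_only: bool = True,
) -> float:
    """Minimal RMSD between two conformers over proper rotations + translations.

    Atom correspondence is positional (identical ordering assumed; no
    graph-symmetry correction).  By default only heavy atoms enter the
    superposition; pass ``heavy_only=False`` or an explicit ``subset`` to
    change that.  Reflections are excluded.
    """
    if a.elements != b.elements:
        raise ValueError("conformers must share atom count and ordering")
    if subset is None:
        idx = a.heavy_atom_indices() if heavy_only else tuple(range(a.n_atoms))
    else:
        idx = tuple(subset)
        if not idx:
            raise ValueError("subset must be non-empty")
        if min(idx) < 0 or max(idx) >= a.n_atoms:
            raise IndexError("subset index out of range")
    if not idx:
        raise ValueError("no atoms selected for superposition")
    pa = a.coords[list(idx)]
    pb = b.coords[list(idx)]
    pa = pa - pa.mean(axis=0)
    pb = pb - pb.mean(axis=0)
    # align_vectors solves the orthogonal Procrustes problem restricted to
    # proper rotations (Kabsch); rssd is sqrt of the residual sum of squares
    _, rssd = Rotation.align_vectors(pa, pb)
    return float(rssd / math.sqrt(len(idx)))


def eliminate_redundant(
    ensemble: Ensemble,
    rmsd_cutoff: float = 1.0,
    energy_window: float = 13.0,
    heavy_only: bool = True,
) -> Ensemble:
    """Drop high-energy and geometrically redundant conformers.

    First removes every conformer more than ``energy_window`` kJ/mol above
    the global minimum, then sweeps the survivors in ascending energy,
    keeping a conformer iff its RMSD to every already-kept conformer is
    ≥ ``rmsd_cutoff`` Å (ties at exactly the cutoff are kept).  The
    global-minimum conformer always survives.  Idempotent.
    """
    if rmsd_cutoff <= 0 or energy_window <= 0:
        raise ValueError("cutoffs must be positive")
    if not ensemble.conformers:
        raise ValueError("cannot prune an empty ensemble")
    e_min = min(c.energy for c in ensemble.conformers)
    window = [c for c in ensemble.conformers if c.energy <= e_min + energy_window]
    # stable sort: input order breaks exact energy ties
    window.sort(key=lambda c: c.energy)
    kept: list[Conformer] = []
    for cand in window:
        if all(
            kabsch_rmsd(cand, ref, heavy_only=heavy_only) >= rmsd_cutoff
            for ref in kept
        ):
            kept.append(cand)
    return replace(ensemble, conformers=tuple(kept))


def boltzmann_weights(energies, T: float = 298.15) -> np.ndarray:
    """Boltzmann populations w_i ∝ exp(−(E_i − E_min)/RT).

    Energies in kJ/mol, T in K.  Weights sum to 1 and decrease with energy;
    invariant under a uniform energy shift.
    """
    e = np.asarray(energies, dtype=float)
    if e.size == 0:
        raise ValueError("empty energy list")
    if not np.all(np.isfinite(e)):
        raise ValueError("non-finite energies")
    if T <= 0:
        raise ValueError("temperature must be positive")
    rt = R_GAS * T / 1000.0  # kJ/mol
    w = np.exp(-(e - e.min()) / rt)
    return w / w.sum()


# ---------------------------------------------------------------------------
# I/O: multi-frame XYZ with E=<float> [unit] on the comment line, and a
# sidecar TSV for isotropic shieldings.
# ---------------------------------------------------------------------------

_ENERGY_UNIT_TO_KJ = {
    "kj/mol": 1.0,
    "kj": 1.0,
    "kcal/mol": KJ_PER_KCAL_TH,
    "kcal": KJ_PER_KCAL_TH,
    "hartree": KJ_PER_HARTREE,
    "au": KJ_PER_HARTREE,
}


def _parse_comment_energy(comment: str) -> float:
    """Extract ``E=<float> [unit]`` from an XYZ comment line, in kJ/mol."""
    for token in comment.replace(",", " ").split():
        if token.upper().startswith("E="):
            value = float(token[2:])
            rest = comment.split(token, 1)[1].split()
            unit = rest[0].lower() if rest else "kj/mol"
            factor = _ENERGY_UNIT_TO_KJ.get(unit, 1.0)
            return value * factor
    return 0.0


def read_xyz(path) -> list[Conformer]:
    """Read a multi-frame XYZ trajectory; energies from comment lines."""
    frames: list[Conformer] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    frame_no = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        body = lines[i + 2 : i + 2 + n]
        if len(body) < n:
            raise ValueError(f"truncated XYZ frame at line {i + 1}")
        elements = []
        coords = []
        for line in body:
            parts = line.split()
            elements.append(parts[0])
            coords.append([float(x) for x in parts[1:4]])
        frames.append(
            Conformer(
                id=f"frame{frame_no}",
                elements=tuple(elements),
                coords=np.array(coords),
                energy=_parse_comment_energy(comment),
            )
        )
        frame_no += 1
        i += 2 + n
    return frames


def write_xyz(path, conformers) -> None:
    """Write conformers as multi-frame XYZ, energy on the comment line."""
    with open(path, "w") as fh:
        for c in conformers:
            fh.write(f"{c.n_atoms}\n")
            fh.write(f"E={c.energy:.6f} kJ/mol id={c.id}\n")
            for el, (x, y, z) in zip(c.elements, c.coords):
                fh.write(f"{el} {x:.6f} {y:.6f} {z:.6f}\n")


def read_shieldings_tsv(path) -> dict[str, dict[int, float]]:
    """Read a shieldings sidecar: conformer_id, atom_index, sigma_ppm."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    out: dict[str, dict[int, float]] = {}
    for cid, grp in df.groupby("conformer_id"):
        out[str(cid)] = dict(
            zip(grp["atom_index"].astype(int), grp["sigma_ppm"].astype(float))
        )
    return out


def write_shieldings_tsv(path, conformers) -> None:
    """Write per-conformer shieldings to a sidecar TSV."""
    with open(path, "w") as fh:
        fh.write("conformer_id\tatom_index\tsigma_ppm\n")
        for c in conformers:
            if c.shieldings is None:
                continue
            for idx in sorted(c.shieldings):
                fh.write(f"{c.id}\t{idx}\t{c.shieldings[idx]:.6f}\n")
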