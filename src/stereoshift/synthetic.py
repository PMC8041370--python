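"""Synthetic inputs with a known ground truth.

Stands in for the two external data sources of the assignment workflow:
the quantum-chemistry stage (conformer ensembles with per-atom isotropic
shieldings) and the biosensor (noisy sensorgrams, in :mod:`.spr`).  The
statistical structure emulated is the one the shift-comparison method
relies on: the correct diastereomer's Boltzmann-averaged predictions
scatter around experiment with no systematic component, while wrong
candidates additionally carry a localised systematic offset on atoms near
the misassigned stereocentre.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .conformer import Conformer, Ensemble, boltzmann_weights
from .nmr_shifts import ReferenceShieldings, ShiftTable

__all__ = [
    "StereoCaseSpec",
    "StereoCase",
    "DEFAULT_REFERENCE",
    "generate_stereo_case",
    "generate_toy_conformers",
]

#: TMS shieldings used by the generator (typical GIAO-scale values)
DEFAULT_REFERENCE = ReferenceShieldings(sigma_tms_h=31.8, sigma_tms_c=190.0)


@dataclass(frozen=True)
class StereoCaseSpec:
    """Parameters of one synthetic configurational-assignment case.

    Defaults mirror the difficulty of a real assignment: ¹³C scatter of
    ~2 ppm and ¹H scatter of ~0.2 ppm around experiment (the scale of the
    MAEs such comparisons produce), and a 3 ppm systematic offset on five
    stereocentre-proximal carbons for each wrong candidate.
    """

    n_atoms_c: int = 20
    n_atoms_h: int = 24
    n_candidates: int = 4
    n_conformers: int = 8
    energy_spread: float = 3.0  # kJ/mol, exponential scale
    shift_noise_c: float = 2.0  # ppm, per-conformer Gaussian sd
    shift_noise_h: float = 0.2  # ppm
    decoy_offset: float = 3.0  # ppm on perturbed carbons; /10 on protons
    n_perturbed_atoms: int = 5
    sp2_fraction: float = 0.2
    temperature: float = 298.15
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory for reproducible generation")
        if self.n_candidates < 2:
            raise ValueError("need at least 2 candidates")
        if min(self.shift_noise_c, self.shift_noise_h, self.decoy_offset) < 0:
            raise ValueError("noise and offset magnitudes must be >= 0")
        if self.decoy_offset == 0 and self.shift_noise_c == 0 and self.shift_noise_h == 0:
            raise ValueError(
                "degenerate case: zero decoy offset with zero noise makes "
                "candidates indistinguishable"
            )
        if self.n_perturbed_atoms > self.n_atoms_c:
            raise ValueError("more perturbed atoms than carbons")


@dataclass(frozen=True)
class StereoCase:
    """One generated case: experiment, candidate ensembles, ground truth."""

    experimental: ShiftTable
    candidates: tuple[tuple[str, Ensemble], ...]
    true_label: str
    reference: ReferenceShieldings
    metadata: dict[int, tuple[str, str, str]] = field(default_factory=dict)


def _toy_geometry(rng: np.random.Generator, n_atoms: int) -> np.ndarray:
    return rng.normal(scale=2.0, size=(n_atoms, 3))


def generate_stereo_case(spec: StereoCaseSpec) -> StereoCase:
    """Generate one assignment case with a known correct candidate.

    Per-conformer shieldings are built as σ = σ_TMS − (δ_exp + offset + ε):
    the true candidate has zero offset, so its Boltzmann average differs
    from experiment only through the noise ε; decoys carry an additional
    ±``decoy_offset`` on a contiguous block of sp³ carbons (and a ten-fold
    smaller offset on a matching block of protons, ¹H shift ranges being
    about ten-fold narrower).  Deterministic for a given spec.
    """
    rng = np.random.default_rng(spec.seed)
    n_c, n_h = spec.n_atoms_c, spec.n_atoms_h

    # --- atom layout: carbons first, then protons; methyls in triples ----
    n_methyls = n_h // 6  # a third of protons sit in methyl groups, in 3s
    elements = tuple(["C"] * n_c + ["H"] * n_h)
    labels_c = [f"C-{i + 1}" for i in range(n_c)]
    labels_h = [f"H-{i + 1}" for i in range(n_h)]
    groups_h = [""] * n_h
    for m in range(n_methyls):
        for k in range(3):
            groups_h[3 * m + k] = f"Me-{m + 1}"

    # perturbed block: contiguous sp3 carbons, kept clear of the sp2 set
    start = int(rng.integers(0, n_c - spec.n_perturbed_atoms + 1))
    perturbed_c = set(range(start, start + spec.n_perturbed_atoms))
    n_sp2 = int(round(spec.sp2_fraction * n_c))
    sp2_pool = [i for i in range(n_c) if i not in perturbed_c]
    sp2_idx = set(
        rng.choice(sp2_pool, size=min(n_sp2, len(sp2_pool)), replace=False).tolist()
    )
    hybrid_c = ["sp2" if i in sp2_idx else "sp3" for i in range(n_c)]
    start_h = int(rng.integers(0, n_h - spec.n_perturbed_atoms + 1))
    perturbed_h = set(range(start_h, start_h + spec.n_perturbed_atoms))

    # --- experimental shifts ---------------------------------------------
    delta_c = np.where(
        [h == "sp2" for h in hybrid_c],
        rng.uniform(110.0, 210.0, size=n_c),
        rng.uniform(10.0, 90.0, size=n_c),
    )
    delta_h = rng.uniform(0.5, 8.0, size=n_h)
    for m in range(n_methyls):  # one resonance per methyl
        delta_h[3 * m : 3 * m + 3] = delta_h[3 * m]

    exp_rows = [
        (labels_c[i], "13C", float(delta_c[i]), hybrid_c[i], "")
        for i in range(n_c)
    ]
    seen = set()
    for j in range(n_h):
        g = groups_h[j]
        if g:
            if g in seen:
                continue
            seen.add(g)
            exp_rows.append((g, "1H", float(delta_h[j]), "sp3", g))
        else:
            exp_rows.append((labels_h[j], "1H", float(delta_h[j]), "sp3", ""))
    experimental = ShiftTable.from_rows(exp_rows)

    # atom-index metadata for boltzmann_average_shifts
    metadata: dict[int, tuple[str, str, str]] = {}
    for i in range(n_c):
        metadata[i] = (labels_c[i], hybrid_c[i], "")
    for j in range(n_h):
        metadata[n_c + j] = (labels_h[j], "sp3", groups_h[j])

    # --- candidate ensembles ---------------------------------------------
    true_idx = int(rng.integers(spec.n_candidates))
    base_geom = _toy_geometry(rng, n_c + n_h)
    candidates: list[tuple[str, Ensemble]] = []
    for cand in range(spec.n_candidates):
        label = f"cand-{chr(ord('a') + cand)}"
        offset = np.zeros(n_c + n_h)
        if cand != true_idx:
            signs_c = rng.choice([-1.0, 1.0], size=len(perturbed_c))
            for s, i in zip(signs_c, sorted(perturbed_c)):
                offset[i] = s * spec.decoy_offset
            signs_h = rng.choice([-1.0, 1.0], size=len(perturbed_h))
            for s, j in zip(signs_h, sorted(perturbed_h)):
                offset[n_c + j] = s * spec.decoy_offset / 10.0
        energies = rng.exponential(spec.energy_spread, size=spec.n_conformers)
        energies -= energies.min()
        conformers = []
        for k in range(spec.n_conformers):
            eps_c = rng.normal(0.0, spec.shift_noise_c, size=n_c)
            eps_h = rng.normal(0.0, spec.shift_noise_h, size=n_h)
            eps = np.concatenate([eps_c, eps_h])
            delta_conf = np.concatenate([delta_c, delta_h]) + offset + eps
            sigma_tms = np.array(
                [DEFAULT_REFERENCE.sigma_tms_c] * n_c
                + [DEFAULT_REFERENCE.sigma_tms_h] * n_h
            )
            shieldings = dict(enumerate(sigma_tms - delta_conf))
            coords = base_geom + rng.normal(scale=2.0, size=base_geom.shape)
            conformers.append(
                Conformer(
                    id=f"{label}-conf{k}",
                    elements=elements,
                    coords=coords,
                    energy=float(energies[k]),
                    shieldings=shieldings,
                )
            )
        candidates.append(
            (label, Ensemble(label, tuple(conformers), spec.temperature))
        )

    return StereoCase(
        experimental=experimental,
        candidates=tuple(candidates),
        true_label=candidates[true_idx][0],
        reference=DEFAULT_REFERENCE,
        metadata=metadata,
    )


def generate_toy_conformers(
    n: int,
    n_atoms: int,
    displacement_sd: float,
    seed: int,
    temperature: float = 298.15,
) -> Ensemble:
    """Toy geometries for RMSD/pruning tests.

    Frame 0 is the undisplaced base geometry at energy 0; every further
    frame is the base plus isotropic Gaussian displacements, with energy
    equal to its RMS displacement magnitude in kJ/mol (so energies grow
    with distance from the base).  Deterministic per seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n_atoms < 3:
        raise ValueError("need at least 3 atoms")
    rng = np.random.default_rng(seed)
    base = _toy_geometry(rng, n_atoms)
    elements = tuple(["C"] * n_atoms)
    conformers = [Conformer("toy0", elements, base, 0.0)]
    for k in range(1, n):
        disp = rng.normal(scale=displacement_sd, size=base.shape)
        magnitude = float(np.sqrt(np.mean(np.sum(disp**2, axis=1))))
        conformers.append(
            Conformer(f"toy{k}", elements, base + disp, magnitude)
        )
    return Ensemble("toy", tuple(conformers), temperature)


def recovery_rate(
    spec_template: StereoCaseSpec, n_runs: int, base_seed: int = 0
) -> float:
    """Fraction of runs in which the pipeline ranks the true candidate first.

    Each run regenerates a case from ``spec_template`` with seed
    ``base_seed + run`` and pushes it through Boltzmann averaging and
    MAE ranking.
    """
    from dataclasses import replace as _replace

    from .nmr_shifts import boltzmann_average_shifts
    from .ranking import rank_candidates

    hits = 0
    for run in range(n_runs):
        case = generate_stereo_case(
            _replace(spec_template, seed=base_seed + run)
        )
        tables = []
        for label, ens in case.candidates:
            w = boltzmann_weights(ens.energies, ens.temperature)
            tables.append(
                (
                    label,
                    boltzmann_average_shifts(
                        ens, w, case.reference, metadata=case.metadata
                    ),
                )
            )
        result = rank_candidates(tables, case.experimental)
        hits += result.best == case.true_label
    return hits / n_runs
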