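"""Per-conformer isotropic shieldings → one referenced shift table.

The chain implemented here is the standard GIAO post-processing used in
chemical-shift-based configurational assignment: reference each shielding
σ against TMS computed at the same level of theory (δ = σ_TMS − σ),
Boltzmann-average across the conformer ensemble, collapse magnetically
equivalent sets (methyl protons) to their mean, and drop sp² carbons,
whose computed shifts are too inaccurate to discriminate diastereomers.
Referencing and weighting are both affine, so the order of averaging and
referencing does not matter; this module references first.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .conformer import Ensemble

__all__ = [
    "ShiftTable",
    "ReferenceShieldings",
    "reference_to_tms",
    "boltzmann_average_shifts",
    "average_equivalent",
    "apply_sp2_exclusion",
]

#: ShiftTable column schema
COLUMNS = ["atom_label", "nucleus", "delta_ppm", "hybridization", "equivalence_group"]

_NUCLEI = ("1H", "13C")


@dataclass(frozen=True)
class ShiftTable:
    """A table of chemical shifts with nucleus / hybridization metadata.

    Wraps a DataFrame with columns atom_label, nucleus ('1H'|'13C'),
    delta_ppm, hybridization ('sp2'|'sp3'|'unknown'), equivalence_group
    (empty string = ungrouped).  Labels are unique within a table.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"ShiftTable missing columns: {missing}")
        df = df[COLUMNS].reset_index(drop=True)
        df["atom_label"] = df["atom_label"].astype(str)
        df["equivalence_group"] = df["equivalence_group"].fillna("").astype(str)
        df["hybridization"] = df["hybridization"].fillna("unknown").astype(str)
        if df["atom_label"].duplicated().any():
            dupes = df.loc[df["atom_label"].duplicated(), "atom_label"].tolist()
            raise ValueError(f"duplicate atom labels: {dupes}")
        bad = set(df["nucleus"]) - set(_NUCLEI)
        if bad:
            raise ValueError(f"unknown nuclei: {sorted(bad)}")
        if not np.all(np.isfinite(df["delta_ppm"].to_numpy(dtype=float))):
            raise ValueError("non-finite chemical shifts")
        object.__setattr__(self, "data", df)

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, nucleus: str) -> pd.DataFrame:
        return self.data[self.data["nucleus"] == nucleus]

    def deltas(self) -> pd.Series:
        """atom_label → delta_ppm."""
        return self.data.set_index("atom_label")["delta_ppm"]

    @classmethod
    def from_rows(cls, rows) -> "ShiftTable":
        """Build from (label, nucleus, delta, hybridization, group) tuples."""
        return cls(pd.DataFrame(rows, columns=COLUMNS))

    @classmethod
    def from_tsv(cls, path) -> "ShiftTable":
        df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[])
        return cls(df)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class ReferenceShieldings:
    """TMS shieldings per nucleus, with optional linear scaling.

    With scaling disabled (default) δ = σ_TMS − σ.  With a per-nucleus
    regression line σ = intercept + slope·δ available, δ is recovered as
    (intercept − σ)/(−slope).
    """

    sigma_tms_h: float
    sigma_tms_c: float
    slope_h: float | None = None
    intercept_h: float | None = None
    slope_c: float | None = None
    intercept_c: float | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.sigma_tms_h) and np.isfinite(self.sigma_tms_c)):
            raise ValueError("TMS shieldings must be finite")
        for s in (self.slope_h, self.slope_c):
            if s is not None and s == 0:
                raise ValueError("scaling slope must be nonzero")

    def params(self, nucleus: str) -> tuple[float, float | None, float | None]:
        if nucleus == "1H":
            return self.sigma_tms_h, self.slope_h, self.intercept_h
        if nucleus == "13C":
            return self.sigma_tms_c, self.slope_c, self.intercept_c
        raise ValueError(f"unknown nucleus {nucleus!r}")


def reference_to_tms(sigma, nucleus: str, ref: ReferenceShieldings):
    """Convert isotropic shielding(s) σ to chemical shift(s) δ in ppm.

    Accepts a scalar or an array; vectorised element-wise.
    """
    sigma_tms, slope, intercept = ref.params(nucleus)
    sigma = np.asarray(sigma, dtype=float)
    if slope is not None and intercept is not None:
        delta = (intercept - sigma) / (-slope)
    else:
        delta = sigma_tms - sigma
    return float(delta) if delta.ndim == 0 else delta


def boltzmann_average_shifts(
    ensemble: Ensemble,
    weights,
    ref: ReferenceShieldings,
    nuclei: dict[int, tuple[str, str]] | None = None,
    metadata: dict[int, tuple[str, str, str]] | None = None,
) -> ShiftTable:
    """Weighted-average referenced shifts over a conformer ensemble.

    Parameters
    ----------
    ensemble : Ensemble
        Conformers carrying per-atom shieldings for a common atom set.
    weights : array-like
        Populations aligned with the conformers, summing to 1.
    ref : ReferenceShieldings
        TMS reference.
    metadata : dict, optional
        atom index → (atom_label, hybridization, equivalence_group).
        Defaults derive label from element+index; nucleus is inferred from
        the element symbol (H → 1H, everything else → 13C).
    """
    w = np.asarray(weights, dtype=float)
    if len(w) != len(ensemble.conformers):
        raise ValueError("weight/conformer length mismatch")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    if not ensemble.conformers:
        raise ValueError("empty ensemble")
    first = ensemble.conformers[0]
    if first.shieldings is None:
        raise ValueError(f"conformer {first.id!r} lacks shieldings")
    atom_idx = sorted(first.shieldings)
    for c in ensemble.conformers:
        if c.shieldings is None or sorted(c.shieldings) != atom_idx:
            raise ValueError(
                f"conformer {c.id!r} shieldings do not cover the common atom set"
            )
    rows = []
    for idx in atom_idx:
        element = first.elements[idx]
        nucleus = "1H" if element == "H" else "13C"
        sigma_avg = float(
            np.dot(w, [c.shieldings[idx] for c in ensemble.conformers])
        )
        delta = reference_to_tms(sigma_avg, nucleus, ref)
        if metadata and idx in metadata:
            label, hybrid, group = metadata[idx]
        else:
            label, hybrid, group = f"{element}{idx}", "unknown", ""
        rows.append((label, nucleus, delta, hybrid, group))
    return ShiftTable.from_rows(rows)


def average_equivalent(table: ShiftTable) -> ShiftTable:
    """Collapse each equivalence group to one row at the group-mean shift.

    The collapsed row takes the group label as its atom label (matching the
    single resonance such a set shows experimentally); ungrouped rows pass
    through untouched.  Group members must share a nucleus.
    """
    df = table.data
    grouped = df[df["equivalence_group"] != ""]
    if grouped.empty:
        return table
    out_rows = []
    seen_groups = set()
    for _, row in df.iterrows():
        g = row["equivalence_group"]
        if g == "":
            out_rows.append(tuple(row[c] for c in COLUMNS))
            continue
        if g in seen_groups:
            continue
        seen_groups.add(g)
        members = df[df["equivalence_group"] == g]
        if members["nucleus"].nunique() > 1:
            raise ValueError(f"equivalence group {g!r} spans multiple nuclei")
        hybrids = members["hybridization"].unique()
        out_rows.append(
            (
                g,
                members["nucleus"].iloc[0],
                float(members["delta_ppm"].mean()),
                hybrids[0] if len(hybrids) == 1 else "unknown",
                g,
            )
        )
    return ShiftTable.from_rows(out_rows)


def apply_sp2_exclusion(table: ShiftTable) -> tuple[ShiftTable, int]:
    """Drop sp² carbons, whose computed shifts are unreliable.

    Only ¹³C rows flagged sp2 are removed; protons (including those on sp²
    carbons) and sp³/unknown carbons stay.  Returns the filtered table and
    the number of rows removed.
    """
    df = table.data
    mask = (df["nucleus"] == "13C") & (df["hybridization"] == "sp2")
    removed = int(mask.sum())
    return ShiftTable(df[~mask]), removed
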