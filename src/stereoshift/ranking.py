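"""Δδ / MAE comparison of candidate diastereomer shift tables.

Each candidate's Boltzmann-averaged calculated table is compared with the
experimental table atom by atom (Δδ = |δ_calc − δ_exp|), summarised as a
mean absolute error per nucleus, and candidates are ordered by (¹³C MAE
rank, ¹H MAE rank).  The lowest MAE indicates the best-fitting relative
configuration.  When the two nuclei disagree on the top candidate the
result carries a disagreement flag rather than resolving it silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nmr_shifts import ShiftTable, apply_sp2_exclusion, average_equivalent

__all__ = ["CandidateScore", "RankingResult", "delta_delta", "mae", "rank_candidates"]


@dataclass(frozen=True)
class CandidateScore:
    """Per-candidate Δδ vectors and per-nucleus MAEs."""

    label: str
    delta_delta: dict[str, float]
    mae_13c: float
    mae_1h: float
    n_13c: int
    n_1h: int
    unmatched_calc: tuple[str, ...] = ()
    unmatched_exp: tuple[str, ...] = ()


@dataclass(frozen=True)
class RankingResult:
    """Ordered candidate ranking with per-candidate scores."""

    scores: dict[str, CandidateScore]
    ranking: tuple[str, ...]
    best: str
    disagreement_flag: bool
    ties: tuple[tuple[str, ...], ...] = field(default_factory=tuple)

    def summary(self) -> str:
        lines = [f"{'candidate':<12} {'13C MAE':>8} {'1H MAE':>8} {'n13C':>5} {'n1H':>5}"]
        for label in self.ranking:
            s = self.scores[label]
            lines.append(
                f"{label:<12} {s.mae_13c:>8.2f} {s.mae_1h:>8.2f} "
                f"{s.n_13c:>5d} {s.n_1h:>5d}"
            )
        lines.append(f"best: {self.best}")
        if self.disagreement_flag:
            lines.append("warning: 13C and 1H rankings disagree on the top candidate")
        return "\n".join(lines)


def delta_delta(calc: ShiftTable, exp: ShiftTable) -> tuple[dict[str, float], list[str], list[str]]:
    """Per-atom |δ_calc − δ_exp| over labels present in both tables.

    Returns (deltas, labels only in calc, labels only in exp); unmatched
    labels are reported, never imputed.
    """
    calc_d = calc.deltas()
    exp_d = exp.deltas()
    common = [lab for lab in calc_d.index if lab in exp_d.index]
    if not common:
        raise ValueError("no overlapping atom labels between tables")
    deltas = {lab: abs(float(calc_d[lab]) - float(exp_d[lab])) for lab in common}
    only_calc = [lab for lab in calc_d.index if lab not in exp_d.index]
    only_exp = [lab for lab in exp_d.index if lab not in calc_d.index]
    return deltas, only_calc, only_exp


def mae(deltas) -> float:
    """Mean absolute error: sum of the Δδ values over their count."""
    arr = np.asarray(list(deltas), dtype=float)
    if arr.size == 0:
        raise ValueError("MAE of an empty collection")
    return float(arr.mean())


def _prepare(table: ShiftTable) -> ShiftTable:
    filtered, _ = apply_sp2_exclusion(average_equivalent(table))
    return filtered


def score_candidate(label: str, calc: ShiftTable, exp: ShiftTable) -> CandidateScore:
    """Score one candidate on the sp²-excluded, equivalence-averaged tables."""
    calc_p = _prepare(calc)
    exp_p = _prepare(exp)
    deltas, only_calc, only_exp = delta_delta(calc_p, exp_p)
    nuc_map = dict(zip(calc_p.data["atom_label"], calc_p.data["nucleus"]))
    d_c = [d for lab, d in deltas.items() if nuc_map[lab] == "13C"]
    d_h = [d for lab, d in deltas.items() if nuc_map[lab] == "1H"]
    return CandidateScore(
        label=label,
        delta_delta=deltas,
        mae_13c=mae(d_c) if d_c else float("nan"),
        mae_1h=mae(d_h) if d_h else float("nan"),
        n_13c=len(d_c),
        n_1h=len(d_h),
        unmatched_calc=tuple(only_calc),
        unmatched_exp=tuple(only_exp),
    )


def rank_from_maes(maes: dict[str, tuple[float, float]]) -> RankingResult:
    """Rank candidates from precomputed (¹³C MAE, ¹H MAE) pairs.

    Ordering is lexicographic on (¹³C MAE rank, ¹H MAE rank); exact-MAE
    ties keep input order and are reported as ties.
    """
    labels = list(maes)
    if len(labels) < 2:
        raise ValueError("ranking needs at least 2 candidates")

    def ranks(values: list[float]) -> list[int]:
        order = sorted(set(values))
        return [order.index(v) for v in values]

    c_vals = [maes[lab][0] for lab in labels]
    h_vals = [maes[lab][1] for lab in labels]
    rc = ranks(c_vals)
    rh = ranks(h_vals)
    keyed = sorted(range(len(labels)), key=lambda i: (rc[i], rh[i], i))
    ranking = tuple(labels[i] for i in keyed)
    # exact ties on both MAEs, in input order
    tie_groups: dict[tuple[float, float], list[str]] = {}
    for lab in labels:
        tie_groups.setdefault(maes[lab], []).append(lab)
    ties = tuple(tuple(g) for g in tie_groups.values() if len(g) > 1)
    best_c = labels[int(np.argmin(c_vals))]
    best_h = labels[int(np.argmin(h_vals))]
    scores = {
        lab: CandidateScore(
            label=lab,
            delta_delta={},
            mae_13c=maes[lab][0],
            mae_1h=maes[lab][1],
            n_13c=0,
            n_1h=0,
        )
        for lab in labels
    }
    return RankingResult(
        scores=scores,
        ranking=ranking,
        best=ranking[0],
        disagreement_flag=best_c != best_h,
        ties=ties,
    )


def rank_candidates(candidates, exp: ShiftTable) -> RankingResult:
    """Rank (label, calculated ShiftTable) candidates against experiment.

    MAEs are computed on sp²-excluded, equivalence-averaged tables.  The
    combined order is lexicographic on (¹³C MAE rank, ¹H MAE rank); a
    disagreement between the nuclei on the top candidate sets
    ``disagreement_flag``.
    """
    candidates = list(candidates)
    if len(candidates) < 2:
        raise ValueError("ranking needs at least 2 candidates")
    scores = {lab: score_candidate(lab, calc, exp) for lab, calc in candidates}
    maes = {lab: (s.mae_13c, s.mae_1h) for lab, s in scores.items()}
    skeleton = rank_from_maes(maes)
    return RankingResult(
        scores=scores,
        ranking=skeleton.ranking,
        best=skeleton.best,
        disagreement_flag=skeleton.disagreement_flag,
        ties=skeleton.ties,
    )
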