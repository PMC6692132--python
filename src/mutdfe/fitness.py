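"""Relative fitness from head-to-head competition colony counts.

A mutant is competed 1:1 against a neutrally marked reference strain;
initial and final aliquots are plated and colonies of each type counted.
Relative fitness per replicate is

    w = (f_final / f_initial) ** (1 / doublings)

where f is the ratio of mutant to reference frequency (equivalently of
counts) on a plate.  Plates with fewer than ``min_colonies`` colonies of
either strain are excluded, as are plates with any zero count.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CompetitionReplicate",
    "FitnessEstimate",
    "ReplicateExcluded",
    "replicate_fitness",
    "aggregate_fitness",
    "marker_control",
    "estimate_fitness_table",
    "DOUBLINGS_LOW_DILUTION",
    "DOUBLINGS_HIGH_DILUTION",
]

#: doublings implied by the two dilution regimes of the assay
DOUBLINGS_LOW_DILUTION = 6.7
DOUBLINGS_HIGH_DILUTION = 13.2

DEFAULT_MIN_COLONIES = 30


class ReplicateExcluded(ValueError):
    """Raised when a replicate fails the inclusion filter; carries the reason."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass(frozen=True)
class CompetitionReplicate:
    """Colony counts for one competition replicate (one initial, one final plate)."""

    mutation_id: str
    mutant_initial: int
    ref_initial: int
    mutant_final: int
    ref_final: int
    doublings: float = DOUBLINGS_LOW_DILUTION

    def __post_init__(self) -> None:
        for c in (self.mutant_initial, self.ref_initial,
                  self.mutant_final, self.ref_final):
            if c < 0:
                raise ValueError("colony counts must be >= 0")
        if self.doublings <= 0:
            raise ValueError("doublings must be positive")


def replicate_fitness(rep: CompetitionReplicate,
                      min_colonies: int = DEFAULT_MIN_COLONIES) -> float:
    """Relative fitness of one replicate, or :class:`ReplicateExcluded`.

    ``w = [(mf/rf) / (mi/ri)] ** (1/d)``.  The inclusion filter requires at
    least ``min_colonies`` colonies of *each* strain on *each* plate.
    """
    counts = (rep.mutant_initial, rep.ref_initial,
              rep.mutant_final, rep.ref_final)
    if any(c == 0 for c in counts):
        raise ReplicateExcluded("zero colony count")
    if min(counts) < min_colonies:
        raise ReplicateExcluded(
            f"fewer than {min_colonies} colonies of one strain")
    f_initial = rep.mutant_initial / rep.ref_initial
    f_final = rep.mutant_final / rep.ref_final
    return (f_final / f_initial) ** (1.0 / rep.doublings)


@dataclass(frozen=True)
class FitnessEstimate:
    """Per-mutation relative fitness with replicate-level provenance."""

    mutation_id: str
    w_mean: float
    sem: float              # NaN when only one replicate survives
    n_replicates: int
    replicate_w: tuple[float, ...]
    excluded: tuple[str, ...] = field(default_factory=tuple)

    @property
    def s(self) -> float:
        """Selection coefficient, w - 1."""
        return self.w_mean - 1.0


def aggregate_fitness(replicates: Iterable[CompetitionReplicate],
                      min_colonies: int = DEFAULT_MIN_COLONIES,
                      warn_few: int = 4) -> FitnessEstimate:
    """Mean and SEM of replicate fitness values for one mutation.

    Excluded replicates are logged on the estimate, never silently dropped;
    zero surviving replicates raises so the caller can flag the mutation as
    missing.
    """
    reps = list(replicates)
    if not reps:
        raise ValueError("no replicates supplied")
    ids = {r.mutation_id for r in reps}
    if len(ids) > 1:
        raise ValueError(f"replicates from multiple mutations: {sorted(ids)}")
    ws: list[float] = []
    excluded: list[str] = []
    for r in reps:
        try:
            ws.append(replicate_fitness(r, min_colonies=min_colonies))
        except ReplicateExcluded as e:
            excluded.append(e.reason)
    if not ws:
        raise ReplicateExcluded(
            f"{reps[0].mutation_id}: all {len(reps)} replicates excluded")
    if len(ws) < warn_few:
        warnings.warn(f"{reps[0].mutation_id}: only {len(ws)} surviving "
                      f"replicates (fewer than {warn_few})")
    arr = np.asarray(ws)
    sem = float(arr.std(ddof=1) / math.sqrt(len(ws))) if len(ws) > 1 else float("nan")
    return FitnessEstimate(
        mutation_id=reps[0].mutation_id,
        w_mean=float(arr.mean()), sem=sem, n_replicates=len(ws),
        replicate_w=tuple(ws), excluded=tuple(excluded))


def marker_control(control_replicates: Iterable[CompetitionReplicate],
                   min_colonies: int = DEFAULT_MIN_COLONIES) -> FitnessEstimate | None:
    """Fitness of the marked reference against the unmarked wild type.

    Shares the mutant code path.  An empty control set yields ``None`` with
    a warning (no correction can be applied).
    """
    reps = list(control_replicates)
    if not reps:
        warnings.warn("empty marker-control set; no correction applied")
        return None
    return aggregate_fitness(reps, min_colonies=min_colonies)


def _replicates_from_frame(df: pd.DataFrame) -> list[CompetitionReplicate]:
    return [CompetitionReplicate(
        mutation_id=str(r.mutation_id),
        mutant_initial=int(r.mutant_initial), ref_initial=int(r.ref_initial),
        mutant_final=int(r.mutant_final), ref_final=int(r.ref_final),
        doublings=float(r.doublings)) for r in df.itertuples()]


def estimate_fitness_table(counts: pd.DataFrame,
                           min_colonies: int = DEFAULT_MIN_COLONIES,
                           control_id: str | None = None,
                           marker_correct: bool = False) -> pd.DataFrame:
    """Per-mutation fitness table from a long replicate count table.

    ``counts`` needs columns mutation_id, mutant_initial, ref_initial,
    mutant_final, ref_final, doublings (and optionally ``class``, carried
    through).  Rows whose mutation_id equals ``control_id`` are treated as
    the marker control.  With ``marker_correct`` the mutant means are divided
    by the control mean (off by default).  Mutations whose replicates are all
    excluded appear with NaN fitness and the exclusion reasons.
    """
    required = {"mutation_id", "mutant_initial", "ref_initial",
                "mutant_final", "ref_final", "doublings"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")

    control_mean = 1.0
    control_est = None
    if control_id is not None:
        ctrl = counts[counts["mutation_id"].astype(str) == control_id]
        control_est = marker_control(_replicates_from_frame(ctrl),
                                     min_colonies=min_colonies)
        if control_est is not None and marker_correct:
            control_mean = control_est.w_mean

    rows = []
    classes = (counts.drop_duplicates("mutation_id")
               .set_index("mutation_id")["class"].astype(str).to_dict()
               if "class" in counts.columns else {})
    for mid, grp in counts.groupby("mutation_id", sort=True):
        mid = str(mid)
        if control_id is not None and mid == control_id:
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est = aggregate_fitness(_replicates_from_frame(grp),
                                        min_colonies=min_colonies)
            rows.append({"mutation_id": mid, "class": classes.get(mid, ""),
                         "w_mean": est.w_mean / control_mean,
                         "sem": est.sem / control_mean,
                         "n_replicates": est.n_replicates,
                         "n_excluded": len(est.excluded),
                         "exclusion_reasons": ";".join(est.excluded)})
        except ReplicateExcluded as e:
            rows.append({"mutation_id": mid, "class": classes.get(mid, ""),
                         "w_mean": float("nan"), "sem": float("nan"),
                         "n_replicates": 0, "n_excluded": len(grp),
                         "exclusion_reasons": e.reason})
    out = pd.DataFrame(rows)
    out.attrs["marker_control"] = (None if control_est is None else
                                   {"w_mean": control_est.w_mean,
                                    "sem": control_est.sem,
                                    "n": control_est.n_replicates,
                                    "corrected": marker_correct})
    return out
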