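"""Selection of AML-associated candidate CpGs from beta matrices.

A candidate CpG must be consistently extreme in healthy blood — control mean
beta below ``low_bound`` (unmethylated) or above ``high_bound`` (methylated)
— with low spread (control sample s.d. below ``sd_max``), and then show the
largest group difference Δβ = mean(AML) − mean(control).  The top ``top_k``
CpGs per direction form a :class:`CandidateSet`; candidate sets selected
independently on several control/AML study pairs are intersected to keep
only CpGs that replicate across cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .model import BetaMatrix, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "SelectionCriteria",
    "CandidateSet",
    "filter_invariant_cpgs",
    "rank_and_select",
    "intersect_candidates",
]


@dataclass(frozen=True)
class SelectionCriteria:
    """Thresholds for candidate selection.

    Defaults: control mean beta < 0.1 or > 0.9, control s.d. < 0.05,
    top 100 CpGs per direction.
    """

    low_bound: float = 0.1
    high_bound: float = 0.9
    sd_max: float = 0.05
    top_k: int = 100

    def __post_init__(self) -> None:
        if not 0 <= self.low_bound < self.high_bound <= 1:
            raise ValidationError(
                f"need 0 <= low_bound < high_bound <= 1, got "
                f"({self.low_bound}, {self.high_bound})"
            )
        if self.sd_max <= 0:
            raise ValidationError(f"sd_max must be > 0, got {self.sd_max}")
        if self.top_k < 1:
            raise ValidationError(f"top_k must be >= 1, got {self.top_k}")


@dataclass
class CandidateSet:
    """Ranked hyper-/hypomethylated candidates with their Δβ values.

    ``hyper`` is ordered by Δβ descending (most hypermethylated in AML
    first), ``hypo`` by \\|Δβ\\| descending; ``delta`` maps every listed CpG to
    mean(AML) − mean(control).
    """

    hyper: list[str] = field(default_factory=list)
    hypo: list[str] = field(default_factory=list)
    delta: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.hyper) & set(self.hypo)
        if overlap:
            raise ValidationError(f"CpGs in both hyper and hypo lists: {sorted(overlap)[:5]}")


def filter_invariant_cpgs(controls: BetaMatrix, criteria: SelectionCriteria | None = None) -> set[str]:
    """CpGs whose control mean beta is extreme and control s.d. is small.

    Uses the sample (n−1) standard deviation; missing betas are dropped
    pairwise.  CpGs with fewer than two non-missing control values cannot be
    assessed and are excluded (logged, not raised).
    """
    criteria = criteria or SelectionCriteria()
    arr = controls.values.to_numpy(dtype=float)
    n_obs = np.sum(~np.isnan(arr), axis=1)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(np.where(np.isnan(arr), np.nan, arr), axis=1)
        sd = np.full(arr.shape[0], np.nan)
        ok = n_obs >= 2
        sd[ok] = np.nanstd(arr[ok], axis=1, ddof=1)
    too_few = int(np.sum(~ok))
    if too_few:
        logger.warning("%d CpG(s) excluded: fewer than 2 non-missing control values", too_few)
    extreme = (mean < criteria.low_bound) | (mean > criteria.high_bound)
    stable = sd < criteria.sd_max
    keep = ok & extreme & stable
    return {cpg for cpg, k in zip(controls.cpg_ids, keep) if k}


def _group_deltas(matrix: BetaMatrix, cpgs: list[str]) -> dict[str, float]:
    sub = matrix.values.loc[cpgs]
    ctrl = sub[matrix.samples_in("control")].mean(axis=1, skipna=True)
    aml = sub[matrix.samples_in("aml")].mean(axis=1, skipna=True)
    return dict((aml - ctrl).items())


def rank_and_select(
    matrix: BetaMatrix,
    eligible: set[str],
    criteria: SelectionCriteria | None = None,
) -> CandidateSet:
    """Rank eligible CpGs by Δβ and keep the top ``top_k`` per direction.

    Ties in Δβ are broken lexicographically by CpG id for determinism.
    """
    criteria = criteria or SelectionCriteria()
    unknown = eligible - set(matrix.cpg_ids)
    if unknown:
        raise ValidationError(f"eligible CpGs not in matrix: {sorted(unknown)[:5]}")
    if not eligible:
        logger.warning("empty eligible set: returning empty candidate set")
        return CandidateSet()
    if not matrix.samples_in("control") or not matrix.samples_in("aml"):
        raise ValidationError("both control and aml groups must be present")
    cpgs = sorted(eligible)
    delta = _group_deltas(matrix, cpgs)
    hyper = sorted((c for c in cpgs if delta[c] > 0), key=lambda c: (-delta[c], c))
    hypo = sorted((c for c in cpgs if delta[c] < 0), key=lambda c: (delta[c], c))
    hyper = hyper[: criteria.top_k]
    hypo = hypo[: criteria.top_k]
    keep = set(hyper) | set(hypo)
    return CandidateSet(hyper=hyper, hypo=hypo, delta={c: float(delta[c]) for c in keep})


def intersect_candidates(sets: list[CandidateSet]) -> CandidateSet:
    """Intersect candidate lists across independently selected study pairs.

    A CpG survives only if present (same direction) in every set.  Survivors
    are ordered by the mean \\|Δβ\\| across sets, descending; ties broken by id.
    The operation is invariant to the order of its arguments.
    """
    if len(sets) < 2:
        raise ValidationError(f"need at least 2 candidate sets, got {len(sets)}")
    hyper = set(sets[0].hyper)
    hypo = set(sets[0].hypo)
    for s in sets[1:]:
        hyper &= set(s.hyper)
        hypo &= set(s.hypo)

    def mean_abs_delta(c: str) -> float:
        return float(np.mean([abs(s.delta[c]) for s in sets]))

    mean_delta = {c: float(np.mean([s.delta[c] for s in sets])) for c in hyper | hypo}
    return CandidateSet(
        hyper=sorted(hyper, key=lambda c: (-mean_abs_delta(c), c)),
        hypo=sorted(hypo, key=lambda c: (-mean_abs_delta(c), c)),
        delta=mean_delta,
    )
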