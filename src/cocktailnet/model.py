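"""Quantitative co-infection model for phage cocktails.

Effective virulence of virus p against host h inside cocktail C is its raw
infection strength modulated multiplicatively by every co-formulated
partner:

    v_eff(p, h | C) = clamp( v(p, h) * prod_{q in C, q != p} w(p, q), 0, 1 )

where w(p, q) is the directed interaction factor (the effect ON p OF q);
w = 1 is neutral, w < 1 antagonistic (w = 0 completely lethal to p's
activity), w > 1 synergistic.  Phages then act independently on each host
(noisy-OR), giving the predicted growth inhibition

    I(h | C) = 1 - prod_{p in C} (1 - v_eff(p, h | C)).

Both quantities are fractions in [0, 1] for arbitrary non-negative factors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .matrices import QPBIN, QPPIN, neutral_qppin

__all__ = [
    "Cocktail",
    "CocktailEvaluation",
    "effective_virulence",
    "host_inhibition",
    "evaluate_cocktail",
    "redundancy_excess",
    "ranking_key",
    "compare_cocktails",
]

OBJECTIVES = ("coverage_first", "virulence_first")
REDUNDANCY_MODES = ("ignore", "minimize_excess", "require_min")


@dataclass(frozen=True)
class Cocktail:
    """An ordered, duplicate-free subset of the network's viruses."""

    viruses: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "viruses", tuple(self.viruses))
        if len(set(self.viruses)) != len(self.viruses):
            raise ValueError(f"duplicate viruses in cocktail: {self.viruses}")

    @property
    def size(self) -> int:
        return len(self.viruses)

    def sorted_names(self) -> tuple[str, ...]:
        return tuple(sorted(self.viruses))

    def __contains__(self, virus: str) -> bool:
        return virus in self.viruses

    def __iter__(self):
        return iter(self.viruses)


@dataclass(frozen=True)
class CocktailEvaluation:
    """All quality criteria of one cocktail on one network."""

    viruses: tuple[str, ...]
    size: int
    per_host_inhibition: Mapping[str, float]
    per_host_redundancy: Mapping[str, int]
    coverage: int  # hosts with predicted inhibition above threshold
    total_inhibition: float  # sum of I(h|C) over hosts
    mean_redundancy: float  # mean lysing-phage count over covered hosts
    antagonism_burden: float  # sum over directed pairs of max(0, 1 - w)
    per_virus_contribution: Mapping[str, float]  # marginal drop in total inhibition


def _subset_arrays(
    cocktail: Cocktail, qpbin: QPBIN, qppin: QPPIN
) -> tuple[np.ndarray, np.ndarray]:
    idx = [qpbin.virus_index(p) for p in cocktail.viruses]
    widx = [qppin.virus_index(p) for p in cocktail.viruses]
    v = qpbin.values[idx, :]
    w = qppin.values[np.ix_(widx, widx)]
    return v, w


def _effective_matrix(v: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Per-(virus, host) effective virulence for the whole subset.

    The diagonal of w is 1 so the full row product already excludes self.
    """
    factors = w.prod(axis=1)
    return np.clip(v * factors[:, None], 0.0, 1.0)


def _inhibition(v_eff: np.ndarray) -> np.ndarray:
    return 1.0 - np.prod(1.0 - v_eff, axis=0) if v_eff.size else np.zeros(v_eff.shape[1])


def effective_virulence(
    virus: str, host: str, cocktail: Cocktail, qpbin: QPBIN, qppin: QPPIN | None = None
) -> float:
    """Effective virulence of one cocktail member against one host."""
    if virus not in cocktail:
        raise ValueError(f"virus {virus!r} is not a member of the cocktail")
    if qppin is None:
        qppin = neutral_qppin(qpbin.virus_names)
    v, w = _subset_arrays(cocktail, qpbin, qppin)
    v_eff = _effective_matrix(v, w)
    i = cocktail.viruses.index(virus)
    return float(v_eff[i, qpbin.host_index(host)])


def host_inhibition(
    host: str, cocktail: Cocktail, qpbin: QPBIN, qppin: QPPIN | None = None
) -> float:
    """Predicted growth inhibition of one host under independent phage action."""
    if qppin is None:
        qppin = neutral_qppin(qpbin.virus_names)
    if cocktail.size == 0:
        return 0.0
    v, w = _subset_arrays(cocktail, qpbin, qppin)
    v_eff = _effective_matrix(v, w)
    return float(_inhibition(v_eff)[qpbin.host_index(host)])


def _antagonism_burden(w: np.ndarray) -> float:
    # diagonal contributes max(0, 1 - 1) = 0, so the full sum is the pair sum
    return float(np.maximum(0.0, 1.0 - w).sum())


def evaluate_cocktail(
    cocktail: Cocktail, qpbin: QPBIN, qppin: QPPIN | None = None, tau: float = 0.0
) -> CocktailEvaluation:
    """Evaluate a cocktail on every quality criterion.

    ``per_virus_contribution[p]`` is total_inhibition(C) minus
    total_inhibition(C without p): the marginal loss if p were dropped.  It
    can be negative when p antagonises its partners.
    """
    if qppin is None:
        qppin = neutral_qppin(qpbin.virus_names)
    v, w = _subset_arrays(cocktail, qpbin, qppin)
    v_eff = _effective_matrix(v, w)
    inhibition = _inhibition(v_eff) if cocktail.size else np.zeros(qpbin.n_hosts)
    covered = inhibition > tau
    counts = (v_eff > tau).sum(axis=0) if cocktail.size else np.zeros(qpbin.n_hosts, int)
    total = float(inhibition.sum())

    contributions: dict[str, float] = {}
    for i, p in enumerate(cocktail.viruses):
        keep = [k for k in range(cocktail.size) if k != i]
        sub_eff = _effective_matrix(v[keep, :], w[np.ix_(keep, keep)])
        sub_total = float(_inhibition(sub_eff).sum()) if keep else 0.0
        contributions[p] = total - sub_total

    return CocktailEvaluation(
        viruses=cocktail.viruses,
        size=cocktail.size,
        per_host_inhibition={h: float(x) for h, x in zip(qpbin.host_names, inhibition)},
        per_host_redundancy={h: int(c) for h, c in zip(qpbin.host_names, counts)},
        coverage=int(covered.sum()),
        total_inhibition=total,
        mean_redundancy=float(counts[covered].mean()) if covered.any() else 0.0,
        antagonism_burden=_antagonism_burden(w),
        per_virus_contribution=contributions,
    )


def redundancy_excess(evaluation: CocktailEvaluation, target: int) -> int:
    """Total co-infection count above the per-host redundancy target."""
    return int(sum(max(0, c - target) for c in evaluation.per_host_redundancy.values()))


def ranking_key(
    evaluation: CocktailEvaluation,
    objective: str = "coverage_first",
    redundancy_mode: str = "minimize_excess",
    redundancy_target: int = 2,
) -> tuple:
    """Sort key under which *smaller is better*; total order over cocktails.

    ``coverage_first`` (antagonism-minimising, broad-host-range design):
    coverage desc, antagonism burden asc, total inhibition desc, size asc.
    ``virulence_first``: total inhibition desc, coverage desc, antagonism
    burden asc, size asc.  Under ``minimize_excess`` the co-infection excess
    over the redundancy target is a late ascending tie-break; the sorted
    virus-name tuple breaks any remaining tie deterministically.
    """
    if objective not in OBJECTIVES:
        raise ValueError(f"unknown objective {objective!r}")
    if redundancy_mode not in REDUNDANCY_MODES:
        raise ValueError(f"unknown redundancy mode {redundancy_mode!r}")
    excess = (
        redundancy_excess(evaluation, redundancy_target)
        if redundancy_mode == "minimize_excess"
        else 0
    )
    names = tuple(sorted(evaluation.viruses))
    if objective == "coverage_first":
        return (
            -evaluation.coverage,
            evaluation.antagonism_burden,
            -evaluation.total_inhibition,
            evaluation.size,
            excess,
            names,
        )
    return (
        -evaluation.total_inhibition,
        -evaluation.coverage,
        evaluation.antagonism_burden,
        evaluation.size,
        excess,
        names,
    )


def compare_cocktails(
    a: CocktailEvaluation,
    b: CocktailEvaluation,
    objective: str = "coverage_first",
    redundancy_mode: str = "minimize_excess",
    redundancy_target: int = 2,
) -> int:
    """-1 if a ranks above b, 1 if below, 0 only for identical cocktails."""
    ka = ranking_key(a, objective, redundancy_mode, redundancy_target)
    kb = ranking_key(b, objective, redundancy_mode, redundancy_target)
    return -1 if ka < kb else (1 if ka > kb else 0)


def meets_redundancy_requirement(
    evaluation: CocktailEvaluation,
    host_degrees: Mapping[str, int],
    target: int,
    tau: float = 0.0,
) -> bool:
    """require_min policy: every covered host that the full network could hit
    with ``target`` phages (d(h) >= target) must actually be hit that often."""
    for h, inhib in evaluation.per_host_inhibition.items():
        if inhib > tau and host_degrees.get(h, 0) >= target:
            if evaluation.per_host_redundancy[h] < target:
                return False
    return True
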