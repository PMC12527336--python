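"""Cocktail designers: exhaustive enumeration and the network-metrics greedy.

Exhaustive search enumerates every virus subset up to the size cap and is
optimal under the configured ordering; it is meant for small collections.
The network-metrics heuristic greedily adds the phage with the largest
resistance-weighted inhibition gain

    gain(p | S) = sum_h (1 / d(h)) * [ I(h | S + p) - I(h | S) ]

where d(h) is the number of phages in the (pruned) network able to lyse
host h: hosts killable by few phages dominate selection, the standard
rare-element prioritisation of greedy set cover.  Both designers are fully
deterministic; ties fall back to lexicographic virus names.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .matrices import QPBIN, QPPIN, neutral_qppin
from .metrics import redundancy_profile
from .model import (
    OBJECTIVES,
    REDUNDANCY_MODES,
    Cocktail,
    CocktailEvaluation,
    evaluate_cocktail,
    meets_redundancy_requirement,
    ranking_key,
)

__all__ = [
    "DesignConfig",
    "DesignResult",
    "BudgetExceededError",
    "prune_network",
    "exhaustive_search",
    "greedy_search",
    "design_cocktails",
    "design_cocktail_series",
]

ALGORITHMS = ("exhaustive", "network_metrics")


class BudgetExceededError(RuntimeError):
    """The exhaustive subset count exceeds the enumeration budget."""


@dataclass(frozen=True)
class DesignConfig:
    """All knobs of a design run.

    ``max_size`` caps cocktails at 12 phages by default (adjustable); it is
    a hard cap, not a target — smaller winning cocktails are preferred by
    the size tie-break.  ``redundancy_target`` defaults to 2 (at least two
    phages per host has been proposed to enhance efficacy).  ``seed`` only
    affects synthetic input generation; the designers are deterministic.
    """

    max_size: int = 12
    algorithm: str = "exhaustive"
    objective: str = "coverage_first"
    tau: float = 0.0
    redundancy_mode: str = "minimize_excess"
    redundancy_target: int = 2
    n_cocktails: int = 1
    enumeration_budget: int = 5_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_size < 1:
            raise ValueError("max_size must be at least 1")
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.objective not in OBJECTIVES:
            raise ValueError(f"unknown objective {self.objective!r}")
        if not 0.0 <= self.tau < 1.0:
            raise ValueError("tau must lie in [0, 1)")
        if self.redundancy_mode not in REDUNDANCY_MODES:
            raise ValueError(f"unknown redundancy mode {self.redundancy_mode!r}")
        if self.redundancy_target < 1:
            raise ValueError("redundancy_target must be at least 1")
        if self.n_cocktails < 1:
            raise ValueError("n_cocktails must be at least 1")
        if self.enumeration_budget < 1:
            raise ValueError("enumeration_budget must be positive")


@dataclass
class DesignResult:
    """Best cocktail per size plus the overall winner and bookkeeping."""

    best_per_size: dict[int, tuple[Cocktail, CocktailEvaluation]]
    overall_best: tuple[Cocktail, CocktailEvaluation] | None
    uncoverable_hosts: list[str] = field(default_factory=list)
    removed_viruses: list[str] = field(default_factory=list)
    subsets_examined: int = 0
    algorithm: str = "exhaustive"
    objective: str = "coverage_first"


def prune_network(qpbin: QPBIN, tau: float = 0.0) -> tuple[QPBIN, list[str], list[str]]:
    """Drop viruses with empty host range; flag hosts no phage can lyse.

    Uncoverable hosts stay in the matrix (they contribute zero inhibition)
    but are reported so coverage denominators can exclude them.
    """
    infected = qpbin.values > tau
    keep = [v for v, row in zip(qpbin.virus_names, infected) if row.any()]
    removed = [v for v in qpbin.virus_names if v not in set(keep)]
    uncoverable = [h for h, col in zip(qpbin.host_names, infected.T) if not col.any()]
    reduced = qpbin.subset(keep) if removed else qpbin
    return reduced, removed, uncoverable


def _empty_result(qpbin: QPBIN, qppin: QPPIN, config: DesignConfig) -> DesignResult:
    empty = Cocktail(())
    return DesignResult(
        best_per_size={},
        overall_best=(empty, evaluate_cocktail(empty, qpbin, qppin, config.tau)),
        algorithm=config.algorithm,
        objective=config.objective,
    )


def _pick_overall(
    per_size: dict[int, tuple[Cocktail, CocktailEvaluation]],
    config: DesignConfig,
) -> tuple[Cocktail, CocktailEvaluation] | None:
    best = None
    best_key = None
    for size in sorted(per_size):
        cocktail, ev = per_size[size]
        key = ranking_key(ev, config.objective, config.redundancy_mode, config.redundancy_target)
        if best_key is None or key < best_key:
            best, best_key = (cocktail, ev), key
    return best


def exhaustive_search(
    qpbin: QPBIN, qppin: QPPIN | None = None, config: DesignConfig | None = None
) -> DesignResult:
    """Enumerate every cocktail of size 1..max_size; optimal and deterministic.

    Raises :class:`BudgetExceededError` before enumerating if the subset
    count exceeds ``config.enumeration_budget``.
    """
    config = config or DesignConfig()
    if qppin is None:
        qppin = neutral_qppin(qpbin.virus_names)
    pruned, removed, uncoverable = prune_network(qpbin, config.tau)
    if pruned.n_viruses == 0:
        result = _empty_result(qpbin, qppin, config)
        result.removed_viruses = removed
        result.uncoverable_hosts = uncoverable
        return result

    n = pruned.n_viruses
    kmax = min(config.max_size, n)
    total = sum(math.comb(n, k) for k in range(1, kmax + 1))
    if total > config.enumeration_budget:
        raise BudgetExceededError(
            f"{total} subsets exceed the enumeration budget of "
            f"{config.enumeration_budget}; use the network_metrics heuristic "
            f"or a smaller max_size"
        )

    # Enumerate over lexicographically sorted virus names so that, with a
    # stable per-chunk sort, the first subset attaining the best numeric key
    # is also the lexicographically smallest — the required tie-break.
    order = sorted(range(n), key=lambda i: pruned.virus_names[i])
    sorted_names = [pruned.virus_names[i] for i in order]
    V = pruned.values[order, :]
    widx = [qppin.virus_index(v) for v in sorted_names]
    W = qppin.values[np.ix_(widx, widx)]

    host_degrees = redundancy_profile(pruned, pruned.virus_names, config.tau)
    minimize = config.redundancy_mode == "minimize_excess"
    require = config.redundancy_mode == "require_min"
    r_star = config.redundancy_target
    deg = np.array([host_degrees[h] for h in pruned.host_names])

    per_size: dict[int, tuple[Cocktail, CocktailEvaluation]] = {}
    examined = 0
    chunk_size = 50_000
    for k in range(1, kmax + 1):
        best_combo: tuple[int, ...] | None = None
        best_key: tuple | None = None
        combos_iter = itertools.combinations(range(n), k)
        while True:
            chunk = list(itertools.islice(combos_iter, chunk_size))
            if not chunk:
                break
            examined += len(chunk)
            S = np.array(chunk, dtype=np.intp)  # (m, k)
            Wsub = W[S[:, :, None], S[:, None, :]]  # (m, k, k)
            factors = Wsub.prod(axis=2)  # (m, k); diag 1 excludes self
            v_eff = np.clip(V[S, :] * factors[:, :, None], 0.0, 1.0)  # (m, k, H)
            inhibition = 1.0 - np.prod(1.0 - v_eff, axis=1)  # (m, H)
            covered = inhibition > config.tau
            coverage = covered.sum(axis=1)
            total_inh = inhibition.sum(axis=1)
            burden = np.maximum(0.0, 1.0 - Wsub).sum(axis=(1, 2))
            counts = (v_eff > config.tau).sum(axis=1)  # (m, H)

            if config.objective == "coverage_first":
                keys = [-coverage, burden, -total_inh]
            else:
                keys = [-total_inh, -coverage, burden]
            if minimize:
                keys.append(np.maximum(0, counts - r_star).sum(axis=1))
            feasible = np.ones(len(chunk), dtype=bool)
            if require:
                relevant = covered & (deg[None, :] >= r_star)
                feasible = np.where(relevant, counts >= r_star, True).all(axis=1)
                if not feasible.any():
                    continue
            key_arr = np.stack(keys, axis=1)
            if require:
                cand = np.flatnonzero(feasible)
            else:
                cand = np.arange(len(chunk))
            sub = key_arr[cand]
            # lexsort: last key is primary, so reverse the column order
            ordering = np.lexsort(tuple(sub[:, j] for j in range(sub.shape[1] - 1, -1, -1)))
            top = cand[ordering[0]]
            key = tuple(key_arr[top])
            if best_key is None or key < best_key:
                best_key = key
                best_combo = chunk[top]
        if best_combo is not None:
            cocktail = Cocktail(tuple(sorted_names[i] for i in best_combo))
            per_size[k] = (cocktail, evaluate_cocktail(cocktail, qpbin, qppin, config.tau))

    return DesignResult(
        best_per_size=per_size,
        overall_best=_pick_overall(per_size, config),
        uncoverable_hosts=uncoverable,
        removed_viruses=removed,
        subsets_examined=examined,
        algorithm="exhaustive",
        objective=config.objective,
    )


def greedy_search(
    qpbin: QPBIN, qppin: QPPIN | None = None, config: DesignConfig | None = None
) -> DesignResult:
    """Network-metrics heuristic: iterative resistance-weighted gain maximisation.

    Stops at the size cap or when no candidate yields a positive gain;
    ``best_per_size`` holds the greedy prefixes.
    """
    config = config or DesignConfig()
    if qppin is None:
        qppin = neutral_qppin(qpbin.virus_names)
    pruned, removed, uncoverable = prune_network(qpbin, config.tau)
    if pruned.n_viruses == 0:
        result = _empty_result(qpbin, qppin, config)
        result.removed_viruses = removed
        result.uncoverable_hosts = uncoverable
        result.algorithm = "network_metrics"
        return result

    host_degrees = redundancy_profile(pruned, pruned.virus_names, config.tau)
    weights = np.array(
        [1.0 / host_degrees[h] if host_degrees[h] > 0 else 0.0 for h in pruned.host_names]
    )
    candidates = sorted(pruned.virus_names)
    widx = {v: qppin.virus_index(v) for v in qpbin.virus_names}
    vidx = {v: pruned.virus_index(v) for v in pruned.virus_names}

    def weighted_inhibition(subset: list[str]) -> tuple[float, np.ndarray]:
        if not subset:
            return 0.0, np.zeros(pruned.n_hosts)
        rows = [vidx[p] for p in subset]
        cols = [widx[p] for p in subset]
        w = qppin.values[np.ix_(cols, cols)]
        v_eff = np.clip(pruned.values[rows, :] * w.prod(axis=1)[:, None], 0.0, 1.0)
        inhibition = 1.0 - np.prod(1.0 - v_eff, axis=0)
        return float((weights * inhibition).sum()), inhibition

    selection: list[str] = []
    current_score, _ = weighted_inhibition(selection)
    examined = 0
    kmax = min(config.max_size, pruned.n_viruses)
    while len(selection) < kmax:
        best_gain = 0.0
        best_virus: str | None = None
        for p in candidates:
            if p in selection:
                continue
            examined += 1
            score, _ = weighted_inhibition(selection + [p])
            gain = score - current_score
            if gain > best_gain:  # strict: earlier (lexicographic) name wins ties
                best_gain = gain
                best_virus = p
        if best_virus is None:
            break
        selection.append(best_virus)
        current_score, _ = weighted_inhibition(selection)

    per_size = {}
    for k in range(1, len(selection) + 1):
        cocktail = Cocktail(tuple(selection[:k]))
        per_size[k] = (cocktail, evaluate_cocktail(cocktail, qpbin, qppin, config.tau))

    if config.redundancy_mode == "require_min":
        feasible = {
            k: pair
            for k, pair in per_size.items()
            if meets_redundancy_requirement(
                pair[1], host_degrees, config.redundancy_target, config.tau
            )
        }
        overall = _pick_overall(feasible, config)
    else:
        overall = _pick_overall(per_size, config)
    if overall is None and not per_size:
        empty = Cocktail(())
        overall = (empty, evaluate_cocktail(empty, qpbin, qppin, config.tau))

    return DesignResult(
        best_per_size=per_size,
        overall_best=overall,
        uncoverable_hosts=uncoverable,
        removed_viruses=removed,
        subsets_examined=examined,
        algorithm="network_metrics",
        objective=config.objective,
    )


def design_cocktails(
    qpbin: QPBIN, qppin: QPPIN | None = None, config: DesignConfig | None = None
) -> DesignResult:
    """Dispatch to the designer named in ``config.algorithm``."""
    config = config or DesignConfig()
    if config.algorithm == "exhaustive":
        return exhaustive_search(qpbin, qppin, config)
    return greedy_search(qpbin, qppin, config)


def design_cocktail_series(
    qpbin: QPBIN, qppin: QPPIN | None = None, config: DesignConfig | None = None
) -> list[DesignResult]:
    """Design ``n_cocktails`` phage-disjoint cocktails for rotation therapy.

    Each subsequent design excludes every virus already used; the series
    stops early (with a warning) once no remaining virus covers any host.
    """
    config = config or DesignConfig()
    if qppin is None:
        qppin = neutral_qppin(qpbin.virus_names)
    single = replace(config, n_cocktails=1)
    results: list[DesignResult] = []
    used: set[str] = set()
    for i in range(config.n_cocktails):
        remaining = [v for v in qpbin.virus_names if v not in used]
        if remaining:
            sub_qpbin = qpbin.subset(remaining)
            sub_qppin = qppin.subset(remaining)
            result = design_cocktails(sub_qpbin, sub_qppin, single)
        else:
            result = None
        if (
            result is None
            or result.overall_best is None
            or result.overall_best[1].coverage == 0
        ):
            warnings.warn(
                f"cocktail series exhausted after {len(results)} of "
                f"{config.n_cocktails} cocktails: no remaining coverage",
                stacklevel=2,
            )
            break
        results.append(result)
        used.update(result.overall_best[0].viruses)
    return results
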