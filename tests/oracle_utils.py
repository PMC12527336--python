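"""Independent brute-force cocktail evaluator and maximizer.

Pure-python re-statement of the co-infection model and ranking, kept free
of any code from the package's search module so it can serve as an oracle:
plain loops, dict arithmetic, and a running maximum over an explicit
re-enumeration of all subsets.
"""

import itertools


def oracle_metrics(subset, qpbin, qppin, tau=0.0, r_star=2):
    """Coverage, burden, total inhibition and redundancy excess by plain loops."""
    per_host = {}
    counts = {}
    for h in qpbin.host_names:
        survival = 1.0
        cnt = 0
        for p in subset:
            f = 1.0
            for q in subset:
                if q != p:
                    f *= qppin.factor(p, q)
            v_eff = min(1.0, max(0.0, qpbin.value(p, h) * f))
            survival *= 1.0 - v_eff
            if v_eff > tau:
                cnt += 1
        per_host[h] = 1.0 - survival
        counts[h] = cnt
    coverage = sum(1 for x in per_host.values() if x > tau)
    total = sum(per_host.values())
    burden = 0.0
    for p in subset:
        for q in subset:
            if p != q:
                burden += max(0.0, 1.0 - qppin.factor(p, q))
    excess = sum(max(0, c - r_star) for c in counts.values())
    return {
        "coverage": coverage,
        "total": total,
        "burden": burden,
        "excess": excess,
        "per_host": per_host,
        "counts": counts,
    }


def oracle_key(subset, metrics, objective, redundancy_mode="minimize_excess"):
    names = tuple(sorted(subset))
    excess = metrics["excess"] if redundancy_mode == "minimize_excess" else 0
    if objective == "coverage_first":
        return (
            -metrics["coverage"],
            metrics["burden"],
            -metrics["total"],
            len(subset),
            excess,
            names,
        )
    return (
        -metrics["total"],
        -metrics["coverage"],
        metrics["burden"],
        len(subset),
        excess,
        names,
    )


def brute_force_best(
    qpbin,
    qppin,
    max_size,
    objective="coverage_first",
    redundancy_mode="minimize_excess",
    r_star=2,
    tau=0.0,
):
    """Running maximum over an explicit enumeration of all non-empty subsets."""
    best_key = None
    best_subset = None
    kmax = min(max_size, len(qpbin.virus_names))
    for k in range(1, kmax + 1):
        for subset in itertools.combinations(qpbin.virus_names, k):
            m = oracle_metrics(subset, qpbin, qppin, tau, r_star)
            key = oracle_key(subset, m, objective, redundancy_mode)
            if best_key is None or key < best_key:
                best_key = key
                best_subset = subset
    return tuple(sorted(best_subset)), best_key


def brute_force_best_per_size(
    qpbin, qppin, max_size, objective="coverage_first",
    redundancy_mode="minimize_excess", r_star=2, tau=0.0,
):
    out = {}
    kmax = min(max_size, len(qpbin.virus_names))
    for k in range(1, kmax + 1):
        best_key = None
        best_subset = None
        for subset in itertools.combinations(qpbin.virus_names, k):
            m = oracle_metrics(subset, qpbin, qppin, tau, r_star)
            key = oracle_key(subset, m, objective, redundancy_mode)
            if best_key is None or key < best_key:
                best_key = key
                best_subset = subset
        out[k] = (tuple(sorted(best_subset)), best_key)
    return out
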