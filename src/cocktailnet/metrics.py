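"""Descriptive statistics of phage-bacteria infection networks.

Matrix *fill* (fraction of positive cells), its *binary entropy* — a proxy
for the combinatorial complexity of cocktail design: both nearly empty and
nearly saturated matrices leave few meaningful choices, while half-filled
ones maximise them — edge *density* (edges per node in the bipartite graph),
per-phage host range and virulence, and per-host resistance/redundancy
profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .matrices import QPBIN

__all__ = [
    "PhageStats",
    "HostStats",
    "NetworkSummary",
    "binary_entropy",
    "summarize_network",
    "redundancy_profile",
    "summary_tables",
]


@dataclass(frozen=True)
class PhageStats:
    virus: str
    host_range: float  # fraction of hosts infected, in [0, 1]
    mean_virulence: float  # mean infection strength over all hosts
    mean_virulence_over_infected: float  # mean over infected hosts only


@dataclass(frozen=True)
class HostStats:
    host: str
    resistance_count: int  # d(h): number of phages that lyse the host


@dataclass(frozen=True)
class NetworkSummary:
    fill: float
    entropy_bits: float
    density: float
    per_phage: tuple[PhageStats, ...]
    per_host: tuple[HostStats, ...]

    @property
    def n_edges(self) -> int:
        return sum(h.resistance_count for h in self.per_host)


def binary_entropy(fill: float) -> float:
    """Binary entropy H(f) = -f log2 f - (1-f) log2(1-f), in bits.

    H(0) = H(1) = 0 by the usual 0 log 0 = 0 convention; the maximum is
    1 bit at f = 0.5.
    """
    f = float(fill)
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"fill must lie in [0, 1], got {f}")
    if f == 0.0 or f == 1.0:
        return 0.0
    return float(-(f * np.log2(f) + (1.0 - f) * np.log2(1.0 - f)))


def summarize_network(qpbin: QPBIN, tau: float = 0.0) -> NetworkSummary:
    """Compute fill, entropy, density and per-phage / per-host profiles.

    A cell counts as an infection (edge) when its value exceeds the
    threshold ``tau``; the default 0 counts any positive value.
    """
    if not 0.0 <= tau < 1.0:
        raise ValueError(f"infection threshold must lie in [0, 1), got {tau}")
    infected = qpbin.values > tau
    n_edges = int(infected.sum())
    n_cells = qpbin.values.size
    fill = n_edges / n_cells if n_cells else 0.0
    density = n_edges / (qpbin.n_viruses + qpbin.n_hosts)

    per_phage = []
    for i, virus in enumerate(qpbin.virus_names):
        row = qpbin.values[i]
        mask = infected[i]
        k = int(mask.sum())
        per_phage.append(
            PhageStats(
                virus=virus,
                host_range=k / qpbin.n_hosts,
                mean_virulence=float(row.mean()),
                mean_virulence_over_infected=float(row[mask].mean()) if k else 0.0,
            )
        )
    per_host = [
        HostStats(host=h, resistance_count=int(infected[:, j].sum()))
        for j, h in enumerate(qpbin.host_names)
    ]
    return NetworkSummary(
        fill=fill,
        entropy_bits=binary_entropy(fill),
        density=density,
        per_phage=tuple(per_phage),
        per_host=tuple(per_host),
    )


def redundancy_profile(qpbin: QPBIN, viruses: Sequence[str], tau: float = 0.0) -> dict[str, int]:
    """Per-host count of subset viruses whose infection strength exceeds tau."""
    idx = [qpbin.virus_index(v) for v in viruses]
    counts = (qpbin.values[idx, :] > tau).sum(axis=0) if idx else np.zeros(qpbin.n_hosts, int)
    return {h: int(c) for h, c in zip(qpbin.host_names, counts)}


def summary_tables(summary: NetworkSummary) -> dict[str, pd.DataFrame]:
    """Render a summary as tidy per-phage and per-host tables (for TSV)."""
    phage = pd.DataFrame(
        [
            (p.virus, p.host_range, p.mean_virulence, p.mean_virulence_over_infected)
            for p in summary.per_phage
        ],
        columns=["virus", "host_range", "mean_virulence", "mean_virulence_over_infected"],
    )
    host = pd.DataFrame(
        [(h.host, h.resistance_count) for h in summary.per_host],
        columns=["host", "lysing_phages"],
    )
    return {"phages": phage, "hosts": host}
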