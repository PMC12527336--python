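"""Seeded synthetic infection/interaction networks and the worked example.

The generators emulate the plain-text matrices the designers consume: a
virus x host infection matrix with a target fill of uniformly virulent
occupied cells, and a square interaction matrix in which a chosen fraction
of virus pairs is antagonistic or synergistic.  All randomness flows through
``numpy.random.default_rng(seed)`` (PCG64), so matrices are bit-reproducible
across runs and platforms.

:func:`worked_example_fixture` builds a small 8-virus x 5-host network whose
design outcome is fully hand-checkable: quantitative search should pick
phages 1, 4 and 5 (avoiding the antagonised phage 3 and preferring the more
virulent phage 1 over phage 2), whereas a purely binary view collapses to a
two-phage cover built around phage 3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrices import QPBIN, QPPIN

__all__ = ["GeneratorSpec", "random_qpbin", "random_qppin", "worked_example_fixture"]


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the synthetic-network generator.

    Defaults emulate a mid-fill empirical infection network (fill 0.3 is in
    the range where cocktail design is combinatorially hardest) with
    antagonism somewhat more frequent than synergy, as reported for phage
    pairs in cocktail studies.
    """

    n_viruses: int = 10
    n_hosts: int = 8
    target_fill: float = 0.3
    p_antagonism: float = 0.15
    p_synergy: float = 0.05
    antagonism_range: tuple[float, float] = (0.1, 0.9)
    synergy_range: tuple[float, float] = (1.1, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_viruses < 1 or self.n_hosts < 1:
            raise ValueError("network must have at least one virus and one host")
        if not 0.0 <= self.target_fill <= 1.0:
            raise ValueError("target_fill must lie in [0, 1]")
        if self.p_antagonism < 0 or self.p_synergy < 0 or self.p_antagonism + self.p_synergy > 1:
            raise ValueError("interaction probabilities must be non-negative and sum to <= 1")
        lo, hi = self.antagonism_range
        if not 0.0 < lo <= hi < 1.0:
            raise ValueError("antagonism_range must lie within (0, 1)")
        lo, hi = self.synergy_range
        if not 1.0 < lo <= hi <= 2.0:
            raise ValueError("synergy_range must lie within (1, 2]")


def _names(prefix: str, n: int) -> list[str]:
    width = len(str(n))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def random_qpbin(spec: GeneratorSpec, allow_empty_lines: bool = False) -> QPBIN:
    """Random infection matrix with the spec's fill in expectation.

    Occupied cells are Bernoulli(target_fill) with virulence uniform on
    (0, 1].  By default all-zero virus rows and host columns are resampled
    (a phage infecting nothing, or an invulnerable host, would be pruned
    anyway); pass ``allow_empty_lines=True`` to keep them, e.g. to exercise
    network pruning.
    """
    rng = np.random.default_rng(spec.seed)
    shape = (spec.n_viruses, spec.n_hosts)

    def draw() -> np.ndarray:
        occupied = rng.random(shape) < spec.target_fill
        # uniform on (0, 1]: 1 - U[0, 1)
        return np.where(occupied, 1.0 - rng.random(shape), 0.0)

    values = draw()
    if not allow_empty_lines and 0.0 < spec.target_fill:
        for _ in range(1000):
            if values.any(axis=1).all() and values.any(axis=0).all():
                break
            values = draw()
    return QPBIN(_names("virus", spec.n_viruses), _names("host", spec.n_hosts), values)


def random_qppin(spec: GeneratorSpec, virus_names: list[str] | None = None) -> QPPIN:
    """Random interaction matrix: unordered virus pairs are antagonistic,
    synergistic or neutral per the spec's probabilities (symmetric values)."""
    rng = np.random.default_rng(spec.seed + 1)
    names = virus_names if virus_names is not None else _names("virus", spec.n_viruses)
    n = len(names)
    values = np.ones((n, n))
    a_lo, a_hi = spec.antagonism_range
    s_lo, s_hi = spec.synergy_range
    for i in range(n):
        for j in range(i + 1, n):
            u = rng.random()
            if u < spec.p_antagonism:
                w = rng.uniform(a_lo, a_hi)
            elif u < spec.p_antagonism + spec.p_synergy:
                w = rng.uniform(s_lo, s_hi)
            else:
                continue
            values[i, j] = values[j, i] = w
    return QPPIN(list(names), values)


def worked_example_fixture() -> tuple[QPBIN, QPPIN]:
    """The hand-checkable 8-phage x 5-host example network.

    Phages 1 and 2 share the binary host range {b1, b2} but phage 1 is more
    virulent; phages 6-8 are interchangeable weak b2 specialists; phage 3 is
    a broad generalist antagonised by (and antagonising) every other phage
    with factor 0.2; phages 4 and 5 are virulent specialists that jointly
    replace phage 3.
    """
    virus_names = [f"phage{i}" for i in range(1, 9)]
    host_names = [f"b{j}" for j in range(1, 6)]
    values = np.array(
        [
            [0.9, 0.8, 0.0, 0.0, 0.0],  # phage1
            [0.6, 0.5, 0.0, 0.0, 0.0],  # phage2
            [0.0, 0.0, 0.5, 0.5, 0.5],  # phage3
            [0.0, 0.0, 0.9, 0.9, 0.0],  # phage4
            [0.0, 0.0, 0.0, 0.0, 0.9],  # phage5
            [0.0, 0.4, 0.0, 0.0, 0.0],  # phage6
            [0.0, 0.4, 0.0, 0.0, 0.0],  # phage7
            [0.0, 0.4, 0.0, 0.0, 0.0],  # phage8
        ]
    )
    qpbin = QPBIN(virus_names, host_names, values)
    w = np.ones((8, 8))
    k = virus_names.index("phage3")
    w[k, :] = 0.2
    w[:, k] = 0.2
    w[k, k] = 1.0
    qppin = QPPIN(virus_names, w)
    return qpbin, qppin
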