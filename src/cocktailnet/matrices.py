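"""Plain-text interaction-matrix I/O, validation and network export.

Two matrix kinds are handled:

* **QPBIN** (quantitative phage-bacteria infection network): one row per
  virus, one column per bacterial host, cells are infection strengths on a
  0 (no lysis) to 1 (complete lysis) scale.
* **QPPIN** (quantitative phage-phage interaction network): a square matrix
  over the same viruses whose cell w(p, q) is the multiplicative factor
  applied to virus p's virulence when virus q is co-formulated.  1 is
  neutral/unknown, values below 1 are antagonistic (0 = complete lethality),
  values above 1 are synergistic.

The on-disk dialect is whitespace-separated text: the first row lists the
column names (hosts for a QPBIN, viruses for a QPPIN), optionally preceded
by a corner token; every following row starts with its row name.  Reading
applies a small set of silent corrections (clamping, neutral fill), each of
which is recorded in a :class:`CorrectionLog`.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "MatrixFormatError",
    "Correction",
    "CorrectionLog",
    "QPBIN",
    "QPPIN",
    "read_qpbin",
    "read_qppin",
    "neutral_qppin",
    "write_matrix",
    "export_network",
]


class MatrixFormatError(ValueError):
    """Raised when an input matrix violates a hard structural rule."""


@dataclass(frozen=True)
class Correction:
    """A single silent mutation applied to an input cell."""

    location: str
    original: str
    corrected: float | str
    rule: str


@dataclass
class CorrectionLog:
    """Ordered record of every correction applied while reading a matrix."""

    entries: list[Correction] = field(default_factory=list)

    def add(self, location: str, original: str, corrected: float | str, rule: str) -> None:
        self.entries.append(Correction(location, original, corrected, rule))

    def extend(self, other: "CorrectionLog") -> None:
        self.entries.extend(other.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[Correction]:
        return iter(self.entries)

    def as_rows(self) -> list[tuple[str, str, str, str]]:
        return [(e.location, e.original, str(e.corrected), e.rule) for e in self.entries]


def _check_names(names: Sequence[str], axis: str) -> None:
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if list(names).count(n) > 1})
        raise MatrixFormatError(f"duplicate {axis} names: {', '.join(dupes)}")
    for n in names:
        if not n or any(c.isspace() for c in n):
            raise MatrixFormatError(f"invalid {axis} name {n!r}")


@dataclass
class QPBIN:
    """Virus x host matrix of infection strengths in [0, 1]."""

    virus_names: list[str]
    host_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.virus_names = list(self.virus_names)
        self.host_names = list(self.host_names)
        self.values = np.asarray(self.values, dtype=float)
        _check_names(self.virus_names, "virus")
        _check_names(self.host_names, "host")
        if self.values.shape != (len(self.virus_names), len(self.host_names)):
            raise MatrixFormatError(
                f"value shape {self.values.shape} does not match "
                f"{len(self.virus_names)} viruses x {len(self.host_names)} hosts"
            )
        if not np.all(np.isfinite(self.values)):
            raise MatrixFormatError("non-finite infection values")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise MatrixFormatError("infection values must lie in [0, 1]")

    @property
    def n_viruses(self) -> int:
        return len(self.virus_names)

    @property
    def n_hosts(self) -> int:
        return len(self.host_names)

    def virus_index(self, name: str) -> int:
        try:
            return self.virus_names.index(name)
        except ValueError:
            raise KeyError(f"unknown virus {name!r}") from None

    def host_index(self, name: str) -> int:
        try:
            return self.host_names.index(name)
        except ValueError:
            raise KeyError(f"unknown host {name!r}") from None

    def value(self, virus: str, host: str) -> float:
        return float(self.values[self.virus_index(virus), self.host_index(host)])

    def subset(self, viruses: Sequence[str]) -> "QPBIN":
        idx = [self.virus_index(v) for v in viruses]
        return QPBIN(list(viruses), self.host_names, self.values[idx, :])

    def binarized(self, tau: float = 0.0) -> "QPBIN":
        """0/1 copy: 1 where infection strength exceeds ``tau``."""
        return QPBIN(self.virus_names, self.host_names, (self.values > tau).astype(float))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.virus_names, columns=self.host_names)


@dataclass
class QPPIN:
    """Square virus x virus matrix of multiplicative interaction factors.

    Read as directed: ``values[p, q]`` is the effect ON virus p OF virus q.
    The diagonal is identically 1 and factors are non-negative; synergy
    above 1 is allowed (no upper bound).
    """

    virus_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.virus_names = list(self.virus_names)
        self.values = np.asarray(self.values, dtype=float)
        _check_names(self.virus_names, "virus")
        n = len(self.virus_names)
        if self.values.shape != (n, n):
            raise MatrixFormatError(f"interaction matrix must be {n}x{n}, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise MatrixFormatError("non-finite interaction values")
        if self.values.size and self.values.min() < 0:
            raise MatrixFormatError("negative interaction values are undefined")
        if n and not np.allclose(np.diag(self.values), 1.0):
            raise MatrixFormatError("interaction matrix diagonal must be 1")

    @property
    def n_viruses(self) -> int:
        return len(self.virus_names)

    def virus_index(self, name: str) -> int:
        try:
            return self.virus_names.index(name)
        except ValueError:
            raise KeyError(f"unknown virus {name!r}") from None

    def factor(self, on: str, of: str) -> float:
        return float(self.values[self.virus_index(on), self.virus_index(of)])

    def is_neutral(self) -> bool:
        return bool(np.all(self.values == 1.0))

    def subset(self, viruses: Sequence[str]) -> "QPPIN":
        idx = [self.virus_index(v) for v in viruses]
        return QPPIN(list(viruses), self.values[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.virus_names, columns=self.virus_names)


def neutral_qppin(virus_names: Sequence[str]) -> QPPIN:
    """All-neutral (all-ones) interaction matrix: the no-information default."""
    n = len(virus_names)
    return QPPIN(list(virus_names), np.ones((n, n)))


# ---------------------------------------------------------------------------
# parsing


def _tokenize(text: str) -> list[tuple[int, list[str]]]:
    rows = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        tokens = line.split()
        if tokens:
            rows.append((lineno, tokens))
    return rows


def _parse_named_matrix(text: str) -> tuple[list[str], list[str], list[list[str]], list[int]]:
    """Split text into (row_names, col_names, cell tokens, data line numbers).

    The header's corner token is optional and auto-detected by token count:
    with C data columns the header has either C or C + 1 tokens.
    """
    rows = _tokenize(text)
    if len(rows) < 2:
        raise MatrixFormatError("matrix needs a header row and at least one data row")
    header = rows[0][1]
    data = rows[1:]
    ncols = len(data[0][1]) - 1
    if ncols < 1:
        raise MatrixFormatError(f"data row at line {data[0][0]} has no value columns")
    for lineno, tokens in data:
        if len(tokens) - 1 != ncols:
            raise MatrixFormatError(
                f"ragged row at line {lineno}: expected {ncols} values, got {len(tokens) - 1}"
            )
    if len(header) == ncols:
        col_names = header
    elif len(header) == ncols + 1:
        col_names = header[1:]
    else:
        raise MatrixFormatError(
            f"header has {len(header)} tokens but data rows have {ncols} value columns"
        )
    row_names = [tokens[0] for _, tokens in data]
    cells = [tokens[1:] for _, tokens in data]
    linenos = [lineno for lineno, _ in data]
    return row_names, col_names, cells, linenos


def _parse_cell(token: str) -> float | None:
    try:
        v = float(token)
    except ValueError:
        return None
    if not math.isfinite(v):
        return None
    return v


def read_qpbin(text: str, rescale_max: float | None = None) -> tuple[QPBIN, CorrectionLog]:
    """Parse a virus x host infection matrix, correcting out-of-range cells.

    Corrections (each logged): non-numeric cells become 0; values above 1
    are clamped to 1 and values below 0 to 0.  With ``rescale_max`` every
    cell is first divided by that maximum (e.g. 3 for a raw 0-3 cross-streak
    virulence scale), logged once.

    Raises :class:`MatrixFormatError` on duplicate names or ragged rows.
    """
    virus_names, host_names, cells, linenos = _parse_named_matrix(text)
    _check_names(virus_names, "virus")
    _check_names(host_names, "host")
    log = CorrectionLog()
    if rescale_max is not None:
        if rescale_max <= 0:
            raise ValueError("rescale_max must be positive")
        log.add("*", f"scale 0-{rescale_max:g}", "scale 0-1", "rescale")
    values = np.zeros((len(virus_names), len(host_names)))
    for i, (virus, row) in enumerate(zip(virus_names, cells)):
        for j, token in enumerate(row):
            loc = f"{virus}:{host_names[j]}"
            v = _parse_cell(token)
            if v is None:
                log.add(loc, token, 0.0, "non_numeric_to_zero")
                v = 0.0
            elif rescale_max is not None:
                v = v / rescale_max
            if v > 1.0:
                log.add(loc, token, 1.0, "clamp_above_one")
                v = 1.0
            elif v < 0.0:
                log.add(loc, token, 0.0, "clamp_below_zero")
                v = 0.0
            values[i, j] = v
    return QPBIN(virus_names, host_names, values), log


def read_qppin(text: str | None, expected_viruses: Sequence[str]) -> tuple[QPPIN, CorrectionLog]:
    """Parse a square virus-virus interaction matrix aligned to a QPBIN.

    The result's row/column order equals ``expected_viruses`` regardless of
    file order.  Viruses absent from the file get neutral (all-1) rows and
    columns, logged; a changed diagonal is forced back to 1 and logged;
    non-numeric cells become 1 (neutral/unknown), logged.  ``text=None``
    yields the all-neutral matrix.

    Raises :class:`MatrixFormatError` for viruses not present in the QPBIN
    (orphan interactions) and for negative entries.
    """
    expected = list(expected_viruses)
    _check_names(expected, "virus")
    log = CorrectionLog()
    if text is None:
        return neutral_qppin(expected), log

    row_names, col_names, cells, linenos = _parse_named_matrix(text)
    _check_names(row_names, "virus")
    _check_names(col_names, "virus")
    if set(row_names) != set(col_names):
        raise MatrixFormatError("interaction matrix row and column names differ")
    orphans = sorted(set(row_names) - set(expected))
    if orphans:
        raise MatrixFormatError(
            f"interaction matrix names not present in the infection matrix: {', '.join(orphans)}"
        )

    pos = {name: k for k, name in enumerate(expected)}
    col_pos = [pos[c] for c in col_names]
    n = len(expected)
    values = np.ones((n, n))
    for virus, row in zip(row_names, cells):
        i = pos[virus]
        for token, j in zip(row, col_pos):
            loc = f"{virus}:{expected[j]}"
            w = _parse_cell(token)
            if w is None:
                log.add(loc, token, 1.0, "non_numeric_to_neutral")
                w = 1.0
            if w < 0:
                raise MatrixFormatError(f"negative interaction value {token} at {loc}")
            if i == j:
                if w != 1.0:
                    log.add(loc, token, 1.0, "diagonal_forced_to_one")
                w = 1.0
            values[i, j] = w
    present = set(row_names)
    for missing in (v for v in expected if v not in present):
        log.add(f"{missing}:*", "absent", 1.0, "missing_virus_neutral_fill")
    return QPPIN(expected, values), log


# ---------------------------------------------------------------------------
# writing


def _format_value(v: float) -> str:
    return format(float(v), ".9g")


def write_matrix(matrix: QPBIN | QPPIN) -> str:
    """Serialize a matrix back to the whitespace dialect ``read_*`` accepts.

    Values survive a read/write round trip to at least 6 significant digits.
    """
    if isinstance(matrix, QPBIN):
        cols = matrix.host_names
        rows = matrix.virus_names
    elif isinstance(matrix, QPPIN):
        cols = matrix.virus_names
        rows = matrix.virus_names
    else:
        raise TypeError(f"cannot serialize {type(matrix).__name__}")
    lines = [" ".join(cols)]
    for name, row in zip(rows, matrix.values):
        lines.append(" ".join([name, *(_format_value(v) for v in row)]))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Cytoscape-compatible export


def export_network(
    qpbin: QPBIN,
    qppin: QPPIN | None = None,
    cocktail: Sequence[str] | None = None,
    include_graphml: bool = False,
) -> dict[str, str]:
    """Export the (cocktail-restricted) network for Cytoscape.

    Returns a mapping of file name to file text: a SIF edge list
    (``network.sif``; interaction types ``infects``, ``antagonizes``,
    ``synergizes``), an edge-attribute table (``edges.tsv``) and optionally
    GraphML (``network.graphml``).  Virus-host edges are emitted for every
    positive infection value; virus-virus edges for every non-neutral
    (w != 1) directed factor.  When ``cocktail`` is given, virus nodes are
    restricted to it.
    """
    if qppin is None:
        qppin = neutral_qppin(qpbin.virus_names)
    if set(qppin.virus_names) != set(qpbin.virus_names):
        raise MatrixFormatError("interaction matrix viruses do not match infection matrix")
    viruses = list(qpbin.virus_names) if cocktail is None else list(cocktail)
    for v in viruses:
        if v not in qpbin.virus_names:
            raise MatrixFormatError(f"cocktail virus {v!r} not in infection matrix")

    edges: list[tuple[str, str, str, float]] = []  # source, interaction, target, weight
    for p in viruses:
        i = qpbin.virus_index(p)
        for j, h in enumerate(qpbin.host_names):
            v = float(qpbin.values[i, j])
            if v > 0:
                edges.append((p, "infects", h, v))
    for p, q in itertools.permutations(viruses, 2):
        w = qppin.factor(p, q)
        if w != 1.0:
            kind = "antagonizes" if w < 1.0 else "synergizes"
            edges.append((q, kind, p, w))  # source q acts on target p

    sif = "".join(f"{s}\t{kind}\t{t}\n" for s, kind, t in ((e[0], e[1], e[2]) for e in edges))
    attr_lines = ["source\ttarget\tinteraction\tweight\n"]
    attr_lines += [f"{s}\t{t}\t{kind}\t{_format_value(w)}\n" for s, kind, t, w in edges]

    files = {"network.sif": sif, "edges.tsv": "".join(attr_lines)}
    if include_graphml:
        g = nx.DiGraph()
        for p in viruses:
            g.add_node(p, kind="virus")
        for h in qpbin.host_names:
            g.add_node(h, kind="host")
        for s, kind, t, w in edges:
            g.add_edge(s, t, interaction=kind, weight=w)
        files["network.graphml"] = "\n".join(nx.generate_graphml(g)) + "\n"
    return files
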