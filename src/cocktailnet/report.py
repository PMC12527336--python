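"""Structured design reports: assembly and deterministic rendering.

A report is a pure function of the inputs and configuration: it echoes the
configuration, lists every correction applied to the input matrices,
summarises the network, tabulates the best cocktail of every size under
both objective orderings (broadest host range vs highest virulence), and
breaks the winning cocktail down into per-virus host targets with expected
lysis efficiency and marginal contributions.  When the interaction matrix
is non-neutral an antagonism-minimised alternative cocktail is reported
alongside the virulence-maximising one.  Rendering is byte-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import pandas as pd

from .matrices import QPBIN, QPPIN, Correction, neutral_qppin
from .metrics import NetworkSummary, summarize_network, summary_tables
from .model import CocktailEvaluation, effective_virulence, Cocktail
from .search import DesignConfig, DesignResult, design_cocktail_series, design_cocktails

__all__ = ["DesignReport", "build_report", "render_report", "design_report"]

_FMT = "{:.4f}".format


@dataclass
class DesignReport:
    config: DesignConfig
    corrections: list[Correction]
    summary: NetworkSummary
    results: dict[str, DesignResult]  # objective -> result
    breakdowns: dict[str, list[tuple[str, str, float]]]  # objective -> (virus, host, v_eff)
    qppin_neutral: bool
    series: list[DesignResult] | None = None


def _breakdown(
    cocktail: Cocktail, qpbin: QPBIN, qppin: QPPIN, tau: float
) -> list[tuple[str, str, float]]:
    rows = []
    for p in cocktail.viruses:
        for h in qpbin.host_names:
            v_eff = effective_virulence(p, h, cocktail, qpbin, qppin)
            if v_eff > tau:
                rows.append((p, h, v_eff))
    return rows


def build_report(
    qpbin: QPBIN,
    qppin: QPPIN | None,
    config: DesignConfig,
    results: dict[str, DesignResult],
    corrections: list[Correction] | None = None,
    series: list[DesignResult] | None = None,
) -> DesignReport:
    """Assemble a report from completed design results (one per objective)."""
    if qppin is None:
        qppin = neutral_qppin(qpbin.virus_names)
    breakdowns = {}
    for objective, result in results.items():
        if result.overall_best is not None:
            cocktail, _ = result.overall_best
            breakdowns[objective] = _breakdown(cocktail, qpbin, qppin, config.tau)
    return DesignReport(
        config=config,
        corrections=list(corrections or []),
        summary=summarize_network(qpbin, config.tau),
        results=results,
        breakdowns=breakdowns,
        qppin_neutral=qppin.is_neutral(),
        series=series,
    )


def design_report(
    qpbin: QPBIN,
    qppin: QPPIN | None = None,
    config: DesignConfig | None = None,
    corrections: list[Correction] | None = None,
) -> DesignReport:
    """Run the configured designer under both orderings and build the report."""
    from dataclasses import replace

    config = config or DesignConfig()
    results = {
        objective: design_cocktails(qpbin, qppin, replace(config, objective=objective))
        for objective in ("coverage_first", "virulence_first")
    }
    series = None
    if config.n_cocktails > 1:
        series = design_cocktail_series(qpbin, qppin, config)
    return build_report(qpbin, qppin, config, results, corrections, series)


# ---------------------------------------------------------------------------
# rendering


def _cocktail_rows(result: DesignResult, objective: str) -> pd.DataFrame:
    rows = []
    for size in sorted(result.best_per_size):
        cocktail, ev = result.best_per_size[size]
        rows.append(
            {
                "objective": objective,
                "size": size,
                "cocktail": "+".join(cocktail.viruses),
                "coverage": ev.coverage,
                "total_inhibition": ev.total_inhibition,
                "mean_redundancy": ev.mean_redundancy,
                "antagonism_burden": ev.antagonism_burden,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "objective",
            "size",
            "cocktail",
            "coverage",
            "total_inhibition",
            "mean_redundancy",
            "antagonism_burden",
        ],
    )


def _evaluation_lines(ev: CocktailEvaluation) -> list[str]:
    lines = [
        f"  viruses: {', '.join(ev.viruses) if ev.viruses else '(empty)'}",
        f"  size: {ev.size}",
        f"  coverage (susceptible hosts): {ev.coverage}",
        f"  total predicted inhibition: {_FMT(ev.total_inhibition)}",
        f"  mean co-infection redundancy: {_FMT(ev.mean_redundancy)}",
        f"  antagonism burden: {_FMT(ev.antagonism_burden)}",
        "  per-host predicted inhibition:",
    ]
    lines += [f"    {h}\t{_FMT(x)}" for h, x in ev.per_host_inhibition.items()]
    lines.append("  per-virus marginal contribution:")
    lines += [f"    {p}\t{_FMT(c)}" for p, c in ev.per_virus_contribution.items()]
    return lines


def _frame_text(frame: pd.DataFrame) -> str:
    return frame.to_csv(sep="\t", index=False, float_format="%.4f")


def render_report(report: DesignReport, format: str = "text") -> dict[str, str]:
    """Render to files: ``text`` gives ``report.txt``; ``tsv`` gives one
    table per section.  Re-rendering the same report is byte-identical."""
    if format == "tsv":
        return _render_tsv(report)
    if format != "text":
        raise ValueError(f"unknown report format {format!r}")

    out: list[str] = ["# Phage cocktail design report", "", "## Configuration"]
    for f in fields(report.config):
        out.append(f"{f.name} = {getattr(report.config, f.name)}")

    out += ["", "## Corrections applied to input matrices"]
    if report.corrections:
        out.append("location\toriginal\tcorrected\trule")
        out += [f"{c.location}\t{c.original}\t{c.corrected}\t{c.rule}" for c in report.corrections]
    else:
        out.append("none")

    s = report.summary
    out += [
        "",
        "## Network summary",
        f"fill = {_FMT(s.fill)}",
        f"binary entropy (bits) = {_FMT(s.entropy_bits)}",
        f"density (edges per node) = {_FMT(s.density)}",
        f"edges = {s.n_edges}",
        "",
        "virus\thost_range\tmean_virulence\tmean_virulence_over_infected",
    ]
    out += [
        f"{p.virus}\t{_FMT(p.host_range)}\t{_FMT(p.mean_virulence)}"
        f"\t{_FMT(p.mean_virulence_over_infected)}"
        for p in s.per_phage
    ]
    out += ["", "host\tlysing_phages"]
    out += [f"{h.host}\t{h.resistance_count}" for h in s.per_host]

    for objective in sorted(report.results):
        result = report.results[objective]
        title = (
            "broadest host range / minimal antagonism"
            if objective == "coverage_first"
            else "highest virulence"
        )
        out += ["", f"## Best cocktails per size — {title} ({objective})"]
        if result.removed_viruses:
            out.append(f"pruned viruses (empty host range): {', '.join(result.removed_viruses)}")
        if result.uncoverable_hosts:
            out.append(f"uncoverable hosts: {', '.join(result.uncoverable_hosts)}")
        frame = _cocktail_rows(result, objective)
        out.append(_frame_text(frame).rstrip("\n"))
        if result.overall_best is not None:
            out += [f"", f"### Winning cocktail ({objective})"]
            out += _evaluation_lines(result.overall_best[1])
            out += ["  virus -> host targets (expected lysis efficiency):"]
            out += [
                f"    {p}\t{h}\t{_FMT(v)}" for p, h, v in report.breakdowns.get(objective, [])
            ]

    if not report.qppin_neutral:
        out += ["", "## Alternative antagonism-minimized cocktail"]
        alt = report.results.get("coverage_first")
        if alt is not None and alt.overall_best is not None:
            out += _evaluation_lines(alt.overall_best[1])
        else:
            out.append("none found")

    if report.series is not None:
        out += ["", f"## Cocktail series (rotation design, {len(report.series)} cocktails)"]
        for i, result in enumerate(report.series, 1):
            if result.overall_best is None:
                continue
            cocktail, ev = result.overall_best
            out.append(
                f"cocktail {i}: {'+'.join(cocktail.viruses)}\t"
                f"coverage={ev.coverage}\ttotal_inhibition={_FMT(ev.total_inhibition)}"
            )

    return {"report.txt": "\n".join(out) + "\n"}


def _render_tsv(report: DesignReport) -> dict[str, str]:
    files: dict[str, str] = {}
    config_frame = pd.DataFrame(
        [(f.name, str(getattr(report.config, f.name))) for f in fields(report.config)],
        columns=["parameter", "value"],
    )
    files["config.tsv"] = _frame_text(config_frame)
    corr_frame = pd.DataFrame(
        [(c.location, c.original, str(c.corrected), c.rule) for c in report.corrections],
        columns=["location", "original", "corrected", "rule"],
    )
    files["corrections.tsv"] = _frame_text(corr_frame)
    tables = summary_tables(report.summary)
    files["summary_phages.tsv"] = _frame_text(tables["phages"])
    files["summary_hosts.tsv"] = _frame_text(tables["hosts"])
    cocktail_frames = [
        _cocktail_rows(result, objective) for objective, result in sorted(report.results.items())
    ]
    files["cocktails.tsv"] = _frame_text(
        pd.concat(cocktail_frames, ignore_index=True)
        if cocktail_frames
        else _cocktail_rows(DesignResult({}, None), "none")
    )
    breakdown_rows = [
        (objective, p, h, v)
        for objective in sorted(report.breakdowns)
        for p, h, v in report.breakdowns[objective]
    ]
    files["breakdown.tsv"] = _frame_text(
        pd.DataFrame(breakdown_rows, columns=["objective", "virus", "host", "expected_lysis"])
    )
    return files
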