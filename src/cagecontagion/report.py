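"""End-to-end analysis: from validated inputs to a self-describing report.

``analyze`` drives the full pipeline — window summaries, copied-visit
detection, per-cage graphs, pooled strain metrics, and the statistical
battery — and ``export_report`` writes the machine-readable artifacts
(JSON report, tidy stats table, per-animal summaries, GraphML/DOT per
cage).  The report embeds the exact conventions used (latency reference,
drinking key, threshold, divisor) and a provenance block, so reruns on the
same inputs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .contagion import (
    DEFAULT_LATENCY_THRESHOLD,
    GroupMetrics,
    PooledMetrics,
    build_graph,
    compute_group_metrics,
    detect_copied_visits,
    pool_metrics,
    write_dot,
    write_graphml,
)
from .events import ExperimentTimeline, cage_strains
from .stats import (
    TestResult,
    UndefinedStatisticError,
    chi_square_2x2,
    nested_anova,
    results_table,
    rm_anova,
    spearman_screen,
)
from .windows import SUMMARY_VALUE_COLUMNS, circadian_compare, paired_long, summarize_window


@dataclass
class AnalysisOptions:
    latency_threshold: float = DEFAULT_LATENCY_THRESHOLD
    latency_reference: str = "exit"
    drinking_key: str = "licks"
    baseline_divisor: float | None = None   # None: length ratio baseline/contagion
    df_convention: str = "reported"

    def resolved_divisor(self, timeline: ExperimentTimeline) -> float:
        if self.baseline_divisor is not None:
            return float(self.baseline_divisor)
        b0, b1 = timeline.baseline_window
        return (b1 - b0) / timeline.contagion_window_length


@dataclass
class AnalysisReport:
    """Everything the pipeline computes, plus provenance."""

    summaries: pd.DataFrame                 # per animal x window (long)
    copied_visits: pd.DataFrame
    graphs: dict[str, "object"]             # cage -> networkx Graph
    cage_metrics: list[GroupMetrics]
    pooled: dict[str, PooledMetrics]        # strain -> pooled counts
    stat_results: list[TestResult]
    spearman: pd.DataFrame
    n_tests: int
    options: AnalysisOptions
    provenance: dict = field(default_factory=dict)


def _strain_pair(pooled: dict[str, PooledMetrics]) -> list[str]:
    return sorted(pooled)


def analyze(
    visits: pd.DataFrame,
    roster: pd.DataFrame,
    timeline: ExperimentTimeline,
    options: AnalysisOptions | None = None,
    provenance: dict | None = None,
) -> AnalysisReport:
    """Run the full contagion analysis on validated inputs.

    The statistical battery (nested ANOVA across strains, repeated-measures
    ANOVA within each strain, pooled chi-square comparisons, Spearman
    screen) is attempted wherever the design supports it: tests whose
    preconditions the data cannot meet (e.g. a single strain, or fewer than
    two cages per strain) are skipped and noted in the provenance block
    rather than failing the whole report.
    """
    opt = options or AnalysisOptions()
    divisor = opt.resolved_divisor(timeline)
    strains = cage_strains(roster)
    notes: list[str] = []

    # ---- per-window summaries -------------------------------------------
    def summarize(window_label, divisor_=1.0):
        return summarize_window(
            visits, roster, timeline.window(window_label), window_label,
            normalization_divisor=divisor_, drinking_key=opt.drinking_key,
            warn_outside_span=False,
        )

    baseline_norm = summarize("baseline", divisor)
    baseline_raw = summarize("baseline", 1.0)
    contagion_sum = summarize("contagion", 1.0)
    circadian = circadian_compare(
        visits, roster, timeline.habituation_morning, timeline.habituation_midday,
        drinking_key=opt.drinking_key,
    )
    summaries = pd.concat(
        [baseline_norm, contagion_sum, circadian], ignore_index=True
    )

    # ---- copied visits, graphs, metrics ---------------------------------
    copied = detect_copied_visits(
        visits, timeline.contagion_window, opt.latency_threshold, opt.latency_reference
    )
    graphs, metrics = {}, []
    for cage in sorted(roster["cage"].unique()):
        cage_roster = roster[roster["cage"] == cage]
        cage_summary = contagion_sum[contagion_sum["animal"].isin(cage_roster["animal"])]
        g = build_graph(copied, roster, cage_summary, cage)
        graphs[cage] = g
        metrics.append(compute_group_metrics(g, copied))
    pooled = {
        s: pool_metrics([m for m in metrics if strains[m.cage] == s], roster, s)
        for s in sorted(set(strains.values()))
    }

    # ---- statistics ------------------------------------------------------
    results: list[TestResult] = []
    meta = roster.set_index("animal")[["cage", "strain", "role"]]
    obs_ids = meta.index[meta["role"] == "observer"]

    def with_meta(summary: pd.DataFrame) -> pd.DataFrame:
        df = summary[summary["animal"].isin(obs_ids)].copy()
        df["cage"] = df["animal"].map(meta["cage"])
        df["strain"] = df["animal"].map(meta["strain"])
        return df

    two_strains = len(pooled) == 2
    enough_cages = (
        meta.loc[obs_ids].groupby("strain")["cage"].nunique().min() >= 2
        if len(obs_ids) else False
    )

    # pooled chi-square comparisons between the two strain cohorts
    if two_strains:
        s1, s2 = _strain_pair(pooled)
        tables = {
            "activated observers": (
                pooled[s1].n_activated_observers, pooled[s1].n_passive_observers,
                pooled[s2].n_activated_observers, pooled[s2].n_passive_observers,
            ),
            "followers": (
                pooled[s1].n_followers,
                pooled[s1].n_observers - pooled[s1].n_followers,
                pooled[s2].n_followers,
                pooled[s2].n_observers - pooled[s2].n_followers,
            ),
            "actualized edges": (
                pooled[s1].actual_edges,
                pooled[s1].possible_edges - pooled[s1].actual_edges,
                pooled[s2].actual_edges,
                pooled[s2].possible_edges - pooled[s2].actual_edges,
            ),
        }
        for name, (a, b, c, d) in tables.items():
            try:
                r = chi_square_2x2(
                    [[a, b], [c, d]],
                    design_label=f"chi-square {name} ({s1} vs {s2})",
                )
                results.append(r)
            except UndefinedStatisticError as exc:
                notes.append(f"chi-square {name}: {exc}")
    else:
        notes.append("chi-square comparisons need exactly two strains; skipped")

    # nested ANOVA per parameter, baseline and contagion
    for window_label, summary in (("baseline", baseline_norm), ("contagion", contagion_sum)):
        df = with_meta(summary)
        for param in SUMMARY_VALUE_COLUMNS:
            if not (two_strains and enough_cages):
                notes.append(f"nested ANOVA {param} ({window_label}): design not supported; skipped")
                continue
            try:
                results.extend(
                    nested_anova(
                        df.rename(columns={param: "value"}),
                        df_convention=opt.df_convention,
                        design_label=f"nested ANOVA {param} ({window_label})",
                    )
                )
            except Exception as exc:  # e.g. singleton cage
                notes.append(f"nested ANOVA {param} ({window_label}): {exc}")

    # repeated-measures ANOVA per strain: baseline vs contagion
    for strain in sorted(set(strains.values())):
        ids = meta.index[(meta["strain"] == strain) & (meta["role"] == "observer")]
        b = baseline_norm[baseline_norm["animal"].isin(ids)]
        c = contagion_sum[contagion_sum["animal"].isin(ids)]
        for param in SUMMARY_VALUE_COLUMNS:
            try:
                long = paired_long(b, c, param)
                long["cage"] = long["animal"].map(meta["cage"])
                results.extend(
                    rm_anova(
                        long, dv="value", within="condition",
                        subject="animal", between="cage",
                        df_convention=opt.df_convention,
                        design_label=f"RM ANOVA {param} ({strain})",
                    )
                )
            except Exception as exc:
                notes.append(f"RM ANOVA {param} ({strain}): {exc}")

    # Spearman screen: baseline vs contagion per observer
    b_obs = baseline_norm[baseline_norm["animal"].isin(obs_ids)]
    c_obs = contagion_sum[contagion_sum["animal"].isin(obs_ids)]
    spear = spearman_screen(b_obs, c_obs)

    prov = dict(provenance or {})
    prov.setdefault("package_version", __version__)
    prov["conventions"] = {
        "latency_threshold_s": opt.latency_threshold,
        "latency_reference": opt.latency_reference,
        "drinking_key": opt.drinking_key,
        "baseline_divisor": divisor,
        "df_convention": opt.df_convention,
        "window_membership": "entry time, half-open [start, end)",
    }
    prov["notes"] = notes

    n_tests = len(results) + int(spear["p_value"].notna().sum())
    return AnalysisReport(
        summaries=summaries,
        copied_visits=copied,
        graphs=graphs,
        cage_metrics=metrics,
        pooled=pooled,
        stat_results=results,
        spearman=spear,
        n_tests=n_tests,
        options=opt,
        provenance=prov,
    )


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def report_json(report: AnalysisReport) -> dict:
    """The report as a plain JSON-serializable document."""
    return {
        "provenance": report.provenance,
        "n_statistical_tests": report.n_tests,
        "cage_metrics": [m.as_dict() for m in report.cage_metrics],
        "pooled_by_strain": {s: p.as_dict() for s, p in report.pooled.items()},
        "statistics": [r.as_dict() for r in report.stat_results],
        "spearman": report.spearman.where(report.spearman.notna(), None).to_dict("records"),
        "n_copied_visits": int(len(report.copied_visits)),
    }


def export_report(report: AnalysisReport, out_dir: str | Path) -> list[Path]:
    """Write all artifacts under ``out_dir``; returns the paths written.

    On any failure, partially written files from this call are removed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        p = out / "report.json"
        with open(p, "w") as fh:
            json.dump(report_json(report), fh, indent=2, sort_keys=True)
            fh.write("\n")
        written.append(p)

        p = out / "summaries.tsv"
        report.summaries.to_csv(p, sep="\t", index=False, float_format="%.17g")
        written.append(p)

        p = out / "copied_visits.tsv"
        report.copied_visits.to_csv(p, sep="\t", index=False, float_format="%.17g")
        written.append(p)

        p = out / "stats.tsv"
        results_table(report.stat_results).to_csv(p, sep="\t", index=False, float_format="%.17g")
        written.append(p)

        for cage, g in sorted(report.graphs.items()):
            gp = out / f"cage_{cage}.graphml"
            write_graphml(g, gp)
            written.append(gp)
            dp = out / f"cage_{cage}.dot"
            write_dot(g, dp)
            written.append(dp)
    except Exception:
        for f in written:
            f.unlink(missing_ok=True)
        raise
    return written
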