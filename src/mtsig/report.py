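"""Markdown report assembly from the pipeline's tidy CSV tables.

Summarizes, for a synthetic cohort, the response-class proportions per
signal, onset/peak latency and duration statistics, cross-signal correlation
ordering, within/between-odor reliability with the paired nonparametric
battery, and odor-pair decoding — the cohort-level readouts of the analysis.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .stats import run_battery, summarize

__all__ = ["build_report"]


def _fmt(m: float, se: float) -> str:
    return f"{m:.3f} ± {se:.3f}"


def _fmt_series(values) -> str:
    """Mean ± SE, or the bare mean when only one value is available."""
    v = pd.Series(values).dropna()
    if len(v) == 0:
        return "–"
    if len(v) == 1:
        return f"{v.iloc[0]:.3f}"
    return _fmt(*summarize(v))


def _section_responses(tab: pd.DataFrame) -> list[str]:
    out = ["## Response classification", "",
           "Fractions of source–odor pairs per auROC response class:", ""]
    pivot = (tab.groupby(["signal_kind", "response_class"]).size()
             .unstack(fill_value=0))
    frac = pivot.div(pivot.sum(axis=1), axis=0).round(3)
    out.append(frac.to_markdown())
    out.append("")
    resp = tab.dropna(subset=["onset_latency"])
    if len(resp) >= 2:
        out += ["Temporal metrics over significant responses (mean ± SE, s):", ""]
        rows = []
        for kind, sub in resp.groupby("signal_kind"):
            rows.append({
                "signal_kind": kind,
                "onset": _fmt_series(sub.onset_latency),
                "peak": _fmt_series(sub.peak_latency),
                "duration": _fmt_series(sub.duration),
                "n": len(sub),
            })
        out.append(pd.DataFrame(rows).to_markdown(index=False))
        out.append("")
    return out


def _section_cross_signal(tab: pd.DataFrame) -> list[str]:
    out = ["## Calcium vs electrophysiology: matched-trial correlation", ""]
    rows = []
    for pair, sub in tab.groupby("signal_pair"):
        rows.append({"signal_pair": pair, "matched |r|": _fmt_series(sub.matched_mean),
                     "n": sub.matched_mean.notna().sum()})
    out.append(pd.DataFrame(rows).to_markdown(index=False))
    out.append("")
    groups = {p: s.matched_mean.dropna().to_numpy()
              for p, s in tab.groupby("signal_pair")}
    if len(groups) > 2 and len({len(v) for v in groups.values()}) == 1:
        res = run_battery(list(groups.values()), paired=True,
                          labels=list(groups))[0]
        out.append(f"{res.test}: statistic {res.statistic:.3f}, "
                   f"p = {res.p_value:.2e}"
                   + ("; post hoc: "
                      + ", ".join(f"{a} vs {b} p={p:.3f}" for a, b, p in res.posthoc)
                      if res.posthoc else ""))
        out.append("")
    return out


def _section_reliability(tab: pd.DataFrame) -> list[str]:
    out = ["## Within-odor vs between-odors reliability", ""]
    rows = []
    for kind, sub in tab.groupby("signal_kind"):
        rows.append({
            "signal_kind": kind,
            "within |r|": _fmt_series(sub.within_mean),
            "between |r|": _fmt_series(sub.between_mean),
            "(W−B)/W": _fmt_series(sub.wb_ratio),
            "n": len(sub),
        })
        if len(sub) >= 6:
            res = run_battery([sub.within_mean.to_numpy(),
                               sub.between_mean.to_numpy()], paired=True,
                              labels=["within", "between"])[0]
            rows[-1]["Wilcoxon p"] = f"{res.p_value:.3g}"
    out.append(pd.DataFrame(rows).to_markdown(index=False))
    out.append("")
    return out


def _section_decoding(pair_tab: pd.DataFrame | None,
                      curve_tab: pd.DataFrame | None) -> list[str]:
    out = ["## Odor-pair discriminability", ""]
    if pair_tab is not None:
        rows = []
        for kind, sub in pair_tab.groupby("signal_kind"):
            rows.append({"signal_kind": kind,
                         "pair auROC (folded)": _fmt_series(sub.auroc_folded),
                         "n pairs": len(sub)})
        out.append(pd.DataFrame(rows).to_markdown(index=False))
        out.append("")
    if curve_tab is not None:
        out += ["Cumulative-window decoding accuracy (mean over 28 pairs and mice):", ""]
        pivot = (curve_tab.groupby(["signal_kind", "t_end"]).accuracy.mean()
                 .unstack().round(3))
        out.append(pivot.to_markdown())
        out.append("")
    return out


def build_report(tables_dir: Path) -> str:
    """Assemble the cohort report from whichever tables are present."""
    tables_dir = Path(tables_dir)
    parts = ["# Synthetic-cohort analysis report", ""]

    def _maybe(name):
        p = tables_dir / name
        return pd.read_csv(p) if p.exists() else None

    responses = _maybe("responses.csv")
    if responses is not None and len(responses):
        parts += _section_responses(responses)
    cross = _maybe("cross_signal.csv")
    if cross is not None and len(cross):
        parts += _section_cross_signal(cross)
    rel = _maybe("reliability.csv")
    if rel is not None and len(rel):
        parts += _section_reliability(rel)
    pair_tab = _maybe("pair_auroc.csv")
    curve_tab = _maybe("decoding_curves.csv")
    if pair_tab is not None or curve_tab is not None:
        parts += _section_decoding(pair_tab, curve_tab)
    if len(parts) == 2:
        parts.append("No tables found; run the pipeline commands first.")
    return "\n".join(parts) + "\n"
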