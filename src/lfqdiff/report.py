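"""Post-hoc annotation and summary statistics for workflow results.

Replaces the web-database step of a typical interferon study with a
local gene -> IRG-flag annotation join, counts proteins per volcano and
detection class, computes cross-sample overlap statistics, and -- when
simulation ground truth is available -- sensitivity and the realized
false-discovery proportion.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

CALL_CLASSES = ("up", "down", "status_change", "not_significant",
                "untestable")


def annotate_irg(
    results: pd.DataFrame, annotation: pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """Join an IRG annotation table onto results by gene symbol.

    Matching is case-folded exact match.  Genes absent from the table
    get flag ``unknown`` and are tallied separately.  Statistical
    columns are never modified.

    Returns the annotated results (new ``irg_flag`` column holding
    ``True``/``False``/``"unknown"``) and a dict of per-class IRG
    counts.
    """
    if "gene" not in results.columns:
        raise ValueError("results lack a 'gene' column")
    ann = annotation.copy()
    ann["_key"] = ann["gene"].astype(str).str.casefold()
    dup = ann.loc[ann["_key"].duplicated(), "gene"].tolist()
    if dup:
        raise ValueError(
            f"duplicate gene symbols in annotation (case-folded): {dup}")
    lookup = ann.set_index("_key")["irg_flag"]
    keys = results["gene"].astype(str).str.casefold()
    flags = keys.map(lookup)
    out = results.copy()
    out["irg_flag"] = flags.astype(object).where(flags.notna(), "unknown")
    counts = {
        cls: int(((out["volcano_class"] == cls) & (out["irg_flag"] == True)
                  ).sum())
        for cls in ("up", "down", "status_change")
    }
    counts["unknown"] = int((out["irg_flag"] == "unknown").sum())
    return out, counts


def overlap_stats(genes_a, genes_b) -> dict:
    """Overlap between two gene sets: shared count, fractions, Jaccard.

    ``fraction_a`` is |A n B| / |A| (undefined -> nan for empty sets);
    Jaccard is |A n B| / |A u B| (0 for two empty sets).
    """
    a, b = set(genes_a), set(genes_b)
    shared = len(a & b)
    union = len(a | b)
    return {
        "n_a": len(a),
        "n_b": len(b),
        "shared": shared,
        "fraction_a": shared / len(a) if a else float("nan"),
        "fraction_b": shared / len(b) if b else float("nan"),
        "jaccard": shared / union if union else 0.0,
    }


def build_report(
    results, truth: pd.DataFrame | None = None,
) -> dict:
    """Summarise one or several workflow result tables.

    ``results`` is a result DataFrame or a mapping workflow ->
    DataFrame.  With ground truth, adds sensitivity (direction-matched
    volcano calls among true responders), the realized false-discovery
    proportion among calls, and a per-branch breakdown.  The report is
    a plain dict, JSON-serialisable with :func:`format_report` as the
    human-readable rendering.
    """
    if isinstance(results, pd.DataFrame):
        results = {str(results["workflow"].iloc[0]) if len(results) else "?":
                   results}
    report: dict = {"workflows": {}}
    for wf, frame in results.items():
        entry: dict = {
            "n_proteins": int(len(frame)),
            "class_counts": {
                cls: int((frame["volcano_class"] == cls).sum())
                for cls in CALL_CLASSES
            },
            "branch_counts": frame["branch"].value_counts().to_dict(),
        }
        if truth is not None:
            entry.update(_truth_metrics(frame, truth))
        report["workflows"][wf] = entry
    return report


def _truth_metrics(frame: pd.DataFrame, truth: pd.DataFrame) -> dict:
    t = truth[~truth["is_decoy"]].set_index("protein_id")
    merged = frame.set_index("protein_id").join(
        t[["responder_class"]], how="left")
    merged["responder_class"] = merged["responder_class"].fillna("null")
    calls = merged["volcano_class"].isin(["up", "down"])
    tp = ((merged["volcano_class"] == "up")
          & (merged["responder_class"] == "up")) | (
        (merged["volcano_class"] == "down")
        & (merged["responder_class"] == "down"))
    n_resp = int((t["responder_class"] != "null").sum())
    n_calls = int(calls.sum())
    n_tp = int(tp.sum())
    per_branch = {
        br: int((tp & (merged["branch"] == br)).sum())
        for br in merged["branch"].unique()
    }
    return {
        "n_responders": n_resp,
        "n_calls": n_calls,
        "n_true_positives": n_tp,
        "sensitivity": n_tp / n_resp if n_resp else float("nan"),
        "fdp": (n_calls - n_tp) / max(1, n_calls),
        "true_positives_per_branch": per_branch,
    }


def format_report(report: dict) -> str:
    """Render a report dict as human-readable text."""
    lines = []
    for wf, entry in report["workflows"].items():
        lines.append(f"Workflow {wf}: {entry['n_proteins']} proteins")
        cc = entry["class_counts"]
        lines.append(
            "  up={up}  down={down}  status_change={status_change}  "
            "not_significant={not_significant}  untestable={untestable}"
            .format(**cc))
        if "sensitivity" in entry:
            lines.append(
                f"  vs truth: responders={entry['n_responders']}  "
                f"calls={entry['n_calls']}  TP={entry['n_true_positives']}  "
                f"sensitivity={entry['sensitivity']:.3f}  "
                f"FDP={entry['fdp']:.3f}")
    return "\n".join(lines)


def write_report(report: dict, json_path, text_path=None) -> None:
    with open(json_path, "w") as fh:
        json.dump(report, fh, indent=1)
    if text_path:
        with open(text_path, "w") as fh:
            fh.write(format_report(report) + "\n")
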