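"""Tab-separated on-disk formats for evidence, truth, matrices, results.

All tables are plain TSV with a header row; missing abundances are
written as ``NA``.  A quant matrix travels with a JSON sidecar holding
design metadata, the quantitation method, and the per-run normalisation
constants needed to reproduce or impute values.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .design import SampleDesign
from .quantify import QuantMatrix
from .simulate import EVIDENCE_COLUMNS, TRUTH_COLUMNS

_BOOL_EV = ["passed_fdr_filter", "is_decoy"]


def write_evidence(evidence: pd.DataFrame, path) -> None:
    evidence[EVIDENCE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_evidence(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in _BOOL_EV:
        if df[col].dtype != bool:
            df[col] = df[col].astype(str).str.lower().isin(["true", "1"])
    return df


def write_truth(truth: pd.DataFrame, path) -> None:
    truth[TRUTH_COLUMNS].to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    # keep_default_na: the responder class "null" is a value, not a missing
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[])
    for col in ["is_decoy", "irg_flag"]:
        if df[col].dtype != bool:
            df[col] = df[col].astype(str).str.lower().isin(["true", "1"])
    return df


def write_matrix(matrix: QuantMatrix, path, sidecar_path=None) -> None:
    """Write matrix TSV (proteins x runs, NA for missing) + JSON sidecar."""
    path = Path(path)
    matrix.values.to_csv(path, sep="\t", na_rep="NA", index_label="protein_id")
    sidecar = Path(sidecar_path) if sidecar_path else path.with_suffix(".json")
    meta = {
        "method": matrix.method,
        "normalized": matrix.normalized,
        "label": matrix.design.label,
        "runs": matrix.design.runs.to_dict(orient="records"),
        "run_denominator": (
            None if matrix.run_denominator is None
            else matrix.run_denominator.to_dict()),
        "norm_factor": matrix.norm_factor.to_dict(),
        "proteins": (
            None if matrix.proteins is None
            else matrix.proteins.reset_index().to_dict(orient="records")),
    }
    sidecar.write_text(json.dumps(meta, indent=1))


def read_matrix(path, sidecar_path=None) -> QuantMatrix:
    path = Path(path)
    sidecar = Path(sidecar_path) if sidecar_path else path.with_suffix(".json")
    meta = json.loads(sidecar.read_text())
    values = pd.read_csv(path, sep="\t", index_col="protein_id",
                         na_values=["NA"])
    design = SampleDesign(
        runs=pd.DataFrame(meta["runs"]), label=meta.get("label", ""))
    proteins = None
    if meta.get("proteins") is not None:
        proteins = pd.DataFrame(meta["proteins"]).set_index("protein_id")
    run_denominator = None
    if meta.get("run_denominator") is not None:
        run_denominator = pd.Series(meta["run_denominator"]).reindex(
            values.columns)
    return QuantMatrix(
        values=values,
        design=design,
        method=meta["method"],
        normalized=bool(meta["normalized"]),
        run_denominator=run_denominator,
        norm_factor=pd.Series(meta["norm_factor"]).reindex(values.columns),
        proteins=proteins,
    )


def write_results(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def read_annotation(path) -> pd.DataFrame:
    """Two-column gene -> IRG-flag annotation table."""
    df = pd.read_csv(path, sep="\t")
    if "gene" not in df.columns or "irg_flag" not in df.columns:
        raise ValueError("annotation table needs columns: gene, irg_flag")
    if df["irg_flag"].dtype != bool:
        df["irg_flag"] = df["irg_flag"].astype(str).str.lower().isin(
            ["true", "1", "yes"])
    return df
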