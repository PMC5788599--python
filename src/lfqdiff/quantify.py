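"""Protein-level label-free quantitation.

Turns per-run identification evidence into protein x run abundance
matrices using the three classical spectral indices:

* ``NSAF`` -- normalised spectral abundance factor,
  ``(SpC_i / L_i) / sum_j (SpC_j / L_j)`` per run;
* ``emPAI`` -- exponentially modified protein abundance index,
  ``10**(N_observed / N_observable) - 1``;
* ``SIN`` -- normalised spectral index,
  ``(SI_i / sum_j SI_j) / L_i`` where ``SI`` is the protein's summed
  peptide/fragment intensity in the run.

Upstream of quantitation sits target-decoy FDR filtering: per run,
proteins are ranked by identification score and the largest score
prefix whose estimated decoy/target ratio stays at or below the chosen
threshold (default 1%) is retained.  The unfiltered target list is kept
alongside, because the missing-value imputation strategy of the
statistics module reaches back into it.

Missing values are explicit (``NaN``) and are never silently coerced to
zero inside this module; deciding how to fill them is a statistical
choice that belongs downstream.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import SampleDesign

METHODS = ("sin", "nsaf", "empai")

#: Evidence columns required for filtering and quantitation.
_REQUIRED = [
    "protein_id", "run_id", "spectral_count", "summed_intensity",
    "n_observed_peptides", "score", "passed_fdr_filter", "is_decoy",
    "protein_length", "n_observable_peptides",
]


@dataclass
class QuantMatrix:
    """Protein x run abundance matrix with explicit missing values.

    Attributes
    ----------
    values : pandas.DataFrame
        Rows indexed by protein_id, columns by run_id; ``NaN`` marks a
        protein not quantified in a run (distinct from an observed 0).
    design : SampleDesign
        Run metadata (condition, biological/technical replicate).
    method : str
        One of ``{"sin", "nsaf", "empai"}``.
    normalized : bool
        Whether per-run total-sum normalisation has been applied.
    run_denominator : pandas.Series
        Per-run denominator of the raw index (total SI for SIN, total
        SpC/L for NSAF; all-1 for emPAI).  Needed to recompute a single
        protein's abundance consistently, e.g. during imputation.
    norm_factor : pandas.Series
        Per-run factor applied by :func:`normalize_matrix` (1.0 when
        unnormalised).
    proteins : pandas.DataFrame
        Per-protein metadata (gene, protein_length,
        n_observable_peptides) indexed by protein_id.
    """

    values: pd.DataFrame
    design: SampleDesign
    method: str
    normalized: bool = False
    run_denominator: pd.Series | None = None
    norm_factor: pd.Series | None = None
    proteins: pd.DataFrame | None = None

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown quant method {self.method!r}")
        if self.values.size:
            with np.errstate(invalid="ignore"):
                if (self.values.to_numpy() < 0).any():
                    raise ValueError("abundance values must be non-negative")
        if self.norm_factor is None:
            self.norm_factor = pd.Series(1.0, index=self.values.columns)

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def run_ids(self) -> list[str]:
        return list(self.values.columns)

    def copy(self) -> "QuantMatrix":
        return replace(
            self,
            values=self.values.copy(),
            norm_factor=None if self.norm_factor is None
            else self.norm_factor.copy(),
        )


# ---------------------------------------------------------------------------
# target-decoy filtering
# ---------------------------------------------------------------------------

def filter_protein_fdr(
    evidence: pd.DataFrame,
    threshold: float = 0.01,
    *,
    plus_one: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-run target-decoy filtering of identification evidence.

    Within each run, rows are ranked by ``score`` descending and the
    estimated FDR at rank k is ``(#decoys <= k) / max(1, #targets <= k)``
    (with ``plus_one`` the numerator becomes ``#decoys + 1``, the
    conservative variant).  The retained set is the largest prefix whose
    estimate stays at or below ``threshold``.  Rows whose
    ``passed_fdr_filter`` flag is already False are treated as upstream
    rejections: they never enter the filtered output, only the
    unfiltered list.

    Returns
    -------
    (filtered, unfiltered) : tuple of DataFrames
        ``filtered``: retained target rows (decoys removed).
        ``unfiltered``: every target row regardless of score or flag
        (decoys removed) -- the "unfiltered list" consumed by the
        imputation strategy.
    """
    _check_schema(evidence, ["score", "is_decoy"])
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    _check_schema(evidence, _REQUIRED)

    unfiltered = evidence[~evidence["is_decoy"]].copy()
    pool = evidence[evidence["passed_fdr_filter"]]
    kept_idx: list[np.ndarray] = []
    for _, grp in pool.groupby("run_id", sort=False):
        grp = grp.sort_values(
            ["score", "protein_id"], ascending=[False, True],
            kind="mergesort")
        decoy = grp["is_decoy"].to_numpy()
        cum_d = np.cumsum(decoy) + (1 if plus_one else 0)
        cum_t = np.cumsum(~decoy)
        fdr = cum_d / np.maximum(1, cum_t)
        ok = np.flatnonzero(fdr <= threshold)
        if ok.size == 0:
            continue
        prefix = grp.iloc[: ok[-1] + 1]
        kept_idx.append(prefix.index[~prefix["is_decoy"]].to_numpy())
    if kept_idx:
        filtered = evidence.loc[np.concatenate(kept_idx)].sort_index()
    else:
        filtered = evidence.iloc[0:0].copy()
    return filtered.copy(), unfiltered


# ---------------------------------------------------------------------------
# the three indices (single run)
# ---------------------------------------------------------------------------

def compute_nsaf(run_evidence: pd.DataFrame) -> tuple[pd.Series, float]:
    """NSAF for one run: (SpC/L) / sum(SpC/L) over quantified proteins.

    Proteins with zero spectral count are omitted (missing).  Returns
    the per-protein series and the denominator ``sum(SpC/L)`` used, so
    a single extra protein can later be put on the same scale.
    """
    spc = run_evidence["spectral_count"].to_numpy(float)
    length = run_evidence["protein_length"].to_numpy(float)
    if (length < 1).any():
        raise ValueError("protein_length must be >= 1")
    mask = spc > 0
    if not mask.any():
        warnings.warn("run has no nonzero spectral counts; empty NSAF result")
        return pd.Series(dtype=float), 0.0
    saf = spc[mask] / length[mask]
    denom = saf.sum()
    return pd.Series(
        saf / denom, index=run_evidence["protein_id"].to_numpy()[mask]
    ), float(denom)


def compute_empai(run_evidence: pd.DataFrame) -> tuple[pd.Series, float]:
    """emPAI for one run: 10**(N_observed/N_observable) - 1.

    Proteins with no observed peptides are omitted (missing).  The
    returned denominator is 1.0 (emPAI has no per-run normalisation).
    """
    n_obs = run_evidence["n_observed_peptides"].to_numpy(float)
    n_able = run_evidence["n_observable_peptides"].to_numpy(float)
    if (n_able < 1).any():
        raise ValueError("n_observable_peptides must be >= 1")
    if (n_obs > n_able).any():
        raise ValueError("observed peptides exceed observable peptides")
    mask = n_obs > 0
    vals = 10.0 ** (n_obs[mask] / n_able[mask]) - 1.0
    return pd.Series(
        vals, index=run_evidence["protein_id"].to_numpy()[mask]
    ), 1.0


def compute_sin(run_evidence: pd.DataFrame) -> tuple[pd.Series, float]:
    """Normalised spectral index for one run: (SI / sum SI) / L.

    ``SI`` is the summed peptide intensity carried on the evidence row.
    Zero-intensity proteins are omitted (missing).  Returns the series
    and the run's total intensity (the denominator).
    """
    si = run_evidence["summed_intensity"].to_numpy(float)
    length = run_evidence["protein_length"].to_numpy(float)
    if (si < 0).any():
        raise ValueError("summed_intensity must be >= 0")
    if (length < 1).any():
        raise ValueError("protein_length must be >= 1")
    mask = si > 0
    if not mask.any():
        warnings.warn("run has no nonzero intensities; empty SIN result")
        return pd.Series(dtype=float), 0.0
    denom = si[mask].sum()
    return pd.Series(
        (si[mask] / denom) / length[mask],
        index=run_evidence["protein_id"].to_numpy()[mask],
    ), float(denom)


_INDEX_FN = {"nsaf": compute_nsaf, "empai": compute_empai, "sin": compute_sin}


def raw_index_value(
    method: str, spc: float, si: float, n_obs: float, n_able: float,
    length: float, denominator: float,
) -> float:
    """Index value of one protein given a run's stored denominator."""
    if method == "nsaf":
        return (spc / length) / denominator if denominator > 0 else np.nan
    if method == "sin":
        return (si / denominator) / length if denominator > 0 else np.nan
    if method == "empai":
        return 10.0 ** (n_obs / n_able) - 1.0
    raise ValueError(f"unknown quant method {method!r}")


# ---------------------------------------------------------------------------
# matrix assembly and normalisation
# ---------------------------------------------------------------------------

def build_matrix(
    evidence: pd.DataFrame, design: SampleDesign, method: str = "sin",
) -> QuantMatrix:
    """Assemble a QuantMatrix from (filtered) evidence.

    Each design run becomes a column; proteins absent from a run are
    missing (``NaN``).  Rows are sorted by protein identifier so the
    result is invariant to evidence row order.
    """
    if method not in METHODS:
        raise ValueError(f"unknown quant method {method!r}")
    _check_schema(evidence, _REQUIRED)
    index_fn = _INDEX_FN[method]
    cols, denoms = {}, {}
    by_run = dict(tuple(evidence.groupby("run_id", sort=False)))
    for run_id in design.run_ids:
        grp = by_run.get(run_id)
        if grp is None or not len(grp):
            cols[run_id] = pd.Series(dtype=float)
            denoms[run_id] = 0.0
            continue
        series, denom = index_fn(grp)
        cols[run_id] = series
        denoms[run_id] = denom
    values = pd.DataFrame(cols).sort_index()
    values = values.reindex(columns=design.run_ids)
    values.index.name = "protein_id"
    prot = (
        evidence.drop_duplicates("protein_id")
        .set_index("protein_id")[
            ["gene", "protein_length", "n_observable_peptides"]]
        .reindex(values.index)
    )
    return QuantMatrix(
        values=values,
        design=design,
        method=method,
        normalized=False,
        run_denominator=pd.Series(denoms).reindex(values.columns),
        proteins=prot,
    )


def normalize_matrix(
    matrix: QuantMatrix, target: str = "total",
) -> QuantMatrix:
    """Remove global per-run technical biases by scaling each run.

    With ``target="total"`` (default) each run's non-missing values are
    divided by that run's total and rescaled by the grand mean of run
    totals, so magnitudes stay comparable across methods; with
    ``target="median"`` the per-run median plays the role of the total.
    Missing cells are untouched.  The operation is idempotent to within
    floating-point round-off: re-normalising a normalised matrix leaves
    it numerically unchanged.
    """
    values = matrix.values
    counts = values.notna().sum(axis=0)
    empty = list(counts.index[counts == 0])
    if empty:
        raise ValueError(f"run(s) with no quantified proteins: {empty}")
    if target == "total":
        stat = values.sum(axis=0, skipna=True)
    elif target == "median":
        stat = values.median(axis=0, skipna=True)
    else:
        raise ValueError(f"unknown normalisation target {target!r}")
    if (stat <= 0).any():
        bad = list(stat.index[stat <= 0])
        raise ValueError(f"non-positive normalisation statistic in run(s): {bad}")
    factor = stat.mean() / stat
    out = matrix.copy()
    out.values = values.mul(factor, axis=1)
    out.normalized = True
    out.norm_factor = matrix.norm_factor * factor
    return out


def _check_schema(df: pd.DataFrame, cols) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"evidence table lacks columns: {missing}")
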