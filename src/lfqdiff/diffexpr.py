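"""Paired differential-abundance testing over a QuantMatrix.

Three workflows compare treated against control abundances for every
protein in a completely paired design:

* **A** -- missing values set to zero, classical paired t-test on every
  testable protein, one Benjamini-Hochberg family over all of them.
* **B** -- missing values set to zero, proteins gated by the
  Shapiro-Wilk test into normally distributed (ND) and not normally
  distributed (NND) sets; paired t-test on ND, Kruskal-Wallis on NND,
  each branch corrected for multiple comparisons separately before the
  results are combined.
* **C** -- as B, but missing values are first imputed from the
  unfiltered identification list: if the protein was identified in the
  run below the FDR threshold, its abundance is recomputed from that
  sub-threshold row with the same quantitation method and normalisation
  constants; otherwise the protein is treated as absent and the value
  set to zero.

A protein is *testable* when it is detected (non-missing before any
fill) in at least ``min_condition_detections`` runs of each condition;
proteins detected in only one condition change detection status rather
than fold change, and a finite fold change is undefined for them.
Volcano classification gates on the BH-adjusted q-value
(strictly below ``fdr_level``) together with inclusive fold-change
thresholds (``fc >= fc_up`` or ``fc <= fc_down``).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .quantify import QuantMatrix, raw_index_value

logger = logging.getLogger(__name__)

WORKFLOWS = ("A", "B", "C")

RESULT_COLUMNS = [
    "protein_id", "gene", "workflow", "branch", "fc", "raw_p", "q_bh",
    "detection_class", "volcano_class", "n_detected_control",
    "n_detected_treated",
]


@dataclass(frozen=True)
class WorkflowConfig:
    """Thresholds and switches of a differential-abundance workflow.

    Attributes
    ----------
    workflow : {"A", "B", "C"}
    alpha_sw : float
        Significance level of the Shapiro-Wilk normality gate.
    fdr_level : float
        BH threshold for calling significance (strict: ``q < fdr_level``).
    fc_up, fc_down : float
        Inclusive ratio gates for up-/down-regulation.
    min_condition_detections : int
        Minimum non-missing runs per condition for a protein to be
        testable in that condition.
    sw_target : {"conditions", "differences"}
        Whether the normality gate is applied to each condition's
        abundance vector (both must pass) or to the paired differences.
    """

    workflow: str = "A"
    alpha_sw: float = 0.05
    fdr_level: float = 0.05
    fc_up: float = 2.5
    fc_down: float = 0.4
    min_condition_detections: int = 1
    sw_target: str = "conditions"

    def __post_init__(self):
        if self.workflow not in WORKFLOWS:
            raise ValueError(f"workflow must be one of {WORKFLOWS}")
        if not 0 < self.fdr_level < 1:
            raise ValueError("fdr_level must lie in (0, 1)")
        if not self.fc_down < 1 < self.fc_up:
            raise ValueError("require fc_down < 1 < fc_up")
        if self.sw_target not in ("conditions", "differences"):
            raise ValueError("sw_target must be 'conditions' or 'differences'")
        if self.min_condition_detections < 1:
            raise ValueError("min_condition_detections must be >= 1")


# ---------------------------------------------------------------------------
# elementary tests
# ---------------------------------------------------------------------------

def paired_t(control, treated, pairing=None) -> float:
    """Two-sided classical paired t-test p-value.

    ``pairing``, if given, maps treated index i to control index
    ``pairing[i]`` and must be a bijection.  Zero-variance differences
    (including identical vectors) make the statistic undefined and
    return ``nan``.
    """
    c = np.asarray(control, dtype=float)
    t = np.asarray(treated, dtype=float)
    if pairing is not None:
        pairing = np.asarray(pairing)
        if sorted(pairing) != list(range(len(c))):
            raise ValueError("pairing must be a bijection over indices")
        c = c[pairing]
    if c.shape != t.shape:
        raise ValueError("control and treated must have equal length")
    if len(c) < 2:
        return np.nan
    d = t - c
    if np.ptp(d) == 0:
        logger.debug("paired_t: zero-variance differences, p undefined")
        return np.nan
    return float(scipy.stats.ttest_rel(t, c).pvalue)


def kruskal(control, treated) -> float:
    """Two-group Kruskal-Wallis p-value (tie-corrected, chi2 with 1 df).

    All values tied across both groups returns p = 1 by convention.
    """
    c = np.asarray(control, dtype=float)
    t = np.asarray(treated, dtype=float)
    if len(c) == 0 or len(t) == 0:
        raise ValueError("both groups must be non-empty")
    if np.ptp(np.concatenate([c, t])) == 0:
        logger.debug("kruskal: all values tied, p = 1 by convention")
        return 1.0
    return float(scipy.stats.kruskal(c, t).pvalue)


def bh_adjust(raw_p):
    """Benjamini-Hochberg step-up adjustment.

    ``q_(i) = min_{k >= i} (m * p_(k) / k)`` capped at 1 and mapped back
    to input order, where m counts the *defined* p-values.  ``nan``
    entries are excluded from the family and returned as ``nan``.
    Accepts array-likes or pandas Series (index preserved).
    """
    p = np.asarray(raw_p, dtype=float)
    mask = ~np.isnan(p)
    with np.errstate(invalid="ignore"):
        if (p[mask] < 0).any() or (p[mask] > 1).any():
            raise ValueError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    if mask.any():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    if isinstance(raw_p, pd.Series):
        return pd.Series(q, index=raw_p.index)
    return q


# ---------------------------------------------------------------------------
# fold change, detection, normality gate
# ---------------------------------------------------------------------------

def compute_fold_change(
    matrix: QuantMatrix,
    zero_fill: bool = True,
    min_condition_detections: int = 1,
    *,
    filled: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-protein fold change FC = mean(treated) / mean(control).

    Detection is evaluated on the matrix's missingness pattern *before*
    any fill.  With ``zero_fill`` missing values count as zero in the
    condition means (the zero-fill convention of workflows A/B);
    ``filled`` can supply a pre-filled value table instead (workflow C).
    FC is undefined (``nan``) when the protein is not detected in both
    conditions or the control mean is zero.

    Returns a DataFrame indexed by protein with columns
    ``n_detected_control``, ``n_detected_treated``, ``detection_class``,
    ``fc``.
    """
    design = matrix.design
    if "condition" not in design.runs.columns:
        raise ValueError("design lacks condition metadata")
    ctrl_ids, trt_ids = design.paired_run_ids()
    values = matrix.values
    n_c = values[ctrl_ids].notna().sum(axis=1)
    n_t = values[trt_ids].notna().sum(axis=1)
    m = int(min_condition_detections)
    detection = np.select(
        [
            (n_c >= m) & (n_t >= m),
            (n_t >= m) & (n_c < m),
            (n_c >= m) & (n_t < m),
        ],
        ["both", "treated_only", "control_only"],
        default="neither",
    )
    if filled is None:
        filled = values.fillna(0.0) if zero_fill else values
    mean_c = filled[ctrl_ids].mean(axis=1)
    mean_t = filled[trt_ids].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(mean_c > 0, mean_t / mean_c, np.nan)
    fc = np.where(detection == "both", fc, np.nan)
    return pd.DataFrame(
        {
            "n_detected_control": n_c,
            "n_detected_treated": n_t,
            "detection_class": detection,
            "fc": fc,
        },
        index=values.index,
    )


def normality_partition(
    filled: pd.DataFrame,
    design,
    alpha_sw: float = 0.05,
    sw_target: str = "conditions",
) -> pd.Series:
    """Gate each protein into the ND or NND branch via Shapiro-Wilk.

    With ``sw_target="conditions"`` a protein is ND iff *both* its
    control and treated abundance vectors (after the workflow's fill
    policy) pass the Shapiro-Wilk test at ``alpha_sw``; with
    ``"differences"`` the test is applied to the paired differences.
    Constant vectors and vectors shorter than 3 are routed to NND (the
    statistic is undefined there).
    """
    ctrl_ids, trt_ids = design.paired_run_ids()
    C = filled[ctrl_ids].to_numpy(float)
    T = filled[trt_ids].to_numpy(float)
    if sw_target == "differences":
        vector_sets = [T - C]
    elif sw_target == "conditions":
        vector_sets = [C, T]
    else:
        raise ValueError("sw_target must be 'conditions' or 'differences'")
    nd = np.ones(len(filled), dtype=bool)
    for vecs in vector_sets:
        for i in range(vecs.shape[0]):
            if not nd[i]:
                continue
            v = vecs[i]
            if len(v) < 3 or np.ptp(v) == 0:
                nd[i] = False
                logger.debug(
                    "protein %s routed to NND (degenerate vector)",
                    filled.index[i])
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if scipy.stats.shapiro(v).pvalue < alpha_sw:
                    nd[i] = False
    return pd.Series(np.where(nd, "ND", "NND"), index=filled.index)


# ---------------------------------------------------------------------------
# imputation from the unfiltered list
# ---------------------------------------------------------------------------

def impute_missing(
    matrix: QuantMatrix, unfiltered: pd.DataFrame,
) -> QuantMatrix:
    """Fill missing cells from sub-threshold identifications.

    For each missing cell, if the protein has a row for that run in the
    unfiltered identification list, its abundance is recomputed from
    that row with the matrix's quantitation method and the stored
    per-run normalisation constants, and the cell is filled with the
    result; otherwise the protein is treated as below the detection
    limit and the cell is filled with zero.

    Returns a new QuantMatrix without missing values; a matrix that has
    none to begin with is returned unchanged (copy).
    """
    values = matrix.values
    arr = values.to_numpy(float).copy()
    nan_mask = np.isnan(arr)
    if not nan_mask.any():
        return matrix.copy()
    if matrix.run_denominator is None:
        raise ValueError(
            "matrix lacks per-run quantitation denominators; cannot "
            "recompute abundances with matching constants")
    needed = ["protein_id", "run_id", "spectral_count", "summed_intensity",
              "n_observed_peptides", "n_observable_peptides",
              "protein_length"]
    missing_cols = [c for c in needed if c not in unfiltered.columns]
    if missing_cols:
        raise ValueError(f"unfiltered list lacks columns: {missing_cols}")

    ii, jj = np.nonzero(nan_mask)
    cells = pd.DataFrame({
        "protein_id": values.index.to_numpy()[ii],
        "run_id": values.columns.to_numpy()[jj],
    })
    unf = unfiltered[needed].drop_duplicates(["protein_id", "run_id"])
    hit = cells.merge(unf, on=["protein_id", "run_id"], how="left")

    denom = hit["run_id"].map(matrix.run_denominator).to_numpy(float)
    factor = hit["run_id"].map(matrix.norm_factor).to_numpy(float)
    spc = hit["spectral_count"].to_numpy(float)
    si = hit["summed_intensity"].to_numpy(float)
    n_obs = hit["n_observed_peptides"].to_numpy(float)
    n_able = hit["n_observable_peptides"].to_numpy(float)
    length = hit["protein_length"].to_numpy(float)

    found = ~np.isnan(spc) & (spc > 0)
    fill = np.zeros(len(hit))
    if found.any():
        with np.errstate(divide="ignore", invalid="ignore"):
            raw = np.array([
                raw_index_value(
                    matrix.method, spc[k], si[k], n_obs[k], n_able[k],
                    length[k], denom[k])
                for k in np.flatnonzero(found)
            ])
        raw = np.nan_to_num(raw, nan=0.0)
        fill[np.flatnonzero(found)] = raw * factor[np.flatnonzero(found)]
    arr[ii, jj] = fill
    out = matrix.copy()
    out.values = pd.DataFrame(arr, index=values.index, columns=values.columns)
    return out


# ---------------------------------------------------------------------------
# workflows
# ---------------------------------------------------------------------------

def run_workflow(
    matrix: QuantMatrix,
    unfiltered: pd.DataFrame | None = None,
    config: WorkflowConfig | None = None,
) -> pd.DataFrame:
    """Run one differential-abundance workflow end to end.

    Returns a result table (one row per protein, columns
    ``RESULT_COLUMNS``) with fold change, branch assignment, raw and
    BH-adjusted p-values, detection class and volcano class.
    """
    config = config or WorkflowConfig()
    wf = config.workflow
    if wf == "C":
        if unfiltered is None:
            raise ValueError(
                "workflow C requires the unfiltered identification list")
        imputed = impute_missing(matrix, unfiltered)
        filled = imputed.values
    else:
        filled = matrix.values.fillna(0.0)

    fcdet = compute_fold_change(
        matrix, zero_fill=True,
        min_condition_detections=config.min_condition_detections,
        filled=filled,
    )
    ctrl_ids, trt_ids = matrix.design.paired_run_ids()
    C = filled[ctrl_ids].to_numpy(float)
    T = filled[trt_ids].to_numpy(float)

    n = len(filled)
    testable = (fcdet["detection_class"] == "both").to_numpy()
    branch = np.array(["none"] * n, dtype=object)
    raw_p = np.full(n, np.nan)

    if wf == "A":
        idx = np.flatnonzero(testable)
        raw_p[idx] = _paired_t_rows(C[idx], T[idx])
        q = bh_adjust(raw_p)
    else:
        part = normality_partition(
            filled, matrix.design, config.alpha_sw, config.sw_target)
        branch[testable] = part.to_numpy()[testable]
        nd_idx = np.flatnonzero(testable & (branch == "ND"))
        nnd_idx = np.flatnonzero(testable & (branch == "NND"))
        raw_p[nd_idx] = _paired_t_rows(C[nd_idx], T[nd_idx])
        for i in nnd_idx:
            raw_p[i] = kruskal(C[i], T[i])
        # one BH family per branch, combined afterwards
        q = np.full(n, np.nan)
        for idx in (nd_idx, nnd_idx):
            if idx.size:
                q[idx] = bh_adjust(raw_p[idx])

    results = pd.DataFrame({
        "protein_id": filled.index,
        "gene": (
            matrix.proteins["gene"].reindex(filled.index).to_numpy()
            if matrix.proteins is not None else filled.index
        ),
        "workflow": wf,
        "branch": branch,
        "fc": fcdet["fc"].to_numpy(),
        "raw_p": raw_p,
        "q_bh": np.asarray(q, dtype=float),
        "detection_class": fcdet["detection_class"].to_numpy(),
        "n_detected_control": fcdet["n_detected_control"].to_numpy(),
        "n_detected_treated": fcdet["n_detected_treated"].to_numpy(),
    })
    results = classify_volcano(results, config)
    return results[RESULT_COLUMNS].reset_index(drop=True)


def _paired_t_rows(C: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Row-wise paired t p-values; zero-variance rows are undefined."""
    if len(C) == 0:
        return np.zeros(0)
    d = T - C
    degenerate = np.ptp(d, axis=1) == 0
    p = np.full(len(C), np.nan)
    ok = ~degenerate
    if ok.any():
        with np.errstate(divide="ignore", invalid="ignore"):
            p[ok] = scipy.stats.ttest_rel(T[ok], C[ok], axis=1).pvalue
    return p


def classify_volcano(
    results: pd.DataFrame, config: WorkflowConfig | None = None,
) -> pd.DataFrame:
    """Assign each protein to one volcano/detection class.

    ``up``/``down`` require detection in both conditions, BH q strictly
    below the FDR level and fold change at or beyond the inclusive
    gates.  Proteins detected in one condition only are
    ``status_change``; both-detected proteins whose test statistic is
    undefined (or detected in neither condition at the required depth)
    are ``untestable``; everything else is ``not_significant``.  The
    classes partition the proteins.
    """
    config = config or WorkflowConfig()
    res = results.copy()
    q = res["q_bh"].to_numpy(float)
    fc = res["fc"].to_numpy(float)
    det = res["detection_class"].to_numpy()
    cls = np.array(["not_significant"] * len(res), dtype=object)
    with np.errstate(invalid="ignore"):
        sig = q < config.fdr_level
        cls[sig & (fc >= config.fc_up)] = "up"
        cls[sig & (fc <= config.fc_down)] = "down"
    cls[np.isin(det, ["treated_only", "control_only"])] = "status_change"
    cls[det == "neither"] = "untestable"
    cls[(det == "both") & np.isnan(q)] = "untestable"
    res["volcano_class"] = cls
    return res


def volcano_table(results: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready coordinates: log10 fold change vs -log2 raw p-value."""
    out = results[["protein_id", "gene", "fc", "raw_p", "q_bh",
                   "volcano_class"]].copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        out["log10_fc"] = np.log10(out["fc"].to_numpy(float))
        out["neg_log2_p"] = -np.log2(out["raw_p"].to_numpy(float))
    return out
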