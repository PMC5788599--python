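"""statsmodels-style model/results interface to the workflows.

``DifferentialAbundance`` is constructed from a quant matrix (or raw
evidence via :meth:`DifferentialAbundance.from_evidence`); ``fit()``
runs the configured workflow and returns a
``DifferentialAbundanceResults`` carrying the per-protein estimates,
class counts and a ``summary()`` table, with volcano plotting attached.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .design import SampleDesign
from .diffexpr import (WorkflowConfig, classify_volcano, run_workflow,
                       volcano_table)
from .quantify import QuantMatrix, build_matrix, filter_protein_fdr, \
    normalize_matrix
from .report import build_report, format_report


class DifferentialAbundance:
    """Paired differential-abundance model over a protein x run matrix.

    Parameters
    ----------
    matrix : QuantMatrix
        Normalised abundance matrix with explicit missing values.
    unfiltered : pandas.DataFrame, optional
        Unfiltered identification list; required for workflow C.
    config : WorkflowConfig, optional
        Workflow choice and thresholds (defaults: workflow A,
        Shapiro-Wilk alpha 0.05, BH level 0.05, fold-change gates
        2.5 / 0.4).
    """

    def __init__(
        self,
        matrix: QuantMatrix,
        unfiltered: pd.DataFrame | None = None,
        config: WorkflowConfig | None = None,
    ):
        self.matrix = matrix
        self.unfiltered = unfiltered
        self.config = config or WorkflowConfig()

    @classmethod
    def from_evidence(
        cls,
        evidence: pd.DataFrame,
        design: SampleDesign,
        method: str = "sin",
        fdr_threshold: float = 0.01,
        normalize: bool = True,
        config: WorkflowConfig | None = None,
    ) -> "DifferentialAbundance":
        """Build the model from raw evidence: filter, quantify, normalise."""
        filtered, unfiltered = filter_protein_fdr(evidence, fdr_threshold)
        matrix = build_matrix(filtered, design, method)
        if normalize:
            matrix = normalize_matrix(matrix)
        return cls(matrix, unfiltered=unfiltered, config=config)

    def fit(self, workflow: str | None = None) -> "DifferentialAbundanceResults":
        """Run the configured workflow (optionally overridden) and return
        the results object."""
        config = self.config
        if workflow is not None:
            config = replace(config, workflow=workflow)
        frame = run_workflow(self.matrix, self.unfiltered, config)
        return DifferentialAbundanceResults(self, frame, config)


class DifferentialAbundanceResults:
    """Per-protein differential-abundance estimates and their classes."""

    def __init__(self, model: DifferentialAbundance, frame: pd.DataFrame,
                 config: WorkflowConfig):
        self.model = model
        self.frame = frame
        self.config = config

    @property
    def class_counts(self) -> pd.Series:
        return self.frame["volcano_class"].value_counts()

    def significant(self) -> pd.DataFrame:
        """Proteins called up- or down-regulated."""
        return self.frame[self.frame["volcano_class"].isin(["up", "down"])]

    def volcano_table(self) -> pd.DataFrame:
        return volcano_table(self.frame)

    def report(self, truth: pd.DataFrame | None = None) -> dict:
        return build_report({self.config.workflow: self.frame}, truth)

    def summary(self, truth: pd.DataFrame | None = None) -> str:
        """Human-readable summary of the fit."""
        cfg = self.config
        head = (
            f"Differential abundance, workflow {cfg.workflow} "
            f"({self.model.matrix.method.upper()} quantitation)\n"
            f"q < {cfg.fdr_level}, FC gates >= {cfg.fc_up} / <= {cfg.fc_down}, "
            f"Shapiro-Wilk alpha = {cfg.alpha_sw}\n"
        )
        return head + format_report(self.report(truth))

    def plot_volcano(self, ax=None):
        """Volcano plot: log10 FC vs -log2 raw p, calls highlighted."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        vt = self.volcano_table().dropna(subset=["log10_fc", "neg_log2_p"])
        colors = {"up": "tab:green", "down": "tab:red"}
        base = vt[~vt["volcano_class"].isin(colors)]
        ax.scatter(base["log10_fc"], base["neg_log2_p"], s=6, c="0.6",
                   label="not significant")
        for cls, col in colors.items():
            sub = vt[vt["volcano_class"] == cls]
            if len(sub):
                ax.scatter(sub["log10_fc"], sub["neg_log2_p"], s=10, c=col,
                           label=cls)
        ax.axvline(np.log10(self.config.fc_up), ls="--", lw=0.8, c="k")
        ax.axvline(np.log10(self.config.fc_down), ls="--", lw=0.8, c="k")
        ax.set_xlabel(r"$\log_{10}$ FC (treated / control)")
        ax.set_ylabel(r"$-\log_2$ p-value")
        ax.legend(fontsize=7)
        return ax

    def to_tsv(self, path) -> None:
        from .io import write_results

        write_results(self.frame, path)
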