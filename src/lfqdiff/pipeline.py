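"""End-to-end synthetic studies: simulate, quantify, test, score.

Convenience layer used by the benchmarks, the acceptance checks and the
command line: one call generates a paired synthetic experiment with
known ground truth, pushes it through filtering/quantitation and the
requested workflows, and returns everything needed to score the calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .design import SampleDesign, generate_design
from .diffexpr import WorkflowConfig
from .model import DifferentialAbundance
from .quantify import QuantMatrix
from .report import build_report
from .simulate import draw_truth, simulate_evidence


@dataclass
class StudyResult:
    """Everything produced by one synthetic study."""

    truth: pd.DataFrame
    design: SampleDesign
    evidence: pd.DataFrame
    matrix: QuantMatrix
    unfiltered: pd.DataFrame
    results: dict  # workflow -> result frame
    report: dict


def run_synthetic_study(
    seed: int,
    n_proteins: int = 2000,
    frac_up: float = 0.05,
    frac_down: float = 0.02,
    frac_contaminated: float = 0.5,
    fc_law=("lognormal", 4.0, 0.25),
    n_bio: int = 2,
    n_tech: int = 5,
    noise_cv: float = 0.2,
    dropout_below_limit_prob: float = 0.0,
    dropout_filter_prob: float = 0.0,
    method: str = "sin",
    fdr_threshold: float = 0.01,
    workflows=("A",),
    config: WorkflowConfig | None = None,
    label: str = "synthetic",
) -> StudyResult:
    """Simulate one paired study and run the requested workflows on it."""
    design = generate_design(n_bio, n_tech, label)
    truth = draw_truth(
        n_proteins,
        frac_up=frac_up,
        frac_down=frac_down,
        frac_contaminated=frac_contaminated,
        fc_law=fc_law,
        seed=seed,
        dropout_below_limit_prob=dropout_below_limit_prob,
        dropout_filter_prob=dropout_filter_prob,
    )
    evidence = simulate_evidence(truth, design, noise_cv=noise_cv, seed=seed)
    model = DifferentialAbundance.from_evidence(
        evidence, design, method=method, fdr_threshold=fdr_threshold,
        config=config,
    )
    results = {wf: model.fit(workflow=wf).frame for wf in workflows}
    return StudyResult(
        truth=truth,
        design=design,
        evidence=evidence,
        matrix=model.matrix,
        unfiltered=model.unfiltered,
        results=results,
        report=build_report(results, truth),
    )
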