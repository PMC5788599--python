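"""Synthetic protein-level evidence for paired label-free experiments.

This module generates protein identification/quantitation evidence with
the statistical structure the downstream analysis assumes, so every
stage of the pipeline can be exercised against a known ground truth:

* a completely paired control/treated replicate design;
* a mixture of well-behaved ("normal") and heavy-tailed ("contaminated")
  protein abundance distributions, emulating data of which roughly half
  fails a Shapiro-Wilk normality check;
* true responder proteins whose treated-condition abundance is shifted
  by a known fold change;
* reversed-sequence-style decoy proteins whose identification scores are
  drawn from the same null law as badly identified targets, so the
  target-decoy FDR filter is a meaningful stage;
* two distinct missingness mechanisms: (1) *below-limit* dropout, where
  the evidence row is absent entirely, and (2) *filter* dropout, where
  the row exists but fails identification filtering and is therefore
  visible only in the unfiltered list.

Randomness is organised as one sub-stream per protein, derived by stable
hashing of ``(seed, protein_id)``: regenerating with more proteins never
perturbs the rows of existing proteins, and identical inputs reproduce
byte-identical tables.
"""

from __future__ import annotations

import hashlib

import numpy as np
import pandas as pd

from .design import CONTROL, TREATED, SampleDesign

#: Columns of the evidence table, in on-disk order.
EVIDENCE_COLUMNS = [
    "protein_id", "gene", "run_id", "condition", "bio_rep", "tech_rep",
    "spectral_count", "summed_intensity", "n_observed_peptides", "score",
    "passed_fdr_filter", "is_decoy", "protein_length",
    "n_observable_peptides",
]

TRUTH_COLUMNS = [
    "protein_id", "gene_symbol", "is_decoy", "responder_class", "true_fc",
    "base_abundance", "distribution_family", "protein_length",
    "n_observable_peptides", "dropout_below_limit_prob",
    "dropout_filter_prob", "irg_flag",
]


def substream(seed: int, *tokens) -> np.random.Generator:
    """Independent RNG derived by stable hashing of (seed, tokens).

    The hash keeps derived seeds below 2**31 so they remain portable.
    """
    key = "|".join([str(int(seed)), *map(str, tokens)])
    digest = hashlib.blake2b(key.encode(), digest_size=8).digest()
    return np.random.default_rng(int.from_bytes(digest, "little") % (2**31))


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def draw_truth(
    n_proteins: int,
    frac_up: float = 0.05,
    frac_down: float = 0.02,
    frac_contaminated: float = 0.5,
    fc_law=("lognormal", 4.0, 0.25),
    n_decoys: int | None = None,
    seed: int = 0,
    *,
    irg_frac_responders: float = 0.6,
    irg_frac_background: float = 0.02,
    dropout_below_limit_prob: float = 0.0,
    dropout_filter_prob: float = 0.0,
    base_abundance_median: float = 100.0,
    base_abundance_sigma: float = 0.7,
    decoy_abundance_median: float = 5.0,
    length_range: tuple[int, int] = (100, 1000),
) -> pd.DataFrame:
    """Draw the per-protein ground-truth table.

    Parameters
    ----------
    n_proteins : int
        Number of target proteins.
    frac_up, frac_down : float
        Fractions of targets that are true up-/down-responders; exactly
        ``round(frac * n)`` of each are generated.
    frac_contaminated : float
        Fraction of targets whose abundance law is the heavy-tailed
        contaminated-normal mixture (default 0.5, i.e. about half the
        proteins fail a normality check).
    fc_law : tuple or float
        Fold-change law for responders.  ``("fixed", v)`` or a bare
        float gives every up-responder fold change ``v``;
        ``("lognormal", median, sigma_log)`` draws log-normal effects.
        Down-responders use the reciprocal law.  Up fold changes are
        floored at 1.25 (down capped at 0.8) so responder classes stay
        unambiguous.
    n_decoys : int, optional
        Number of decoy entries appended (default: same as targets).
    irg_frac_responders, irg_frac_background : float
        Probability that an up-responder (resp. any other target) is
        flagged as the product of an interferon-regulated gene.
    dropout_below_limit_prob, dropout_filter_prob : float
        Per-cell probabilities of the two missingness mechanisms,
        applied uniformly to all targets.

    Returns
    -------
    pandas.DataFrame
        One row per protein (targets then decoys), columns
        ``TRUTH_COLUMNS``.  Deterministic for fixed arguments.
    """
    if n_proteins < 0:
        raise ValueError("n_proteins must be >= 0")
    for name, f in [("frac_up", frac_up), ("frac_down", frac_down),
                    ("frac_contaminated", frac_contaminated)]:
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {f}")
    if frac_up + frac_down > 1.0:
        raise ValueError("frac_up + frac_down must not exceed 1")
    for name, p in [("dropout_below_limit_prob", dropout_below_limit_prob),
                    ("dropout_filter_prob", dropout_filter_prob)]:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {p}")
    if n_decoys is None:
        n_decoys = n_proteins
    if n_decoys < 0:
        raise ValueError("n_decoys must be >= 0")

    rng = substream(seed, "truth")
    n = int(n_proteins)
    n_up = round(frac_up * n)
    n_down = round(frac_down * n)

    responder = np.array(["null"] * n, dtype=object)
    responder[:n_up] = "up"
    responder[n_up:n_up + n_down] = "down"

    true_fc = np.ones(n)
    true_fc[:n_up] = _draw_fold_changes(fc_law, n_up, rng)
    true_fc[n_up:n_up + n_down] = 1.0 / _draw_fold_changes(
        fc_law, n_down, rng)

    n_contam = round(frac_contaminated * n)
    family = np.array(["normal"] * n, dtype=object)
    # spread contaminated proteins across responder classes deterministically
    contam_idx = rng.permutation(n)[:n_contam]
    family[contam_idx] = "contaminated"

    base = base_abundance_median * np.exp(
        base_abundance_sigma * rng.standard_normal(n))
    length = rng.integers(length_range[0], length_range[1] + 1, size=n)
    observable = np.maximum(1, np.rint(
        length / 25.0 + rng.normal(0, 2, size=n)).astype(int))

    irg = np.where(
        responder == "up",
        rng.random(n) < irg_frac_responders,
        rng.random(n) < irg_frac_background,
    )

    targets = pd.DataFrame({
        "protein_id": [f"P{i:05d}" for i in range(n)],
        "gene_symbol": [f"GENE{i}" for i in range(n)],
        "is_decoy": False,
        "responder_class": responder,
        "true_fc": true_fc,
        "base_abundance": base,
        "distribution_family": family,
        "protein_length": length,
        "n_observable_peptides": observable,
        "dropout_below_limit_prob": dropout_below_limit_prob,
        "dropout_filter_prob": dropout_filter_prob,
        "irg_flag": irg,
    })

    m = int(n_decoys)
    drng = substream(seed, "decoys")
    dlength = drng.integers(length_range[0], length_range[1] + 1, size=m)
    decoys = pd.DataFrame({
        "protein_id": [f"DECOY_P{i:05d}" for i in range(m)],
        "gene_symbol": [f"DECOY_GENE{i}" for i in range(m)],
        "is_decoy": True,
        "responder_class": "null",
        "true_fc": 1.0,
        "base_abundance": decoy_abundance_median * np.exp(
            0.5 * drng.standard_normal(m)),
        "distribution_family": "normal",
        "protein_length": dlength,
        "n_observable_peptides": np.maximum(
            1, np.rint(dlength / 25.0).astype(int)),
        "dropout_below_limit_prob": 0.0,
        "dropout_filter_prob": 0.0,
        "irg_flag": False,
    })

    out = pd.concat([targets, decoys], ignore_index=True)
    return out[TRUTH_COLUMNS]


def _draw_fold_changes(fc_law, size: int, rng: np.random.Generator):
    """Draw ``size`` up-direction fold changes (> 1) from ``fc_law``."""
    if size == 0:
        return np.ones(0)
    if isinstance(fc_law, (int, float)):
        fc_law = ("fixed", float(fc_law))
    kind = fc_law[0]
    if kind == "fixed":
        return np.full(size, float(fc_law[1]))
    if kind == "lognormal":
        median, sigma = float(fc_law[1]), float(fc_law[2])
        draws = median * np.exp(sigma * rng.standard_normal(size))
        return np.maximum(draws, 1.25)
    raise ValueError(f"unknown fold-change law {fc_law!r}")


# ---------------------------------------------------------------------------
# evidence
# ---------------------------------------------------------------------------

def simulate_evidence(
    truth: pd.DataFrame,
    design: SampleDesign,
    noise_cv: float = 0.2,
    seed: int = 0,
    *,
    contam_weight: float = 0.2,
    contam_scale: float = 5.0,
    spc_per_unit: float = 4e-4,
    intensity_per_unit: float = 1000.0,
    run_effect_sd: float = 0.1,
    target_score_loc: float = 6.0,
    null_score_loc: float = 0.0,
    score_scale: float = 1.0,
    decoy_detect_prob: float = 0.3,
) -> pd.DataFrame:
    """Simulate per-(protein, run) identification/quantitation evidence.

    The expected abundance of a protein is ``base_abundance`` in control
    runs and ``base_abundance * true_fc`` in treated runs.  Normal-family
    proteins draw run abundances from Normal(mu, (cv*mu)^2) truncated at
    zero; contaminated-family proteins from the mixture
    ``(1-w)*Normal(mu, (cv*mu)^2) + w*Normal(mu, (contam_scale*cv*mu)^2)``.
    Spectral counts are Poisson with mean proportional to
    ``abundance * protein_length``; summed intensity is proportional to
    abundance.  Each run carries a log-normal global efficiency factor
    (``run_effect_sd`` on the log scale) applied to both channels, which
    per-run normalisation is expected to remove.

    Missingness: rows are absent entirely with probability
    ``dropout_below_limit_prob`` (below detection limit) and present but
    failing identification filtering (``passed_fdr_filter = False``,
    score drawn from the null law) with probability
    ``dropout_filter_prob``.  Decoy proteins appear in a run with
    probability ``decoy_detect_prob`` and always score from the null law.

    Returns a DataFrame with columns ``EVIDENCE_COLUMNS``; only rows
    with at least one assigned spectrum are emitted.
    """
    if len(truth) == 0 or design.n_runs == 0:
        raise ValueError("truth table and design must be non-empty")
    if noise_cv <= 0:
        raise ValueError("noise_cv must be > 0")
    missing_cols = [c for c in TRUTH_COLUMNS if c not in truth.columns]
    if missing_cols:
        raise ValueError(f"truth table lacks columns: {missing_cols}")

    runs = design.runs.reset_index(drop=True)
    n_runs = len(runs)
    treated = (runs["condition"] == TREATED).to_numpy()
    run_eff = np.exp(
        run_effect_sd * substream(seed, "run-effects").standard_normal(n_runs)
    ) if run_effect_sd > 0 else np.ones(n_runs)

    chunks: list[dict] = []
    for prot in truth.itertuples(index=False):
        rng = substream(seed, prot.protein_id)
        mu = float(prot.base_abundance) * np.where(
            treated, float(prot.true_fc), 1.0)

        sd = noise_cv * mu
        if prot.distribution_family == "contaminated":
            wide = rng.random(n_runs) < contam_weight
            sd = np.where(wide, contam_scale * sd, sd)
        abundance = _truncated_normal(mu, sd, rng)

        if prot.is_decoy:
            present = rng.random(n_runs) < decoy_detect_prob
            spc = np.where(present, 1 + rng.poisson(0.5, n_runs), 0)
            score = null_score_loc + score_scale * rng.standard_normal(n_runs)
            passed = np.ones(n_runs, dtype=bool)
        else:
            lam = abundance * float(prot.protein_length) * spc_per_unit
            spc = rng.poisson(lam * run_eff)
            drop_below = rng.random(n_runs) < float(
                prot.dropout_below_limit_prob)
            spc = np.where(drop_below, 0, spc)
            drop_filter = rng.random(n_runs) < float(
                prot.dropout_filter_prob)
            score = np.where(
                drop_filter,
                null_score_loc + score_scale * rng.standard_normal(n_runs),
                target_score_loc + score_scale * rng.standard_normal(n_runs),
            )
            passed = ~drop_filter

        keep = spc > 0
        if not keep.any():
            continue

        n_observable = int(prot.n_observable_peptides)
        p_obs = 1.0 - np.exp(-spc / max(1.0, float(n_observable)))
        n_obs = rng.binomial(n_observable, np.clip(p_obs, 0.0, 1.0))
        n_obs = np.minimum(np.maximum(n_obs, 1), np.minimum(spc, n_observable))
        intensity = np.where(
            keep, abundance * intensity_per_unit * run_eff, 0.0)

        idx = np.flatnonzero(keep)
        chunks.append({
            "protein_id": np.repeat(prot.protein_id, idx.size),
            "gene": np.repeat(prot.gene_symbol, idx.size),
            "run_id": runs["run_id"].to_numpy()[idx],
            "condition": runs["condition"].to_numpy()[idx],
            "bio_rep": runs["bio_rep"].to_numpy()[idx],
            "tech_rep": runs["tech_rep"].to_numpy()[idx],
            "spectral_count": spc[idx].astype(int),
            "summed_intensity": intensity[idx],
            "n_observed_peptides": n_obs[idx].astype(int),
            "score": score[idx],
            "passed_fdr_filter": passed[idx],
            "is_decoy": np.repeat(bool(prot.is_decoy), idx.size),
            "protein_length": np.repeat(int(prot.protein_length), idx.size),
            "n_observable_peptides": np.repeat(n_observable, idx.size),
        })

    if not chunks:
        return pd.DataFrame(columns=EVIDENCE_COLUMNS)
    data = {
        col: np.concatenate([c[col] for c in chunks])
        for col in EVIDENCE_COLUMNS
    }
    return pd.DataFrame(data)


def _truncated_normal(mu, sd, rng, max_redraws: int = 6):
    """Normal draws truncated at zero by redraw (clip as last resort)."""
    x = rng.normal(mu, sd)
    for _ in range(max_redraws):
        neg = x < 0
        if not np.any(neg):
            break
        x = np.where(neg, rng.normal(mu, sd), x)
    return np.clip(x, 0.0, None)
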