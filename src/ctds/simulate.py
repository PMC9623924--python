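"""Ground-truth simulation of proteomes and search results.

The simulator is the desk-scale stand-in for benchmarking the two FDR
estimators against a known truth.  Its generative model for one spectrum:

* with probability ``1 − frac_incorrect`` the best (rank-1) match is
  correct: it is a target, drawn from the reference part of the target
  database (flipped to entrapment with probability ``entrap_frac``), and
  its score comes from the high-scoring component ``Normal(mu1, sigma1)``;
* otherwise the best match is incorrect: its candidate counts
  ``(target_i, decoy_i)`` are drawn as ``1 + Poisson(λ)`` with separate
  rates for the two databases, the match is labelled target with
  probability ``P(t_i) = target_i/(target_i+decoy_i)`` (decoy otherwise),
  and its score comes from ``Normal(mu0, sigma0)``.  Incorrect targets are
  classed as entrapment matches, which is what an entrapment experiment
  observes.

Correct matches also receive drawn candidate counts (a correct match still
has a candidate list).  Sub-ranks 2..n_ranks are always incorrect and are
generated the same way, so the rank-5 correction factor is exercisable.

Everything is reproducible from (config, seed): the same configuration and
seed give byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import fdr as _fdr
from .constants import SWISSPROT_AA_FREQS
from .digest import ProteinRecord


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the simulated search.

    Candidate-count rates default to ``λ_t = λ_d = 40``: the resulting
    P(t_i) distribution concentrates near 0.5 with a heavy-tailed minority
    and has an exactly-0.5 fraction of about 1/(2·√(πλ)) ≈ 4.5%, matching
    the qualitative shape reported for real protein-level searches.
    """

    n_spectra: int = 50_000
    frac_incorrect: float = 0.3
    lambda_target: float = 40.0
    lambda_decoy: float = 40.0
    mu_correct: float = 4.0
    sigma_correct: float = 1.0
    mu_incorrect: float = 0.0
    sigma_incorrect: float = 1.0
    entrap_frac: float = 0.0
    n_ranks: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.frac_incorrect <= 1:
            raise ValueError("frac_incorrect must be in [0, 1]")
        if self.lambda_target <= 0 or self.lambda_decoy <= 0:
            raise ValueError("candidate-count rates must be positive")
        if self.sigma_correct <= 0 or self.sigma_incorrect <= 0:
            raise ValueError("score standard deviations must be positive")
        if self.n_ranks < 1:
            raise ValueError("n_ranks must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimTruth:
    """Per-spectrum ground truth of a simulated search."""

    table: pd.DataFrame  # spectrum_id, correct, target_count, decoy_count, label

    def true_fdp(self, accepted_target_ids: Sequence[str]) -> float:
        """True false-discovery proportion among an accepted set of target ids."""
        ids = list(accepted_target_ids)
        if not ids:
            return float("nan")
        sub = self.table.set_index("spectrum_id").loc[ids]
        return float((~sub["correct"]).mean())


def simulate_proteome(
    n_proteins: int,
    mean_length: int,
    aa_freqs: Mapping[str, float] | None = None,
    seed: int = 0,
) -> list[ProteinRecord]:
    """Generate i.i.d. random proteins.

    Lengths are ``1 + Poisson(mean_length − 1)``; residues are drawn from
    *aa_freqs* (default: average database amino-acid frequencies).
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    if mean_length < 10:
        raise ValueError("mean_length must be >= 10")
    aa_freqs = dict(aa_freqs or SWISSPROT_AA_FREQS)
    letters = np.array(sorted(aa_freqs))
    probs = np.array([aa_freqs[aa] for aa in letters])
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    lengths = 1 + rng.poisson(mean_length - 1, size=n_proteins)
    records = []
    for i, L in enumerate(lengths):
        seq = "".join(rng.choice(letters, size=int(L), p=probs))
        records.append(ProteinRecord(f"SIM{i:05d}", "simulated protein", seq, "target"))
    return records


def simulate_search(config: SimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Draw a simulated PSM table and its ground truth from *config*."""
    rng = np.random.default_rng(config.seed)
    n = config.n_spectra
    ids = np.array([f"S{i:06d}" for i in range(n)])

    correct = rng.random(n) >= config.frac_incorrect
    t_counts = 1 + rng.poisson(config.lambda_target, size=n)
    d_counts = 1 + rng.poisson(config.lambda_decoy, size=n)
    p_target = t_counts / (t_counts + d_counts)
    # correct matches are targets by construction; incorrect ones follow P(t_i)
    is_target = np.where(correct, True, rng.random(n) < p_target)
    score = np.where(
        correct,
        rng.normal(config.mu_correct, config.sigma_correct, size=n),
        rng.normal(config.mu_incorrect, config.sigma_incorrect, size=n),
    )
    entrap_flip = rng.random(n) < config.entrap_frac
    ref_class = np.select(
        [~is_target, correct & ~entrap_flip],
        ["", "reference"],
        default="entrapment",
    )
    label = np.where(is_target, "target", "decoy")
    truth = np.where(correct, "correct", "incorrect")

    frames = [
        pd.DataFrame(
            {
                "spectrum_id": ids,
                "rank": 1,
                "peptide": "PEPTIDE",
                "score": score,
                "label": label,
                "ref_class": ref_class,
                "target_count": t_counts,
                "decoy_count": d_counts,
                "truth": truth,
            }
        )
    ]

    n_sub = config.n_ranks - 1
    if n_sub > 0:
        sub_t = 1 + rng.poisson(config.lambda_target, size=(n, n_sub))
        sub_d = 1 + rng.poisson(config.lambda_decoy, size=(n, n_sub))
        sub_p = sub_t / (sub_t + sub_d)
        sub_target = rng.random((n, n_sub)) < sub_p
        sub_score = rng.normal(config.mu_incorrect, config.sigma_incorrect, size=(n, n_sub))
        order = np.argsort(-sub_score, axis=1)  # rank 2 = best sub-rank score
        rows = np.arange(n)[:, None]
        sub_t, sub_d = sub_t[rows, order], sub_d[rows, order]
        sub_target, sub_score = sub_target[rows, order], sub_score[rows, order]
        frames.append(
            pd.DataFrame(
                {
                    "spectrum_id": np.repeat(ids, n_sub),
                    "rank": np.tile(np.arange(2, config.n_ranks + 1), n),
                    "peptide": "PEPTIDE",
                    "score": sub_score.ravel(),
                    "label": np.where(sub_target.ravel(), "target", "decoy"),
                    "ref_class": "",
                    "target_count": sub_t.ravel(),
                    "decoy_count": sub_d.ravel(),
                    "truth": "incorrect",
                }
            )
        )

    psms = pd.concat(frames, ignore_index=True)
    truth_table = pd.DataFrame(
        {
            "spectrum_id": ids,
            "correct": correct,
            "target_count": t_counts,
            "decoy_count": d_counts,
            "label": label,
        }
    )
    return psms, SimTruth(truth_table)


def evaluate_estimators(
    psms: pd.DataFrame,
    truth: SimTruth,
    alphas: Sequence[float] = tuple(np.round(np.arange(0.01, 0.105, 0.01), 3)),
    factor_rank: int = 5,
) -> pd.DataFrame:
    """Score each estimator against the ground truth at several FDR thresholds.

    For every alpha and method (``tds``, ``tds_corrected``, ``ctds``):
    accepted target count, estimated FDR at the chosen cutoff (the q-value
    of the accepted prefix), the true false-discovery proportion among the
    accepted targets, the simulated-entrapment FMR when available, and the
    absolute calibration error |estimate − true FDP|.
    """
    rank1 = psms[psms["rank"] == 1]
    plain = _fdr.fdr_curve(rank1)
    try:
        factor = _fdr.correction_factor(psms, rank=factor_rank)
        corrected = _fdr.fdr_curve(rank1, factor=factor)
    except ValueError:
        factor, corrected = None, None

    truth_idx = truth.table.set_index("spectrum_id")["correct"]
    has_ref = "ref_class" in rank1.columns
    ref_idx = rank1.set_index("spectrum_id")["ref_class"] if has_ref else None

    rows = []
    for alpha in alphas:
        for method, curve, qcol in (
            ("tds", plain, "q_tds"),
            ("tds_corrected", corrected, "q_tds"),
            ("ctds", plain, "q_ctds"),
        ):
            if curve is None:
                continue
            acc = _fdr.accepted_psms(curve, alpha, method="tds" if qcol == "q_tds" else "ctds")
            acc_targets = acc[acc["label"] == "target"]
            n_acc = len(acc_targets)
            estimate = float(acc[qcol].iloc[-1]) if len(acc) else float("nan")
            if n_acc:
                fdp = float((~truth_idx.loc[acc_targets["spectrum_id"]]).mean())
            else:
                fdp = float("nan")
            fmr_val = float("nan")
            if has_ref and n_acc:
                classes = ref_idx.loc[acc_targets["spectrum_id"]]
                n_ref = int((classes == "reference").sum())
                if n_ref:
                    fmr_val = int((classes == "entrapment").sum()) / n_ref
            rows.append(
                {
                    "alpha": alpha,
                    "method": method,
                    "factor": factor if method == "tds_corrected" else 1.0,
                    "n_accepted": n_acc,
                    "fdr_estimate": estimate,
                    "true_fdp": fdp,
                    "fmr": fmr_val,
                    "abs_error": abs(estimate - fdp) if n_acc else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def replicate_comparison(
    config: SimConfig,
    n_reps: int = 20,
    alphas: Sequence[float] = tuple(np.round(np.arange(0.01, 0.105, 0.01), 3)),
    base_seed: int = 0,
) -> pd.DataFrame:
    """Run *n_reps* independent simulations and pool the evaluations.

    Replicate seeds are drawn from a generator seeded with *base_seed*, so
    the whole experiment is reproducible from one integer.
    """
    seed_rng = np.random.default_rng(base_seed)
    seeds = seed_rng.integers(0, 2**31 - 1, size=n_reps)
    tables = []
    for rep, seed in enumerate(seeds):
        cfg = replace(config, seed=int(seed))
        psms, truth = simulate_search(cfg)
        ev = evaluate_estimators(psms, truth, alphas=alphas)
        ev.insert(0, "replicate", rep)
        tables.append(ev)
    return pd.concat(tables, ignore_index=True)


def summarize_comparison(report: pd.DataFrame) -> pd.DataFrame:
    """Mean absolute calibration error and FMR gap per method over replicates."""
    out = report.copy()
    out["fmr_gap"] = (out["fmr"] - out["alpha"]).abs()
    return (
        out.groupby("method")
        .agg(
            mean_abs_error=("abs_error", "mean"),
            mean_fmr_gap=("fmr_gap", "mean"),
            mean_accepted=("n_accepted", "mean"),
        )
        .reset_index()
    )
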