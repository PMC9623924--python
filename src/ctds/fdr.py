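"""FDR estimation: classical target-decoy (TDS) and candidate-weighted (cTDS).

Classical TDS estimates the false discovery rate of the target PSMs
accepted above a score cutoff as

    FDR_TDS = (D + 1) / T            (optionally × factor)

where ``T`` and ``D`` are the numbers of target and decoy PSMs above the
cutoff and ``factor`` corrects for unequal target/decoy database sizes
(estimated as the ratio of target to decoy PSMs at a low rank, by default
rank 5).  TDS assumes an incorrect match is equally likely to land on a
target or a decoy candidate.  When the per-spectrum candidate counts are
known, that assumption can be dropped: an incorrect match on spectrum i
lands on a target with probability P(t_i) = target_i/(target_i+decoy_i),
and the candidate-weighted estimator

    FDR_cTDS = Σ_{i ∈ D} 1/P(d_i)  /  Σ_{i ∈ T} 1/P(t_i)

replaces each hit with the geometric expectation of draws needed to produce
it, so no external correction factor is required.

PSM tables are pandas DataFrames with columns ``spectrum_id, rank, peptide,
score, label`` and optionally ``ref_class, target_count, decoy_count,
truth``.  Only rank-1 PSMs enter FDR curves; lower ranks serve the
correction factor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PSM_COLUMNS = ["spectrum_id", "rank", "peptide", "score", "label"]
OPTIONAL_COLUMNS = ["ref_class", "target_count", "decoy_count", "truth"]


@dataclass(frozen=True)
class PSMRecord:
    """One peptide-spectrum match (row schema of the PSM tables)."""

    spectrum_id: str
    rank: int
    peptide: str
    score: float
    label: str  # target | decoy
    ref_class: str | None = None  # reference | entrapment (targets only)
    target_count: int | None = None
    decoy_count: int | None = None
    truth: str | None = None  # correct | incorrect (simulation only)


def psms_to_frame(psms: Sequence[PSMRecord]) -> pd.DataFrame:
    df = pd.DataFrame([vars(p) for p in psms])
    return df if not df.empty else pd.DataFrame(columns=PSM_COLUMNS + OPTIONAL_COLUMNS)


# ---------------------------------------------------------------------------
# Point estimators


def tds_fdr(T: int, D: int) -> float:
    """(D + 1) / T — classical target-decoy FDR with the +1 convention."""
    if T < 1:
        raise ValueError("FDR undefined: no target PSMs above the cutoff")
    return (D + 1) / T


def tds_fdr_corrected(T: int, D: int, factor: float) -> float:
    """((D + 1) / T) × factor for unequal database sizes."""
    if factor <= 0:
        raise ValueError("correction factor must be positive")
    return tds_fdr(T, D) * factor


def correction_factor(psms: pd.DataFrame, rank: int = 5) -> float:
    """Database-size correction factor: #target / #decoy PSMs at *rank*."""
    at_rank = psms[psms["rank"] == rank]
    n_target = int((at_rank["label"] == "target").sum())
    n_decoy = int((at_rank["label"] == "decoy").sum())
    if n_decoy == 0:
        raise ValueError(
            f"no decoy PSMs at rank {rank}; correction factor undefined "
            "(try a different rank)"
        )
    return n_target / n_decoy


def _weights(psms: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Per-PSM cTDS weights (w_target for target rows, w_decoy for decoy rows).

    Rows whose required probability is undefined (zero total candidates, or
    a label whose own count is 0 — which violates the label invariant) get
    NaN and are excluded from the sums by the callers, with a logged count.
    """
    t = psms["target_count"].to_numpy(dtype=float)
    d = psms["decoy_count"].to_numpy(dtype=float)
    total = t + d
    is_target = (psms["label"] == "target").to_numpy()
    own = np.where(is_target, t, d)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(own > 0, total / own, np.nan)
    return w, is_target


def ctds_fdr(psms: pd.DataFrame) -> float:
    """Candidate-weighted FDR of a PSM set (no score sweep).

    Requires ``target_count``/``decoy_count`` on every row.  Rows with
    undefined probabilities are excluded and counted in a log message.
    """
    if psms.empty or not (psms["label"] == "target").any():
        raise ValueError("FDR undefined: no target PSMs")
    w, is_target = _weights(psms)
    bad = np.isnan(w)
    if bad.any():
        logger.info("excluded %d PSMs with undefined candidate probabilities", int(bad.sum()))
    num = np.nansum(np.where(~is_target, w, 0.0))
    den = np.nansum(np.where(is_target, w, 0.0))
    if den == 0:
        raise ValueError("FDR undefined: no target PSMs with defined P(t_i)")
    return float(num / den)


# ---------------------------------------------------------------------------
# Score sweep


@dataclass
class FDRCurve:
    """Score-ordered cumulative TDS/cTDS estimates and q-values.

    ``table`` has one row per rank-1 PSM, sorted by descending score (ties:
    decoy before target, then spectrum_id), with columns ``score, label,
    cum_targets, cum_decoys, fdr_tds, fdr_ctds, q_tds, q_ctds``.  FDR values
    are uncapped; q-values (the running minimum FDR over all cutoffs at
    least as permissive) are capped at 1.
    """

    table: pd.DataFrame
    factor: float = 1.0
    n_excluded: int = 0

    def __len__(self) -> int:
        return len(self.table)


def fdr_curve(
    psms: pd.DataFrame,
    factor: float = 1.0,
    plus_one: str = "as-paper",
) -> FDRCurve:
    """Sweep the score axis and estimate TDS and cTDS FDR at every cutoff.

    Only rank-1 PSMs are used.  ``plus_one`` controls the pseudocount
    convention: ``"as-paper"`` adds 1 decoy to the TDS numerator only (the
    printed forms of both estimators), ``"none"`` to neither, ``"both"`` to
    both numerators.
    """
    if plus_one not in ("as-paper", "none", "both"):
        raise ValueError("plus_one must be 'as-paper', 'none' or 'both'")
    if factor <= 0:
        raise ValueError("factor must be positive")
    df = psms[psms["rank"] == 1].copy()
    if df.empty:
        raise ValueError("no rank-1 PSMs")
    if df["spectrum_id"].duplicated().any():
        raise ValueError("multiple rank-1 PSMs for the same spectrum")

    df["_is_target"] = (df["label"] == "target").astype(int)
    # ties: decoy before target (conservative), then spectrum_id for determinism
    df = df.sort_values(
        ["score", "_is_target", "spectrum_id"], ascending=[False, True, True], kind="stable"
    ).reset_index(drop=True)

    is_target = df["_is_target"].to_numpy(dtype=bool)
    cum_t = np.cumsum(is_target)
    cum_d = np.cumsum(~is_target)

    tds_add = 1.0 if plus_one in ("as-paper", "both") else 0.0
    ctds_add = 1.0 if plus_one == "both" else 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr_tds = np.where(cum_t > 0, (cum_d + tds_add) / np.maximum(cum_t, 1) * factor, np.inf)

    n_excluded = 0
    if {"target_count", "decoy_count"} <= set(df.columns) and df["target_count"].notna().all():
        w, _ = _weights(df)
        bad = np.isnan(w)
        n_excluded = int(bad.sum())
        if n_excluded:
            logger.info("cTDS sums exclude %d PSMs with undefined probabilities", n_excluded)
        w = np.where(bad, 0.0, w)
        cum_wt = np.cumsum(np.where(is_target, w, 0.0))
        cum_wd = np.cumsum(np.where(~is_target, w, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            fdr_ctds = np.where(cum_wt > 0, (cum_wd + ctds_add) / np.maximum(cum_wt, 1e-300), np.inf)
    else:
        fdr_ctds = np.full(len(df), np.nan)

    table = pd.DataFrame(
        {
            "spectrum_id": df["spectrum_id"],
            "score": df["score"],
            "label": df["label"],
            "cum_targets": cum_t,
            "cum_decoys": cum_d,
            "fdr_tds": fdr_tds,
            "fdr_ctds": fdr_ctds,
            "q_tds": _qvalues(fdr_tds),
            "q_ctds": _qvalues(fdr_ctds),
        }
    )
    return FDRCurve(table, factor=factor, n_excluded=n_excluded)


def _qvalues(fdr: np.ndarray) -> np.ndarray:
    """Running minimum from the most permissive cutoff upward, capped at 1."""
    q = np.minimum.accumulate(fdr[::-1])[::-1]
    return np.minimum(q, 1.0)


def accept_at(curve: FDRCurve, alpha: float, method: str = "ctds") -> tuple[float, int]:
    """Largest score cutoff whose q-value is ≤ *alpha*.

    Returns ``(score_cutoff, n_accepted_targets)``; ``(nan, 0)`` when no
    prefix qualifies.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if method not in ("tds", "ctds"):
        raise ValueError("method must be 'tds' or 'ctds'")
    q = curve.table[f"q_{method}"].to_numpy()
    ok = np.nonzero(q <= alpha)[0]
    if ok.size == 0:
        return float("nan"), 0
    last = int(ok[-1])
    return float(curve.table["score"].iloc[last]), int(curve.table["cum_targets"].iloc[last])


def accepted_psms(curve: FDRCurve, alpha: float, method: str = "ctds") -> pd.DataFrame:
    """Rows of the curve table accepted at q ≤ *alpha* (targets and decoys)."""
    q = curve.table[f"q_{method}"].to_numpy()
    ok = np.nonzero(q <= alpha)[0]
    if ok.size == 0:
        return curve.table.iloc[0:0]
    return curve.table.iloc[: int(ok[-1]) + 1]


def fmr(accepted: pd.DataFrame) -> float:
    """False match rate: entrapment / reference among accepted *target* PSMs.

    In an entrapment experiment the target database is a reference database
    (peptides known to be present) plus an entrapment database (known to be
    absent), so accepted targets matching the entrapment part approximate
    false positives.
    """
    targets = accepted[accepted["label"] == "target"]
    if "ref_class" not in targets.columns:
        raise ValueError("accepted PSMs carry no ref_class annotation")
    n_entrap = int((targets["ref_class"] == "entrapment").sum())
    n_refer = int((targets["ref_class"] == "reference").sum())
    if n_refer == 0:
        raise ValueError("FMR undefined: no reference PSMs accepted")
    return n_entrap / n_refer


def p_distribution_summary(psms: pd.DataFrame, factor: float | None = None) -> pd.DataFrame:
    """Fractions of PSMs with P(t_i) below / exactly at / above 0.5.

    Computed separately for target- and decoy-labelled PSMs.  Equality is
    exact rational equality (``target_count == decoy_count``, or
    ``target_count == decoy_count × factor`` when a correction factor is
    applied to the decoy counts).
    """
    rows = []
    f = 1.0 if factor is None else float(factor)
    for label in ("target", "decoy"):
        sub = psms[psms["label"] == label]
        n = len(sub)
        if n == 0:
            rows.append({"label": label, "n": 0, "frac_below": np.nan,
                         "frac_exact": np.nan, "frac_above": np.nan})
            continue
        t = sub["target_count"].to_numpy(dtype=float)
        d = sub["decoy_count"].to_numpy(dtype=float) * f
        rows.append(
            {
                "label": label,
                "n": n,
                "frac_below": float((t < d).sum()) / n,
                "frac_exact": float((t == d).sum()) / n,
                "frac_above": float((t > d).sum()) / n,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O


def read_psms_tsv(
    path: str | Path,
    decoy_prefix: str | None = None,
    protein_column: str = "protein",
) -> pd.DataFrame:
    """Read a PSM table from TSV.

    If ``label`` is absent and *decoy_prefix* is given, the label is derived
    from *protein_column* by the accession-prefix rule.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        dtype={"spectrum_id": str, "ref_class": str, "truth": str},
        low_memory=False,
    )
    if "label" not in df.columns:
        if decoy_prefix is None or protein_column not in df.columns:
            raise ValueError("PSM table lacks a 'label' column and no decoy prefix/protein column given")
        df["label"] = np.where(
            df[protein_column].astype(str).str.startswith(decoy_prefix), "decoy", "target"
        )
    missing = set(PSM_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"PSM table missing columns: {sorted(missing)}")
    return df


def write_psms_tsv(psms: pd.DataFrame, path: str | Path, comments: Sequence[str] = ()) -> None:
    with Path(path).open("w") as out:
        for line in comments:
            out.write(f"# {line}\n")
        psms.to_csv(out, sep="\t", index=False)
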