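"""Precursor-mass candidate counting.

For each spectrum the search engine scores every *candidate peptide* whose
neutral monoisotopic mass lies within the precursor tolerance of the
spectrum's neutral mass.  The per-spectrum counts of target and decoy
candidates, ``target_i`` and ``decoy_i``, define the probability that an
incorrect match lands on a target peptide,

    P(t_i) = target_i / (target_i + decoy_i),

and symmetrically ``P(d_i)`` for decoys.  The reciprocals ``1/P(t_i)`` and
``1/P(d_i)`` — the expectations of the geometric number of draws until a
target (resp. decoy) candidate is hit — are the weights of the
candidate-aware FDR estimator in :mod:`ctds.fdr`.

Candidates are counted as distinct (peptide sequence, modification-variant)
pairs, deduplicated across parent proteins within each of target/decoy.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import PROTON_MASS
from .digest import PeptideEntry

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpectrumQuery:
    """Spectrum identifier with neutral (uncharged) monoisotopic mass in Da."""

    spectrum_id: str
    neutral_mass: float
    charge: int = 2

    def __post_init__(self) -> None:
        if not self.neutral_mass > 0:
            raise ValueError(f"neutral_mass must be positive ({self.spectrum_id})")


@dataclass(frozen=True)
class CandidateCounts:
    """Per-spectrum candidate counts and the derived probabilities."""

    spectrum_id: str
    target_count: int
    decoy_count: int

    @property
    def total(self) -> int:
        return self.target_count + self.decoy_count

    @property
    def p_target(self) -> float:
        """P(t_i); NaN when the spectrum has no candidates at all."""
        if self.total == 0:
            return math.nan
        return self.target_count / self.total

    @property
    def p_decoy(self) -> float:
        if self.total == 0:
            return math.nan
        return self.decoy_count / self.total

    @property
    def w_target(self) -> float:
        """E(X_i) = 1/P(t_i), the geometric expectation; defined when P(t_i) > 0."""
        p = self.p_target
        return 1.0 / p if p > 0 else math.nan

    @property
    def w_decoy(self) -> float:
        p = self.p_decoy
        return 1.0 / p if p > 0 else math.nan


def corrected_p_target(counts: CandidateCounts, factor: float) -> float:
    """P(t_i) after scaling the decoy count by a database-size correction factor.

    Returns ``target / (target + decoy * factor)``; equals ``p_target`` at
    ``factor = 1``.  Raises on a spectrum with no candidates.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    if counts.total == 0:
        raise ValueError(f"no candidates for {counts.spectrum_id}; probability undefined")
    return counts.target_count / (counts.target_count + counts.decoy_count * factor)


class MassIndex:
    """Sorted index over all (mass variant, origin) pairs of a peptide set.

    One entry per modification variant per distinct (sequence, origin)
    peptide.  Range queries are O(log n + hits) via binary search on the
    sorted mass array with a prefix-sum split by origin.
    """

    def __init__(self, peptides: Sequence[PeptideEntry]):
        if not peptides:
            raise ValueError("empty peptide set")
        masses: list[float] = []
        is_target: list[bool] = []
        for pep in peptides:
            if not pep.masses:
                raise ValueError(f"peptide {pep.sequence!r} carries no mass")
            for m in pep.masses:
                masses.append(m)
                is_target.append(pep.origin != "decoy")
        order = np.argsort(masses, kind="stable")
        self.masses = np.asarray(masses, dtype=float)[order]
        self.is_target = np.asarray(is_target, dtype=bool)[order]
        # prefix[i] = number of target entries among the first i
        self._target_prefix = np.concatenate([[0], np.cumsum(self.is_target)])

    def __len__(self) -> int:
        return self.masses.size

    def range_counts(self, lo: float, hi: float) -> tuple[int, int]:
        """(target, decoy) entry counts with mass in the closed interval [lo, hi]."""
        i = int(np.searchsorted(self.masses, lo, side="left"))
        j = int(np.searchsorted(self.masses, hi, side="right"))
        n_target = int(self._target_prefix[j] - self._target_prefix[i])
        return n_target, (j - i) - n_target


def build_mass_index(peptides: Sequence[PeptideEntry]) -> MassIndex:
    """Build a :class:`MassIndex` over digested target+decoy peptides."""
    return MassIndex(peptides)


def count_candidates(
    index: MassIndex, query: SpectrumQuery, tol_ppm: float = 20.0
) -> CandidateCounts:
    """Count target/decoy candidates within ±(mass · tol_ppm · 1e-6) of the query."""
    if not tol_ppm > 0:
        raise ValueError("tol_ppm must be positive")
    tol = query.neutral_mass * tol_ppm * 1e-6
    t, d = index.range_counts(query.neutral_mass - tol, query.neutral_mass + tol)
    return CandidateCounts(query.spectrum_id, t, d)


def count_candidates_batch(
    index: MassIndex, queries: Iterable[SpectrumQuery], tol_ppm: float = 20.0
) -> pd.DataFrame:
    """Candidate counts for many spectra as a tidy table."""
    rows = []
    n_empty = 0
    for q in queries:
        c = count_candidates(index, q, tol_ppm)
        if c.total == 0:
            n_empty += 1
        rows.append(
            {
                "spectrum_id": c.spectrum_id,
                "target_count": c.target_count,
                "decoy_count": c.decoy_count,
                "p_target": c.p_target,
            }
        )
    if n_empty:
        logger.info("%d spectra have zero candidates within tolerance", n_empty)
    return pd.DataFrame(rows, columns=["spectrum_id", "target_count", "decoy_count", "p_target"])


def annotate_psms(
    psms: pd.DataFrame, counts: Mapping[str, CandidateCounts] | pd.DataFrame
) -> pd.DataFrame:
    """Attach candidate counts to a PSM table.

    Counts already embedded in the PSM table take precedence; disagreements
    with the computed counts are logged.  PSMs with neither embedded nor
    computable counts raise an error listing the spectrum ids.
    """
    if isinstance(counts, pd.DataFrame):
        counts = {
            r.spectrum_id: CandidateCounts(r.spectrum_id, int(r.target_count), int(r.decoy_count))
            for r in counts.itertuples()
        }
    out = psms.copy()
    if "target_count" not in out.columns:
        out["target_count"] = np.nan
    if "decoy_count" not in out.columns:
        out["decoy_count"] = np.nan

    have = out["target_count"].notna() & out["decoy_count"].notna()
    n_conflicts = 0
    for sid in out.loc[have, "spectrum_id"].unique():
        c = counts.get(sid)
        if c is None:
            continue
        row = out.loc[(out["spectrum_id"] == sid) & have].iloc[0]
        if (int(row["target_count"]), int(row["decoy_count"])) != (c.target_count, c.decoy_count):
            n_conflicts += 1
    if n_conflicts:
        logger.warning(
            "%d spectra carry embedded candidate counts differing from computed ones "
            "(embedded kept)",
            n_conflicts,
        )

    missing_mask = ~have
    if missing_mask.any():
        sids = out.loc[missing_mask, "spectrum_id"]
        unknown = sorted(set(sids) - set(counts))
        if unknown:
            raise ValueError(f"no candidate counts available for spectra: {unknown}")
        out.loc[missing_mask, "target_count"] = [counts[s].target_count for s in sids]
        out.loc[missing_mask, "decoy_count"] = [counts[s].decoy_count for s in sids]
    out["target_count"] = out["target_count"].astype(int)
    out["decoy_count"] = out["decoy_count"].astype(int)
    return out


# ---------------------------------------------------------------------------
# Readers


def read_spectra_tsv(path: str | Path) -> list[SpectrumQuery]:
    """Read a spectrum list: TSV with columns spectrum_id, neutral_mass, charge."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"spectrum_id", "neutral_mass"}
    if not required <= set(df.columns):
        raise ValueError(f"spectrum list must have columns {sorted(required)}")
    charges = df["charge"] if "charge" in df.columns else [2] * len(df)
    return [
        SpectrumQuery(str(s), float(m), int(z))
        for s, m, z in zip(df["spectrum_id"], df["neutral_mass"], charges)
    ]


def read_mgf_precursors(path: str | Path) -> list[SpectrumQuery]:
    """Extract precursor neutral masses from an MGF file.

    Neutral mass = PEPMASS·charge − charge·(proton mass).  Peak lists are
    ignored; only the precursor lines are used.
    """
    from pyteomics import mgf

    queries = []
    with mgf.MGF(str(path)) as reader:
        for i, spec in enumerate(reader):
            params = spec["params"]
            mz = float(params["pepmass"][0])
            charge = int(params.get("charge", [2])[0])
            sid = str(params.get("title", f"index={i}"))
            queries.append(SpectrumQuery(sid, mz * charge - charge * PROTON_MASS, charge))
    return queries


def write_counts_tsv(counts: pd.DataFrame, path: str | Path, comments: Sequence[str] = ()) -> None:
    """Write a candidate-count table with an optional ``#`` comment block."""
    with Path(path).open("w") as out:
        for line in comments:
            out.write(f"# {line}\n")
        counts.to_csv(out, sep="\t", index=False)
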