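"""FASTA handling and in-silico tryptic digestion.

This module supplies peptides (with monoisotopic mass variants for the
configured modifications) to decoy generation and precursor-mass candidate
counting.  Digestion is fully tryptic: cleavage C-terminal to K or R, by
default not when the next residue is proline, matching the default trypsin
rule of common search engines.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from pyteomics import fasta as _pyt_fasta

from .constants import (
    CARBAMIDOMETHYL,
    NONSTANDARD_AA,
    OXIDATION,
    RESIDUE_MASS,
    STANDARD_AA,
    WATER_MASS,
)

logger = logging.getLogger(__name__)

#: Default fixed modifications: carbamidomethylation of cysteine.
DEFAULT_FIXED_MODS: dict[str, float] = {"C": CARBAMIDOMETHYL}
#: Default variable modifications: oxidation of methionine.
DEFAULT_VARIABLE_MODS: dict[str, float] = {"M": OXIDATION}


@dataclass(frozen=True)
class ProteinRecord:
    """One FASTA entry with decoy/entrapment provenance.

    ``origin`` is ``"decoy"`` exactly when the accession starts with the
    decoy prefix used when reading or generating the database; entrapment
    proteins are targets known to be absent from the sample.
    """

    accession: str
    description: str
    sequence: str
    origin: str = "target"  # target | decoy | entrapment

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.accession!r}")
        if self.origin not in ("target", "decoy", "entrapment"):
            raise ValueError(f"unknown origin {self.origin!r}")


@dataclass
class PeptideEntry:
    """A digested peptide with its modification-variant masses.

    ``masses`` holds one neutral monoisotopic mass per variable-modification
    combination (sorted ascending, lowest = fixed modifications only).
    """

    sequence: str
    missed_cleavages: int
    masses: tuple[float, ...]
    origin: str
    parent_accessions: frozenset[str] = field(default_factory=frozenset)


def read_fasta(
    path: str | Path,
    decoy_prefix: str = "DECOY_",
    entrapment_prefix: str | None = None,
) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects.

    The accession is the header token before the first whitespace; sequences
    are upper-cased.  Origin is assigned from the accession prefix: decoy if
    it starts with *decoy_prefix*, entrapment if it starts with
    *entrapment_prefix* (when given), otherwise target.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    with path.open() as handle:
        for lineno, (header, sequence) in enumerate(_iter_fasta(handle), 1):
            accession, _, description = header.partition(" ")
            if accession.startswith(decoy_prefix):
                origin = "decoy"
            elif entrapment_prefix and accession.startswith(entrapment_prefix):
                origin = "entrapment"
            else:
                origin = "target"
            records.append(
                ProteinRecord(accession, description.strip(), sequence.upper(), origin)
            )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def _iter_fasta(handle) -> Iterator[tuple[str, str]]:
    """Yield (header, sequence) pairs, reporting the offending line on error."""
    first = handle.readline()
    if first and not first.startswith(">"):
        raise ValueError("malformed FASTA: line 1 does not start with '>'")
    handle.seek(0)
    for header, sequence in _pyt_fasta.read(handle):
        if not sequence:
            raise ValueError(f"malformed FASTA: entry {header.split()[0]!r} has no sequence")
        yield header, sequence


def write_fasta(
    records: Sequence[ProteinRecord], path: str | Path, line_width: int = 60
) -> None:
    """Write records to *path*, wrapping sequences at *line_width* columns.

    Round-trips with :func:`read_fasta` (accessions and sequences are
    preserved exactly).
    """
    if not records:
        raise ValueError("no records to write")
    if line_width < 1:
        raise ValueError("line_width must be >= 1")
    path = Path(path)
    with path.open("w") as out:
        for rec in records:
            header = rec.accession if not rec.description else f"{rec.accession} {rec.description}"
            out.write(f">{header}\n")
            for i in range(0, len(rec.sequence), line_width):
                out.write(rec.sequence[i : i + line_width] + "\n")


# ---------------------------------------------------------------------------
# Digestion


def cleavage_sites(sequence: str, proline_rule: bool = True) -> list[int]:
    """Positions after which trypsin cleaves (indices into *sequence*).

    A site ``i`` means cleavage between ``sequence[i-1]`` and ``sequence[i]``.
    The protein C-terminus is not reported as a site.
    """
    sites = []
    for i in range(len(sequence) - 1):
        if sequence[i] in "KR" and not (proline_rule and sequence[i + 1] == "P"):
            sites.append(i + 1)
    return sites


def tryptic_digest(
    sequence: str,
    max_missed: int = 2,
    min_length: int | None = None,
    max_length: int | None = None,
    proline_rule: bool = True,
) -> list[tuple[str, int]]:
    """Fully tryptic digestion of *sequence*.

    Returns ``(peptide, missed_cleavages)`` pairs ordered by start position
    then missed-cleavage count.  Peptides outside ``[min_length, max_length]``
    are excluded; either bound may be ``None`` (disabled).
    """
    if not sequence:
        raise ValueError("empty sequence")
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    bounds = [0] + cleavage_sites(sequence, proline_rule) + [len(sequence)]
    out: list[tuple[str, int]] = []
    n_seg = len(bounds) - 1
    for a in range(n_seg):
        for m in range(min(max_missed, n_seg - 1 - a) + 1):
            pep = sequence[bounds[a] : bounds[a + m + 1]]
            if min_length is not None and len(pep) < min_length:
                continue
            if max_length is not None and len(pep) > max_length:
                continue
            out.append((pep, m))
    return out


def peptide_masses(
    sequence: str,
    fixed_mods: Mapping[str, float] | None = None,
    variable_mods: Mapping[str, float] | None = None,
    max_var_mods: int = 3,
) -> list[float]:
    """Neutral monoisotopic masses of *sequence*, one per modification variant.

    The lowest mass carries fixed modifications only; each additional mass
    corresponds to a distinct combination of variable-modification counts,
    with at most *max_var_mods* variable modifications in total.  Raises
    ``KeyError`` naming the residue if one has no defined mass.
    """
    fixed_mods = fixed_mods or {}
    variable_mods = variable_mods or {}
    base = WATER_MASS
    for aa in sequence:
        if aa not in RESIDUE_MASS:
            raise KeyError(f"no monoisotopic mass defined for residue {aa!r}")
        base += RESIDUE_MASS[aa] + fixed_mods.get(aa, 0.0)

    mod_residues = [
        (delta, sequence.count(aa)) for aa, delta in variable_mods.items() if aa in sequence
    ]
    if not mod_residues:
        return [base]
    masses = set()
    ranges = [range(n + 1) for _, n in mod_residues]
    for combo in itertools.product(*ranges):
        if sum(combo) > max_var_mods:
            continue
        masses.add(base + sum(c * delta for c, (delta, _) in zip(combo, mod_residues)))
    return sorted(masses)


@dataclass(frozen=True)
class DigestParams:
    """Digestion settings for database-wide peptide generation."""

    max_missed: int = 2
    min_length: int | None = 7
    max_length: int | None = 50
    proline_rule: bool = True
    fixed_mods: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_FIXED_MODS))
    variable_mods: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_VARIABLE_MODS))
    max_var_mods: int = 3


def digest_records(
    records: Iterable[ProteinRecord], params: DigestParams | None = None
) -> list[PeptideEntry]:
    """Digest a database into unique peptides with mass variants.

    Peptides are deduplicated by (sequence, origin), merging parent
    accessions; peptides containing letters with no defined monoisotopic
    mass are dropped with a logged count.
    """
    params = params or DigestParams()
    by_key: dict[tuple[str, str], PeptideEntry] = {}
    parents: dict[tuple[str, str], set[str]] = {}
    n_skipped = 0
    for rec in records:
        for pep, missed in tryptic_digest(
            rec.sequence,
            params.max_missed,
            params.min_length,
            params.max_length,
            params.proline_rule,
        ):
            key = (pep, rec.origin)
            if key in by_key:
                parents[key].add(rec.accession)
                continue
            if set(pep) & NONSTANDARD_AA:
                n_skipped += 1
                continue
            masses = peptide_masses(
                pep, params.fixed_mods, params.variable_mods, params.max_var_mods
            )
            by_key[key] = PeptideEntry(pep, missed, tuple(masses), rec.origin)
            parents[key] = {rec.accession}
    if n_skipped:
        logger.info("excluded %d peptides containing non-standard letters", n_skipped)
    return [
        PeptideEntry(e.sequence, e.missed_cleavages, e.masses, e.origin, frozenset(parents[k]))
        for k, e in by_key.items()
    ]


def peptides_to_frame(peptides: Sequence[PeptideEntry]) -> pd.DataFrame:
    """Long-format peptide table: one row per (peptide, mass variant)."""
    rows = [
        {
            "peptide": p.sequence,
            "missed_cleavages": p.missed_cleavages,
            "mass": m,
            "origin": p.origin,
            "parents": ";".join(sorted(p.parent_accessions)),
        }
        for p in peptides
        for m in p.masses
    ]
    return pd.DataFrame(rows, columns=["peptide", "missed_cleavages", "mass", "origin", "parents"])
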