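"""Decoy protein database generation.

Five protein-level constructions are provided: reverse, pseudo-reverse,
shuffle, pseudo-shuffle and de Bruijn.  The "pseudo" variants and the
de Bruijn method operate on the segments between tryptic anchors: the
sequence is split so that every K or R terminates a segment and stays at
its original position, and only the residues before each anchor are
rearranged.  This keeps the decoy's tryptic peptide boundaries aligned with
the target's, so target and decoy databases digest into comparable peptide
populations.

All stochastic methods draw from a per-protein random stream derived from
``(seed, accession)``, so regenerating a database with the same seed is
byte-identical and adding or removing proteins does not perturb the decoys
of the others.
"""

from __future__ import annotations

import hashlib
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .constants import STANDARD_AA
from .digest import ProteinRecord

logger = logging.getLogger(__name__)

METHODS = ("reverse", "pseudo_reverse", "shuffle", "pseudo_shuffle", "de_bruijn")


@dataclass(frozen=True)
class DecoyConfig:
    """Settings for decoy database generation.

    ``k`` is the k-mer order of the de Bruijn construction (ignored by the
    other methods).  ``seed`` drives all stochastic methods.
    """

    method: str = "reverse"
    seed: int = 0
    decoy_prefix: str = "DECOY_"
    k: int = 2

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown decoy method {self.method!r}; choose from {METHODS}")
        if self.k < 2:
            raise ValueError("de Bruijn order k must be >= 2")


def _segments(sequence: str) -> list[tuple[str, str]]:
    """Split into (body, anchor) segments; every K/R is an anchor.

    The trailing segment may have an empty anchor (no terminal K/R).  No
    proline exception is applied here: the printed worked examples of the
    pseudo methods are reproduced only under plain K/R segmentation.
    """
    segs: list[tuple[str, str]] = []
    start = 0
    for i, aa in enumerate(sequence):
        if aa in "KR":
            segs.append((sequence[start:i], aa))
            start = i + 1
    if start < len(sequence):
        segs.append((sequence[start:], ""))
    return segs


def reverse_protein(sequence: str) -> str:
    """Character-wise reversal of the whole protein."""
    if not sequence:
        raise ValueError("empty sequence")
    return sequence[::-1]


def pseudo_reverse_protein(sequence: str) -> str:
    """Reverse each segment between tryptic anchors, leaving K/R in place."""
    if not sequence:
        raise ValueError("empty sequence")
    return "".join(body[::-1] + anchor for body, anchor in _segments(sequence))


def shuffle_protein(sequence: str, rng: np.random.Generator) -> str:
    """Uniform random permutation of the whole protein (Fisher–Yates)."""
    if not sequence:
        raise ValueError("empty sequence")
    chars = np.array(list(sequence))
    rng.shuffle(chars)
    return "".join(chars)


def pseudo_shuffle_protein(sequence: str, rng: np.random.Generator) -> str:
    """Independently permute each inter-anchor segment, K/R fixed."""
    if not sequence:
        raise ValueError("empty sequence")
    out = []
    for body, anchor in _segments(sequence):
        if len(body) > 1:
            chars = np.array(list(body))
            rng.shuffle(chars)
            body = "".join(chars)
        out.append(body + anchor)
    return "".join(out)


def _debruijn_walk_segment(
    body: str,
    k: int,
    aa_freqs: Mapping[str, float],
    rng: np.random.Generator,
    max_tries: int = 32,
) -> str | None:
    """Random Eulerian walk on the segment's k-mer multigraph.

    Nodes are (k-1)-mers and each k-mer of the segment contributes one edge
    emitting its last letter; a complete walk from the segment's first
    (k-1)-mer consumes every edge exactly once, so the output preserves the
    segment's length, residue multiset and k-mer multiset.  At branch points
    the next edge is drawn with probability proportional to the database
    amino-acid frequency of the emitted letter.  Returns ``None`` when no
    complete walk is found within *max_tries* restarts.
    """
    n = len(body)
    if n < k:
        return None
    edges: dict[str, list[str]] = defaultdict(list)
    for i in range(n - k + 1):
        edges[body[i : i + k - 1]].append(body[i + k - 1])
    start = body[: k - 1]
    n_edges = n - k + 1
    for _ in range(max_tries):
        avail = {node: list(chars) for node, chars in edges.items()}
        out = list(start)
        node = start
        complete = True
        for _ in range(n_edges):
            choices = avail.get(node)
            if not choices:
                complete = False
                break
            if len(choices) == 1:
                idx = 0
            else:
                w = np.array([aa_freqs.get(c, 1e-12) for c in choices], dtype=float)
                idx = int(rng.choice(len(choices), p=w / w.sum()))
            emitted = choices.pop(idx)
            out.append(emitted)
            node = node[1:] + emitted
        if complete:
            return "".join(out)
    return None


def debruijn_decoy(
    sequence: str,
    aa_freqs: Mapping[str, float],
    k: int = 2,
    rng: np.random.Generator | None = None,
) -> str:
    """De Bruijn decoy: regenerate each inter-anchor segment by a k-mer walk.

    Segments shorter than *k*, or whose graph admits no complete walk within
    the retry budget, fall back to a pseudo-shuffle of that segment (logged
    at debug level).  Anchors and per-segment composition are preserved.
    """
    if not sequence:
        raise ValueError("empty sequence")
    total = sum(aa_freqs.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"aa_freqs must sum to 1 (got {total})")
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = rng if rng is not None else np.random.default_rng()
    out = []
    n_fallback = 0
    for body, anchor in _segments(sequence):
        walked = _debruijn_walk_segment(body, k, aa_freqs, rng)
        if walked is None:
            if len(body) > 1:
                chars = np.array(list(body))
                rng.shuffle(chars)
                walked = "".join(chars)
            else:
                walked = body
            n_fallback += 1
        out.append(walked + anchor)
    if n_fallback:
        logger.debug("de Bruijn fallback to pseudo-shuffle for %d segment(s)", n_fallback)
    return "".join(out)


def database_aa_freqs(records: Sequence[ProteinRecord]) -> dict[str, float]:
    """Empirical amino-acid frequencies pooled over *records* (standard letters)."""
    counts: Counter[str] = Counter()
    for rec in records:
        counts.update(c for c in rec.sequence if c in STANDARD_AA)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no standard residues in database")
    return {aa: c / total for aa, c in sorted(counts.items())}


def _protein_rng(seed: int, accession: str) -> np.random.Generator:
    """Per-protein stream: independent of other proteins in the database."""
    digest = hashlib.sha256(accession.encode()).digest()
    return np.random.default_rng([seed, int.from_bytes(digest[:4], "big")])


def generate_decoy_db(
    records: Sequence[ProteinRecord], config: DecoyConfig
) -> list[ProteinRecord]:
    """Generate one decoy per target record.

    Decoy accessions are ``config.decoy_prefix + accession``; an error is
    raised if that collides with an existing accession.  For the de Bruijn
    method, amino-acid frequencies are pooled over the target records.
    """
    if any(rec.origin == "decoy" for rec in records):
        raise ValueError("input records must all be targets (or entrapment targets)")
    existing = {rec.accession for rec in records}
    aa_freqs = database_aa_freqs(records) if config.method == "de_bruijn" else None
    decoys = []
    for rec in records:
        decoy_acc = config.decoy_prefix + rec.accession
        if decoy_acc in existing:
            raise ValueError(f"decoy accession {decoy_acc!r} collides with an existing record")
        rng = _protein_rng(config.seed, rec.accession)
        if config.method == "reverse":
            seq = reverse_protein(rec.sequence)
        elif config.method == "pseudo_reverse":
            seq = pseudo_reverse_protein(rec.sequence)
        elif config.method == "shuffle":
            seq = shuffle_protein(rec.sequence, rng)
        elif config.method == "pseudo_shuffle":
            seq = pseudo_shuffle_protein(rec.sequence, rng)
        else:
            seq = debruijn_decoy(rec.sequence, aa_freqs, config.k, rng)
        decoys.append(ProteinRecord(decoy_acc, rec.description, seq, "decoy"))
    return decoys
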