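"""Consensus building and per-base error labels.

Error labels are the supervised signal for quality-score training: a base
call is labelled 1 when it matches the consensus reference at its aligned
position and 0 otherwise.  Bases that are unaligned (clipped, inserted,
unmapped) or that map onto a masked ``N`` in the reference are labelled
:data:`~phredlogit.io_formats.MISSING` and excluded from fitting and
evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import MISSING, NUCLEOTIDES, AlignmentLayout, atomic_write

_CODE = {b: k for k, b in enumerate(NUCLEOTIDES)}


@dataclass
class ErrorLabels:
    """Per (read, cycle) correctness indicators.

    ``values`` has shape (n_reads, L); entries are 1 (correct call),
    0 (error) or MISSING (-1, excluded).
    """

    read_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int8)
        ok = np.isin(self.values, (0, 1, MISSING))
        if not ok.all():
            raise ValueError("labels must be 0, 1 or MISSING")

    @property
    def n_reads(self) -> int:
        return len(self.read_ids)

    def flat(self) -> np.ndarray:
        return self.values.ravel()

    def defined_mask(self) -> np.ndarray:
        """Flat boolean mask of bases with a 0/1 label."""
        return self.flat() != MISSING

    def error_rate(self) -> float:
        f = self.flat()
        d = f[f != MISSING]
        if d.size == 0:
            raise ValueError("no labelled bases")
        return float(np.mean(d == 0))


def build_consensus(layout: AlignmentLayout, called_bases) -> str:
    """Most-frequent-nucleotide consensus over the aligned read layout.

    Positions with zero coverage become ``N``.  Pileup ties are broken by
    lexicographic nucleotide order (A<C<G<T), which is what ``argmax``
    yields on the fixed A,C,G,T channel ordering.
    """
    ref_len = layout.reference_length
    counts = np.zeros((ref_len, 4), dtype=np.int64)
    for pos, seq in zip(layout.positions, called_bases, strict=True):
        aligned = pos >= 0
        if not aligned.any():
            continue
        codes = np.array([_CODE[b] for b in seq], dtype=np.int64)
        np.add.at(counts, (pos[aligned], codes[aligned]), 1)
    best = counts.argmax(axis=1)
    cons = np.array(list(NUCLEOTIDES))[best]
    cons[counts.sum(axis=1) == 0] = "N"
    return "".join(cons)


def mask_variants(consensus: str, variant_positions) -> str:
    """Replace the given 0-based positions with ``N``.

    Used to exclude polymorphic sites from error labelling: a base mapped to
    a masked position later receives a MISSING label.
    """
    out = list(consensus)
    for p in variant_positions:
        p = int(p)
        if not 0 <= p < len(out):
            raise IndexError(f"variant position {p} outside consensus of length {len(out)}")
        out[p] = "N"
    return "".join(out)


def label_errors(layout: AlignmentLayout, called_bases, consensus: str) -> ErrorLabels:
    """Compare called bases with the consensus at their mapped positions.

    y = 1 iff the called base equals the consensus base; unaligned bases and
    bases over a consensus ``N`` are MISSING.
    """
    cons = np.frombuffer(consensus.encode(), dtype=np.uint8)
    values = []
    for pos, seq in zip(layout.positions, called_bases, strict=True):
        y = np.full(len(seq), MISSING, dtype=np.int8)
        aligned = pos >= 0
        if aligned.any():
            idx = pos[aligned]
            ref = cons[idx]
            called = np.frombuffer(seq.encode(), dtype=np.uint8)[aligned]
            match = (called == ref).astype(np.int8)
            match[ref == ord("N")] = MISSING
            y[aligned] = match
        values.append(y)
    return ErrorLabels(list(layout.read_ids), np.asarray(values))


def write_labels_tsv(labels: ErrorLabels, path) -> None:
    with atomic_write(path) as fh:
        fh.write("read_id\tcycle\ty\n")
        for rid, row in zip(labels.read_ids, labels.values):
            for c, y in enumerate(row, start=1):
                fh.write(f"{rid}\t{c}\t{y}\n")


def read_labels_tsv(path) -> ErrorLabels:
    df = pd.read_csv(path, sep="\t", dtype={"read_id": str})
    read_ids, rows = [], []
    for rid, grp in df.groupby("read_id", sort=False):
        grp = grp.sort_values("cycle")
        read_ids.append(str(rid))
        rows.append(grp["y"].to_numpy(dtype=np.int8))
    if not read_ids:
        raise ValueError(f"{path}: no records")
    return ErrorLabels(read_ids, np.asarray(rows))
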