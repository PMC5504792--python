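"""Readers and writers for the intensity-table dialect, FASTQ, alignment
layouts and model files.

The intensity dialect is a headered TSV with one row per (read, cycle):

    read_id  cycle  A  C  G  T  called_base

Cycles are 1-based, rows for a read must be contiguous and cycle-sorted,
and every read must have the same number of cycles.  Channel order is fixed
as A, C, G, T everywhere in the package.
"""

from __future__ import annotations

import json
import os
import tempfile
from contextlib import contextmanager
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NUCLEOTIDES = "ACGT"
_NUC_SET = frozenset(NUCLEOTIDES)
#: methods a model file may declare
MODEL_METHODS = ("mle", "be_aic", "be_bic", "l1", "elastic_net")
_MODEL_FORMAT = "phredlogit-model"
_MODEL_VERSION = 1

MISSING = -1  # sentinel for unaligned / masked positions and labels


class IntensityParseError(ValueError):
    """Raised when an intensity table violates the dialect."""


@contextmanager
def atomic_write(path, mode="w"):
    """Write to a temporary file in the target directory, then rename.

    Guarantees the destination is never observed half-written.
    """
    path = os.fspath(path)
    d = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=d, prefix=".tmp-", suffix=os.path.basename(path))
    try:
        with os.fdopen(fd, mode) as fh:
            yield fh
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


@dataclass
class IntensityTile:
    """Per-read, per-cycle four-channel corrected signals plus called bases.

    ``intensities`` has shape (n_reads, L, 4) with channel order A,C,G,T.
    """

    read_ids: list[str]
    intensities: np.ndarray
    called_bases: list[str]
    L: int

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.validate()

    @property
    def n_reads(self) -> int:
        return len(self.read_ids)

    @property
    def n_bases(self) -> int:
        return self.n_reads * self.L

    def validate(self) -> None:
        n = len(self.read_ids)
        if n == 0:
            raise ValueError("tile has no reads")
        if self.intensities.shape != (n, self.L, 4):
            raise ValueError(
                f"intensities shape {self.intensities.shape} != ({n}, {self.L}, 4)"
            )
        if not np.isfinite(self.intensities).all():
            raise ValueError("non-finite intensity values")
        if len(self.called_bases) != n:
            raise ValueError("called_bases length mismatch")
        for i, s in enumerate(self.called_bases):
            if len(s) != self.L:
                raise ValueError(f"read {self.read_ids[i]}: {len(s)} bases != L={self.L}")
            if not _NUC_SET.issuperset(s):
                bad = sorted(set(s) - _NUC_SET)
                raise ValueError(f"read {self.read_ids[i]}: unknown base symbol {bad}")

    def called_codes(self) -> np.ndarray:
        """Called bases as integer codes A=0,C=1,G=2,T=3, shape (n_reads, L)."""
        flat = np.frombuffer("".join(self.called_bases).encode(), dtype=np.uint8)
        codes = np.full(256, -1, np.int8)
        for k, b in enumerate(NUCLEOTIDES):
            codes[ord(b)] = k
        return codes[flat].reshape(self.n_reads, self.L).astype(np.int64)


@dataclass
class AlignmentLayout:
    """Mapping of each called base to a reference coordinate.

    ``positions[i][c]`` is the 0-based reference position of cycle ``c`` of
    read ``i``, or :data:`MISSING` for bases that are soft-clipped, inserted
    relative to the reference, or unmapped.  Deleted reference bases simply
    do not appear.  Reads are assumed to be stored in reference orientation.
    """

    read_ids: list[str]
    positions: list[np.ndarray]
    reference_name: str = "ref"
    reference_length: int = 0

    def __post_init__(self):
        self.positions = [np.asarray(p, dtype=np.int64) for p in self.positions]
        if len(self.positions) != len(self.read_ids):
            raise ValueError("positions/read_ids length mismatch")
        for rid, pos in zip(self.read_ids, self.positions):
            aligned = pos[pos >= 0]
            if aligned.size and np.any(np.diff(aligned) <= 0):
                raise ValueError(f"read {rid}: aligned positions not strictly increasing")
        if self.reference_length == 0:
            mx = max((int(p[p >= 0].max()) for p in self.positions if (p >= 0).any()),
                     default=-1)
            self.reference_length = mx + 1


# ---------------------------------------------------------------------------
# intensity table dialect


def read_intensity_table(path) -> IntensityTile:
    """Parse the intensity TSV dialect into an :class:`IntensityTile`.

    Raises :class:`IntensityParseError` naming the offending line for
    malformed rows, non-numeric channel values, inconsistent cycle counts
    and unknown base symbols.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        raise IntensityParseError(f"{path}: no records") from None
    required = ["read_id", "cycle", "A", "C", "G", "T", "called_base"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise IntensityParseError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise IntensityParseError(f"{path}: no records")
    # line numbers in the physical file: header is line 1
    lineno = df.index.to_numpy() + 2

    def _numeric(col):
        vals = pd.to_numeric(df[col], errors="coerce").to_numpy()
        bad = ~np.isfinite(vals)
        if bad.any():
            raise IntensityParseError(
                f"line {lineno[bad][0]}: non-numeric value in column {col!r}"
            )
        return vals

    chans = np.column_stack([_numeric(c) for c in "ACGT"])
    cycles = pd.to_numeric(df["cycle"], errors="coerce").to_numpy()
    if np.any(~np.isfinite(cycles)) or np.any(cycles != np.round(cycles)):
        bad = np.where(~np.isfinite(cycles) | (cycles != np.round(cycles)))[0][0]
        raise IntensityParseError(f"line {lineno[bad]}: cycle must be a positive integer")
    cycles = cycles.astype(int)
    bases = df["called_base"].to_numpy()
    for i, b in enumerate(bases):
        if not (isinstance(b, str) and len(b) == 1 and b in _NUC_SET):
            raise IntensityParseError(f"line {lineno[i]}: unknown base symbol {b!r}")

    rids = df["read_id"].to_numpy()
    # contiguity: each read_id must form exactly one block
    change = np.r_[True, rids[1:] != rids[:-1]]
    block_ids = rids[change]
    if len(set(block_ids)) != len(block_ids):
        dup = pd.Series(block_ids).loc[lambda s: s.duplicated()].iloc[0]
        raise IntensityParseError(f"read {dup!r}: rows are not contiguous")

    starts = np.where(change)[0]
    ends = np.r_[starts[1:], len(df)]
    L = int(ends[0] - starts[0])
    read_ids, intens, called = [], [], []
    for s, e in zip(starts, ends):
        rid = rids[s]
        if e - s != L:
            raise IntensityParseError(
                f"line {lineno[s]}: inconsistent cycle count for read {rid!r} "
                f"({e - s} cycles, expected {L})"
            )
        order = np.argsort(cycles[s:e], kind="stable")
        cyc = cycles[s:e][order]
        if not np.array_equal(cyc, np.arange(1, L + 1)):
            raise IntensityParseError(
                f"line {lineno[s]}: read {rid!r} cycles are not 1..{L}"
            )
        read_ids.append(str(rid))
        intens.append(chans[s:e][order])
        called.append("".join(bases[s:e][order]))
    return IntensityTile(read_ids, np.asarray(intens), called, L)


def write_intensity_table(tile: IntensityTile, path, header_comment: str | None = None):
    """Write a tile in the TSV dialect (inverse of :func:`read_intensity_table`)."""
    with atomic_write(path) as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("read_id\tcycle\tA\tC\tG\tT\tcalled_base\n")
        for i, rid in enumerate(tile.read_ids):
            for c in range(tile.L):
                a, cc, g, t = tile.intensities[i, c]
                fh.write(
                    f"{rid}\t{c + 1}\t{a:.6g}\t{cc:.6g}\t{g:.6g}\t{t:.6g}\t"
                    f"{tile.called_bases[i][c]}\n"
                )


# ---------------------------------------------------------------------------
# FASTQ


def write_fastq(read_ids, called_bases, phred_scores, path) -> None:
    """Write Sanger FASTQ (Phred+33) records.

    ``phred_scores`` holds one integer score per base per read; scores must
    lie in [0, 60] (the package's score cap) and match the base string
    lengths.
    """
    records = []
    for rid, seq, scores in zip(read_ids, called_bases, phred_scores, strict=True):
        scores = [int(q) for q in np.asarray(scores).tolist()]
        if len(scores) != len(seq):
            raise ValueError(
                f"read {rid}: {len(scores)} scores for {len(seq)} bases"
            )
        if scores and (min(scores) < 0 or max(scores) > 60):
            raise ValueError(f"read {rid}: scores outside [0, 60]")
        rec = SeqRecord(Seq(seq), id=str(rid), description="")
        rec.letter_annotations["phred_quality"] = scores
        records.append(rec)
    with atomic_write(path) as fh:
        SeqIO.write(records, fh, "fastq")


def read_fastq_scores(path):
    """Return (read_ids, sequences, per-read integer score lists)."""
    ids, seqs, quals = [], [], []
    for rec in SeqIO.parse(os.fspath(path), "fastq"):
        ids.append(rec.id)
        seqs.append(str(rec.seq))
        quals.append(list(rec.letter_annotations["phred_quality"]))
    return ids, seqs, quals


# ---------------------------------------------------------------------------
# alignment layouts


def read_sam_layout(path) -> AlignmentLayout:
    """Build an :class:`AlignmentLayout` from a plain-text SAM file.

    Only POS and the M/I/D/S CIGAR operations are interpreted; unmapped
    reads get all-MISSING positions.
    """
    import pysam

    read_ids, positions = [], []
    ref_name, ref_len = "ref", 0
    with pysam.AlignmentFile(os.fspath(path), "r", check_sq=False) as sam:
        if sam.header.nreferences:
            ref_name = sam.header.references[0]
            ref_len = sam.header.lengths[0]
        for aln in sam:
            read_ids.append(aln.query_name)
            qlen = aln.query_length or (len(aln.query_sequence or ""))
            pos = np.full(qlen, MISSING, dtype=np.int64)
            if not aln.is_unmapped:
                for qpos, rpos in aln.get_aligned_pairs(matches_only=True):
                    pos[qpos] = rpos
            positions.append(pos)
    return AlignmentLayout(read_ids, positions, ref_name, ref_len)


def read_layout_tsv(path) -> AlignmentLayout:
    """Internal layout dialect: TSV with columns read_id, cycle, ref_pos.

    ``ref_pos`` is 0-based, -1 marking unaligned bases.
    """
    df = pd.read_csv(path, sep="\t", dtype={"read_id": str})
    read_ids, positions = [], []
    for rid, grp in df.groupby("read_id", sort=False):
        grp = grp.sort_values("cycle")
        read_ids.append(str(rid))
        positions.append(grp["ref_pos"].to_numpy(dtype=np.int64))
    return AlignmentLayout(read_ids, positions)


def write_layout_tsv(layout: AlignmentLayout, path) -> None:
    with atomic_write(path) as fh:
        fh.write("read_id\tcycle\tref_pos\n")
        for rid, pos in zip(layout.read_ids, layout.positions):
            for c, rp in enumerate(pos, start=1):
                fh.write(f"{rid}\t{c}\t{rp}\n")


# ---------------------------------------------------------------------------
# model serialization


def save_model(model, path) -> None:
    """Serialize a fitted QualityModel as self-describing JSON."""
    payload = {
        "format": _MODEL_FORMAT,
        "version": _MODEL_VERSION,
        "method": model.method,
        "coefficients": {n: float(b) for n, b in zip(model.feature_names, model.beta)},
        "knots": None if model.knots is None else [float(k) for k in model.knots],
        "trim_avg": [float(v) for v in model.trim_avg],
        "trim_sd": [float(v) for v in model.trim_sd],
        "lambda": None if model.lam is None else float(model.lam),
        "alpha": None if model.alpha is None else float(model.alpha),
        "n_train": model.n_train,
        "loglik": None if model.loglik is None else float(model.loglik),
    }
    with atomic_write(path) as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def load_model(path):
    from .model import QualityModel

    try:
        with open(path) as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: truncated or corrupt model file ({exc})") from None
    if payload.get("format") != _MODEL_FORMAT:
        raise ValueError(f"{path}: not a {_MODEL_FORMAT} file")
    if payload.get("version") != _MODEL_VERSION:
        raise ValueError(f"{path}: unsupported model file version {payload.get('version')}")
    if payload.get("method") not in MODEL_METHODS:
        raise ValueError(f"{path}: unknown method tag {payload.get('method')!r}")
    coef = payload["coefficients"]
    names = list(coef.keys())
    knots = payload.get("knots")
    return QualityModel(
        feature_names=names,
        beta=np.array([coef[n] for n in names], dtype=float),
        method=payload["method"],
        lam=payload.get("lambda"),
        alpha=payload.get("alpha"),
        n_train=payload.get("n_train"),
        loglik=payload.get("loglik"),
        knots=None if knots is None else np.asarray(knots, dtype=float),
        trim_avg=tuple(payload.get("trim_avg", (0.02, 3.0))),
        trim_sd=tuple(payload.get("trim_sd", (0.02, 1.0))),
    )


def write_consensus_fasta(consensus: str, path, name: str = "consensus") -> None:
    with atomic_write(path) as fh:
        SeqIO.write([SeqRecord(Seq(consensus), id=name, description="")], fh, "fasta")


def read_consensus_fasta(path) -> str:
    recs = list(SeqIO.parse(os.fspath(path), "fasta"))
    if not recs:
        raise ValueError(f"{path}: no FASTA records")
    return str(recs[0].seq)
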