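"""From fitted model to error probabilities, Phred scores and FASTQ.

The Phred transform is q = -10*log10(eps) where eps is the probability the
base call is wrong; q = 30 corresponds to eps = 0.001 (99.9% accuracy).
Integer scores are capped at 60 (eps floored at 1e-6) so that a saturated
model cannot emit unencodable scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .features import FeatureMatrix, build_design_matrix
from .io_formats import IntensityTile, atomic_write, write_fastq
from .model import QualityModel

EPS_FLOOR = 1e-6  # q cap of 60
Q_MAX = 60


@dataclass
class ScoredBases:
    """Per-base scoring results, read-major order."""

    read_ids: list[str]
    read_index: np.ndarray
    cycles: np.ndarray
    p: np.ndarray       # probability the call is correct
    eps: np.ndarray     # error probability, floored at EPS_FLOOR
    q_real: np.ndarray
    q_int: np.ndarray

    def per_read_scores(self, L: int):
        """Integer scores regrouped as one list per read."""
        return self.q_int.reshape(len(self.read_ids), L)

    def to_tsv(self, path) -> None:
        with atomic_write(path) as fh:
            fh.write("read_id\tcycle\tp\teps\tq_real\tq_int\n")
            for r, c, p, e, qr, qi in zip(
                self.read_index, self.cycles, self.p, self.eps, self.q_real, self.q_int
            ):
                fh.write(f"{self.read_ids[r]}\t{c}\t{p:.8g}\t{e:.8g}\t{qr:.4f}\t{qi}\n")


def predict_prob(model: QualityModel, X) -> np.ndarray:
    """Probability each base is called correctly: logistic(x^T beta).

    ``X`` may be a FeatureMatrix (column names are checked against the
    model, names and order) or a bare array of matching width.
    """
    if isinstance(X, FeatureMatrix):
        if X.feature_names != model.feature_names:
            missing = [n for n in model.feature_names if n not in X.feature_names]
            extra = [n for n in X.feature_names if n not in model.feature_names]
            raise ValueError(
                f"feature mismatch: missing from matrix {missing}, unexpected {extra}"
                if (missing or extra) else "feature columns are ordered differently"
            )
        X = X.X
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.beta.size:
        raise ValueError(f"design has {X.shape[1]} columns, model {model.beta.size}")
    return expit(X @ model.beta)


def phred_from_error_prob(eps):
    """q = -10*log10(eps) for eps in (0, 1]."""
    eps = np.asarray(eps, dtype=float)
    if np.any(eps <= 0) or np.any(eps > 1):
        raise ValueError("error probability must lie in (0, 1]")
    q = -10.0 * np.log10(eps)
    return float(q) if q.ndim == 0 else q


def error_prob_from_phred(q):
    """Inverse transform eps = 10^(-q/10)."""
    q = np.asarray(q, dtype=float)
    eps = np.power(10.0, -q / 10.0)
    return float(eps) if eps.ndim == 0 else eps


def integer_scores(q_real) -> np.ndarray:
    """Round half away from zero, then clamp into [0, 60]."""
    q = np.floor(np.asarray(q_real, dtype=float) + 0.5)
    return np.clip(q, 0, Q_MAX).astype(int)


def score_tile(model: QualityModel, tile: IntensityTile, fastq_path=None) -> ScoredBases:
    """Score every base of a tile with a fitted model.

    The model must carry the training knots (persisted at fit time) so the
    piecewise bases are evaluated exactly as during training.  Optionally
    writes a Sanger FASTQ with the integer scores.
    """
    if model.knots is None:
        raise ValueError("model carries no knots; was it fitted on a FeatureMatrix?")
    fm = build_design_matrix(tile, knots=model.knots)
    p = predict_prob(model, fm)
    eps = np.clip(1.0 - p, EPS_FLOOR, None)
    q_real = -10.0 * np.log10(eps)
    q_int = integer_scores(q_real)
    scored = ScoredBases(
        read_ids=list(tile.read_ids),
        read_index=fm.read_index,
        cycles=fm.cycles,
        p=p,
        eps=eps,
        q_real=q_real,
        q_int=q_int,
    )
    if fastq_path is not None:
        write_fastq(tile.read_ids, tile.called_bases,
                    scored.per_read_scores(tile.L), fastq_path)
    return scored
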