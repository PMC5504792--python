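"""Assessment of quality-scoring methods.

Three instruments:

* calibration — the observed score per predicted-score bin,
  ``q_obs(q) = -10*log10(Err_q / (Err_q + Corr_q))``; a well-calibrated
  scorer has q_obs close to q;
* discrimination power — the largest fraction of bases whose (empirical or
  expected) error rate stays below a threshold r, computed over
  score-sorted prefixes;
* ROC / precision-recall — treating "called correctly" as the positive
  class and the quality score as the classifier score.

Plus a kernel-density diagnostic of dinucleotide quenching: the T-channel
signal of T-called bases stratified by the preceding called base, which
exposes the reduced T signal after G.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import NUCLEOTIDES, IntensityTile, atomic_write

#: default threshold grid: -log10(r) from 3.3 to 3.7 in steps of 0.01
DEFAULT_R_GRID = 10.0 ** (-np.arange(3.30, 3.7001, 0.01))


def observed_score(err: int, corr: int) -> float:
    """Observed (empirical) Phred score of a predicted-score bin.

    With zero errors the empirical rate is 0 and the score unbounded;
    +inf is returned and should be reported as "> ceiling" in tables.
    """
    if err < 0 or corr < 0:
        raise ValueError("counts must be non-negative")
    total = err + corr
    if total == 0:
        raise ValueError("observed score undefined for an empty bin")
    if err == 0:
        return float("inf")
    return -10.0 * np.log10(err / total)


def calibration_table(q_int, labels) -> pd.DataFrame:
    """Counts and observed score stratified by integer predicted score.

    ``labels``: 1 = correct call, 0 = error.  Returns a DataFrame with
    columns q, n_err, n_corr, q_obs (one row per occupied score).
    """
    q_int = np.asarray(q_int, dtype=int)
    labels = np.asarray(labels, dtype=int)
    if q_int.size == 0:
        raise ValueError("no bases to stratify")
    if q_int.shape != labels.shape:
        raise ValueError("scores/labels length mismatch")
    rows = []
    for q in np.unique(q_int):
        m = q_int == q
        err = int(np.sum(labels[m] == 0))
        corr = int(np.sum(labels[m] == 1))
        rows.append({"q": int(q), "n_err": err, "n_corr": corr,
                     "q_obs": observed_score(err, corr)})
    return pd.DataFrame(rows)


def empirical_discrimination_power(scores, labels, r) -> float:
    """Largest fraction of bases whose prefix empirical error rate is < r.

    Bases are sorted by descending predicted score (stable, so score ties
    keep input order); the largest prefix whose observed error fraction is
    strictly below ``r`` defines the power.  Returns 0 when no prefix
    qualifies.
    """
    if not 0.0 < r < 1.0:
        raise ValueError("r must lie in (0, 1)")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n = scores.size
    order = np.argsort(-scores, kind="stable")
    err = (labels[order] == 0).astype(np.int64)
    rates = np.cumsum(err) / np.arange(1, n + 1)
    ok = np.flatnonzero(rates < r)
    if ok.size == 0:
        return 0.0
    return float((ok[-1] + 1) / n)


def expected_discrimination_power(error_probs, r) -> float:
    """Largest fraction whose mean *assigned* error probability is < r.

    This is the classical (expectation-based) discrimination power; it uses
    the scorer's own probabilities instead of observed errors and is
    therefore blind to calibration bias.
    """
    if not 0.0 < r < 1.0:
        raise ValueError("r must lie in (0, 1)")
    eps = np.sort(np.asarray(error_probs, dtype=float))
    if np.any(eps <= 0) or np.any(eps >= 1):
        raise ValueError("error probabilities must lie in (0, 1)")
    means = np.cumsum(eps) / np.arange(1, eps.size + 1)
    ok = np.flatnonzero(means < r)
    if ok.size == 0:
        return 0.0
    return float((ok[-1] + 1) / eps.size)


def discrimination_curve(scores, labels, r_grid=None, error_probs=None) -> pd.DataFrame:
    """Empirical (and optionally expected) power over a grid of thresholds."""
    r_grid = DEFAULT_R_GRID if r_grid is None else np.asarray(r_grid, dtype=float)
    rows = []
    for r in r_grid:
        row = {"r": float(r),
               "p_emp": empirical_discrimination_power(scores, labels, r)}
        if error_probs is not None:
            row["p_exp"] = expected_discrimination_power(error_probs, r)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    precision: np.ndarray
    recall: np.ndarray

    def to_tsv(self, roc_path=None, pr_path=None):
        if roc_path is not None:
            with atomic_write(roc_path) as fh:
                pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr}).to_csv(
                    fh, sep="\t", index=False)
        if pr_path is not None:
            with atomic_write(pr_path) as fh:
                pd.DataFrame({"recall": self.recall, "precision": self.precision}
                             ).to_csv(fh, sep="\t", index=False)


def roc_and_pr(scores, labels) -> RocCurve:
    """ROC and precision-recall curves from a threshold sweep.

    Positive class = correctly called base; AUC is the trapezoid area,
    equal to the probability a random correct call outscores a random
    error (ties counted 1/2).
    """
    from sklearn.metrics import auc as _auc
    from sklearn.metrics import precision_recall_curve, roc_curve

    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, _ = roc_curve(labels, np.asarray(scores, dtype=float))
    prec, rec, _ = precision_recall_curve(labels, np.asarray(scores, dtype=float))
    return RocCurve(fpr=fpr, tpr=tpr, auc=float(_auc(fpr, tpr)),
                    precision=prec, recall=rec)


# ---------------------------------------------------------------------------
# quenching diagnostic


@dataclass
class QuenchDensity:
    grid: np.ndarray
    densities: dict  # preceding base -> density over grid
    means: dict      # preceding base -> mean called-channel signal
    counts: dict


def quench_density(tile: IntensityTile, nucleotide="T", cycles=(8, 12),
                   bandwidth=0.01, grid_size=512) -> QuenchDensity:
    """Kernel density of the called-channel signal stratified by context.

    For each preceding called base X, collects the intensity of the called
    channel for bases called ``nucleotide`` at the (1-based, inclusive)
    cycle window whose previous called base is X, and evaluates a Gaussian
    KDE with fixed kernel width ``bandwidth``.  A reduced mean after G is
    the signature of GT-dinucleotide quenching.
    """
    lo, hi = cycles
    if not 2 <= lo <= hi <= tile.L:
        raise ValueError(f"cycle window {cycles} not covered by reads of length {tile.L}")
    codes = tile.called_codes()
    nt = NUCLEOTIDES.index(nucleotide)
    window = slice(lo - 1, hi)  # 0-based
    cur = codes[:, window]
    prev = codes[:, lo - 2:hi - 1]
    signal = tile.intensities[:, window, nt]  # called channel == nucleotide's channel
    sel = cur == nt

    samples = {}
    for k, x in enumerate(NUCLEOTIDES):
        vals = signal[sel & (prev == k)]
        if vals.size < 2:
            warnings.warn(f"context {x}{nucleotide}: fewer than 2 observations; omitted")
            continue
        samples[x] = vals

    if not samples:
        raise ValueError("no context group has at least 2 observations")
    allv = np.concatenate(list(samples.values()))
    grid = np.linspace(allv.min() - 4 * bandwidth, allv.max() + 4 * bandwidth, grid_size)
    dens, means, counts = {}, {}, {}
    norm = 1.0 / (np.sqrt(2 * np.pi) * bandwidth)
    for x, vals in samples.items():
        z = (grid[:, None] - vals[None, :]) / bandwidth
        dens[x] = norm * np.exp(-0.5 * z * z).mean(axis=1)
        means[x] = float(vals.mean())
        counts[x] = int(vals.size)
    return QuenchDensity(grid=grid, densities=dens, means=means, counts=counts)
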