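"""Construction of the 75-column design matrix (intercept x0 + features x1-x74).

The feature set encodes, for every called base, the information a base
caller has available about its own reliability:

* x1, x2 — largest and second-largest channel intensity in the cycle;
* x3-x5 — read-level summaries (mean of x1; mean and sample SD of
  ``|x1 - x2|``), winsorized into fixed trim bounds;
* x6-x8 — nonlinear transforms 1/x3, sqrt(x5), log(x5);
* x9-x17 — nine hinge (piecewise-linear) bases of ``|x1 - x2|`` at
  training-decile knots;
* x18, x19 — cycle number and inverse distance to the final cycle;
* x20-x26 — indicators for cycles 1..7;
* x27-x74 — 48 trinucleotide-context dummies "P(CS)": previous called base
  P, current called base C (largest channel) and second-largest channel S.

Cycle-1 bases have no previous base, so all 48 context dummies are zero
there; every later base activates exactly one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import NUCLEOTIDES, IntensityTile, atomic_write

#: winsorizing bounds for the read-level statistics
AVG_TRIM = (0.02, 3.0)
SD_TRIM = (0.02, 1.0)

N_FEATURES = 75

#: the 12 ordered unequal (called, second) pairs, lexicographic
ORDERED_PAIRS = [a + b for a in NUCLEOTIDES for b in NUCLEOTIDES if a != b]
#: context-dummy labels in design-matrix column order, x27 = "A(AC)" ... x74 = "T(TG)"
TRINUC_LABELS = [f"{p}({pair})" for p in NUCLEOTIDES for pair in ORDERED_PAIRS]

FEATURE_NAMES = [f"x{j}" for j in range(N_FEATURES)]

FEATURE_DESCRIPTIONS = dict(
    [
        ("x0", "intercept"),
        ("x1", "largest intensity"),
        ("x2", "second largest intensity"),
        ("x3", "average of x1"),
        ("x4", "average of |x1-x2|"),
        ("x5", "standard error of |x1-x2|"),
        ("x6", "1/x3"),
        ("x7", "sqrt(x5)"),
        ("x8", "log(x5)"),
    ]
    + [(f"x{9 + j}", f"piecewise function of |x1-x2|, knot {j + 1}") for j in range(9)]
    + [
        ("x18", "current cycle number"),
        ("x19", "inverse distance to last cycle"),
    ]
    + [(f"x{20 + j}", f"indicator of cycle {j + 1}") for j in range(7)]
    + [(f"x{27 + j}", TRINUC_LABELS[j]) for j in range(48)]
)

_CODE = {b: k for k, b in enumerate(NUCLEOTIDES)}
# pair-rank lookup: _PAIR_RANK[called, second] -> 0..11, -1 on the diagonal
_PAIR_RANK = np.full((4, 4), -1, dtype=np.int64)
for _r, _pair in enumerate(ORDERED_PAIRS):
    _PAIR_RANK[_CODE[_pair[0]], _CODE[_pair[1]]] = _r


@dataclass
class FeatureMatrix:
    """n_bases x 75 design matrix with its fitted knot/trim metadata.

    Rows are ordered read-major (read 0 cycles 1..L, read 1 cycles 1..L, ...).
    """

    X: np.ndarray
    knots: np.ndarray
    read_ids: list[str]
    read_index: np.ndarray  # row -> index into read_ids
    cycles: np.ndarray  # row -> 1-based cycle
    feature_names: list[str] = field(default_factory=lambda: list(FEATURE_NAMES))
    trim_avg: tuple = AVG_TRIM
    trim_sd: tuple = SD_TRIM

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.knots = np.asarray(self.knots, dtype=float)
        if self.X.shape[1] != N_FEATURES:
            raise ValueError(f"expected {N_FEATURES} columns, got {self.X.shape[1]}")
        if self.knots.shape != (9,) or np.any(np.diff(self.knots) < 0):
            raise ValueError("knots must be 9 ascending reals")
        if not np.isfinite(self.X).all():
            raise ValueError("non-finite design-matrix entries")

    @property
    def n_bases(self) -> int:
        return self.X.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.X[:, self.feature_names.index(name)]

    def to_tsv(self, path) -> None:
        with atomic_write(path) as fh:
            fh.write("read_id\tcycle\t" + "\t".join(self.feature_names) + "\n")
            for r, c, row in zip(self.read_index, self.cycles, self.X):
                vals = "\t".join(f"{v:.6g}" for v in row)
                fh.write(f"{self.read_ids[r]}\t{c}\t{vals}\n")


# ---------------------------------------------------------------------------
# per-base / per-read operations (scalar reference forms)


def top_two_intensities(channel_values):
    """Largest/second-largest intensity and their nucleotides for one cycle.

    Ties are broken by lexicographic nucleotide order (A<C<G<T), i.e. the
    first maximum in the fixed A,C,G,T channel order wins.
    Returns ``(x1, x2, called_nt, second_nt)``.
    """
    v = np.asarray(channel_values, dtype=float)
    if v.shape != (4,) or not np.isfinite(v).all():
        raise ValueError("expected 4 finite channel values")
    called = int(v.argmax())
    rest = v.copy()
    rest[called] = -np.inf
    second = int(rest.argmax())
    return float(v[called]), float(v[second]), NUCLEOTIDES[called], NUCLEOTIDES[second]


def read_summary_stats(x1, x2):
    """Read-level statistics (x3, x4, x5) from per-cycle x1, x2 arrays.

    x3 = mean(x1) winsorized into AVG_TRIM; x4 = mean(|x1-x2|);
    x5 = sample standard deviation (ddof=1) of |x1-x2| winsorized into SD_TRIM.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.size < 2:
        raise ValueError("read length must be >= 2 (sample SD undefined)")
    d = np.abs(x1 - x2)
    x3 = float(np.clip(x1.mean(), *AVG_TRIM))
    x4 = float(d.mean())
    x5 = float(np.clip(d.std(ddof=1), *SD_TRIM))
    return x3, x4, x5


def derived_transforms(x3, x5):
    """Nonlinear transforms (x6, x7, x8) = (1/x3, sqrt(x5), ln x5).

    The inputs are assumed already winsorized (>= 0.02), so every output is
    finite.
    """
    return 1.0 / x3, float(np.sqrt(x5)), float(np.log(x5))


def piecewise_basis(d, knots):
    """Hinge basis max(0, d - k_j) over the nine knots -> (x9..x17)."""
    knots = np.asarray(knots, dtype=float)
    if knots.shape != (9,) or np.any(np.diff(knots) < 0):
        raise ValueError("knots must be 9 ascending reals")
    return np.maximum(0.0, d - knots)


def positional_features(cycle, L):
    """Cycle-position features (x18..x26) for 1-based ``cycle`` in a read of length L."""
    if not 1 <= cycle <= L:
        raise ValueError(f"cycle {cycle} outside 1..{L}")
    out = np.zeros(9)
    out[0] = cycle
    out[1] = 1.0 / (L - cycle + 1)
    if cycle <= 7:
        out[1 + cycle] = 1.0
    return out


def trinucleotide_dummy_index(prev_base, called_base, second_base) -> int:
    """Index (0..47) of the context dummy "prev(called second)".

    Matches the design-matrix column order: x27 = A(AC), ..., x74 = T(TG);
    index = 12 * rank(prev) + rank of the ordered pair among the 12
    lexicographically sorted unequal pairs.
    """
    if called_base == second_base:
        raise ValueError("called and second nucleotide must differ")
    try:
        idx = 12 * _CODE[prev_base] + int(_PAIR_RANK[_CODE[called_base], _CODE[second_base]])
    except KeyError as exc:
        raise ValueError(f"unknown nucleotide {exc}") from None
    return idx


def default_knots(d: np.ndarray) -> np.ndarray:
    """Nine decile knots (10%..90%) of the intensity margin ``|x1 - x2|``."""
    return np.quantile(np.asarray(d, dtype=float).ravel(), np.arange(1, 10) / 10.0)


# ---------------------------------------------------------------------------
# design-matrix assembly (vectorized)


def build_design_matrix(tile: IntensityTile, knots: np.ndarray | None = None) -> FeatureMatrix:
    """Assemble the full n_bases x 75 design matrix for a tile.

    When ``knots`` is None the nine decile knots of ``|x1 - x2|`` over this
    tile are computed and stored in the matrix metadata (and should be
    persisted with any model trained on it, so that scoring reuses the
    training knots).
    """
    if tile.L < 2:
        raise ValueError("tile reads must have at least 2 cycles")
    n, L = tile.n_reads, tile.L
    intens = tile.intensities  # (n, L, 4)

    called = intens.argmax(axis=2)  # ties -> first max = lexicographic
    masked = intens.copy()
    np.put_along_axis(masked, called[..., None], -np.inf, axis=2)
    second = masked.argmax(axis=2)
    x1 = np.take_along_axis(intens, called[..., None], axis=2)[..., 0]
    x2 = np.take_along_axis(intens, second[..., None], axis=2)[..., 0]
    d = np.abs(x1 - x2)  # (n, L)

    if knots is None:
        knots = default_knots(d)
    knots = np.asarray(knots, dtype=float)

    x3 = np.clip(x1.mean(axis=1), *AVG_TRIM)  # (n,)
    x4 = d.mean(axis=1)
    x5 = np.clip(d.std(axis=1, ddof=1), *SD_TRIM)

    nb = n * L
    X = np.zeros((nb, N_FEATURES))
    X[:, 0] = 1.0
    X[:, 1] = x1.ravel()
    X[:, 2] = x2.ravel()
    X[:, 3] = np.repeat(x3, L)
    X[:, 4] = np.repeat(x4, L)
    X[:, 5] = np.repeat(x5, L)
    X[:, 6] = np.repeat(1.0 / x3, L)
    X[:, 7] = np.repeat(np.sqrt(x5), L)
    X[:, 8] = np.repeat(np.log(x5), L)
    X[:, 9:18] = np.maximum(0.0, d.ravel()[:, None] - knots[None, :])

    cyc = np.tile(np.arange(1, L + 1), n)
    X[:, 18] = cyc
    X[:, 19] = 1.0 / (L - cyc + 1)
    for j in range(1, 8):
        if j <= L:
            X[cyc == j, 19 + j] = 1.0

    # context dummies: previous *called* base (from the tile's base string),
    # current largest / second-largest channel from the intensities
    prev = tile.called_codes()[:, :-1]  # (n, L-1)
    cur_called = called[:, 1:]
    cur_second = second[:, 1:]
    col = 27 + 12 * prev + _PAIR_RANK[cur_called, cur_second]
    rows = (np.arange(n)[:, None] * L + np.arange(1, L)[None, :]).ravel()
    X[rows, col.ravel()] = 1.0

    return FeatureMatrix(
        X=X,
        knots=knots,
        read_ids=list(tile.read_ids),
        read_index=np.repeat(np.arange(n), L),
        cycles=cyc,
    )
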