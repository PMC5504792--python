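"""Synthetic four-channel intensity tiles with known ground truth.

The generator emulates the main error mechanisms of sequencing-by-synthesis
signals — phasing carry-over from the previous cycle (with a G-specific
offset), color crosstalk between channels, dinucleotide quenching of the T
channel after a G, per-cycle signal decay, and additive noise — while
deliberately *not* sharing the functional form of the quality-model
features, so that feature-recovery tests are non-circular.

Per cycle the channel vector is built as::

    s = decay^(c-1) * [ (1 - phi_c) * onehot(true_c) + phi_c * onehot(true_{c-1}) ]
    s[T] *= gamma                     if true_{c-1} == G
    s = M @ s + noise                 (M row-stochastic, noise ~ N(0, sigma), clipped at 0)

and the called base is the argmax channel.  Identical seed and
configuration give bitwise-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io_formats import NUCLEOTIDES, IntensityTile
from .labeling import ErrorLabels


def _identity():
    return np.eye(4)


@dataclass
class SimulationConfig:
    n_reads: int = 200
    read_length: int = 50
    base_probs: tuple = (0.25, 0.25, 0.25, 0.25)
    reference: str | None = None  # sample fragments from this sequence instead
    phasing: float = 0.04          # phi: carry-over fraction from previous cycle
    g_phasing_delta: float = 0.03  # added to phi when the previous base is G
    crosstalk: np.ndarray = field(default_factory=_identity)  # row-stochastic 4x4
    quench: float = 0.75           # gamma: T-channel factor after a true G
    noise: float = 0.1             # sigma of additive Gaussian noise, clipped at 0
    decay: float = 0.004           # delta: per-cycle signal decay
    seed: int = 0

    def __post_init__(self):
        self.crosstalk = np.asarray(self.crosstalk, dtype=float)
        if self.n_reads < 1 or self.read_length < 2:
            raise ValueError("need n_reads >= 1 and read_length >= 2")
        if not 0.0 <= self.phasing < 0.5:
            raise ValueError("phasing must lie in [0, 0.5)")
        if not 0.0 <= self.phasing + self.g_phasing_delta < 0.5:
            raise ValueError("phasing + g_phasing_delta must lie in [0, 0.5)")
        if not 0.0 < self.quench <= 1.0:
            raise ValueError("quench factor must lie in (0, 1]")
        if self.noise < 0:
            raise ValueError("noise must be >= 0")
        if not 0.0 <= self.decay <= 1.0:
            raise ValueError("decay must lie in [0, 1]")
        if self.crosstalk.shape != (4, 4) or np.any(self.crosstalk < 0) or \
                not np.allclose(self.crosstalk.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("crosstalk must be a row-stochastic 4x4 matrix")
        p = np.asarray(self.base_probs, dtype=float)
        if p.shape != (4,) or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
            raise ValueError("base_probs must be 4 non-negative values summing to 1")
        if self.reference is not None:
            if len(self.reference) < self.read_length:
                raise ValueError("reference shorter than read_length")
            if set(self.reference) - set(NUCLEOTIDES):
                raise ValueError("reference may contain only A, C, G, T")


@dataclass
class SimulationResult:
    tile: IntensityTile
    true_sequences: list[str]
    labels: ErrorLabels
    starts: np.ndarray | None = None  # fragment starts when a reference was used

    def error_rate(self) -> float:
        return self.labels.error_rate()


def simulate_tile(config: SimulationConfig) -> SimulationResult:
    """Generate one tile plus ground truth under ``config``."""
    rng = np.random.default_rng(config.seed)
    n, L = config.n_reads, config.read_length
    G = NUCLEOTIDES.index("G")
    T = NUCLEOTIDES.index("T")

    starts = None
    if config.reference is not None:
        ref_codes = np.array([NUCLEOTIDES.index(b) for b in config.reference])
        starts = rng.integers(0, len(config.reference) - L + 1, size=n)
        true = np.stack([ref_codes[s:s + L] for s in starts])
    else:
        true = rng.choice(4, size=(n, L), p=np.asarray(config.base_probs, dtype=float))

    onehot = np.eye(4)[true]  # (n, L, 4)
    signal = onehot.copy()
    prev_is_g = np.zeros((n, L), dtype=bool)
    prev_is_g[:, 1:] = true[:, :-1] == G
    phi = np.zeros((n, L))
    phi[:, 1:] = config.phasing
    phi[:, 1:][prev_is_g[:, 1:]] = config.phasing + config.g_phasing_delta
    signal[:, 1:] = (1.0 - phi[:, 1:, None]) * onehot[:, 1:] \
        + phi[:, 1:, None] * onehot[:, :-1]
    # GT quenching: T channel attenuated after a true G
    signal[:, :, T] = np.where(prev_is_g, config.quench * signal[:, :, T],
                               signal[:, :, T])
    decay = (1.0 - config.decay) ** np.arange(L)
    signal *= decay[None, :, None]
    signal = signal @ config.crosstalk.T
    if config.noise > 0:
        signal = signal + rng.normal(0.0, config.noise, size=signal.shape)
    signal = np.clip(signal, 0.0, None)

    called = signal.argmax(axis=2)
    nuc = np.array(list(NUCLEOTIDES))
    called_bases = ["".join(nuc[row]) for row in called]
    true_sequences = ["".join(nuc[row]) for row in true]
    read_ids = [f"sim_{config.seed}_{i:06d}" for i in range(n)]

    tile = IntensityTile(read_ids, signal, called_bases, L)
    labels = ErrorLabels(read_ids, (called == true).astype(np.int8))
    return SimulationResult(tile=tile, true_sequences=true_sequences,
                            labels=labels, starts=starts)


# ---------------------------------------------------------------------------
# bundled fixtures

_MIXED_CROSSTALK = np.full((4, 4), 0.02) + np.eye(4) * (0.94 - 0.02)
_MIXED_CROSSTALK /= _MIXED_CROSSTALK.sum(axis=1, keepdims=True)

#: tiny deterministic datasets used throughout the test suite.
#: "noisy-mixed" is the canonical *training* condition: its noise level and
#: crosstalk were calibrated once, at generation time, to land the overall
#: error rate inside (0.005, 0.05).
FIXTURES = {
    "clean": SimulationConfig(n_reads=50, read_length=20, phasing=0.0,
                              g_phasing_delta=0.0, quench=1.0, noise=0.0,
                              decay=0.0, seed=101),
    "quenched": SimulationConfig(n_reads=200, read_length=50, quench=0.7,
                                 noise=0.05, seed=202),
    "phased": SimulationConfig(n_reads=200, read_length=50, phasing=0.25,
                               g_phasing_delta=0.0, quench=1.0, noise=0.22,
                               seed=303),
    "noisy-mixed": SimulationConfig(n_reads=200, read_length=50, noise=0.22,
                                    crosstalk=_MIXED_CROSSTALK, seed=404),
}


def training_config(n_reads: int, read_length: int = 50, seed: int = 0) -> SimulationConfig:
    """The noisy-mixed condition at an arbitrary size — the package's
    standard setting for model-training experiments."""
    return replace(FIXTURES["noisy-mixed"], n_reads=n_reads,
                   read_length=read_length, seed=seed)


def make_fixture(name: str) -> SimulationResult:
    """Deterministic small dataset by registered name.

    Names: "clean" (noiseless identity channel, zero errors), "quenched"
    (gamma=0.7), "phased" (phi=0.25), "noisy-mixed" (training condition).
    """
    try:
        config = FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; choose from {sorted(FIXTURES)}") from None
    return simulate_tile(config)
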