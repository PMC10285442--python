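"""Block-design construction and GLM design matrices.

Each fMRI session presents four picture categories in blocks of 10 pictures,
1.5 s per picture, so one block spans 15 s = 10 volumes at TR 1.5 s.  The
"spider" session shows tarantulas, daddy-long-legs spiders, beetles and
leaves; the "fear" session shows tarantulas, beetles, snakes and lizards.
An 8-minute session therefore holds 32 blocks (8 per condition) and 320
volumes.

Block order is pseudorandom but carryover-balanced: every ordered pair of
conditions follows one another equally often.  Balance is exact on the
circular adjacency count (the sequence closes on itself) and is achieved by
a seeded Eulerian circuit on the condition-transition multigraph.  With
``blocks_per_condition`` a multiple of 4 each ordered pair *including*
same-condition repeats occurs ``blocks_per_condition / 4`` times; with a
multiple of 3 the 12 distinct ordered pairs are used instead.  Other counts
cannot be balanced exactly and raise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

SESSION_CONDITIONS: Mapping[str, tuple[str, ...]] = {
    "spider": ("tarantula", "daddy_long_legs", "beetle", "leaves"),
    "fear": ("tarantula", "beetle", "snake", "lizard"),
}

#: canonical double-gamma HRF (SPM-like): response peak 6 s, undershoot
#: peaking at 16 s with 1/6 relative amplitude, unit dispersion
DEFAULT_HRF_PARAMS: Mapping[str, float] = {
    "peak_delay": 6.0,
    "undershoot_delay": 16.0,
    "peak_disp": 1.0,
    "undershoot_disp": 1.0,
    "undershoot_ratio": 1.0 / 6.0,
    "duration_s": 32.0,
}


@dataclass(frozen=True)
class SessionDesign:
    session_kind: str
    conditions: tuple[str, ...]
    block_sequence: tuple[str, ...]
    pictures_per_block: int = 10
    stimulus_duration_s: float = 1.5
    tr_s: float = 1.5

    def __post_init__(self) -> None:
        counts = {c: self.block_sequence.count(c) for c in self.conditions}
        if len(set(counts.values())) != 1:
            raise ValueError(f"conditions appear unequally often: {counts}")
        if set(self.block_sequence) - set(self.conditions):
            raise ValueError("block_sequence contains unknown conditions")

    @property
    def block_duration_s(self) -> float:
        return self.pictures_per_block * self.stimulus_duration_s

    @property
    def session_duration_s(self) -> float:
        return len(self.block_sequence) * self.block_duration_s

    @property
    def n_volumes(self) -> int:
        n = self.session_duration_s / self.tr_s
        if abs(n - round(n)) > 1e-9:
            raise ValueError("session duration is not a whole number of TRs")
        return int(round(n))

    def onsets(self) -> pd.DataFrame:
        """BIDS-style events table (onset, duration, trial_type), seconds."""
        rows = [
            {"onset": i * self.block_duration_s, "duration": self.block_duration_s, "trial_type": c}
            for i, c in enumerate(self.block_sequence)
        ]
        return pd.DataFrame(rows)

    def to_events_tsv(self, path) -> None:
        self.onsets().to_csv(path, sep="\t", index=False)

    def adjacency_counts(self, circular: bool = True) -> dict[tuple[str, str], int]:
        """Count ordered condition adjacencies in the block sequence."""
        seq = list(self.block_sequence)
        pairs = list(zip(seq, seq[1:]))
        if circular:
            pairs.append((seq[-1], seq[0]))
        counts: dict[tuple[str, str], int] = {}
        for p in pairs:
            counts[p] = counts.get(p, 0) + 1
        return counts


def build_session(session_kind: str, blocks_per_condition: int = 8,
                  seed: int = 0, require_balance: bool | None = None) -> SessionDesign:
    """Carryover-balanced pseudorandom block sequence for one session.

    The transition multigraph has the four conditions as nodes and each
    admissible ordered pair as a repeated edge; an Eulerian circuit through
    it visits every transition equally often.  The seed permutes condition
    labels, shuffles edge insertion order and rotates the circuit, giving a
    pseudorandom but exactly balanced order.

    Exact balance requires ``blocks_per_condition`` to be a multiple of 4
    (all 16 ordered pairs incl. same-condition repeats) or of 3 (the 12
    distinct ordered pairs).  Other counts fall back to a seeded equal-count
    permutation, or raise if ``require_balance=True``.
    """
    if session_kind not in SESSION_CONDITIONS:
        raise ValueError(f"unknown session kind {session_kind!r}; expected one of {sorted(SESSION_CONDITIONS)}")
    if blocks_per_condition < 1:
        raise ValueError("blocks_per_condition must be >= 1")
    conditions = SESSION_CONDITIONS[session_kind]
    k = len(conditions)
    rng = np.random.default_rng(seed)
    if blocks_per_condition % k == 0:
        mult = blocks_per_condition // k
        with_loops = True
    elif blocks_per_condition % (k - 1) == 0:
        mult = blocks_per_condition // (k - 1)
        with_loops = False
    else:
        if require_balance:
            raise ValueError(
                f"cannot carryover-balance {blocks_per_condition} blocks/condition over {k} conditions"
            )
        blocks = [c for c in conditions for _ in range(blocks_per_condition)]
        sequence = tuple(blocks[i] for i in rng.permutation(len(blocks)))
        return SessionDesign(session_kind=session_kind, conditions=conditions,
                             block_sequence=sequence)
    labels = list(conditions)
    rng.shuffle(labels)
    edges = [
        (a, b)
        for a in labels
        for b in labels
        if with_loops or a != b
        for _ in range(mult)
    ]
    order = rng.permutation(len(edges))
    g = nx.MultiDiGraph()
    g.add_nodes_from(labels)
    g.add_edges_from(edges[i] for i in order)
    circuit = [u for u, _v in nx.eulerian_circuit(g, source=labels[0])]
    shift = int(rng.integers(len(circuit)))
    sequence = tuple(circuit[shift:] + circuit[:shift])
    return SessionDesign(session_kind=session_kind, conditions=conditions,
                         block_sequence=sequence)


def double_gamma_hrf(t: np.ndarray, params: Mapping[str, float] | None = None) -> np.ndarray:
    """Canonical double-gamma hemodynamic impulse response, peak-normalized."""
    p = dict(DEFAULT_HRF_PARAMS)
    if params:
        p.update(params)
    t = np.asarray(t, dtype=float)
    pos = gamma_dist.pdf(t, p["peak_delay"] / p["peak_disp"], scale=p["peak_disp"])
    neg = gamma_dist.pdf(t, p["undershoot_delay"] / p["undershoot_disp"], scale=p["undershoot_disp"])
    h = pos - p["undershoot_ratio"] * neg
    peak = np.max(np.abs(h))
    return h / peak if peak > 0 else h


@dataclass(frozen=True)
class DesignMatrix:
    matrix: np.ndarray  # n_volumes x n_regressors
    regressor_names: tuple[str, ...]
    hrf_params: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_HRF_PARAMS))

    def __post_init__(self) -> None:
        if self.matrix.shape[1] != len(self.regressor_names):
            raise ValueError("regressor_names must match matrix columns")
        if np.linalg.matrix_rank(self.matrix) < self.matrix.shape[1]:
            raise ValueError("design matrix is rank deficient")

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_regressors(self) -> int:
        return self.matrix.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.regressor_names.index(name)]

    def contrast_vector(self, positive: str, negative: str | None = None) -> np.ndarray:
        """Unit contrast, e.g. ('tarantula', 'beetle') for spider>beetle."""
        c = np.zeros(self.n_regressors)
        c[self.regressor_names.index(positive)] = 1.0
        if negative is not None:
            c[self.regressor_names.index(negative)] = -1.0
        return c


def condition_boxcars(session: SessionDesign) -> tuple[np.ndarray, tuple[str, ...]]:
    """Volume-by-condition indicator matrix (before HRF convolution)."""
    n_vol = session.n_volumes
    vols_per_block = session.block_duration_s / session.tr_s
    if abs(vols_per_block - round(vols_per_block)) > 1e-9:
        raise ValueError("block duration must be a whole number of TRs")
    vols_per_block = int(round(vols_per_block))
    box = np.zeros((n_vol, len(session.conditions)))
    for i, cond in enumerate(session.block_sequence):
        j = session.conditions.index(cond)
        box[i * vols_per_block:(i + 1) * vols_per_block, j] = 1.0
    return box, session.conditions


def build_design_matrix(session: SessionDesign,
                        hrf_params: Mapping[str, float] | None = None,
                        drift_order: int = 1) -> DesignMatrix:
    """HRF-convolved condition regressors + intercept + Legendre drift terms.

    Each condition regressor is the condition's block boxcar (1 while its
    pictures are on screen) convolved with the canonical double-gamma HRF
    sampled at TR.  Slow scanner drift is modeled with Legendre polynomials
    up to ``drift_order`` (degree 0 is the intercept).
    """
    box, names = condition_boxcars(session)
    if np.any(box.sum(axis=0) == 0):
        dead = [n for n, s in zip(names, box.sum(axis=0)) if s == 0]
        raise ValueError(f"degenerate all-zero regressor(s): {dead}")
    p = dict(DEFAULT_HRF_PARAMS)
    if hrf_params:
        p.update(hrf_params)
    t = np.arange(0.0, p["duration_s"] + session.tr_s / 2, session.tr_s)
    hrf = double_gamma_hrf(t, p)
    n_vol = session.n_volumes
    cols = [np.convolve(box[:, j], hrf)[:n_vol] for j in range(box.shape[1])]
    reg_names = list(names) + ["intercept"]
    cols.append(np.ones(n_vol))
    if drift_order >= 1:
        x = np.linspace(-1.0, 1.0, n_vol)
        for d in range(1, drift_order + 1):
            cols.append(np.polynomial.legendre.Legendre.basis(d)(x))
            reg_names.append(f"drift_{d}")
    return DesignMatrix(matrix=np.column_stack(cols), regressor_names=tuple(reg_names),
                        hrf_params=p)
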