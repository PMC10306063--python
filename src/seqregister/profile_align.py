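"""Gapless profile-to-sequence alignment with calibrated p-values.

A window of per-residue 20-class probabilities is scored against every
offset of every target sequence with a log-odds score

    S(offset) = sum_i log( P_i(a_{offset+i}) / q(a_{offset+i}) )

in nats, where q is the background composition. The null distribution of
the single-offset score under an i.i.d. background sequence is computed
exactly by convolving per-position atom distributions on a discretized
score lattice. The p-value of the best alignment over M offsets is
1 - (1 - theta * tail)^M, where theta <= 1 is a declumping factor for
exceedances clustered at strongly correlated overlapping offsets (theta
is 1, and the formula the plain independence correction, when no lag
correlation is strong).

Discretization: per-position atoms are binned onto a lattice of
``grid_step`` nats, rounding values down. A tail query compensates the
expected accumulated rounding (L atoms, each rounded down by step/2 on
average) by shifting the threshold L/2 steps, and splits the threshold
bin's mass with a geometric within-bin model, so the discretized tail
tracks the exact tail to well under a percent at the default step
(verified against exhaustive enumeration).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .alphabet import N_TYPES, seq_to_indices
from .structure_io import TargetSequence

#: truncate lattice tails carrying less than this total mass
_TAIL_TRUNCATION = 1e-12


@dataclass
class AlignmentParams:
    """Scoring and calibration parameters.

    background: amino-acid frequencies (uniform by default);
    grid_step: score lattice step in nats;
    pvalue_threshold: outlier threshold on the alignment p-value;
    probability_floor: floor applied to profile rows before logs.
    """

    background: np.ndarray = None
    grid_step: float = 0.002
    pvalue_threshold: float = 0.14
    probability_floor: float = 1e-4

    def __post_init__(self):
        if self.background is None:
            self.background = np.full(N_TYPES, 1.0 / N_TYPES)
        self.background = np.asarray(self.background, dtype=float)
        if self.background.shape != (N_TYPES,) or np.any(self.background <= 0):
            raise ValueError("background must be 20 positive frequencies")
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError("background must sum to 1")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        if not 0 < self.pvalue_threshold < 1:
            raise ValueError("pvalue_threshold must be in (0,1)")


@dataclass
class WindowAlignment:
    seq_id: str
    offset: int
    score: float
    pvalue: Optional[float] = None
    n_offsets: int = 1


@dataclass
class NullDistribution:
    """Discretized distribution of the single-offset window score.

    mass[i] is the probability of score bin (min_bin + i); a bin b holds
    per-position atom values rounded down to b*step and summed.
    """

    min_bin: int
    mass: np.ndarray
    step: float
    length: int
    #: lag-d correlation of scores at offsets d apart (same letters hit
    #: different profile rows); drives the clustering correction
    lag_rho: np.ndarray = None
    _suffix: np.ndarray = field(default=None, repr=False)

    @property
    def total_mass(self) -> float:
        return float(self.mass.sum())

    def _suffix_sums(self) -> np.ndarray:
        if self._suffix is None:
            self._suffix = np.cumsum(self.mass[::-1])[::-1]
        return self._suffix

    def threshold_bin(self, score: float) -> int:
        return int(np.floor(score / self.step - 0.5 * self.length + 1e-9))

    def tail(self, score) -> np.ndarray:
        """P(S >= score) under the null, vectorized over scores.

        The query threshold is shifted by L/2 lattice steps (the mean
        accumulated rounding of the L floor-binned atoms) and the mass
        of the bin the threshold lands in is split by a geometric
        within-bin model whose decay is estimated from the next bin
        (tails fall ~exponentially, so uniform in-bin splitting would
        overestimate the upper part by ~rate*step/2 relative).
        """
        scores = np.atleast_1d(np.asarray(score, dtype=float))
        suffix = self._suffix_sums()
        n = len(self.mass)
        t_real = scores / self.step - 0.5 * self.length
        t0 = np.floor(t_real + 1e-9).astype(np.int64)
        frac = np.clip(t_real - t0, 0.0, 1.0)
        idx = t0 - self.min_bin
        below = idx < 0
        above = idx >= n
        idx_c = np.clip(idx, 0, n - 1)
        upper = np.where(idx_c + 1 < n, suffix[np.minimum(idx_c + 1, n - 1)], 0.0)
        m0 = self.mass[idx_c]
        m1 = np.where(idx_c + 1 < n, self.mass[np.minimum(idx_c + 1, n - 1)], 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(m0 > 0, m1 / np.where(m0 > 0, m0, 1.0), 1.0)
        r = np.clip(r, 1e-12, 1.0)
        geometric = r < 1.0 - 1e-9
        with np.errstate(divide="ignore", invalid="ignore"):
            part = np.where(geometric,
                            (np.power(r, frac) - r) / np.where(geometric, 1.0 - r, 1.0),
                            1.0 - frac)
        out = upper + part * m0
        out = np.where(below, 1.0, out)
        out = np.where(above, 0.0, out)
        out = np.minimum(out, 1.0)
        return out[0] if np.ndim(score) == 0 else out

    def dump(self, path: str) -> None:
        """Two-column text dump: score_bin_value, mass."""
        with open(path, "w") as fh:
            for i, m in enumerate(self.mass):
                fh.write(f"{(self.min_bin + i) * self.step:.6f}\t{m:.12e}\n")


def floor_rows(window: np.ndarray, floor: float) -> np.ndarray:
    """Apply a probability floor to profile rows and renormalize.

    Entries below the floor are raised to it; rows that already respect
    the floor are returned unchanged (up to normalization).
    """
    w = np.asarray(window, dtype=float)
    if w.ndim != 2 or w.shape[1] != N_TYPES:
        raise ValueError("window must be (L, 20)")
    w = np.maximum(w, floor)
    return w / w.sum(axis=1, keepdims=True)


def logodds_matrix(window: np.ndarray, params: AlignmentParams) -> np.ndarray:
    """(L, 21) log-odds matrix; the extra zero column absorbs 'X'."""
    w = floor_rows(window, params.probability_floor)
    lo = np.log(w) - np.log(params.background)
    return np.hstack([lo, np.zeros((len(lo), 1))])


def alignment_score(window: np.ndarray, seq: TargetSequence, offset: int,
                    params: AlignmentParams) -> float:
    """Log-odds score (nats) of the window at one offset of one sequence."""
    L = len(window)
    if not 0 <= offset <= len(seq) - L:
        raise ValueError(f"offset {offset} out of range for length-{len(seq)} sequence")
    lo = logodds_matrix(window, params)
    idx = seq_to_indices(seq.residues[offset : offset + L])
    return float(lo[np.arange(L), idx].sum())


def sequence_scores(lo: np.ndarray, seq_idx: np.ndarray) -> np.ndarray:
    """Scores of a log-odds matrix at every offset of an encoded sequence."""
    L = lo.shape[0]
    M = len(seq_idx) - L + 1
    if M <= 0:
        return np.empty(0)
    sw = np.lib.stride_tricks.sliding_window_view(seq_idx, L)
    return lo[np.arange(L), sw].sum(axis=1)


def count_offsets(sequences: Sequence[TargetSequence], L: int) -> int:
    return sum(max(0, len(s) - L + 1) for s in sequences)


def window_scores_matrix(lo: np.ndarray, seq_idx: np.ndarray, L: int) -> np.ndarray:
    """Scores of every length-L window of a log-odds matrix at every offset.

    Entry (w, o) is the score of profile rows [w, w+L) aligned at
    sequence offset o. Computed with diagonal prefix sums in O(n*m);
    used by the register scanner to score a whole chain at once.
    """
    n = lo.shape[0]
    m = len(seq_idx)
    if n < L or m < L:
        return np.empty((max(0, n - L + 1), max(0, m - L + 1)))
    E = lo[:, seq_idx]
    P = np.zeros((n + 1, m + 1))
    for j in range(n):
        P[j + 1, 1:] = E[j] + P[j, :-1]
    return P[L:, L:] - P[: n - L + 1, : m - L + 1]


def best_gapless_alignment(window: np.ndarray, sequences: Sequence[TargetSequence],
                           params: AlignmentParams) -> WindowAlignment:
    """Best-scoring gapless placement over all offsets of all sequences.

    Ties are broken by sequence order, then by the lowest offset.
    """
    L = len(window)
    n_offsets = count_offsets(sequences, L)
    if n_offsets == 0:
        raise ValueError(f"no sequence admits a length-{L} window")
    lo = logodds_matrix(window, params)
    best = None
    for seq in sequences:
        scores = sequence_scores(lo, seq_to_indices(seq.residues))
        if len(scores) == 0:
            continue
        off = int(np.argmax(scores))
        if best is None or scores[off] > best.score:
            best = WindowAlignment(seq_id=seq.id, offset=off,
                                   score=float(scores[off]), n_offsets=n_offsets)
    return best


# ---------------------------------------------------------------------------
# null distribution
# ---------------------------------------------------------------------------

def _position_atoms(lo: np.ndarray, background: np.ndarray, step: float):
    """Per-position (bins, weights) with duplicate bins merged."""
    bins = np.floor(lo[:, :N_TYPES] / step + 1e-9).astype(np.int64)
    out = []
    for row_bins in bins:
        ub, inv = np.unique(row_bins, return_inverse=True)
        uw = np.zeros(len(ub))
        np.add.at(uw, inv, background)
        out.append((ub, uw))
    return out


def _lag_correlations(lo: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Correlation of window scores at offsets d apart (d = 1..L-1).

    A letter shared by two overlapping placements is scored by rows d
    apart, so Cov(S_o, S_{o+d}) sums the same-letter cross-row
    covariances Cov_a(W_r, W_{r-d}) over the L-d shared positions.
    """
    W = lo[:, :N_TYPES]
    L = len(W)
    m = W @ background
    cov = (W * background) @ W.T - np.outer(m, m)
    var_s = float(np.trace(cov))
    if var_s <= 0 or L < 2:
        return np.zeros(max(L - 1, 0))
    return np.array([
        sum(cov[r, r - d] for r in range(d, L)) / var_s for d in range(1, L)
    ])


def null_score_distribution(window: np.ndarray, params: AlignmentParams,
                            cache: Optional[dict] = None) -> NullDistribution:
    """Exact discretized null distribution of the single-offset score.

    Per-position atom distributions (20 atoms with background weights,
    values binned down onto the lattice) are convolved across the window.
    An optional cache memoises the result by the multiset of per-position
    atom distributions, which is invariant under row relabelling.
    """
    L = len(window)
    lo = logodds_matrix(window, params)
    atoms = _position_atoms(lo, params.background, params.grid_step)
    key = None
    if cache is not None:
        # the convolved mass depends only on the multiset of rows; the lag
        # correlations depend on row order and are recomputed every time
        key = (L, b"".join(sorted(b.tobytes() + w.tobytes() for b, w in atoms)))
        hit = cache.get(key)
        if hit is not None:
            base, mass = hit
            return NullDistribution(min_bin=base, mass=mass,
                                    step=params.grid_step, length=L,
                                    lag_rho=_lag_correlations(lo, params.background))
    mass = np.ones(1)
    base = 0
    for ub, uw in atoms:
        shifts = ub - ub[0]
        new = np.zeros(len(mass) + int(shifts[-1]))
        for s, w in zip(shifts, uw):
            new[s : s + len(mass)] += w * mass
        base += int(ub[0])
        # truncate negligible lattice tails
        csum = np.cumsum(new)
        lo_i = int(np.searchsorted(csum, _TAIL_TRUNCATION))
        hi_csum = np.cumsum(new[::-1])
        hi_i = len(new) - int(np.searchsorted(hi_csum, _TAIL_TRUNCATION))
        lo_i = min(lo_i, len(new) - 1)
        hi_i = max(hi_i, lo_i + 1)
        base += lo_i
        mass = new[lo_i:hi_i]
    null = NullDistribution(min_bin=base, mass=mass, step=params.grid_step,
                            length=L, lag_rho=_lag_correlations(lo, params.background))
    if cache is not None:
        cache[key] = (base, mass)
    return null


#: lag correlations below this are not resolved well enough to declump
_RHO_MIN = 0.1


def _extremal_index(tail: float, lag_rho) -> float:
    """Declumping factor for the best-of-M correction.

    Overlapping offsets with a strong score correlation produce
    clustered exceedances; the expected fraction of exceedances that
    start a new cluster is estimated as prod_d (1 - q_d) with
    q_d = P(S_d >= s | S_0 >= s) under a bivariate normal coupling with
    the exact lag correlation (evaluated with Owen's T function). Weakly
    correlated lags (|rho| < 0.1) are left uncorrected: the Gaussian
    joint tail overstates their clustering.
    """
    if lag_rho is None or len(lag_rho) == 0 or not 0.0 < tail < 0.5:
        return 1.0
    strong = [r for r in lag_rho if abs(r) >= _RHO_MIN]
    if not strong:
        return 1.0
    from scipy.special import ndtr, ndtri, owens_t

    z = -ndtri(tail)
    theta = 1.0
    for r in strong:
        r = min(max(r, -0.99), 0.99)
        joint = ndtr(-z) - 2.0 * owens_t(z, math.sqrt((1 - r) / (1 + r)))
        theta *= max(0.0, 1.0 - min(joint / tail, 1.0))
    return theta


def alignment_pvalue(score: float, null: NullDistribution, n_offsets: int) -> float:
    """P-value of the best-of-M alignment score.

    tail = P(S >= score) for a single offset; the best over M offsets is
    corrected as p = 1 - (1 - theta * tail)^M, where theta <= 1 is the
    extremal-index (declumping) factor accounting for clustered
    exceedances at strongly correlated overlapping offsets. With no
    strong lag correlation theta = 1 and the formula reduces to the
    plain independence correction 1 - (1 - tail)^M.
    """
    if n_offsets < 1:
        raise ValueError("n_offsets must be >= 1")
    tail = float(null.tail(score))
    tail = min(max(tail, 0.0), 1.0)
    if tail >= 1.0:
        return 1.0
    eff = min(tail * _extremal_index(tail, null.lag_rho), 1.0 - 1e-16)
    p = -np.expm1(n_offsets * np.log1p(-eff))
    return float(min(max(p, 1e-300), 1.0))


def certified_pvalue_bound(score: float, length: int, n_offsets: int,
                           grid_step: float) -> float:
    """Certified upper bound on the discretized best-of-M p-value.

    For the log-odds score the exponential Markov inequality at unit
    rate is tight and free: E[exp(S)] = 1 under the null, hence
    P(S >= s) <= exp(-s). The margin absorbs the lattice discretization
    (at most one grid step per position plus the threshold compensation),
    so the bound also dominates the discretized tail; with the union
    bound over offsets, p <= M * exp(-(s - margin)). Used to skip the
    exact convolution when the bound already settles a threshold test.
    """
    margin = (length + 2) * grid_step
    return float(min(1.0, n_offsets * np.exp(-(score - margin))))


def score_pvalues(scores, null: NullDistribution, n_offsets: int) -> np.ndarray:
    """Vectorized `alignment_pvalue` for an array of scores."""
    return np.array([alignment_pvalue(float(s), null, n_offsets)
                     for s in np.asarray(scores, dtype=float)])
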