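"""Random walk with restart (RWR) over the PPA network.

The walker steps along edges of the column-stochastic transition matrix W and
at every step returns to the seed distribution p0 with probability r.  The
stationary distribution

    p_inf = r * (I - (1 - r) * W)^-1 * p0

measures global network proximity of every gene to the seed set.  Because p0
is 1/m on the m seed genes and 0 elsewhere, p_inf is the mean of the m seed
columns of R = r * (I - (1 - r) * W)^-1, an O(m*n) reduction once R is
available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .network import SeedSet, TransitionMatrix

#: restart probability used throughout unless overridden
DEFAULT_RESTART = 0.7

#: above this network size the linear system is kept factorized instead of
#: forming the dense resolvent explicitly
DENSE_THRESHOLD = 2000


@dataclass
class RWRParams:
    """Tuning knobs of the walk.

    r: restart probability in (0, 1]; tol: L1 convergence tolerance of the
    iterative method; max_iter: iteration cap for the iterative method.
    """

    r: float = DEFAULT_RESTART
    tol: float = 1e-10
    max_iter: int = 10_000

    def __post_init__(self) -> None:
        if not 0.0 < self.r <= 1.0:
            raise ValueError(f"restart probability must be in (0, 1], got {self.r}")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class WalkMatrix:
    """Precomputed resolvent R = r(I - (1-r)W)^-1, dense or factorized.

    For small networks ``R`` is held explicitly; for large ones only the LU
    factorization of (I - (1-r)W) is stored and seed columns are produced by
    back-substitution.  Either route yields the same stationary profile.
    """

    r: float
    n: int
    genes: tuple[str, ...]
    R: np.ndarray | None = None
    lu: tuple = field(default=None, repr=False)  # type: ignore[assignment]

    def seed_columns(self, idx: np.ndarray) -> np.ndarray:
        """Columns of R for the given gene indices, shape (n, len(idx))."""
        if self.R is not None:
            return self.R[:, idx]
        rhs = np.zeros((self.n, len(idx)))
        rhs[idx, np.arange(len(idx))] = self.r
        return scipy.linalg.lu_solve(self.lu, rhs)


@dataclass
class WalkProfile:
    """Stationary probability vector of one walk, indexed like the network."""

    p: np.ndarray
    genes: tuple[str, ...]
    seeds: SeedSet
    r: float

    def score_of(self, gene: str) -> float | None:
        try:
            return float(self.p[self.genes.index(gene)])
        except ValueError:
            return None


def precompute_walk_matrix(W: TransitionMatrix, params: RWRParams) -> WalkMatrix:
    """Factor (I - (1-r)W); materialize R densely below DENSE_THRESHOLD.

    The system is nonsingular for any r > 0 with a column-stochastic W
    (spectral radius of (1-r)W is 1-r < 1); a singular report indicates a
    broken transition matrix and is raised loudly.
    """
    n = W.n
    M = np.eye(n) - (1.0 - params.r) * W.W
    if n <= DENSE_THRESHOLD:
        R = params.r * np.linalg.solve(M, np.eye(n))
        return WalkMatrix(r=params.r, n=n, genes=W.genes, R=R)
    lu = scipy.linalg.lu_factor(M)
    return WalkMatrix(r=params.r, n=n, genes=W.genes, lu=lu)


def rwr_closed_form(R: WalkMatrix, seeds: SeedSet) -> WalkProfile:
    """Stationary profile via the seed-column shortcut.

    Sums the m seed columns of R and divides by m — O(m*n) given a dense R —
    which equals the full product R @ p0 exactly.
    """
    if seeds.m == 0:
        raise ValueError("empty seed set")
    idx = np.array([R.genes.index(g) for g in seeds.members])
    cols = R.seed_columns(idx)
    p = cols.sum(axis=1) / seeds.m
    return WalkProfile(p=p, genes=R.genes, seeds=seeds, r=R.r)


def rwr_iterative(
    W: TransitionMatrix, seeds: SeedSet, params: RWRParams
) -> WalkProfile:
    """Stationary profile by power iteration of the defining recurrence
    p_{t+1} = (1-r) W p_t + r p0, stopped when the L1 change drops below tol.

    Used as an independent oracle for the closed form and as a fallback.
    """
    if seeds.m == 0:
        raise ValueError("empty seed set")
    p0 = seeds.p0
    p = p0.copy()
    one_minus_r = 1.0 - params.r
    for _ in range(params.max_iter):
        p_next = one_minus_r * (W.W @ p) + params.r * p0
        delta = np.abs(p_next - p).sum()
        p = p_next
        if delta < params.tol:
            return WalkProfile(p=p, genes=W.genes, seeds=seeds, r=params.r)
    raise RuntimeError(
        f"RWR did not converge within {params.max_iter} iterations "
        f"(last L1 residual {delta:.3e})"
    )


def walk_scores(
    profile: WalkProfile, candidates: list[str]
) -> tuple[dict[str, float], set[str]]:
    """Stationary probability per candidate gene.

    Returns (scores, off_network): candidates absent from the network score
    0.0 and are flagged in the off_network set.
    """
    index = {g: i for i, g in enumerate(profile.genes)}
    scores: dict[str, float] = {}
    off_network: set[str] = set()
    for gene in candidates:
        i = index.get(gene)
        if i is None:
            scores[gene] = 0.0
            off_network.add(gene)
        else:
            scores[gene] = float(profile.p[i])
    return scores, off_network


def walk_percentiles(profile: WalkProfile, scores: dict[str, float]) -> dict[str, float]:
    """Percentile of each candidate's stationary probability among all
    network genes' values (fraction of genes with a value <= the candidate's).

    Off-network candidates (score 0.0, not a network gene) get percentile 0.
    Raw stationary probabilities scale as 1/n across networks; the percentile
    is the scale-free feature the score fusion uses by default.
    """
    sorted_p = np.sort(profile.p)
    n = len(sorted_p)
    index = set(profile.genes)
    out: dict[str, float] = {}
    for gene, s in scores.items():
        if gene not in index:
            out[gene] = 0.0
        else:
            out[gene] = float(np.searchsorted(sorted_p, s, side="right") / n)
    return out
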