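"""Two-point linkage analysis for 1:1-segregating markers.

For a pair of markers that are both informative in the same parent of an
F1 pseudo-testcross, the co-observed progeny fall into four combined
genotype classes (aa/aa, aa/ab, ab/aa, ab/ab). Under linkage at
recombination fraction r with known phase, recombinant gametes occur with
probability r, so the recombinant count k is Binomial(n, r). The phase is
unknown a priori and is inferred by taking the arrangement that minimises
the recombinant count, i.e. maximises the likelihood:

    r_hat = min(m, n - m) / n,   m = off-diagonal (aa/ab + ab/aa) count

The LOD score is the base-10 log likelihood ratio of linkage at r_hat
against independence (r = 1/2):

    LOD = (n - k) log10(2 (1 - r_hat)) + k log10(2 r_hat)

with the k log10(2 r) term taken as 0 when k = 0. Its expectation under
true recombination fraction r,

    ELOD(r, n) = n [(1 - r) log10(2 (1 - r)) + r log10(2 r)]

measures the support a cross of n progeny is expected to provide; at
n = 150 and r = 0.30 it equals 5.36. Map distances use the Kosambi
function d = 25 ln((1 + 2r) / (1 - 2r)) cM, whose inverse is
r = tanh(2d / 100) / 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix import AA, AB, GenotypeMatrix

COUPLING = "coupling"
REPULSION = "repulsion"
UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class PairCounts:
    """Co-observed 2x2 genotype-class table for one marker pair."""

    n_aa_aa: int
    n_aa_ab: int
    n_ab_aa: int
    n_ab_ab: int

    def __post_init__(self) -> None:
        if min(self.n_aa_aa, self.n_aa_ab, self.n_ab_aa, self.n_ab_ab) < 0:
            raise ValueError("class counts must be non-negative")

    @property
    def n(self) -> int:
        """Total co-observed progeny."""
        return self.n_aa_aa + self.n_aa_ab + self.n_ab_aa + self.n_ab_ab

    @property
    def off_diagonal(self) -> int:
        """Progeny whose coded classes differ between the two markers."""
        return self.n_aa_ab + self.n_ab_aa


@dataclass(frozen=True)
class PairwiseLinkage:
    """Two-point estimate for one marker pair."""

    r_hat: float
    phase: str
    lod: float
    n: int


class UninformativePairError(ValueError):
    """Raised for marker pairs that carry no recombination information."""


def count_pair(g_a: np.ndarray, g_b: np.ndarray) -> PairCounts:
    """Tabulate combined genotype classes over co-observed progeny."""
    g_a = np.asarray(g_a)
    g_b = np.asarray(g_b)
    if g_a.shape != g_b.shape:
        raise ValueError("marker call vectors must share the progeny ordering")
    both = (g_a >= 0) & (g_b >= 0)
    a, b = g_a[both], g_b[both]
    return PairCounts(
        n_aa_aa=int(((a == AA) & (b == AA)).sum()),
        n_aa_ab=int(((a == AA) & (b == AB)).sum()),
        n_ab_aa=int(((a == AB) & (b == AA)).sum()),
        n_ab_ab=int(((a == AB) & (b == AB)).sum()),
    )


def _lod_from_nk(n: int, k: int) -> float:
    r = k / n
    lod = (n - k) * np.log10(2.0 * (1.0 - r))
    if k > 0:
        lod += k * np.log10(2.0 * r)
    return float(lod)


def estimate_rf(counts: PairCounts) -> PairwiseLinkage:
    """Maximum-likelihood recombination fraction, phase and LOD for a pair.

    The phase minimising the recombinant count is selected; a tie
    (m = n - m) gives r_hat = 0.5, LOD = 0 and an undetermined phase.
    """
    n = counts.n
    if n == 0:
        raise UninformativePairError("no co-observed progeny for this pair")
    m = counts.off_diagonal
    if m < n - m:
        phase, k = COUPLING, m
    elif m > n - m:
        phase, k = REPULSION, n - m
    else:
        phase, k = UNDETERMINED, m
    return PairwiseLinkage(r_hat=k / n, phase=phase, lod=_lod_from_nk(n, k), n=n)


def expected_lod(r: float, n: int) -> float:
    """Expected LOD score for a pair at true recombination fraction r."""
    if not (0.0 < r <= 0.5):
        raise ValueError("r must lie in (0, 0.5]")
    if n < 1:
        raise ValueError("n must be at least 1")
    return float(n * ((1.0 - r) * np.log10(2.0 * (1.0 - r)) + r * np.log10(2.0 * r)))


def kosambi_distance(r):
    """Kosambi map distance in cM; r may be a scalar or array in [0, 0.5)."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0.0) or np.any(r >= 0.5):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    d = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    return float(d) if d.ndim == 0 else d


def kosambi_inverse(d):
    """Recombination fraction for a Kosambi distance d >= 0 (cM)."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0.0):
        raise ValueError("map distance must be non-negative")
    r = np.tanh(2.0 * d / 100.0) / 2.0
    return float(r) if r.ndim == 0 else r


def pairwise_matrix(
    mat: GenotypeMatrix,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs two-point analysis for a single-parent marker set.

    Returns
    -------
    rf, lod, n, coupling : ndarray
        Symmetric (markers x markers) arrays: recombination fraction
        estimate, LOD score, co-observed progeny count, and a boolean
        phase indicator (True where the inferred phase is coupling,
        i.e. the off-diagonal class count is the minority). Diagonal
        entries are rf = 0, lod = 0, n = per-marker observed count.
    """
    seg = set(mat.markers["seg_type"])
    if len(seg) > 1:
        raise UninformativePairError(
            "markers of different parental segregation types cannot provide "
            f"recombination information (got {sorted(seg)})"
        )
    obs = mat.observed()
    is_ab = ((mat.calls == AB) & obs).astype(np.int64)
    is_aa = ((mat.calls == AA) & obs).astype(np.int64)
    n = obs.astype(np.int64) @ obs.T.astype(np.int64)
    same = is_ab @ is_ab.T + is_aa @ is_aa.T
    m = n - same  # off-diagonal class count

    k = np.minimum(m, n - m)
    with np.errstate(divide="ignore", invalid="ignore"):
        rf = np.where(n > 0, k / np.maximum(n, 1), np.nan)
        lod = (n - k) * np.log10(2.0 * (1.0 - rf))
        term = k * np.log10(2.0 * rf)
        lod = lod + np.where(k > 0, term, 0.0)
    lod = np.where(n > 0, lod, np.nan)
    np.fill_diagonal(rf, 0.0)
    np.fill_diagonal(lod, 0.0)
    coupling = m <= n - m
    return rf, lod, n, coupling
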