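"""Structure comparison: distance maps, the Modified Jaccard Index (IMJ),
accuracy normalization, and the exponential accuracy-vs-contacts model.

Two conformations are compared through their pairwise distance matrices D
and D', which are invariant to rigid motion and mirror reflection. IMJ is

    IMJ = ||(D - D')/2|| / ||(D + D')/2||        (Frobenius norms)

0 for identical structures and ~0.378 for two unrelated random symmetric
matrices. Dividing each matrix by the radius of gyration of its polymer
makes the comparison scale-free, so structures produced by methods with
different spatial units can be compared. The reconstruction accuracy is the
linear rescaling A = (IMJ_r - IMJ) / IMJ_r * 100% with the random baseline
IMJ_r = 0.378, and it decays exponentially with the number of contacts per
bead x:

    accuracy(x) = (1 - A * exp(-x / beta)) * A_max.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr

from .conformations import Conformation, radius_of_gyration
from .contacts import ContactMap

__all__ = [
    "DistanceMap",
    "AccuracyCurve",
    "IMJ_RANDOM",
    "distance_map",
    "imj",
    "imj_random_baseline",
    "accuracy",
    "expected_accuracy",
    "fit_accuracy_curve",
    "map_similarity",
    "mirror",
]

#: Mean IMJ of two independent random symmetric matrices with iid uniform
#: [0, 1] entries; analytically sqrt(1/7) ~ 0.37796, quoted as 0.378.
IMJ_RANDOM = 0.378


@dataclass
class DistanceMap:
    """Symmetric all-pairs Euclidean distance matrix of a conformation.

    ``normalized`` marks division by the radius of gyration (values then
    dimensionless); ``mask`` is an optional symmetric boolean matrix of
    missing entries, excluded from comparisons.
    """

    values: np.ndarray
    normalized: bool = False
    mask: Optional[np.ndarray] = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance map must be square")
        if not np.allclose(v, v.T):
            raise ValueError("distance map must be symmetric")
        if (np.diag(v) != 0).any():
            raise ValueError("distance map must have zero diagonal")
        if (v < 0).any():
            raise ValueError("distances must be non-negative")
        self.values = v
        if self.mask is not None:
            m = np.asarray(self.mask, dtype=bool)
            if m.shape != v.shape:
                raise ValueError("mask shape mismatch")
            self.mask = m | m.T

    @property
    def n(self) -> int:
        return self.values.shape[0]


def distance_map(
    conf: Conformation | np.ndarray,
    normalize: bool = False,
    mask: Optional[np.ndarray] = None,
) -> DistanceMap:
    """All-pairs Euclidean distances of a conformation.

    With ``normalize`` the matrix is divided by the radius of gyration of
    the whole polymer, removing the spatial scale.
    """
    coords = conf.coords if isinstance(conf, Conformation) else np.asarray(conf)
    if coords.shape[0] < 2:
        raise ValueError("distance map needs at least 2 beads")
    d = squareform(pdist(coords))
    if normalize:
        d = d / radius_of_gyration(coords)
    return DistanceMap(d, normalized=normalize, mask=mask)


def imj(d1: DistanceMap, d2: DistanceMap) -> float:
    """Modified Jaccard Index between two distance maps.

    ``||(D - D')/2|| / ||(D + D')/2||`` with Frobenius norms; entries
    missing in either map's mask are excluded from both norms. 0 iff the
    maps are identical; in [0, 1] for non-negative inputs.
    """
    if d1.n != d2.n:
        raise ValueError(f"size mismatch: {d1.n} vs {d2.n}")
    a = d1.values
    b = d2.values
    if d1.mask is not None or d2.mask is not None:
        keep = np.ones(a.shape, dtype=bool)
        if d1.mask is not None:
            keep &= ~d1.mask
        if d2.mask is not None:
            keep &= ~d2.mask
        a = a[keep]
        b = b[keep]
    minus = np.linalg.norm((a - b) / 2.0)
    plus = np.linalg.norm((a + b) / 2.0)
    if plus == 0:
        return 0.0
    return float(minus / plus)


def imj_random_baseline(n: int = 2000, reps: int = 10, seed: int = 0) -> float:
    """Monte Carlo estimate of the IMJ of two unrelated random maps.

    Averages the IMJ over ``reps`` pairs of symmetric matrices with iid
    uniform [0, 1] entries on the off-diagonal (mirrored, zero diagonal).
    Converges to sqrt(1/7) ~ 0.37796 and is stable in ``n``.
    """
    if n < 100:
        raise ValueError("baseline estimate needs n >= 100")
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, k=1)
    vals = []
    for _ in range(reps):
        m1 = np.zeros((n, n))
        m2 = np.zeros((n, n))
        m1[iu] = rng.random(iu[0].size)
        m2[iu] = rng.random(iu[0].size)
        m1 += m1.T
        m2 += m2.T
        vals.append(imj(DistanceMap(m1), DistanceMap(m2)))
    return float(np.mean(vals))


def accuracy(imj_12: float, imj_r: float = IMJ_RANDOM) -> float:
    """Normalize an IMJ to a reconstruction accuracy in percent.

    ``A = (IMJ_r - IMJ_12) / IMJ_r * 100``: 100% for identical structures,
    0% at the random baseline. Values below 0 (worse than random) are
    reported as-is, not clipped.
    """
    if imj_r <= 0:
        raise ValueError("imj_r must be positive")
    return (imj_r - imj_12) / imj_r * 100.0


def expected_accuracy(
    x: float | np.ndarray,
    A: float = 0.642,
    beta: float = 0.239,
    a_max: float = 93.7,
) -> float | np.ndarray:
    """Exponential accuracy model: ``(1 - A * exp(-x / beta)) * a_max``.

    ``x`` is the number of contacts per bead; ``a_max`` is the accuracy
    ceiling imposed by thermal fluctuations of the reconstructed structure.
    The defaults are the fitted constants for the DPD reconstruction of an
    equilibrium globule.
    """
    return (1.0 - A * np.exp(-np.asarray(x, dtype=float) / beta)) * a_max


def fit_accuracy_curve(
    x: np.ndarray, acc: np.ndarray
) -> tuple[float, float, float]:
    """Least-squares fit of the exponential accuracy model.

    Returns (A, beta, a_max) with bounds 0 <= A <= 1, beta > 0,
    0 < a_max <= 100. Needs at least 4 points.
    """
    x = np.asarray(x, dtype=float)
    acc = np.asarray(acc, dtype=float)
    if x.size < 4:
        raise ValueError("fit needs at least 4 points")

    def model(xx, A, beta, a_max):
        return (1.0 - A * np.exp(-xx / beta)) * a_max

    x0 = (0.5, max(np.median(x), 1e-3), min(max(acc.max(), 1.0), 100.0))
    try:
        popt, _ = curve_fit(
            model, x, acc, p0=x0,
            bounds=([0.0, 1e-9, 1e-9], [1.0, np.inf, 100.0]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        resid = np.abs(acc - model(x, *x0))
        raise RuntimeError(
            f"accuracy-curve fit did not converge (initial residual "
            f"max {resid.max():.3g})"
        ) from exc
    return float(popt[0]), float(popt[1]), float(popt[2])


@dataclass
class AccuracyCurve:
    """(contacts-per-bead, accuracy%) points with an optional model fit.

    ``replicates`` keeps the raw per-replicate accuracies behind each
    averaged point.
    """

    x: np.ndarray
    acc: np.ndarray
    fit: Optional[tuple[float, float, float]] = None
    replicates: Optional[list[np.ndarray]] = None

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        if self.x.shape != self.acc.shape:
            raise ValueError("x and acc must align")
        if (self.x < 0).any():
            raise ValueError("contacts per bead must be >= 0")

    def fitted(self) -> "AccuracyCurve":
        return AccuracyCurve(
            self.x, self.acc, fit=fit_accuracy_curve(self.x, self.acc),
            replicates=self.replicates,
        )


def map_similarity(
    cmap1: ContactMap, cmap2: ContactMap, method: str = "imj"
) -> float:
    """Similarity of two contact maps of the same size.

    ``imj``: densify to symmetric 0/1 matrices and return the IMJ-based
    accuracy (percent; ~0 or negative for unrelated maps of equal
    density). ``spearman``: rank correlation of the upper triangles
    (1 for identical maps).
    """
    if cmap1.n_beads != cmap2.n_beads:
        raise ValueError("contact maps differ in size")
    m1 = cmap1.to_dense().astype(float)
    m2 = cmap2.to_dense().astype(float)
    if method == "imj":
        return accuracy(imj(DistanceMap(m1), DistanceMap(m2)))
    if method == "spearman":
        iu = np.triu_indices(cmap1.n_beads, k=1)
        a, b = m1[iu], m2[iu]
        if np.all(a == a[0]) or np.all(b == b[0]):
            raise ValueError("all-constant map: Spearman undefined")
        rho, _ = spearmanr(a, b)
        return float(rho)
    raise ValueError("method must be 'imj' or 'spearman'")


def mirror(conf: Conformation) -> Conformation:
    """Mirror image of a conformation (x axis negated).

    The distance map is invariant under reflection, so the comparison
    metric cannot distinguish a structure from its mirror image; this
    helper produces the enantiomer explicitly, e.g. for visualization with
    consistent chirality.
    """
    coords = conf.coords.copy()
    coords[:, 0] = -coords[:, 0]
    return Conformation(coords, list(conf.chains), box=conf.box,
                        genomic_bins=conf.genomic_bins,
                        meta={**conf.meta, "mirrored": True})
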