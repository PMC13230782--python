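"""Truncated integer degree distributions.

Every analytic and generative component of the package works with explicit,
finite degree distributions: a probability mass function on an inclusive
integer support ``[k_lo, k_hi]``.  Four families are supported:

``poisson``
    Poisson with mean ``z``, truncated at the smallest ``k_hi`` whose
    untruncated tail mass is below ``truncation_mass`` and renormalised.
``power_law``
    Discrete power law ``pmf(k) ∝ k**(-lam)`` on ``[k_min, k_max]``,
    normalised by direct summation over the support (no zeta-function
    approximation), as appropriate for a hard-truncated support.
``regular``
    A point mass at a fixed degree.
``empirical``
    An observed degree histogram, renormalised.

The truncation matters because the tree-like solver evaluates nested sums
over the support; all anchors reported by the package were checked to be
stable when the truncation mass is tightened tenfold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple

import numpy as np
from scipy import stats

from .errors import ParameterError

__all__ = [
    "DegreeDistribution",
    "make_distribution",
    "calibrate_power_law_mean",
    "sample_degrees",
    "PowerLawCalibration",
    "write_histogram_csv",
    "read_histogram_csv",
]

#: default untruncated tail mass allowed beyond k_hi
DEFAULT_TRUNCATION_MASS = 1e-10


@dataclass(frozen=True)
class DegreeDistribution:
    """A normalised pmf over the integer degrees ``k_lo .. k_hi`` (inclusive).

    Attributes
    ----------
    kind:
        One of ``poisson``, ``power_law``, ``regular``, ``empirical``.
    params:
        The constructor parameters, kept for provenance and serialisation.
    k_lo, k_hi:
        Inclusive support bounds.
    pmf:
        Probabilities for ``k = k_lo .. k_hi``; sums to 1 within 1e-12.
    mean:
        Expected degree computed from the pmf.
    """

    kind: str
    params: Mapping[str, float]
    k_lo: int
    k_hi: int
    pmf: np.ndarray = field(repr=False)
    mean: float

    def __post_init__(self) -> None:
        pmf = np.asarray(self.pmf, dtype=float)
        if self.k_lo < 0 or self.k_hi < self.k_lo:
            raise ParameterError(f"invalid support [{self.k_lo}, {self.k_hi}]")
        if pmf.shape != (self.k_hi - self.k_lo + 1,):
            raise ParameterError("pmf length does not match support")
        if np.any(pmf < 0):
            raise ParameterError("pmf entries must be non-negative")
        if abs(pmf.sum() - 1.0) > 1e-12:
            raise ParameterError("pmf must sum to 1 within 1e-12")
        if abs(float(self.support @ pmf) - self.mean) > 1e-9:
            raise ParameterError("stored mean inconsistent with pmf")
        object.__setattr__(self, "pmf", pmf)

    @property
    def support(self) -> np.ndarray:
        return np.arange(self.k_lo, self.k_hi + 1)

    def dense_pmf(self) -> np.ndarray:
        """pmf on ``0 .. k_hi`` with zeros below ``k_lo``."""
        out = np.zeros(self.k_hi + 1)
        out[self.k_lo :] = self.pmf
        return out


def _normalised(kind: str, params: Mapping, k_lo: int, weights: np.ndarray) -> DegreeDistribution:
    total = float(weights.sum())
    if total <= 0:
        raise ParameterError(f"{kind}: empty support after truncation")
    pmf = weights / total
    ks = np.arange(k_lo, k_lo + len(pmf))
    return DegreeDistribution(
        kind=kind,
        params=dict(params),
        k_lo=k_lo,
        k_hi=int(ks[-1]),
        pmf=pmf,
        mean=float(ks @ pmf),
    )


def make_distribution(
    kind: str,
    params: Mapping[str, float],
    truncation_mass: float = DEFAULT_TRUNCATION_MASS,
) -> DegreeDistribution:
    """Construct a truncated, renormalised degree distribution.

    Parameters
    ----------
    kind:
        Distribution family (see module docstring).
    params:
        ``poisson``: ``{"z": mean}``; ``power_law``: ``{"lam", "k_min",
        "k_max"}``; ``regular``: ``{"degree"}``; ``empirical``:
        ``{"degrees", "weights"}`` (parallel sequences).
    truncation_mass:
        Maximum untruncated tail mass allowed beyond ``k_hi`` for unbounded
        families.  Must lie in ``(0, 1e-6]``.
    """
    if not (0.0 < truncation_mass <= 1e-6):
        raise ParameterError("truncation_mass must lie in (0, 1e-6]")

    if kind == "poisson":
        z = float(params["z"])
        if z < 0:
            raise ParameterError("poisson: z must be >= 0")
        if z == 0:
            return _normalised(kind, {"z": z}, 0, np.array([1.0]))
        # smallest k_hi with P(K > k_hi) <= truncation_mass
        k_hi = int(stats.poisson.isf(truncation_mass, z))
        while stats.poisson.sf(k_hi, z) > truncation_mass:
            k_hi += 1
        weights = stats.poisson.pmf(np.arange(k_hi + 1), z)
        return _normalised(kind, {"z": z}, 0, weights)

    if kind == "power_law":
        lam = float(params["lam"])
        k_min = int(params["k_min"])
        k_max = int(params["k_max"])
        if lam <= 2:
            raise ParameterError("power_law: lam must exceed 2 for a finite mean")
        if not (1 <= k_min <= k_max):
            raise ParameterError("power_law: need 1 <= k_min <= k_max")
        ks = np.arange(k_min, k_max + 1, dtype=float)
        weights = ks ** (-lam)
        return _normalised(kind, {"lam": lam, "k_min": k_min, "k_max": k_max}, k_min, weights)

    if kind == "regular":
        degree = int(params["degree"])
        if degree < 0:
            raise ParameterError("regular: degree must be >= 0")
        return _normalised(kind, {"degree": degree}, degree, np.array([1.0]))

    if kind == "empirical":
        degrees = np.asarray(params["degrees"], dtype=int)
        weights = np.asarray(params["weights"], dtype=float)
        if degrees.ndim != 1 or degrees.shape != weights.shape or len(degrees) == 0:
            raise ParameterError("empirical: degrees/weights must be parallel non-empty sequences")
        if np.any(weights < 0) or weights.sum() <= 0:
            raise ParameterError("empirical: weights must be non-negative with positive total")
        k_lo, k_hi = int(degrees.min()), int(degrees.max())
        dense = np.zeros(k_hi - k_lo + 1)
        np.add.at(dense, degrees - k_lo, weights)
        return _normalised(kind, {"degrees": degrees.tolist(), "weights": weights.tolist()}, k_lo, dense)

    raise ParameterError(f"unknown distribution kind {kind!r}")


class PowerLawCalibration(NamedTuple):
    k_min: int
    achieved_mean: float


def _truncated_power_law_mean(lam: float, k_min: int, k_max: int) -> float:
    ks = np.arange(k_min, k_max + 1, dtype=float)
    w = ks ** (-lam)
    return float((ks * w).sum() / w.sum())


def calibrate_power_law_mean(lam: float, target_mean: float, k_max: int) -> PowerLawCalibration:
    """Find the integer ``k_min`` whose truncated power-law mean on
    ``[k_min, k_max]`` is closest to ``target_mean``.

    The truncated mean is strictly increasing in ``k_min`` (from the
    ``k_min = 1`` value up to ``k_max`` at ``k_min = k_max``), so a scan is
    exact.  Returns the chosen ``k_min`` together with the achieved mean so
    callers can record the deviation from the requested value.
    """
    if lam <= 2:
        raise ParameterError("lam must exceed 2 for a finite mean")
    if k_max < 1:
        raise ParameterError("k_max must be >= 1")
    lo = _truncated_power_law_mean(lam, 1, k_max)
    if not (lo <= target_mean <= k_max):
        raise ParameterError(
            f"target_mean={target_mean} not achievable on [1, {k_max}]: "
            f"attainable range is [{lo:.6g}, {k_max}]"
        )
    best = PowerLawCalibration(1, lo)
    for k_min in range(1, k_max + 1):
        m = _truncated_power_law_mean(lam, k_min, k_max)
        if abs(m - target_mean) < abs(best.achieved_mean - target_mean):
            best = PowerLawCalibration(k_min, m)
        if m > target_mean:
            break  # mean increases with k_min; no better candidate ahead
    return best


def sample_degrees(dist: DegreeDistribution, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` i.i.d. degrees from ``dist`` (deterministic per seeded rng)."""
    if n < 1:
        raise ParameterError("n must be >= 1")
    idx = rng.choice(len(dist.pmf), size=n, p=dist.pmf)
    return idx + dist.k_lo


def write_histogram_csv(path, dist: DegreeDistribution) -> None:
    """Two-column CSV (degree, probability) for any distribution's pmf."""
    with open(path, "w") as fh:
        fh.write("degree,probability\n")
        for k, p in zip(dist.support, dist.pmf):
            fh.write(f"{k},{float(p)!r}\n")


def read_histogram_csv(path) -> DegreeDistribution:
    """Load a two-column (degree, probability) CSV as an empirical distribution."""
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    return make_distribution("empirical", {"degrees": data[:, 0].astype(int),
                                           "weights": data[:, 1]})
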