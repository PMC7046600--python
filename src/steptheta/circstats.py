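"""Circular statistics: mean resultant vector, Rayleigh test, histograms.

The depth of phase modulation is quantified by summing all event phases
as unit vectors and normalizing by the event count (Zar's mean-vector
method): r ranges from 0 (uniform phase distribution) to 1 (all phases
identical) and the direction of the resultant is the preferred mean
phase.  Significance of phase concentration uses the Rayleigh test with
Zar's exponential approximation of the p value.

All public interfaces take and return degrees; radians appear only
internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as spstats

DEFAULT_BIN_DEG = 18


def mean_vector(phases_deg: np.ndarray) -> tuple[float, float]:
    """Mean resultant length and mean angle of a phase sample.

    r = |sum exp(i*phi)| / n; the angle is the argument of the sum
    mapped to [0, 360).  For r below 1e-12 the direction is numerically
    meaningless and the angle is returned as NaN.
    """
    phi = np.radians(np.asarray(phases_deg, dtype=float))
    if phi.size == 0:
        raise ValueError("empty phase sample")
    z = np.exp(1j * phi).sum() / phi.size
    r = float(np.abs(z))
    if r < 1e-12:
        return r, float("nan")
    ang = float(np.degrees(np.angle(z))) % 360.0
    if 360.0 - ang < 1e-9:          # fold the wraparound back to 0
        ang = 0.0
    return r, ang


def circular_mean_deg(angles_deg: np.ndarray) -> float:
    """Circular mean of a set of angles (e.g. per-session mean phases)."""
    _, ang = mean_vector(np.asarray(angles_deg, dtype=float))
    return ang


def rayleigh_test(phases_deg: np.ndarray, method: str = "zar") -> float:
    """Rayleigh test p value for circular uniformity.

    ``zar`` (default) uses the exponential approximation
    p = exp( sqrt(1 + 4n + 4(n^2 - R^2)) - (1 + 2n) ) with R = n*r;
    ``refined`` adds the higher-order series correction to exp(-z),
    z = n*r^2.  Both are clipped into (0, 1].  Accurate for n >= 5;
    smaller samples are accepted but the approximation is rough.
    """
    phi = np.asarray(phases_deg, dtype=float)
    if phi.size == 0:
        raise ValueError("empty phase sample")
    n = phi.size
    r, _ = mean_vector(phi)
    R = n * r
    z = n * r * r
    if method == "zar":
        p = np.exp(np.sqrt(1.0 + 4.0 * n + 4.0 * (n * n - R * R))
                   - (1.0 + 2.0 * n))
    elif method == "refined":
        p = np.exp(-z) * (1.0 + (2.0 * z - z * z) / (4.0 * n)
                          - (24.0 * z - 132.0 * z ** 2 + 76.0 * z ** 3
                             - 9.0 * z ** 4) / (288.0 * n * n))
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(np.clip(p, np.finfo(float).tiny, 1.0))


def phase_histogram(phases_deg: np.ndarray,
                    bin_deg: int = DEFAULT_BIN_DEG) -> np.ndarray:
    """Counts over half-open phase bins [k*bin, (k+1)*bin)."""
    if 360 % bin_deg != 0:
        raise ValueError("bin_deg must divide 360")
    phi = np.mod(np.asarray(phases_deg, dtype=float), 360.0)
    nbins = 360 // bin_deg
    counts, _ = np.histogram(phi, bins=nbins, range=(0.0, 360.0))
    return counts


def duplicated_histogram(counts: np.ndarray) -> np.ndarray:
    """Two-cycle (0-720 degree) view of a phase histogram, for plotting
    rhythmicity the way phase histograms are conventionally shown."""
    return np.concatenate([counts, counts])


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction; p from chi-square (k-1 df).

    Degenerate input where every value across all groups is identical is
    reported as no effect (H = 0, p = 1).
    """
    if len(groups) < 2 or any(len(g) < 1 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = spstats.kruskal(*groups)
    return float(h), float(p)


@dataclass
class CouplingResult:
    """Phase-coupling summary for one event set against one phase signal."""

    n: int
    r: float
    mean_angle_deg: float
    rayleigh_p: float
    histogram: np.ndarray = field(default_factory=lambda: np.zeros(0, int))
    bin_deg: int = DEFAULT_BIN_DEG
    excluded: bool = False        # below the minimum-event filter
    n_dropped: int = 0            # events outside the valid phase span

    @classmethod
    def from_phases(cls, phases_deg: np.ndarray,
                    bin_deg: int = DEFAULT_BIN_DEG,
                    n_dropped: int = 0,
                    rayleigh_method: str = "zar") -> "CouplingResult":
        r, ang = mean_vector(phases_deg)
        return cls(n=int(np.asarray(phases_deg).size), r=r,
                   mean_angle_deg=ang,
                   rayleigh_p=rayleigh_test(phases_deg, rayleigh_method),
                   histogram=phase_histogram(phases_deg, bin_deg),
                   bin_deg=bin_deg, n_dropped=n_dropped)

    @classmethod
    def below_threshold(cls, n: int, n_dropped: int = 0) -> "CouplingResult":
        """Marker for event sets failing the minimum-count filter: the
        count is kept but no statistics are computed."""
        return cls(n=n, r=float("nan"), mean_angle_deg=float("nan"),
                   rayleigh_p=float("nan"), excluded=True,
                   n_dropped=n_dropped)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "r": None if np.isnan(self.r) else self.r,
            "mean_angle_deg": (None if np.isnan(self.mean_angle_deg)
                               else self.mean_angle_deg),
            "rayleigh_p": (None if np.isnan(self.rayleigh_p)
                           else self.rayleigh_p),
            "histogram": self.histogram.tolist(),
            "bin_deg": self.bin_deg,
            "excluded": self.excluded,
            "n_dropped": self.n_dropped,
        }
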