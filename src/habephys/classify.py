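"""Subtype classification: VB-GMM clustering on (RDP duration, frequency
adaptation index), threshold derivation, four-subtype assignment and
behavioural phenotyping.

Feature scaling: both features are standardized before fitting (the
fitting routine can optionally log10-transform RDP durations, which span
two orders of magnitude) and the transform is inverted for reporting.
Thresholds between the short/long and HF/LF groups are the midpoints
between the nearest opposing cluster members along each axis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.mixture import BayesianGaussianMixture

WEIGHT_FLOOR = 0.01  # fraction of total weight below which a component
                     # does not count as "effective"

# published decision boundaries
DEFAULT_THETA_RDP_MS = 400.0
DEFAULT_THETA_FAI = 0.8


@dataclass
class ClusterModel:
    """Fitted VB-GMM in (rdp_ms, fai) feature space (original units)."""

    means: np.ndarray          # (k, 2) in original units
    covariances: np.ndarray    # (k, 2, 2) in original units
    weights: np.ndarray        # (k,)
    labels: np.ndarray         # hard assignment of the training points
    responsibilities: np.ndarray
    log_rdp: bool
    seed: int
    k_max: int = 10
    weight_floor: float = WEIGHT_FLOOR

    @property
    def effective_components(self) -> np.ndarray:
        """Indices of components carrying more than ``weight_floor``."""
        return np.flatnonzero(self.weights > self.weight_floor)

    @property
    def n_effective(self) -> int:
        return int(self.effective_components.size)

    def to_json(self) -> str:
        return json.dumps({
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
            "weights": self.weights.tolist(),
            "log_rdp": self.log_rdp,
            "seed": self.seed,
            "k_max": self.k_max,
            "weight_floor": self.weight_floor,
            "n_effective": self.n_effective,
        }, indent=2)


@dataclass
class Thresholds:
    """Axis-wise decision boundaries between the 2x2 subtype groups."""

    theta_rdp_ms: float = DEFAULT_THETA_RDP_MS
    theta_fai: float = DEFAULT_THETA_FAI

    def __post_init__(self) -> None:
        if not self.theta_rdp_ms > 0:
            raise ValueError("theta_rdp_ms must be > 0")
        if not 0.0 < self.theta_fai < 1.0:
            raise ValueError("theta_fai must lie in (0, 1)")

    def to_json(self) -> str:
        return json.dumps({"theta_rdp_ms": self.theta_rdp_ms,
                           "theta_fai": self.theta_fai}, indent=2)


@dataclass
class SubtypeLabel:
    rdp_class: str                  # "short" | "long"
    firing_class: Optional[str]     # "HF" | "LF" | None (undefined fai)

    @property
    def combined(self) -> Optional[str]:
        if self.firing_class is None:
            return None
        return f"{self.rdp_class}&{self.firing_class}"


def _prepare(points: np.ndarray, log_rdp: bool):
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (rdp_ms, fai)")
    if not np.isfinite(pts).all():
        raise ValueError("points must be finite")
    x = pts.copy()
    if log_rdp:
        if (x[:, 0] < 0).any():
            raise ValueError("rdp_ms must be >= 0 for the log transform")
        x[:, 0] = np.log10(x[:, 0] + 1.0)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return (x - mu) / sd, mu, sd


def fit_vbgmm(points, seed: int = 0, *, k_max: int = 10, n_init: int = 10,
              log_rdp: bool = False) -> ClusterModel:
    """Variational Bayesian GMM on (rdp_ms, fai) pairs.

    Standardizes features (optionally log10-transforming durations),
    fits a Dirichlet-distribution-weighted mixture with up to ``k_max``
    components over ``n_init`` seeded restarts and maps the fitted
    parameters back to original units.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 10:
        raise ValueError("need at least 10 points")
    z, mu, sd = _prepare(pts, log_rdp)
    gmm = BayesianGaussianMixture(
        n_components=k_max,
        weight_concentration_prior_type="dirichlet_distribution",
        covariance_type="full",
        n_init=n_init,
        max_iter=500,
        random_state=int(seed),
        reg_covar=1e-6,
    )
    labels = gmm.fit_predict(z)
    resp = gmm.predict_proba(z)
    # invert standardization (log-axis means stay on the log scale of the
    # transformed feature, converted back below)
    means = gmm.means_ * sd + mu
    covs = gmm.covariances_ * np.outer(sd, sd)
    if log_rdp:
        means[:, 0] = 10.0 ** means[:, 0] - 1.0
    return ClusterModel(means=means, covariances=covs,
                        weights=gmm.weights_.copy(), labels=labels,
                        responsibilities=resp, log_rdp=log_rdp,
                        seed=int(seed), k_max=k_max)


class ThresholdsUndefined(ValueError):
    """Raised when a model has too few components to derive thresholds."""


def derive_thresholds(model: ClusterModel, points) -> Thresholds:
    """Axis-wise boundaries from a fitted cluster model.

    Components are merged into low/high groups along each axis by their
    means (split at the largest gap between sorted effective-component
    means); the threshold is the midpoint between the nearest opposing
    training points along that axis.
    """
    pts = np.asarray(points, dtype=float)
    eff = model.effective_components
    if eff.size < 2:
        raise ThresholdsUndefined(
            "threshold derivation needs >= 2 effective components")
    out = {}
    for axis, name in ((0, "theta_rdp_ms"), (1, "theta_fai")):
        cmeans = model.means[eff, axis]
        order = np.argsort(cmeans)
        if np.ptp(cmeans) <= 0:
            raise ThresholdsUndefined(f"no separation along axis {name}")
        vals = pts[:, axis]
        # candidate low/high groupings: every split between adjacent
        # sorted component means; keep the one whose member points leave
        # the widest empty band (the mixture may split a broad group
        # into several components, so the largest mean-to-mean gap can
        # fall inside one group)
        best = None
        for split in range(eff.size - 1):
            low_comps = eff[order[:split + 1]]
            member_low = np.isin(model.labels, low_comps)
            lo_vals = vals[member_low]
            hi_vals = vals[~member_low]
            if lo_vals.size == 0 or hi_vals.size == 0:
                continue
            margin = hi_vals.min() - lo_vals.max()
            if best is None or margin > best[0]:
                best = (margin, lo_vals.max(), hi_vals.min())
        if best is None:
            raise ThresholdsUndefined(f"degenerate grouping along {name}")
        out[name] = 0.5 * (best[1] + best[2])
    return Thresholds(theta_rdp_ms=out["theta_rdp_ms"],
                      theta_fai=out["theta_fai"])


def assign_subtype(rdp_ms: float, fai: Optional[float],
                   thresholds: Thresholds = Thresholds()) -> SubtypeLabel:
    """short iff rdp_ms < theta_rdp; HF iff fai <= theta_fai.

    An undefined ``fai`` (None or NaN) leaves ``firing_class`` undefined;
    such cells are retained in two-way RDP tables but excluded from
    four-way tables.
    """
    if not np.isfinite(rdp_ms) or rdp_ms < 0:
        raise ValueError("rdp_ms must be finite and >= 0")
    rdp_class = "short" if rdp_ms < thresholds.theta_rdp_ms else "long"
    if fai is None or not np.isfinite(fai):
        return SubtypeLabel(rdp_class=rdp_class, firing_class=None)
    firing = "HF" if fai <= thresholds.theta_fai else "LF"
    return SubtypeLabel(rdp_class=rdp_class, firing_class=firing)


def phenotype_mouse(interaction_time_s: float,
                    interaction_ratio: float) -> str:
    """susceptible iff (ratio < 1 and time < 40 s); else resilient iff
    (ratio > 1 or time > 60 s); else intermediate."""
    if not (np.isfinite(interaction_time_s) and np.isfinite(interaction_ratio)):
        raise ValueError("inputs must be finite")
    if interaction_time_s < 0 or interaction_ratio < 0:
        raise ValueError("inputs must be non-negative")
    if interaction_ratio < 1.0 and interaction_time_s < 40.0:
        return "susceptible"
    if interaction_ratio > 1.0 or interaction_time_s > 60.0:
        return "resilient"
    return "intermediate"


# ---------------------------------------------------------------------------
# synthetic layouts for recovery tests
# ---------------------------------------------------------------------------

def two_cluster_layout(n_per: int = 100, seed: int = 0):
    """Two well-separated Gaussians in (rdp_ms, fai); returns (points,
    labels)."""
    rng = np.random.default_rng(seed)
    a = np.column_stack([rng.normal(250.0, 40.0, n_per),
                         rng.normal(0.2, 0.05, n_per)])
    b = np.column_stack([rng.normal(4000.0, 500.0, n_per),
                         rng.normal(0.9, 0.04, n_per)])
    pts = np.vstack([a, b])
    labels = np.repeat([0, 1], n_per)
    return pts, labels


def five_cluster_layout(n_per: int = 40, seed: int = 0):
    """Five-cluster layout in (rdp_ms, fai) emulating a 2x2 subtype map
    with one extra long-duration cluster; returns (points, labels)."""
    rng = np.random.default_rng(seed)
    centers = [
        (150.0, 0.15), (250.0, 0.95),       # short & HF / short & LF
        (2000.0, 0.2), (2500.0, 0.92),      # long & HF / long & LF
        (6000.0, 0.55),                      # very-long cluster
    ]
    sds = [(35.0, 0.045), (45.0, 0.035), (250.0, 0.05),
           (300.0, 0.04), (500.0, 0.06)]
    pts, labels = [], []
    for k, ((cx, cy), (sx, sy)) in enumerate(zip(centers, sds)):
        pts.append(np.column_stack([rng.normal(cx, sx, n_per),
                                    rng.normal(cy, sy, n_per)]))
        labels.append(np.full(n_per, k))
    pts = np.vstack(pts)
    pts[:, 1] = np.clip(pts[:, 1], 0.0, 1.0)
    pts[:, 0] = np.clip(pts[:, 0], 1.0, None)
    return pts, np.concatenate(labels)


def gapped_duration_layout(n_per: int = 60, seed: int = 0,
                           gap_lo_ms: float = 350.0,
                           gap_hi_ms: float = 450.0):
    """Cohort whose duration histogram has an empty gap (default
    350-450 ms) between the short and long groups; returns (points,
    labels).  Threshold recovery should land inside the gap."""
    rng = np.random.default_rng(seed)
    short = np.column_stack([rng.uniform(120.0, gap_lo_ms, n_per),
                             rng.normal(0.25, 0.08, n_per)])
    long_ = np.column_stack([rng.uniform(gap_hi_ms, 2500.0, n_per),
                             rng.normal(0.9, 0.05, n_per)])
    pts = np.vstack([short, long_])
    pts[:, 1] = np.clip(pts[:, 1], 0.0, 1.0)
    return pts, np.repeat([0, 1], n_per)


def assignment_accuracy(true_labels: Sequence[int],
                        predicted: Sequence[int]) -> float:
    """Best-case accuracy over label permutations (greedy by overlap)."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted)
    mapping = {}
    used = set()
    # assign predicted clusters to true labels by decreasing overlap
    pairs = []
    for pv in np.unique(p):
        for tv in np.unique(t):
            pairs.append((int(np.sum((p == pv) & (t == tv))), pv, tv))
    for count, pv, tv in sorted(pairs, reverse=True):
        if pv not in mapping and tv not in used:
            mapping[pv] = tv
            used.add(tv)
    mapped = np.array([mapping.get(v, -1) for v in p])
    return float(np.mean(mapped == t))
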