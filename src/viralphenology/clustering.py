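"""Seasonal-profile construction and k-medoids clustering.

Seasonal taxa are summarized by their z-scored monthly mean profile (12
values, Jan..Dec) and clustered by PAM (partitioning around medoids,
BUILD then SWAP) under Euclidean distance; the number of clusters is the
one minimizing a medoid-based Davies-Bouldin index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import RegularSeries

__all__ = [
    "SeasonalProfile",
    "ClusterSolution",
    "seasonal_profile",
    "kmedoids",
    "davies_bouldin",
    "select_k",
    "peak_month",
    "season_of_month",
]

MONTHS = ["Jan", "Feb", "Mar", "Apr", "May", "Jun",
          "Jul", "Aug", "Sep", "Oct", "Nov", "Dec"]

#: Meteorological season bins: Dec-Feb winter, Mar-May spring, etc.
_SEASONS = ["winter", "winter", "spring", "spring", "spring", "summer",
            "summer", "summer", "fall", "fall", "fall", "winter"]


@dataclass
class SeasonalProfile:
    """z-scored monthly mean abundance, indexed Jan..Dec (0-based months)."""

    taxon_id: str
    z: np.ndarray
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.shape != (12,):
            raise ValueError("seasonal profile must have 12 monthly values")


@dataclass
class ClusterSolution:
    k: int
    assignments: dict[str, int]  # taxon -> cluster id (0-based)
    medoids: dict[int, str]  # cluster id -> medoid taxon
    db_index: float | None = None
    db_by_k: dict[int, float] = field(default_factory=dict)


def seasonal_profile(series: RegularSeries) -> SeasonalProfile:
    """Monthly means across years, z-scored over the 12 calendar months.

    Requires every calendar month to be represented at least once on the
    series grid (i.e. >= 12 consecutive months).  A flat profile (zero
    variance across months) is returned as a zero vector flagged degenerate.
    """
    months = series.calendar_months
    if len(np.unique(months)) < 12:
        raise ValueError(
            f"{series.taxon_id or 'series'}: needs all 12 calendar months, "
            f"got {len(np.unique(months))}"
        )
    m = np.array([series.values[months == mo].mean() for mo in range(12)])
    sd = m.std()
    if sd == 0:
        return SeasonalProfile(series.taxon_id, np.zeros(12), degenerate=True)
    return SeasonalProfile(series.taxon_id, (m - m.mean()) / sd)


def _profile_matrix(profiles: list[SeasonalProfile]) -> tuple[list[str], np.ndarray]:
    ids = [p.taxon_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate taxon ids among profiles")
    return ids, np.vstack([p.z for p in profiles])


def _pam(D: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """PAM on a precomputed distance matrix; returns medoid indices (sorted).

    BUILD greedily picks medoids minimizing total distance-to-nearest-medoid;
    SWAP tries all (medoid, non-medoid) exchanges until no exchange lowers
    the objective.  Deterministic given D (ties broken by lowest index);
    the rng is reserved for tie-breaking extensions and keeps the call
    signature stable.
    """
    n = D.shape[0]
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        dmin = D[:, medoids].min(axis=1)
        # gain of adding candidate c: sum of reductions in nearest-medoid distance
        gains = np.maximum(dmin[None, :] - D, 0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))

    medoids = sorted(medoids)
    def objective(meds: list[int]) -> float:
        return float(D[:, meds].min(axis=1).sum())

    best = objective(medoids)
    improved = True
    while improved:
        improved = False
        non_medoids = [i for i in range(n) if i not in medoids]
        for mi, m in enumerate(list(medoids)):
            for h in non_medoids:
                trial = medoids[:mi] + [h] + medoids[mi + 1:]
                obj = objective(trial)
                if obj < best - 1e-12:
                    best, medoids, improved = obj, sorted(trial), True
                    break
            if improved:
                break
    return np.array(sorted(medoids))


def kmedoids(profiles: list[SeasonalProfile], k: int, seed: int = 0) -> ClusterSolution:
    """PAM clustering of seasonal profiles under Euclidean distance."""
    ids, Z = _profile_matrix(profiles)
    n = len(ids)
    if not 2 <= k < n:
        raise ValueError(f"k must satisfy 2 <= k < {n}, got {k}")
    D = np.linalg.norm(Z[:, None, :] - Z[None, :, :], axis=2)
    rng = np.random.default_rng(seed)
    med_idx = _pam(D, k, rng)
    assign_idx = np.argmin(D[:, med_idx], axis=1)
    assignments = {ids[i]: int(assign_idx[i]) for i in range(n)}
    medoids = {c: ids[med_idx[c]] for c in range(k)}
    return ClusterSolution(k=k, assignments=assignments, medoids=medoids)


def davies_bouldin(solution: ClusterSolution, profiles: list[SeasonalProfile]) -> float:
    """Medoid-based Davies-Bouldin index (lower = tighter/better separated).

    S_i is the mean distance of cluster-i members to their medoid and
    M_ij the distance between medoids:
    DB = (1/k) sum_i max_{j != i} (S_i + S_j) / M_ij.
    """
    ids, Z = _profile_matrix(profiles)
    pos = {t: i for i, t in enumerate(ids)}
    k = solution.k
    S = np.zeros(k)
    med_vecs = np.zeros((k, Z.shape[1]))
    for c in range(k):
        members = [t for t, cc in solution.assignments.items() if cc == c]
        if not members:
            raise ValueError(f"cluster {c} is empty")
        med_vecs[c] = Z[pos[solution.medoids[c]]]
        S[c] = np.mean(
            [np.linalg.norm(Z[pos[t]] - med_vecs[c]) for t in members]
        )
    M = np.linalg.norm(med_vecs[:, None, :] - med_vecs[None, :, :], axis=2)
    off = ~np.eye(k, dtype=bool)
    if np.any(M[off] == 0):
        raise ValueError("coincident medoids: Davies-Bouldin undefined")
    R = (S[:, None] + S[None, :]) / np.where(off, M, np.inf)
    return float(np.mean(R.max(axis=1)))


def select_k(
    profiles: list[SeasonalProfile],
    k_range: range | list[int] = range(2, 11),
    seed: int = 0,
) -> ClusterSolution:
    """Run k-medoids across ``k_range`` and keep the minimum-DB solution.

    Ties break toward smaller k; the DB value of every k is recorded in
    ``db_by_k``.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("empty k_range")
    best: ClusterSolution | None = None
    db_by_k: dict[int, float] = {}
    for k in ks:
        sol = kmedoids(profiles, k, seed=seed)
        sol.db_index = davies_bouldin(sol, profiles)
        db_by_k[k] = sol.db_index
        if best is None or sol.db_index < best.db_index - 1e-12:
            best = sol
    assert best is not None
    best.db_by_k = db_by_k
    return best


def peak_month(profile: SeasonalProfile) -> int:
    """Calendar month (0=Jan) at which the profile is maximal."""
    return int(np.argmax(profile.z))


def season_of_month(month: int) -> str:
    """Meteorological season bin of a 0-based calendar month."""
    return _SEASONS[month % 12]
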