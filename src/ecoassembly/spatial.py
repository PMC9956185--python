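"""Geographic distances and distance-decay of community similarity."""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .io import SampleMetadata
from .matrices import PairwiseMatrix

EARTH_RADIUS_KM = 6371.0088


def haversine_km(lat1, lon1, lat2, lon2, radius_km: float = EARTH_RADIUS_KM) -> float:
    """Great-circle distance between two points in km (haversine formula)."""
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlmb = np.radians(lon2) - np.radians(lon1)
    h = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlmb / 2.0) ** 2
    return float(2.0 * radius_km * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0))))


def haversine_matrix(meta: SampleMetadata, radius_km: float = EARTH_RADIUS_KM) -> PairwiseMatrix:
    """Pairwise great-circle distances (km) between all samples."""
    coords = np.radians(meta.coordinates())
    lat = coords[:, 0][:, None]
    lon = coords[:, 1][:, None]
    h = (
        np.sin((lat - lat.T) / 2.0) ** 2
        + np.cos(lat) * np.cos(lat.T) * np.sin((lon - lon.T) / 2.0) ** 2
    )
    d = 2.0 * radius_km * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # exact symmetry against fp round-off
    return PairwiseMatrix(meta.sample_ids, d, "geographic_km")


@dataclass
class DecayFit:
    """Spearman distance-decay fit of community similarity (1 - Bray-Curtis)
    against geographic distance, with a label-permutation (Mantel) p-value
    and an OLS line for plotting."""

    rho: float
    p_value: float
    slope: float
    intercept: float
    n_pairs: int
    permutations: int
    seed: int

    def to_dict(self) -> dict:
        return asdict(self)


def _pearson_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of vector ``x`` against each row of ``y``."""
    xc = x - x.mean()
    yc = y - y.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc**2).sum() * (yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (yc @ xc) / denom


def distance_decay(
    bc: PairwiseMatrix,
    geo: PairwiseMatrix,
    permutations: int = 999,
    seed: int = 0,
) -> DecayFit:
    """Distance-decay analysis: similarity = 1 - Bray-Curtis versus km.

    The statistic is the Spearman rho over the m(m-1)/2 sample pairs.  Because
    pairs sharing a sample are not independent, significance comes from a
    Mantel-style permutation test: sample labels of the similarity matrix are
    permuted, and the two-sided p is (1 + #{|rho_perm| >= |rho_obs|}) /
    (1 + permutations).
    """
    if bc.labels != geo.labels:
        if set(bc.labels) == set(geo.labels):
            geo = geo.subset(bc.labels)
        else:
            raise ValueError("distance_decay: matrices have mismatched labels")
    if permutations < 99:
        raise ValueError("permutations must be >= 99")
    m = bc.n
    if m < 3:
        raise ValueError("need at least 3 samples")
    iu, ju = np.triu_indices(m, k=1)
    sim = 1.0 - bc.values
    dist = geo.condensed()
    sim_cond = sim[iu, ju]

    rho_obs = float(stats.spearmanr(dist, sim_cond).statistic)

    # ranks are permutation-stable: a label permutation re-pairs the same
    # multiset of similarity values, so rank the full matrix once
    rank_cond = stats.rankdata(sim_cond)
    rank_mat = np.zeros((m, m))
    rank_mat[iu, ju] = rank_cond
    rank_mat += rank_mat.T
    dist_rank = stats.rankdata(dist)

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(m) for _ in range(permutations)])
    perm_vals = rank_mat[perms[:, iu], perms[:, ju]]  # permutations x n_pairs
    rho_perm = _pearson_rows(dist_rank, perm_vals)
    p = float((1 + np.count_nonzero(np.abs(rho_perm) >= abs(rho_obs) - 1e-12)) / (1 + permutations))

    slope, intercept = np.polyfit(dist, sim_cond, 1)
    return DecayFit(
        rho=rho_obs,
        p_value=p,
        slope=float(slope),
        intercept=float(intercept),
        n_pairs=int(len(dist)),
        permutations=permutations,
        seed=seed,
    )
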