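"""Two-stage null-model quantification of community assembly.

Stage one is phylogenetic: the abundance-weighted between-community mean
nearest taxon distance (bMNTD) is compared against a null distribution
obtained by shuffling taxa across the tips of the phylogeny, giving a
z-score (bNTI).  Pairs with |bNTI| > 2 are attributed to selection
(heterogeneous when positive, homogeneous when negative).  Stage two is
taxonomic: for the remaining pairs, observed Bray-Curtis is located within
a null distribution of probabilistically reassembled communities
(Raup-Crick, rescaled to [-1, 1]); RC > 0.95 indicates dispersal
limitation, RC < -0.95 homogenizing dispersal, anything else is
undominated.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from scipy.spatial.distance import braycurtis as _braycurtis

from .io import OTUTable, SampleMetadata, ValidationError, to_relative
from .matrices import PairwiseMatrix

logger = logging.getLogger(__name__)

PROCESSES = (
    "heterogeneous_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "undominated",
)

DEFAULT_BNTI_THRESHOLD = 2.0
DEFAULT_RC_THRESHOLD = 0.95
DEFAULT_NULL_REPS = 999

# cap on reps * nA * nB elements materialised per null chunk (~8e7 B of f8)
_CHUNK_ELEMENTS = 10_000_000


class DegenerateNullError(RuntimeError):
    """The null distribution has zero variance; the statistic is uninformative."""


def pair_seed(global_seed: int, sample_a: str, sample_b: str) -> int:
    """Deterministic per-pair seed, order-independent in (a, b)."""
    a, b = sorted((str(sample_a), str(sample_b)))
    return zlib.crc32(f"{global_seed}:{a}:{b}".encode("utf-8"))


# ---------------------------------------------------------------------------
# Patristic distances
# ---------------------------------------------------------------------------


def read_tree(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def patristic_distances(tree: dendropy.Tree, taxa: list[str] | None = None) -> PairwiseMatrix:
    """Tip-to-tip patristic distances (sum of branch lengths on the path).

    The tree is pruned to ``taxa`` first when given; requesting a tip that is
    not on the tree, or a tree with missing branch lengths, is an error.
    """
    tree = tree.clone(depth=1)
    tip_labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if taxa is not None:
        missing = sorted(set(taxa) - set(tip_labels))
        if missing:
            raise ValueError(f"taxa absent from tree: {missing[:10]}" + ("..." if len(missing) > 10 else ""))
        if set(taxa) != set(tip_labels):
            tree.retain_taxa_with_labels(list(taxa))
        labels = list(taxa)
    else:
        labels = tip_labels
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValueError("tree has a missing branch length")
    pdm = tree.phylogenetic_distance_matrix()
    taxon_by_label = {t.label: t for t in tree.taxon_namespace if t.label in set(labels)}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        ti = taxon_by_label[labels[i]]
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(ti, taxon_by_label[labels[j]])
    return PairwiseMatrix(labels, d, "phylo_patristic")


# ---------------------------------------------------------------------------
# bMNTD / bNTI
# ---------------------------------------------------------------------------


def _weights(vec: np.ndarray):
    idx = np.flatnonzero(vec > 0)
    if idx.size == 0:
        raise ValidationError("empty community in bMNTD")
    w = vec[idx] / vec[idx].sum()
    return idx, w


def _bmntd_from_sub(sub: np.ndarray, wa: np.ndarray, wb: np.ndarray) -> float:
    return 0.5 * float(sub.min(axis=1) @ wa + sub.min(axis=0) @ wb)


def bmntd(rel_a, rel_b, d: PairwiseMatrix) -> float:
    """Abundance-weighted between-community mean nearest taxon distance.

    For each taxon present in one community, the patristic distance to its
    nearest taxon present in the other community is averaged with weights
    equal to within-community relative abundance; the two directed means are
    then averaged.  A taxon shared by both communities has nearest-taxon
    distance zero (itself).
    """
    a = np.asarray(rel_a, dtype=float)
    b = np.asarray(rel_b, dtype=float)
    if a.shape != (d.n,) or b.shape != (d.n,):
        raise ValueError("abundance vectors must align with the distance matrix labels")
    ia, wa = _weights(a)
    ib, wb = _weights(b)
    sub = d.values[np.ix_(ia, ib)]
    return _bmntd_from_sub(sub, wa, wb)


def _null_bmntd_perms(
    d: np.ndarray, ia: np.ndarray, ib: np.ndarray, wa: np.ndarray, wb: np.ndarray, perms: np.ndarray
) -> np.ndarray:
    """bMNTD under each tip-label permutation (rows of ``perms``), chunked."""
    reps = perms.shape[0]
    out = np.empty(reps)
    step = max(1, _CHUNK_ELEMENTS // max(1, ia.size * ib.size))
    for start in range(0, reps, step):
        p = perms[start : start + step]
        sub = d[p[:, ia][:, :, None], p[:, ib][:, None, :]]  # chunk x nA x nB
        out[start : start + p.shape[0]] = 0.5 * (
            sub.min(axis=2) @ wa + sub.min(axis=1) @ wb
        )
    return out


def bnti(
    pair: tuple[str, str],
    table: OTUTable,
    d: PairwiseMatrix,
    reps: int = DEFAULT_NULL_REPS,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Observed bMNTD and its z-score against a taxa-shuffle null.

    Each null replicate draws a uniform permutation of taxon labels across
    the tips of the phylogeny (abundances fixed, phylogenetic positions
    permuted) and recomputes bMNTD.  Returns ``(bmntd_obs, bnti)``.
    """
    if reps < 99:
        raise ValueError("reps must be >= 99")
    if rng is None:
        rng = np.random.default_rng(seed)
    rel = table if table.is_relative else to_relative(table)
    rel = rel.select_taxa(d.labels)
    a = rel.sample(pair[0])
    b = rel.sample(pair[1])
    ia, wa = _weights(a)
    ib, wb = _weights(b)
    sub = d.values[np.ix_(ia, ib)]
    obs = _bmntd_from_sub(sub, wa, wb)
    n = d.n
    perms = np.empty((reps, n), dtype=np.intp)
    for r in range(reps):
        perms[r] = rng.permutation(n)
    null = _null_bmntd_perms(d.values, ia, ib, wa, wb, perms)
    sd = float(null.std(ddof=1))
    if sd == 0.0:
        raise DegenerateNullError(
            f"degenerate null for pair {pair}: all {reps} shuffles give bMNTD={null[0]:.6g}"
        )
    return obs, float((obs - null.mean()) / sd)


def bnti_exact(
    pair: tuple[str, str], table: OTUTable, d: PairwiseMatrix
) -> tuple[float, float]:
    """Exact bNTI by enumerating every tip-label permutation (n! of them).

    Only feasible for very small trees; guarded at 8 tips.
    """
    from itertools import permutations as iterperms

    n = d.n
    if n > 8:
        raise ValueError("exact enumeration limited to <= 8 tips")
    rel = table if table.is_relative else to_relative(table)
    rel = rel.select_taxa(d.labels)
    a = rel.sample(pair[0])
    b = rel.sample(pair[1])
    ia, wa = _weights(a)
    ib, wb = _weights(b)
    sub_obs = d.values[np.ix_(ia, ib)]
    obs = _bmntd_from_sub(sub_obs, wa, wb)
    perms = np.array(list(iterperms(range(n))), dtype=np.intp)
    null = _null_bmntd_perms(d.values, ia, ib, wa, wb, perms)
    sd = float(null.std(ddof=1))
    if sd == 0.0:
        raise DegenerateNullError(f"degenerate null for pair {pair}")
    return obs, float((obs - null.mean()) / sd)


# ---------------------------------------------------------------------------
# Raup-Crick with Bray-Curtis
# ---------------------------------------------------------------------------


def _regional_pool(counts: np.ndarray):
    occurrence = (counts > 0).sum(axis=1).astype(float)
    abundance = counts.sum(axis=1)
    pool = np.flatnonzero(occurrence > 0)
    if pool.size == 0:
        raise ValidationError("empty regional pool")
    return pool, occurrence[pool], abundance[pool] / abundance[pool].sum()


def _weighted_sample_wor(
    weights: np.ndarray, size: int, reps: int, rng: np.random.Generator
) -> np.ndarray:
    """``reps`` weighted samples of ``size`` indices without replacement.

    Exponential-race keys: the ``size`` smallest values of Exp(1)/w select a
    sample with inclusion law identical to sequential weighted draws
    (Efraimidis-Spirakis).  Returns reps x size index array.
    """
    keys = rng.exponential(size=(reps, weights.size)) / weights
    return np.argpartition(keys, size - 1, axis=1)[:, :size]


def raup_crick_bc(
    pair: tuple[str, str],
    table: OTUTable,
    reps: int = DEFAULT_NULL_REPS,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Raup-Crick deviation of Bray-Curtis from a stochastic-assembly null.

    Each replicate reassembles both communities independently from the
    regional pool: taxon identities are drawn without replacement to match
    the observed richness with probability proportional to occurrence
    frequency; each drawn taxon is seeded with one individual (so null
    richness is exact) and the remaining observed individuals are allocated
    with replacement with probability proportional to regional relative
    abundance.  RC = 2 * ((#{null < obs} + 0.5 * #{null == obs}) / reps -
    0.5), in [-1, 1].

    Requires integer counts (use :func:`reconstitute_counts` for relative
    tables).
    """
    if reps < 99:
        raise ValueError("reps must be >= 99")
    if table.is_relative:
        raise ValidationError("raup_crick_bc needs integer counts, not a relative table")
    if rng is None:
        rng = np.random.default_rng(seed)
    counts = table.counts
    if not np.allclose(counts, np.round(counts)):
        raise ValidationError("raup_crick_bc needs integer counts")
    pool, occ, reg_ab = _regional_pool(counts)

    cols = []
    for s in pair:
        v = counts[:, table.sample_index(s)]
        if v.sum() <= 0:
            raise ValidationError(f"sample {s!r} has zero total count")
        cols.append(v)
    obs_bc = float(_braycurtis(cols[0], cols[1]))

    richness = [int(np.count_nonzero(v)) for v in cols]
    totals = [int(round(v.sum())) for v in cols]
    for s, r in zip(pair, richness):
        if r > pool.size:
            raise ValidationError(f"sample {s!r} richness {r} exceeds regional pool {pool.size}")

    # identities for all reps at once, abundances rep by rep
    picks = [_weighted_sample_wor(occ, r, reps, rng) for r in richness]
    null_bc = np.empty(reps)
    npool = pool.size
    for r in range(reps):
        nulls = []
        for k in (0, 1):
            idx = picks[k][r]
            p = reg_ab[idx]
            # each drawn taxon is seeded with one individual so that null
            # richness matches exactly; the remainder is abundance-weighted
            alloc = 1 + rng.multinomial(totals[k] - idx.size, p / p.sum())
            full = np.zeros(npool)
            full[idx] = alloc
            nulls.append(full)
        num = np.abs(nulls[0] - nulls[1]).sum()
        den = (nulls[0] + nulls[1]).sum()
        null_bc[r] = num / den
    return obs_bc, rc_score(null_bc, obs_bc)


def rc_score(null_bc: np.ndarray, obs_bc: float) -> float:
    """Raup-Crick rescaling of an observed value against its null sample:
    2 * ((#{null < obs} + 0.5 * #{null == obs}) / reps - 0.5), in [-1, 1].
    Ties count as half; non-decreasing in ``obs_bc`` for fixed nulls."""
    null_bc = np.asarray(null_bc, dtype=float)
    reps = null_bc.size
    less = int(np.count_nonzero(null_bc < obs_bc - 1e-12))
    equal = int(np.count_nonzero(np.abs(null_bc - obs_bc) <= 1e-12))
    return float(2.0 * ((less + 0.5 * equal) / reps - 0.5))


def reconstitute_counts(table: OTUTable, depth: int = 10_000) -> OTUTable:
    """Turn a relative table into integer counts at a fixed per-sample depth
    using largest-remainder rounding (column sums equal ``depth`` exactly).

    This changes the null variance of Raup-Crick and is therefore recorded
    in run manifests whenever it is applied.
    """
    if not table.is_relative:
        raise ValidationError("reconstitute_counts expects a relative table")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    out = np.zeros_like(table.counts)
    for j in range(table.n_samples):
        ideal = table.counts[:, j] * depth
        base = np.floor(ideal)
        short = int(round(depth - base.sum()))
        if short > 0:
            remainder = ideal - base
            top = np.argsort(-remainder, kind="stable")[:short]
            base[top] += 1
        out[:, j] = base
    return OTUTable(table.taxon_ids, table.sample_ids, out, is_relative=False)


# ---------------------------------------------------------------------------
# Classification and summaries
# ---------------------------------------------------------------------------


def classify_pair(
    bnti_value: float,
    rc_value: float,
    bnti_thresh: float = DEFAULT_BNTI_THRESHOLD,
    rc_thresh: float = DEFAULT_RC_THRESHOLD,
) -> str:
    """Assign an assembly process from the (bNTI, RC) pair.

    bnti > +thresh -> heterogeneous_selection; bnti < -thresh ->
    homogeneous_selection; otherwise RC > +rc_thresh -> dispersal_limitation,
    RC < -rc_thresh -> homogenizing_dispersal, else undominated.  The five
    regions partition the finite plane.
    """
    if bnti_thresh <= 0 or rc_thresh <= 0:
        raise ValueError("thresholds must be positive")
    if not (np.isfinite(bnti_value) and np.isfinite(rc_value)):
        raise ValueError(f"non-finite inputs to classify_pair: ({bnti_value}, {rc_value})")
    if bnti_value > bnti_thresh:
        return "heterogeneous_selection"
    if bnti_value < -bnti_thresh:
        return "homogeneous_selection"
    if rc_value > rc_thresh:
        return "dispersal_limitation"
    if rc_value < -rc_thresh:
        return "homogenizing_dispersal"
    return "undominated"


@dataclass
class PairAssembly:
    sample_a: str
    sample_b: str
    bmntd_obs: float
    bnti: float
    bc_obs: float
    rc: float
    process: str
    null_reps: int
    seed: int

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.rc <= 1.0 + 1e-12:
            raise ValueError(f"rc={self.rc} outside [-1, 1]")
        if self.bmntd_obs < 0:
            raise ValueError("bmntd_obs must be >= 0")
        if self.process not in PROCESSES:
            raise ValueError(f"unknown process {self.process!r}")


@dataclass
class ProcessSummary:
    stratum: str
    fractions: dict[str, float]
    n_pairs: int

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {total}, expected 1")


def summarize_processes(
    pairs: list[PairAssembly] | pd.DataFrame,
    layer_of: dict[str, str] | None = None,
    strata: tuple[str, ...] = ("surface", "bottom", "all"),
) -> list[ProcessSummary]:
    """Per-stratum fraction of pairs assigned to each process.

    Layer strata use within-layer pairs only (both samples in the layer);
    the ``all`` stratum uses every pair.  Empty strata are omitted with a
    warning.
    """
    if isinstance(pairs, pd.DataFrame):
        df = pairs
    else:
        df = pd.DataFrame([p.__dict__ for p in pairs])
    if df.empty:
        raise ValueError("no pairs to summarise")
    out = []
    for stratum in strata:
        if stratum == "all":
            sub = df
        else:
            if layer_of is None:
                continue
            mask = df["sample_a"].map(layer_of).eq(stratum) & df["sample_b"].map(layer_of).eq(stratum)
            sub = df[mask]
        if sub.empty:
            logger.warning("summarize_processes: stratum %r has no pairs; omitted", stratum)
            continue
        tally = sub["process"].value_counts()
        n = int(tally.sum())
        fractions = {p: float(tally.get(p, 0)) / n for p in PROCESSES}
        out.append(ProcessSummary(stratum=stratum, fractions=fractions, n_pairs=n))
    return out


def per_site_fractions(
    pairs: pd.DataFrame, site_of: dict[str, str]
) -> pd.DataFrame:
    """Distribution of process classes over all pairs involving each site.

    This is one interpretation of 'per-site assembly mechanism': a pair
    contributes to both of its endpoints' sites.
    """
    rows = []
    sites = sorted(set(site_of.values()))
    for site in sites:
        mask = pairs["sample_a"].map(site_of).eq(site) | pairs["sample_b"].map(site_of).eq(site)
        sub = pairs[mask]
        if sub.empty:
            continue
        tally = sub["process"].value_counts()
        n = int(tally.sum())
        row = {"site_id": site, "n_pairs": n}
        row.update({p: float(tally.get(p, 0)) / n for p in PROCESSES})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pairwise driver
# ---------------------------------------------------------------------------


def _pair_universe(
    sample_ids: list[str], meta: SampleMetadata | None, strata: str
) -> list[tuple[str, str]]:
    if strata == "all" or meta is None:
        ids = sample_ids
        return [(ids[i], ids[j]) for i in range(len(ids)) for j in range(i + 1, len(ids))]
    if strata == "within-layer":
        pairs = []
        for layer in ("surface", "bottom"):
            ids = [s for s in sample_ids if s in set(meta.samples_in_layer(layer))]
            pairs.extend((ids[i], ids[j]) for i in range(len(ids)) for j in range(i + 1, len(ids)))
        return pairs
    raise ValueError(f"unknown pair universe {strata!r}")


def _one_pair(pair, counts_table, rel_table, dists, reps, global_seed, bnti_thresh, rc_thresh):
    s = pair_seed(global_seed, *pair)
    rng = np.random.default_rng(s)
    obs_bmntd, z = bnti(pair, rel_table, dists, reps=reps, rng=rng)
    bc_obs, rc = raup_crick_bc(pair, counts_table, reps=reps, rng=rng)
    process = classify_pair(z, rc, bnti_thresh, rc_thresh)
    return PairAssembly(
        sample_a=pair[0],
        sample_b=pair[1],
        bmntd_obs=obs_bmntd,
        bnti=z,
        bc_obs=bc_obs,
        rc=rc,
        process=process,
        null_reps=reps,
        seed=s,
    )


def assembly_analysis(
    table: OTUTable,
    tree: dendropy.Tree | PairwiseMatrix,
    meta: SampleMetadata | None = None,
    reps: int = DEFAULT_NULL_REPS,
    seed: int = 42,
    bnti_thresh: float = DEFAULT_BNTI_THRESHOLD,
    rc_thresh: float = DEFAULT_RC_THRESHOLD,
    pairs: list[tuple[str, str]] | None = None,
    strata: str = "within-layer",
    n_jobs: int = 1,
) -> pd.DataFrame:
    """Classify every sample pair with the two-stage null model.

    ``table`` must be integer counts; taxa are pruned to those present in
    both table and tree.  Pairs default to all within-layer pairs when
    metadata is given (``strata='within-layer'``), otherwise all pairs.
    Per-pair RNG streams make parallel execution (joblib, in-process
    threads/processes) bitwise identical to serial execution.
    """
    if table.is_relative:
        raise ValidationError("assembly_analysis requires integer counts")
    dists = tree if isinstance(tree, PairwiseMatrix) else patristic_distances(tree)
    shared = [t for t in table.taxon_ids if t in set(dists.labels)]
    if not shared:
        raise ValidationError("no taxa shared between table and tree")
    dropped = table.n_taxa - len(shared)
    if dropped:
        logger.info("assembly_analysis: dropping %d taxa absent from tree", dropped)
    counts_table = table.select_taxa(shared)
    dists = dists.subset(shared)
    rel_table = to_relative(counts_table)
    if pairs is None:
        pairs = _pair_universe(counts_table.sample_ids, meta, strata if meta is not None else "all")
    worker = delayed(_one_pair)
    results = Parallel(n_jobs=n_jobs, backend="loky" if n_jobs != 1 else "sequential")(
        worker(p, counts_table, rel_table, dists, reps, seed, bnti_thresh, rc_thresh)
        for p in pairs
    )
    return pd.DataFrame([r.__dict__ for r in results])
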