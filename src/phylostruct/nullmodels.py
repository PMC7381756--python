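"""Richness-preserving null model and the NRI/NTI standardized indices.

Null communities are drawn uniformly from the all-site species pool,
keeping each site's observed richness (999 draws by default). The
indices are

    NRI = -(MPD_obs  - mean(MPD_null))  / SD(MPD_null)
    NTI = -(MNTD_obs - mean(MNTD_null)) / SD(MNTD_null)

so positive values mean the community is more closely related than
expected by chance (phylogenetic clustering) and negative values mean
overdispersion.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from phylostruct.community import CommunityMatrix, SpeciesPool, species_pool
from phylostruct.metrics import mntd, mpd, pd_faith
from phylostruct.trees import DistanceMatrix, PhyloTree, cophenetic_matrix

logger = logging.getLogger(__name__)

DEFAULT_N_NULL = 999

CLASS_LABELS = (
    "clustered_sig",
    "clustered_ns",
    "overdispersed_sig",
    "overdispersed_ns",
    "undefined",
)


def site_seed(global_seed: int, site_id) -> int:
    """Stable per-site seed, independent of site processing order."""
    digest = hashlib.sha256(f"{global_seed}:{site_id}".encode()).digest()
    return int.from_bytes(digest[:8], "big")


@dataclass
class NullEnsemble:
    """Null distribution of MPD or MNTD at one site's richness."""

    metric: str
    n_null: int
    null_values: np.ndarray
    rng_seed: int | None = None
    mean_null: float = field(init=False)
    sd_null: float = field(init=False)

    def __post_init__(self) -> None:
        self.null_values = np.asarray(self.null_values, dtype=float)
        if self.metric not in ("MPD", "MNTD"):
            raise ValueError(f"unknown metric {self.metric!r}")
        self.mean_null = float(self.null_values.mean())
        self.sd_null = float(self.null_values.std(ddof=1))


def _null_index_matrix(
    n_pool: int, richness: int, n_null: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_null, richness) matrix of pool indices, uniform without replacement."""
    if richness > n_pool:
        raise ValueError(f"richness {richness} exceeds pool size {n_pool}")
    # argsort of iid uniforms = independent uniform permutation per row
    u = rng.random((n_null, n_pool))
    return np.argsort(u, axis=1)[:, :richness]


def draw_null(
    pool: SpeciesPool, richness: int, n_null: int = DEFAULT_N_NULL, seed: int = 0
) -> list[frozenset]:
    """Draw ``n_null`` uniform subsets of the pool at the given richness."""
    species = np.array(pool.sorted())
    if richness < 2:
        raise ValueError("richness < 2: null model undefined")
    rng = np.random.default_rng(seed)
    idx = _null_index_matrix(len(species), richness, n_null, rng)
    return [frozenset(species[row]) for row in idx]


def null_ensemble(
    metric: str,
    dm_pool: np.ndarray,
    richness: int,
    n_null: int,
    seed: int,
) -> NullEnsemble:
    """Null MPD or MNTD values on uniform subsets of a pool distance matrix."""
    rng = np.random.default_rng(seed)
    idx = _null_index_matrix(dm_pool.shape[0], richness, n_null, rng)
    sub = dm_pool[idx[:, :, None], idx[:, None, :]]  # (n_null, k, k)
    k = richness
    if metric == "MPD":
        vals = sub.sum(axis=(1, 2)) / (k * (k - 1))
    elif metric == "MNTD":
        sub = sub + np.where(np.eye(k, dtype=bool), np.inf, 0.0)
        vals = sub.min(axis=2).mean(axis=1)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return NullEnsemble(metric=metric, n_null=n_null, null_values=vals, rng_seed=seed)


def ses_index(obs: float, ensemble: NullEnsemble) -> tuple[float, float]:
    """Standardized index and null quantile of an observed value.

    index = -(obs - mean_null) / sd_null; the quantile is the
    mid-rank position of the observation within the null distribution,
    in (0, 1). Degenerate nulls (sd = 0) yield (NaN, NaN).
    """
    if not math.isfinite(obs):
        return (math.nan, math.nan)
    # a numerically-constant null (e.g. community = pool) has no spread
    spread = np.ptp(ensemble.null_values)
    if ensemble.sd_null == 0 or spread <= 1e-12 * max(abs(ensemble.mean_null), 1.0):
        logger.warning("null SD is zero (%s): index undefined", ensemble.metric)
        return (math.nan, math.nan)
    index = -(obs - ensemble.mean_null) / ensemble.sd_null
    nv = ensemble.null_values
    quantile = (np.sum(nv < obs) + 0.5 * np.sum(nv == obs) + 1) / (
        ensemble.n_null + 1
    )
    return (float(index), float(quantile))


def classify(index: float, quantile: float, alpha: float = 0.05) -> str:
    """One-tailed structure class in the direction of the observed sign.

    index > 0 → clustered (significant when the observation sits in the
    lower null tail, quantile ≤ alpha); index ≤ 0 → overdispersed
    (significant when quantile ≥ 1 - alpha). An exactly-zero index
    tie-breaks to ``overdispersed_ns``.
    """
    if not math.isfinite(index):
        return "undefined"
    if index > 0:
        return "clustered_sig" if quantile <= alpha else "clustered_ns"
    return "overdispersed_sig" if quantile >= 1 - alpha else "overdispersed_ns"


def ses_table(
    tree: PhyloTree,
    cm: CommunityMatrix,
    n_null: int = DEFAULT_N_NULL,
    seed: int = 0,
    alpha: float = 0.05,
    include_root: bool = True,
    dm: DistanceMatrix | None = None,
) -> pd.DataFrame:
    """Per-site PD, NRI, NTI, null quantiles and structure classes.

    The species pool is the union of species over all sites; null draws
    are seeded per site from ``seed`` and the site id so results do not
    depend on processing order. Sites with richness < 2 get missing
    NRI/NTI (logged).
    """
    if dm is None:
        dm = cophenetic_matrix(tree)
    pool = species_pool(cm)
    pool_species = pool.sorted()
    dm_pool = dm.submatrix(pool_species)
    pos = {sp: i for i, sp in enumerate(pool_species)}

    rows = []
    for site in cm.site_ids:
        present = cm.present_at(site)
        k = len(present)
        row: dict = {
            "site_id": site,
            "SR": k,
            "PD": pd_faith(tree, present, include_root=include_root),
        }
        if k < 2:
            logger.info("site %r has richness %d (<2); NRI/NTI undefined", site, k)
            row.update(
                MPD_obs=math.nan,
                MNTD_obs=math.nan,
                NRI=math.nan,
                NTI=math.nan,
                quantile_mpd=math.nan,
                quantile_mntd=math.nan,
                class_nri="undefined",
                class_nti="undefined",
            )
            rows.append(row)
            continue
        obs_mpd = mpd(dm, present)
        obs_mntd = mntd(dm, present)
        sseed = site_seed(seed, site)
        ens_mpd = null_ensemble("MPD", dm_pool, k, n_null, sseed)
        # distinct stream for MNTD so the two ensembles are independent
        ens_mntd = null_ensemble("MNTD", dm_pool, k, n_null, sseed + 1)
        nri, q_mpd = ses_index(obs_mpd, ens_mpd)
        nti, q_mntd = ses_index(obs_mntd, ens_mntd)
        row.update(
            MPD_obs=obs_mpd,
            MNTD_obs=obs_mntd,
            NRI=nri,
            NTI=nti,
            quantile_mpd=q_mpd,
            quantile_mntd=q_mntd,
            class_nri=classify(nri, q_mpd, alpha),
            class_nti=classify(nti, q_mntd, alpha),
        )
        rows.append(row)
    out = pd.DataFrame(rows).set_index("site_id")
    if cm.habitat is not None:
        out.insert(0, "habitat", cm.habitat.reindex(out.index))
    return out


def _tally(sub: pd.DataFrame) -> dict:
    n = len(sub)

    def pct(x: int) -> float:
        return round(100.0 * x / n, 2) if n else math.nan

    nri_def = sub[sub["class_nri"] != "undefined"]
    nti_def = sub[sub["class_nti"] != "undefined"]
    nri_neg = (nri_def["class_nri"].isin(["overdispersed_sig", "overdispersed_ns"])).sum()
    nri_neg_sig = (nri_def["class_nri"] == "overdispersed_sig").sum()
    nri_pos = (nri_def["class_nri"].isin(["clustered_sig", "clustered_ns"])).sum()
    nri_pos_sig = (nri_def["class_nri"] == "clustered_sig").sum()
    nti_neg = (nti_def["class_nti"].isin(["overdispersed_sig", "overdispersed_ns"])).sum()
    nti_neg_sig = (nti_def["class_nti"] == "overdispersed_sig").sum()
    nti_pos = (nti_def["class_nti"].isin(["clustered_sig", "clustered_ns"])).sum()
    nti_pos_sig = (nti_def["class_nti"] == "clustered_sig").sum()
    return {
        "n_sites": n,
        "nri_neg": int(nri_neg),
        "nri_neg_pct": pct(nri_neg),
        "nri_neg_sig": int(nri_neg_sig),
        "nri_neg_sig_pct": pct(nri_neg_sig),
        "nri_pos": int(nri_pos),
        "nri_pos_pct": pct(nri_pos),
        "nri_pos_sig": int(nri_pos_sig),
        "nri_pos_sig_pct": pct(nri_pos_sig),
        "nti_neg": int(nti_neg),
        "nti_neg_pct": pct(nti_neg),
        "nti_neg_sig": int(nti_neg_sig),
        "nti_neg_sig_pct": pct(nti_neg_sig),
        "nti_pos": int(nti_pos),
        "nti_pos_pct": pct(nti_pos),
        "nti_pos_sig": int(nti_pos_sig),
        "nti_pos_sig_pct": pct(nti_pos_sig),
    }


def tabulate_structure(results: pd.DataFrame, habitat: pd.Series | None = None) -> pd.DataFrame:
    """Counts (and percentages) of NRI/NTI signs and significance by habitat.

    Sites with undefined indices are excluded from the sign tallies but
    still counted in ``n_sites``. An ``Overall`` row aggregates all sites.
    """
    df = results.copy()
    if habitat is not None:
        df["habitat"] = habitat.reindex(df.index)
    if "habitat" not in df.columns:
        df["habitat"] = "all"
    undef = (df["class_nri"] == "undefined") | (df["class_nti"] == "undefined")
    if undef.any():
        logger.info("%d sites with undefined indices excluded from tallies", int(undef.sum()))
    rows = {}
    for hab, sub in df.groupby("habitat", sort=True):
        rows[hab] = _tally(sub)
    rows["Overall"] = _tally(df)
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "habitat"
    return out
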