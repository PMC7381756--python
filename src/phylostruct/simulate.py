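"""Synthetic two-habitat community data with tunable phylogenetic structure.

A pure-birth tree supplies the species pool; sites are assembled by a
distance-dependent kernel whose single strength parameter interpolates
from phylogenetic clustering (positive) through uniform randomness
(zero) to overdispersion (negative). Habitat-correlated environmental
covariates are drawn from per-habitat Gaussians, independent of the
assembly process given habitat.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from phylostruct.community import CommunityMatrix
from phylostruct.trees import DistanceMatrix, PhyloTree, cophenetic_matrix, parse_newick

# per-habitat (mean, sd) of each covariate; temperature anomalies are
# larger in the alpine group so anomaly/structure relationships are
# non-degenerate in generated data
ENV_DEFAULTS: dict[str, dict[str, tuple[float, float]]] = {
    "desert": {
        "MAT": (4.0, 1.0),
        "MAP": (80.0, 25.0),
        "SWC": (5.0, 2.0),
        "coverage": (20.0, 8.0),
        "Anomaly1": (0.6, 0.2),
        "Anomaly2": (4.5, 0.8),
        "Anomaly3": (3.9, 0.7),
    },
    "alpine": {
        "MAT": (-1.5, 1.5),
        "MAP": (450.0, 100.0),
        "SWC": (25.0, 8.0),
        "coverage": (60.0, 15.0),
        "Anomaly1": (0.9, 0.3),
        "Anomaly2": (6.5, 1.0),
        "Anomaly3": (5.6, 0.9),
    },
}


@dataclass
class SyntheticConfig:
    seed: int = 0
    n_pool: int = 285
    birth_rate: float = 1.0
    n_desert: int = 20
    n_alpine: int = 41
    richness_desert: float = 12.35
    richness_alpine: float = 33.39
    lambda_desert: float = 3.0
    lambda_alpine: float = -3.0
    # probability that a desert site's first species comes from the
    # designated desert clade (phylogenetic habitat affinity)
    desert_clade_affinity: float = 0.9
    env: dict = field(default_factory=lambda: {h: dict(v) for h, v in ENV_DEFAULTS.items()})

    def __post_init__(self) -> None:
        if self.n_pool < 10:
            raise ValueError("n_pool must be at least 10")
        if max(self.richness_desert, self.richness_alpine) >= self.n_pool:
            raise ValueError("richness means must be below the pool size")
        for lam in (self.lambda_desert, self.lambda_alpine):
            if not np.isfinite(lam):
                raise ValueError("assembly strength must be finite")


@dataclass
class SyntheticDataset:
    tree: PhyloTree
    community: CommunityMatrix
    env: pd.DataFrame
    clade_map: dict
    config: SyntheticConfig


def simulate_tree(
    n_pool: int,
    birth_rate: float = 1.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> PhyloTree:
    """Pure-birth (Yule) tree with ``n_pool`` tips.

    Lineages split at rate ``birth_rate`` each; with k lineages the
    waiting time to the next split is Exp(k·rate). The process starts
    from the root's two children and runs one further interval after the
    last split, so the expected depth is sum_{k=2..n} 1/(k·rate).
    Tips are labeled ``sp0001``... in creation order.
    """
    if n_pool < 2:
        raise ValueError("need at least 2 tips")
    if rng is None:
        rng = np.random.default_rng(seed)

    # each active lineage: [accumulated pendant length, children or None]
    class _N:
        __slots__ = ("length", "children")

        def __init__(self) -> None:
            self.length = 0.0
            self.children: list[_N] | None = None

    root_children = [_N(), _N()]
    active = list(root_children)
    k = 2
    while k < n_pool:
        dt = rng.exponential(1.0 / (birth_rate * k))
        for node in active:
            node.length += dt
        i = rng.integers(len(active))
        parent = active[i]
        parent.children = [_N(), _N()]
        active[i] = parent.children[0]
        active.append(parent.children[1])
        k += 1
    dt = rng.exponential(1.0 / (birth_rate * k))
    for node in active:
        node.length += dt

    counter = [0]

    def render(node: _N) -> str:
        if node.children is None:
            counter[0] += 1
            return f"sp{counter[0]:04d}:{node.length:.10g}"
        inner = ",".join(render(c) for c in node.children)
        return f"({inner}):{node.length:.10g}"

    newick = "(" + ",".join(render(c) for c in root_children) + ");"
    return parse_newick(newick)


def assemble_site(
    tree: PhyloTree,
    richness: int,
    lam: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    dm: DistanceMatrix | None = None,
    first_pool: list | None = None,
) -> frozenset:
    """Assemble one community by distance-dependent sequential draws.

    The first species is uniform (optionally restricted to
    ``first_pool``); each later species j joins with probability
    proportional to exp(-lam · mean distance from j to the current
    members), without replacement. lam > 0 clusters, lam < 0
    overdisperses, lam = 0 reduces to uniform sampling.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if dm is None:
        dm = cophenetic_matrix(tree)
    labels = np.array(dm.labels)
    n = len(labels)
    if not 2 <= richness <= n:
        raise ValueError(f"richness {richness} out of range [2, {n}]")

    if first_pool:
        cand = dm.indexer(first_pool)
        first = int(cand[rng.integers(len(cand))])
    else:
        first = int(rng.integers(n))
    chosen = [first]
    in_set = np.zeros(n, dtype=bool)
    in_set[first] = True
    dist_sum = dm.values[:, first].copy()
    while len(chosen) < richness:
        mean_d = dist_sum / len(chosen)
        logits = -lam * mean_d
        logits[in_set] = -np.inf
        logits -= logits[~in_set].max()
        w = np.exp(logits)
        w[in_set] = 0.0
        w /= w.sum()
        nxt = int(rng.choice(n, p=w))
        chosen.append(nxt)
        in_set[nxt] = True
        dist_sum += dm.values[:, nxt]
    return frozenset(labels[chosen])


def clade_assignments(tree: PhyloTree, n_clades: int = 3) -> dict:
    """Assign tips to pseudo-clades by repeatedly splitting the deepest nodes.

    The largest resulting groups get the labels ``eudicots``,
    ``monocots`` and ``magnoliids``; any remainder is ``other``.
    """
    dtree = tree.dendropy_tree
    groups = list(dtree.seed_node.child_nodes())
    while len(groups) < n_clades:
        sizes = [len(g.leaf_nodes()) for g in groups]
        i = int(np.argmax(sizes))
        node = groups.pop(i)
        children = node.child_nodes()
        if not children:  # cannot split a tip further
            groups.append(node)
            break
        groups.extend(children)
    groups.sort(key=lambda g: -len(g.leaf_nodes()))
    names = ["eudicots", "monocots", "magnoliids"]
    mapping: dict[str, str] = {}
    for i, g in enumerate(groups):
        label = names[i] if i < len(names) else "other"
        for lf in g.leaf_nodes():
            mapping[lf.taxon.label] = label
    return mapping


def _draw_richness(rng: np.random.Generator, mean: float, n_pool: int) -> int:
    # shifted Poisson with a floor of 2 species, preserving the mean
    k = 2 + int(rng.poisson(mean - 2.0))
    return int(min(k, n_pool))


def generate_dataset(cfg: SyntheticConfig) -> SyntheticDataset:
    """Generate a full two-habitat dataset from a config.

    Produces the tree, the site-by-species incidence matrix with habitat
    labels, the per-site environment table and a species → pseudo-clade
    map. Fully reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    tree = simulate_tree(cfg.n_pool, cfg.birth_rate, rng=rng)
    dm = cophenetic_matrix(tree)
    clade_map = clade_assignments(tree)
    desert_clade = [sp for sp, c in clade_map.items() if c == "eudicots"]

    site_ids: list[str] = []
    habitats: list[str] = []
    plan: list[tuple[str, float, float]] = []
    for i in range(cfg.n_desert):
        site_ids.append(f"d{i + 1:02d}")
        habitats.append("desert")
        plan.append(("desert", cfg.richness_desert, cfg.lambda_desert))
    for i in range(cfg.n_alpine):
        site_ids.append(f"a{i + 1:02d}")
        habitats.append("alpine")
        plan.append(("alpine", cfg.richness_alpine, cfg.lambda_alpine))

    incidence = pd.DataFrame(
        0, index=site_ids, columns=list(dm.labels), dtype=int
    )
    env_rows = []
    for site, (habitat, mean_k, lam) in zip(site_ids, plan):
        k = _draw_richness(rng, mean_k, cfg.n_pool)
        first_pool = None
        if habitat == "desert" and rng.random() < cfg.desert_clade_affinity:
            first_pool = desert_clade
        members = assemble_site(
            tree, k, lam, rng=rng, dm=dm, first_pool=first_pool
        )
        incidence.loc[site, list(members)] = 1
        row = {"site_id": site, "habitat": habitat}
        for var, (mu, sd) in cfg.env[habitat].items():
            row[var] = rng.normal(mu, sd)
        env_rows.append(row)

    community = CommunityMatrix(
        incidence=incidence,
        habitat=pd.Series(habitats, index=site_ids, name="habitat"),
    )
    env = pd.DataFrame(env_rows).set_index("site_id")
    return SyntheticDataset(
        tree=tree, community=community, env=env, clade_map=clade_map, config=cfg
    )


def write_dataset(ds: SyntheticDataset, outdir) -> dict:
    """Write tree.nwk, community.csv, env.csv, clades.csv and manifest.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "tree": outdir / "tree.nwk",
        "community": outdir / "community.csv",
        "env": outdir / "env.csv",
        "clades": outdir / "clades.csv",
        "manifest": outdir / "manifest.json",
    }
    paths["tree"].write_text(ds.tree.to_newick())
    out = ds.community.incidence.copy()
    out.insert(0, "habitat", ds.community.habitat)
    out.index.name = "site"
    out.to_csv(paths["community"])
    ds.env.to_csv(paths["env"])
    pd.Series(ds.clade_map, name="clade").rename_axis("species").to_csv(
        paths["clades"]
    )
    manifest = {"seed": ds.config.seed, "config": dataclasses.asdict(ds.config)}
    paths["manifest"].write_text(json.dumps(manifest, indent=2))
    return {k: str(v) for k, v in paths.items()}
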