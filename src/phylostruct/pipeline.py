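"""End-to-end orchestration: load inputs, run every analysis stage and
write the paper-shaped output tables."""

from __future__ import annotations

import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import phylostruct
from phylostruct.community import read_community
from phylostruct.nullmodels import ses_table, tabulate_structure
from phylostruct.pcps import SQRT_BRAYCURTIS, pcps_analysis
from phylostruct.stats import (
    correlation_table,
    habitat_contrasts,
    ols_slope,
    one_sample_t,
    pearson_cor,
    varpart3,
)
from phylostruct.trees import cophenetic_matrix, normalize_name, parse_newick, prune_to_taxa

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class RunConfig:
    tree: str
    community: str
    outdir: str
    env: str | None = None
    clades: str | None = None
    n_null: int = 999
    alpha: float = 0.05
    seed: int = 0
    distance: str = SQRT_BRAYCURTIS
    include_root: bool = True
    graft_missing: bool = False
    varpart_response: str = "PD"
    varpart_predictors: tuple = ("Anomaly1", "Anomaly2", "Anomaly3")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load a flat key-value TOML config."""
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        if "varpart_predictors" in raw:
            raw["varpart_predictors"] = tuple(raw["varpart_predictors"])
        return cls(**raw)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, float_format=FLOAT_FORMAT)


def run_all(cfg: RunConfig) -> dict:
    """Run the full analysis; returns {output name: path}.

    Outputs: metrics.csv, table1.csv, table2.csv (when an environment
    table is given), varpart.csv, pcps/ (P, eigenvalues, scores,
    centroids), contrasts.csv and run.log. Any stage failure aborts with
    the stage name; partial outputs are removed.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    log_lines: list[str] = [
        f"phylostruct {phylostruct.__version__}",
        f"seed={cfg.seed} n_null={cfg.n_null} alpha={cfg.alpha}",
        f"distance={cfg.distance} include_root={cfg.include_root}",
        "null model: uniform richness-preserving draws from the all-site pool",
        "significance: one-tailed at alpha in the direction of the observed sign",
    ]
    stage = "load inputs"
    try:
        for name, p in (("tree", cfg.tree), ("community", cfg.community),
                        ("env", cfg.env), ("clades", cfg.clades)):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} path does not exist: {p}")
        tree = parse_newick(Path(cfg.tree).read_text())
        cm = read_community(cfg.community)
        env = None
        if cfg.env:
            env = pd.read_csv(cfg.env, index_col=0)
            env.index = env.index.astype(str)
        clade_map: dict = {}
        if cfg.clades:
            cl = pd.read_csv(cfg.clades, index_col=0)
            clade_map = {
                normalize_name(sp): str(c) for sp, c in cl.iloc[:, 0].items()
            }

        stage = "prune tree"
        tip_keys = {normalize_name(t) for t in tree.tip_labels}
        requested = cm.species_names
        missing = [s for s in requested if normalize_name(s) not in tip_keys]
        if missing and not cfg.graft_missing:
            raise ValueError(
                f"species absent from the tree (grafting disabled): {missing}"
            )
        tree, report = prune_to_taxa(tree, requested, graft_missing=cfg.graft_missing)
        dropped = report.loc[report["status"] == "dropped", "name"].tolist()
        if dropped:
            raise ValueError(f"species not resolvable on the tree: {dropped}")
        report_path = outdir / "prune_report.csv"
        report.to_csv(report_path, index=False)
        written.append(report_path)
        log_lines.append(
            "prune: "
            + ", ".join(
                f"{s}={n}" for s, n in report["status"].value_counts().items()
            )
        )

        stage = "distance matrix"
        dm = cophenetic_matrix(tree)

        stage = "null-model metrics"
        metrics = ses_table(
            tree,
            cm,
            n_null=cfg.n_null,
            seed=cfg.seed,
            alpha=cfg.alpha,
            include_root=cfg.include_root,
            dm=dm,
        )

        stage = "structure tallies"
        table1 = tabulate_structure(metrics)
        p1 = outdir / "table1.csv"
        _write_csv(table1, p1)
        written.append(p1)

        stage = "pcps"
        res = pcps_analysis(dm, cm, clade_map=clade_map, distance=cfg.distance)
        pcps_dir = outdir / "pcps"
        pcps_dir.mkdir(exist_ok=True)
        _write_csv(res.P, pcps_dir / "matrix_p.csv")
        eig = pd.DataFrame(
            {
                "axis": np.arange(1, len(res.eigenvalues) + 1),
                "eigenvalue": res.eigenvalues,
                "percent": res.percentages,
            }
        ).set_index("axis")
        _write_csv(eig, pcps_dir / "eigenvalues.csv")
        _write_csv(res.site_scores, pcps_dir / "site_scores.csv")
        _write_csv(res.species_scores, pcps_dir / "species_scores.csv")
        _write_csv(res.clade_centroids, pcps_dir / "clade_centroids.csv")
        written.append(pcps_dir)
        metrics["PCPS1"] = res.site_scores["pcps_1"].reindex(metrics.index)

        stage = "write metrics"
        p_metrics = outdir / "metrics.csv"
        _write_csv(metrics, p_metrics)
        written.append(p_metrics)

        stage = "t tests vs zero"
        ttests = []
        for hab, sub in (
            metrics.groupby("habitat") if "habitat" in metrics else [("all", metrics)]
        ):
            for m in ("NRI", "NTI"):
                vals = sub[m].dropna()
                t, p = one_sample_t(vals, 0.0)
                ttests.append(
                    {"habitat": hab, "metric": m, "mean": vals.mean(), "t": t, "p": p}
                )
        p_t = outdir / "ttests_vs_zero.csv"
        _write_csv(pd.DataFrame(ttests).set_index(["habitat", "metric"]), p_t)
        written.append(p_t)

        if "habitat" in metrics:
            stage = "habitat contrasts"
            contrasts = habitat_contrasts(
                metrics, ["PD", "NRI", "NTI", "PCPS1"], habitat_col="habitat"
            )
            p_c = outdir / "contrasts.csv"
            _write_csv(contrasts, p_c)
            written.append(p_c)

        if env is not None:
            stage = "environment merge"
            joined = metrics.join(env.drop(columns=["habitat"], errors="ignore"))

            stage = "correlation table"
            table2 = correlation_table(joined)
            p2 = outdir / "table2.csv"
            table2.to_csv(p2)
            written.append(p2)

            stage = "anomaly relationships"
            rel_rows = []
            for m in ("NRI", "NTI"):
                sub = joined[[m, "Anomaly2"]].dropna()
                slope, intercept = ols_slope(sub["Anomaly2"], sub[m])
                r, p, stars = pearson_cor(sub["Anomaly2"], sub[m])
                rel_rows.append(
                    {"metric": m, "slope": slope, "intercept": intercept,
                     "r": r, "p": p, "stars": stars}
                )
            p_rel = outdir / "anomaly_relationships.csv"
            _write_csv(pd.DataFrame(rel_rows).set_index("metric"), p_rel)
            written.append(p_rel)

            stage = "variation partitioning"
            cols = [cfg.varpart_response, *cfg.varpart_predictors]
            sub = joined[cols].dropna()
            vp = varpart3(
                sub[cfg.varpart_response],
                *(sub[c] for c in cfg.varpart_predictors),
            )
            named = {}
            for key, val in vp.fractions.items():
                for i, pred in enumerate(cfg.varpart_predictors, 1):
                    key = key.replace(f"x{i}", pred)
                named[key] = val
            p_v = outdir / "varpart.csv"
            _write_csv(pd.Series(named, name="fraction").rename_axis("component").to_frame(), p_v)
            written.append(p_v)

        stage = "run log"
        (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
        written.append(outdir / "run.log")
    except Exception as exc:
        for p in written:
            if p.is_dir():
                shutil.rmtree(p, ignore_errors=True)
            else:
                p.unlink(missing_ok=True)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    return {p.name: str(p) for p in written}
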