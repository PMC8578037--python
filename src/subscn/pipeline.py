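"""End-to-end orchestration: one configuration in, a result bundle out.

Stages: load (or simulate) → covariate residualization → group covariance
networks across the density sweep → global/nodal topology → permutation +
FDA comparisons for each group pair → degree-distribution fits and
resilience curves → volumetric and demographic statistics.  Every output
lands in the configured directory as TSV/JSON, with a manifest recording
the configuration, seeds and per-stage log.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as scn_io
from ._rng import substream
from .adjustment import residualize
from .catalog import default_catalog
from .clinical import StatsError, demographic_tests, mancova, per_roi_ancova, \
    roi_psychometric_correlations
from .inference import GLOBAL_METRICS, NodalTestResult, compare_groups
from .metrics import MetricError, fit_truncated_power_law, global_metrics, random_failure
from .network import association_matrix, build_sweep, minimum_connected_density
from .synthetic import CohortSpec, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "simulate", "global_summary_table"]

DEFAULT_COMPARISONS = (("cMDD", "HC"), ("RD", "HC"), ("cMDD", "RD"))


@dataclass
class RunConfig:
    """Everything a pipeline run depends on; sub-seeds derive from ``seed``."""

    volumes_path: str | None = None
    participants_path: str | None = None
    spec_path: str | None = None              # synthetic alternative to input files
    output_dir: str = "results"
    comparisons: tuple[tuple[str, str], ...] = DEFAULT_COMPARISONS
    d_min: float = 0.17
    d_max: float = 0.45
    d_step: float = 0.02
    n_perm: int = 1000
    n_random_graphs: int = 20
    modularity_restarts: int = 1000
    resilience_reps: int = 100
    fdr_q: float = 0.05
    seed: int = 0
    nodal: bool = True
    metrics: tuple[str, ...] = GLOBAL_METRICS
    alias_path: str | None = None

    def __post_init__(self) -> None:
        for name in ("n_perm", "n_random_graphs", "modularity_restarts", "resilience_reps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.d_min <= self.d_max <= 1):
            raise ValueError("density grid invalid")
        self.comparisons = tuple(tuple(c) for c in self.comparisons)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def simulate(spec: CohortSpec | str | Path, out_dir: str | Path, seed: int | None = None):
    """Draw a cohort and write participants.tsv + volumes.tsv."""
    if not isinstance(spec, CohortSpec):
        spec = CohortSpec.from_yaml(spec)
    records, table = generate_cohort(spec, seed=seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scn_io.write_participants(records, out / "participants.tsv")
    scn_io.write_volume_table(table, out / "volumes.tsv")
    return out / "participants.tsv", out / "volumes.tsv"


def global_summary_table(results_by_pair: dict) -> pd.DataFrame:
    """Comparison summary: one row per metric, one column triple per pair
    (group means across densities and the FDA p)."""
    cols = {}
    for pair, res in results_by_pair.items():
        tag = f"{pair[0]} vs {pair[1]}"
        for name, r in res.items():
            if isinstance(r, NodalTestResult):
                continue
            cols.setdefault(name, {})[f"{tag}: {pair[0]}"] = np.nanmean(r.observed_group1)
            cols[name][f"{tag}: {pair[1]}"] = np.nanmean(r.observed_group2)
            cols[name][f"{tag}: p(FDA)"] = r.fda_p
    return pd.DataFrame(cols).T


def _load_inputs(config: RunConfig):
    catalog = default_catalog()
    if config.spec_path is not None:
        spec = CohortSpec.from_yaml(config.spec_path)
        _, table = generate_cohort(spec, seed=config.seed)
        return table, spec.roi_names
    if config.volumes_path is None or config.participants_path is None:
        raise ValueError("config needs either spec_path or volumes+participants paths")
    participants = scn_io.load_participants(config.participants_path)
    aliases = scn_io.load_alias_map(config.alias_path) if config.alias_path else None
    table = scn_io.load_volume_table(
        config.volumes_path, catalog, aliases=aliases, participants=participants
    )
    return table, table.roi_names


def run_pipeline(config: RunConfig, table: scn_io.ROIVolumeTable | None = None) -> dict:
    """Run every stage; returns the result bundle (also written to disk)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: list[dict] = []
    bundle: dict = {"config": asdict(config), "stages": stages}

    def stage(name):
        t0 = time.time()
        logger.info("stage %s started", name)

        def done(**info):
            stages.append({"stage": name, "seconds": round(time.time() - t0, 2), **info})
            logger.info("stage %s finished (%.1fs)", name, time.time() - t0)

        return done

    try:
        finish = stage("load")
        if table is None:
            table, roi_names = _load_inputs(config)
        else:
            roi_names = table.roi_names
        finish(n_participants=table.n_participants, n_rois=len(roi_names))

        # --- clinical arm (raw volumes) ----------------------------------
        finish = stage("clinical")
        demo = demographic_tests(table.participants)
        scn_io.write_table(demo, out / "demographics.tsv", index=False)
        ancova_rows = per_roi_ancova(table, q=config.fdr_q)
        anc_df = pd.DataFrame(
            [
                {
                    "roi": r.roi,
                    **{f"mean_{g}": m for g, m in r.group_means.items()},
                    **{f"sd_{g}": s for g, s in r.group_sds.items()},
                    "F": r.f, "p": r.p_raw, "p_fdr": r.p_fdr,
                    "partial_eta_sq": r.partial_eta_squared,
                    **{f"posthoc_{k}": v for k, v in r.posthoc_p.items()},
                }
                for r in ancova_rows
            ]
        )
        scn_io.write_table(anc_df, out / "roi_ancova.tsv", index=False)
        mancova_out = None
        try:
            mancova_out = mancova(table)
            scn_io.write_json(mancova_out, out / "mancova.json")
        except StatsError as exc:
            logger.warning("MANCOVA skipped: %s", exc)
        corr = roi_psychometric_correlations(
            table.volumes, table.participants, roi_names
        )
        scn_io.write_table(corr, out / "roi_psychometric_correlations.tsv", index=False)
        finish(n_ancova_discoveries=int((anc_df["p_fdr"] < config.fdr_q).sum()),
               mancova="ok" if mancova_out else "skipped")
        bundle.update(demographics=demo, roi_ancova=anc_df, mancova=mancova_out,
                      correlations=corr)

        # --- per-group topology ------------------------------------------
        groups = sorted(set(g for pair in config.comparisons for g in pair))
        groups = [g for g in groups if (table.participants["group"] == g).any()]
        finish = stage("group-topology")
        group_tables: dict[str, pd.DataFrame] = {}
        degree_fits = {}
        resilience = {}
        dmin = {}
        for g in groups:
            res_g = residualize(table.select_groups([g]), fit_scope="pooled_all")
            assoc = association_matrix(res_g, g)
            dmin[g] = minimum_connected_density(assoc)
            sweep = build_sweep(assoc, config.d_min, config.d_max, config.d_step)
            if sweep.flagged:
                logger.warning("group %s: disconnected at densities %s", g, sweep.flagged)
            rows = []
            for d, net in zip(sweep.densities, sweep.networks):
                sub = substream(config.seed, f"metrics:{g}:{d}")
                try:
                    gm = global_metrics(
                        net, n_random=config.n_random_graphs,
                        modularity_restarts=config.modularity_restarts,
                        seed=int(sub.integers(2**31)),
                    )
                    rows.append({"density": d, **asdict(gm)})
                except MetricError as exc:
                    rows.append({"density": d, "error": str(exc)})
            group_tables[g] = pd.DataFrame(rows)
            scn_io.write_table(group_tables[g], out / f"global_metrics_{g}.tsv", index=False)
            net_low = sweep.networks[0]
            scn_io.write_adjacency(net_low.adjacency, net_low.node_labels,
                                   out / f"adjacency_{g}_d{config.d_min}.tsv")
            scn_io.write_graphml(net_low.adjacency, net_low.node_labels,
                                 out / f"network_{g}_d{config.d_min}.graphml")
            try:
                fit = fit_truncated_power_law(net_low)
                degree_fits[g] = asdict(fit)
            except MetricError as exc:
                degree_fits[g] = {"error": str(exc)}
            rc = random_failure(
                net_low, reps=config.resilience_reps,
                seed=int(substream(config.seed, f"resilience:{g}").integers(2**31)),
            )
            resilience[g] = rc
            scn_io.write_table(
                pd.DataFrame({"fraction_removed": rc.fractions_removed,
                              "relative_lcc": rc.relative_lcc}),
                out / f"resilience_{g}.tsv", index=False,
            )
        scn_io.write_json({"minimum_connected_density": dmin,
                           "degree_fits": degree_fits}, out / "degree_fits.json")
        finish(groups=groups, d_min_observed=dmin)
        bundle.update(group_metrics=group_tables, degree_fits=degree_fits,
                      resilience=resilience, minimum_connected_density=dmin)

        # --- permutation comparisons -------------------------------------
        finish = stage("permutation-inference")
        comparisons = {}
        for pair in config.comparisons:
            if not all((table.participants["group"] == g).any() for g in pair):
                logger.warning("comparison %s skipped: group missing", pair)
                continue
            pair_table = table.select_groups(pair)
            res_pair = residualize(pair_table, fit_scope="pooled_pair")
            sub = substream(config.seed, f"compare:{pair[0]}:{pair[1]}")
            results = compare_groups(
                res_pair, pair[0], pair[1],
                metrics=config.metrics,
                densities=np.round(
                    np.arange(config.d_min, config.d_max + config.d_step / 2, config.d_step), 10
                ),
                n_perm=config.n_perm,
                n_random=config.n_random_graphs,
                modularity_restarts=max(1, config.modularity_restarts // 50),
                seed=int(sub.integers(2**31)),
                nodal=config.nodal,
                q=config.fdr_q,
            )
            comparisons[pair] = results
            doc = {}
            for name, r in results.items():
                if isinstance(r, NodalTestResult):
                    doc[name] = {
                        "p_raw": dict(zip(r.node_labels, r.p_raw)),
                        "p_fdr": dict(zip(r.node_labels, r.p_fdr)),
                        "n_reject_raw": int(r.reject_raw.sum()),
                        "n_reject_fdr": int(r.reject_fdr.sum()),
                    }
                else:
                    doc[name] = {
                        "densities": r.densities.tolist(),
                        "observed_group1": r.observed_group1.tolist(),
                        "observed_group2": r.observed_group2.tolist(),
                        "p_per_density": r.p_per_density.tolist(),
                        "fda_statistic": r.fda_statistic,
                        "fda_p": r.fda_p,
                        "n_perm": r.n_perm,
                        "seed": r.seed,
                    }
            scn_io.write_json(doc, out / f"comparison_{pair[0]}_vs_{pair[1]}.json")
        summary = global_summary_table(comparisons)
        scn_io.write_table(summary, out / "topology_summary.tsv")
        finish(n_comparisons=len(comparisons))
        bundle.update(comparisons=comparisons, topology_summary=summary)

        # --- manifest ----------------------------------------------------
        import subscn

        scn_io.write_json(
            {"config": asdict(config), "stages": stages, "version": subscn.__version__},
            out / "manifest.json",
        )
        return bundle
    except Exception as exc:
        scn_io.write_json(
            {"config": asdict(config), "stages": stages, "error": str(exc)},
            out / "manifest.json",
        )
        logger.error("pipeline aborted in stage %r: %s",
                      stages[-1]["stage"] if stages else "load", exc)
        raise
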