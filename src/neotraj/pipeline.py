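"""End-to-end orchestration: one config, reproducible seeds, tidy CSV outputs.

A run is described by a RunConfig (YAML-friendly): either paths to the
three input tables or a ``simulate`` block of generator overrides, the
stages to run, thresholds, a global seed and an output directory.  The
global seed fans out deterministically to per-stage seeds through a
fixed per-stage counter (SeedSequence([seed, stage_counter])), so
toggling one stage never shifts another stage's draws.  Identical
(config, seed) produce byte-identical result CSVs; a run record
(config + seed + package version) is written alongside the outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .contrasts import fit_group_model, group_fits_table
from .geometry import prematurity_association, standardize_and_project, trajectory_distances
from .io import (
    CohortBundle,
    assemble_cohort,
    read_adult_reference,
    read_clinical_table,
    read_immune_table,
    read_taxa_table,
    write_immune_table,
    write_taxa_table,
)
from .link import run_link_stage
from .microbiome import (
    diversity_series,
    family_inclusion_filter,
    group_slope_summary,
    subject_slopes,
    weighted_mann_whitney,
)
from .network import all_pairwise_correlations, build_network, edges_table, prune_nested
from .simulate import SimConfig, generate_cohort, generate_taxa_tracks
from .trajectories import run_adult_deviation_stage, run_slope_stage

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "stage_seed", "load_run_config"]

STAGES = (
    "simulate",
    "trajectories",
    "geometry",
    "network",
    "microbiome",
    "link",
    "contrasts",
)
_STAGE_COUNTER = {name: i + 1 for i, name in enumerate(STAGES)}


@dataclass
class RunConfig:
    out_dir: str = "results"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    simulate: dict = field(default_factory=dict)  # SimConfig overrides
    inputs: dict = field(default_factory=dict)  # immune/taxa/clinical/adults paths
    alpha: float = 0.05
    rho_threshold: float = 0.3
    p_threshold: float = 0.008
    bin_width_days: float = 5.0
    min_bins: int = 4
    n_perm: int = 100_000
    slope_model: str = "mixed"
    nested_pairs: list[tuple[str, str]] = field(default_factory=list)
    #: caps on immune parameters entering the quadratic-cost stages
    #: (all-pairs network, link cross-product, per-parameter mixed fits);
    #: None = all
    max_network_parameters: int | None = 40
    max_link_parameters: int | None = 10
    max_contrast_parameters: int | None = 20

    def validate(self) -> "RunConfig":
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stage name(s): {unknown}")
        if "simulate" not in self.stages and not self.inputs:
            raise ValueError("need either a simulate stage or input paths")
        return self


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: SeedSequence([seed, stage counter])."""
    ss = np.random.SeedSequence([int(global_seed), _STAGE_COUNTER[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


def load_run_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    if "nested_pairs" in raw:
        raw["nested_pairs"] = [tuple(p) for p in raw["nested_pairs"]]
    return RunConfig(**raw).validate()


def _write(df: pd.DataFrame, path: Path, manifest: list[str]) -> None:
    df.to_csv(path, index=False, float_format="%.10g")
    manifest.append(str(path))


def _load_bundle(config: RunConfig) -> CohortBundle:
    immune = read_immune_table(config.inputs["immune"])
    clinical = read_clinical_table(config.inputs["clinical"])
    taxa = (
        read_taxa_table(config.inputs["taxa"]) if config.inputs.get("taxa") else None
    )
    adults = (
        read_adult_reference(config.inputs["adults"])
        if config.inputs.get("adults")
        else None
    )
    return assemble_cohort(immune, clinical, taxa=taxa, adult_reference=adults)


def run_pipeline(config: RunConfig) -> list[str]:
    """Run the configured stages in dependency order; return the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []

    if "simulate" in config.stages:
        sim = SimConfig(**config.simulate)
        seed = stage_seed(config.seed, "simulate")
        logger.info("stage simulate (seed %d)", seed)
        bundle = generate_cohort(sim, seed=seed)
        bundle.taxa = generate_taxa_tracks(sim, seed=seed)
        write_immune_table(bundle.immune, out / "immune.csv")
        manifest.append(str(out / "immune.csv"))
        write_taxa_table(bundle.taxa, out / "taxa.tsv")
        manifest.append(str(out / "taxa.tsv"))
        clin = pd.DataFrame(
            [
                (r.subject_id, r.gestational_age_days, r.group, r.sex)
                for r in bundle.clinical.values()
            ],
            columns=["subject_id", "gestational_age_days", "group", "sex"],
        ).sort_values("subject_id")
        _write(clin, out / "clinical.csv", manifest)
        adults = bundle.adult_reference.rename_axis("donor_id").reset_index()
        _write(adults, out / "adults.csv", manifest)
    else:
        bundle = _load_bundle(config)

    idx = bundle.immune.data.index
    ages = idx.get_level_values("postnatal_age_days").to_numpy(dtype=float)
    sids = idx.get_level_values("subject_id").to_numpy()
    groups = np.array([bundle.clinical[s].group for s in sids])

    deviations = None
    if "trajectories" in config.stages:
        logger.info("stage trajectories")
        deviations = run_adult_deviation_stage(bundle)
        _write(deviations, out / "adult_deviation.csv", manifest)
        slopes, quadrants = run_slope_stage(
            bundle, model=config.slope_model, alpha=config.alpha,
            deviations=deviations,
        )
        # also emit the cheap per-subject-mean slopes for comparison with
        # the mixed-model estimates
        if config.slope_model != "per_subject":
            per_subj, _ = run_slope_stage(bundle, model="per_subject")
            slopes = pd.concat([slopes, per_subj], ignore_index=True)
        _write(slopes, out / "slopes.csv", manifest)
        _write(quadrants, out / "quadrants.csv", manifest)

    if "geometry" in config.stages:
        logger.info("stage geometry")
        scores = standardize_and_project(bundle.immune, n_components=2)
        sc = scores.scores.reset_index()
        _write(sc, out / "pca_scores.csv", manifest)
        dists = trajectory_distances(bundle, scores)
        _write(dists, out / "trajectory_distances.csv", manifest)
        if len(dists) >= 5:
            assoc = prematurity_association(dists)
            with open(out / "prematurity_association.json", "w") as fh:
                json.dump(assoc, fh, indent=1)
            manifest.append(str(out / "prematurity_association.json"))

    if "network" in config.stages:
        logger.info("stage network")
        params = prune_nested(bundle.immune.parameters, config.nested_pairs)
        if config.max_network_parameters:
            params = params[: config.max_network_parameters]
        edges = all_pairwise_correlations(bundle.immune.data, params)
        et = edges_table(edges, config.rho_threshold, config.p_threshold)
        _write(et, out / "edges.csv", manifest)
        g = build_network(edges, config.rho_threshold, config.p_threshold)
        nodes = pd.DataFrame(
            sorted((n, d["degree"]) for n, d in g.nodes(data=True)),
            columns=["parameter", "degree"],
        )
        _write(nodes, out / "nodes.csv", manifest)
        import networkx as nx

        nx.write_graphml(g, out / "network.graphml")
        manifest.append(str(out / "network.graphml"))

    if "microbiome" in config.stages and bundle.taxa is not None:
        logger.info("stage microbiome")
        div = diversity_series(bundle.taxa)
        _write(div, out / "diversity.csv", manifest)
        taxa_groups = {
            s: bundle.clinical[s].group
            for s in bundle.taxa.data.index.get_level_values("subject_id").unique()
        }
        slope_rows, contrast_rows = [], []
        quantities = {"diversity": div.rename(columns={"inverse_simpson": "value"})}
        ent = bundle.taxa.data["Enterobacteriaceae"].reset_index()
        ent["value"] = ent["Enterobacteriaceae"] * 100.0  # percent scale
        quantities["family:Enterobacteriaceae"] = ent
        for qty, tidy in quantities.items():
            slopes_all = subject_slopes(tidy, "value", qty)
            by_group: dict[str, list] = {}
            for s in slopes_all:
                g = taxa_groups[s.subject_id]
                by_group.setdefault(g, []).append(s)
                slope_rows.append((qty, s.subject_id, g, s.slope_per_week, s.n_points))
            for g, sl in sorted(by_group.items()):
                wmed = group_slope_summary(sl)
                wmean = float(np.average(
                    [s.slope_per_week for s in sl],
                    weights=[s.n_points for s in sl],
                ))
                contrast_rows.append((qty, g, g, wmed, wmean, float("nan")))
            names = sorted(by_group)
            mw_seed = stage_seed(config.seed, "microbiome")
            for i, ga in enumerate(names):
                for gb in names[i + 1 :]:
                    p = weighted_mann_whitney(
                        [s.slope_per_week for s in by_group[ga]],
                        [s.n_points for s in by_group[ga]],
                        [s.slope_per_week for s in by_group[gb]],
                        [s.n_points for s in by_group[gb]],
                        n_perm=config.n_perm,
                        seed=mw_seed,
                    )
                    contrast_rows.append(
                        (qty, ga, gb, float("nan"), float("nan"), p)
                    )
        _write(
            pd.DataFrame(
                slope_rows,
                columns=["quantity", "subject_id", "group", "slope_per_week",
                         "n_points"],
            ),
            out / "subject_slopes.csv",
            manifest,
        )
        _write(
            pd.DataFrame(
                contrast_rows,
                columns=["quantity", "group_a", "group_b", "weighted_median",
                         "weighted_mean", "p"],
            ),
            out / "group_contrasts.csv",
            manifest,
        )

    if "link" in config.stages and bundle.taxa is not None:
        logger.info("stage link")
        immune_tidy = bundle.immune.data.reset_index()
        taxa_tidy = bundle.taxa.data.reset_index()
        params = bundle.immune.parameters
        if config.max_link_parameters:
            params = params[: config.max_link_parameters]
        fams = family_inclusion_filter(bundle.taxa)
        pairs, per_subj = run_link_stage(
            immune_tidy,
            taxa_tidy,
            params,
            fams,
            bin_width_days=config.bin_width_days,
            min_bins=config.min_bins,
        )
        _write(pairs, out / "link_results.csv", manifest)
        _write(per_subj, out / "link_per_subject.csv", manifest)

    if "contrasts" in config.stages:
        logger.info("stage contrasts")
        fits = []
        cap = config.max_contrast_parameters or len(bundle.immune.parameters)
        for param in bundle.immune.parameters[:cap]:
            vals = bundle.immune.data[param].to_numpy(dtype=float)
            fits.append(
                fit_group_model(vals, ages, sids, groups, parameter=param)
            )
        _write(group_fits_table(fits), out / "group_fits.csv", manifest)

    record = {
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "manifest": manifest,
    }
    with open(out / "run_record.json", "w") as fh:
        json.dump(record, fh, indent=1, default=str)
    manifest.append(str(out / "run_record.json"))
    return manifest
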