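"""One-command orchestration of the three analysis stages.

Stage order mirrors the analysis: (1) richness — polynomial screen,
backward-stepwise set models, A/E/S variance partitioning; (2) composition —
beta_sim, UPGMA dendrogram + k-cut, CAP model selection for the E and S
sets, composition partitioning, richness/log-area covariate checks;
(3) decay — similarity transform, latitude split, exponential decay fits
per group, bootstrap slope comparison.

A single run seed fans out to per-stage sub-seeds through fixed offsets, so
re-running one stage in isolation reproduces its numbers.  All randomised
p-values are reported together with their permutation/bootstrap counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .core_io import (
    OccurrenceMatrix,
    SiteTable,
    read_occurrences,
    read_site_table,
    write_dissimilarity,
    write_occurrences,
    write_report,
    write_site_table,
)
from .beta_diversity import pairwise_matrix, to_similarity
from .composition_ordination import (
    cap_fit,
    cut_clusters,
    gower_pcoa,
    partition_composition,
    select_model,
    single_covariate_test,
    trend_surface_terms,
    upgma,
)
from .distance_decay import (
    bootstrap_slopes,
    centroid_distances,
    compare_slopes,
    fit_decay,
    split_by_latitude,
)
from .richness_models import (
    SET_A,
    SET_E,
    SET_S,
    Term,
    backward_stepwise,
    partition_richness,
    polynomial_screen,
)
from .synthetic_data import SyntheticConfig, generate_landscape, generate_occurrences

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("betascape")

# fixed per-stage offsets off the run seed
_STAGE_OFFSET = {"composition": 101, "decay_perm": 202, "boot_north": 303, "boot_south": 404}


@dataclass
class PipelineConfig:
    """Everything one run needs; ``synthetic`` generates inputs in place of
    occurrence/site CSV paths."""

    occurrences_path: str | None = None
    site_table_path: str | None = None
    synthetic: bool = False
    synthetic_config: SyntheticConfig | None = None
    stages: tuple[str, ...] = ("richness", "composition", "decay")
    alpha: float = 0.05
    n_perm: int = 999
    n_boot: int = 1000
    max_terms: int = 4
    k_clusters: int = 4
    threshold_lat: float = 48.0
    decay_fit_perms: int = 199
    seed: int | None = None
    output_dir: str = "results"

    def validate(self) -> None:
        stochastic = {"composition", "decay"} & set(self.stages)
        if (stochastic or self.synthetic) and self.seed is None:
            raise ValueError("seed required: a stochastic stage is enabled")
        if not self.synthetic:
            if "richness" in self.stages or "composition" in self.stages or "decay" in self.stages:
                if self.occurrences_path is None or self.site_table_path is None:
                    raise ValueError("occurrence and site-table paths (or synthetic=True) required")

    def stage_seed(self, stage: str) -> int:
        return (int(self.seed) + _STAGE_OFFSET[stage]) % (2 ** 31 - 1)


def _config_hash(config: PipelineConfig) -> str:
    d = asdict(config)
    return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _load_inputs(config: PipelineConfig, outdir: Path):
    if config.synthetic:
        syn = config.synthetic_config or SyntheticConfig(seed=config.seed)
        landscape = generate_landscape(syn)
        occ, truth = generate_occurrences(syn, landscape)
        write_site_table(landscape, outdir / "site_table.csv")
        write_occurrences(occ, outdir / "occurrences.csv")
        truth.to_json(outdir / "synthetic_truth.json")
        return occ, landscape, truth
    occ = read_occurrences(config.occurrences_path)
    landscape = read_site_table(config.site_table_path).align_to(occ)
    return occ, landscape, None


def _richness_stage(occ: OccurrenceMatrix, table: SiteTable, config: PipelineConfig, outdir: Path) -> dict:
    rich = occ.richness()
    screen = polynomial_screen(rich, table, alpha=config.alpha)
    screen_rows = [m.to_report_rows()[0] for m in screen]

    def set_candidates(names) -> list[Term]:
        cands: list[Term] = []
        for m in screen:
            if not m.terms or m.function == "ns":
                continue
            var = m.terms[0].variable
            if var not in names and not (m.terms[0].log and var == "Area" and "log(Area)" in names):
                continue
            cands.extend(m.terms)
        return cands

    models = {}
    for key, names in (("A", set(SET_A) | {"Area"}), ("E", set(SET_E)), ("S", set(SET_S))):
        cands = set_candidates(names)
        models[key] = backward_stepwise(rich, table, cands, alpha_stay=config.alpha)
    part = partition_richness(
        rich, table, models["A"].terms, models["E"].terms, models["S"].terms
    )
    rows = screen_rows + [
        {**m.to_report_rows()[0], "Variable": f"Model for {k}: " + m.to_report_rows()[0]["Variable"]}
        for k, m in models.items()
    ]
    result = {
        "screen": screen_rows,
        "set_models": {
            k: {"terms": [t.label() for t in m.terms], "variance_pct": m.variance_pct,
                "adj_variance_pct": m.adj_variance_pct, "F": m.F, "df": list(m.df), "p": m.p}
            for k, m in models.items()
        },
        "partition": {"fractions": part.fractions, "source_r2": part.source_r2},
    }
    write_report(result, outdir / "richness", rows=rows)
    log.info("richness: R2%% A=%.1f E=%.1f S=%.1f, E&S shared=%.1f",
             part.source_r2["A"], part.source_r2["E"], part.source_r2["S"],
             part.fractions["E&S"])
    return {"models": models, "partition": part, "screen": screen, "richness": rich}


def _composition_stage(occ: OccurrenceMatrix, table: SiteTable, config: PipelineConfig, outdir: Path) -> dict:
    import pandas as pd

    seed = config.stage_seed("composition")
    d = pairwise_matrix(occ, "sim")
    write_dissimilarity(d, outdir / "beta_sim.csv")
    clust = upgma(d)
    (outdir / "dendrogram.nwk").write_text(clust.newick + "\n")
    labels = cut_clusters(clust, config.k_clusters)
    emb = gower_pcoa(d)

    X_A = pd.DataFrame({"log(Area)": np.log(table["Area"])})
    X_E = pd.DataFrame({v: table[v] for v in SET_E if v in table.data.columns})
    X_S = trend_surface_terms(table["Lat"], table["Long"])

    model_E = select_model(emb, X_E, alpha=config.alpha, max_terms=config.max_terms,
                           n_perm=config.n_perm, seed=seed)
    model_S = select_model(emb, X_S, alpha=config.alpha, max_terms=config.max_terms,
                           n_perm=config.n_perm, seed=seed + 1)
    sel_E = X_E[list(model_E.retained_terms)] if model_E.retained_terms else X_E.iloc[:, :0]
    sel_S = X_S[list(model_S.retained_terms)] if model_S.retained_terms else X_S.iloc[:, :0]
    part = partition_composition(emb, X_A, sel_E, sel_S)

    F_rich, p_rich = single_covariate_test(emb, occ.richness().astype(float),
                                           n_perm=config.n_perm, seed=seed + 2)
    F_area, p_area = single_covariate_test(emb, np.log(table["Area"]),
                                           n_perm=config.n_perm, seed=seed + 3)

    result = {
        "cluster_labels": labels,
        "pcoa": {
            "represented_inertia": emb.represented_inertia,
            "discarded_abs_share": emb.discarded_abs_share,
        },
        "model_E": {"terms": list(model_E.retained_terms),
                    "constrained_pct": model_E.constrained_pct,
                    "pseudo_F": model_E.pseudo_F, "df": list(model_E.df),
                    "p": model_E.p_perm, "n_perm": model_E.n_perm},
        "model_S": {"terms": list(model_S.retained_terms),
                    "constrained_pct": model_S.constrained_pct,
                    "pseudo_F": model_S.pseudo_F, "df": list(model_S.df),
                    "p": model_S.p_perm, "n_perm": model_S.n_perm},
        "partition": {"fractions": part.fractions, "source_r2": part.source_r2},
        "richness_covariate": {"pseudo_F": F_rich, "p": p_rich},
        "log_area_covariate": {"pseudo_F": F_area, "p": p_area},
    }
    rows = model_E.to_report_rows() + model_S.to_report_rows()
    write_report(result, outdir / "composition", rows=rows)
    log.info("composition: E=%.1f%% S=%.1f%%, unique(S)=%.1f unique(E)=%.1f",
             model_E.constrained_pct, model_S.constrained_pct,
             part.fractions["S"], part.fractions["E"])
    return {"labels": labels, "model_E": model_E, "model_S": model_S,
            "partition": part, "cluster": clust, "beta_sim": d}


def _decay_stage(occ: OccurrenceMatrix, table: SiteTable, config: PipelineConfig, outdir: Path) -> dict:
    sim = to_similarity(pairwise_matrix(occ, "sim"))
    dist, dist_ids = centroid_distances(table)
    north, south = split_by_latitude(table, config.threshold_lat)
    fits = {}
    boots = {}
    for name, subset, boot_key in (("north", north, "boot_north"), ("south", south, "boot_south")):
        fits[name] = fit_decay(sim, dist, dist_ids, subset,
                               n_perm=config.decay_fit_perms,
                               seed=config.stage_seed("decay_perm"))
        boots[name] = bootstrap_slopes(sim, dist, dist_ids, subset,
                                       n_boot=config.n_boot,
                                       seed=config.stage_seed(boot_key))
    comp = compare_slopes(fits["south"], fits["north"],
                          boots["south"], boots["north"],
                          labels=("south", "north"))
    result = {
        "groups": {"north": list(north), "south": list(south)},
        "fits": {
            name: {"a_init": f.a_init, "slope": f.slope, "b_rate": f.b_rate,
                   "r2": f.r2, "n_pairs": f.n_pairs, "p_perm": f.p_perm,
                   "n_perm": f.n_perm}
            for name, f in fits.items()
        },
        "comparison": {"p_diff": comp.p_diff, "direction": comp.direction,
                       "n_boot": comp.n_boot},
    }
    write_report(result, outdir / "decay")
    log.info("decay: b_south=%.2e b_north=%.2e (steeper: %s, p_diff=%.4g)",
             fits["south"].b_rate, fits["north"].b_rate, comp.direction, comp.p_diff)
    return {"fits": fits, "boots": boots, "comparison": comp}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages and write every artefact under the output
    directory; returns the in-memory stage results keyed by stage name."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    occ, table, truth = _load_inputs(config, outdir)
    results: dict = {"occurrences": occ, "site_table": table, "truth": truth}
    stage_fns = {
        "richness": _richness_stage,
        "composition": _composition_stage,
        "decay": _decay_stage,
    }
    for stage in ("richness", "composition", "decay"):
        if stage not in config.stages:
            continue
        try:
            results[stage] = stage_fns[stage](occ, table, config, outdir)
        except Exception as exc:
            raise RuntimeError(f"[{stage}] stage failed: {exc}") from exc
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "config": json.loads(json.dumps(asdict(config), default=str)),
        "stages_run": [s for s in config.stages],
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1)
        fh.write("\n")
    return results
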