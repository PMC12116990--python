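"""End-to-end pipeline: simulate/load -> filter -> guilds -> screen -> ordinate -> associate.

A run is driven by a YAML config validated up front (all errors reported at
once, unknown keys rejected).  One top-level seed is recorded; each stage
derives its own seed from (seed, stage name), so any stage can be re-run in
isolation and adding a stage never perturbs another's draws.  Every stage
writes TSV outputs into the run directory plus a JSON manifest capturing
parameters, derived seeds, input checksums, and wall times.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import association, guilds, ordination, simulate, stats, tables

logger = logging.getLogger(__name__)


def derive_seed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") & 0x7FFFFFFF


_SECTION_KEYS = {
    "inputs": {"abundance", "metadata", "metabolites"},
    "simulate": {
        "enabled", "n_subjects", "timepoints", "sex_ratio", "n_features",
        "block_sizes", "within_guild_corr", "subject_sd", "sample_sd",
        "feature_sd", "suppressed_guilds", "increased_guilds",
        "effect_magnitude", "metabolite_analytes", "target_guild",
    },
    "filter": {"min_prevalence"},
    "guilds": {"alpha", "n_permutations", "correlation"},
    "screen": {"q_threshold", "posthoc", "baseline", "contrasts", "blocked_anova"},
    "ordinate": {"metric", "adjust", "n_permutations", "baseline"},
    "associate": {"enabled"},
}
_TOP_KEYS = {"seed", "output_dir"} | set(_SECTION_KEYS)


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "guildflow_run"
    inputs: dict = field(default_factory=dict)
    simulate: dict = field(default_factory=lambda: {"enabled": True})
    filter: dict = field(default_factory=dict)
    guilds: dict = field(default_factory=dict)
    screen: dict = field(default_factory=dict)
    ordinate: dict = field(default_factory=dict)
    associate: dict = field(default_factory=lambda: {"enabled": True})


def validate_config(raw: dict) -> tuple[RunConfig | None, list[str]]:
    """Validate a parsed config mapping; returns (config, full error list)."""
    errors: list[str] = []
    if not isinstance(raw, dict):
        return None, ["config must be a mapping"]
    for key in raw:
        if key not in _TOP_KEYS:
            errors.append(f"unknown key: {key}")
    for section, allowed in _SECTION_KEYS.items():
        sec = raw.get(section, {})
        if sec is None:
            continue
        if not isinstance(sec, dict):
            errors.append(f"{section}: must be a mapping")
            continue
        for key in sec:
            if key not in allowed:
                errors.append(f"{section}.{key}: unknown key")

    cfg = RunConfig(
        seed=raw.get("seed", 0),
        output_dir=str(raw.get("output_dir", "guildflow_run")),
        inputs=dict(raw.get("inputs") or {}),
        simulate=dict(raw.get("simulate") or {"enabled": True}),
        filter=dict(raw.get("filter") or {}),
        guilds=dict(raw.get("guilds") or {}),
        screen=dict(raw.get("screen") or {}),
        ordinate=dict(raw.get("ordinate") or {}),
        associate=dict(raw.get("associate") or {"enabled": True}),
    )
    if not isinstance(cfg.seed, int):
        errors.append("seed: must be an integer")

    def check(section: str, key: str, ctor, *args, **kwargs):
        try:
            ctor(*args, **kwargs)
        except (ValueError, TypeError) as exc:
            errors.append(f"{section}.{key}: {exc}")

    check("filter", "min_prevalence", guilds_mod_filter, cfg.filter.get("min_prevalence", 0.20))
    check("guilds", "alpha/n_permutations", guilds_mod_cut,
          cfg.guilds.get("alpha", 0.001), cfg.guilds.get("n_permutations", 9999))
    q = cfg.screen.get("q_threshold", 0.25)
    if not (isinstance(q, (int, float)) and 0 < q <= 1):
        errors.append("screen.q_threshold: must be in (0, 1]")
    posthoc = cfg.screen.get("posthoc", "nemenyi")
    if posthoc not in ("nemenyi", "dunnett", "both"):
        errors.append("screen.posthoc: must be nemenyi, dunnett, or both")
    metric = cfg.ordinate.get("metric", "bray_curtis")
    if metric not in ("bray_curtis", "jaccard", "euclidean_z"):
        errors.append("ordinate.metric: must be bray_curtis, jaccard, or euclidean_z")
    adjust = cfg.ordinate.get("adjust", "subject")
    if adjust not in ("none", "subject"):
        errors.append("ordinate.adjust: must be none or subject")
    if not cfg.simulate.get("enabled", True):
        for key in ("abundance", "metadata"):
            if not cfg.inputs.get(key):
                errors.append(f"inputs.{key}: required when simulate.enabled is false")
    return (None, errors) if errors else (cfg, [])


def guilds_mod_filter(min_prevalence):
    guilds.FilterParams(min_prevalence=min_prevalence)


def guilds_mod_cut(alpha, n_permutations):
    guilds.CutParams(alpha=alpha, n_permutations=n_permutations)


def load_config(path) -> tuple[RunConfig | None, list[str]]:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return validate_config(raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute all configured stages; returns the run directory."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": cfg.seed,
        "stage_seeds": {},
        "parameters": {
            k: getattr(cfg, k)
            for k in ("inputs", "simulate", "filter", "guilds", "screen",
                      "ordinate", "associate")
        },
        "input_checksums": {},
        "stage_seconds": {},
        "outputs": [],
    }

    def record(stage: str, t0: float, *paths: Path) -> None:
        manifest["stage_seconds"][stage] = round(time.perf_counter() - t0, 3)
        manifest["outputs"].extend(str(p) for p in paths)

    try:
        # --- inputs -------------------------------------------------------
        t0 = time.perf_counter()
        metabolites = None
        if cfg.simulate.get("enabled", True):
            sim_seed = derive_seed(cfg.seed, "simulate")
            manifest["stage_seeds"]["simulate"] = sim_seed
            design = simulate.CohortDesign(
                n_subjects=cfg.simulate.get("n_subjects", 27),
                timepoints=tuple(cfg.simulate.get("timepoints", simulate.DEFAULT_TIMEPOINTS)),
                sex_ratio=tuple(cfg.simulate.get("sex_ratio", (16, 11))),
                seed=sim_seed,
            )
            guild_spec = simulate.GuildSpec(
                n_features=cfg.simulate.get("n_features", 120),
                block_sizes=tuple(cfg.simulate.get("block_sizes", (8,) * 10)),
                within_guild_corr=cfg.simulate.get("within_guild_corr", 0.7),
                subject_sd=cfg.simulate.get("subject_sd", 1.0),
                sample_sd=cfg.simulate.get("sample_sd", 0.3),
                feature_sd=cfg.simulate.get("feature_sd", 1.0),
            )
            effect_spec = simulate.EffectSpec.default_transient(
                suppressed=tuple(cfg.simulate.get("suppressed_guilds", (0,))),
                increased=tuple(cfg.simulate.get("increased_guilds", (1,))),
                magnitude=cfg.simulate.get("effect_magnitude", 1.5),
            )
            table, metadata, truth = simulate.simulate_abundance(
                design, guild_spec, effect_spec
            )
            met_spec = simulate.MetaboliteSpec(
                target_guild=cfg.simulate.get("target_guild", 0)
            )
            metabolites = simulate.simulate_metabolites(
                table, metadata, truth, met_spec, sim_seed
            )
            tables.write_abundance_table(table, out / "abundance.tsv")
            tables.write_metadata(metadata, out / "metadata.tsv")
            tables.write_metabolite_table(metabolites, out / "metabolites.tsv")
            truth_df = tables.pd.DataFrame(
                sorted(truth.guild_of_feature.items()),
                columns=["feature_id", "true_guild"],
            )
            truth_df.to_csv(out / "truth_partition.tsv", sep="\t", index=False)
            record("simulate", t0, out / "abundance.tsv", out / "metadata.tsv",
                   out / "metabolites.tsv", out / "truth_partition.tsv")
        else:
            table = tables.read_abundance_table(cfg.inputs["abundance"])
            metadata = tables.read_metadata(cfg.inputs["metadata"])
            for key in ("abundance", "metadata", "metabolites"):
                p = cfg.inputs.get(key)
                if p:
                    manifest["input_checksums"][key] = _sha256(Path(p))
            if cfg.inputs.get("metabolites"):
                metabolites = tables.read_metabolite_table(cfg.inputs["metabolites"])
            record("load", t0)
        table, metadata = tables.align(table, metadata)

        # --- prevalence filter -------------------------------------------
        t0 = time.perf_counter()
        filtered, report = guilds.filter_prevalent(
            table, guilds.FilterParams(cfg.filter.get("min_prevalence", 0.20))
        )
        manifest["filter_report"] = asdict(report)
        record("filter", t0)

        # --- guild inference ---------------------------------------------
        t0 = time.perf_counter()
        guild_seed = derive_seed(cfg.seed, "guilds")
        manifest["stage_seeds"]["guilds"] = guild_seed
        D = guilds.correlation_distance_matrix(
            filtered, metadata, method=cfg.guilds.get("correlation", "within_subject")
        )
        tree = guilds.ward_tree(D)
        partition = guilds.cut_tree_to_guilds(
            tree, D,
            guilds.CutParams(
                alpha=cfg.guilds.get("alpha", 0.001),
                n_permutations=cfg.guilds.get("n_permutations", 9999),
                seed=guild_seed,
            ),
        )
        part_df = tables.pd.DataFrame(
            sorted(partition.assignments.items()), columns=["feature_id", "guild_id"]
        )
        part_df.to_csv(out / "guild_partition.tsv", sep="\t", index=False)
        gtable = guilds.guild_abundance(filtered, partition)
        tables.write_abundance_table(gtable, out / "guild_abundance.tsv")
        record("guilds", t0, out / "guild_partition.tsv", out / "guild_abundance.tsv")

        # --- screening ----------------------------------------------------
        t0 = time.perf_counter()
        screen_seed = derive_seed(cfg.seed, "screen")
        manifest["stage_seeds"]["screen"] = screen_seed
        plan = stats.ContrastPlan(
            baseline=str(cfg.screen.get("baseline", "0")),
            contrasts=[tuple(c) for c in cfg.screen.get(
                "contrasts", [("-5", "0"), ("0", "2"), ("0", "4"), ("0", "10")]
            )],
        )
        screen_df = stats.screen_features(
            gtable, metadata, plan,
            q_threshold=cfg.screen.get("q_threshold", 0.25),
            posthoc=cfg.screen.get("posthoc", "nemenyi"),
            blocked_anova=cfg.screen.get("blocked_anova", True),
            seed=screen_seed,
        )
        screen_df.to_csv(out / "screen_results.tsv", sep="\t", index=False)
        record("screen", t0, out / "screen_results.tsv")

        # --- ordination ----------------------------------------------------
        t0 = time.perf_counter()
        ord_seed = derive_seed(cfg.seed, "ordinate")
        manifest["stage_seeds"]["ordinate"] = ord_seed
        Ds = ordination.sample_distance(gtable, cfg.ordinate.get("metric", "bray_curtis"))
        if cfg.ordinate.get("adjust", "subject") == "subject":
            ores = ordination.adjusted_pcoa(Ds, metadata)
        else:
            ores = ordination.pcoa(Ds)
        ordination.ordination_frame(ores, n_axes=4).to_csv(
            out / "ordination_coords.tsv", sep="\t", index=False
        )
        tables.pd.DataFrame(
            {
                "axis": np.arange(1, len(ores.eigenvalues) + 1),
                "eigenvalue": ores.eigenvalues,
                "proportion_explained": ores.proportion_explained,
            }
        ).to_csv(out / "ordination_eigenvalues.tsv", sep="\t", index=False)
        perm_df = ordination.pairwise_day_permanova(
            Ds, metadata,
            baseline=str(cfg.ordinate.get("baseline", cfg.screen.get("baseline", "0"))),
            n_permutations=cfg.ordinate.get("n_permutations", 9999),
            seed=ord_seed,
        )
        perm_df.to_csv(out / "permanova_results.tsv", sep="\t", index=False)
        record("ordinate", t0, out / "ordination_coords.tsv",
               out / "ordination_eigenvalues.tsv", out / "permanova_results.tsv")

        # --- association ---------------------------------------------------
        if cfg.associate.get("enabled", True) and metabolites is not None:
            t0 = time.perf_counter()
            assoc = association.associate(gtable, metabolites, metadata)
            assoc.to_csv(out / "association_results.tsv", sep="\t", index=False)
            record("associate", t0, out / "association_results.tsv")
    except Exception as exc:
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
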