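"""End-to-end orchestration of the variability pipeline.

``run_pipeline`` executes, in order: low-expression filtering -> pooled
median normalization -> per-gene eta -> reciprocal-regression outliers
(with probe-SNP cleanup) -> heterozygosity cutoff sweep per cis-region ->
permutation differential expression -> directional enrichment of DE
outliers -> eta tails and over-representation -> gene-group comparisons
(rank-sum, bootstrap CI, immune-keyword exclusion, annotation-matched
nulls).  Every stage writes a deterministic TSV; a manifest records the
configuration hash, master seed and library versions, so a rerun with
the same config file is byte-identical.

Configuration is a plain ``key = value`` text file; ``simulate = true``
replaces the input files with the synthetic generator (``simulate.*``
keys override :class:`~popvar.simulate.SimulationConfig` fields).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .containers import SNP_REGIONS
from .diffexpr import de_analysis, directional_enrichment, tscore_variability_relation
from .errors import ConfigError, PopvarError
from .heterozygosity import run_hetsweep
from .outliers import reciprocal_outliers, remove_probe_snp_genes
from .sets import (
    bootstrap_ci,
    exclude_keyword_genes,
    group_vs_genome,
    matched_null_comparison,
    overrepresentation,
    select_tails,
)
from .simulate import SimulationConfig, generate_all
from .variability import (
    build_profile,
    correlate_eta,
    filter_low_expression,
    median_normalize,
)

__all__ = [
    "PipelineConfig",
    "load_config",
    "run_pipeline",
    "write_simulated_dataset",
    "STAGE_SETS",
]

#: which computation blocks each CLI stage needs
STAGE_SETS = {
    "simulate": frozenset(),
    "variability": frozenset({"variability"}),
    "outliers": frozenset({"variability", "outliers"}),
    "hetsweep": frozenset({"variability", "outliers", "hetsweep"}),
    "diffexpr": frozenset({"variability", "outliers", "diffexpr"}),
    "setanalysis": frozenset({"variability", "outliers", "setanalysis"}),
    "run-all": frozenset(
        {"variability", "outliers", "hetsweep", "diffexpr", "setanalysis"}
    ),
}

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All thresholds and inputs of one pipeline run."""

    out_dir: str = "popvar_out"
    seed: int = 0
    # inputs (ignored when simulate is true)
    expression: str | None = None
    population_map: str | None = None
    snp_table: str | None = None
    gene_sets: str | None = None
    category_codes: str | None = None
    probe_flags: str | None = None
    simulate: bool = False
    simulate_config: SimulationConfig | None = None
    # stage thresholds
    filter_fraction: float = 0.10
    outlier_level: float = 0.95
    studentize: str = "external"
    sweep_step: float = 0.04
    test_cutoff: float = 0.04
    de_fdr: float = 0.01
    tail_fraction: float = 0.025
    eta_cap: float = 0.05
    n_perm: int = 10000
    n_boot: int = 5000
    n_null_sets: int = 1000
    n_direction_draws: int = 10000
    group_set: str = "virus_interacting"
    immune_keyword: str = "immune"
    raw: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        checks = [
            ("filter_fraction", 0.0, 1.0), ("outlier_level", 0.0, 1.0),
            ("de_fdr", 0.0, 1.0), ("tail_fraction", 0.0, 0.5),
        ]
        for name, lo, hi in checks:
            v = getattr(self, name)
            if not lo <= v < hi:
                raise ConfigError(f"{name} must be in [{lo}, {hi}), got {v}")
        for name in ("n_perm", "n_boot", "n_null_sets", "n_direction_draws"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.sweep_step <= 0:
            raise ConfigError("sweep_step must be > 0")

    def hash(self) -> str:
        # out_dir identifies where results go, not what they are
        items = {
            f.name: getattr(self, f.name)
            for f in dc_fields(self)
            if f.name not in ("raw", "out_dir")
        }
        if self.simulate_config is not None:
            items["simulate_config"] = tuple(
                sorted(self.simulate_config.as_dict().items(), key=lambda kv: kv[0])
            )
        return pio.config_hash({k: repr(v) for k, v in items.items()})


_BOOL = {"true": True, "false": False, "1": True, "0": False, "yes": True, "no": False}


def _parse_value(raw: str, target_type):
    raw = raw.strip()
    if target_type is bool:
        if raw.lower() not in _BOOL:
            raise ConfigError(f"expected boolean, got {raw!r}")
        return _BOOL[raw.lower()]
    if target_type is int:
        return int(raw)
    if target_type is float:
        return float(raw)
    return raw


def load_config(path, overrides: dict | None = None) -> PipelineConfig:
    """Parse a ``key = value`` config file (``#`` starts a comment)."""
    entries: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
            key, value = line.split("=", 1)
            entries[key.strip()] = value.strip()
    if overrides:
        entries.update({k: str(v) for k, v in overrides.items()})

    sim_entries = {k[len("simulate."):]: v for k, v in entries.items()
                   if k.startswith("simulate.")}
    plain = {k: v for k, v in entries.items() if not k.startswith("simulate.")}

    known = {f.name: f.type for f in dc_fields(PipelineConfig)}
    kwargs: dict = {}
    for key, value in plain.items():
        if key not in known or key in ("simulate_config", "raw"):
            raise ConfigError(f"unknown config key {key!r}")
        default = getattr(PipelineConfig, key, None)
        target = type(default) if default is not None else str
        kwargs[key] = _parse_value(value, target)

    sim_config = None
    if kwargs.get("simulate") or sim_entries:
        sim_kwargs: dict = {}
        sim_fields = {f.name for f in dc_fields(SimulationConfig)}
        defaults = SimulationConfig()
        for key, value in sim_entries.items():
            if key not in sim_fields:
                raise ConfigError(f"unknown simulate key {key!r}")
            default = getattr(defaults, key)
            if isinstance(default, tuple):
                parts = [p.strip() for p in value.split(",")]
                conv = [
                    p if i == 0 and not _is_number(p) else float(p)
                    for i, p in enumerate(parts)
                ]
                sim_kwargs[key] = tuple(conv)
            elif isinstance(default, bool):
                sim_kwargs[key] = _parse_value(value, bool)
            elif isinstance(default, int):
                sim_kwargs[key] = int(value)
            elif isinstance(default, float):
                sim_kwargs[key] = float(value)
            else:
                sim_kwargs[key] = value
        sim_config = SimulationConfig(**sim_kwargs)
    config = PipelineConfig(**kwargs, simulate_config=sim_config, raw=entries)
    return config


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def _load_inputs(config: PipelineConfig):
    if config.simulate:
        sim = (config.simulate_config or SimulationConfig()).with_seed(config.seed)
        data = generate_all(sim)
        return (data.matrix_a, data.matrix_b, data.snps, data.gene_sets,
                data.probe_flags, data.truth)
    if config.expression is None or config.population_map is None:
        raise ConfigError("expression and population_map are required "
                          "unless simulate = true")
    matrices = pio.read_expression(config.expression, config.population_map)
    if len(matrices) != 2:
        raise ConfigError(
            f"expected exactly two populations, found {len(matrices)}"
        )
    snps = pio.read_snp_table(config.snp_table) if config.snp_table else None
    gene_sets = (
        pio.read_gene_sets(config.gene_sets, config.category_codes)
        if config.gene_sets
        else None
    )
    probe_flags = (
        pio.read_probe_flags(config.probe_flags) if config.probe_flags else None
    )
    return matrices[0], matrices[1], snps, gene_sets, probe_flags, None


class _StageTimer:
    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        logger.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc is None:
            logger.info("stage %s: done in %.2fs", self.name, dt)
        else:
            logger.error("stage %s: failed after %.2fs: %s", self.name, dt, exc)
        return False


def _stage(name):
    return _StageTimer(name)


def write_simulated_dataset(config: PipelineConfig) -> dict:
    """Generate a synthetic dataset and write its input-format files."""
    sim = (config.simulate_config or SimulationConfig()).with_seed(config.seed)
    data = generate_all(sim)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pio.write_expression(
        [data.matrix_a, data.matrix_b],
        out_dir / "expression.tsv",
        out_dir / "population_map.tsv",
    )
    pio.write_snp_table(data.snps, out_dir / "snp_table.tsv", seed=config.seed)
    pio.write_gene_sets(
        data.gene_sets, out_dir / "gene_sets.gmt", out_dir / "category_codes.tsv"
    )
    pio.write_probe_flags(data.probe_flags, out_dir / "probe_flags.tsv")
    truth_tables = {
        "truth_outliers": pd.DataFrame(
            sorted(data.truth.outlier_direction.items()),
            columns=["gene_id", "direction"],
        ),
        "truth_de": pd.DataFrame(
            sorted(data.truth.de_sign.items()), columns=["gene_id", "sign"]
        ),
    }
    pio.write_results(truth_tables, out_dir, seed=config.seed)
    return {
        "seed": config.seed,
        "n_genes": sim.n_genes,
        "n_per_pop": sim.n_per_pop,
        "n_snps": len(data.snps),
        "n_gene_sets": len(data.gene_sets.sets),
        "out_dir": str(out_dir),
    }


def run_pipeline(config: PipelineConfig, stage: str = "run-all") -> dict:
    """Execute the pipeline up to ``stage`` and write outputs.

    ``stage`` selects how far to go (see :data:`STAGE_SETS`); the default
    runs everything.  Returns a report dict with the headline numbers of
    each executed stage.  Any stage failure raises
    :class:`~popvar.errors.PopvarError` naming the stage.
    """
    if stage not in STAGE_SETS:
        raise ConfigError(f"unknown stage {stage!r}")
    if stage == "simulate":
        if not config.simulate:
            raise ConfigError("stage 'simulate' requires simulate = true")
        return write_simulated_dataset(config)
    wanted = STAGE_SETS[stage]
    out_dir = Path(config.out_dir)
    meta = {"config_hash": config.hash(), "seed": config.seed}
    master = np.random.SeedSequence(config.seed)
    (de_ss, dir_ss, boot_ss, null_ss) = master.spawn(4)
    report: dict = {"config_hash": config.hash(), "seed": config.seed}
    tables: dict[str, pd.DataFrame] = {}

    def run_stage(name, fn):
        with _stage(name):
            try:
                return fn()
            except PopvarError as exc:
                raise type(exc)(f"stage {name}: {exc}") from exc

    # --- inputs -----------------------------------------------------------
    mat_a, mat_b, snps, gene_sets, probe_flags, truth = run_stage(
        "inputs", lambda: _load_inputs(config)
    )
    if stage == "hetsweep" and (snps is None or len(snps) == 0):
        raise ConfigError("stage hetsweep: SNP table required but missing or empty")
    pop_a, pop_b = mat_a.population, mat_b.population
    report["populations"] = [pop_a, pop_b]
    report["n_genes_input"] = mat_a.n_genes

    # --- preprocessing and eta -------------------------------------------
    def _variability():
        filtered = filter_low_expression([mat_a, mat_b], config.filter_fraction)
        normalized = median_normalize(filtered)
        profile = build_profile(normalized)
        corr = correlate_eta(profile, pop_a, pop_b)
        return normalized, profile, corr

    normalized, profile, corr = run_stage("variability", _variability)
    report["n_genes_retained"] = len(profile.gene_ids)
    report["eta_correlation_r"] = corr.r
    report["eta_correlation_p"] = corr.p_value
    report["genome_median_eta"] = {
        p: profile.genome_median(p) for p in (pop_a, pop_b)
    }
    tables["variability"] = (
        profile.etas.rename(columns=lambda p: f"eta_{p}")
        .rename_axis("gene_id")
        .reset_index()
    )

    # --- outlier detection ------------------------------------------------
    def _outliers():
        partition = reciprocal_outliers(
            profile, pop_a, pop_b,
            level=config.outlier_level, studentize=config.studentize,
        )
        if probe_flags is not None:
            cleaned, removal = remove_probe_snp_genes(
                partition, probe_flags, universe=profile.gene_ids
            )
        else:
            cleaned, removal = partition, {}
        return partition, cleaned, removal

    partition, cleaned, removal = run_stage("outliers", _outliers)
    report["outliers"] = {**partition.summary(), **removal}
    fit1, fit2 = partition.fits
    flagged = (
        probe_flags.is_flagged(profile.gene_ids)
        if probe_flags is not None
        else pd.Series(False, index=profile.gene_ids)
    )
    direction_label = pd.Series("", index=profile.gene_ids)
    direction_label[list(partition.high_a)] = f"high_{pop_a}"
    direction_label[list(partition.high_b)] = f"high_{pop_b}"
    tables["outliers"] = pd.DataFrame(
        {
            "gene_id": profile.gene_ids,
            f"eta_{pop_a}": profile.eta(pop_a).to_numpy(),
            f"eta_{pop_b}": profile.eta(pop_b).to_numpy(),
            "studentized_residual_dir1": fit1.studentized.to_numpy(),
            "studentized_residual_dir2": fit2.studentized.to_numpy(),
            "in_intersection": profile.gene_ids.isin(partition.intersection),
            "direction_label": direction_label.to_numpy(),
            "probe_flagged": flagged.to_numpy(),
        }
    )

    # --- heterozygosity sweep --------------------------------------------
    if "hetsweep" in wanted and snps is not None and len(snps):
        def _hetsweep():
            sweep_rows, summary_rows = [], []
            for region in SNP_REGIONS:
                if snps.for_region(region).empty:
                    continue
                results = run_hetsweep(
                    cleaned, snps, region,
                    step=config.sweep_step, test_cutoff=config.test_cutoff,
                )
                for res in results.values():
                    sweep_rows.append(res.to_frame())
                    summary_rows.append(
                        {
                            "region": region,
                            "group": res.group,
                            "n_focal": res.n_focal,
                            "n_background": res.n_background,
                            "test_cutoff": res.test_cutoff,
                            "chi2": res.chi2,
                            "p_value": res.p_value,
                        }
                    )
            return pd.concat(sweep_rows, ignore_index=True), pd.DataFrame(summary_rows)

        sweep_table, sweep_summary = run_stage("hetsweep", _hetsweep)
        tables["hetsweep"] = sweep_table
        tables["hetsweep_summary"] = sweep_summary
        report["hetsweep"] = sweep_summary.to_dict(orient="records")
        report["n_sweep_cutoffs"] = int(
            sweep_table.groupby(["region", "group"]).size().iloc[0]
        )
    else:
        logger.info("no SNP table (or empty one); heterozygosity sweep skipped")

    # --- differential expression -----------------------------------------
    if "diffexpr" in wanted:
        def _diffexpr():
            return de_analysis(
                normalized[0], normalized[1],
                n_perm=config.n_perm,
                seed=np.random.default_rng(de_ss),
                fdr_threshold=config.de_fdr,
            )

        de = run_stage("diffexpr", _diffexpr)
        de_genes = set(de.de_genes)
        de_outliers = sorted(de_genes & (cleaned.high_a | cleaned.high_b))
        non_outlier_de = de_genes - partition.union
        report["n_de_genes"] = len(de_genes)
        report["n_de_outliers"] = len(de_outliers)
        report["n_de_non_outliers"] = len(non_outlier_de)
        tables["diffexpr"] = de.table.rename_axis("gene_id").reset_index()

        def _directional():
            if not de_outliers:
                return None
            return directional_enrichment(
                de_outliers, cleaned, focal="b",
                n_draws=config.n_direction_draws,
                seed=np.random.default_rng(dir_ss),
            )

        enr = run_stage("directional_enrichment", _directional)
        if enr is not None:
            report["directional_enrichment"] = {
                "focal_label": enr.focal_label,
                "observed_fraction": enr.observed_fraction,
                "pool_fraction": enr.pool_fraction,
                "n_de": enr.n_de,
                "n_pool": enr.n_pool,
                "p_value": enr.p_value,
            }

        def _relation():
            non_outlier_profile = profile.subset(
                profile.gene_ids.difference(partition.union)
            )
            return tscore_variability_relation(
                de, non_outlier_profile, pop_a, eta_cap=config.eta_cap
            )

        relation = run_stage("tscore_eta_relation", _relation)
        report["tscore_eta_r"] = relation.r
        report["tscore_eta_p"] = relation.p_value
        report["tscore_eta_n"] = relation.n

    # --- tails and set analysis ------------------------------------------
    if "setanalysis" in wanted:
        def _tails():
            return select_tails(
                profile, pop_a,
                exclusion=partition.union, tail_fraction=config.tail_fraction,
            )

        tails = run_stage("tails", _tails)
        report["tails"] = {
            "universe_size": tails.universe_size,
            "tail_size": tails.tail_size,
        }
        tables["tails"] = pd.DataFrame(
            {
                "gene_id": tails.bottom + tails.top,
                "tail": ["bottom"] * tails.tail_size + ["top"] * tails.tail_size,
            }
        )

    if "setanalysis" in wanted and gene_sets is not None:
        def _enrichment():
            universe = profile.gene_ids.difference(partition.union)
            frames = []
            for label, study in (("top", tails.top), ("bottom", tails.bottom)):
                rows = overrepresentation(study, gene_sets, universe)
                rows.insert(0, "tail", label)
                frames.append(rows)
            return pd.concat(frames, ignore_index=True)

        tables["tail_enrichment"] = run_stage("tail_enrichment", _enrichment)

        def _groups():
            rows = []
            if config.group_set not in gene_sets.sets:
                raise ConfigError(
                    f"group set {config.group_set!r} not in the collection"
                )
            members = [
                g for g in gene_sets[config.group_set] if g in profile.gene_ids
            ]
            boot_rng = np.random.default_rng(boot_ss)
            null_rng = np.random.default_rng(null_ss)
            for pop in (pop_a, pop_b):
                comp = group_vs_genome(members, profile, pop, name=config.group_set)
                lo, hi = bootstrap_ci(
                    profile.eta(pop).loc[members].to_numpy(),
                    n_boot=config.n_boot, seed=boot_rng,
                )
                comp.ci_low, comp.ci_high = lo, hi
                rows.append(comp)
            trimmed = exclude_keyword_genes(
                members, gene_sets, keyword=config.immune_keyword
            )
            if len(trimmed) >= 2:
                for pop in (pop_a, pop_b):
                    comp = group_vs_genome(
                        trimmed, profile, pop,
                        name=f"{config.group_set}_no_{config.immune_keyword}",
                    )
                    lo, hi = bootstrap_ci(
                        profile.eta(pop).loc[trimmed].to_numpy(),
                        n_boot=config.n_boot, seed=boot_rng,
                    )
                    comp.ci_low, comp.ci_high = lo, hi
                    rows.append(comp)
            matched = None
            if gene_sets.codes is not None:
                matched = matched_null_comparison(
                    members, gene_sets, profile, pop_a,
                    n_sets=config.n_null_sets, seed=null_rng,
                    name=config.group_set,
                )
                rows.append(matched)
            return rows

        group_rows = run_stage("group_comparisons", _groups)
        tables["group_comparisons"] = pd.DataFrame(
            [
                {
                    "group": c.group,
                    "population": c.population,
                    "n_group": c.n_group,
                    "group_mean_eta": c.group_mean_eta,
                    "group_median_eta": c.group_median_eta,
                    "genome_median_eta": c.genome_median_eta,
                    "ranksum_p": c.ranksum_p,
                    "ci_low": c.ci_low,
                    "ci_high": c.ci_high,
                    "null_exceedance": c.null_exceedance,
                    "n_null_sets": c.n_null_sets,
                    "mean_relative_excess": c.mean_relative_excess,
                }
                for c in group_rows
            ]
        )
        report["group_comparisons"] = (
            tables["group_comparisons"]
            .astype(object)
            .where(tables["group_comparisons"].notna(), None)
            .to_dict(orient="records")
        )

    # --- truth-based evaluation (synthetic runs only) ---------------------
    if truth is not None:
        planted = set(truth.outlier_direction)
        called = cleaned.high_a | cleaned.high_b
        present = planted & set(profile.gene_ids)
        tp = len(called & present)
        report["planted_outlier_recovery"] = {
            "n_planted_retained": len(present),
            "n_called": len(called),
            "sensitivity": tp / len(present) if present else float("nan"),
            "specificity": 1
            - len(called - present) / max(len(profile.gene_ids) - len(present), 1),
        }

    # --- write outputs ----------------------------------------------------
    with _stage("write"):
        pio.write_results(tables, out_dir, **meta)
        manifest = {
            "config_hash": config.hash(),
            "seed": config.seed,
            "n_sweep_cutoffs": report.get("n_sweep_cutoffs", 0),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        }
        manifest_df = pd.DataFrame(
            sorted(manifest.items()), columns=["key", "value"]
        )
        pio.write_results({"manifest": manifest_df}, out_dir, **meta)
    return report
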