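"""End-to-end reproducible runs: config, stage orchestration, reporting.

A run is driven by a single :class:`RunConfig` (serialisable to/from JSON,
unknown keys rejected) and one seed.  Per-stage random streams are derived
from the seed by stable hashing of the stage name, so re-running one stage
never perturbs another's draws.  Every table written carries a header comment
with the seed and a hash of the configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import genotypes as gt
from . import mapping, phenotypes, power, varcomp
from .errors import AcylQTLError, InvalidConfigError
from .population import (
    CausalLocus,
    PhenotypeTable,
    PopulationConfig,
    build_marker_map,
    default_causal_loci,
    degrade_calls,
    simulate_f2,
    simulate_phenotypes,
    write_phenotype_tsv,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """All parameters of an end-to-end run."""

    seed: int = 1
    out_dir: str = "acylqtl_run"
    population: PopulationConfig = field(default_factory=PopulationConfig)
    alpha: float = 0.05
    relaxed_p: float | None = None
    maf_threshold: float = 0.05
    max_missing: float = 0.80
    max_qtl: int = 10
    power_sizes: tuple[int, ...] = (20, 40, 60, 80, 100)
    power_reps: int = 100
    power_window_mb: float = 10.0
    run_scans: bool = True
    run_varcomp: bool = True
    run_power: bool = True
    make_plots: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InvalidConfigError(f"unknown config keys: {sorted(unknown)}")
        if "population" in d and isinstance(d["population"], dict):
            pop = dict(d["population"])
            pop_known = {f.name for f in dataclasses.fields(PopulationConfig)}
            bad = set(pop) - pop_known
            if bad:
                raise InvalidConfigError(f"unknown population keys: {sorted(bad)}")
            if "chrom_lengths" in pop:
                pop["chrom_lengths"] = {int(k): int(v) for k, v in pop["chrom_lengths"].items()}
            d["population"] = PopulationConfig(**pop)
        if "power_sizes" in d:
            d["power_sizes"] = tuple(int(s) for s in d["power_sizes"])
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["power_sizes"] = list(self.power_sizes)
        return d

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir", None)  # the destination is not part of run identity
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def with_seed(self, seed: int) -> "RunConfig":
        pop = dataclasses.replace(self.population, seed=seed)
        return dataclasses.replace(self, seed=seed, population=pop)


def _write_tsv(df: pd.DataFrame, path: Path, seed: int, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# seed={seed} config_hash={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def simulate_stage(config: RunConfig):
    """Build the map, simulate genotypes and phenotypes, apply degradation."""
    pop = dataclasses.replace(config.population, seed=config.seed)
    marker_map = build_marker_map(pop)
    loci = default_causal_loci()
    g = simulate_f2(marker_map, loci, pop)
    if pop.missing_rate > 0 or pop.het_miscall_rate > 0:
        g = degrade_calls(g, pop)
    ph = simulate_phenotypes(g, loci, pop)
    return g, ph, loci, pop


def run_pipeline(config: RunConfig) -> dict:
    """Execute every enabled stage and write outputs under ``config.out_dir``.

    Returns a summary dict (selected QTL, intervals, table paths).  Any stage
    failure is re-raised as :class:`AcylQTLError` labelled with the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed, cfg_hash = config.seed, config.config_hash()
    summary: dict = {"seed": seed, "config_hash": cfg_hash, "out_dir": str(out)}

    echo = {"seed": seed, "config_hash": cfg_hash, "config": config.to_dict()}
    (out / "config.json").write_text(json.dumps(echo, indent=2, default=str))

    def stage(name):
        def deco(fn):
            try:
                log.info("stage %s: start", name)
                result = fn()
                log.info("stage %s: done", name)
                return result
            except AcylQTLError:
                raise
            except Exception as exc:  # pragma: no cover - defensive
                raise AcylQTLError(f"stage {name!r} failed: {exc}") from exc
        return deco

    @stage("simulate")
    def _sim():
        g, ph, loci, pop = simulate_stage(config)
        tag = f"seed={seed} config_hash={cfg_hash}"
        gt.write_genotype_tsv(g, out / "genotypes.tsv", header_comment=tag)
        write_phenotype_tsv(ph, out / "phenotypes.tsv", header_comment=tag)
        return g, ph, loci, pop

    g, ph, loci, pop = _sim

    @stage("phenotype")
    def _derive():
        traits = phenotypes.derive_traits(
            ph.peaks, standard_total_area=pop.standard_total_area,
            standard_ac=pop.standard_ac,
        )
        dup = ("ac_mg_kg", "acylation_pct", "is_reduced_acylation")
        merged = traits.merge(
            ph.table.drop(columns=[c for c in dup if c in ph.table]), on="sample"
        )
        _write_tsv(merged, out / "traits.tsv", seed, cfg_hash)
        return merged

    traits = _derive

    @stage("genotype_filter")
    def _filter():
        g2 = gt.filter_samples_by_missing(g, config.max_missing)
        g2 = gt.recompute_maf(g2)
        g2 = gt.filter_maf(g2, config.maf_threshold)
        log.info(
            "filters kept %d/%d samples, %d/%d markers",
            g2.n_samples, g.n_samples, g2.n_markers, g.n_markers,
        )
        return g2

    g2 = _filter
    trait_by_sample = traits.set_index("sample").loc[g2.samples]
    summary["n_samples"] = g2.n_samples
    summary["n_markers"] = g2.n_markers

    thr = mapping.bonferroni(config.alpha, g2.n_markers)
    summary["bonferroni_minus_log10"] = thr.minus_log10

    if config.run_scans:
        @stage("scan")
        def _scans():
            results = {}
            acyl_locus = next(l for l in loci if l.is_acylation_locus)

            y_ac = trait_by_sample["acylation_pct"].to_numpy()
            step_acyl = mapping.stepwise_scan(
                g2, y_ac, thr, config.max_qtl, trait="acylation_pct"
            )
            first = step_acyl.rounds[0]
            _write_tsv(first.table, out / "scan_acylation.tsv", seed, cfg_hash)
            man = mapping.manhattan_export(first, thr)
            _write_tsv(man, out / "manhattan_acylation.tsv", seed, cfg_hash)
            if config.make_plots:
                mapping.manhattan_plot(man, thr, out / "manhattan_acylation.png")
            interval = mapping.significant_interval(first, thr, acyl_locus.chromosome)
            sel = [
                (int(first.table.loc[i, "chrom"]), int(first.table.loc[i, "pos"]))
                for i in step_acyl.selected
            ]
            results["acylation_selected"] = sel
            results["acylation_interval"] = interval

            # control traits: log-AC (intensifier locus), colorless score
            y_logac = np.log(np.maximum(trait_by_sample["ac_mg_kg"].to_numpy(), 1e-9))
            res_logac = mapping.scan_single_marker(g2, y_logac, trait="log_ac")
            _write_tsv(res_logac.table, out / "scan_log_ac.tsv", seed, cfg_hash)
            if "c1_score" in trait_by_sample:
                res_c1 = mapping.scan_single_marker(
                    g2, trait_by_sample["c1_score"].to_numpy(dtype=float), trait="c1_score"
                )
                _write_tsv(res_c1.table, out / "scan_c1.tsv", seed, cfg_hash)

            # stepwise on raw AC at the relaxed threshold when configured
            thr_ac = (
                mapping.Threshold.from_per_test_p(config.relaxed_p)
                if config.relaxed_p
                else thr
            )
            step_ac = mapping.stepwise_scan(
                g2, trait_by_sample["ac_mg_kg"].to_numpy(), thr_ac,
                config.max_qtl, trait="ac_mg_kg",
            )
            _write_tsv(
                step_ac.rounds[-1].table, out / "stepwise_ac_last_round.tsv", seed, cfg_hash
            )
            results["ac_selected"] = [
                (int(step_ac.rounds[0].table.loc[i, "chrom"]),
                 int(step_ac.rounds[0].table.loc[i, "pos"]))
                for i in step_ac.selected
            ]
            return results

        summary.update(_scans)

    if config.run_varcomp:
        @stage("varcomp")
        def _vc():
            factors = pd.DataFrame(
                {
                    "in1": trait_by_sample["in1_recessive"],
                    "c1": trait_by_sample["c1_recessive"],
                    "r1": trait_by_sample["r1_recessive"],
                    "reduced_acylation": trait_by_sample["aat1_recessive"],
                }
            ).reset_index(drop=True)
            y = trait_by_sample["ac_mg_kg"].to_numpy()
            vd = varcomp.decompose_variance(y, factors, trait="ac_mg_kg")
            _write_tsv(vd.components, out / "varcomp_ac.tsv", seed, cfg_hash)
            fe = varcomp.fixed_effects_summary(y, factors, trait="ac_mg_kg")
            _write_tsv(fe.table, out / "fixed_effects_ac.tsv", seed, cfg_hash)
            return {"varcomp_method": vd.method}

        summary.update(_vc)

    if config.run_power:
        @stage("power")
        def _pw():
            acyl_locus = next(l for l in loci if l.is_acylation_locus)
            flags = trait_by_sample["aat1_recessive"].to_numpy(dtype=float)
            rep = power.run_power_simulation(
                g2,
                trait_by_sample["acylation_pct"].to_numpy(),
                (acyl_locus.chromosome, acyl_locus.position),
                sizes=config.power_sizes,
                reps=config.power_reps,
                window_bp=int(config.power_window_mb * 1e6),
                alpha=config.alpha,
                seed=seed,
                mutant_flags=flags,
                phenotype_class_label="reduced_acylation",
            )
            _write_tsv(rep.table, out / "power_acylation.tsv", seed, cfg_hash)
            return {"power_table": str(out / "power_acylation.tsv")}

        summary.update(_pw)

    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    _write_summary_md(out, summary)
    return summary


def _write_summary_md(out: Path, summary: dict) -> None:
    lines = [
        "# Run summary",
        "",
        f"- seed: {summary['seed']}",
        f"- config hash: {summary['config_hash']}",
        f"- samples x markers after filters: "
        f"{summary.get('n_samples')} x {summary.get('n_markers')}",
        f"- Bonferroni -log10(p) threshold: "
        f"{summary.get('bonferroni_minus_log10', float('nan')):.4f}",
    ]
    if "acylation_selected" in summary:
        lines.append(f"- acylation QTL selected (chrom, pos): {summary['acylation_selected']}")
        lines.append(f"- acylation significant interval: {summary['acylation_interval']}")
    if "ac_selected" in summary:
        lines.append(f"- AC QTL selected (chrom, pos): {summary['ac_selected']}")
    (out / "summary.md").write_text("\n".join(lines) + "\n")
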