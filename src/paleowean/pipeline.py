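"""Configuration-driven end-to-end runner.

Executes the full reconstruction in order — quality screening, age grouping,
descriptive summaries, breast-milk source construction, per-group mixing
fits, the ABC weaning fit, and the comparative statistics — and writes a
report bundle: delimiter-separated summary tables, machine-readable posterior
archives, and a manifest with seeds, configuration hash and per-artifact
checksums, so a rerun with the same seeds is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import isotope_data as idata
from .group_stats import AnovaResult, format_p, oneway_anova, shapiro_test, tukey_kramer
from .isotope_data import GROUP_LABELS, CollagenSample, group_juveniles, load_samples, qc_pass, summarize_group
from .mixing_model import MixingConfig, MixingPosterior, fit_mixing
from .source_model import SourceSpec, load_source_table, milk_source_from_females
from .warn_model import ABCConfig, TurnoverModel, WeaningPosterior, fit_warn_abc

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "write_report"]

log = logging.getLogger("paleowean")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Everything a full run needs; defaults reproduce the bundled analysis."""

    samples_path: str | None = None  # None -> bundled collagen table
    sources_path: str | None = None  # None -> bundled source table
    qc_override: list[str] = field(default_factory=list)  # sample ids kept despite QC failure
    drop_qc_failures: bool = False
    mixing: MixingConfig = field(default_factory=MixingConfig)
    abc: ABCConfig = field(default_factory=ABCConfig)
    turnover: TurnoverModel = field(default_factory=TurnoverModel)
    output_dir: str = "paleowean_output"
    make_figures: bool = False
    verbosity: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        for key, sub in (("mixing", MixingConfig), ("abc", ABCConfig), ("turnover", TurnoverModel)):
            if key in kwargs and isinstance(kwargs[key], dict):
                fixed = {
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in kwargs[key].items()
                }
                kwargs[key] = sub(**fixed)
        return cls(**kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineResults:
    config: PipelineConfig
    samples: list[CollagenSample]
    qc_report: list[dict]
    groups: dict[str, list[CollagenSample]]
    summaries: dict[str, idata.GroupSummary]
    sources: list[SourceSpec]
    mixing: dict[str, MixingPosterior]
    weaning: WeaningPosterior
    anova: dict[str, AnovaResult]
    tukey: dict[str, list]
    shapiro: dict[str, tuple[float, float]]


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - named-stage abort is the contract
                raise PipelineError(name, str(exc)) from exc
            log.info("stage %s: done in %.2f s", name, time.perf_counter() - t0)
            return out

        return wrapper

    return deco


@_stage("isotope_data")
def _load_and_screen(config: PipelineConfig):
    path = config.samples_path or idata.bundled_samples_path()
    samples = load_samples(path)
    if not samples:
        raise ValueError(f"no samples loaded from {path}")
    qc_report = []
    kept = []
    for s in samples:
        ok, violations = qc_pass(s)
        overridden = (not ok) and (s.sample_id in config.qc_override or not config.drop_qc_failures)
        qc_report.append(
            {"sample_id": s.sample_id, "qc_pass": bool(ok), "violations": violations,
             "kept": bool(ok or overridden)}
        )
        if ok or overridden:
            kept.append(s)
    return kept, qc_report


@_stage("source_model")
def _build_sources(config: PipelineConfig, female_summary: idata.GroupSummary):
    path = config.sources_path
    if path is not None and not Path(path).exists():
        raise FileNotFoundError(f"source table not found: {path}")
    from .source_model import bundled_source_path

    table = load_source_table(path or bundled_source_path())
    milk = milk_source_from_females(female_summary)
    # derived milk source replaces any bundled milk row
    plants = [s for s in table if s.name.lower() != milk.name.lower()]
    return [milk] + plants


@_stage("mixing_model")
def _fit_groups(config: PipelineConfig, groups, sources):
    out = {}
    for g in GROUP_LABELS:
        if groups[g]:
            out[g] = fit_mixing(groups[g], sources, config.mixing, group_label=g)
    return out


@_stage("warn_model")
def _fit_weaning(config: PipelineConfig, groups, female_mean: float):
    juv = [
        (s.age.midpoint, s.d15N)
        for g in GROUP_LABELS
        for s in groups[g]
    ]
    return fit_warn_abc(juv, female_mean, config.turnover, config.abc)


@_stage("group_stats")
def _comparative_stats(groups):
    vals15 = {g: [s.d15N for s in m] for g, m in groups.items() if m}
    vals13 = {g: [s.d13C for s in m] for g, m in groups.items() if m}
    anova = {
        "N": oneway_anova(vals15, isotope="N"),
        "C": oneway_anova(vals13, isotope="C"),
    }
    tukey = {"N": tukey_kramer(vals15), "C": tukey_kramer(vals13)}
    pooled15 = [v for vs in vals15.values() for v in vs]
    pooled13 = [v for vs in vals13.values() for v in vs]
    juv15 = [v for g, vs in vals15.items() for v in vs if g != "females"]
    juv13 = [v for g, vs in vals13.items() for v in vs if g != "females"]
    shapiro = {
        "C_all": shapiro_test(pooled13),
        "N_all": shapiro_test(pooled15),
        "C_juveniles": shapiro_test(juv13),
        "N_juveniles": shapiro_test(juv15),
    }
    return anova, tukey, shapiro


def run_pipeline(config: PipelineConfig | None = None) -> PipelineResults:
    """Run every stage on the configured inputs and return in-memory results."""
    config = config or PipelineConfig()
    logging.basicConfig(level=logging.INFO if config.verbosity else logging.WARNING)

    samples, qc_report = _load_and_screen(config)
    groups = group_juveniles(samples)
    summaries = {
        g: summarize_group(m, g) for g, m in groups.items() if m
    }
    if "females" not in summaries:
        raise PipelineError("isotope_data", "no adult females in the sample")
    sources = _build_sources(config, summaries["females"])
    mixing = _fit_groups(config, groups, sources)
    weaning = _fit_weaning(config, groups, summaries["females"].mean_d15N)
    anova, tukey, shapiro = _comparative_stats(groups)
    return PipelineResults(
        config=config,
        samples=samples,
        qc_report=qc_report,
        groups=groups,
        summaries=summaries,
        sources=sources,
        mixing=mixing,
        weaning=weaning,
        anova=anova,
        tukey=tukey,
        shapiro=shapiro,
    )


def _write_text(path: Path, text: str) -> None:
    path.write_text(text)


def write_report(results: PipelineResults, directory: str | Path) -> dict[str, str]:
    """Write the report bundle; returns {relative path: sha256} (the manifest)."""
    outdir = Path(directory)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = results.config
    header = (
        f"# paleowean v0.1.0  config_hash={cfg.config_hash()}  "
        f"mixing_seed={cfg.mixing.rng_seed}  abc_seed={cfg.abc.rng_seed}  "
        f"turnover=r0:{cfg.turnover.r0},r_inf:{cfg.turnover.r_inf},tau:{cfg.turnover.tau}\n"
    )

    # group summaries
    lines = [header, "group\tn\tmean_d13C\tsd_d13C\tmin_d13C\tmax_d13C\tmean_d15N\tsd_d15N\tmin_d15N\tmax_d15N\n"]
    for g, s in results.summaries.items():
        r = s.rounded()
        lines.append(
            f"{g}\t{r.n}\t{r.mean_d13C}\t{r.sd_d13C}\t{r.min_d13C}\t{r.max_d13C}"
            f"\t{r.mean_d15N}\t{r.sd_d15N}\t{r.min_d15N}\t{r.max_d15N}\n"
        )
    _write_text(outdir / "group_summaries.tsv", "".join(lines))

    # qc
    lines = [header, "sample_id\tqc_pass\tkept\tviolations\n"]
    for row in results.qc_report:
        lines.append(
            f"{row['sample_id']}\t{row['qc_pass']}\t{row['kept']}\t{';'.join(row['violations'])}\n"
        )
    _write_text(outdir / "qc_report.tsv", "".join(lines))

    # source table
    from .source_model import save_source_table

    save_source_table(results.sources, outdir / "sources_used.tsv")

    # mixing posterior summaries + archives
    lines = [header, "group\tsource\tmode_pct\tlci_pct\thci_pct\n"]
    for g, post in results.mixing.items():
        for k, name in enumerate(post.source_names):
            lines.append(
                f"{g}\t{name}\t{post.mode_pct[k]:.0f}\t{post.lci_pct[k]:.0f}\t{post.hci_pct[k]:.0f}\n"
            )
    _write_text(outdir / "mixing_summary.tsv", "".join(lines))
    for g, post in results.mixing.items():
        arr = np.column_stack([post.draws, post.residual_sd_draws])
        cols = [*post.source_names, "sigma_N", "sigma_C"]
        np.savetxt(
            outdir / f"mixing_draws_{g}.tsv",
            arr,
            delimiter="\t",
            header=header.strip("#\n ") + "\n" + "\t".join(cols),
            fmt="%.6f",
        )

    # weaning posterior
    w = results.weaning
    summary = {
        "mde": {"t1": w.mde.t1, "t2": w.mde.t2, "enrich": w.mde.enrich,
                "d15N_wnfood": w.mde.d15N_wnfood, "d15N_female": w.mde.d15N_female},
        "ci95": {k: list(v) for k, v in w.ci95.items()},
        "distance_threshold": w.distance_threshold,
        "n_accepted": int(w.accepted.shape[0]),
        "config_hash": cfg.config_hash(),
        "abc_seed": cfg.abc.rng_seed,
    }
    _write_text(outdir / "weaning_summary.json", json.dumps(summary, indent=2))
    np.savetxt(
        outdir / "weaning_accepted_draws.tsv",
        w.accepted,
        delimiter="\t",
        header=header.strip("#\n ") + "\nt1\tt2\tenrich\td15N_wnfood",
        fmt="%.6f",
    )

    # comparative statistics
    lines = [header]
    for iso in ("N", "C"):
        a = results.anova[iso]
        lines.append(
            f"# ANOVA {iso}: F={a.F:.3f} df=({a.df_between},{a.df_within}) p={a.p:.4f}\n"
        )
        lines.append("pair\tdiff\tlower\tupper\tp_adj\n")
        for c in results.tukey[iso]:
            lines.append(
                f"{c.pair[0]}—{c.pair[1]}\t{c.diff:.3f}\t{c.lower:.3f}\t{c.upper:.3f}\t{format_p(c.p_adj)}\n"
            )
    for k, (wstat, p) in results.shapiro.items():
        lines.append(f"# Shapiro {k}: W={wstat:.3f} p={p:.3f}\n")
    _write_text(outdir / "group_statistics.tsv", "".join(lines))

    if results.config.make_figures:
        _write_figures(results, outdir)

    manifest = {}
    for p in sorted(outdir.iterdir()):
        if p.name == "manifest.json" or p.is_dir():
            continue
        manifest[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    _write_text(
        outdir / "manifest.json",
        json.dumps({"config_hash": cfg.config_hash(), "artifacts": manifest}, indent=2),
    )
    return manifest


def _write_figures(results: PipelineResults, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    figdir = outdir / "figures"
    figdir.mkdir(exist_ok=True)

    # biplot per group: consumers vs fractionation-corrected sources
    for g, post in results.mixing.items():
        fig, ax = plt.subplots(figsize=(5, 4))
        xs = [s.d13C for s in results.groups[g]]
        ys = [s.d15N for s in results.groups[g]]
        ax.scatter(xs, ys, c="k", marker="x", label="consumers")
        for s in results.sources:
            ax.errorbar(
                s.mu_C + s.frac_C, s.mu_N + s.frac_N,
                xerr=(s.sd_C**2 + s.sd_frac_C**2) ** 0.5,
                yerr=(s.sd_N**2 + s.sd_frac_N**2) ** 0.5,
                fmt="o", capsize=3, label=s.name,
            )
        ax.set_xlabel("δ13C (‰ VPDB)")
        ax.set_ylabel("δ15N (‰ AIR)")
        ax.legend(fontsize=7)
        ax.set_title(f"{g}: consumers and corrected sources")
        fig.tight_layout()
        fig.savefig(figdir / f"biplot_{g}.png", dpi=100)
        plt.close(fig)

    # joint (t1, t2) weaning density
    w = results.weaning
    grid = w.density_grid
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.contourf(grid["t1_axis"], grid["t2_axis"], grid["joint_density"].T, levels=20)
    ax.plot(w.mde.t1, w.mde.t2, "r+", markersize=12)
    ax.set_xlabel("start of weaning t1 (y)")
    ax.set_ylabel("end of weaning t2 (y)")
    fig.tight_layout()
    fig.savefig(figdir / "weaning_joint_density.png", dpi=100)
    plt.close(fig)

    # trajectory at the MDE over the observed age span
    from .warn_model import collagen_trajectory

    ages = np.linspace(0, 5.5, 200)
    traj = collagen_trajectory(w.mde, results.config.turnover, ages)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(ages, traj, label="MDE trajectory")
    pts = [(s.age.midpoint, s.d15N) for g in GROUP_LABELS for s in results.groups[g]]
    ax.scatter(*zip(*pts), c="k", marker="x", label="juveniles")
    ax.axhline(w.mde.d15N_female, ls=":", c="gray", label="female mean")
    ax.set_xlabel("age (y)")
    ax.set_ylabel("δ15N (‰ AIR)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(figdir / "weaning_trajectory.png", dpi=100)
    plt.close(fig)
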