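"""Orchestrate the full threshold-sweep experiment.

Simulate (or load) a RAD-Seq dataset, assemble it at every similarity
threshold in the sweep (93-99% by default), remove paralog-flagged loci,
run the split diagnostics and population-genetic summaries, and collect
one row per threshold into a machine-readable report table.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import popstats, splitdiag, treedepth
from .simgen import (SimParams, SimulatedDataset, load_popmap, load_reads,
                     load_truth, simulate_dataset)
from .stackasm import Assembly, AssemblyParams, assemble

__all__ = ["SweepConfig", "SweepReport", "run_sweep", "compare_lineages",
           "write_assembly"]

REPORT_COLUMNS = [
    "threshold", "n_loci_total", "n_loci", "mean_individuals_per_locus",
    "mean_segregating_sites", "mean_alleles_per_locus",
    "undersplit_n", "undersplit_prop",
    "oversplit_n", "oversplit_prop", "oversplit_baseline",
    "true_oversplit_rate", "true_undersplit_rate",
    "mean_p_distance", "mean_jc_distance", "mean_fst", "mean_tree_depth",
    "theta_a", "tau", "theta_pop1", "theta_pop2",
]


@dataclass
class SweepConfig:
    """Everything one sweep needs; either ``sim`` or ``reads_dir``+``popmap_path``."""

    thresholds: list[int] = field(default_factory=lambda: list(range(93, 100)))
    sim: SimParams | None = None
    reads_dir: str | None = None
    popmap_path: str | None = None
    truth_path: str | None = None
    min_depth_m: int = 10
    max_alleles: int = 3
    out_dir: str | None = None
    seed: int = 0
    tree_sample: int = 1000
    oversplit_proxy: bool = True
    oversplit_reference: int = 93
    truth_diagnostics: bool = True
    plots: bool = False

    def __post_init__(self) -> None:
        if not self.thresholds:
            raise ValueError("thresholds must be non-empty")
        if any(not 0 < t <= 100 for t in self.thresholds):
            raise ValueError("thresholds must lie in (0, 100]")
        self.thresholds = sorted(set(self.thresholds))
        if self.sim is None and (self.reads_dir is None
                                 or self.popmap_path is None):
            raise ValueError("provide sim params or reads_dir + popmap_path")
        if (self.oversplit_proxy and len(self.thresholds) > 1
                and self.oversplit_reference not in self.thresholds):
            raise ValueError(
                f"over-split proxy needs the {self.oversplit_reference}% "
                "reference threshold in the sweep")


@dataclass
class SweepReport:
    """Per-threshold summary table plus the cached assemblies."""

    table: pd.DataFrame
    assemblies: dict[int, Assembly]
    filtered: dict[int, Assembly]
    dataset: SimulatedDataset | None = None

    def write(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _obtain_dataset(config: SweepConfig) -> tuple[dict, dict, dict | None,
                                                  SimulatedDataset | None,
                                                  int]:
    if config.sim is not None:
        ds = simulate_dataset(config.sim)
        return (ds.reads_by_individual, ds.populations, ds.truth, ds,
                ds.params.locus_length)
    populations = load_popmap(config.popmap_path)
    truth = load_truth(config.truth_path) if config.truth_path else None
    reads = load_reads(config.reads_dir, populations, truth)
    some = next(r for recs in reads.values() for r in recs)
    return reads, populations, truth, None, len(some.sequence)


def run_sweep(config: SweepConfig) -> SweepReport:
    """Run the whole experiment and return the per-threshold report.

    Paralog-flagged (under-split) loci are removed before every downstream
    statistic; the over-split proxy maps each stringent assembly onto the
    most liberal one, subtracting the liberal self-map baseline. The run is
    deterministic given the config and seed.
    """
    reads, populations, truth, dataset, L = _obtain_dataset(config)
    assemblies: dict[int, Assembly] = {}
    filtered: dict[int, Assembly] = {}
    for s in config.thresholds:
        params = AssemblyParams(similarity_s=s, locus_length=L,
                                min_depth_m=config.min_depth_m,
                                max_alleles=config.max_alleles)
        assemblies[s] = assemble(reads, params)
        flagged, _ = splitdiag.flag_undersplit(assemblies[s])
        filtered[s] = assemblies[s].drop(set(flagged))

    ref_s = config.oversplit_reference
    use_proxy = config.oversplit_proxy and ref_s in filtered
    baseline = (splitdiag.selfmap_baseline(filtered[ref_s], ref_s)
                if use_proxy else None)
    true_keys = dataset.true_locus_keys if dataset is not None else None

    rows = []
    for s in config.thresholds:
        asm, filt = assemblies[s], filtered[s]
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(s,)))
        _, under_prop = splitdiag.flag_undersplit(asm)
        under_n = asm.n_loci - filt.n_loci
        row: dict = {
            "threshold": s,
            "n_loci_total": asm.n_loci,
            "n_loci": filt.n_loci,
            "undersplit_n": under_n,
            "undersplit_prop": under_prop,
            "oversplit_n": np.nan, "oversplit_prop": np.nan,
            "oversplit_baseline": np.nan,
            "true_oversplit_rate": np.nan, "true_undersplit_rate": np.nan,
        }
        if filt.n_loci:
            row["mean_individuals_per_locus"] = float(np.mean(
                [len(loc.genotypes) for loc in filt.loci]))
            row["mean_alleles_per_locus"] = float(np.mean(
                [len(loc.distinct_alleles) for loc in filt.loci]))
            seg = [popstats.segregating_sites(
                [c for ind in loc.genotypes
                 for c in (loc.allele_copies(ind) or [])])
                for loc in filt.loci]
            row["mean_segregating_sites"] = float(np.mean(seg))
        else:
            row["mean_individuals_per_locus"] = np.nan
            row["mean_alleles_per_locus"] = np.nan
            row["mean_segregating_sites"] = np.nan
        if use_proxy and s > ref_s:
            rep = splitdiag.oversplit_index(filt, filtered[ref_s],
                                            min_identity=ref_s,
                                            baseline=baseline)
            row["oversplit_n"] = rep.oversplit_count
            row["oversplit_prop"] = rep.oversplit_proportion
            row["oversplit_baseline"] = rep.baseline_selfmap_count
        if config.truth_diagnostics and truth is not None:
            over, under = splitdiag.true_split_rates(filt, truth, true_keys)
            row["true_oversplit_rate"] = over
            row["true_undersplit_rate"] = under
        row["mean_p_distance"] = popstats.mean_distance(filt, "p")
        row["mean_jc_distance"] = popstats.mean_distance(filt, "jc")
        row["mean_fst"] = popstats.mean_fst(filt, populations)
        row["mean_tree_depth"] = treedepth.mean_depth(
            filt, n_sample=config.tree_sample, seed=rng)
        try:
            est = popstats.isolation_moments(filt, populations, rng)
            row.update(theta_a=est.theta_a, tau=est.tau,
                       theta_pop1=est.theta1, theta_pop2=est.theta2)
        except ValueError:
            row.update(theta_a=np.nan, tau=np.nan,
                       theta_pop1=np.nan, theta_pop2=np.nan)
        rows.append(row)

    table = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    report = SweepReport(table=table, assemblies=assemblies,
                         filtered=filtered, dataset=dataset)
    if config.out_dir:
        os.makedirs(config.out_dir, exist_ok=True)
        for s in config.thresholds:
            write_assembly(assemblies[s],
                           os.path.join(config.out_dir, f"threshold_{s}"))
        report.write(os.path.join(config.out_dir, "sweep_report.tsv"))
        if config.plots:
            _plot_report(table, os.path.join(config.out_dir, "sweep.png"))
    return report


def write_assembly(assembly: Assembly, out_dir: str) -> None:
    """Catalog FASTA + genotype TSV + flat key-value metadata sidecar."""
    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "catalog.fasta"), "w") as fh:
        for loc in assembly.loci:
            fh.write(f">locus_{loc.catalog_id}\n{loc.consensus}\n")
    with open(os.path.join(out_dir, "genotypes.tsv"), "w") as fh:
        fh.write("locus\tindividual\tallele_index\tsequence\tdepth\n")
        for loc in assembly.loci:
            for ind in sorted(loc.genotypes):
                for k, st in enumerate(loc.genotypes[ind].alleles):
                    fh.write(f"{loc.catalog_id}\t{ind}\t{k}\t"
                             f"{st.consensus}\t{st.depth}\n")
    with open(os.path.join(out_dir, "params.txt"), "w") as fh:
        p = assembly.params
        fh.write(f"similarity_s={p.similarity_s}\n"
                 f"locus_length={p.locus_length}\n"
                 f"min_depth_m={p.min_depth_m}\n"
                 f"max_alleles={p.max_alleles}\n")
        for key, val in sorted(assembly.provenance.items()):
            fh.write(f"{key}={val}\n")


def compare_lineages(reports: dict[str, pd.DataFrame],
                     baseline: str | None = None) -> pd.DataFrame:
    """Cross-lineage comparison over shared thresholds.

    For each statistic and threshold: each lineage's ratio to the baseline
    lineage and the variance of lineage means. Reports with mismatched
    threshold sets are restricted to the intersection (with a warning).
    """
    if len(reports) < 2:
        raise ValueError("need at least two reports")
    names = sorted(reports)
    if baseline is None:
        baseline = names[0]
    shared = set(reports[names[0]]["threshold"])
    for name in names[1:]:
        shared &= set(reports[name]["threshold"])
    if not shared:
        raise ValueError("no shared thresholds")
    if any(set(reports[n]["threshold"]) != shared for n in names):
        warnings.warn("threshold sets differ; restricting to intersection")
    stats = [c for c in REPORT_COLUMNS
             if c != "threshold" and all(
                 pd.api.types.is_numeric_dtype(reports[n][c]) for n in names)]
    rows = []
    for t in sorted(shared):
        for stat in stats:
            vals = {n: float(reports[n].loc[reports[n]["threshold"] == t,
                                            stat].iloc[0]) for n in names}
            base = vals[baseline]
            for n in names:
                rows.append({
                    "threshold": t, "statistic": stat, "lineage": n,
                    "value": vals[n],
                    "ratio_to_baseline": (vals[n] / base if base else np.nan),
                })
            rows.append({
                "threshold": t, "statistic": stat, "lineage": "__variance__",
                "value": float(np.var(list(vals.values()))),
                "ratio_to_baseline": np.nan,
            })
    return pd.DataFrame(rows)


def _plot_report(table: pd.DataFrame, path: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    panels = [("mean_alleles_per_locus", "alleles / locus"),
              ("oversplit_prop", "over-split proportion"),
              ("mean_jc_distance", "mean JC distance"),
              ("mean_fst", "mean Fst"),
              ("mean_tree_depth", "mean tree depth"),
              ("theta_a", "ancestral theta")]
    fig, axes = plt.subplots(2, 3, figsize=(12, 6), sharex=True)
    for ax, (col, label) in zip(axes.ravel(), panels):
        ax.plot(table["threshold"], table[col], "o-")
        ax.set_ylabel(label)
        ax.set_xlabel("similarity threshold (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
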