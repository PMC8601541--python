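"""Simulation-study orchestration and cross-method evaluation.

For each scenario and simulated dataset the harness preprocesses the
counts exactly like experimental data (closure → filter → zero
replacement → clr → centering/autoscaling per method), runs the requested
community- and OTU-level methods, and collects:

* community detection — fraction of datasets where the diet term's
  p-value is below alpha, plus the explained variance;
* TPR/TNR of each OTU method's significance calls against the simulation
  ground truth;
* pairwise Spearman agreement between evidence-ranked OTU statistics;
* the abundance-dependence diagnostic (Spearman correlation of evidence
  rank with log mean relative abundance).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from . import community as comm
from . import otu as otumod
from . import preprocess as prep
from .design import DesignMatrices, build_design
from .simulate import SimulationParams, SimulatedDataset, generate_scenario_batch

logger = logging.getLogger("microbench")

__all__ = [
    "BenchmarkResult",
    "tpr_tnr",
    "spearman_agreement",
    "abundance_dependence",
    "analyze_dataset",
    "run_benchmark",
    "summarize",
]

COMMUNITY_METHODS = ("asca", "ffmanova", "permanova", "anosim")
OTU_METHODS = ("rotation", "simper", "asca-uve", "ancom", "dirichlet-clr", "nbglm")


# ---------------------------------------------------------------------------
# elementary metrics

def tpr_tnr(calls: pd.Series, truth: pd.Series) -> tuple[float, float]:
    """True positive rate TP/P and true negative rate TN/N.

    TPR is NaN (undefined) when the truth has no positives.
    """
    if set(calls.index) != set(truth.index):
        raise ValueError("calls and truth must cover the same OTUs")
    calls = calls.reindex(truth.index).astype(bool)
    truth = truth.astype(bool)
    P = int(truth.sum())
    N = int((~truth).sum())
    tp = int((calls & truth).sum())
    tn = int((~calls & ~truth).sum())
    tpr = tp / P if P else float("nan")
    tnr = tn / N if N else float("nan")
    return tpr, tnr


def spearman_agreement(tables: dict[str, otumod.RankingTable]) -> pd.DataFrame:
    """Pairwise Spearman correlation of evidence ranks across methods.

    Polarity is harmonized by the evidence rank itself (1 = strongest),
    so p-ascending and W-descending statistics are directly comparable.
    """
    names = list(tables)
    if len(names) < 2:
        raise ValueError("need at least two ranking tables")
    base = set(tables[names[0]].table.index)
    for n in names[1:]:
        if set(tables[n].table.index) != base:
            raise ValueError(f"OTU sets differ between {names[0]} and {n}")
    idx = tables[names[0]].table.index
    ranks = pd.DataFrame({n: tables[n].evidence_rank.reindex(idx) for n in names})
    out = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            rho = spearmanr(ranks[a], ranks[b]).statistic
            out.loc[a, b] = out.loc[b, a] = rho
    return out


def abundance_dependence(
    table: otumod.RankingTable, rel: pd.DataFrame
) -> tuple[float, pd.DataFrame]:
    """Spearman correlation between evidence rank and log mean abundance.

    Returns the correlation and a per-OTU diagnostic table suitable for
    the abundance-versus-statistic scatter plot.
    """
    mean_ab = rel.mean(axis=0).reindex(table.table.index)
    log_ab = np.log10(np.clip(mean_ab, 1e-300, None))
    rho = spearmanr(table.evidence_rank, log_ab).statistic
    diag = pd.DataFrame(
        {
            "log10_mean_abundance": log_ab,
            "statistic": table.table["statistic"],
            "rank": table.evidence_rank,
        }
    )
    return float(rho), diag


# ---------------------------------------------------------------------------
# per-dataset analysis

@dataclass
class DatasetAnalysis:
    community: dict[str, tuple[float, float]]        # method -> (p, explained %)
    rankings: dict[str, otumod.RankingTable]
    truth: pd.Series
    rel_filtered: pd.DataFrame
    failures: dict[str, str] = field(default_factory=dict)


def _contrast_pair(sim: SimulatedDataset, factor: str) -> tuple[str, str]:
    """Affected diet level (carrying the simulated effect) vs the next one."""
    levels = sorted(map(str, pd.unique(sim.dataset.metadata[factor])))
    return levels[0], levels[1]


def analyze_dataset(
    sim: SimulatedDataset,
    community_methods=("asca", "ffmanova", "permanova"),
    otu_methods=("rotation", "simper", "asca-uve", "ancom", "dirichlet-clr", "nbglm"),
    n_perm=999,
    seed: int = 0,
    min_rel: float = 5e-5,
    prevalence: float = 0.5,
    uve_reps: int = 100,
    n_mc: int = 128,
    factor: str | None = None,
) -> DatasetAnalysis:
    """Run the full preprocessing + method battery on one dataset."""
    ds = sim.dataset
    meta = ds.metadata
    factor = factor or meta.columns[0]
    other = [c for c in meta.columns if c != factor]
    design = ds.design
    formula_terms = design.terms if design is not None else ((factor,),)
    groups = meta.astype(str).agg(".".join, axis=1)

    rel = prep.to_relative(ds.counts)
    rel_f = prep.filter_otus(rel, groups, min_rel=min_rel, prevalence=prevalence)
    lib = ds.counts.library_sizes
    rel_z = prep.replace_zeros_czm(
        prep.to_relative(rel_f), library_sizes=lib.to_numpy() if lib is not None else None
    )
    X = prep.clr(rel_z)
    Xc = prep.scale_columns(X, "center")
    Xs = prep.scale_columns(X, "autoscale")
    D = build_design(meta, formula_terms)
    pair = _contrast_pair(sim, factor)

    ss = np.random.SeedSequence(entropy=seed, spawn_key=(7,))
    seeds = [int(s) & 0x7FFFFFFF for s in ss.generate_state(16)]

    out = DatasetAnalysis(
        community={}, rankings={}, truth=sim.truth, rel_filtered=rel_f
    )

    asca_result = None
    for i, meth in enumerate(community_methods):
        try:
            if meth == "asca":
                asca_result = comm.asca(Xc, D, n_perm=n_perm, seed=seeds[0])
                row = asca_result.decomposition.table.loc[f"{factor}"]
            elif meth == "ffmanova":
                dec = comm.ffmanova_community(Xs, D, n_perm=n_perm, seed=seeds[1])
                row = dec.table.loc[f"{factor}"]
            elif meth == "permanova":
                dec = comm.permanova(comm.distance(X, "euclidean"), D,
                                     n_perm=n_perm, seed=seeds[2])
                row = dec.table.loc[f"{factor}"]
            elif meth == "anosim":
                res = comm.anosim(comm.distance(X, "euclidean"), groups,
                                  n_perm=n_perm, seed=seeds[3])
                out.community[meth] = (res.p_value, 100.0 * res.r)
                continue
            else:
                raise ValueError(f"unknown community method {meth!r}")
            out.community[meth] = (
                float(row["p_value"]), float(row["explained_variance_pct"])
            )
        except Exception as exc:  # noqa: BLE001 - record and continue
            logger.warning("community method %s failed: %s", meth, exc)
            out.failures[meth] = str(exc)

    for meth in otu_methods:
        try:
            if meth == "rotation":
                rt = otumod.rotation_pvalues(Xs, D, term=factor,
                                             n_rot=n_perm, seed=seeds[4])
            elif meth == "simper":
                rt = otumod.simper(rel_f, meta[factor], pair,
                                   n_perm=n_perm, seed=seeds[5])
            elif meth == "asca-uve":
                if asca_result is None:
                    asca_result = comm.asca(Xc, D, n_perm=19, seed=seeds[0])
                pred = (asca_result.decomposition.effects[factor]
                        + asca_result.decomposition.residual)
                n_levels = meta[factor].nunique()
                stat = None
                if n_levels == 2:
                    stat = asca_result.loadings[factor]["PC1"].abs()
                rt = otumod.uve_select(pred, meta[factor], pair, n_rep=uve_reps,
                                       seed=seeds[6], ranking_statistic=stat)
            elif meth == "ancom":
                cov = meta[other] if other else None
                rt = otumod.ancom_w(rel_z, meta[factor], covariates=cov)
            elif meth == "dirichlet-clr":
                sel = meta[factor].astype(str).isin(pair)
                sub_meta = meta.loc[sel]
                terms = tuple((c,) for c in ([factor] + other)
                              if sub_meta[c].nunique() > 1)
                Dsub = build_design(sub_meta, terms)
                rt = otumod.dirichlet_clr_test(
                    ds.counts.values.loc[sel, rel_f.columns], Dsub,
                    term=factor, n_mc=n_mc, seed=seeds[7],
                )
            elif meth == "nbglm":
                terms = tuple((c,) for c in [factor] + other)
                rt = otumod.nbglm_test(
                    ds.counts.values[rel_f.columns], meta, terms,
                    contrast=(factor, pair[0], pair[1]),
                )
            else:
                raise ValueError(f"unknown OTU method {meth!r}")
            out.rankings[meth] = rt
        except Exception as exc:  # noqa: BLE001
            logger.warning("OTU method %s failed: %s", meth, exc)
            out.failures[meth] = str(exc)
    return out


# ---------------------------------------------------------------------------
# the benchmark loop

@dataclass
class BenchmarkResult:
    """Per-scenario, per-dataset metrics of the simulation study."""

    community: pd.DataFrame   # scenario, dataset, method, p_value, explained_variance_pct, detected
    otu_metrics: pd.DataFrame  # scenario, dataset, method, tpr, tnr, n_significant
    spearman: pd.DataFrame     # scenario, dataset, method_a, method_b, rho
    abundance: pd.DataFrame    # scenario, dataset, method, rho_abundance
    n_datasets: int
    alpha: float
    seed: int
    failures: pd.DataFrame


def run_benchmark(
    template: SimulationParams,
    scenarios=("few-low", "few-high", "many-low", "many-high"),
    n_datasets: int = 100,
    community_methods=("asca", "ffmanova", "permanova"),
    otu_methods=("rotation", "simper", "asca-uve", "ancom", "dirichlet-clr", "nbglm"),
    alpha: float = 0.05,
    n_perm=999,
    seed: int = 0,
    factor: str | None = None,
    **analysis_kwargs,
) -> BenchmarkResult:
    """Simulate, preprocess and analyse ``n_datasets`` per scenario.

    Fully reproducible from the master seed: simulation streams use a
    counter-based spawn per (scenario, dataset), analysis streams a
    separate spawn, so changing the method list never perturbs the data.
    Method failures on single datasets are recorded and the run continues.
    """
    comm_rows, otu_rows, sp_rows, ab_rows, fail_rows = [], [], [], [], []
    for s_i, scen in enumerate(scenarios):
        scen_seed = int(
            np.random.SeedSequence(entropy=seed, spawn_key=(11, s_i)).generate_state(1)[0]
        ) & 0x7FFFFFFF
        sims = generate_scenario_batch(template, scen, n_datasets=n_datasets, seed=scen_seed)
        for k, sim in enumerate(sims):
            a_seed = int(
                np.random.SeedSequence(entropy=seed, spawn_key=(13, s_i, k)).generate_state(1)[0]
            ) & 0x7FFFFFFF
            res = analyze_dataset(
                sim,
                community_methods=community_methods,
                otu_methods=otu_methods,
                n_perm=n_perm,
                seed=a_seed,
                factor=factor,
                **analysis_kwargs,
            )
            for meth, (p, ev) in res.community.items():
                comm_rows.append({
                    "scenario": scen, "dataset": k, "method": meth,
                    "p_value": p, "explained_variance_pct": ev,
                    "detected": p < alpha,
                })
            for meth, rt in res.rankings.items():
                calls = rt.significant.reindex(res.truth.index, fill_value=False)
                tpr, tnr = tpr_tnr(calls, res.truth)
                otu_rows.append({
                    "scenario": scen, "dataset": k, "method": meth,
                    "tpr": tpr, "tnr": tnr,
                    "n_significant": int(rt.significant.sum()),
                })
                rho, _ = abundance_dependence(rt, res.rel_filtered)
                ab_rows.append({
                    "scenario": scen, "dataset": k, "method": meth,
                    "rho_abundance": rho,
                })
            names = list(res.rankings)
            for i, a in enumerate(names):
                for b in names[i + 1:]:
                    mat = spearman_agreement({a: res.rankings[a], b: res.rankings[b]})
                    sp_rows.append({
                        "scenario": scen, "dataset": k,
                        "method_a": a, "method_b": b, "rho": mat.loc[a, b],
                    })
            for meth, msg in res.failures.items():
                fail_rows.append({"scenario": scen, "dataset": k,
                                  "method": meth, "error": msg})

    def frame(rows, cols):
        return pd.DataFrame(rows) if rows else pd.DataFrame(columns=cols)

    return BenchmarkResult(
        community=frame(comm_rows, ["scenario", "dataset", "method", "p_value",
                                    "explained_variance_pct", "detected"]),
        otu_metrics=frame(otu_rows, ["scenario", "dataset", "method",
                                     "tpr", "tnr", "n_significant"]),
        spearman=frame(sp_rows, ["scenario", "dataset", "method_a", "method_b", "rho"]),
        abundance=frame(ab_rows, ["scenario", "dataset", "method", "rho_abundance"]),
        n_datasets=n_datasets,
        alpha=alpha,
        seed=seed,
        failures=frame(fail_rows, ["scenario", "dataset", "method", "error"]),
    )


def summarize(result: BenchmarkResult) -> dict[str, pd.DataFrame]:
    """Aggregate the per-dataset metrics into the four report tables:
    community detection/effect size, TPR/TNR, pairwise Spearman agreement
    and the abundance-dependence diagnostic."""
    tables: dict[str, pd.DataFrame] = {}
    if len(result.community):
        tables["community"] = (
            result.community.groupby(["scenario", "method"])
            .agg(detection_rate=("detected", "mean"),
                 mean_explained_variance_pct=("explained_variance_pct", "mean"),
                 sd_explained_variance_pct=("explained_variance_pct", "std"))
            .reset_index()
        )
    else:
        tables["community"] = pd.DataFrame(
            columns=["scenario", "method", "detection_rate",
                     "mean_explained_variance_pct", "sd_explained_variance_pct"])
    if len(result.otu_metrics):
        tables["tpr_tnr"] = (
            result.otu_metrics.groupby(["scenario", "method"])
            .agg(mean_tpr=("tpr", "mean"), mean_tnr=("tnr", "mean"),
                 mean_n_significant=("n_significant", "mean"))
            .reset_index()
        )
    else:
        tables["tpr_tnr"] = pd.DataFrame(
            columns=["scenario", "method", "mean_tpr", "mean_tnr", "mean_n_significant"])
    if len(result.spearman):
        tables["spearman"] = (
            result.spearman.groupby(["scenario", "method_a", "method_b"])
            .agg(median_rho=("rho", "median"), mean_rho=("rho", "mean"))
            .reset_index()
        )
    else:
        tables["spearman"] = pd.DataFrame(
            columns=["scenario", "method_a", "method_b", "median_rho", "mean_rho"])
    if len(result.abundance):
        tables["abundance"] = (
            result.abundance.groupby(["scenario", "method"])
            .agg(mean_rho_abundance=("rho_abundance", "mean"),
                 mean_abs_rho_abundance=("rho_abundance", lambda s: s.abs().mean()))
            .reset_index()
        )
    else:
        tables["abundance"] = pd.DataFrame(
            columns=["scenario", "method", "mean_rho_abundance",
                     "mean_abs_rho_abundance"])
    return tables
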