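"""Gamma + multivariate-hypergeometric 16S count simulator.

Counts for each sample are generated in two steps: (1) per-OTU expected
relative intensities are drawn from per-group Gamma distributions (the
group = one design cell, e.g. a diet × dose combination); (2) an integer
urn proportional to the drawn intensities is sampled without replacement
with a multivariate hypergeometric draw of the sample's sequencing depth,
so each simulated sample's counts sum to its depth exactly.

Intensity parameters can be estimated from a template count matrix by
moment matching, or generated synthetically (:func:`make_default_template`)
with a log-normal abundance profile — a few dominant OTUs above 1%
relative abundance and a long tail of rare ones, as in real gut data.
Differential-abundance scenarios multiply the intensities of randomly
chosen OTUs by uniform log2 fold changes in the cells of one affected
diet level, with no effect of the second factor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np
import pandas as pd

from .data import CountMatrix, Dataset, StudyDesign

logger = logging.getLogger("microbench")

__all__ = [
    "SimulationParams",
    "ScenarioSpec",
    "SimulatedDataset",
    "SCENARIOS",
    "estimate_params",
    "make_default_template",
    "apply_scenario",
    "sample_counts",
    "generate_scenario_batch",
]

#: scenario name → (number of differentially abundant OTUs,
#:                  lower and upper bound of the uniform log2 fold change)
SCENARIOS: dict[str, tuple[int, float, float]] = {
    "few-low": (10, 3.0, 4.0),
    "few-high": (10, 8.0, 9.0),
    "many-low": (254, 3.0, 4.0),
    "many-high": (254, 8.0, 9.0),
}


@dataclass
class SimulationParams:
    """Per-OTU × per-group Gamma intensity parameters plus the layout.

    ``shape`` and ``rate`` are OTU × group DataFrames; the Gamma mean
    shape/rate is the expected relative intensity of the OTU in that
    group.  ``cell_metadata`` maps each group (design cell) to its factor
    levels.  Depths are drawn from a log-normal with the given mean and
    coefficient of variation unless ``empirical_depths`` is set.
    """

    shape: pd.DataFrame
    rate: pd.DataFrame
    cell_metadata: pd.DataFrame
    n_per_cell: int = 6
    depth_mean: float = 5e4
    depth_cv: float = 0.25
    empirical_depths: np.ndarray | None = None

    def __post_init__(self) -> None:
        if list(self.shape.columns) != list(self.rate.columns) or list(
            self.shape.index
        ) != list(self.rate.index):
            raise ValueError("shape and rate must share index and columns")
        if np.any(self.shape.to_numpy() < 0) or np.any(self.rate.to_numpy() <= 0):
            raise ValueError("Gamma parameters must be positive (shape 0 marks an absent OTU)")
        if list(self.shape.columns) != list(self.cell_metadata.index):
            raise ValueError("parameter groups must match the design cells")

    @property
    def mean_intensity(self) -> pd.DataFrame:
        return self.shape / self.rate

    @property
    def otu_ids(self) -> list[str]:
        return list(self.shape.index)

    @property
    def cells(self) -> list[str]:
        return list(self.shape.columns)

    def study_design(self) -> StudyDesign:
        factors = {
            c: sorted(map(str, pd.unique(self.cell_metadata[c])))
            for c in self.cell_metadata.columns
        }
        names = list(self.cell_metadata.columns)
        terms: list[tuple[str, ...]] = [(n,) for n in names]
        if len(names) == 2:
            terms.append(tuple(names))
        return StudyDesign(factors=factors, terms=tuple(terms))


@dataclass
class ScenarioSpec:
    """One differential-abundance scenario."""

    n_da: int
    log2fc_low: float
    log2fc_high: float
    affected_level: str | None = None  # default: first level of the first factor
    affected_factor: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_da < 0:
            raise ValueError("n_da must be non-negative")
        if self.n_da and not self.log2fc_low < self.log2fc_high:
            raise ValueError("log2fc_low must be < log2fc_high")

    @staticmethod
    def named(name: str, seed: int = 0, **kwargs) -> "ScenarioSpec":
        key = name.lower().replace("_", "-")
        if key not in SCENARIOS:
            raise ValueError(f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}")
        n_da, lo, hi = SCENARIOS[key]
        return ScenarioSpec(n_da=n_da, log2fc_low=lo, log2fc_high=hi, seed=seed, **kwargs)


@dataclass
class SimulatedDataset:
    """Simulated counts plus the differential-abundance ground truth."""

    dataset: Dataset
    truth: pd.Series          # per-OTU bool, exactly n_da positives
    realized_log2fc: pd.Series

    def __post_init__(self) -> None:
        if (self.realized_log2fc[~self.truth] != 0).any():
            raise ValueError("non-zero fold change on a null OTU")


def estimate_params(
    counts: CountMatrix,
    groups: pd.Series,
    cell_metadata: pd.DataFrame | None = None,
    var_floor_rel: float = 1e-4,
    n_per_cell: int | None = None,
) -> SimulationParams:
    """Moment-match per-group Gamma intensity parameters from counts.

    For each OTU × group, shape = m²/v and rate = m/v with m, v the group
    mean and (sample) variance of the relative abundance; the variance is
    floored at ``var_floor_rel * m²`` so constant groups get a finite
    shape of 1/var_floor_rel.  The observed library sizes become the
    empirical depth distribution.
    """
    rel = counts.values.div(counts.values.sum(axis=1), axis=0)
    groups = groups.astype(str).reindex(rel.index)
    sizes = groups.value_counts()
    if sizes.min() < 2:
        raise ValueError("every group needs at least 2 samples to estimate a variance")
    cells = sorted(sizes.index)
    shape = pd.DataFrame(index=rel.columns, columns=cells, dtype=float)
    rate = pd.DataFrame(index=rel.columns, columns=cells, dtype=float)
    for g in cells:
        sub = rel.loc[groups == g]
        m = sub.mean(axis=0).to_numpy()
        v = sub.var(axis=0, ddof=1).to_numpy()
        v = np.maximum(v, var_floor_rel * m ** 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            sh = np.where(m > 0, m ** 2 / v, 0.0)
            ra = np.where(m > 0, m / v, 1.0)
        shape[g] = sh
        rate[g] = ra
    if cell_metadata is None:
        cell_metadata = pd.DataFrame({"group": cells}, index=cells)
    return SimulationParams(
        shape=shape,
        rate=rate,
        cell_metadata=cell_metadata,
        n_per_cell=n_per_cell or int(sizes.min()),
        empirical_depths=counts.library_sizes.to_numpy(),
    )


def make_default_template(
    n_otus: int = 507,
    n_per_cell: int = 6,
    diet_levels: tuple[str, ...] = ("A", "B", "C"),
    dose_levels: tuple[str, ...] = ("low", "high"),
    depth_mean: float = 5e4,
    depth_cv: float = 0.25,
    abundance_sigma: float = 2.2,
    gamma_shape_median: float = 0.4,
    gamma_shape_log_sd: float = 0.8,
    seed: int = 0,
) -> SimulationParams:
    """Fully synthetic two-factor (diet × dose) template, no download needed.

    Mean relative intensities are log-normal (``abundance_sigma`` in ln
    units gives a handful of OTUs above 1% and a long rare tail, the
    typical gut profile).  Per-OTU Gamma shapes are log-normal around
    ``gamma_shape_median``; the default median of 0.4 corresponds to a
    biological coefficient of variation around 1.6 (range roughly 0.7-3.5),
    matching the strongly overdispersed intensities that moment estimation
    recovers from real gut count data.  The same parameters are used in
    every design cell, so the template is null until a scenario is
    applied.  Deterministic in ``seed``.
    """
    if n_otus < 10:
        raise ValueError("n_otus must be >= 10")
    rng = np.random.default_rng(seed)
    otus = [f"OTU{j + 1:04d}" for j in range(n_otus)]
    intensity = np.exp(rng.normal(0.0, abundance_sigma, size=n_otus))
    intensity = intensity / intensity.sum()
    shape_vec = np.exp(rng.normal(np.log(gamma_shape_median), gamma_shape_log_sd, size=n_otus))
    rate_vec = shape_vec / intensity

    cells = [f"{d}.{o}" for d, o in product(diet_levels, dose_levels)]
    cell_metadata = pd.DataFrame(
        [(d, o) for d, o in product(diet_levels, dose_levels)],
        index=cells,
        columns=["diet", "dose"],
    )
    shape = pd.DataFrame({c: shape_vec for c in cells}, index=otus)
    rate = pd.DataFrame({c: rate_vec for c in cells}, index=otus)
    return SimulationParams(
        shape=shape,
        rate=rate,
        cell_metadata=cell_metadata,
        n_per_cell=n_per_cell,
        depth_mean=depth_mean,
        depth_cv=depth_cv,
    )


def apply_scenario(
    params: SimulationParams,
    scenario: ScenarioSpec,
    rng: np.random.Generator | None = None,
) -> tuple[SimulationParams, pd.Series, pd.Series]:
    """Inject a differential-abundance scenario into intensity parameters.

    ``n_da`` OTUs are chosen uniformly without replacement and their mean
    intensities multiplied by 2**log2fc (log2fc ~ U[low, high]) in every
    design cell whose affected factor matches the affected level; all
    other cells are untouched (no effect of the second factor).  Each
    group's intensities are then re-normalized to sum 1, so the spike-ins
    have the usual compositional side effect on the other OTUs.
    """
    rng = rng or np.random.default_rng(scenario.seed)
    otus = params.otu_ids
    m = len(otus)
    if scenario.n_da > m:
        raise ValueError(f"n_da={scenario.n_da} exceeds the {m} available OTUs")
    factor = scenario.affected_factor or params.cell_metadata.columns[0]
    levels = sorted(map(str, pd.unique(params.cell_metadata[factor])))
    level = str(scenario.affected_level) if scenario.affected_level else levels[0]
    if level not in levels:
        raise ValueError(f"affected level {level!r} not a level of {factor!r}")

    truth = pd.Series(False, index=otus)
    log2fc = pd.Series(0.0, index=otus)
    rate = params.rate.copy()
    if scenario.n_da > 0:
        chosen = rng.choice(m, size=scenario.n_da, replace=False)
        fc = rng.uniform(scenario.log2fc_low, scenario.log2fc_high, size=scenario.n_da)
        truth.iloc[chosen] = True
        log2fc.iloc[chosen] = fc
        affected_cells = params.cell_metadata.index[
            params.cell_metadata[factor].astype(str) == level
        ]
        for cell in affected_cells:
            # mean = shape/rate, so dividing the rate multiplies the mean
            # while preserving the coefficient of variation
            rate.loc[rate.index[chosen], cell] /= 2.0 ** fc
    # re-close every group's mean intensities to 1
    mean = params.shape / rate
    totals = mean.sum(axis=0)
    rate = rate * totals
    return replace(params, rate=rate), truth, log2fc


def _draw_depths(params: SimulationParams, n: int, rng: np.random.Generator) -> np.ndarray:
    if params.empirical_depths is not None:
        return rng.choice(params.empirical_depths, size=n, replace=True).astype(np.int64)
    sigma = np.sqrt(np.log(1.0 + params.depth_cv ** 2))
    mu = np.log(params.depth_mean) - sigma ** 2 / 2.0
    return np.maximum(np.round(rng.lognormal(mu, sigma, size=n)), 1).astype(np.int64)


def sample_counts(
    params: SimulationParams,
    seed: int = 0,
    urn_scale: float = 1e6,
    truth: pd.Series | None = None,
    realized_log2fc: pd.Series | None = None,
) -> SimulatedDataset:
    """Draw a full dataset of counts from the intensity parameters.

    Per sample: OTU intensities λ_j are drawn from their Gamma laws, an
    integer urn with round(λ_j × urn_scale) items is formed, the depth N
    is drawn, and counts follow a multivariate hypergeometric draw of N
    items from the urn — so counts sum to N exactly.  If N exceeds the
    urn, the urn scale is inflated (and logged).
    """
    rng = np.random.default_rng(seed)
    otus = params.otu_ids
    m = len(otus)
    rows, meta_rows, ids = [], [], []
    k = 0
    for cell in params.cells:
        sh = params.shape[cell].to_numpy()
        ra = params.rate[cell].to_numpy()
        depths = _draw_depths(params, params.n_per_cell, rng)
        for r in range(params.n_per_cell):
            lam = np.where(sh > 0, rng.standard_gamma(np.maximum(sh, 1e-300)) / ra, 0.0)
            scale = urn_scale
            urn = np.round(lam * scale).astype(np.int64)
            while urn.sum() < depths[r]:
                scale *= 10.0
                logger.warning("sample_counts: urn smaller than depth; inflating urn scale to %g", scale)
                urn = np.round(lam * scale).astype(np.int64)
            counts = rng.multivariate_hypergeometric(urn, int(depths[r]), method="marginals")
            rows.append(counts)
            meta_rows.append(params.cell_metadata.loc[cell])
            k += 1
            ids.append(f"S{k:03d}")

    values = pd.DataFrame(np.asarray(rows), index=ids, columns=otus)
    metadata = pd.DataFrame(meta_rows, index=ids).astype(str)
    design = params.study_design()
    dataset = Dataset(counts=CountMatrix(values), metadata=metadata, design=design)
    if truth is None:
        truth = pd.Series(False, index=otus)
    if realized_log2fc is None:
        realized_log2fc = pd.Series(0.0, index=otus)
    return SimulatedDataset(dataset=dataset, truth=truth, realized_log2fc=realized_log2fc)


def generate_scenario_batch(
    template: SimulationParams,
    scenario_name: str,
    n_datasets: int = 100,
    seed: int = 0,
    affected_level: str | None = None,
) -> list[SimulatedDataset]:
    """Generate independent datasets for one named scenario.

    Per-dataset seeds are derived from the master seed with a counter-
    based spawn so adding analyses elsewhere never perturbs the streams.
    """
    out = []
    for k in range(int(n_datasets)):
        ss = np.random.SeedSequence(entropy=seed, spawn_key=(k,))
        scen_seed, samp_seed = (int(s) for s in ss.generate_state(2))
        spec = ScenarioSpec.named(scenario_name, seed=scen_seed, affected_level=affected_level)
        p2, truth, fc = apply_scenario(template, spec)
        out.append(sample_counts(p2, seed=samp_seed, truth=truth, realized_log2fc=fc))
    return out
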