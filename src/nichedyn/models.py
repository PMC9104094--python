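"""Model-level API: fit a niche-shift analysis or a reciprocal SDM.

Two estimator classes wrap the functional layers the way regression
models wrap their linear algebra: a model object is constructed from the
data (stacks and occurrence sets, or a synthetic scenario), ``fit()``
runs the analysis, and the returned results object carries the estimates,
their permutation uncertainties and a ``summary()`` table.

>>> model = NicheShiftModel.from_scenario(scenario)
>>> res = model.fit()
>>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dynamics, envspace, sdm
from .containers import EnvLayerStack, OccurrenceSet
from .io import extract_env_at_points

__all__ = ["NicheShiftModel", "NicheShiftResults",
           "ReciprocalSDM", "ReciprocalSDMResults"]


class NicheShiftModel:
    """Realized-niche comparison between a native and an invaded range.

    Builds one shared PCA-env space from both ranges' backgrounds,
    kernel-density occupancy surfaces per entity, and computes overlap,
    the expansion / maximum-niche-stability / unfilling decomposition
    across marginality quantiles, permutation tests, and (when records
    are dated) the yearly dynamics series.

    Parameters
    ----------
    native_stack, invaded_stack : EnvLayerStack
    native_occ, invaded_occ : OccurrenceSet
    grid_resolution : int
        R of the R x R environmental-space grid (default 100).
    bandwidth : float or (float, float), optional
        Fixed kernel bandwidth; default is Silverman's rule per axis.
    quantiles : sequence of float
        Intersect quantiles for the marginality sweep.
    occupancy_threshold : float
        Occupancy-mass fraction trimmed when binarizing niches (default 0).
    n_perm : int
        Permutations for the equivalency and similarity tests.
    """

    def __init__(self, native_stack: EnvLayerStack, native_occ: OccurrenceSet,
                 invaded_stack: EnvLayerStack, invaded_occ: OccurrenceSet,
                 grid_resolution: int = 100, bandwidth=None,
                 quantiles=(0.0, 0.1, 0.2), occupancy_threshold: float = 0.0,
                 n_perm: int = 99, seed: int = 0, entity: str = "invasive"):
        self.native_stack = native_stack
        self.invaded_stack = invaded_stack
        self.native_occ = native_occ
        self.invaded_occ = invaded_occ
        self.R = int(grid_resolution)
        self.bandwidth = bandwidth
        self.quantiles = tuple(quantiles)
        self.occupancy_threshold = float(occupancy_threshold)
        self.n_perm = int(n_perm)
        self.seed = int(seed)
        self.entity = entity

    @classmethod
    def from_scenario(cls, scenario, **kwargs) -> "NicheShiftModel":
        return cls(scenario.native_stack, scenario.native_occ,
                   scenario.invaded_stack, scenario.invaded_occ, **kwargs)

    def fit(self, equivalency: bool = True, similarity: bool = True,
            temporal: bool | None = None) -> "NicheShiftResults":
        nat_bg = self.native_stack.table()
        inv_bg = self.invaded_stack.table()
        pca = envspace.fit_pca_env([nat_bg, inv_bg])
        nat_bg_scores = pca.project(nat_bg)
        inv_bg_scores = pca.project(inv_bg)
        nat_occ_env = extract_env_at_points(self.native_stack, self.native_occ)
        inv_occ_env = extract_env_at_points(self.invaded_stack, self.invaded_occ)
        nat_scores = pca.project(nat_occ_env)
        inv_scores = pca.project(inv_occ_env)
        bounds = envspace.shared_bounds(nat_bg_scores, inv_bg_scores,
                                        nat_scores, inv_scores)
        nat_grid = envspace.build_density_grid(
            nat_scores, nat_bg_scores, self.R, self.bandwidth, bounds, "native")
        inv_grid = envspace.build_density_grid(
            inv_scores, inv_bg_scores, self.R, self.bandwidth, bounds, self.entity)

        sweep = dynamics.marginality_sweep(
            nat_grid, inv_grid, self.quantiles, self.occupancy_threshold)
        base = dynamics.compare_niches(
            nat_grid, inv_grid, self.quantiles[0], self.occupancy_threshold)

        equiv = None
        if equivalency:
            equiv = dynamics.equivalency_test(
                nat_scores, inv_scores, nat_bg_scores, inv_bg_scores,
                self.R, self.n_perm, self.seed, bandwidth=self.bandwidth)
        simil = None
        if similarity:
            simil = dynamics.similarity_test(
                nat_grid, inv_grid, self.n_perm, self.seed + 1)

        if temporal is None:
            temporal = self.invaded_occ.years.notna().any()
        series = None
        if temporal:
            dated = self.invaded_occ.dated()
            if len(dated):
                env = extract_env_at_points(self.invaded_stack, dated)
                scores = pca.project(env)
                yrs = dated.years.loc[env.index].to_numpy(dtype=int)
                series = dynamics.temporal_dynamics(
                    nat_grid, scores, yrs, inv_bg_scores,
                    self.quantiles[0], self.occupancy_threshold, self.bandwidth)

        mess_vals, mess_frac = envspace.mess(nat_bg, inv_bg)
        return NicheShiftResults(
            model=self, pca=pca, native_grid=nat_grid, invasive_grid=inv_grid,
            overlap=base, marginality=sweep, equivalency=equiv,
            similarity=simil, temporal=series,
            mess_values=mess_vals, mess_fraction_nonnegative=mess_frac)


@dataclass
class NicheShiftResults:
    """Fitted niche-comparison results."""

    model: NicheShiftModel
    pca: envspace.PcaModel
    native_grid: envspace.EntityDensityGrid
    invasive_grid: envspace.EntityDensityGrid
    overlap: dynamics.NicheDynamicsResult
    marginality: pd.DataFrame
    equivalency: dynamics.PermutationTestResult | None
    similarity: dynamics.PermutationTestResult | None
    temporal: pd.DataFrame | None
    mess_values: np.ndarray = field(repr=False, default=None)
    mess_fraction_nonnegative: float = np.nan

    @property
    def D(self) -> float:
        return self.overlap.D

    @property
    def expansion(self) -> float:
        return self.overlap.expansion

    @property
    def max_niche_stability(self) -> float:
        return self.overlap.max_niche_stability

    @property
    def unfilling(self) -> float:
        return self.overlap.unfilling

    def summary(self) -> str:
        lines = ["Niche dynamics summary", "=" * 54]
        lines.append(f"PCA-env variance explained: "
                     f"{self.pca.variance_explained[0]:.1%} / "
                     f"{self.pca.variance_explained[1]:.1%}")
        lines.append(f"Schoener's D            {self.D:8.3f}")
        lines.append(f"Expansion               {self.expansion:8.3f}")
        lines.append(f"Max niche stability     {self.max_niche_stability:8.3f}")
        lines.append(f"Unfilling               {self.unfilling:8.3f}")
        lines.append(f"MESS fraction analogue  {self.mess_fraction_nonnegative:8.3f}")
        if self.equivalency is not None:
            lines.append(f"Equivalency test        p = {self.equivalency.p_value:.4f} "
                         f"({self.equivalency.n_perm} perms, "
                         f"{self.equivalency.direction})")
        if self.similarity is not None:
            lines.append(f"Similarity test         p = {self.similarity.p_value:.4f} "
                         f"({self.similarity.n_perm} perms, "
                         f"{self.similarity.direction})")
        lines.append("")
        lines.append("Marginality sweep (intersect quantiles):")
        lines.append(self.marginality.drop(columns="flagged").round(3).to_string(index=False))
        if self.temporal is not None:
            lines.append("")
            lines.append("Temporal dynamics (cumulative records per year):")
            lines.append(self.temporal.round(3).to_string(index=False))
        return "\n".join(lines)

    def tidy(self) -> pd.DataFrame:
        """All metric rows (population x year x quantile) as one tidy frame."""
        rows = self.marginality.assign(year=pd.NA, entity=self.invasive_grid.entity)
        if self.temporal is not None:
            t = self.temporal.assign(
                intersect_quantile=self.model.quantiles[0],
                entity=self.invasive_grid.entity)
            rows = pd.concat([rows, t], ignore_index=True)
        return rows


class ReciprocalSDM:
    """Reciprocal ensemble distribution models between two ranges.

    Fits one 10 x 3 ensemble per range, projects each onto the other
    range, and overlays the two invaded-range consensus maps into risk
    categories. The niche-shift signature is read off the reciprocal
    coverages: under niche conservatism each ensemble covers most of the
    other range's presences; a shifted invader's ensemble fails to predict
    the native occurrences.
    """

    def __init__(self, native_stack: EnvLayerStack, native_occ: OccurrenceSet,
                 invaded_stack: EnvLayerStack, invaded_occ: OccurrenceSet,
                 reps: int = 10, ratio: int = 5, train_fraction: float = 0.75,
                 algorithms=sdm.ALGORITHMS, seed: int = 0):
        self.native_stack = native_stack
        self.invaded_stack = invaded_stack
        self.native_occ = native_occ
        self.invaded_occ = invaded_occ
        self.reps = reps
        self.ratio = ratio
        self.train_fraction = train_fraction
        self.algorithms = tuple(algorithms)
        self.seed = int(seed)

    @classmethod
    def from_scenario(cls, scenario, **kwargs) -> "ReciprocalSDM":
        return cls(scenario.native_stack, scenario.native_occ,
                   scenario.invaded_stack, scenario.invaded_occ, **kwargs)

    def fit(self) -> "ReciprocalSDMResults":
        native = sdm.run_ensemble(
            self.native_stack, self.native_occ, self.algorithms, self.reps,
            self.train_fraction, self.ratio, self.seed, dataset="native")
        invaded = sdm.run_ensemble(
            self.invaded_stack, self.invaded_occ, self.algorithms, self.reps,
            self.train_fraction, self.ratio, self.seed + 1, dataset="invasive")
        native_on_invaded = sdm.project_ensemble(native, self.invaded_stack)
        invaded_on_native = sdm.project_ensemble(invaded, self.native_stack)
        cov_native_model = sdm.presence_coverage(
            native_on_invaded, self.invaded_stack, self.invaded_occ)
        cov_invaded_model = sdm.presence_coverage(
            invaded_on_native, self.native_stack, self.native_occ)
        risk = sdm.risk_overlay(native_on_invaded, invaded.consensus_binary,
                                self.invaded_stack.valid_mask)
        return ReciprocalSDMResults(
            model=self, native_ensemble=native, invaded_ensemble=invaded,
            native_on_invaded=native_on_invaded,
            invaded_on_native=invaded_on_native,
            coverage_native_to_invaded=cov_native_model,
            coverage_invaded_to_native=cov_invaded_model,
            risk=risk)


@dataclass
class ReciprocalSDMResults:
    model: ReciprocalSDM
    native_ensemble: sdm.EnsembleResult
    invaded_ensemble: sdm.EnsembleResult
    native_on_invaded: np.ndarray
    invaded_on_native: np.ndarray
    coverage_native_to_invaded: float
    coverage_invaded_to_native: float
    risk: sdm.RiskMap

    @property
    def run_table(self) -> pd.DataFrame:
        nat = self.native_ensemble.run_table.assign(dataset="native")
        inv = self.invaded_ensemble.run_table.assign(dataset="invasive")
        return pd.concat([nat, inv], ignore_index=True)

    def summary(self) -> str:
        tab = self.run_table.groupby(["dataset", "algorithm"])["auc"] \
                            .agg(["mean", "min", "max"]).round(3)
        lines = ["Reciprocal distribution model summary", "=" * 54]
        lines.append("Held-out AUC by dataset and algorithm:")
        lines.append(tab.to_string())
        lines.append("")
        lines.append(f"Native ensemble covers {self.coverage_native_to_invaded:.1%} "
                     "of invaded-range presences")
        lines.append(f"Invaded ensemble covers {self.coverage_invaded_to_native:.1%} "
                     "of native-range presences")
        lines.append("")
        lines.append("Risk shares over the invaded range:")
        for name, share in self.risk.shares.items():
            lines.append(f"  {name:<15s} {share:6.1%}")
        high = 1.0 - self.risk.shares["neither"]
        lines.append(f"  {'high_risk':<15s} {high:6.1%}")
        return "\n".join(lines)
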