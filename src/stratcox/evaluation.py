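"""Monte-Carlo replication experiment and estimator-performance summaries.

A *scenario* is one cell of the experimental grid: a sampling design
(simple random or stratified), a loss-to-follow-up mode (none, random,
differential), one of the three Cox specifications, and whether the fit uses
the design weights or not.  :func:`run_replications` draws R samples from a
fixed generated population, pushes each through sample -> loss -> fit, and
records the coefficient estimates and their estimated variances.

Per-replicate seeds are derived from the scenario's root seed with
``numpy.random.SeedSequence(root, spawn_key=(rep, stream))`` (stream 0 for
sampling, 1 for loss), so every replicate is individually reproducible and -
deliberately - two scenarios sharing a root seed and design re-use the *same*
samples, which makes loss-scenario comparisons paired.

Summaries report, per coefficient: mean estimate, bias on the log-HR scale
against a census reference fit, empirical variance (R-1 divisor), average of
the per-replicate estimated variances, and MSE = empirical variance + bias^2.
The sampling distribution of HR estimates can be displayed with a Gaussian
kernel density (classic Silverman bandwidth by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .attrition import LossSpec, apply_loss
from .cox import FitResult, ModelSpec, build_design_matrix, fit_weighted_cox
from .errors import ConfigError, ConvergenceError, InvalidParameterError
from .sampling import DesignSpec, draw_sample

__all__ = [
    "ScenarioSpec",
    "ReplicationResult",
    "replicate_seed",
    "run_replications",
    "summarize",
    "kernel_density",
    "silverman_bandwidth",
    "compare_scenarios",
    "density_table",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the simulation grid."""

    name: str
    design: DesignSpec
    loss: LossSpec
    model: ModelSpec
    weighting: str = "weighted"
    replicates: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.weighting not in ("weighted", "unweighted"):
            raise InvalidParameterError(
                f"weighting must be 'weighted' or 'unweighted', got {self.weighting!r}"
            )
        if self.replicates < 1:
            raise InvalidParameterError("replicates must be >= 1")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "design": self.design.to_dict(),
            "loss": self.loss.to_dict(),
            "model": self.model.name,
            "weighting": self.weighting,
            "replicates": self.replicates,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, mapping: dict) -> "ScenarioSpec":
        known = {"name", "design", "loss", "model", "weighting", "replicates", "seed"}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError(f"unknown scenario keys: {sorted(unknown)}")
        m = dict(mapping)
        m["design"] = DesignSpec.from_dict(m["design"])
        m["loss"] = LossSpec.from_dict(m.get("loss", {"mode": "none"}))
        m["model"] = ModelSpec(m["model"])
        return cls(**m)


def replicate_seed(root_seed: int, rep: int, stream: int) -> int:
    """Deterministic integer sub-seed for replicate ``rep``.

    Stream 0 feeds the sample draw, stream 1 the loss draw.  The value is
    the first 32-bit word of ``SeedSequence(root_seed, spawn_key=(rep,
    stream))``, so sub-streams are statistically independent and each
    replicate can be re-run in isolation.
    """
    ss = np.random.SeedSequence(root_seed, spawn_key=(rep, stream))
    return int(ss.generate_state(1)[0])


@dataclass
class ReplicationResult:
    """Per-replicate estimates from one scenario.

    ``estimates`` holds log-HRs (one row per converged replicate, one column
    per coefficient); ``est_variances`` the matching per-replicate estimated
    variances (sandwich for weighted fits, model-based for unweighted ones).
    """

    scenario: ScenarioSpec
    estimates: pd.DataFrame
    est_variances: pd.DataFrame
    n_failed: int
    failed_replicates: list = field(default_factory=list)


def run_one(population: pd.DataFrame, scenario: ScenarioSpec, rep: int) -> FitResult:
    """Run a single replicate (sample -> loss -> fit) of a scenario."""
    sample = draw_sample(
        population, scenario.design, replicate_seed(scenario.seed, rep, 0)
    )
    sample = apply_loss(sample, scenario.loss, replicate_seed(scenario.seed, rep, 1))
    X, names, time, event, weights = build_design_matrix(sample, scenario.model)
    if scenario.weighting == "unweighted":
        weights = np.ones_like(weights)
    return fit_weighted_cox(X, time, event, weights, names=names)


def run_replications(population: pd.DataFrame, scenario: ScenarioSpec) -> ReplicationResult:
    """Execute all replicates of a scenario.

    Non-converged replicates are recorded and excluded; more than 5% of them
    raises, signalling a mis-specified scenario.
    """
    names = scenario.model.columns
    rows, var_rows, kept, failed = [], [], [], []
    for rep in range(scenario.replicates):
        try:
            fit = run_one(population, scenario, rep)
        except ConvergenceError:
            failed.append(rep)
            continue
        rows.append(fit.coef)
        if scenario.weighting == "weighted":
            var_rows.append(np.diag(fit.robust_cov))
        else:
            var_rows.append(np.diag(fit.cov))
        kept.append(rep)
    if len(failed) > 0.05 * scenario.replicates:
        raise ConvergenceError(
            f"scenario {scenario.name!r}: {len(failed)}/{scenario.replicates} "
            "replicates failed to converge (>5%)"
        )
    estimates = pd.DataFrame(rows, columns=list(names), index=kept)
    variances = pd.DataFrame(var_rows, columns=list(names), index=kept)
    return ReplicationResult(scenario, estimates, variances, len(failed), failed)


def summarize(
    estimates: pd.DataFrame,
    reference: FitResult,
    est_variances: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-coefficient performance summary against a census reference fit.

    Bias is ``mean(log-HR) - reference log-HR``; empirical variance uses the
    R-1 divisor; ``mse = emp_var + bias**2`` by construction.  ``q025``/
    ``q975`` bound the central 95% of the replicate log-HRs and
    ``excludes_reference`` flags a reference value outside that band.
    """
    if isinstance(estimates, ReplicationResult):
        if est_variances is None:
            est_variances = estimates.est_variances
        estimates = estimates.estimates
    if len(estimates) < 2:
        raise InvalidParameterError("need >= 2 replicates to summarize")
    if tuple(estimates.columns) != tuple(reference.names):
        raise InvalidParameterError(
            f"coefficient mismatch: estimates {tuple(estimates.columns)} vs "
            f"reference {tuple(reference.names)}"
        )
    R = len(estimates)
    mean_loghr = estimates.mean(axis=0)
    emp_var = estimates.var(axis=0, ddof=1)
    ref = pd.Series(reference.coef, index=list(reference.names))
    bias = mean_loghr - ref
    q025 = estimates.quantile(0.025, axis=0)
    q975 = estimates.quantile(0.975, axis=0)
    out = pd.DataFrame(
        {
            "coefficient": estimates.columns,
            "mean_loghr": mean_loghr.to_numpy(),
            "mean_hr": np.exp(estimates).mean(axis=0).to_numpy(),
            "ref_loghr": ref.to_numpy(),
            "ref_hr": np.exp(ref).to_numpy(),
            "bias": bias.to_numpy(),
            "emp_var": emp_var.to_numpy(),
            "avg_est_var": (
                est_variances.mean(axis=0).to_numpy()
                if est_variances is not None
                else np.full(estimates.shape[1], np.nan)
            ),
            "mse": (emp_var + bias**2).to_numpy(),
            "mc_se": np.sqrt(emp_var.to_numpy() / R),
            "q025": q025.to_numpy(),
            "q975": q975.to_numpy(),
            "excludes_reference": ((ref < q025) | (ref > q975)).to_numpy(),
            "n_replicates": R,
        }
    )
    return out.reset_index(drop=True)


def silverman_bandwidth(x: np.ndarray) -> float:
    """Classic Silverman rule-of-thumb: 0.9 min(sd, IQR/1.34) n^(-1/5)."""
    x = np.asarray(x, dtype=float)
    sd = np.std(x, ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * spread * len(x) ** (-0.2)


def kernel_density(estimates, bandwidth: float | None = None, grid_size: int = 512):
    """Gaussian kernel density of a vector of estimates.

    Returns ``(grid, density)`` with the grid spanning the data +/- 4
    bandwidths.  The emitted curve integrates to 1 within 1e-3 (trapezoid
    rule).  Zero-variance input is rejected - report the point mass directly.
    """
    x = np.asarray(estimates, dtype=float)
    if x.size < 2:
        raise InvalidParameterError("need >= 2 estimates for a density")
    if np.ptp(x) == 0:
        raise InvalidParameterError(
            "zero-variance input: report the point mass directly instead of a density"
        )
    h = silverman_bandwidth(x) if bandwidth is None else float(bandwidth)
    if not h > 0:
        raise InvalidParameterError("bandwidth must be > 0")
    grid = np.linspace(x.min() - 4 * h, x.max() + 4 * h, grid_size)
    z = (grid[:, None] - x[None, :]) / h
    dens = np.exp(-0.5 * z**2).sum(axis=1) / (x.size * h * np.sqrt(2 * np.pi))
    return grid, dens


def density_table(estimates: pd.DataFrame, bandwidth: float | None = None) -> pd.DataFrame:
    """Long-form density curves of the HR estimates, one block per coefficient."""
    blocks = []
    for name in estimates.columns:
        hr = np.exp(estimates[name].to_numpy())
        grid, dens = kernel_density(hr, bandwidth=bandwidth)
        blocks.append(
            pd.DataFrame({"coefficient": name, "hr": grid, "density": dens})
        )
    return pd.concat(blocks, ignore_index=True)


def compare_scenarios(summaries: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Cross-scenario comparison of estimator quality.

    ``summaries`` maps scenario name -> :func:`summarize` output.  Returns a
    long table with, per coefficient, the scenarios ranked by MSE (rank 1 =
    smallest) and the 95% exclusion flag for scenarios whose reference value
    lies outside the central 95% of their replicate estimates.
    """
    if not summaries:
        raise InvalidParameterError("no summaries to compare")
    rows = []
    for name, summ in summaries.items():
        for _, r in summ.iterrows():
            rows.append(
                {
                    "coefficient": r["coefficient"],
                    "scenario": name,
                    "mean_hr": r["mean_hr"],
                    "bias": r["bias"],
                    "emp_var": r["emp_var"],
                    "avg_est_var": r["avg_est_var"],
                    "mse": r["mse"],
                    "excludes_reference": bool(r["excludes_reference"]),
                }
            )
    table = pd.DataFrame(rows)
    shared = table.groupby("coefficient")["scenario"].nunique()
    if (shared >= 2).sum() == 0:
        raise InvalidParameterError("scenarios share no coefficient to compare")
    table["mse_rank"] = (
        table.groupby("coefficient")["mse"].rank(method="min").astype(int)
    )
    return table.sort_values(["coefficient", "mse_rank"]).reset_index(drop=True)


# -- optional figures ------------------------------------------------------------


def plot_density_panel(estimates_by_scenario: dict, coefficient: str, path) -> None:
    """Overlayed HR sampling densities for one coefficient across scenarios."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for name, est in estimates_by_scenario.items():
        hr = np.exp(est[coefficient].to_numpy())
        grid, dens = kernel_density(hr)
        ax.plot(grid, dens, label=name)
    ax.set_xlabel(f"hazard ratio: {coefficient}")
    ax.set_ylabel("density")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_metric_bars(comparison: pd.DataFrame, metric: str, path) -> None:
    """Bar chart of a summary metric (e.g. mse, avg_est_var) by scenario."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    pivot = comparison.pivot(index="coefficient", columns="scenario", values=metric)
    ax = pivot.plot.bar(figsize=(8, 4))
    ax.set_ylabel(metric)
    fig = ax.get_figure()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
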