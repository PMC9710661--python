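"""Monte-Carlo study of clustering accuracy under controlled cohort designs.

Three cohort generators are provided, all with two true subject groups
(default sizes N1 = 60, N2 = 40) and ``n`` cells per subject:

* ``beta-shift-A`` — every cell intensity in Group 1 is drawn from
  Beta(2.17, 300), a sharply peaked, thin-tailed profile; Group 2 draws from
  Beta(alpha', 300) where alpha' is chosen so the distribution's mode exceeds
  the Group-1 mode by l percent.
* ``beta-shift-B`` — the same mode-shift construction on the flatter,
  heavier-tailed base Beta(1.78, 45).
* ``threshold-scheme`` — data generated exactly under the assumptions of the
  two-threshold positivity rule: Group-1 subjects carry a positive-cell
  fraction of exactly t2 (cells above the cutoff t1), Group-2 subjects carry
  strictly more.

Each replication runs the competing stratification methods on the same cohort
— JSD-based hierarchical clustering, 95% / 97.5% pooled-quantile
positivity thresholding with t2 = 0.01, and K-means on the (97.5%, 99%,
99.5%) quantile vector — and scores each against the true groups with the
adjusted Rand index.  Beta draws already live in [0, 1], so no rescaling is
applied to simulated cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from ._errors import InfeasibleShiftError, ParameterError
from .cohort_clustering import (
    ClusterLabels,
    ThresholdParams,
    hierarchical_cluster,
    quantile_cluster,
    threshold_cluster,
)
from .density_distance import estimate_cohort_densities, jsd_matrix

DESIGN_BASES = {
    "beta-shift-A": (2.17, 300.0),
    "beta-shift-B": (1.78, 45.0),
}

ALL_METHODS = ("jsd", "threshold-95", "threshold-97.5", "quantile")


@dataclass
class SimulationConfig:
    """Parameters of one cell of the simulation study."""

    design: str = "beta-shift-A"
    N1: int = 60
    N2: int = 40
    n: int = 200
    l: float = 0.0  # percent mode shift (beta designs)
    alpha: float | None = None
    beta: float | None = None
    t1: float = 0.05  # threshold design: positivity cutoff
    t2: float = 0.01  # threshold design: positive-cell fraction of Group 1
    reps: int = 100
    seed: int = 0
    grid_size: int = 1024
    linkage: str = "complete"
    exact_count: bool = True  # Group-1 positives as an exact count, not binomial
    threshold_t2: float = 0.01  # comparator proportion cutoff
    quantile_levels: tuple[float, ...] = (0.975, 0.99, 0.995)

    def __post_init__(self) -> None:
        if self.design not in (*DESIGN_BASES, "threshold-scheme"):
            raise ParameterError(f"unknown design '{self.design}'")
        if min(self.N1, self.N2, self.n, self.reps) < 1:
            raise ParameterError("N1, N2, n and reps must be >= 1")
        if self.l < 0:
            raise ParameterError("mode shift l must be >= 0")
        if self.design in DESIGN_BASES:
            a0, b0 = DESIGN_BASES[self.design]
            if self.alpha is None:
                self.alpha = a0
            if self.beta is None:
                self.beta = b0
            if self.alpha <= 1 or self.beta <= 1:
                raise ParameterError("mode-shift designs need alpha > 1 and beta > 1")
        else:
            if not (0.0 < self.t1 < 1.0 and 0.0 < self.t2 < 1.0):
                raise ParameterError("threshold design needs t1, t2 in (0, 1)")


@dataclass
class ReplicationResult:
    """Per-replication ARI values plus their means and Monte-Carlo SEs."""

    config: SimulationConfig
    per_rep: pd.DataFrame  # columns: rep, method, ari
    means: dict[str, float] = field(init=False)
    ses: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        g = self.per_rep.groupby("method")["ari"]
        self.means = g.mean().to_dict()
        self.ses = (g.std(ddof=1) / np.sqrt(g.size())).fillna(0.0).to_dict()

    def summary(self) -> pd.DataFrame:
        rows = [
            {"method": m, "mean_ari": self.means[m], "mc_se": self.ses[m]}
            for m in self.means
        ]
        return pd.DataFrame(rows)


def beta_mode_shift(alpha: float, beta: float, l: float) -> float:
    """Shift the mode of Beta(alpha, beta) up by l percent, keeping beta fixed.

    With m1 = (alpha-1)/(alpha+beta-2) and m2 = (1+l/100) m1, the returned
    alpha' solves (alpha'-1)/(alpha'+beta-2) = m2.  Raises when the target
    mode reaches 1, where no Beta with this beta can place its mode.
    """
    if alpha <= 1 or beta <= 1:
        raise ParameterError("mode is interior only for alpha > 1, beta > 1")
    m1 = (alpha - 1.0) / (alpha + beta - 2.0)
    m2 = (1.0 + l / 100.0) * m1
    if m2 >= 1.0:
        raise InfeasibleShiftError(f"target mode {m2:.4f} >= 1 is infeasible")
    alpha_new = (1.0 + m2 * (beta - 2.0)) / (1.0 - m2)
    achieved = (alpha_new - 1.0) / (alpha_new + beta - 2.0)
    assert abs(achieved - m2) < 1e-10
    return alpha_new


def simulate_beta_cohort(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Draw one two-group Beta mode-shift cohort.

    Returns (samples keyed by subject id, true group labels in subject order).
    """
    if config.design not in DESIGN_BASES:
        raise ParameterError("simulate_beta_cohort needs a beta-shift design")
    alpha2 = beta_mode_shift(config.alpha, config.beta, config.l)
    samples: dict[str, np.ndarray] = {}
    labels = np.concatenate(
        [np.zeros(config.N1, dtype=int), np.ones(config.N2, dtype=int)]
    )
    for j in range(config.N1 + config.N2):
        a = config.alpha if labels[j] == 0 else alpha2
        samples[f"S{j + 1:03d}"] = rng.beta(a, config.beta, size=config.n)
    return samples, labels


def simulate_threshold_cohort(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Draw one cohort under the two-threshold generative scheme.

    Group-1 subjects receive exactly round(t2 * n) positive cells; Group-2
    subjects receive a positive fraction drawn uniformly from (t2, 3 t2]
    (capped at 1), always strictly more positives than Group 1.  Positive
    intensities are uniform on (t1, 1], negative ones uniform on [0, t1].
    """
    if config.design != "threshold-scheme":
        raise ParameterError("simulate_threshold_cohort needs the threshold design")
    n, t1, t2 = config.n, config.t1, config.t2
    k1 = int(round(t2 * n))
    if k1 == 0:
        import warnings

        warnings.warn("round(t2*n) = 0: Group-1 positivity vanishes", stacklevel=2)
    samples: dict[str, np.ndarray] = {}
    labels = np.concatenate(
        [np.zeros(config.N1, dtype=int), np.ones(config.N2, dtype=int)]
    )
    for j in range(config.N1 + config.N2):
        if labels[j] == 0:
            k = k1 if config.exact_count else rng.binomial(n, t2)
        else:
            frac = rng.uniform(t2, min(3.0 * t2, 1.0))
            k = max(k1 + 1, int(round(frac * n)))
            k = min(k, n)
        pos = t1 + (1.0 - t1) * rng.uniform(size=k)
        neg = t1 * rng.uniform(size=n - k)
        vals = np.concatenate([pos, neg])
        rng.shuffle(vals)
        samples[f"S{j + 1:03d}"] = vals
    return samples, labels


def _simulate(config, rng):
    if config.design == "threshold-scheme":
        return simulate_threshold_cohort(config, rng)
    return simulate_beta_cohort(config, rng)


def _run_methods(
    samples: dict[str, np.ndarray],
    config: SimulationConfig,
    methods: tuple[str, ...],
    rep_seed: int,
) -> dict[str, ClusterLabels]:
    out: dict[str, ClusterLabels] = {}
    if "jsd" in methods:
        densities = estimate_cohort_densities(
            samples, grid_size=config.grid_size, method="binned"
        )
        D = jsd_matrix(densities)
        out["jsd"] = hierarchical_cluster(D, k=2, linkage_rule=config.linkage)
    if "threshold-95" in methods:
        out["threshold-95"] = threshold_cluster(
            samples, ThresholdParams(t1="q95", t2=config.threshold_t2)
        )
    if "threshold-97.5" in methods:
        out["threshold-97.5"] = threshold_cluster(
            samples, ThresholdParams(t1="q97.5", t2=config.threshold_t2)
        )
    if "threshold-true" in methods:
        out["threshold-true"] = threshold_cluster(
            samples, ThresholdParams(t1=config.t1, t2=config.t2)
        )
    if "quantile" in methods:
        out["quantile"] = quantile_cluster(
            samples,
            quantile_levels=config.quantile_levels,
            k=2,
            seed=rep_seed % (2**31),
        )
    return out


def run_study(
    config: SimulationConfig,
    methods: tuple[str, ...] = ALL_METHODS,
    stream_path: str | None = None,
) -> ReplicationResult:
    """Run the full replication study for one parameter cell.

    One master seed spawns an independent substream per replication, so every
    method within a replication sees the identical cohort.  With
    ``stream_path`` each replication's rows are appended to a tidy CSV
    (columns rep, method, ari) as they complete.
    """
    children = np.random.SeedSequence(config.seed).spawn(config.reps)
    rows: list[dict] = []
    for rep, child in enumerate(children):
        rng = np.random.Generator(np.random.PCG64(child))
        samples, truth = _simulate(config, rng)
        rep_seed = int(child.generate_state(1, np.uint32)[0]) % (2**31)
        labelings = _run_methods(samples, config, methods, rep_seed)
        new = [
            {
                "rep": rep,
                "method": m,
                "ari": float(adjusted_rand_score(truth, lab.labels)),
            }
            for m, lab in labelings.items()
        ]
        rows.extend(new)
        if stream_path is not None:
            pd.DataFrame(new).to_csv(
                stream_path, mode="a", header=(rep == 0), index=False
            )
    return ReplicationResult(config=config, per_rep=pd.DataFrame(rows))


def study_grid(
    design: str,
    n_values: tuple[int, ...] = (200, 2000),
    l_values: tuple[float, ...] = (10, 20, 50, 100, 200),
    reps: int = 100,
    seed: int = 0,
    methods: tuple[str, ...] = ALL_METHODS,
) -> pd.DataFrame:
    """Mean-ARI table over an (n, l) grid, one row per cell, methods as columns."""
    base = SimulationConfig(design=design, reps=reps)
    rows = []
    for i, n in enumerate(n_values):
        for j, l in enumerate(l_values):
            cell_seed = (seed * 10007 + i * 101 + j) % (2**31)
            cfg = replace(base, n=n, l=float(l), seed=cell_seed)
            result = run_study(cfg, methods=methods)
            row = {"n": n, "l": l}
            row.update({m: result.means[m] for m in result.means})
            row.update({f"se_{m}": result.ses[m] for m in result.ses})
            rows.append(row)
    return pd.DataFrame(rows)
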