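"""Monte-Carlo comparison of meta-analytic pooling estimators for correlation matrices.

Studies are simulated by drawing N observations from a multivariate normal
with a known population correlation matrix Sigma, estimating the sample
Pearson correlation matrix, and knocking out entries to mimic unreported
correlations.  Four cellwise pooling estimators are compared by mean squared
error against Sigma:

- ``avg``           unweighted mean of the observed correlations;
- ``fisher_weight`` inverse-variance weighted mean on the Fisher-z scale
                    (weight N - 3, the reciprocal sampling variance of z),
                    back-transformed;
- ``var_weight``    weighted mean of raw correlations with weight
                    var(r)^(-q), var(r) = (1 - r^2)^2 / (N - 1); the
                    exponent q defaults to 2 ("reciprocal square"), with
                    q = 1 available as standard inverse-variance weighting;
- ``zero``          missing cells replaced by 0 in each study, then an
                    unweighted mean over all studies.

Two experiment designs are provided: varying the number of pooled studies
with one randomly-placed missing pair per study (experiment 1), and varying
the probability that one fixed cell is missing with the study count held at
10, scoring only that cell (experiment 2).
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .corematrix import CorMatrix, validate
from .errors import DimensionError, PoolingError, ValidityError

ESTIMATORS = ("avg", "fisher_weight", "var_weight", "zero")

#: Default population correlation matrix of the simulation study.
DEFAULT_SIGMA = np.array(
    [
        [1.0, 0.5, 0.5, 0.0],
        [0.5, 1.0, 0.5, 0.3],
        [0.5, 0.5, 1.0, -0.1],
        [0.0, 0.3, -0.1, 1.0],
    ]
)


# -- elementary transforms ---------------------------------------------------


def fisher_z(r):
    """Fisher's variance-stabilizing transform z = atanh(r); requires |r| < 1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        raise ValidityError("Fisher z requires |r| < 1")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def inv_fisher_z(z):
    """Inverse Fisher transform r = tanh(z)."""
    out = np.tanh(np.asarray(z, dtype=float))
    return float(out) if out.ndim == 0 else out


def correlation_variance(rho, N):
    """Large-sample variance of a Pearson correlation: (1 - rho^2)^2 / (N - 1)."""
    rho = np.asarray(rho, dtype=float)
    N = np.asarray(N)
    if np.any(N < 2):
        raise ValidityError("sample size must be at least 2")
    out = (1.0 - rho**2) ** 2 / (N - 1.0)
    return float(out) if out.ndim == 0 else out


# -- configuration and containers --------------------------------------------


@dataclasses.dataclass
class SimConfig:
    """Configuration of one simulation experiment.

    Defaults reproduce the study conditions: a 4-variable multivariate
    normal with mean zero and the correlation matrix ``DEFAULT_SIGMA``,
    per-study sample sizes drawn as Normal(100, 20) rounded to the nearest
    integer and floored at ``n_min`` = 10, and 1,000 replications.
    """

    mu: np.ndarray = dataclasses.field(default_factory=lambda: np.zeros(4))
    Sigma: np.ndarray = dataclasses.field(default_factory=lambda: DEFAULT_SIGMA.copy())
    n_studies: int = 10
    obs_mean: float = 100.0
    obs_sd: float = 20.0
    missing_mode: str = "random_pair"  # or "fixed_cell"
    fixed_cell: tuple[int, int] = (2, 1)  # 1-based lower-triangle position
    p_missing: float = 0.0
    reps: int = 1000
    seed: int = 0
    n_min: int = 10
    weight_exponent: int = 2

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.Sigma = np.asarray(self.Sigma, dtype=float)
        rep = validate(self.Sigma)
        if not (rep.is_valid and rep.psd):
            raise ValidityError("Sigma must be a valid PSD correlation matrix")
        if self.mu.shape[0] != self.Sigma.shape[0]:
            raise DimensionError(
                f"mu has length {self.mu.shape[0]} but Sigma is {self.Sigma.shape[0]}x"
                f"{self.Sigma.shape[1]}"
            )
        if self.n_studies < 1:
            raise ValidityError("n_studies must be at least 1")
        if not 0.0 <= self.p_missing <= 1.0:
            raise ValidityError(f"p_missing must be in [0, 1], got {self.p_missing}")
        if self.missing_mode not in ("random_pair", "fixed_cell"):
            raise ValidityError(f"unknown missing_mode {self.missing_mode!r}")
        i, j = self.fixed_cell
        if not (1 <= j < i <= self.Sigma.shape[0]):
            raise ValidityError(
                f"fixed_cell must be a 1-based lower-triangle position, got {self.fixed_cell}"
            )
        if self.weight_exponent not in (1, 2):
            raise ValidityError("weight_exponent must be 1 or 2")


@dataclasses.dataclass
class StudySet:
    """Per-study sample correlation matrices (missingness applied) and sample sizes."""

    matrices: list[CorMatrix]
    sample_sizes: list[int]

    @property
    def n_studies(self) -> int:
        return len(self.matrices)


@dataclasses.dataclass
class PoolResult:
    """Pooled matrix and lower-triangle MSE per estimator."""

    pooled: dict[str, CorMatrix]
    mse: dict[str, float]


# -- simulation --------------------------------------------------------------


def simulate_studies(config: SimConfig, rng: np.random.Generator) -> StudySet:
    """Simulate one replication's worth of study correlation matrices.

    Per study: N ~ Normal(obs_mean, obs_sd) rounded and floored at n_min;
    N observations from MVN(mu, Sigma); sample Pearson correlations; then
    missingness — ``random_pair``: one uniformly-chosen lower-triangle cell
    and its mirror set missing per study; ``fixed_cell``: the configured
    cell set missing with probability p_missing.
    """
    p = config.Sigma.shape[0]
    chol = np.linalg.cholesky(
        config.Sigma + 1e-14 * np.eye(p)  # guard against semidefinite Sigma
    )
    tril = np.tril_indices(p, k=-1)
    matrices: list[CorMatrix] = []
    sizes: list[int] = []
    for _ in range(config.n_studies):
        N = max(config.n_min, int(round(rng.normal(config.obs_mean, config.obs_sd))))
        X = config.mu + rng.standard_normal((N, p)) @ chol.T
        R = np.corrcoef(X, rowvar=False)
        if config.missing_mode == "random_pair":
            k = rng.integers(len(tril[0]))
            i, j = int(tril[0][k]), int(tril[1][k])
            R[i, j] = np.nan
            R[j, i] = np.nan
        elif config.p_missing > 0 and rng.random() < config.p_missing:
            i, j = config.fixed_cell[0] - 1, config.fixed_cell[1] - 1
            R[i, j] = np.nan
            R[j, i] = np.nan
        matrices.append(CorMatrix(R, copy=False))
        sizes.append(N)
    return StudySet(matrices=matrices, sample_sizes=sizes)


# -- pooling -----------------------------------------------------------------

_VAR_CLIP = 0.999  # |r| clip inside the variance formula so weights stay finite


def pool(
    studies: StudySet,
    estimator: str,
    *,
    weight_exponent: int = 2,
    on_empty: str = "error",
) -> CorMatrix:
    """Pool study correlation matrices cellwise into one matrix.

    ``on_empty`` controls what happens when a cell is observed in zero
    studies under an estimator that needs data: ``"error"`` (default) raises
    :class:`PoolingError` naming the cell; ``"zero"`` pools the cell as 0
    (the convention the zero estimator uses everywhere).
    """
    if estimator not in ESTIMATORS:
        raise PoolingError(f"unknown estimator {estimator!r}; choose one of {ESTIMATORS}")
    R = np.stack([m.values for m in studies.matrices])  # (n, p, p)
    obs = ~np.isnan(R)
    N = np.asarray(studies.sample_sizes, dtype=float)[:, None, None]
    p = R.shape[1]

    if estimator == "zero":
        pooled = np.where(obs, R, 0.0).mean(axis=0)
    else:
        n_obs = obs.sum(axis=0)
        empty = np.tril(n_obs == 0, k=-1)
        if empty.any():
            if on_empty == "error":
                i, j = np.argwhere(empty)[0]
                raise PoolingError(
                    f"cell ({i + 1}, {j + 1}) is observed in zero studies; "
                    f"the {estimator!r} estimator is undefined there"
                )
        Rz = np.where(obs, R, 0.0)
        if estimator == "avg":
            w = obs.astype(float)
        elif estimator == "fisher_weight":
            w = np.where(obs, N - 3.0, 0.0)
            Rz = np.arctanh(np.clip(Rz, -1 + 1e-15, 1 - 1e-15))
        else:  # var_weight
            r_clip = np.clip(Rz, -_VAR_CLIP, _VAR_CLIP)
            var = (1.0 - r_clip**2) ** 2 / (N - 1.0)
            w = np.where(obs, var ** (-float(weight_exponent)), 0.0)
        wsum = w.sum(axis=0)
        with np.errstate(invalid="ignore"):
            pooled = (w * Rz).sum(axis=0) / wsum
        pooled = np.where(wsum > 0, pooled, 0.0)
        if estimator == "fisher_weight":
            pooled = np.tanh(pooled)

    pooled = (pooled + pooled.T) / 2.0
    np.fill_diagonal(pooled, 1.0)
    return CorMatrix(pooled, copy=False)


def lower_triangle_mse(pooled: CorMatrix, Sigma: CorMatrix | np.ndarray) -> float:
    """Mean squared deviation over the strictly-lower-triangle cells."""
    S = Sigma.values if isinstance(Sigma, CorMatrix) else np.asarray(Sigma, dtype=float)
    if S.shape != pooled.values.shape:
        raise DimensionError(
            f"dimension mismatch: pooled is {pooled.values.shape}, Sigma is {S.shape}"
        )
    idx = np.tril_indices(pooled.p, k=-1)
    d = pooled.values[idx] - S[idx]
    return float(np.mean(d**2))


def pool_all(
    studies: StudySet,
    Sigma: np.ndarray,
    *,
    weight_exponent: int = 2,
    on_empty: str = "error",
) -> PoolResult:
    """Pool with all four estimators and score the lower-triangle MSE."""
    pooled = {
        est: pool(studies, est, weight_exponent=weight_exponent, on_empty=on_empty)
        for est in ESTIMATORS
    }
    mse = {est: lower_triangle_mse(m, Sigma) for est, m in pooled.items()}
    return PoolResult(pooled=pooled, mse=mse)


# -- experiments -------------------------------------------------------------


def run_experiment_1(
    config: SimConfig,
    n_grid: Iterable[int] = range(1, 31),
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Mean lower-triangle MSE per estimator as the study count varies.

    One randomly-placed missing pair per study.  A cell unobserved in every
    study of a replication (certain when n = 1) is pooled as 0 for all
    estimators — the only convention under which the small-n end of the grid
    is defined.

    Returns a tidy frame with columns ``n_studies``, ``estimator``,
    ``mean_mse``, ``reps``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rows = []
    for n in n_grid:
        cfg = dataclasses.replace(config, n_studies=int(n), missing_mode="random_pair")
        acc = {est: 0.0 for est in ESTIMATORS}
        for _ in range(config.reps):
            studies = simulate_studies(cfg, rng)
            result = pool_all(
                studies,
                cfg.Sigma,
                weight_exponent=cfg.weight_exponent,
                on_empty="zero",
            )
            for est in ESTIMATORS:
                acc[est] += result.mse[est]
        for est in ESTIMATORS:
            rows.append(
                {
                    "n_studies": int(n),
                    "estimator": est,
                    "mean_mse": acc[est] / config.reps,
                    "reps": config.reps,
                }
            )
    return pd.DataFrame(rows)


def run_experiment_2(
    config: SimConfig,
    p_grid: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8),
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Mean squared error at one fixed cell as its missingness probability varies.

    Ten studies per replication; only the configured cell (default (2, 1))
    can be missing, with probability p; the squared error is scored on that
    cell alone.  A replication in which the cell is missing in all ten
    studies is redrawn for every estimator (count reported in ``redraws``)
    since the data-dependent estimators are undefined on an empty set.

    Returns a tidy frame with columns ``p_missing``, ``estimator``,
    ``mean_mse``, ``reps``, ``redraws``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    i, j = config.fixed_cell
    truth = config.Sigma[i - 1, j - 1]
    rows = []
    for pm in p_grid:
        cfg = dataclasses.replace(
            config, missing_mode="fixed_cell", p_missing=float(pm), n_studies=10
        )
        acc = {est: 0.0 for est in ESTIMATORS}
        redraws = 0
        done = 0
        while done < config.reps:
            studies = simulate_studies(cfg, rng)
            all_missing = all(
                np.isnan(m.values[i - 1, j - 1]) for m in studies.matrices
            )
            if all_missing:
                redraws += 1
                continue
            for est in ESTIMATORS:
                pooled = pool(studies, est, weight_exponent=cfg.weight_exponent)
                acc[est] += (pooled.values[i - 1, j - 1] - truth) ** 2
            done += 1
        for est in ESTIMATORS:
            rows.append(
                {
                    "p_missing": float(pm),
                    "estimator": est,
                    "mean_mse": acc[est] / config.reps,
                    "reps": config.reps,
                    "redraws": redraws,
                }
            )
    return pd.DataFrame(rows)


def plot_experiment(df: pd.DataFrame, path, *, x: str | None = None) -> None:
    """Line plot of mean MSE per estimator over the experiment grid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if x is None:
        x = "n_studies" if "n_studies" in df.columns else "p_missing"
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for est, sub in df.groupby("estimator"):
        ax.plot(sub[x], sub["mean_mse"], marker="o", label=est)
    ax.set_xlabel(x)
    ax.set_ylabel("mean MSE")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
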