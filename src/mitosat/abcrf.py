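"""ABC random forests: reference tables, model choice, parameter estimation.

Model choice trains a classification forest on simulated summary statistics
(augmented with linear-discriminant projections) labelled by scenario; the
share of trees voting for each scenario on the observed statistics gives the
vote percentages, the out-of-bag misclassification rate is the prior error
rate, and the posterior probability of the selected scenario is estimated by
a regression forest fitted to the out-of-bag correctness indicators.

Parameter estimation uses quantile regression forests: the training points
sharing leaves with the observed dataset define a weighted posterior sample
from which expectation, median, variance and credible quantiles are read.
Validation on pseudo-observed datasets (PODs) reports normalised errors and
credible-interval coverage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .coalsim import (
    MarkerConfig,
    PriorSpec,
    ScenarioSpec,
    sample_prior,
    simulate_joint,
)
from .sumstats import STAT_NAMES, summarize_pair

logger = logging.getLogger(__name__)

#: parameters whose priors are log-uniform are estimated on the log10 scale
LOG10_PARAMS = frozenset(
    {"n1_sat", "n2_sat", "nanc_sat", "n1_mt", "n2_mt", "nanc_mt", "t2",
     "m12_sat", "m21_sat", "m12_mt", "m21_mt", "mu_sat", "mu_mt"}
)


@dataclass
class ReferenceTable:
    """Simulated (scenario, parameters, summary statistics) rows.

    ``df`` holds one row per simulated dataset: a ``scenario`` column,
    ``param_*`` columns and the 19 statistic columns, plus ``lda_*``
    projections once :func:`append_lda` has run.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ("scenario", *STAT_NAMES) if c not in self.df.columns]
        if missing:
            raise ValueError(f"reference table lacks columns: {missing}")
        if self.df[list(STAT_NAMES)].isna().any().any():
            raise ValueError("reference table contains missing statistics")

    @property
    def stat_cols(self) -> list[str]:
        return list(STAT_NAMES)

    @property
    def lda_cols(self) -> list[str]:
        return [c for c in self.df.columns if c.startswith("lda_")]

    @property
    def feature_cols(self) -> list[str]:
        return self.stat_cols + self.lda_cols

    @property
    def param_cols(self) -> list[str]:
        return [c for c in self.df.columns if c.startswith("param_")]

    @property
    def scenarios(self) -> list[int]:
        return sorted(self.df["scenario"].unique())

    def subset_scenario(self, scenario_id: int) -> "ReferenceTable":
        return ReferenceTable(
            self.df[self.df["scenario"] == scenario_id].reset_index(drop=True)
        )


def simulate_reference_row(
    scenario: ScenarioSpec,
    prior: PriorSpec,
    config: MarkerConfig,
    rng: np.random.Generator,
) -> dict[str, float]:
    params = sample_prior(prior, rng)
    table, alignment = simulate_joint(scenario, params, config, rng)
    stats = summarize_pair(table, alignment)
    row: dict[str, float] = {"scenario": scenario.scenario_id}
    row.update({f"param_{k}": v for k, v in params.as_dict().items()})
    row.update(stats.as_dict())
    return row


def build_reference(
    prior: PriorSpec,
    scenarios: list[int],
    n_per_scenario: int,
    config: MarkerConfig,
    rng: np.random.Generator,
) -> ReferenceTable:
    """Simulate ``n_per_scenario`` paired datasets per scenario and reduce
    each to its summary statistics; rows are shuffled. A failed simulation
    is retried with the next generator substream (and logged)."""
    rows = []
    for sid in scenarios:
        scenario = ScenarioSpec(sid)
        done = 0
        while done < n_per_scenario:
            try:
                rows.append(simulate_reference_row(scenario, prior, config, rng))
            except Exception:  # pragma: no cover - defensive retry
                logger.warning("simulation failed, retrying", exc_info=True)
                continue
            done += 1
    df = pd.DataFrame(rows)
    perm = rng.permutation(len(df))
    return ReferenceTable(df.iloc[perm].reset_index(drop=True))


def prior_range_check(reference: ReferenceTable, observed: np.ndarray) -> pd.DataFrame:
    """Does each observed statistic fall inside the simulated min-max
    envelope? One row per statistic with the envelope and a flag."""
    lo = reference.df[reference.stat_cols].min()
    hi = reference.df[reference.stat_cols].max()
    obs = pd.Series(np.asarray(observed, dtype=float), index=reference.stat_cols)
    return pd.DataFrame(
        {"observed": obs, "sim_min": lo, "sim_max": hi,
         "inside": (obs >= lo) & (obs <= hi)}
    )


def append_lda(
    reference: ReferenceTable, observed: np.ndarray
) -> tuple[ReferenceTable, np.ndarray]:
    """Fit an LDA on the reference statistics with scenario labels and
    append the (n_scenarios - 1) discriminant projections to every row and
    to the observed vector."""
    if len(reference.scenarios) < 2:
        raise ValueError("need >= 2 scenarios for LDA")
    x = reference.df[reference.stat_cols].to_numpy()
    y = reference.df["scenario"].to_numpy()
    lda = LinearDiscriminantAnalysis(solver="svd")
    try:
        proj = lda.fit_transform(x, y)
    except np.linalg.LinAlgError:  # pragma: no cover - degenerate scatter
        logger.warning("singular within-class scatter; refitting with shrinkage")
        lda = LinearDiscriminantAnalysis(solver="eigen", shrinkage="auto")
        proj = lda.fit_transform(x, y)
    df = reference.df.copy()
    for j in range(proj.shape[1]):
        df[f"lda_{j + 1}"] = proj[:, j]
    obs = np.asarray(observed, dtype=float).reshape(1, -1)
    obs_proj = lda.transform(obs)
    return ReferenceTable(df), np.concatenate([obs.ravel(), obs_proj.ravel()])


@dataclass
class ModelChoiceResult:
    votes: dict[int, float]  # percent of trees per scenario
    selected: int
    posterior_probability: float
    prior_error_rate: float
    votes_se: dict[int, float] = field(default_factory=dict)
    replicates: list["ModelChoiceResult"] = field(default_factory=list)


def rf_model_choice(
    reference: ReferenceTable,
    observed: np.ndarray,
    n_trees: int = 500,
    rng: np.random.Generator | None = None,
    compute_posterior: bool = True,
) -> ModelChoiceResult:
    """Classification-forest model choice on one observed vector.

    Vote percentages sum to 100; ties in the argmax go to the lowest
    scenario id (logged). The posterior probability of the selected
    scenario is the regression-forest estimate of P(selected correctly |
    statistics) built from out-of-bag correctness indicators.
    """
    rng = np.random.default_rng() if rng is None else rng
    if len(reference.scenarios) < 2:
        raise ValueError("model choice needs >= 2 scenarios in the reference")
    x = reference.df[reference.feature_cols].to_numpy()
    y = reference.df["scenario"].to_numpy()
    seed = int(rng.integers(0, 2**31 - 1))
    clf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    clf.fit(x, y)
    obs = np.asarray(observed, dtype=float).reshape(1, -1)
    # trees predict encoded class indices; map back to scenario ids
    tree_votes = clf.classes_[
        np.array([int(tree.predict(obs)[0]) for tree in clf.estimators_])
    ]
    votes = {
        int(s): 100.0 * float(np.mean(tree_votes == s)) for s in reference.scenarios
    }
    best = max(votes.values())
    winners = sorted(s for s, v in votes.items() if v == best)
    if len(winners) > 1:
        logger.info("vote tie between scenarios %s; selecting lowest id", winners)
    selected = winners[0]
    oob = clf.oob_decision_function_
    valid = ~np.isnan(oob).any(axis=1)
    oob_pred = clf.classes_[np.argmax(oob[valid], axis=1)]
    correct = (oob_pred == y[valid]).astype(float)
    prior_error = float(1.0 - correct.mean())
    if compute_posterior:
        reg = RandomForestRegressor(
            n_estimators=n_trees, max_features=1 / 3, random_state=seed + 1,
            n_jobs=1,
        )
        reg.fit(x[valid], correct)
        posterior = float(np.clip(reg.predict(obs)[0], 0.0, 1.0))
    else:
        posterior = float("nan")
    return ModelChoiceResult(votes, selected, posterior, prior_error)


def replicate_model_choice(
    reference_pool: ReferenceTable,
    observed: np.ndarray,
    n_rep: int = 10,
    subsample: int = 20000,
    n_trees: int = 500,
    rng: np.random.Generator | None = None,
) -> ModelChoiceResult:
    """Replicate model choice on independent scenario-balanced subsamples
    of the pool; votes are averaged (with their standard errors) and the
    winner is the scenario with the highest mean vote."""
    rng = np.random.default_rng() if rng is None else rng
    n_pool = len(reference_pool.df)
    if subsample > n_pool:
        raise ValueError("subsample larger than the reference pool")
    per_scenario = subsample // len(reference_pool.scenarios)
    reps: list[ModelChoiceResult] = []
    for _ in range(n_rep):
        if subsample == n_pool:
            ref = reference_pool
        else:
            parts = []
            for sid in reference_pool.scenarios:
                block = reference_pool.df[reference_pool.df["scenario"] == sid]
                take = rng.choice(len(block), size=min(per_scenario, len(block)), replace=False)
                parts.append(block.iloc[take])
            ref = ReferenceTable(
                pd.concat(parts).sample(frac=1.0, random_state=int(rng.integers(2**31 - 1))).reset_index(drop=True)
            )
        reps.append(rf_model_choice(ref, observed, n_trees=n_trees, rng=rng))
    scenarios = reference_pool.scenarios
    vote_mat = np.array([[r.votes[s] for s in scenarios] for r in reps])
    mean_votes = {s: float(vote_mat[:, j].mean()) for j, s in enumerate(scenarios)}
    se_votes = {
        s: float(vote_mat[:, j].std(ddof=1) / np.sqrt(n_rep)) if n_rep > 1 else 0.0
        for j, s in enumerate(scenarios)
    }
    best = max(mean_votes.values())
    selected = min(s for s, v in mean_votes.items() if v == best)
    return ModelChoiceResult(
        mean_votes,
        selected,
        float(np.mean([r.posterior_probability for r in reps])),
        float(np.mean([r.prior_error_rate for r in reps])),
        votes_se=se_votes,
        replicates=reps,
    )


# ---------------------------------------------------------------------------
# quantile-forest parameter estimation
# ---------------------------------------------------------------------------

def _qrf_weights(forest: RandomForestRegressor, x_train: np.ndarray, x_query: np.ndarray) -> np.ndarray:
    """Leaf-co-membership posterior weights, shape (n_query, n_train)."""
    leaves_train = forest.apply(x_train)  # (n, trees)
    leaves_query = forest.apply(x_query)  # (m, trees)
    n, m = x_train.shape[0], x_query.shape[0]
    w = np.zeros((m, n))
    for t in range(leaves_train.shape[1]):
        lt = leaves_train[:, t]
        order = np.argsort(lt, kind="stable")
        sorted_leaves = lt[order]
        uniq, starts, counts = np.unique(
            sorted_leaves, return_index=True, return_counts=True
        )
        pos = np.searchsorted(uniq, leaves_query[:, t])
        for q in range(m):
            j = pos[q]
            if j < len(uniq) and uniq[j] == leaves_query[q, t]:
                members = order[starts[j] : starts[j] + counts[j]]
                w[q, members] += 1.0 / counts[j]
    return w / leaves_train.shape[1]


def _weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cw = np.cumsum(w)
    cw /= cw[-1]
    return float(np.interp(q, cw, v))


@dataclass
class ParamEstimate:
    """Posterior summaries per parameter (log10 scale where the prior is
    log-uniform) plus optional POD validation metrics."""

    estimates: pd.DataFrame  # index=param, cols=expectation/median/variance/q025/q975/oob_mse
    log10_scale: dict[str, bool]
    validation: pd.DataFrame | None = None  # NMSE/NMAE/CI metrics per param

    def point(self, param: str, kind: str = "expectation") -> float:
        return float(self.estimates.loc[param, kind])

    def natural(self, param: str, kind: str = "expectation") -> float:
        """Back-transformed point estimate (10**x for log10 parameters)."""
        v = self.point(param, kind)
        return 10**v if self.log10_scale[param] else v


class ParamEstimator:
    """Quantile regression forests for the parameters of one scenario."""

    def __init__(self, n_trees: int = 500, params: list[str] | None = None) -> None:
        self.n_trees = n_trees
        self.params = params
        self.forests: dict[str, RandomForestRegressor] = {}
        self.y_train: dict[str, np.ndarray] = {}
        self.x_train: np.ndarray | None = None
        self.log10_scale: dict[str, bool] = {}
        self.feature_cols: list[str] | None = None

    def fit(self, reference: ReferenceTable, rng: np.random.Generator | None = None) -> "ParamEstimator":
        if len(reference.scenarios) != 1:
            raise ValueError("parameter estimation expects a single-scenario reference")
        rng = np.random.default_rng() if rng is None else rng
        self.feature_cols = reference.feature_cols
        x = reference.df[self.feature_cols].to_numpy()
        self.x_train = x
        names = self.params or [c.removeprefix("param_") for c in reference.param_cols]
        for name in names:
            col = reference.df[f"param_{name}"].to_numpy(dtype=float)
            if col.std() == 0.0 and name in ("p_gsm", "kappa_like", "t1", "m12_sat",
                                             "m21_sat", "m12_mt", "m21_mt"):
                continue  # fixed by the prior / unused by the scenario
            log_scale = name in LOG10_PARAMS and (col > 0).all()
            y = np.log10(col) if log_scale else col
            # regression forests use the field's regression default
            # mtry = p/3 (the sqrt(p) rule belongs to classification)
            forest = RandomForestRegressor(
                n_estimators=self.n_trees,
                max_features=1 / 3,
                oob_score=True,
                random_state=int(rng.integers(0, 2**31 - 1)),
                n_jobs=1,
            )
            forest.fit(x, y)
            self.forests[name] = forest
            self.y_train[name] = y
            self.log10_scale[name] = log_scale
        return self

    def estimate(self, observed: np.ndarray) -> ParamEstimate:
        obs = np.asarray(observed, dtype=float).reshape(1, -1)
        rows = {}
        for name, forest in self.forests.items():
            y = self.y_train[name]
            w = _qrf_weights(forest, self.x_train, obs)[0]
            if y.std() == 0.0:
                exp = med = float(y[0])
                var = 0.0
                q025 = q975 = float(y[0])
            else:
                exp = float(np.sum(w * y))
                med = _weighted_quantile(y, w, 0.5)
                var = float(np.sum(w * (y - exp) ** 2))
                q025 = _weighted_quantile(y, w, 0.025)
                q975 = _weighted_quantile(y, w, 0.975)
            oob = forest.oob_prediction_
            rows[name] = {
                "expectation": exp,
                "median": med,
                "variance": var,
                "q025": q025,
                "q975": q975,
                "oob_mse": float(np.mean((oob - y) ** 2)),
            }
        return ParamEstimate(pd.DataFrame.from_dict(rows, orient="index"),
                             dict(self.log10_scale))

    def estimate_batch(self, observed: np.ndarray) -> dict[str, pd.DataFrame]:
        """Point estimates and credible bounds for many query vectors at
        once; returns per-parameter DataFrames with one row per query."""
        obs = np.asarray(observed, dtype=float)
        out: dict[str, pd.DataFrame] = {}
        for name, forest in self.forests.items():
            y = self.y_train[name]
            w = _qrf_weights(forest, self.x_train, obs)
            exp = w @ y
            med = np.array([_weighted_quantile(y, w[i], 0.5) for i in range(len(obs))])
            q025 = np.array([_weighted_quantile(y, w[i], 0.025) for i in range(len(obs))])
            q975 = np.array([_weighted_quantile(y, w[i], 0.975) for i in range(len(obs))])
            out[name] = pd.DataFrame(
                {"expectation": exp, "median": med, "q025": q025, "q975": q975}
            )
        return out


def rf_param_estimate(
    reference: ReferenceTable,
    observed: np.ndarray,
    n_trees: int = 500,
    params: list[str] | None = None,
    rng: np.random.Generator | None = None,
) -> ParamEstimate:
    """Convenience wrapper: fit a :class:`ParamEstimator` on a single-
    scenario reference and summarise the posterior at the observed vector."""
    est = ParamEstimator(n_trees=n_trees, params=params).fit(reference, rng=rng)
    return est.estimate(observed)


def validate_pods(
    estimator: ParamEstimator,
    pod_stats: np.ndarray,
    pod_truth: pd.DataFrame,
    batches: dict[str, pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """Validation metrics over pseudo-observed datasets with known truth.

    Per parameter (on the estimation scale): ``NMSE = mean((est-true)^2) /
    var(true)``; ``NMAE = mean|est-true| / mean|true - mean(true)|``;
    relative CI width ``(q97.5 - q2.5)/|median|`` summarised by mean and
    median; empirical coverage of the nominal 95% interval. Precomputed
    ``estimate_batch`` output may be passed to avoid recomputation.
    """
    if batches is None:
        batches = estimator.estimate_batch(pod_stats)
    rows = {}
    for name, est in batches.items():
        truth = pod_truth[name].to_numpy(dtype=float)
        if estimator.log10_scale[name]:
            truth = np.log10(truth)
        err = est["expectation"].to_numpy() - truth
        var_truth = truth.var()
        mad_truth = np.abs(truth - truth.mean()).mean()
        med = est["median"].to_numpy()
        width = est["q975"].to_numpy() - est["q025"].to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            rel_ci = np.where(med != 0, width / np.abs(med), np.nan)
        cover = (
            (truth >= est["q025"].to_numpy()) & (truth <= est["q975"].to_numpy())
        ).mean()
        rows[name] = {
            "nmse": float((err**2).mean() / var_truth) if var_truth > 0 else np.nan,
            "nmae": float(np.abs(err).mean() / mad_truth) if mad_truth > 0 else np.nan,
            "mean_rel_ci": float(np.nanmean(rel_ci)),
            "median_rel_ci": float(np.nanmedian(rel_ci)),
            "coverage_95": float(cover),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
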