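"""Random-forest inference stack with shadow-feature importance ranking.

The procedure mirrors a common ecological workflow: random-forest models
scored out-of-bag (percent variance explained for regression; prediction
accuracy = 100 − OOB error for classification), a shadow-feature wrapper that
confirms or rejects predictors by comparing their importance to shuffled
copies of the data (Boruta-style), collinearity handled by fitting month and
water-temperature variants separately and reporting the better one, and a
Dunnett–Tukey–Kramer (DTK) pairwise post-hoc test — Tukey–Kramer generalized
to unequal group sizes and variances via Welch–Satterthwaite degrees of
freedom and studentized-range critical values — to order factor levels.

Targeted species models (restricted to each species' calling season and
circadian window) and seasonal sound-producer contribution models complete
the stack.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

log = logging.getLogger(__name__)

MIN_ROWS = 50

CATEGORICAL = ("station", "lunar_phase", "tidal_phase", "diel", "weekday",
               "season", "month")


class InsufficientDataError(ValueError):
    pass


class DegenerateModelError(ValueError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    response: str
    predictors: tuple[str, ...]
    task: str = "regression"             # or "classification"
    n_trees: int = 500
    rng_seed: int = 42
    alpha: float = 0.01
    max_iter: int = 100

    def __post_init__(self) -> None:
        if not self.predictors:
            raise ValueError("predictors must be non-empty")
        if "month" in self.predictors and "water_temp_c" in self.predictors:
            raise ValueError("month and water_temp_c are collinear; "
                             "fit them in separate model variants")
        if self.task not in ("regression", "classification"):
            raise ValueError(f"unknown task {self.task!r}")


@dataclass
class ImportanceResult:
    """Shadow-ranking outcome: per-predictor Z statistics vs the shadow pool,
    a confirmed/rejected/tentative decision, and the OOB model score."""

    spec: ModelSpec
    table: pd.DataFrame        # predictor, mean_z, min_z, max_z, decision
    score: float               # % variance explained or prediction accuracy
    label: str = ""

    def decision(self, predictor: str) -> str:
        return self.table.set_index("predictor").loc[predictor, "decision"]

    @property
    def confirmed(self) -> list[str]:
        t = self.table
        return t.loc[t["decision"] == "confirmed", "predictor"].tolist()

    @property
    def rejected(self) -> list[str]:
        t = self.table
        return t.loc[t["decision"] == "rejected", "predictor"].tolist()


@dataclass
class PosthocResult:
    factor: str
    pairs: pd.DataFrame        # level_a, level_b, diff, lower, upper, significant
    ordering: list[str]        # levels by descending group mean
    means: dict

    def significant_pair(self, a, b) -> bool:
        p = self.pairs
        row = p.loc[((p["level_a"] == a) & (p["level_b"] == b))
                    | ((p["level_a"] == b) & (p["level_b"] == a))]
        if row.empty:
            raise KeyError((a, b))
        return bool(row.iloc[0]["significant"])


# ----------------------------------------------------------------------------
# Design matrix and random-forest fit
# ----------------------------------------------------------------------------

def _design_matrix(table: pd.DataFrame, predictors: tuple[str, ...]) -> pd.DataFrame:
    """Numeric design matrix; categoricals ordinal-encoded over their sorted
    observed levels (deterministic, one column per predictor so importances
    map one-to-one)."""
    X = pd.DataFrame(index=table.index)
    for col in predictors:
        s = table[col]
        if col in CATEGORICAL or s.dtype == object or isinstance(
                s.dtype, pd.CategoricalDtype):
            cats = pd.Index(sorted(pd.unique(s.dropna().astype(str))))
            X[col] = pd.Categorical(s.astype(str), categories=cats).codes
        else:
            X[col] = pd.to_numeric(s)
    return X


def _complete_rows(table: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    cols = [spec.response, *spec.predictors]
    sub = table[cols].dropna()
    if "missing_env" in table:
        sub = sub.loc[~table.loc[sub.index, "missing_env"].astype(bool)]
    return sub


def _new_forest(spec: ModelSpec, seed: int, oob: bool):
    # Ecosystem defaults for ecological random forests: mtry = p/3 and
    # node size 5 for regression, mtry = sqrt(p) and node size 1 for
    # classification.
    kw = dict(n_estimators=spec.n_trees, random_state=seed,
              oob_score=oob, bootstrap=True, n_jobs=1)
    if spec.task == "regression":
        return RandomForestRegressor(max_features=1 / 3, min_samples_leaf=5,
                                     **kw)
    return RandomForestClassifier(max_features="sqrt", **kw)


def _oob_z_importance(forest, X: np.ndarray, y: np.ndarray, task: str,
                      rng: np.random.Generator) -> np.ndarray:
    """Permutation-importance Z-scores from out-of-bag samples.

    For each tree, the increase in OOB error (MSE or misclassification rate)
    after permuting one column; the Z-score is the across-tree mean divided
    by its standard error — the scaled mean-decrease-accuracy measure.
    """
    n, p = X.shape
    diffs = np.full((len(forest.estimators_), p), np.nan)
    for ti, (tree, samp) in enumerate(zip(forest.estimators_,
                                          forest.estimators_samples_)):
        mask = np.ones(n, dtype=bool)
        mask[samp] = False
        idx = np.nonzero(mask)[0]
        if idx.size < 3:
            continue
        Xo, yo = X[idx], y[idx]
        pred = tree.predict(Xo)
        if task == "regression":
            base = float(np.mean((yo - pred) ** 2))
        else:
            base = float(np.mean(pred != yo))
        perm = rng.permutation(idx.size)
        for j in range(p):
            Xp = Xo.copy()
            Xp[:, j] = Xo[perm, j]
            pj = tree.predict(Xp)
            if task == "regression":
                err = float(np.mean((yo - pj) ** 2))
            else:
                err = float(np.mean(pj != yo))
            diffs[ti, j] = err - base
    mean = np.nanmean(diffs, axis=0)
    sd = np.nanstd(diffs, axis=0, ddof=1)
    count = np.sum(~np.isnan(diffs), axis=0)
    se = np.where(sd > 0, sd / np.sqrt(np.maximum(count, 1)), np.inf)
    return np.where(np.isfinite(se), mean / se, 0.0)


def fit_rf(spec: ModelSpec, table: pd.DataFrame):
    """Fit the random forest and return ``(model, score)``.

    Score is the OOB percent variance explained (regression) or OOB
    prediction accuracy in percent (classification); both are what one gets
    by subtracting the OOB error estimate from 100%.
    """
    sub = _complete_rows(table, spec)
    if len(sub) < MIN_ROWS:
        raise InsufficientDataError(
            f"{len(sub)} complete rows; need at least {MIN_ROWS}")
    y = sub[spec.response]
    if y.nunique() < 2:
        raise DegenerateModelError(f"response {spec.response} is constant")
    X = _design_matrix(sub, spec.predictors)
    model = _new_forest(spec, spec.rng_seed, oob=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X.to_numpy(), y.to_numpy())
    score = 100.0 * float(model.oob_score_)
    return model, score


# ----------------------------------------------------------------------------
# Shadow-feature (Boruta-style) ranking
# ----------------------------------------------------------------------------

def shadow_rank(spec: ModelSpec, table: pd.DataFrame,
                max_iter: int | None = None,
                rough_fix: bool = False,
                subsample: float = 2 / 3) -> ImportanceResult:
    """Iterative shadow-feature selection.

    Each iteration draws a fresh row subsample (fraction ``subsample``,
    mirroring the two-thirds bootstrap-training convention), appends a
    shuffled (shadow) copy of every live predictor, fits a forest, and
    computes OOB permutation-importance Z-scores for real and shadow
    columns; a predictor scores a "hit" when its Z beats the best shadow Z.
    The per-iteration subsample decorrelates chance associations between
    iterations, so persistent hits reflect real structure.  The shadow pool is kept at five or more columns (padded with
    extra shuffled copies) so the best-shadow bar stays meaningful.  Hits are
    tested against a fair coin with one-sided binomial tests at
    ``spec.alpha``, Bonferroni-corrected over the number of predictors:
    reliably above half → confirmed, reliably below → rejected (and dropped
    from the design).  Predictors still undecided when the iteration budget
    runs out are tentative; with ``rough_fix`` they are resolved by comparing
    their median Z to the median best-shadow Z (the ecosystem's standard
    tentative rough fix).  The reported Z statistics are the per-iteration
    importance Z-scores; the model score comes from an OOB fit on the
    original predictors only.
    """
    if max_iter is None:
        max_iter = spec.max_iter
    sub = _complete_rows(table, spec)
    if len(sub) < MIN_ROWS:
        raise InsufficientDataError(
            f"{len(sub)} complete rows; need at least {MIN_ROWS}")
    y = sub[spec.response].to_numpy()
    X_full = _design_matrix(sub, spec.predictors)
    rng = np.random.default_rng(spec.rng_seed)

    predictors = list(spec.predictors)
    decision = {p: "tentative" for p in predictors}
    undecided = set(predictors)
    alive = list(predictors)          # everything not rejected stays in the fit
    hits = {p: 0 for p in predictors}
    tested = {p: 0 for p in predictors}
    z_history: dict[str, list[float]] = {p: [] for p in predictors}

    alpha_adj = spec.alpha / len(predictors)   # Bonferroni over attributes
    min_shadows = 5
    shadow_max_history: list[float] = []
    n_rows = len(sub)
    for _ in range(max_iter):
        if not undecided:
            break
        if subsample < 1.0:
            rows = rng.choice(n_rows, size=max(int(subsample * n_rows),
                                               MIN_ROWS // 2),
                              replace=False)
        else:
            rows = np.arange(n_rows)
        y_it = y[rows]
        X = X_full[alive].to_numpy()[rows]
        base = X.copy()
        n_pad = max(min_shadows - len(alive), 0)
        if n_pad:
            extra = base[:, rng.integers(0, len(alive), size=n_pad)]
            base = np.hstack([base, extra])
        shadows = base.copy()
        for j in range(shadows.shape[1]):
            rng.shuffle(shadows[:, j])
        design = np.hstack([X, shadows])
        forest = _new_forest(spec, int(rng.integers(2**31 - 1)), oob=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            forest.fit(design, y_it)
        z = _oob_z_importance(forest, design, y_it, spec.task, rng)
        real, shadow = z[: len(alive)], z[len(alive):]
        sh_max = shadow.max()
        shadow_max_history.append(float(sh_max))
        for j, p in enumerate(alive):
            z_history[p].append(real[j])
            if p in undecided:
                tested[p] += 1
                hits[p] += bool(real[j] > sh_max)
        # Binomial decisions on accumulated hits.
        for p in list(undecided):
            n_t, k = tested[p], hits[p]
            if stats.binom.sf(k - 1, n_t, 0.5) < alpha_adj:
                decision[p] = "confirmed"
                undecided.discard(p)
            elif stats.binom.cdf(k, n_t, 0.5) < alpha_adj:
                decision[p] = "rejected"
                undecided.discard(p)
                alive.remove(p)

    if rough_fix and undecided and shadow_max_history:
        bar = float(np.median(shadow_max_history))
        for p in list(undecided):
            decision[p] = ("confirmed" if np.median(z_history[p]) > bar
                           else "rejected")
    rows = []
    for p in predictors:
        zs = z_history[p] or [np.nan]
        rows.append({"predictor": p, "mean_z": float(np.mean(zs)),
                     "min_z": float(np.min(zs)), "max_z": float(np.max(zs)),
                     "decision": decision[p]})
    out = pd.DataFrame(rows).sort_values("mean_z", ascending=False,
                                         ignore_index=True)
    _, score = fit_rf(spec, table)
    return ImportanceResult(spec, out, score)


def select_month_or_temp(spec_base: ModelSpec, table: pd.DataFrame,
                         max_iter: int | None = None) -> ImportanceResult:
    """Fit the month and water-temperature variants separately (they are
    collinear) and return the higher-scoring shadow ranking; ties go to the
    temperature variant."""
    others = tuple(p for p in spec_base.predictors
                   if p not in ("month", "water_temp_c"))
    res_t = shadow_rank(replace(spec_base,
                                predictors=("water_temp_c", *others)),
                        table, max_iter)
    res_t.label = "temperature"
    res_m = shadow_rank(replace(spec_base, predictors=("month", *others)),
                        table, max_iter)
    res_m.label = "month"
    return res_m if res_m.score > res_t.score else res_t


# ----------------------------------------------------------------------------
# Dunnett–Tukey–Kramer post-hoc
# ----------------------------------------------------------------------------

def dtk_posthoc(values, group_labels, conf: float = 0.95,
                factor: str = "") -> PosthocResult:
    """All-pairs DTK comparisons with simultaneous confidence intervals.

    For groups i, j the interval is ``(mi − mj) ± q/√2 · √(si²/ni + sj²/nj)``
    with q the studentized-range quantile at the pairwise Welch–Satterthwaite
    degrees of freedom; a pair is significant iff its interval excludes 0.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    groups = pd.unique(labels)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    stats_by = {}
    for g in groups:
        x = values[labels == g]
        if x.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
        stats_by[g] = (x.mean(), x.var(ddof=1), x.size)
    k = len(groups)
    rows = []
    for a, b in itertools.combinations(groups, 2):
        ma, va, na = stats_by[a]
        mb, vb, nb = stats_by[b]
        se2 = va / na + vb / nb
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        q = stats.studentized_range.ppf(conf, k, df)
        half = q / np.sqrt(2.0) * np.sqrt(se2)
        diff = ma - mb
        rows.append({"level_a": a, "level_b": b, "diff": diff,
                     "lower": diff - half, "upper": diff + half,
                     "significant": bool(diff - half > 0 or diff + half < 0)})
    means = {g: stats_by[g][0] for g in groups}
    ordering = sorted(groups, key=lambda g: -means[g])
    return PosthocResult(factor, pd.DataFrame(rows), list(ordering), means)


def noise_direction(result: PosthocResult) -> str:
    """Direction label for a binary noise factor: '0 > 1' when the quiet
    group mean is significantly higher, '1 > 0' for the reverse, else
    '0 = 1' (0 = no noise; 1 = noise present)."""
    sig = result.significant_pair(0, 1)
    if not sig:
        return "0 = 1"
    return "0 > 1" if result.means[0] > result.means[1] else "1 > 0"


# ----------------------------------------------------------------------------
# Targeted species models
# ----------------------------------------------------------------------------

#: Calling season (months) and circadian window (local hours, wrap-around)
#: used when confirming noise effects per species.
TARGETED_WINDOWS: dict[str, tuple[frozenset[int], tuple[float, float] | None]] = {
    "black_drum": (frozenset({3, 4}), (15.0, 0.0)),
    "oyster_toadfish": (frozenset({3, 4, 5, 6}), None),
    "silver_perch": (frozenset({3, 4, 5, 6}), (15.0, 5.0)),
    "spotted_seatrout": (frozenset({3, 4, 5, 6, 7, 8, 9}), (14.0, 2.0)),
    "red_drum": (frozenset({8, 9, 10}), (13.0, 20.0)),
    "dolphin": (frozenset({11, 12, 1, 2}), None),
}


@dataclass
class TargetedResult:
    species: str
    direction: str
    posthoc: PosthocResult
    importance: ImportanceResult | None
    n_rows: int


def _in_window(hours: np.ndarray, window: tuple[float, float] | None) -> np.ndarray:
    if window is None:
        return np.ones_like(hours, dtype=bool)
    lo, hi = window
    if lo <= hi:
        return (hours >= lo) & (hours < hi)
    return (hours >= lo) | (hours < hi)


def targeted_model(species: str, annotations: pd.DataFrame,
                   covariates: pd.DataFrame,
                   windows: dict = None, spec: ModelSpec | None = None,
                   rank: bool = True) -> TargetedResult:
    """Noise-effect model restricted to a species' season and calling hours.

    Merges annotations with covariates, restricts to the species window,
    optionally reruns the shadow ranking with noise among the predictors, and
    labels the noise effect from a DTK comparison of the response between
    noise-absent (0) and noise-present (1) files.
    """
    windows = TARGETED_WINDOWS if windows is None else windows
    if species not in windows:
        raise KeyError(f"no targeted window registered for {species}")
    months, hours = windows[species]
    response = "dolphin_sum" if species == "dolphin" else species
    merged = annotations.merge(covariates, on="file_id", suffixes=("", "_cov"))
    mask = merged["month"].isin(months).to_numpy()
    mask &= _in_window(merged["local_hour"].to_numpy(), hours)
    sub = merged.loc[mask]
    if len(sub) < MIN_ROWS:
        raise InsufficientDataError(
            f"{species}: only {len(sub)} files in the targeted window")
    importance = None
    if rank:
        task = "regression" if species == "dolphin" else "classification"
        base = spec or ModelSpec(response, ("station", "water_temp_c",
                                            "lunar_phase", "tidal_phase",
                                            "diel", "noise"), task=task)
        base = replace(base, response=response)
        importance = shadow_rank(base, sub)
    posthoc = dtk_posthoc(sub[response].to_numpy(),
                          sub["noise"].to_numpy(), factor="noise")
    return TargetedResult(species, noise_direction(posthoc), posthoc,
                          importance, len(sub))


# ----------------------------------------------------------------------------
# Seasonal sound-producer contribution models
# ----------------------------------------------------------------------------

@dataclass
class ContributionResult:
    season: str
    diel: str
    band: str
    ranked: pd.DataFrame       # contributor, mean_z, decision (non-negative)
    removed: list[str]         # negative-relationship contributors
    score: float
    n_rows: int


def contribution_model(spl_table: pd.DataFrame, annotations: pd.DataFrame,
                       covariates: pd.DataFrame, season: str, diel: str,
                       band: str = "low",
                       contributors: tuple[str, ...] | None = None,
                       spec: ModelSpec | None = None) -> ContributionResult | None:
    """Rank sound producers' contribution to band SPL within one
    season x day/night stratum.

    Low-band models use every fish species' intensity, the dolphin
    vocalization count, and the noise flag as predictors; high-band models
    use dolphins and noise only.  Contributors whose DTK comparison of SPL
    between presence and absence is significantly negative are moved to the
    removed list (their presence lowered SPL, so they did not contribute);
    the rest are ranked by mean Z.  Returns None (logged) for strata below
    the minimum row count.
    """
    if contributors is None:
        from .scene_sim import FISH_SPECIES
        if band == "low":
            contributors = tuple(sp for sp in FISH_SPECIES
                                 if sp in annotations.columns) + (
                "dolphin_sum", "noise")
        else:
            contributors = ("dolphin_sum", "noise")
    spl_band = spl_table.loc[spl_table["band"] == band,
                             ["file_id", "spl_db"]]
    merged = (spl_band.merge(annotations, on="file_id")
              .merge(covariates, on="file_id", suffixes=("", "_cov")))
    sub = merged.loc[(merged["season"] == season) & (merged["diel"] == diel)]
    if len(sub) < MIN_ROWS:
        log.info("stratum %s/%s skipped: %d rows", season, diel, len(sub))
        return None
    base = spec or ModelSpec("spl_db", contributors, task="regression")
    base = replace(base, response="spl_db", predictors=contributors)
    importance = shadow_rank(base, sub)

    removed = []
    for c in contributors:
        present = (sub[c].to_numpy() >= 1).astype(int)
        if present.sum() < 2 or (1 - present).sum() < 2:
            continue
        ph = dtk_posthoc(sub["spl_db"].to_numpy(), present, factor=c)
        # group 1 = contributor present; negative relationship when SPL is
        # significantly lower with the contributor present.
        if ph.significant_pair(0, 1) and ph.means[1] < ph.means[0]:
            removed.append(c)
    ranked = importance.table.loc[
        ~importance.table["predictor"].isin(removed)].rename(
        columns={"predictor": "contributor"}).reset_index(drop=True)
    return ContributionResult(season, diel, band, ranked, removed,
                              importance.score, len(sub))
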