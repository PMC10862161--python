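"""Statistical models and permutation-based inference.

The analysis fits (i) ordinary least squares of each whole-network metric
(density, modularity, CV of edge weights) on the daily midday THI, (ii) a
Gaussian random-intercept model of individual shade minutes on THI, and
(iii) quadratic random-intercept models of each node metric (degree with a
Poisson/log link, strength and betweenness Gaussian) on scaled shade use.

Because network metrics violate independence assumptions, p-values come
from permutations rather than asymptotics: whole-network effects are tested
against data-stream (pre-network) randomisations that swap individuals
between grouping events of the same day — conserving group sizes and each
individual's observation count — and node-level effects against node-label
randomisations that shuffle shade use across individuals within each day.
Two-sided p-values double the smaller tail count, capped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterator, Sequence

import numpy as np
import pandas as pd

from .mixedmodels import MixedFit, fit_lmm, fit_poisson_glmm
from .socialnet import (
    GbiMatrix,
    cv_edge_weights,
    density,
    modularity,
    node_metrics,
    sri_network,
)

__all__ = [
    "ModelFit",
    "PermutationResult",
    "scale_covariate",
    "fit_network_model",
    "fit_shade_thi_model",
    "fit_node_model",
    "pre_network_permute",
    "node_label_permute",
    "permutation_pvalue",
    "run_full_inference",
    "InferenceResults",
]

WHOLE_NETWORK_METRICS = ("density", "modularity", "cv_edge_weights")
NODE_METRICS = ("degree", "strength", "betweenness")


@dataclass
class ModelFit:
    """Coefficients of one fitted model in results-table layout."""

    family: str
    terms: list[str]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    statistics: np.ndarray            # t (Gaussian) or Z (Poisson)
    r_squared: float | None = None
    random_intercept_variance: float | None = None
    residual_variance: float | None = None
    singular: bool = False

    def coef(self, term: str) -> float:
        return float(self.coefficients[self.terms.index(term)])

    def se(self, term: str) -> float:
        return float(self.standard_errors[self.terms.index(term)])


@dataclass
class PermutationResult:
    """Observed statistic against its permutation null distribution."""

    observed: float
    null_sample: np.ndarray
    p_two_sided: float
    n_permutations: int
    scheme: str

    def __post_init__(self) -> None:
        if len(self.null_sample) != self.n_permutations:
            raise ValueError("null sample size mismatch")
        if not 0.0 <= self.p_two_sided <= 1.0:
            raise ValueError("p outside [0, 1]")


@dataclass
class ScaledCovariate:
    """z-scored covariate with its square, kept with the scaling constants."""

    raw: np.ndarray
    scaled: np.ndarray
    squared: np.ndarray
    mean: float
    sd: float


def scale_covariate(values) -> ScaledCovariate:
    """Centre and scale to unit SD over the analysis sample (R ``scale``)."""
    raw = np.asarray(values, float)
    mean = float(raw.mean())
    sd = float(raw.std(ddof=1))
    if sd == 0:
        raise ValueError("cannot scale a constant covariate")
    z = (raw - mean) / sd
    return ScaledCovariate(raw, z, z**2, mean, sd)


def _from_mixedfit(fit: MixedFit, terms: list[str]) -> ModelFit:
    return ModelFit(
        family=fit.family,
        terms=terms,
        coefficients=fit.params,
        standard_errors=fit.se,
        statistics=fit.tvalues,
        random_intercept_variance=fit.sigma_u**2,
        residual_variance=None if fit.sigma_e is None else fit.sigma_e**2,
        singular=fit.singular,
    )


def _ols_slope(y: np.ndarray, x: np.ndarray) -> float:
    """Closed-form simple-regression slope (the permutation-loop fast path;
    identical to the slope ``fit_network_model`` reports)."""
    xc = x - x.mean()
    return float(xc @ y / (xc @ xc))


def fit_network_model(metric_series, thi_series) -> ModelFit:
    """OLS of one whole-network metric on daily THI, with intercept."""
    y = np.asarray(metric_series, float)
    x = np.asarray(thi_series, float)
    if len(y) != len(x) or len(y) < 3:
        raise ValueError("need equal-length series of at least 3 days")
    if np.ptp(x) == 0:
        raise ValueError("THI series is constant; slope undefined")
    import statsmodels.api as sm

    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    return ModelFit(
        family="gaussian",
        terms=["intercept", "thi"],
        coefficients=np.asarray(res.params),
        standard_errors=np.asarray(res.bse),
        statistics=np.asarray(res.tvalues),
        r_squared=float(res.rsquared),
    )


def _marginal_r2(fit: MixedFit, X: np.ndarray) -> float:
    """Marginal (fixed-effects) R²: var(Xβ) over total model variance."""
    var_f = float(np.var(X @ fit.params))
    var_u = fit.sigma_u**2
    var_e = fit.sigma_e**2 if fit.sigma_e is not None else 0.0
    denom = var_f + var_u + var_e
    return var_f / denom if denom > 0 else 0.0


def fit_shade_thi_model(shade_minutes, thi, ids) -> ModelFit:
    """Gaussian LMM: shade minutes ~ THI + (1 | individual), REML."""
    y = np.asarray(shade_minutes, float)
    x = np.asarray(thi, float)
    X = np.column_stack([np.ones_like(x), x])
    fit = fit_lmm(y, X, ids, names=["intercept", "thi"])
    out = _from_mixedfit(fit, ["intercept", "thi"])
    out.r_squared = _marginal_r2(fit, X)
    return out


def fit_node_model(metric, shade: ScaledCovariate, ids,
                   family: str = "gaussian") -> ModelFit:
    """Quadratic shade-use model of one node metric with individual
    random intercepts: metric ~ shade + shade² + (1 | individual).

    ``family="poisson"`` (degree counts) uses a log link; strength and
    betweenness use the Gaussian family.
    """
    y = np.asarray(metric, float)
    X = np.column_stack([np.ones_like(shade.scaled), shade.scaled, shade.squared])
    names = ["intercept", "shade", "shade_sq"]
    if family == "poisson":
        fit = fit_poisson_glmm(y, X, ids, names=names)
    elif family == "gaussian":
        fit = fit_lmm(y, X, ids, names=names)
    else:
        raise ValueError(f"unknown family {family!r}")
    out = _from_mixedfit(fit, names)
    if family == "gaussian":
        out.r_squared = _marginal_r2(fit, X)
    return out


# ---------------------------------------------------------------------------
# permutation schemes
# ---------------------------------------------------------------------------


def _swap_once(matrix: np.ndarray, rng: np.random.Generator,
               max_tries: int = 200) -> bool:
    """One accepted GBI swap: exchange two individuals between two groups.

    Picks two rows and two individuals such that each occurs in exactly one
    of the rows, then swaps their memberships.  Conserves row sums and
    column sums by construction.  Returns False when no legal swap was
    found in ``max_tries`` attempts.
    """
    n_rows = matrix.shape[0]
    if n_rows < 2:
        return False
    for _ in range(max_tries):
        a, b = rng.choice(n_rows, size=2, replace=False)
        in_a = matrix[a].astype(bool) & ~matrix[b].astype(bool)
        in_b = matrix[b].astype(bool) & ~matrix[a].astype(bool)
        ia = np.flatnonzero(in_a)
        ib = np.flatnonzero(in_b)
        if ia.size == 0 or ib.size == 0:
            continue
        i = ia[rng.integers(ia.size)]
        j = ib[rng.integers(ib.size)]
        matrix[a, i], matrix[a, j] = 0, 1
        matrix[b, j], matrix[b, i] = 0, 1
        return True
    return False


def _instant_row_pairs(gbi: GbiMatrix) -> list[np.ndarray] | None:
    """Row indices grouped by instant, keeping instants with >= 2 groups."""
    groups: dict[int, list[int]] = {}
    for r, t in enumerate(gbi.instant_of_row):
        groups.setdefault(int(t), []).append(r)
    out = [np.asarray(rows) for rows in groups.values() if len(rows) >= 2]
    return out or None


def _swap_once_instant(matrix: np.ndarray, row_sets: list[np.ndarray],
                       rng: np.random.Generator) -> bool:
    """One swap between two groups of the same instant.

    Within an instant the groups partition the present individuals, so any
    member of one group is a legal exchange partner for any member of the
    other; the per-instant partition structure is conserved exactly.
    """
    rows = row_sets[rng.integers(len(row_sets))]
    a, b = rng.choice(rows, size=2, replace=False)
    ia = np.flatnonzero(matrix[a])
    ib = np.flatnonzero(matrix[b])
    i = ia[rng.integers(ia.size)]
    j = ib[rng.integers(ib.size)]
    matrix[a, i], matrix[a, j] = 0, 1
    matrix[b, j], matrix[b, i] = 0, 1
    return True


def _instant_permutation_plan(gbi: GbiMatrix):
    """Precompute, per distinct instant, its row block and present columns."""
    inst = gbi.instant_of_row
    order = np.argsort(inst, kind="stable")
    uniq, starts = np.unique(inst[order], return_index=True)
    blocks = []
    for k, t in enumerate(uniq):
        rows = order[starts[k]: starts[k + 1] if k + 1 < len(uniq) else None]
        cols = np.flatnonzero(gbi.matrix[rows].any(axis=0))
        blocks.append((rows, cols))
    return blocks


def _reassign_instants(
    gbi: GbiMatrix, rng: np.random.Generator, plan=None
) -> np.ndarray:
    """Exact uniform reassignment: per instant, permute the present
    individuals among that instant's groups (sizes conserved)."""
    m = gbi.matrix
    n_ind = m.shape[1]
    if plan is None:
        plan = _instant_permutation_plan(gbi)
    # per-row gather index: start from identity, randomise each instant's
    # present columns, then apply one vectorised gather per day
    col_index = np.tile(np.arange(n_ind), (m.shape[0], 1))
    for rows, cols in plan:
        if cols.size < 2:
            continue
        col_index[rows[0], cols] = cols[rng.permutation(cols.size)]
        col_index[rows[1:]] = col_index[rows[0]]
    return np.take_along_axis(m, col_index, axis=1)


def pre_network_permute(
    gbi_by_day: Sequence[GbiMatrix],
    n_perm: int = 1000,
    swaps_per_step: int = 10,
    seed: int | np.random.Generator = 0,
    burn_in: int = 1000,
    swap_scope: str = "instant",
    independent: bool | None = None,
) -> Iterator[list[GbiMatrix]]:
    """Stream of data-stream permutations of the daily GBI matrices.

    Every emission preserves each day's group sizes (row sums) and
    per-individual observation counts (column sums).  A day with nothing
    to randomise is emitted unchanged.

    ``swap_scope`` picks the exchange neighbourhood:

    * ``"instant"`` (default) — members are exchanged only between groups
      of the same grid instant, so each emission is a valid synchronous
      grouping (everyone in exactly one group per instant) and the null
      is the uniform reassignment given each instant's group sizes.
    * ``"day"`` — any two groups of the day may trade members, the
      neighbourhood of the classic GBI swap randomisation; emissions may
      then book an individual into two groups at one instant.

    ``independent`` (default: true for instant scope, unavailable for day
    scope) draws each permutation as an exact independent sample of the null — per instant, the present
    individuals are randomly permuted among the conserved group sizes —
    instead of walking a sequential swap chain.  With ``independent=False``
    a chain advances ``swaps_per_step`` accepted swaps between emissions
    after ``burn_in`` initial swaps, the cumulative idiom of classic GBI
    randomisation; successive emissions are then serially correlated.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if swap_scope not in ("instant", "day"):
        raise ValueError("swap_scope must be 'instant' or 'day'")
    if independent is None:
        independent = swap_scope == "instant"
    if independent and swap_scope != "instant":
        raise ValueError("independent sampling requires instant scope")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )

    def emit(mats: list[np.ndarray]) -> list[GbiMatrix]:
        return [
            GbiMatrix(
                ids=list(g.ids),
                matrix=m.copy(),
                instant_of_row=g.instant_of_row,
                present=g.present,
                validate=False,
            )
            for g, m in zip(gbi_by_day, mats)
        ]

    if independent:
        plans = [_instant_permutation_plan(g) for g in gbi_by_day]
        for _ in range(n_perm):
            yield emit(
                [
                    _reassign_instants(g, rng, plan)
                    for g, plan in zip(gbi_by_day, plans)
                ]
            )
        return

    states = [g.matrix.astype(np.uint8).copy() for g in gbi_by_day]
    if swap_scope == "instant":
        row_sets = [_instant_row_pairs(g) for g in gbi_by_day]
    else:
        row_sets = [None] * len(gbi_by_day)

    def advance(k: int, n_swaps: int) -> bool:
        m = states[k]
        if swap_scope == "instant":
            rs = row_sets[k]
            if rs is None:
                return False
            for _ in range(n_swaps):
                _swap_once_instant(m, rs, rng)
            return True
        for _ in range(n_swaps):
            if not _swap_once(m, rng):
                return False
        return True

    swappable = [advance(k, burn_in) for k in range(len(states))]

    for _ in range(n_perm):
        for k in range(len(states)):
            if swappable[k]:
                swappable[k] = advance(k, swaps_per_step)
        yield emit(states)


def node_label_permute(values, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Uniform random permutation of per-individual values for one day."""
    values = np.asarray(values)
    if len(values) < 2:
        raise ValueError("need at least 2 individuals to permute")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    return values[rng.permutation(len(values))]


def permutation_pvalue(observed: float, null_sample) -> float:
    """Two-sided permutation p: twice the smaller tail count over N.

    Ties with the observed value count as at least as extreme; the doubled
    tail is capped at 1.  (The literal doubled-count rule can return 0 when
    the observed statistic lies beyond every permuted one.)
    """
    null = np.asarray(null_sample, float)
    if null.size == 0:
        raise ValueError("empty null sample")
    ge = int(np.count_nonzero(null >= observed))
    le = int(np.count_nonzero(null <= observed))
    return min(1.0, 2.0 * min(ge, le) / null.size)


# ---------------------------------------------------------------------------
# full pipeline inference
# ---------------------------------------------------------------------------


@dataclass
class InferenceResults:
    """Observed fits, null distributions and permutation p-values."""

    whole_network_table: pd.DataFrame
    node_table: pd.DataFrame
    whole_network_fits: dict[str, ModelFit]
    node_fits: dict[str, ModelFit]
    permutations: dict[str, PermutationResult] = field(default_factory=dict)
    daily_metrics: pd.DataFrame | None = None


def _daily_whole_network(
    gbis: Sequence[GbiMatrix],
    metrics: Sequence[str] = WHOLE_NETWORK_METRICS,
) -> pd.DataFrame:
    rows = []
    for k, gbi in enumerate(gbis):
        net = sri_network(gbi)
        row = {"day_index": k}
        if "density" in metrics:
            row["density"] = density(net)
        if "cv_edge_weights" in metrics:
            try:
                row["cv_edge_weights"] = cv_edge_weights(net)
            except ValueError:
                row["cv_edge_weights"] = np.nan
        if "modularity" in metrics:
            try:
                row["modularity"] = modularity(net)
            except ValueError:
                row["modularity"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def _node_long_table(gbis: Sequence[GbiMatrix]) -> pd.DataFrame:
    frames = []
    for k, gbi in enumerate(gbis):
        nm = node_metrics(sri_network(gbi))
        nm.insert(0, "day_index", k)
        frames.append(nm)
    return pd.concat(frames, ignore_index=True)


def run_full_inference(
    gbis: Sequence[GbiMatrix],
    thi_by_day: Sequence[float],
    shade_by_day: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    swaps_per_step: int = 10,
    burn_in: int = 1000,
    swap_scope: str = "instant",
    perm_independent: bool | None = None,
    node_families: dict[str, str] | None = None,
    whole_network_metrics: Sequence[str] = WHOLE_NETWORK_METRICS,
    node_metric_list: Sequence[str] = NODE_METRICS,
    progress: Callable[[str], None] | None = None,
) -> InferenceResults:
    """Fit all observed models and their permutation nulls.

    Parameters
    ----------
    gbis
        One GBI per daily midday window, in day order.
    thi_by_day
        Mean midday THI per day, aligned with ``gbis``.
    shade_by_day
        Long table with columns id, day (or day_index) and minutes.
    n_perm, seed, swaps_per_step, burn_in
        Permutation settings; both schemes derive their streams from
        ``seed``.

    Whole-network metrics are regressed on THI and tested against the
    pre-network swap null; node metrics are regressed on scaled shade use
    (quadratic) and tested against within-day node-label shuffles, re-fitting
    the full mixed model for every shuffle.
    """
    thi = np.asarray(thi_by_day, float)
    if len(gbis) != len(thi):
        raise ValueError("gbis and thi_by_day must align")
    note = progress or (lambda s: None)
    rng = np.random.default_rng(seed)
    if node_families is None:
        node_families = {
            "degree": "poisson",
            "strength": "gaussian",
            "betweenness": "gaussian",
        }

    wn_metrics = tuple(whole_network_metrics)
    node_list = tuple(node_metric_list)

    # ---- observed whole-network fits -------------------------------------
    note("whole-network metrics")
    daily = _daily_whole_network(gbis, wn_metrics)
    wn_fits: dict[str, ModelFit] = {}
    for metric in wn_metrics:
        y = daily[metric].to_numpy()
        ok = np.isfinite(y)
        wn_fits[metric] = fit_network_model(y[ok], thi[ok])

    # ---- pre-network permutation nulls -----------------------------------
    null_coefs = {m: np.empty(n_perm) for m in wn_metrics}
    if wn_metrics:
        note(f"pre-network permutations (n={n_perm})")
        stream = pre_network_permute(
            gbis, n_perm=n_perm, swaps_per_step=swaps_per_step,
            seed=rng, burn_in=burn_in, swap_scope=swap_scope,
            independent=perm_independent,
        )
        for b, perm_gbis in enumerate(stream):
            pd_daily = _daily_whole_network(perm_gbis, wn_metrics)
            for metric in wn_metrics:
                y = pd_daily[metric].to_numpy()
                ok = np.isfinite(y)
                null_coefs[metric][b] = _ols_slope(y[ok], thi[ok])

    permutations: dict[str, PermutationResult] = {}
    wn_rows = []
    for metric in wn_metrics:
        fit = wn_fits[metric]
        obs = fit.coef("thi")
        p = permutation_pvalue(obs, null_coefs[metric])
        permutations[f"{metric}~thi"] = PermutationResult(
            obs, null_coefs[metric], p, n_perm, "pre_network"
        )
        wn_rows.append(
            {
                "dependent": metric,
                "term": "thi",
                "coefficient": obs,
                "se": fit.se("thi"),
                "t": fit.statistics[fit.terms.index("thi")],
                "r_squared": fit.r_squared,
                "p_rand": p,
            }
        )
    wn_table = pd.DataFrame(wn_rows)

    # ---- node-level models -----------------------------------------------
    if not node_list:
        return InferenceResults(
            whole_network_table=wn_table,
            node_table=pd.DataFrame(),
            whole_network_fits=wn_fits,
            node_fits={},
            permutations=permutations,
            daily_metrics=daily,
        )
    note("node-level metrics")
    node_long = _node_long_table(gbis)
    shade = shade_by_day.copy()
    if "day_index" not in shade.columns:
        day_order = {d: k for k, d in enumerate(sorted(shade["day"].unique()))}
        shade["day_index"] = shade["day"].map(day_order)
    merged = node_long.merge(shade[["id", "day_index", "minutes"]],
                             on=["id", "day_index"], how="inner")
    cov = scale_covariate(merged["minutes"].to_numpy())
    ids = merged["id"].to_numpy()

    node_fits: dict[str, ModelFit] = {}
    node_rows = []
    for metric in node_list:
        fam = node_families[metric]
        fit = fit_node_model(merged[metric].to_numpy(), cov, ids, family=fam)
        node_fits[metric] = fit

        note(f"node-label permutations for {metric} (n={n_perm})")
        null_lin = np.empty(n_perm)
        null_quad = np.empty(n_perm)
        day_groups = merged.groupby("day_index").indices
        minutes = merged["minutes"].to_numpy()
        for b in range(n_perm):
            shuffled = minutes.copy()
            for idx in day_groups.values():
                shuffled[idx] = shuffled[idx][rng.permutation(len(idx))]
            pcov = scale_covariate(shuffled)
            pfit = fit_node_model(merged[metric].to_numpy(), pcov, ids,
                                  family=fam)
            null_lin[b] = pfit.coef("shade")
            null_quad[b] = pfit.coef("shade_sq")

        for term, null in (("shade", null_lin), ("shade_sq", null_quad)):
            obs = fit.coef(term)
            p = permutation_pvalue(obs, null)
            permutations[f"{metric}~{term}"] = PermutationResult(
                obs, null, p, n_perm, "node_label"
            )
            node_rows.append(
                {
                    "dependent": metric,
                    "term": term,
                    "coefficient": obs,
                    "se": fit.se(term),
                    "stat": fit.statistics[fit.terms.index(term)],
                    "family": fam,
                    "p_rand": p,
                }
            )
    node_table = pd.DataFrame(node_rows)

    return InferenceResults(
        whole_network_table=wn_table,
        node_table=node_table,
        whole_network_fits=wn_fits,
        node_fits=node_fits,
        permutations=permutations,
        daily_metrics=daily,
    )
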