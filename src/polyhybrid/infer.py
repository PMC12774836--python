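"""Estimation toolkit for hybrid fitness data.

Covers the analysis chain used on the selfing-series and multi-line-panel
designs: Box–Cox trait transformation (skew-minimising or cross-ploidy
SMA-r2-maximising), nonlinear least-squares fits of the geometric
heterozygosity-decay model with a ploidy scan, the balanced/unbalanced
heterozygote-class regression with a delta-method ratio CI, standardized
major axis regression, normalized heterosis contrasts with line/pair
jackknives, and a small nested-model AIC selection for two-ploidy cross
means.

Fitting routines are scikit-learn style estimators (``fit`` populates
trailing-underscore attributes; ``get_params``/``set_params`` inherited
from :class:`sklearn.base.BaseEstimator`); module-level functions are
thin wrappers.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator

from . import io as phio
from .theory import beta_retention, tetraploid_class_probs

__all__ = [
    "TransformSpec",
    "boxcox",
    "shift_positive",
    "choose_lambda_skewmin",
    "choose_lambda_sma",
    "SelfingDecayModel",
    "fit_selfing_decay",
    "PloidyScan",
    "ploidy_scan",
    "HeterozygoteClassModel",
    "fit_het_classes",
    "SMARegression",
    "sma_fit",
    "sma_impute",
    "heterosis_table",
    "JackknifeResult",
    "jackknife",
    "RyeModelSelection",
    "select_rye_model",
]

_GRID = (-2.0, 2.0, 0.01)


def boxcox(values, lam: float) -> np.ndarray:
    """Box–Cox transform (x^lam - 1)/lam, natural log at lam = 0."""
    values = np.asarray(values, dtype=float)
    if np.any(values <= 0):
        raise ValueError(
            "Box-Cox requires strictly positive values; apply shift_positive first"
        )
    return special.boxcox(values, lam)


def shift_positive(values, eps_frac: float = 0.01) -> float:
    """Additive shift making data strictly positive (0 if already positive).

    Shifted minimum lands at eps = eps_frac * range (a small floor when
    the data are constant).
    """
    values = np.asarray(values, dtype=float)
    vmin, vmax = values.min(), values.max()
    if vmin > 0:
        return 0.0
    rng = vmax - vmin
    eps = eps_frac * rng if rng > 0 else 1e-6
    return float(eps - vmin)


@dataclass(frozen=True)
class TransformSpec:
    """A chosen Box–Cox transform: exponent, shift and selection criterion."""

    lam: float
    objective: str  # "skew-min" or "sma-r2-max"
    shift: float = 0.0
    grid: tuple = _GRID
    score: float = float("nan")

    def transform(self, values) -> np.ndarray:
        return boxcox(np.asarray(values, dtype=float) + self.shift, self.lam)


def _lambda_grid(grid):
    lo, hi, step = grid
    n = int(round((hi - lo) / step))
    return np.round(np.linspace(lo, hi, n + 1), 10)


def _pick_tied(lams, scores, minimise):
    scores = np.asarray(scores, dtype=float)
    best = scores.min() if minimise else scores.max()
    tied = np.abs(scores - best) <= 1e-12
    cand = lams[tied]
    lam = cand[np.argmin(np.abs(cand - 1.0))]  # ties broken toward lam = 1
    return float(lam), float(best)


def _safe_skew(x) -> float:
    x = np.asarray(x, dtype=float)
    if x.size < 3 or np.ptp(x) == 0:
        return 0.0  # sample skewness undefined or trivially zero
    s = stats.skew(x, bias=False)
    return float(s) if np.isfinite(s) else 0.0


def choose_lambda_skewmin(groups, grid=_GRID, eps_frac=50.0) -> TransformSpec:
    """Exponent minimising aggregate squared sample skewness around means.

    Each element of ``groups`` is either one value set, or a list of
    cells (value sets) that share a skewness pool: every cell is
    transformed and centred on its own mean, the centred values are
    pooled within the group, and the objective is the sum over groups of
    the squared adjusted Fisher–Pearson skewness of the pool.  Pooling
    centred cells (e.g. all replicate cells of one generation) gives the
    skewness a real sample size and lets it notice transforms that are
    nearly singular inside the data range, which a per-cell skewness —
    being scale invariant — cannot see.  Minimised on a grid,
    deterministic given the grid; ties broken toward lam = 1.

    ``eps_frac`` sets where the additive shift anchors non-positive
    data: the shifted minimum lands at ``eps_frac`` times the data
    range.  Strictly positive data are never shifted.  The zero of a
    signed deviation scale is not a feature of the data, so the default
    anchors such data many ranges away from the transform family's
    singularity, where every exponent on the grid acts near-affinely:
    the chosen exponent then corrects genuine asymmetry without being
    able to bend the response wildly when the skewness signal is weak
    (as it is for replicate means, which are near-Gaussian by
    averaging).  Pass a small ``eps_frac`` to anchor close to zero and
    give the transform full leverage.
    """

    def as_cells(g):
        if isinstance(g, (list, tuple)):
            return [np.asarray(c, dtype=float) for c in g]
        return [np.asarray(g, dtype=float)]

    groups = [as_cells(g) for g in groups]
    if not groups or any(c.size < 2 for g in groups for c in g):
        raise ValueError("each cell needs at least 2 values")
    shift = shift_positive(
        np.concatenate([c for g in groups for c in g]), eps_frac=eps_frac
    )
    lams = _lambda_grid(grid)
    scores = []
    for lam in lams:
        total = 0.0
        for g in groups:
            cells = [boxcox(c + shift, lam) for c in g]
            pooled = np.concatenate([c - c.mean() for c in cells])
            total += _safe_skew(pooled) ** 2
        scores.append(total)
    lam, score = _pick_tied(lams, scores, minimise=True)
    return TransformSpec(lam=lam, objective="skew-min", shift=shift, grid=grid, score=score)


def choose_lambda_sma(dip_means, tet_means, grid=_GRID) -> TransformSpec:
    """Exponent maximising the SMA r2 between jointly transformed pairs.

    Both axes share one exponent and one shift; pairs with a missing
    value are excluded.  Used on the fixed genotypes (parents and F1) of
    a two-ploidy panel to put both ploidies on a common fitness scale.
    """
    x = np.asarray(dip_means, dtype=float)
    y = np.asarray(tet_means, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError(f"need at least 3 complete pairs, got {x.size}")
    shift = shift_positive(np.concatenate([x, y]))
    lams = _lambda_grid(grid)
    scores = []
    for lam in lams:
        tx, ty = boxcox(x + shift, lam), boxcox(y + shift, lam)
        if np.ptp(tx) == 0 or np.ptp(ty) == 0:
            scores.append(-np.inf)
            continue
        scores.append(float(np.corrcoef(tx, ty)[0, 1] ** 2))
    lam, score = _pick_tied(lams, scores, minimise=False)
    return TransformSpec(lam=lam, objective="sma-r2-max", shift=shift, grid=grid, score=score)


# ---------------------------------------------------------------------------
# Selfing-decay fit and ploidy scan


def _require_columns(data: pd.DataFrame, cols):
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"data is missing column(s) {missing}")


class SelfingDecayModel(BaseEstimator):
    """Least-squares fit of the geometric heterozygosity-decay model.

    Model: ``E(y_t) = b_c + (beta^t - 1) m_c`` with one shared retention
    rate ``beta`` per fit, a cross-specific amplitude ``m_c = M_c / 4``
    and a cross-specific nuisance baseline ``b_c`` (the baseline absorbs
    affine changes of the response scale, so ``beta`` is invariant to
    them; disable with ``include_baseline=False``).  Errors are i.i.d.
    Gaussian; confidence intervals come from the asymptotic covariance at
    the optimum (Gauss–Newton Jacobian).

    Parameters
    ----------
    ploidy : int, optional
        Informational ploidy tag; when ``fix_beta="ploidy"`` the rate is
        fixed at its theoretical value ``beta(ploidy)``.
    fix_beta : float or "ploidy", optional
        Fix the retention rate instead of estimating it.
    include_baseline : bool
        Fit the per-cross baseline term (default True).

    Attributes
    ----------
    beta_, beta_se_, beta_ci_ : point estimate, standard error, 95% CI
    amplitudes_, baselines_ : pd.Series indexed by cross
    rss_, sigma2_, loglik_, n_obs_, dof_ : fit summaries
    """

    def __init__(self, ploidy=None, fix_beta=None, include_baseline=True):
        self.ploidy = ploidy
        self.fix_beta = fix_beta
        self.include_baseline = include_baseline

    def _resolve_fixed(self):
        if self.fix_beta is None:
            return None
        if isinstance(self.fix_beta, str) and self.fix_beta == "ploidy":
            if self.ploidy is None:
                raise ValueError('fix_beta="ploidy" requires the ploidy parameter')
            return float(beta_retention(self.ploidy))
        return float(self.fix_beta)

    def fit(self, data: pd.DataFrame):
        _require_columns(data, ("generation", "value"))
        t = data["generation"].to_numpy(dtype=float)
        y = data["value"].to_numpy(dtype=float)
        crosses = (
            data["cross"].astype(str).to_numpy()
            if "cross" in data.columns
            else np.full(len(data), "pooled")
        )
        if np.unique(t).size < 2:
            raise ValueError("need at least 2 distinct generations to fit the decay")
        labels = sorted(set(crosses))
        groups = {c: np.flatnonzero(crosses == c) for c in labels}

        def linear_fit(beta):
            """Profile out baselines/amplitudes at fixed beta."""
            rss = 0.0
            coef = {}
            for c, idx in groups.items():
                x = beta ** t[idx] - 1.0
                X = (
                    np.column_stack([np.ones_like(x), x])
                    if self.include_baseline
                    else x[:, None]
                )
                b, *_ = np.linalg.lstsq(X, y[idx], rcond=None)
                r = y[idx] - X @ b
                rss += float(r @ r)
                coef[c] = b
            return rss, coef

        fixed = self._resolve_fixed()
        if fixed is not None:
            beta = fixed
            self.converged_ = True
        else:
            res = optimize.minimize_scalar(
                lambda b: linear_fit(b)[0],
                bounds=(1e-6, 1.0 - 1e-6),
                method="bounded",
                options={"xatol": 1e-12},
            )
            if not res.success:
                raise RuntimeError(
                    f"decay fit did not converge: {res.message}; "
                    f"profile RSS at bounds: {linear_fit(1e-6)[0]:.4g} / "
                    f"{linear_fit(1 - 1e-6)[0]:.4g}"
                )
            beta = float(res.x)
            self.converged_ = bool(res.success)

        rss, coef = linear_fit(beta)
        n = len(y)
        n_linear = (2 if self.include_baseline else 1) * len(labels)
        p = n_linear + (0 if fixed is not None else 1)

        # Gauss-Newton Jacobian of the residuals at the optimum.
        cols = []
        if fixed is None:
            dbeta = np.zeros(n)
            for c, idx in groups.items():
                m = coef[c][-1]
                ti = t[idx]
                dbeta[idx] = -m * np.where(ti > 0, ti * beta ** np.clip(ti - 1, 0, None), 0.0)
            cols.append(dbeta)
        for c, idx in groups.items():
            if self.include_baseline:
                col = np.zeros(n)
                col[idx] = -1.0
                cols.append(col)
            col = np.zeros(n)
            col[idx] = -(beta ** t[idx] - 1.0)
            cols.append(col)
        J = np.column_stack(cols)
        dof = n - p
        sigma2 = rss / dof if dof > 0 else float("nan")
        try:
            cov = sigma2 * np.linalg.inv(J.T @ J)
        except np.linalg.LinAlgError:
            cov = np.full((p, p), np.nan)

        self.beta_ = beta
        if fixed is None:
            self.beta_se_ = float(np.sqrt(max(cov[0, 0], 0.0)))
            self.beta_ci_ = (beta - 1.96 * self.beta_se_, beta + 1.96 * self.beta_se_)
        else:
            self.beta_se_ = 0.0
            self.beta_ci_ = (beta, beta)
        self.amplitudes_ = pd.Series({c: coef[c][-1] for c in labels}, name="amplitude")
        # amplitude is M_c / 4 on the response scale
        self.masking_ = 4.0 * self.amplitudes_.rename("masking")
        self.baselines_ = pd.Series(
            {c: (coef[c][0] if self.include_baseline else 0.0) for c in labels},
            name="baseline",
        )
        self.rss_ = rss
        self.sigma2_ = sigma2
        self.loglik_ = -0.5 * n * np.log(max(rss, 1e-300) / n)
        self.n_obs_ = n
        self.dof_ = dof
        self.cov_ = cov
        return self

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        _require_columns(data, ("generation",))
        t = data["generation"].to_numpy(dtype=float)
        crosses = (
            data["cross"].astype(str).to_numpy()
            if "cross" in data.columns
            else np.full(len(data), "pooled")
        )
        m = self.amplitudes_
        b = self.baselines_
        return np.array(
            [b[c] + m[c] * (self.beta_ ** ti - 1.0) for c, ti in zip(crosses, t)]
        )


def fit_selfing_decay(data, ploidy=None, fix_beta=None, include_baseline=True):
    """Fit the selfing decay model; returns the fitted estimator."""
    return SelfingDecayModel(
        ploidy=ploidy, fix_beta=fix_beta, include_baseline=include_baseline
    ).fit(data)


@dataclass(frozen=True)
class PloidyScan:
    """Profile log-likelihood per candidate ploidy and the winner."""

    table: pd.DataFrame  # columns: ploidy, beta, loglik
    best_ploidy: int


def ploidy_scan(data, ploidies=(2, 4, 6), include_baseline=True) -> PloidyScan:
    """Gaussian profile likelihood of the decay model with beta fixed at
    its theoretical value for each candidate ploidy.

    Log-likelihoods are ``-(n/2) log(RSS/n)`` with constants dropped;
    only differences are meaningful.
    """
    rows = []
    for K in ploidies:
        beta = float(beta_retention(K))
        m = SelfingDecayModel(
            ploidy=K, fix_beta=beta, include_baseline=include_baseline
        ).fit(data)
        rows.append({"ploidy": K, "beta": beta, "loglik": m.loglik_})
    table = pd.DataFrame(rows)
    best = int(table.loc[table["loglik"].idxmax(), "ploidy"])
    return PloidyScan(table=table, best_ploidy=best)


# ---------------------------------------------------------------------------
# Balanced vs unbalanced heterozygote classes (tetraploid)


class HeterozygoteClassModel(BaseEstimator):
    """Linear fit of the tetraploid heterozygote-class decay model.

    Model: ``E(y_t) = b_c + b22 (Pr_t(AABB) - 1) + b13 Pr_t(AAAB u ABBB)``
    with the class probabilities at their theoretical values and a
    per-cross baseline.  ``b22``/``b13`` absorb the (assumed shared)
    masking coefficient, so only their ratio is interpretable; the model
    predicts ``b13/b22 = (3/16)/(4/16) = 3/4``.  The ratio CI uses the
    first-order delta method on the coefficient covariance.
    """

    def __init__(self, include_baseline=True):
        self.include_baseline = include_baseline

    def fit(self, data: pd.DataFrame):
        _require_columns(data, ("generation", "value"))
        t = data["generation"].to_numpy(dtype=int)
        y = data["value"].to_numpy(dtype=float)
        crosses = (
            data["cross"].astype(str).to_numpy()
            if "cross" in data.columns
            else np.full(len(data), "pooled")
        )
        probs = {ti: tetraploid_class_probs(int(ti)) for ti in np.unique(t)}
        x1 = np.array([float(probs[ti].pr_balanced) - 1.0 for ti in t])
        x2 = np.array([float(probs[ti].pr_unbalanced) for ti in t])
        if np.linalg.matrix_rank(np.column_stack([x1, x2])) < 2:
            raise ValueError(
                "balanced and unbalanced class probabilities are collinear over "
                f"the available generations {sorted(probs)}; cannot separate the "
                "two class weights"
            )
        labels = sorted(set(crosses))
        cols = []
        if self.include_baseline:
            for c in labels:
                cols.append((crosses == c).astype(float))
        cols += [x1, x2]
        X = np.column_stack(cols)
        b, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ b
        n, p = X.shape
        rss = float(r @ r)
        dof = n - p
        sigma2 = rss / dof if dof > 0 else float("nan")
        cov = sigma2 * np.linalg.pinv(X.T @ X)

        self.b22_, self.b13_ = float(b[-2]), float(b[-1])
        self.baselines_ = pd.Series(
            {c: float(v) for c, v in zip(labels, b)} if self.include_baseline else {},
            dtype=float,
        )
        self.cov_ = cov[-2:, -2:]
        self.rss_, self.sigma2_, self.n_obs_, self.dof_ = rss, sigma2, n, dof
        self.ratio_defined_ = abs(self.b22_) > 1e-10 * max(1.0, abs(self.b13_))
        if self.ratio_defined_:
            self.ratio_ = self.b13_ / self.b22_
            g = np.array([-self.b13_ / self.b22_**2, 1.0 / self.b22_])
            var = float(g @ self.cov_ @ g)
            self.ratio_se_ = float(np.sqrt(max(var, 0.0)))
            self.ratio_ci_ = (
                self.ratio_ - 1.96 * self.ratio_se_,
                self.ratio_ + 1.96 * self.ratio_se_,
            )
        else:
            self.ratio_ = float("nan")
            self.ratio_se_ = float("nan")
            self.ratio_ci_ = (float("nan"), float("nan"))
        return self


def fit_het_classes(data, include_baseline=True):
    """Fit the heterozygote-class model; returns the fitted estimator."""
    return HeterozygoteClassModel(include_baseline=include_baseline).fit(data)


# ---------------------------------------------------------------------------
# Standardized major axis regression


class SMARegression(BaseEstimator):
    """Standardized major axis (reduced major axis) line.

    ``|slope| = SD(y)/SD(x)`` with the sign of the correlation (positive
    when the correlation is exactly zero); the line passes through the
    centroid.  Symmetric in x and y: swapping them inverts the slope and
    preserves r2.
    """

    def fit(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if x.size < 3:
            raise ValueError(f"need at least 3 points, got {x.size}")
        sx, sy = x.std(ddof=1), y.std(ddof=1)
        if sx == 0 or sy == 0:
            raise ValueError("zero variance in x or y")
        r = float(np.corrcoef(x, y)[0, 1])
        sign = np.sign(r) if r != 0 else 1.0
        self.slope_ = float(sign * sy / sx)
        self.intercept_ = float(y.mean() - self.slope_ * x.mean())
        self.r2_ = r**2
        self.n_ = int(x.size)
        return self

    def predict(self, x) -> np.ndarray:
        return self.intercept_ + self.slope_ * np.asarray(x, dtype=float)


def sma_fit(x, y) -> SMARegression:
    return SMARegression().fit(x, y)


def sma_impute(fit: SMARegression, x_new):
    """Impute y for new x points from the fitted SMA line."""
    return fit.predict(x_new)


# ---------------------------------------------------------------------------
# Heterosis contrasts, jackknife, model selection on cross means


def _classify(df: pd.DataFrame) -> pd.DataFrame:
    """Attach parsed kind/P/lines columns (cached per unique cross)."""
    parsed = {s: phio.parse_cross(s) for s in df["cross"].astype(str).unique()}
    out = df.copy()
    out["_kind"] = [parsed[s].kind for s in df["cross"].astype(str)]
    out["_P"] = [parsed[s].n_parents for s in df["cross"].astype(str)]
    out["_lines"] = [frozenset(parsed[s].lines) for s in df["cross"].astype(str)]
    return out


def _group_means(df: pd.DataFrame) -> dict:
    """Cohort means keyed by (ploidy, group) with F2 split by P."""
    cl = df if "_kind" in df.columns else _classify(df)
    means = {}
    for (K, kind, P), sub in cl.groupby(["ploidy", "_kind", "_P"]):
        group = {
            "parent": "Par",
            "F1": "F1",
            "F2-self": f"F2[{P}]",
            "F2-cross": f"F2[{P}]",
        }[kind]
        key = (int(K), group)
        means.setdefault(key, []).append(sub["value"])
    return {k: float(pd.concat(v).mean()) for k, v in means.items()}


_CONTRASTS = [  # (name, minuend group, subtrahend group, model prediction)
    ("F1-Par", "F1", "Par", 1.0),
    ("F2[2]-F1", "F2[2]", "F1", None),
    ("F2[3]-F2[2]", "F2[3]", "F2[2]", 0.25),
    ("F2[4]-F2[3]", "F2[4]", "F2[3]", 0.25),
]


def heterosis_table(df: pd.DataFrame) -> pd.DataFrame:
    """Normalized heterosis contrasts for a two-ploidy cross-mean panel.

    Each contrast is a difference of cohort means divided by the diploid
    parent-to-F1 difference; the ``predicted`` column carries the model's
    expectation where it is parameter-free (1 for F1 heterosis by
    construction of the normalizer, 1/4 for each added-parent increment
    at any ploidy).  Missing cohorts yield NaN values flagged in the
    ``missing`` column.
    """
    means = _group_means(df)
    try:
        denom = means[(2, "F1")] - means[(2, "Par")]
    except KeyError as exc:
        raise ValueError(f"missing diploid normalizer cohort: {exc}") from None
    if denom == 0:
        raise ValueError("diploid F1 - parent difference is zero; cannot normalize")
    rows = []
    for K in sorted({k for k, _ in means}):
        for name, a, b, pred in _CONTRASTS:
            have = (K, a) in means and (K, b) in means
            value = (means[(K, a)] - means[(K, b)]) / denom if have else float("nan")
            rows.append(
                {
                    "ploidy": K,
                    "contrast": name,
                    "value": value,
                    "predicted": pred,
                    "missing": not have,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class JackknifeResult:
    """Per-resample statistic values and their jackknife spread."""

    scheme: str
    values: pd.DataFrame  # index: resample label
    se: pd.Series  # jackknife standard error per statistic component
    failed: list = field(default_factory=list)  # (label, message)

    @property
    def spread(self) -> pd.Series:
        """Range (max - min) of the resample values per component."""
        return self.values.max() - self.values.min()


def jackknife(df: pd.DataFrame, statistic, scheme: str) -> JackknifeResult:
    """Delete-group jackknife over parental lines of a cross-mean table.

    ``scheme="leave-line"`` drops, in turn, every cross with ancestry
    from each line (one resample per line); ``scheme="leave-pair"`` drops
    crosses containing both lines of each unordered pair.  A resample on
    which the statistic fails is flagged, not silently dropped.
    """
    cl = _classify(df)
    lines = sorted(set().union(*cl["_lines"]))
    if scheme == "leave-line":
        resamples = [(l, frozenset([l])) for l in lines]
    elif scheme == "leave-pair":
        resamples = [
            (f"{a}{b}", frozenset([a, b])) for a, b in itertools.combinations(lines, 2)
        ]
    else:
        raise ValueError(f"unknown scheme {scheme!r}; use 'leave-line' or 'leave-pair'")
    values, failed = {}, []
    for label, drop in resamples:
        keep = [not drop <= s for s in cl["_lines"]]
        sub = cl.loc[keep]
        try:
            v = statistic(sub)
        except Exception as exc:  # noqa: BLE001 - flagged, not dropped
            failed.append((label, str(exc)))
            v = None
        if v is not None:
            values[label] = pd.Series(v) if not np.isscalar(v) else pd.Series({"stat": v})
    vdf = pd.DataFrame(values).T
    m = len(vdf)
    se = (
        np.sqrt((m - 1) / m * ((vdf - vdf.mean()) ** 2).sum())
        if m > 1
        else pd.Series(np.nan, index=vdf.columns)
    )
    return JackknifeResult(scheme=scheme, values=vdf, se=se, failed=failed)


@dataclass(frozen=True)
class RyeModelSelection:
    """AIC table over the nested two-ploidy mean models and the winner."""

    table: pd.DataFrame
    best: str
    coefficients: pd.Series  # of the preferred model
    n_obs: int
    all_coefficients: dict = field(default_factory=dict)  # model -> Series


def select_rye_model(df: pd.DataFrame) -> RyeModelSelection:
    """AIC comparison of nested landscape mean-models on cross means.

    The base model predicts each cross mean from per-line fitnesses plus
    shared masking and epistasis terms through the exact ancestry sums of
    its cross type.  Optional terms: a constant tetraploid offset
    (polyploidization cost), a constant offset for all F2 (maternal
    effect of the F1 seed parent), and a free tetraploid slope (separate
    masking/epistasis coefficients for tetraploids, relaxing the
    slope-one hypothesis that the genetic parameters are ploidy
    invariant).  All 8 combinations are fitted by equal-weight OLS on the
    cross means; AIC = n log(RSS/n) + 2(k+1).  Residual sums of squares
    are floored at the numerical precision of the response scale so that
    exactly-fitting nested models are compared by parsimony alone rather
    than by floating-point noise.
    """
    cl = _classify(df)
    lines = sorted(set().union(*cl["_lines"]))
    parsed = {s: phio.parse_cross(s) for s in cl["cross"].astype(str).unique()}
    H = np.stack([parsed[s].h_vector(lines) for s in cl["cross"].astype(str)])
    K = cl["ploidy"].to_numpy(dtype=int)
    kind = cl["_kind"].to_numpy()
    P = cl["_P"].to_numpy(dtype=int)
    s_prod = (1.0 - (H**2).sum(axis=1)) / 2.0
    s_pair = np.zeros(len(cl))
    f1 = kind == "F1"
    s_pair[f1] = 0.25
    f2 = np.isin(kind, ("F2-self", "F2-cross"))
    s_pair[f2] = P[f2] / 16.0 + (K[f2] - 2.0) / (8.0 * (K[f2] - 1.0))
    tet = (K > 2).astype(float)
    y = cl["value"].to_numpy(dtype=float)
    n = len(y)

    base_cols = [H[:, i] for i in range(len(lines))] + [s_pair, s_prod]
    base_names = [f"W[{l}]" for l in lines] + ["Mbar", "Ibar"]
    rss_floor = n * (1e-8 * max(1.0, float(np.std(y)))) ** 2
    rows, fits = [], {}
    for use_cost, use_mat, use_slope in itertools.product([False, True], repeat=3):
        cols, names = list(base_cols), list(base_names)
        terms = []
        if use_cost:
            cols.append(tet)
            names.append("ploidy_cost")
            terms.append("cost")
        if use_mat:
            cols.append(f2.astype(float))
            names.append("maternal")
            terms.append("maternal")
        if use_slope:
            cols += [tet * s_pair, tet * s_prod]
            names += ["Mbar_tet_extra", "Ibar_tet_extra"]
            terms.append("free-slope")
        name = "+".join(terms) if terms else "base"
        X = np.column_stack(cols)
        rank = np.linalg.matrix_rank(X)
        b, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((y - X @ b) ** 2))
        k = X.shape[1]
        aic = n * np.log(max(rss, rss_floor) / n) + 2 * (k + 1)
        rows.append(
            {
                "model": name,
                "k": k,
                "rss": rss,
                "aic": aic,
                "rank_deficient": rank < k,
            }
        )
        fits[name] = pd.Series(b, index=names)
    table = pd.DataFrame(rows).sort_values("aic", ignore_index=True)
    ok = table[~table["rank_deficient"]]
    if ok.empty:
        raise ValueError("all candidate models are rank deficient on these data")
    best = str(ok.iloc[0]["model"])
    table["delta_aic"] = table["aic"] - table["aic"].min()
    return RyeModelSelection(
        table=table,
        best=best,
        coefficients=fits[best],
        n_obs=n,
        all_coefficients=fits,
    )
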