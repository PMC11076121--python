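"""Mixed-model inference and the within-plot node-permutation null.

Four models relate per-chick responses to the density covariates:

1. **movement** — sqrt movement activity, Gaussian LMM;
2. **homerange** — sqrt 95% KUD area, Gaussian LMM;
3. **degree** — non-sibling degree centrality, Poisson GLMM (plot random
   intercept);
4. **strength** — log non-sibling association strength, Gaussian LMM (plot
   random intercept; zero-strength chicks are excluded and logged).

Fixed effects are sex, age-corrected body size, pre- and post-natal NN3
distance (tracked-neighbour variant in the network models) and fence
proximity; the movement/home-range models additionally carry the
pre x post interaction, dropped when non-significant.  Gaussian terms are
tested by 1-d.f. maximum-likelihood ratio chi-squares, Poisson terms by
Wald z.

Because network-derived responses violate independence, significance is
additionally assessed against a node-permutation null: the response vector
is shuffled among chicks *within each plot* (edges and covariates fixed),
the model refitted each round, and the observed coefficient compared with
the null coefficient distribution (two-tailed p with the +1 correction, and
the central-95%-interval exclusion flag).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from ._lmm import poisson_glmm_fit, ri_lmm_fit, ri_lmm_grid_fit, ri_lmm_lrt

logger = logging.getLogger("colonytrack")

TERM_COLUMNS = {
    "sex": "sex_male",
    "size": "body_size",
    "nn3_pre": "nn3_prenatal_m",
    "nn3_post": "nn3_postnatal_m",
    "nn3_post_tracked": "nn3_postnatal_tracked_m",
    "fence": "near_fence",
    "nn3_pre_x_post": "_interaction",
}


@dataclass(frozen=True)
class ModelSpec:
    """One of the four response models."""

    response: str  # movement | homerange | degree | strength
    family: str  # gaussian | poisson
    fixed_terms: tuple[str, ...]
    random: str  # "plot" | "nest_in_plot"

    def __post_init__(self):
        if self.family == "poisson" and self.response != "degree":
            raise ValueError("only the degree model is Poisson")
        if "nn3_pre_x_post" in self.fixed_terms and self.response in ("degree", "strength"):
            raise ValueError("the pre x post interaction belongs to the movement/home-range models")


STANDARD_MODELS: dict[str, ModelSpec] = {
    "movement": ModelSpec(
        "movement", "gaussian",
        ("sex", "size", "nn3_pre", "nn3_post", "fence", "nn3_pre_x_post"),
        "nest_in_plot",
    ),
    "homerange": ModelSpec(
        "homerange", "gaussian",
        ("sex", "size", "nn3_pre", "nn3_post", "fence", "nn3_pre_x_post"),
        "nest_in_plot",
    ),
    "degree": ModelSpec(
        "degree", "poisson",
        ("sex", "size", "nn3_pre", "nn3_post_tracked", "fence"),
        "plot",
    ),
    "strength": ModelSpec(
        "strength", "gaussian",
        ("sex", "size", "nn3_pre", "nn3_post_tracked", "fence"),
        "plot",
    ),
}

RESPONSE_COLUMNS = {
    "movement": "movement_activity",
    "homerange": "area_m2",
    "degree": "degree",
    "strength": "strength",
}


def body_size_index(chicks: pd.DataFrame) -> pd.Series:
    """Age-corrected body size: OLS residuals of tarsus length on age."""
    if len(chicks) < 3:
        raise ValueError("body size index needs >= 3 chicks")
    age = chicks["age_days"].to_numpy(dtype=float)
    if np.var(age) == 0:
        raise ValueError("zero age variance: cannot age-correct tarsus length")
    tarsus = chicks["tarsus_mm"].to_numpy(dtype=float)
    slope, intercept = np.polyfit(age, tarsus, 1)
    resid = tarsus - (intercept + slope * age)
    return pd.Series(resid, index=chicks.index, name="body_size")


def prepare_model_data(
    metrics: pd.DataFrame, chicks: pd.DataFrame, covariates: pd.DataFrame
) -> pd.DataFrame:
    """Merge chick attributes, density covariates and responses; add
    ``sex_male``, ``body_size`` and the centred NN3 interaction column."""
    data = chicks.merge(covariates, on="chick_id").merge(metrics, on="chick_id", how="left")
    data["sex_male"] = (data["sex"] == "M").astype(float)
    data["body_size"] = body_size_index(data).to_numpy()
    data["near_fence"] = data["near_fence"].astype(float)
    pre = data["nn3_prenatal_m"]
    post = data["nn3_postnatal_m"]
    data["_interaction"] = (pre - pre.mean()) * (post - post.mean())
    return data


def _design(data: pd.DataFrame, terms: tuple[str, ...]) -> tuple[np.ndarray, list[str]]:
    cols = [TERM_COLUMNS[t] for t in terms]
    X = np.column_stack([np.ones(len(data))] + [data[c].to_numpy(dtype=float) for c in cols])
    return X, ["intercept"] + list(terms)


def _response(data: pd.DataFrame, spec: ModelSpec) -> tuple[pd.DataFrame, np.ndarray]:
    col = RESPONSE_COLUMNS[spec.response]
    sub = data.dropna(subset=[col]).copy()
    y = sub[col].to_numpy(dtype=float)
    if spec.response in ("movement", "homerange"):
        y = np.sqrt(y)
    elif spec.response == "strength":
        pos = y > 0
        if (~pos).any():
            logger.info("strength model: excluding %d zero-strength chick(s)", int((~pos).sum()))
        sub, y = sub.loc[pos], np.log(y[pos])
    return sub, y


@dataclass
class ModelFit:
    """Coefficient table and variance components of one model fit."""

    spec: ModelSpec
    terms: pd.DataFrame  # index: term; columns coef, se, statistic, stat_kind, p
    variance_components: dict[str, float]
    n: int
    converged: bool

    def coef(self, term: str) -> float:
        return float(self.terms.loc[term, "coef"])

    def p(self, term: str) -> float:
        return float(self.terms.loc[term, "p"])


def fit_model(spec: ModelSpec, data: pd.DataFrame) -> ModelFit:
    """Fit one model; Gaussian by REML with ML likelihood-ratio term tests,
    Poisson by Gauss-Hermite ML with Wald z tests."""
    sub, y = _response(data, spec)
    X, names = _design(sub, spec.fixed_terms)
    plots = sub["plot_id"].to_numpy()
    if spec.family == "poisson":
        fit = poisson_glmm_fit(sub[RESPONSE_COLUMNS[spec.response]].to_numpy(dtype=float),
                               X, plots)
        table = pd.DataFrame(
            {
                "coef": fit.beta,
                "se": fit.se,
                "statistic": fit.zvalues,
                "stat_kind": "z",
                "p": fit.pvalues,
            },
            index=names,
        )
        return ModelFit(spec, table.drop(index="intercept"),
                        {"plot_sd": fit.tau}, len(sub), fit.converged)
    if spec.random == "nest_in_plot":
        return _fit_gaussian_nested(spec, sub, y, X, names)
    fit = ri_lmm_fit(y, X, plots, reml=True)
    rows = []
    for j, name in enumerate(names):
        if name == "intercept":
            continue
        chi2, p = ri_lmm_lrt(y, X, plots, term=j)
        rows.append({"term": name, "coef": fit.beta[j], "se": fit.se[j],
                     "statistic": chi2, "stat_kind": "chi2", "p": p})
    table = pd.DataFrame(rows).set_index("term")
    return ModelFit(spec, table,
                    {"plot_var": fit.sigma2_group, "resid_var": fit.sigma2_resid},
                    len(sub), True)


def _fit_gaussian_nested(spec, sub, y, X, names) -> ModelFit:
    """Gaussian LMM with nest nested in plot via statsmodels MixedLM."""
    from statsmodels.regression.mixed_linear_model import MixedLM, VCSpec

    sub = sub.reset_index(drop=True)
    nest = pd.get_dummies(sub["nest_foster"]).to_numpy(dtype=float)
    plots = sub["plot_id"].to_numpy()
    labels = sorted(pd.unique(plots))
    mats, colnames = [], []
    for lbl in labels:
        rows = plots == lbl
        cols = nest.any(axis=0) & nest[rows].any(axis=0)
        mats.append(nest[np.ix_(rows, np.flatnonzero(cols))])
        colnames.append([f"n{k}" for k in np.flatnonzero(cols)])
    vcspec = VCSpec(["nest"], [colnames], [mats])

    def mixed_fit(Xd, reml):
        import warnings

        md = MixedLM(y, Xd, groups=plots, exog_re=np.ones((len(y), 1)), exog_vc=vcspec)
        with np.errstate(all="ignore"), warnings.catch_warnings():
            # variance components at the boundary (plot variance ~ 0) are
            # expected and handled; silence the repeated notices
            warnings.simplefilter("ignore")
            return md.fit(reml=reml, method="lbfgs", maxiter=400, disp=False)

    full_reml = mixed_fit(X, reml=True)
    full_ml = mixed_fit(X, reml=False)
    rows = []
    converged = bool(full_reml.converged) and bool(full_ml.converged)
    for j, name in enumerate(names):
        if name == "intercept":
            continue
        red = mixed_fit(np.delete(X, j, axis=1), reml=False)
        converged &= bool(red.converged)
        chi2 = max(0.0, 2.0 * (full_ml.llf - red.llf))
        rows.append({
            "term": name,
            "coef": float(full_reml.fe_params[j]),
            "se": float(np.asarray(full_reml.bse_fe)[j]),
            "statistic": chi2,
            "stat_kind": "chi2",
            "p": float(stats.chi2.sf(chi2, df=1)),
        })
    table = pd.DataFrame(rows).set_index("term")
    vc = {"plot_var": float(np.asarray(full_reml.cov_re)[0, 0]),
          "nest_var": float(full_reml.vcomp[0]) if len(full_reml.vcomp) else 0.0,
          "resid_var": float(full_reml.scale)}
    return ModelFit(spec, table, vc, len(sub), converged)


def drop_nonsig_interaction(spec: ModelSpec, data: pd.DataFrame, alpha: float = 0.05):
    """Fit the full model; refit without the NN3 interaction if p >= alpha.

    Returns ``(spec_used, fit)``.
    """
    if "nn3_pre_x_post" not in spec.fixed_terms:
        raise ValueError("spec does not contain the interaction term")
    full = fit_model(spec, data)
    if full.p("nn3_pre_x_post") < alpha:
        return spec, full
    reduced = replace(
        spec, fixed_terms=tuple(t for t in spec.fixed_terms if t != "nn3_pre_x_post")
    )
    return reduced, fit_model(reduced, data)


@dataclass
class PermutationResult:
    """Observed coefficient versus its within-plot node-permutation null."""

    term: str
    observed_coef: float
    null_coefs: np.ndarray
    p_two: float
    outside_central_95: bool
    n_perm: int
    seed: object


def _within_plot_permutations(plots: np.ndarray, n_perm: int, rng) -> np.ndarray:
    """(n_perm, n) row-index matrix; each row permutes indices within plots."""
    n = len(plots)
    idx = np.tile(np.arange(n), (n_perm, 1))
    for lbl in pd.unique(plots):
        rows = np.flatnonzero(plots == lbl)
        if len(rows) < 2:
            logger.info("permutation: plot %s has a single chick (no freedom)", lbl)
            continue
        for b in range(n_perm):
            idx[b, rows] = rows[rng.permutation(len(rows))]
    return idx


def node_permutation_test(
    spec: ModelSpec,
    data: pd.DataFrame,
    n_perm: int = 10000,
    seed: int | np.random.Generator | None = None,
    terms: tuple[str, ...] | None = None,
) -> dict[str, PermutationResult]:
    """Within-plot node-label permutation null for every model term.

    The response vector is permuted among chicks within each plot (the
    network, hence the derived response values, stays fixed — shuffling node
    labels), the model is refitted, and each term's coefficient recorded.
    Gaussian models are refitted with the fast plot-random-intercept REML;
    the Poisson degree model is refitted by Gauss-Hermite ML per round.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sub, y = _response(data, spec)
    X, names = _design(sub, spec.fixed_terms)
    plots = sub["plot_id"].to_numpy()
    terms = terms or tuple(t for t in names if t != "intercept")
    perm_idx = _within_plot_permutations(plots, n_perm, rng)
    if spec.family == "gaussian":
        Y = np.column_stack([y] + [y[perm_idx[b]] for b in range(n_perm)])
        betas = ri_lmm_grid_fit(Y, X, plots, reml=True)
        obs_beta = betas[:, 0]
        null_beta = betas[:, 1:]
    else:
        y_raw = sub[RESPONSE_COLUMNS[spec.response]].to_numpy(dtype=float)
        obs_beta = poisson_glmm_fit(y_raw, X, plots).beta
        null_beta = np.empty((X.shape[1], n_perm))
        for b in range(n_perm):
            null_beta[:, b] = poisson_glmm_fit(y_raw[perm_idx[b]], X, plots).beta
    out = {}
    for term in terms:
        j = names.index(term)
        obs = float(obs_beta[j])
        null = null_beta[j]
        p_two = (1.0 + np.sum(np.abs(null) >= abs(obs))) / (n_perm + 1.0)
        lo, hi = np.percentile(null, [2.5, 97.5])
        out[term] = PermutationResult(
            term=term, observed_coef=obs, null_coefs=null,
            p_two=float(p_two), outside_central_95=bool(obs < lo or obs > hi),
            n_perm=n_perm, seed=seed,
        )
    return out


@dataclass
class SiblingCorrelation:
    r: float
    p: float
    r_symmetric: float
    n_pairs: int


def sibling_correlation(metric: pd.Series, chicks: pd.DataFrame) -> SiblingCorrelation:
    """Pearson correlation of a per-chick metric across sibling pairs.

    *metric* is indexed by chick id.  Pairs are sibling groups with exactly
    two tracked chicks; within-pair order is by chick id (and the
    order-symmetrised correlation over both orderings is also reported).
    """
    pairs = []
    for _, grp in chicks.groupby("sibling_group"):
        ids = sorted(grp["chick_id"])
        if len(ids) == 2 and all(i in metric.index for i in ids):
            a, b = metric[ids[0]], metric[ids[1]]
            if np.isfinite(a) and np.isfinite(b):
                pairs.append((a, b))
    if len(pairs) < 3:
        raise ValueError(f"sibling correlation needs >= 3 complete pairs, got {len(pairs)}")
    arr = np.array(pairs)
    r, p = stats.pearsonr(arr[:, 0], arr[:, 1])
    r_sym, _ = stats.pearsonr(
        np.concatenate([arr[:, 0], arr[:, 1]]), np.concatenate([arr[:, 1], arr[:, 0]])
    )
    return SiblingCorrelation(float(r), float(p), float(r_sym), len(pairs))


def compare_density_classes(
    nn3_per_nest: pd.Series, density_class: pd.Series, plot: pd.Series
) -> tuple[float, float]:
    """Likelihood-ratio chi-square (1 d.f.) for an HD/LD difference in NN3,
    from mixed models with a plot random intercept."""
    classes = pd.unique(density_class)
    if len(classes) < 2:
        raise ValueError("both density classes must be present")
    y = nn3_per_nest.to_numpy(dtype=float)
    x = (density_class == classes[0]).to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(y)), x])
    groups = plot.to_numpy()
    if pd.Series(groups).groupby(pd.Series(density_class.to_numpy())).nunique().min() < 2:
        logger.warning("compare_density_classes: a class has a single plot; "
                       "random effect is weakly identified")
    full = ri_lmm_fit(y, X, groups, reml=False)
    null = ri_lmm_fit(y, X[:, :1], groups, reml=False)
    chi2 = max(0.0, 2.0 * (full.loglike - null.loglike))
    return float(chi2), float(stats.chi2.sf(chi2, df=1))
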